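Program,xPONENT
Build,3.1.871.0
Date,09/09/2014
SN,SYNTH0001
Session,synthetic_session_01
Operator,synthetic
Batch,synthetic_batch
Version,1
DataType:,Median
Location,Sample,IL6,TNFa,Total Events
"1(1,A1)",Standard1,5120.5,8413.2,120
"2(1,B1)",Standard2,2710.4,4515.8,118
"3(1,C1)",Standard3,1422.9,2369.5,125
"4(1,D1)",Standard4,748.3,1244.0,117
"5(1,E1)",Standard5,390.1,652.7,121
"6(1,F1)",Standard6,205.6,342.4,119
"7(1,G1)",Standard7,109.2,180.9,122
"8(1,H1)",Standard8,58.8,96.5,116
"9(1,A2)",Background0,14.1,19.6,124
"10(1,B2)",Background0,13.2,21.3,120
"11(1,C2)",Control1,950.0,1580.2,118
"12(1,D2)",S1,430.7,712.4,119
"13(1,E2)",S2,86.5,140.8,123
"14(1,F2)",S3,1205.3,2011.6,121
"15(1,G2)",S4,19.8,28.3,117
DataType:,Count
Location,Sample,IL6,TNFa,Total Events
"1(1,A1)",Standard1,120,118,120
"2(1,B1)",Standard2,118,117,118
"3(1,C1)",Standard3,125,122,125
"4(1,D1)",Standard4,117,115,117
"5(1,E1)",Standard5,121,120,121
"6(1,F1)",Standard6,119,117,119
"7(1,G1)",Standard7,122,121,122
"8(1,H1)",Standard8,116,114,116
"9(1,A2)",Background0,124,122,124
"10(1,B2)",Background0,120,119,120
"11(1,C2)",Control1,118,116,118
"12(1,D2)",S1,119,117,119
"13(1,E2)",S2,123,121,123
"14(1,F2)",S3,121,119,121
"15(1,G2)",S4,117,115,117
DataType:,Net MFI
Location,Sample,IL6,TNFa,Total Events
"1(1,A1)",Standard1,5106.9,8392.8,120
"2(1,B1)",Standard2,2696.8,4495.4,118
"3(1,C1)",Standard3,1409.3,2349.1,125
"4(1,D1)",Standard4,734.7,1223.6,117
"5(1,E1)",Standard5,376.5,632.3,121
"6(1,F1)",Standard6,192.0,322.0,119
"7(1,G1)",Standard7,95.6,160.5,122
"8(1,H1)",Standard8,45.2,76.1,116
"9(1,A2)",Background0,0.5,0.2,124
"10(1,B2)",Background0,0.0,1.9,120
"11(1,C2)",Control1,936.4,1559.8,118
"12(1,D2)",S1,417.1,692.0,119
"13(1,E2)",S2,72.9,120.4,123
"14(1,F2)",S3,1191.7,1991.2,121
"15(1,G2)",S4,6.2,7.9,117
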