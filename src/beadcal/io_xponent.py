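"""Reading and writing raw xPONENT 3.1 exports.

The instrument software writes two kinds of CSV export:

fluorescence type
    One sectioned file per run: free-form ``key,value`` metadata lines,
    then a series of named blocks each introduced by a line whose first
    cell is ``DataType:`` (e.g. ``Median``, ``Count``, ``Net MFI``),
    each block being an ordinary CSV table with a header row.  Block
    names are not enumerated anywhere, so unknown blocks are kept
    generically.

bead type
    One CSV per analyte with bead-level events; on import all files are
    merged into a single table tagged with the source analyte/file.

``data_selection`` then partitions the wells of a tidy long table into
standards / blanks / controls / tests by sample-name patterns and joins
the standards to their expected concentrations from a dilution map
(top concentration + serial factor, or an explicit per-sample table):
the raw export never carries expected concentrations reliably, so they
are always supplied by the user.
"""

from __future__ import annotations

import csv
import io
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BLOCK_TOKEN = "DataType:"

#: default sample-role patterns (overridable)
DEFAULT_ROLES = {
    "standard": r"^Standard\d+",
    "blank": r"^Background",
    "control": r"^Control",
}

WELL_RE = re.compile(r"([A-Ha-h])\s*0*(\d{1,2})\s*\)?\s*$")


class XponentParseError(ValueError):
    pass


@dataclass
class XponentBundle:
    """Parsed raw export: metadata plus named blocks or merged bead rows."""

    kind: str                                   # "fluorescence" | "bead"
    metadata: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)  # name -> DataFrame
    bead_records: pd.DataFrame | None = None
    bad_lines: list = field(default_factory=list)   # (lineno, text)


def _sniff_delim(text: str) -> str:
    head = "\n".join(text.splitlines()[:40])
    return ";" if head.count(";") > head.count(",") else ","


def _split(line: str, delim: str) -> list:
    # quote-aware: Location cells like "1(1,A1)" embed the delimiter
    row = next(csv.reader([line], delimiter=delim, quotechar='"'), [])
    return [c.strip() for c in row]


def lum_import(path, kind: str = "fluorescence") -> XponentBundle:
    """Import a raw export.

    ``fluorescence``: one sectioned CSV file.  ``bead``: a file, a list
    of files, a directory of CSVs, or a zip archive; all bead tables are
    merged with ``analyte``/``source_file`` columns added.
    """
    if kind == "fluorescence":
        return _import_fluorescence(Path(path))
    if kind == "bead":
        return _import_bead(path)
    raise ValueError(f"unknown kind {kind!r}; use 'fluorescence' or 'bead'")


def _import_fluorescence(path: Path) -> XponentBundle:
    text = path.read_text(encoding="utf-8-sig")
    if not text.strip():
        raise XponentParseError(f"{path}: file is empty")
    delim = _sniff_delim(text)
    lines = text.splitlines()

    bundle = XponentBundle(kind="fluorescence")
    i, n = 0, len(lines)
    # header metadata until the first block marker
    while i < n and not lines[i].startswith(BLOCK_TOKEN):
        cells = _split(lines[i], delim)
        if cells and cells[0]:
            bundle.metadata[cells[0]] = delim.join(cells[1:]).strip(delim)
        i += 1
    if i == n:
        raise XponentParseError(
            f"{path}: no '{BLOCK_TOKEN}' block marker found (line 1 is the "
            "first offending line)")

    while i < n:
        cells = _split(lines[i], delim)
        name = cells[1] if len(cells) > 1 and cells[1] else "unnamed"
        i += 1
        block_lines = []
        while i < n and not lines[i].startswith(BLOCK_TOKEN):
            if lines[i].strip(delim + " \t"):
                block_lines.append((i + 1, lines[i]))
            i += 1
        if not block_lines:
            continue
        ncol = len(_split(block_lines[0][1], delim))
        rows, bad = [], []
        for lineno, raw in block_lines:
            cells_ = _split(raw, delim)
            if len(cells_) == ncol:
                rows.append(cells_)
            elif len(cells_) < ncol:
                rows.append(cells_ + [""] * (ncol - len(cells_)))
            else:
                bad.append((lineno, raw))
        bundle.bad_lines.extend(bad)
        if len(rows) == 1:
            # single line: scalar-style block (e.g. a lone value)
            bundle.blocks[name] = pd.DataFrame([rows[0]])
            continue
        df = pd.DataFrame(rows[1:], columns=rows[0])
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.notna().all():
                df[col] = converted
        bundle.blocks[name] = df
    if not bundle.blocks:
        raise XponentParseError(f"{path}: no data blocks parsed")
    return bundle


def _import_bead(path) -> XponentBundle:
    if isinstance(path, (str, Path)):
        p = Path(path)
        if p.is_dir():
            files = sorted(p.glob("*.csv"))
        elif p.suffix == ".zip":
            return _import_bead_zip(p)
        else:
            files = [p]
    else:
        files = [Path(f) for f in path]
    if not files:
        raise XponentParseError("no bead CSV files found")
    frames = []
    for f in files:
        if f.stat().st_size == 0:
            raise XponentParseError(f"{f}: file is empty")
        df = pd.read_csv(f)
        df["analyte"] = f.stem
        df["source_file"] = f.name
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    return XponentBundle(kind="bead", bead_records=merged,
                         metadata={"n_files": len(files)})


def _import_bead_zip(p: Path) -> XponentBundle:
    with zipfile.ZipFile(p) as zf:
        names = [n for n in zf.namelist() if n.endswith(".csv")]
        if not names:
            raise XponentParseError(f"{p}: archive holds no CSV")
        merged = pd.read_csv(io.BytesIO(zf.read(names[0])))
    return XponentBundle(kind="bead", bead_records=merged,
                         metadata={"archive": p.name})


# ---------------------------------------------------------------------------
# export

def lum_export(bundle: XponentBundle, outdir) -> list:
    """Write a bundle back to disk; returns the paths written.

    Fluorescence bundles produce one CSV per block plus a sectioned
    ``xponent.csv`` that re-imports to an equal bundle; bead bundles
    produce a single zip archive with the merged table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if bundle.kind == "fluorescence":
        for name, df in bundle.blocks.items():
            safe = re.sub(r"[^\w.-]+", "_", name)
            p = outdir / f"block_{safe}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        combined = outdir / "xponent.csv"
        with open(combined, "w", encoding="utf-8", newline="\n") as fh:
            for k, v in bundle.metadata.items():
                fh.write(f"{k},{v}\n")
            for name, df in bundle.blocks.items():
                fh.write(f"{BLOCK_TOKEN},{name}\n")
                fh.write(df.to_csv(index=False, lineterminator="\n"))
                fh.write("\n")
        written.append(combined)
    elif bundle.kind == "bead":
        p = outdir / "beads.zip"
        with zipfile.ZipFile(p, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("beads.csv",
                        bundle.bead_records.to_csv(index=False))
        written.append(p)
    else:
        raise ValueError(f"cannot export bundle of kind {bundle.kind!r}")
    return written


# ---------------------------------------------------------------------------
# selection

def normalize_well(label: str) -> str:
    """Normalize plate coordinates: '77(1,E10)' or 'e05' -> 'E10'/'E5'."""
    m = WELL_RE.search(str(label).strip())
    if not m:
        raise ValueError(f"cannot parse well coordinate from {label!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= 12:
        raise ValueError(f"well column out of 96-well range in {label!r}")
    return f"{row}{col}"


def bundle_to_long(bundle: XponentBundle, block: str = "Median",
                   plate_id: str = "plate_01",
                   location_col: str = "Location",
                   sample_col: str = "Sample",
                   drop_cols: tuple = ("Total Events",)) -> pd.DataFrame:
    """Melt one fluorescence block into tidy long format.

    Every column that is not the location, the sample id, or in
    ``drop_cols`` is treated as an analyte; MFI values are the cell
    contents.
    """
    if block not in bundle.blocks:
        raise KeyError(f"block {block!r} not in bundle "
                       f"(have {sorted(bundle.blocks)})")
    df = bundle.blocks[block].copy()
    analytes = [c for c in df.columns
                if c not in (location_col, sample_col) and c not in drop_cols]
    long = df.melt(id_vars=[location_col, sample_col], value_vars=analytes,
                   var_name="analyte", value_name="mfi")
    long["well"] = long[location_col].map(normalize_well)
    long["plate_id"] = plate_id
    long = long.rename(columns={sample_col: "sample"})
    long["mfi"] = pd.to_numeric(long["mfi"], errors="coerce")
    return long[["plate_id", "well", "analyte", "sample", "mfi"]]


def dilution_series(top_conc: float, factor: float, n: int,
                    names=None) -> pd.DataFrame:
    """Expected-concentration map for a serial dilution:
    top, top/factor, ..., top/factor**(n-1)."""
    if names is None:
        names = [f"Standard{i + 1}" for i in range(n)]
    conc = [top_conc / factor ** i for i in range(n)]
    return pd.DataFrame({"sample": names, "expected_conc": conc})


def data_selection(table, roles: dict | None = None,
                   dilution_map: pd.DataFrame | None = None) -> dict:
    """Partition a tidy long table into standards/blanks/controls/tests.

    ``roles`` maps role names to sample-name regexes (defaults match
    ``Standard<k>`` / ``Background...`` / ``Control...``); anything
    unmatched is a test well.  The partition is checked to be disjoint
    (colliding patterns raise) and exhaustive.  ``dilution_map`` (a
    ``sample -> expected_conc`` table, e.g. from
    :func:`dilution_series`) is joined onto the standards.
    """
    if isinstance(table, XponentBundle):
        table = bundle_to_long(table)
    roles = {**DEFAULT_ROLES, **(roles or {})}
    samples = table["sample"].astype(str)

    masks = {}
    for role, pattern in roles.items():
        masks[role] = samples.str.match(pattern)
    overlap = np.zeros(len(table), dtype=int)
    for m in masks.values():
        overlap += m.to_numpy(dtype=int)
    if np.any(overlap > 1):
        bad = sorted(samples[overlap > 1].unique())
        raise ValueError(f"role patterns collide on samples: {bad}")

    out = {}
    std = table[masks["standard"]].copy()
    if len(std) == 0:
        out["warning"] = "no samples matched the standard pattern"
    if dilution_map is not None and len(std):
        std = std.merge(dilution_map, on="sample", how="left")
    std["flagged"] = False
    blk = table[masks["blank"]].copy()
    blk["flagged"] = False
    ctl = table[masks["control"]].copy()
    tests = table[overlap == 0].copy()
    out.update({"standards": std, "blanks": blk, "controls": ctl,
                "tests": tests})
    return out
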