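"""Readers and writers for the tabular formats the pipeline touches.

Internal convention: all coordinates are 0-based, intervals half-open.
methratio-style TSVs are 1-based (the convention of BSMAP's methratio
output); BED files are 0-based half-open; genome-browser style region
strings like ``chr18:79,461,612-79,461,992`` are 1-based inclusive.
Conversions happen at the file boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

METHRATIO_COLUMNS = ["chrom", "pos", "strand", "context", "ratio", "c_count", "ct_count"]


@dataclass(frozen=True)
class ContrastDesign:
    """Assignment of samples to the two groups of a named comparison."""

    name: str
    groups: Mapping[str, str]  # sample_id -> "case" | "control"

    def __post_init__(self) -> None:
        vals = set(self.groups.values())
        if not vals <= {"case", "control"}:
            raise ValueError(f"group labels must be case/control, got {vals}")
        if "case" not in vals or "control" not in vals:
            raise ValueError("both groups must be non-empty")

    @property
    def case_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "control"]


def median_split(expression: Mapping[str, float], name: str = "median-split") -> ContrastDesign:
    """Split samples at the median of a per-sample expression value.

    Samples strictly above the median become the "case" (high) group; ties
    at the median go to "control" (low).  Used for the PD-L1-high vs -low
    contrast, where groups are defined by median PD-L1 expression.
    """
    if len(expression) < 2:
        raise ValueError("median split needs at least two samples")
    values = np.array(list(expression.values()), dtype=float)
    med = float(np.median(values))
    if np.all(values == values[0]):
        raise ValueError("all expression values identical: degenerate contrast")
    groups = {s: ("case" if v > med else "control") for s, v in expression.items()}
    return ContrastDesign(name=name, groups=groups)


def read_methratio(
    path,
    has_header: bool | None = None,
    collapse_dyads: bool = True,
    cpg_only: bool = True,
) -> pd.DataFrame:
    """Read a methratio-style TSV into an internal site table.

    File positions are 1-based and converted to 0-based.  Rows with zero
    total reads are dropped (undefined ratio); rows with c_count > ct_count
    are rejected with a warning; other malformed rows are counted and
    reported.  With ``collapse_dyads`` the two strands of a CpG dyad
    (position p on ``+``, p+1 on ``-``) are merged by summing counts —
    common practice before region-level segmentation.
    """
    try:
        first = open(path).readline()
    except FileNotFoundError:
        raise
    if not first.strip():
        warnings.warn(f"{path}: empty file")
        return pd.DataFrame(columns=METHRATIO_COLUMNS)
    if has_header is None:
        token = first.split("\t")[0].strip().lower()
        has_header = token in ("chr", "chrom", "chromosome")
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=METHRATIO_COLUMNS,
        dtype={0: str},
        comment="#",
    )
    df.columns = METHRATIO_COLUMNS
    n_raw = len(df)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("ratio", "c_count", "ct_count"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    malformed = df[["pos", "c_count", "ct_count"]].isna().any(axis=1)
    if malformed.any():
        warnings.warn(f"{path}: dropped {int(malformed.sum())} malformed rows")
        df = df[~malformed]
    bad = df["c_count"] > df["ct_count"]
    if bad.any():
        warnings.warn(f"{path}: rejected {int(bad.sum())} rows with c_count > ct_count")
        df = df[~bad]
    if cpg_only:
        df = df[df["context"].astype(str).str.upper().isin(["CG", "CPG"])]
    df = df[df["ct_count"] > 0].copy()
    df["pos"] = df["pos"].astype(np.int64) - 1  # file is 1-based
    df[["c_count", "ct_count"]] = df[["c_count", "ct_count"]].astype(np.int64)
    if collapse_dyads:
        df = collapse_cpg_dyads(df)
    df["ratio"] = df["c_count"] / df["ct_count"]
    if df.empty and n_raw == 0:
        warnings.warn(f"{path}: no usable rows")
    return df.reset_index(drop=True)


def collapse_cpg_dyads(df: pd.DataFrame) -> pd.DataFrame:
    """Merge +/- strand records of each CpG dyad by summing counts.

    A minus-strand record at position p is re-keyed to p-1 (the C of the
    plus strand); records sharing (chrom, pos) are then summed and reported
    on the plus strand.
    """
    df = df.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    agg = (
        df.groupby(["chrom", "pos"], sort=True, as_index=False)
        .agg(c_count=("c_count", "sum"), ct_count=("ct_count", "sum"))
    )
    agg["strand"] = "+"
    agg["context"] = "CG"
    agg["ratio"] = agg["c_count"] / agg["ct_count"]
    return agg[METHRATIO_COLUMNS]


def write_methratio(df: pd.DataFrame, path) -> None:
    """Write an internal site table as a 1-based methratio-style TSV."""
    out = df[METHRATIO_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out["ratio"] = out["ratio"].map(lambda r: f"{r:.6g}")
    out.to_csv(path, sep="\t", index=False)


DMR_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "mark", "n_cpgs", "mean_case", "mean_control", "mean_diff",
    "p", "q", "direction", "significant",
]


def write_dmr_bed(dmrs: Sequence, path) -> None:
    """Write DMRs as a sorted BED6+ file (0-based half-open).

    Extra columns carry the mark, CpG count, group means, difference,
    p/q values, direction and the significance flag.  Floats are written
    with ``repr`` so a read-back round-trips exactly.
    """
    ordered = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end, d.mark))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_BED_COLUMNS) + "\n")
        for i, d in enumerate(ordered):
            fh.write(
                "\t".join(
                    [
                        d.chrom, str(d.start), str(d.end), f"dmr_{i + 1:05d}",
                        "0", ".", d.mark, str(d.n_cpgs),
                        repr(float(d.mean_case)), repr(float(d.mean_control)),
                        repr(float(d.mean_diff)), repr(float(d.p)),
                        repr(float(d.q)), d.direction, str(int(d.significant)),
                    ]
                )
                + "\n"
            )


def read_dmr_bed(path) -> list:
    from .dmr_calling import DMR  # local import to avoid a cycle

    dmrs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            dmrs.append(
                DMR(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), mark=f[6],
                    n_cpgs=int(f[7]), mean_case=float(f[8]),
                    mean_control=float(f[9]), mean_diff=float(f[10]),
                    p=float(f[11]), q=float(f[12]),
                    significant=bool(int(f[14])),
                )
            )
    return dmrs


def parse_region_string(s: str) -> tuple[str, int, int]:
    """Parse a browser-style region like ``chr18:79,461,612-79,461,992``.

    Treated as 1-based inclusive (genome-browser convention) and returned
    0-based half-open.  Accepts hyphen or en-dash separators.
    """
    chrom, _, coords = s.partition(":")
    coords = coords.replace(",", "").replace("–", "-")
    lo, _, hi = coords.partition("-")
    start, end = int(lo) - 1, int(hi)
    if end <= start:
        raise ValueError(f"empty region {s!r}")
    return chrom, start, end


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV: sample_id, path_bs, path_ox plus group columns."""
    sheet = pd.read_csv(path)
    required = {"sample_id", "path_bs", "path_ox"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sheet


def write_region_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="region")


def read_region_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region")
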