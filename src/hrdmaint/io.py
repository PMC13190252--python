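"""Readers and writers for the delimited table formats and the SEG dialect.

All tables are UTF-8 text with a header row; the SEG dialect is
tab-delimited with columns ``sample chrom start end major_cn minor_cn`` and
1-based inclusive coordinates.  Readers validate rather than coerce: a
malformed row raises a parse error naming the offending line.  The missing
token is ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "SegParseError",
    "read_seg",
    "write_seg",
    "read_table",
    "write_table",
    "read_clinical",
    "read_survival",
    "read_config",
    "SEG_HEADER",
]

SEG_HEADER = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
NA_TOKEN = "NA"


class SegParseError(ValueError):
    """Raised with the 1-based line number of the offending SEG row."""


def read_seg(path: str | Path, known_chroms: set[str] | None = None) -> pd.DataFrame:
    """Read a SEG-dialect file, validating coordinates and per-chromosome
    non-overlap; raises :class:`SegParseError` naming the bad line."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise SegParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != SEG_HEADER:
        raise SegParseError(f"{path}:1: header must be {SEG_HEADER}, got {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(SEG_HEADER):
            raise SegParseError(f"{path}:{lineno}: expected {len(SEG_HEADER)} fields")
        sample, chrom = parts[0], parts[1]
        try:
            start, end, major, minor = (int(v) for v in parts[2:])
        except ValueError:
            raise SegParseError(f"{path}:{lineno}: non-integer coordinate or copy number")
        if start < 1 or end < 1:
            raise SegParseError(f"{path}:{lineno}: coordinates must be >= 1 (1-based)")
        if start > end:
            raise SegParseError(f"{path}:{lineno}: start > end")
        if minor > major or minor < 0:
            raise SegParseError(f"{path}:{lineno}: invalid copy numbers ({major}, {minor})")
        if known_chroms is not None and chrom not in known_chroms:
            raise SegParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        rows.append((sample, chrom, start, end, major, minor))
    df = pd.DataFrame(rows, columns=SEG_HEADER)
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise SegParseError(f"{path}: overlapping segments for {sample}/{chrom}")
    return df


def write_seg(table: pd.DataFrame, path: str | Path) -> None:
    """Write a SEG-dialect file (tab-delimited, header, stable column order)."""
    missing = [c for c in SEG_HEADER if c not in table.columns]
    if missing:
        raise ValueError(f"segment table missing columns {missing}")
    table[SEG_HEADER].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-delimited table with header and NA tokens."""
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a comma-delimited table with header; missing values as NA."""
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


_CLINICAL_REQUIRED = ["patient_id", "cohort", "measurable"]
_SURVIVAL_REQUIRED = ["patient_id", "pfs_months", "pfs_event", "os_months", "os_event"]


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    return df


def read_survival(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in _SURVIVAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: survival table missing columns {missing}")
    if (df["pfs_months"] < 0).any() or (df["os_months"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    return df


def read_config(path: str | Path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
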