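"""Readers and writers for the pipeline's interchange formats.

Formats handled here:

* PennCNV-style CNV call text (one call per line, 1-based inclusive);
* BED (0-based half-open on disk, converted to 1-based inclusive on read);
* GMT-like gene-set text (set name, description, member symbols);
* plain TSV tables and sample-by-probe matrices, optionally prefixed with
  ``# key: value`` audit-trail comment lines.

Everything in memory uses 1-based inclusive coordinates; conversions
happen only at the BED boundary.  Chromosome labels are normalized by
stripping any leading ``chr`` prefix ("X" stays literal).
"""
from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

CALL_COLUMNS = [
    "sample_id", "chrom", "start_bp", "end_bp",
    "copy_number", "n_snps", "confidence",
]

# PennCNV state label for each copy number as written by detect_cnv.pl
_STATE_FOR_CN = {0: 1, 1: 2, 2: 3, 3: 5, 4: 6}

_CALL_RE = re.compile(
    r"^(?:chr)?(?P<chrom>\S+?):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=\S+)?(?:\s+endsnp=\S+)?"
    r"(?:\s+conf=(?P<conf>[-+.\deE]+))?\s*$"
)


def normalize_chrom(label) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def read_penncnv_calls(path) -> pd.DataFrame:
    """Parse PennCNV-like call lines into a call table.

    Raises ``ValueError`` naming the offending line number on malformed
    input.  Missing ``conf=`` fields become NaN.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            m = _CALL_RE.match(line.strip())
            if m is None:
                raise ValueError(
                    f"{path}: unparseable CNV call at line {lineno}: {line.strip()!r}"
                )
            start, end = int(m["start"]), int(m["end"])
            if end < start:
                raise ValueError(
                    f"{path}: end < start at line {lineno}: {line.strip()!r}"
                )
            rows.append(
                (
                    m["sample"], normalize_chrom(m["chrom"]), start, end,
                    int(m["cn"]), int(m["numsnp"]),
                    float(m["conf"]) if m["conf"] is not None else float("nan"),
                )
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_penncnv_calls(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            cn = int(row.copy_number)
            state = _STATE_FOR_CN.get(cn, cn + 1)
            length = int(row.end_bp) - int(row.start_bp) + 1
            fh.write(
                f"chr{row.chrom}:{int(row.start_bp)}-{int(row.end_bp)}\t"
                f"numsnp={int(row.n_snps)}\tlength={length:,}\t"
                f"state{state},cn={cn}\t{row.sample_id}\t"
                f"conf={float(row.confidence):.3f}\n"
            )


def read_bed(path, payload_names=("name", "score")) -> pd.DataFrame:
    """Read BED3+ into a 1-based inclusive interval table.

    Disk ``(start, end)`` half-open becomes memory ``(start + 1, end)``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: short BED line {lineno}")
            chrom, start, end = normalize_chrom(parts[0]), int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"{path}: BED end <= start at line {lineno}: {line.strip()!r}"
                )
            rows.append([chrom, start + 1, end, *parts[3 : 3 + len(payload_names)]])
    ncol = max((len(r) for r in rows), default=3)
    cols = ["chrom", "start_bp", "end_bp"] + list(payload_names)[: ncol - 3]
    df = pd.DataFrame([r + [None] * (len(cols) - len(r)) for r in rows], columns=cols)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path, payload_cols=()) -> None:
    """Write a 1-based inclusive interval table as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            extra = "".join(f"\t{getattr(row, c)}" for c in payload_cols)
            fh.write(
                f"chr{row.chrom}\t{int(row.start_bp) - 1}\t{int(row.end_bp)}{extra}\n"
            )


def read_gmt(path) -> dict[str, list[str]]:
    """GMT-like gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, genes")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_table(df: pd.DataFrame, path, header_notes: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV, prefixed with ``# key: value`` audit comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header_notes or {}).items():
            fh.write(f"# {key}: {value}\n")
    df.to_csv(path, sep="\t", index=index, mode="a", float_format="%.6g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_matrix(df: pd.DataFrame, path, header_notes: dict | None = None) -> None:
    """Sample-by-probe matrix TSV with the sample id as the index column."""
    write_table(df.rename_axis("sample_id"), path, header_notes, index=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
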