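"""Tab-separated readers/writers and the GMT gene-set parser.

TSV is the canonical tabular dialect (UTF-8, '.' decimal separator) because
gene identifiers may contain commas.  Readers validate row-level invariants
and report violations with 1-based file line numbers (the header is line 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import GENOTYPES
from .simulate import COHORT_COLUMNS, DEG_COLUMNS

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_deg",
    "write_deg",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table (one subject per row)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["genotype"] not in GENOTYPES:
            problems.append(f"line {line}: unknown genotype {row['genotype']!r}")
            continue
        try:
            lt = float(row["lesion_time"])
            ft = float(row["followup_time"])
            le = int(row["lesion_event"])
            de = int(row["death_event"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric time or event flag")
            continue
        if lt <= 0 or ft <= 0:
            problems.append(f"line {line}: times must be positive")
        if le not in (0, 1) or de not in (0, 1):
            problems.append(f"line {line}: event flags must be 0/1")
        elif le == 1 and lt > ft:
            problems.append(
                f"line {line}: lesion_event=1 but lesion_time {lt} > followup_time {ft}"
            )
        elif le == 0 and lt != min(lt, ft):
            # a censored lesion time is the censoring time, never beyond follow-up
            if lt > ft:
                problems.append(
                    f"line {line}: censored lesion_time {lt} exceeds followup_time {ft}"
                )
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        problems.append(f"duplicate subject_id {dup!r}")
    if problems:
        raise ValueError(f"{path}: invalid cohort table:\n" + "\n".join(problems))
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, columns=list(COHORT_COLUMNS))


def read_deg(path) -> pd.DataFrame:
    """Read and validate a differential-expression result table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    for col in ("pvalue", "padj"):
        vals = df[col].to_numpy(dtype=float)
        bad = np.nonzero((vals < 0) | (vals > 1))[0]
        if bad.size:
            raise ValueError(f"{path}: line {bad[0] + 2}: {col} outside [0, 1]")
    return df


def write_deg(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=list(DEG_COLUMNS))


def read_counts(path) -> pd.DataFrame:
    """Gene-by-sample count matrix, genes in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: ``name TAB description TAB gene...`` per line.

    Duplicate genes within one set are deduplicated with a warning; an empty
    file yields an empty collection with a warning.
    """
    sets: dict[str, set[str]] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            unique = set(genes)
            if len(unique) < len(genes):
                warnings.warn(f"{path}: line {lineno}: duplicate genes in set {name!r}")
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = unique
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in gene_sets:
            genes = sorted(gene_sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")
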