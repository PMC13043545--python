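"""Spacer quantification: raw reads -> sgRNA count matrix.

Reads are matched against the library by exact 20-mer lookup: every 20-nt
window of a read is scanned left to right and the first window equal to a
library spacer increments that guide (a read counts at most once). Exact
matching keeps counts deterministic; scanning all offsets is robust to
stagger bases and unknown amplicon layout. Reverse-complement matching is
off by default and available by flag.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "read_library",
    "write_library",
    "extract_spacers",
    "coverage_summary",
    "cells_required",
    "read_counts",
    "write_counts",
]

_VALID_BASES = set("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class CountMatrix:
    """sgRNA x sample integer counts with sample condition labels.

    ``counts`` is indexed by sgRNA id with one integer column per sample;
    ``genes`` maps sgRNA id -> gene symbol; ``conditions`` maps sample ->
    {control, exposed}. ``unmatched``/``total_reads`` carry per-sample read
    accounting when the matrix came from FASTQ extraction.
    """

    counts: pd.DataFrame
    genes: pd.Series
    conditions: dict[str, str]
    unmatched: dict[str, int] = field(default_factory=dict)
    total_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.genes.index):
            self.genes = self.genes.reindex(self.counts.index)
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]


def read_library(path: str | Path) -> pd.DataFrame:
    """Load and validate a guide library TSV (sgrna, gene, sequence).

    Raises ``ValueError`` naming offending rows for missing columns,
    duplicate ids, duplicate spacers, or malformed spacers (wrong length /
    non-ACGT). Line numbers are 1-based file lines (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sgrna", "gene", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library {path}: missing columns {sorted(missing)}")
    df = df[["sgrna", "gene", "sequence"]]
    bad = [
        f"line {i + 2} ({row.sgrna}): bad spacer {row.sequence!r}"
        for i, row in enumerate(df.itertuples())
        if not isinstance(row.sequence, str)
        or len(row.sequence) != 20
        or not set(row.sequence) <= _VALID_BASES
    ]
    if bad:
        raise ValueError(f"library {path}: " + "; ".join(bad))
    dup_ids = df["sgrna"][df["sgrna"].duplicated(keep=False)]
    if len(dup_ids):
        raise ValueError(
            f"library {path}: duplicate sgRNA ids {sorted(dup_ids.unique())}"
        )
    dup_seq = df[df["sequence"].duplicated(keep=False)]
    if len(dup_seq):
        groups = dup_seq.groupby("sequence")["sgrna"].apply(list)
        detail = "; ".join(f"{seq}: {ids}" for seq, ids in groups.items())
        raise ValueError(f"library {path}: duplicate spacers shared by {detail}")
    return df.reset_index(drop=True)


def write_library(library: pd.DataFrame, path: str | Path) -> None:
    library[["sgrna", "gene", "sequence"]].to_csv(path, sep="\t", index=False)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def extract_spacers(
    library: pd.DataFrame,
    sample_fastqs: dict[str, str | Path],
    conditions: dict[str, str],
    revcomp: bool = False,
) -> CountMatrix:
    """Count exact spacer matches per sample from FASTQ files.

    ``sample_fastqs`` maps sample name -> FASTQ path (gzip by suffix).
    Each read is scanned over all 20-mer windows left to right; the first
    window found in the library increments that sgRNA. With ``revcomp``,
    a read with no forward match is rescanned as its reverse complement.
    """
    spacer_to_row = {seq: i for i, seq in enumerate(library["sequence"])}
    n_guides = len(library)
    samples = list(sample_fastqs)
    mat = np.zeros((n_guides, len(samples)), dtype=np.int64)
    unmatched: dict[str, int] = {}
    totals: dict[str, int] = {}
    for j, sample in enumerate(samples):
        path = sample_fastqs[sample]
        n_total = 0
        n_unmatched = 0
        try:
            with _open_text(path) as fh:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    n_total += 1
                    row = _first_match(seq.upper(), spacer_to_row)
                    if row is None and revcomp:
                        rc = seq.upper().translate(_COMP)[::-1]
                        row = _first_match(rc, spacer_to_row)
                    if row is None:
                        n_unmatched += 1
                    else:
                        mat[row, j] += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ {path} near record {n_total + 1}: {exc}"
            ) from exc
        unmatched[sample] = n_unmatched
        totals[sample] = n_total
        logger.info(
            "%s: %d reads, %d matched, %d unmatched",
            sample, n_total, n_total - n_unmatched, n_unmatched,
        )
    counts = pd.DataFrame(
        mat, index=pd.Index(library["sgrna"], name="sgrna"), columns=samples
    )
    genes = pd.Series(library["gene"].to_numpy(), index=counts.index, name="gene")
    return CountMatrix(
        counts=counts,
        genes=genes,
        conditions={s: conditions[s] for s in samples},
        unmatched=unmatched,
        total_reads=totals,
    )


def _first_match(seq: str, spacer_to_row: dict[str, int]) -> int | None:
    for i in range(len(seq) - 19):
        row = spacer_to_row.get(seq[i:i + 20])
        if row is not None:
            return row
    return None


def cells_required(library_size: int, representation: float) -> int:
    """Cells per replicate needed to maintain a given fold-representation
    of the library (e.g. 40,000 guides at 400X -> 16,000,000 cells)."""
    if library_size <= 0 or representation <= 0:
        raise ValueError("library_size and representation must be positive")
    return int(round(library_size * representation))


def coverage_summary(matrix: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-condition mean coverage (column total / library size).

    Returns ``(per_sample, per_condition)`` frames carrying both the
    unrounded coverage and the nearest-integer value used for reporting.
    """
    n_guides = len(matrix.counts)
    if n_guides == 0:
        raise ValueError("empty library")
    totals = matrix.counts.sum(axis=0)
    per_sample = pd.DataFrame(
        {
            "sample": totals.index,
            "condition": [matrix.conditions[s] for s in totals.index],
            "total_reads": totals.to_numpy(),
            "coverage": totals.to_numpy() / n_guides,
        }
    )
    per_sample["coverage_rounded"] = per_sample["coverage"].round().astype(int)
    rows = []
    for cond, grp in per_sample.groupby("condition", sort=False):
        cov = grp["total_reads"].mean() / n_guides
        rows.append((cond, grp["total_reads"].mean(), cov, int(round(cov))))
    per_condition = pd.DataFrame(
        rows, columns=["condition", "mean_total_reads", "coverage", "coverage_rounded"]
    )
    return per_sample, per_condition


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write the standard count TSV: header sgRNA / gene / <samples...>."""
    out = pd.DataFrame({"sgRNA": matrix.counts.index, "gene": matrix.genes.to_numpy()})
    for s in matrix.samples:
        out[s] = matrix.counts[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path, conditions: dict[str, str] | None = None
) -> CountMatrix:
    """Read a count TSV (sgRNA, gene, one column per sample).

    Cells must be non-negative integers; violations are reported with
    their sgRNA and sample. When ``conditions`` is omitted, labels are
    inferred from sample names containing ``control`` / ``exposed``.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sgrna" not in cols or "gene" not in cols:
        raise ValueError(f"count table {path}: needs sgRNA and gene columns")
    sg_col, gene_col = cols["sgrna"], cols["gene"]
    samples = [c for c in df.columns if c not in (sg_col, gene_col)]
    if not samples:
        raise ValueError(f"count table {path}: no sample columns")
    for s in samples:
        vals = pd.to_numeric(df[s], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"count table {path}: non-integer or negative cell at "
                f"sgRNA {df[sg_col].iloc[i]!r}, sample {s!r}: {df[s].iloc[i]!r}"
            )
        df[s] = vals.astype(np.int64)
    if conditions is None:
        conditions = {}
        for s in samples:
            low = s.lower()
            if "control" in low or low.startswith(("ctrl", "c_")):
                conditions[s] = "control"
            elif "exposed" in low or "treat" in low or low.startswith(("exp", "t_")):
                conditions[s] = "exposed"
            else:
                raise ValueError(
                    f"cannot infer condition for sample {s!r}; pass conditions"
                )
    counts = df.set_index(sg_col)[samples]
    counts.index.name = "sgrna"
    genes = pd.Series(df[gene_col].to_numpy(), index=counts.index, name="gene")
    return CountMatrix(counts=counts, genes=genes, conditions=conditions)
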