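"""Readers, writers and preprocessing filters for the pipeline's file formats.

Expression matrices and binary mutation matrices travel as TSV with one
header row of identifiers and one identifier column; somatic variant calls
may instead arrive as a MAF table that is binarized per (sample, gene);
pathway gene sets are standard GMT.  All tables are held in lightweight
dataclasses wrapping a numpy matrix plus ordered identifier lists, and every
reader validates identifiers and cell values with located error messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")
DEFAULT_EXCLUDED_CLASSES = frozenset({"Silent"})


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: Set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionTable:
    """Samples x genes matrix of nonnegative FPKM-like expression values."""

    sample_ids: List[str]
    gene_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionTable":
        """Restrict to ``genes`` (in the given order); missing genes are skipped
        with a logged warning."""
        present = [g for g in genes if g in set(self.gene_ids)]
        missing = [g for g in genes if g not in set(self.gene_ids)]
        if missing:
            logger.warning(
                "%d of %d requested genes absent from expression table: %s%s",
                len(missing),
                len(genes),
                ", ".join(missing[:5]),
                "..." if len(missing) > 5 else "",
            )
        if not present:
            raise ValueError("none of the requested genes are present")
        col = {g: k for k, g in enumerate(self.gene_ids)}
        idx = [col[g] for g in present]
        return ExpressionTable(list(self.sample_ids), present, self.values[:, idx])


@dataclass
class MutationTable:
    """Samples x genes binary somatic-mutation indicator matrix (1 = mutated)."""

    sample_ids: List[str]
    gene_ids: List[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        bad = ~np.isin(self.calls, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary mutation call {self.calls[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
        self.calls = self.calls.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.gene_ids)

    def gene_column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in mutation table") from None
        return self.calls[:, j].copy()


@dataclass
class GeneSet:
    """A named pathway gene set (one GMT line)."""

    name: str
    description: str
    genes: List[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, "gene-set member")


# ---------------------------------------------------------------------------
# readers


def _read_id_matrix(path: str | Path) -> pd.DataFrame:
    # pandas mangles duplicate header fields, so validate the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: Set[str] = set()
    for name in header:
        if name in seen:
            raise ValueError(f"{path}: duplicate column identifier {name!r}")
        seen.add(name)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column identifier {dup!r}")
    return df


def read_expression(
    path: str | Path, orientation: str = "samples_in_rows"
) -> ExpressionTable:
    """Read an expression TSV in either orientation into samples x genes form.

    Parameters
    ----------
    path:
        TSV with one header row and one leading identifier column.
    orientation:
        ``"samples_in_rows"`` (rows are samples) or ``"genes_in_rows"``
        (rows are genes; the table is transposed on read).
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_id_matrix(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric expression value {df.iat[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "genes_in_rows":
        numeric = numeric.T
    return ExpressionTable(
        list(numeric.index), list(numeric.columns), numeric.to_numpy(dtype=float)
    )


def read_mutation_matrix(path: str | Path) -> MutationTable:
    """Read a samples x genes 0/1 mutation TSV; any non-binary entry is rejected."""
    df = _read_id_matrix(path)
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isin(arr, (0, 1)) | np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary mutation entry {df.iat[i, j]!r} at sample "
            f"{df.index[i]!r}, gene {df.columns[j]!r}"
        )
    return MutationTable(list(df.index), list(df.columns), arr.astype(np.int8))


def write_mutation_matrix(table: MutationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    # %.17g keeps the write/read round trip bit-exact
    table.to_frame().to_csv(
        path, sep="\t", index_label="sample_id", float_format="%.17g"
    )


def binarize_maf(
    path: str | Path,
    excluded_classes: Set[str] | frozenset = DEFAULT_EXCLUDED_CLASSES,
) -> MutationTable:
    """Collapse a MAF variant table to a binary samples x genes matrix.

    Entry (s, g) is 1 iff at least one retained variant record exists for
    sample s and gene g.  Records whose Variant_Classification is in
    ``excluded_classes`` (by default only ``"Silent"``) are dropped first.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: MAF is missing required column {col!r}")
    kept = df[~df["Variant_Classification"].isin(excluded_classes)]
    samples = sorted(df["Tumor_Sample_Barcode"].unique())
    genes = sorted(df["Hugo_Symbol"].unique())
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(genes)}
    calls = np.zeros((len(samples), len(genes)), dtype=np.int8)
    for s, g in zip(kept["Tumor_Sample_Barcode"], kept["Hugo_Symbol"]):
        calls[srow[s], gcol[g]] = 1
    return MutationTable(samples, genes, calls)


def read_gmt(path: str | Path) -> List[GeneSet]:
    """Parse a GMT gene-set file (name, description, then member genes per line).

    Duplicate genes within a line are deduplicated with a logged warning.
    """
    sets: List[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains %d duplicated gene(s); deduplicated",
                    path,
                    lineno,
                    name,
                    len(genes) - len(deduped),
                )
            sets.append(GeneSet(name, desc, deduped))
    return sets


# ---------------------------------------------------------------------------
# preprocessing filters


def align_cohort(
    expr: ExpressionTable, mut: MutationTable
) -> Tuple[ExpressionTable, MutationTable]:
    """Restrict both tables to their common samples, lexicographically sorted.

    Only tumor samples profiled on both platforms enter the causal analysis,
    so both tables are cut down to the sample-id intersection and re-ordered
    identically.
    """
    common = sorted(set(expr.sample_ids) & set(mut.sample_ids))
    if not common:
        raise ValueError("expression and mutation tables share no samples")
    erow = {s: i for i, s in enumerate(expr.sample_ids)}
    mrow = {s: i for i, s in enumerate(mut.sample_ids)}
    eidx = [erow[s] for s in common]
    midx = [mrow[s] for s in common]
    return (
        ExpressionTable(common, list(expr.gene_ids), expr.values[eidx]),
        MutationTable(common, list(mut.gene_ids), mut.calls[midx]),
    )


def filter_expressed_genes(
    expr: ExpressionTable, threshold: float = 10.0, rule: str = "mean_below"
) -> ExpressionTable:
    """Drop non-expressed genes from an expression table.

    ``mean_below`` (default) removes a gene when its cohort mean is below
    ``threshold``; ``all_below`` removes it only when every sample is below.
    The default threshold of 10 FPKM-like units reflects the preprocessing
    this pipeline targets.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if rule == "mean_below":
        keep = expr.values.mean(axis=0) >= threshold
    elif rule == "all_below":
        keep = (expr.values >= threshold).any(axis=0)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not keep.any():
        raise ValueError(
            f"every gene falls below threshold {threshold}; lower the threshold"
        )
    kept_genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionTable(list(expr.sample_ids), kept_genes, expr.values[:, keep])
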