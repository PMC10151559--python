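"""Readers, writers and validated containers for the pipeline's input tables.

Expression, clinical and covariate tables are plain delimited text (``.tsv``
tab-separated, ``.csv`` comma-separated, auto-detected from the extension and
overridable).  Gene sets use the GMT convention (name, description, then one
gene per tab-separated field).  Mutations arrive as a MAF-style tab-delimited
table with at least ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
``Variant_Classification`` columns.

All analyses downstream run on the intersection of sample IDs across the
supplied tables; :func:`align_samples` performs that intersection and logs
what was dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mmpscore")

#: Variant classes excluded from burden/mutation calls by default
#: (conventional non-synonymous filter).
DEFAULT_EXCLUDED_CLASSES = frozenset(
    ["Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"]
)

#: Survival endpoints recognised in clinical tables.
ENDPOINTS = ("OS", "PFS", "DSS", "DFS")

#: Ordinal clinicopathological covariates recognised in clinical tables.
STAGE_COVARIATES = ("T", "N", "M", "G", "TNM")


class DataError(ValueError):
    """Raised when an input file fails validation."""


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    ``values`` is a DataFrame indexed by gene ID with sample IDs as columns.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene IDs: {dupes[:5]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dupes[:5]}")
        if v.shape[0] < 2 or v.shape[1] < 3:
            raise DataError(
                f"expression matrix needs >=2 genes and >=3 samples, got {v.shape}"
            )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite expression value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in matrix order); missing genes logged."""
        genes = set(genes)
        present = [g for g in self.values.index if g in genes]
        missing = genes - set(present)
        if missing:
            logger.info("subset_genes: %d gene(s) absent from matrix: %s",
                        len(missing), sorted(missing)[:10])
        if len(present) < 2:
            raise DataError("fewer than 2 requested genes present in matrix")
        return ExpressionMatrix(self.values.loc[present])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)])


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene IDs (GMT line)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.genes | other.genes)


def union_gene_sets(sets: Sequence[GeneSet], name: str = "union") -> GeneSet:
    """Union several gene sets into one (e.g. the two MMP pathway sets)."""
    genes: frozenset[str] = frozenset()
    for s in sets:
        genes |= s.genes
    return GeneSet(name, genes)


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and ordinal stage covariates.

    ``data`` is indexed by sample ID.  Endpoint columns come in
    ``<EP>_time`` / ``<EP>_event`` pairs for any subset of OS/PFS/DSS/DFS;
    times are months.  Optional ordinal covariates: T, N, M, G, TNM.
    Missing values are permitted per-endpoint; :meth:`endpoint` drops them.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise DataError("duplicate sample IDs in clinical table")
        if not self.endpoints:
            raise DataError("clinical table has no <EP>_time/<EP>_event pairs")
        for ep in self.endpoints:
            t = pd.to_numeric(d[f"{ep}_time"], errors="coerce")
            e = pd.to_numeric(d[f"{ep}_event"], errors="coerce")
            if (t.dropna() < 0).any():
                raise DataError(f"negative {ep}_time")
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise DataError(
                    f"{ep}_event values outside {{0,1}}: {bad.unique().tolist()[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def endpoints(self) -> list[str]:
        return [
            ep for ep in ENDPOINTS
            if f"{ep}_time" in self.data.columns and f"{ep}_event" in self.data.columns
        ]

    @property
    def stage_covariates(self) -> list[str]:
        return [c for c in STAGE_COVARIATES if c in self.data.columns]

    def endpoint(self, ep: str) -> pd.DataFrame:
        """Return a two-column (time, event) frame for endpoint ``ep``.

        Samples missing either the time or the event flag for this endpoint
        are excluded from it (but remain available for other endpoints).
        """
        if ep not in self.endpoints:
            raise DataError(f"endpoint {ep!r} not present (have {self.endpoints})")
        t = pd.to_numeric(self.data[f"{ep}_time"], errors="coerce")
        e = pd.to_numeric(self.data[f"{ep}_event"], errors="coerce")
        out = pd.DataFrame({"time": t, "event": e}).dropna()
        out["event"] = out["event"].astype(int)
        n_drop = len(self.data) - len(out)
        if n_drop:
            logger.info("endpoint %s: %d sample(s) with missing data excluded", ep, n_drop)
        return out

    def subset_samples(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)])


@dataclass
class MutationMatrix:
    """Binary gene x sample mutation calls plus per-sample variant burden.

    ``values[g, s] = 1`` iff sample *s* carries at least one qualifying
    variant in gene *g*; ``burden[s]`` counts qualifying variant rows, so a
    sample's burden is >= the number of its mutated genes (multiple variants
    per gene are allowed).
    """

    values: pd.DataFrame
    burden: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if self.burden is None:
            self.burden = v.sum(axis=0).astype(int)
        arr = v.to_numpy()
        if arr.size and not np.isin(arr, [0, 1]).all():
            raise DataError("mutation matrix values must be 0/1")
        if (self.burden < 0).any():
            raise DataError("negative mutation burden")
        per_gene = v.sum(axis=0)
        if arr.size and (self.burden.reindex(v.columns) < per_gene).any():
            raise DataError("burden smaller than number of mutated genes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited genes x samples table (first row sample IDs, first
    column gene IDs).

    Non-numeric cells (including ``NA``) raise :class:`DataError` naming the
    offending gene and sample.  Duplicate gene rows are collapsed by mean
    (logged); duplicate sample IDs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = _detect_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = pd.Index(sample_ids)
        raise DataError(
            f"duplicate sample IDs in header: "
            f"{dupes[dupes.duplicated()].unique().tolist()[:5]}"
        )
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = sample_ids
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (raw != "")
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell {raw.iat[gi, si]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r} in {path.name}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(
            f"empty cell at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("read_expression_matrix: collapsing %d duplicate gene row(s) by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    numeric.index = numeric.index.astype(str)
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    expr.values.to_csv(path, sep=sep, index_label="gene_id")


def read_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path.name}:{lineno}: GMT line needs name, description and "
                    f">=1 gene ({len(fields)} field(s) found)"
                )
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(fields[0], genes))
    return sets


def write_gene_sets_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_clinical_table(path: str | Path, delimiter: str | None = None) -> ClinicalTable:
    """Read a per-sample clinical table (first column sample ID)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = _detect_delimiter(path, delimiter)
    data = pd.read_csv(path, sep=sep, index_col=0)
    data.index = data.index.astype(str)
    data.index.name = None
    return ClinicalTable(data)


def write_clinical_table(clinical: ClinicalTable, path: str | Path,
                         delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    clinical.data.to_csv(path, sep=sep, index_label="sample_id")


_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def mutation_matrix_from_maf(
    path: str | Path,
    excluded_classes: Iterable[str] = DEFAULT_EXCLUDED_CLASSES,
    samples: Sequence[str] | None = None,
) -> MutationMatrix:
    """Reduce a MAF to a binary gene x sample matrix plus per-sample burden.

    A variant row qualifies when its ``Variant_Classification`` is not in
    ``excluded_classes``.  ``burden`` counts qualifying rows per sample (a
    gene mutated twice contributes 2).  When ``samples`` is given, samples
    absent from the MAF are zero-filled so the cohort stays complete.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    maf = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_REQUIRED if c not in maf.columns]
    if missing:
        raise DataError(f"MAF missing required column(s): {missing}")
    excluded = set(excluded_classes)
    qual = maf[~maf["Variant_Classification"].isin(excluded)]
    maf_samples = list(pd.unique(maf["Tumor_Sample_Barcode"].dropna()))
    all_samples = list(samples) if samples is not None else maf_samples
    if samples is not None:
        extra = set(maf_samples) - set(all_samples)
        if extra:
            logger.info("mutation_matrix_from_maf: %d MAF sample(s) outside cohort "
                        "list dropped", len(extra))
        qual = qual[qual["Tumor_Sample_Barcode"].isin(set(all_samples))]
    if qual.empty:
        values = pd.DataFrame(
            np.zeros((0, len(all_samples)), dtype=int), columns=all_samples
        )
        burden = pd.Series(0, index=all_samples, dtype=int)
        return MutationMatrix(values, burden)
    values = (
        pd.crosstab(qual["Hugo_Symbol"], qual["Tumor_Sample_Barcode"])
        .reindex(columns=all_samples, fill_value=0)
    )
    burden = values.sum(axis=0).astype(int)
    return MutationMatrix((values > 0).astype(int), burden)


def align_samples(*tables: ExpressionMatrix | ClinicalTable | MutationMatrix | pd.DataFrame,
                  ) -> list:
    """Restrict every table to the intersection of their sample IDs.

    The intersection keeps the sample order of the first table.  Dropped IDs
    are logged per table.  DataFrames are treated as sample-indexed covariate
    tables.
    """
    def ids(t):
        if isinstance(t, (ExpressionMatrix, MutationMatrix)):
            return list(t.values.columns)
        if isinstance(t, ClinicalTable):
            return list(t.data.index)
        return list(t.index)

    common = None
    for t in tables:
        s = set(ids(t))
        common = s if common is None else common & s
    if not common:
        raise DataError("no common samples across tables")
    ordered = [s for s in ids(tables[0]) if s in common]
    out = []
    for t in tables:
        dropped = set(ids(t)) - common
        if dropped:
            logger.info("align_samples: dropping %d sample(s) from %s",
                        len(dropped), type(t).__name__)
        if isinstance(t, ExpressionMatrix):
            out.append(t.subset_samples(ordered))
        elif isinstance(t, MutationMatrix):
            out.append(MutationMatrix(t.values.loc[:, ordered],
                                      t.burden.loc[ordered]))
        elif isinstance(t, ClinicalTable):
            out.append(t.subset_samples(ordered))
        else:
            out.append(t.loc[ordered])
    return out
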