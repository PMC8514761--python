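"""Population-exclusive transcript analysis on a normalized FPKM matrix.

Mirrors the tissue-restricted-antigen workflow: a gene counts as expressed
in a population when strictly more than 0.5 FPKM in at least 3 of 6 (TEC
subsets) or 2 of 4 (fibroblast/endothelial) samples; genes expressed in
exactly one population are that population's exclusive transcripts;
housekeeping genes are excluded and the remainder is categorized against a
user-supplied tissue-specificity annotation table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataError

logger = logging.getLogger("thymoflow")

DEFAULT_MIN_SAMPLES = {"cTEC": 3, "mTEC": 3, "FB": 2, "EC": 2}


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with a sample -> population map."""

    values: pd.DataFrame
    sample_population: pd.Series

    def __post_init__(self):
        if self.values.isna().any().any():
            raise DataError("expression matrix must not contain missing values")
        if (self.values.to_numpy() < 0).any():
            raise DataError("FPKM values must be non-negative")
        unmapped = set(self.values.columns) - set(self.sample_population.index)
        if unmapped:
            raise ConfigError(f"samples without population label: {sorted(unmapped)}")
        counts = self.sample_population.loc[list(self.values.columns)].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ConfigError(f"populations need >= 2 samples: {dict(small)}")

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def populations(self):
        return sorted(self.sample_population.loc[list(self.values.columns)].unique())

    @classmethod
    def from_tsv(cls, matrix_path, groups_path):
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t")
        mapping = pd.Series(groups.iloc[:, 1].values, index=groups.iloc[:, 0].astype(str))
        return cls(values=values, sample_population=mapping)

    def to_tsv(self, matrix_path, groups_path):
        self.values.to_csv(matrix_path, sep="\t")
        (self.sample_population.rename_axis("sample").rename("population")
         .reset_index().to_csv(groups_path, sep="\t", index=False))


@dataclass(frozen=True)
class ExpressionFilterSpec:
    """Expression call: value strictly above ``threshold`` FPKM in at least
    ``min_samples[population]`` samples of that population. ``strict=False``
    switches to >= for sensitivity analysis."""

    threshold: float = 0.5
    min_samples: dict = field(default_factory=lambda: dict(DEFAULT_MIN_SAMPLES))
    strict: bool = True


def expressed_mask(matrix: ExpressionMatrix, spec: ExpressionFilterSpec | None = None
                   ) -> pd.DataFrame:
    """Genes x populations boolean expression calls."""
    spec = spec or ExpressionFilterSpec()
    pops = matrix.populations
    missing = [p for p in pops if p not in spec.min_samples]
    if missing:
        raise ConfigError(f"min_samples missing for populations: {missing}")
    above = (matrix.values > spec.threshold if spec.strict
             else matrix.values >= spec.threshold)
    cols = {}
    sample_pop = matrix.sample_population
    for pop in pops:
        samples = [s for s in matrix.values.columns if sample_pop[s] == pop]
        k = spec.min_samples[pop]
        if not 1 <= k <= len(samples):
            raise ConfigError(
                f"min_samples[{pop!r}]={k} outside 1..{len(samples)}")
        cols[pop] = above[samples].sum(axis=1) >= k
    return pd.DataFrame(cols, index=matrix.values.index)


def exclusive_genes(mask: pd.DataFrame) -> dict:
    """Genes expressed in exactly one population, keyed by population."""
    n_pops = mask.sum(axis=1)
    only_one = n_pops == 1
    return {pop: sorted(mask.index[only_one & mask[pop]]) for pop in mask.columns}


def exclude_housekeeping(genes, housekeeping):
    """Case-sensitive exact-id set difference; returns (kept, removed)."""
    hk = set(housekeeping)
    kept = [g for g in genes if g not in hk]
    removed = [g for g in genes if g in hk]
    return kept, removed


@dataclass
class TissueAnnotation:
    """Gene -> (specificity category, dominant tissue) lookup."""

    table: pd.DataFrame  # columns: gene, category, tissue

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if not {"gene", "category"}.issubset(df.columns):
            raise ConfigError("annotation table needs columns gene, category")
        if "tissue" not in df.columns:
            df["tissue"] = ""
        return cls(df)

    def lookup(self):
        return self.table.set_index("gene")


def assign_tissue_categories(genes, annotation: TissueAnnotation):
    """Map genes to specificity categories; returns (per-gene assignment,
    category counts, per-tissue counts within 'tissue enriched').

    Genes absent from the annotation count as 'unassigned' (an atlas
    snapshot never covers every transcript).
    """
    lookup = annotation.lookup()
    rows = []
    for gene in genes:
        if gene in lookup.index:
            rec = lookup.loc[gene]
            rows.append({"gene": gene, "category": rec["category"],
                         "tissue": rec.get("tissue", "")})
        else:
            rows.append({"gene": gene, "category": "unassigned", "tissue": ""})
    assigned = pd.DataFrame(rows, columns=["gene", "category", "tissue"])
    category_counts = assigned["category"].value_counts()
    enriched = assigned[assigned["category"] == "tissue enriched"]
    tissue_counts = enriched["tissue"].value_counts()
    return assigned, category_counts, tissue_counts


@dataclass
class ExclusiveReport:
    """Per-population exclusive transcript lists after housekeeping exclusion."""

    exclusive: dict                 # population -> gene list
    counts: dict                    # population -> count
    housekeeping_excluded: list
    n_expressed_nowhere: int
    n_expressed_multi: int

    @property
    def total_exclusive(self) -> int:
        return sum(self.counts.values())


def exclusive_report(matrix: ExpressionMatrix, spec: ExpressionFilterSpec | None = None,
                     housekeeping=()) -> ExclusiveReport:
    """Full pipeline: expression mask -> exclusivity -> housekeeping exclusion."""
    mask = expressed_mask(matrix, spec)
    exclusive = exclusive_genes(mask)
    removed_all = []
    cleaned = {}
    for pop, genes in exclusive.items():
        kept, removed = exclude_housekeeping(genes, housekeeping)
        cleaned[pop] = kept
        removed_all.extend(removed)
    n_pops = mask.sum(axis=1)
    return ExclusiveReport(
        exclusive=cleaned,
        counts={pop: len(genes) for pop, genes in cleaned.items()},
        housekeeping_excluded=sorted(removed_all),
        n_expressed_nowhere=int((n_pops == 0).sum()),
        n_expressed_multi=int((n_pops >= 2).sum()),
    )


class ExclusiveTranscriptFilter(BaseEstimator):
    """Exclusive-transcript selection as a fit/transform estimator.

    ``fit`` computes the expression mask and per-population exclusive gene
    lists; ``transform`` restricts a matrix to the exclusive genes of one
    (or all) populations.
    """

    def __init__(self, threshold: float = 0.5, min_samples: dict | None = None,
                 strict: bool = True, housekeeping=()):
        self.threshold = threshold
        self.min_samples = min_samples
        self.strict = strict
        self.housekeeping = housekeeping

    def _spec(self) -> ExpressionFilterSpec:
        return ExpressionFilterSpec(
            threshold=self.threshold,
            min_samples=dict(self.min_samples or DEFAULT_MIN_SAMPLES),
            strict=self.strict,
        )

    def fit(self, X: ExpressionMatrix, y=None):
        self.mask_ = expressed_mask(X, self._spec())
        report = exclusive_report(X, self._spec(), housekeeping=self.housekeeping)
        self.report_ = report
        self.exclusive_genes_ = report.exclusive
        self.counts_ = report.counts
        return self

    def transform(self, X: ExpressionMatrix, population: str | None = None):
        if not hasattr(self, "exclusive_genes_"):
            raise DataError("ExclusiveTranscriptFilter is not fitted")
        if population is None:
            genes = sorted(g for gs in self.exclusive_genes_.values() for g in gs)
        else:
            genes = self.exclusive_genes_[population]
        present = [g for g in genes if g in X.values.index]
        return X.values.loc[present]
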