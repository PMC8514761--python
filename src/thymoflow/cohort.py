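"""Cohort-level quantitation: per-donor population frequencies, derived
ratios, group comparisons, correlations, and qPCR 2^-ddCt fold changes.

Frequencies are reported as percent of total live single events; age groups
follow the pediatric bins 0-3, 3-6 and 6-12 months (month = 30.44 days).
Group comparisons standardize on the Mann-Whitney U test (the frequency
distributions are skewed); correlations are ordinary least squares with the
regression F-test p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .gating import PopulationStats, apply_gating, build_thymic_gating_tree, \
    default_fixed_thresholds, fit_tree
from .io import TransformSpec, transform_events

logger = logging.getLogger("thymoflow")

_MONTH_DAYS = 30.44
REQUIRED_NODES = ("TEC", "cTEC", "mTEC", "matureSP", "CD4SP", "CD8SP")
ACCESSORY_NODES = ("EC", "LEC", "FB", "DC", "MP")


def age_group_from_days(age_days: int) -> str:
    if age_days < 0:
        raise ConfigError("age_days must be >= 0")
    months = age_days / _MONTH_DAYS
    if months < 3:
        return "0-3m"
    if months < 6:
        return "3-6m"
    if months <= 12:
        return "6-12m"
    return "other"


def summarize_donor(stats: PopulationStats, metadata: dict) -> dict:
    """One cohort-table row from a donor's gated population statistics.

    Frequencies are percent of total events; a zero mTEC (or CD8SP) count
    flags the corresponding ratio as undefined (NaN) while keeping the row
    for frequency analyses.
    """
    for node in REQUIRED_NODES:
        if node not in stats.table.index:
            raise DataError(f"population statistics lack required node {node!r}")
    row = {
        "donor_id": metadata.get("donor_id", ""),
        "age_days": metadata.get("age_days"),
        "sex": metadata.get("sex", "NA"),
    }
    row["age_group"] = (age_group_from_days(row["age_days"])
                        if row["age_days"] is not None else metadata.get("age_group", "other"))
    for node in REQUIRED_NODES + ACCESSORY_NODES:
        if node in stats.table.index:
            row[f"freq_{node}"] = 100.0 * stats.freq_of_total(node)
    ctec, mtec = stats.count("cTEC"), stats.count("mTEC")
    if mtec == 0:
        logger.info("donor %s: mTEC count 0, cTEC/mTEC ratio undefined", row["donor_id"])
        row["ctec_mtec_ratio"] = np.nan
    else:
        row["ctec_mtec_ratio"] = ctec / mtec
    cd4, cd8 = stats.count("CD4SP"), stats.count("CD8SP")
    row["cd4sp_freq"] = 100.0 * stats.freq_of_total("CD4SP")
    row["cd8sp_freq"] = 100.0 * stats.freq_of_total("CD8SP")
    row["cd4sp_cd8sp_ratio"] = cd4 / cd8 if cd8 else np.nan
    return row


def process_cohort(donors, *, cofactor=150.0, tree=None) -> pd.DataFrame:
    """Gate every donor sample and assemble the measured cohort table.

    ``donors`` is an iterable of ``(EventTable, labels_or_None, metadata)``.
    By default gating uses the panel-calibrated fixed thresholds so every
    donor is gated identically (per-sample auto-fit is available by passing
    a fitted or unfitted tree explicitly).
    """
    fixed_default = tree is None
    if fixed_default:
        tree = build_thymic_gating_tree(overrides=default_fixed_thresholds(cofactor=cofactor))
    rows = []
    for table, _labels, meta in donors:
        if table.scale_state == "raw":
            table = transform_events(table, TransformSpec("asinh", cofactor))
        if tree.fitted:
            fitted = tree
        else:
            fitted = fit_tree(tree, table)
            if fixed_default:
                tree = fitted  # all cuts fixed: sample-independent, reuse
        _, stats = apply_gating(table, fitted)
        rows.append(summarize_donor(stats, meta))
    return pd.DataFrame(rows)


def run_cohort(spec, *, cofactor=150.0, sigma=None):
    """Simulate and gate a whole cohort donor-by-donor (streaming).

    Returns ``(measured, truth)`` cohort tables; peak memory stays at one
    donor's events. The measured table comes from panel-calibrated fixed
    gates applied identically to every donor.
    """
    from .simulate import iter_cohort

    stream = iter_cohort(spec, sigma=sigma)

    truth_rows = []

    def donors():
        for table, labels, meta, truth_row in stream:
            truth_rows.append(truth_row)
            yield table, labels, meta

    measured = process_cohort(donors(), cofactor=cofactor)
    return measured, pd.DataFrame(truth_rows)


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """OLS fit of y on x; r^2 is the squared Pearson correlation and the
    p-value comes from the regression F statistic (equivalent to the slope
    t-test for simple regression)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise DataError("correlation needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant variable")
    fit = sps.linregress(x, y)
    return CorrelationResult(slope=float(fit.slope), intercept=float(fit.intercept),
                             r_squared=float(fit.rvalue ** 2),
                             p_value=float(fit.pvalue), n=int(x.size))


@dataclass
class GroupComparison:
    groups: tuple
    n: tuple
    statistic: float
    p_value: float
    effect: float  # difference of group medians (first - second)
    n_dropped: int = 0


def compare_groups(cohort: pd.DataFrame, metric: str, grouping: str,
                   test: str = "mann_whitney", filter: dict | None = None) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of a cohort metric between the two
    groups of ``grouping`` (after optional equality filters).

    Uses the exact null distribution when both groups have n <= 8 and no
    ties, the tie-corrected normal approximation otherwise. Rows where the
    metric is undefined are dropped with a logged count.
    """
    if test != "mann_whitney":
        raise ConfigError(f"unsupported test {test!r}")
    df = cohort
    for col, value in (filter or {}).items():
        df = df[df[col] == value]
    values = df[metric]
    dropped = int(values.isna().sum())
    if dropped:
        logger.info("compare_groups: dropped %d rows with undefined %s", dropped, metric)
    df = df[values.notna()]
    groups = sorted(df[grouping].dropna().unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 groups in {grouping!r}, found {groups}")
    a = df.loc[df[grouping] == groups[0], metric].to_numpy(dtype=float)
    b = df.loc[df[grouping] == groups[1], metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError(f"each group needs >= 2 observations (got {len(a)} and {len(b)})")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(groups=tuple(groups), n=(len(a), len(b)),
                           statistic=float(res.statistic), p_value=float(res.pvalue),
                           effect=float(np.median(a) - np.median(b)), n_dropped=dropped)


def adjust_pvalues(p_values, method: str = "fdr_bh"):
    """Benjamini-Hochberg adjustment across a comparison family (off by
    default in single planned comparisons)."""
    return multipletests(np.asarray(p_values, dtype=float), method=method)[1]


def ddct_fold_change(ct: pd.DataFrame, targets, references, calibrator) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``ct`` is tidy (gene, sample, Ct). dCt subtracts the arithmetic mean Ct
    of the reference genes in the same sample; ddCt subtracts the
    calibrator sample's dCt; fold = 2^-ddCt (identically 1 for the
    calibrator).
    """
    required = {"gene", "sample", "Ct"}
    if not required.issubset(ct.columns):
        raise ConfigError(f"Ct table needs columns {sorted(required)}")
    wide = ct.pivot_table(index="gene", columns="sample", values="Ct")
    samples = list(wide.columns)
    if calibrator not in samples:
        raise DataError(f"calibrator sample {calibrator!r} not present")
    for ref in references:
        if ref not in wide.index:
            raise DataError(f"reference gene {ref!r} not measured")
        missing = wide.columns[wide.loc[ref].isna()]
        if len(missing):
            raise DataError(f"reference gene {ref!r} missing in sample(s) {list(missing)}")
    ref_mean = wide.loc[list(references)].mean(axis=0)
    rows = []
    for gene in targets:
        if gene not in wide.index:
            raise DataError(f"target gene {gene!r} not measured")
        dct = wide.loc[gene] - ref_mean
        ddct = dct - dct[calibrator]
        for sample in samples:
            rows.append({"gene": gene, "sample": sample, "dCt": float(dct[sample]),
                         "ddCt": float(ddct[sample]),
                         "fold": float(2.0 ** (-ddct[sample]))})
    return pd.DataFrame(rows)


def cohort_report(cohort: pd.DataFrame, *, adjust: bool = False) -> dict:
    """The planned cohort analyses: male-vs-female cTEC/mTEC ratio in the
    0-3-month group, and the cTEC/mTEC vs mature CD4SP/CD8SP correlation."""
    out = {}
    out["sex_ctec_mtec_0_3m"] = compare_groups(
        cohort, metric="ctec_mtec_ratio", grouping="sex",
        filter={"age_group": "0-3m"})
    mask = cohort["ctec_mtec_ratio"].notna() & cohort["cd4sp_cd8sp_ratio"].notna()
    out["ctec_mtec_vs_cd4_cd8"] = correlate(
        cohort.loc[mask, "ctec_mtec_ratio"], cohort.loc[mask, "cd4sp_cd8sp_ratio"])
    if adjust:
        out["adjusted_p"] = dict(zip(
            ["sex_ctec_mtec_0_3m", "ctec_mtec_vs_cd4_cd8"],
            adjust_pvalues([out["sex_ctec_mtec_0_3m"].p_value,
                            out["ctec_mtec_vs_cd4_cd8"].p_value]),
        ))
    return out
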