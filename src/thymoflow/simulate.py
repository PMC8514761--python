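"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: multi-parameter
cytometry samples (mixtures of labeled populations with log-normal marker
intensities), stepwise-enriched fractions, 332-marker screening plates with
planted discriminatory markers, FPKM expression matrices with planted
population-exclusive genes, and pediatric cohorts with a planted male-infant
cortical-TEC deficit coupled to a CD4/CD8 mature-thymocyte shift.

All generators are deterministic given their seed. Defaults encode the
study conditions: population phenotypes from the published gating scheme
(``data/thymic_phenotypes.yaml``) and cohort baseline frequencies from the
reported pediatric medians (TEC 0.067/0.033/0.016% by age group; MP 0.044%,
DC 0.057%, FB 0.06%, EC 0.061%, LEC 0.0013%).
"""

from __future__ import annotations

import functools
import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .errors import AlignmentError, ConfigError
from .io import ChannelMeta, EventTable
from .screen import ScreenPlate

logger = logging.getLogger("thymoflow")

POPULATIONS = (
    "cTEC", "mTEC", "FB", "EC", "LEC", "DC", "MP",
    "thymocyte_immature", "thymocyte_CD4SP", "thymocyte_CD8SP", "B", "other",
)

#: Reported median frequencies (fractions of total events) used as generator
#: baselines. TEC totals are age-group dependent; accessory populations are
#: age-constant. B-cell and residual-stromal baselines are modeling choices.
TEC_FREQ_BY_AGE_GROUP = {"0-3m": 6.7e-4, "3-6m": 3.3e-4, "6-12m": 1.6e-4}
ACCESSORY_BASELINES = {
    "MP": 4.4e-4, "DC": 5.7e-4, "FB": 6.0e-4, "EC": 6.1e-4, "LEC": 1.3e-5,
    "B": 5.0e-3, "other": 1.0e-2,
}

AGE_GROUP_RANGES = {"0-3m": (1, 91), "3-6m": (92, 183), "6-12m": (184, 365)}


@functools.lru_cache(maxsize=None)
def load_phenotypes():
    """Load the editable population-phenotype configuration shipped as data."""
    ref = importlib.resources.files("thymoflow") / "data" / "thymic_phenotypes.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class PopulationModel:
    """One labeled population: its mixture frequency and per-marker log-normal
    intensity parameters (mu = log geometric mean on the raw scale)."""

    name: str
    frequency: float
    intensity_params: dict  # marker -> (mu, sigma)

    def __post_init__(self):
        for marker, (mu, sigma) in self.intensity_params.items():
            if not sigma > 0:
                raise ConfigError(f"{self.name}/{marker}: sigma must be > 0")


@dataclass(frozen=True)
class SampleSpec:
    populations: tuple
    n_events: int
    seed: int
    clip_sigma: float | None = None  # truncate log-space draws at k*sigma

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("population names must be unique")
        total = sum(p.frequency for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"population frequencies sum to {total}, not 1")
        if self.n_events < 0:
            raise ConfigError("n_events must be non-negative")


def population_model(name, frequency, *, sigma=None, levels=None, phenotypes=None):
    """Build a PopulationModel from the named phenotype configuration."""
    pheno = phenotypes or load_phenotypes()
    levels = levels or pheno["levels"]
    sigma = sigma if sigma is not None else pheno["sigma"]
    if name not in pheno["populations"]:
        raise ConfigError(f"unknown population {name!r}")
    spec = pheno["populations"][name] or {}
    params = {}
    for marker in pheno["markers"]:
        level = spec.get(marker, "neg")
        params[marker] = (math.log(levels[level]), sigma)
    return PopulationModel(name, frequency, params)


def build_sample_spec(frequencies, n_events, seed, *, sigma=None, clip_sigma=None,
                      phenotypes=None) -> SampleSpec:
    """SampleSpec from a population -> frequency map using the default phenotypes."""
    pops = tuple(
        population_model(name, freq, sigma=sigma, phenotypes=phenotypes)
        for name, freq in frequencies.items()
    )
    return SampleSpec(pops, n_events, seed, clip_sigma=clip_sigma)


def simulate_sample(spec: SampleSpec, *, rng=None):
    """Draw one cytometry sample; returns (raw EventTable, truth label array).

    Per-event populations are multinomial in the spec frequencies; marker
    intensities are i.i.d. log-normal per population. With ``clip_sigma``
    set, log-space deviates are truncated at ``k * sigma`` so population
    supports are provably disjoint when mode separation exceeds ``2 k sigma``.
    """
    pheno = load_phenotypes()
    markers = pheno["markers"]
    for pop in spec.populations:
        unknown = set(pop.intensity_params) - set(markers)
        if unknown:
            raise ConfigError(f"{pop.name}: markers {sorted(unknown)} not in panel")

    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_events
    freqs = np.array([p.frequency for p in spec.populations])
    # multinomial counts with a contiguous block per population: equivalent
    # to per-event draws for every order-invariant downstream computation
    counts = rng.multinomial(n, freqs) if n else np.zeros(len(freqs), dtype=int)
    mus = np.array([[p.intensity_params[mk][0] for mk in markers]
                    for p in spec.populations], dtype=np.float32)
    sigmas = np.array([[p.intensity_params[mk][1] for mk in markers]
                       for p in spec.populations], dtype=np.float32)
    z = rng.standard_normal((n, len(markers)), dtype=np.float32)
    if spec.clip_sigma is not None:
        np.clip(z, -spec.clip_sigma, spec.clip_sigma, out=z)
    start = 0
    for i in range(len(spec.populations)):
        end = start + counts[i]
        if end > start:
            z[start:end] *= sigmas[i]
            z[start:end] += mus[i]
        start = end
    data = np.exp(z, out=z)
    labels = np.repeat(np.array([p.name for p in spec.populations]), counts)

    channels = [ChannelMeta(mk) for mk in markers]
    table = EventTable(f"sim-{spec.seed}", data, channels, "raw", None)
    return table, labels


@dataclass(frozen=True)
class EnrichmentSpec:
    """Stepwise-enrichment emulation: per-class event retention probabilities.

    Modeled on the density-gradient + CD45-depletion protocol that yields an
    approx. 200-fold proportional enrichment of stromal cells.
    """

    cd45_retention: float = 0.004
    nonstromal_cd45neg_retention: float = 0.9
    stromal_retention: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in ("cd45_retention", "nonstromal_cd45neg_retention", "stromal_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


def expected_enrichment_factor(frequencies: dict, spec: EnrichmentSpec,
                               stromal=("cTEC", "mTEC", "FB", "EC", "LEC")) -> float:
    """Closed-form expected fold enrichment of the stromal fraction:
    p' / p with p' = p*r_s / (p*r_s + sum_other p_i*r_i)."""
    classes = load_phenotypes()["enrichment_class"]
    r = {"stromal": spec.stromal_retention, "cd45pos": spec.cd45_retention,
         "cd45neg_nonstromal": spec.nonstromal_cd45neg_retention}
    p_s = sum(f for name, f in frequencies.items() if name in stromal)
    kept_s = p_s * spec.stromal_retention
    kept_total = sum(f * r[classes[name]] for name, f in frequencies.items())
    return (kept_s / kept_total) / p_s


def simulate_enrichment(table: EventTable, labels, spec: EnrichmentSpec):
    """Subsample events with per-class retention; intensities are untouched."""
    labels = np.asarray(labels)
    if len(labels) != table.n_events:
        raise AlignmentError("labels are not aligned with the event table")
    classes = load_phenotypes()["enrichment_class"]
    r = {"stromal": spec.stromal_retention, "cd45pos": spec.cd45_retention,
         "cd45neg_nonstromal": spec.nonstromal_cd45neg_retention}
    retention = np.array([r[classes[str(lbl)]] for lbl in labels])
    rng = np.random.default_rng(spec.seed)
    keep = rng.random(table.n_events) < retention
    if table.n_events and not keep.any():
        logger.warning("enrichment retained no events")
    out = EventTable(table.sample_id + "-enriched", table.events[keep],
                     list(table.channels), table.scale_state, table.transform)
    return out, labels[keep]


@dataclass(frozen=True)
class CohortSpec:
    """Pediatric cohort generator: donor demographics, baseline population
    frequencies with log-normal donor variability, a male 0-3-month cTEC
    deficit, and a logistic coupling of the mature CD8SP share to
    log(cTEC/mTEC)."""

    n_donors: int = 31
    age_group_probs: dict = field(default_factory=lambda: {"0-3m": 0.4, "3-6m": 0.3, "6-12m": 0.3})
    sex_probs: dict = field(default_factory=lambda: {"F": 0.5, "M": 0.5})
    baseline_frequencies: dict = field(default_factory=lambda: dict(ACCESSORY_BASELINES))
    tec_freq_by_age_group: dict = field(default_factory=lambda: dict(TEC_FREQ_BY_AGE_GROUP))
    ctec_fraction: float = 0.6
    male_0_3m_ctec_multiplier: float = 0.5
    coupling_slope: float = 1.0
    coupling_intercept: float | None = None
    cd8sp_baseline_share: float = 0.3
    mature_fraction: float = 0.25
    donor_cv: float = 0.5
    n_events: int = 200_000
    seed: int = 0

    def __post_init__(self):
        for probs, label in ((self.age_group_probs, "age_group_probs"),
                             (self.sex_probs, "sex_probs")):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{label} must sum to 1")
        if not 0 < self.male_0_3m_ctec_multiplier <= 1:
            raise ConfigError("male_0_3m_ctec_multiplier must be in (0, 1]")
        if self.donor_cv < 0:
            raise ConfigError("donor_cv must be >= 0")
        base = sum(self.baseline_frequencies.values()) + max(self.tec_freq_by_age_group.values())
        if base > 1:
            raise ConfigError("baseline frequencies exceed 1")

    @property
    def intercept(self) -> float:
        """Logit intercept of the CD8SP-share link, anchored so the baseline
        cTEC/mTEC ratio maps to the baseline CD8SP share."""
        if self.coupling_intercept is not None:
            return self.coupling_intercept
        base_ratio = self.ctec_fraction / (1.0 - self.ctec_fraction)
        return float(logit(self.cd8sp_baseline_share) - self.coupling_slope * math.log(base_ratio))


def _donor_frequencies(spec: CohortSpec, age_group, sex, rng):
    noise = lambda: math.exp(rng.normal(0.0, spec.donor_cv))
    freqs = {name: base * noise() for name, base in spec.baseline_frequencies.items()}
    tec = spec.tec_freq_by_age_group[age_group]
    ctec = tec * spec.ctec_fraction * noise()
    mtec = tec * (1.0 - spec.ctec_fraction) * noise()
    if sex == "M" and age_group == "0-3m":
        ctec *= spec.male_0_3m_ctec_multiplier
    freqs["cTEC"], freqs["mTEC"] = ctec, mtec

    thymo = 1.0 - sum(freqs.values())
    mature = thymo * spec.mature_fraction
    share_cd8 = float(expit(spec.intercept + spec.coupling_slope * math.log(ctec / mtec)))
    freqs["thymocyte_immature"] = thymo - mature
    freqs["thymocyte_CD8SP"] = mature * share_cd8
    freqs["thymocyte_CD4SP"] = mature * (1.0 - share_cd8)
    total = sum(freqs.values())
    return {k: v / total for k, v in freqs.items()}


def iter_cohort(spec: CohortSpec, *, sigma=None):
    """Stream the donors of a cohort one at a time.

    Yields ``(EventTable, truth_labels, metadata, truth_row)`` per donor, so
    large cohorts can be gated donor-by-donor without holding every event
    table in memory. The truth row carries the planted frequencies (percent
    of total events) and derived ratios, before any sampling noise.
    """
    if spec.n_donors < 2:
        raise ConfigError("a cohort needs at least 2 donors")
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.age_group_probs)
    sexes = list(spec.sex_probs)
    for d in range(spec.n_donors):
        age_group = groups[rng.choice(len(groups), p=[spec.age_group_probs[g] for g in groups])]
        sex = sexes[rng.choice(len(sexes), p=[spec.sex_probs[s] for s in sexes])]
        lo, hi = AGE_GROUP_RANGES[age_group]
        age_days = int(rng.integers(lo, hi + 1))
        freqs = _donor_frequencies(spec, age_group, sex, rng)
        child_seed = int(rng.integers(2**31))
        sample_spec = build_sample_spec(freqs, spec.n_events, child_seed, sigma=sigma)
        table, labels = simulate_sample(sample_spec)
        donor_id = f"donor_{d:03d}"
        table.sample_id = donor_id
        meta = {"donor_id": donor_id, "age_days": age_days, "age_group": age_group, "sex": sex}
        truth_row = {
            **meta,
            **{f"freq_{k}": 100.0 * v for k, v in freqs.items()},
            "ctec_mtec_ratio": freqs["cTEC"] / freqs["mTEC"],
            "cd4sp_cd8sp_ratio": freqs["thymocyte_CD4SP"] / freqs["thymocyte_CD8SP"],
        }
        yield table, labels, meta, truth_row


def simulate_cohort(spec: CohortSpec, *, sigma=None):
    """Generate a donor cohort; returns (donors, ground-truth table).

    ``donors`` is a list of ``(EventTable, truth_labels, metadata)``. For
    cohorts too large to hold in memory use :func:`iter_cohort`.
    """
    donors, truth_rows = [], []
    for table, labels, meta, truth_row in iter_cohort(spec, sigma=sigma):
        donors.append((table, labels, meta))
        truth_rows.append(truth_row)
    return donors, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ScreenSpec:
    """332-marker screening plate with planted discriminatory markers.

    ``planted_effects`` lists ``(marker_index, population, fold)``: that
    marker's MFI in the named reference population is multiplied by ``fold``.
    ``well_noise_cv`` is the log-scale SD of the per-well multiplicative noise.
    """

    n_markers: int = 332
    planted_effects: tuple = ()
    baseline_mu: float = math.log(300.0)
    baseline_sigma: float = 1.0
    well_noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        seen = set()
        for idx, pop, fold in self.planted_effects:
            if not 0 <= idx < self.n_markers:
                raise ConfigError(f"planted marker index {idx} out of range")
            if (idx, pop) in seen:
                raise ConfigError(f"duplicate planted effect for marker {idx} in {pop!r}")
            seen.add((idx, pop))
            if not fold > 0:
                raise ConfigError("planted fold change must be > 0")


def default_screen_spec(seed=0, pop_high="EpCAM_high", *, n_high=5, n_low=5) -> ScreenSpec:
    """ScreenSpec with the acceptance-style planting: markers at fold >= 5
    and fold <= 0.2 in the first reference population."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(332, size=n_high + n_low, replace=False)
    folds_high = [5.0, 6.0, 8.0, 10.0, 15.0][:n_high]
    folds_low = [0.2, 0.15, 0.1, 0.08, 0.05][:n_low]
    effects = tuple(
        (int(i), pop_high, f) for i, f in zip(idx, folds_high + folds_low)
    )
    return ScreenSpec(planted_effects=effects, seed=seed)


def simulate_screen_plate(spec: ScreenSpec, reference_pops, *, donor_id="donor_0"):
    """One well per marker with per-reference-population MFIs; returns
    (ScreenPlate, planted-truth DataFrame)."""
    if len(reference_pops) < 2:
        raise ConfigError("need at least 2 reference populations")
    rng = np.random.default_rng(spec.seed)
    markers = [f"M{i + 1:03d}" for i in range(spec.n_markers)]
    baseline = np.exp(rng.normal(spec.baseline_mu, spec.baseline_sigma, spec.n_markers))
    folds = {pop: np.ones(spec.n_markers) for pop in reference_pops}
    for idx, pop, fold in spec.planted_effects:
        if pop not in folds:
            raise ConfigError(f"planted population {pop!r} not among reference populations")
        folds[pop][idx] = fold
    mfi = {}
    for pop in reference_pops:
        noise = (np.exp(rng.normal(0.0, spec.well_noise_cv, spec.n_markers))
                 if spec.well_noise_cv > 0 else 1.0)
        mfi[pop] = baseline * folds[pop] * noise
    wells = pd.DataFrame(mfi, index=pd.Index(markers, name="marker"))
    truth = pd.DataFrame(
        [{"marker": markers[idx], "population": pop, "fold": fold}
         for idx, pop, fold in spec.planted_effects]
    )
    return ScreenPlate(donor_id=donor_id, wells=wells), truth


@dataclass(frozen=True)
class ExpressionSpec:
    """FPKM matrix emulating bulk-sorted stromal subsets: planted
    population-exclusive genes, ubiquitous housekeeping genes, shared-on
    genes and background-level off genes."""

    n_genes: int = 20_000
    samples_per_population: dict = field(
        default_factory=lambda: {"cTEC": 6, "mTEC": 6, "FB": 4, "EC": 4})
    planted_exclusive: dict = field(
        default_factory=lambda: {"mTEC": 841, "cTEC": 128, "FB": 227, "EC": 104})
    housekeeping_count: int = 1000
    expressed_mu: float = math.log(5.0)
    expressed_sigma: float = 1.0
    background_max: float = 0.4
    dropout_prob: float = 0.05
    shared_prob: float = 0.3
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if sum(self.planted_exclusive.values()) + self.housekeeping_count > self.n_genes:
            raise ConfigError("planted + housekeeping genes exceed n_genes")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if not self.background_max < self.threshold:
            raise ConfigError("background_max must stay below the expression threshold")
        unknown = set(self.planted_exclusive) - set(self.samples_per_population)
        if unknown:
            raise ConfigError(f"planted populations {sorted(unknown)} have no samples")


def simulate_expression_matrix(spec: ExpressionSpec):
    """Generate (ExpressionMatrix, truth). "On" values are threshold-shifted
    log-normal (strictly above threshold); dropout replaces an "on" draw with
    a background-level value in that sample."""
    from .exclusive import ExpressionMatrix  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    pops = list(spec.samples_per_population)
    samples, sample_pop = [], {}
    for pop in pops:
        for i in range(spec.samples_per_population[pop]):
            sid = f"{pop}_{i + 1}"
            samples.append(sid)
            sample_pop[sid] = pop
    genes = [f"gene_{i + 1:05d}" for i in range(spec.n_genes)]
    n, m = spec.n_genes, len(samples)

    order = rng.permutation(n)
    cursor = 0
    planted = {}
    for pop in pops:
        k = spec.planted_exclusive.get(pop, 0)
        planted[pop] = sorted(int(i) for i in order[cursor:cursor + k])
        cursor += k
    housekeeping = sorted(int(i) for i in order[cursor:cursor + spec.housekeeping_count])
    cursor += spec.housekeeping_count
    rest = order[cursor:]
    shared_mask = rng.random(len(rest)) < spec.shared_prob
    shared_idx = rest[shared_mask]
    shared = {}
    for gi in shared_idx:
        k = int(rng.integers(2, len(pops) + 1))
        chosen = rng.choice(len(pops), size=k, replace=False)
        shared[int(gi)] = tuple(pops[int(c)] for c in sorted(chosen))

    # "on" boolean matrix gene x sample
    on = np.zeros((n, m), dtype=bool)
    pop_cols = {pop: np.array([j for j, s in enumerate(samples) if sample_pop[s] == pop])
                for pop in pops}
    for pop, idx in planted.items():
        if idx:
            on[np.ix_(idx, pop_cols[pop])] = True
    if housekeeping:
        on[housekeeping, :] = True
    for gi, gpops in shared.items():
        for pop in gpops:
            on[gi, pop_cols[pop]] = True

    values = rng.uniform(0.0, spec.background_max, size=(n, m))
    n_on = int(on.sum())
    on_vals = spec.threshold + np.exp(rng.normal(spec.expressed_mu, spec.expressed_sigma, n_on))
    if spec.dropout_prob > 0:
        drop = rng.random(n_on) < spec.dropout_prob
        on_vals[drop] = rng.uniform(0.0, spec.background_max, int(drop.sum()))
    values[on] = on_vals

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        sample_population=pd.Series(sample_pop),
    )
    truth = {
        "planted": {pop: [genes[i] for i in idx] for pop, idx in planted.items()},
        "housekeeping": [genes[i] for i in housekeeping],
        "shared": {genes[i]: p for i, p in shared.items()},
    }
    return matrix, truth


def simulate_tissue_annotation(genes, seed=0, *, assignable_frac=0.946,
                               category_probs=None, tissue_probs=None) -> pd.DataFrame:
    """Synthetic tissue-specificity annotation table for a gene list.

    Emulates an atlas-style categorization: most genes map to a specificity
    category and "tissue enriched" genes carry a dominant tissue, with brain
    and testis leading. Returns columns (gene, category, tissue).
    """
    category_probs = category_probs or {
        "tissue enriched": 0.33, "group enriched": 0.27, "tissue enhanced": 0.40}
    tissue_probs = tissue_probs or {
        "brain": 0.38, "testis": 0.30, "liver": 0.12, "kidney": 0.10, "pancreas": 0.10}
    rng = np.random.default_rng(seed)
    cats = list(category_probs)
    tissues = list(tissue_probs)
    rows = []
    for gene in genes:
        if rng.random() >= assignable_frac:
            continue  # unannotated -> absent from the table
        cat = cats[rng.choice(len(cats), p=[category_probs[c] for c in cats])]
        tissue = ""
        if cat == "tissue enriched":
            tissue = tissues[rng.choice(len(tissues), p=[tissue_probs[t] for t in tissues])]
        rows.append({"gene": gene, "category": cat, "tissue": tissue})
    return pd.DataFrame(rows, columns=["gene", "category", "tissue"])
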