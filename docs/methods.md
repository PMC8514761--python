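# Methods

This note documents the models, numerical choices and limitations behind
`thymoflow`: what the synthetic data emulates, how gates are placed, which
statistics are computed and why, and what the passing test suite does and
does not demonstrate about real cytometry data.

## Intensity model and scale

Raw fluorescence intensities are modeled per population and marker as
log-normal: `x = exp(N(log L, σ))`, where `L` is the level's geometric mean
and `σ` the log-scale SD (default 0.4). Four named levels are used —
neg = 20, lo = 500, int = 3000, hi = 20 000 arbitrary units — chosen so
adjacent levels sit ≥ 3σ apart on the gating scale at the default σ. The
population phenotype table (which marker sits at which level in cTEC,
mTEC, FB, vascular and lymphatic EC, DC, MP, immature and mature CD4/CD8
single-positive thymocytes, B cells, and an ungated CD45⁻ remainder) ships
as editable YAML (`thymoflow/data/thymic_phenotypes.yaml`), not code.

Gating operates on `asinh(x / cofactor)` with cofactor 150 — a convention
for conventional-cytometer ranges, since the display scale used in manual
analysis software is rarely reported; the cofactor is a parameter
everywhere. Screen MFIs are computed on the raw scale, because the ratio
ranking logic of the screen is defined on instrument-scale means; the MFI
statistic (arithmetic mean by default; median and geometric mean
available) is likewise exposed because published "MFI" rarely states the
estimator.

An optional `clip_sigma` truncates log-space draws at ±kσ. Its purpose is
the exact-recovery regime: with σ = 0.25 and clipping at 2.5σ the
population supports are provably disjoint (≥ 6.4σ mode separation), so
gate counts must equal the planted truth event-for-event. The truncation
places a small probability atom at the support edge, which is irrelevant
for thresholding.

Samples are laid out as one contiguous block per population with
multinomial block sizes. This is distributionally equivalent to per-event
draws for every order-invariant computation (gating is proven
order-invariant by a test), and is what makes 200k-event × 13-marker
donors cheap enough to simulate by the thousands.

## Threshold placement

Clause thresholds are one of `fixed(v)`, `quantile(q)`, or a density
valley. The valley method estimates the density by binned KDE: 1024 bins,
Gaussian smoothing with Silverman's bandwidth
`0.9·min(s, IQR/1.34)·n^(−1/5)` floored at 1% of the data range (the floor
matters because spike-dominated mixtures collapse the IQR). Modes are
density peaks that (a) carry the mass equivalent of ≥ 15 events within one
bandwidth — keeping sub-percent subpopulations detectable while ignoring
stray-tail wiggles — and (b) have prominence ≥ half their own height, so
histogram jitter on a mode's shoulder cannot split it. The public
`place_threshold(values, "valley")` cuts at the density minimum between
the two *largest* modes (≥ 50 values required; unimodal data falls back to
`quantile(0.99)` with a warning). Gate clauses may instead reference the
k-th *inter-mode* valley left-to-right (`valley:2`): the TEC gate's lower
pdpn cut is the rank-2 valley, i.e. above the fibroblast pdpn mode but
below the mTEC mode — the published gates draw this boundary by eye, and
the rank-2 valley is this package's reconstruction of it.

Thresholds are fitted per sample by default, each clause on the events
passing its parent gate (which is what makes lower gates like the CD4/CD8
split bimodal in scope even though the full-sample distribution is not).
For cohorts, panel-calibrated fixed cuts — midpoints between the
configured phenotype levels on the asinh scale — gate every donor
identically; this mirrors the practice of locking gates across a study and
is also what keeps 6 000+ donor gatings inside a few minutes.

Tie rule: positive gates use `≥`, so an event exactly on a cut goes to the
positive side; `between` is `lo ≤ x < hi`. An event satisfying two
same-depth sibling gates (possible only in distribution tails) keeps the
first-declared gate; events are labeled with the deepest gate whose full
ancestor path they satisfy. CD45 is deliberately absent from the TEC path
(it is dispensable for TEC identification) but retained in the accessory
gates. Double-positive CD49f⁺CD200⁺ events inside the TEC gate match the
lymphatic-endothelial phenotype and are assigned to neither TEC subset.

## Stepwise enrichment

Density-gradient plus CD45-depletion enrichment is emulated as independent
per-event retention with three class probabilities (CD45⁺ cells, stromal
cells, other CD45⁻ cells; defaults 0.004 / 0.9 / 0.9). Intensities are
never modified — enrichment only changes membership. The expected
post-enrichment stromal proportion has the closed form
`p' = p·r_s / (p·r_s + Σᵢ pᵢ·rᵢ)`, which the tests use as the oracle for
the realized enrichment factor.

## Cohort generator and statistics

Per-donor population frequencies are baseline × `exp(N(0, donor_cv))`,
independently per population (`donor_cv` is the log-scale SD; ~CV for
small values). Baselines are the reported pediatric medians: TEC
0.067/0.033/0.016% of events for ages 0–3/3–6/6–12 months, accessory
populations MP 0.044%, DC 0.057%, FB 0.06%, EC 0.061%, LEC 0.0013%; B
cells (0.5%) and a residual CD45⁻ fraction (1%) are modeling choices. The
TEC total splits 60/40 into cTEC/mTEC (baseline ratio 1.5). Male donors in
the 0–3-month group have their cTEC frequency multiplied by
`male_0_3m_ctec_multiplier` (default 0.5). The mature CD8SP share among
single-positive thymocytes follows a logistic link,
`s = expit(b₀ + β·log(cTEC/mTEC))` with β = +1 by default, which induces
the inverse CD4/CD8-vs-cTEC/mTEC correlation; only a correlation is
reported for the real cohort, so the link form is this package's choice,
anchored so the baseline ratio maps to a CD8SP share of 0.3. Demographics
default to age-group probabilities 0.4/0.3/0.3 (infant cardiac-surgery
cohorts skew young) and an even sex split; acquisitions default to 200 000
events per donor. Donor variance of TEC frequencies is not reported for
the real cohort (medians only), so `donor_cv` defaults to 0.5 as a
modeling choice; analyses that prescribe a different value pass it
explicitly.

Group comparisons standardize on the two-sided Mann–Whitney U test — the
frequency distributions are log-normal-skewed, and the test the original
analysis used is not stated, so exact p-value agreement with published
figures is not expected. The exact null distribution is used when both
groups have n ≤ 8 and no ties; otherwise the tie-corrected normal
approximation. The effect is reported as the difference of group medians.
Correlations are simple OLS; r² is the squared Pearson correlation and the
p-value the regression F-test (equivalent to the slope t-test). A
Benjamini–Hochberg helper is provided but off by default: the planned
comparisons are analyzed unadjusted, as single pre-specified tests.
Frequencies are percent of total (live single) events; age groups use
month = 30.44 days. A donor with zero mTEC events keeps its row (the
frequencies remain usable) but its cTEC/mTEC ratio is flagged undefined
and excluded from ratio statistics with a log entry.

Power note: at the planted deficit (multiplier 0.5) with donor_cv 0.2, the
per-population independence of donor noise puts a log-SD of ≈ 0.28 on the
cTEC/mTEC ratio against an effect of ln 2, and the 0–3-month subgroup holds
~12 of 31 donors under the default demographics. An exact Mann–Whitney on
~6 vs 6 donors then detects the deficit in roughly three quarters of
replicate cohorts — counting noise at 200k events/donor (≈ 40 cTEC events)
costs a few further points. Detection rates in this range are an honest
property of cohorts of this size and structure, not an implementation
artifact; a younger-skewed cohort or larger acquisitions would push the
rate up.

qPCR quantification implements 2^(−ΔΔCt): ΔCt subtracts the arithmetic
mean Ct of the reference genes (e.g. GAPDH, HPRT-1, RPLP13) within each
sample, ΔΔCt subtracts the calibrator sample's ΔCt, and the calibrator's
fold is identically 1.

## Exclusive transcripts

The expression call is strict: a gene is expressed in a population iff its
FPKM is **> 0.5** (the printed convention; a flag switches to ≥ for
sensitivity analysis) in at least 3 of 6 (cTEC, mTEC) or 2 of 4 (FB, EC)
samples. Exclusivity means expressed in exactly one population. The
default order is mask → exclusivity → housekeeping exclusion; whether the
original analysis excluded housekeeping genes before or after the
uniqueness step is ambiguous, so the steps are separate functions and the
order is the caller's. Housekeeping and tissue-specificity tables are
user-supplied TSVs rather than a live database dependency: the published
counts depend on a specific protein-atlas snapshot that cannot be pinned;
the generator includes a synthetic annotation table for self-contained
runs. Gene identifiers are opaque strings; no ID mapping is performed.

The generator plants exclusive genes as threshold-shifted log-normals
(`0.5 + exp(N(log 5, 1))`, strictly above threshold), housekeeping genes
on everywhere, a fraction of the remainder on in ≥ 2 random populations,
and the rest at background `U(0, 0.4)`. Dropout replaces an "on" draw with
background in that sample, and applies to *every* on-gene: a shared gene
can therefore drop to single-population expression and appear as a
spurious exclusive, so under dropout the recovered-⊆-planted guarantee is
asserted on the planted genes themselves. With zero dropout, recovery of
the planted lists is exact and checked against a brute-force enumeration.

## What the synthetic data does not emulate

No spillover/compensation, no logicle/biexponential scales, no doublets,
debris or viability-dye artifacts (events are assumed pre-cleaned, as
after live-single-cell gating), no spectral overlap, and unimodal
log-normal populations rather than the smeared, auto-fluorescent continua
of real digests. Passing gate-recovery tests therefore demonstrates that
the gating logic and threshold placement are correct for well-separated
unimodal mixtures — the regime the published strategy itself asserts for
these markers — not that the pipeline is robust to poorly stained or
heavily overlapping real samples. Likewise FPKM matrices are generated
directly; read processing, quantification and normalization are upstream
and out of scope.

## Numerical and degenerate-input conventions

Float32 is used for simulated event data (float64 everywhere else);
transform inversion is exact to 1e-9 relative in float64. FCS I/O is a
minimal native FCS 3.1 implementation (list-mode float data, one dataset;
spillover and analysis segments ignored); a transformed table is written
with keywords recording the transform so a round trip restores its scale
state. Empty event tables gate to all-zero statistics with an emptiness
flag; empty MFI selections, constant-x correlations, single-donor CV
requests and missing reference genes are errors, not NaNs. Ranking ties
break alphabetically by marker; an infinite ratio (zero denominator)
sorts above all finite ratios and is flagged, and a 0/0 ratio row is
excluded with a log entry. Seeds drive `numpy.random.default_rng`
exclusively; every generator is bit-reproducible given its seed, and
derived seeds stay below 2³¹.

## Problem sizes used in the checks

Gate recovery runs at 100 000 events with every population ≥ 200 events
(1 000–50 000); screen recovery uses ten 332-marker plates with five
planted markers per direction; exclusive-transcript checks use twenty
2 000 × 20 matrices against brute force plus one default-scale
(20 000-gene) run; cohort recovery uses 31-donor replicate cohorts at
200 000 events per donor — 100 replicates per arm in the test suite and 40
per arm in the acceptance script, sizes chosen to keep each check's
runtime proportionate to what it measures.
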