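# thymoflow

Flow-cytometry identification and quantitation of human thymic stromal
cells, with a ground-truth synthetic-data generator that makes every stage
of the analysis testable without tissue.

## The problem

Thymic epithelial cells (TECs) orchestrate T-cell development, but in human
thymus they are rare (on the order of 0.01–0.1% of a digested cell
suspension) and EpCAM alone does not separate them cleanly from other
CD45⁻ stromal cells: a subset of cytokeratin⁺ TECs carries very low surface
EpCAM. A surface-marker screen identifies podoplanin (pdpn) as the missing
handle: TECs are pdpn^high/int at any EpCAM level, and within the TEC gate
CD49f (integrin α6) and CD200 split cortical from medullary subsets —
cTEC = CD49f⁺CD200⁻, mTEC = CD49f^int/low CD200⁺. Accessory gates cover
vascular endothelium (CD45⁻CD31⁺pdpn⁻), lymphatic endothelium
(CD45⁻CD31⁺pdpn⁺CD49f^hi CD200^hi), fibroblasts (CD45⁻EpCAM⁻HLA-DR⁻pdpn^int),
dendritic cells (CD45⁺HLA-DR⁺CD11c⁺CD11b⁺), macrophages
(CD45⁺HLA-DR⁺CD11c⁻CD11b⁺), thymocytes (CD3⁺ and/or CD1a⁺) and mature
single-positive thymocytes (CD3^high CD1a^int/low, split by CD4/CD8).

`thymoflow` turns this strategy into an executable, automatically fitted
gate tree and surrounds it with the analyses that use it:

- **`thymoflow.screen`** — screening-plate analytics: per-population MFI,
  MFI-ratio ranking between two reference populations
  (r_m = MFI_A(m)/MFI_B(m), ranked descending), top-N candidate selection
  with an absolute-MFI floor, and inter-donor reproducibility
  (CV = s/x̄ across donors).
- **`thymoflow.gating`** — the hierarchical gate tree with automatic
  threshold placement (kernel-density valleys between intensity modes on
  the asinh(x/150) scale, quantile and fixed cuts), evaluation against
  ground truth (precision/recall/F1), and a scikit-learn
  `GatingClassifier` (fit places thresholds, predict assigns populations).
- **`thymoflow.cohort`** — per-donor population frequencies (% of total
  events), cTEC/mTEC and CD4SP/CD8SP ratios, Mann–Whitney group
  comparisons, OLS correlations, and qPCR relative quantification by
  2^(−ΔΔCt) against a reference-gene mean.
- **`thymoflow.exclusive`** — tissue-restricted-antigen analysis on an
  FPKM matrix: a gene is "expressed" in a population when > 0.5 FPKM in at
  least 3 of 6 (cTEC, mTEC) or 2 of 4 (FB, EC) samples; genes expressed in
  exactly one population are its exclusive transcripts; housekeeping genes
  are excluded and the rest categorized against a tissue-specificity table.
- **`thymoflow.simulate`** — generators for all of the above with planted
  ground truth: mixture-model cytometry samples (log-normal intensities per
  marker per population, phenotypes in an editable YAML), stepwise
  enrichment, 332-marker screen plates, expression matrices, and pediatric
  cohorts with a planted male-infant cTEC deficit coupled to the mature
  CD4/CD8 ratio.

## Worked example

```python
import thymoflow as tf

freqs = {"cTEC": 0.02, "mTEC": 0.02, "FB": 0.02, "EC": 0.02, "LEC": 0.01,
         "DC": 0.02, "MP": 0.02, "B": 0.02, "other": 0.05,
         "thymocyte_immature": 0.50, "thymocyte_CD4SP": 0.20,
         "thymocyte_CD8SP": 0.10}
table, truth = tf.simulate_sample(tf.build_sample_spec(freqs, 100_000, seed=1))

assignment, stats = tf.apply_gating(tf.transform_events(table),
                                    tf.build_thymic_gating_tree())
print(stats.table[["count", "freq_of_total"]].loc[["TEC", "cTEC", "mTEC"]])
report = tf.evaluate_gating(assignment, truth, tf.thymic_label_map())
print(report.per_population[["precision", "recall", "f1"]].round(3))
```

prints (seed 1):

```
            count  freq_of_total
population
TEC          3900        0.03900
cTEC         1976        0.01976
mTEC         1924        0.01924
```

and per-population F1 between 0.987 and 1.000. The TEC gate holds 3.90% of
events against a planted 4% (cTEC 1.98% / mTEC 1.92% vs 2%/2%): the
automatically placed valley thresholds recover the planted composition to
within counting noise, and the small F1 shortfalls are the expected
tail-overlap of log-normal populations at the default 0.4 log-SD.

The same pipeline runs from the shell:

```sh
thymoflow simulate sample --n-events 100000 --seed 1 --out demo
thymoflow gate --in demo.csv --truth demo.labels.csv --out stats.tsv
thymoflow simulate cohort --n-donors 31 --seed 1 --out cohort/
thymoflow quantify --cohort-dir cohort/ --out cohort.tsv
```

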