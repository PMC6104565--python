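# dbdr — pathway-deregulation-driven drug repurposing

`dbdr` implements a database-driven drug-repurposing pipeline for tumor
subtypes, built around per-sample **pathway deregulation scores** computed
with principal curves. It is aimed at computational biologists who want to
go from gene-expression cohorts (e.g., breast-cancer microarray and RNA-seq
studies with PAM50 subtype labels) to ranked, druggable, differentially
expressed pathway targets — and, per patient, to a conflict-screened list
of approved drugs expected to push deregulated targets back toward their
normal expression level.

Because the real cohorts such a study uses are access-controlled, the
package ships a first-class synthetic-data module that emulates their
statistical structure (two platforms measuring one population, planted
deregulated pathways, a sparse drug–target table), so every stage is
testable against planted ground truth.

## The method

**Pathway Deregulation Score (PDS).** For a pathway *P* with member genes
*g₁…gₘ* and a cohort of tumor and control samples, each gene is
standardized by its control mean and SD, the samples (as points in the
standardized gene space) are reduced by PCA to the fewest components
explaining ≥ 85% of variance (max 10), and a one-dimensional **principal
curve** *f(λ)* is fitted through the cloud by the Hastie–Stuetzle
iteration: initialize with the first principal component, then alternate
(i) projecting each sample to its nearest point on the current polyline
and (ii) smoothing each coordinate against arc-length λ with a
local-linear scatterplot smoother. The curve is oriented so the median
control sits at the low end, and

PDS(sample) = (λ(sample) − min λ) / (max λ − min λ) ∈ [0, 1]

measures how far along the "disease trajectory" a sample lies.

**Subtype ranking and cross-platform consensus.** PDS rows are z-scored
across samples (**PDSz**), each (subtype, platform) run is summarized by
the median PDSz over the subtype's tumors, and the top-*k* pathways of the
two platforms are intersected into the subtype's consensus deregulated
set. Hierarchical clustering (correlation distance, average linkage) of
the median-PDSz profiles checks that profiles group by biology, not by
platform.

**Differential expression.** Per gene, a Welch two-sample *t* on log2
values (subtype vs controls) with Benjamini–Hochberg adjustment; a gene is
called up/down when |log2FC| > 1 and adjusted *p* < 0.001.

**Drug effect classification.** Each drug–target claim is mapped to an
interaction direction (inhibitor/antagonist/blocker/… → inhibitory;
inducer/activator/agonist/… → activating; anything else → other) and
combined with the target's DE status:

| DE status | inhibitory | activating | other |
|-----------|------------|-----------|-------|
| up   | **Homeostasis** | Anti-homeostasis | Undetermined |
| down | Anti-homeostasis | **Homeostasis** | Undetermined |

Homeostasis drugs push a deregulated target back toward control levels;
they are the recommendable ones.

**Per-patient recommendation.** A patient's pathways with PDS ≥ 0.45
(configurable) are mapped to their homeostasis drugs; drug pairs with a
known drug–drug interaction are resolved by dropping the drug whose best
supporting pathway has the lower PDS.

## Worked example

Two basal-subtype patient profiles (pathway → PDS, with their documented
homeostasis drug options) are bundled in `dbdr.examples`:

```python
from dbdr.examples import basal_prioritization_table, empty_ddi, patient_profile
from dbdr.prioritize import classify_effect, classify_interaction_direction
from dbdr.recommend import recommend_drugs

direction = classify_interaction_direction("Inhibitor")
print("SQLE (log2FC +2.703) + Inhibitor ->", classify_effect("up", direction))

rec = recommend_drugs(patient_profile("MB.3058"), basal_prioritization_table(), empty_ddi())
for pathway, pds in rec.selected:
    print(f"  {pathway}: PDS {pds:.3f}")
print("recommended drugs:", ", ".join(sorted(rec.drug_set)))
```

prints

```
SQLE (log2FC +2.703) + Inhibitor -> Homeostasis
  Steroid biosynthesis: PDS 0.937
  Sphingolipid metabolism: PDS 0.628
  Pyrimidine metabolism: PDS 0.466
recommended drugs: CAPECITABINE, PEMETREXED, SK1-I, TERBINAFINE
```

SQLE is overexpressed (log2FC 2.703) and terbinafine inhibits it, so the
interaction is homeostatic; apoptosis, oocyte meiosis, and cell cycle fall
below the 0.45 PDS threshold for this patient, so their drugs (alvocidib,
paclitaxel, alisertib, dinaciclib) are not recommended; three further
pathways are deregulated but carry no druggable DE target.

## The analysis pipeline

The numbered drivers under `analysis/` run the full study on synthetic
data and write their tables under `results/` (large intermediates go to
`scratch/`):

1. `01_simulate_cohorts.py` — dual-platform cohort (4 subtypes + controls,
   20 pathways, 3 planted per subtype at 1.5 control-SD) and drug tables
2. `02_score_pathway_deregulation.py` — PDS matrices per (subtype, platform)
3. `03_rank_and_consensus.py` — PDSz medians, top-10 lists, cross-platform
   consensus, profile clustering
4. `04_differential_expression.py` — Welch/BH DE per subtype
5. `05_prioritize_drugs.py` — prioritization database, target counts,
   tripartite pathway–gene–drug network
6. `06_patient_recommendations.py` — case-study and simulated patients
7. `07_calibration_studies.py` — multi-seed recovery and calibration

The same stages are available as a CLI (`dbdr simulate|pds|rank|de|
prioritize|recommend|run-all`, each with `--seed`, `--config`,
`--out-dir`).

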