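# secep

Secretome-to-transcriptome ("secreto-transcriptomic") discovery of
prognostic biomarker panels for breast cancer, as a tested, reusable
pipeline.

Breast tumors are routinely classified into the PAM50 molecular subtypes
(Basal-like, Luminal A/B, Her2-enriched, Normal-like), but patients within
a single subtype still have very different outcomes. Proteins that tumor
cells secrete into extracellular space are attractive liquid-biopsy
markers — they are measurable in blood — but secretome screens alone say
nothing about patient outcomes. This package implements the integrated
approach: call proteins with **subtype-specific secretion** from label-free
quantitative (LFQ) proteomics of cell-line conditioned media, keep the
genes whose **mRNA is significantly over-expressed in patients of the same
subtype** (Secretion-Correlated mRNA Expression Pattern, *SeCEP* genes),
and then exhaustively screen **combinations of up to five SeCEP genes** for
patient subgroups with jointly over-expressed mRNA and significantly worse
survival in two independent cohorts.

## Method at a glance

1. **Secretion calling** (`secep.secretome`). Log2 LFQ intensities are
   row z-scored (population σ); each protein's per-cell-line mean z
   profile is matched by Pearson correlation (default r ≥ 0.8) against
   reference profiles (basal-up/-down, luminal-up/-down, plus single-line
   variants); candidate patterns are validated by one-way ANOVA across
   cell lines (p < 0.05, technical replicates averaged into biological
   replicates). Ward/euclidean clustering (ward.D2 convention) provides
   heatmap row ordering.
2. **SeCEP classification** (`secep.classify`). Per gene, a two-sided
   Mann-Whitney-Wilcoxon test compares mRNA z-scores of Basal vs
   Luminal A/B patients (exact enumeration for group sizes ≤ 7,
   tie-corrected normal approximation otherwise). P-values are
   Benjamini-Hochberg adjusted over **every** gene measured in the cohort.
   A gene is basal-SeCEP iff adjusted p < 0.05, its median z is higher
   among Basal patients, and (concordance) its protein showed *increased*
   basal secretion; symmetrically for luminal. The working set is the
   intersection across cohorts.
3. **Combination screen** (`secep.combos`). For each gene set
   G ⊆ SeCEP, |G| ≤ 5, patients of the analysis population are *altered*
   iff z<sub>g</sub> > median(z<sub>g</sub>) for **all** g ∈ G. A
   combination passes a cohort when the altered fraction is ≥ 8% (strictly
   > 10% for the relapse-endpoint variant), the two-group log-rank
   p < 0.05, and the Cox hazard-ratio lower 95% Wald bound exceeds 1
   (HR = e<sup>β̂</sup>, single binary covariate, Efron ties). A
   combination is reported only if it passes **both** the discovery and
   the validation cohort — replication is the error control.
4. **Survival core** (`secep.survival`). Kaplan-Meier, log-rank and the
   binary-covariate Cox fit are lean array implementations (the screen
   runs them for millions of splits); they are cross-validated against
   `lifelines` in the test suite.
5. **Synthetic data** (`secep.simulate`). A seeded generator produces LFQ
   matrices with planted subtype-specific secretion and patient cohort
   pairs with planted differential genes, a latent co-overexpressing
   high-risk subgroup, and exponential survival coupled to that subgroup
   through a hazard ratio — so every stage is testable end to end with
   known ground truth.

## Worked example

Generate a synthetic study in which genes G001–G004 define a planted
high-risk subgroup (20% of Basal patients, hazard ratio 4), then run the
full pipeline:

```bash
python - <<'PY'
from secep.simulate import SimConfig, PlantedCombo, write_fixture_bundle
cfg = SimConfig(seed=42, n_proteins=120, n_planted_secretion=12,
                n_genes=200, n_planted_diff_genes=12, diff_shift=1.5,
                n_patients_by_subtype={"Basal": 150, "LumA": 100, "LumB": 100})
cfg.planted_combos = (PlantedCombo(tuple(cfg.gene_ids()[:4]),
                                   fraction=0.2, hazard_ratio=4.0),)
write_fixture_bundle(cfg, "bundle")
PY
secep run --bundle bundle --out run --max-k 4
# secretion calls: 13  SeCEP genes: 12  passing combos: 87
secep km-export --cohort discovery=bundle/expr_discovery.tsv,bundle/clinical_discovery.tsv \
    --genes G001+G002+G003+G004 --scope Basal --out km.tsv
head -5 km.tsv
# genes: G001+G002+G003+G004
# cohort: discovery endpoint: OS scope: Basal
# N_altered=32 NE_altered=31
# N_not_altered=118 NE_not_altered=74
# logrank_p=2.32423e-16 HR=5.60941 CI=[3.55073, 8.86172]
```

Reading this output: of 150 Basal patients in the discovery cohort, 32
(21%) jointly over-express all four genes ("altered", N/NE = patients /
events); their survival separates from the remaining 118 patients at
log-rank p ≈ 2×10⁻¹⁶ with hazard ratio 5.6 (95% CI 3.6–8.9) — the
planted subgroup, recovered from the LFQ matrix onward. The planted
combination also passes the independent validation cohort, so it appears
among the `passes = True` rows of `run/screen_results.tsv`.

The same stages are available individually (`secep secretome`,
`secep classify`, `secep screen`, `secep specificity`) and as library
functions; `run/manifest.json` records config, seed, input digests and
timings for every run.

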