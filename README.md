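# her2het

Quantitative analysis of intratumor HER2 (*ERBB2*) amplification
heterogeneity and treatment response in HER2-positive breast cancer, built
for neoadjuvant paired-biopsy study designs: single-cell FISH heterogeneity
quantification, paired-biopsy RNA-seq distance analysis, dual-marker
immunofluorescence exclusivity scoring, and hotspot-mutation screening —
plus a synthetic-cohort generator with known ground truth so the whole
pipeline is testable without any patient data.

## Who this is for

Translational researchers analyzing dual-probe *ERBB2*/CEP17 FISH counts,
bulk RNA-seq of pretreatment/posttreatment biopsies, per-cell
immunofluorescence intensities, or tabulated allele counts from trials of
HER2-targeted therapy, and methodologists who need a reproducible,
ground-truthed testbed for these analyses.

## The quantities at the core

**Per-cell amplification call.** A tumor cell with *ERBB2* count *h* and
CEP17 count *c* is amplified iff *h*/*c* ≥ 2 or *h* ≥ 6 (ASCO/CAP-style
disjunction; with *c* = 0 the copy-number arm alone decides).

**Heterogeneity (HET) class.** With amplified-cell fraction *f* over all
counted cells of a patient: HET iff 0.05 < *f* < 0.50 (strict); *f* ≥ 0.50
is non-heterogeneous amplified; *f* ≤ 0.05 is non-amplified.

**Shannon equitability over copy-number species.** Each distinct tuple
(*h*, *c*) is a species with frequency *p* = count/total cells. The Shannon
index is H = −Σ *p* ln *p* and equitability is E = H / ln N with N the
total cell count (primary; the Pielou normalization H / ln S over S species
is available via `denominator="species"` and both are always reported).
E ∈ [0, 1]; a clonally uniform tumor has E = 0.

**Transcriptomic distance.** Raw counts are filtered of all-zero genes,
TMM-normalized (Robinson–Oshlack trimmed mean of M-values, matching
edgeR to ≈1e-12), converted to log2(CPM + 1), and QC'd by removing samples
whose PC2 score lies > 5 SD from the cohort mean. Treatment response per
patient is the Euclidean distance between the mean of the (up to two)
pretreatment biopsies and the residual-tumor sample; the lowest quartile of
distances are "weak" transcriptomic responders.

**Hotspot screen.** Allele counts at *PIK3CA* (N345, C420, E542, E545,
H1047) and *ERBB2* (L755, V777) codons are called mutant at depth ≥ 10,
alt ≥ 3, VAF ≥ 0.05 (all configurable); sites without coverage are excluded
from denominators.

## Worked example

Generate a synthetic cohort emulating a 129-patient neoadjuvant study
(64 non-HET/pCR, 51 non-HET/no-pCR, 14 HET/no-pCR patients; 6 tumor areas ×
75 cells per patient; clone-selective treatment for no-pCR patients) and
profile it:

```bash
her2het simulate fish --seed 7 --out sim
her2het fish-het --cells sim/fish_cells.tsv --out out
```

which prints

```
# Cohort analysis report

- config hash: `4bb0d868d952`
- seed: 0
- skipped stages: transcriptome, marker_if, hotspot

## ERBB2 FISH heterogeneity
- patients profiled: 129
- pretreatment class counts: {'NON_HET_AMP': 115, 'HET': 14}
- posttreatment class counts: {'NON_HET_AMP': 46, 'HET': 19}
- mean pre-to-post equitability change: 0.0279
```

All 14 designed-HET patients are detected as HET before treatment; after
clone-selective killing some near-boundary tumors shift class, and mean
equitability rises (+0.028) — residual tumors are more heterogeneous.
`out/fish_profiles.tsv` holds the per-patient profiles:

```
patient_id    timepoint  fraction_amplified  shannon_h  equitability  het_class
het_nopcr_001 post       0.328076            3.678410   0.638735      HET
het_nopcr_001 pre        0.411111            3.899248   0.638253      HET
het_nopcr_002 post       0.200000            3.364065   0.580102      HET
het_nopcr_002 pre        0.277778            3.580997   0.586160      HET
```

The other stages work the same way (`simulate expression` +
`rnaseq-distance`, `simulate if` + `if-exclusivity`, `simulate hotspot` +
`hotspot`), and `run-all` executes every stage for which inputs exist,
writing a combined `run_summary.json` and `report.md`. Exit codes: 0 ok,
2 validation failure, 3 stage failure.

## Layout

- `her2het.fish` — FISH heterogeneity profiles, classification, transitions
- `her2het.rnaseq` — TMM/log-CPM normalization, PCA QC, distances, responder
  split, association tests
- `her2het.markers` — HER2/CK5 dichotomization, Fisher exact, correlation
- `her2het.hotspot` — variant calls from allele counts, cohort summary
- `her2het.simulate` — synthetic cohorts with ground truth
- `her2het.io`, `her2het.pipeline`, `her2het.cli` — tabular I/O +
  validation, stage orchestration, command line

See `docs/methods.md` for the statistical model, parameter defaults, and
the design decisions behind them.
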