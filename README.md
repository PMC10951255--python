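# msihetero

Metabolic-heterogeneity analysis for imaging mass spectrometry (MSI)
cohorts: segment pooled pixel spectra into metabolic subpopulations,
quantify per-patient heterogeneity, link subpopulations to survival, and
characterise them by differential metabolites, adduct annotation, pathway
enrichment and correlation networks. A synthetic-cohort generator with
planted ground truth makes every stage testable end to end.

## Pipeline

1. **simulate** — synthetic cohorts: per-patient pixel grids composed of
   spatially coherent (Voronoi-patch) subpopulations with distinct
   multiplicative metabolite signatures; exponential survival whose hazard
   is scaled when a designated risk subpopulation is sufficiently present;
   response labels derived from survival at a cutoff (default 13.8 months).
2. **preprocess** — per-pixel TIC normalisation, peak selection (local
   maxima of the cohort-mean spectrum ranked by mean intensity),
   edge-preserving per-ion-image median denoising.
3. **segment** — K-means under correlation distance (1 − Pearson r) on
   pixels pooled across patients, K = 2..10, best of `n_init` seeded
   restarts; labels renumbered by descending cluster size.
4. **diversity** — Simpson's index `D = 1 − Σ p_i²` per patient plus a
   cutoff-optimised high/low split (minimal log-rank p with an explicit
   selection-bias caveat in the output).
5. **survival-grid** — cluster-presence thresholding (strict `share > t`,
   t = 4–40%), one joint Cox model (Breslow ties, Newton iterations) per
   (K, threshold) cell, AIC model selection over the grid; Kaplan–Meier
   curves; pairwise subpopulation comparisons via a count-process stacking
   with robust patient-clustered variance (Wald test); Spearman/Fisher
   response associations.
6. **differential** — pixel-wise Mann–Whitney U per channel
   (subpopulation vs pooled rest; exact p for small tie-free samples),
   Benjamini–Hochberg adjustment per subpopulation, fold-change filter
   (1.5); Fligner–Killeen variance comparison.
7. **annotate / enrich / network** — negative-mode adducts (M−H, M−H₂O−H,
   M+K−2H, M+Na−2H, M+Cl; shifts validated against atomic masses at
   import), ppm-tolerance annotation against a metabolite mass table,
   hypergeometric pathway over-representation with BH q-values, and
   Spearman correlation networks (edges at adjusted p < 0.05, weight |rho|).

## CLI

```sh
msihetero run --config config.yaml --out run/ --seed 7       # full pipeline
msihetero simulate --out sim/ --seed 7
msihetero preprocess --in sim/pixels.tsv --n-peaks 150 --out cube.tsv
msihetero segment --cube cube.tsv --k-min 2 --k-max 10 --seed 7 --out seg/
msihetero diversity --labels seg/labels.tsv --k 9 --surv sim/meta.tsv --out div/
msihetero survival-grid --labels seg/labels.tsv --surv sim/meta.tsv --out surv/
msihetero differential --cube cube.tsv --labels seg/labels.tsv --k 9 --out diff/
msihetero annotate --peaks cube_peaks.tsv --tol-ppm 4
msihetero enrich --query query.txt --gmt pathways.gmt
msihetero network --cube cube.tsv --labels seg/labels.tsv --k 9 --subpop 9
```

`run` writes plain-text TSV/JSON outputs plus `manifest.json` (config
snapshot, package version, SHA-256 per output, analysis caveats); re-runs
with unchanged inputs skip cached stages. Exit codes: 0 ok, 2 config
error, 3 stage error. Example config:

```yaml
cohort:
  n_patients: 45
  grid_shape: [20, 20]
  n_channels: 300
  k_true: 4
n_peaks: 150
k_min: 2
k_max: 10
seed: 7
```

## Caveats baked into the outputs

- The optimised diversity cutoff minimises the log-rank p; the reported p
  is selection-biased and flagged as such.
- Pixel-wise differential tests are pseudoreplicated across pixels of the
  same patient; a `patient_median` aggregation mode is provided.
- Survival p-values are not adjusted for multiplicity.
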