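# dtiabv

Combined DTI + atlas-based volumetry group analysis for the
bvFTD / ALS-FTD continuum, reimplemented as a tested, reusable pipeline and
exercised end to end on synthetic phantom cohorts.

Neuroimaging studies of behavioral-variant frontotemporal dementia (bvFTD)
and ALS with frontotemporal dementia (ALS-FTD) typically combine four
analyses on the same cohort:

* **WBSS** — whole-brain voxel-wise statistics on smoothed, age-corrected,
  site-harmonized fractional-anisotropy (FA) maps: Welch's t per voxel
  (FA > 0.2 analysis mask), Benjamini–Hochberg FDR at q = 0.05, and a
  256 mm³ cluster-extent threshold;
* **TFAS** — tract-of-interest analysis: deterministic seed-to-target
  tractography on an averaged control tensor dataset, then per-subject
  arithmetic mean FA over each tract's voxels, compared between groups with
  pooled-SD z-scores, z = (m₁−m₂)/s_p,
  s_p = √(((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2));
* **ABV** — atlas-based volumetry: structure volumes by integrating tissue
  probability maps under atlas masks, standardized to the mean control
  intracranial volume, tested with `volume ~ group + age` models, and
  longitudinal percent change 100·(FU−BL)/BL of the group means;
* **Random forest** — classification of subjects from TOI-FA + SOI-volume
  features (100 trees, Gini, depth 4, sqrt feature subsampling, stratified
  80/20 split with 5-fold CV) with Gini-importance ranking and iterative
  feature elimination.

Because the underlying patient MRI is not public, the package ships a
first-class synthetic-data module (`dtiabv.phantom`) that generates DWI
volumes, tissue maps, atlas labels and cohort tables with known injected
group, site, age, severity and longitudinal effects — so every stage is
testable against ground truth.  See `docs/methods.md` for the models and
all numerical choices.

## Worked example: longitudinal volumetry

The bundled worked-example table (`dtiabv.datasets.LONGITUDINAL_VOLUMES`)
holds group-mean ICV-standardized volumes for 19 bvFTD patients at baseline
and 1-year follow-up alongside 39 controls.  Percent change of the group
means:

```python
>>> from dtiabv.datasets import LONGITUDINAL_VOLUMES as T
>>> from dtiabv.abv import percent_change
>>> for s in ("Cerebrum GM", "Cerebrum WM", "Caudate R", "Putamen L"):
...     row = T.loc[s]
...     print(f"{s}: {percent_change(row.baseline_mean, row.followup_mean):+.2f} %")
Cerebrum GM: -4.74 %
Cerebrum WM: +0.77 %
Caudate R: -11.76 %
Putamen L: -16.00 %
```

Cortical gray matter shrinks by ~4.7% in one year while cerebral white
matter volume is essentially flat (+0.77%), and the caudate and putamen
lose volume fastest — the signed convention keeps increases positive.

## Running the pipeline

```bash
dtiabv run --out runs/demo --seed 3
dtiabv report --run-dir runs/demo
```

runs the full chain (phantom cohort → tensor fits → smoothing / age
correction / harmonization → WBSS + TOI + ABV → random forest) on the
default demo cohort and writes TSV tables (cluster reports, TFAS group
statistics, SOI volumes and statistics, longitudinal percent change,
clinical correlations), NIfTI maps, per-task classification JSON, and a
SHA-256 provenance manifest.  Individual stages are available as
subcommands (`simulate`, `wbss`, `toi`, `abv`, `classify`, ...); a YAML
config passed via `--config` overrides any threshold (smoothing FWHM,
FA floor, q, cluster extent, forest hyperparameters).

A typical TFAS line from the demo run (n = 16/arm):

```
uncinate_L  bvFTD vs control  mean 0.721 ± 0.047 vs 0.804 ± 0.021  z=-2.29  q<0.01
```

i.e. the injected 12% uncinate FA reduction appears as a pooled-SD z of
about −2.3, the regime such cohorts report.

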