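# polarperf

Normal-database analysis of myocardial perfusion polar maps ("bull's eye"
images). The package builds pixel-wise normal stress databases from 65×65
count grids, compares groups with permutation-corrected pixel-wise t-tests
(max-|t| thresholding, strong family-wise error control), and summarizes
differences per anatomical segment on a −100..100 normalized count scale.
A synthetic cohort generator emulates paired NC/AC (non-corrected /
attenuation-corrected) stress maps with gender- and BMI-dependent
attenuation deficits, so the entire pipeline is testable without clinical
data.

## Modules

| Module | Purpose |
| --- | --- |
| `polarperf.geometry` | 65×65 disc geometry, radial/angular coordinates, apical + four-quadrant + basal-ring segment partition |
| `polarperf.synthetic` | paired NC/AC cohort generator; calibration of deficit amplitudes to segmental targets by root-finding on the noise-free forward model |
| `polarperf.normalization` | per-map scaling so the median of the brightest 10% of valid pixels equals 100 |
| `polarperf.database` | pixel-wise mean/SD normal databases per stratum |
| `polarperf.stats` | pooled-variance two-sample and paired t-maps; max-\|t\| permutation threshold (label reshuffle / sign flips, exhaustive when feasible) |
| `polarperf.segmental` | per-segment mean difference ± 2 SD tables |
| `polarperf.io` | CSV/JSON round-trip-safe readers and writers |
| `polarperf.cli`, `polarperf.viz` | `polarperf` command line, bull's eye rendering with green/yellow significance overlays |
| `polarperf.replication` | end-to-end drivers: null FWER simulation and effect-size recovery |

## Command line

Simulate a cohort and run the full set of group comparisons:

```bash
polarperf simulate --config examples/config.yaml --out scratch/cohort --seed 1
polarperf -v run-study --cohort scratch/cohort/manifest.csv \
    --alpha 0.001 --permutations 500 --seed 1 --out scratch/study
```

`run-study` normalizes the cohort, builds the four gender×correction normal
databases, executes all 18 protocol comparisons (gender and correction
contrasts in each BMI stratum, plus weight contrasts overall and within each
gender), and writes per-comparison t-maps, signed significance masks,
thresholds, a segment table, and rendered bull's eye figures.

Note that at `--alpha 0.001` the permutation scheme needs at least 999
permutations to have resolution (the implementation warns otherwise, and no
pixel can reach significance below that resolution).

## Conventions

- Orientation: anterior wall at the top of the image, inferior at the bottom,
  septal left, lateral right; angles counterclockwise with 90° at the top.
- Gender contrasts are reported as men minus women; correction contrasts as
  NC minus AC.
- Maps store NaN outside the circular validity disc; counts are non-negative
  inside it.
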