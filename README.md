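# focimix

Quantification of inter-chromosomal DNA mixing and DNA-focus mobility from
dual-channel 3-D confocal image stacks.

## The problem

Interphase chromosomes occupy discrete chromosome territories (CTs) built
from ~0.4 µm DNA foci.  When the DNA of neighboring territories is labeled in
two colors, the degree to which the two labels share nuclear space measures
how much chromatin from different chromosomes actually mixes.  `focimix`
implements the full voxel-level analysis for this question:

* **Preprocessing** — 3×3×3 median filtering (removes isolated
  maximal-intensity "electronic" voxels), physical-scale Gaussian filtering,
  and the empirical background rule that sets each channel's threshold equal
  to the standard deviation of its voxel-intensity distribution.
* **Co-localization** — a voxel is co-localized when it is strictly above
  threshold in *both* channels.  The package reports the Pearson coefficient
  (PC ∈ [−1, 1], voxel-wise intensity correlation), the Mander pair
  (M_green, M_red ∈ [0, 1], the fraction of each channel's integrated
  intensity in voxels where the other channel is above threshold), the
  co-localized volume (voxel count × voxel volume, µm³), per-channel
  occupancies, and the same metrics inside a fixed-volume region of interest
  (default 65 µm³) placed by exhaustive search to maximize the co-localized
  voxel count — an upper bound on local mixing.
* **Tracking** — LoG foci detection with intensity-weighted mass centers,
  translation registration on the spatially stable mid/late-replicating
  (heterochromatic) foci, unambiguous nearest-neighbor linking, and the
  mobility statistic: the change in separation of neighboring same-class
  focus pairs, in µm per 15 min, pooled as G/G (early) and R/R (late) pairs.
* **Statistics** — Table-style mean ± SD summaries, two-sided Mann-Whitney
  (exact by enumeration for small samples) and Kruskal-Wallis comparisons
  across conditions.
* **Synthetic nuclei** — a generator producing two-channel ellipsoidal
  nuclei (~1950 µm³ at 0.8 × 0.8 × 0.34 µm voxels) with Voronoi territories,
  clustered sub-voxel foci, a ground-truth mixing fraction `f_mix`, a
  TSA-analog `dispersion_factor`, and 4-D time lapses with class-dependent
  focus mobility.  Every stack comes with its ground truth, so the whole
  pipeline is validated end to end.

## Worked example

```bash
focimix demo --seed 0 --n 10 --out demo_out
```

generates 10 baseline nuclei and 10 dispersion-analog (TSA-like,
`dispersion_factor 2.0`) nuclei, analyzes each with the default pipeline
(median 3×3×3 filter, SD-rule thresholds over the nuclear mask), and writes
per-condition summaries plus the nonparametric comparison.  Representative
output (`summary_baseline_nucleus.csv` vs `summary_dispersed_nucleus.csv`):

| metric | baseline | dispersed |
| --- | --- | --- |
| co-localized volume (µm³) | 0.96 ± 0.89 | 51.1 ± 20.3 |
| % co-localized | 0.052 ± 0.048 | 3.10 ± 1.21 |
| % green / % red | 11.4 / 10.9 | 33.6 / 29.3 |
| Pearson coefficient | −0.118 ± 0.010 | −0.342 ± 0.067 |
| M green / M red | 0.035 / 0.037 | 0.131 / 0.150 |

Baseline nuclei mix in well under 1% of their volume, with a negative
whole-nucleus PC — segregated territories anticorrelate the two labels —
while dispersing the foci raises the co-localized volume by more than an
order of magnitude.  The accompanying `comparison.csv` bears this out
statistically (co-localized volume: Mann-Whitney U = 0,
p ≈ 1.8 × 10⁻⁴; Kruskal-Wallis H ≈ 14.3, p ≈ 1.5 × 10⁻⁴).

Library use mirrors the CLI:

```python
from focimix import NucleusSpec, generate_nucleus, coloc_report

stack, truth = generate_nucleus(NucleusSpec(seed=0, f_mix=0.25))
nucleus_row, roi_row = coloc_report(stack)
print(nucleus_row.pct_coloc, truth.mixing_percent)
```

Other subcommands: `focimix simulate` (stacks + ground truth to TIFF/CSV),
`focimix coloc` (analyze stacks to a results CSV), `focimix track`
(time-lapse detection, registration, linking, mobility), `focimix report`
(condition comparison over result CSVs).

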