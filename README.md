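# dyssync

Left-ventricular (LV) mechanical dyssynchrony from cine cardiac MR, built
around the **systolic dyssynchrony index (SDI)** and its use for predicting
response to cardiac resynchronization therapy (CRT).

About a third of CRT recipients do not improve. One proposed selection
marker is mechanical (rather than electrical) dyssynchrony: if the 16
standard AHA segments of the LV reach their minimum regional cavity volume
at very different times, the ventricle contracts inefficiently and has
something to gain from resynchronization. The SDI condenses this into one
number:

```
SDI = SD(t_peak,1 … t_peak,16) / T_cycle × 100   [% of cardiac cycle]
```

where `t_peak,s` is segment *s*'s time to peak — minimum regional volume,
maximum wall thickness, or peak strain, depending on the mechanics measure —
and the normalization by the cycle length makes the index comparable across
heart rates. A volume-change SDI **> 9.75%** dichotomizes patients into
likely/unlikely reverse remodellers (≥ 15% reduction in end-systolic volume
after CRT).

No patient data ship with this package. Instead it provides every stage of
the measurement and analysis chain plus a synthetic ground-truth generator,
so the whole pipeline can be validated end to end:

| module | what it does |
|---|---|
| `dyssync.phantom` | analytic truncated-ellipsoid LV with per-segment activation delays (ground-truth deformation and SDI known), SSFP-like and CSPAMM-like (7.7 mm tag) renderers, CRT cohort simulator |
| `dyssync.geometry` | LV shell pair, AHA 16-segment partition, regional cavity volumes (signed-tetrahedron wedges), wall thickness (endo→epi surface distance) |
| `dyssync.registration` | per-slice rigid realignment; serial-propagation cubic B-spline FFD registration of the two channels with border-weighted SSD; quantitative tracking quality (surface distance, Dice) |
| `dyssync.mechanics` | ED-referenced deformation fields, Green–Lagrange strain in radial/circumferential/longitudinal directions, volume/thickness/strain curves, time-to-peak |
| `dyssync.sdi` | the SDI itself and cut-off dichotomization |
| `dyssync.stats` | reverse-remodelling and 2-of-3 clinical response classification, ROC with Youden-optimal cut-off, prevalence ratios via robust Poisson regression, Fisher's exact test, Bland–Altman agreement |
| `dyssync.pipeline` / `dyssync.cli` | end-to-end runs with a checksummed manifest; `dyssync` command-line tool |

## Worked example

```python
import numpy as np
from dyssync.phantom import dyssynchronous_params, generate_phantom
from dyssync.mechanics import volume_curves
from dyssync.sdi import compute_sdi, dichotomize

# LBBB-like phantom: the free wall activates 200 ms late
truth = generate_phantom(dyssynchronous_params(n_phases=30))
print(f"ground-truth SDI: {truth.true_sdi:.2f}%")

curves = volume_curves(truth.geometry_per_phase, cycle_length_ms=1000.0)
result = compute_sdi(curves)
print(f"measured SDI:     {result.sdi:.2f}%  "
      f"({result.n_segments_used} segments)")
print("dyssynchronous at 9.75% cut-off:", bool(dichotomize([result.sdi])[0]))
```

prints

```
ground-truth SDI: 10.00%
measured SDI:     10.00%  (16 segments)
dyssynchronous at 9.75% cut-off: True
```

i.e. the regional volume curves measured from the deforming meshes recover
the analytically known index to about 0.001 percentage points, and the
phantom is (correctly) classified as dyssynchronous.

The same thing end to end from the shell, going through rendered images and
deformable registration instead of the analytic truth:

```bash
dyssync run --seed 1 --out run1                    # registration path
dyssync run --seed 1 --out run2 --skip-registration  # true-field path
dyssync cohort --n-patients 500 --out cohort.csv
dyssync stats --cohort cohort.csv --out stats.json
```

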