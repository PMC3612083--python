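# ibrp

Quantitative image analysis for bead-based protein-interaction assays.

In an imaging beads-retained prey (IBRP) experiment, a GST-tagged bait
protein is immobilized on glutathione-agarose beads and incubated with a
lysate containing a GFP-tagged prey. Prey retained on a bead makes the
bead fluoresce, so the fluorescence of each bead reports how much prey
that bait captured. This package turns such micrographs into per-bead
numbers and condition-level binding statistics:

1. **Preprocess** — Gaussian denoising (radius 1 px) and rolling-ball
   background subtraction (ball radius 400 px).
2. **Segment** — Otsu thresholding, distance-transform watershed to
   split touching beads, then a particle filter: area ≥ 200 px²,
   circularity 0.60–1.00, edge-touching particles excluded.
3. **Measure** — per-bead mean fluorescence, corrected for blank-bead
   autofluorescence and normalized by exposure time
   (`intensity_per_ms`).
4. **Normalize** — the *IBRP affinity* of a condition:
   per-bead `intensity_per_ms / (prey_input_per_ms × bait_input)`,
   where the prey input is the mock-corrected, exposure-normalized
   lysate fluorescence and the bait input is the loaded bait
   concentration. Within a comparison set, relative affinities are
   rescaled so the largest mean is exactly 100.
5. **Compare** — Welch's unequal-variance t-test (two-tailed), fold
   changes, ordinary least-squares linearity checks, and a field SNR
   estimate.

A synthetic scene generator renders bead fields with exact ground truth
(uniform 30 µm beads or peripheral-bright 90 µm beads, illumination
gradients, Gaussian camera noise, touching pairs), so the whole pipeline
is testable without real micrographs.

## Worked example

Simulate two noisy fields of 60 beads, quantify them with the default
parameter profile, and compare the two (identically prepared)
conditions:

```console
$ ibrp simulate --out-dir fields --seed 42 --n-fields 2 --n-beads 60 \
      --noise-sd 50 --touching-fraction 0.2
INFO ibrp: rendered field_000 with 60 beads
INFO ibrp: rendered field_001 with 60 beads
wrote 2 field(s) to fields

$ ibrp quantify --manifest fields/manifest.yaml --out-dir quant
INFO ibrp: field_000: masked=60 size=60 circ=60 edge=60 snr=20.48
INFO ibrp: field_001: masked=60 size=60 circ=60 edge=60 snr=20.30
wrote 120 bead measurements to quant

$ head -6 quant/measurements.csv
condition,bead_id,area_px,circularity,mean_intensity_raw,mean_intensity_corrected,intensity_per_ms
field_000,1,2790,0.885380514,197.554066,197.554066,1.97554066
field_000,2,3655,0.894878623,199.211863,199.211863,1.99211863
field_000,3,2549,0.893518796,197.618494,197.618494,1.97618494
field_000,4,3067,0.890269166,198.179969,198.179969,1.98179969
field_000,5,3549,0.897671374,199.17765,199.17765,1.9917765

$ ibrp affinity --measurements quant/measurements.csv --out-dir aff
wrote affinities for 2 condition(s) to aff

$ cat aff/affinity.csv
condition,affinity_mean,affinity_sd,n,relative_affinity
field_000,1.98969543,0.0136386482,60,99.6542758
field_001,1.99659815,0.0120134317,60,100

$ cat aff/comparisons.csv
condition_a,condition_b,fold_change,t,df,p
field_000,field_001,0.996542758,-2.94183682,116.149978,0.00393945647
```

The beads were rendered with a true mean signal of 200 counts over a
100 ms exposure, i.e. 2.0 counts/ms; the pipeline recovers per-bead
means of ~197–199 (the Gaussian denoise blurs bead rims a few percent
low, a bias that cancels between conditions). With bait and prey inputs
left at their default of 1, the affinity equals the mean
`intensity_per_ms`, and the two fields agree to 0.35%.

`quantify` also writes per-field label maps (`*_labels.tif`), overlay
PNGs with numbered outlines, and `run_log.yaml` recording the config
hash and the per-stage particle counts
(`masked ≥ size ≥ circularity ≥ edge`).

Condition metadata (bait/prey inputs per condition) is supplied to
`ibrp affinity` via `--conditions conditions.csv` with columns
`condition,bait_input,prey_input_per_ms`.

## Python API

```python
from ibrp import SceneSpec, render_scene, quantify_image, PipelineConfig

img, truth = render_scene(SceneSpec(n_beads=100, noise_sd=50.0,
                                    background_level=300.0, seed=1))
result = quantify_image(img, PipelineConfig())
print(len(result.measurements), "beads,", f"SNR {result.snr:.1f}")
```

`PipelineConfig()` is the default profile described above; any field
can be overridden or loaded from YAML (`PipelineConfig.from_yaml`).

## Reproduction

All randomness derives from explicit seeds; identical seeds give
byte-identical CSV outputs.

```bash
pip install --no-build-isolation -e .[test]
python -m pytest tests -q            # full suite, ~1 minute on 1 CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per release criterion
(mask recovery ≥ 95% at SNR 4 with zero false particles, filter-reason
attribution, background-subtraction oracle equivalence within 1 count,
watershed splitting, affinity recovery across a 3 bait × 4 prey grid
with CV ≤ 20% and per-bait R² ≥ 0.98, exposure-invariance laws,
statistics oracles at 1e-10, and CSV determinism).
`scripts/acceptance.py` recomputes the same quantities end to end and
writes them to the given JSON path; with `--seed 1` the run above
reported, among others, mask recovery 0.998 over 1170 beads with zero
false particles, affinity-grid CV 0.027, and minimum per-bait R²
0.9995. See `docs/methods.md` for the underlying models and numerical
choices.
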