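# mfoct

Multi-functional OCT analysis for polarization-resolved cranial imaging,
exercised end-to-end on a synthetic layered-cranium phantom with ground
truth.  The package covers:

- **phantom** — synthetic dual-channel complex tomogram series of a
  three-layer cranium (skin / skull / brain) with pigment spots, a pigmented
  skull base, a birefringent skull plate with non-birefringent suture gaps,
  fully developed speckle, and planted vasculature (including transcranial
  vessels routed through the sutures), plus exported ground truth.
- **signals** — PS-OCT contrast volumes: intensity (linear/dB), accumulative
  retardation (`arctan(|V|/|H|)`, degrees), and DOPU (windowed Stokes-vector
  averaging).
- **angiography** — split-spectrum amplitude-decorrelation angiography
  (SSADA): synthetic-spectrum Gaussian band splitting and repeat-pair
  amplitude decorrelation with an intensity-floor mask.
- **segmentation** — six-step DOPU/intensity threshold-mask organ
  segmentation producing the Air–Skin, Skin–Skull and Skull–Brain boundaries
  (morphological opening against pigment spots, per-B-scan robust smoothing
  splines), layer masks, and the cranial midline.
- **projections** — DOPU-Intensity fused B-scans, per-layer mean
  intensity/retardation projections, retardation grayscale images,
  extra/intracranial OCTA split with red/green merge (yellow = skull
  vessels), and depth-color-encoded OCTA.
- **quantify** — transcranial-channel detection (intersection of upper/lower
  half-skull angiograms), suture mapping (high intensity + low retardation),
  channel–suture co-localization, and injury-recovery metrics (vessel
  density, avascular area) over a time series.
- **io / config / pipeline / cli** — HDF5 + paired-TIFF containers, a single
  JSON-serializable configuration with one rng seed feeding per-stage
  substreams, and a subcommand CLI.

## Tests

```sh
python -m pytest -q tests/
```

Unit and property tests run on reduced grids in seconds;
`tests/test_acceptance.py` runs the acceptance criteria at full scale
(20 seeded phantoms on the default 256×192×96 grid, 20-seed channel
detection Monte-Carlo, …) and takes several minutes.

## CLI

```sh
mfoct all --out out/ --seed 1                  # simulate + full pipeline
mfoct simulate --out sim/ --seed 1             # phantom tomogram + truth
mfoct signals  --in sim/tomogram.h5 --out sig/ # intensity / retardation / DOPU
mfoct angio    --in sim/tomogram.h5 --out sig/ # SSADA angiogram
mfoct segment  --in sig/ --out seg/            # boundaries + layer masks
mfoct project  --in run/ --out proj/           # en-face renderings
mfoct channels --in run/ --out chan/           # transcranial channels
mfoct tbi      --out tbi/ --seed 1             # injury time series metrics
```

All subcommands accept `--config config.json` (schema = `PipelineConfig`;
defaults are used when omitted) and `--seed` to override the config seed.
Exit codes: 0 ok, 2 config error, 3 format error, 4 stage failure.  Running
stages individually on stored intermediates reproduces `mfoct all`
bit-for-bit.

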