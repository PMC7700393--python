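# ciliaquant

Quantification of ciliary beating in high-speed video microscopy (HSVM)
recordings of ciliated epithelium — the functional readout used in
primary ciliary dyskinesia (PCD) diagnostics and in air–liquid interface
(ALI) culture quality control.

Given a grayscale video stack recorded at hundreds of frames per second,
`ciliaquant` computes:

* a **per-block beat-frequency map** — the field of view is tiled into
  square pixel blocks (≥ 4×4 px) and each block's dominant temporal
  frequency is detected by Fourier analysis within a 2–50 Hz band;
* **percent area of ciliary movement** ("cilia coverage") per field of
  view, and its unweighted mean across the fields sampled along a
  culture-insert midline (every 3rd field, up to 16 fields);
* **mean ciliary beat frequency (CBF)** over ≥ 6 regions of interest,
  flagged against the normal ex vivo range of 11–20 Hz (a fully static
  sample reports 0 Hz);
* **trans-epithelial electrical resistance (TEER)** in Ω·cm² from
  triplicate readings, blank-corrected and area-normalised;
* seeded **synthetic beating-epithelium videos** with exact ground truth
  (moving mask, frequency field, metachronal phase gradients, drifting
  particulates) for validating all of the above.

## Method

For block $b$ with pixel time series $x_p(t)$, $t = 0 \dots T-1$,
sampled at rate $f_s$ (Hz), each detrended, Hann-tapered series is
transformed and the one-sided power spectra are averaged over pixels:

$$P_b(f_k) = \frac{1}{|b|} \sum_{p \in b} \frac{c_k}{T}\,\bigl|\mathrm{DFT}[w\,(x_p - \bar x_p)]_k\bigr|^2 ,
\qquad f_k = k\,f_s/T,$$

with $c_k$ the one-sided folding factor. Power — not complex
amplitude — is averaged so that metachronally phase-shifted cilia
reinforce instead of cancelling. The block is *moving* when the peak of
$P_b$ over the inclusive band $[f_{\min}, f_{\max}] = [2, 50]$ Hz
exceeds $k = 8$ times the in-band median power (a robust noise floor);
its CBF is the peak's bin frequency (resolution $f_s/T$; ties break to
the lower bin). Coverage is the percentage of moving blocks; insert
coverage is the unweighted mean over fields of view. TEER is
$(\overline{R}_\text{test} - \overline{R}_\text{blank}) \times A$ for
membrane area $A$ in cm².

See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

Simulate a 4-field insert with 38.9% true cilia coverage beating at
14 Hz (500 fps, 250 frames, noise SD = amplitude/3), then analyse it:

```sh
ciliaquant simulate --out demo/sim --seed 1 --n-fov 4 --coverage 0.389 \
    --freq 14 --patch-shape rect --align 4
ciliaquant analyze demo/sim/fov_*.tif --out demo/maps
ciliaquant coverage-report demo/maps/coverage.csv --out demo/summary.csv
```

which prints

```
wrote 4 field(s) to demo/sim
mean coverage 38.84% over 4 field(s)
mean coverage 38.84% (sd 0.35) over 4 field(s)
```

and writes per-field tables plus a rendered map image per field
(0 Hz → black, ≥ 25 Hz → white). The per-field table shows each field's
block counts and mean beat frequency of the moving area:

```
fov_id,percent_moving,n_blocks_moving,n_blocks_total,mean_moving_freq_hz,excluded
fov_000,39.0625,400,1024,14,False
fov_001,39.16015625,401,1024,14,False
...
```

Every field recovers the simulated 14 Hz beat exactly, and the insert
mean (38.84%) sits within the patch-placement tolerance of the 38.9%
target. The same analysis applied to your own recordings needs only a
multi-page TIFF (or raw binary) plus a `<file>.meta` sidecar giving the
frame rate.

Library use mirrors the CLI:

```python
from ciliaquant import SimScene, simulate_stack, compute_cbf_map, percent_area_moving

stack, truth = simulate_stack(SimScene(seed=1))
result = percent_area_moving(compute_cbf_map(stack))
print(result.percent_moving, truth.realized_coverage * 100)
```

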