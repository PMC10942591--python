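# piezomech

Quantification pipeline for membrane mechanosensing in migrating human
T cells: interference-reflection-microscopy (IRM) membrane-tension
mapping, tension–fluorescence lagged correlation, mean-squared-
displacement motility analysis, front/back polarity metrics, and an
object-randomization colocalization test — each validated against a
built-in synthetic-data generator with known ground truth.

## Who this is for

Labs quantifying how mechanosensitive channels (e.g. Piezo1) couple to
membrane tension in motile immune cells. Raw imaging data for such
studies are rarely deposited, so every analysis stage here ships with a
generative counterpart that produces movies, tracks and puncta fields
with known parameters, letting you verify the estimator before pointing
it at real data.

## The model at the core

IRM encodes the membrane–substrate distance *h* in reflected intensity.
Within the first branch (0 ≤ h ≤ λ/4n ≈ 100 nm),

    I(h) = i_min + (i_max − i_min)/2 · (1 − cos(4π n h / λ)),

which is inverted per pixel to height movies. The temporal fluctuation
spectrum of *h* is fitted with a Helfrich-type model for a confined,
actively driven membrane,

    PSD(f) = (4 η_eff A k_B T / π) ∫_{q_min}^{q_max} dq /
             [ (4 η_eff · 2πf)² + (κq³ + σq + γ/q)² ],

with fluctuation tension σ (reported in pN/µm), effective viscosity
η_eff (Pa·s), confinement γ (N/m³), active temperature A
(dimensionless) and bending rigidity κ fixed at 15 k_BT. Spectra are
estimated both by Welch FFT and by the autoregressive covariance
("pcov") method with the order chosen to best match the FFT estimate.
Each wavenumber relaxes as an Ornstein–Uhlenbeck mode with
τ_q = 4η_eff/E(q) and variance A·k_BT·Δq/(4πE(q)), which is exactly how
the synthetic generator draws height movies.

The remaining stages use the field's standard definitions: time-averaged
MSD per track; F/B ratio and polarity index (A−B)/(A+B) of ellipse
halves split perpendicular to the migration direction (or long axis);
object colocalization as the percentage of query puncta sharing ≥1 pixel
with a reference set, tested against an area-matched uniform
random-placement null with a two-sided Mann–Whitney U.

## Worked example

```bash
piezomech demo --seed 3 --out demo_out
```

runs every stage on synthetic data and prints (abridged):

```json
{
  "tension_trajectory": {
    "baseline_median_pn_um": 51.17,
    "post_step_significant": [true, true, true]
  },
  "tension_correlation": {"pearson_r": 0.959, "n_pairs": 19},
  "msd": {"D_true_um2_s": 0.5, "D_fit_um2_s": 0.492},
  "polarity": {"expected_fb": 3.0, "mean_fb": 2.962, "n_cells": 4},
  "coloc": {"n_observations": 52, "p_value": 1.5e-18}
}
```

Reading: ROIs simulated at σ = 50 pN/µm fit back to a median of
51.2 pN/µm; after an emulated chemokine step (σ doubled) every post-
baseline time point is flagged significant versus baseline
(Mann–Whitney U, Bonferroni). Brownian tracks at D = 0.5 µm²/s fit to
0.492; cells drawn with 75% of intensity in the leading half measure
F/B ≈ 3; and 52 cell-time-point observations (13 cells × 4 time points)
with 60% built-in colocalization decisively reject the random-placement
null.

Library use mirrors the CLI:

```python
from piezomech import fluctsim, irm
from piezomech.model import DEFAULT_PARAMS, DEFAULT_GRID

hm = fluctsim.simulate_height_series(DEFAULT_PARAMS, DEFAULT_GRID,
                                     n_pixels=(30, 16), seed=1)
spec = irm.tile_spectrum(hm.heights[:, 0, :].T, DEFAULT_GRID.fs)
fit = irm.fit_helfrich(spec, grid=DEFAULT_GRID, fix={"A": 1.0},
                       exposure=1.0)
print(fit.params.sigma_pn_per_um, fit.r_squared)
```

## Layout

| module | contents |
|---|---|
| `piezomech.model` | Helfrich spectrum, mechanical parameters, wavenumber grid |
| `piezomech.optics` / `stacks` | IRM cosine relation; TIFF stack containers and drift correction |
| `piezomech.fluctsim` | synthetic generators (heights, IRM movies, tracks, polarized cells, puncta) |
| `piezomech.irm` | calibration, FBR selection, Welch/AR PSDs, Helfrich fits, tension maps and trajectories |
| `piezomech.tension_corr` | band-filtered pixel counts, max-1 normalization, lagged correlation |
| `piezomech.motility` | centroid linking, MSD curves, percent migration |
| `piezomech.polarity` | segmentation, ellipse bisection, F/B, polarity indices, polar histograms |
| `piezomech.coloc` | puncta detection, overlap, randomization null, Manders coefficients |
| `piezomech.cli` / `config` / `demo` | subcommand CLI, validated YAML config, end-to-end synthetic study |

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, numerical choices, and known limitations.
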