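# ftszring

Quantitative analysis of treadmilling FtsZ rings on supported lipid
bilayers, for TIRF microscopists studying bacterial cell-division proteins
in reconstituted systems. Membrane-anchored FtsZ self-organises into
ring-shaped vortices whose intensity pattern rotates — not because
filaments move, but because subunits add at one filament end and leave at
the other (treadmilling). This package measures that dynamic from
time-lapse movies and separates true membrane unbinding from
photobleaching in single-molecule residence times, validated end-to-end on
synthetic movies with known ground truth.

## What it computes

**Treadmilling speed and chirality** from circular kymographs. A ring is
fitted to a circle of radius *r* from two seed points; intensity is sampled
on circles *r*−1, *r*, *r*+1 px and averaged into a kymograph *K*(*s*, *t*)
(arc position × time). After Savitzky–Golay smoothing and CLAHE contrast
enhancement, the per-position temporal FFT yields the characteristic
frequency *f*\* (dominant mean spectral magnitude), and the unwrapped phase
at *f*\* is linear in arc position with slope *q* (rad/sample):

    v = 2π f* / |q| · Δs,        ω = v / r

with Δs the arc step (≈ 1 pixel). The sign of *q* gives the rotation sense
(chirality). Arc blocks are rejected unless the spectral peak is ≥ 10-fold
the mean magnitude and the phase line has R² ≥ 0.95 — static rings
(GTPase-dead mutants) fail these gates.

**Single-molecule residence times** with photobleaching correction. Spots
are detected by difference-of-Gaussians bandpass + brightness-weighted
centroid, linked between consecutive frames within 10 px, and the survival
of track durations *S*(*t*) is fitted with the constrained double
exponential

    S(t) = A e^(−k t) + B e^(−kp t),   A = 1 − B,   B ∈ [0.2, 0.25]

where *k* is the unbinding rate (mean residence time *t*ᵣ = 1/*k*) and
*kp* = 0.031 s⁻¹ the photobleaching rate calibrated from immobilised
fluorophores. Events shorter than two frames are excluded.

**Derived metrics**: mean treadmilling filament length ⟨l⟩ = v·*t*ᵣ
(≈ 390 nm = 78 monomers at 34 nm/s × 11.5 s), angular↔linear speed
conversion, surface-density regime classification, ring-size statistics and
adsorption-curve synchronisation.

**Synthetic data generators** (`ftszring.simulate`) produce the matching
ground-truth movies: rotating rings rendered through a Gaussian PSF with
Poisson + read noise, and sparse single-molecule channels whose dwells mix
unbinding and bleaching.

## Worked example

```bash
python analysis/01_simulate_example_data.py   # writes scratch/example_data/
ftszring velocity --movie scratch/example_data/ring_34nm_s.tif \
    --seeds scratch/example_data/ring_seeds.csv \
    --pixel-size-um 0.042 --frame-interval-s 3 --out ring_velocity.csv
ftszring residence --movie scratch/example_data/sm_channel.tif \
    --threshold 32 --fps 1 --out residence_out
```

The velocity command reports one accepted ring:

```
ring_id  r_px   f_star_hz  r2     peak_ratio  v_nm_s  omega_deg_s  chirality  accepted
0        11.76  0.0217     0.999  12.9        33.8    3.92         clockwise  True
```

— the simulated 34 nm/s clockwise ring is recovered within 0.5% (the
characteristic kymograph frequency is ~0.022 Hz, and 33.8 nm/s on this
0.49-um-radius circle corresponds to 3.9°/s). The residence command ends
with

```
fit: t_r = 11.34 s (k = 0.0882 1/s, kp = 0.0310 1/s, B = 0.200, N = 210)
```

i.e. after removing the photobleaching-limited population the mean membrane
residence time of the simulated molecules (true value 11.5 s) is recovered
within 1.5%. The numbered
scripts under `analysis/` run the same machinery as population-scale
experiments (120 rings over 25–108 nm/s; 5,000-event survival fits across
four kinetic regimes) and write their tables to `results/`.

## Layout

- `src/ftszring/` — library: `simulate`, `kymo`, `smtrack`, `quantify`,
  `workflows`, `io`, `cli`
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `scripts/acceptance.py` — headline-number reproduction
- `docs/methods.md` — models, parameters, numerical choices, limitations
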