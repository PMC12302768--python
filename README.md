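# nexifit

Gray-matter microstructure and water-exchange imaging from multi-diffusion-time
diffusion MRI, built on the anisotropic Kärger model (two exchanging
compartments: anisotropic "stick" neurites and isotropic extracellular water).

**Who this is for.** Researchers with pulsed-gradient spin-echo (PGSE) dMRI
acquired at several diffusion times and strong diffusion weighting — the kind
of data produced by high-gradient-performance human scanners — who want
voxel-wise or ROI-wise maps of the apparent neurite–extracellular exchange
time `tex`, neurite fraction `f`, diffusivities `Dn`, `De`, and the
orientation-dispersion invariant `p2`; and for methodologists who want a
tested, seeded sandbox for studying how protocol timing, Rician noise and
solver choice propagate into those estimates.

## The model

A voxel signal is the convolution of a fiber-bundle kernel with the neurite
orientation distribution. Per bundle, the magnetizations of the neurite (n)
and extracellular (e) pools obey the rate equations

```
d/dt [Mn, Me] = ( [[-rn, re], [rn, -re]] − q²(t)·diag(Dn ε², De) ) [Mn, Me]
```

with detailed balance `rn f = re (1−f)` and exchange time
`tex = (1−f)/rn`. Two routes evaluate the kernel `K(b, ε, t) = Mn + Me`:

* the **narrow-pulse analytic solution** `K = f′₁e^(−a₁) + f′₂e^(−a₂)`
  (exact for the Kärger propagator with `q² = b/t`), and
* the **finite-pulse ODE solution** for trapezoidal waveforms of any pulse
  duration.

Estimation works on rotational invariants: per (b, t) shell the directional
signals are reduced to `S₀` (spherical mean) and `S₂` via a spherical-harmonic
fit, and the model invariants `S₀ = K₀`, `S₂ = p₂|K₂|` are fitted by either
voxel-wise bounded least squares (NLLS) or a batched Adam optimizer that
minimizes one loss over all in-mask voxels, optionally with total-variation
regularization of the `f` map and an exact Rice-mean forward model for the
magnitude noise floor. See `docs/methods.md` for the full account.

## Worked example

Simulate a noise-propagation experiment on the fast-protocol fixture "C2"
(diffusion times 13/21/30 ms, b up to 17.5 ms/μm², 64 directions per shell),
with Rician noise at SNR 50, and fit the spherical mean per draw:

```
$ nexifit simulate --protocol C2 --noise rician --snr 50 --n 200 --seed 1 \
      --out-dir sim_c2
$ python -c "
import pandas as pd
s = pd.read_csv('sim_c2/propagation_summary.tsv', sep='\t')
print(s[(s.parameter=='tex')].to_string(index=False))"
parameter stratum   n  median_bias       iqr
      tex     all 200     9.391659 52.640202
      tex tex<=20  83     5.686029 29.619039
      tex  tex>20 117    13.030527 42.150193
```

Reading: with the Rician noise floor left uncorrected, the median fitted
exchange time overshoots the truth by ~9 ms across 200 random
gray-matter-like tissues (~5.7 ms in the fast-exchange stratum,
true `tex ≤ 20` ms). Re-running with `--noise rician-mean`, which folds the
exact Rice-distribution mean into the forward model, collapses those numbers
to −0.9 / −0.8 ms with roughly a third of the spread — the central reason
noise-floor handling (and, on slower hardware with longer minimum diffusion
times, protocol timing) matters for exchange imaging.

The same estimators run on image data: `nexifit phantom` writes a labelled
in-silico phantom (NIfTI + ground-truth maps), `nexifit fit` produces
parameter maps from any 4D DWI + scheme description (FSL bval/bvec + timing
TSV, or a named protocol), `nexifit invariants` exports the rotational
invariants, and `nexifit evaluate` tabulates per-label bias and IQR against
ground truth. Every run writes a JSON manifest (config, seeds, input
checksums) sufficient to reproduce it bit-identically.

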