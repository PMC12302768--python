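# Methods

## The model

`nexifit` implements the two-compartment anisotropic Kärger (exchange) model
of water diffusion in gray matter. A voxel contains "stick" neurites
(signal fraction `f`, diffusivity `Dn` along the stick axis, zero across)
exchanging water with an isotropic extracellular pool (fraction `1 − f`,
diffusivity `De`). Exchange is described by rate equations with the
neurite→extracellular rate `rn` and its detailed-balance partner
`re = rn·f/(1 − f)`; the exchange time is `tex = 1/(rn + re) = (1 − f)/rn`.
For a single bundle the magnetizations obey

    d/dt [Mn, Me] = ( R − q²(t) · diag(Dn ε², De) ) [Mn, Me],

with `R = [[−rn, re], [rn, −re]]`, `q(t) = γ∫G dt′` the accumulated wave
vector of the pulsed-gradient waveform, and `ε = n̂·ĝ` the projection of the
gradient direction onto the stick. The bundle kernel is `K = Mn + Me` at the
end of the waveform.

Two evaluation routes are provided:

* **Analytic (narrow-pulse) kernel** — with `q² = b/t` constant over the
  diffusion time `t`, the 2×2 system has the closed two-exponential solution
  `K = f′₁ e^(−a₁) + f′₂ e^(−a₂)`. We derive the amplitudes from the
  resolvent identity, `f′₁ = (a₂ − bD̄)/(a₂ − a₁)`,
  `f′₂ = (bD̄ − a₁)/(a₂ − a₁)` with `bD̄ = b(f·Dn·ε² + (1−f)·De)`, which
  fixes the sign convention unambiguously (`f′₁ + f′₂ = 1`) and reduces
  correctly in every limit. The discriminant is
  `√((bDnε² − bDe + t·rn − t·re)² + 4t²·rn·re)`; the `t²` in the cross term
  is required for dimensional consistency and is validated against the exact
  matrix exponential (agreement ~1e-12). Coincident exponents
  (discriminant → 0) use the explicit limit `K = e^(−a)(1 + a − bD̄)` rather
  than 0/0 arithmetic.
* **Finite-pulse ODE kernel** — direct integration of the coupled system
  over the trapezoidal waveform with an adaptive high-order solver (DOP853),
  segmented at the waveform corners where `q²(t)` has kinks. Tolerances
  default to rtol 1e-9 / atol 1e-12; halving-step self-consistency is below
  1e-6. Batches of (parameter, ε) evaluations are stacked into one linear
  system so a full simulation costs a single solve per shell.

Voxel signals convolve the kernel with an axially symmetric orientation
distribution truncated at l = 2 (`p0 = 1`, dispersion invariant `p2`,
`p4 = 0`): `S(ĝ) = K0 + 5·p2·K2·P2(û·ĝ)`, where
`K_l = ∫₀¹ K(ε) P_l(ε) dε` by fixed-order Gauss–Legendre quadrature
(60 nodes in the public projection API; 24 nodes inside the fitting loop,
where the difference is below 1e-12 for these smooth kernels). The
truncation at l = 2 reflects the low anisotropy of gray matter (simulated
`p2 ≤ 0.3`); higher orders are an extension point.

### Sign convention for S2

The measured l = 2 invariant is a spherical-harmonic coefficient norm and is
therefore non-negative, whereas the Legendre projection `K2` of a decaying
kernel is typically negative (the signal is largest perpendicular to the
sticks). The model prediction compared against measured invariants is
`S2 = p2·|K2|`; the signed `K2` is used wherever directional signals are
synthesized. Fitted `S2` inputs are floored at zero before estimation.

## Rotational invariants

Measured per-direction volumes are b0-normalized (per-voxel mean across
interleaved b0 volumes; non-positive b0 voxels are masked), then fitted per
(b, t) shell with real even spherical harmonics up to l = 4 (l = 4 guards
the lower orders against aliasing and is not returned by default). The
invariant normalization `S_l = W_l·‖c_l‖` with `W_l = 1/√(4π(2l+1))` is
fixed by the forward round-trip contract: on synthesized signals the
pipeline returns exactly `S0 = K0` and `S2 = p2·|K2|`. The noise level σ
(b0-normalized) can be estimated from ≥ 3 repeated b0 volumes as the
temporal std/mean per voxel.

The b = 1 ms/μm² shell is excluded from fitting by default: at weak
diffusion weighting the soma compartment, which the model folds into the
extracellular pool, still contributes restricted signal. The flag
`--exclude-b` overrides this.

## Estimation

Both solvers minimize `W_l`-weighted residuals between measured and model
invariants over all (b, t, l ≤ lmax):

* **NLLS** — per-voxel bounded trust-region least squares with analytic
  Jacobians (closed-form differentiation of the kernel through the
  quadrature).
* **Batched Adam** — all in-mask voxels share one scalar loss (L1 by
  default, which is more robust than L2 at moderate SNR; L2 and MSE are
  options), parameters are box-constrained via θ = lo + (hi−lo)·sigmoid(z),
  and Adam (lr 0.01, β = 0.9/0.999) runs until the relative loss change
  drops below 1e-8 or 4000 iterations. The learning rate was chosen for
  convergence within the iteration cap on the phantom; the loss and its
  gradient are computed by a fused compiled kernel (analytic derivatives, no
  finite differences), which is what makes joint whole-image optimization
  practical on a CPU. An essentially zero loss stops immediately, so a
  noiseless fixed point stays exactly at the truth.

Spatial regularization adds `λ·‖M∇f‖₁`, the anisotropic in-plane total
variation of the neurite-fraction map with differences scaled by 1/voxel
size (so λ is in mm; 0.002 mm reproduces the weak-regularization setting).
Only the batched solver supports it, since all voxels must update together.

**Initialization** is dictionary matching: 10,000 uniform draws over
`rn ∈ [0.001, 0.99] /ms`, `f ∈ [0.01, 0.99]`, `Dn ∈ [1.5, 3]`,
`De ∈ [0.5, 1.5] μm²/ms` (and `p2 ∈ [0, 0.6]` when lmax = 2 — the
simulations use `p2 ≤ 0.3`, and the wider range keeps the start unbiased
near the top of that interval), forward-simulated once, L2-normalized, and
matched by maximum inner product; ties break to the lowest index. An
all-zero measurement gets the range midpoint and a flag.

**Rate units.** Printed ranges for exchange rates in the source literature
mix s⁻¹ notation with millisecond exchange times; `tex = (1−f)/rn` with
`tex ∈ [1, 50]` ms and `f ≈ 0.3` forces `rn` onto the ms⁻¹ scale, so all
rate bounds here are ms⁻¹ (fitting box `rn ∈ [0, 1] /ms`, i.e.
`tex ≥ (1−f)` ms).

**Rician noise floor.** Magnitude MR data at low SNR acquires a positive
floor. With `rician_mean` enabled, the model passes the per-direction signal
through the exact Rice-distribution mean before orientation averaging (the
floor arises per direction, before any averaging; applying it after the
average would understate it). `rice_mean` uses the scaled-Bessel closed form
`σ√(π/2)[(1+x)I₀(x/2) + x I₁(x/2)]e^{−x/2}`, `x = ν²/2σ²`, switching to
`√(ν² + σ²)` only above ν/σ = 100 where the two agree beyond 1e-8. This mode
needs a σ estimate (known exactly in simulations; from b0 repeats in vivo)
and uses finite-difference Jacobians.

## Synthetic data

The generator reproduces the study conditions rather than arbitrary data:

* **Protocols.** Two fixtures: "C2" (t ∈ {13, 21, 30} ms, δ = 6 ms FWHM,
  ramp 0.83 ms, Gmax 500 mT/m) and "C1" (t ∈ {21, 30, 40} ms, δ = 10 ms,
  ramp 1.5 ms, Gmax 300 mT/m); shells [1, 2.3, 3.5, 4.8, 6.5] ms/μm² at the
  shortest t, adding 11.5 and 17.5 at the longer ones; a b0 volume leads and
  is interleaved every 16 diffusion volumes. Diffusion time is the
  leading-edge pulse separation and δ the trapezoid FWHM; whether the source
  protocols measured t edge-to-edge or centre-to-centre is not documented,
  and the choice shifts implied gradient amplitudes by O(δ) (our top-shell
  amplitudes are 493 and 258 mT/m, consistent with but slightly below the
  stated maxima). Directions are deterministic Fibonacci-spiral sets,
  rotated per shell; the original direction tables are not published.
* **Tissue draws.** Uniform over tex ∈ [1, 50] ms, f ∈ [0.01, 0.99],
  Dn, De ∈ [0.1, 3] μm²/ms with Dn ≥ De by rejection; `rn = (1−f)/tex`;
  `p2 ∈ [0, 0.3]` when the l = 2 channel is simulated, else an isotropic
  ODF. Each voxel gets a random symmetry axis.
* **Noise.** Complex Gaussian at σ = 1/SNR of the b0 signal, applied per
  direction *before* invariant extraction (this is what creates the floor in
  the spherical mean); Gaussian mode keeps the real channel only, Rician
  mode takes the magnitude. b0 volumes receive noise like any other volume;
  fits use the exactly known σ unless the user estimates it from b0 repeats.
* **Phantom.** The in-vivo-derived head phantom cannot be regenerated (its
  per-label ground truth is not published), so the stand-in is a geometric
  2D phantom: a ring of 20 cortex-like sectors around a core label on a
  64×64 grid (~2800 voxels at 2 mm in-plane), each label carrying constant
  tissue parameters spanning in-vivo-like magnitudes (f 0.27–0.37,
  Dn 2.5–3, De 0.77–0.95 μm²/ms, tex 10–40 ms, p2 0.19–0.33), with
  user-suppliable truth tables. What passing phantom tests shows is solver
  behaviour under controlled truth — not robustness to partial volume,
  motion, distortion or spatially correlated noise, none of which the
  generator emulates.

Evaluation follows the bias/IQR convention: per label and parameter, the
median of (estimate − truth) and the IQR of the estimates, stratified at
tex = 20 ms where relevant (the fast-exchange regime in which short
diffusion times matter most). Cross-label summaries use the median across
labels, matching how multi-ROI results are usually reported.

## Numerical choices and problem sizes

* All arithmetic in float64; every stochastic stage takes an explicit seed
  and the full pipeline is byte-reproducible.
* The acceptance tests run the noise experiments at n = 500 draws and the
  phantom at ~2800 voxels; the batched solver there is capped at 2000
  iterations, by which point its per-label exchange-time medians agree with
  NLLS well inside the 1 ms criterion (the cap halves runtime and only
  tightens, never relaxes, the agreement check). `scripts/acceptance.py`
  uses n = 50–200 and a 48×48 phantom for the same quantities.
* The NLLS trust-region tolerances are 1e-10; the dictionary is rebuilt per
  fit call (deterministic per seed) rather than cached, keeping results
  independent of call order.

## Known limitations

* The finite-pulse correction to the analytic kernel is O(δ·(rn+re)). At
  δ = 0.01 ms it exceeds 0.1% relative only in the extreme corner
  (tex → 1 ms, f → 1, b = 17.5 ms/μm², ε = 1, where K ~ 1e-9); at
  protocol pulse widths (6–10 ms) the bias it induces on fitted exchange
  times is well below the noise-driven spread, which is the practically
  relevant statement.
* No soma compartment, no compartmental T2 differences, no myelinated-fiber
  signal, no microscopic kurtosis: estimates are apparent parameters of
  this model.
* `Dn` is weakly identified without low-b data (which are excluded for soma
  reasons) and often sits at its upper bound, as expected for this protocol
  family.
* The Adam route inherits the same degeneracies as NLLS; it adds speed and
  spatial regularization, not a different likelihood.
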