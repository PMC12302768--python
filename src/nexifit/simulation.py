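"""In-silico experiments: noise propagation and a labelled head-like phantom.

The generators emulate the study conditions of multi-diffusion-time PGSE
acquisitions of exchanging gray-matter tissue: uniform tissue-parameter draws
(exchange times 1-50 ms, fractions 0.01-0.99, diffusivities 0.1-3 um^2/ms
with the along-neurite one at least the extracellular one), per-direction
forward signals from either the narrow-pulse analytic kernel or the
finite-pulse ODE kernel, and complex Gaussian noise at a b0-referenced SNR
(magnitude extraction yields Rician statistics).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

from .estimation import FitOptions, FitResult, fit_adam, fit_nlls
from .forward import TissueParams, nexi_invariant_kernels, smex_kernel
from .invariants import extract_invariants, normalize_by_b0
from .scheme import AcquisitionScheme, PGSEWaveform, build_protocol, gradient_amplitude_for_b

__all__ = [
    "DEFAULT_RANGES",
    "PhantomSpec",
    "PropagationConfig",
    "PropagationResult",
    "sample_parameters",
    "add_noise",
    "forward_directional_signals",
    "run_noise_propagation",
    "make_phantom",
    "default_phantom_labels",
    "evaluate_maps",
]

#: Ground-truth sampling ranges of the noise-propagation experiments.
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = {
    "tex": (1.0, 50.0),  # ms
    "f": (0.01, 0.99),
    "dn": (0.1, 3.0),  # um^2/ms, constrained dn >= de
    "de": (0.1, 3.0),
    "p2": (0.0, 0.3),
}


def sample_parameters(
    n: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    with_p2: bool = False,
) -> TissueParams:
    """Uniform tissue-parameter draws with the dn >= de rejection constraint.

    The exchange rate is derived from the sampled exchange time and fraction,
    rn = (1 - f)/tex.  ``with_p2`` additionally draws the dispersion
    invariant p2 (otherwise 0).  Deterministic per seed.
    """
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    dn_lo, dn_hi = ranges["dn"]
    de_lo, de_hi = ranges["de"]
    if dn_hi < de_lo:
        raise ValueError("infeasible ranges: dn upper bound below de lower bound")
    rng = np.random.default_rng(seed)
    tex = rng.uniform(*ranges["tex"], size=n)
    f = rng.uniform(*ranges["f"], size=n)
    dn = rng.uniform(dn_lo, dn_hi, size=n)
    de = rng.uniform(de_lo, de_hi, size=n)
    bad = dn < de
    guard = 0
    while np.any(bad):
        m = int(bad.sum())
        dn[bad] = rng.uniform(dn_lo, dn_hi, size=m)
        de[bad] = rng.uniform(de_lo, de_hi, size=m)
        bad = dn < de
        guard += 1
        if guard > 10000:
            raise ValueError("rejection sampling cannot satisfy dn >= de")
    p2 = rng.uniform(*ranges["p2"], size=n) if with_p2 else np.zeros(n)
    return TissueParams(f=f, dn=dn, de=de, rn=(1.0 - f) / tex, p2=p2)


def add_noise(signals: np.ndarray, snr: float, mode: str = "gaussian", seed: int = 0) -> np.ndarray:
    """Inject noise at sigma = 1/SNR (signals are b0-normalized).

    gaussian : signal + real N(0, sigma)
    rician   : |signal + N(0, sigma) + i N(0, sigma)| (magnitude of complex
               Gaussian noise, the realistic MR case)
    none     : identity
    """
    if mode == "none":
        return np.asarray(signals, dtype=float)
    if snr <= 0:
        raise ValueError("SNR must be positive")
    sigma = 1.0 / snr
    rng = np.random.default_rng(seed)
    signals = np.asarray(signals, dtype=float)
    if mode == "gaussian":
        return signals + rng.normal(0.0, sigma, size=signals.shape)
    if mode == "rician":
        re = signals + rng.normal(0.0, sigma, size=signals.shape)
        im = rng.normal(0.0, sigma, size=signals.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise mode {mode!r}")


# ---------------------------------------------------------------------------
# forward per-direction signal generation
# ---------------------------------------------------------------------------

def _smex_invariant_kernels_shell(
    b: float,
    t: float,
    delta: float,
    ramp: float,
    params: TissueParams,
    order: int = 20,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> dict[int, np.ndarray]:
    """{l: K_l} for one (b, t) shell from the finite-pulse ODE kernel.

    The eps quadrature grid and all parameter vectors are stacked into one
    linear system, so a full batch costs a single adaptive solve.
    """
    g = gradient_amplitude_for_b(b, t, delta, ramp)
    wf = PGSEWaveform(g=g, delta=delta, ramp=ramp, separation=t)
    nodes, weights = leggauss(order)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    f = np.asarray(params.f)[:, None]
    kernel = smex_kernel(
        wf,
        x[None, :],
        TissueParams(
            f=np.broadcast_to(f, (f.size, order)),
            dn=np.broadcast_to(np.asarray(params.dn)[:, None], (f.size, order)),
            de=np.broadcast_to(np.asarray(params.de)[:, None], (f.size, order)),
            rn=np.broadcast_to(np.asarray(params.rn)[:, None], (f.size, order)),
        ),
        rtol=rtol,
        atol=atol,
    ).k
    return {l: kernel @ (w * eval_legendre(l, x)) for l in (0, 2)}


def forward_directional_signals(
    scheme: AcquisitionScheme,
    params: TissueParams,
    axes: np.ndarray,
    generator: str = "nexi",
    delta: float | None = None,
    order: int = 20,
) -> np.ndarray:
    """Per-volume signals (V voxels x n_volumes) for a batch of voxels.

    Each voxel is an axially symmetric kernel/ODF pair with symmetry axis
    ``axes[v]``; S(g) = K0 + 5 p2 K2 P2(axis . g) per shell, b0 volumes = 1.
    ``generator`` picks the kernel route: "nexi" (narrow pulse) or "smex"
    (finite-pulse ODE with pulse duration ``delta``, defaulting to the
    scheme's).
    """
    axes = np.asarray(axes, dtype=float)
    axes = axes / np.linalg.norm(axes, axis=-1, keepdims=True)
    nvox = np.asarray(params.f).size
    out = np.ones((nvox, scheme.n_volumes))
    p2 = np.asarray(params.p2).reshape(nvox)
    for b, t in scheme.shells():
        idx = scheme.shell_indices(b, t)
        if generator == "nexi":
            kl = nexi_invariant_kernels(b, t, params, lmax=2, order=order)
        elif generator == "smex":
            d = float(delta) if delta is not None else float(scheme.delta[idx[0]])
            kl = _smex_invariant_kernels_shell(
                b, t, d, float(scheme.ramp[idx[0]]), params, order=order
            )
        else:
            raise ValueError(f"unknown generator {generator!r}")
        cosang = axes @ scheme.directions[idx].T  # (V, ndir)
        p2leg = eval_legendre(2, cosang)
        out[:, idx] = (
            np.asarray(kl[0]).reshape(nvox, 1)
            + 5.0 * p2.reshape(nvox, 1) * np.asarray(kl[2]).reshape(nvox, 1) * p2leg
        )
    return out


# ---------------------------------------------------------------------------
# noise propagation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PropagationConfig:
    """End-to-end noise-propagation experiment settings.

    ``noise`` in {"gaussian", "rician", "rician-mean", "none"}; "rician-mean"
    injects Rician noise and enables the Rice-mean forward correction in the
    fit.  ``generator`` in {"nexi", "smex"}; ``delta`` overrides the pulse
    duration for the smex generator (e.g. 6, 8, 10 ms).
    """

    protocol: str = "C2"
    directions: int = 64
    generator: str = "nexi"
    delta: float | None = None
    noise: str = "gaussian"
    snr: float = 50.0
    n: int = 10000
    lmax: int = 0
    solver: str = "nlls"
    seed: int = 0
    exclude_b: float = 1.0
    ranges: Mapping[str, tuple[float, float]] | None = None


@dataclasses.dataclass
class PropagationResult:
    """Raw draws + estimates with recomputable summary statistics."""

    truth: pd.DataFrame
    estimates: pd.DataFrame
    meta: dict

    def table(self) -> pd.DataFrame:
        t = self.truth.add_suffix("_true")
        e = self.estimates.add_suffix("_est")
        return pd.concat([t, e], axis=1)

    def summary(self, tex_split: float = 20.0) -> pd.DataFrame:
        """Median bias and IQR per parameter, overall and split by exchange time.

        The split at 20 ms separates the fast-exchange regime, where short
        diffusion times matter most, from the slow regime.
        """
        rows = []
        strata = {
            "all": np.ones(len(self.truth), dtype=bool),
            f"tex<={tex_split:g}": self.truth["tex"].to_numpy() <= tex_split,
            f"tex>{tex_split:g}": self.truth["tex"].to_numpy() > tex_split,
        }
        for param in self.estimates.columns:
            if param not in self.truth.columns:
                continue
            err = self.estimates[param].to_numpy() - self.truth[param].to_numpy()
            est = self.estimates[param].to_numpy()
            for name, m in strata.items():
                if not m.any():
                    continue
                q1, q3 = np.percentile(est[m], [25, 75])
                rows.append(
                    {
                        "parameter": param,
                        "stratum": name,
                        "n": int(m.sum()),
                        "median_bias": float(np.median(err[m])),
                        "iqr": float(q3 - q1),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, draws_path, summary_path=None) -> None:
        self.table().to_csv(draws_path, sep="\t", index=False)
        if summary_path is not None:
            self.summary().to_csv(summary_path, sep="\t", index=False)


def run_noise_propagation(config: PropagationConfig) -> PropagationResult:
    """Sample -> forward per-direction signals -> noise -> invariants -> fit.

    All stages are seeded from ``config.seed``; the fitted invariants exclude
    the b = ``config.exclude_b`` shells, and the noise level used by the
    Rice-mean correction is the known 1/SNR of the generator.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"noise propagation failed at stage {name!r}: {exc}") from exc

        return _Ctx()

    with stage("sample"):
        params = sample_parameters(
            config.n, ranges=config.ranges, seed=int(seeds[0]), with_p2=config.lmax == 2
        )
        axes = np.random.default_rng(int(seeds[1])).normal(size=(config.n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    with stage("forward"):
        scheme = build_protocol(config.protocol, config.directions)
        signals = forward_directional_signals(
            scheme, params, axes, generator=config.generator, delta=config.delta
        )
    with stage("noise"):
        noise_mode = {"gaussian": "gaussian", "rician": "rician",
                      "rician-mean": "rician", "none": "none"}[config.noise]
        noisy = add_noise(signals, config.snr, noise_mode, seed=int(seeds[2]))
    with stage("invariants"):
        normalized, dw_scheme, _ = normalize_by_b0(noisy, scheme)
        sigma = None if config.noise == "none" else 1.0 / config.snr
        rotinv = extract_invariants(normalized, dw_scheme, sigma=sigma)
        rotinv = rotinv.exclude_b(config.exclude_b)
    with stage("fit"):
        options = FitOptions(
            lmax=config.lmax,
            solver=config.solver,
            rician_mean=config.noise == "rician-mean",
            seed=int(seeds[3]),
        )
        if config.solver == "adam":
            result = fit_adam(rotinv, options=options)
        else:
            result = fit_nlls(rotinv, options)

    cols = ["f", "dn", "de", "rn"] + (["p2"] if config.lmax == 2 else [])
    truth = pd.DataFrame({c: np.asarray(getattr(params, c)).ravel() for c in cols})
    truth["tex"] = np.asarray(params.tex).ravel()
    est = pd.DataFrame({c: np.asarray(result.params[c]).ravel() for c in cols})
    est["tex"] = np.asarray(result.tex).ravel()
    meta = {
        "protocol": config.protocol,
        "directions": config.directions,
        "generator": config.generator,
        "delta": config.delta,
        "noise": config.noise,
        "snr": config.snr,
        "n": config.n,
        "lmax": config.lmax,
        "solver": config.solver,
        "seed": config.seed,
    }
    return PropagationResult(truth=truth, estimates=est, meta=meta)


# ---------------------------------------------------------------------------
# labelled phantom
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomSpec:
    """Concentric-parcel phantom: a ring of cortex-like labels around a core.

    ``label_params`` maps label id -> TissueParams-like dict; when omitted a
    default table spanning in-vivo-like magnitudes (f 0.27-0.37, dn 2.5-3,
    de 0.77-0.95, tex 10-40 ms, p2 0.19-0.33) is generated from the seed.
    """

    shape: tuple[int, int] = (64, 64)
    n_ring_labels: int = 20
    core_radius_frac: float = 0.4
    outer_radius_frac: float = 0.95
    snr: float = 50.0
    protocol: str = "C2"
    directions: int = 32
    noise: str = "gaussian"
    seed: int = 0
    voxel_size: tuple[float, float] = (2.0, 2.0)  # mm
    label_params: Mapping[int, Mapping[str, float]] | None = None

    def __post_init__(self):
        if self.snr <= 0 and self.noise != "none":
            raise ValueError("SNR must be positive")
        if self.n_ring_labels < 1:
            raise ValueError("need at least one ring label")


def default_phantom_labels(spec: PhantomSpec) -> dict[int, dict[str, float]]:
    """Per-label ground-truth table: ring labels 1..n plus core label n+1."""
    rng = np.random.default_rng(spec.seed)
    table: dict[int, dict[str, float]] = {}
    for label in range(1, spec.n_ring_labels + 2):
        f = float(rng.uniform(0.27, 0.37))
        tex = float(rng.uniform(10.0, 40.0))
        table[label] = {
            "f": f,
            "dn": float(rng.uniform(2.5, 3.0)),
            "de": float(rng.uniform(0.77, 0.95)),
            "rn": (1.0 - f) / tex,
            "p2": float(rng.uniform(0.19, 0.33)),
        }
    return table


def _phantom_geometry(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    rmax = min(cy, cx)
    core = r < spec.core_radius_frac * rmax
    ring = (r >= spec.core_radius_frac * rmax) & (r < spec.outer_radius_frac * rmax)
    ang = np.arctan2(yy - cy, xx - cx)  # (-pi, pi]
    sector = np.floor((ang + np.pi) / (2 * np.pi) * spec.n_ring_labels).astype(int)
    sector = np.clip(sector, 0, spec.n_ring_labels - 1)
    labels = np.zeros(spec.shape, dtype=int)
    labels[ring] = sector[ring] + 1
    labels[core] = spec.n_ring_labels + 1
    return labels


def make_phantom(spec: PhantomSpec):
    """Forward-simulate a labelled 2D phantom under the named protocol.

    Returns (dwi (ny, nx, n_volumes), truth maps {param: (ny, nx)}, labels,
    scheme).  Background voxels (label 0) carry zero signal; each labelled
    voxel takes its label's tissue parameters with its own random ODF axis,
    and noise is injected at spec.snr per volume.
    """
    labels = _phantom_geometry(spec)
    table = dict(spec.label_params) if spec.label_params is not None else default_phantom_labels(spec)
    present = np.unique(labels[labels > 0])
    missing = [int(l) for l in present if int(l) not in table]
    if missing:
        raise ValueError(f"labels without parameter entries: {missing}")

    scheme = build_protocol(spec.protocol, spec.directions)
    rng = np.random.default_rng(spec.seed)
    noise_seed = int(rng.integers(0, 2**31 - 1))

    in_mask = labels > 0
    vox_labels = labels[in_mask]
    order = {int(l): i for i, l in enumerate(present)}
    fields = {k: np.array([table[int(l)][k] for l in present]) for k in ("f", "dn", "de", "rn", "p2")}
    idx = np.array([order[int(l)] for l in vox_labels])
    params = TissueParams(**{k: v[idx] for k, v in fields.items()})
    axes = rng.normal(size=(idx.size, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    per_voxel = forward_directional_signals(scheme, params, axes)

    dwi = np.zeros(spec.shape + (scheme.n_volumes,))
    dwi[in_mask] = per_voxel
    dwi = add_noise(dwi, spec.snr, {"rician": "rician", "gaussian": "gaussian", "none": "none"}[spec.noise], seed=noise_seed)
    dwi[~in_mask] = 0.0

    truth = {}
    for k in ("f", "dn", "de", "rn", "p2"):
        m = np.full(spec.shape, np.nan)
        m[in_mask] = fields[k][idx]
        truth[k] = m
    tex_map = np.full(spec.shape, np.nan)
    tex_map[in_mask] = ((1.0 - fields["f"]) / fields["rn"])[idx]
    truth["tex"] = tex_map
    return dwi, truth, labels, scheme


def evaluate_maps(
    estimated: Mapping[str, np.ndarray],
    truth: Mapping[str, np.ndarray],
    labels: np.ndarray,
) -> pd.DataFrame:
    """Per-label accuracy/precision: median(est - truth) and IQR(est)."""
    labels = np.asarray(labels)
    rows = []
    for param, est in estimated.items():
        if param not in truth:
            continue
        est = np.asarray(est, dtype=float)
        tru = np.asarray(truth[param], dtype=float)
        if est.shape != labels.shape or tru.shape != labels.shape:
            raise ValueError("map shapes do not match the label volume")
        for label in np.unique(labels[labels > 0]):
            m = (labels == label) & np.isfinite(est) & np.isfinite(tru)
            if not m.any():
                continue
            q1, q3 = np.percentile(est[m], [25, 75])
            rows.append(
                {
                    "label": int(label),
                    "parameter": param,
                    "n": int(m.sum()),
                    "median_bias": float(np.median(est[m] - tru[m])),
                    "iqr": float(q3 - q1),
                }
            )
    return pd.DataFrame(rows)
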