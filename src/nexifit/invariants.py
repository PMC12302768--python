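"""Rotational-invariant signal extraction from directional dMRI volumes.

Measured per-direction signals are reduced, per (b, t) shell, to orientation-
independent invariants S_l by least-squares fitting of real even spherical
harmonics and taking the per-order coefficient norms.  The normalization
constant W_l = 1/sqrt(4 pi (2l+1)) is fixed so that S0 equals the spherical
mean and, on signals synthesized from an axially symmetric kernel/ODF pair,
S2 = p2 * K2 (self-consistent round trip with the forward module).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .scheme import AcquisitionScheme

try:  # scipy >= 1.15
    from scipy.special import sph_harm_y

    def _sph_harm(l, m, theta, phi):
        return sph_harm_y(l, m, theta, phi)

except ImportError:  # pragma: no cover - older scipy
    from scipy.special import sph_harm

    def _sph_harm(l, m, theta, phi):
        return sph_harm(m, l, phi, theta)

logger = logging.getLogger(__name__)

__all__ = [
    "RotInvSignal",
    "invariant_weight",
    "real_sh_basis",
    "normalize_by_b0",
    "extract_invariants",
    "estimate_sigma_b0",
]


def invariant_weight(l: int) -> float:
    """W_l = 1/sqrt(4 pi (2l+1)), the per-order invariant weight."""
    return 1.0 / np.sqrt(4.0 * np.pi * (2 * l + 1))


def n_even_coeffs(lmax: int) -> int:
    """Number of even-order spherical-harmonic coefficients up to lmax."""
    return (lmax + 1) * (lmax + 2) // 2


def real_sh_basis(lmax: int, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real even spherical-harmonic design matrix.

    Returns (B, l_index): B has one column per coefficient, ordered by
    ascending even l and m = -l..l within each order; l_index labels each
    column's order.  The basis is orthonormal on the sphere (m = 0 columns are
    Y_l0, |m| > 0 columns are sqrt(2) times the real/imaginary parts), so
    per-order coefficient norms are rotation invariant.
    """
    directions = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    cols = []
    l_index = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = _sph_harm(l, abs(m), theta, phi)
            if m < 0:
                col = np.sqrt(2.0) * y.imag
            elif m == 0:
                col = y.real
            else:
                col = np.sqrt(2.0) * y.real
            cols.append(col)
            l_index.append(l)
    return np.stack(cols, axis=1), np.array(l_index)


@dataclasses.dataclass
class RotInvSignal:
    """Rotational invariants S_l per (b, t) shell.

    sl maps order l -> array of shape (..., n_shells); ``shells`` lists the
    matching (b, t) pairs.  ``sigma`` is the per-voxel noise level in
    b0-normalized units (optional).  S2 values below zero are floored at zero
    when consumed by estimation; raw values live in ``raw_sl``.
    """

    sl: dict[int, np.ndarray]
    shells: list[tuple[float, float]]
    sigma: np.ndarray | float | None = None
    raw_sl: dict[int, np.ndarray] | None = None

    def s(self, l: int) -> np.ndarray:
        return self.sl[l]

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    def select_shells(self, keep: np.ndarray) -> "RotInvSignal":
        keep = np.asarray(keep)
        return RotInvSignal(
            sl={l: v[..., keep] for l, v in self.sl.items()},
            shells=[s for s, k in zip(self.shells, keep) if k],
            sigma=self.sigma,
            raw_sl=None if self.raw_sl is None else {l: v[..., keep] for l, v in self.raw_sl.items()},
        )

    def exclude_b(self, b_excluded: float = 1.0, atol: float = 1e-6) -> "RotInvSignal":
        """Drop shells at the given b (default the low-b soma-contaminated shell)."""
        keep = np.array([abs(b - b_excluded) > atol for b, _ in self.shells])
        return self.select_shells(keep)


def normalize_by_b0(
    dwi: np.ndarray, scheme: AcquisitionScheme
) -> tuple[np.ndarray, AcquisitionScheme, np.ndarray]:
    """Divide each voxel by its mean b0 signal; drop b0 volumes.

    Returns (normalized diffusion-weighted signals, the scheme restricted to
    diffusion-weighted volumes, valid-voxel mask).  Voxels with non-positive
    mean b0 are masked out (normalized values set to NaN) with a warning.
    """
    dwi = np.asarray(dwi, dtype=float)
    b0_mask = scheme.is_b0
    if not np.any(b0_mask):
        raise ValueError("scheme contains no b0 volume")
    b0_mean = dwi[..., b0_mask].mean(axis=-1)
    valid = b0_mean > 0
    if not np.all(valid):
        logger.warning("masking %d voxels with non-positive mean b0", int((~valid).sum()))
    safe = np.where(valid, b0_mean, 1.0)
    normalized = dwi[..., ~b0_mask] / safe[..., None]
    normalized[~valid] = np.nan

    dw = ~b0_mask
    sub = AcquisitionScheme(
        b=scheme.b[dw], t=scheme.t[dw], delta=scheme.delta[dw],
        ramp=scheme.ramp[dw], directions=scheme.directions[dw],
        gmax=scheme.gmax, name=scheme.name,
    )
    return normalized, sub, valid


def extract_invariants(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    lmax_fit: int = 4,
    lmax_out: int = 2,
    sigma: np.ndarray | float | None = None,
) -> RotInvSignal:
    """Fit real even spherical harmonics per shell and reduce to invariants.

    ``signals`` has shape (..., n_volumes) aligned with the (b0-free)
    ``scheme``.  The fit runs up to ``lmax_fit`` (default 4, guarding the
    lower orders against aliasing); invariants above ``lmax_out`` are computed
    but not returned.  Requires at least (lmax_fit+1)(lmax_fit+2)/2 directions
    per shell.
    """
    signals = np.asarray(signals, dtype=float)
    shells = scheme.shells()
    if not shells:
        raise ValueError("scheme has no diffusion-weighted shells")
    need = n_even_coeffs(lmax_fit)
    lead_shape = signals.shape[:-1]
    orders_out = list(range(0, lmax_out + 1, 2))
    out = {l: np.empty(lead_shape + (len(shells),)) for l in orders_out}
    for ishell, (b, t) in enumerate(shells):
        idx = scheme.shell_indices(b, t)
        dirs = scheme.directions[idx]
        if idx.size < need:
            raise ValueError(
                f"shell (b={b}, t={t}) has {idx.size} directions; "
                f"lmax_fit={lmax_fit} needs at least {need}"
            )
        basis, l_index = real_sh_basis(lmax_fit, dirs)
        y = signals[..., idx].reshape(-1, idx.size).T  # (ndirs, nvox)
        coeffs, _, rank, _ = np.linalg.lstsq(basis, y, rcond=None)
        if rank < basis.shape[1]:
            raise ValueError(
                f"rank-deficient spherical-harmonic design on shell (b={b}, t={t})"
            )
        for l in orders_out:
            sel = l_index == l
            if l == 0:
                vals = coeffs[sel][0] * invariant_weight(0)
            else:
                vals = invariant_weight(l) * np.linalg.norm(coeffs[sel], axis=0)
            out[l][..., ishell] = vals.reshape(lead_shape)
    return RotInvSignal(sl=out, shells=shells, sigma=sigma, raw_sl={l: v.copy() for l, v in out.items()})


def estimate_sigma_b0(b0_volumes: np.ndarray) -> np.ndarray:
    """Noise level from temporal statistics of repeated b0 volumes.

    ``b0_volumes`` has the repeats on the last axis.  Returns the per-voxel
    standard deviation across repeats divided by the per-voxel mean, i.e.
    sigma in b0-normalized units (SNR = 1/sigma).  Needs >= 3 repeats.
    """
    b0 = np.asarray(b0_volumes, dtype=float)
    if b0.shape[-1] < 3:
        raise ValueError("need at least 3 b0 volumes to estimate sigma")
    mean = b0.mean(axis=-1)
    std = b0.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), np.nan)
    return sigma
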