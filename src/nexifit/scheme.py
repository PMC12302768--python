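"""Pulsed-gradient spin-echo acquisition schemes.

Units are fixed package-wide: b in ms/um^2, time in ms, gradient amplitude in
mT/m, diffusivity in um^2/ms, exchange rate in 1/ms.  The proton gyromagnetic
ratio in these units is ``GAMMA`` [rad / (ms * um * mT/m)].

A diffusion volume is described by (b, t, delta, ramp, direction).  The pulse
duration ``delta`` follows the full-width-at-half-maximum convention for a
trapezoidal pulse (flat top + one ramp), and the diffusion time ``t`` is the
separation between the leading edges of the two pulses.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA",
    "PGSEWaveform",
    "AcquisitionScheme",
    "sphere_directions",
    "build_protocol",
    "read_scheme",
    "gradient_amplitude_for_b",
    "b_value_for_gradient",
]

#: Proton gyromagnetic ratio, rad / (ms * um * (mT/m)).
#: 267.51525e6 rad/s/T expressed in the package unit system.
GAMMA = 2.6751525e-4

# Table-style protocol fixtures: shells share the pattern
# [1, 2.3, 3.5, 4.8, 6.5] at the shortest diffusion time, adding 11.5 at the
# middle one and 17.5 at the longest.  b = 1 ms/um^2 is acquired but excluded
# from model fitting downstream (soma contamination at low b).
_BASE_SHELLS = (1.0, 2.3, 3.5, 4.8, 6.5)
_PROTOCOLS = {
    "C2": {"t": (13.0, 21.0, 30.0), "delta": 6.0, "ramp": 0.83, "gmax": 500.0},
    "C1": {"t": (21.0, 30.0, 40.0), "delta": 10.0, "ramp": 1.5, "gmax": 300.0},
}
_B0_EVERY = 16  # interleave a b=0 volume every N diffusion-weighted volumes


@dataclasses.dataclass(frozen=True)
class PGSEWaveform:
    """Trapezoidal pulsed-gradient pair with refocusing sign convention.

    The first pulse has amplitude +G, the second -G (the 180-degree pulse is
    absorbed into the sign flip), so the accumulated wave vector
    q(t) = gamma * int G dt' returns to zero at the end of the second pulse.

    Parameters
    ----------
    g : float
        Flat-top amplitude (mT/m).
    delta : float
        Pulse duration, FWHM convention: flat top + one ramp (ms).
    ramp : float
        Ramp time (ms); ``ramp <= delta`` so the flat top is non-negative.
    separation : float
        Leading-edge to leading-edge pulse separation (= diffusion time t, ms).
    """

    g: float
    delta: float
    ramp: float
    separation: float

    def __post_init__(self):
        if self.ramp < 0 or self.delta <= 0 or self.separation <= 0:
            raise ValueError("waveform timings must be positive")
        if self.ramp > self.delta:
            raise ValueError("ramp time exceeds FWHM pulse duration")
        if self.delta + self.ramp > self.separation:
            raise ValueError("pulses overlap: require delta + ramp <= separation")

    @property
    def duration(self) -> float:
        """Total waveform duration (end of second pulse), ms."""
        return self.separation + self.delta + self.ramp

    def breakpoints(self) -> np.ndarray:
        """Times of the piecewise-linear corners of G(t)."""
        r, d, t = self.ramp, self.delta, self.separation
        flat = d - r
        pts = [0.0, r, r + flat, d + r, t, t + r, t + r + flat, t + d + r]
        return np.unique(np.array(pts))

    def amplitude(self, times: np.ndarray) -> np.ndarray:
        """Gradient amplitude G(t) (mT/m) at ``times``."""
        r, d, t = self.ramp, self.delta, self.separation
        flat = d - r
        times = np.asarray(times, dtype=float)
        out = np.zeros_like(times)

        def trapezoid(t0, sign):
            local = times - t0
            up = np.clip(local / r, 0.0, 1.0) if r > 0 else (local >= 0).astype(float)
            down = np.clip((local - r - flat) / r, 0.0, 1.0) if r > 0 else (local > r + flat).astype(float)
            return sign * self.g * (up - down) * (local >= 0) * (local <= d + r)

        out = trapezoid(0.0, +1.0) + trapezoid(t, -1.0)
        return out

    def q_of_t(self, times: np.ndarray) -> np.ndarray:
        """Accumulated diffusion wave vector q(t) = gamma * int_0^t G, in 1/um."""
        times = np.asarray(times, dtype=float)
        out = np.empty_like(times)
        for i, tt in np.ndenumerate(times):
            out[i] = self._q_scalar(float(tt))
        return out

    def _q_scalar(self, tt: float) -> float:
        r, d, t = self.ramp, self.delta, self.separation
        area = _trap_area(tt, r, d, self.g) - _trap_area(tt - t, r, d, self.g)
        return GAMMA * area

    def b_value(self) -> float:
        """b = int q^2 dt, exact per-segment Gauss-Legendre quadrature.

        q(t) is piecewise quadratic so q^2 is piecewise quartic; 3-node
        Gauss-Legendre per segment integrates it exactly.
        """
        nodes, weights = np.polynomial.legendre.leggauss(3)
        pts = self.breakpoints()
        b = 0.0
        for a, c in zip(pts[:-1], pts[1:]):
            mid, half = 0.5 * (a + c), 0.5 * (c - a)
            tt = mid + half * nodes
            q = self.q_of_t(tt)
            b += half * float(np.sum(weights * q * q))
        return b


def _trap_area(tt: float, r: float, d: float, g: float) -> float:
    """Area under a single trapezoidal pulse of FWHM d, ramp r, up to time tt."""
    if tt <= 0:
        return 0.0
    flat = d - r
    total = d + r
    if tt >= total:
        return g * d  # full area: FWHM convention makes area = G * delta
    if r == 0:
        return g * min(tt, d)
    if tt <= r:  # on the up-ramp
        return 0.5 * g * tt * tt / r
    if tt <= r + flat:  # on the flat top
        return 0.5 * g * r + g * (tt - r)
    # on the down-ramp
    td = tt - r - flat
    return 0.5 * g * r + g * flat + g * td - 0.5 * g * td * td / r


import functools


@functools.lru_cache(maxsize=4096)
def b_value_for_gradient(g: float, t: float, delta: float, ramp: float) -> float:
    """b-value (ms/um^2) of a trapezoidal PGSE pair with flat-top amplitude g."""
    return PGSEWaveform(g=g, delta=delta, ramp=ramp, separation=t).b_value()


def gradient_amplitude_for_b(
    b: float, t: float, delta: float, ramp: float, gmax: float | None = None
) -> float:
    """Flat-top gradient amplitude (mT/m) producing the requested b-value.

    b scales as G^2 for a fixed timing, so the inversion is exact:
    G = sqrt(b / b(G=1)).  Raises if a scheme maximum ``gmax`` is supplied and
    exceeded.
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    if b == 0:
        return 0.0
    b_unit = b_value_for_gradient(1.0, t, delta, ramp)
    g = float(np.sqrt(b / b_unit))
    if gmax is not None and g > gmax * (1 + 1e-9):
        raise ValueError(
            f"required gradient {g:.1f} mT/m exceeds the maximum {gmax:.0f} mT/m"
        )
    return g


def sphere_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (n, 3), Fibonacci spiral layout.

    Serves as the fixture direction sets (e.g. 32 or 64 per shell); the layout
    is fixed and reproducible, with good angular coverage for spherical
    harmonic fitting up to l = 4.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    golden = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    dirs = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclasses.dataclass
class AcquisitionScheme:
    """Per-volume pulsed-gradient encoding description.

    Attributes
    ----------
    b : (n,) array
        Diffusion weightings, ms/um^2 (0 for b0 volumes).
    t : (n,) array
        Diffusion times (leading-edge separation), ms.
    delta : (n,) array
        Pulse durations (FWHM), ms.
    ramp : (n,) array
        Ramp times, ms.
    directions : (n, 3) array
        Unit gradient directions; zero rows for b0 volumes.
    gmax : float
        Scanner maximum gradient amplitude, mT/m.
    name : str
        Optional protocol label.
    """

    b: np.ndarray
    t: np.ndarray
    delta: np.ndarray
    ramp: np.ndarray
    directions: np.ndarray
    gmax: float = np.inf
    name: str = ""

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        self.ramp = np.atleast_1d(np.asarray(self.ramp, dtype=float))
        self.directions = np.asarray(self.directions, dtype=float)
        n = self.b.size
        if not (self.t.size == self.delta.size == self.ramp.size == n):
            raise ValueError("scheme arrays must share one length")
        if self.directions.shape != (n, 3):
            raise ValueError("directions must be (n, 3)")
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if np.any(self.b < 0):
            raise ValueError("negative b-value")
        dw = ~self.is_b0
        if np.any(self.delta[dw] + self.ramp[dw] >= self.t[dw]):
            raise ValueError("require delta + ramp < t for diffusion-weighted volumes")
        norms = np.linalg.norm(self.directions[dw], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-unit gradient direction")
        for i in np.flatnonzero(dw):
            g = gradient_amplitude_for_b(
                self.b[i], self.t[i], self.delta[i], self.ramp[i]
            )
            if g > self.gmax * (1 + 1e-9):
                raise ValueError(
                    f"volume {i}: implied gradient {g:.1f} mT/m exceeds "
                    f"Gmax = {self.gmax:.0f} mT/m"
                )

    # -- derived views ---------------------------------------------------
    @property
    def n_volumes(self) -> int:
        return self.b.size

    @property
    def is_b0(self) -> np.ndarray:
        return self.b == 0

    @property
    def dw_mask(self) -> np.ndarray:
        return ~self.is_b0

    def shells(self) -> list[tuple[float, float]]:
        """Sorted unique (b, t) pairs of the diffusion-weighted volumes."""
        dw = self.dw_mask
        pairs = sorted({(float(b), float(t)) for b, t in zip(self.b[dw], self.t[dw])})
        return pairs

    def shell_indices(self, b: float, t: float, atol: float = 1e-6) -> np.ndarray:
        return np.flatnonzero(
            (np.abs(self.b - b) < atol) & (np.abs(self.t - t) < atol) & self.dw_mask
        )

    def gradient_amplitudes(self) -> np.ndarray:
        """Implied flat-top amplitude per volume (mT/m)."""
        out = np.zeros(self.n_volumes)
        for i in np.flatnonzero(self.dw_mask):
            out[i] = gradient_amplitude_for_b(
                self.b[i], self.t[i], self.delta[i], self.ramp[i]
            )
        return out

    def waveform(self, index: int) -> PGSEWaveform:
        """Trapezoidal waveform of volume ``index``."""
        g = gradient_amplitude_for_b(
            self.b[index], self.t[index], self.delta[index], self.ramp[index]
        )
        return PGSEWaveform(
            g=g, delta=float(self.delta[index]), ramp=float(self.ramp[index]),
            separation=float(self.t[index]),
        )

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "b": self.b,
                "t": self.t,
                "delta": self.delta,
                "ramp": self.ramp,
                "gx": self.directions[:, 0],
                "gy": self.directions[:, 1],
                "gz": self.directions[:, 2],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, gmax: float = np.inf) -> "AcquisitionScheme":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        dirs = df[["gx", "gy", "gz"]].to_numpy()
        return cls(
            b=df["b"].to_numpy(), t=df["t"].to_numpy(), delta=df["delta"].to_numpy(),
            ramp=df["ramp"].to_numpy(), directions=dirs, gmax=gmax,
        )


def build_protocol(name: str, directions_per_shell: int = 64) -> AcquisitionScheme:
    """Construct a named multi-(b, t) protocol fixture.

    ``"C2"``: diffusion times {13, 21, 30} ms, delta = 6 ms, ramp = 0.83 ms,
    Gmax = 500 mT/m.  ``"C1"``: diffusion times {21, 30, 40} ms, delta = 10 ms,
    ramp = 1.5 ms, Gmax = 300 mT/m.  Shells are [1, 2.3, 3.5, 4.8, 6.5]
    ms/um^2 at the shortest diffusion time, adding 11.5 at the middle and 17.5
    at the longest.  A b0 volume leads the series and is interleaved every 16
    diffusion-weighted volumes.  Directions use the deterministic Fibonacci
    layout, rotated per shell index so shells do not share identical sets.
    """
    if name not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {name!r}; known: {sorted(_PROTOCOLS)}")
    p = _PROTOCOLS[name]
    base_dirs = sphere_directions(directions_per_shell)

    b_list: list[float] = []
    t_list: list[float] = []
    dirs: list[np.ndarray] = []
    n_dw = 0

    def push_b0(t_ref: float):
        b_list.append(0.0)
        t_list.append(t_ref)
        dirs.append(np.zeros(3))

    for it, t in enumerate(p["t"]):
        shells = _BASE_SHELLS + ((11.5,) if it >= 1 else ()) + ((17.5,) if it >= 2 else ())
        for ib, b in enumerate(shells):
            # deterministic per-shell rotation about z to decorrelate shells
            ang = 2 * np.pi * (it * len(shells) + ib) / 23.0
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            shell_dirs = base_dirs @ rot.T
            for d in shell_dirs:
                if n_dw % _B0_EVERY == 0:
                    push_b0(t)
                b_list.append(float(b))
                t_list.append(float(t))
                dirs.append(d)
                n_dw += 1
    push_b0(p["t"][-1])

    n = len(b_list)
    return AcquisitionScheme(
        b=np.array(b_list),
        t=np.array(t_list),
        delta=np.full(n, p["delta"]),
        ramp=np.full(n, p["ramp"]),
        directions=np.vstack(dirs),
        gmax=p["gmax"],
        name=name,
    )


def read_scheme(
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
    timing_path: str | os.PathLike,
    gmax: float = np.inf,
) -> AcquisitionScheme:
    """Read an FSL-style bval/bvec pair plus a timing TSV.

    The timing table must have columns (volume, t, delta, ramp) in ms.  bvals
    are auto-detected as s/mm^2 when any value exceeds 100 and converted to
    ms/um^2 by multiplying with 1e-3 (conventional s/mm^2 DWI shells are
    >= 1000).
    """
    import pandas as pd

    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T  # FSL layout: one column per volume
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec shape {bvecs.shape} inconsistent with {bvals.size} bvals"
        )
    timing = pd.read_csv(timing_path, sep="\t")
    required = {"volume", "t", "delta", "ramp"}
    if not required.issubset(timing.columns):
        raise ValueError(f"timing table needs columns {sorted(required)}")
    if len(timing) != bvals.size:
        raise ValueError(
            f"{len(timing)} timing rows for {bvals.size} volumes"
        )
    timing = timing.sort_values("volume")

    if np.any(bvals > 100):  # s/mm^2 -> ms/um^2
        bvals = bvals * 1e-3

    dirs = np.array(bvecs, dtype=float)
    dw = bvals > 0
    norms = np.linalg.norm(dirs[dw], axis=1)
    if norms.size and np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("non-unit gradient direction in bvec file")
    if norms.size:  # tighten to exact unit norm
        dirs[dw] /= np.linalg.norm(dirs[dw], axis=1, keepdims=True)
    dirs[~dw] = 0.0

    return AcquisitionScheme(
        b=bvals,
        t=timing["t"].to_numpy(dtype=float),
        delta=timing["delta"].to_numpy(dtype=float),
        ramp=timing["ramp"].to_numpy(dtype=float),
        directions=dirs,
        gmax=gmax,
    )
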