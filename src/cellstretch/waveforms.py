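"""Applied substrate-strain waveforms.

Stretch devices impose a non-negative membrane strain, so every waveform here
starts at zero strain at t = 0, rises to the configured maximal strain
``eps_max`` within each period and returns to zero (sine) or near zero
(brachial) at the period boundary.

Two shapes are provided:

* ``sine`` — a raised cosine, eps(t) = eps_max * (1 - cos(2*pi*f*t)) / 2.
* ``brachial`` — a pulse mimicking brachial-artery distension over the cardiac
  cycle, defined by a tabulated normalized shape (one period, unit peak).
  The packaged default table is a synthetic stand-in built from two wrapped
  Gaussian lobes (systolic upstroke peaking near 0.33 T with a dicrotic
  secondary bump near 0.58 T and a long diastolic decay); any user table with
  the same CSV layout can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import InvalidParameterError, InvalidShapeError

__all__ = [
    "StrainWaveform",
    "make_sine_waveform",
    "make_brachial_waveform",
    "waveform_series",
    "load_shape_table",
    "default_brachial_shape",
]

#: Hard floor on temporal resolution: the time step never exceeds T/50.
MIN_STEPS_PER_CYCLE = 50

_PERIODIC_TOL = 1e-6


@dataclass(frozen=True)
class StrainWaveform:
    """A periodic applied-substrate-strain function of time.

    Parameters
    ----------
    kind : {"sine", "brachial"}
    eps_max : float
        Maximal engineering strain over one period (dimensionless, e.g. 0.075
        for 7.5 %). Must lie in (0, 0.5].
    frequency : float
        Loading frequency in Hz.
    shape_table : (n, 2) ndarray, optional
        Normalized shape samples ``(t_frac, amplitude)`` with ``t_frac``
        strictly increasing over [0, 1]; required for ``kind="brachial"``.
    """

    kind: str
    eps_max: float
    frequency: float
    shape_table: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("sine", "brachial"):
            raise InvalidParameterError(f"unknown waveform kind {self.kind!r}")
        if not (0.0 < self.eps_max <= 0.5):
            raise InvalidParameterError(
                f"eps_max must be in (0, 0.5], got {self.eps_max}"
            )
        if self.frequency <= 0.0:
            raise InvalidParameterError(
                f"frequency must be positive, got {self.frequency}"
            )
        if self.kind == "brachial":
            if self.shape_table is None:
                raise InvalidShapeError("brachial waveform requires a shape table")
            interp = _build_shape_interpolator(self.shape_table)
            object.__setattr__(self, "_interp", interp)

    @property
    def period(self) -> float:
        """Loading period T = 1/frequency in seconds."""
        return 1.0 / self.frequency

    def __call__(self, t):
        """Evaluate the applied strain at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sine":
            val = 0.5 * self.eps_max * (1.0 - np.cos(2.0 * np.pi * self.frequency * t))
        else:
            frac = np.mod(t * self.frequency, 1.0)
            val = self.eps_max * self._interp(frac)
        # Guard tiny interpolation round-off outside [0, eps_max].
        return np.clip(val, 0.0, self.eps_max)


def _build_shape_interpolator(table: np.ndarray) -> PchipInterpolator:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 3:
        raise InvalidShapeError("shape table must be an (n>=3, 2) array")
    t_frac, amp = table[:, 0], table[:, 1]
    if not (np.all(np.diff(t_frac) > 0) and t_frac[0] >= 0.0 and t_frac[-1] <= 1.0):
        raise InvalidShapeError("t_frac must be strictly increasing within [0, 1]")
    if abs(t_frac[0]) > _PERIODIC_TOL or abs(t_frac[-1] - 1.0) > _PERIODIC_TOL:
        raise InvalidShapeError("shape table must cover the full period [0, 1]")
    if np.any(amp < -_PERIODIC_TOL):
        raise InvalidShapeError("shape amplitudes must be non-negative")
    peak = amp.max()
    if peak <= 0.0:
        raise InvalidShapeError("shape table is all zeros and cannot be normalized")
    amp = np.clip(amp / peak, 0.0, 1.0)
    if abs(amp[0] - amp[-1]) > 1e-3:
        raise InvalidShapeError(
            "shape endpoints differ beyond tolerance; table is not periodic"
        )
    # Close the period exactly so interpolation is continuous at the seam.
    amp = amp.copy()
    amp[-1] = amp[0]
    # Monotone piecewise-cubic: no overshoot above the unit peak.
    return PchipInterpolator(t_frac, amp, extrapolate=False)


def load_shape_table(path) -> np.ndarray:
    """Read a 2-column ``t_frac,amplitude`` CSV shape table."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1, dtype=float)
    return np.atleast_2d(arr)


def default_brachial_shape() -> np.ndarray:
    """The packaged synthetic brachial distension shape (one period, peak 1)."""
    ref = resources.files("cellstretch.data").joinpath("brachial_shape.csv")
    with ref.open("r") as fh:
        return load_shape_table(fh)


def make_sine_waveform(eps_max: float, frequency: float) -> StrainWaveform:
    """Raised-cosine strain cycle: 0 -> eps_max -> 0 over each period."""
    return StrainWaveform(kind="sine", eps_max=eps_max, frequency=frequency)


def make_brachial_waveform(
    eps_max: float, frequency: float, shape_table: Optional[np.ndarray] = None
) -> StrainWaveform:
    """Brachial-pulse strain cycle from a normalized shape table.

    With ``shape_table=None`` the packaged synthetic shape is used.
    """
    if shape_table is None:
        shape_table = default_brachial_shape()
    return StrainWaveform(
        kind="brachial", eps_max=eps_max, frequency=frequency, shape_table=shape_table
    )


def waveform_series(
    w: StrainWaveform, n_cycles: int, steps_per_cycle: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly sample ``n_cycles`` periods including both endpoints.

    Returns ``(times, strains)`` of length ``n_cycles * steps_per_cycle + 1``.
    ``steps_per_cycle`` below 50 is refused: the time step must not exceed
    T/50.
    """
    if n_cycles < 1:
        raise InvalidParameterError(f"n_cycles must be >= 1, got {n_cycles}")
    if steps_per_cycle < MIN_STEPS_PER_CYCLE:
        raise InvalidParameterError(
            f"steps_per_cycle must be >= {MIN_STEPS_PER_CYCLE} "
            f"(time step <= T/50), got {steps_per_cycle}"
        )
    n = n_cycles * steps_per_cycle
    times = np.arange(n + 1) * (w.period / steps_per_cycle)
    return times, w(times)
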