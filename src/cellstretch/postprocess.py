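"""Reductions of field histories to reported nuclear quantities.

"Nuclear strain" throughout means the element-volume-weighted average of a
strain component over the nucleus region (the extremum of the average within
a cycle, not the maximum over nucleus points). Per-cycle peaks are signed
extrema of largest magnitude, so compressive z peaks come out negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .fem import FieldHistory, VOIGT

__all__ = [
    "NuclearStrainSeries",
    "CycleSummary",
    "volume_average",
    "extract_nuclear_series",
    "per_cycle_peaks",
    "steady_state_cycle",
    "NOT_CONVERGED",
]

NOT_CONVERGED = -1

_STRAIN = {f"eps_{c}": i for i, c in enumerate(VOIGT)}
_STRESS = {f"sigma_{c}": i for i, c in enumerate(VOIGT)}


def volume_average(history: FieldHistory, region, component: str) -> np.ndarray:
    """Volume-weighted average of a field component over a region, per step.

    ``component`` is one of ``eps_xx .. eps_yz``, ``sigma_xx .. sigma_yz`` or
    ``sigma_vm`` (von Mises).
    """
    mask = history.mesh.region_mask(region)
    vols = history.tet_volumes(mask)
    w = vols / vols.sum()
    if component in _STRAIN:
        series = history.strain_series(mask)[:, :, _STRAIN[component]]
    elif component in _STRESS:
        series = history.stress_series(mask)[:, :, _STRESS[component]]
    elif component == "sigma_vm":
        s = history.stress_series(mask)
        sx, sy, sz, sxy, sxz, syz = (s[:, :, i] for i in range(6))
        series = np.sqrt(
            0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
            + 3.0 * (sxy**2 + sxz**2 + syz**2)
        )
    else:
        raise InvalidParameterError(f"unknown field component {component!r}")
    return series @ w


@dataclass
class NuclearStrainSeries:
    """Volume-averaged nuclear strain/stress component time series."""

    times: np.ndarray
    mean_eps_xx: np.ndarray
    mean_eps_yy: np.ndarray
    mean_eps_zz: np.ndarray
    mean_sigma_xx: np.ndarray
    applied_strain: np.ndarray
    steps_per_cycle: int
    n_cycles: int
    stress_component: str = "sigma_xx"

    def cycle_slice(self, cycle: int) -> slice:
        """Inclusive step window of 1-based ``cycle`` (shares endpoints)."""
        if not (1 <= cycle <= self.n_cycles):
            raise InvalidParameterError(f"cycle {cycle} out of range")
        return slice((cycle - 1) * self.steps_per_cycle, cycle * self.steps_per_cycle + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "eps_xx": self.mean_eps_xx,
                "eps_yy": self.mean_eps_yy,
                "eps_zz": self.mean_eps_zz,
                "sigma_xx_pa": self.mean_sigma_xx,
                "applied_strain": self.applied_strain,
            }
        )


def extract_nuclear_series(
    history: FieldHistory, stress_component: str = "sigma_xx"
) -> NuclearStrainSeries:
    """Reduce a field history to the nuclear series driving all reporting.

    Computes the nucleus strain/stress tensors once and reuses them for all
    components (equivalent to repeated :func:`volume_average` calls).
    """
    mask = history.mesh.region_mask("nucleus")
    vols = history.tet_volumes(mask)
    w = vols / vols.sum()
    eps = history.strain_series(mask)
    if stress_component in _STRESS:
        sig = history.stress_series(mask)[:, :, _STRESS[stress_component]] @ w
    else:
        sig = volume_average(history, "nucleus", stress_component)
    return NuclearStrainSeries(
        times=history.times,
        mean_eps_xx=eps[:, :, 0] @ w,
        mean_eps_yy=eps[:, :, 1] @ w,
        mean_eps_zz=eps[:, :, 2] @ w,
        mean_sigma_xx=sig,
        applied_strain=history.applied_strain,
        steps_per_cycle=history.program.steps_per_cycle,
        n_cycles=history.program.n_cycles,
        stress_component=stress_component,
    )


@dataclass
class CycleSummary:
    """Per-cycle signed peak strains and the long/short-axis (X/Y) ratio."""

    cycles: np.ndarray  # 1-based
    peak_x: np.ndarray
    peak_y: np.ndarray
    peak_z: np.ndarray
    peak_applied: np.ndarray
    xy_ratio_per_cycle: np.ndarray
    xy_ratio: float  # final-cycle ratio
    xy_ratio_defined: bool = True
    _ratio_note: str = field(default="", repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "peak_x": self.peak_x,
                "peak_y": self.peak_y,
                "peak_z": self.peak_z,
                "peak_applied": self.peak_applied,
                "xy_ratio": self.xy_ratio_per_cycle,
            }
        )


def _signed_extremum(arr: np.ndarray) -> float:
    return float(arr[np.argmax(np.abs(arr))])


def per_cycle_peaks(series: NuclearStrainSeries) -> CycleSummary:
    """Signed extrema of largest magnitude per cycle window, per component.

    The headline X/Y ratio uses the final (steady-state-most) cycle; a zero
    y peak yields an undefined (NaN) ratio flagged on the summary rather
    than an infinity.
    """
    n = series.n_cycles
    px, py, pz, pa = (np.zeros(n) for _ in range(4))
    for c in range(1, n + 1):
        win = series.cycle_slice(c)
        px[c - 1] = _signed_extremum(series.mean_eps_xx[win])
        py[c - 1] = _signed_extremum(series.mean_eps_yy[win])
        pz[c - 1] = _signed_extremum(series.mean_eps_zz[win])
        pa[c - 1] = np.max(series.applied_strain[win])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(py != 0.0, px / np.where(py == 0, np.nan, py), np.nan)
    defined = py[-1] != 0.0
    return CycleSummary(
        cycles=np.arange(1, n + 1),
        peak_x=px,
        peak_y=py,
        peak_z=pz,
        peak_applied=pa,
        xy_ratio_per_cycle=ratios,
        xy_ratio=float(ratios[-1]) if defined else float("nan"),
        xy_ratio_defined=bool(defined),
        _ratio_note="" if defined else "undefined: final-cycle y peak is zero",
    )


def steady_state_cycle(series: NuclearStrainSeries, rel_tol: float = 0.01) -> int:
    """First cycle whose peaks (all components) are within ``rel_tol`` of the
    final cycle's and stay there, or :data:`NOT_CONVERGED` if that only
    happens at the final cycle itself (the series is still moving)."""
    if series.n_cycles < 3:
        raise InvalidParameterError("need at least 3 cycles")
    summ = per_cycle_peaks(series)
    first = np.full(3, NOT_CONVERGED, dtype=int)
    for i, comp in enumerate((summ.peak_x, summ.peak_y, summ.peak_z)):
        ref = comp[-1]
        scale = max(abs(ref), 1e-30)
        ok = np.abs(comp - ref) < rel_tol * scale
        # require convergence to persist through the final cycle
        idx = NOT_CONVERGED
        for c in range(len(comp)):
            if np.all(ok[c:]):
                idx = c + 1
                break
        if idx == series.n_cycles:  # only the final cycle matches itself
            idx = NOT_CONVERGED
        first[i] = idx
    if np.any(first == NOT_CONVERGED):
        return NOT_CONVERGED
    return int(first.max())
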