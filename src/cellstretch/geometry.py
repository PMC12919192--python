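"""Cell/nucleus geometry: a half-ellipsoid cell with an embedded ellipsoidal nucleus.

Coordinates: x is the cell's long axis, y the short in-plane axis, z vertical.
The basal (substrate-attached) plane is z = 0 and the origin sits at the basal
center. All lengths are in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidParameterError

__all__ = ["CellGeometry", "MeshSizing", "build_geometry"]

# Typical spread mesenchymal-stem-cell scale; explicit, config-overridable
# placeholders (semi-axes, um).
DEFAULT_CELL_SEMI_AXES = (25.0, 15.0, 6.0)
DEFAULT_NUCLEUS_SEMI_AXES = (8.0, 6.0, 3.0)
DEFAULT_NUCLEUS_CENTER = (0.0, 0.0, 3.0)
DEFAULT_MEMBRANE_THICKNESS = 0.01  # 10 nm plasma membrane


@dataclass(frozen=True)
class CellGeometry:
    """Half-ellipsoid cell (z >= 0) with an ellipsoidal nucleus inside.

    Attributes
    ----------
    cell_semi_axes : (a_x, a_y, a_z) um, a_x >= a_y (x is the long axis).
    nucleus_semi_axes : (b_x, b_y, b_z) um.
    nucleus_center : (c_x, c_y, c_z) um.
    membrane_thickness : um; the plasma membrane is treated as a thin
        viscoelastic shell on the outer curved surface, not meshed in 3D.
    """

    cell_semi_axes: tuple[float, float, float] = DEFAULT_CELL_SEMI_AXES
    nucleus_semi_axes: tuple[float, float, float] = DEFAULT_NUCLEUS_SEMI_AXES
    nucleus_center: tuple[float, float, float] = DEFAULT_NUCLEUS_CENTER
    membrane_thickness: float = DEFAULT_MEMBRANE_THICKNESS

    def __post_init__(self) -> None:
        a = np.asarray(self.cell_semi_axes, float)
        b = np.asarray(self.nucleus_semi_axes, float)
        c = np.asarray(self.nucleus_center, float)
        if np.any(a <= 0) or np.any(b <= 0):
            raise GeometryError("all semi-axes must be positive")
        if self.membrane_thickness <= 0:
            raise GeometryError("membrane thickness must be positive")
        if a[0] < a[1]:
            raise GeometryError(
                "cell a_x must be >= a_y (x is the long axis); "
                f"got a_x={a[0]}, a_y={a[1]}"
            )
        if a[0] == a[1]:
            warnings.warn(
                "cell a_x == a_y: long/short-axis (X/Y) ratio analyses are "
                "degenerate for a rotationally symmetric cell",
                stacklevel=3,
            )
        self._check_containment(a, b, c)

    @staticmethod
    def _check_containment(a, b, c, n_samples: int = 2048) -> None:
        """Nucleus surface must lie strictly inside the cell ellipsoid and at
        z >= 0 (touching the basal plane is allowed, with a warning)."""
        pts = _fibonacci_sphere(n_samples) * b + c
        # include the six axis-extreme surface points exactly
        ext = np.concatenate([np.diag(b), -np.diag(b)]) + c
        pts = np.vstack([pts, ext])
        level = np.sum((pts / a) ** 2, axis=1)
        if np.any(level > 1.0 + 1e-9):
            worst = pts[np.argmax(level)]
            axis = "xyz"[int(np.argmax(np.abs(worst) / a))]
            raise GeometryError(
                "nucleus surface extends outside the cell ellipsoid "
                f"(worst offending axis: {axis}, sample point {worst.round(3)})"
            )
        if level.max() > 1.0 - 1e-9:
            warnings.warn(
                "nucleus touches the cell surface (tangent contact)",
                stacklevel=4,
            )
        zmin = pts[:, 2].min()
        if zmin < -1e-9:
            raise GeometryError(
                f"nucleus surface extends below the basal plane (min z = {zmin:.4g})"
            )
        if zmin < 1e-9:
            warnings.warn(
                "nucleus touches the basal plane z=0 (tangent contact)",
                stacklevel=4,
            )

    def inside_cell(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask: points inside the half-ellipsoid cell domain."""
        a = np.asarray(self.cell_semi_axes)
        pts = np.atleast_2d(pts)
        return (np.sum((pts / a) ** 2, axis=1) <= 1.0) & (pts[:, 2] >= 0.0)

    def inside_nucleus(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask: points inside the nucleus ellipsoid."""
        b = np.asarray(self.nucleus_semi_axes)
        c = np.asarray(self.nucleus_center)
        pts = np.atleast_2d(pts)
        return np.sum(((pts - c) / b) ** 2, axis=1) <= 1.0

    @property
    def cell_volume(self) -> float:
        """Analytic half-ellipsoid volume (2/3) pi a_x a_y a_z, um^3."""
        a = self.cell_semi_axes
        return 2.0 / 3.0 * np.pi * a[0] * a[1] * a[2]

    @property
    def nucleus_volume(self) -> float:
        """Analytic nucleus volume (full ellipsoid; it lies in z >= 0), um^3."""
        b = self.nucleus_semi_axes
        return 4.0 / 3.0 * np.pi * b[0] * b[1] * b[2]


@dataclass(frozen=True)
class MeshSizing:
    """Mesh sizing: global cap ``h_max``, growth rate, and refined size near
    the nucleus surface and the outer membrane surface.

    Defaults are the reference sizing (h_max 0.99 um, growth 1.4, refined
    0.159 um); desk-scale runs use the coarser ``ci()`` profile.
    """

    h_max: float = 0.99
    growth_rate: float = 1.4
    h_refined: float = 0.159

    def __post_init__(self) -> None:
        if self.h_max <= 0 or self.h_refined <= 0:
            raise InvalidParameterError("mesh sizes must be positive")
        if self.h_refined >= self.h_max:
            raise InvalidParameterError("h_refined must be smaller than h_max")
        if self.growth_rate <= 1.0:
            raise InvalidParameterError("growth_rate must exceed 1")

    @classmethod
    def ci(cls) -> "MeshSizing":
        """Coarse desk-scale profile used by tests and the default sweep."""
        return cls(h_max=2.5, growth_rate=1.4, h_refined=1.0)


def build_geometry(config: dict | None = None, **kwargs) -> CellGeometry:
    """Build and validate a :class:`CellGeometry` from a config mapping.

    Recognized keys: ``cell_semi_axes_um``, ``nucleus_semi_axes_um``,
    ``nucleus_center_um``, ``membrane_thickness_um``; keyword arguments of
    :class:`CellGeometry` are also accepted directly.
    """
    cfg = dict(config or {})
    cfg.update(kwargs)
    mapping = {
        "cell_semi_axes_um": "cell_semi_axes",
        "nucleus_semi_axes_um": "nucleus_semi_axes",
        "nucleus_center_um": "nucleus_center",
        "membrane_thickness_um": "membrane_thickness",
    }
    fields = {}
    for key, val in cfg.items():
        name = mapping.get(key, key)
        if name not in CellGeometry.__dataclass_fields__:
            raise InvalidParameterError(f"unknown geometry key {key!r}")
        fields[name] = tuple(val) if np.ndim(val) else float(val)
    return CellGeometry(**fields)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
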