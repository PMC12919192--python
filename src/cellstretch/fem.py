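"""Quasi-static small-strain Kelvin-Voigt viscoelastic finite elements.

Constitutive model
------------------
Each bulk compartment (cytoplasm, nucleus) carries a scalar elasticity E (Pa)
and viscosity eta (Pa s). The 3D realization is stiffness-proportional
Kelvin-Voigt: with the isotropic Hooke tensor C(E, nu),

    sigma = C : eps + tau * C : deps/dt,      tau = eta / E,

i.e. a single relaxation time per compartment. The plasma membrane is a thin
viscoelastic shell: plane-stress constant-strain triangles on the outer
curved facets, scaled by the membrane thickness, with the same proportional
damping. Inertia is neglected (loading at <= 1 Hz is far below any inertial
time scale of a cell), so time stepping integrates

    K u + D du/dt = f(t)

with Dirichlet constraints on the basal plane following the substrate strain.
Linear P1 tetrahedra; Dirichlet elimination (not penalty); one sparse LU
factorization reused across all steps of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigurationError, InvalidParameterError, SolverError
from .geometry import CellGeometry, MeshSizing
from .meshing import (
    CYTOPLASM,
    NUCLEUS,
    LabeledMesh,
    _boundary_facets,
    mesh_geometry,
)
from .waveforms import MIN_STEPS_PER_CYCLE, StrainWaveform

__all__ = [
    "Material",
    "LoadingProgram",
    "FieldHistory",
    "default_materials",
    "assemble_operators",
    "apply_substrate_strain",
    "step",
    "run_simulation",
    "SimulationEngine",
]

#: Voigt component order used throughout (engineering shear in B matrices).
VOIGT = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass(frozen=True)
class Material:
    """Isotropic Kelvin-Voigt material: elasticity E (Pa), viscosity eta
    (Pa s), Poisson ratio nu."""

    name: str
    E: float
    eta: float
    nu: float = 0.45

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise InvalidParameterError(f"{self.name}: E must be positive")
        if self.eta < 0:
            raise InvalidParameterError(f"{self.name}: eta must be >= 0")
        if not (0.0 <= self.nu < 0.5):
            raise InvalidParameterError(f"{self.name}: nu must be in [0, 0.5)")

    @property
    def tau(self) -> float:
        """Relaxation time eta/E in seconds."""
        return self.eta / self.E

    def hooke(self) -> np.ndarray:
        """6x6 isotropic stiffness in Voigt order (engineering shears)."""
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.arange(3), np.arange(3)] += 2 * mu
        C[np.arange(3, 6), np.arange(3, 6)] = mu
        return C

    def plane_stress(self) -> np.ndarray:
        """3x3 plane-stress stiffness (for the membrane shell)."""
        f = self.E / (1 - self.nu**2)
        return f * np.array(
            [[1, self.nu, 0], [self.nu, 1, 0], [0, 0, (1 - self.nu) / 2.0]]
        )


def default_materials() -> dict[str, Material]:
    """Literature-based compartment properties of a generic adherent cell:
    membrane 2.98 kPa / 4.01 kPa s, cytoplasm 4 kPa / 5.43 kPa s, nucleus
    2.01 kPa / 0.97 kPa s; nu = 0.45 (near-incompressible) throughout."""
    return {
        "membrane": Material("membrane", 2980.0, 4010.0, 0.45),
        "cytoplasm": Material("cytoplasm", 4000.0, 5430.0, 0.45),
        "nucleus": Material("nucleus", 2010.0, 970.0, 0.45),
    }


@dataclass(frozen=True)
class LoadingProgram:
    """Cyclic substrate-strain loading program.

    ``mode="equibiaxial"`` stretches the basal plane equally in x and y;
    ``mode="anisotropic"`` applies u_y = y_to_x_ratio * eps * y instead.
    ``boundary_mode="affine_all"`` prescribes the affine displacement map on
    every boundary node (patch-test mode) rather than only on the basal plane.
    """

    waveform: StrainWaveform
    n_cycles: int = 10
    steps_per_cycle: int = MIN_STEPS_PER_CYCLE
    mode: str = "equibiaxial"
    y_to_x_ratio: float = 1.0
    scheme: str = "backward_euler"
    rho_inf: float = 0.85
    boundary_mode: str = "basal"

    def __post_init__(self) -> None:
        if self.steps_per_cycle < MIN_STEPS_PER_CYCLE:
            raise InvalidParameterError(
                f"steps_per_cycle must be >= {MIN_STEPS_PER_CYCLE}"
            )
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")
        if self.mode not in ("equibiaxial", "anisotropic"):
            raise InvalidParameterError(f"unknown loading mode {self.mode!r}")
        if not (-0.5 <= self.y_to_x_ratio <= 1.0):
            raise InvalidParameterError("y_to_x_ratio must be in [-0.5, 1]")
        if self.scheme not in ("backward_euler", "generalized_alpha"):
            raise InvalidParameterError(f"unknown scheme {self.scheme!r}")
        if self.boundary_mode not in ("basal", "affine_all"):
            raise InvalidParameterError(f"unknown boundary_mode {self.boundary_mode!r}")

    @property
    def dt(self) -> float:
        return self.waveform.period / self.steps_per_cycle

    @property
    def n_steps(self) -> int:
        return self.n_cycles * self.steps_per_cycle


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _tet_gradients(verts: np.ndarray, tets: np.ndarray):
    """Shape-function gradients (m,4,3) and volumes (m,) for P1 tets."""
    p = verts[tets]
    J = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if np.any(vol <= 0):
        raise SolverError("mesh contains non-positively-oriented tetrahedra")
    Jinv = np.linalg.inv(J)
    g123 = Jinv.transpose(0, 2, 1)  # gradients of N1..N3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def _element_stiffness(C: np.ndarray, grads: np.ndarray, vol: np.ndarray):
    """Dense element stiffness matrices (m,12,12) for one Hooke tensor."""
    m = len(vol)
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 1] = gz
        B[:, 5, c + 2] = gy
    CB = np.einsum("ij,mjk->mik", C, B)
    return np.einsum("mji,mjk,m->mik", B, CB, vol), B


def _membrane_elements(mesh: LabeledMesh, mat: Material, thickness: float):
    """Shell stiffness (plane-stress CST x thickness) on membrane facets.

    Returns (m, 9, 9) global-frame element matrices and the facet node array.
    """
    tris = mesh.membrane_facets
    if len(tris) == 0:
        return np.zeros((0, 9, 9)), tris
    p = mesh.vertices[tris]  # (m, 3, 3)
    e1 = p[:, 1] - p[:, 0]
    e2raw = p[:, 2] - p[:, 0]
    n = np.cross(e1, e2raw)
    area2 = np.linalg.norm(n, axis=1)
    n = n / area2[:, None]
    e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    # Local 2D coordinates of the three vertices.
    x2 = np.einsum("mi,mi->m", p[:, 1] - p[:, 0], e1)
    x3 = np.einsum("mi,mi->m", p[:, 2] - p[:, 0], e1)
    y3 = np.einsum("mi,mi->m", p[:, 2] - p[:, 0], e2)
    area = 0.5 * area2
    m = len(tris)
    # CST shape-function derivatives in local frame.
    b = np.zeros((m, 3, 2))  # dN_a/dx, dN_a/dy
    b[:, 0, 0] = (0.0 - y3) ; b[:, 0, 1] = (x3 - x2)
    b[:, 1, 0] = y3         ; b[:, 1, 1] = -x3
    b[:, 2, 0] = 0.0        ; b[:, 2, 1] = x2
    b /= (2 * area)[:, None, None]
    B = np.zeros((m, 3, 6))
    for a in range(3):
        B[:, 0, 2 * a] = b[:, a, 0]
        B[:, 1, 2 * a + 1] = b[:, a, 1]
        B[:, 2, 2 * a] = b[:, a, 1]
        B[:, 2, 2 * a + 1] = b[:, a, 0]
    C = mat.plane_stress()
    Kloc = np.einsum("mji,jk,mkl,m->mil", B, C, B, area * thickness)
    # Transformation: local (u,v) per node from global (ux,uy,uz).
    T = np.zeros((m, 6, 9))
    for a in range(3):
        T[:, 2 * a, 3 * a : 3 * a + 3] = e1
        T[:, 2 * a + 1, 3 * a : 3 * a + 3] = e2
    Kglob = np.einsum("mji,mjk,mkl->mil", T, Kloc, T)
    return Kglob, tris


def _scatter(Ke: np.ndarray, conn: np.ndarray, ndof: int) -> sp.csr_matrix:
    """Scatter dense element matrices into a global CSR matrix."""
    npern = Ke.shape[1] // 3
    dofs = (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), -1)
    rows = np.repeat(dofs, 3 * npern, axis=1).ravel()
    cols = np.tile(dofs, (1, 3 * npern)).ravel()
    A = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof))
    return A.tocsr()


def assemble_operators(
    mesh: LabeledMesh,
    materials: dict[str, Material],
    membrane_material: Material | None = None,
    membrane_thickness: float = 0.01,
):
    """Assemble the elastic (K) and viscous (D) operators.

    ``materials`` maps region names to bulk materials; the optional membrane
    material adds an in-plane shell contribution on the membrane facets. Both
    operators are symmetric positive-semidefinite; K becomes positive-definite
    once the basal constraints are applied.
    """
    region_ids = {CYTOPLASM: "cytoplasm", NUCLEUS: "nucleus"}
    ndof = 3 * mesh.n_vertices
    grads, vol = _tet_gradients(mesh.vertices, mesh.tets)

    Ke = np.zeros((mesh.n_tets, 12, 12))
    damp = np.zeros(mesh.n_tets)
    for label in np.unique(mesh.region):
        name = region_ids.get(int(label))
        if name not in materials:
            raise ConfigurationError(f"no material assigned to region {name or label!r}")
        mat = materials[name]
        mask = mesh.region == label
        Ke[mask], _ = _element_stiffness(mat.hooke(), grads[mask], vol[mask])
        damp[mask] = mat.tau
    K = _scatter(Ke, mesh.tets, ndof)
    D = _scatter(Ke * damp[:, None, None], mesh.tets, ndof)

    if membrane_material is not None and len(mesh.membrane_facets):
        Km, tris = _membrane_elements(mesh, membrane_material, membrane_thickness)
        K = K + _scatter(Km, tris, ndof)
        D = D + _scatter(Km * membrane_material.tau, tris, ndof)
    return K.tocsr(), D.tocsr()


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------

def apply_substrate_strain(
    mesh: LabeledMesh,
    eps: float,
    mode: str = "equibiaxial",
    y_to_x_ratio: float = 1.0,
    boundary_mode: str = "basal",
    nu: float = 0.45,
):
    """Dirichlet constraints for an applied substrate strain ``eps``.

    Basal mode (the physical configuration): every node on z = 0 follows the
    membrane affinely, u = (eps x, eps_y y, 0) with eps_y = eps (equibiaxial)
    or eps_y = y_to_x_ratio * eps (anisotropic). Patch-test mode
    (``affine_all``) prescribes the laterally-stretched, Poisson-contracted
    affine field u = (eps x, eps_y y, -nu (1+r)/(1-nu) eps z) on all boundary
    nodes.

    Returns ``(dof_indices, values)``.
    """
    if abs(eps) >= 0.5:
        raise InvalidParameterError("|eps| must be < 0.5")
    ry = 1.0 if mode == "equibiaxial" else y_to_x_ratio
    if boundary_mode == "basal":
        nodes = mesh.basal_nodes
        coords = mesh.vertices[nodes]
        uz = np.zeros(len(nodes))
    elif boundary_mode == "affine_all":
        faces = _boundary_facets(mesh.tets)
        nodes = np.unique(faces)
        coords = mesh.vertices[nodes]
        c = nu * (1.0 + ry) / (1.0 - nu)
        uz = -c * eps * coords[:, 2]
    else:
        raise InvalidParameterError(f"unknown boundary_mode {boundary_mode!r}")
    dofs = np.concatenate([3 * nodes, 3 * nodes + 1, 3 * nodes + 2])
    vals = np.concatenate([eps * coords[:, 0], ry * eps * coords[:, 1], uz])
    return dofs, vals


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

class ViscoelasticStepper:
    """Implicit time stepping of K u + D du/dt = f with fixed dt.

    Backward Euler (default) or the generalized-alpha method for first-order
    systems (Jansen-Whiting-Hulbert parametrization by its spectral radius
    ``rho_inf``). The constrained sparse system is factorized once.
    """

    def __init__(
        self,
        K: sp.csr_matrix,
        D: sp.csr_matrix,
        dt: float,
        constrained_dofs: np.ndarray,
        scheme: str = "backward_euler",
        rho_inf: float = 0.85,
    ):
        if dt <= 0:
            raise InvalidParameterError("dt must be positive")
        ndof = K.shape[0]
        self.K, self.D, self.dt, self.scheme = K, D, dt, scheme
        self.cons = np.asarray(constrained_dofs, dtype=np.int64)
        free = np.ones(ndof, bool)
        free[self.cons] = False
        self.free = np.flatnonzero(free)
        if scheme == "backward_euler":
            self.alpha_f, self.c_v = 1.0, 1.0 / dt
        elif scheme == "generalized_alpha":
            am = 0.5 * (3.0 - rho_inf) / (1.0 + rho_inf)
            af = 1.0 / (1.0 + rho_inf)
            self.gamma = 0.5 + am - af
            self.alpha_m, self.alpha_f = am, af
            self.c_v = am / (self.gamma * dt)
        else:
            raise InvalidParameterError(f"unknown scheme {scheme!r}")
        A = (self.alpha_f * K + self.c_v * D).tocsc()
        A_ff = A[self.free][:, self.free]
        self.A_fc = A[self.free][:, self.cons]
        try:
            self.lu = splu(A_ff.tocsc())
        except RuntimeError as exc:
            raise SolverError(
                "constrained system is singular; boundary constraints are "
                f"likely missing ({exc})"
            ) from exc
        self.v = np.zeros(ndof)  # du/dt state (generalized-alpha only)

    def step(self, u_prev: np.ndarray, cons_values: np.ndarray, f_ext=None):
        """Advance one time step; returns the full displacement vector."""
        ndof = self.K.shape[0]
        f = np.zeros(ndof) if f_ext is None else np.asarray(f_ext, float)
        if self.scheme == "backward_euler":
            rhs = f + self.D @ (u_prev / self.dt)
        else:
            am, af, g, dt = self.alpha_m, self.alpha_f, self.gamma, self.dt
            vcoef = (1.0 - am) - am * (1.0 - g) / g
            rhs = (
                f
                - self.K @ ((1.0 - af) * u_prev)
                - self.D @ (vcoef * self.v)
                + self.D @ ((am / (g * dt)) * u_prev)
            )
        u = np.empty(ndof)
        u[self.cons] = cons_values
        u[self.free] = self.lu.solve(rhs[self.free] - self.A_fc @ cons_values)
        if self.scheme == "generalized_alpha":
            g, dt = self.gamma, self.dt
            self.v = (u - u_prev) / (g * dt) - (1.0 - g) / g * self.v
        return u

    def residual(self, u: np.ndarray, u_prev: np.ndarray, f_ext=None) -> float:
        """Relative residual of the free equations at the accepted state."""
        f = np.zeros(self.K.shape[0]) if f_ext is None else f_ext
        r = (self.alpha_f * self.K + self.c_v * self.D) @ u - (
            f + self.c_v * self.D @ u_prev
        )
        # Only meaningful for backward Euler; generalized-alpha mixes levels.
        num = np.linalg.norm(r[self.free])
        den = max(np.linalg.norm(u[self.free]) * np.linalg.norm(self.K.diagonal()), 1e-30)
        return num / den


def step(
    K,
    D,
    u_prev: np.ndarray,
    constraints_t,
    dt: float,
    scheme: str = "backward_euler",
    period: float | None = None,
    f_ext=None,
    state: dict | None = None,
) -> np.ndarray:
    """Single implicit update (functional wrapper over the stepper).

    ``constraints_t`` is a ``(dof_indices, values)`` pair; ``period``, when
    given, enforces the dt <= T/50 step-size limit. For repeated stepping use
    :class:`ViscoelasticStepper`, which reuses the factorization (a ``state``
    dict can carry it between calls here).
    """
    if period is not None and dt > period / MIN_STEPS_PER_CYCLE * (1 + 1e-12):
        raise InvalidParameterError(
            f"dt={dt} exceeds the step-size limit T/50={period / 50}"
        )
    dofs, vals = constraints_t
    key = (dt, scheme, tuple(np.asarray(dofs).tolist()))
    stepper = None
    if state is not None:
        stepper = state.get(key)
    if stepper is None:
        stepper = ViscoelasticStepper(
            sp.csr_matrix(K), sp.csr_matrix(D), dt, np.asarray(dofs), scheme
        )
        if state is not None:
            state[key] = stepper
    return stepper.step(np.asarray(u_prev, float), np.asarray(vals, float), f_ext)


# ---------------------------------------------------------------------------
# Field history and simulation driver
# ---------------------------------------------------------------------------

@dataclass
class FieldHistory:
    """Time-indexed displacement history with lazy strain/stress evaluation.

    Displacements are stored per step; per-tet strain and stress tensors are
    reconstructed on demand (optionally on a region mask) to keep memory
    bounded. Strain-rate for the viscous stress uses central differences of
    the stored strain history (second order; one-sided at the ends).
    """

    mesh: LabeledMesh
    times: np.ndarray  # (n_steps + 1,)
    displacements: np.ndarray  # (n_steps + 1, n_vertices, 3)
    applied_strain: np.ndarray  # (n_steps + 1,)
    program: LoadingProgram
    materials: dict[str, Material]
    _grads: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self._grads is None:
            self._grads, self._vols = _tet_gradients(self.mesh.vertices, self.mesh.tets)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    def strain_series(self, tet_mask=None) -> np.ndarray:
        """Per-tet small-strain tensors, shape (n_times, n_sel, 6).

        Components in Voigt order xx, yy, zz, xy, xz, yz with *tensor* shears
        (eps_xy, not 2 eps_xy).
        """
        if tet_mask is None:
            tet_mask = np.ones(self.mesh.n_tets, bool)
        conn = self.mesh.tets[tet_mask]
        g = self._grads[tet_mask]  # (m, 4, 3)
        u = self.displacements[:, conn, :]  # (t, m, 4, 3)
        grad_u = np.einsum("tmai,maj->tmij", u, g)
        eps = 0.5 * (grad_u + grad_u.transpose(0, 1, 3, 2))
        ii = ([0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2])
        return eps[:, :, ii[0], ii[1]]

    def stress_series(self, tet_mask=None) -> np.ndarray:
        """Per-tet Kelvin-Voigt stress tensors (Pa), same layout as strain."""
        if tet_mask is None:
            tet_mask = np.ones(self.mesh.n_tets, bool)
        eps = self.strain_series(tet_mask)
        deps = np.gradient(eps, self.times, axis=0)
        region = self.mesh.region[tet_mask]
        out = np.zeros_like(eps)
        for label, name in ((CYTOPLASM, "cytoplasm"), (NUCLEUS, "nucleus")):
            sel = region == label
            if not np.any(sel):
                continue
            mat = self.materials[name]
            C = mat.hooke()
            # Engineering-shear Voigt product on tensor-shear storage.
            scale = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
            e = eps[:, sel] * scale
            de = deps[:, sel] * scale
            out[:, sel] = np.einsum("ij,tmj->tmi", C, e + mat.tau * de)
        return out

    def tet_volumes(self, tet_mask=None) -> np.ndarray:
        if tet_mask is None:
            return self._vols
        return self._vols[tet_mask]


class SimulationEngine:
    """Reusable assembled model: mesh + operators + cached factorizations."""

    def __init__(
        self,
        mesh: LabeledMesh,
        materials: dict[str, Material] | None = None,
        with_membrane: bool = True,
        membrane_thickness: float | None = None,
    ):
        self.mesh = mesh
        self.materials = materials or default_materials()
        mem = self.materials.get("membrane") if with_membrane else None
        self.membrane_thickness = membrane_thickness or 0.01
        self.K, self.D = assemble_operators(
            mesh, self.materials, mem, self.membrane_thickness
        )
        self._steppers: dict = {}

    def _stepper(self, program: LoadingProgram, dofs: np.ndarray):
        key = (
            round(program.dt, 15),
            program.scheme,
            program.boundary_mode,
            program.mode,
            round(program.y_to_x_ratio, 12),
        )
        if key not in self._steppers:
            self._steppers[key] = ViscoelasticStepper(
                self.K, self.D, program.dt, dofs, program.scheme, program.rho_inf
            )
        st = self._steppers[key]
        st.v = np.zeros(self.K.shape[0])  # reset rate state between runs
        return st

    def run(self, program: LoadingProgram) -> FieldHistory:
        w = program.waveform
        nu = self.materials["cytoplasm"].nu
        # Unit-strain constraint pattern; constraint values scale with eps(t).
        dofs, unit_vals = apply_substrate_strain(
            self.mesh, 1e-3, program.mode, program.y_to_x_ratio,
            program.boundary_mode, nu,
        )
        unit_vals = unit_vals / 1e-3
        stepper = self._stepper(program, dofs)
        n = program.n_steps
        times = np.arange(n + 1) * program.dt
        eps_t = w(times)
        U = np.zeros((n + 1, self.mesh.n_vertices, 3))
        u = np.zeros(3 * self.mesh.n_vertices)
        for i in range(1, n + 1):
            try:
                u = stepper.step(u, eps_t[i] * unit_vals)
            except Exception as exc:
                raise SolverError(f"time step {i} failed: {exc}") from exc
            U[i] = u.reshape(-1, 3)
        return FieldHistory(
            mesh=self.mesh,
            times=times,
            displacements=U,
            applied_strain=eps_t,
            program=program,
            materials=self.materials,
        )


def run_simulation(
    geometry: CellGeometry,
    sizing: MeshSizing,
    materials: dict[str, Material] | None = None,
    program: LoadingProgram | None = None,
    mesh: LabeledMesh | None = None,
) -> FieldHistory:
    """Mesh the cell, assemble the viscoelastic model and advance the loading
    program from an undeformed initial state. Fully deterministic."""
    if program is None:
        raise InvalidParameterError("a LoadingProgram is required")
    if mesh is None:
        mesh = mesh_geometry(geometry, sizing)
    engine = SimulationEngine(
        mesh, materials, membrane_thickness=geometry.membrane_thickness
    )
    return engine.run(program)
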