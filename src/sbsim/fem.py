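"""Geometrically nonlinear membrane finite elements for the eye shell.

Constant-strain triangles undergoing large deformation carry the 3-D
fibre-reinforced hyperelastic law through a plane-stress condensation: the
thickness stretch of each element is found by a local Newton solve enforcing
zero through-thickness Cauchy stress, and the condensed in-plane stress
drives the nodal forces.  Intraocular pressure is a follower load applied
through its enclosed-volume potential -p V (exact for a closed shell under
uniform pressure), so the discrete problem has a potential and the internal
force is the gradient of the total energy.  The lens interior is an
equivalent volumetric spring on the capsule's enclosed volume, and the
zonules are linear attachment springs; the volumetric spring's rank-one
tangent is applied with a Woodbury update rather than assembled.

Bending resistance enters through discrete hinges on element edges at the
physical plate stiffness, making this a thin shell rather than a pure
membrane; an optional content-rigidity term regulates the enclosed globe
volume (ocular rigidity).  Equilibrium is found by Newton's method with
consistent (per-element finite-differenced) tangents, Levenberg damping
with energy-descent acceptance, load stepping with adaptive halving, and a
clipped-Newton freewheel for traversing snap-through folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    MaterialParams,
    TISSUE_REGISTRY,
    _fiber_dpsi,
    _matrix_range_guard_dpsi,
    pk2_from_C,
)
from .geometry import SurfaceMesh

__all__ = [
    "BoundaryConditions",
    "SolverSettings",
    "SolutionState",
    "DivergenceError",
    "MembraneSystem",
    "solve_static",
    "membrane_constitutive_condensation",
    "default_rigid_constraints",
]

#: mesh region -> material registry label
REGION_TISSUE = {
    "cornea": "cornea",
    "limbus": "limbus",
    "sclera": "sclera",
    "nerve": "nerve",
    "lens": "lens_capsule",
}


class DivergenceError(RuntimeError):
    """Raised when Newton fails below the minimum load increment."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


@dataclass
class BoundaryConditions:
    """Follower pressure (MPa) plus prescribed nodal displacements.

    ``prescribed`` maps (node id, component 0..2) to a displacement in mm;
    zero-valued entries act as supports.  Rigid-body constraints are ordinary
    zero prescriptions kept in a separate set for bookkeeping.
    """

    pressure: float = 0.0
    prescribed: dict[tuple[int, int], float] = field(default_factory=dict)
    rigid_body_constraints: dict[tuple[int, int], float] = field(default_factory=dict)

    def all_prescribed(self) -> dict[tuple[int, int], float]:
        overlap = set(self.prescribed) & set(self.rigid_body_constraints)
        if overlap:
            raise ValueError(f"prescribed dofs overlap rigid-body constraints: {sorted(overlap)}")
        merged = dict(self.rigid_body_constraints)
        merged.update(self.prescribed)
        return merged


@dataclass
class SolverSettings:
    newton_rel_tol: float = 1e-8
    newton_abs_tol: float = 1e-10  # N
    max_newton_iters: int = 30
    load_steps: int = 10
    line_search: bool = False
    min_step_fraction: float = 1.0 / 256.0
    #: temporary spring-to-previous-converged-state stiffness (N/mm) used
    #: while ramping through wrinkling instabilities; the final state of a
    #: solve is always re-equilibrated without it
    stabilization: float = 0.0
    #: additional force-residual convergence criterion, relative to the
    #: internal-force norm, active only for stabilized (wrinkling-regime)
    #: solves where micro-cycles prevent deep Newton convergence
    force_rel_tol: float = 3e-5


@dataclass
class SolutionState:
    """Converged equilibrium fields."""

    displacements: np.ndarray
    element_F: np.ndarray  # per-element total deformation gradient (local stress-free frame -> global)
    cauchy: np.ndarray  # per-element Cauchy stress, global frame (MPa)
    max_principal_stress: np.ndarray
    log_strain: np.ndarray  # max principal logarithmic strain
    residual_norm: float
    newton_history: list = field(default_factory=list)

    def coords(self, mesh: SurfaceMesh) -> np.ndarray:
        return mesh.nodes + self.displacements


def default_rigid_constraints(mesh: SurfaceMesh) -> dict[tuple[int, int], float]:
    """3-2-1 suppression of the six rigid modes on three band-ring nodes.

    Node A (near phi=0): all components; B (near phi=90deg): x and z;
    C (near phi=180deg): z.  Chosen on the band ring so any local reaction
    artefact stays away from the optical axis where lengths are measured.
    """
    ring = mesh.region_map["band_candidate"]
    center = 12.5
    arcs = mesh.arc_from_limbus[ring]
    sel = ring[np.abs(arcs - arcs[np.argmin(np.abs(arcs - center))]) < 1e-9]
    phi = np.arctan2(mesh.nodes[sel, 1], mesh.nodes[sel, 0])

    def nearest(target):
        return int(sel[np.argmin(np.abs(np.angle(np.exp(1j * (phi - target)))))])

    a, b, c = nearest(0.0), nearest(np.pi / 2), nearest(np.pi)
    return {(a, 0): 0.0, (a, 1): 0.0, (a, 2): 0.0, (b, 0): 0.0, (b, 2): 0.0, (c, 2): 0.0}


# ---------------------------------------------------------------------------
# element-level machinery
# ---------------------------------------------------------------------------

_PARAM_FIELDS = ("D_penalty", "C1", "C2", "k1", "k2", "k3", "k4")


def _cross_matrix(v: np.ndarray) -> np.ndarray:
    """Batched skew matrices [v]_x, shape (..., 3, 3)."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def _solve_lam3(tr2, tr2sq, det2, q4, q6, par, lam0, tol=5e-16, max_iter=100):
    """Thickness stretch making dPsi/dlam3 = 0 (zero normal Cauchy stress).

    All arguments are per-element arrays; the residual derivative is obtained
    by a small finite difference of the analytic first derivative.
    """

    def dpsi(lam):
        J = np.sqrt(det2) * lam
        Jm23 = J ** (-2.0 / 3.0)
        I1 = Jm23 * (tr2 + lam * lam)
        dI1 = Jm23 * (2.0 * lam - 2.0 / (3.0 * lam) * (tr2 + lam * lam))
        Jm43 = Jm23 * Jm23
        s2 = tr2sq + lam**4
        dI2 = I1 * dI1 - 0.5 * (-(4.0 / (3.0 * lam)) * Jm43 * s2 + Jm43 * 4.0 * lam**3)
        I4 = Jm23 * q4
        I6 = Jm23 * q6
        out = np.log(J) / (par["D_penalty"] * lam)
        out = out + 0.5 * par["C1"] * dI1 + 0.5 * par["C2"] * dI2
        out = out + _matrix_range_guard_dpsi(I1, par["C1"], par["C2"]) * dI1
        out = out + _fiber_dpsi(I4, par["k1"], par["k2"]) * (-2.0 / (3.0 * lam)) * I4
        out = out + _fiber_dpsi(I6, par["k3"], par["k4"]) * (-2.0 / (3.0 * lam)) * I6
        return out

    lam = np.clip(lam0, 0.2, 5.0).copy()
    for _ in range(max_iter):
        r = dpsi(lam)
        h = 1e-7 * lam
        drdl = (dpsi(lam + h) - r) / h
        step = np.where(np.abs(drdl) > 0, r / np.where(drdl == 0, 1.0, drdl), 0.0)
        step = np.clip(step, -0.2 * lam, 0.2 * lam)
        lam = lam - step
        if np.max(np.abs(step) / lam) < tol:
            break
    return lam


class MembraneSystem:
    """Assembled membrane model: mesh + materials + optional prestrain."""

    def __init__(
        self,
        mesh: SurfaceMesh,
        materials: dict[str, MaterialParams] | None = None,
        prestrain=None,
        bending_scale: float = 1.0,
    ):
        self.mesh = mesh
        registry = materials or TISSUE_REGISTRY
        tri = mesh.elements
        X = mesh.nodes[tri]  # (E, 3 nodes, 3)
        d1 = X[:, 1] - X[:, 0]
        d2 = X[:, 2] - X[:, 0]
        nrm = np.cross(d1, d2)
        self.A0 = 0.5 * np.linalg.norm(nrm, axis=1)
        self.normal0 = nrm / (2.0 * self.A0[:, None])
        self.e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        self.e2 = np.cross(self.normal0, self.e1)
        # reference in-plane edge matrix and shape-function gradients
        M = np.empty((tri.shape[0], 2, 2))
        M[:, 0, 0] = (d1 * self.e1).sum(1)
        M[:, 1, 0] = (d1 * self.e2).sum(1)
        M[:, 0, 1] = (d2 * self.e1).sum(1)
        M[:, 1, 1] = (d2 * self.e2).sum(1)
        Minv = np.linalg.inv(M)
        g = np.empty((tri.shape[0], 3, 2))
        g[:, 1] = Minv[:, 0, :]
        g[:, 2] = Minv[:, 1, :]
        g[:, 0] = -(g[:, 1] + g[:, 2])
        self.g = g
        self.t0 = mesh.thickness[tri].mean(axis=1)

        self.par = {}
        labels = np.array([REGION_TISSUE[r] for r in mesh.element_region])
        for f in _PARAM_FIELDS:
            self.par[f] = np.array([getattr(registry[l], f) for l in labels])

        # fibre directions in the element plane (2-vectors, zero if inactive)
        def to_plane(v):
            p = np.stack([(v * self.e1).sum(1), (v * self.e2).sum(1)], axis=1)
            n = np.linalg.norm(p, axis=1, keepdims=True)
            return np.where(n > 1e-12, p / np.where(n > 0, n, 1.0), 0.0)

        self.m2 = to_plane(mesh.fiber_m)
        self.n2 = to_plane(mesh.fiber_n)

        self.set_prestrain(prestrain)
        self.lam3_cache = np.ones(tri.shape[0])
        self._build_bending(bending_scale)
        if prestrain is not None and getattr(prestrain, "bend_theta0", None) is not None:
            self.bend_theta0 = prestrain.bend_theta0.copy()

        # pressure acts on the globe component only
        self.globe_els = mesh.globe_elements
        self.lens_els = mesh.lens_elements
        if len(self.lens_els):
            self.V0_lens = self._volume(mesh.nodes, self.lens_els)
            self.beta_lens = mesh.lens_bulk_modulus / self.V0_lens
        else:
            self.V0_lens = 0.0
            self.beta_lens = 0.0
        # content regulation: wall pressure p0 - kv (V - V0) about the
        # reference enclosed volume (ocular rigidity; kv = 0 disables)
        self.kv = float(getattr(mesh, "content_rigidity", 0.0))
        self.V0_globe = self._volume(mesh.nodes, self.globe_els) if len(self.globe_els) else 0.0

        self.ndof = 3 * mesh.n_nodes
        s = mesh.springs
        self.spring_pairs = s[:, :2].astype(int) if len(s) else np.zeros((0, 2), int)
        self.spring_k = s[:, 2] if len(s) else np.zeros(0)
        self.spring_ref = (
            mesh.nodes[self.spring_pairs[:, 0]] - mesh.nodes[self.spring_pairs[:, 1]]
            if len(s)
            else np.zeros((0, 3))
        )
        if prestrain is not None and getattr(prestrain, "spring_ref", None) is not None:
            self.spring_ref = prestrain.spring_ref.copy()
        self.radial_bound = None  # optional unilateral support (see set_radial_bound)

    # -- bending regularisation -------------------------------------------

    def _build_bending(self, scale: float) -> None:
        """Discrete hinge bending at the physical thin-shell stiffness.

        Each interior edge carries the energy 0.5 K_e (theta - theta0)^2 with
        K_e ~ D_b * 3 |e|^2 / (A1 + A2) and D_b = E t^3 / 9 the plate bending
        stiffness (E from the linearised matrix moduli, nu = 1/2).  This is
        the leading bending resistance of the wall; it suppresses the
        spurious inextensional dimpling a pure membrane mesh admits.
        """
        tri = self.mesh.elements
        edge_map: dict[tuple[int, int], list] = {}
        for t in range(tri.shape[0]):
            a, b, c = tri[t]
            for p, q, o in ((a, b, c), (b, c, a), (c, a, b)):
                edge_map.setdefault((min(p, q), max(p, q)), []).append((p, q, o, t))
        quads = []  # x0 (opp 1), x1 (opp 2), x2, x3 (edge), tri1, tri2
        for (_, _), lst in edge_map.items():
            if len(lst) == 2:
                (p, q, o1, t1), (_, _, o2, t2) = lst
                quads.append((o1, o2, p, q, t1, t2))
        quads = np.array(quads, dtype=int)
        self.bend_nodes = quads[:, :4]
        t1, t2 = quads[:, 4], quads[:, 5]
        E_eff = 3.0 * np.maximum(self.par["C1"] + self.par["C2"], 1e-4)
        D_b = E_eff * self.t0**3 / 9.0
        X = self.mesh.nodes
        le2 = ((X[quads[:, 3]] - X[quads[:, 2]]) ** 2).sum(1)
        self.bend_k = scale * 0.5 * (D_b[t1] + D_b[t2]) * 3.0 * le2 / (self.A0[t1] + self.A0[t2])
        self.bend_theta0 = self._dihedrals(X)

    def _dihedrals(self, x: np.ndarray) -> np.ndarray:
        q = x[self.bend_nodes]
        x0, x1, x2, x3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
        e = x3 - x2
        n1 = np.cross(x2 - x0, x3 - x0)
        n2 = np.cross(x3 - x1, x2 - x1)
        eh = e / np.linalg.norm(e, axis=1, keepdims=True)
        n1h = n1 / np.linalg.norm(n1, axis=1, keepdims=True)
        n2h = n2 / np.linalg.norm(n2, axis=1, keepdims=True)
        return np.arctan2((np.cross(n1h, n2h) * eh).sum(1), (n1h * n2h).sum(1))

    def _bending_edge_forces(self, q: np.ndarray) -> np.ndarray:
        """Per-edge nodal forces dE/dx, q of shape (n_edges, 4, 3)."""
        x0, x1, x2, x3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
        e = x3 - x2
        le = np.linalg.norm(e, axis=1)
        n1 = np.cross(x2 - x0, x3 - x0)
        n2 = np.cross(x3 - x1, x2 - x1)
        nn1 = (n1 * n1).sum(1)
        nn2 = (n2 * n2).sum(1)
        eh = e / le[:, None]
        n1h = n1 / np.sqrt(nn1)[:, None]
        n2h = n2 / np.sqrt(nn2)[:, None]
        theta = np.arctan2((np.cross(n1h, n2h) * eh).sum(1), (n1h * n2h).sum(1))
        g0 = -(le / nn1)[:, None] * n1
        g1 = -(le / nn2)[:, None] * n2
        a1 = ((x3 - x0) * e).sum(1) / (le * nn1)
        a2 = ((x3 - x1) * e).sum(1) / (le * nn2)
        b1 = ((x2 - x0) * e).sum(1) / (le * nn1)
        b2 = ((x2 - x1) * e).sum(1) / (le * nn2)
        g2 = a1[:, None] * n1 + a2[:, None] * n2
        g3 = -b1[:, None] * n1 - b2[:, None] * n2
        coef = (self.bend_k * (theta - self.bend_theta0))[:, None, None]
        return coef * np.stack([g0, g1, g2, g3], axis=1)

    def _bending_energy(self, x: np.ndarray) -> float:
        d = self._dihedrals(x) - self.bend_theta0
        return 0.5 * float(np.sum(self.bend_k * d * d))

    # -- prestrain ---------------------------------------------------------

    def set_prestrain(self, prestrain) -> None:
        E = self.mesh.elements.shape[0]
        if prestrain is None:
            self.F0 = np.tile(np.eye(2), (E, 1, 1))
            self.lam30 = np.ones(E)
        else:
            self.F0 = prestrain.F0_2D.copy()
            self.lam30 = prestrain.lam30.copy()
            sref = getattr(prestrain, "spring_ref", None)
            if sref is not None and hasattr(self, "spring_ref"):
                self.spring_ref = sref.copy()
            th0 = getattr(prestrain, "bend_theta0", None)
            if th0 is not None and hasattr(self, "bend_theta0"):
                self.bend_theta0 = th0.copy()
        self.F0inv = np.linalg.inv(self.F0)
        self.detF0 = np.linalg.det(self.F0) * self.lam30
        # fibre directions pulled back to the stress-free configuration
        def pull(v2):
            w = np.einsum("eij,ej->ei", self.F0inv, v2)
            n = np.linalg.norm(w, axis=1, keepdims=True)
            return np.where(n > 1e-12, w / np.where(n > 0, n, 1.0), 0.0)

        self.m_sf = np.concatenate([pull(self.m2), np.zeros((E, 1))], axis=1)
        self.n_sf = np.concatenate([pull(self.n2), np.zeros((E, 1))], axis=1)

    # -- unilateral radial support ----------------------------------------

    def set_radial_bound(self, nodes, e_r=None, bound: float = 0.0, stiffness: float = 10.0) -> None:
        """One-sided penalty keeping nodes' radial displacement >= ``bound``.

        Models a rigid support surface (e.g. the body of an encircling band)
        below the listed nodes: tissue may lift off freely but is pushed
        back when its cylindrical-radial displacement drops below ``bound``
        (mm, negative inward).  Pass ``nodes=None`` to clear.
        """
        if nodes is None:
            self.radial_bound = None
        else:
            self.radial_bound = {
                "nodes": np.asarray(nodes, int),
                "er": np.asarray(e_r, float),
                "bound": float(bound),
                "k": float(stiffness),
            }

    def _bound_gap(self, u2: np.ndarray):
        rb = self.radial_bound
        delta = (u2[rb["nodes"], :2] * rb["er"]).sum(1)
        return np.maximum(rb["bound"] - delta, 0.0)

    def _bound_forces(self, u2: np.ndarray, f: np.ndarray) -> None:
        rb = self.radial_bound
        g = self._bound_gap(u2)
        f[rb["nodes"], :2] += (-rb["k"] * g)[:, None] * rb["er"]

    def _bound_energy(self, u2: np.ndarray) -> float:
        g = self._bound_gap(u2)
        return 0.5 * self.radial_bound["k"] * float(g @ g)

    # -- geometry helpers --------------------------------------------------

    def _volume(self, x: np.ndarray, els: np.ndarray) -> float:
        p = x[self.mesh.elements[els]]
        return float(np.einsum("ei,ei->", np.cross(p[:, 0], p[:, 1]), p[:, 2]) / 6.0)

    def _volume_gradient(self, x: np.ndarray, els: np.ndarray) -> np.ndarray:
        """dV/dx as a full (n, 3) array."""
        tri = self.mesh.elements[els]
        p = x[tri]
        grad = np.empty_like(p)
        grad[:, 0] = np.cross(p[:, 1], p[:, 2]) / 6.0
        grad[:, 1] = np.cross(p[:, 2], p[:, 0]) / 6.0
        grad[:, 2] = np.cross(p[:, 0], p[:, 1]) / 6.0
        out = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(out, tri.ravel(), grad.reshape(-1, 3))
        return out

    def _volume_hessian_blocks(self, x: np.ndarray, els: np.ndarray) -> np.ndarray:
        """Per-element 9x9 Hessian of the enclosed volume (exact)."""
        tri = self.mesh.elements[els]
        p = x[tri]
        K = np.zeros((len(els), 3, 3, 3, 3))
        # d2V/dx_a dx_b = [x_c]_x / 6 with (a,b,c) cyclic
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            blk = _cross_matrix(p[:, c]) / 6.0
            K[:, b, :, a, :] = blk
            K[:, a, :, b, :] = -blk
        return K.reshape(len(els), 9, 9)

    # -- constitutive evaluation ------------------------------------------

    def _element_state(self, xe: np.ndarray, lam3_init: np.ndarray):
        """Kinematics + condensed stress for element nodal coords ``xe`` (E,3,3)."""
        Fs = np.einsum("eai,eaj->eij", xe, self.g)  # (E, 3, 2)
        C2 = np.einsum("eki,ekj->eij", Fs, Fs)
        C2t = np.einsum("eki,ekl,elj->eij", self.F0, C2, self.F0)
        tr2 = C2t[:, 0, 0] + C2t[:, 1, 1]
        tr2sq = np.einsum("eij,eji->e", C2t, C2t)
        det2 = C2t[:, 0, 0] * C2t[:, 1, 1] - C2t[:, 0, 1] * C2t[:, 1, 0]
        m2, n2 = self.m_sf[:, :2], self.n_sf[:, :2]
        q4 = np.einsum("ei,eij,ej->e", m2, C2t, m2)
        q6 = np.einsum("ei,eij,ej->e", n2, C2t, n2)
        # deterministic init (exact for an incompressible material) keeps the
        # condensed force a pure function of the nodal coordinates
        lam3 = _solve_lam3(tr2, tr2sq, det2, q4, q6, self.par, 1.0 / np.sqrt(np.clip(det2, 1e-4, None)))
        C3 = np.zeros((len(Fs), 3, 3))
        C3[:, :2, :2] = C2t
        C3[:, 2, 2] = lam3 * lam3
        S = pk2_from_C(
            C3,
            self.par["D_penalty"],
            self.par["C1"],
            self.par["C2"],
            self.par["k1"],
            self.par["k2"],
            self.par["k3"],
            self.par["k4"],
            self.m_sf,
            self.n_sf,
        )
        return Fs, C3, S, lam3

    def _element_forces(self, xe: np.ndarray, lam3_init: np.ndarray):
        Fs, C3, S, lam3 = self._element_state(xe, lam3_init)
        Seff = np.einsum("eik,ekl,ejl->eij", self.F0, S[:, :2, :2], self.F0)
        scale = (self.A0 * self.t0 / self.detF0)[:, None, None]
        FsS = np.einsum("eij,ejk->eik", Fs, Seff)
        fe = scale * np.einsum("eik,eak->eai", FsS, self.g)
        return fe, lam3

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        """Gradient of the total energy (membrane + springs + lens volume - pV)."""
        x = self.mesh.nodes + u.reshape(-1, 3)
        fe, lam3 = self._element_forces(x[self.mesh.elements], self.lam3_cache)
        self.lam3_cache = lam3 / self.lam30
        f = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(f, self.mesh.elements.ravel(), fe.reshape(-1, 3))
        if len(self.bend_k):
            fb = self._bending_edge_forces(x[self.bend_nodes])
            np.add.at(f, self.bend_nodes.ravel(), fb.reshape(-1, 3))
        f += self._spring_forces(x)
        if self.radial_bound is not None:
            self._bound_forces(u.reshape(-1, 3), f)
        V = self._volume(x, self.lens_els)
        f += self.beta_lens * (V - self.V0_lens) * self._volume_gradient(x, self.lens_els)
        return f.ravel()

    def _spring_forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros((self.mesh.n_nodes, 3))
        if len(self.spring_k):
            d = x[self.spring_pairs[:, 0]] - x[self.spring_pairs[:, 1]] - self.spring_ref
            fs = self.spring_k[:, None] * d
            np.add.at(f, self.spring_pairs[:, 0], fs)
            np.add.at(f, self.spring_pairs[:, 1], -fs)
        return f

    def effective_pressure(self, u: np.ndarray, pressure: float) -> float:
        """Wall pressure including the content-rigidity correction."""
        if self.kv == 0.0:
            return pressure
        x = self.mesh.nodes + u.reshape(-1, 3)
        return pressure - self.kv * (self._volume(x, self.globe_els) - self.V0_globe)

    def external_force(self, u: np.ndarray, pressure: float) -> np.ndarray:
        x = self.mesh.nodes + u.reshape(-1, 3)
        p_eff = pressure
        if self.kv != 0.0:
            p_eff = pressure - self.kv * (self._volume(x, self.globe_els) - self.V0_globe)
        return p_eff * self._volume_gradient(x, self.globe_els).ravel()

    def total_energy(self, u: np.ndarray, pressure: float) -> float:
        """Potential whose gradient is internal_force - external_force."""
        x = self.mesh.nodes + u.reshape(-1, 3)
        _, C3, _, lam3 = self._element_state(x[self.mesh.elements], self.lam3_cache)
        from .constitutive import psi_from_C

        psi = psi_from_C(
            C3,
            self.par["D_penalty"],
            self.par["C1"],
            self.par["C2"],
            self.par["k1"],
            self.par["k2"],
            self.par["k3"],
            self.par["k4"],
            self.m_sf,
            self.n_sf,
        )
        W = float(np.sum(psi * self.A0 * self.t0 / self.detF0))
        if len(self.bend_k):
            W += self._bending_energy(x)
        if self.radial_bound is not None:
            W += self._bound_energy(u.reshape(-1, 3))
        if len(self.spring_k):
            d = x[self.spring_pairs[:, 0]] - x[self.spring_pairs[:, 1]] - self.spring_ref
            W += 0.5 * float(np.sum(self.spring_k * (d * d).sum(1)))
        V_l = self._volume(x, self.lens_els)
        W += 0.5 * self.beta_lens * (V_l - self.V0_lens) ** 2
        dV = self._volume(x, self.globe_els) - self.V0_globe
        W += -pressure * dV + 0.5 * self.kv * dV * dV
        return W

    # -- tangent -----------------------------------------------------------

    def _tangent(self, u: np.ndarray, pressure: float):
        """Sparse tangent (without the lens rank-one term) + Woodbury vector."""
        mesh = self.mesh
        x = mesh.nodes + u.reshape(-1, 3)
        xe = x[mesh.elements]
        f0, _ = self._element_forces(xe, self.lam3_cache)
        E = xe.shape[0]
        Ke = np.empty((E, 9, 9))
        eps = 1e-7 * max(1.0, float(np.abs(x).max()))
        for k in range(9):
            a, c = divmod(k, 3)
            pert = xe.copy()
            pert[:, a, c] += eps
            fp, _ = self._element_forces(pert, self.lam3_cache)
            Ke[:, :, k] = (fp - f0).reshape(E, 9) / eps
        Ke = 0.5 * (Ke + np.transpose(Ke, (0, 2, 1)))

        # follower-pressure and lens-volume geometric stiffness (exact)
        p_eff = pressure
        if self.kv != 0.0:
            p_eff = pressure - self.kv * (self._volume(x, self.globe_els) - self.V0_globe)
        Kp = -p_eff * self._volume_hessian_blocks(x, self.globe_els)
        V_l = self._volume(x, self.lens_els)
        Kl = self.beta_lens * (V_l - self.V0_lens) * self._volume_hessian_blocks(x, self.lens_els)

        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 9)
        rows = np.repeat(dofs, 9, axis=1).ravel()
        cols = np.tile(dofs, (1, 9)).ravel()
        vals = Ke.ravel()

        def extra(blocks, els):
            d = (3 * mesh.elements[els][:, :, None] + np.arange(3)[None, None, :]).reshape(len(els), 9)
            return (
                np.repeat(d, 9, axis=1).ravel(),
                np.tile(d, (1, 9)).ravel(),
                blocks.ravel(),
            )

        r2, c2, v2 = extra(Kp, self.globe_els)
        r3, c3, v3 = extra(Kl, self.lens_els)
        rows = np.concatenate([rows, r2, r3])
        cols = np.concatenate([cols, c2, c3])
        vals = np.concatenate([vals, v2, v3])

        if len(self.bend_k):
            qe = x[self.bend_nodes]
            fb0 = self._bending_edge_forces(qe)
            nE = qe.shape[0]
            Kb = np.empty((nE, 12, 12))
            for k in range(12):
                a, c = divmod(k, 3)
                pert = qe.copy()
                pert[:, a, c] += eps
                Kb[:, :, k] = (self._bending_edge_forces(pert) - fb0).reshape(nE, 12) / eps
            Kb = 0.5 * (Kb + np.transpose(Kb, (0, 2, 1)))
            dq = (3 * self.bend_nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(nE, 12)
            rows = np.concatenate([rows, np.repeat(dq, 12, axis=1).ravel()])
            cols = np.concatenate([cols, np.tile(dq, (1, 12)).ravel()])
            vals = np.concatenate([vals, Kb.ravel()])

        if self.radial_bound is not None:
            rb = self.radial_bound
            u2 = x - mesh.nodes
            pen = self._bound_gap(u2) > 0.0
            if pen.any():
                nn = rb["nodes"][pen]
                ee = rb["er"][pen]
                blocks = rb["k"] * np.einsum("ni,nj->nij", ee, ee)
                d2 = (3 * nn[:, None] + np.arange(2)[None, :])  # (m, 2)
                rows = np.concatenate([rows, np.repeat(d2, 2, axis=1).ravel()])
                cols = np.concatenate([cols, np.tile(d2, (1, 2)).ravel()])
                vals = np.concatenate([vals, blocks.ravel()])

        if len(self.spring_k):
            pa = self.spring_pairs[:, 0]
            pb = self.spring_pairs[:, 1]
            for (na, nb, sgn) in ((pa, pa, 1.0), (pb, pb, 1.0), (pa, pb, -1.0), (pb, pa, -1.0)):
                for c in range(3):
                    rows = np.concatenate([rows, 3 * na + c])
                    cols = np.concatenate([cols, 3 * nb + c])
                    vals = np.concatenate([vals, sgn * self.spring_k])

        K = sp.coo_matrix((vals, (rows, cols)), shape=(self.ndof, self.ndof)).tocsc()
        # rank-one volume terms, applied by Woodbury at solve time:
        # lens content penalty and globe content rigidity
        wlist = []
        if self.beta_lens > 0.0:
            wlist.append((self.beta_lens, self._volume_gradient(x, self.lens_els).ravel()))
        if self.kv != 0.0:
            wlist.append((self.kv, self._volume_gradient(x, self.globe_els).ravel()))
        return K, wlist

    # -- Newton / load stepping -------------------------------------------

    def solve(
        self,
        bcs: BoundaryConditions,
        settings: SolverSettings | None = None,
        u0: np.ndarray | None = None,
        pressure_start: float = 0.0,
        prescribed_start: dict | None = None,
    ) -> SolutionState:
        """Static equilibrium, ramping loads from the start values to ``bcs``.

        ``u0`` warm-starts the solution (must be in equilibrium with the
        start loads for the ramp to be meaningful).
        """
        st = settings or SolverSettings()
        u = np.zeros(self.ndof) if u0 is None else np.asarray(u0, float).ravel().copy()
        target = bcs.all_prescribed()
        start = dict(prescribed_start or {})
        dof_p = np.array([3 * n + c for (n, c) in target], dtype=int)
        val_end = np.array([target[k] for k in target])
        val_start = np.array([start.get(k, 0.0) for k in target])
        free = np.setdiff1d(np.arange(self.ndof), dof_p)

        history = []
        s_done, ds = 0.0, 1.0 / st.load_steps
        u_good = u.copy()
        while s_done < 1.0 - 1e-12:
            s_try = min(1.0, s_done + ds)
            p = pressure_start + s_try * (bcs.pressure - pressure_start)
            u = u_good.copy()
            if len(dof_p):
                u[dof_p] = val_start + s_try * (val_end - val_start)
            ok, res_hist = self._newton(
                u, p, free, st, kstab=st.stabilization, u_ref=u_good,
                use_force_tol=st.stabilization > 0.0,
            )
            history.append({"load_factor": s_try, "residuals": res_hist, "converged": ok})
            if ok:
                s_done = s_try
                u_good = u.copy()
                ds = min(ds * 2.0, 1.0 / st.load_steps)
            else:
                ds *= 0.5
                if ds < st.min_step_fraction / st.load_steps:
                    raise DivergenceError(
                        f"no convergence above minimum load increment (at load factor {s_done:.4f})",
                        residual_history=history,
                    )
        if st.stabilization > 0.0:
            # anneal the stabilizer to zero: each stage re-equilibrates with
            # a 5x weaker spring anchored at the previous stage's state, so
            # the final unstabilized solve starts essentially at equilibrium
            u = u_good.copy()
            for fac in (0.1, 0.01, 0.0):
                ok, res_hist = self._newton(
                    u, bcs.pressure, free, st, kstab=st.stabilization * fac, u_ref=u.copy(),
                    use_force_tol=True,
                )
                history.append(
                    {"load_factor": 1.0, "residuals": res_hist, "converged": ok, "anneal": fac}
                )
                if not ok:
                    raise DivergenceError(
                        "stabilized ramp completed but the equilibrium did not survive "
                        f"stabilizer annealing (factor {fac:g})",
                        residual_history=history,
                    )
            u_good = u
        return self._make_state(u_good, history)

    def _solve_linear(self, Kff, wflist, rhs, damping: float):
        """Damped reduced solve with rank-one Woodbury corrections.

        ``wflist`` holds (coefficient, reduced vector) pairs for the volume
        terms whose c w w^T contributions are not assembled into ``Kff``.
        """
        if damping > 0.0:
            Kff = Kff + sp.identity(Kff.shape[0], format="csc") * damping
        lu = spla.splu(Kff.tocsc())
        y = lu.solve(rhs)
        terms = [(c, w) for c, w in wflist if c != 0.0 and np.any(w)]
        if terms:
            U = np.stack([w for _, w in terms], axis=1)  # (n, m)
            cinv = np.diag([1.0 / c for c, _ in terms])
            Z = lu.solve(U)
            small = cinv + U.T @ Z
            g = np.linalg.solve(small, U.T @ y)
            y = y - Z @ g
        return y

    def _newton(
        self,
        u: np.ndarray,
        pressure: float,
        free: np.ndarray,
        st: SolverSettings,
        kstab: float = 0.0,
        u_ref: np.ndarray | None = None,
        use_force_tol: bool = False,
    ):
        """Levenberg-damped Newton with a snap-through freewheel fallback.

        A membrane has no out-of-plane stiffness until tension develops, so
        the tangent can be indefinite early in a load step; diagonal damping
        (adapted by residual/energy decrease) walks into the energy basin and
        is annealed to zero so that terminal convergence is quadratic.  If
        the guarded iteration stalls or exhausts its budget away from the
        noise floor (a fold in the equilibrium path), a short phase of
        clipped full Newton steps with unconditional acceptance tracks the
        path through the fold, after which the guarded iteration resumes.
        """
        if u_ref is None or kstab <= 0.0:
            kstab = 0.0
            u_ref = u  # unused

        def resid(v):
            r = self.internal_force(v) - self.external_force(v, pressure)
            if kstab:
                r = r + kstab * (v - u_ref)
            return r

        def energy(v):
            e = self.total_energy(v, pressure)
            if kstab:
                d = v - u_ref
                e += 0.5 * kstab * float(d @ d)
            return e

        res_hist = []
        r = resid(u)
        rn = float(np.linalg.norm(r[free]))
        en = energy(u)
        res_hist.append(rn)
        # force scale for the stall criterion: all dofs, so the reactions at
        # prescribed nodes (the loads actually driving the system) count
        f_scale = max(float(np.linalg.norm(self.internal_force(u))), 1e-3)
        conv_tol = max(st.newton_abs_tol, st.newton_rel_tol * rn)
        if use_force_tol:
            conv_tol = max(conv_tol, st.force_rel_tol * f_scale)
        # two benign stall mechanisms: ~1 ulp force noise from the
        # penalty-eliminated thickness stretch, and limit cycles between
        # nearly-degenerate wrinkle states under deep indentation.  A
        # residual that stops improving but is negligible against the
        # internal-force scale counts as converged (still two orders
        # tighter than typical engineering force-residual tolerances).
        floor_tol = max(10.0 * st.newton_abs_tol, 3e-5 * f_scale)

        kappa = 0.0
        kappa0 = None
        freewheels_left = 1
        iters_left = st.max_newton_iters
        step_cap = 1.0  # mm; caps trial increments while damping is active
        stuck = False
        while True:
            if not np.isfinite(rn):
                return False, res_hist
            if rn <= conv_tol:
                return True, res_hist
            at_floor = rn <= floor_tol
            if stuck or iters_left <= 0:
                if at_floor:
                    return True, res_hist
                if freewheels_left <= 0:
                    return False, res_hist
                freewheels_left -= 1
                best = rn
                ok_fw = False
                for _ in range(25):
                    try:
                        K, wl = self._tangent(u, pressure)
                        du = self._solve_linear(
                            K[free][:, free], [(c, w[free]) for c, w in wl], -r[free], kstab
                        )
                    except RuntimeError:
                        return False, res_hist
                    step = np.clip(du, -0.2, 0.2)
                    for _half in range(5):
                        u[free] += step
                        r = resid(u)
                        rn = float(np.linalg.norm(r[free]))
                        if np.isfinite(rn):
                            break
                        u[free] -= step  # overflow region: shorten the move
                        step *= 0.25
                    res_hist.append(rn)
                    if not np.isfinite(rn) or rn > 1e5 * max(best, 1.0):
                        return False, res_hist
                    if rn < best:
                        ok_fw = True
                        break
                if not ok_fw:
                    return False, res_hist
                en = energy(u)
                kappa = 0.0
                stuck = False
                iters_left = st.max_newton_iters
                continue
            # one guarded iteration
            K, wl = self._tangent(u, pressure)
            if kappa0 is None:
                kappa0 = 1e-3 * float(np.abs(K.diagonal()).mean())
            Kff = K[free][:, free]
            wf = [(c, w[free]) for c, w in wl]
            accepted = False
            for _trial in range(20):
                try:
                    du = self._solve_linear(Kff, wf, -r[free], kappa + kstab)
                except RuntimeError:
                    kappa = max(10.0 * kappa, kappa0)
                    continue
                if np.abs(du).max() > step_cap:
                    kappa = max(10.0 * kappa, kappa0)
                    continue
                u_try = u.copy()
                u_try[free] += du
                r_try = resid(u_try)
                rn_try = float(np.linalg.norm(r_try[free]))
                en_try = energy(u_try)
                # heavily damped steps follow the energy gradient, so energy
                # descent is the robust acceptance rule away from equilibrium;
                # residual descent takes over in the terminal Newton phase
                ok = np.isfinite(rn_try) and (
                    rn_try < rn or en_try < en - 1e-12 * max(1.0, abs(en))
                )
                if ok:
                    contraction = rn_try / rn if rn > 0 else 0.0
                    u[free] += du
                    r, rn, en = r_try, rn_try, en_try
                    res_hist.append(rn)
                    if contraction < 0.2 or kappa < 0.05 * kappa0:
                        kappa = 0.0
                    else:
                        kappa *= 0.3
                    accepted = True
                    break
                kappa = max(10.0 * kappa, kappa0)
            iters_left -= 1
            stuck = not accepted
            if accepted and rn <= floor_tol and len(res_hist) >= 4 and res_hist[-4] < 1.2 * rn:
                return True, res_hist
    # -- state extraction --------------------------------------------------

    def _make_state(self, u: np.ndarray, history) -> SolutionState:
        mesh = self.mesh
        x = mesh.nodes + u.reshape(-1, 3)
        xe = x[mesh.elements]
        Fs, C3, S, lam3 = self._element_state(xe, self.lam3_cache)
        # deformed unit normal and full deformation map (stress-free -> global)
        ncur = np.cross(Fs[:, :, 0], Fs[:, :, 1], axis=1)
        ncur /= np.linalg.norm(ncur, axis=1, keepdims=True)
        lam3_inc = lam3 / self.lam30
        A = np.concatenate([Fs, (lam3_inc[:, None] * ncur)[:, :, None]], axis=2)
        F0_3 = np.zeros((len(Fs), 3, 3))
        F0_3[:, :2, :2] = self.F0
        F0_3[:, 2, 2] = self.lam30
        # express the local in-plane reference basis in global coordinates
        R = np.stack([self.e1, self.e2, self.normal0], axis=2)  # local -> global
        Ftot = np.einsum("eij,ejk->eik", A, F0_3)
        J = np.linalg.det(np.einsum("eij,ejk->eik", A, F0_3))
        sig = np.einsum("eij,ejk,elk->eil", Ftot, S, Ftot) / J[:, None, None]
        sig = 0.5 * (sig + np.transpose(sig, (0, 2, 1)))
        eigs = np.linalg.eigvalsh(sig)
        smax = eigs[:, -1]
        lam2 = np.linalg.eigvalsh(C3)
        log_strain = 0.5 * np.log(lam2[:, -1])
        rlast = history[-1]["residuals"][-1] if history else 0.0
        return SolutionState(
            displacements=u.reshape(-1, 3).copy(),
            element_F=Ftot,
            cauchy=sig,
            max_principal_stress=smax,
            log_strain=log_strain,
            residual_norm=float(rlast),
            newton_history=history,
        )


def solve_static(
    mesh: SurfaceMesh,
    materials: dict[str, MaterialParams] | None = None,
    bcs: BoundaryConditions | None = None,
    settings: SolverSettings | None = None,
    prestrain=None,
    u0: np.ndarray | None = None,
    pressure_start: float = 0.0,
    prescribed_start: dict | None = None,
) -> SolutionState:
    """One-shot static solve (see :class:`MembraneSystem.solve`)."""
    system = MembraneSystem(mesh, materials, prestrain)
    return system.solve(
        bcs or BoundaryConditions(),
        settings,
        u0=u0,
        pressure_start=pressure_start,
        prescribed_start=prescribed_start,
    )


def membrane_constitutive_condensation(F_surface: np.ndarray, params: MaterialParams, m2=None, n2=None):
    """Plane-stress condensation of the 3-D law for one surface deformation.

    ``F_surface`` is the in-plane deformation gradient (2x2, or 3x2 whose
    columns span the deformed tangent plane).  Returns ``(sigma, lam3)``:
    the full local Cauchy stress (3x3, with through-thickness component
    driven to zero, |sigma_33| <= 1e-10 MPa) and the thickness stretch.
    """
    F = np.asarray(F_surface, float)
    C2 = F.T @ F if F.shape[0] != 2 else F.T @ F
    par = {f: np.array([getattr(params, f)]) for f in _PARAM_FIELDS}
    m = np.zeros((1, 3)) if m2 is None else np.array([[m2[0], m2[1], 0.0]])
    n = np.zeros((1, 3)) if n2 is None else np.array([[n2[0], n2[1], 0.0]])
    tr2 = np.array([C2[0, 0] + C2[1, 1]])
    tr2sq = np.array([np.einsum("ij,ji->", C2, C2)])
    det2 = np.array([np.linalg.det(C2)])
    q4 = np.array([m[0, :2] @ C2 @ m[0, :2]])
    q6 = np.array([n[0, :2] @ C2 @ n[0, :2]])
    lam3 = _solve_lam3(tr2, tr2sq, det2, q4, q6, par, np.array([1.0 / np.sqrt(max(det2[0], 1e-6))]))
    C3 = np.zeros((1, 3, 3))
    C3[0, :2, :2] = C2
    C3[0, 2, 2] = lam3[0] ** 2
    S = pk2_from_C(
        C3,
        par["D_penalty"],
        par["C1"],
        par["C2"],
        par["k1"],
        par["k2"],
        par["k3"],
        par["k4"],
        m,
        n,
    )[0]
    # push forward with the principal-stretch decomposition of C3
    U = np.zeros((3, 3))
    w, V = np.linalg.eigh(C3[0])
    U = V @ np.diag(np.sqrt(w)) @ V.T
    sigma = U @ S @ U / np.linalg.det(U)
    return 0.5 * (sigma + sigma.T), float(lam3[0])
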