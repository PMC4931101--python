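"""Parametric eye-globe surface mesh and the simulated-scenario catalogue.

The globe exterior is a single shell blending two ellipsoids: the corneal
ellipsoid (semi-axes ``a``, ``b`` transverse/vertical, ``c`` axial) and a
triaxial scleral ellipsoid whose transverse/vertical semi-axes come from the
globe diameters and whose axial semi-axis is solved so that (i) the shell
passes through the limbus ring and (ii) the apex-to-posterior-pole distance
equals the configured axial length.  The limbus is a smoothstep blend band
between the two ellipsoids.  The crystalline lens is a separate closed
capsule shell (two spherical caps) coupled to the globe by a ring of
zonular attachment springs; its interior (cortex + nucleus) enters the
mechanics as an equivalent volumetric stiffness of the enclosed volume.

Coordinates: optical axis = z, anterior corneal apex at +z, nasal-temporal =
x, superior-inferior = y, globe centroid at the origin.  All lengths in mm.

Meridional node rings on the sclera are placed by arc distance from the
limbus, with a refined band of rings around the encircling-band site so the
prescribed indentation is well resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EyeGeometryConfig",
    "SurfaceMesh",
    "Scenario",
    "build_eye_mesh",
    "assign_fibers",
    "compute_axial_length",
    "corneal_apex_curvature",
    "enumerate_scenarios",
    "base_cases",
]

REGIONS = ("cornea", "limbus", "sclera", "nerve", "lens")


class ConfigurationError(ValueError):
    """Raised for geometrically inconsistent or under-resolved configurations."""


@dataclass(frozen=True)
class EyeGeometryConfig:
    """Average-eye dimensions defining the parametric model.

    Defaults are population-average values; the scleral thickness anchors
    (arc distance from the limbus in mm, thickness in mm) follow the
    literature-typical thin-equator/thick-pole profile.
    """

    cornea_semiaxes: tuple[float, float, float] = (10.43, 10.27, 14.26)
    #: (sagittal/vertical, transverse/horizontal) corneal diameters
    corneal_diameters: tuple[float, float] = (11.26, 11.51)
    central_corneal_thickness: float = 0.550
    #: (sagittal, transverse, axial) exterior globe dimensions
    globe_dimensions: tuple[float, float, float] = (25.43, 25.76, 24.86)
    #: anterior and posterior lens surface radii (posterior negative)
    lens_radii: tuple[float, float] = (11.0, -6.5)
    scleral_thickness_profile: tuple[tuple[float, float], ...] = (
        (0.0, 0.80),
        (12.5, 0.49),
        (30.0, 1.00),
    )
    limbus_width: float = 1.0
    nerve_patch_radius: float = 1.0
    lens_diameter: float = 9.0
    anterior_chamber_depth: float = 3.0
    #: effective structural thickness of the capsule-plus-outer-cortex shell;
    #: the anatomical capsule alone (~0.02 mm) has no usable bending
    #: stiffness and would crumple through inextensional modes, whereas the
    #: lens in vivo is a stable quasi-rigid occupant
    lens_capsule_thickness: float = 0.5
    #: arc window (mm posterior to limbus) meshed at fine meridional spacing
    fine_window: tuple[float, float] = (10.25, 14.75)
    #: ocular-rigidity slope dIOP/dV of the eye contents (MPa per mm^3).
    #: On surgical timescales the aqueous/vitreous cannot drain, so the
    #: enclosed volume is regulated: the wall pressure rises/falls with
    #: volume loss/gain about the reference state (Friedenwald rigidity,
    #: ~0.025 mmHg per microlitre).  Without it a constant-pressure membrane
    #: eye reaches an unbounded ballooning limit under deep banding.
    ocular_rigidity: float = 3.3e-6

    def __post_init__(self) -> None:
        lengths = (
            *self.cornea_semiaxes,
            *self.corneal_diameters,
            self.central_corneal_thickness,
            *self.globe_dimensions,
            self.lens_radii[0],
            -self.lens_radii[1],
            self.limbus_width,
            self.nerve_patch_radius,
            self.lens_diameter,
            self.anterior_chamber_depth,
            self.lens_capsule_thickness,
        )
        if any(not v > 0.0 for v in lengths):
            raise ConfigurationError("all lengths must be positive")
        if any(t <= 0.0 for _, t in self.scleral_thickness_profile):
            raise ConfigurationError("thickness anchors must be positive")
        arcs = [s for s, _ in self.scleral_thickness_profile]
        if sorted(arcs) != arcs or len(set(arcs)) != len(arcs):
            raise ConfigurationError("thickness anchors must be strictly increasing in arc")


@dataclass
class SurfaceMesh:
    """Labelled triangle shell of the eye (globe + lens capsule).

    ``element_region`` holds one of :data:`REGIONS` per triangle.  Fibre
    direction arrays carry zero vectors where a family is inactive.
    ``arc_from_limbus`` is the meridional arc coordinate of each globe node
    (negative on the corneal side, NaN on the lens).
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    thickness: np.ndarray
    fiber_m: np.ndarray
    fiber_n: np.ndarray
    region_map: dict[str, np.ndarray]
    arc_from_limbus: np.ndarray
    apex_node: int
    pole_node: int
    lens_anterior_node: int
    #: (lens node, globe node, stiffness N/mm) zonular attachment springs
    springs: np.ndarray
    lens_bulk_modulus: float
    #: dIOP/dV of the enclosed contents (MPa/mm^3); 0 = pure pressure control
    content_rigidity: float = 0.0
    config: EyeGeometryConfig = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def globe_elements(self) -> np.ndarray:
        return np.flatnonzero(self.element_region != "lens")

    @property
    def lens_elements(self) -> np.ndarray:
        return np.flatnonzero(self.element_region == "lens")

    def element_areas(self, coords: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if coords is None else coords
        p = x[self.elements]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def element_normals(self, coords: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if coords is None else coords
        p = x[self.elements]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return cr / np.linalg.norm(cr, axis=1, keepdims=True)

    def euler_characteristic(self, which: str = "globe") -> int:
        """V - E + F of one closed component (2 for a topological sphere)."""
        els = self.elements[self.globe_elements if which == "globe" else self.lens_elements]
        verts = np.unique(els)
        edges = np.concatenate([els[:, [0, 1]], els[:, [1, 2]], els[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return int(verts.size - edges.shape[0] + els.shape[0])


@dataclass(frozen=True)
class Scenario:
    """One simulated combination of band width, IOP and tightening level."""

    case_id: int
    bandwidth_mm: float
    iop_mmHg: float
    tightening_pct: float


#: Case table order: bands wide to narrow, IOP low to high.
BANDWIDTHS_MM = (2.5, 2.0, 1.0)
IOPS_MMHG = (11.0, 15.0, 18.0)
TIGHTENING_LEVELS_PCT = (33.0, 67.0, 100.0)


def base_cases() -> list[tuple[int, float, float]]:
    """The nine (case id, bandwidth mm, IOP mmHg) combinations, in case order."""
    out = []
    cid = 1
    for bw in BANDWIDTHS_MM:
        for iop in IOPS_MMHG:
            out.append((cid, bw, iop))
            cid += 1
    return out


def enumerate_scenarios() -> list[Scenario]:
    """All 27 scenarios: nine base cases x three tightening levels."""
    return [
        Scenario(cid, bw, iop, tp)
        for cid, bw, iop in base_cases()
        for tp in TIGHTENING_LEVELS_PCT
    ]


# ---------------------------------------------------------------------------
# surface construction helpers
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _ray_ellipsoid(p0: np.ndarray, d: np.ndarray, center_z: float, semis: tuple) -> float:
    """Distance along unit ray ``d`` from ``p0`` to an axis-aligned ellipsoid."""
    ax, ay, az = semis
    rel = p0 - np.array([0.0, 0.0, center_z])
    inv = np.array([1.0 / ax**2, 1.0 / ay**2, 1.0 / az**2])
    A = np.dot(d * d, inv)
    B = 2.0 * np.dot(rel * d, inv)
    C = np.dot(rel * rel, inv) - 1.0
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        raise ConfigurationError("ray misses ellipsoid; inconsistent geometry")
    return (-B + np.sqrt(disc)) / (2.0 * A)


class _GlobeSurface:
    """Ray-parametrised blended globe surface (apex initially at z = 0)."""

    def __init__(self, cfg: EyeGeometryConfig):
        self.cfg = cfg
        a_c, b_c, c_c = cfg.cornea_semiaxes
        AL = cfg.globe_dimensions[2]
        self.cornea_semis = (a_c, b_c, c_c)
        self.z_cc = -c_c  # corneal ellipsoid centre (apex at z = 0)
        sx = cfg.corneal_diameters[1] / 2.0  # transverse (x)
        sy = cfg.corneal_diameters[0] / 2.0  # vertical (y)
        self.limbus_semis = (sx, sy)
        zx = self.z_cc + c_c * np.sqrt(1.0 - (sx / a_c) ** 2)
        zy = self.z_cc + c_c * np.sqrt(1.0 - (sy / b_c) ** 2)
        self.z_limbus = 0.5 * (zx + zy)
        Ax = cfg.globe_dimensions[1] / 2.0
        Ay = cfg.globe_dimensions[0] / 2.0
        self.globe_semis_xy = (Ax, Ay)

        def mismatch(c_s: float) -> float:
            z0 = c_s - AL
            r = 0.0
            for rho, A in ((sx, Ax), (sy, Ay)):
                r += (rho / A) ** 2 + ((self.z_limbus - z0) / c_s) ** 2 - 1.0
            return r

        self.c_s = brentq(mismatch, 0.35 * AL, 0.75 * AL, xtol=1e-12)
        self.z0 = self.c_s - AL  # scleral ellipsoid centre = ray origin
        self.p0 = np.array([0.0, 0.0, self.z0])
        self.sclera_semis = (Ax, Ay, self.c_s)

    def _dir(self, theta: float, phi: float) -> np.ndarray:
        st = np.sin(theta)
        return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])

    def cornea_point(self, theta: float, phi: float) -> np.ndarray:
        d = self._dir(theta, phi)
        return self.p0 + _ray_ellipsoid(self.p0, d, self.z_cc, self.cornea_semis) * d

    def sclera_point(self, theta: float, phi: float) -> np.ndarray:
        d = self._dir(theta, phi)
        return self.p0 + _ray_ellipsoid(self.p0, d, self.z0, self.sclera_semis) * d

    def theta_limbus_start(self, phi: float) -> float:
        sx, sy = self.limbus_semis
        rho_t = np.hypot(sx * np.cos(phi), sy * np.sin(phi))

        def g(theta: float) -> float:
            p = self.cornea_point(theta, phi)
            return np.hypot(p[0], p[1]) - rho_t

        return brentq(g, 1e-3, np.pi / 2 - 1e-3, xtol=1e-12)

    def point(self, theta: float, phi: float, theta1: float, theta2: float) -> np.ndarray:
        """Blended surface point; [theta1, theta2] is the limbus band."""
        if theta <= theta1:
            return self.cornea_point(theta, phi)
        if theta >= theta2:
            return self.sclera_point(theta, phi)
        t = _smoothstep((theta - theta1) / (theta2 - theta1))
        return (1.0 - t) * self.cornea_point(theta, phi) + t * self.sclera_point(theta, phi)


def _sclera_arc_table(surf: _GlobeSurface, phi: float, theta2: float, n: int = 400):
    """Cumulative meridional arc length from the posterior limbus edge to the pole."""
    thetas = np.linspace(theta2, np.pi, n)
    pts = np.array([surf.sclera_point(t, phi) for t in thetas])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return thetas, arc


def _interp_thickness(arc: np.ndarray, anchors) -> np.ndarray:
    s = np.array([a for a, _ in anchors])
    t = np.array([b for _, b in anchors])
    return np.interp(arc, s, t)


def build_eye_mesh(config: EyeGeometryConfig | None = None, resolution: float = 1.0) -> SurfaceMesh:
    """Build the labelled eye shell mesh.

    ``resolution`` scales both azimuthal and meridional node densities; the
    default places rings every ~0.3 mm of arc under the band site and every
    ~1.3 mm elsewhere.  Raises :class:`ConfigurationError` if the band window
    would be resolved by fewer than 3 node rings per mm.
    """
    cfg = config or EyeGeometryConfig()
    surf = _GlobeSurface(cfg)

    n_phi = max(12, int(round(28 * resolution)))
    ds_fine = 0.30 / resolution
    ds_coarse = 1.30 / resolution
    if 1.0 / ds_fine < 3.0:
        raise ConfigurationError(
            f"fine meridional spacing {ds_fine:.3f} mm gives fewer than 3 node rings "
            "per mm at the band site; increase resolution"
        )

    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    theta1 = np.array([surf.theta_limbus_start(p) for p in phis])
    r_lim = np.array(
        [np.linalg.norm(surf.cornea_point(t, p) - surf.p0) for t, p in zip(theta1, phis)]
    )
    theta2 = theta1 + cfg.limbus_width / r_lim

    # ring parameter grids (shared topology across phi)
    n_cornea = max(4, int(round(np.mean(theta1) * np.mean(r_lim) / ds_coarse)))
    n_limbus = max(2, int(round(cfg.limbus_width / min(0.5, ds_coarse))))

    s_fa, s_fb = cfg.fine_window
    arcs_pre = np.linspace(0.0, s_fa, max(2, int(round(s_fa / ds_coarse)) + 1))
    arcs_fine = np.linspace(s_fa, s_fb, int(np.ceil((s_fb - s_fa) / ds_fine)) + 1)

    # assemble rings: cornea (excl. apex) | limbus | sclera
    ring_nodes = []
    ring_arcs_all = []  # arc-from-limbus per ring per phi
    s_poles = []
    n_post = None
    for j, phi in enumerate(phis):
        th_tab, arc_tab = _sclera_arc_table(surf, phi, theta2[j])
        s_pole = arc_tab[-1]
        s_poles.append(s_pole)
        if n_post is None:
            n_post = max(3, int(round((s_pole - s_fb - cfg.nerve_patch_radius) / ds_coarse)))
            # the soft nerve patch needs a small pole fan: a coarse fan apex
            # acts as an artificially compliant point under pressure
            n_nerve = max(3, int(round(cfg.nerve_patch_radius / min(0.35, ds_coarse))))
        arcs_post = s_fb + (s_pole - cfg.nerve_patch_radius - s_fb) * np.linspace(
            0.0, 1.0, n_post + 1
        )
        arcs_nerve = (s_pole - cfg.nerve_patch_radius) + cfg.nerve_patch_radius * np.linspace(
            0.0, 1.0, n_nerve + 1
        )[1:-1]
        arcs_sclera = np.concatenate([arcs_pre, arcs_fine[1:], arcs_post[1:], arcs_nerve])
        th_sclera = np.interp(arcs_sclera, arc_tab, th_tab)

        th_cornea = np.mean(theta1) * np.arange(1, n_cornea + 1) / n_cornea
        th_cornea = th_cornea * (theta1[j] / th_cornea[-1])
        th_limbus = theta1[j] + (theta2[j] - theta1[j]) * np.arange(1, n_limbus + 1) / n_limbus

        col_pts = []
        col_arcs = []
        for th in th_cornea:
            p = surf.point(th, phi, theta1[j], theta2[j])
            col_pts.append(p)
            # corneal arc coordinate: negative chord-ish estimate along meridian
            col_arcs.append(-(cfg.limbus_width + (theta1[j] - th) * r_lim[j]))
        for i, th in enumerate(th_limbus):
            col_pts.append(surf.point(th, phi, theta1[j], theta2[j]))
            col_arcs.append(-cfg.limbus_width * (1.0 - (i + 1.0) / n_limbus))
        for s, th in zip(arcs_sclera[1:], th_sclera[1:]):
            col_pts.append(surf.point(th, phi, theta1[j], theta2[j]))
            col_arcs.append(s)
        ring_nodes.append(np.array(col_pts))
        ring_arcs_all.append(np.array(col_arcs))

    ring_nodes = np.array(ring_nodes)  # (n_phi, n_rings, 3)
    ring_arcs = np.array(ring_arcs_all).mean(axis=0)
    n_rings = ring_nodes.shape[1]

    apex = np.array([0.0, 0.0, 0.0])
    pole = surf.sclera_point(np.pi, 0.0)

    nodes = [apex]
    for r in range(n_rings):
        for j in range(n_phi):
            nodes.append(ring_nodes[j, r])
    nodes.append(pole)
    nodes = np.array(nodes)
    apex_node = 0
    pole_node = nodes.shape[0] - 1

    def nid(r: int, j: int) -> int:
        return 1 + r * n_phi + (j % n_phi)

    # ring region bands
    ring_region = (
        ["cornea"] * n_cornea + ["limbus"] * n_limbus + ["sclera"] * (n_rings - n_cornea - n_limbus)
    )
    assert len(ring_region) == n_rings

    elements = []
    regions = []
    # nerve patch: everything within the patch radius of the posterior pole
    arc_pole = float(np.mean(s_poles))
    nerve_cut = arc_pole - cfg.nerve_patch_radius - 1e-9

    # apex fan (cornea)
    for j in range(n_phi):
        elements.append([apex_node, nid(0, j), nid(0, j + 1)])
        regions.append("cornea")
    # quad strips
    for r in range(n_rings - 1):
        reg = ring_region[r + 1]
        mid_arc = 0.5 * (ring_arcs[r] + ring_arcs[r + 1])
        if reg == "sclera" and mid_arc >= nerve_cut:
            reg = "nerve"
        for j in range(n_phi):
            a, b = nid(r, j), nid(r, j + 1)
            c, d = nid(r + 1, j), nid(r + 1, j + 1)
            elements.append([a, b, d])
            elements.append([a, d, c])
            regions.append(reg)
            regions.append(reg)
    # pole fan (nerve if patch present)
    pole_reg = "nerve" if cfg.nerve_patch_radius > 0 else "sclera"
    for j in range(n_phi):
        elements.append([pole_node, nid(n_rings - 1, j + 1), nid(n_rings - 1, j)])
        regions.append(pole_reg)

    arc_from_limbus = np.empty(nodes.shape[0])
    arc_from_limbus[apex_node] = -(cfg.limbus_width + np.mean(theta1 * r_lim))
    arc_from_limbus[pole_node] = arc_pole
    for r in range(n_rings):
        arc_from_limbus[1 + r * n_phi : 1 + (r + 1) * n_phi] = ring_arcs[r]

    # --- lens capsule shell -------------------------------------------------
    n_glob = nodes.shape[0]
    lens_nodes, lens_els, lens_eq_ids, lens_ant_id = _build_lens(cfg, n_phi_lens=max(12, n_phi // 2))
    z_lens_ant = -cfg.central_corneal_thickness - cfg.anterior_chamber_depth
    lens_nodes = lens_nodes + np.array([0.0, 0.0, z_lens_ant])
    nodes = np.vstack([nodes, lens_nodes])
    elements = np.array(elements + (lens_els + n_glob).tolist())
    regions = np.array(regions + ["lens"] * lens_els.shape[0], dtype=object)
    lens_anterior_node = n_glob + lens_ant_id
    lens_eq = n_glob + lens_eq_ids

    # zonular springs: lens equator ring -> globe ring ~2 mm posterior to limbus
    ciliary_ring = int(np.argmin(np.abs(ring_arcs - 2.0)))
    globe_ring_ids = np.array([nid(ciliary_ring, j) for j in range(n_phi)])
    k_total = 1.0  # N/mm summed over the ring (taut in-vivo suspension)
    springs = []
    gphi = np.arctan2(nodes[globe_ring_ids, 1], nodes[globe_ring_ids, 0])
    for ln in lens_eq:
        lphi = np.arctan2(nodes[ln, 1], nodes[ln, 0])
        j = int(np.argmin(np.abs(np.angle(np.exp(1j * (gphi - lphi))))))
        springs.append([ln, globe_ring_ids[j], k_total / len(lens_eq)])

    # optic-nerve trunk tether: the nerve-head patch is not a free membrane
    # in vivo — the nerve trunk and its dural sheath anchor it to the
    # scleral canal rim.  Without this support the soft patch balloons to a
    # membrane limit point under the surgical elongation.
    nerve_node_ids = np.unique(
        np.array(elements)[np.array(regions, dtype=object) == "nerve"]
    )
    rim_ring = n_rings - n_nerve  # scleral-canal rim ring bounding the patch
    rim_ids = np.array([nid(rim_ring, j) for j in range(n_phi)])
    inner_nerve = np.setdiff1d(nerve_node_ids, rim_ids)
    k_trunk_total = 1.0  # N/mm, dural-sheath-scale axial stiffness
    rphi = np.arctan2(nodes[rim_ids, 1], nodes[rim_ids, 0])
    for nn in inner_nerve:
        if nn == pole_node:
            j = 0
        else:
            nphi_ = np.arctan2(nodes[nn, 1], nodes[nn, 0])
            j = int(np.argmin(np.abs(np.angle(np.exp(1j * (rphi - nphi_))))))
        springs.append([nn, rim_ids[j], k_trunk_total / max(1, len(inner_nerve))])
    springs = np.array(springs, dtype=float)

    # --- thickness ----------------------------------------------------------
    thickness = np.empty(nodes.shape[0])
    glob_ids = np.arange(n_glob)
    arcs = arc_from_limbus[glob_ids]
    t_scl = _interp_thickness(np.clip(arcs, 0.0, None), cfg.scleral_thickness_profile)
    t0_scl = cfg.scleral_thickness_profile[0][1]
    cct = cfg.central_corneal_thickness
    blend = np.clip(-arcs / cfg.limbus_width, 0.0, 1.0)  # 0 at sclera edge, 1 at cornea edge
    t_glob = np.where(arcs >= 0.0, t_scl, (1.0 - blend) * t0_scl + blend * cct)
    t_glob = np.where(arcs <= -cfg.limbus_width, cct, t_glob)
    thickness[glob_ids] = t_glob
    thickness[n_glob:] = cfg.lens_capsule_thickness

    # --- region map ---------------------------------------------------------
    el = np.array(elements)
    region_map = {}
    for reg in ("cornea", "limbus", "sclera", "nerve", "lens"):
        ids = np.unique(el[regions == reg])
        region_map[reg] = ids
    band_lo, band_hi = 12.5 - 1.25, 12.5 + 1.25
    region_map["band_candidate"] = glob_ids[(arcs >= band_lo) & (arcs <= band_hi)]

    # equivalent interior bulk stiffness of the lens contents (volume-weighted
    # cortex/nucleus compressibilities from the material registry)
    from .constitutive import TISSUE_REGISTRY

    k_cortex = TISSUE_REGISTRY["lens_cortex"].bulk_modulus
    k_nucleus = TISSUE_REGISTRY["lens_nucleus"].bulk_modulus
    lens_bulk = 0.6 * k_cortex + 0.4 * k_nucleus

    mesh = SurfaceMesh(
        nodes=nodes,
        elements=el,
        element_region=regions,
        thickness=thickness,
        fiber_m=np.zeros_like(el, dtype=float),
        fiber_n=np.zeros_like(el, dtype=float),
        region_map=region_map,
        arc_from_limbus=np.concatenate([arc_from_limbus, np.full(lens_nodes.shape[0], np.nan)]),
        apex_node=apex_node,
        pole_node=pole_node,
        lens_anterior_node=lens_anterior_node,
        springs=springs,
        lens_bulk_modulus=lens_bulk,
        content_rigidity=cfg.ocular_rigidity,
        config=cfg,
    )
    _fix_orientation(mesh)
    assign_fibers(mesh)

    # centre the globe centroid at the origin
    centroid = mesh.nodes[:n_glob].mean(axis=0)
    mesh.nodes -= centroid

    areas = mesh.element_areas()
    if np.any(areas <= 1e-8):
        raise ConfigurationError("degenerate elements produced; adjust resolution")
    return mesh


def build_sphere_mesh(
    radius: float = 12.0,
    thickness: float = 0.5,
    n_phi: int = 24,
    n_theta: int = 16,
    region: str = "sclera",
) -> SurfaceMesh:
    """Closed thin-sphere shell, a single-region validation mesh.

    The arc coordinate is measured from the north pole; the band-candidate
    ring sits at the equator so the standard rigid-body constraints apply.
    """
    thetas = np.pi * np.arange(1, n_theta) / n_theta
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    nodes = [np.array([0.0, 0.0, radius])]
    for t in thetas:
        for p in phis:
            nodes.append(radius * np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)]))
    nodes.append(np.array([0.0, 0.0, -radius]))
    nodes = np.array(nodes)
    pole_s = nodes.shape[0] - 1

    def nid(r, j):
        return 1 + r * n_phi + (j % n_phi)

    els = []
    for j in range(n_phi):
        els.append([0, nid(0, j), nid(0, j + 1)])
    for r in range(len(thetas) - 1):
        for j in range(n_phi):
            a, b = nid(r, j), nid(r, j + 1)
            c, d = nid(r + 1, j), nid(r + 1, j + 1)
            els.append([a, b, d])
            els.append([a, d, c])
    for j in range(n_phi):
        els.append([pole_s, nid(len(thetas) - 1, j + 1), nid(len(thetas) - 1, j)])
    els = np.array(els)
    regions = np.array([region] * len(els), dtype=object)

    arc = radius * np.arccos(np.clip(nodes[:, 2] / radius, -1.0, 1.0))
    eq_band = np.flatnonzero(np.abs(nodes[:, 2]) < radius * np.sin(np.pi / (2 * n_theta)))
    mesh = SurfaceMesh(
        nodes=nodes,
        elements=els,
        element_region=regions,
        thickness=np.full(len(nodes), thickness),
        fiber_m=np.zeros((len(els), 3)),
        fiber_n=np.zeros((len(els), 3)),
        region_map={region: np.unique(els), "band_candidate": eq_band},
        arc_from_limbus=arc,
        apex_node=0,
        pole_node=pole_s,
        lens_anterior_node=-1,
        springs=np.zeros((0, 3)),
        lens_bulk_modulus=0.0,
        config=None,
    )
    _fix_orientation(mesh)
    return mesh


def _build_lens(cfg: EyeGeometryConfig, n_phi_lens: int):
    """Closed capsule shell from two spherical caps; local frame: anterior pole at z=0."""
    Ra = cfg.lens_radii[0]
    Rp = -cfg.lens_radii[1]
    req = cfg.lens_diameter / 2.0
    sag_a = Ra - np.sqrt(Ra * Ra - req * req)
    sag_p = Rp - np.sqrt(Rp * Rp - req * req)
    n_cap = 5
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi_lens, endpoint=False)

    nodes = [np.array([0.0, 0.0, 0.0])]  # anterior pole
    rings = []
    # anterior cap: polar angle from anterior pole (sphere centre at z = -Ra)
    beta_max_a = np.arcsin(req / Ra)
    for b in np.linspace(0.0, beta_max_a, n_cap + 1)[1:]:
        rho = Ra * np.sin(b)
        z = -(Ra - Ra * np.cos(b))
        rings.append((rho, z))
    # posterior cap rings (from equator towards posterior pole), sphere centre
    # at z = -(sag_a + sag_p) + Rp
    zc = -(sag_a + sag_p) + Rp
    beta_max_p = np.arcsin(req / Rp)
    for b in np.linspace(beta_max_p, 0.0, n_cap + 1)[1:-1]:
        rho = Rp * np.sin(b)
        z = zc - Rp * np.cos(b)
        rings.append((rho, z))
    for rho, z in rings:
        for p in phis:
            nodes.append(np.array([rho * np.cos(p), rho * np.sin(p), z]))
    nodes.append(np.array([0.0, 0.0, -(sag_a + sag_p)]))  # posterior pole
    nodes = np.array(nodes)
    n_rings = len(rings)
    post_pole = nodes.shape[0] - 1

    def nid(r, j):
        return 1 + r * n_phi_lens + (j % n_phi_lens)

    els = []
    for j in range(n_phi_lens):
        els.append([0, nid(0, j), nid(0, j + 1)])
    for r in range(n_rings - 1):
        for j in range(n_phi_lens):
            a, b = nid(r, j), nid(r, j + 1)
            c, d = nid(r + 1, j), nid(r + 1, j + 1)
            els.append([a, b, d])
            els.append([a, d, c])
    for j in range(n_phi_lens):
        els.append([post_pole, nid(n_rings - 1, j + 1), nid(n_rings - 1, j)])
    equator_ring = n_cap - 1  # ring at rho = req
    eq_ids = np.array([nid(equator_ring, j) for j in range(n_phi_lens)])
    return nodes, np.array(els), eq_ids, 0


def _component_volume(nodes: np.ndarray, els: np.ndarray) -> float:
    p = nodes[els]
    return float(np.einsum("ei,ei->", np.cross(p[:, 0], p[:, 1]), p[:, 2]) / 6.0)


def _fix_orientation(mesh: SurfaceMesh) -> None:
    """Flip triangles so both closed components have outward normals."""
    for ids in (mesh.globe_elements, mesh.lens_elements):
        if _component_volume(mesh.nodes, mesh.elements[ids]) < 0.0:
            mesh.elements[ids] = mesh.elements[ids][:, [0, 2, 1]]


def assign_fibers(mesh: SurfaceMesh) -> SurfaceMesh:
    """Attach per-element fibre directions.

    Cornea: orthogonal nasal-temporal / superior-inferior tangent families.
    Limbus and lens capsule: circumferential first family only (the second
    family has zero stiffness in the registry).  Sclera, nerve and lens
    interior carry no active fibres (zero vectors).
    """
    normals = mesh.element_normals()
    cent = mesh.nodes[mesh.elements].mean(axis=1)
    m = np.zeros_like(normals)
    n = np.zeros_like(normals)

    def project(vec, nrm):
        v = vec - (vec * nrm).sum(axis=1, keepdims=True) * nrm
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        return v / np.where(norm > 0, norm, 1.0)

    cornea = mesh.element_region == "cornea"
    ex = np.broadcast_to(np.array([1.0, 0.0, 0.0]), normals.shape)
    m[cornea] = project(ex, normals)[cornea]
    n[cornea] = np.cross(normals, m)[cornea]

    circ_regions = (mesh.element_region == "limbus") | (mesh.element_region == "lens")
    tang = np.stack([-cent[:, 1], cent[:, 0], np.zeros(len(cent))], axis=1)
    m[circ_regions] = project(tang, normals)[circ_regions]

    mesh.fiber_m = m
    mesh.fiber_n = n
    return mesh


def compute_axial_length(mesh: SurfaceMesh, coords: np.ndarray | None = None) -> float:
    """Distance between the anterior corneal apex and the posterior pole (mm)."""
    x = mesh.nodes if coords is None else coords
    return float(np.linalg.norm(x[mesh.apex_node] - x[mesh.pole_node]))


def corneal_apex_curvature(
    mesh: SurfaceMesh,
    meridian: str = "NT",
    method: str = "closed_form",
    coords: np.ndarray | None = None,
    fit_radius: float = 2.5,
) -> float:
    """Anterior apical radius of curvature (mm) along one principal meridian.

    ``closed_form`` evaluates a^2/c (NT) or b^2/c (SI) of the configured
    corneal ellipsoid; ``fit`` estimates the radius from a quadric fitted to
    mesh nodes near the apex (usable on deformed coordinates).
    """
    a, b, c = mesh.config.cornea_semiaxes
    if method == "closed_form":
        return a * a / c if meridian == "NT" else b * b / c
    x = mesh.nodes if coords is None else coords
    apex = x[mesh.apex_node]
    rel = x - apex
    rho2 = rel[:, 0] ** 2 + rel[:, 1] ** 2
    near = (rho2 < fit_radius**2) & (np.abs(rel[:, 2]) < 2.0 * fit_radius)
    near &= ~np.isnan(mesh.arc_from_limbus) & (mesh.arc_from_limbus < -mesh.config.limbus_width)
    pts = rel[near]
    # z = c0 + c1 x + c2 y - x^2/(2Rx) - y^2/(2Ry) - cxy x y + quartic terms
    # (the quartic terms absorb the ellipsoid's higher-order sag so the
    # quadratic coefficients estimate the apical curvatures without bias)
    xq, yq = pts[:, 0], pts[:, 1]
    A = np.stack(
        [np.ones(len(pts)), xq, yq, xq**2, yq**2, xq * yq, xq**4, yq**4, xq**2 * yq**2],
        axis=1,
    )
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    curv = -2.0 * (coef[3] if meridian == "NT" else coef[4])
    return float(1.0 / curv)
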