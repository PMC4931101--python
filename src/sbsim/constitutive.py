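"""Fibre-reinforced hyperelastic constitutive model for ocular tissues.

The strain energy is decoupled into a volumetric penalty, an isochoric
Mooney--Rivlin matrix and two exponential collagen-fibre families::

    Psi = (1/(2D)) ln^2 J
        + (C1/2)(I1b - 3) + (C2/2)(I2b - 3)
        + (k1/(2 k2)) [exp(k2 (I4b - 1)^2) - 1]
        + (k3/(2 k4)) [exp(k4 (I6b - 1)^2) - 1]

with ``J = det F``, ``I1b, I2b`` the modified (isochoric) invariants of
``Cb = J^(-2/3) F^T F`` and ``I4b = m0.Cb.m0``, ``I6b = n0.Cb.n0`` the squared
fibre stretches along the two reference fibre directions.  Fibre terms are
tension-only: they contribute only where the corresponding pseudo-invariant
exceeds one, the standard convention for exponential fibre models.  The limit
of a vanishing exponential coefficient is handled as the quadratic
``(k/2)(I - 1)^2``.

Units are fixed package-wide: mm, N, MPa; intraocular pressure is converted
with 1 mmHg = 1.33322e-4 MPa.

All tensor helpers are batched: they accept stacked arrays with leading
dimensions, which is how the finite-element assembly calls them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_MPA",
    "MaterialParams",
    "FiberDirections",
    "Kinematics",
    "TISSUE_REGISTRY",
    "tissue",
    "compute_kinematics",
    "strain_energy",
    "cauchy_stress",
    "registry_to_config",
    "registry_from_config",
]

MMHG_TO_MPA = 1.33322e-4

# Range-extension guard for Mooney-Rivlin matrices with C2 < 0 (the sclera).
# Such fits soften in biaxial tension once I1bar - 3 exceeds ~0.006 (biaxial
# stretch ~2.3%), which is an artefact of extrapolating a small-strain fit,
# not tissue behaviour (real sclera stiffens).  Beyond the fitted range the
# matrix energy gains a generic collagen-stiffening term
#     (C1 / (2 m)) [exp(m <I1bar - 3 - c0>^2) - 1]
# that is identically zero inside the fitted range and restores a monotone
# biaxial stress response outside it.
_GUARD_M = 150.0
_GUARD_OFFSET = 5.82e-3


def matrix_range_guard_energy(I1, C1, C2):
    """Guard energy density (zero unless C2 < 0 and I1bar exceeds the range)."""
    I1, C1v, C2v = np.broadcast_arrays(
        np.asarray(I1, float), np.asarray(C1, float), np.asarray(C2, float)
    )
    g = np.maximum(I1 - 3.0 - _GUARD_OFFSET, 0.0)
    e = C1v / (2.0 * _GUARD_M) * np.expm1(_GUARD_M * g * g)
    return np.where(C2v < 0.0, e, 0.0)


def _matrix_range_guard_dpsi(I1, C1, C2):
    """d(guard energy)/dI1bar."""
    I1, C1v, C2v = np.broadcast_arrays(
        np.asarray(I1, float), np.asarray(C1, float), np.asarray(C2, float)
    )
    g = np.maximum(I1 - 3.0 - _GUARD_OFFSET, 0.0)
    d = C1v * g * np.exp(_GUARD_M * g * g)
    return np.where(C2v < 0.0, d, 0.0)

_TISSUE_LABELS = (
    "cornea",
    "limbus",
    "sclera",
    "lens_cortex",
    "lens_nucleus",
    "lens_capsule",
    "nerve",
)


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


@dataclass(frozen=True)
class MaterialParams:
    """Parameter set of one tissue.

    ``D_penalty`` (MPa^-1) controls near-incompressibility (effective bulk
    modulus 1/D); ``C1``/``C2`` (MPa) are the Mooney--Rivlin matrix constants;
    ``k1``/``k3`` (MPa) and ``k2``/``k4`` (dimensionless) parametrise the two
    exponential fibre families.
    """

    tissue_label: str
    D_penalty: float
    C1: float
    C2: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue_label not in _TISSUE_LABELS:
            raise ValueError(f"unknown tissue label {self.tissue_label!r}")
        if self.D_penalty <= 0.0:
            raise ValueError("D_penalty must be positive")
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def bulk_modulus(self) -> float:
        """Effective bulk modulus 1/D in MPa."""
        return 1.0 / self.D_penalty


#: Built-in registry of the seven ocular tissues (D in MPa^-1, C/k in MPa).
TISSUE_REGISTRY: dict[str, MaterialParams] = {
    "cornea": MaterialParams("cornea", 1e-5, 1e-1, 0.0, 0.234, 29.917, 23.4e-2, 29.917),
    "limbus": MaterialParams("limbus", 1e-5, 1e-1, 0.0, 0.234, 29.917, 0.0, 0.0),
    "sclera": MaterialParams("sclera", 1e-5, 35.0, -32.0, 0.0, 0.0, 0.0, 0.0),
    "lens_cortex": MaterialParams("lens_cortex", 34.54, 58.295e-5, 0.0),
    "lens_nucleus": MaterialParams("lens_nucleus", 214.96, 93.667e-6, 0.0),
    "lens_capsule": MaterialParams("lens_capsule", 28.35e-2, 21.60e-2, 0.0, 3.39e-2, 9.7406, 0.0, 0.0),
    "nerve": MaterialParams("nerve", 4.0, 50.335e-4, 0.0),
}


def tissue(label: str) -> MaterialParams:
    """Look up a tissue parameter set from the built-in registry."""
    try:
        return TISSUE_REGISTRY[label]
    except KeyError:
        raise KeyError(f"no such tissue {label!r}; known: {sorted(TISSUE_REGISTRY)}") from None


def registry_to_config(registry: dict[str, MaterialParams] | None = None) -> dict:
    """Serialise a material registry to a plain config mapping."""
    registry = TISSUE_REGISTRY if registry is None else registry
    return {
        label: {
            "D_MPa_inv": p.D_penalty,
            "C1_MPa": p.C1,
            "C2_MPa": p.C2,
            "k1_MPa": p.k1,
            "k2": p.k2,
            "k3_MPa": p.k3,
            "k4": p.k4,
        }
        for label, p in registry.items()
    }


def registry_from_config(block: dict) -> dict[str, MaterialParams]:
    """Inverse of :func:`registry_to_config`."""
    return {
        label: MaterialParams(
            label,
            row["D_MPa_inv"],
            row["C1_MPa"],
            row["C2_MPa"],
            row.get("k1_MPa", 0.0),
            row.get("k2", 0.0),
            row.get("k3_MPa", 0.0),
            row.get("k4", 0.0),
        )
        for label, row in block.items()
    }


@dataclass(frozen=True)
class FiberDirections:
    """Two unit fibre directions in the reference configuration."""

    m0: np.ndarray
    n0: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.m0, self.n0):
            a = np.asarray(v, dtype=float)
            if a.shape != (3,) or abs(np.linalg.norm(a) - 1.0) > 1e-12:
                raise ValueError("fibre directions must be unit 3-vectors")

    @property
    def M(self) -> np.ndarray:
        """Structural tensor m0 (x) m0."""
        m = np.asarray(self.m0, float)
        return np.outer(m, m)

    @property
    def N(self) -> np.ndarray:
        n = np.asarray(self.n0, float)
        return np.outer(n, n)


_ISOTROPIC_FIBERS = None  # sentinel: no fibre families


@dataclass(frozen=True)
class Kinematics:
    """Deformation measures entering the strain energy."""

    F: np.ndarray
    J: float
    Cbar: np.ndarray
    I1bar: float
    I2bar: float
    I4bar: float
    I6bar: float
    fibers: FiberDirections | None = field(default=None, repr=False)


def compute_kinematics(F: np.ndarray, fibers: FiberDirections | None = None) -> Kinematics:
    """Modified invariants of a deformation gradient.

    Raises :class:`InvalidDeformationError` if ``det F <= 0``.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det F = {J:g} <= 0")
    C = F.T @ F
    Cbar = J ** (-2.0 / 3.0) * C
    I1 = float(np.trace(Cbar))
    I2 = 0.5 * (I1 * I1 - float(np.trace(Cbar @ Cbar)))
    if fibers is not None:
        m0 = np.asarray(fibers.m0, float)
        n0 = np.asarray(fibers.n0, float)
        I4 = float(m0 @ Cbar @ m0)
        I6 = float(n0 @ Cbar @ n0)
    else:
        I4 = I6 = 1.0
    return Kinematics(F=F, J=J, Cbar=Cbar, I1bar=I1, I2bar=I2, I4bar=I4, I6bar=I6, fibers=fibers)


# ---------------------------------------------------------------------------
# batched scalar helpers (used both by the public API and the FE assembly)
# ---------------------------------------------------------------------------

def _fiber_energy(I: np.ndarray, k: np.ndarray, kexp: np.ndarray) -> np.ndarray:
    """Tension-only exponential fibre energy, quadratic in the kexp->0 limit."""
    I, k, kexp = np.broadcast_arrays(np.asarray(I, float), np.asarray(k, float), np.asarray(kexp, float))
    e = I - 1.0
    active = (k > 0.0) & (e > 0.0)
    es = np.where(active, e, 0.0)
    with np.errstate(over="raise"):
        exp_term = np.where(kexp > 1e-12, kexp, 1.0)
        out = np.where(
            kexp > 1e-12,
            k / (2.0 * exp_term) * np.expm1(exp_term * es * es),
            0.5 * k * es * es,
        )
    return np.where(active, out, 0.0)


def _fiber_dpsi(I: np.ndarray, k: np.ndarray, kexp: np.ndarray) -> np.ndarray:
    """d(fibre energy)/dI: k (I-1) exp(kexp (I-1)^2) where in tension."""
    I, k, kexp = np.broadcast_arrays(np.asarray(I, float), np.asarray(k, float), np.asarray(kexp, float))
    e = I - 1.0
    active = (k > 0.0) & (e > 0.0)
    es = np.where(active, e, 0.0)
    return np.where(active, k * es * np.exp(kexp * es * es), 0.0)


def psi_from_C(C, D, C1, C2, k1=0.0, k2=0.0, k3=0.0, k4=0.0, m0=None, n0=None):
    """Strain energy density from right Cauchy-Green tensors ``C`` (..., 3, 3)."""
    C = np.asarray(C, float)
    detC = np.linalg.det(C)
    J = np.sqrt(detC)
    Cbar = detC[..., None, None] ** (-1.0 / 3.0) * C
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1 * I1 - np.trace(Cbar @ Cbar, axis1=-2, axis2=-1))
    lnJ = np.log(J)
    psi = 0.5 / np.asarray(D, float) * lnJ * lnJ
    psi = psi + 0.5 * np.asarray(C1, float) * (I1 - 3.0) + 0.5 * np.asarray(C2, float) * (I2 - 3.0)
    psi = psi + matrix_range_guard_energy(I1, C1, C2)
    if m0 is not None:
        I4 = np.einsum("...i,...ij,...j->...", m0, Cbar, m0)
        psi = psi + _fiber_energy(I4, k1, k2)
    if n0 is not None:
        I6 = np.einsum("...i,...ij,...j->...", n0, Cbar, n0)
        psi = psi + _fiber_energy(I6, k3, k4)
    return psi


def pk2_from_C(C, D, C1, C2, k1=0.0, k2=0.0, k3=0.0, k4=0.0, m0=None, n0=None):
    """Second Piola-Kirchhoff stress ``S = 2 dPsi/dC`` (batched, analytic)."""
    C = np.asarray(C, float)
    eye = np.broadcast_to(np.eye(3), C.shape)
    detC = np.linalg.det(C)
    J = np.sqrt(detC)
    Cinv = np.linalg.inv(C)
    Cbar = detC[..., None, None] ** (-1.0 / 3.0) * C
    Cbarinv = detC[..., None, None] ** (1.0 / 3.0) * Cinv
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)

    # volumetric part: S_vol = J p C^-1 with p = lnJ / (D J)
    lnJ = np.log(J)
    p = lnJ / (np.asarray(D, float) * J)
    S = (J * p)[..., None, None] * Cinv

    # isochoric part: Sbar = 2 dPsibar/dCbar, deviatoric projection
    C1a = np.asarray(C1, float)
    C2a = np.asarray(C2, float)
    Sbar = C1a[..., None, None] * eye if np.ndim(C1a) else C1a * eye
    Sbar = Sbar + (np.asarray(C2a)[..., None, None] if np.ndim(C2a) else C2a) * (
        I1[..., None, None] * eye - Cbar
    )
    guard = _matrix_range_guard_dpsi(I1, C1, C2)
    if np.any(guard):
        Sbar = Sbar + 2.0 * np.asarray(guard)[..., None, None] * eye
    if m0 is not None:
        I4 = np.einsum("...i,...ij,...j->...", m0, Cbar, m0)
        psi4 = _fiber_dpsi(I4, k1, k2)
        Sbar = Sbar + 2.0 * psi4[..., None, None] * np.einsum("...i,...j->...ij", m0, m0)
    if n0 is not None:
        I6 = np.einsum("...i,...ij,...j->...", n0, Cbar, n0)
        psi6 = _fiber_dpsi(I6, k3, k4)
        Sbar = Sbar + 2.0 * psi6[..., None, None] * np.einsum("...i,...j->...ij", n0, n0)
    trace_SC = np.einsum("...ij,...ij->...", Sbar, Cbar)
    Siso = detC[..., None, None] ** (-1.0 / 3.0) * (
        Sbar - (trace_SC / 3.0)[..., None, None] * Cbarinv
    )
    return S + Siso


def energy_nonnegativity_report(
    params: MaterialParams,
    n_samples: int = 500,
    max_I1_excess: float = 0.3,
    seed: int = 0,
) -> dict:
    """Sample random admissible deformations and report negative energies.

    A Mooney-Rivlin matrix with C2 < 0 (the sclera) is not pointwise
    non-negative: biaxial stretches with I2bar growing faster than I1bar
    can make the isochoric term negative inside |I1bar - 3| <= 0.3.  This
    check quantifies where that happens so the operating range is explicit.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_violations = 0
    n_in_range = 0
    for _ in range(n_samples):
        F = np.eye(3) + 0.09 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.05:
            continue
        kin = compute_kinematics(F)
        if abs(kin.I1bar - 3.0) > max_I1_excess:
            continue
        n_in_range += 1
        psi = strain_energy(kin, params)
        if psi < -1e-12:
            n_violations += 1
            worst = min(worst, psi)
    return {
        "tissue": params.tissue_label,
        "n_in_range": n_in_range,
        "n_violations": n_violations,
        "worst_energy_MPa": worst,
    }


def strain_energy(kin: Kinematics, params: MaterialParams) -> float:
    """Strain energy density Psi (MPa) at the given kinematic state."""
    psi = 0.5 / params.D_penalty * np.log(kin.J) ** 2
    psi += 0.5 * params.C1 * (kin.I1bar - 3.0) + 0.5 * params.C2 * (kin.I2bar - 3.0)
    psi += float(matrix_range_guard_energy(kin.I1bar, params.C1, params.C2))
    psi += float(_fiber_energy(kin.I4bar, params.k1, params.k2))
    psi += float(_fiber_energy(kin.I6bar, params.k3, params.k4))
    return float(psi)


def cauchy_stress(kin: Kinematics, params: MaterialParams) -> np.ndarray:
    """Cauchy stress (MPa, symmetric 3x3) by analytic differentiation of Psi."""
    F = kin.F
    C = F.T @ F
    m0 = n0 = None
    if kin.fibers is not None:
        m0 = np.asarray(kin.fibers.m0, float)
        n0 = np.asarray(kin.fibers.n0, float)
    S = pk2_from_C(
        C,
        params.D_penalty,
        params.C1,
        params.C2,
        params.k1,
        params.k2,
        params.k3,
        params.k4,
        m0,
        n0,
    )
    sig = F @ S @ F.T / kin.J
    return 0.5 * (sig + sig.T)
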