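"""Static linear-elastic corneal deformation under intraocular pressure.

The cornea is modelled as a meniscus-shaped axisymmetric solid: a spherical
anterior surface of given radius of curvature, a posterior surface offset
by a radially varying thickness (thin centrally, thicker at the periphery;
the relation reverses its *contrast* in keratoconus, where the centre
thins further while the periphery thickens).  The periphery is clamped —
zero displacement on the whole peripheral face, modelling attachment to
the stiff limbus — and a uniform pressure (the intraocular pressure,
default 2000 Pa ≈ 20 mmHg) loads the posterior surface as a normal
traction.  Gravity and extraocular muscle forces are excluded.

Because load, geometry and boundary conditions are all axisymmetric, the
problem is solved on the meridian cross-section with axisymmetric
continuum elasticity: 9-node biquadratic quadrilateral elements, 3×3
Gauss quadrature, small strains, isotropic Hooke's law.  Quadratic
elements are used because bilinear quadrilaterals shear-lock in the thin
bending regime at the ~1000-element budget this model targets.  Internal
units are SI (m, Pa); micrometres, millimetres and MPa appear only at the
interface.

A clamped flat circular plate under uniform pressure, for which the
Kirchhoff closed form ``w = p a^4 / (64 D)`` with ``D = E h^3 / (12 (1 -
nu^2))`` is exact in the thin limit, serves as the verification oracle.
For moderately thick plates the transverse-shear-corrected (Mindlin) form
adds ``p a^2 / (4 k G h)`` with ``k = 5/6``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "CorneaGeometry",
    "MaterialProperties",
    "LoadCase",
    "Mesh",
    "DeflectionField",
    "build_geometry",
    "mesh_cornea",
    "solve_static",
    "clamped_plate_reference",
    "deflection_summary",
    "HEALTHY_GEOMETRY",
    "KC_GEOMETRY",
    "HEALTHY_MATERIAL",
    "KC_MATERIAL",
]

_UM = 1e-6
_MM = 1e-3
_MPA = 1e6


@dataclass(frozen=True)
class CorneaGeometry:
    """Axisymmetric corneal geometry (interface units: µm, mm).

    The thickness profile interpolates quadratically in radius from
    ``central_thickness`` at the apex to ``peripheral_thickness`` at the
    rim and is measured along the axis.  ``anterior_radius_mm=None``
    degenerates to a flat disc (used by the verification oracle).
    """

    central_thickness_um: float
    peripheral_thickness_um: float
    corneal_diameter_mm: float = 11.5
    anterior_radius_mm: float | None = 7.8
    label: str = "healthy"

    def __post_init__(self) -> None:
        if min(self.central_thickness_um, self.peripheral_thickness_um,
               self.corneal_diameter_mm) <= 0:
            raise ValueError("all geometric dimensions must be positive")
        if self.anterior_radius_mm is not None:
            if self.anterior_radius_mm <= 0:
                raise ValueError("anterior radius must be positive")
            if self.anterior_radius_mm <= self.rim_radius_mm:
                raise ValueError(
                    "anterior radius of curvature must exceed the corneal "
                    "semi-diameter"
                )

    @classmethod
    def flat_disc(cls, radius_mm: float, thickness_um: float) -> "CorneaGeometry":
        return cls(
            central_thickness_um=thickness_um,
            peripheral_thickness_um=thickness_um,
            corneal_diameter_mm=2.0 * radius_mm,
            anterior_radius_mm=None,
            label="flat_disc",
        )

    @property
    def rim_radius_mm(self) -> float:
        return self.corneal_diameter_mm / 2.0

    def thickness(self, r_mm: float | np.ndarray) -> float | np.ndarray:
        """Axial thickness in µm at radial position ``r_mm`` (mm)."""
        s = np.asarray(r_mm, dtype=float) / self.rim_radius_mm
        t = self.central_thickness_um + (
            self.peripheral_thickness_um - self.central_thickness_um
        ) * s**2
        return float(t) if np.isscalar(r_mm) else t

    # -- SI surfaces used by the mesher ---------------------------------
    def _z_anterior_m(self, r_m: np.ndarray) -> np.ndarray:
        if self.anterior_radius_mm is None:
            return np.zeros_like(r_m)
        ra = self.anterior_radius_mm * _MM
        return -(ra - np.sqrt(ra**2 - r_m**2))  # sag, 0 at the apex

    def _z_posterior_m(self, r_m: np.ndarray) -> np.ndarray:
        return self._z_anterior_m(r_m) - self.thickness(r_m / _MM) * _UM


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic linear-elastic material (E in MPa, density in g/cm³)."""

    elastic_modulus_mpa: float
    poisson_ratio: float = 0.42
    density_g_cm3: float = 1.038

    def __post_init__(self) -> None:
        if self.elastic_modulus_mpa <= 0:
            raise ValueError("elastic modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    @property
    def E_pa(self) -> float:
        return self.elastic_modulus_mpa * _MPA

    def hooke_matrix(self) -> np.ndarray:
        """4×4 axisymmetric stiffness for strains (ε_rr, ε_zz, ε_θθ, γ_rz)."""
        e, nu = self.E_pa, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        d = np.diag([lam + 2 * mu] * 3 + [mu])
        d[:3, :3] += lam * (1 - np.eye(3))
        return d


@dataclass(frozen=True)
class LoadCase:
    """Uniform posterior pressure with a clamped peripheral face."""

    iop_pa: float = 2000.0
    boundary: str = "clamped_periphery"

    def __post_init__(self) -> None:
        if self.iop_pa < 0:
            raise ValueError("pressure must be non-negative")


# Default material properties: keratoconic vs healthy corneal stroma.
KC_MATERIAL = MaterialProperties(elastic_modulus_mpa=2.4)
HEALTHY_MATERIAL = MaterialProperties(elastic_modulus_mpa=3.1)

# Default geometries.  Central/peripheral thicknesses, diameter and
# anterior curvature are stand-in typical values for a healthy and a
# keratoconic cornea (KC: central thinning, peripheral thickening),
# exposed in config for substitution by subject-specific measurements.
HEALTHY_GEOMETRY = CorneaGeometry(550.0, 700.0, 11.5, 7.8, label="healthy")
KC_GEOMETRY = CorneaGeometry(450.0, 750.0, 11.5, 7.8, label="kc")


def build_geometry(
    central_thickness_um: float,
    peripheral_thickness_um: float,
    corneal_diameter_mm: float = 11.5,
    anterior_radius_mm: float | None = 7.8,
    label: str = "healthy",
    healthy_reference: CorneaGeometry | None = None,
) -> CorneaGeometry:
    """Validated corneal geometry.

    When ``label == "kc"`` and a healthy reference is supplied, the
    keratoconic relation is enforced: thinner centre, no thinner periphery.
    """
    geom = CorneaGeometry(
        central_thickness_um, peripheral_thickness_um,
        corneal_diameter_mm, anterior_radius_mm, label,
    )
    if label == "kc" and healthy_reference is not None:
        if geom.central_thickness_um >= healthy_reference.central_thickness_um:
            raise ValueError(
                "keratoconic central thickness must be below the healthy value"
            )
        if geom.peripheral_thickness_um < healthy_reference.peripheral_thickness_um:
            raise ValueError(
                "keratoconic peripheral thickness must not be below the healthy value"
            )
    return geom


@dataclass
class Mesh:
    """Structured biquadratic mesh of the meridian cross-section.

    ``nodes`` are (r, z) in metres; ``elements`` hold 9 node ids per
    element in row-major local order (η from posterior to anterior, ξ from
    axis to rim).  ``posterior_edges`` lists the 3-node posterior edges
    carrying the pressure load.
    """

    nodes: np.ndarray  # (n_nodes, 2)
    elements: np.ndarray  # (n_elems, 9)
    n_r: int
    n_t: int
    rim_nodes: np.ndarray
    axis_nodes: np.ndarray
    posterior_edges: np.ndarray  # (n_r, 3) node ids, ξ-ordered
    apex_anterior_node: int
    geometry: CorneaGeometry | None = None

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _grid_counts(n_elements: int, aspect: float) -> tuple[int, int]:
    """Split an element budget into (meridian, through-thickness) counts
    so element aspect ratios stay near one."""
    n_t = max(2, int(round(np.sqrt(n_elements / max(aspect, 1.0)))))
    n_r = max(2, int(round(n_elements / n_t)))
    return n_r, n_t


def mesh_cornea(geometry: CorneaGeometry, n_elements: int = 1024) -> Mesh:
    """Mesh the meridian cross-section with ~``n_elements`` biquadratic
    quadrilaterals (within 10% of the target)."""
    if n_elements < 16:
        raise ValueError("need at least 16 elements")
    rim_m = geometry.rim_radius_mm * _MM
    mean_t_m = 0.5 * (geometry.central_thickness_um + geometry.peripheral_thickness_um) * _UM
    n_r, n_t = _grid_counts(n_elements, rim_m / mean_t_m)
    if abs(n_r * n_t - n_elements) > 0.1 * n_elements:
        # fall back to exact factorization near the square-ish split
        n_r, n_t = n_elements // n_t * 1, n_t
    ni, nj = 2 * n_r + 1, 2 * n_t + 1
    s = np.linspace(0.0, 1.0, ni)
    tau = np.linspace(0.0, 1.0, nj)
    r = s * rim_m
    z_post = geometry._z_posterior_m(r)
    thick = geometry.thickness(r / _MM) * _UM
    R = np.repeat(r, nj)
    Z = (z_post[:, None] + tau[None, :] * thick[:, None]).ravel()
    nodes = np.column_stack([R, Z])

    def nid(i, j):
        return i * nj + j

    elements = np.empty((n_r * n_t, 9), dtype=np.int64)
    e = 0
    for ei in range(n_r):
        for ej in range(n_t):
            i0, j0 = 2 * ei, 2 * ej
            elements[e] = [
                nid(i0 + a, j0 + b) for b in range(3) for a in range(3)
            ]
            e += 1
    rim_nodes = np.array([nid(ni - 1, j) for j in range(nj)])
    axis_nodes = np.array([nid(0, j) for j in range(nj)])
    posterior_edges = np.array(
        [[nid(2 * ei, 0), nid(2 * ei + 1, 0), nid(2 * ei + 2, 0)] for ei in range(n_r)]
    )
    mesh = Mesh(
        nodes, elements, n_r, n_t, rim_nodes, axis_nodes, posterior_edges,
        apex_anterior_node=nid(0, nj - 1), geometry=geometry,
    )
    _check_jacobians(mesh)
    return mesh


# -- reference element ---------------------------------------------------

_G1 = np.sqrt(3.0 / 5.0)
_GAUSS_PTS = np.array([-_G1, 0.0, _G1])
_GAUSS_WTS = np.array([5.0, 8.0, 5.0]) / 9.0


def _lagrange(x: float) -> np.ndarray:
    return np.array([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])


def _lagrange_d(x: float) -> np.ndarray:
    return np.array([x - 0.5, -2.0 * x, x + 0.5])


def _shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Q9 shape functions and reference-space gradients, local order
    k = 3*b + a (a along ξ, b along η)."""
    la, lb = _lagrange(xi), _lagrange(eta)
    da, db = _lagrange_d(xi), _lagrange_d(eta)
    n = (lb[:, None] * la[None, :]).ravel()
    dn = np.stack(
        [(lb[:, None] * da[None, :]).ravel(), (db[:, None] * la[None, :]).ravel()],
        axis=1,
    )
    return n, dn


_QUAD = [
    (float(_GAUSS_PTS[a]), float(_GAUSS_PTS[b]), float(_GAUSS_WTS[a] * _GAUSS_WTS[b]))
    for a in range(3)
    for b in range(3)
]


def _check_jacobians(mesh: Mesh) -> None:
    coords = mesh.nodes[mesh.elements]  # (ne, 9, 2)
    for xi, eta, _ in _QUAD:
        _, dn = _shape(xi, eta)
        jac = np.einsum("nka,kb->nab", coords, dn)
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        if np.any(det <= 0):
            bad = int(np.argmax(det <= 0))
            raise ValueError(
                f"degenerate geometry: non-positive Jacobian in element {bad}"
            )


@dataclass
class DeflectionField:
    """Solved nodal displacements on a mesh (metres)."""

    mesh: Mesh
    displacement: np.ndarray  # (n_nodes, 2): (u_r, u_z)
    residual: float  # relative residual of the solved linear system

    @property
    def magnitude(self) -> np.ndarray:
        """Per-node displacement-vector magnitude."""
        return np.linalg.norm(self.displacement, axis=1)

    @property
    def axial_deflection(self) -> np.ndarray:
        """Per-node axial deformation |u_z| — the model's deflection map.

        The deformation measure of interest is the axial one: it is what
        the pressure load produces at the apex and what the deformation
        map reports.  (The full-vector magnitude differs from it only by
        the small radial sliding component.)
        """
        return np.abs(self.displacement[:, 1])

    @property
    def central_deflection_m(self) -> float:
        """Axial deflection at the anterior apex node."""
        return float(self.axial_deflection[self.mesh.apex_anterior_node])

    @property
    def max_deflection_node(self) -> int:
        return int(np.argmax(self.axial_deflection))

    @property
    def max_deflection_radius_m(self) -> float:
        """Radial position of the maximum-deflection node."""
        return float(self.mesh.nodes[self.max_deflection_node, 0])


def _assemble(
    mesh: Mesh, material: MaterialProperties
) -> sp.csr_matrix:
    """Global stiffness, vectorised over elements per quadrature point."""
    coords = mesh.nodes[mesh.elements]  # (ne, 9, 2)
    ne = mesh.n_elements
    d_mat = material.hooke_matrix()
    ke = np.zeros((ne, 18, 18))
    for xi, eta, w in _QUAD:
        n, dn = _shape(xi, eta)
        jac = np.einsum("nka,kb->nab", coords, dn)  # (ne, 2, 2)
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        inv = np.empty_like(jac)
        inv[:, 0, 0] = jac[:, 1, 1]
        inv[:, 1, 1] = jac[:, 0, 0]
        inv[:, 0, 1] = -jac[:, 0, 1]
        inv[:, 1, 0] = -jac[:, 1, 0]
        inv /= det[:, None, None]
        dndx = np.einsum("kb,nba->nka", dn, inv)  # (ne, 9, 2): d/dr, d/dz
        r_gp = coords[:, :, 0] @ n  # (ne,)
        b = np.zeros((ne, 4, 18))
        cols_u = np.arange(0, 18, 2)
        cols_w = cols_u + 1
        b[:, 0, cols_u] = dndx[:, :, 0]
        b[:, 1, cols_w] = dndx[:, :, 1]
        b[:, 2, cols_u] = n[None, :] / r_gp[:, None]
        b[:, 3, cols_u] = dndx[:, :, 1]
        b[:, 3, cols_w] = dndx[:, :, 0]
        scale = (w * 2.0 * np.pi) * r_gp * det
        ke += np.einsum("nip,ij,njq,n->npq", b, d_mat, b, scale)
    dofs = np.empty((ne, 18), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 18, axis=1).ravel()
    cols = np.tile(dofs, (1, 18)).ravel()
    k = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)
    )
    return k.tocsr()


def _pressure_load(mesh: Mesh, pressure: float) -> np.ndarray:
    """Consistent nodal forces from a uniform normal pressure on the
    posterior surface, acting toward the anterior side."""
    f = np.zeros(2 * mesh.n_nodes)
    for edge in mesh.posterior_edges:
        xy = mesh.nodes[edge]  # (3, 2), ξ-ordered
        for x, wgt in zip(_GAUSS_PTS, _GAUSS_WTS):
            n1 = _lagrange(float(x))
            d1 = _lagrange_d(float(x))
            r_gp = n1 @ xy[:, 0]
            drdxi = d1 @ xy[:, 0]
            dzdxi = d1 @ xy[:, 1]
            # traction * edge Jacobian: p * (-dz/dξ, dr/dξ) points from the
            # fluid side into the shell (anteriorward)
            tr = pressure * np.array([-dzdxi, drdxi])
            scale = wgt * 2.0 * np.pi * r_gp
            for a in range(3):
                f[2 * edge[a]] += scale * n1[a] * tr[0]
                f[2 * edge[a] + 1] += scale * n1[a] * tr[1]
    return f


def solve_static(
    mesh: Mesh, material: MaterialProperties, load: LoadCase
) -> DeflectionField:
    """Solve the clamped, pressure-loaded axisymmetric elasticity problem.

    Constraints: all displacement components vanish on the peripheral rim
    face; the radial component vanishes on the symmetry axis.  The reduced
    symmetric positive-definite system is solved directly and the relative
    residual is verified below 1e-10.
    """
    k = _assemble(mesh, material)
    f = _pressure_load(mesh, load.iop_pa)
    fixed = np.zeros(2 * mesh.n_nodes, dtype=bool)
    fixed[2 * mesh.rim_nodes] = True
    fixed[2 * mesh.rim_nodes + 1] = True
    fixed[2 * mesh.axis_nodes] = True  # u_r = 0 on the axis
    if not fixed.any():
        raise ValueError("no constrained degrees of freedom; system is singular")
    free = ~fixed
    u = np.zeros(2 * mesh.n_nodes)
    if np.any(f[free]):
        kff = k[free][:, free].tocsc()
        ff = f[free]
        lu = spla.splu(kff)
        uf = lu.solve(ff)
        fnorm = np.linalg.norm(ff)
        knorm = abs(kff).sum(axis=1).max()  # inf-norm

        def backward_error(x: np.ndarray) -> float:
            # normwise backward error; the meaningful residual measure for
            # the ill-conditioned stiffness of a thin shell
            return float(
                np.linalg.norm(kff @ x - ff) / (knorm * np.linalg.norm(x) + fnorm)
            )

        res = backward_error(uf)
        for _ in range(5):  # iterative refinement on the LU factor
            if res <= 1e-14:
                break
            uf = uf + lu.solve(ff - kff @ uf)
            res = backward_error(uf)
        u[free] = uf
        if res > 1e-10:
            raise ArithmeticError(f"linear solve residual {res:.2e} exceeds 1e-10")
    else:
        res = 0.0
    return DeflectionField(mesh, u.reshape(-1, 2), residual=float(res))


def clamped_plate_reference(
    radius_m: float,
    thickness_m: float,
    E_pa: float,
    nu: float,
    pressure_pa: float,
    include_shear: bool = False,
) -> float:
    """Central deflection (m) of a clamped circular plate under uniform
    pressure: the Kirchhoff closed form ``p a⁴ / (64 D)``.

    With ``include_shear`` the first-order transverse-shear (Mindlin)
    correction ``p a² / (4 κ G h)``, κ = 5/6, is added — appropriate for
    moderately thick plates outside the Kirchhoff regime.
    """
    d = E_pa * thickness_m**3 / (12.0 * (1.0 - nu**2))
    w = pressure_pa * radius_m**4 / (64.0 * d)
    if include_shear:
        g = E_pa / (2.0 * (1.0 + nu))
        w += pressure_pa * radius_m**2 / (4.0 * (5.0 / 6.0) * g * thickness_m)
    return w


def deflection_summary(
    healthy_field: DeflectionField, kc_field: DeflectionField
) -> dict:
    """Central deflections, their KC/healthy ratio, and the location of
    the maximum-deflection node for each field."""
    wh = healthy_field.central_deflection_m
    wk = kc_field.central_deflection_m
    if wh == 0.0:
        raise ZeroDivisionError("healthy central deflection is zero")
    return {
        "healthy_central_deflection_um": wh / _UM,
        "kc_central_deflection_um": wk / _UM,
        "kc_to_healthy_ratio": wk / wh,
        "healthy_max_deflection_radius_mm": healthy_field.max_deflection_radius_m / _MM,
        "kc_max_deflection_radius_mm": kc_field.max_deflection_radius_m / _MM,
    }
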