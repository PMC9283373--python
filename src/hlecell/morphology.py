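"""Morphological microstates: mesh, spline displacement field, kinematics.

A microstate of the adherent cell is a smooth planar displacement field
applied to a reference disc of radius ``R0 = 1``.  The field is a bicubic
tensor-product spline with a 4x4 net of control points (open knot vectors
with multiplicity four and unit weights, i.e. a single Bezier patch)
parameterised over the bounding square ``[-1, 1]^2`` of the disc.  The low
control-point count acts as a morphological low-pass filter: shapes with
features finer than the patch wavelength (sub-filopodium scale) cannot be
represented.

The disc is discretised by constant-strain triangles; each element carries a
constant deformation gradient, principal stretches and a region label
(nucleus or cytoplasm).  Out-of-plane incompressibility sets the current
thickness ``b = b0 / (lambda_I * lambda_II)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .errors import (
    HLECellError,
    InadmissibleMicrostateError,
    InvalidKinematicsError,
    NonSimpleBoundaryError,
)
from .parameters import CellParameters

__all__ = [
    "ReferenceMesh",
    "ControlNet",
    "DeformedConfiguration",
    "StripePattern",
    "GeometryObservables",
    "build_reference_mesh",
    "bezier_basis",
    "nurbs_displacement",
    "deform",
    "geometry_observables",
    "polygon_properties",
    "stripe_admissible",
    "stripe_barrier_energy",
]

REGION_CYTOPLASM = 0
REGION_NUCLEUS = 1

#: Greville abscissae of a cubic Bezier segment (parameter values at which the
#: control net reproduces linear fields exactly).
GREVILLE = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])


# ----------------------------------------------------------------------
# Bezier patch displacement field
# ----------------------------------------------------------------------
def _bernstein3(t: np.ndarray) -> np.ndarray:
    """Cubic Bernstein polynomials B_{i,3}(t), shape (n, 4)."""
    t = np.asarray(t, dtype=float)
    s = 1.0 - t
    return np.stack([s**3, 3.0 * s**2 * t, 3.0 * s * t**2, t**3], axis=-1)


def bezier_basis(X: np.ndarray) -> np.ndarray:
    """Tensor-product cubic Bernstein basis at points ``X`` in ``[-1, 1]^2``.

    Returns an array of shape ``(n, 16)`` such that the displacement is
    ``basis @ c`` with ``c`` the ``(16, 2)`` flattened control displacements
    (row-major over the 4x4 net).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    s = (X[:, 0] + 1.0) / 2.0
    t = (X[:, 1] + 1.0) / 2.0
    eps = 1e-12
    if np.any(s < -eps) or np.any(s > 1 + eps) or np.any(t < -eps) or np.any(t > 1 + eps):
        raise HLECellError("evaluation point outside the spline parameter domain")
    Bs = _bernstein3(np.clip(s, 0.0, 1.0))
    Bt = _bernstein3(np.clip(t, 0.0, 1.0))
    return (Bs[:, :, None] * Bt[:, None, :]).reshape(-1, 16)


@dataclass
class ControlNet:
    """4x4 net of control-point displacements (32 scalar degrees of freedom).

    ``r[i, j]`` is the planar displacement of the control point at Greville
    position ``(GREVILLE[i], GREVILLE[j])`` of the parameter square, stored in
    units of ``R0``.
    """

    r: np.ndarray  # (4, 4, 2)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (4, 4, 2):
            raise HLECellError(f"control net must be (4, 4, 2), got {self.r.shape}")
        if not np.all(np.isfinite(self.r)):
            raise HLECellError("control net contains non-finite entries")

    @classmethod
    def zeros(cls) -> "ControlNet":
        return cls(np.zeros((4, 4, 2)))

    @classmethod
    def from_flat(cls, c: np.ndarray) -> "ControlNet":
        return cls(np.asarray(c, dtype=float).reshape(4, 4, 2))

    def flat(self) -> np.ndarray:
        return self.r.reshape(32).copy()

    @classmethod
    def affine(
        cls,
        a1: float = 1.0,
        a2: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "ControlNet":
        """Net whose spline reproduces ``u(X) = ((a1-1) X1 + t1, (a2-1) X2 + t2)``.

        Exact by the linear-precision property of the Bezier patch with
        control values sampled at the Greville abscissae.
        """
        g = -1.0 + 2.0 * GREVILLE  # Greville positions in square coordinates
        r = np.zeros((4, 4, 2))
        r[:, :, 0] = (a1 - 1.0) * g[:, None] + translation[0]
        r[:, :, 1] = (a2 - 1.0) * g[None, :] + translation[1]
        return cls(r)

    def translated(self, dx: float, dy: float) -> "ControlNet":
        r = self.r.copy()
        r[:, :, 0] += dx
        r[:, :, 1] += dy
        return ControlNet(r)


def nurbs_displacement(net: ControlNet, X: np.ndarray) -> np.ndarray:
    """Evaluate the spline displacement field at reference points ``X``."""
    return bezier_basis(X) @ net.r.reshape(16, 2)


# ----------------------------------------------------------------------
# reference mesh
# ----------------------------------------------------------------------
@dataclass
class ReferenceMesh:
    """Triangulated reference disc with nucleus/cytoplasm region labels."""

    nodes: np.ndarray          # (n, 2)
    triangles: np.ndarray      # (m, 3)
    region: np.ndarray         # (m,) REGION_*
    target_edge: float
    rim: np.ndarray            # boundary node indices, CCW by reference angle
    areas: np.ndarray = field(init=False)     # (m,) reference element areas
    Dinv: np.ndarray = field(init=False)      # (m, 2, 2) inverse edge matrices
    basis: np.ndarray = field(init=False)     # (n, 16) Bezier basis at nodes

    def __post_init__(self) -> None:
        X = self.nodes
        tri = self.triangles
        d1 = X[tri[:, 1]] - X[tri[:, 0]]
        d2 = X[tri[:, 2]] - X[tri[:, 0]]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        self.areas = 0.5 * np.abs(det)
        D = np.stack([d1, d2], axis=-1)  # columns are reference edges
        self.Dinv = np.linalg.inv(D)
        self.basis = bezier_basis(X)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_volumes(self, params: CellParameters) -> np.ndarray:
        """Reference element volumes [R0^3] (area times resting thickness)."""
        return self.areas * params.b0_over_R0

    def min_angle_deg(self) -> float:
        X = self.nodes[self.triangles]
        angs = []
        for k in range(3):
            a = X[:, (k + 1) % 3] - X[:, k]
            b = X[:, (k + 2) % 3] - X[:, k]
            cosang = np.sum(a * b, axis=1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angs))

    def to_table(self) -> str:
        """Plain-text export: node table, connectivity, region labels."""
        lines = [f"# nodes {self.n_nodes} elements {self.n_elements}"]
        for i, (x, y) in enumerate(self.nodes):
            lines.append(f"n {i} {x:.12g} {y:.12g}")
        for e, (t, rg) in enumerate(zip(self.triangles, self.region)):
            lines.append(f"e {e} {t[0]} {t[1]} {t[2]} {int(rg)}")
        return "\n".join(lines) + "\n"


def _ring_points(radii: np.ndarray, edge: float, jitter: float, rng) -> np.ndarray:
    pts = [np.zeros((1, 2))]
    for j, r in enumerate(radii[1:], start=1):
        n_k = max(6, int(round(2.0 * math.pi * r / edge)))
        offset = 0.5 * (j % 2) + jitter * rng.uniform(-0.5, 0.5)
        th = 2.0 * math.pi * (np.arange(n_k) + offset) / n_k
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    return np.vstack(pts)


def build_reference_mesh(
    params: CellParameters | None = None,
    target_edge: float = 0.1,
    min_angle: float = 15.0,
    seed: int = 0,
) -> ReferenceMesh:
    """Quasi-uniform triangulation of the unit disc with a nucleus disc.

    Nodes are placed on concentric rings (one ring exactly at the nucleus
    radius so elements classify cleanly) and triangulated by Delaunay.  If
    the worst element angle falls below ``min_angle`` degrees the ring
    phases are re-seeded with a small perturbation.
    """
    if target_edge <= 0:
        raise HLECellError("target_edge must be positive")
    params = params or CellParameters()
    RN = params.RN_over_R0
    n_in = max(2, int(round(RN / target_edge)))
    n_out = max(2, int(round((1.0 - RN) / target_edge)))
    radii = np.concatenate(
        [np.linspace(0.0, RN, n_in + 1), np.linspace(RN, 1.0, n_out + 1)[1:]]
    )
    rng = np.random.default_rng(seed)
    for attempt in range(8):
        nodes = _ring_points(radii, target_edge, jitter=0.2 * attempt, rng=rng)
        tri = Delaunay(nodes).simplices
        centroids = nodes[tri].mean(axis=1)
        region = np.where(
            np.hypot(centroids[:, 0], centroids[:, 1]) < RN,
            REGION_NUCLEUS,
            REGION_CYTOPLASM,
        ).astype(np.int64)
        # rim nodes: outermost ring, ordered counter-clockwise
        rad = np.hypot(nodes[:, 0], nodes[:, 1])
        rim = np.where(rad > 1.0 - 1e-9)[0]
        rim = rim[np.argsort(np.arctan2(nodes[rim, 1], nodes[rim, 0]))]
        mesh = ReferenceMesh(nodes, tri, region, target_edge, rim)
        if mesh.min_angle_deg() >= min_angle:
            return mesh
    raise HLECellError(
        f"could not build a mesh with min angle >= {min_angle} deg "
        f"at target_edge={target_edge}"
    )


# ----------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------
@dataclass
class DeformedConfiguration:
    """Per-element kinematics of a deformed microstate."""

    mesh: ReferenceMesh
    net: ControlNet
    x: np.ndarray                # (n, 2) deformed nodal coordinates
    F: np.ndarray                # (m, 2, 2) deformation gradients
    lI: np.ndarray               # (m,) major principal stretch
    lII: np.ndarray              # (m,) minor principal stretch
    principal_dirs: np.ndarray   # (m, 2, 2) columns = principal directions
    b0_over_R0: float

    @property
    def J(self) -> np.ndarray:
        """In-plane area stretch det F = lI * lII."""
        return self.lI * self.lII

    @property
    def thickness(self) -> np.ndarray:
        """Current thickness b = b0 / (lI lII) from incompressibility."""
        return self.b0_over_R0 / self.J

    @property
    def boundary(self) -> np.ndarray:
        """Deformed boundary polygon (rim nodes, CCW in reference angle)."""
        return self.x[self.mesh.rim]

    @property
    def centroid(self) -> np.ndarray:
        return polygon_properties(self.boundary)["centroid"]

    def right_cauchy_green(self) -> np.ndarray:
        """Per-element C = F^T F."""
        return np.einsum("eki,ekj->eij", self.F, self.F)


def deform(
    mesh: ReferenceMesh,
    net: ControlNet,
    b0_over_R0: float = 0.05,
    check: bool = True,
) -> DeformedConfiguration:
    """Apply the spline displacement to the mesh and compute kinematics.

    Raises :class:`InvalidKinematicsError` if any element folds over
    (``det F <= 0``) and ``check`` is true.
    """
    u = mesh.basis @ net.r.reshape(16, 2)
    x = mesh.nodes + u
    tri = mesh.triangles
    d1 = x[tri[:, 1]] - x[tri[:, 0]]
    d2 = x[tri[:, 2]] - x[tri[:, 0]]
    dm = np.stack([d1, d2], axis=-1)
    F = dm @ mesh.Dinv
    detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if check and np.any(detF <= 0):
        raise InvalidKinematicsError(
            f"{int(np.sum(detF <= 0))} element(s) with det F <= 0"
        )
    C = np.einsum("eki,ekj->eij", F, F)
    tr = C[:, 0, 0] + C[:, 1, 1]
    disc = np.sqrt(np.maximum((0.5 * (C[:, 0, 0] - C[:, 1, 1])) ** 2 + C[:, 0, 1] ** 2, 0.0))
    lI = np.sqrt(np.maximum(0.5 * tr + disc, 0.0))
    lII = np.sqrt(np.maximum(0.5 * tr - disc, 1e-300))
    # principal directions of C (reference frame)
    dirs = np.empty_like(C)
    a = C[:, 0, 0] - 0.5 * tr + disc  # eigvec of largest eigenvalue
    v1 = np.stack([C[:, 0, 1], disc - 0.5 * (C[:, 0, 0] - C[:, 1, 1])], axis=1)
    degenerate = np.linalg.norm(v1, axis=1) < 1e-14
    v1[degenerate] = [1.0, 0.0]
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    dirs[:, :, 0] = v1
    dirs[:, 0, 1] = -v1[:, 1]
    dirs[:, 1, 1] = v1[:, 0]
    del a
    return DeformedConfiguration(
        mesh=mesh,
        net=net,
        x=x,
        F=F,
        lI=lI,
        lII=lII,
        principal_dirs=dirs,
        b0_over_R0=b0_over_R0,
    )


# ----------------------------------------------------------------------
# shape observables
# ----------------------------------------------------------------------
@dataclass
class GeometryObservables:
    """Coarse morphometrics of the cell outline."""

    A: float          # enclosed area [R0^2]
    p: float          # perimeter [R0]
    AS: float         # aspect ratio of best-fit ellipse (>= 1)
    phi_cell: float   # major-axis angle from the x2 (stripe) axis, (-pi/2, pi/2]
    FF: float         # form factor p^2 / (4 pi A)
    centroid: np.ndarray


def polygon_properties(poly: np.ndarray) -> dict:
    """Area, perimeter, centroid and second central area moments of a polygon.

    Vertex order may be CW or CCW; results are orientation-independent.
    """
    poly = np.asarray(poly, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * np.sum(cross)
    if A < 0:  # normalise to CCW
        return polygon_properties(poly[::-1])
    if A == 0:
        raise NonSimpleBoundaryError("degenerate boundary polygon")
    cx = np.sum((x + xn) * cross) / (6.0 * A)
    cy = np.sum((y + yn) * cross) / (6.0 * A)
    Ixx = np.sum((y**2 + y * yn + yn**2) * cross) / 12.0
    Iyy = np.sum((x**2 + x * xn + xn**2) * cross) / 12.0
    Ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    # central moments
    Ixx -= A * cy**2
    Iyy -= A * cx**2
    Ixy -= A * cx * cy
    p = float(np.sum(np.hypot(xn - x, yn - y)))
    return {
        "A": float(A),
        "p": p,
        "centroid": np.array([cx, cy]),
        "Ixx": float(Ixx),
        "Iyy": float(Iyy),
        "Ixy": float(Ixy),
    }


def geometry_observables(
    config: DeformedConfiguration | np.ndarray,
    check_simple: bool = True,
) -> GeometryObservables:
    """Shape observables from the (deformed) boundary polygon.

    The best-fit ellipse is the ellipse with the same area and the same
    second area moments as the enclosed polygon (the standard image-analysis
    construction); ``AS`` is its axis ratio and ``phi_cell`` the major-axis
    inclination to the x2 axis.
    """
    poly = config.boundary if isinstance(config, DeformedConfiguration) else np.asarray(config)
    if check_simple and not Polygon(poly).is_simple:
        raise NonSimpleBoundaryError("boundary polygon self-intersects")
    props = polygon_properties(poly)
    A, p = props["A"], props["p"]
    # covariance of the enclosed region; eigenvalues ~ (semi-axis/2)^2 * A
    cov = np.array([[props["Iyy"], props["Ixy"]], [props["Ixy"], props["Ixx"]]]) / A
    evals, evecs = np.linalg.eigh(cov)
    AS = float(math.sqrt(max(evals[1], 0.0) / max(evals[0], 1e-300)))
    major = evecs[:, 1]  # (x, y) components of the major axis
    phi = math.atan2(major[0], major[1])  # angle from x2 axis
    if phi <= -math.pi / 2:
        phi += math.pi
    elif phi > math.pi / 2:
        phi -= math.pi
    return GeometryObservables(
        A=A,
        p=p,
        AS=AS,
        phi_cell=phi,
        FF=p**2 / (4.0 * math.pi * A),
        centroid=props["centroid"],
    )


# ----------------------------------------------------------------------
# substrate pattern
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class StripePattern:
    """Adhesive stripe of normalised width ``W_hat = W / (2 R0)``.

    The stripe axis is the x2 direction; adhesion is possible only where
    ``|x1| <= W_hat * R0``.  ``W_hat = inf`` is the unpatterned substrate.
    """

    W_hat: float = math.inf

    def __post_init__(self) -> None:
        if not self.W_hat > 0:
            raise HLECellError("W_hat must be positive")

    @property
    def half_width(self) -> float:
        """Stripe half-width W/2 in units of R0 (equals W_hat)."""
        return self.W_hat

    @property
    def patterned(self) -> bool:
        return math.isfinite(self.W_hat)


def stripe_admissible(
    config: DeformedConfiguration,
    pattern: StripePattern,
) -> bool:
    """True iff every deformed node lies on the adhesive stripe."""
    if not pattern.patterned:
        return True
    return bool(np.all(np.abs(config.x[:, 0]) <= pattern.half_width))


def stripe_barrier_energy(
    x: np.ndarray,
    pattern: StripePattern,
    stiffness: float = 1.0e4,
) -> float:
    """Smooth quartic barrier penalising nodes outside the stripe.

    Zero inside the stripe and C^3-continuous at its edge; used by the
    Langevin integrator, which needs a differentiable confinement force
    (the Monte-Carlo sampler uses hard rejection instead).  Returned in
    units of the normalised free energy.
    """
    if not pattern.patterned:
        return 0.0
    excess = np.maximum(np.abs(x[:, 0]) - pattern.half_width, 0.0)
    return float(stiffness * np.sum(excess**4))
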