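"""Core diffraction geometry for polychromatic (Laue) stills.

This module holds the joint crystal/beam/detector/goniometer model shared by
every stage of the reduction pipeline, together with the handful of geometric
primitives everything else is built from: the reciprocal basis (Busing--Levy
``B`` matrix), the Ewald condition that fixes the diffraction wavelength of a
reciprocal-lattice vector, and the mapping between scattered rays and detector
pixels.

Conventions
-----------
* Right-handed lab frame.  The incident beam propagates along ``+z`` by
  default (``s0_hat = (0, 0, 1)``), the goniometer axis defaults to ``+x``,
  and the detector panel sits downstream at ``z = distance`` with its inward
  normal facing the sample.
* Reciprocal-space vectors are in 1/Angstrom.  In the Ewald construction the
  incident and scattered wavevectors ``s0``/``s1`` have magnitude
  ``1/lambda``; unit-direction variants carry a ``_hat`` suffix.
* Pixel coordinates are 0-based and continuous; the center of pixel
  ``(i, j)`` is at ``(i + 0.5, j + 0.5)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "GeometryError",
    "InvalidCellError",
    "NoDiffractionError",
    "DegenerateDirectionError",
    "UnitCell",
    "CrystalModel",
    "BeamModel",
    "DetectorModel",
    "GoniometerModel",
    "Experiment",
    "reciprocal_basis",
    "cell_from_B",
    "wavelength_for_q",
    "wavelengths_for_q",
    "project_to_detector",
    "observed_q_direction",
    "axis_angle_matrix",
    "rotation_angle_deg",
    "misorientation_deg",
    "hkl_box_bounds",
    "resolution_filtered_hkls",
    "feasible_hkls",
]


class GeometryError(ValueError):
    """Base class for geometry-model errors."""


class InvalidCellError(GeometryError):
    """Unit-cell parameters do not define a positive-definite metric."""


class NoDiffractionError(GeometryError):
    """No wavelength puts the requested scattering vector on an Ewald sphere."""


class DegenerateDirectionError(GeometryError):
    """A scattering direction is undefined (e.g. centroid at the beam center)."""


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise GeometryError(f"{name} must be a nonzero finite vector")
    return v / n


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if not all(x > 0 for x in (self.a, self.b, self.c)):
            raise InvalidCellError("cell lengths must be positive")
        if not all(0.0 < x < 180.0 for x in (self.alpha, self.beta, self.gamma)):
            raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        G = self.metric()
        # positive definiteness: all leading minors > 0
        if np.linalg.det(G) <= 0 or np.linalg.eigvalsh(G)[0] <= 0:
            raise InvalidCellError("cell angles are inconsistent (metric not positive definite)")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def metric(self) -> np.ndarray:
        """Real-space metric tensor G with G[i, j] = a_i . a_j."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric())))

    def d_spacing(self, hkl) -> np.ndarray:
        """Lattice-plane spacing(s) for integer index triples."""
        B = reciprocal_basis(self)
        q = np.atleast_2d(hkl) @ B.T
        return 1.0 / np.linalg.norm(q, axis=-1)


@dataclass(frozen=True)
class CrystalModel:
    """Oriented crystal: unit cell plus orthonormal orientation matrix U."""

    cell: UnitCell
    U: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        if U.shape != (3, 3):
            raise GeometryError("U must be 3x3")
        if not np.allclose(U.T @ U, np.eye(3), atol=1e-10):
            raise GeometryError("U must be orthonormal to 1e-10")
        if np.linalg.det(U) < 0:
            raise GeometryError("U must be a proper rotation (det = +1)")
        object.__setattr__(self, "U", U)

    @property
    def UB(self) -> np.ndarray:
        return self.U @ reciprocal_basis(self.cell)

    def rotated(self, R: np.ndarray) -> "CrystalModel":
        return replace(self, U=np.asarray(R) @ self.U)


@dataclass(frozen=True)
class BeamModel:
    """Polychromatic incident beam.

    ``s0_hat`` is the unit propagation direction; ``lambda_min``/``lambda_max``
    bound the usable bandpass and double as the support of the spectrum, and
    ``spectrum`` optionally tabulates (wavelength, relative intensity) pairs.
    """

    s0_hat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    lambda_nominal: float = 1.05
    lambda_min: float = 0.9
    lambda_max: float = 1.2
    spectrum: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "s0_hat", _as_unit(self.s0_hat, "s0_hat"))
        if not (0 < self.lambda_min < self.lambda_nominal < self.lambda_max):
            raise GeometryError("need 0 < lambda_min < lambda_nominal < lambda_max")
        if self.spectrum is not None:
            spec = np.asarray(self.spectrum, dtype=float)
            if spec.ndim != 2 or spec.shape[1] != 2 or spec.shape[0] < 2:
                raise GeometryError("spectrum must be an (n, 2) table of (wavelength, intensity)")
            if np.any(spec[:, 1] < 0):
                raise GeometryError("spectrum intensities must be >= 0")
            order = np.argsort(spec[:, 0])
            object.__setattr__(self, "spectrum", spec[order])


@dataclass(frozen=True)
class DetectorModel:
    """Single flat panel.

    ``origin_mm`` is the beam-center position in panel coordinates (mm along
    fast/slow from the pixel-(0,0) corner); ``distance`` is the sample-to-panel
    distance in mm along the panel normal ``fast_hat x slow_hat``.
    """

    distance: float = 200.0
    origin_mm: np.ndarray = field(default_factory=lambda: np.array([169.0, 169.0]))
    fast_hat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    slow_hat: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    pixel_size: float = 0.088
    n_fast: int = 3840
    n_slow: int = 3840

    def __post_init__(self):
        if self.distance <= 0 or self.pixel_size <= 0:
            raise GeometryError("distance and pixel_size must be positive")
        f = _as_unit(self.fast_hat, "fast_hat")
        s = _as_unit(self.slow_hat, "slow_hat")
        if abs(float(f @ s)) > 1e-10:
            raise GeometryError("fast_hat and slow_hat must be orthogonal")
        object.__setattr__(self, "fast_hat", f)
        object.__setattr__(self, "slow_hat", s)
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, dtype=float))

    @property
    def normal_hat(self) -> np.ndarray:
        """Panel normal pointing downstream (away from the sample)."""
        return np.cross(self.fast_hat, self.slow_hat)

    @property
    def beam_center_lab(self) -> np.ndarray:
        """Lab-frame point where the panel plane crosses the normal axis."""
        return self.distance * self.normal_hat

    @property
    def beam_center_px(self) -> np.ndarray:
        return self.origin_mm / self.pixel_size

    def pixel_to_lab(self, centroids_px) -> np.ndarray:
        """Lab-frame positions of continuous pixel coordinates, shape (n, 3)."""
        xy = np.atleast_2d(np.asarray(centroids_px, dtype=float))
        d_mm = xy * self.pixel_size - self.origin_mm
        return (
            self.beam_center_lab
            + d_mm[:, :1] * self.fast_hat
            + d_mm[:, 1:2] * self.slow_hat
        )

    def contains(self, centroids_px) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(centroids_px, dtype=float))
        return (
            (xy[:, 0] >= 0)
            & (xy[:, 0] < self.n_fast)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] < self.n_slow)
        )


@dataclass(frozen=True)
class GoniometerModel:
    """Single rotation axis with per-image setting angles (degrees)."""

    axis_hat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    angles_deg: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    def __post_init__(self):
        object.__setattr__(self, "axis_hat", _as_unit(self.axis_hat, "axis_hat"))
        ang = np.asarray(self.angles_deg, dtype=float)
        if not np.all(np.isfinite(ang)):
            raise GeometryError("goniometer angles must be finite")
        object.__setattr__(self, "angles_deg", ang)

    def rotation(self, i: int) -> np.ndarray:
        return axis_angle_matrix(self.axis_hat, self.angles_deg[i])


@dataclass(frozen=True)
class Experiment:
    """One still or pseudo-rotation series with a shared geometry model."""

    crystal: CrystalModel
    beam: BeamModel
    detector: DetectorModel
    goniometer: GoniometerModel
    image_ids: tuple = ()

    def __post_init__(self):
        ids = tuple(self.image_ids) if len(self.image_ids) else tuple(
            range(len(self.goniometer.angles_deg))
        )
        if len(ids) != len(self.goniometer.angles_deg):
            raise GeometryError("image_ids must match the goniometer angle list")
        if len(set(ids)) != len(ids):
            raise GeometryError("image_ids must be unique")
        object.__setattr__(self, "image_ids", ids)

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def crystal_at(self, i: int) -> CrystalModel:
        """Crystal rotated to the setting of image index ``i``."""
        return self.crystal.rotated(self.goniometer.rotation(i))


# ---------------------------------------------------------------------------
# reciprocal basis
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _reciprocal_basis_cached(cell: UnitCell) -> np.ndarray:
    G = cell.metric()
    try:
        Gstar = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught by UnitCell
        raise InvalidCellError("degenerate metric tensor") from exc
    astar = math.sqrt(Gstar[0, 0])
    bstar = math.sqrt(Gstar[1, 1])
    cstar = math.sqrt(Gstar[2, 2])
    cos_gstar = Gstar[0, 1] / (astar * bstar)
    cos_bstar = Gstar[0, 2] / (astar * cstar)
    sin_gstar = math.sqrt(max(0.0, 1.0 - cos_gstar**2))
    sin_bstar = math.sqrt(max(0.0, 1.0 - cos_bstar**2))
    cos_alpha = math.cos(math.radians(cell.alpha))
    B = np.array(
        [
            [astar, bstar * cos_gstar, cstar * cos_bstar],
            [0.0, bstar * sin_gstar, -cstar * sin_bstar * cos_alpha],
            [0.0, 0.0, 1.0 / cell.c],
        ]
    )
    B.setflags(write=False)
    return B


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Busing--Levy ``B``: columns are the reciprocal basis a*, b*, c* (1/A).

    For any integer triple ``h`` the reciprocal-lattice vector in the crystal
    setting frame is ``q = U @ B @ h``.
    """
    return _reciprocal_basis_cached(cell)


def cell_from_B(B: np.ndarray) -> UnitCell:
    """Recover the six cell parameters from a reciprocal basis matrix."""
    B = np.asarray(B, dtype=float)
    G = np.linalg.inv(B.T @ B)
    a, b, c = (math.sqrt(G[i, i]) for i in range(3))
    alpha = math.degrees(math.acos(G[1, 2] / (b * c)))
    beta = math.degrees(math.acos(G[0, 2] / (a * c)))
    gamma = math.degrees(math.acos(G[0, 1] / (a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


# ---------------------------------------------------------------------------
# Ewald condition
# ---------------------------------------------------------------------------


def wavelength_for_q(q, s0_hat) -> float:
    """The unique wavelength placing reciprocal vector ``q`` on an Ewald sphere.

    lambda = -2 (q . s0_hat) / |q|^2.  With ``s0 = s0_hat / lambda`` the
    elastic condition ``|s0 + q| = 1/lambda`` then holds exactly.
    """
    q = np.asarray(q, dtype=float)
    s0_hat = np.asarray(s0_hat, dtype=float)
    q2 = float(q @ q)
    proj = float(q @ s0_hat)
    if q2 == 0.0 or proj >= 0.0:
        raise NoDiffractionError("q . s0_hat must be negative for diffraction")
    return -2.0 * proj / q2


def wavelengths_for_q(q: np.ndarray, s0_hat) -> np.ndarray:
    """Vectorized :func:`wavelength_for_q`; infeasible rows come back NaN."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    s0_hat = np.asarray(s0_hat, dtype=float)
    q2 = np.einsum("ij,ij->i", q, q)
    proj = q @ s0_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = -2.0 * proj / q2
    lam[(q2 == 0.0) | (proj >= 0.0)] = np.nan
    return lam


# ---------------------------------------------------------------------------
# detector projection
# ---------------------------------------------------------------------------


def project_to_detector(s1, detector: DetectorModel) -> np.ndarray:
    """Intersect rays along ``s1`` (from the sample) with the panel plane.

    Returns continuous 0-based pixel coordinates, shape (n, 2).  Rays parallel
    to the panel or pointing away yield NaN rows (off-detector signal, not an
    exception); callers decide whether to additionally clip to panel bounds
    with :meth:`DetectorModel.contains`.
    """
    s1 = np.atleast_2d(np.asarray(s1, dtype=float))
    n_hat = detector.normal_hat
    denom = s1 @ n_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        t = detector.distance / denom
    p = t[:, None] * s1 - detector.beam_center_lab
    x_mm = p @ detector.fast_hat + detector.origin_mm[0]
    y_mm = p @ detector.slow_hat + detector.origin_mm[1]
    xy = np.column_stack([x_mm, y_mm]) / detector.pixel_size
    xy[denom <= 1e-12] = np.nan
    return xy


def observed_q_direction(centroids_px, detector: DetectorModel, s0_hat) -> np.ndarray:
    """Unit scattering-vector directions implied by observed centroids.

    Returns ``normalize(s1_hat - s0_hat)`` row-wise; this direction is
    wavelength-independent, which is what makes direction-space index
    matching possible without knowing per-spot wavelengths.
    """
    s0_hat = _as_unit(s0_hat, "s0_hat")
    pos = detector.pixel_to_lab(centroids_px)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    s1_hat = pos / norms
    dq = s1_hat - s0_hat
    dn = np.linalg.norm(dq, axis=1, keepdims=True)
    if np.any(dn < 1e-12):
        raise DegenerateDirectionError(
            "centroid at the beam center has no defined scattering direction"
        )
    return dq / dn


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def axis_angle_matrix(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = _as_unit(axis, "axis")
    t = math.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + math.sin(t) * K + (1.0 - math.cos(t)) * (K @ K)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, from the trace identity."""
    c = (np.trace(R) - 1.0) / 2.0
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def misorientation_deg(U1: np.ndarray, U2: np.ndarray) -> float:
    """Angle of the rotation carrying orientation ``U1`` onto ``U2``.

    Quaternion-based, so tiny misorientations (down to ~1e-8 degrees) are
    resolved; the trace formula loses them to acos round-off near +1.
    """
    from scipy.spatial.transform import Rotation

    R = np.asarray(U2) @ np.asarray(U1).T
    return math.degrees(Rotation.from_matrix(R).magnitude())


# ---------------------------------------------------------------------------
# feasible reflection enumeration (shared by generator, assignment, prediction)
# ---------------------------------------------------------------------------


def hkl_box_bounds(cell: UnitCell, d_min: float) -> tuple[int, int, int]:
    """Index bounding box |h| <= ceil(a/d_min) etc. covering |q| <= 1/d_min."""
    return tuple(int(math.ceil(length / d_min)) for length in cell.lengths)


@lru_cache(maxsize=8)
def _resolution_filtered_cached(cell: UnitCell, d_min: float, cap: int):
    hmax, kmax, lmax = hkl_box_bounds(cell, d_min)
    n_box = (2 * hmax + 1) * (2 * kmax + 1) * (2 * lmax + 1)
    if n_box > cap:
        raise GeometryError(
            f"candidate box of {n_box} indices exceeds the cap of {cap}; "
            "raise d_min or the cap"
        )
    h = np.arange(-hmax, hmax + 1)
    k = np.arange(-kmax, kmax + 1)
    l = np.arange(-lmax, lmax + 1)
    H = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    qB = H @ reciprocal_basis(cell).T
    absq = np.linalg.norm(qB, axis=1)
    keep = absq <= 1.0 / d_min
    out = (H[keep], qB[keep], absq[keep])
    for a in out:
        a.setflags(write=False)
    return out


def resolution_filtered_hkls(cell: UnitCell, d_min: float, cap: int = 10_000_000):
    """All integer triples with d >= d_min: (hkl, B@h, |q|), cached per cell."""
    return _resolution_filtered_cached(cell, float(d_min), int(cap))


def feasible_hkls(
    crystal: CrystalModel,
    s0_hat,
    lambda_min: float,
    lambda_max: float,
    d_min: float,
    R_setting: np.ndarray | None = None,
    cap: int = 10_000_000,
):
    """Reflections inside the Ewald envelope of ``[lambda_min, lambda_max]``.

    Returns ``(hkl, q, lam)`` arrays for every integer triple with
    ``d >= d_min`` whose Ewald wavelength at the given orientation lies in the
    bandpass.  The setting rotation ``R_setting`` (goniometer) premultiplies
    the crystal orientation.
    """
    H, qB, _ = resolution_filtered_hkls(crystal.cell, d_min, cap)
    R = crystal.U if R_setting is None else np.asarray(R_setting) @ crystal.U
    q = qB @ R.T
    lam = wavelengths_for_q(q, s0_hat)
    keep = np.isfinite(lam) & (lam >= lambda_min) & (lam <= lambda_max)
    return H[keep], q[keep], lam[keep]
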