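"""Per-still least-squares refinement of the experimental geometry.

After wavelength assignment every reflection carries an index and a
wavelength, so each still can be refined independently against its observed
spot centroids.  The objective is the 2-D centroid mismatch summed over
inlier reflections, minimized by Levenberg--Marquardt with a numerically
differentiated Jacobian, with minimum-covariance-determinant outlier
rejection refreshing the inlier set between macrocycles.

Wavelengths are never parameters: inside every function evaluation each
reflection's wavelength is re-derived analytically from the observed
scattering direction at the model scattering-vector magnitude, so scattering
vectors always lie exactly on the Ewald sphere of their own wavelength.
This is what drives the radial component of centroid residuals to (near)
zero and leaves the fit sensitive to the tangential/orientational part of
the geometry.

Because relaxed wavelengths absorb any overall scale, the detector distance
and the |a| cell axis are hard constraints: they are bit-identical before and
after refinement, as is the beam direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .assignment import mcd_outliers
from .geometry import (
    DetectorModel,
    Experiment,
    UnitCell,
    axis_angle_matrix,
    observed_q_direction,
    project_to_detector,
    reciprocal_basis,
)

__all__ = [
    "RefinementParams",
    "RefineResult",
    "SkipImage",
    "centroid_residuals",
    "refine_still",
    "refine_series",
]


class SkipImage(RuntimeError):
    """Too few assigned reflections to refine this image (flag, not fatal)."""


@dataclass(frozen=True)
class RefinementParams:
    """Free/fixed parameter choices and stopping rules.

    Fixed always: detector distance, beam direction, and the |a| axis length
    (relaxed wavelengths make an overall scale unobservable; pinning |a| and
    the distance breaks that degeneracy).  Free: the three crystal
    orientation angles, the remaining cell parameters of the declared lattice
    family, and (optionally) two in-plane detector translations plus three
    detector rotations.
    """

    n_macrocycles: int = 3
    convergence_tol: float = 1e-4  # px change in RMSD between macrocycles
    cell_family: str = "auto"  # auto|triclinic|monoclinic|orthorhombic|tetragonal|hexagonal|cubic
    refine_detector: bool = True
    diff_step: float = 1e-6
    mcd_support_fraction: float | None = None
    mcd_cutoff_quantile: float = 0.975
    max_nfev: int = 200
    # restraint sigmas pulling detector nuisance parameters toward their
    # imported values (mm for translations, radians for rotations).  For a
    # single still the in-plane detector rotation is exactly degenerate with
    # a crystal rotation about the beam axis, and the tilts are nearly
    # absorbed by per-reflection wavelength relaxation; unrestrained they
    # drift freely along those null directions.
    detector_restraint_mm: float = 1.0
    detector_restraint_rad: float = 0.01


_FAMILY_FREE = {
    "cubic": (),
    "tetragonal": ("c",),
    "hexagonal": ("c",),
    "orthorhombic": ("b", "c"),
    "monoclinic": ("b", "c", "beta"),
    "triclinic": ("b", "c", "alpha", "beta", "gamma"),
}


def _detect_family(cell: UnitCell, tol: float = 1e-6) -> str:
    right = all(abs(x - 90.0) < tol for x in cell.angles)
    if right:
        if abs(cell.a - cell.b) < tol and abs(cell.b - cell.c) < tol:
            return "cubic"
        if abs(cell.a - cell.b) < tol:
            return "tetragonal"
        return "orthorhombic"
    if (
        abs(cell.alpha - 90.0) < tol
        and abs(cell.beta - 90.0) < tol
        and abs(cell.gamma - 120.0) < tol
        and abs(cell.a - cell.b) < tol
    ):
        return "hexagonal"
    if abs(cell.alpha - 90.0) < tol and abs(cell.gamma - 90.0) < tol:
        return "monoclinic"
    return "triclinic"


@dataclass
class _Parameterization:
    base: Experiment
    free_cell: tuple
    refine_detector: bool

    @property
    def n_params(self) -> int:
        return 3 + len(self.free_cell) + (5 if self.refine_detector else 0)

    def build(self, x: np.ndarray) -> Experiment:
        base = self.base
        # crystal orientation: small rotation vector (radians)
        rv = x[:3]
        angle = float(np.linalg.norm(rv))
        R = (
            np.eye(3)
            if angle == 0.0
            else axis_angle_matrix(rv / angle, math.degrees(angle))
        )
        cell_kw = {}
        for name, val in zip(self.free_cell, x[3 : 3 + len(self.free_cell)]):
            base_val = getattr(base.crystal.cell, name)
            if name in ("b", "c"):
                cell_kw[name] = base_val * (1.0 + val)  # fractional length change
            else:
                cell_kw[name] = base_val + math.degrees(val)  # angle change
        cell = replace(base.crystal.cell, **cell_kw) if cell_kw else base.crystal.cell
        crystal = replace(base.crystal, cell=cell, U=R @ base.crystal.U)
        detector = base.detector
        if self.refine_detector:
            tf, ts, rf, rs, rn = x[3 + len(self.free_cell) :]
            Rd = (
                axis_angle_matrix(detector.normal_hat, math.degrees(rn))
                @ axis_angle_matrix(detector.slow_hat, math.degrees(rs))
                @ axis_angle_matrix(detector.fast_hat, math.degrees(rf))
            )
            detector = replace(
                detector,
                origin_mm=detector.origin_mm + np.array([tf, ts]),
                fast_hat=Rd @ detector.fast_hat,
                slow_hat=Rd @ detector.slow_hat,
            )
        return replace(base, crystal=crystal, detector=detector)


def _predict(
    centroids: np.ndarray,
    hkl: np.ndarray,
    experiment: Experiment,
    lambda_mode: str = "relaxed",
):
    """Predicted centroids and relaxed wavelengths for assigned reflections."""
    beam, det = experiment.beam, experiment.detector
    qm = hkl @ experiment.crystal.UB.T
    absq = np.linalg.norm(qm, axis=1)
    obs_dirs = observed_q_direction(centroids, det, beam.s0_hat)
    lam = -2.0 * (obs_dirs @ beam.s0_hat) / absq
    if lambda_mode == "nominal":
        lam_pred = np.full(len(hkl), beam.lambda_nominal)
    else:
        lam_pred = lam
    s1 = beam.s0_hat / lam_pred[:, None] + qm
    pred = project_to_detector(s1, det)
    return pred, lam, qm, obs_dirs


def centroid_residuals(
    still: pd.DataFrame, experiment: Experiment, lambda_mode: str = "relaxed"
) -> pd.DataFrame:
    """Per-reflection centroid residuals and the rotation diagnostic dpsi.

    Residuals are observed minus predicted pixel coordinates, decomposed into
    radial/tangential parts about the beam center.  ``dpsi_deg`` is the angle
    by which the crystal would have to rotate about the goniometer axis to
    superpose the model scattering direction onto the observed one
    (diagnostic only; it is never minimized).  ``lambda_mode='nominal'``
    repredicts at the single nominal wavelength, the monochromatic contrast
    mode.
    """
    if still[["h", "k", "l"]].isna().any().any():
        raise ValueError("all reflections must carry assigned Miller indices")
    centroids = still[["x_px", "y_px"]].to_numpy(dtype=float)
    hkl = still[["h", "k", "l"]].to_numpy(dtype=float)
    pred, lam, qm, obs_dirs = _predict(centroids, hkl, experiment, lambda_mode)
    delta = centroids - pred
    center = experiment.detector.beam_center_px
    rad_dir = pred - center
    rad_norm = np.linalg.norm(rad_dir, axis=1, keepdims=True)
    rad_norm[rad_norm == 0] = 1.0
    rad_dir = rad_dir / rad_norm
    radial = np.einsum("ij,ij->i", delta, rad_dir)
    tangential = delta[:, 0] * -rad_dir[:, 1] + delta[:, 1] * rad_dir[:, 0]
    # dpsi: azimuth difference of q about the goniometer axis
    axis = experiment.goniometer.axis_hat
    qm_hat = qm / np.linalg.norm(qm, axis=1, keepdims=True)
    pm = qm_hat - np.outer(qm_hat @ axis, axis)
    po = obs_dirs - np.outer(obs_dirs @ axis, axis)
    cross = np.cross(pm, po) @ axis
    dot = np.einsum("ij,ij->i", pm, po)
    dpsi = np.degrees(np.arctan2(cross, dot))
    return pd.DataFrame(
        {
            "x_pred": pred[:, 0],
            "y_pred": pred[:, 1],
            "dx_px": delta[:, 0],
            "dy_px": delta[:, 1],
            "radial_px": radial,
            "tangential_px": tangential,
            "dpsi_deg": dpsi,
            "wavelength_relaxed": lam,
        },
        index=still.index,
    )


@dataclass
class RefineResult:
    experiment: Experiment
    reflections: pd.DataFrame
    inlier: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    rmsd_initial: float = float("nan")
    rmsd_final: float = float("nan")
    n_macrocycles_run: int = 0
    converged: bool = False


def _rmsd(delta: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))


def refine_still(
    still: pd.DataFrame,
    experiment: Experiment,
    params: RefinementParams | None = None,
) -> RefineResult:
    """Refine one still's geometry against its assigned reflections.

    Raises :class:`SkipImage` when fewer than ``max(6, n_free + 2)`` assigned
    inlier reflections are available.  The returned reflection table carries
    wavelengths re-relaxed at the refined geometry and the final inlier mask.
    """
    params = params or RefinementParams()
    family = (
        _detect_family(experiment.crystal.cell)
        if params.cell_family == "auto"
        else params.cell_family
    )
    if family not in _FAMILY_FREE:
        raise ValueError(f"unknown cell family {family!r}")
    par = _Parameterization(experiment, _FAMILY_FREE[family], params.refine_detector)

    inlier = (
        still["inlier"].to_numpy(dtype=bool)
        if "inlier" in still.columns
        else np.ones(len(still), dtype=bool)
    )
    min_n = max(6, par.n_params + 2)
    if int(inlier.sum()) < min_n:
        raise SkipImage(
            f"{int(inlier.sum())} inlier reflections < required {min_n}"
        )
    centroids = still[["x_px", "y_px"]].to_numpy(dtype=float)
    hkl = still[["h", "k", "l"]].to_numpy(dtype=float)

    if params.refine_detector:
        restraint = np.concatenate(
            [
                np.full(2, 1.0 / params.detector_restraint_mm),
                np.full(3, 1.0 / params.detector_restraint_rad),
            ]
        )
    else:
        restraint = np.zeros(0)

    def residual_fn(x, mask):
        exp = par.build(x)
        pred, _, _, _ = _predict(centroids[mask], hkl[mask], exp)
        r = (centroids[mask] - pred).ravel()
        r = np.nan_to_num(r, nan=1e4)
        if restraint.size:
            r = np.concatenate([r, x[-5:] * restraint])
        return r

    x = np.zeros(par.n_params)
    pred0, _, _, _ = _predict(centroids[inlier], hkl[inlier], experiment)
    rmsd_prev = _rmsd(centroids[inlier] - pred0)
    rmsd_initial = rmsd_prev
    converged = False
    cycles = 0
    for _ in range(params.n_macrocycles):
        cycles += 1
        sol = least_squares(
            residual_fn,
            x,
            args=(inlier,),
            method="lm",
            diff_step=params.diff_step,
            max_nfev=params.max_nfev * par.n_params,
        )
        x = sol.x
        exp = par.build(x)
        pred_all, _, _, _ = _predict(centroids, hkl, exp)
        delta_all = centroids - pred_all
        new_inlier = mcd_outliers(
            delta_all,
            support_fraction=params.mcd_support_fraction,
            cutoff_quantile=params.mcd_cutoff_quantile,
        )
        if int(new_inlier.sum()) >= min_n:
            inlier = new_inlier
        rmsd = _rmsd(delta_all[inlier])
        if abs(rmsd_prev - rmsd) < params.convergence_tol:
            rmsd_prev = rmsd
            converged = True
            break
        rmsd_prev = rmsd

    refined = par.build(x)
    out = still.copy()
    pred, lam, _, _ = _predict(centroids, hkl, refined)
    out["wavelength"] = lam
    out["inlier"] = inlier
    out["dx_px"] = centroids[:, 0] - pred[:, 0]
    out["dy_px"] = centroids[:, 1] - pred[:, 1]
    return RefineResult(
        experiment=refined,
        reflections=out,
        inlier=inlier,
        rmsd_initial=rmsd_initial,
        rmsd_final=rmsd_prev,
        n_macrocycles_run=cycles,
        converged=converged,
    )


def refine_series(
    stills: dict,
    experiments: dict,
    params: RefinementParams | None = None,
):
    """Refine every still independently; skipped images are flagged, not fatal.

    ``stills`` maps image_id -> assigned reflection table; ``experiments``
    maps image_id -> per-still :class:`Experiment`.  Returns
    ``(results, skipped)`` where ``results`` maps image_id ->
    :class:`RefineResult` and ``skipped`` maps image_id -> reason string.
    """
    results, skipped = {}, {}
    for image_id, df in stills.items():
        try:
            results[image_id] = refine_still(df, experiments[image_id], params)
        except SkipImage as exc:
            skipped[image_id] = str(exc)
    return results, skipped
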