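"""Joint Miller-index and wavelength assignment for polychromatic stills.

A monochromatic indexing solution gives each still an approximate crystal
orientation but leaves most spots unindexed, because a single nominal
wavelength only explains the reflections that happen to sit on that one Ewald
sphere.  This module relaxes the monochromatic constraint: every reflection
may take any wavelength inside a user-provided bandpass, which makes the
*direction* of the scattering vector (wavelength-independent) the observable
to match on.

Per still, :func:`optimize_indexing` iterates:

1. enumerate all reflections geometrically feasible inside the bandpass,
2. build the cost matrix of angles between observed and candidate
   scattering-vector directions,
3. solve the rectangular linear sum assignment problem,
4. assign each matched spot the wavelength placing its scattering vector on
   its own Ewald sphere,
5. reject outliers with the minimum covariance determinant (MCD) estimator
   on centroid residuals, and
6. update the crystal orientation by solving the orthogonal Procrustes
   problem on the inlier direction pairs.

The unit cell is held fixed throughout; only the orientation rotates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2
from sklearn.covariance import MinCovDet

from .geometry import (
    BeamModel,
    CrystalModel,
    Experiment,
    feasible_hkls,
    observed_q_direction,
    project_to_detector,
)

__all__ = [
    "AssignmentParams",
    "AssignmentError",
    "NonConvergenceError",
    "enumerate_feasible_hkls",
    "build_cost_matrix",
    "assign_indices",
    "procrustes_rotation",
    "mcd_outliers",
    "optimize_indexing",
]


class AssignmentError(RuntimeError):
    pass


class NonConvergenceError(AssignmentError):
    """Too few inliers survived an assignment macrocycle."""


@dataclass(frozen=True)
class AssignmentParams:
    """Knobs for :func:`optimize_indexing`.

    ``max_angle_deg`` gates matches after the assignment solve: pairs whose
    observed/predicted directions disagree by more than this are released to
    unmatched rather than forced.  ``capture_angle_deg`` is the wider gate
    used during the orientation-correction macrocycles, where the initial
    orientation error can exceed the release gate; it bounds the recoverable
    initial misorientation.  MCD parameters control the robust outlier
    rejection applied to 2-D centroid residuals between macrocycles.
    """

    lambda_min: float = 0.9
    lambda_max: float = 1.2
    d_min: float = 1.4
    n_macrocycles: int = 3
    max_angle_deg: float = 0.1
    capture_angle_deg: float = 1.0
    mcd_support_fraction: float | None = None
    mcd_cutoff_quantile: float = 0.975
    candidate_cap: int = 10_000_000

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if not self.lambda_min < self.lambda_max:
            raise ValueError("lambda bounds must be ordered")
        if self.n_macrocycles < 1:
            raise ValueError("n_macrocycles must be >= 1")


def enumerate_feasible_hkls(
    crystal: CrystalModel,
    beam: BeamModel,
    d_min: float,
    R_setting: np.ndarray | None = None,
    lambda_min: float | None = None,
    lambda_max: float | None = None,
    cap: int = 10_000_000,
):
    """All (hkl, q, lambda) with d >= d_min and lambda inside the bandpass."""
    return feasible_hkls(
        crystal,
        beam.s0_hat,
        beam.lambda_min if lambda_min is None else lambda_min,
        beam.lambda_max if lambda_max is None else lambda_max,
        d_min,
        R_setting=R_setting,
        cap=cap,
    )


def build_cost_matrix(obs_dirs: np.ndarray, cand_dirs: np.ndarray) -> np.ndarray:
    """Angles (radians) between observed and candidate unit directions."""
    obs = np.atleast_2d(np.asarray(obs_dirs, dtype=float))
    cand = np.atleast_2d(np.asarray(cand_dirs, dtype=float))
    for arr, name in ((obs, "observed"), (cand, "candidate")):
        norms = np.linalg.norm(arr, axis=1)
        if np.any(norms < 1e-12):
            raise AssignmentError(f"zero-norm {name} direction")
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise AssignmentError(f"{name} directions must be unit vectors")
    return np.arccos(np.clip(obs @ cand.T, -1.0, 1.0))


def assign_indices(cost: np.ndarray, max_angle: float):
    """Minimum-total-cost one-to-one matching, then release poor matches.

    ``max_angle`` is in the same units as the cost entries (radians for
    matrices from :func:`build_cost_matrix`).  Returns ``(obs_idx, cand_idx)``
    of the retained matches.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    if n > m:
        raise AssignmentError(f"more observations ({n}) than candidates ({m})")
    rows, cols = linear_sum_assignment(cost)
    keep = cost[rows, cols] <= max_angle
    return rows[keep], cols[keep]


def procrustes_rotation(
    pred_dirs: np.ndarray, obs_dirs: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Proper rotation R minimizing sum_i w_i |obs_i - R pred_i|^2 (Kabsch)."""
    pred = np.atleast_2d(np.asarray(pred_dirs, dtype=float))
    obs = np.atleast_2d(np.asarray(obs_dirs, dtype=float))
    if pred.shape[0] < 2:
        raise AssignmentError("need at least 2 direction pairs")
    w = np.ones(pred.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    C = (obs * w[:, None]).T @ pred
    U, s, Vt = np.linalg.svd(C)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise AssignmentError("degenerate geometry: directions are collinear")
    D = np.diag([1.0, 1.0, math.copysign(1.0, np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def _exact_mcd(points: np.ndarray, h: int):
    best = (np.inf, None)
    n = points.shape[0]
    for subset in combinations(range(n), h):
        sub = points[list(subset)]
        cov = np.cov(sub, rowvar=False)
        det = np.linalg.det(np.atleast_2d(cov))
        if det < best[0]:
            best = (det, np.asarray(subset))
    subset = best[1]
    sub = points[subset]
    return sub.mean(axis=0), np.atleast_2d(np.cov(sub, rowvar=False))


def mcd_outliers(
    points: np.ndarray,
    support_fraction: float | None = None,
    cutoff_quantile: float = 0.975,
) -> np.ndarray:
    """Inlier mask from the minimum covariance determinant estimator.

    The h-point subset minimizing the covariance determinant defines a robust
    location/scatter; points whose robust squared Mahalanobis distance exceeds
    the chi-square ``cutoff_quantile`` (d degrees of freedom) are flagged.
    Exact subset search for n <= 12, FAST-MCD otherwise.  A singular robust
    covariance degrades to an all-inlier mask with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    if n <= d + 1:
        raise AssignmentError(f"need more than d+1={d + 1} points for MCD, got {n}")
    h_min = int(math.ceil((n + d + 1) / 2.0))
    h = h_min if support_fraction is None else max(h_min, int(math.ceil(support_fraction * n)))
    h = min(h, n)
    try:
        if n <= 12:
            loc, cov = _exact_mcd(pts, h)
            diff = pts - loc
            md2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            # consistency rescale (h-th distance onto the h/n chi2 quantile),
            # then the standard one-step reweighting from the provisional
            # inliers -- the raw subset covariance is biased low
            scale = np.sort(md2)[h - 1] / chi2.ppf(h / n, d)
            if scale <= 0:
                raise np.linalg.LinAlgError("zero scatter")
            good = md2 / scale <= chi2.ppf(cutoff_quantile, d)
            if good.sum() > d + 1:
                loc = pts[good].mean(axis=0)
                cov = np.atleast_2d(np.cov(pts[good], rowvar=False))
                diff = pts - loc
                md2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            else:
                md2 = md2 / scale
        else:
            mcd = MinCovDet(
                support_fraction=h / n, random_state=0, assume_centered=False
            ).fit(pts)
            md2 = mcd.mahalanobis(pts)
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("singular robust covariance; treating all points as inliers")
        return np.ones(n, dtype=bool)
    if not np.all(np.isfinite(md2)):
        warnings.warn("non-finite robust distances; treating all points as inliers")
        return np.ones(n, dtype=bool)
    return md2 <= chi2.ppf(cutoff_quantile, d)


# ---------------------------------------------------------------------------
# the per-still driver
# ---------------------------------------------------------------------------


def _prune_candidates(cost: np.ndarray, prune_angle: float):
    """Keep candidate columns plausibly matchable to some observation."""
    min_per_col = cost.min(axis=0)
    keep = np.flatnonzero(min_per_col <= prune_angle)
    n = cost.shape[0]
    if keep.size < n:  # always leave a feasible rectangular problem
        keep = np.argsort(min_per_col)[: max(n, keep.size)]
        keep = np.sort(keep)
    return keep


def _central_ray_tiebreak(rows, cols, hkl, absq, obs_dirs, cost, beam, params, max_angle):
    """Resolve same-ray (harmonic-order) assignment degeneracy.

    All integer multiples of one coprime index share a scattering direction,
    so the angle cost cannot distinguish them; among the in-band members of
    the matched central ray that fit the observation equally well, prefer the
    one whose relaxed wavelength is closest to the spectral peak (the most
    probable wavelength).  The matched index may still be any harmonic when
    the spectrum does not discriminate.
    """
    if rows.size == 0:
        return cols
    g = np.gcd.reduce(np.abs(hkl), axis=1)
    g = np.where(g == 0, 1, g)
    reduced = hkl // g[:, None]
    ray_map: dict[tuple, list[int]] = {}
    for j in np.unique(cols):
        ray_map.setdefault(tuple(reduced[j]), []).append(j)
    # include unmatched members of matched rays
    matched_rays = set(ray_map)
    for j in range(len(hkl)):
        key = tuple(reduced[j])
        if key in matched_rays and j not in ray_map[key]:
            ray_map[key].append(j)
    new_cols = cols.copy()
    used = set(cols.tolist())
    for i, (r, j) in enumerate(zip(rows, cols)):
        members = ray_map[tuple(reduced[j])]
        if len(members) == 1:
            continue
        best, best_dist = j, np.inf
        for m in members:
            if m != j and m in used:
                continue  # keep the matching one-to-one
            if cost[r, m] > max_angle:
                continue
            lam_m = -2.0 * float(obs_dirs[r] @ beam.s0_hat) / absq[m]
            if not (params.lambda_min <= lam_m <= params.lambda_max):
                continue
            dist = abs(lam_m - beam.lambda_nominal)
            if dist < best_dist:
                best, best_dist = m, dist
        if best != j:
            used.discard(int(j))
            used.add(int(best))
        new_cols[i] = best
    return new_cols


def optimize_indexing(
    observed: pd.DataFrame,
    experiment: Experiment,
    params: AssignmentParams | None = None,
):
    """Assign Miller indices and wavelengths to one still's strong spots.

    ``observed`` needs ``x_px``/``y_px`` centroids (one image).  Returns
    ``(assigned, crystal, info)``: the assigned reflection table (columns
    ``h k l wavelength d match_angle_deg inlier`` added), the optimized
    :class:`CrystalModel`, and a per-macrocycle diagnostic dict.

    Raises :class:`NonConvergenceError` if fewer than 6 inliers survive a
    macrocycle (the Procrustes update would be meaningless).
    """
    params = params or AssignmentParams()
    image = (
        f"image {observed['image_id'].iloc[0]}"
        if "image_id" in observed.columns and len(observed)
        else "still"
    )
    if len(observed) < 6:
        raise NonConvergenceError(
            f"{image}: need at least 6 strong spots, got {len(observed)}"
        )
    beam, det = experiment.beam, experiment.detector
    crystal = experiment.crystal
    centroids = observed[["x_px", "y_px"]].to_numpy(dtype=float)
    obs_dirs = observed_q_direction(centroids, det, beam.s0_hat)
    max_angle = math.radians(params.max_angle_deg)
    capture_angle = math.radians(max(params.capture_angle_deg, params.max_angle_deg))
    prune_angle = max(5.0 * max_angle, 1.2 * capture_angle)

    info = {"n_matched": [], "n_inliers": [], "rotation_deg": []}

    def _match(crystal, gate):
        hkl, q, lam = enumerate_feasible_hkls(
            crystal,
            beam,
            params.d_min,
            lambda_min=params.lambda_min,
            lambda_max=params.lambda_max,
            cap=params.candidate_cap,
        )
        if len(hkl) == 0:
            raise AssignmentError("empty feasible set; check bandpass and d_min")
        absq = np.linalg.norm(q, axis=1)
        cand_dirs = q / absq[:, None]
        cost = build_cost_matrix(obs_dirs, cand_dirs)
        keep = _prune_candidates(cost, prune_angle)
        rows, cols = assign_indices(cost[:, keep], gate)
        cols = keep[cols]
        cols = _central_ray_tiebreak(
            rows, cols, hkl, absq, obs_dirs, cost, beam, params, gate
        )
        # wavelength from the observed direction at the model magnitude:
        # lambda = -2 (q_obs_hat . s0_hat) / |B h|
        lam_obs = -2.0 * (obs_dirs[rows] @ beam.s0_hat) / absq[cols]
        in_band = (lam_obs >= params.lambda_min) & (lam_obs <= params.lambda_max)
        rows, cols, lam_obs = rows[in_band], cols[in_band], lam_obs[in_band]
        if rows.size < 6:
            raise NonConvergenceError(
                f"{image}: only {rows.size} matched spots inside the bandpass"
            )
        # centroid residuals at the model wavelength feed outlier rejection
        s1_pred = beam.s0_hat / lam[cols, None] + q[cols]
        pred_px = project_to_detector(s1_pred, det)
        resid = centroids[rows] - pred_px
        inlier = mcd_outliers(
            resid,
            support_fraction=params.mcd_support_fraction,
            cutoff_quantile=params.mcd_cutoff_quantile,
        )
        if int(inlier.sum()) < 6:
            raise NonConvergenceError(
                f"{image}: only {int(inlier.sum())} inliers after MCD rejection"
            )
        return hkl, q, absq, cand_dirs, rows, cols, lam_obs, inlier

    for _ in range(params.n_macrocycles):
        hkl, q, absq, cand_dirs, rows, cols, lam_obs, inlier = _match(crystal, capture_angle)
        R = procrustes_rotation(cand_dirs[cols[inlier]], obs_dirs[rows[inlier]])
        crystal = crystal.rotated(R)
        info["n_matched"].append(int(rows.size))
        info["n_inliers"].append(int(inlier.sum()))
        info["rotation_deg"].append(
            math.degrees(math.acos(min(1.0, max(-1.0, (np.trace(R) - 1) / 2))))
        )

    # output pass at the final orientation, so assigned indices are feasible
    # for (and angles measured against) the orientation actually reported
    hkl, q, absq, cand_dirs, rows, cols, lam_obs, inlier = _match(crystal, max_angle)
    assigned = observed.iloc[rows].copy().reset_index(drop=True)
    assigned[["h", "k", "l"]] = hkl[cols]
    assigned["wavelength"] = lam_obs
    assigned["d"] = 1.0 / absq[cols]
    assigned["match_angle_deg"] = np.degrees(
        np.arccos(np.clip(np.einsum("ij,ij->i", obs_dirs[rows], cand_dirs[cols]), -1, 1))
    )
    assigned["inlier"] = inlier
    assigned["predicted"] = False
    return assigned, crystal, info
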