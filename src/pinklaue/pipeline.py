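"""End-to-end driver: stills -> assignment -> refinement -> prediction.

Convenience layer tying the per-still stages together for a whole
pseudo-rotation series; each image is processed independently and failures
are flagged rather than fatal, mirroring how a beamline pipeline treats a
bad frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .assignment import AssignmentParams, NonConvergenceError, optimize_indexing
from .geometry import Experiment
from .io import StillsSet, sequence_to_stills
from .predict import fit_bandpass, predict_still
from .refine import RefinementParams, refine_series

__all__ = ["SeriesResult", "process_series"]


@dataclass
class SeriesResult:
    assigned: pd.DataFrame
    refined: pd.DataFrame
    stills: StillsSet
    refined_experiments: dict
    refine_reports: dict
    failed_images: dict = field(default_factory=dict)

    @property
    def refined_inliers(self) -> pd.DataFrame:
        return self.refined[self.refined["inlier"]]


def process_series(
    observed: pd.DataFrame,
    experiment: Experiment,
    assignment: AssignmentParams | None = None,
    refinement: RefinementParams | None = None,
) -> SeriesResult:
    """Run wavelength assignment then geometric refinement on every image.

    ``observed`` is the pooled strong-spot table (``image_id`` column keyed
    to the experiment's image ids); ``experiment`` the sequence-level
    geometry, split into stills here.  Images that fail to converge or have
    too few reflections are recorded in ``failed_images``.
    """
    assignment = assignment or AssignmentParams()
    refinement = refinement or RefinementParams()
    stills = sequence_to_stills(experiment)
    by_image = stills.by_image()

    assigned_parts: dict = {}
    optimized: dict = {}
    failed: dict = {}
    for image_id, group in observed.groupby("image_id", sort=True):
        exp_i = by_image.get(image_id)
        if exp_i is None:
            failed[image_id] = "no geometry for image"
            continue
        try:
            assigned, crystal, _ = optimize_indexing(group, exp_i, assignment)
        except NonConvergenceError as exc:
            failed[image_id] = str(exc)
            continue
        assigned_parts[image_id] = assigned
        optimized[image_id] = Experiment(
            crystal=crystal,
            beam=exp_i.beam,
            detector=exp_i.detector,
            goniometer=exp_i.goniometer,
            image_ids=exp_i.image_ids,
        )
    if not assigned_parts:
        raise NonConvergenceError("wavelength assignment failed on every image")
    assigned_all = pd.concat(assigned_parts.values(), ignore_index=True)

    results, skipped = refine_series(assigned_parts, optimized, refinement)
    failed.update(skipped)
    refined_all = pd.concat(
        [r.reflections for r in results.values()], ignore_index=True
    )
    refined_experiments = {i: r.experiment for i, r in results.items()}
    reports = {
        i: {
            "rmsd_initial": r.rmsd_initial,
            "rmsd_final": r.rmsd_final,
            "converged": r.converged,
        }
        for i, r in results.items()
    }
    return SeriesResult(
        assigned=assigned_all,
        refined=refined_all,
        stills=stills,
        refined_experiments=refined_experiments,
        refine_reports=reports,
        failed_images=failed,
    )


def predict_series(
    result: SeriesResult,
    lambda_min: float,
    lambda_max: float,
    d_min: float,
    cutoff_quantile: float = 0.01,
) -> pd.DataFrame:
    """Predict full reflection lists for every refined still.

    The KDE bandpass is trained on the pooled strong assigned inliers of the
    whole series (per-image training sets are too sparse), then applied per
    still; observed strong spots ride through unconditionally.
    """
    train = result.refined[result.refined["inlier"]]
    bandpass = fit_bandpass(train, cutoff_quantile=cutoff_quantile)
    parts = []
    for image_id, exp in result.refined_experiments.items():
        obs = result.refined[result.refined["image_id"] == image_id]
        pred = predict_still(
            exp,
            lambda_min,
            lambda_max,
            d_min,
            bandpass=bandpass,
            observed=obs,
        )
        pred["image_id"] = image_id
        parts.append(pred)
    return pd.concat(parts, ignore_index=True)
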