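"""Ground-truth audits and residual summaries.

With the synthetic generator's truth tables available, the pipeline can be
audited quantitatively: indexing accuracy per stage (exact match vs harmonic
of the correct central ray), wavelength accuracy after a single
multiplicative correction (the polychromatic cell-scale ambiguity), and
per-detector-region centroid residual maps contrasting relaxed-wavelength
prediction with a monochromatic repredict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DetectorModel
from .refine import centroid_residuals

__all__ = [
    "IndexingAudit",
    "WavelengthAudit",
    "truth_for_observed",
    "misindexing_report",
    "wavelength_error_report",
    "panel_residual_summary",
    "radial_residual_contrast",
]


@dataclass(frozen=True)
class IndexingAudit:
    label: str
    n_total: int
    n_correct: int
    n_harmonic_of_correct: int
    n_misindexed: int

    def __post_init__(self):
        if self.n_correct + self.n_misindexed != self.n_total:
            raise ValueError("audit counts must partition the total")

    @property
    def fraction_correct(self) -> float:
        return self.n_correct / self.n_total if self.n_total else float("nan")


@dataclass(frozen=True)
class WavelengthAudit:
    slope: float
    r_squared: float
    fraction_within_tol: float
    tol: float
    n: int


def truth_for_observed(truth: pd.DataFrame) -> pd.DataFrame:
    """One truth row per observed spot: the dominant harmonic member.

    The spot-level true wavelength is the intensity-weighted mean over the
    stack (``lambda_spot``), matching how a pixel-level truth assignment
    would average coincident harmonics.
    """
    dom = truth[truth["is_dominant"]].set_index(["image_id", "spot_id"])
    return dom


def misindexing_report(
    assigned: pd.DataFrame, truth: pd.DataFrame, label: str = ""
) -> IndexingAudit:
    """Audit assigned Miller indices against generator ground truth.

    A record is *correct* iff the signed integer triple equals the truth
    exactly; *harmonic of correct* iff it reduces to the same coprime central
    ray (and same side); anything else is misindexed.  Friedel mates count as
    misindexed.
    """
    if not {"spot_id", "image_id"}.issubset(assigned.columns):
        raise ValueError("assigned table must carry image_id and spot_id")
    dom = truth_for_observed(truth)
    key = pd.MultiIndex.from_frame(assigned[["image_id", "spot_id"]])
    missing = ~key.isin(dom.index)
    if missing.any():
        raise ValueError(f"{int(missing.sum())} assigned spots lack ground truth")
    t = dom.loc[key]
    a_hkl = assigned[["h", "k", "l"]].to_numpy(dtype=int)
    t_hkl = t[["h_true", "k_true", "l_true"]].to_numpy(dtype=int)
    exact = np.all(a_hkl == t_hkl, axis=1)

    def reduce(h):
        g = np.gcd.reduce(np.abs(h), axis=1)
        g = np.where(g == 0, 1, g)
        return h // g[:, None]

    same_ray = np.all(reduce(a_hkl) == reduce(t_hkl), axis=1)
    harmonic = same_ray & ~exact
    return IndexingAudit(
        label=label,
        n_total=len(assigned),
        n_correct=int(exact.sum()),
        n_harmonic_of_correct=int(harmonic.sum()),
        n_misindexed=int((~exact).sum()),
    )


def wavelength_error_report(
    assigned: pd.DataFrame,
    truth: pd.DataFrame,
    tol: float = 0.001,
    experiment=None,
) -> WavelengthAudit:
    """Through-origin regression of true on assigned wavelengths.

    The polychromatic pipeline can carry a single multiplicative wavelength
    error (the monochromatic cell-scale ambiguity); the closed-form
    through-origin slope ``a = sum(la*lt) / sum(la^2)`` estimates it, and the
    reported fraction counts reflections whose corrected wavelength
    ``a * lambda_assigned`` is within ``tol`` of truth.

    With ``experiment`` given (detector/beam shared across the series), the
    truth wavelength is evaluated at the observed centroid -- the wavelength
    the photon ensemble of the true reflection had at that detector position,
    ``-2 (q_obs_hat . s0_hat) * d_true`` -- which is how a pixel-level truth
    map audits wavelengths and makes the comparison insensitive to
    centroiding noise.  Without it, the comparison uses the spot-level
    ensemble wavelength, which convolves centroid noise into the error.
    """
    if len(assigned) < 2:
        raise ValueError("need at least 2 assigned wavelengths")
    dom = truth_for_observed(truth)
    key = pd.MultiIndex.from_frame(assigned[["image_id", "spot_id"]])
    if experiment is not None:
        from .geometry import observed_q_direction

        centroids = assigned[["x_px", "y_px"]].to_numpy(dtype=float)
        q_hat = observed_q_direction(
            centroids, experiment.detector, experiment.beam.s0_hat
        )
        d_true = dom.loc[key, "d_true"].to_numpy(dtype=float)
        lt = -2.0 * (q_hat @ experiment.beam.s0_hat) * d_true
    else:
        lt = dom.loc[key, "lambda_spot"].to_numpy(dtype=float)
    la = assigned["wavelength"].to_numpy(dtype=float)
    slope = float((la @ lt) / (la @ la))
    resid = lt - slope * la
    ss_tot = float(((lt - lt.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    frac = float(np.mean(np.abs(slope * la - lt) < tol))
    return WavelengthAudit(
        slope=slope, r_squared=r2, fraction_within_tol=frac, tol=tol, n=len(assigned)
    )


def panel_residual_summary(
    residuals: pd.DataFrame, detector: DetectorModel, n_panels: int = 64
) -> pd.DataFrame:
    """Mean residual vectors on a virtual panel grid (default 8 x 8).

    ``residuals`` needs x_px/y_px spot positions plus dx_px/dy_px/dpsi_deg.
    Empty bins are absent from the output.
    """
    side = int(round(np.sqrt(n_panels)))
    if side * side != n_panels:
        raise ValueError("n_panels must be a perfect square")
    px = residuals["x_px"].to_numpy(dtype=float)
    py = residuals["y_px"].to_numpy(dtype=float)
    ix = np.clip((px / detector.n_fast * side).astype(int), 0, side - 1)
    iy = np.clip((py / detector.n_slow * side).astype(int), 0, side - 1)
    g = residuals.assign(panel=iy * side + ix).groupby("panel")
    out = g[["dx_px", "dy_px", "dpsi_deg"]].mean()
    out["n"] = g.size()
    out["x_center_px"] = (out.index % side + 0.5) * detector.n_fast / side
    out["y_center_px"] = (out.index // side + 0.5) * detector.n_slow / side
    return out.reset_index()


def plot_bandpass(bandpass, predictions: pd.DataFrame | None, path) -> None:
    """Scatter of (wavelength, 1/d^2) with KDE density contours.

    Shows the resolution-dependent bandpass: training (observed) points,
    optionally the predicted set, and the contour at the retention
    threshold.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    tp = bandpass.training_points
    lam = np.linspace(tp[:, 0].min() - 0.05, tp[:, 0].max() + 0.05, 120)
    q2 = np.linspace(max(0, tp[:, 1].min() - 0.05), tp[:, 1].max() + 0.05, 120)
    L, Q = np.meshgrid(lam, q2)
    dens = bandpass.density(L.ravel(), Q.ravel()).reshape(L.shape)
    if predictions is not None and len(predictions):
        ax.scatter(
            predictions["wavelength"], 1.0 / predictions["d"] ** 2,
            s=2, c="0.8", label="predicted",
        )
    ax.scatter(tp[:, 0], tp[:, 1], s=4, c="tab:orange", label="observed")
    ax.contour(L, Q, dens, levels=[bandpass.threshold()], colors="k")
    ax.set_xlabel("wavelength (A)")
    ax.set_ylabel("1/d^2 (1/A^2)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_panel_residuals(summary: pd.DataFrame, detector: DetectorModel, path) -> None:
    """Quiver map of per-virtual-panel mean residuals, colored by dpsi."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    q = ax.quiver(
        summary["x_center_px"], summary["y_center_px"],
        summary["dx_px"], summary["dy_px"], summary["dpsi_deg"],
        angles="xy", cmap="coolwarm",
    )
    fig.colorbar(q, ax=ax, label="mean dpsi (deg)")
    ax.set_xlim(0, detector.n_fast)
    ax.set_ylim(0, detector.n_slow)
    ax.set_aspect("equal")
    ax.set_xlabel("fast (px)")
    ax.set_ylabel("slow (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def radial_residual_contrast(still: pd.DataFrame, experiment) -> dict:
    """Mean |radial residual| with relaxed vs nominal wavelengths.

    Relaxing per-reflection wavelengths absorbs the radial mismatch that a
    single nominal wavelength cannot, so the nominal mode's radial residuals
    are the monochromatic-model penalty on polychromatic data.
    """
    relaxed = centroid_residuals(still, experiment, lambda_mode="relaxed")
    nominal = centroid_residuals(still, experiment, lambda_mode="nominal")
    return {
        "relaxed_mean_abs_radial_px": float(np.abs(relaxed["radial_px"]).mean()),
        "nominal_mean_abs_radial_px": float(np.abs(nominal["radial_px"]).mean()),
    }
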