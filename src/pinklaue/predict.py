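"""Full-still spot prediction with harmonic reduction and a KDE bandpass.

With a refined geometry in hand, every reflection satisfying the diffraction
condition inside the wavelength envelope can be predicted regardless of
whether spot finding saw it.  Harmonics (integer multiples of one coprime
index on a central ray) coincide on the detector, so the enumeration is
reduced to minimal Miller indices with a multiplicity count.  Because the
incident spectrum is resolution-dependent in practice -- reflections only
diffract measurably where spectral intensity is appreciable -- the feasible
set is filtered by a Gaussian kernel density estimate over the observed
(wavelength, 1/d^2) distribution: predictions falling in regions where no
strong spot was ever observed are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .geometry import Experiment, project_to_detector, wavelengths_for_q
from .assignment import enumerate_feasible_hkls

__all__ = [
    "BandpassModel",
    "BandpassError",
    "dedup_harmonics",
    "fit_bandpass",
    "predict_still",
]

MIN_TRAINING_POINTS = 20


class BandpassError(RuntimeError):
    pass


def dedup_harmonics(hkls: np.ndarray):
    """Reduce indices to coprime central-ray representatives.

    Each index maps to ``hkl / gcd(|h|,|k|,|l|)`` (sign preserved, so Friedel
    opposites stay distinct rays).  Returns ``(minimal, multiplicity,
    inverse)``: unique minimal indices, how many input harmonics each
    absorbed, and the map from input rows to minimal rows.
    """
    hkls = np.atleast_2d(np.asarray(hkls, dtype=int))
    if np.any(np.all(hkls == 0, axis=1)):
        raise ValueError("(0,0,0) is not a reflection")
    g = np.gcd.reduce(np.abs(hkls), axis=1)
    reduced = hkls // g[:, None]
    minimal, inverse, counts = np.unique(
        reduced, axis=0, return_inverse=True, return_counts=True
    )
    return minimal, counts, inverse


@dataclass
class BandpassModel:
    """Gaussian KDE over (wavelength, 1/d^2) of observed non-harmonic spots.

    ``cutoff_quantile`` sets the retention threshold as a quantile of the
    densities at the training points themselves, making the threshold
    scale-invariant: a cutoff of q retains, by construction, at least the
    fraction (1 - q) of the training population's density region.
    """

    kde: gaussian_kde
    training_points: np.ndarray  # (n, 2) columns (lambda, 1/d^2)
    cutoff_quantile: float = 0.01
    bandwidth: float | str = "scott"

    def __post_init__(self):
        self.training_densities = self.kde(self.training_points.T)

    def density(self, lam, inv_d2) -> np.ndarray:
        lam, inv_d2 = np.broadcast_arrays(np.atleast_1d(lam), np.atleast_1d(inv_d2))
        return self.kde(np.vstack([lam, inv_d2]))

    def threshold(self, cutoff_quantile: float | None = None) -> float:
        q = self.cutoff_quantile if cutoff_quantile is None else cutoff_quantile
        if q <= 0.0:
            return 0.0
        return float(np.quantile(self.training_densities, q))


def fit_bandpass(
    observed: pd.DataFrame,
    cutoff_quantile: float = 0.01,
    bandwidth: float | str = "scott",
) -> BandpassModel:
    """Train the resolution-dependent bandpass on strong assigned spots.

    ``observed`` needs ``wavelength`` and ``d`` columns; harmonic rows
    (non-coprime assigned index, or a recorded multiplicity > 1) are removed
    from the training set.  Refuses to fit on fewer than 20 points.
    """
    df = observed
    if {"h", "k", "l"}.issubset(df.columns):
        hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
        g = np.gcd.reduce(np.abs(hkl), axis=1)
        df = df[g == 1]
    if "multiplicity" in df.columns:
        df = df[df["multiplicity"] <= 1]
    pts = np.column_stack(
        [df["wavelength"].to_numpy(dtype=float), 1.0 / df["d"].to_numpy(dtype=float) ** 2]
    )
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < MIN_TRAINING_POINTS:
        raise BandpassError(
            f"only {len(pts)} non-harmonic assigned spots; need >= "
            f"{MIN_TRAINING_POINTS} (lower the spot threshold or pool images)"
        )
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    return BandpassModel(
        kde=kde,
        training_points=pts,
        cutoff_quantile=cutoff_quantile,
        bandwidth=bandwidth,
    )


def predict_still(
    experiment: Experiment,
    lambda_min: float,
    lambda_max: float,
    d_min: float,
    bandpass: BandpassModel | None = None,
    cutoff_quantile: float | None = None,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predict every plausibly diffracting reflection on one still.

    Enumerates the Ewald envelope, reduces harmonics to minimal indices,
    keeps scattered rays that hit the panel, and retains predictions whose
    KDE density is at or above the bandpass threshold.  When ``observed``
    (the still's assigned strong spots) is given, observed spots are merged
    in marked ``strong`` and retained regardless of their KDE density;
    predictions duplicating an observed central ray are dropped in favor of
    the observation.
    """
    beam, det = experiment.beam, experiment.detector
    hkl, q, lam = enumerate_feasible_hkls(
        experiment.crystal,
        beam,
        d_min,
        lambda_min=lambda_min,
        lambda_max=lambda_max,
    )
    if len(hkl) == 0:
        return _empty_prediction()
    minimal, counts, inverse = dedup_harmonics(hkl)
    # representative geometry comes from the minimal index of each ray
    qmin = minimal @ experiment.crystal.UB.T
    lam_min_idx = wavelengths_for_q(qmin, beam.s0_hat)
    keep = np.isfinite(lam_min_idx)
    s1 = beam.s0_hat / np.where(keep, lam_min_idx, np.nan)[:, None] + qmin
    cen = project_to_detector(s1, det)
    on_panel = np.all(np.isfinite(cen), axis=1) & det.contains(
        np.nan_to_num(cen, nan=-1.0)
    )
    keep &= on_panel
    absq = np.linalg.norm(qmin, axis=1)
    inv_d2 = absq**2
    if bandpass is not None:
        dens = bandpass.density(lam_min_idx, inv_d2)
        keep &= dens >= bandpass.threshold(cutoff_quantile)
    out = pd.DataFrame(
        {
            "h": minimal[keep, 0],
            "k": minimal[keep, 1],
            "l": minimal[keep, 2],
            "wavelength": lam_min_idx[keep],
            "d": 1.0 / absq[keep],
            "x_px": cen[keep, 0],
            "y_px": cen[keep, 1],
            "multiplicity": counts[keep],
            "harmonic_orders": [
                ";".join(
                    str(int(round(g)))
                    for g in sorted(
                        np.gcd.reduce(np.abs(hkl[inverse == i]), axis=1)
                    )
                )
                for i in np.flatnonzero(keep)
            ],
            "strong": False,
            "predicted": True,
        }
    )
    if observed is not None and len(observed):
        obs = observed.copy()
        obs["strong"] = True
        obs["predicted"] = False
        if {"h", "k", "l"}.issubset(obs.columns):
            ohkl = obs[["h", "k", "l"]].to_numpy(dtype=int)
            ominimal, ocounts, _ = dedup_harmonics(ohkl)
            seen = {tuple(r) for r in (ohkl // np.gcd.reduce(np.abs(ohkl), axis=1)[:, None])}
            dup = out.apply(lambda r: (r["h"], r["k"], r["l"]) in seen, axis=1)
            out = out[~dup.to_numpy(dtype=bool)]
        out = pd.concat([obs, out], ignore_index=True)
    return out.reset_index(drop=True)


def _empty_prediction() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "h",
            "k",
            "l",
            "wavelength",
            "d",
            "x_px",
            "y_px",
            "multiplicity",
            "harmonic_orders",
            "strong",
            "predicted",
        ]
    )
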