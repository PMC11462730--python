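"""Synthetic Laue pseudo-rotation series with known ground truth.

Generates per-image reflection lists (and optionally small raster images)
from a forward kinematical model with controllable crystal mosaicity, beam
divergence, spectral bandwidth, detector noise, and Wilson-like intensity
falloff.  Every observed spot carries ground-truth Miller indices,
wavelengths, centroids, and intensities, which is what lets the reduction
pipeline be audited end to end.

The forward model works at the spot-list level rather than simulating pixel
physics: each reflection's mosaic/divergence broadening is represented by a
small antithetic ensemble of perturbed sub-rays whose intensity-weighted mean
defines the true centroid and true wavelength of the spot.  This mirrors how
a physical spot centroid averages over the mosaic-block and divergence
distributions of the crystal and beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorModel,
    Experiment,
    GoniometerModel,
    UnitCell,
    axis_angle_matrix,
    project_to_detector,
    resolution_filtered_hkls,
    rotation_angle_deg,
    wavelengths_for_q,
)

__all__ = [
    "SyntheticConfig",
    "EmptyDatasetError",
    "spectrum_density",
    "reference_experiment",
    "reference_config",
    "generate_series",
    "render_image",
    "perturb_orientation",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548


class EmptyDatasetError(RuntimeError):
    """The generator produced no observable reflections."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs.

    The defaults emulate a dual-undulator pink-beam reference condition:
    0.1 deg mosaic spread (FWHM), 0.1 deg beam divergence, a Gaussian
    spectrum of 5.5% FWHM bandwidth, and 0.3 px centroid noise, with
    intensities drawn Wilson-like and thresholded so a still carries on the
    order of two hundred strong spots.
    """

    mosaicity_deg: float = 0.1
    divergence_deg: float = 0.1
    spectrum_kind: str = "gaussian"  # "gaussian" | "tabulated"
    bandwidth_fwhm_pct: float = 5.5
    centroid_jitter_px: float = 0.3
    background_level: float = 10.0
    wilson_b: float = 10.0
    n_images: int = 180
    step_deg: float = 1.0
    seed: int = 0
    # forward-model details
    d_min: float = 1.4
    intensity_scale: float = 2.0e4
    min_intensity: float = 1.0e4
    n_mosaic_samples: int = 20
    # rendering
    spot_sigma_px: float = 1.2
    read_noise: float = 3.0
    poisson_noise: bool = True
    gain: float = 1.0

    def __post_init__(self):
        if min(self.mosaicity_deg, self.divergence_deg, self.centroid_jitter_px) < 0:
            raise ValueError("spreads and jitter must be >= 0")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.spectrum_kind not in ("gaussian", "tabulated"):
            raise ValueError("spectrum_kind must be 'gaussian' or 'tabulated'")


def reference_experiment(
    n_images: int = 180,
    step_deg: float = 1.0,
    cell: UnitCell | None = None,
    spectrum: np.ndarray | None = None,
) -> Experiment:
    """Reference pseudo-rotation geometry used throughout tests and examples.

    Orthorhombic 34 x 45 x 99 A cell, beam along +z with a 1.05 A nominal
    wavelength inside a 0.9--1.2 A bandpass, a 3840^2 panel of 0.088 mm
    pixels at 200 mm, and a +x goniometer axis stepped ``step_deg`` per image.
    """
    cell = cell or UnitCell(34.0, 45.0, 99.0)
    return Experiment(
        crystal=CrystalModel(cell=cell),
        beam=BeamModel(spectrum=spectrum),
        detector=DetectorModel(),
        goniometer=GoniometerModel(
            angles_deg=np.arange(n_images, dtype=float) * step_deg
        ),
    )


def reference_config(**overrides) -> SyntheticConfig:
    """The reference simulation condition, optionally with field overrides."""
    return SyntheticConfig(**overrides)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def spectrum_density(lam, beam: BeamModel, config: SyntheticConfig) -> np.ndarray:
    """Relative spectral intensity at wavelength(s) ``lam``.

    Gaussian mode peaks at 1 on ``beam.lambda_nominal`` with
    ``FWHM = lambda_nominal * bandwidth_fwhm_pct / 100``; tabulated mode
    linearly interpolates ``beam.spectrum`` and is 0 outside its support.
    """
    lam = np.asarray(lam, dtype=float)
    if config.spectrum_kind == "tabulated":
        if beam.spectrum is None:
            raise ValueError("tabulated spectrum requested but beam.spectrum is None")
        return np.interp(lam, beam.spectrum[:, 0], beam.spectrum[:, 1], left=0.0, right=0.0)
    fwhm = beam.lambda_nominal * config.bandwidth_fwhm_pct / 100.0
    sigma = fwhm * FWHM_TO_SIGMA
    return np.exp(-((lam - beam.lambda_nominal) ** 2) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# per-HKL structure-factor amplitudes
# ---------------------------------------------------------------------------

_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= _MIX1
    x ^= x >> np.uint64(27)
    x *= _MIX2
    x ^= x >> np.uint64(31)
    return x


def _f_squared(hkl: np.ndarray, d: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Wilson-like squared structure factors, deterministic per unique HKL.

    F^2 ~ Exponential with mean ``intensity_scale * exp(-wilson_b / (2 d^2))``,
    hashed from (seed, h, k, l) so the same index gives the same F^2 on every
    image and for every harmonic bookkeeping path.
    """
    with np.errstate(over="ignore"):
        key = np.uint64(config.seed & 0xFFFFFFFF)
        x = _splitmix64(hkl[:, 0].astype(np.int64).view(np.uint64) + key)
        x = _splitmix64(x + hkl[:, 1].astype(np.int64).view(np.uint64))
        x = _splitmix64(x + hkl[:, 2].astype(np.int64).view(np.uint64))
    u = (x >> np.uint64(11)).astype(np.float64) / float(1 << 53)
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    mean = config.intensity_scale * np.exp(-config.wilson_b / (2.0 * d**2))
    return -np.log(1.0 - u) * mean


# ---------------------------------------------------------------------------
# orientation perturbation
# ---------------------------------------------------------------------------


def perturb_orientation(U: np.ndarray, angle_deg: float, seed: int | np.random.Generator = 0):
    """Rotate ``U`` by ``angle_deg`` about a uniformly random axis."""
    if angle_deg < 0:
        raise ValueError("angle must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return axis_angle_matrix(axis, angle_deg) @ np.asarray(U)


# ---------------------------------------------------------------------------
# series generation
# ---------------------------------------------------------------------------


def _coprime_reduce(hkl: np.ndarray) -> np.ndarray:
    g = np.gcd.reduce(np.abs(hkl), axis=1)
    g = np.where(g == 0, 1, g)
    return hkl // g[:, None]


def _divergence_basis(s0_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(helper @ s0_hat)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(s0_hat, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(s0_hat, e1)
    return e1, e2


def generate_series(experiment: Experiment, config: SyntheticConfig):
    """Forward-model a pseudo-rotation series.

    Returns ``(observed, truth)`` DataFrames.  ``observed`` is what the
    reduction pipeline sees: per-image strong-spot centroids with intensities
    (harmonic stacks merged into a single spot whose intensity is the sum over
    members).  ``truth`` carries one row per contributing reciprocal-lattice
    point: true index, wavelength, centroid, intensity, spectral weight, and
    harmonic membership, linked to observations by ``spot_id``.
    """
    beam, det, gonio = experiment.beam, experiment.detector, experiment.goniometer
    rng = np.random.default_rng(config.seed)
    s0_hat = beam.s0_hat

    H_all, qB_all, absq_all = resolution_filtered_hkls(experiment.crystal.cell, config.d_min)
    d_all = 1.0 / absq_all

    sigma_mos = math.radians(config.mosaicity_deg) * FWHM_TO_SIGMA
    sigma_div = math.radians(config.divergence_deg) * FWHM_TO_SIGMA
    e1, e2 = _divergence_basis(s0_hat)
    ensemble = (config.mosaicity_deg > 0 or config.divergence_deg > 0)
    n_half = max(1, config.n_mosaic_samples // 2)

    obs_rows, truth_rows = [], []
    spot_id = 0
    for i, image_id in enumerate(experiment.image_ids):
        crystal_i = experiment.crystal_at(i)
        q_nom = qB_all @ crystal_i.U.T
        lam_nom = wavelengths_for_q(q_nom, s0_hat)
        in_band = (
            np.isfinite(lam_nom)
            & (lam_nom >= beam.lambda_min)
            & (lam_nom <= beam.lambda_max)
        )
        idx = np.flatnonzero(in_band)
        if idx.size == 0:
            continue
        w_nom = spectrum_density(lam_nom[idx], beam, config)
        F2 = _f_squared(H_all[idx], d_all[idx], config)
        detected = w_nom * F2 >= config.min_intensity
        idx = idx[detected]
        if idx.size == 0:
            continue
        K = idx.size
        q0 = q_nom[idx]
        absq = absq_all[idx]

        if ensemble:
            # antithetic ensemble: +/- mosaic rotvecs paired with +/- beam tilts
            rv = rng.normal(size=(K, n_half, 3))
            rv /= np.linalg.norm(rv, axis=2, keepdims=True)
            rv *= rng.normal(0.0, sigma_mos or 1e-300, size=(K, n_half, 1))
            rv = np.concatenate([rv, -rv], axis=1)  # (K, S, 3)
            tilt2d = rng.normal(0.0, sigma_div or 0.0, size=(K, n_half, 2))
            tilt2d = np.concatenate([tilt2d, -tilt2d], axis=1)
            S = 2 * n_half
            rot = Rotation.from_rotvec(rv.reshape(-1, 3))
            q_s = rot.apply(np.repeat(q0, S, axis=0)).reshape(K, S, 3)
            tilt_vec = tilt2d[..., :1] * e1 + tilt2d[..., 1:] * e2  # (K, S, 3)
            b_rot = Rotation.from_rotvec(tilt_vec.reshape(-1, 3))
            b_s = b_rot.apply(np.tile(s0_hat, (K * S, 1))).reshape(K, S, 3)
            lam_s = -2.0 * np.einsum("ksj,ksj->ks", q_s, b_s) / absq[:, None] ** 2
            w_s = spectrum_density(lam_s, beam, config)
            w_s[(lam_s < beam.lambda_min) | (lam_s > beam.lambda_max) | (lam_s <= 0)] = 0.0
            s1_s = b_s / lam_s[..., None] + q_s
            cen_s = project_to_detector(s1_s.reshape(-1, 3), det).reshape(K, S, 2)
            w_s[np.any(~np.isfinite(cen_s), axis=2)] = 0.0
            wsum = w_s.sum(axis=1)
            ok = wsum > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                cen = np.einsum("ks,ksj->kj", w_s, cen_s) / wsum[:, None]
                lam_true = (w_s * lam_s).sum(axis=1) / wsum
            weight = w_s.mean(axis=1)
        else:
            lam_true = lam_nom[idx]
            s1 = s0_hat / lam_true[:, None] + q0
            cen = project_to_detector(s1, det)
            ok = np.all(np.isfinite(cen), axis=1)
            weight = spectrum_density(lam_true, beam, config)

        intensity = _f_squared(H_all[idx], d_all[idx], config) * weight
        ok &= det.contains(np.nan_to_num(cen, nan=-1.0))
        ok &= intensity >= config.min_intensity
        if not np.any(ok):
            continue
        sel = np.flatnonzero(ok)
        hkl = H_all[idx[sel]]
        absq = absq[sel]
        cen = cen[sel]
        lam_true = lam_true[sel]
        intensity = intensity[sel]
        weight = weight[sel]

        # merge harmonic stacks (same central ray, same still) into one spot
        reduced = _coprime_reduce(hkl)
        order = np.lexsort((reduced[:, 2], reduced[:, 1], reduced[:, 0]))
        groups: dict[tuple, list[int]] = {}
        for j in order:
            groups.setdefault(tuple(reduced[j]), []).append(j)

        for members in groups.values():
            members = np.asarray(members)
            I_tot = float(intensity[members].sum())
            wts = intensity[members] / I_tot
            c_spot = wts @ cen[members]
            lam_spot = float(wts @ lam_true[members])
            c_obs = c_spot + rng.normal(0.0, config.centroid_jitter_px, size=2) \
                if config.centroid_jitter_px > 0 else c_spot
            dominant = members[np.argmax(intensity[members])]
            obs_rows.append(
                (image_id, spot_id, c_obs[0], c_obs[1], I_tot, math.sqrt(max(I_tot, 1.0)))
            )
            for m in members:
                truth_rows.append(
                    (
                        image_id,
                        spot_id,
                        int(hkl[m, 0]),
                        int(hkl[m, 1]),
                        int(hkl[m, 2]),
                        float(lam_true[m]),
                        lam_spot,
                        float(1.0 / absq[m]),
                        float(cen[m, 0]),
                        float(cen[m, 1]),
                        float(intensity[m]),
                        float(weight[m]),
                        len(members) > 1,
                        m == dominant,
                    )
                )
            spot_id += 1

    if not obs_rows:
        raise EmptyDatasetError(
            "no observable reflections; check d_min, spectrum support, and thresholds"
        )
    observed = pd.DataFrame(
        obs_rows, columns=["image_id", "spot_id", "x_px", "y_px", "intensity", "sigma"]
    )
    observed["strong"] = True
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "image_id",
            "spot_id",
            "h_true",
            "k_true",
            "l_true",
            "lambda_true",
            "lambda_spot",
            "d_true",
            "x_true",
            "y_true",
            "intensity_true",
            "spectral_weight",
            "is_harmonic_member",
            "is_dominant",
        ],
    )
    return observed, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_image(
    reflections: pd.DataFrame,
    detector: DetectorModel,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a spot list into a 2-D count array of shape (n_slow, n_fast).

    Each reflection becomes an elliptical Gaussian integrating to its
    intensity (isotropic ``spot_sigma_px`` unless the table carries
    ``sxx/sxy/syy`` covariance columns), on a uniform background, with
    optional Poisson noise and Gaussian read noise.
    """
    rng = rng or np.random.default_rng(config.seed)
    img = np.full((detector.n_slow, detector.n_fast), float(config.background_level))
    has_cov = {"sxx", "sxy", "syy"}.issubset(reflections.columns)
    for row in reflections.itertuples(index=False):
        x0, y0, inten = float(row.x_px), float(row.y_px), float(row.intensity)
        if has_cov:
            cov = np.array([[row.sxx, row.sxy], [row.sxy, row.syy]], dtype=float)
        else:
            cov = np.eye(2) * config.spot_sigma_px**2
        # window out to 5 sigma of the widest axis
        wmax = 5.0 * math.sqrt(max(np.linalg.eigvalsh(cov)))
        ix0, ix1 = int(max(0, x0 - wmax)), int(min(detector.n_fast, x0 + wmax + 1))
        iy0, iy1 = int(max(0, y0 - wmax)), int(min(detector.n_slow, y0 + wmax + 1))
        if ix1 <= ix0 or iy1 <= iy0:
            continue
        xs = np.arange(ix0, ix1) + 0.5
        ys = np.arange(iy0, iy1) + 0.5
        dx, dy = np.meshgrid(xs - x0, ys - y0)
        P = np.linalg.inv(cov)
        md2 = P[0, 0] * dx**2 + 2 * P[0, 1] * dx * dy + P[1, 1] * dy**2
        norm = inten / (2.0 * math.pi * math.sqrt(np.linalg.det(cov)))
        img[iy0:iy1, ix0:ix1] += norm * np.exp(-0.5 * md2)
    if config.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.read_noise > 0:
        img = img + rng.normal(0.0, config.read_noise, size=img.shape)
    return img
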