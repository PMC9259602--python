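"""Miniscope movie preprocessing and PCA/ICA source extraction.

The chain runs in a fixed order: defective-pixel repair (3x3 median),
temporal downsampling to 5 Hz (block mean), spatial bandpass
(difference of Gaussians), rigid motion correction against the mean
projection, per-pixel dF/F with the temporal minimum as baseline, PCA/ICA
spatio-temporal demixing with ceil(1.15 x n_cells) components, and ROI
quality control (area, SNR, blob count, neighbor distance, soma shape).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.registration import phase_cross_correlation
from sklearn.decomposition import FastICA

from ._utils import robust_noise_sd

__all__ = [
    "CalciumMovie",
    "DffMovie",
    "SpatialFootprint",
    "fix_defective_pixels",
    "downsample_temporal",
    "bandpass_spatial",
    "motion_correct",
    "compute_dff",
    "pca_ica_extract",
    "qc_filter_rois",
    "preprocess_movie",
]


@dataclass
class CalciumMovie:
    """Raw fluorescence stack F(t, y, x) with its frame rate."""

    data: np.ndarray  # (frames, height, width)
    frame_rate: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("movie must be a (frames, height, width) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class DffMovie:
    """Per-pixel dF/F stack with its baseline image and invalid-pixel mask."""

    data: np.ndarray
    baseline: np.ndarray
    frame_rate: float
    masked_pixels: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class SpatialFootprint:
    """One extracted source: spatial weight map, trace, and QC metrics."""

    map: np.ndarray  # (height, width) weights, zero outside the mask
    mask: np.ndarray  # boolean
    trace: np.ndarray  # dF/F-scale temporal weights
    area: int
    centroid: tuple[float, float]  # (row, col), intensity-weighted
    snr: float
    n_components: int  # disconnected blobs in the mask
    eccentricity: float


def fix_defective_pixels(movie: CalciumMovie) -> CalciumMovie:
    """Replace every pixel by its 3x3 neighborhood median (reflect edges)."""
    if movie.data.shape[1] < 3 or movie.data.shape[2] < 3:
        raise ValueError("frames must be at least 3x3 for median repair")
    out = ndimage.median_filter(movie.data, size=(1, 3, 3), mode="reflect")
    return CalciumMovie(out, movie.frame_rate, movie.pixel_size_um)


def downsample_temporal(movie: CalciumMovie, target_hz: float = 5.0) -> CalciumMovie:
    """Non-overlapping block mean of consecutive frames down to ``target_hz``."""
    ratio = movie.frame_rate / target_hz
    k = int(round(ratio))
    if abs(ratio - k) > 1e-6 or k < 1:
        raise ValueError(
            f"source rate {movie.frame_rate} Hz is not an integer multiple of "
            f"target {target_hz} Hz"
        )
    if k == 1:
        return CalciumMovie(movie.data.copy(), target_hz, movie.pixel_size_um)
    n = (movie.n_frames // k) * k
    blocks = movie.data[:n].reshape(n // k, k, *movie.data.shape[1:])
    return CalciumMovie(blocks.mean(axis=1), target_hz, movie.pixel_size_um)


def bandpass_spatial(
    movie: CalciumMovie, sigma_low_px: float = 20.0, sigma_high_px: float = 2.0
) -> CalciumMovie:
    """Difference-of-Gaussians bandpass: blur(sigma_high) - blur(sigma_low).

    Removes the smooth background (scales above ``sigma_low_px``) and
    smooths pixel noise (scales below ``sigma_high_px``).  A spatially
    constant frame maps to zero.
    """
    if sigma_low_px <= 0 or sigma_high_px <= 0:
        raise ValueError("sigmas must be > 0")
    if sigma_high_px >= sigma_low_px:
        raise ValueError("require sigma_high_px < sigma_low_px")
    lo = ndimage.gaussian_filter(movie.data, sigma=(0, sigma_low_px, sigma_low_px))
    hi = ndimage.gaussian_filter(movie.data, sigma=(0, sigma_high_px, sigma_high_px))
    return CalciumMovie(hi - lo, movie.frame_rate, movie.pixel_size_um)


def _apply_shift(frame: np.ndarray, shift: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(frame), shift)))


def motion_correct(
    movie: CalciumMovie,
    upsample_factor: int = 10,
    n_iter: int = 2,
    max_shift_px: float | None = None,
) -> tuple[CalciumMovie, np.ndarray]:
    """Rigid translation of each frame onto the mean-projection reference.

    Per-frame subpixel shifts are estimated by FFT cross-correlation with
    the mean projection and applied by Fourier translation.  Because the
    first mean projection is blurred by the motion itself, the estimate is
    refined ``n_iter`` times against the re-computed mean of the corrected
    movie; total shifts are re-applied to the original frames each pass so
    interpolation error does not accumulate.  Returns the corrected movie
    and the (n_frames, 2) array of applied (dy, dx) shifts; shifts are
    defined up to the common offset of the reference.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames for motion correction")
    if not np.any(movie.data.mean(axis=0)):
        raise ValueError("degenerate all-zero reference image")
    corrected = movie.data.astype(float).copy()
    shifts = np.zeros((movie.n_frames, 2))
    for _ in range(max(1, n_iter)):
        reference = corrected.mean(axis=0)
        for t in range(movie.n_frames):
            delta, _, _ = phase_cross_correlation(
                reference, corrected[t], upsample_factor=upsample_factor
            )
            total = shifts[t] + delta
            if max_shift_px is not None:
                total = np.clip(total, -max_shift_px, max_shift_px)
            shifts[t] = total
            corrected[t] = (
                _apply_shift(movie.data[t], total) if np.any(total) else movie.data[t]
            )
    return CalciumMovie(corrected, movie.frame_rate, movie.pixel_size_um), shifts


def compute_dff(movie: CalciumMovie) -> DffMovie:
    """Per-pixel dF/F with the temporal minimum as the baseline image.

    F'(x, y, t) = (F(x, y, t) - Fbase(x, y)) / Fbase(x, y) where Fbase is
    the minimum of the pixel across all frames; pixels with non-positive
    baseline are masked (set to 0) and reported.
    """
    baseline = movie.data.min(axis=0)
    bad = baseline <= 0
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} pixels with non-positive baseline masked in dF/F")
    safe = np.where(bad, 1.0, baseline)
    dff = (movie.data - baseline) / safe
    dff[:, bad] = 0.0
    return DffMovie(
        data=dff,
        baseline=baseline,
        frame_rate=movie.frame_rate,
        masked_pixels=np.argwhere(bad),
    )


def preprocess_movie(
    movie: CalciumMovie,
    target_hz: float = 5.0,
    sigma_low_px: float = 20.0,
    sigma_high_px: float = 2.0,
    bandpass: bool = True,
) -> tuple[DffMovie, np.ndarray]:
    """Full preprocessing chain in the fixed order, returning dF/F + shifts."""
    movie = fix_defective_pixels(movie)
    if movie.frame_rate != target_hz:
        movie = downsample_temporal(movie, target_hz)
    if bandpass:
        bp = bandpass_spatial(movie, sigma_low_px, sigma_high_px)
        # DoG output is signed; restore a positive offset so the minimum
        # baseline of Eq-style dF/F stays meaningful
        bp = CalciumMovie(
            bp.data - bp.data.min() + 1.0, bp.frame_rate, bp.pixel_size_um
        )
        movie = bp
    movie, shifts = motion_correct(movie)
    movie = CalciumMovie(
        np.clip(movie.data, a_min=max(movie.data.min(), 0.0), a_max=None) + 1e-6,
        movie.frame_rate,
        movie.pixel_size_um,
    )
    return compute_dff(movie), shifts


# ---------------------------------------------------------------------------
# PCA/ICA source extraction


def n_ica_components(n_cells_estimate: int) -> int:
    """Component count: 15% over the estimated cell count, rounded up."""
    if n_cells_estimate < 1:
        raise ValueError("n_cells_estimate must be >= 1")
    return math.ceil(1.15 * n_cells_estimate)


def pca_ica_extract(
    dff: DffMovie,
    n_cells_estimate: int,
    mu: float = 0.2,
    map_threshold_sd: float = 3.0,
    map_threshold_rel: float = 0.1,
    seed: int = 0,
    max_iter: int = 1000,
) -> list[SpatialFootprint]:
    """Spatio-temporal PCA/ICA demixing into candidate cell footprints.

    The movie (frames x pixels) is reduced to ``ceil(1.15 x n_cells)``
    principal components; independent components are then sought on the
    concatenation of spatial and temporal PC loadings weighted by ``mu``
    (the spatio-temporal mixing parameter: 0 = pure temporal, 1 = pure
    spatial).  Each IC's spatial map is z-scored and thresholded at
    ``map_threshold_sd`` robust SDs to form the footprint mask; the trace
    is the weighted mean of the dF/F movie over the mask.
    """
    n_comp = n_ica_components(n_cells_estimate)
    T = dff.n_frames
    H, W = dff.data.shape[1:]
    P = H * W
    if T < n_comp:
        raise ValueError(f"movie has {T} frames < {n_comp} requested components")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")

    X = dff.data.reshape(T, P)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]

    spatial = Vt  # (k, P), unit-norm rows
    temporal = U.T  # (k, T), unit-norm columns of U
    joint = np.concatenate(
        [mu * spatial * math.sqrt(P), (1.0 - mu) * temporal * math.sqrt(T)], axis=1
    )
    ica = FastICA(
        n_components=n_comp,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence warnings on noise
        sources = ica.fit_transform(joint.T).T  # (k, P + T)

    footprints: list[SpatialFootprint] = []
    for comp in sources:
        smap = comp[:P].copy()
        # orient so the footprint weights are positive
        if -smap.min() > smap.max():
            smap = -smap
        med = np.median(smap)
        sd = robust_noise_sd(smap) or smap.std() or 1.0
        # absolute (noise) threshold plus a floor relative to the peak:
        # low-weight crosstalk from other cells must not inflate the mask
        thr = max(med + map_threshold_sd * sd, med + map_threshold_rel * (smap.max() - med))
        mask = smap >= thr
        area = int(mask.sum())
        weights = np.where(mask, smap - med, 0.0).reshape(H, W)
        if area == 0:
            footprints.append(
                SpatialFootprint(
                    map=weights,
                    mask=mask.reshape(H, W),
                    trace=np.zeros(T),
                    area=0,
                    centroid=(float("nan"), float("nan")),
                    snr=0.0,
                    n_components=0,
                    eccentricity=1.0,
                )
            )
            continue
        wsum = weights.sum()
        yy, xx = np.mgrid[0:H, 0:W]
        centroid = (float((yy * weights).sum() / wsum), float((xx * weights).sum() / wsum))
        trace = X @ weights.reshape(-1) / wsum
        noise = robust_noise_sd(trace)
        snr = float(trace.max() / noise) if noise > 0 else 0.0
        labels = measure.label(mask.reshape(H, W), connectivity=2)
        n_blobs = int(labels.max())
        ecc = 0.0
        props = measure.regionprops(labels)
        if props:
            largest = max(props, key=lambda p: p.area)
            ecc = float(largest.eccentricity) if largest.area >= 2 else 0.0
        footprints.append(
            SpatialFootprint(
                map=weights,
                mask=mask.reshape(H, W),
                trace=trace,
                area=area,
                centroid=centroid,
                snr=snr,
                n_components=n_blobs,
                eccentricity=ecc,
            )
        )
    return footprints


def qc_filter_rois(
    footprints: list[SpatialFootprint],
    min_area: int = 4,
    max_area: int = 400,
    min_snr: float = 3.0,
    max_blobs: int = 2,
    min_centroid_dist_px: float = 5.0,
    max_eccentricity: float = 0.95,
) -> tuple[list[SpatialFootprint], list[tuple[int, str]]]:
    """Apply the three ROI exclusion rules; return survivors + rejection log.

    Rule 1: area < 4 px or not soma-shaped (area > ``max_area`` or
    eccentricity > ``max_eccentricity``).  Rule 2: trace SNR < 3 or the
    spatial map splits into more than 2 disconnected blobs.  Rule 3: of two
    neighbors with centroids closer than 5 px, only the higher-SNR one is
    kept.  The log records ``(index, rule)`` for every rejection.
    """
    log: list[tuple[int, str]] = []
    survivors: list[int] = []
    for i, fp in enumerate(footprints):
        if fp.area < min_area or fp.area > max_area or fp.eccentricity > max_eccentricity:
            log.append((i, "rule1_area_or_shape"))
            continue
        if fp.snr < min_snr or fp.n_components > max_blobs:
            log.append((i, "rule2_snr_or_components"))
            continue
        survivors.append(i)

    # rule 3: greedy by descending SNR so the stronger neighbor survives
    kept: list[int] = []
    for i in sorted(survivors, key=lambda j: -footprints[j].snr):
        ci = np.asarray(footprints[i].centroid)
        if any(
            np.linalg.norm(ci - np.asarray(footprints[j].centroid)) < min_centroid_dist_px
            for j in kept
        ):
            log.append((i, "rule3_neighbor"))
            continue
        kept.append(i)
    kept.sort()
    return [footprints[i] for i in kept], log
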