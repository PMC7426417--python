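"""Transcriptional-burst quantification.

The measurement chain mirrors the standard MS2/MCP live-imaging workflow:
max-project the MCP z-stack onto one plane, locate the bright nuclear foci
(one per genomic integration site), fit an axis-aligned 2D Gaussian with a
free background offset to a small window around each focus, and report the
volume under the fitted Gaussian above background,

    I = 2 * pi * A * sigma_x * sigma_y,

as the burst intensity for that site and frame.  Because integration sites
do not move, focus positions are linked across frames by nearest-neighbor
gating and each track is re-fit at its mean position in every frame, so
traces cover the full movie; frames where the fit fails are reported as
missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .errors import AnalysisError, ValidationError
from .movie_synth import MovieStack

__all__ = [
    "GaussianFitResult",
    "FocusTrack",
    "max_project",
    "detect_foci",
    "fit_gaussian2d",
    "track_foci",
    "detect_and_track",
    "burst_traces",
    "mean_burst_trace",
]


@dataclass(frozen=True)
class GaussianFitResult:
    """One axis-aligned 2D Gaussian fit; ``integrated_intensity`` excludes background."""

    amplitude: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    background: float
    residual_norm: float
    converged: bool

    @property
    def integrated_intensity(self) -> float:
        if not self.converged:
            return float("nan")
        return 2.0 * np.pi * self.amplitude * self.sigma_x * self.sigma_y


@dataclass
class FocusTrack:
    """Per-site focus positions and fits across frames."""

    site_id: int
    positions: list[tuple[float, float] | None] = field(default_factory=list)
    fits: list[GaussianFitResult | None] = field(default_factory=list)

    @property
    def frames_present(self) -> int:
        return sum(p is not None for p in self.positions)

    @property
    def mean_position(self) -> tuple[float, float]:
        pts = [p for p in self.positions if p is not None]
        if not pts:
            raise AnalysisError("track has no localized frames")
        arr = np.asarray(pts)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def intensity_trace(self) -> np.ndarray:
        return np.array([
            f.integrated_intensity if (f is not None and f.converged) else np.nan
            for f in self.fits
        ])


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum across the z axis of a Z×Y×X slab."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1 or zstack.size == 0:
        raise ValidationError("expected a nonempty Z x Y x X stack")
    return zstack.max(axis=0)


def detect_foci(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    log_sigma_px: float = 1.3,
    snr_threshold: float = 5.0,
    min_separation_px: int = 4,
) -> list[tuple[float, float, float]]:
    """Laplacian-of-Gaussian blob detection inside the nucleus.

    Blob-shaped candidates come from non-maximum suppression of the -LoG
    response at ``min_separation_px``; a candidate is retained if its image
    peak exceeds ``median + snr_threshold * MAD`` of the masked pixels
    (MAD scaled by 1.4826 to estimate sigma; the raw image is used for the
    noise floor because the response statistics are contaminated by the
    blobs themselves).  Returns (x, y, score) sorted by descending score.
    """
    image = np.asarray(image, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if nucleus_mask.shape != image.shape:
        raise ValidationError("mask shape does not match image")
    if nucleus_mask.sum() < 16:
        raise ValidationError("degenerate nucleus mask")
    # -LoG is positive at bright blobs of scale ~sigma
    response = -ndimage.gaussian_laplace(image, sigma=log_sigma_px) * log_sigma_px ** 2
    vals = image[nucleus_mask]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med)) * 1.4826
    # photon-counting floor: even a noise-free rendering should not admit
    # ripples smaller than the shot noise its background level implies
    noise_scale = max(mad, np.sqrt(max(med, 0.0)), 1e-12)
    thresh = med + snr_threshold * noise_scale
    masked = np.where(nucleus_mask, response, -np.inf)
    peaks = peak_local_max(masked, min_distance=1, threshold_abs=0.0,
                           exclude_border=False)
    cands = sorted(
        ((float(x), float(y), float(response[y, x]))
         for y, x in peaks if image[y, x] > thresh),
        key=lambda p: -p[2],
    )
    # greedy Euclidean non-maximum suppression, strongest first
    out: list[tuple[float, float, float]] = []
    for x, y, s in cands:
        if all(np.hypot(x - ox, y - oy) >= min_separation_px for ox, oy, _ in out):
            out.append((x, y, s))
    return out


def _gauss2d(coords, A, x0, y0, sx, sy, b):
    x, y = coords
    return (b + A * np.exp(-((x - x0) ** 2) / (2 * sx ** 2)
                           - ((y - y0) ** 2) / (2 * sy ** 2))).ravel()


def fit_gaussian2d(
    image: np.ndarray,
    center_guess: tuple[float, float],
    roi_halfwidth_px: int = 4,
    sigma_bounds: tuple[float, float] | None = None,
    center_halfwidth_px: float | None = None,
) -> GaussianFitResult:
    """Least-squares axis-aligned 2D Gaussian fit on a square ROI.

    Initialization uses the ROI maximum and intensity moments; the center is
    bounded to the ROI (or to ``center_halfwidth_px`` of the guess, when the
    position is already known from tracking) and sigma to
    ``[0.5, roi_halfwidth_px]`` px by default.  A fit that does not converge,
    or whose amplitude collapses to the lower bound, is returned with
    ``converged=False`` (integrated intensity missing).
    """
    image = np.asarray(image, dtype=float)
    hw = int(roi_halfwidth_px)
    x_c, y_c = (int(round(center_guess[0])), int(round(center_guess[1])))
    ny, nx = image.shape
    if x_c - hw < 0 or y_c - hw < 0 or x_c + hw >= nx or y_c + hw >= ny:
        raise ValidationError("ROI extends outside the image")
    roi = image[y_c - hw:y_c + hw + 1, x_c - hw:x_c + hw + 1]
    yy, xx = np.mgrid[y_c - hw:y_c + hw + 1, x_c - hw:x_c + hw + 1]

    lo_s, hi_s = sigma_bounds if sigma_bounds is not None else (0.5, float(hw))
    c_hw = float(hw) if center_halfwidth_px is None else float(center_halfwidth_px)
    # median background start: the ROI minimum is biased low by noise and
    # inflates the moment widths toward the upper sigma bound
    b0 = float(np.median(roi))
    a0 = float(roi.max() - b0)
    dev = np.clip(roi - b0, 0, None)
    tot = dev.sum()
    if a0 <= 0 or tot <= 0:
        return GaussianFitResult(0.0, float(x_c), float(y_c), np.nan, np.nan,
                                 b0, float(np.linalg.norm(roi - roi.mean())), False)
    x0_init = float(np.clip((xx * dev).sum() / tot,
                            center_guess[0] - c_hw, center_guess[0] + c_hw))
    y0_init = float(np.clip((yy * dev).sum() / tot,
                            center_guess[1] - c_hw, center_guess[1] + c_hw))
    sx_init = float(np.sqrt(np.clip(((xx - x0_init) ** 2 * dev).sum() / tot, lo_s ** 2, hi_s ** 2)))
    sy_init = float(np.sqrt(np.clip(((yy - y0_init) ** 2 * dev).sum() / tot, lo_s ** 2, hi_s ** 2)))

    p0 = [a0, x0_init, y0_init, sx_init, sy_init, b0]
    lower = [0.0, center_guess[0] - c_hw, center_guess[1] - c_hw, lo_s, lo_s, -np.inf]
    upper = [np.inf, center_guess[0] + c_hw, center_guess[1] + c_hw, hi_s, hi_s, np.inf]
    try:
        popt, _ = curve_fit(_gauss2d, (xx, yy), roi.ravel(), p0=p0,
                            bounds=(lower, upper), maxfev=2000)
    except (RuntimeError, ValueError):
        return GaussianFitResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 b0, np.nan, False)
    A, x0, y0, sx, sy, b = (float(v) for v in popt)
    resid = float(np.linalg.norm(_gauss2d((xx, yy), *popt) - roi.ravel()))
    # amplitude collapsed onto zero: no spot distinguishable from background
    roi_sd = float(roi.std())
    converged = A > max(1e-6, 0.1 * roi_sd)
    return GaussianFitResult(A, x0, y0, sx, sy, b, resid, converged)


def track_foci(
    detections_per_frame: list[list[tuple[float, float, float]]],
    max_disp_px: float = 3.0,
    max_gap_frames: int = 3,
    min_frames: int = 3,
) -> list[FocusTrack]:
    """Greedy nearest-neighbor linking of stationary foci across frames.

    A detection continues an existing track if within ``max_disp_px`` of the
    track's mean position and the track was seen within ``max_gap_frames``.
    Tracks localized in fewer than ``min_frames`` frames are dropped.
    """
    n_frames = len(detections_per_frame)
    active: list[dict] = []
    for f_idx, dets in enumerate(detections_per_frame):
        dets = sorted(dets, key=lambda d: -d[2])
        claimed = set()
        for d_idx, (x, y, _) in enumerate(dets):
            best, best_dist = None, np.inf
            for tr in active:
                if f_idx - tr["last_frame"] > max_gap_frames + 1:
                    continue
                if tr["claimed_frame"] == f_idx:
                    continue
                mx, my = tr["sum_x"] / tr["n"], tr["sum_y"] / tr["n"]
                dist = np.hypot(x - mx, y - my)
                if dist < best_dist:
                    best, best_dist = tr, dist
            if best is not None and best_dist <= max_disp_px:
                best["positions"][f_idx] = (x, y)
                best["sum_x"] += x
                best["sum_y"] += y
                best["n"] += 1
                best["last_frame"] = f_idx
                best["claimed_frame"] = f_idx
                claimed.add(d_idx)
            else:
                active.append({
                    "positions": {f_idx: (x, y)},
                    "sum_x": x, "sum_y": y, "n": 1,
                    "last_frame": f_idx, "claimed_frame": f_idx,
                })
    tracks = []
    sid = 0
    for tr in active:
        if tr["n"] < min_frames:
            continue
        positions = [tr["positions"].get(f) for f in range(n_frames)]
        tracks.append(FocusTrack(site_id=sid, positions=positions,
                                 fits=[None] * n_frames))
        sid += 1
    return tracks


def detect_and_track(
    movie: MovieStack,
    nucleus_mask: np.ndarray | None = None,
    log_sigma_px: float = 1.3,
    snr_threshold: float = 5.0,
    min_separation_px: int = 4,
    max_disp_px: float = 3.0,
    max_gap_frames: int = 3,
    min_frames: int = 5,
) -> list[FocusTrack]:
    """Detect foci on every max-projected MCP frame and link them into tracks."""
    if nucleus_mask is None:
        nucleus_mask = _mask_from_movie(movie)
    mcp = movie.channel("MCP")
    dets = [
        detect_foci(max_project(mcp[f]), nucleus_mask, log_sigma_px,
                    snr_threshold, min_separation_px)
        for f in range(movie.n_frames)
    ]
    return track_foci(dets, max_disp_px, max_gap_frames, min_frames)


def _mask_from_movie(movie: MovieStack) -> np.ndarray:
    """Nucleus mask from attached geometry, else by thresholding the H2B channel."""
    if movie.ground_truth is not None and movie.ground_truth[1] is not None:
        return movie.ground_truth[1].nucleus_mask()
    h2b = movie.channel("H2B")[0][movie.data.shape[1] // 2]
    thresh = 0.5 * (h2b.min() + h2b.max())
    return ndimage.binary_fill_holes(h2b > thresh)


def burst_traces(
    movie: MovieStack,
    tracks: list[FocusTrack],
    roi_halfwidth_px: int = 4,
) -> list[FocusTrack]:
    """Fit every track at its mean position in every frame of the MCP channel.

    Returns the tracks with ``fits`` populated; use
    :meth:`FocusTrack.intensity_trace` for the per-frame integrated
    intensities (NaN where the fit failed).
    """
    mcp = movie.channel("MCP")
    projections = [max_project(mcp[f]) for f in range(movie.n_frames)]

    def fit_all(mx, my, sigma_bounds):
        fits: list[GaussianFitResult | None] = []
        for img in projections:
            try:
                # the position is known from tracking and the PSF width is
                # constant through the movie, so constrain both: free fits on
                # empty frames otherwise chase noise with inflated footprints
                fits.append(fit_gaussian2d(
                    img, (mx, my), roi_halfwidth_px,
                    sigma_bounds=sigma_bounds, center_halfwidth_px=1.5,
                ))
            except ValidationError:
                fits.append(None)
        return fits

    for tr in tracks:
        mx, my = tr.mean_position
        first = fit_all(mx, my, (0.7, 2.2))
        # pin the width to the track's own bright-frame estimate (two-pass)
        bright = sorted((f for f in first if f is not None and f.converged),
                        key=lambda f: -f.amplitude)[:max(3, len(first) // 4)]
        if bright:
            sig = float(np.median([s for f in bright for s in (f.sigma_x, f.sigma_y)]))
            lo = max(0.7, 0.75 * sig)
            hi = min(2.2, max(1.35 * sig, lo + 0.1))
            tr.fits = fit_all(mx, my, (lo, hi))
        else:
            tr.fits = first
    return tracks


def mean_burst_trace(tracks: list[FocusTrack]) -> np.ndarray:
    """Across-track mean intensity per frame, ignoring missing fits."""
    if not tracks:
        raise AnalysisError("no tracks to average")
    arr = np.vstack([tr.intensity_trace() for tr in tracks])
    with np.errstate(invalid="ignore"):
        return np.nanmean(arr, axis=0)
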