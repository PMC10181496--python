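"""Kernelized correlation filter (KCF) tracking of a surgical-instrument tip.

The tracker models the region of interest (ROI) around the instrument tip
with multi-channel HOG features. Training solves a kernelized ridge
regression against an ideal Gaussian response over all cyclic shifts of the
feature patch; because the data matrix of cyclic shifts is circulant, the
solve diagonalizes in the Fourier domain and reduces to element-wise
divisions. Detection correlates the candidate patch with the learned model
and moves the ROI center to the response peak.

Conventions: images are indexed (row, col) with the origin at the top-left;
x runs rightward (columns), y downward (rows). ROIs are (x_min, y_min, w, h)
in pixels and the tracked point is the ROI center. Peaks are localized at
integer feature-grid resolution; there is no scale adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TrackerConfig",
    "TrackerState",
    "FeatureMap",
    "GaussianResponse",
    "CorrelationFilter",
    "ResponseMap",
    "TrackingFailure",
    "extract_features",
    "gaussian_kernel_correlation",
    "make_gaussian_response",
    "train_filter",
    "detect",
    "update_model",
    "track",
]


class TrackingFailure(RuntimeError):
    """Raised when the ROI leaves the frame or a frame cannot be read."""


@dataclass(frozen=True)
class TrackerConfig:
    """Hyper-parameters of the correlation-filter tracker.

    Attributes
    ----------
    padding : float
        Context factor: the search window is ``padding`` times the target
        box, so the filter sees background around the tip.
    cell_size : int
        HOG cell size in pixels; also the pixel granularity of the
        integer-resolution peak localization.
    n_orientations : int
        Number of unsigned gradient-orientation bins.
    sigma_kernel : float
        Gaussian kernel bandwidth in normalized feature units (the raw
        squared distance is divided by the number of feature elements).
    sigma_target_factor : float
        The ideal-response Gaussian sigma is
        ``sqrt(grid_w * grid_h) / sigma_target_factor`` grid cells.
    lambda_reg : float
        Ridge regularizer of the circulant least-squares solve.
    interp_factor : float
        Per-frame linear interpolation rate of the model (0 freezes the
        model learned on the first frame).
    detect_iterations : int
        Detect/move repetitions per frame: after moving by the detected
        cell displacement, detection is re-run at the new center until the
        displacement is zero or the budget is exhausted. This removes the
        closed-loop lag that cell-granular peaks otherwise accumulate on
        fast targets, without sub-cell interpolation.
    """

    padding: float = 2.5
    cell_size: int = 4
    n_orientations: int = 9
    sigma_kernel: float = 0.5
    sigma_target_factor: float = 10.0
    lambda_reg: float = 1e-4
    interp_factor: float = 0.02
    detect_iterations: int = 2

    def to_dict(self) -> dict:
        return {
            "padding": self.padding,
            "cell_size": self.cell_size,
            "n_orientations": self.n_orientations,
            "sigma_kernel": self.sigma_kernel,
            "sigma_target_factor": self.sigma_target_factor,
            "lambda_reg": self.lambda_reg,
            "interp_factor": self.interp_factor,
            "detect_iterations": self.detect_iterations,
        }


@dataclass
class TrackerState:
    """Center (x, y) in image pixels, fixed ROI size, and the frame index."""

    center: tuple[float, float]
    roi_size: tuple[int, int]  # (w, h) pixels, constant over a track
    frame_index: int = 0

    @classmethod
    def from_roi(cls, roi: Sequence[float], frame_index: int = 0) -> "TrackerState":
        """Build a state from an ``(x_min, y_min, w, h)`` box."""
        x0, y0, w, h = roi
        if w < 8 or h < 8:
            raise ValueError(f"degenerate ROI: w={w}, h={h} (minimum 8 px)")
        return cls(center=(x0 + w / 2.0, y0 + h / 2.0),
                   roi_size=(int(w), int(h)), frame_index=frame_index)


@dataclass
class FeatureMap:
    """Multi-channel spatial feature tensor over the (padded) ROI."""

    grid: np.ndarray  # (height, width, channels), real
    window_applied: bool = False

    @property
    def channels(self) -> int:
        return self.grid.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]


@dataclass
class GaussianResponse:
    """Ideal regression target: circular 2-D Gaussian, peak 1 at the origin."""

    grid: np.ndarray
    peak_location: tuple[int, int]
    sigma_target: float


@dataclass
class CorrelationFilter:
    """Learned model: Fourier-domain dual coefficients plus the template."""

    alpha_hat: np.ndarray      # complex, (h, w)
    template: np.ndarray       # real feature grid (h, w, c)
    sigma_kernel: float
    lambda_reg: float

    @property
    def template_hat(self) -> np.ndarray:
        """Per-channel 2-D Fourier transform of the model feature map."""
        return np.fft.fft2(self.template, axes=(0, 1))


@dataclass
class ResponseMap:
    """Detection response with its (row, col) integer peak."""

    grid: np.ndarray
    peak_value: float
    peak_location: tuple[int, int]

    @property
    def displacement(self) -> tuple[int, int]:
        """Signed (drow, dcol) displacement, unwrapping circular shifts."""
        h, w = self.grid.shape
        dr, dc = self.peak_location
        if dr > h // 2:
            dr -= h
        if dc > w // 2:
            dc -= w
        return dr, dc


def _as_gray(frame: np.ndarray) -> np.ndarray:
    """Luma grayscale as float in [0, 1]."""
    a = np.asarray(frame)
    if a.ndim == 3:
        a = a[..., :3] @ np.array([0.299, 0.587, 0.114])
    a = a.astype(np.float64)
    if a.max() > 1.5:  # integer-range input
        a = a / 255.0
    return a


def _crop_padded(gray: np.ndarray, center: tuple[float, float],
                 size: tuple[int, int]) -> np.ndarray:
    """Crop a (h, w) window around center with edge replication."""
    w, h = size
    cx, cy = int(round(center[0])), int(round(center[1]))
    r0 = cy - h // 2
    c0 = cx - w // 2
    rows = np.clip(np.arange(r0, r0 + h), 0, gray.shape[0] - 1)
    cols = np.clip(np.arange(c0, c0 + w), 0, gray.shape[1] - 1)
    return gray[np.ix_(rows, cols)]


def _window_size(state: TrackerState, cfg: TrackerConfig) -> tuple[int, int]:
    """Padded search-window size (w, h), a multiple of the HOG cell size."""
    c = cfg.cell_size

    def fit(v: float) -> int:
        return max(2 * c, int(round(v * cfg.padding / c)) * c)

    return fit(state.roi_size[0]), fit(state.roi_size[1])


def cosine_window(shape: tuple[int, int]) -> np.ndarray:
    """Outer product of Hann tapers; attenuates the periodic wrap seam."""
    h, w = shape
    return np.outer(np.hanning(h), np.hanning(w))


def cell_orientation_histograms(patch: np.ndarray, cell_size: int,
                                n_orientations: int) -> np.ndarray:
    """Gradient-magnitude-weighted unsigned orientation histograms per cell.

    Gradients are central differences; orientations fold to [0, 180) and
    hard-assign to equal-width bins; each pixel votes its gradient magnitude
    into its cell's bin. Output shape (rows/cell, cols/cell, bins).
    """
    gy, gx = np.gradient(patch)
    mag = np.hypot(gx, gy)
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ang * n_orientations / 180.0).astype(int),
                      n_orientations - 1)
    H, W = patch.shape
    gh, gw = H // cell_size, W // cell_size
    out = np.zeros((gh, gw, n_orientations))
    cell_idx = ((np.arange(H) // cell_size)[:, None] * gw
                + (np.arange(W) // cell_size)[None, :])
    np.add.at(out.reshape(-1), (cell_idx * n_orientations + bins).ravel(),
              mag.ravel())
    return out


def extract_features(frame: np.ndarray, state: TrackerState,
                     cfg: TrackerConfig = TrackerConfig(),
                     windowed: bool = True) -> FeatureMap:
    """HOG feature map over the padded ROI around ``state.center``.

    The search window is ``cfg.padding`` times the ROI, cropped with edge
    replication, converted to luma grayscale, and binned into unsigned
    gradient-orientation histograms over ``cell_size`` cells. The whole
    grid is L2-normalized as one block, which preserves the relative
    strength of the target's edges over weak background texture (per-cell
    normalization would equalize them and let a static background pin the
    response at zero shift). A Hann window is applied unless ``windowed``
    is False; the cyclic-shift model assumes periodicity, which the taper
    enforces approximately.
    """
    gray = _as_gray(frame)
    H, W = gray.shape
    cx, cy = state.center
    if not (0 <= cx < W and 0 <= cy < H):
        raise TrackingFailure(
            f"ROI center ({cx:.1f}, {cy:.1f}) outside {W}x{H} frame")
    win_w, win_h = _window_size(state, cfg)
    patch = _crop_padded(gray, state.center, (win_w, win_h))
    grid = cell_orientation_histograms(patch, cfg.cell_size,
                                       cfg.n_orientations)
    norm = np.sqrt((grid ** 2).sum())
    if norm > 1e-12:
        grid = grid / norm
    if windowed:
        grid = grid * cosine_window(grid.shape[:2])[:, :, None]
    return FeatureMap(grid=grid, window_applied=windowed)


def gaussian_kernel_correlation(x: FeatureMap | np.ndarray,
                                x_prime: FeatureMap | np.ndarray,
                                sigma_kernel: float) -> np.ndarray:
    """Gaussian kernel between ``x`` and every cyclic shift of ``x_prime``.

    Returns the map ``k[s] = exp(-||x - P_s x'||^2 / sigma^2)`` for all 2-D
    circular shifts ``s``, evaluated in O(n log n) through the Fourier
    identity: the cross term of the expanded squared distance is a circular
    cross-correlation, so it is a single inverse FFT of the channel-summed
    spectral product. Negative values of the bracketed distance (possible
    only through round-off) are clipped at zero before exponentiation.
    """
    xg = x.grid if isinstance(x, FeatureMap) else np.asarray(x, dtype=float)
    xpg = (x_prime.grid if isinstance(x_prime, FeatureMap)
           else np.asarray(x_prime, dtype=float))
    if xg.ndim == 2:
        xg = xg[:, :, None]
    if xpg.ndim == 2:
        xpg = xpg[:, :, None]
    if xg.shape != xpg.shape:
        raise ValueError(f"shape mismatch: {xg.shape} vs {xpg.shape}")
    if sigma_kernel <= 0:
        raise ValueError("sigma_kernel must be positive")
    xf = np.fft.fft2(xg, axes=(0, 1))
    xpf = np.fft.fft2(xpg, axes=(0, 1))
    # c[s] = sum_n x[n] * x'[n - s]  (circular)
    cross = np.fft.ifft2((xf * np.conj(xpf)).sum(axis=2)).real
    dist2 = (xg ** 2).sum() + (xpg ** 2).sum() - 2.0 * cross
    return np.exp(-np.maximum(dist2, 0.0) / sigma_kernel ** 2)


def make_gaussian_response(grid_shape: tuple[int, int],
                           sigma_target: float) -> GaussianResponse:
    """Circularly centered 2-D Gaussian target with peak 1 at grid (0, 0).

    Distances wrap around the grid so the target is consistent with the
    cyclic-shift sample model; the peak sits at the zero-shift position.
    """
    h, w = grid_shape
    if h <= 0 or w <= 0 or sigma_target <= 0:
        raise ValueError("grid dimensions and sigma_target must be positive")
    r = np.arange(h)
    c = np.arange(w)
    dr = np.minimum(r, h - r)[:, None]
    dc = np.minimum(c, w - c)[None, :]
    grid = np.exp(-(dr ** 2 + dc ** 2) / (2.0 * sigma_target ** 2))
    return GaussianResponse(grid=grid, peak_location=(0, 0),
                            sigma_target=sigma_target)


def train_filter(x: FeatureMap, y: GaussianResponse, sigma_kernel: float,
                 lambda_reg: float) -> CorrelationFilter:
    """Kernelized ridge regression over all cyclic shifts of ``x``.

    In the Fourier domain the circulant kernel matrix diagonalizes, so the
    dual coefficients are ``alpha_hat = y_hat / (k_hat_xx + lambda)``
    element-wise.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    if x.spatial_shape != y.grid.shape:
        raise ValueError(
            f"feature grid {x.spatial_shape} vs response {y.grid.shape}")
    kxx = gaussian_kernel_correlation(x, x, sigma_kernel)
    denom = np.fft.fft2(kxx) + lambda_reg
    if np.any(denom == 0):
        raise FloatingPointError(
            "zero spectral denominator in ridge solve (lambda too small)")
    alpha_hat = np.fft.fft2(y.grid) / denom
    if not np.all(np.isfinite(alpha_hat)):
        raise FloatingPointError("non-finite filter coefficients")
    return CorrelationFilter(alpha_hat=alpha_hat, template=x.grid.copy(),
                             sigma_kernel=sigma_kernel, lambda_reg=lambda_reg)


def detect(filt: CorrelationFilter, z: FeatureMap) -> ResponseMap:
    """Correlate candidate features ``z`` against the model.

    The response is ``ifft2(k_hat_zx * alpha_hat)``; its peak's circular
    shift is the displacement of the target inside the search window.
    Ties at the maximum break to the first cell in row-major order.
    """
    if z.spatial_shape != filt.template.shape[:2]:
        raise ValueError(
            f"candidate grid {z.spatial_shape} vs model {filt.template.shape[:2]}")
    kzx = gaussian_kernel_correlation(z.grid, filt.template, filt.sigma_kernel)
    resp = np.fft.ifft2(np.fft.fft2(kzx) * filt.alpha_hat).real
    flat = int(np.argmax(resp))
    loc = np.unravel_index(flat, resp.shape)
    return ResponseMap(grid=resp, peak_value=float(resp[loc]),
                       peak_location=(int(loc[0]), int(loc[1])))


def update_model(filt: CorrelationFilter, new_filt: CorrelationFilter,
                 interp_factor: float) -> CorrelationFilter:
    """Linear interpolation ``(1 - eta) * old + eta * new`` of the model."""
    if not 0.0 <= interp_factor <= 1.0:
        raise ValueError("interp_factor must lie in [0, 1]")
    if filt.alpha_hat.shape != new_filt.alpha_hat.shape:
        raise ValueError("filter shape mismatch")
    eta = interp_factor
    return CorrelationFilter(
        alpha_hat=(1 - eta) * filt.alpha_hat + eta * new_filt.alpha_hat,
        template=(1 - eta) * filt.template + eta * new_filt.template,
        sigma_kernel=filt.sigma_kernel,
        lambda_reg=filt.lambda_reg,
    )


def _train_on_frame(frame: np.ndarray, state: TrackerState,
                    cfg: TrackerConfig) -> CorrelationFilter:
    x = extract_features(frame, state, cfg)
    gh, gw = x.spatial_shape
    sigma_t = np.sqrt(gh * gw) / cfg.sigma_target_factor
    y = make_gaussian_response((gh, gw), sigma_t)
    # sigma_kernel is configured in normalized feature units
    sigma_raw = cfg.sigma_kernel * np.sqrt(x.grid.size)
    return train_filter(x, y, sigma_raw, cfg.lambda_reg)


def track(frames: Iterable[np.ndarray], initial_roi: Sequence[float],
          cfg: TrackerConfig = TrackerConfig(), fps: float = 30.0,
          reseed: dict[int, Sequence[float]] | None = None):
    """Track an ROI through a frame sequence.

    Parameters
    ----------
    frames : iterable of images
        Decoded frames in display order (grayscale or RGB arrays).
    initial_roi : (x_min, y_min, w, h)
        Target box in the first frame.
    cfg : TrackerConfig
        Tracker hyper-parameters.
    fps : float
        Sampling frequency; the n-th frame is stamped ``n / fps`` seconds.
    reseed : dict mapping frame index -> ROI, optional
        Manual corrections: at the stated frame the ROI is reset and the
        model relearned from scratch, mirroring manual re-selection.

    Returns
    -------
    Trajectory
        Per-frame time stamps and ROI centers (from ``sitskill.features``).
    """
    from .features import Trajectory  # local import to avoid a cycle

    reseed = dict(reseed or {})
    it = iter(frames)
    try:
        first = next(it)
    except StopIteration:
        raise TrackingFailure("empty frame source")
    state = TrackerState.from_roi(reseed.pop(0, initial_roi))
    filt = _train_on_frame(first, state, cfg)
    H, W = _as_gray(first).shape

    ts, xs, ys = [0.0], [state.center[0]], [state.center[1]]
    for n, frame in enumerate(it, start=1):
        if frame is None:
            raise TrackingFailure(f"unreadable frame at index {n}")
        if n in reseed:
            state = TrackerState.from_roi(reseed.pop(n), frame_index=n)
            filt = _train_on_frame(frame, state, cfg)
        else:
            for _ in range(max(1, cfg.detect_iterations)):
                z = extract_features(frame, state, cfg)
                resp = detect(filt, z)
                dr, dc = resp.displacement
                cx = float(np.clip(state.center[0] + dc * cfg.cell_size,
                                   0, W - 1))
                cy = float(np.clip(state.center[1] + dr * cfg.cell_size,
                                   0, H - 1))
                state = replace(state, center=(cx, cy), frame_index=n)
                if dr == 0 and dc == 0:
                    break
            if cfg.interp_factor > 0:
                filt = update_model(filt, _train_on_frame(frame, state, cfg),
                                    cfg.interp_factor)
        ts.append(n / fps)
        xs.append(state.center[0])
        ys.append(state.center[1])
    return Trajectory(t=np.array(ts), x=np.array(xs), y=np.array(ys), fps=fps)
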