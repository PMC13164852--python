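"""Preprocessing chain for leaf-surface voltage recordings.

The fixed order is: wavelet threshold denoising of the whole recording,
segmentation into non-overlapping 30 s windows (900 points at 30 Hz),
per-window min-max normalization x' = (x - x_min) / (x_max - x_min),
and reshaping of each 900-point window into a 30 x 30 matrix in
row-major time order for the convolutional classifier.

Denoising is applied to the full recording rather than per window: the
universal threshold needs a long series for a stable noise estimate and
900-point windows would limit the decomposition depth.  Normalization is
per window because the extrema in the formula are taken within the
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import h5py
import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import PositionLabel, Recording

__all__ = [
    "DenoiseConfig",
    "WindowSample",
    "SampleMatrix",
    "WaveletDenoiser",
    "wavelet_denoise",
    "segment_windows",
    "minmax_normalize",
    "window_to_matrix",
    "matrix_to_window",
    "preprocess_recording",
    "preprocess_study",
    "save_samples_hdf5",
    "load_samples_hdf5",
]

WINDOW_POINTS = 900  # 30 s at 30 Hz
MATRIX_SIDE = 30


@dataclass
class DenoiseConfig:
    """Wavelet threshold denoising parameters.

    The defaults — Daubechies-4, decomposition to level
    ``min(5, max permitted by the signal length)``, universal threshold
    sigma * sqrt(2 ln N) with sigma from the median absolute deviation of
    the finest detail coefficients, soft shrinkage — are the standard
    configuration for low-SNR nonstationary biosignals.
    ``threshold_scale`` multiplies the universal threshold (0 disables
    shrinkage entirely, giving perfect reconstruction).
    """

    wavelet_name: str = "db4"
    decomposition_level: int | None = None  # None = auto
    threshold_rule: Literal["universal"] = "universal"
    threshold_mode: Literal["soft", "hard"] = "soft"
    boundary_mode: str = "symmetric"
    threshold_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.decomposition_level is not None and self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")
        if self.threshold_scale < 0:
            raise ValueError("threshold_scale must be nonnegative")


class WaveletDenoiser(BaseEstimator, TransformerMixin):
    """Stateless wavelet-threshold denoiser with a sklearn Transformer API.

    ``transform`` accepts a 1-D signal or a 2-D array of row signals and
    denoises each row independently.
    """

    def __init__(
        self,
        wavelet_name: str = "db4",
        decomposition_level: int | None = None,
        threshold_mode: str = "soft",
        boundary_mode: str = "symmetric",
        threshold_scale: float = 1.0,
    ):
        self.wavelet_name = wavelet_name
        self.decomposition_level = decomposition_level
        self.threshold_mode = threshold_mode
        self.boundary_mode = boundary_mode
        self.threshold_scale = threshold_scale

    def _config(self) -> DenoiseConfig:
        return DenoiseConfig(
            wavelet_name=self.wavelet_name,
            decomposition_level=self.decomposition_level,
            threshold_mode=self.threshold_mode,  # type: ignore[arg-type]
            boundary_mode=self.boundary_mode,
            threshold_scale=self.threshold_scale,
        )

    def fit(self, X, y=None):
        self._config()  # validate
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            return wavelet_denoise(X, self._config())
        return np.stack([wavelet_denoise(row, self._config()) for row in X])


def _resolve_level(n: int, wavelet: pywt.Wavelet, requested: int | None) -> int:
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    if max_level < 1:
        raise ValueError(
            f"signal of length {n} too short for wavelet '{wavelet.name}'"
        )
    if requested is None:
        return min(5, max_level)
    if requested > max_level:
        raise ValueError(
            f"decomposition level {requested} exceeds maximum {max_level} "
            f"for length {n}"
        )
    return requested


def wavelet_denoise(values: Sequence[float], cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Universal-threshold wavelet shrinkage of one signal.

    sigma is estimated as MAD(finest detail coefficients) / 0.6745 and the
    threshold sigma * sqrt(2 ln N) (times ``cfg.threshold_scale``) is
    applied to every detail level; approximation coefficients pass
    through untouched.  Output length equals input length.
    """
    cfg = cfg or DenoiseConfig()
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("wavelet_denoise expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or infinite values")
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    if len(x) < wavelet.dec_len:
        raise ValueError(
            f"signal length {len(x)} shorter than wavelet filter "
            f"length {wavelet.dec_len}"
        )
    level = _resolve_level(len(x), wavelet, cfg.decomposition_level)
    coeffs = pywt.wavedec(x, wavelet, mode=cfg.boundary_mode, level=level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest))) / 0.6745
    threshold = cfg.threshold_scale * sigma * np.sqrt(2.0 * np.log(len(x)))
    shrunk = [coeffs[0]] + [
        pywt.threshold(c, threshold, mode=cfg.threshold_mode) for c in coeffs[1:]
    ]
    rec = pywt.waverec(shrunk, wavelet, mode=cfg.boundary_mode)
    return rec[: len(x)]


@dataclass
class WindowSample:
    """One 30 s labelled segment of a recording (900 points at 30 Hz)."""

    values: np.ndarray
    label_mM: int
    plant_id: str
    position: PositionLabel
    window_index: int
    x_min: float | None = None  # recorded at normalization time
    x_max: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("window values must be 1-D")


@dataclass
class SampleMatrix:
    """A window reshaped to a 30 x 30 grid in row-major time order."""

    grid: np.ndarray
    label_mM: int
    plant_id: str
    position: PositionLabel
    window_index: int
    x_min: float | None = None
    x_max: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != (MATRIX_SIDE, MATRIX_SIDE):
            raise ValueError(
                f"grid must be {MATRIX_SIDE}x{MATRIX_SIDE}, got {self.grid.shape}"
            )


def segment_windows(recording: Recording, window_s: float = 30.0) -> list[WindowSample]:
    """Cut a recording into consecutive non-overlapping fixed windows.

    Returns ``floor(N / window_points)`` windows in time order; trailing
    remainder samples are dropped.  A 2 h recording at 30 Hz with 30 s
    windows yields 240 windows of 900 points.
    """
    wp = window_s * recording.sampling_rate_hz
    if abs(wp - round(wp)) > 1e-9 or round(wp) <= 0:
        raise ValueError(
            f"window_s * sampling_rate = {wp} is not a positive integer"
        )
    wp = int(round(wp))
    n_windows = len(recording.values) // wp
    return [
        WindowSample(
            values=recording.values[i * wp : (i + 1) * wp],
            label_mM=recording.concentration_mM,
            plant_id=recording.plant_id,
            position=recording.position,
            window_index=i,
        )
        for i in range(n_windows)
    ]


def minmax_normalize(
    window: WindowSample, constant_policy: Literal["error", "zeros"] = "error"
) -> WindowSample:
    """Min-max normalize one window: x' = (x - x_min) / (x_max - x_min).

    The extrema are taken within the window and recorded on the returned
    sample.  A constant window makes the denominator zero; by default
    this raises (it signals a dead electrode or a degenerate simulation),
    or with ``constant_policy='zeros'`` maps the window to all zeros.
    """
    x = window.values
    x_min, x_max = float(np.min(x)), float(np.max(x))
    if x_max == x_min:
        if constant_policy == "error":
            raise ValueError(
                f"degenerate constant window (plant={window.plant_id}, "
                f"position={window.position.key()}, index={window.window_index})"
            )
        scaled = np.zeros_like(x)
    else:
        scaled = (x - x_min) / (x_max - x_min)
    return replace(window, values=scaled, x_min=x_min, x_max=x_max)


class MinMaxWindowScaler(BaseEstimator, TransformerMixin):
    """Row-wise min-max scaling to [0, 1] (sklearn Transformer form)."""

    def __init__(self, constant_policy: str = "error"):
        self.constant_policy = constant_policy

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        span = hi - lo
        degenerate = span[:, 0] == 0
        if np.any(degenerate) and self.constant_policy == "error":
            raise ValueError(f"{int(degenerate.sum())} degenerate constant rows")
        span[degenerate] = 1.0
        out = (X - lo) / span
        out[degenerate] = 0.0
        return out


def window_to_matrix(window: WindowSample) -> SampleMatrix:
    """Reshape a 900-point window to 30 x 30, row-major in time."""
    if len(window.values) != WINDOW_POINTS:
        raise ValueError(
            f"window must have {WINDOW_POINTS} points, got {len(window.values)}"
        )
    return SampleMatrix(
        grid=window.values.reshape(MATRIX_SIDE, MATRIX_SIDE),
        label_mM=window.label_mM,
        plant_id=window.plant_id,
        position=window.position,
        window_index=window.window_index,
        x_min=window.x_min,
        x_max=window.x_max,
    )


def matrix_to_window(matrix: SampleMatrix) -> WindowSample:
    """Inverse of :func:`window_to_matrix` (lossless)."""
    return WindowSample(
        values=matrix.grid.reshape(-1),
        label_mM=matrix.label_mM,
        plant_id=matrix.plant_id,
        position=matrix.position,
        window_index=matrix.window_index,
        x_min=matrix.x_min,
        x_max=matrix.x_max,
    )


def preprocess_recording(
    recording: Recording,
    denoise_cfg: DenoiseConfig | None = None,
    window_s: float = 30.0,
    constant_policy: Literal["error", "zeros"] = "error",
) -> list[SampleMatrix]:
    """Full chain for one recording: denoise -> segment -> normalize -> reshape."""
    denoised = replace(
        recording, values=wavelet_denoise(recording.values, denoise_cfg)
    )
    return [
        window_to_matrix(minmax_normalize(w, constant_policy))
        for w in segment_windows(denoised, window_s)
    ]


def preprocess_study(
    recordings: Iterable[Recording],
    denoise_cfg: DenoiseConfig | None = None,
    window_s: float = 30.0,
    constant_policy: Literal["error", "zeros"] = "error",
) -> list[SampleMatrix]:
    """Apply :func:`preprocess_recording` to every recording of a study."""
    out: list[SampleMatrix] = []
    for rec in recordings:
        out.extend(
            preprocess_recording(rec, denoise_cfg, window_s, constant_policy)
        )
    return out


# ---------------------------------------------------------------------------
# Preprocessed-sample container I/O (single HDF5 file).
# ---------------------------------------------------------------------------

def save_samples_hdf5(samples: Sequence[SampleMatrix], path: str | Path) -> None:
    """Write samples as matrices [N,1,30,30] + labels + string metadata."""
    n = len(samples)
    mats = np.zeros((n, 1, MATRIX_SIDE, MATRIX_SIDE), dtype=np.float32)
    labels = np.zeros(n, dtype=np.int64)
    str_dt = h5py.string_dtype("utf-8")
    plants = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=object)
    indices = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(samples):
        mats[i, 0] = s.grid
        labels[i] = s.label_mM
        plants[i] = s.plant_id
        positions[i] = s.position.key()
        indices[i] = s.window_index
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=mats)
        f.create_dataset("labels", data=labels)
        f.create_dataset("plant_ids", data=plants, dtype=str_dt)
        f.create_dataset("positions", data=positions, dtype=str_dt)
        f.create_dataset("window_indices", data=indices)


def load_samples_hdf5(path: str | Path) -> list[SampleMatrix]:
    with h5py.File(path, "r") as f:
        mats = f["matrices"][()]
        labels = f["labels"][()]
        plants = [p.decode() if isinstance(p, bytes) else p for p in f["plant_ids"][()]]
        positions = [
            p.decode() if isinstance(p, bytes) else p for p in f["positions"][()]
        ]
        indices = f["window_indices"][()]
    return [
        SampleMatrix(
            grid=mats[i, 0].astype(np.float64),
            label_mM=int(labels[i]),
            plant_id=plants[i],
            position=PositionLabel.from_key(positions[i]),
            window_index=int(indices[i]),
        )
        for i in range(len(labels))
    ]
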