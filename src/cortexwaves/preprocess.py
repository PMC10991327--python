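"""Movie → time × pixel matrix preprocessing.

The decomposition stages operate on a flat ``TimeByPixelMatrix``: every
in-mask pixel of the movie becomes one column of a real ``n_time × n_pixels``
matrix, in row-major grid order.  The canonical pipeline order is

    flatten_movie → bandpass → zscore (→ regress_global_signal)

Bandpass filtering is a zero-phase Chebyshev type II design; z-scoring uses
the population-variance convention (downstream correlations are invariant to
this choice); global signal regression (GSR) is per-pixel ordinary least
squares on the spatial-mean trace, with intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


class PreprocessError(ValueError):
    """Invalid input to a preprocessing step."""


@dataclass(frozen=True)
class FrequencyBand:
    """A passband ``[low, high]`` in Hz; must fit below Nyquist."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise PreprocessError(
                f"invalid band: need 0 <= low < high, got ({self.low}, {self.high})"
            )

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.high >= sampling_rate / 2:
            raise PreprocessError(
                f"band high edge {self.high} Hz is not below Nyquist "
                f"({sampling_rate / 2} Hz)"
            )


@dataclass
class TimeByPixelMatrix:
    """Masked, flattened movie: real matrix of shape (n_time, n_pixels).

    ``pixel_index[j] = (row, col)`` maps column ``j`` back onto the 2-D grid
    of shape ``grid_shape``.  Provenance flags record which preprocessing
    steps have been applied.
    """

    values: np.ndarray
    pixel_index: np.ndarray  # (n_pixels, 2) int
    grid_shape: tuple[int, int]
    sampling_rate: float
    filtered: bool = False
    zscored: bool = False
    gsr: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.pixel_index[:, 0], self.pixel_index[:, 1]] = True
        return m

    def to_grid(self, pixel_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-pixel vector back onto the 2-D grid."""
        return to_grid(np.asarray(pixel_values), self.pixel_index, self.grid_shape, fill)

    def to_movie(self, fill: float = 0.0) -> np.ndarray:
        """Un-flatten to a (n_time, H, W) movie; out-of-mask pixels = fill."""
        out = np.full((self.n_time, *self.grid_shape), fill, dtype=self.values.dtype)
        out[:, self.pixel_index[:, 0], self.pixel_index[:, 1]] = self.values
        return out


def to_grid(
    pixel_values: np.ndarray,
    pixel_index: np.ndarray,
    grid_shape: tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    out = np.full(grid_shape, fill, dtype=np.result_type(pixel_values, type(fill)))
    out[pixel_index[:, 0], pixel_index[:, 1]] = pixel_values
    return out


def flatten_movie(
    movie: np.ndarray, mask: np.ndarray, sampling_rate: float
) -> TimeByPixelMatrix:
    """Flatten a (n_time, H, W) movie to time × pixels over the mask.

    Columns are ordered row-major over in-mask grid positions, so
    ``m.to_movie()`` reproduces the masked frames exactly.
    """
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if movie.ndim != 3:
        raise PreprocessError(f"movie must be 3-D (time, H, W), got shape {movie.shape}")
    if mask.shape != movie.shape[1:]:
        raise PreprocessError(
            f"mask shape {mask.shape} does not match frame shape {movie.shape[1:]}"
        )
    if mask.sum() < 2:
        raise PreprocessError("mask must contain at least 2 pixels")
    pixel_index = np.argwhere(mask)  # row-major
    values = movie[:, mask]  # same row-major order as argwhere
    return TimeByPixelMatrix(
        values=values,
        pixel_index=pixel_index,
        grid_shape=mask.shape,
        sampling_rate=float(sampling_rate),
    )


def design_bandpass(
    band: FrequencyBand,
    sampling_rate: float,
    order: int = 4,
    stopband_db: float = 40.0,
) -> np.ndarray:
    """Chebyshev type II bandpass in second-order sections.

    SciPy's ``cheby2`` critical frequencies are *stopband* edges, so they are
    placed at ``low/2`` and midway between ``high`` and Nyquist: the nominal
    band then sits in the passband, with ≥ ``stopband_db`` attenuation beyond
    the stopband edges (doubled by forward-backward application).
    """
    band.validate_for_rate(sampling_rate)
    nyq = sampling_rate / 2
    ws_low = band.low / 2
    ws_high = (band.high + nyq) / 2
    if ws_low <= 0:
        raise PreprocessError("band low edge must be > 0 for a bandpass design")
    return signal.cheby2(
        order, stopband_db, [ws_low, ws_high], btype="bandpass", fs=sampling_rate,
        output="sos",
    )


def bandpass(
    m: TimeByPixelMatrix,
    band: FrequencyBand,
    order: int = 4,
    stopband_db: float = 40.0,
    edge_seconds: float = 5.0,
) -> TimeByPixelMatrix:
    """Zero-phase (forward-backward) Chebyshev II bandpass along time.

    The first/last ``edge_seconds`` may carry filter transients; they are
    flagged in ``meta['edge_seconds']`` but not trimmed.
    """
    sos = design_bandpass(band, m.sampling_rate, order=order, stopband_db=stopband_db)
    min_len = 3 * (2 * sos.shape[0] + 1)
    if m.n_time < min_len:
        raise PreprocessError(
            f"n_time={m.n_time} too short for filter transients (need ≥ {min_len})"
        )
    filtered = signal.sosfiltfilt(sos, m.values, axis=0)
    meta = dict(m.meta)
    meta.update(
        band=(band.low, band.high),
        filter=f"cheby2(order={order}, rs={stopband_db} dB, zero-phase)",
        edge_seconds=edge_seconds,
    )
    return replace(m, values=filtered, filtered=True, meta=meta)


def zscore(m: TimeByPixelMatrix) -> TimeByPixelMatrix:
    """Per-pixel z-score: (S - mean(S)) / sqrt(Var(S)), population variance."""
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0)  # population (1/N) convention
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        r, c = m.pixel_index[bad[0]]
        raise PreprocessError(
            f"zero-variance pixel at grid position ({r}, {c}) (column {bad[0]})"
        )
    meta = dict(m.meta)
    meta["variance_convention"] = "population (1/N)"
    return replace(m, values=(m.values - mu) / sd, zscored=True, meta=meta)


def regress_global_signal(m: TimeByPixelMatrix) -> TimeByPixelMatrix:
    """Residualize every pixel on the pixel-averaged (global) time course.

    Ordinary least squares with intercept; residuals are exactly uncorrelated
    with the global mean trace.
    """
    if not m.zscored:
        warnings.warn("regress_global_signal expects z-scored input", stacklevel=2)
    g = m.values.mean(axis=1)
    if np.allclose(g, 0.0, atol=1e-14):
        raise PreprocessError("global mean trace is identically zero")
    gc = g - g.mean()
    denom = gc @ gc
    if denom == 0:
        raise PreprocessError("global mean trace is constant")
    beta = (gc @ m.values) / denom
    intercept = m.values.mean(axis=0) - beta * g.mean()
    resid = m.values - np.outer(g, beta) - intercept
    meta = dict(m.meta)
    meta["gsr"] = "per-pixel OLS on spatial-mean trace, with intercept"
    return replace(m, values=resid, gsr=True, meta=meta)
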