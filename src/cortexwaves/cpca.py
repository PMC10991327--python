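"""Complex PCA wave decomposition of the analytic signal.

Each z-scored pixel time series N_p is lifted to its analytic signal
C_p = N_p + i·H[N_p] (Hilbert transform), forming a complex matrix M of
shape (n_time, n_pixels).  The singular value decomposition M = U·diag(d)·Vᴴ
yields, per component k:

* score  t_k = U_k · d_k  — the complex waveform (its real part is the
  displayed waveform; φ_k = t_k / d_k is the unit-normalized score),
* loading l_k = V_k = ρ_k·e^{iθ_k} — the complex spatial map: per-pixel
  amplitude ρ and phase (time-lag) θ,
* variance fraction d_k² / Σ_j d_j².

A component with (near-)constant θ is a standing wave — a zero-lag,
spatially coherent oscillation; substantial phase spread marks a traveling
wave whose crest moves across the field.  The component is defined only up
to a global phase e^{iα} (gauge); the gauge is fixed so the amplitude-
weighted circular mean of θ is zero, making standing waves display θ ≈ 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import TimeByPixelMatrix

_GAUGE_EPS = 1e-12


class DecompositionError(ValueError):
    pass


@dataclass
class AnalyticMatrix:
    """Hilbert-transformed signal matrix: complex (n_time, n_pixels)."""

    values: np.ndarray
    pixel_index: np.ndarray
    grid_shape: tuple[int, int]
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]


@dataclass
class WaveComponent:
    """One standing/traveling wave Φ_k.

    ``loading`` is ℓ2-normalized complex over pixels (ρ e^{iθ});
    ``score`` is the complex waveform t_k with ‖t_k‖₂ = eigenvalue d_k.
    """

    loading: np.ndarray  # complex (n_pixels,)
    score: np.ndarray  # complex (n_time,)
    eigenvalue: float  # singular value d_k
    variance_fraction: float
    pixel_index: np.ndarray
    grid_shape: tuple[int, int]
    sampling_rate: float

    @property
    def rho(self) -> np.ndarray:
        return np.abs(self.loading)

    @property
    def theta(self) -> np.ndarray:
        return np.angle(self.loading)

    @property
    def phi(self) -> np.ndarray:
        """Unit-normalized score φ_k."""
        return self.score / self.eigenvalue

    def loading_map(self) -> np.ndarray:
        """Complex loading scattered onto the 2-D grid (0 outside mask)."""
        out = np.zeros(self.grid_shape, dtype=complex)
        out[self.pixel_index[:, 0], self.pixel_index[:, 1]] = self.loading
        return out


@dataclass
class WaveDecomposition:
    components: list[WaveComponent]
    n_time: int
    n_pixels: int
    total_variance: float  # Σ over all singular values of d²
    rank: int
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, k: int) -> WaveComponent:
        return self.components[k]


def analytic_signal(m: TimeByPixelMatrix) -> AnalyticMatrix:
    """Per-column analytic signal x + iH[x].

    Positive-frequency convention: the analytic signal of cos(ωt) is e^{iωt}.
    The real part equals the input exactly; the imaginary part of each column
    has zero mean (discrete Hilbert transform property).
    """
    if m.n_time < 4:
        raise DecompositionError("need at least 4 time points for the Hilbert transform")
    if not m.zscored:
        warnings.warn("analytic_signal expects z-scored input", stacklevel=2)
    # keep the real part exactly equal to the input (the FFT round trip in
    # the Hilbert transform otherwise leaves ~1e-16 residue)
    values = m.values + 1j * np.imag(hilbert(m.values, axis=0))
    return AnalyticMatrix(
        values=values,
        pixel_index=m.pixel_index,
        grid_shape=m.grid_shape,
        sampling_rate=m.sampling_rate,
        meta=dict(m.meta),
    )


def _fix_gauge(loading: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate (loading, score) by e^{iα} so Σ_p ρ_p e^{iθ_p} has zero angle.

    ρ_p e^{iθ_p} is the loading itself, so the resultant is loading.sum().
    A further π flip would negate the resultant, so the zero-circular-mean
    condition fixes the gauge completely unless the resultant vanishes; in
    that degenerate case the sign is fixed so the score's largest-magnitude
    real excursion is positive.
    """
    resultant = loading.sum()
    if np.abs(resultant) > _GAUGE_EPS * np.abs(loading).sum():
        alpha = -np.angle(resultant)
    else:
        peak = np.argmax(np.abs(score))
        alpha = -np.angle(score[peak]) if score[peak] != 0 else 0.0
    rot = np.exp(1j * alpha)
    # t·conj(l) is invariant under rotating both by the same phase
    return loading * rot, score * rot


def cpca_decompose(a: AnalyticMatrix, n_components: int = 10) -> WaveDecomposition:
    """SVD of the analytic matrix M, returning the top components.

    Column means are already ≈ 0 (z-scored real signals; the Hilbert
    transform preserves zero mean), so no centering is applied.
    Variance fractions are d_k² / Σ_j d_j² over *all* singular values.
    Rank-deficient input yields fewer nonzero components, flagged in
    ``meta['rank']``, not an error.
    """
    n_time, n_pixels = a.values.shape
    max_rank = min(n_time, n_pixels)
    if n_components > max_rank:
        raise DecompositionError(
            f"n_components={n_components} exceeds min(n_time, n_pixels)={max_rank}"
        )
    U, d, Vh = np.linalg.svd(a.values, full_matrices=False)
    total = float(np.sum(d**2))
    tol = d[0] * max(n_time, n_pixels) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    n_keep = min(n_components, max(rank, 1))
    if n_keep < n_components:
        warnings.warn(
            f"input has rank {rank} < n_components={n_components}; "
            f"returning {n_keep} components",
            stacklevel=2,
        )
    components = []
    for k in range(n_keep):
        loading = Vh[k].conj()  # V_k: M[t,p] = Σ_k t_k(t)·conj(loading_k(p))
        score = U[:, k] * d[k]
        loading, score = _fix_gauge(loading, score)
        components.append(
            WaveComponent(
                loading=loading,
                score=score,
                eigenvalue=float(d[k]),
                variance_fraction=float(d[k] ** 2 / total),
                pixel_index=a.pixel_index,
                grid_shape=a.grid_shape,
                sampling_rate=a.sampling_rate,
            )
        )
    return WaveDecomposition(
        components=components,
        n_time=n_time,
        n_pixels=n_pixels,
        total_variance=total,
        rank=rank,
        meta={"n_components_requested": n_components, "singular_values": d},
    )


def reconstruct_component(c: WaveComponent) -> TimeByPixelMatrix:
    """Real spatiotemporal pattern of one wave: Re[t_k(t)·conj(l_k(p))]."""
    values = np.real(np.outer(c.score, c.loading.conj()))
    return TimeByPixelMatrix(
        values=values,
        pixel_index=c.pixel_index,
        grid_shape=c.grid_shape,
        sampling_rate=c.sampling_rate,
        zscored=False,
        meta={"source": "wave reconstruction"},
    )


def reconstruct_sum(d: WaveDecomposition, upto_k: int | None = None) -> np.ndarray:
    """Sum of real reconstructions of the first ``upto_k`` components.

    With all components of a full-rank decomposition this reproduces the
    real input matrix exactly.
    """
    comps = d.components if upto_k is None else d.components[:upto_k]
    out = np.zeros((d.n_time, d.n_pixels))
    for c in comps:
        out += np.real(np.outer(c.score, c.loading.conj()))
    return out


def cycle_pattern(c: WaveComponent, n_phases: int) -> np.ndarray:
    """Spatial maps over one oscillation cycle: stack of (H, W) frames.

    map_j(p) = Re[ρ(p)·e^{iθ(p)}·e^{−i2πj/n_phases}]; frame 0 is the
    gauge-aligned peak.
    """
    if n_phases < 2:
        raise DecompositionError("n_phases must be ≥ 2")
    lm = c.loading_map()
    phases = np.exp(-2j * np.pi * np.arange(n_phases) / n_phases)
    return np.real(lm[None, :, :] * phases[:, None, None])


def concatenate_experiments(matrices: list[TimeByPixelMatrix]) -> TimeByPixelMatrix:
    """Stack z-scored experiments along time for group-level decomposition.

    Longer concatenated signals raise the effective signal-to-noise ratio of
    the group decomposition.  Per-experiment boundaries are recorded in
    ``meta['boundaries']``.
    """
    if not matrices:
        raise DecompositionError("empty experiment list")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.pixel_index.shape != ref.pixel_index.shape or not np.array_equal(
            m.pixel_index, ref.pixel_index
        ):
            raise DecompositionError("experiments have mismatched pixel sets")
        if m.sampling_rate != ref.sampling_rate:
            raise DecompositionError("experiments have mismatched sampling rates")
    if not all(m.zscored for m in matrices):
        warnings.warn("concatenating experiments that are not all z-scored", stacklevel=2)
    boundaries = np.cumsum([m.n_time for m in matrices])[:-1]
    values = np.concatenate([m.values for m in matrices], axis=0)
    return TimeByPixelMatrix(
        values=values,
        pixel_index=ref.pixel_index.copy(),
        grid_shape=ref.grid_shape,
        sampling_rate=ref.sampling_rate,
        filtered=all(m.filtered for m in matrices),
        zscored=all(m.zscored for m in matrices),
        gsr=all(m.gsr for m in matrices),
        meta={"boundaries": boundaries.tolist()},
    )
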