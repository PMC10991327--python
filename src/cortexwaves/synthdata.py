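"""Synthetic widefield movies with known standing/traveling-wave structure.

The generator emulates the validation simulation used to justify per-pixel
normalization before complex PCA: several mutually unrelated narrowband
source waveforms, each multiplied by a spatial amplitude map and delayed
per-pixel by a spatial phase (time-lag) map, linearly superimposed, coupled
with zero-mean Gaussian noise, and multiplied by a simulated fluorescent-
protein expression-efficiency map.

Each source waveform is a stochastically driven second-order linear
oscillator (white-noise input) discretized at the sampling rate — the model
whose autocorrelation is exactly the damped-oscillator form fitted by
``wavemetrics.fit_oscillator``.  Per-pixel time delay is implemented as a
phase rotation of the analytic waveform (valid for narrowband signals),
matching the complex-PCA phase model.

Everything is deterministic given the ground-truth seed: identical
``SyntheticGroundTruth`` ⇒ bit-identical movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment
from scipy.signal import hilbert

__all__ = [
    "WavePatternSpec",
    "SyntheticGroundTruth",
    "simulate_waveform",
    "make_wave_pattern",
    "simulate_movie",
    "simulate_gene_maps",
    "recovery_report",
    "default_truth",
]


class SimulationError(ValueError):
    pass


def simulate_waveform(
    freq: float,
    damping: float,
    duration: float,
    rate: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Complex analytic waveform of a noise-driven damped oscillator.

    A second-order system x'' + 2ξω_n x' + ω_n² x = w(t) driven by white
    noise, discretized by the bilinear transform.  Its power concentrates at
    ``freq`` with quality factor Q ≈ 1/(2ξ); the autocorrelation of the real
    part follows the damped-oscillator ACF model.  The real part is
    normalized to zero mean and unit variance, then lifted to its analytic
    signal.

    Parameters
    ----------
    freq : natural frequency f_n in Hz (must be below Nyquist).
    damping : damping ratio ξ in (0, 1).
    duration, rate : length in seconds and sampling rate in Hz.
    seed : integer or SeedSequence; same inputs ⇒ identical output.
    """
    if not (0 < freq < rate / 2):
        raise SimulationError(f"freq={freq} must lie in (0, Nyquist={rate / 2}) Hz")
    if not (0 < damping < 1):
        raise SimulationError(f"damping={damping} must lie in (0, 1)")
    n = int(round(duration * rate))
    if n < 2:
        raise SimulationError("duration·rate must be ≥ 2")
    rng = np.random.default_rng(seed)
    wn = 2 * np.pi * freq
    b, a = signal.bilinear([1.0], [1.0, 2 * damping * wn, wn**2], fs=rate)
    # burn-in of ~10 envelope time constants so the output is stationary
    tau = 1.0 / (2 * np.pi * freq * damping)
    burn = min(int(10 * tau * rate), 5 * n)
    x = signal.lfilter(b, a, rng.standard_normal(n + burn))[burn:]
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise SimulationError("degenerate waveform (zero variance)")
    return hilbert(x / sd)


def _gaussian_blob(grid_shape, center, width) -> np.ndarray:
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    return np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * width**2)))


def _gaussian_ridge(grid_shape, axis, center, width) -> np.ndarray:
    """Amplitude varying along one axis only (a smooth symmetric profile)."""
    n = grid_shape[axis]
    profile = np.exp(-((np.arange(n) - center) ** 2) / (2 * width**2))
    return np.broadcast_to(
        profile if axis == 1 else profile[:, None], grid_shape
    ).copy()


def make_wave_pattern(
    kind: str,
    grid_shape: tuple[int, int],
    *,
    blobs: list[tuple[tuple[float, float], float]] | None = None,
    ridge: tuple[int, float, float] | None = None,
    amplitude_floor: float = 0.0,
    phase_geometry: str = "constant",
    phase_range: float = np.pi,
    gradient_axis: int = 1,
    lobe_axis: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Build an (amplitude_map, phase_map) pair for one wave.

    Amplitude is uniform (ρ = 1), a sum of Gaussian blobs
    ``[(center, width), ...]``, or a 1-D Gaussian ridge
    ``(axis, center, width)`` varying along one axis only, plus
    ``amplitude_floor``.  Phase geometry:

    * ``"constant"`` — all zeros (standing wave);
    * ``"linear-gradient"`` — 0 → ``phase_range`` along ``gradient_axis``
      (a wave sweeping across the field);
    * ``"two-lobe"`` — 0 on the first half, π on the second half along
      ``lobe_axis`` (a peak-to-valley, anti-phase pattern).
    """
    if kind not in ("standing", "traveling"):
        raise SimulationError(f"unknown wave kind {kind!r}")
    h, w = grid_shape
    if h < 1 or w < 1:
        raise SimulationError("grid_shape must be positive")
    if blobs is not None and ridge is not None:
        raise SimulationError("give either blobs or ridge, not both")
    if blobs is None and ridge is None:
        amplitude = np.ones(grid_shape)
    elif ridge is not None:
        axis, center, width = ridge
        if axis not in (0, 1):
            raise SimulationError("ridge axis must be 0 or 1")
        if not 0 <= center < grid_shape[axis]:
            raise SimulationError(f"ridge center {center} outside grid {grid_shape}")
        amplitude = float(amplitude_floor) + _gaussian_ridge(grid_shape, axis, center, width)
    else:
        amplitude = np.full(grid_shape, float(amplitude_floor))
        for center, width in blobs:
            if not (0 <= center[0] < h and 0 <= center[1] < w):
                raise SimulationError(f"blob center {center} outside grid {grid_shape}")
            amplitude += _gaussian_blob(grid_shape, center, width)
    if kind == "standing" or phase_geometry == "constant":
        phase = np.zeros(grid_shape)
    elif phase_geometry == "linear-gradient":
        n = grid_shape[gradient_axis]
        ramp = np.linspace(0.0, phase_range, n)
        phase = np.broadcast_to(
            ramp if gradient_axis == 1 else ramp[:, None], grid_shape
        ).copy()
    elif phase_geometry == "two-lobe":
        n = grid_shape[lobe_axis]
        idx = np.arange(n) >= n // 2
        lobe = np.where(idx, np.pi, 0.0)
        phase = np.broadcast_to(
            lobe if lobe_axis == 1 else lobe[:, None], grid_shape
        ).copy()
    else:
        raise SimulationError(f"unknown phase geometry {phase_geometry!r}")
    return amplitude, phase


@dataclass
class WavePatternSpec:
    """Ground-truth description of one simulated wave."""

    kind: str  # "standing" | "traveling"
    amplitude_map: np.ndarray  # ρ ≥ 0, arbitrary fluorescence units
    phase_map: np.ndarray  # θ in radians; time lag = θ / (2πf)
    waveform_freq: float  # Hz
    waveform_damping: float  # ξ ∈ (0, 1)
    variance_share: float  # fraction of total movie energy in (0, 1]

    def __post_init__(self) -> None:
        self.amplitude_map = np.asarray(self.amplitude_map, dtype=float)
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        if self.kind not in ("standing", "traveling"):
            raise SimulationError(f"unknown wave kind {self.kind!r}")
        if self.amplitude_map.shape != self.phase_map.shape:
            raise SimulationError("amplitude and phase maps must share a grid")
        if np.any(self.amplitude_map < 0):
            raise SimulationError("amplitude_map must be nonnegative")
        if not (0 < self.variance_share <= 1):
            raise SimulationError("variance_share must lie in (0, 1]")
        if self.kind == "standing" and np.ptp(self.phase_map) > 1e-9:
            raise SimulationError("standing wave requires a constant phase_map")

    @property
    def complex_map(self) -> np.ndarray:
        return self.amplitude_map * np.exp(1j * self.phase_map)


@dataclass
class SyntheticGroundTruth:
    """Full description of a synthetic movie; determines it bit-exactly.

    ``noise_sigma`` is the per-pixel noise standard deviation on the scale
    where the summed wave signal has total energy Σ variance_share; by
    default it is sqrt(1 − Σ variance_share), so shares partition unit
    energy and the remainder is noise.
    """

    wave_specs: list[WavePatternSpec]
    sampling_rate: float = 30.0
    duration: float = 100.0
    seed: int = 0
    noise_sigma: float | None = None
    efficiency_map: np.ndarray | None = None  # positive gain; None ⇒ 1
    mask: np.ndarray | None = None  # boolean grid; None ⇒ all pixels

    def __post_init__(self) -> None:
        if not self.wave_specs:
            raise SimulationError("wave_specs must be non-empty")
        shapes = {s.amplitude_map.shape for s in self.wave_specs}
        if len(shapes) > 1:
            raise SimulationError(f"wave maps on mismatched grids: {shapes}")
        total_share = sum(s.variance_share for s in self.wave_specs)
        if total_share > 1 + 1e-12:
            raise SimulationError(
                f"variance shares sum to {total_share:.3f} > 1 (remainder is noise)"
            )
        if self.noise_sigma is None:
            self.noise_sigma = float(np.sqrt(max(1.0 - total_share, 0.0)))
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be ≥ 0")
        if self.efficiency_map is not None:
            self.efficiency_map = np.asarray(self.efficiency_map, dtype=float)
            if self.efficiency_map.shape != self.grid_shape:
                raise SimulationError("efficiency_map grid mismatch")
            if np.any(self.efficiency_map <= 0):
                raise SimulationError("efficiency_map must be strictly positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise SimulationError("mask grid mismatch")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.wave_specs[0].amplitude_map.shape

    @property
    def n_time(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def simulate_movie(truth: SyntheticGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Render the movie: (n_time, H, W) float array plus the boolean mask.

    Per in-mask pixel p:  movie(t, p) = E(p)·(Σ_k a_k ρ_k(p)·Re[w_k(t)·
    e^{−iθ_k(p)}] + noise(t, p)), where a_k scales wave k so its realized
    energy fraction matches ``variance_share`` and E is the expression-
    efficiency gain.  The efficiency map multiplies the noise as well — it
    models a per-pixel optical gain on the detected signal — which is what
    makes per-pixel z-scoring remove it exactly downstream.
    """
    grid = truth.grid_shape
    mask = truth.mask if truth.mask is not None else np.ones(grid, dtype=bool)
    if mask.sum() < 2:
        raise SimulationError("mask must contain at least 2 pixels")
    n_time = truth.n_time
    root = np.random.SeedSequence(truth.seed)
    children = root.spawn(len(truth.wave_specs) + 1)

    flat = np.zeros((n_time, int(mask.sum())))
    for spec, child in zip(truth.wave_specs, children[:-1]):
        w = simulate_waveform(
            spec.waveform_freq, spec.waveform_damping, truth.duration,
            truth.sampling_rate, child,
        )
        cmap = spec.complex_map[mask]  # ρ e^{iθ} over in-mask pixels
        component = np.real(np.outer(w, cmap.conj()))  # ρ·Re[w e^{−iθ}]
        energy = np.mean(component**2)
        if energy == 0:
            raise SimulationError("wave with zero energy over the mask")
        flat += component * np.sqrt(spec.variance_share / energy)
    if truth.noise_sigma > 0:
        noise_rng = np.random.default_rng(children[-1])
        flat += noise_rng.normal(0.0, truth.noise_sigma, size=flat.shape)
    if truth.efficiency_map is not None:
        flat *= truth.efficiency_map[mask]
    movie = np.zeros((n_time, *grid))
    movie[:, mask] = flat
    return movie, mask


def simulate_gene_maps(
    reference_map: np.ndarray,
    target_correlations: list[float],
    smoothness: float = 2.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Smooth spatial maps with prescribed Pearson correlation to a reference.

    Each map is r·ẑ + sqrt(1−r²)·n̂, where ẑ is the standardized reference
    and n̂ a standardized smooth random field orthogonalized against it, so
    the realized in-mask correlation equals the target up to rounding.
    Returns ``{"gene_000": map, ...}`` in input order.
    """
    reference_map = np.asarray(reference_map, dtype=float)
    if mask is None:
        mask = np.ones(reference_map.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    ref = reference_map[mask]
    ref_z = (ref - ref.mean()) / ref.std()
    from scipy.ndimage import gaussian_filter

    out: dict[str, np.ndarray] = {}
    for i, r in enumerate(target_correlations):
        if not -1 <= r <= 1:
            raise SimulationError(f"target correlation {r} outside [−1, 1]")
        field2d = gaussian_filter(rng.standard_normal(reference_map.shape), smoothness)
        n = field2d[mask]
        n = n - n.mean()
        n = n - (n @ ref_z) / (ref_z @ ref_z) * ref_z  # orthogonalize
        n_sd = n.std()
        if n_sd == 0:  # pathological: field collinear with reference
            n = rng.standard_normal(n.shape)
            n = n - n.mean()
            n = n - (n @ ref_z) / (ref_z @ ref_z) * ref_z
            n_sd = n.std()
        vals = r * ref_z + np.sqrt(max(1 - r**2, 0.0)) * (n / n_sd)
        gmap = np.zeros(reference_map.shape)
        gmap[mask] = vals
        out[f"gene_{i:03d}"] = gmap
    return out


@dataclass
class RecoveryReport:
    """Truth-wave ↔ recovered-component match table plus leftovers."""

    matches: pd.DataFrame  # truth_index, component, loading_corr, shares, errors
    unmatched_truth: list[int]
    unmatched_components: list[int]
    component_variance_fractions: np.ndarray

    @property
    def min_loading_corr(self) -> float:
        return float(self.matches["loading_corr"].min())

    @property
    def max_share_error(self) -> float:
        return float(self.matches["share_error"].abs().max())


def recovery_report(truth: SyntheticGroundTruth, decomposition) -> RecoveryReport:
    """Assess how well a decomposition recovered the ground-truth waves.

    Each truth wave's complex map ρ e^{iθ} (restricted to the decomposition's
    pixels, ℓ2-normalized) is compared against every recovered loading by the
    modulus of the complex inner product — invariant to the arbitrary global
    phase (gauge) of either side.  Truth waves are assigned one-to-one to
    components by maximizing total |corr| (Hungarian assignment); components
    beyond the truth set, or truth waves without a component, are reported as
    unmatched.
    """
    comps = decomposition.components
    if not comps:
        raise SimulationError("decomposition has no components")
    pix = comps[0].pixel_index
    truth_loadings = []
    for spec in truth.wave_specs:
        v = spec.complex_map[pix[:, 0], pix[:, 1]]
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise SimulationError("truth wave has zero amplitude over decomposition pixels")
        truth_loadings.append(v / nrm)
    n_t, n_c = len(truth_loadings), len(comps)
    corr = np.zeros((n_t, n_c))
    for i, tv in enumerate(truth_loadings):
        for j, c in enumerate(comps):
            corr[i, j] = np.abs(np.vdot(tv, c.loading))
    rows_avail = min(n_t, n_c)
    ri, cj = linear_sum_assignment(-corr)
    records = []
    for i, j in zip(ri, cj):
        records.append(
            {
                "truth_index": int(i),
                "component": int(j),
                "loading_corr": float(corr[i, j]),
                "truth_share": truth.wave_specs[i].variance_share,
                "recovered_share": comps[j].variance_fraction,
                "share_error": comps[j].variance_fraction
                - truth.wave_specs[i].variance_share,
            }
        )
    matches = pd.DataFrame.from_records(records).sort_values("truth_index")
    matched_truth = set(ri[:rows_avail])
    matched_comp = set(cj[:rows_avail])
    return RecoveryReport(
        matches=matches.reset_index(drop=True),
        unmatched_truth=sorted(set(range(n_t)) - matched_truth),
        unmatched_components=sorted(set(range(n_c)) - matched_comp),
        component_variance_fractions=np.array([c.variance_fraction for c in comps]),
    )


def save_simulation(
    outdir, truth: SyntheticGroundTruth, movie: np.ndarray, mask: np.ndarray
) -> dict:
    """Write a simulated dataset: movie.npy (float32), mask.npy, ground truth.

    The ground truth goes to a JSON manifest (scalar parameters) plus an NPZ
    of the spatial maps, enough to reconstruct the ``SyntheticGroundTruth``.
    """
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "movie.npy", movie.astype(np.float32))
    np.save(outdir / "mask.npy", mask)
    maps = {}
    manifest = {
        "sampling_rate": truth.sampling_rate,
        "duration": truth.duration,
        "seed": truth.seed,
        "noise_sigma": truth.noise_sigma,
        "waves": [],
    }
    for k, s in enumerate(truth.wave_specs):
        maps[f"amplitude_{k}"] = s.amplitude_map
        maps[f"phase_{k}"] = s.phase_map
        manifest["waves"].append(
            {
                "kind": s.kind,
                "waveform_freq": s.waveform_freq,
                "waveform_damping": s.waveform_damping,
                "variance_share": s.variance_share,
            }
        )
    if truth.efficiency_map is not None:
        maps["efficiency"] = truth.efficiency_map
    np.savez(outdir / "truth_maps.npz", **maps)
    (outdir / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "movie": outdir / "movie.npy",
        "mask": outdir / "mask.npy",
        "manifest": outdir / "truth_manifest.json",
        "maps": outdir / "truth_maps.npz",
    }


def load_ground_truth(outdir) -> SyntheticGroundTruth:
    """Rebuild a SyntheticGroundTruth written by :func:`save_simulation`."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    manifest = json.loads((outdir / "truth_manifest.json").read_text())
    maps = np.load(outdir / "truth_maps.npz")
    specs = [
        WavePatternSpec(
            kind=w["kind"],
            amplitude_map=maps[f"amplitude_{k}"],
            phase_map=maps[f"phase_{k}"],
            waveform_freq=w["waveform_freq"],
            waveform_damping=w["waveform_damping"],
            variance_share=w["variance_share"],
        )
        for k, w in enumerate(manifest["waves"])
    ]
    return SyntheticGroundTruth(
        wave_specs=specs,
        sampling_rate=manifest["sampling_rate"],
        duration=manifest["duration"],
        seed=manifest["seed"],
        noise_sigma=manifest["noise_sigma"],
        efficiency_map=maps["efficiency"] if "efficiency" in maps else None,
    )


def default_truth(
    seed: int = 0,
    grid_shape: tuple[int, int] = (40, 40),
    duration: float = 100.0,
    sampling_rate: float = 30.0,
) -> SyntheticGroundTruth:
    """The default validation fixture: 3 waves + 20% noise.

    One standing wave carrying ~35% of the energy (the dominant global
    zero-lag mode), a traveling wave sweeping one full phase cycle across
    the columns (25%), and a two-lobe anti-phase wave split across the rows
    (20%); the remaining 20% is white noise.  Amplitude profiles vary along
    the axis orthogonal to each wave's phase variation and are symmetric, so
    the three complex ground-truth maps are mutually orthogonal — distinct
    spatial sources that the decomposition can in principle separate
    exactly.  Waveform frequencies 0.3 / 1.2 / 3.0 Hz with damping
    0.05 / 0.1 / 0.1 (Q = 10 / 5 / 5).
    """
    h, w = grid_shape
    amp0, ph0 = make_wave_pattern(
        "standing", grid_shape,
        ridge=(0, (h - 1) / 2, 0.45 * h), amplitude_floor=0.6,
    )
    # one full 2π turn over the columns: θ_c = 2πc/w, so Σ_c e^{iθ_c} = 0
    amp1, ph1 = make_wave_pattern(
        "traveling", grid_shape,
        ridge=(0, (h - 1) / 2, 0.3 * h), amplitude_floor=0.6,
        phase_geometry="linear-gradient",
        phase_range=2 * np.pi * (w - 1) / w,
        gradient_axis=1,
    )
    amp2, ph2 = make_wave_pattern(
        "traveling", grid_shape,
        ridge=(1, (w - 1) / 2, 0.35 * w), amplitude_floor=0.6,
        phase_geometry="two-lobe",
        lobe_axis=0,
    )
    specs = [
        WavePatternSpec("standing", amp0, ph0, 0.3, 0.05, 0.35),
        WavePatternSpec("traveling", amp1, ph1, 1.2, 0.10, 0.25),
        WavePatternSpec("traveling", amp2, ph2, 3.0, 0.10, 0.20),
    ]
    return SyntheticGroundTruth(
        wave_specs=specs,
        sampling_rate=sampling_rate,
        duration=duration,
        seed=seed,
    )
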