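"""Functional connectivity and its decomposition into per-wave structure.

Functional connectivity (FC) is the pairwise Pearson correlation of pixel
(or seed) time series, with or without global signal regression (GSR).
Because complex-PCA components are orthogonal, the covariance of the
analytic signal decomposes exactly as Σ_k d_k²·l_k l_kᴴ, and the raw FC is
well approximated by a weighted superposition of the per-wave correlation
matrices C_Φk — the correlation of the real pixel time courses
reconstructed from wave k alone.  For a long, circularly symmetric analytic
score, C_Φk(j, l) ≈ cos(θ_j − θ_l): a phase lag of π between two regions
appears as a *negative* connection, which is the mechanism relating
traveling waves to the negative correlations seen after GSR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .cpca import WaveComponent, WaveDecomposition
from .preprocess import TimeByPixelMatrix

_R_CLIP = 1.0 - 1e-7  # Pearson r clipped here before Fisher z


class FCError(ValueError):
    pass


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal.

    ``undefined`` marks nodes whose series is identically zero (e.g. pixels
    with ρ = 0 in a wave reconstruction); their rows/columns are NaN.
    """

    values: np.ndarray
    node_index: np.ndarray  # pixel coordinates (n, 2) or object labels (n,)
    gsr_applied: bool = False
    source: str = "raw"
    undefined: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


def _check_same_nodes(a: FCMatrix, b: FCMatrix) -> None:
    if a.node_index.shape != b.node_index.shape or not np.array_equal(
        a.node_index, b.node_index
    ):
        raise FCError("FC matrices are defined on different node sets")


def fc_matrix(m: TimeByPixelMatrix) -> FCMatrix:
    """Pixel × pixel Pearson correlation of the preprocessed signals."""
    if m.n_time < 3:
        raise FCError("need at least 3 time points for correlations")
    sd = m.values.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise FCError(f"zero-variance pixel column {j}")
    values = np.corrcoef(m.values.T)
    np.fill_diagonal(values, 1.0)
    return FCMatrix(
        values=values,
        node_index=m.pixel_index.copy(),
        gsr_applied=m.gsr,
        source="raw",
    )


def wave_fc(c: WaveComponent) -> FCMatrix:
    """C_Φ: correlation matrix of one wave's reconstructed pixel series.

    Pixels with ρ = 0 reconstruct to the zero series; they are flagged
    undefined (NaN rows/columns) rather than raised.
    """
    if np.linalg.norm(c.score) == 0:
        raise FCError("component has a zero score")
    # Re[t(t)·conj(l_j)] = ρ_j·(x cosθ_j + y sinθ_j) with x, y the score's
    # real/imag parts: every pixel series lives in a 2-D subspace, so the
    # full correlation matrix follows from the 2×2 score covariance.
    x, y = np.real(c.score), np.imag(c.score)
    cov2 = np.cov(np.stack([x, y]), bias=True)
    rho, theta = c.rho, c.theta
    P = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    G = P @ cov2 @ P.T
    dg = np.sqrt(np.diag(G))
    defined = (rho > rho.max() * 1e-12) & (dg > 0)
    n = rho.size
    values = np.full((n, n), np.nan)
    idx = np.flatnonzero(defined)
    values[np.ix_(idx, idx)] = G[np.ix_(idx, idx)] / np.outer(dg[idx], dg[idx])
    np.fill_diagonal(values, 1.0)
    undefined = ~defined
    return FCMatrix(
        values=values,
        node_index=c.pixel_index.copy(),
        source="wave",
        undefined=undefined if undefined.any() else None,
    )


def _uptri_pearson(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


def fc_superposition(
    d: WaveDecomposition,
    upto_k: int,
    reference: FCMatrix | None = None,
    renormalize: bool = True,
) -> tuple[FCMatrix, np.ndarray | None]:
    """Weighted superposition Σ_{t≤k} s_t·C_Φt of per-wave FC matrices.

    Weights s_t are the components' variance fractions; the sum is
    renormalized to unit diagonal (a uniform rescaling, since every C_Φ has
    unit diagonal).  If a reference FC is given, also returns the similarity
    curve: Pearson correlation between vectorized upper triangles of the
    running superposition and the reference, for k = 1 … upto_k.  As more
    waves are added the superposition approaches the raw FC.
    """
    if not (1 <= upto_k <= len(d)):
        raise FCError(f"upto_k={upto_k} outside 1..{len(d)}")
    acc = np.zeros((d.n_pixels, d.n_pixels))
    weight = 0.0
    curve = [] if reference is not None else None
    for t in range(upto_k):
        c = d[t]
        acc += c.variance_fraction * wave_fc(c).values
        weight += c.variance_fraction
        if reference is not None:
            running = acc / weight if renormalize else acc
            curve.append(_uptri_pearson(running, reference.values))
    values = acc / weight if renormalize else acc
    np.fill_diagonal(values, 1.0)
    fc = FCMatrix(
        values=values,
        node_index=d[0].pixel_index.copy(),
        source=f"superposition:{upto_k}",
    )
    return fc, (np.array(curve) if curve is not None else None)


def mean_fc_map(fc: FCMatrix, absolute: bool = True) -> np.ndarray:
    """Per-pixel mean (absolute) correlation to all other pixels."""
    vals = np.abs(fc.values) if absolute else fc.values.copy()
    np.fill_diagonal(vals, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=1)


def hemispheric_difference_map(fc: FCMatrix, midline_column: int) -> np.ndarray:
    """Homolateral-minus-contralateral mean absolute FC, per pixel.

    Pixels with grid column < ``midline_column`` form one hemisphere.  For
    each pixel: mean |FC| to same-side pixels (self excluded) minus mean
    |FC| to opposite-side pixels; positive values mean stronger within-
    hemisphere than cross-hemisphere coupling.
    """
    cols = fc.node_index[:, 1]
    left = cols < midline_column
    if left.sum() < 2 or (~left).sum() < 2:
        raise FCError("midline must leave at least 2 pixels on each side")
    a = np.abs(fc.values)
    np.fill_diagonal(a, np.nan)
    out = np.empty(fc.n_nodes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        same = np.where(left[None, :], np.nan, a)  # right-side partners
        cross = np.where(left[None, :], a, np.nan)  # left-side partners
        mean_right = np.nanmean(same, axis=1)
        mean_left = np.nanmean(cross, axis=1)
    out[left] = mean_left[left] - mean_right[left]
    out[~left] = mean_right[~left] - mean_left[~left]
    return out


def fc_similarity_map(fc_a: FCMatrix, fc_b: FCMatrix) -> np.ndarray:
    """Per-node Pearson correlation between FC rows of two matrices.

    S_i = Pearson(row i of A, row i of B) with the diagonal entry excluded.
    Pearson is affine-invariant, so FC ≈ α·FC_GSR + β yields S ≈ 1.
    """
    _check_same_nodes(fc_a, fc_b)
    n = fc_a.n_nodes
    out = np.empty(n)
    for i in range(n):
        sel = np.arange(n) != i
        out[i] = np.corrcoef(fc_a.values[i, sel], fc_b.values[i, sel])[0, 1]
    return out


@dataclass
class SeedSet:
    """Cluster-derived seed pixels: one representative per FC cluster."""

    seeds: list[tuple[str, tuple[int, int]]]
    cluster_assignment: np.ndarray  # per pixel, cluster id
    k: int
    silhouette_by_k: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.seeds]

    @property
    def coords(self) -> np.ndarray:
        return np.array([s[1] for s in self.seeds])


def select_seeds(
    fc: FCMatrix,
    k_range=range(2, 26),
    replicates: int = 10,
    seed: int = 0,
    k_override: int | None = None,
    silhouette_sample: int = 400,
) -> SeedSet:
    """k-means clustering of FC rows, one seed pixel per cluster.

    k is chosen by maximum silhouette over ``k_range`` (the manual choice the
    clustering assists can be forced with ``k_override``); the seed of a
    cluster is the in-mask pixel whose FC row is nearest its centroid.
    Deterministic given ``seed``.
    """
    X = fc.values
    if np.isnan(X).any():
        raise FCError("FC matrix with undefined entries cannot be clustered")
    n = X.shape[0]
    ks = [k for k in ([k_override] if k_override else k_range) if 2 <= k <= n - 1]
    if not ks:
        raise FCError(f"no feasible k in range for {n} pixels")
    if np.allclose(X, X[0], atol=1e-12):
        warnings.warn("degenerate (constant) FC: returning trivial k=2 split")
        labels = (np.arange(n) >= n // 2).astype(int)
        seeds = [("c0", tuple(fc.node_index[0])), ("c1", tuple(fc.node_index[n // 2]))]
        return SeedSet(seeds=seeds, cluster_assignment=labels, k=2)
    best = None
    scores = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=replicates, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        sample = min(silhouette_sample, n)
        s = silhouette_score(
            X, km.labels_, sample_size=sample,
            random_state=np.random.RandomState(seed),
        ) if sample < n else silhouette_score(X, km.labels_)
        scores[k] = float(s)
        if best is None or s > best[0]:
            best = (s, k, km)
    if best is None:
        raise FCError("clustering failed for every k in range")
    _, k, km = best
    seeds = []
    for j in range(k):
        members = np.flatnonzero(km.labels_ == j)
        dists = np.linalg.norm(X[members] - km.cluster_centers_[j], axis=1)
        pick = members[np.argmin(dists)]
        seeds.append((f"c{j}", tuple(int(v) for v in fc.node_index[pick])))
    return SeedSet(
        seeds=seeds, cluster_assignment=km.labels_.copy(), k=k, silhouette_by_k=scores
    )


def _pixel_column(m: TimeByPixelMatrix, coord: tuple[int, int]) -> int:
    hits = np.flatnonzero(
        (m.pixel_index[:, 0] == coord[0]) & (m.pixel_index[:, 1] == coord[1])
    )
    if hits.size == 0:
        raise FCError(f"seed {coord} is outside the mask")
    return int(hits[0])


def seed_fc(
    m: TimeByPixelMatrix, seeds: SeedSet
) -> tuple[FCMatrix, np.ndarray]:
    """Seed–seed FC matrix plus one full-pixel FC map per seed.

    Returns (k × k FCMatrix over seed labels, (k, n_pixels) map array).
    """
    cols = [_pixel_column(m, coord) for _, coord in seeds.seeds]
    series = m.values[:, cols]
    sd = series.std(axis=0)
    if np.any(sd == 0):
        raise FCError("seed with zero-variance series")
    k = len(cols)
    values = np.corrcoef(series.T) if k > 1 else np.ones((1, 1))
    values = np.atleast_2d(values)
    np.fill_diagonal(values, 1.0)
    zs = (series - series.mean(0)) / series.std(0)
    zm = (m.values - m.values.mean(0)) / m.values.std(0)
    maps = (zs.T @ zm) / m.n_time
    fc = FCMatrix(
        values=values,
        node_index=np.array(seeds.labels, dtype=object),
        gsr_applied=m.gsr,
        source="seeds",
    )
    return fc, maps


def short_range_fc(m: TimeByPixelMatrix, seeds: SeedSet) -> pd.DataFrame:
    """Correlation of each seed with the mean of its in-mask 8-neighborhood.

    Isolated seeds get NaN, flagged; edge seeds use exactly their in-mask
    neighbors.
    """
    mask = m.mask
    lookup = {tuple(rc): j for j, rc in enumerate(map(tuple, m.pixel_index))}
    rows = []
    for label, (r, c) in seeds.seeds:
        col = _pixel_column(m, (r, c))
        neigh = [
            lookup[(r + dr, c + dc)]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if not (dr == 0 and dc == 0)
            and 0 <= r + dr < mask.shape[0]
            and 0 <= c + dc < mask.shape[1]
            and (r + dr, c + dc) in lookup
        ]
        if not neigh:
            rows.append({"seed": label, "short_range_fc": np.nan,
                         "n_neighbors": 0, "flag": "isolated seed"})
            continue
        nm = m.values[:, neigh].mean(axis=1)
        if nm.std() == 0 or m.values[:, col].std() == 0:
            rows.append({"seed": label, "short_range_fc": np.nan,
                         "n_neighbors": len(neigh), "flag": "zero variance"})
            continue
        r_val = float(np.corrcoef(m.values[:, col], nm)[0, 1])
        rows.append({"seed": label, "short_range_fc": r_val,
                     "n_neighbors": len(neigh), "flag": ""})
    return pd.DataFrame(rows)


def group_fc_tests(
    group_a: list[FCMatrix],
    group_b: list[FCMatrix] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise group statistics on Fisher-z-transformed correlations.

    One-sample two-sided t-tests of mean z = 0 when one group is given;
    Welch's unequal-variances two-sided t-test between groups otherwise.
    p-values are Benjamini–Hochberg corrected across all tested edges
    (upper triangle); edges are significant at q < ``alpha``.  r is clipped
    to |r| < 1 − 1e−7 before the z transform; zero-variance edges get an
    infinite statistic with p ∈ {0, 1}, flagged.
    """
    if len(group_a) < 3 or (group_b is not None and len(group_b) < 3):
        raise FCError("need at least 3 FC matrices per group")
    ref = group_a[0]
    for fc in group_a + (group_b or []):
        _check_same_nodes(ref, fc)
    iu = np.triu_indices(ref.n_nodes, k=1)

    def zstack(group):
        r = np.stack([fc.values[iu] for fc in group])
        return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))

    za = zstack(group_a)
    flags = np.full(za.shape[1], "", dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if group_b is None:
            stat, p = stats.ttest_1samp(za, 0.0, axis=0)
            mean_effect = za.mean(axis=0)
            degenerate = za.std(axis=0) == 0
        else:
            zb = zstack(group_b)
            stat, p = stats.ttest_ind(za, zb, axis=0, equal_var=False)
            mean_effect = za.mean(axis=0) - zb.mean(axis=0)
            degenerate = (za.std(axis=0) == 0) & (zb.std(axis=0) == 0)
    bad = degenerate | ~np.isfinite(p)
    if bad.any():
        stat = np.where(bad, np.sign(mean_effect) * np.inf, stat)
        p = np.where(bad, np.where(np.abs(mean_effect) > 0, 0.0, 1.0), p)
        flags[bad] = "zero-variance edge: infinite statistic"
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "node_i": iu[0],
            "node_j": iu[1],
            "mean_z": mean_effect,
            "statistic": stat,
            "p": p,
            "q": q,
            "significant": rejected,
            "flag": flags,
        }
    )
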