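"""Cross-condition wave matching via per-wave connectivity matrices.

Complex-PCA components from different recordings (cell types, ages,
states) cannot be compared directly — the decomposition carries no
component identity.  Corresponding waves are instead identified through
their reconstructed correlation matrices C_Φ: waves whose C_Φ matrices have
the lowest mean squared error are considered the same type.  C_Φ depends
only on phase *differences*, so the comparison is invariant to each
component's arbitrary global phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cpca import WaveDecomposition
from .fcanalysis import FCMatrix, wave_fc


class MatchingError(ValueError):
    pass


def correlation_mse(fc_a: FCMatrix, fc_b: FCMatrix) -> float:
    """Mean squared difference over the upper triangle (diagonal excluded)."""
    if fc_a.values.shape != fc_b.values.shape or not np.array_equal(
        fc_a.node_index, fc_b.node_index
    ):
        raise MatchingError("FC matrices on different node sets; align grids first")
    iu = np.triu_indices(fc_a.n_nodes, k=1)
    diff = fc_a.values[iu] - fc_b.values[iu]
    return float(np.mean(diff**2))


@dataclass
class MatchResult:
    """Query-wave → reference-wave assignment by lowest C_Φ MSE."""

    mse_matrix: np.ndarray  # (n_query, n_reference)
    assignment: np.ndarray  # per query row, argmin reference index
    matched_mse: np.ndarray  # per query row
    injective: bool  # False if two query waves map to one reference

    def hungarian_assignment(self) -> np.ndarray:
        """One-to-one variant (minimum total MSE) for fixtures needing it."""
        ri, cj = linear_sum_assignment(self.mse_matrix)
        out = np.full(self.mse_matrix.shape[0], -1)
        out[ri] = cj
        return out


def match_waves(query: WaveDecomposition, reference: WaveDecomposition) -> MatchResult:
    """Match every query wave to the reference wave with the lowest C_Φ MSE.

    Per-row argmin (ties broken toward the lower reference index); the
    assignment need not be injective — duplicates are flagged, and a
    one-to-one Hungarian variant is available on the result.
    """
    if len(query) == 0 or len(reference) == 0:
        raise MatchingError("cannot match empty decompositions")
    if query.n_pixels != reference.n_pixels or not np.array_equal(
        query[0].pixel_index, reference[0].pixel_index
    ):
        raise MatchingError("decompositions are on different pixel grids")
    q_fc = [wave_fc(c) for c in query]
    r_fc = [wave_fc(c) for c in reference]
    mse = np.empty((len(query), len(reference)))
    for i, qa in enumerate(q_fc):
        for j, rb in enumerate(r_fc):
            mse[i, j] = correlation_mse(qa, rb)
    assignment = mse.argmin(axis=1)  # ties → lower index
    return MatchResult(
        mse_matrix=mse,
        assignment=assignment,
        matched_mse=mse[np.arange(len(query)), assignment],
        injective=len(set(assignment.tolist())) == len(query),
    )
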