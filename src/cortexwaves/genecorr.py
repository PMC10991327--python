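"""Correlating wave spatial maps with per-gene expression maps.

Given a wave's spatial distribution (its amplitude map ρ by default, or the
signed map Re[ρ·e^{iθ}]) and a set of spatial gene-expression maps on the
same pixel grid, each gene is scored by the Pearson correlation r over
in-mask pixels and bucketed by conventional effect-size thresholds:
|r| < 0.3 negligible, |r| ≥ 0.3 correlated, |r| ≥ 0.75 highly correlated
(both boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpca import WaveComponent

LOW_THRESHOLD = 0.3
HIGH_THRESHOLD = 0.75

CATEGORY_NEGLIGIBLE = "negligible"
CATEGORY_CORRELATED = "correlated"
CATEGORY_HIGH = "highly_correlated"


class GeneCorrError(ValueError):
    pass


@dataclass
class GeneMapSet:
    """Per-gene spatial expression maps sharing one grid and mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for gene, m in self.maps.items():
            m = np.asarray(m, dtype=float)
            if m.shape != self.mask.shape:
                raise GeneCorrError(f"gene {gene!r} map shape {m.shape} ≠ mask {self.mask.shape}")
            if np.isnan(m[self.mask]).any():
                raise GeneCorrError(f"gene {gene!r} has missing in-mask values")
            self.maps[gene] = m

    def __len__(self) -> int:
        return len(self.maps)


def wave_spatial_map(c: WaveComponent, signed: bool = False) -> np.ndarray:
    """A wave's spatial distribution on the grid: ρ, or Re[ρe^{iθ}] if signed."""
    lm = c.loading_map()
    return np.real(lm) if signed else np.abs(lm)


def map_gene_correlations(wave_map: np.ndarray, genes: GeneMapSet) -> pd.DataFrame:
    """Pearson r of every gene map with the wave map over in-mask pixels.

    Sorted by |r| descending; genes with constant (zero-variance) maps are
    flagged and placed last with r = NaN.
    """
    wave_map = np.asarray(wave_map, dtype=float)
    if wave_map.shape != genes.mask.shape:
        raise GeneCorrError("wave map and gene maps are on different grids")
    w = wave_map[genes.mask]
    if w.std() == 0:
        raise GeneCorrError("wave map is constant over the mask")
    rows = []
    for gene, m in genes.maps.items():
        g = m[genes.mask]
        if g.std() == 0:
            rows.append({"gene_id": gene, "r": np.nan, "flag": "constant map"})
        else:
            rows.append(
                {"gene_id": gene, "r": float(np.corrcoef(w, g)[0, 1]), "flag": ""}
            )
    df = pd.DataFrame(rows)
    df["abs_r"] = df["r"].abs()
    df = df.sort_values("abs_r", ascending=False, na_position="last")
    return df.drop(columns="abs_r").reset_index(drop=True)


def classify_correlations(
    table: pd.DataFrame,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Bucket genes by |r|: < low negligible, ≥ low correlated, ≥ high highly.

    Both thresholds are inclusive on the upper category (|r| = 0.3 counts as
    correlated, |r| = 0.75 as highly correlated).  Returns the table with a
    ``category`` column plus counts per category; the ``correlated`` count
    excludes the highly-correlated genes.
    """
    if low >= high:
        raise GeneCorrError(f"need low < high, got {low} ≥ {high}")
    table = table.copy()

    def bucket(r: float) -> str:
        if np.isnan(r):
            return "undefined"
        a = abs(r)
        if a >= high:
            return CATEGORY_HIGH
        if a >= low:
            return CATEGORY_CORRELATED
        return CATEGORY_NEGLIGIBLE

    table["category"] = table["r"].map(bucket)
    counts = {
        CATEGORY_HIGH: int((table["category"] == CATEGORY_HIGH).sum()),
        CATEGORY_CORRELATED: int((table["category"] == CATEGORY_CORRELATED).sum()),
        CATEGORY_NEGLIGIBLE: int((table["category"] == CATEGORY_NEGLIGIBLE).sum()),
    }
    return table, counts
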