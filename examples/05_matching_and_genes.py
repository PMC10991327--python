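"""Match waves across two recordings and correlate a wave map with gene maps.

Waves from different decompositions carry no shared labels; corresponding
waves are identified by the mean squared error between their per-wave
correlation matrices C_Phi (gauge-invariant). A wave's amplitude map can
then be compared with spatial gene-expression maps: Pearson r per gene,
bucketed at the conventional |r| thresholds 0.3 (correlated) and 0.75
(highly correlated).
"""

import numpy as np

from cortexwaves import cpca, genecorr, matching, preprocess, synthdata


def decompose(seed):
    truth = synthdata.default_truth(seed=seed, grid_shape=(12, 12), duration=80.0)
    movie, mask = synthdata.simulate_movie(truth)
    m = preprocess.zscore(preprocess.flatten_movie(movie, mask, truth.sampling_rate))
    return cpca.cpca_decompose(cpca.analytic_signal(m), n_components=3), mask


query, mask = decompose(seed=4)
reference, _ = decompose(seed=5)  # same conditions, an independent recording
result = matching.match_waves(query, reference)
print("C_Phi MSE matrix (rows: query waves, cols: reference waves):")
print(np.array_str(result.mse_matrix, precision=3))
print(f"assignment (query -> reference): {result.assignment.tolist()}, "
      f"injective: {result.injective}")
print("each wave matches its counterpart: far lower MSE than any other pairing.\n")

wave_map = genecorr.wave_spatial_map(query[1])  # the first traveling wave
targets = [0.85, 0.6, 0.31, 0.1, -0.5, -0.8]
gene_maps = synthdata.simulate_gene_maps(wave_map, targets, seed=0, mask=mask)
genes = genecorr.GeneMapSet(maps=gene_maps, mask=mask)
table = genecorr.map_gene_correlations(wave_map, genes)
table, counts = genecorr.classify_correlations(table)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\ncategory counts: {counts}")
print("genes with |r| >= 0.75 share the wave's spatial footprint; |r| < 0.3 are negligible.")
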