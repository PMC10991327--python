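"""Characterize recovered waves: natural frequency, damping, quality, phase spread.

Each wave's waveform is summarized by fitting its autocorrelation with the
damped-oscillator model R(tau) (natural frequency f_n, damping ratio xi =
1/(2Q)); its spatial map by the PSNR quality score (structured maps score
higher) and the circular variance of its phase map (0 = standing wave,
toward 1 = traveling/dispersed phases).
"""

from cortexwaves import cpca, pipeline, preprocess, synthdata

truth = synthdata.default_truth(seed=1, grid_shape=(20, 20), duration=100.0)
movie, mask = synthdata.simulate_movie(truth)
m = preprocess.zscore(
    preprocess.bandpass(
        preprocess.flatten_movie(movie, mask, truth.sampling_rate),
        preprocess.FrequencyBand(0.1, 14.5),
    )
)
decomposition = cpca.cpca_decompose(cpca.analytic_signal(m), n_components=4)

table = pipeline.wave_metrics_table(decomposition, mask)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(
    "\nwave 0 is the standing wave: ~35% of the variance, f_n near the simulated"
    "\n0.3 Hz, damping near xi = 0.05 (Q = 10), and low circular variance"
    "\n(coherent phase). Waves 1-2 are the traveling waves (simulated at 1.2 and"
    "\n3.0 Hz) with high circular variance; later components are noise."
)
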