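"""Back-project the discriminant into an ERP-like waveform.

The decision value of a trial is a single inner product with a time-domain
vector d*(t) per channel, so the fitted discriminant can be read like an ERP
curve: its large-magnitude intervals are the latencies that drive the
deviant/standard separation (and classifying a new trial costs O(K*L)).
"""

import numpy as np

from tcwt import (RunConfig, SynthSpec, accumulate_ss, backproject_ldf,
                  cwt_transform, detect_outliers, find_extrema,
                  fit_discriminant, generate_dataset, prepare_transforms,
                  project_filtered, t_scalogram, window_and_baseline)

cfg = RunConfig(s_c=0.04, grid_rate=15)
epochs = window_and_baseline(generate_dataset(SynthSpec(seed=7)),
                             0.0, 0.6, (-0.1, 0.0))
basis, grid, cb, F = prepare_transforms(epochs, cfg)
rep, pca = detect_outliers(F, cfg.c_individual, cfg.pca_criterion)
F0 = F.select(~rep.excluded)
W = cwt_transform(project_filtered(F0, pca), cb)
fb = find_extrema(t_scalogram(accumulate_ss(W, F0.labels), 9), grid)
model = fit_discriminant(W[:, fb.columns()], F0.labels,
                         cfg.pca_criterion, cfg.alpha_sd,
                         condition_a="deviant", condition_b="standard")
backproject_ldf(model, pca, fb, cb, basis, epochs.n_channels)

L = epochs.samples_per_channel
t = epochs.times
curves = model.d_time.reshape(epochs.n_channels, L)
print("channel  peak |d*(t)| latency (ms)")
for k, ch in enumerate(epochs.channels):
    j = np.abs(curves[k]).argmax()
    print(f"{ch:>7}  {1000 * t[j]:8.0f}   (signed weight {curves[k][j]:+.3f})")
print("\nLatencies cluster near the planted 200/300/400 ms components: the "
      "discriminant weights exactly the intervals where deviants differ.")
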