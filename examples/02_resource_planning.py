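"""Plan a study's computational budget before touching any data.

The exact matrix-element counts of the principal-component stage (N_P) and
the wavelet stage (N_W) follow from the channel count K, window length T,
cutoff scale S_c and log-grid rate R alone; with ~8 bytes and ~1 µs per
element they translate into memory and time estimates without building a
single matrix.
"""

from tcwt import estimate_demands

for K, T, s_c, R in [(64, 1.0, 0.05, 15), (9, 0.6, 0.04, 15)]:
    r = estimate_demands(K, T, s_c, R)
    print(f"K={K}, T={T}s, S_c={s_c * 1000:.0f}ms, R={R}:")
    print(f"  {r}")
print("\nN_F/N_G are the per-channel frequency and scale-time grid sizes; "
      "the approximations in parentheses are the closed forms 4T/S_c, "
      "3R^2T/S_c, 32K^2T^2/S_c^2 and 12KR^2T^2/S_c^2.")
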