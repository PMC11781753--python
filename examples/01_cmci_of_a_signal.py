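"""Compute the CMCI of a single series and unpack its provenance.

Builds two 30 s signals sampled at 100 Hz — a clean two-tone sway and the
same sway buried in broadband noise at 0 dB SNR — and prints the CMCI of
each with the per-IMF breakdown.  The noisy signal should come out far
more "complex": higher sample entropy of the analytic amplitude and phase
of its fast modes.
"""

import numpy as np

from cmci import compute_cmci

fs = 100.0
t = np.arange(3000) / fs
clean = np.sin(2 * np.pi * 0.4 * t) + 0.7 * np.sin(2 * np.pi * 2.1 * t)
rng = np.random.default_rng(0)
noise = rng.standard_normal(t.size)
noise *= np.std(clean) / np.std(noise)  # SNR 0 dB

for name, sig in [("clean two-tone sway", clean),
                  ("same sway + 0 dB broadband noise", clean + noise)]:
    res = compute_cmci(sig, sample_rate=fs)
    print(f"{name}: CMCI = {res.cmci:.3f}")
    print(f"  {res.n_imfs_total} IMFs, retained {res.retained_indices}")
    for i, (sa, sp, tc) in enumerate(zip(res.se_amplitude, res.se_phase,
                                         res.total_complexity)):
        print(f"  IMF {res.retained_indices[i] + 1}: SE_amp={sa:.3f} "
              f"SE_phase={sp:.3f} total={tc:.3f}")

print("\nThe CMCI is the mean of the per-IMF total complexities; a larger "
      "value means less predictable amplitude/phase dynamics across scales.")
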