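"""Striation quantification: recover filament lengths from noisy profiles.

Builds three synthetic myofibril profiles with known geometry — Z-disc
bands at the larval 8.5 um spacing, a titin N/C band pair at 2.1 um, and
an A-band block of 3.2 um — and recovers each length with the
autocorrelation / cross-correlation / sub-pixel fitting pipeline.
"""

import numpy as np

from sarcokit.profiles import analyze_profile, compute_metrics
from sarcokit.synth import PatternSpec, gen_profile

# Z-disc channel: one band per Z-disc, 8.5 um apart, SNR 10
pat = PatternSpec("single_band")
prof, _ = gen_profile(pat, period=8.5, n_sarcomeres=40, pixel_size=0.1,
                      psf_sigma=0.3, noise_sd=0.1, seed=1)
an = analyze_profile(prof, pat)
print(f"Z-disc channel: period = {an.period.period:.3f} um "
      f"over {len(an.segments)} segments (planted 8.5)")

# titin span: band pair symmetric about each Z-disc, 2.1 um apart
pat2 = PatternSpec("band_pair", pair_separation=2.1)
prof2, _ = gen_profile(pat2, period=8.5, n_sarcomeres=40, pixel_size=0.1,
                       psf_sigma=0.3, noise_sd=0.1, seed=2)
an2 = analyze_profile(prof2, pat2)
seps = an2.pair_separations()
print(f"titin N-to-C span: {np.mean(seps):.3f} +/- {np.std(seps):.3f} um "
      f"(planted 2.1)")

# A-band channel: 3.2 um block per sarcomere
pat3 = PatternSpec("block", block_width=3.2)
prof3, _ = gen_profile(pat3, period=8.5, n_sarcomeres=40, pixel_size=0.1,
                       psf_sigma=0.3, noise_sd=0.1, seed=3)
an3 = analyze_profile(prof3, pat3)
blocks = an3.block_lengths()
print(f"A-band length: {np.mean(blocks):.3f} +/- {np.std(blocks):.3f} um "
      f"(planted 3.2)")

m = compute_metrics(z_positions=an.band_positions(), block_lengths=blocks,
                    pair_separations=seps)
s = m.summary
print("\nderived per-sarcomere metrics:")
print(f"  sarcomere length {s['sarcomere_length']['mean']:.2f} um, "
      f"I-band = sarcomere - A-band = {s['i_band_length']['mean']:.2f} um")
print(f"  A-band/sarcomere = {s['ratio_a_band_sarcomere']:.3f}, "
      f"Sls-span/sarcomere = {s['ratio_sls_sarcomere']:.3f}")
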