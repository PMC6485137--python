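"""Plant a known divergence on a duplicate pair and recover it with NG86.

Evolves a 500-codon CDS into two copies at Ks = 0.2 with ω = 0.3
(purifying selection), estimates Ka/Ks back with Nei–Gojobori site
counting + Jukes–Cantor correction, and shows Ks-peak finding and WGD-era
assignment on a bimodal sample.
"""

import numpy as np

from genefam.kaks import (
    CodonAlignment,
    assign_wgd_era,
    compute_kaks,
    ks_distribution_peaks,
)
from genefam.synthio import _random_codons, evolve_duplicate_pair

rng = np.random.default_rng(0)
cds = "".join(_random_codons(rng, 500))
a, b = evolve_duplicate_pair(cds, ks=0.2, omega=0.3, rng=rng)
al = CodonAlignment([(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)])
r = compute_kaks(al)
print(f"sites: S={r.S:.1f}, N={r.N:.1f}  differences: Sd={r.Sd:.2f}, Nd={r.Nd:.2f}")
print(f"Ka={r.Ka:.4f}  Ks={r.Ks:.4f}  omega={r.omega:.3f}  -> {r.selection_class}")
print(f"planted: Ks=0.2, omega=0.3  (estimates recover them within noise)")

era = assign_wgd_era(r.Ks)
print(f"WGD era for Ks={r.Ks:.3f}: {era.label} (interval {era.ks_interval})")

# bimodal Ks sample: one recent-WGD peak, one ancient-WGD peak
vals = np.concatenate([rng.normal(0.2, 0.05, 200), rng.normal(1.65, 0.15, 200)])
for p in ks_distribution_peaks(vals):
    if p.mass > 0.05:
        print(f"Ks density mode at {p.mode:.3f} holding {p.mass:.0%} of pairs")
# The two modes match the planted duplication eras: pairs in the low-Ks
# peak date to the recent WGD, the high-Ks peak to the ancient one.
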