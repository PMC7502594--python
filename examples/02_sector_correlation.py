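"""Stoma-sector correlation zeta(r) with a CSR null ensemble and bootstrap band.

zeta(r) = S(r)/<R(r)> - 1 compares the observed count of stomata at distance
r from the sector boundary with its expectation under uniform random
placement inside the same blade.  For a clustered pattern zeta is strongly
positive near the sector and decays toward 0; the 95% band comes from
case-resampling the observed distances.
"""

from space_stomata import (
    CotyledonMap,
    SyntheticPatternSpec,
    filter_sectors,
    generate_ensemble,
    generate_pattern,
    log_bins,
    sector_correlation,
    with_bootstrap_ci,
)
from space_stomata import synth_cotyledon, synth_sector

cot = synth_cotyledon(seed=1)
sector = synth_sector(20_000, cot, seed=2)
stomata = generate_pattern(SyntheticPatternSpec(kind="clustered", n=400, seed=3), cot, sector)
m = CotyledonMap(cotyledon=cot, sectors=[sector], stomata=stomata, label="clustered-demo")

kept = filter_sectors(m)  # area window 15,000-40,000 µm², 200 µm separation
ensemble = generate_ensemble(m.n_stomata, cot, n_sets=200, seed=4)
cf = with_bootstrap_ci(sector_correlation(m, kept, ensemble, log_bins(5, 2000, 24)), n_boot=500, seed=5)

print(f"{'r_mid (µm)':>10}  {'S':>5}  {'<R>':>7}  {'zeta':>7}  {'95% band':>18}")
for i in range(cf.n_bins):
    if cf.defined[i] and cf.R_expected[i] >= 3:
        print(
            f"{cf.r_mid[i]:>10.1f}  {cf.S[i]:>5.0f}  {cf.R_expected[i]:>7.2f}  "
            f"{cf.zeta[i]:>7.2f}  [{cf.ci_lo[i]:>7.2f}, {cf.ci_hi[i]:>7.2f}]"
        )
print("\nzeta >> 0 in the first bins: a several-fold excess of stomata near the")
print("sector. It decays through 0 and turns negative far out — this fully")
print("clustered demo pattern leaves the distant blade depleted. The distance at")
print("which zeta reaches 0 is the effective range of the sector's influence.")
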