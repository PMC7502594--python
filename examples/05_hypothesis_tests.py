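"""Indices and hypothesis tests on count data and density samples.

The stomatal index (percent of epidermal cells that are stomata) is compared
between groups with a Pearson chi-squared test on the 2x2 table; stomatal
density samples across cotyledons are compared with the Mann-Whitney U test
(no normality assumption) or Kruskal-Wallis for three or more genotypes.
"""

from space_stomata import ContingencyTable2x2, chi_square_2x2, kruskal_wallis, mann_whitney_u, stomatal_index

# stomatal index inside a peptide-overexpressing sector vs a control sector
si_ctrl = stomatal_index(stomata=28, non_stomatal=92)
si_ox = stomatal_index(stomata=9, non_stomatal=111)
print(f"stomatal index: control {si_ctrl:.1f}%, overexpressor {si_ox:.1f}%")

t = ContingencyTable2x2("control", "EPF1-ox", 28, 92, 9, 111)
stat, p = chi_square_2x2(t)
print(f"chi-squared (df=1, no correction): stat={stat:.3f}, p={p:.4f}")

# per-cotyledon densities (stomata/mm²), two genotypes
ctrl = [312.0, 280.5, 341.2, 295.0, 310.8, 327.4]
ox = [198.2, 210.0, 173.5, 225.1, 190.7, 205.3]
u, p = mann_whitney_u(ctrl, ox)
print(f"Mann-Whitney U (exact, n=6+6): U={u:.0f}, p={p:.4f}")

third = [250.1, 260.4, 248.8, 271.0, 255.2, 244.6]
h, p = kruskal_wallis(ctrl, ox, third)
print(f"Kruskal-Wallis (3 groups): H={h:.3f}, p={p:.4f}")
print("\nsmall p-values: the sector genotype shifts both index and density.")
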