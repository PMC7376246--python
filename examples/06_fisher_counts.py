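"""Exact Fisher test on small group-comparison counts.

Compares the fraction of brains with early tumor clusters between two
genotypes (8 of 14 vs 1 of 9) by exact hypergeometric enumeration, and
prints a multi-group proportion report.
"""

from karyoevo import CountTable2x2, fisher_exact_2x2, proportion_report

p = fisher_exact_2x2(CountTable2x2(8, 6, 1, 8))
print(f"8/14 (57.1%) vs 1/9 (11.1%): two-sided p = {p:.4f}"
      f" -> {'significant' if p < 0.05 else 'not significant'} at 0.05")

report = proportion_report({"groupA": (8, 14), "groupB": (1, 9),
                            "groupC": (4, 10)})
for label, frac in report.fractions.items():
    k, n = report.counts[label]
    print(f"{label}: {k}/{n} = {100 * frac:.1f}%")
for (g1, g2), pv in report.pairwise_p.items():
    print(f"  {g1} vs {g2}: p = {pv:.4f}")
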