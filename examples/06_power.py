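"""Closed-form power to detect a locus of given effect size.

How large a panel is needed to see a QTL explaining q of phenotypic
variance? Power follows the noncentral t distribution with noncentrality
2 sqrt(q/(1-q)) sqrt(n/4) at the genome-wide significance threshold.
"""

from crossvar import power_curve, qtl_power
from crossvar.power import ALPHA_ADDITIVE, ALPHA_INTERACTION, PowerQuery

for n in (100, 1000, 4000, 4390):
    p = qtl_power(PowerQuery(n=n, q=0.005, alpha=ALPHA_ADDITIVE))
    print(f"n={n:5d}: power {p:.3f} for a 0.5%-variance additive QTL")
# only panels in the thousands can see sub-percent effects at genome-wide
# stringency

p_int = qtl_power(PowerQuery(n=4390, q=0.008, alpha=ALPHA_INTERACTION))
print(f"n=4390: power {p_int:.3f} for a 0.8%-variance interaction")

table = power_curve([1000, 4000], [0.0025, 0.005, 0.01, 0.02], ALPHA_ADDITIVE)
print(table.round(3).to_string(index=False))
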