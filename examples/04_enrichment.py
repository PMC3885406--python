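"""Cancer-gene enrichment of disruptive variants, and the test's power.

First the one-sided Fisher's exact test on the bundled marginal counts of
the NSCLC screen (188 of 803 disruptive genes cancer-associated, against
1347 of 6462 genes overall), then a label simulation showing how the
p-value responds to a planted odds ratio.
"""

import numpy as np

from utrvar import published_tables as pub
from utrvar.benchmark import enrichment_power
from utrvar.enrichment import enrichment_from_counts

res = enrichment_from_counts(
    pub.N_DISRUPTIVE_CANCER_GENES,
    pub.N_DISRUPTIVE_GENES,
    pub.N_CANCER_GENES,
    pub.N_GENES_TOTAL,
)
print(f"2x2 table: a={res.table.a} b={res.table.b} c={res.table.c} d={res.table.d}")
print(f"cancer-gene fraction among disruptive genes: {res.observed_ratio:.1%}")
print(f"cancer-gene fraction in the whole universe:  {res.background_ratio:.1%}")
print(f"one-sided Fisher p = {res.p_one_sided:.3f}")
print("-> disruptive UTR variants concentrate modestly but significantly in cancer genes.\n")

for odds in (1.0, 3.0):
    p = enrichment_power(odds_ratio=odds, n_genes=500, n_seeds=50, rng=7)
    print(
        f"planted odds ratio {odds:.0f} at 500 genes: "
        f"median p = {np.median(p):.3f}, fraction p<0.05 = {np.mean(p < 0.05):.2f}"
    )
print("-> at odds ratio 3 the test detects the enrichment in most simulated cohorts.")
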