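"""Classify an SNV that destroys a canonical miRNA seed site.

The target carries a perfect 8mer-1a site (Watson-Crick match to miRNA
positions 2-8 plus an A opposite position 1).  The substitution breaks one
seed pair: the seed type vanishes, the duplex energy collapses above the
relaxed -5 kcal/mol cutoff, and the event is classified `destroy`.
"""

from utrvar import classify_site_change, find_seed_matches, scan_duplex, seed_change_filter
from utrvar.mirna import MirnaRecord, revcomp, strongest_differing_site

mir = MirnaRecord("mir-example", "ACGGACGGCACACCAACACCAA")
site = revcomp(mir.sequence[1:8]) + "A"  # seed match + 1a adenosine
wt = "CAACACCAACAACACCAAAC" + site + "CAACCA"
pos = wt.index(site) + 4  # an interior seed-pairing position (1-based)
mt = wt[: pos - 1] + "A" + wt[pos:]

wt_seeds = find_seed_matches(mir, wt)
mt_seeds = find_seed_matches(mir, mt)
print("seed matches WT:", [(m.type, m.site_end) for m in wt_seeds])
print("seed matches MT:", [(m.type, m.site_end) for m in mt_seeds])
print("seed-type change:", seed_change_filter(wt_seeds, mt_seeds))

wt_sites = scan_duplex(mir, wt)
mt_sites = scan_duplex(mir, mt)
pick = strongest_differing_site(wt_sites, mt_sites)
dg_wt, dg_mt, register, *_ = pick
print(f"strongest differing site at register {register}:")
print(f"  dG_WT  = {dg_wt:.2f} kcal/mol" if dg_wt is not None else "  dG_WT  = N/A")
print(f"  dG_SNV = {dg_mt:.2f} kcal/mol" if dg_mt is not None else "  dG_SNV = N/A")
print("class:", classify_site_change(dg_wt, dg_mt))
print("-> the wild type binds below -11 kcal/mol, the mutant site is gone: destroy.")
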