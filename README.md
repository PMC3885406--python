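# utrvar

Most variant-effect predictors look at protein-coding changes. `utrvar`
addresses the other side of the transcript: single-nucleotide variants
(SNVs) in the 5′ and 3′ untranslated regions of mRNAs, which can disrupt
post-transcriptional regulation in two ways this package models explicitly —

1. **Local RNA secondary structure.** For each SNV a window around the
   variant is folded into equilibrium base-pair probability matrices
   *P*<sup>WT</sup> and *P*<sup>MT</sup> (McCaskill-style partition
   function). Two measures compare them over every local region
   *[i, j]* of the window:

   - the length-normalized Euclidean distance
     *d* = √( Σ<sub>i≤k<l≤j</sub> (P<sup>WT</sup><sub>kl</sub> −
     P<sup>MT</sup><sub>kl</sub>)² ) / (j − i + 1), maximized over regions
     (**d_max**), and
   - the Pearson correlation *r* of the position-wise pairing profiles
     p<sub>k</sub> = Σ<sub>l</sub> P<sub>kl</sub>, minimized (**r_min**).

   Empirical p-values come from ranking the observed change against random
   single substitutions resampled in the same window; the d- and r-based
   candidate lists are each Benjamini–Hochberg corrected and fused.

2. **microRNA target sites.** Each SNV's 61-mer is screened against mature
   miRNAs for changes of canonical seed-match type (7mer-1a < 7mer-m8 <
   8mer-1a); changed pairs are re-scored with a seed-weighted
   complementarity alignment (relaxed cutoffs: score ≥ 45, duplex energy
   ≤ −5 kcal/mol) and a nearest-neighbor hybridization energy. The
   strongest site that differs between alleles is classified **create** /
   **destroy** / **alter** at a working threshold of −11 kcal/mol; alter
   events are ranked by the log-ratio *lr* = log₂(ΔG<sub>SNV</sub> /
   ΔG<sub>WT</sub>) and filtered at the mean |lr|; wild-type-supported
   sites must fall inside Ago CLIP clusters with biological complexity
   ≥ 2, and miRNAs must be expressed in the target tissue.

Genes carrying disruptive SNVs from either arm are tested for enrichment
among cancer-associated genes with a one-sided Fisher's exact test, at the
gene and at the SNV level.

Because the original tumor transcriptome variant calls are not
redistributable, the package ships a **synthetic-data generator** that
plants ground-truth signals — fold-verified stem-loop hairpins and
stem-breaking substitutions, seed sites that SNVs create/destroy/weaken,
CLIP clusters, and cancer labels at a configurable enrichment odds ratio —
so every stage is testable end to end with no downloads.

## Worked example

```python
>>> from utrvar.enrichment import enrichment_from_counts
>>> res = enrichment_from_counts(188, 803, 1347, 6462)
>>> round(res.p_one_sided, 3), round(res.observed_ratio, 3), round(res.background_ratio, 3)
(0.032, 0.234, 0.208)
```

188 of 803 genes carrying a disruptive UTR SNV are cancer-associated
(23.4%), against 1347 of 6462 genes overall (20.8%); the one-sided
Fisher's exact test puts the probability of an enrichment at least this
strong under the hypergeometric null at p = 0.032.

Scoring a structure-disrupting SNV (`python examples/02_structure_disruption.py`):

```
stem-breaking SNV at 36:
  d_max = 0.208 over region 35-44  (empirical p = 0.010)
  r_min = -0.148  (empirical p = 0.270)
flank SNV at 5:
  d_max = 0.000  (empirical p = 0.620)
```

The substitution in the stem melts the helix — the maximal region-wise
ensemble distance d_max = 0.208 is larger than that of 99 of 100 random
substitutions in the same window (p = 0.01) — while a substitution in the
unpaired flank leaves the ensemble untouched. The other `examples/`
scripts walk through folding, seed-site classification, enrichment power,
and a full synthetic-cohort pipeline run.

A thin CLI wraps the same pipeline:

```bash
utrvar simulate --seed 3 --out cohort/
utrvar demo --data-dir cohort/ --out run/ --seed 5 --flank-structure 60 --k-null 49
```

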