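# Methods

## Scope and model overview

`utrvar` predicts two consequences of a single-nucleotide substitution in
an mRNA untranslated region: a change of the local secondary-structure
ensemble, and a change of canonical microRNA target sites. Both arms work
in transcript coordinates (1-based, inclusive; BED-like inputs are 0-based
half-open on disk and converted on read), on RNA-alphabet sequences
(DNA input is transcribed on read). Every (transcript, SNV) pair is
analyzed independently; gene-level outputs collapse isoforms by gene
symbol and deduplicate SNVs as unique (gene, position, alleles) triples.

## Folding engine

Pair probabilities come from a McCaskill-style inside/outside dynamic
program over pseudoknot-free secondary structures under a simplified
nearest-neighbor model:

- allowed pairs: Watson–Crick plus GU/UG wobble;
- stacking free energies from a bundled 6×6 table (kcal/mol at 37 °C,
  symmetrized under strand flip);
- affine hairpin penalty `4.8 + 0.15·loop_len`, affine interior/bulge
  penalty `2.0 + 0.4·unpaired` with interior loops capped at 30 unpaired
  bases (the standard O(n³) restriction), and an affine multiloop term
  `3.4 + 0.4·branches` (the closing helix counts as a branch);
- minimum hairpin loop of 3 nt; temperature 310.15 K (RT ≈ 0.616
  kcal/mol); duplex initiation +4.1 kcal/mol for the intermolecular
  hybridization routine.

No dangling ends, terminal-AU penalties, or special tetraloops are
modeled: the analysis rests on *differences* between wild-type and mutant
ensembles of the same window, which this level of detail captures, and the
model is pluggable (all parameters load from a small TSV, including an
all-zero model under which probabilities reduce to uniform-ensemble
frequencies). Partition functions are rescaled per nucleotide with an
adaptive factor to stay inside double range on 401-nt windows. An
exhaustive enumeration oracle (sequences ≤ 20 nt) shares the identical
energy function; the test suite requires DP–enumeration agreement within
1e-9, so the dynamic program is exact with respect to its model by
construction.

The kernels are numba-compiled; a 401-nt window folds in ~0.3 s, a 61-nt
window in ~2 ms on one CPU.

## Structure-disruption scoring

For an SNV the window is ±200 nt by default (clipped at transcript ends;
windows containing ambiguity codes are skipped with a logged count). All
local regions of length ≥ 10 nt are scanned with 2-D prefix sums (O(n²)
for the full scan), maximizing the length-normalized Euclidean distance d
and minimizing the profile Pearson correlation r; regions with a
zero-variance profile slice are excluded from the r minimum; ties break to
the longer region, then the smaller start, so outputs are deterministic.

The empirical p-value ranks the observed d_max (and, mirrored, r_min)
among K random single substitutions drawn uniformly over window positions
and alternate bases, excluding the observed one, with the plus-one
convention p = (1 + #{null ≥ obs})/(K + 1). K defaults to 1000 (desk-scale
runs and the test suite use 49–199; K ≥ 19 is enforced so p < 0.1 is
resolvable). This same-window resampling null is exchangeable by
construction, hence exactly calibrated under the null — the suite verifies
KS distance < 0.1 from U(0,1) at 200 replicates — and it differs from
precomputed GC/length-binned random-sequence tables used by some tools;
the choice is recorded in run metadata.

The d- and r-based candidate lists are each Benjamini–Hochberg corrected
(step-up with cumulative minimum; pass = q ≤ 0.10) and downstream
candidates are the union. Confidence tiers: high if both p < 0.05, medium
if either p < 0.1. "Disruptive" for the integration stage defaults to
p < 0.1 on either measure plus overlap with a conserved-structure
interval (configurable to require the BH pass). Conserved overlap is
reported as round(100·|region ∩ interval| / |region|), best interval per
annotation source; the region length is the denominator (printed values
≤ 100 are consistent with either convention).

Linked-variant re-testing applies both substitutions of an LD pair to the
mutant window (partner must lie within the flank) and calls the haplotype
stabilizing when neither measure stays significant at p < 0.1 against the
single-substitution null — a conservative re-use of the same null rather
than a bespoke two-substitution null.

## Target-site scoring

Seed matches follow the canonical definitions: 8mer-1a (Watson–Crick
match to miRNA positions 2–8 plus A opposite position 1), 7mer-m8 (match
2–8), 7mer-1a (match 2–7 plus the 1a adenosine); GU pairs never count; at
one register only the strongest type is reported. The seed-change filter
keeps (SNV, miRNA) pairs whose multiset of (register, type) differs
between alleles.

Duplex scoring anchors an affine-gap complementarity alignment at every
register (target position opposite miRNA position 1), antiparallel,
with published-family constants: WC +5, GU +1, mismatch −3, gap open −9,
gap extend −4, and substitution scores opposite miRNA positions 2–8
multiplied by the seed scale (default 2, deliberately low so compensated
poor seeds survive). All alignment endpoints reaching the score cutoff at
a register are candidate interpretations; the one with the lowest
nearest-neighbor duplex energy (stacks over adjacent paired columns,
affine penalties for interior gaps, +4.1 initiation) defines the site.
Registers are stable across alleles for substitutions, so wild-type and
mutant sites pair one-to-one; among differing registers the site
minimizing min(ΔG_WT, ΔG_SNV) is retained and classified create / destroy
/ alter at −11 kcal/mol. The log-ratio lr = log₂(ΔG_SNV/ΔG_WT) (defined
for two negative energies; base 2 read from "ld", logarithmus dualis; the
sign convention is base-independent) feeds the alter filter, which keeps
|lr| strictly above the mean |lr| of the run's alter set; μ is computed
after the CLIP filter by default (the flow chart orders CLIP before final
selection) with a pre-CLIP mode available. The CLIP filter requires the
SNV inside an Ago cluster with biological complexity ≥ 2 for destroy/alter
and passes create through (no wild-type CLIP evidence can exist for a
site that only exists in the mutant). Expression and lung-cancer miRNA
memberships are annotated from plain ID lists.

## Enrichment

The one-sided Fisher's exact test is an upper-tail hypergeometric sum
implemented with log-factorials (exact against integer-combinatorics
enumeration on all tables with totals ≤ 30 in the tests, and against an
independent library implementation). Gene-level: disruptive = carries ≥ 1
structure candidate or final site change; SNV-level analogous with SNVs as
units. Degenerate tables (zero margin) return p = 1 with a warning.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 40 genes × 1 transcript, 5′/3′ UTRs of 100–160 and
700–900 nt, background GC uniform in 40–60%, 80 SNVs, 30 miRNAs of which
10 are planted and the rest are shuffled decoys).

Planted elements are **verified at generation time by running the actual
analysis primitives** (fold-and-check), not assumed:

- *Hairpins*: one perfect stem-loop per 3′ UTR (stem 8–12 bp, GC-biased;
  loop 4–6 nt), resampled until every stem pair carries > 0.55
  probability in the folded neighbourhood. Compact loops are used because
  the loop-proximal pairs carry the densest probability change — they
  drive the d signal — and because wide-loop GC helices absorb a single
  mismatch, which would make a "stem-break" label false.
- *Stem-break SNVs*: candidate substitutions over stem positions are
  folded and the deepest melt kept, requiring the mean loop-proximal pair
  probability to drop below 0.2 in the mutant.
- *Seed sites*: planted miRNAs have moderate-GC seeds resampled until the
  seed-only duplex clears −11.5 kcal/mol while every interior single-pair
  break rises above −4.7 kcal/mol; miRNA positions 1 and 9+ and the
  site's flanking pads are drawn from {A, C}, which cannot pair with each
  other, confining planted duplexes to the seed (plus an explicit
  3′-supplementary block for alter events, which break the m8 pair so
  both alleles stay bound). Each planted substitution is verified against
  the duplex scanner: the intact allele must carry a ≤ −11 site, the
  broken allele none.
- *LD pairs*: compensatory partners restore the broken stem pair and are
  kept only if the double mutant's d_max falls below 0.05; neutral
  partners sit 40 nt away and must leave ≥ 80% of the single-mutant
  d_max.
- *Annotations*: conserved intervals cover planted hairpins; CLIP
  clusters cover wild-type-supported planted sites with probability 0.9
  and BC drawn from {1..4}; cancer labels are Bernoulli with the base
  rate solved (bisection) so the cohort hits the target cancer fraction
  at the configured enrichment odds ratio.

Everything is deterministic given the seed, and `truth.tsv` suffices to
score stage-wise sensitivity and specificity without re-reading sequences.

**What the generator does not emulate**: dinucleotide composition and
repeat structure of real UTRs, sequencing error and allele frequencies,
germ-line/somatic mixtures, isoform complexity beyond shared gene symbols,
and miRNA 3′-pairing beyond the planted supplementary blocks. Passing
recovery tests therefore demonstrates that the pipeline detects the
signals it models, under its own folding model — not field performance on
tumor transcriptomes.

## Problem sizes and evaluation settings

Synthetic evaluations use windows of ±60 nt (the planted elements span
< 40 nt, so the window carries the whole element plus background) and
K = 49 null substitutions; null calibration uses 61-nt windows with
K = 199 and 200 replicates; enrichment power uses 500 genes × 50 label
draws at a disruptive fraction of 0.124 and cancer fraction 0.20. These
sizes are the package's desk-scale study conditions; all thresholds
(p < 0.1, high-confidence 0.05, FDR 0.10, score 45, energy −5, −11
kcal/mol, scale 2, BC ≥ 2, ±200/±30 nt production windows) are the
published defaults and live in `RunConfig`.

## Known limitations

- The simplified energy model ranks ensemble *changes* reliably (exact
  against enumeration) but its absolute probabilities differ from a full
  Turner-parameter engine; a full-parameter backend can be swapped in
  behind `EnergyModel` without touching downstream contracts.
- The anchored-register alignment does not model miRanda's full position
  weighting; constants are configurable.
- The empirical null resamples substitutions within the same window, so
  p-values measure "is this substitution unusual *for this window*";
  windows that are globally fragile yield conservative p-values for any
  single variant.
- Multi-mapping SNVs across isoform sets larger than one gene are not
  deduplicated across genes; headline counts use unique (gene, SNV)
  pairs, noted in run metadata.
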