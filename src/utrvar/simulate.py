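"""Synthetic transcripts, SNVs, miRNAs and annotations with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
mRNAs with 5'/3' UTRs at 40-60% GC, perfect stem-loop hairpins planted at
recorded positions (with matching conserved-structure intervals), SNVs that
either break a planted stem pair or fall in unstructured background, seed
sites that SNVs create / destroy / weaken, CLIP clusters covering planted
wild-type sites, and a cancer-gene labelling with a configurable enrichment
odds ratio.  Everything is deterministic given the seed, and the truth
ledger suffices to score stage-wise sensitivity and specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AnnotationBundle,
    ClipCluster,
    ConservedInterval,
    SnvRecord,
    TranscriptRecord,
    classify_utr,
    write_clip_bed,
    write_conserved_bed,
    write_gene_list,
    write_snvs,
    write_transcripts,
)
from .enrichment import EnrichmentResult, enrichment_from_counts
from .mirna import MirnaRecord, revcomp, write_mirnas

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_genes: int = 40
    transcripts_per_gene: int = 1
    utr5_len: tuple[int, int] = (100, 160)
    cds_len: tuple[int, int] = (150, 250)
    utr3_len: tuple[int, int] = (700, 900)
    gc_range: tuple[float, float] = (0.40, 0.60)
    n_snvs: int = 80
    fraction_structural_positives: float = 0.25
    fraction_site_create: float = 0.125
    fraction_site_destroy: float = 0.125
    fraction_site_alter: float = 0.125
    n_mirnas: int = 30
    n_planted_mirnas: int = 10
    mirna_length: int = 22
    stem_len: tuple[int, int] = (8, 12)
    loop_len: tuple[int, int] = (4, 6)
    plant_margin: int = 50
    cancer_gene_fraction: float = 0.20
    planted_enrichment_odds: float = 1.0
    clip_coverage_prob: float = 0.9
    bc_values: tuple[int, ...] = (1, 2, 3, 4)
    bc_weights: tuple[float, ...] = (0.15, 0.35, 0.30, 0.20)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fr = (
            self.fraction_structural_positives
            + self.fraction_site_create
            + self.fraction_site_destroy
            + self.fraction_site_alter
        )
        if not 0 <= fr <= 1:
            raise ValueError("event fractions must be in [0, 1] and sum to <= 1")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")


@dataclass
class PlantedHairpin:
    transcript_id: str
    start: int  # 1-based transcript coordinate of the first stem base
    end: int
    stem_len: int
    loop_len: int

    @property
    def stem_pairs(self) -> list[tuple[int, int]]:
        """Transcript-coordinate (5', 3') base pairs of the planted stem."""
        return [
            (self.start + k, self.end - k) for k in range(self.stem_len)
        ]


@dataclass
class PlantedSite:
    transcript_id: str
    mirna_id: str
    start: int  # 1-based transcript span of the planted site (WT frame)
    end: int
    kind: str  # create / destroy / alter


@dataclass
class SyntheticLedger:
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    planted_mirnas: list[MirnaRecord] = field(default_factory=list)
    ld_kinds: list[str] = field(default_factory=list)  # aligned with ld_pairs
    truth: pd.DataFrame | None = None


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    transcripts: list[TranscriptRecord]
    snvs: list[SnvRecord]
    mirnas: list[MirnaRecord]
    annotations: AnnotationBundle
    ledger: SyntheticLedger

    def truth_label(self, snv: SnvRecord) -> str:
        t = self.ledger.truth
        row = t[(t.transcript_id == snv.transcript_id) & (t.snv == snv.token)]
        return row.label.iloc[0]

    def write(self, outdir) -> None:
        """Emit the exact on-disk formats the readers consume plus truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_transcripts(
            self.transcripts, outdir / "transcripts.fa", outdir / "utr_table.tsv"
        )
        write_snvs(self.snvs, outdir / "snvs.tsv")
        write_mirnas(self.mirnas, outdir / "mirnas.fa")
        write_conserved_bed(
            self.annotations.conserved_intervals, outdir / "conserved.bed"
        )
        write_clip_bed(self.annotations.clip_clusters, outdir / "clip_clusters.bed")
        write_gene_list(self.annotations.cancer_genes, outdir / "cancer_genes.txt")
        write_gene_list(
            self.annotations.expressed_mirnas, outdir / "expressed_mirnas.txt"
        )
        write_gene_list(
            self.annotations.lung_cancer_mirnas, outdir / "lung_cancer_mirnas.txt"
        )
        self.ledger.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.annotations.ld_pairs:
            rows = [
                dict(
                    transcript_id=s.transcript_id,
                    snv=s.token,
                    partner_position=pos,
                    partner_ref=ref,
                    partner_alt=alt,
                )
                for s, pos, ref, alt in self.annotations.ld_pairs
            ]
            pd.DataFrame(rows).to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGU"), size=length, p=p))


def _make_hairpin(rng: np.random.Generator, stem_len: int, loop_len: int) -> str:
    """Perfect stem-loop, GC-biased stem so the helix dominates the ensemble."""
    left = "".join(
        rng.choice(list("GCAU"), p=[0.35, 0.35, 0.15, 0.15]) for _ in range(stem_len)
    )
    loop = _random_seq(rng, loop_len, 0.3)
    right = "".join(_COMP[b] for b in reversed(left))
    return left + loop + right


def _seed_duplex_energy(seed: str, broken: int | None = None) -> float:
    """Duplex energy of a seed-only site (miRNA positions 2-8 paired), with
    an optional broken pair at seed position ``broken`` (2-8)."""
    from .rna_folding import DEFAULT_MODEL, duplex_energy

    cols: list[tuple[str | None, str | None]] = []
    for j, b in enumerate(seed, start=2):
        cols.append((b, "X" if j == broken else _COMP[b]))
    # an impossible base marks the broken column; replace by a real
    # non-pairing base for the energy routine
    cols = [
        (mb, ("A" if mb in "ACG" else "C") if tb == "X" else tb) for mb, tb in cols
    ]
    return duplex_energy(cols, DEFAULT_MODEL)


def _make_planted_mirna(rng: np.random.Generator, length: int, idx: int) -> MirnaRecord:
    """Mature miRNA whose seed supports the planted site semantics.

    The seed (positions 2-8) is resampled until a seed-only duplex clears
    the -11 kcal/mol working threshold while every interior single-pair
    break pushes it above the -5 kcal/mol relaxed cutoff, so destroy /
    create plants behave as labelled.  Positions 1 and 9+ are drawn from
    {A, C}, which can pair with neither the A/C-rich site padding nor the
    1a adenosine, keeping planted duplexes confined to the seed (plus the
    explicitly planted 3'-supplementary block for alter events).
    """
    for _ in range(1000):
        seed = "".join(
            rng.choice(list("GCAU"), p=[0.3, 0.3, 0.2, 0.2]) for _ in range(7)
        )
        if _seed_duplex_energy(seed) > -11.5:
            continue
        if min(_seed_duplex_energy(seed, broken=p) for p in range(3, 8)) < -4.7:
            continue
        break
    else:
        raise RuntimeError("could not sample a seed satisfying the energy windows")
    first = str(rng.choice(["A", "C"]))
    rest = "".join(rng.choice(["A", "C"]) for _ in range(length - 8))
    return MirnaRecord(f"sim-miR-{idx + 1}", first + seed + rest)


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    lo: int,
    hi: int,
    length: int,
    margin: int,
    tries: int = 400,
) -> int | None:
    """Random start in [lo, hi] for an interval of ``length`` that keeps
    ``margin`` nt clear of every occupied interval."""
    if hi - length + 1 < lo:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi - length + 2))
        end = start + length - 1
        if all(end + margin < s or start - margin > e for s, e in occupied):
            occupied.append((start, end))
            return start
    return None


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def simulate_transcripts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptRecord], SyntheticLedger, dict]:
    """Generate transcripts with planted hairpins and seed sites.

    Returns the transcripts, the ledger of planted elements, and the
    internal placement state consumed by :func:`simulate_snvs`.
    """
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    ledger = SyntheticLedger()
    ledger.planted_mirnas = [
        _make_planted_mirna(rng, config.mirna_length, i)
        for i in range(config.n_planted_mirnas)
    ]

    n_break = round(config.n_snvs * config.fraction_structural_positives)
    n_create = round(config.n_snvs * config.fraction_site_create)
    n_destroy = round(config.n_snvs * config.fraction_site_destroy)
    n_alter = round(config.n_snvs * config.fraction_site_alter)
    site_plan = (
        [("destroy", k) for k in range(n_destroy)]
        + [("create", k) for k in range(n_create)]
        + [("alter", k) for k in range(n_alter)]
    )

    transcripts: list[TranscriptRecord] = []
    state = {
        "occupied": {},  # transcript_id -> list of occupied (start, end) in utr3
        "site_snvs": [],  # (tid, pos, ref, alt, label, mirna_id)
        "attempts": {},  # site_plan index -> placement attempts so far
        "n_break": n_break,
        "n_neutral": config.n_snvs - n_break - len(site_plan),
    }
    site_cursor = 0
    for g in range(config.n_genes):
        gene = f"GENE{g:03d}"
        for t in range(config.transcripts_per_gene):
            tid = f"NM_SIM{g:03d}{t}"
            u5 = int(rng.integers(*config.utr5_len))
            cds = int(rng.integers(*config.cds_len))
            u3 = int(rng.integers(*config.utr3_len))
            gc = float(rng.uniform(*config.gc_range))
            seq = list(_random_seq(rng, u5 + cds + u3, gc))
            utr3_lo, utr3_hi = u5 + cds + 1, u5 + cds + u3
            occupied: list[tuple[int, int]] = []

            # one perfect hairpin per 3' UTR, fold-checked so every stem
            # pair dominates the local ensemble (prob > 0.5)
            stem = int(rng.integers(*config.stem_len))
            loop = int(rng.integers(*config.loop_len))
            start = _place(
                rng,
                occupied,
                utr3_lo + config.plant_margin,
                utr3_hi - config.plant_margin,
                2 * config.stem_len[1] + config.loop_len[1],
                config.plant_margin,
            )
            if start is None:
                raise RuntimeError(f"{tid}: 3' UTR too short for the hairpin plant")
            hp = None
            for _ in range(20):
                hp_seq = _make_hairpin(rng, stem, loop)
                trial = list(seq)
                trial[start - 1 : start - 1 + len(hp_seq)] = hp_seq
                cand = PlantedHairpin(tid, start, start + len(hp_seq) - 1, stem, loop)
                if _hairpin_folds(trial, cand):
                    seq[:] = trial
                    hp = cand
                    break
            if hp is None:
                raise RuntimeError(f"{tid}: could not plant a stably folding hairpin")
            ledger.hairpins.append(hp)

            # planted seed sites (round-robin over transcripts)
            while site_cursor < len(site_plan):
                kind, k = site_plan[site_cursor]
                # rotate through planted miRNAs on repeated failures (some
                # seed contexts admit no clean breaking substitution)
                attempt = state["attempts"].get(site_cursor, 0)
                state["attempts"][site_cursor] = attempt + 1
                mir = ledger.planted_mirnas[
                    (site_cursor + k + attempt) % len(ledger.planted_mirnas)
                ]
                placed = _plant_site(
                    rng, seq, occupied, utr3_lo, utr3_hi, config, tid, mir, kind, ledger, state
                )
                if not placed:
                    break  # this UTR is full; continue on the next transcript
                site_cursor += 1
                if rng.random() < 0.5:
                    break  # spread sites over transcripts
            state["occupied"][tid] = occupied
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene=gene,
                    sequence="".join(seq),
                    utr5=(1, u5),
                    utr3=(utr3_lo, utr3_hi),
                )
            )
    if site_cursor < len(site_plan):
        raise RuntimeError("not enough UTR room to plant all requested sites")
    return transcripts, ledger, state


def _plant_site(
    rng, seq, occupied, utr3_lo, utr3_hi, config, tid, mir, kind, ledger, state
) -> bool:
    """Embed one seed site and record the SNV that creates/destroys/alters it."""
    m = mir.sequence
    seed_site = revcomp(m[1:8]) + "A"  # positions opposite miRNA 8..2, then 1a
    # A/C buffer pads: the anchored alignment can reach ~20 nt past the seed,
    # and A/C target bases cannot pair with the A/C-only miRNA 3' region, so
    # the planted duplex stays confined to the seed (+ supplementary block)
    pad5 = "".join(rng.choice(["A", "C"]) for _ in range(20))
    pad3 = "".join(rng.choice(["A", "C"]) for _ in range(6))
    if kind == "alter":
        # 3'-supplementary pairing keeps both alleles bound below -11
        supp = revcomp(m[11:19])
        spacer = "".join(rng.choice(["A", "C"]) for _ in range(2))
        site = pad5 + supp + spacer + seed_site + pad3
    else:
        site = pad5 + seed_site + pad3
    start = _place(
        rng,
        occupied,
        utr3_lo + config.plant_margin,
        utr3_hi - config.plant_margin,
        len(site),
        config.plant_margin,
    )
    if start is None:
        return False
    end = start + len(site) - 1
    site_chars = list(site)
    # 0-based offsets of the 1a adenosine and the first seed-pairing base
    # (the base opposite miRNA position 8) within the padded site
    a1_off = len(site) - len(pad3) - 1
    seed_offset = a1_off - 7
    plant = _choose_site_snv(rng, mir, site_chars, seed_offset, kind)
    if plant is None:
        return False
    site_chars, pos_in_site, ref, alt = plant
    snv = (tid, start + pos_in_site, ref, alt, f"site_{kind}", mir.mirna_id)
    seq[start - 1 : end] = site_chars
    ledger.sites.append(PlantedSite(tid, mir.mirna_id, start, end, kind))
    state["site_snvs"].append(snv)
    return True


def _choose_site_snv(rng, mir, site_chars, seed_offset, kind):
    """Pick the site substitution and verify the planted semantics with the
    actual duplex scanner (fold-and-check).

    destroy / create: the intact allele must carry a site at or below the
    -11 kcal/mol working threshold while the broken allele yields no site at
    all under the relaxed cutoffs; alter: both alleles must carry sites with
    differing energies, the stronger one at or below -11.  Returns
    (site_chars for the reference allele, SNV offset in the site, ref, alt)
    or None when no substitution satisfies the checks.
    """
    from .mirna import DEFAULT_PARAMS, scan_duplex

    def site_ok(chars) -> float | None:
        sites = scan_duplex(mir, "".join(chars), DEFAULT_PARAMS)
        return min((s.energy for s in sites), default=None)

    intact = site_ok(site_chars)
    if intact is None or intact > -11.0:
        return None
    if kind == "alter":
        # break the m8 pair (8mer-1a -> 7mer-1a); both alleles stay bound
        pos = seed_offset
        ref = site_chars[pos]
        for alt in _non_pairing_choices(rng, mir.sequence[6:9], ref):
            broken = site_chars.copy()
            broken[pos] = alt
            e = site_ok(broken)
            if e is not None and not math.isclose(e, intact):
                return site_chars, pos, ref, alt
        return None
    # destroy / create: break an interior seed pair (m7..m3)
    for k in rng.permutation(range(1, 6)):
        pos = seed_offset + int(k)
        mpos = 7 - int(k)  # 0-based miRNA index of the paired base
        context = mir.sequence[mpos - 1 : mpos + 2]
        cur = site_chars[pos]
        for alt in _non_pairing_choices(rng, context, cur):
            broken = site_chars.copy()
            broken[pos] = alt
            if site_ok(broken) is not None:
                continue  # the broken allele still binds; try another base
            if kind == "destroy":
                return site_chars, pos, cur, alt
            return broken, pos, alt, cur  # create: wild type is the broken allele
    return None


def _non_pairing_choices(rng, mir_bases: str, current: str) -> list[str]:
    """Bases that can form neither a Watson-Crick nor a GU pair with any of
    ``mir_bases`` and differ from ``current``, in random order."""
    forbidden = {current}
    for mb in mir_bases:
        forbidden.add(_COMP[mb])
        if mb == "G":
            forbidden.add("U")
        if mb == "U":
            forbidden.add("G")
    choices = [b for b in "ACGU" if b not in forbidden]
    rng.shuffle(choices)
    return choices


def _non_pairing_base(rng, mir_bases: str, current: str) -> str | None:
    choices = _non_pairing_choices(rng, mir_bases, current)
    return choices[0] if choices else None


def simulate_snvs(
    config: SimulationConfig,
    transcripts: list[TranscriptRecord],
    ledger: SyntheticLedger,
    state: dict,
    rng: np.random.Generator | None = None,
) -> list[SnvRecord]:
    """Place structural-positive, site-event and neutral SNVs; fill the truth
    ledger."""
    rng = np.random.default_rng(
        config.rng_seed + 1 if rng is None else rng
    )
    by_id = {t.transcript_id: t for t in transcripts}
    rows = []
    snvs: list[SnvRecord] = []

    # structural positives: a substitution verified (fold-and-check) to melt
    # the planted helix, i.e. the stem pair probabilities drop below 0.2
    hp_pool = list(ledger.hairpins)
    rng.shuffle(hp_pool)
    n_placed = 0
    for hp in hp_pool:
        if n_placed >= state["n_break"]:
            break
        tr = by_id[hp.transcript_id]
        pick = _choose_stem_break(tr, hp, rng)
        if pick is None:
            continue  # this helix absorbs any single mismatch; try another
        pos, ref, alt = pick
        snvs.append(_mk_snv(tr, pos, ref, alt, by_id))
        rows.append(
            dict(
                transcript_id=tr.transcript_id,
                snv=f"{ref}{pos}{alt}",
                label="stem_break",
                mirna_id="",
            )
        )
        n_placed += 1
    if n_placed < state["n_break"]:
        raise RuntimeError("could not place all stem-breaking SNVs")

    # site-event SNVs recorded during planting
    for tid, pos, ref, alt, label, mirna_id in state["site_snvs"]:
        tr = by_id[tid]
        assert tr.base(pos) == ref, "planted site bookkeeping error"
        snvs.append(_mk_snv(tr, pos, ref, alt, by_id))
        rows.append(
            dict(
                transcript_id=tid, snv=f"{ref}{pos}{alt}", label=f"{label}", mirna_id=mirna_id
            )
        )

    # neutral SNVs: unstructured background >= margin away from every plant
    n_neutral = state["n_neutral"]
    tr_cycle = list(transcripts)
    rng.shuffle(tr_cycle)
    placed = 0
    ci = 0
    guard = 0
    while placed < n_neutral:
        tr = tr_cycle[ci % len(tr_cycle)]
        ci += 1
        guard += 1
        if guard > 50 * n_neutral:
            raise RuntimeError("could not place neutral SNVs away from plants")
        occupied = state["occupied"].get(tr.transcript_id, [])
        span = tr.utr5 if rng.random() < 0.4 and tr.utr5 else tr.utr3
        pos = int(rng.integers(span[0], span[1] + 1))
        if any(s - config.plant_margin <= pos <= e + config.plant_margin for s, e in occupied):
            continue
        if any(
            s.transcript_id == tr.transcript_id and abs(s.position - pos) < 5
            for s in snvs
        ):
            continue
        ref = tr.base(pos)
        alt = str(rng.choice([b for b in "ACGU" if b != ref]))
        snvs.append(_mk_snv(tr, pos, ref, alt, by_id))
        rows.append(
            dict(
                transcript_id=tr.transcript_id,
                snv=f"{ref}{pos}{alt}",
                label="neutral",
                mirna_id="",
            )
        )
        placed += 1
    ledger.truth = pd.DataFrame(rows)
    return snvs


def _hairpin_folds(
    seq_chars: list[str], hp: PlantedHairpin, min_prob: float = 0.55, context: int = 40
) -> bool:
    """Fold the hairpin neighbourhood and require every planted stem pair to
    carry more than ``min_prob`` probability."""
    from .rna_folding import compute_pair_probabilities

    lo = max(1, hp.start - context)
    hi = min(len(seq_chars), hp.end + context)
    bpm = compute_pair_probabilities("".join(seq_chars[lo - 1 : hi]))
    return all(bpm.p[i - lo, j - lo] > min_prob for i, j in hp.stem_pairs)


def _choose_stem_break(
    tr: TranscriptRecord,
    hp: PlantedHairpin,
    rng: np.random.Generator,
    melt_below: float = 0.2,
    context: int = 45,
) -> tuple[int, str, str] | None:
    """Substitution in a planted stem verified to melt the helix.

    Folds the hairpin neighbourhood for candidate (position, alt) pairs,
    middle of the stem first, and returns the first whose mutant drops the
    mean planted stem pair probability below ``melt_below``; None when the
    helix absorbs every single mismatch.
    """
    from .rna_folding import compute_pair_probabilities

    lo = max(1, hp.start - context)
    hi = min(len(tr), hp.end + context)
    sub = tr.sequence[lo - 1 : hi]
    # the loop-proximal pairs carry the densest probability change, so the
    # melt is judged on them; candidates are tried middle-of-stem first and
    # the deepest melt wins
    proximal = hp.stem_pairs[-4:]
    order = sorted(range(hp.stem_len), key=lambda k: abs(k - (hp.stem_len - 1) / 2))
    best = None
    for k in order:
        pos5, pos3 = hp.stem_pairs[k]
        for pos, partner_pos in ((pos5, pos3), (pos3, pos5)):
            ref = tr.base(pos)
            alt = _non_pairing_base(rng, tr.base(partner_pos), ref)
            if alt is None:
                continue
            mt = list(sub)
            mt[pos - lo] = alt
            bpm = compute_pair_probabilities("".join(mt))
            residual = float(
                np.mean(
                    [
                        bpm.p[i - lo, j - lo]
                        for i, j in proximal
                        if (i, j) != (pos5, pos3)
                    ]
                )
            )
            if residual < melt_below and (best is None or residual < best[0]):
                best = (residual, pos, ref, alt)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _mk_snv(tr, pos, ref, alt, by_id) -> SnvRecord:
    snv = SnvRecord(tr.transcript_id, pos, ref, alt)
    label = classify_utr(snv, [tr])
    return SnvRecord(tr.transcript_id, pos, ref, alt, utr_label=label)


def simulate_mirnas_and_annotations(
    config: SimulationConfig,
    transcripts: list[TranscriptRecord],
    snvs: list[SnvRecord],
    ledger: SyntheticLedger,
    rng: np.random.Generator | None = None,
) -> tuple[list[MirnaRecord], AnnotationBundle]:
    """Materialize miRNAs (planted + shuffled decoys) and all annotations."""
    rng = np.random.default_rng(config.rng_seed + 2 if rng is None else rng)
    mirnas = list(ledger.planted_mirnas)
    n_decoys = max(0, config.n_mirnas - len(mirnas))
    for k in range(n_decoys):
        src = ledger.planted_mirnas[k % len(ledger.planted_mirnas)]
        shuffled = list(src.sequence)
        rng.shuffle(shuffled)
        mirnas.append(MirnaRecord(f"sim-miR-decoy-{k + 1}", "".join(shuffled)))

    ann = AnnotationBundle()
    # conserved intervals over planted hairpins, alternating source tags
    for i, hp in enumerate(ledger.hairpins):
        src = "cmfinder" if i % 2 == 0 else "rnaz"
        ann.conserved_intervals.setdefault(hp.transcript_id, []).append(
            ConservedInterval(hp.transcript_id, hp.start, hp.end, src)
        )
    # CLIP clusters over planted wild-type sites (destroy / alter only have
    # wild-type support)
    probs = np.asarray(config.bc_weights) / np.sum(config.bc_weights)
    ci = 0
    for site in ledger.sites:
        if site.kind == "create":
            continue
        if rng.random() > config.clip_coverage_prob:
            continue
        bc = int(rng.choice(config.bc_values, p=probs))
        pad = int(rng.integers(5, 20))
        ci += 1
        ann.clip_clusters.setdefault(site.transcript_id, []).append(
            ClipCluster(site.transcript_id, max(1, site.start - pad), site.end + pad, bc)
        )
    # expressed miRNAs: all planted plus half the decoys
    ann.expressed_mirnas = {m.mirna_id for m in ledger.planted_mirnas} | {
        m.mirna_id for m in mirnas[len(ledger.planted_mirnas) :: 2]
    }
    ann.lung_cancer_mirnas = {
        m.mirna_id for i, m in enumerate(ledger.planted_mirnas) if i % 2 == 0
    }
    # cancer-gene labelling with the planted enrichment odds
    truth = ledger.truth
    disruptive_tids = set(truth[truth.label != "neutral"].transcript_id)
    gene_of = {t.transcript_id: t.gene for t in transcripts}
    genes = sorted({t.gene for t in transcripts})
    disruptive_genes = {gene_of[tid] for tid in disruptive_tids}
    q = len(disruptive_genes) / len(genes)
    p0 = _solve_base_rate(config.cancer_gene_fraction, q, config.planted_enrichment_odds)
    p1 = _odds_to_prob(config.planted_enrichment_odds * _prob_to_odds(p0))
    for gene in genes:
        p = p1 if gene in disruptive_genes else p0
        if rng.random() < p:
            ann.cancer_genes.add(gene)

    # LD partners for structural positives: compensatory rescues (verified
    # to restore the wild-type ensemble) and neutral distant substitutions
    # (verified to leave the disruption in place); kinds are recorded in
    # the ledger
    breaks = truth[truth.label == "stem_break"]
    hp_by_tid = {hp.transcript_id: hp for hp in ledger.hairpins}
    by_tid = {t.transcript_id: t for t in transcripts}
    snv_by_key = {(s.transcript_id, s.token): s for s in snvs}
    n_comp = n_neut = 0
    for row in breaks.itertuples(index=False):
        if n_comp >= 3 and n_neut >= 3:
            break
        snv = snv_by_key[(row.transcript_id, row.snv)]
        tr = by_tid[row.transcript_id]
        hp = hp_by_tid[row.transcript_id]
        partner_pos = next(
            (j if snv.position == i else i)
            for i, j in hp.stem_pairs
            if snv.position in (i, j)
        )
        d_single = _double_mutant_dmax(tr, snv, None)
        if n_comp < 3:
            ref_p = tr.base(partner_pos)
            alt_p = _COMP[snv.alt]
            # restoring the pair must bring the ensemble back: tiny d
            if alt_p != ref_p and _double_mutant_dmax(
                tr, snv, (partner_pos, alt_p)
            ) < 0.05:
                ann.ld_pairs.append((snv, partner_pos, ref_p, alt_p))
                ledger.ld_kinds.append("compensatory")
                n_comp += 1
                continue
        if n_neut < 3:
            pos = snv.position + 40 if snv.position + 40 <= len(tr) else snv.position - 40
            ref_n = tr.base(pos)
            alt_n = str(rng.choice([b for b in "ACGU" if b != ref_n]))
            # the disruption must persist alongside the neutral partner
            if _double_mutant_dmax(tr, snv, (pos, alt_n)) > 0.8 * d_single:
                ann.ld_pairs.append((snv, pos, ref_n, alt_n))
                ledger.ld_kinds.append("neutral")
                n_neut += 1
    return mirnas, ann


def _double_mutant_dmax(
    tr: TranscriptRecord,
    snv: SnvRecord,
    partner: tuple[int, str] | None,
    flank: int = 60,
) -> float:
    """d_max of the SNV window with an optional partner substitution applied
    on top of the mutant allele."""
    from .rna_folding import compute_pair_probabilities
    from .structure import scan_local_regions

    from .core_io import extract_window

    window = extract_window(snv, tr, flank)
    mt = list(window.mt_seq)
    if partner is not None:
        pos, alt = partner
        off = pos - window.window_start
        if not 0 <= off < len(mt):
            return float("inf")
        mt[off] = alt
    bpm_wt = compute_pair_probabilities(window.wt_seq)
    bpm_mt = compute_pair_probabilities("".join(mt))
    d, _, _, _ = scan_local_regions(bpm_wt, bpm_mt)
    return d


def _prob_to_odds(p: float) -> float:
    return p / (1 - p)


def _odds_to_prob(o: float) -> float:
    return o / (1 + o)


def _solve_base_rate(target: float, q: float, odds_ratio: float) -> float:
    """Base cancer probability p0 such that the mixture hits the target
    fraction when disruptive genes get odds multiplied by ``odds_ratio``."""
    if math.isclose(odds_ratio, 1.0):
        return target

    def mix(p0: float) -> float:
        return q * _odds_to_prob(odds_ratio * _prob_to_odds(p0)) + (1 - q) * p0

    lo, hi = 1e-9, 1 - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mix(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """End-to-end synthetic cohort, deterministic for a given config seed."""
    config = config or SimulationConfig()
    transcripts, ledger, state = simulate_transcripts(config)
    snvs = simulate_snvs(config, transcripts, ledger, state)
    mirnas, ann = simulate_mirnas_and_annotations(config, transcripts, snvs, ledger)
    return SyntheticDataset(
        config=config,
        transcripts=transcripts,
        snvs=snvs,
        mirnas=mirnas,
        annotations=ann,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# label-only enrichment simulation (power / calibration studies)
# ---------------------------------------------------------------------------


def simulate_enrichment_labels(
    n_genes: int = 500,
    disruptive_fraction: float = 0.124,
    cancer_fraction: float = 0.2,
    odds_ratio: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentResult:
    """Draw disruptive/cancer gene labels at a planted odds ratio and run the
    gene-level Fisher test (no sequences involved)."""
    rng = np.random.default_rng(rng)
    n_disr = round(n_genes * disruptive_fraction)
    disruptive = np.zeros(n_genes, dtype=bool)
    disruptive[rng.choice(n_genes, size=n_disr, replace=False)] = True
    p0 = _solve_base_rate(cancer_fraction, n_disr / n_genes, odds_ratio)
    p1 = _odds_to_prob(odds_ratio * _prob_to_odds(p0))
    cancer = np.where(disruptive, rng.random(n_genes) < p1, rng.random(n_genes) < p0)
    return enrichment_from_counts(
        n_disruptive_cancer=int((disruptive & cancer).sum()),
        n_disruptive=int(disruptive.sum()),
        n_cancer=int(cancer.sum()),
        n_total=n_genes,
    )
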