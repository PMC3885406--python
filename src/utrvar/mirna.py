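"""Seed-match typing, duplex scoring and classification of miRNA target-site changes.

The cascade mirrors a two-method screen: a conservative seed-type filter
(canonical 7mer-1a / 7mer-m8 / 8mer-1a site definitions) selects
(SNV, miRNA) pairs whose seed match differs between alleles; those pairs are
re-scored with a complementarity alignment (seed-weighted, relaxed cutoffs)
and a nearest-neighbor duplex free energy; the strongest differing site is
classified as create / destroy / alter, and CLIP-cluster and expression
filters prune the candidate list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .core_io import (
    AnnotationBundle,
    ClipCluster,
    SnvRecord,
    TranscriptRecord,
    extract_window,
    normalize_rna,
)
from .rna_folding import DEFAULT_MODEL, EnergyModel, PAIR_TABLE, BASE_INDEX, duplex_energy

logger = logging.getLogger(__name__)

SEED_ORDER = {"none": 0, "7mer-1a": 1, "7mer-m8": 2, "8mer-1a": 3}

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA sequence, 5'->3'."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"{self.mirna_id}: mature miRNA shorter than 15 nt")
        if set(self.sequence) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: non-ACGU characters")


def read_mirnas(fasta_path) -> list[MirnaRecord]:
    return [
        MirnaRecord(entry.id, normalize_rna(str(entry.seq)))
        for entry in SeqIO.parse(str(fasta_path), "fasta")
    ]


def write_mirnas(mirnas: Sequence[MirnaRecord], fasta_path) -> None:
    with open(fasta_path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedMatch:
    """A canonical seed match; ``site_end`` is the 1-based target position
    opposite miRNA position 1 (the '1a' position)."""

    type: str
    site_end: int


def find_seed_matches(mirna: MirnaRecord, subseq: str) -> list[SeedMatch]:
    """All canonical seed matches of a miRNA in a target subsequence.

    At each register only the strongest of 8mer-1a > 7mer-m8 > 7mer-1a is
    reported; GU pairs never count as seed matches.
    """
    m = mirna.sequence
    rc2_8 = revcomp(m[1:8])  # pairs target positions site_end-7 .. site_end-1
    rc2_7 = revcomp(m[1:7])  # pairs target positions site_end-6 .. site_end-1
    n = len(subseq)
    out: list[SeedMatch] = []
    for r in range(7, n + 1):
        has_a1 = subseq[r - 1] == "A"
        m8 = r >= 8 and subseq[r - 8 : r - 1] == rc2_8
        if m8 and has_a1:
            out.append(SeedMatch("8mer-1a", r))
        elif m8:
            out.append(SeedMatch("7mer-m8", r))
        elif has_a1 and subseq[r - 7 : r - 1] == rc2_7:
            out.append(SeedMatch("7mer-1a", r))
    return out


def seed_change_filter(
    wt_matches: Iterable[SeedMatch], mt_matches: Iterable[SeedMatch]
) -> bool:
    """True iff the multiset of (register, type) differs between alleles."""
    return sorted((s.site_end, s.type) for s in wt_matches) != sorted(
        (s.site_end, s.type) for s in mt_matches
    )


# ---------------------------------------------------------------------------
# duplex scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MirandaParams:
    """Alignment constants for the seed-weighted complementarity scan."""

    scale: float = 2.0
    score_min: float = 45.0
    energy_relaxed: float = -5.0
    match: float = 5.0
    gu: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    max_bulge: int = 6  # extra target bases a site may consume beyond the miRNA


DEFAULT_PARAMS = MirandaParams()


@dataclass
class DuplexResult:
    """One scored site at one register."""

    register: int  # target position opposite miRNA position 1
    score: float
    energy: float
    target_span: tuple[int, int]  # 1-based inclusive on the subsequence
    columns: list[tuple[str | None, str | None]]  # (miRNA base, target base)


def _column_score(mb: str, tb: str, pos: int, params: MirandaParams) -> float:
    pt = PAIR_TABLE[BASE_INDEX[mb], BASE_INDEX[tb]]
    if pt < 0:
        s = params.mismatch
    elif pt >= 4:  # GU / UG wobble
        s = params.gu
    else:
        s = params.match
    if 2 <= pos <= 8:
        s *= params.scale
    return s


def _align_register(
    mirna_seq: str, subseq: str, register: int, params: MirandaParams
):
    """Anchored antiparallel alignment of the miRNA at one register.

    The alignment starts with miRNA position 1 opposite target position
    ``register`` and proceeds 5'->3' along the miRNA, 3'->5' along the
    target, with affine gaps; the 3' end of either strand may dangle.
    Returns a list of (score, columns, target_span) candidates, one per
    alignment endpoint whose score reaches ``params.score_min`` (strongest
    first, capped at 20); empty when the register yields no such alignment.
    """
    m = len(mirna_seq)
    tmax = register  # target positions register, register-1, ... are consumed
    kmax = min(tmax, m + params.max_bulge)
    if kmax < 1:
        return []
    neg = -math.inf
    # dp[state][i][k]: best score of an alignment consuming miRNA 1..i and
    # target register..register-k+1, ending in state M (column), X (target
    # gap: miRNA base unopposed) or Y (miRNA gap: target base unopposed)
    M = np.full((m + 1, kmax + 1), neg)
    X = np.full((m + 1, kmax + 1), neg)
    Y = np.full((m + 1, kmax + 1), neg)
    back: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    M[1][1] = _column_score(mirna_seq[0], subseq[register - 1], 1, params)
    for i in range(1, m + 1):
        for k in range(1, kmax + 1):
            if i == 1 and k == 1:
                continue
            tb = subseq[register - k]
            mb = mirna_seq[i - 1]
            # column state
            cands = [
                ("M", M[i - 1][k - 1]),
                ("X", X[i - 1][k - 1]),
                ("Y", Y[i - 1][k - 1]),
            ]
            st, val = max(cands, key=lambda c: c[1])
            if val > neg:
                M[i][k] = val + _column_score(mb, tb, i, params)
                back[("M", i, k)] = (st, i - 1, k - 1)
            # gap on target strand (miRNA base i unopposed)
            cands = [
                ("M", M[i - 1][k] + params.gap_open),
                ("X", X[i - 1][k] + params.gap_extend),
            ]
            st, val = max(cands, key=lambda c: c[1])
            if val > neg:
                X[i][k] = val
                back[("X", i, k)] = (st, i - 1, k)
            # gap on miRNA strand (target base unopposed)
            cands = [
                ("M", M[i][k - 1] + params.gap_open),
                ("Y", Y[i][k - 1] + params.gap_extend),
            ]
            st, val = max(cands, key=lambda c: c[1])
            if val > neg:
                Y[i][k] = val
                back[("Y", i, k)] = (st, i, k - 1)
    # alignments end in a column state (dangling ends are free); every
    # endpoint reaching score_min is a candidate site interpretation at
    # this register, and the caller keeps the lowest-energy one
    ends = []
    for i in range(1, m + 1):
        for k in range(1, kmax + 1):
            if math.isfinite(M[i][k]) and M[i][k] >= params.score_min:
                ends.append((M[i][k], i, k))
    if not ends:
        return []
    ends.sort(reverse=True)
    out = []
    for score, bi, bk in ends[:20]:
        cols: list[tuple[str | None, str | None]] = []
        node = ("M", bi, bk)
        while True:
            st, i, k = node
            if st == "M":
                cols.append((mirna_seq[i - 1], subseq[register - k]))
            elif st == "X":
                cols.append((mirna_seq[i - 1], None))
            else:
                cols.append((None, subseq[register - k]))
            if node not in back:
                break
            node = back[node]
        cols.reverse()
        out.append((score, cols, (register - bk + 1, register)))
    return out


def scan_duplex(
    mirna: MirnaRecord,
    subseq: str,
    params: MirandaParams = DEFAULT_PARAMS,
    model: EnergyModel = DEFAULT_MODEL,
) -> list[DuplexResult]:
    """Score candidate sites at every register of the subsequence.

    A site is reported only when its alignment score reaches
    ``params.score_min`` and its duplex free energy is at most
    ``params.energy_relaxed`` kcal/mol.
    """
    out: list[DuplexResult] = []
    for register in range(1, len(subseq) + 1):
        best = None
        for score, cols, span in _align_register(
            mirna.sequence, subseq, register, params
        ):
            energy = duplex_energy(cols, model)
            if energy > params.energy_relaxed:
                continue
            if best is None or energy < best.energy:
                best = DuplexResult(
                    register=register,
                    score=score,
                    energy=energy,
                    target_span=span,
                    columns=cols,
                )
        if best is not None:
            out.append(best)
    return out


# ---------------------------------------------------------------------------
# site-change classification
# ---------------------------------------------------------------------------

ENERGY_THRESHOLD = -11.0


@dataclass
class SiteChange:
    """A classified (SNV, miRNA) target-site event."""

    snv: SnvRecord
    mirna_id: str
    gene: str
    cls: str  # create / destroy / alter
    dg_wt: float | None
    dg_snv: float | None
    lr: float | None = None
    target_span: tuple[int, int] | None = None  # transcript coordinates
    register: int | None = None
    clip_pass: bool | None = None  # None = not applicable (create)
    mirna_expressed: bool = False
    lung_cancer_mirna: bool = False
    cancer_gene: bool = False
    passed_lr_filter: bool | None = None


def strongest_differing_site(
    wt_sites: Sequence[DuplexResult], mt_sites: Sequence[DuplexResult]
):
    """Retain the strongest site whose presence or energy differs by register.

    Sites are paired by register (the target position opposite miRNA
    position 1, stable across alleles for a substitution); among differing
    registers the one minimizing min(dG_wt, dG_snv) wins.  Returns
    (dG_wt | None, dG_snv | None, register, wt_site | None, mt_site | None)
    or None when no register differs.
    """
    wt_by_reg = {s.register: s for s in wt_sites}
    mt_by_reg = {s.register: s for s in mt_sites}
    best = None
    for reg in sorted(set(wt_by_reg) | set(mt_by_reg)):
        w = wt_by_reg.get(reg)
        m = mt_by_reg.get(reg)
        if w is not None and m is not None and math.isclose(w.energy, m.energy):
            continue
        dgw = w.energy if w is not None else None
        dgm = m.energy if m is not None else None
        key = min(x for x in (dgw, dgm) if x is not None)
        if best is None or key < best[0]:
            best = (key, dgw, dgm, reg, w, m)
    if best is None:
        return None
    _, dgw, dgm, reg, w, m = best
    return dgw, dgm, reg, w, m


def classify_site_change(
    dg_wt: float | None, dg_snv: float | None, threshold: float = ENERGY_THRESHOLD
) -> str | None:
    """create / destroy / alter classification of one site pair.

    create: site only in the mutant with dG_snv <= threshold;
    destroy: site only in the wild type with dG_wt <= threshold;
    alter: site in both with min(dG) <= threshold; else None.
    """
    if dg_wt is None and dg_snv is None:
        raise ValueError("at least one energy must be present")
    if dg_wt is None:
        return "create" if dg_snv <= threshold else None
    if dg_snv is None:
        return "destroy" if dg_wt <= threshold else None
    return "alter" if min(dg_wt, dg_snv) <= threshold else None


def log_ratio(dg_wt: float, dg_snv: float) -> float | None:
    """lr = log2(dG_snv / dG_wt) for two negative binding energies.

    Zero when the energy is unchanged, negative when the wild type binds
    more strongly (lower energy), positive otherwise; undefined (None)
    unless both energies are negative.
    """
    if dg_wt >= 0 or dg_snv >= 0:
        return None
    return math.log2(dg_snv / dg_wt)


def alter_mean_filter(alter_set: Sequence[SiteChange]):
    """Retain alter events with |lr| strictly above the set's mean |lr|.

    Returns (retained list, mu); an empty retained list with a logged
    warning when all |lr| are equal.
    """
    if not alter_set:
        raise ValueError("alter set is empty")
    abs_lr = [abs(s.lr) for s in alter_set if s.lr is not None]
    mu = float(np.mean(abs_lr)) if abs_lr else 0.0
    retained = [s for s in alter_set if s.lr is not None and abs(s.lr) > mu]
    for s in alter_set:
        s.passed_lr_filter = s.lr is not None and abs(s.lr) > mu
    if not retained:
        logger.warning("alter mean filter retained nothing (all |lr| equal)")
    return retained, mu


def clip_filter(
    site_change: SiteChange,
    clip_clusters: Sequence[ClipCluster],
    bc_min: int = 2,
) -> bool:
    """Ago CLIP cluster filter for wild-type-supported sites.

    destroy/alter events pass iff the SNV position lies inside a cluster
    with biological complexity >= ``bc_min``; create events cannot be
    checked against wild-type CLIP data and pass through (flag recorded as
    not applicable).
    """
    if site_change.cls == "create":
        site_change.clip_pass = None
        return True
    pos = site_change.snv.position
    ok = any(
        c.start <= pos <= c.end and c.bc >= bc_min
        for c in clip_clusters
        if c.transcript_id == site_change.snv.transcript_id
    )
    site_change.clip_pass = ok
    return ok


def expression_filter(site_change: SiteChange, expressed_set: set[str]) -> bool:
    """Pass iff the miRNA is in the tissue-expressed set."""
    if not expressed_set:
        logger.warning("expressed-miRNA set is empty; all miRNAs fail the filter")
    ok = site_change.mirna_id in expressed_set
    site_change.mirna_expressed = ok
    return ok


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


@dataclass
class MirnaPipelineResult:
    all_changes: list[SiteChange]
    final: list[SiteChange]
    stage_counts: dict[str, int]
    lr_mu: float | None


def run_mirna_pipeline(
    snvs: Sequence[SnvRecord],
    transcripts: Sequence[TranscriptRecord],
    mirnas: Sequence[MirnaRecord],
    annotations: AnnotationBundle,
    params: MirandaParams = DEFAULT_PARAMS,
    model: EnergyModel = DEFAULT_MODEL,
    flank: int = 30,
    energy_threshold: float = ENERGY_THRESHOLD,
    bc_min: int = 2,
    lr_filter_stage: str = "post_clip",
) -> MirnaPipelineResult:
    """Run the full target-site cascade and log per-stage counts.

    Stage order: seed-change filter -> duplex scan + strongest differing
    site -> create/destroy/alter classification -> CLIP filter
    (destroy/alter) -> alter |lr| mean filter -> expression filter.  Counts
    are monotonically non-increasing along the cascade.
    """
    if lr_filter_stage not in ("post_clip", "pre_clip"):
        raise ValueError("lr_filter_stage must be 'post_clip' or 'pre_clip'")
    by_id = {t.transcript_id: t for t in transcripts}
    counts: dict[str, int] = {
        "screen_pairs": len(mirnas) * len(snvs),
        "seed_change": 0,
        "classified": 0,
        "clip_pass": 0,
        "lr_pass": 0,
        "expressed": 0,
    }
    changes: list[SiteChange] = []
    for snv in snvs:
        tr = by_id.get(snv.transcript_id)
        if tr is None or snv.utr_label == "none":
            continue
        window = extract_window(snv, tr, flank)
        if set(window.wt_seq) - set("ACGU"):
            continue
        for mir in mirnas:
            wt_matches = find_seed_matches(mir, window.wt_seq)
            mt_matches = find_seed_matches(mir, window.mt_seq)
            if not seed_change_filter(wt_matches, mt_matches):
                continue
            counts["seed_change"] += 1
            wt_sites = scan_duplex(mir, window.wt_seq, params, model)
            mt_sites = scan_duplex(mir, window.mt_seq, params, model)
            pick = strongest_differing_site(wt_sites, mt_sites)
            if pick is None:
                continue
            dgw, dgm, reg, wsite, msite = pick
            cls = classify_site_change(dgw, dgm, energy_threshold)
            if cls is None:
                continue
            lr = log_ratio(dgw, dgm) if dgw is not None and dgm is not None else None
            site = wsite if wsite is not None else msite
            span = (
                window.to_transcript(site.target_span[0]),
                window.to_transcript(site.target_span[1]),
            )
            changes.append(
                SiteChange(
                    snv=snv,
                    mirna_id=mir.mirna_id,
                    gene=tr.gene,
                    cls=cls,
                    dg_wt=dgw,
                    dg_snv=dgm,
                    lr=lr,
                    target_span=span,
                    register=reg,
                    cancer_gene=tr.gene in annotations.cancer_genes,
                    lung_cancer_mirna=mir.mirna_id in annotations.lung_cancer_mirnas,
                )
            )
    counts["classified"] = len(changes)

    def apply_lr(pool: list[SiteChange]) -> tuple[list[SiteChange], float | None]:
        alters = [s for s in pool if s.cls == "alter"]
        if not alters:
            return pool, None
        retained, mu = alter_mean_filter(alters)
        kept = [s for s in pool if s.cls != "alter" or s in retained]
        return kept, mu

    mu = None
    pool = list(changes)
    if lr_filter_stage == "pre_clip":
        pool, mu = apply_lr(pool)
        counts["lr_pass"] = len(pool)
    pool = [
        s
        for s in pool
        if clip_filter(s, annotations.clip_clusters.get(s.snv.transcript_id, []), bc_min)
    ]
    counts["clip_pass"] = len(pool)
    if lr_filter_stage == "post_clip":
        pool, mu = apply_lr(pool)
        counts["lr_pass"] = len(pool)
    # record CLIP flags on discarded events too (informational)
    for s in changes:
        if s.clip_pass is None and s.cls != "create":
            clip_filter(s, annotations.clip_clusters.get(s.snv.transcript_id, []), bc_min)
    final = [s for s in pool if expression_filter(s, annotations.expressed_mirnas)]
    for s in changes:
        s.mirna_expressed = s.mirna_id in annotations.expressed_mirnas
    counts["expressed"] = len(final)
    return MirnaPipelineResult(
        all_changes=changes, final=final, stage_counts=counts, lr_mu=mu
    )
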