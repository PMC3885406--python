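"""Combine both pipeline arms and compute cancer-gene enrichment statistics.

The central statistic is a one-sided Fisher's exact test on a 2x2 table of
genes (or SNVs) carrying / not carrying a disruptive variant versus being
cancer-associated / other, evaluated in the enrichment direction (more
cancer genes among carriers than expected under the hypergeometric null).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import SnvRecord
from .mirna import SiteChange
from .structure import StructureResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = carries / does-not-carry a disruptive SNV,
    columns = cancer-associated / other."""

    a: int  # disruptive & cancer
    b: int  # disruptive & other
    c: int  # non-disruptive & cancer
    d: int  # non-disruptive & other

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    p_one_sided: float
    observed_ratio: float  # cancer fraction among carriers
    background_ratio: float  # cancer fraction in the whole universe


def _log_factorials(n: int) -> list[float]:
    return [math.lgamma(k + 1) for k in range(n + 1)]


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail hypergeometric probability of an association at least as
    strong as observed, computed with log-factorials.

    With a zero margin the test is undefined and p = 1 is returned with a
    warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.warning("degenerate contingency table (zero margin); p = 1")
        return 1.0
    lf = _log_factorials(n)
    log_norm = lf[r1] + lf[n - r1] + lf[c1] + lf[n - c1] - lf[n]
    k_max = min(r1, c1)
    total = 0.0
    for k in range(a, k_max + 1):
        # table with carriers-and-cancer = k under fixed margins
        kb, kc, kd = r1 - k, c1 - k, n - r1 - c1 + k
        if kb < 0 or kc < 0 or kd < 0:
            continue
        total += math.exp(log_norm - (lf[k] + lf[kb] + lf[kc] + lf[kd]))
    return min(total, 1.0)


def enrichment_from_counts(
    n_disruptive_cancer: int, n_disruptive: int, n_cancer: int, n_total: int
) -> EnrichmentResult:
    """Build the 2x2 from marginal counts and run the one-sided test."""
    a = n_disruptive_cancer
    b = n_disruptive - a
    c = n_cancer - a
    d = n_total - n_disruptive - c
    table = ContingencyTable(a, b, c, d)
    return EnrichmentResult(
        table=table,
        p_one_sided=fisher_one_sided(table),
        observed_ratio=a / n_disruptive if n_disruptive else 0.0,
        background_ratio=n_cancer / n_total if n_total else 0.0,
    )


def disruptive_structure_results(
    results: Sequence[StructureResult],
    p_cutoff: float = 0.1,
    require_conserved: bool = True,
    require_bh: bool = False,
) -> list[StructureResult]:
    """Structure-arm candidates: p < cutoff on either measure, overlapping a
    conserved-structure interval (optionally requiring the BH pass instead)."""
    out = []
    for res in results:
        sig = False
        for meas in (res.d, res.r):
            if meas.p_value is None:
                continue
            passes = (
                meas.q_value is not None and meas.q_value <= p_cutoff
                if require_bh
                else meas.p_value < p_cutoff
            )
            if passes and (not require_conserved or meas.conserved_overlap):
                sig = True
        if sig:
            out.append(res)
    return out


def gene_level_enrichment(
    structure_results: Sequence[StructureResult],
    site_changes: Sequence[SiteChange],
    cancer_genes: set[str],
    all_genes: Iterable[str],
) -> EnrichmentResult:
    """Gene-level enrichment of disruptive SNVs in cancer-associated genes.

    A gene is disruptive when it carries at least one structure-arm
    candidate or one final target-site change; the 2x2 is built over the
    supplied gene universe.
    """
    universe = set(all_genes)
    disruptive = {r.gene for r in structure_results} | {s.gene for s in site_changes}
    if not disruptive <= universe:
        raise ValueError("disruptive genes must be a subset of the gene universe")
    cancer_in_universe = cancer_genes & universe
    return enrichment_from_counts(
        n_disruptive_cancer=len(disruptive & cancer_in_universe),
        n_disruptive=len(disruptive),
        n_cancer=len(cancer_in_universe),
        n_total=len(universe),
    )


def snv_level_enrichment(
    all_snvs: Sequence[SnvRecord],
    disruptive_snvs: Sequence[SnvRecord],
    cancer_genes: set[str],
    gene_of: Mapping[str, str],
) -> EnrichmentResult:
    """As gene_level_enrichment with SNVs as the counting unit.

    ``gene_of`` maps transcript IDs to gene symbols; SNVs are deduplicated
    by (gene, position, alleles).
    """

    def key(s: SnvRecord):
        return (gene_of[s.transcript_id], s.position, s.ref, s.alt)

    universe = {key(s) for s in all_snvs}
    disruptive = {key(s) for s in disruptive_snvs}
    if not disruptive <= universe:
        raise ValueError("disruptive SNVs must be a subset of the input set")
    in_cancer = {k for k in universe if k[0] in cancer_genes}
    return enrichment_from_counts(
        n_disruptive_cancer=len(disruptive & in_cancer),
        n_disruptive=len(disruptive),
        n_cancer=len(in_cancer),
        n_total=len(universe),
    )


# ---------------------------------------------------------------------------
# stage intersection and recurrence summaries
# ---------------------------------------------------------------------------


def structure_mirts_overlap(
    structure_results: Sequence[StructureResult],
    site_changes: Sequence[SiteChange],
) -> list[tuple[StructureResult, SiteChange]]:
    """Pairs where the retained target site lies inside the SNV's disrupted
    local region (either measure, transcript coordinates)."""
    by_snv: dict[tuple, StructureResult] = {}
    for res in structure_results:
        by_snv[(res.snv.transcript_id, res.snv.position, res.snv.alt)] = res
    out = []
    for sc in site_changes:
        res = by_snv.get((sc.snv.transcript_id, sc.snv.position, sc.snv.alt))
        if res is None or sc.target_span is None:
            continue
        for meas in (res.d, res.r):
            reg = meas.transcript_region
            if reg is None:
                continue
            if sc.target_span[0] <= reg[1] and reg[0] <= sc.target_span[1]:
                out.append((res, sc))
                break
    return out


def multi_hit_summary(candidates: pd.DataFrame):
    """Recurrence tables: genes with >= 2 disruptive SNVs, miRNAs with > 2
    changed targets.

    ``candidates`` needs ``gene`` and ``snv`` columns; a ``mirna`` column
    enables the per-miRNA table (rows without one are ignored there).
    Returns (gene_table, mirna_table) DataFrames sorted by count.
    """
    per_gene = (
        candidates.groupby("gene")["snv"]
        .nunique()
        .reset_index(name="n_snvs")
        .query("n_snvs >= 2")
        .sort_values(["n_snvs", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if "mirna" in candidates.columns and candidates["mirna"].notna().any():
        per_mirna = (
            candidates.dropna(subset=["mirna"])[["mirna", "gene", "snv"]]
            .drop_duplicates()
            .groupby("mirna")
            .size()
            .reset_index(name="n_targets")
            .query("n_targets > 2")
            .sort_values(["n_targets", "mirna"], ascending=[False, True])
            .reset_index(drop=True)
        )
    else:
        per_mirna = pd.DataFrame(columns=["mirna", "n_targets"])
    return per_gene, per_mirna
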