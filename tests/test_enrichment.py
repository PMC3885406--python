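import math

import pandas as pd
import pytest
from scipy import stats

from utrvar import published_tables as pub
from utrvar.enrichment import (
    ContingencyTable,
    enrichment_from_counts,
    fisher_one_sided,
    multi_hit_summary,
    snv_level_enrichment,
)


def brute_force_upper_tail(a, b, c, d):
    """Exact hypergeometric upper tail with integer combinatorics."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    num = 0
    for k in range(a, min(r1, c1) + 1):
        if c1 - k <= n - r1:
            num += math.comb(r1, k) * math.comb(n - r1, c1 - k)
    return num / math.comb(n, c1)


class TestFisherOneSided:
    def test_published_gene_counts(self):
        # 188 of 803 disruptive genes cancer-associated vs 1347 of 6462 overall
        res = enrichment_from_counts(188, 803, 1347, 6462)
        assert res.p_one_sided == pytest.approx(0.032, abs=5e-4)
        assert res.observed_ratio == pytest.approx(0.234, abs=5e-4)
        assert res.background_ratio == pytest.approx(0.208, abs=5e-4)

    def test_unit_table(self):
        assert fisher_one_sided(ContingencyTable(1, 1, 1, 1)) == pytest.approx(5 / 6)

    def test_minimum_possible_count_gives_one(self):
        # a is at its minimum given the margins -> upper tail covers everything
        assert fisher_one_sided(ContingencyTable(0, 5, 5, 0)) == pytest.approx(1.0)

    def test_zero_margin_returns_one(self):
        assert fisher_one_sided(ContingencyTable(0, 0, 3, 4)) == 1.0

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if (a + b == 0) or (a + c == 0) or (b + d == 0) or (c + d == 0):
                continue
            ours = fisher_one_sided(ContingencyTable(a, b, c, d))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert ours == pytest.approx(p, rel=1e-9)

    def test_matches_brute_force_sample(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            t = ContingencyTable(a, b, c, d)
            if a + b == 0 or a + c == 0 or a + b == t.n or a + c == t.n:
                continue
            assert fisher_one_sided(t) == pytest.approx(
                brute_force_upper_tail(a, b, c, d), abs=1e-12
            )

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            p1 = fisher_one_sided(ContingencyTable(a, b, c, d))
            p2 = fisher_one_sided(ContingencyTable(a, c, b, d))
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestEnrichmentUnits:
    def test_zero_disruptive(self):
        res = enrichment_from_counts(0, 0, 100, 1000)
        assert res.p_one_sided == 1.0

    def test_snv_level_delegates_to_fisher(self, dataset):
        gene_of = {t.transcript_id: t.gene for t in dataset.transcripts}
        disruptive = dataset.snvs[:10]
        res = snv_level_enrichment(
            dataset.snvs, disruptive, dataset.annotations.cancer_genes, gene_of
        )
        t = res.table
        direct = fisher_one_sided(t)
        assert res.p_one_sided == pytest.approx(direct)
        assert t.n == len({(gene_of[s.transcript_id], s.position, s.ref, s.alt) for s in dataset.snvs})

    def test_no_cancer_genes_p_one(self, dataset):
        gene_of = {t.transcript_id: t.gene for t in dataset.transcripts}
        res = snv_level_enrichment(dataset.snvs, dataset.snvs[:5], set(), gene_of)
        assert res.p_one_sided == 1.0

    def test_disruptive_outside_universe_rejected(self, dataset):
        from utrvar.core_io import SnvRecord

        gene_of = {t.transcript_id: t.gene for t in dataset.transcripts}
        gene_of["NM_FAKE"] = "FAKE"
        alien = SnvRecord("NM_FAKE", 10, "A", "G")
        with pytest.raises(ValueError):
            snv_level_enrichment(
                dataset.snvs, [alien], dataset.annotations.cancer_genes, gene_of
            )


class TestMultiHitSummary:
    def test_published_structure_table_has_15_multi_snv_genes(self):
        table = pub.structure_multi_snv_candidates()
        genes, _ = multi_hit_summary(table.assign(mirna=None))
        assert len(genes) == 15

    def test_published_mirna_table_recurrence(self):
        table = pub.recurrent_mirna_sites()
        _, mirnas = multi_hit_summary(table)
        # every miRNA in the recurrent table has more than two targets
        assert set(mirnas.mirna) == set(table.mirna.unique())
        assert (mirnas.n_targets == 3).all()

    def test_single_candidate_empty_summary(self):
        df = pd.DataFrame([dict(gene="G1", snv="A1G", mirna="m1")])
        genes, mirnas = multi_hit_summary(df)
        assert genes.empty and mirnas.empty

    def test_matches_naive_groupby(self, rng):
        df = pd.DataFrame(
            dict(
                gene=rng.choice(["G1", "G2", "G3"], 40),
                snv=[f"A{i % 13}G" for i in range(40)],
                mirna=rng.choice(["m1", "m2"], 40),
            )
        )
        genes, _ = multi_hit_summary(df)
        naive = {
            g: df[df.gene == g].snv.nunique()
            for g in df.gene.unique()
            if df[df.gene == g].snv.nunique() >= 2
        }
        assert dict(zip(genes.gene, genes.n_snvs)) == naive


class TestStructureMirtsOverlap:
    def test_span_inside_region_combined(self, dataset, mirna_result):
        from utrvar.enrichment import structure_mirts_overlap
        from utrvar.structure import LocalRegion, MeasureResult, StructureResult
        from utrvar.core_io import extract_window

        by_id = {t.transcript_id: t for t in dataset.transcripts}
        sc = mirna_result.final[0]
        tr = by_id[sc.snv.transcript_id]
        window = extract_window(sc.snv, tr, 60)
        span = sc.target_span
        inside = StructureResult(
            snv=sc.snv,
            gene=sc.gene,
            window=window,
            d=MeasureResult(
                score=0.2,
                region=LocalRegion(1, 10),
                p_value=0.01,
                transcript_region=(span[0] - 5, span[1] + 5),
            ),
            r=MeasureResult(score=1.0, region=None),
        )
        assert structure_mirts_overlap([inside], [sc]) == [(inside, sc)]
        disjoint = StructureResult(
            snv=sc.snv,
            gene=sc.gene,
            window=window,
            d=MeasureResult(
                score=0.2,
                region=LocalRegion(1, 10),
                p_value=0.01,
                transcript_region=(span[1] + 50, span[1] + 80),
            ),
            r=MeasureResult(score=1.0, region=None),
        )
        assert structure_mirts_overlap([disjoint], [sc]) == []
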