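import math

import numpy as np
import pytest

from utrvar.core_io import ConservedInterval, WindowPair, extract_window
from utrvar.rna_folding import BasePairMatrix, compute_pair_probabilities
from utrvar.structure import (
    LocalRegion,
    bh_adjust,
    classify_confidence,
    conserved_overlap_pct,
    empirical_pvalue,
    gc_compare,
    ld_haplotype_test,
    region_corr_pearson,
    region_distance_euclidean,
    scan_local_regions,
    structure_pvalues,
)


def random_sym_matrix(rng, n):
    m = rng.random((n, n)) * 0.2
    m = np.triu(m, k=4)
    return m + m.T


# ---------------------------------------------------------------------------
# region measures vs naive oracles
# ---------------------------------------------------------------------------


def naive_region_distance(p_wt, p_mt, region):
    s, e = region.start, region.end
    total = 0.0
    for k in range(s, e + 1):
        for l in range(k + 1, e + 1):
            total += (p_wt[k - 1, l - 1] - p_mt[k - 1, l - 1]) ** 2
    return math.sqrt(total) / (e - s + 1)


class TestRegionDistance:
    def test_identity(self, rng):
        p = random_sym_matrix(rng, 30)
        assert region_distance_euclidean(p, p, LocalRegion(3, 20)) == 0.0

    def test_single_cell_difference(self):
        p = np.zeros((20, 20))
        q = np.zeros((20, 20))
        q[4, 9] = q[9, 4] = 1.0
        # one unit cell inside a length-10 region: sqrt(1)/10
        assert region_distance_euclidean(p, q, LocalRegion(1, 10)) == pytest.approx(0.1)

    def test_matches_naive_double_loop(self, rng):
        a, b = random_sym_matrix(rng, 25), random_sym_matrix(rng, 25)
        for _ in range(10):
            s = int(rng.integers(1, 15))
            e = int(rng.integers(s + 1, 26))
            reg = LocalRegion(s, e)
            assert region_distance_euclidean(a, b, reg) == pytest.approx(
                naive_region_distance(a, b, reg), abs=1e-12
            )


class TestRegionCorrelation:
    def test_identical_profiles(self, rng):
        x = rng.random(30)
        assert region_corr_pearson(x, x.copy(), LocalRegion(2, 25)) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.array([0.1, 0.9, 0.1, 0.9, 0.1])
        y = x.mean() - (x - x.mean())
        assert region_corr_pearson(x, y, LocalRegion(1, 5)) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.random(40), rng.random(40)
        reg = LocalRegion(5, 30)
        xs, ys = x[4:30], y[4:30]
        expected = (
            ((xs - xs.mean()) * (ys - ys.mean())).sum()
            / math.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        )
        assert region_corr_pearson(x, y, reg) == pytest.approx(expected)

    def test_degenerate_slice_rejected(self):
        with pytest.raises(ValueError):
            region_corr_pearson(np.zeros(20), np.ones(20), LocalRegion(1, 15))


# ---------------------------------------------------------------------------
# region scan vs naive O(n^4) oracle
# ---------------------------------------------------------------------------


def naive_scan(p_wt, p_mt, l_min=10):
    n = p_wt.shape[0]
    prof_wt, prof_mt = p_wt.sum(1), p_mt.sum(1)
    best_d, best_d_reg = -1.0, None
    best_r, best_r_reg = np.inf, None
    for s in range(1, n + 1):
        for e in range(s + l_min - 1, n + 1):
            reg = LocalRegion(s, e)
            d = naive_region_distance(p_wt, p_mt, reg)
            better = d > best_d or (
                d == best_d
                and (
                    reg.length > best_d_reg.length
                    or (reg.length == best_d_reg.length and s < best_d_reg.start)
                )
            )
            if better:
                best_d, best_d_reg = d, reg
            xs, ys = prof_wt[s - 1 : e], prof_mt[s - 1 : e]
            if np.ptp(xs) < 1e-7 or np.ptp(ys) < 1e-7:
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            better = r < best_r or (
                r == best_r
                and (
                    reg.length > best_r_reg.length
                    or (reg.length == best_r_reg.length and s < best_r_reg.start)
                )
            )
            if better:
                best_r, best_r_reg = r, reg
    return best_d, best_d_reg, best_r, best_r_reg


class TestScanLocalRegions:
    def test_no_change_flags(self, rng):
        seq_bpm = compute_pair_probabilities("GGGCGAAAGCGCCC")
        d, d_reg, r, r_reg = scan_local_regions(seq_bpm, seq_bpm)
        assert d == 0.0
        assert r == pytest.approx(1.0)

    def test_localized_difference_found(self, rng):
        n = 80
        a = random_sym_matrix(rng, n)
        b = a.copy()
        b[42:58, 42:58] = np.triu(rng.random((16, 16)), 4)
        b[42:58, 42:58] += b[42:58, 42:58].T
        bpm_a = BasePairMatrix(n, a)
        bpm_b = BasePairMatrix(n, b)
        _, d_reg, _, _ = scan_local_regions(bpm_a, bpm_b)
        assert d_reg.end >= 43 and d_reg.start <= 58  # overlaps the planted block

    @pytest.mark.parametrize("n", [20, 35])
    def test_matches_naive_scan(self, rng, n):
        a, b = random_sym_matrix(rng, n), random_sym_matrix(rng, n)
        bpm_a, bpm_b = BasePairMatrix(n, a), BasePairMatrix(n, b)
        d, d_reg, r, r_reg = scan_local_regions(bpm_a, bpm_b)
        nd, nd_reg, nr, nr_reg = naive_scan(a, b)
        assert d == pytest.approx(nd, abs=1e-12)
        assert (d_reg.start, d_reg.end) == (nd_reg.start, nd_reg.end)
        assert r == pytest.approx(nr, abs=1e-9)
        assert (r_reg.start, r_reg.end) == (nr_reg.start, nr_reg.end)


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------


class TestEmpiricalPvalue:
    def test_plus_one_convention_floor(self, rng):
        # pick the substitution with the strictly largest d among every
        # possible single substitution of the window: no null can reach it,
        # so the plus-one convention gives exactly p = 1/(K+1)
        from utrvar.structure import _mutate, scan_local_regions

        for attempt in range(10):
            wt = "".join(rng.choice(list("ACGU"), 30))
            bpm_wt = compute_pair_probabilities(wt)
            scored = []
            for pos in range(1, 31):
                for alt in "ACGU":
                    if alt == wt[pos - 1]:
                        continue
                    bpm_mt = compute_pair_probabilities(_mutate(wt, pos, alt))
                    d, _, _, _ = scan_local_regions(bpm_wt, bpm_mt)
                    scored.append((d, pos, alt))
            scored.sort(reverse=True)
            if scored[0][0] > scored[1][0] + 1e-9:
                break
        else:
            pytest.skip("no window with a strict argmax substitution found")
        _, pos, alt = scored[0]
        window = WindowPair(wt, _mutate(wt, pos, alt), 1, pos)
        p = empirical_pvalue(window, "d", k_null=19, rng_seed=0)
        assert p == pytest.approx(1 / 20)

    def test_neutral_substitution_large_p(self):
        # substitution in a poly-A stretch of an otherwise structured window
        wt = "GGCGCGGCUUCGGCCGCGCC" + "A" * 40
        pos = 40
        mt = wt[: pos - 1] + "C" + wt[pos:]
        window = WindowPair(wt, mt, 1, pos)
        p = empirical_pvalue(window, "d", k_null=19, rng_seed=0)
        assert p > 0.5

    def test_reproducible_given_seed(self, toy_transcript, toy_snv):
        w = extract_window(toy_snv, toy_transcript, 25)
        a = structure_pvalues(w, k_null=19, rng=42)
        b = structure_pvalues(w, k_null=19, rng=42)
        assert a[0].p_value == b[0].p_value and a[1].p_value == b[1].p_value

    def test_k_floor_enforced(self, toy_transcript, toy_snv):
        w = extract_window(toy_snv, toy_transcript, 25)
        with pytest.raises(ValueError):
            structure_pvalues(w, k_null=5)


# ---------------------------------------------------------------------------
# BH adjustment and confidence tiers
# ---------------------------------------------------------------------------


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        q, passed = bh_adjust([0.005, 0.05, 0.5], fdr=0.10)
        np.testing.assert_allclose(q, [0.015, 0.075, 0.5])
        assert passed.tolist() == [True, True, False]

    def test_all_equal(self):
        q, _ = bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, [0.2, 0.2, 0.2])

    def test_single_and_empty(self):
        q, _ = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)
        q, passed = bh_adjust([])
        assert len(q) == 0 and len(passed) == 0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        q, passed = bh_adjust(p, fdr=0.1)
        reject, q_sm, *_ = multipletests(p, alpha=0.1, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm)
        assert (passed == reject).all()

    def test_q_monotone_and_at_least_p(self, rng):
        p = rng.random(50)
        q, _ = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestClassifyConfidence:
    @pytest.mark.parametrize(
        "pd_, pr_, expected",
        [
            (0.0030, 0.0213, "high"),
            (0.0815, 0.15, "medium"),
            (0.2, 0.15, "none"),
            (0.0474, 0.0427, "high"),
            (0.049, 0.051, "medium"),
        ],
    )
    def test_tiers(self, pd_, pr_, expected):
        assert classify_confidence(pd_, pr_) == expected


class TestConservedOverlap:
    def test_full_overlap(self):
        ivs = [ConservedInterval("T", 100, 300, "cmfinder")]
        assert conserved_overlap_pct((150, 200), ivs) == {"cmfinder": 100}

    def test_half_overlap(self):
        ivs = [ConservedInterval("T", 150, 249, "rnaz")]
        assert conserved_overlap_pct((100, 199), ivs) == {"rnaz": 50}

    def test_no_overlap(self):
        ivs = [ConservedInterval("T", 500, 600, "rnaz")]
        assert conserved_overlap_pct((100, 199), ivs) == {}

    def test_best_per_source(self):
        ivs = [
            ConservedInterval("T", 100, 120, "cmfinder"),
            ConservedInterval("T", 100, 199, "cmfinder"),
        ]
        assert conserved_overlap_pct((100, 199), ivs) == {"cmfinder": 100}


class TestRegionStats:
    def _result(self, reg_start, reg_end, snv_offset):
        from utrvar.structure import LocalRegion, MeasureResult, StructureResult
        from utrvar.core_io import SnvRecord

        wt = "ACGU" * 20
        off = snv_offset
        mt = wt[: off - 1] + ("A" if wt[off - 1] != "A" else "C") + wt[off:]
        window = WindowPair(wt, mt, 1, off)
        return StructureResult(
            snv=SnvRecord("T", off, wt[off - 1], mt[off - 1], utr_label="3"),
            gene="G",
            window=window,
            d=MeasureResult(score=0.2, region=LocalRegion(reg_start, reg_end), p_value=0.01),
            r=MeasureResult(score=0.5, region=None, p_value=0.5),
        )

    def test_snv_inside_region_distance_zero(self):
        res = self._result(10, 30, 20)
        assert res.snv_region_distance == 0

    def test_snv_outside_region_gap_to_edge(self):
        res = self._result(10, 20, 25)
        assert res.snv_region_distance == 5
        assert res.region_length == 11

    def test_histograms(self):
        from utrvar.structure import region_stats

        results = [self._result(10, 30, 20), self._result(10, 20, 25)]
        len_hist, dist_hist = region_stats(results)
        assert int(len_hist["count"].sum()) == 2
        assert int(dist_hist.loc[dist_hist["bin"] == "0", "count"].iloc[0]) == 1


def test_gene_level_enrichment_counts(dataset, mirna_result):
    from utrvar.enrichment import gene_level_enrichment

    all_genes = {t.gene for t in dataset.transcripts}
    res = gene_level_enrichment(
        [], mirna_result.final, dataset.annotations.cancer_genes, all_genes
    )
    disruptive = {s.gene for s in mirna_result.final}
    assert res.table.a + res.table.b == len(disruptive)
    assert res.table.n == len(all_genes)
    assert 0 < res.p_one_sided <= 1


# ---------------------------------------------------------------------------
# GC comparison
# ---------------------------------------------------------------------------


class TestGcCompare:
    def test_identical_samples(self):
        w = ["ACGU" * 10, "GGCC" * 10, "AAUU" * 10]
        _, _, d, p = gc_compare(w, w)
        assert d == 0 and p == pytest.approx(1.0)

    def test_disjoint_support(self):
        _, _, d, _ = gc_compare(["AAAA", "AAAU"], ["GGGG", "GGGC"])
        assert d == 1.0

    def test_matches_naive_cdf_sweep(self, rng):
        a = ["".join(rng.choice(list("ACGU"), 50)) for _ in range(40)]
        b = ["".join(rng.choice(list("ACGU"), 50)) for _ in range(30)]
        gc1, gc2, d, _ = gc_compare(a, b)
        grid = np.unique(np.concatenate([gc1, gc2]))
        naive = max(
            abs((gc1 <= x).mean() - (gc2 <= x).mean()) for x in grid
        )
        assert d == pytest.approx(naive)


# ---------------------------------------------------------------------------
# linked-variant haplotype re-testing
# ---------------------------------------------------------------------------


class TestLdHaplotype:
    def test_partner_outside_window_skipped(self, dataset):
        snv, pos, ref, alt = dataset.annotations.ld_pairs[0]
        tr = {t.transcript_id: t for t in dataset.transcripts}[snv.transcript_id]
        verdict = ld_haplotype_test(
            snv, (snv.position + 300, "A", "C"), tr, flank=200, k_null=19
        )
        assert verdict == "skipped"

    def test_compensatory_partner_stabilizes(self, dataset):
        # planted compensatory partners restore the wild-type ensemble
        by_id = {t.transcript_id: t for t in dataset.transcripts}
        pairs = [
            p
            for p, kind in zip(dataset.annotations.ld_pairs, dataset.ledger.ld_kinds)
            if kind == "compensatory"
        ]
        assert pairs
        for snv, pos, ref, alt in pairs:
            verdict = ld_haplotype_test(
                snv, (pos, ref, alt), by_id[snv.transcript_id],
                flank=60, k_null=49, rng=3,
            )
            assert verdict == "stabilizing"

    def test_neutral_partner_stays_disruptive(self, dataset):
        by_id = {t.transcript_id: t for t in dataset.transcripts}
        pairs = [
            p
            for p, kind in zip(dataset.annotations.ld_pairs, dataset.ledger.ld_kinds)
            if kind == "neutral"
        ]
        assert pairs
        verdicts = [
            ld_haplotype_test(
                snv, (pos, ref, alt), by_id[snv.transcript_id],
                flank=60, k_null=49, rng=3,
            )
            for snv, pos, ref, alt in pairs
        ]
        assert verdicts.count("still_disruptive") > len(verdicts) / 2
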