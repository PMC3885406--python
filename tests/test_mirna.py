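import math

import numpy as np
import pytest

from utrvar.core_io import ClipCluster, SnvRecord
from utrvar.mirna import (
    DEFAULT_PARAMS,
    MirnaRecord,
    SiteChange,
    alter_mean_filter,
    classify_site_change,
    clip_filter,
    expression_filter,
    find_seed_matches,
    log_ratio,
    revcomp,
    scan_duplex,
    seed_change_filter,
    strongest_differing_site,
)

MIR = MirnaRecord("mir-test", "UACGUACGUACGUACGUACGUA")
# seed 2-8 = ACGUACG, revcomp = CGUACGU; seed 2-7 = ACGUAC, revcomp = GUACGU


def embed(core, flank_len=20):
    return "A" * flank_len + core + "A" * flank_len


class TestSeedMatching:
    def test_8mer_1a(self):
        subseq = embed("CGUACGUA")
        matches = find_seed_matches(MIR, subseq)
        assert any(m.type == "8mer-1a" for m in matches)

    def test_7mer_m8(self):
        subseq = embed("CGUACGUC")
        types = {m.type for m in find_seed_matches(MIR, subseq)}
        assert "7mer-m8" in types and "8mer-1a" not in types

    def test_7mer_1a(self):
        subseq = embed("UGUACGUA")
        m = [x for x in find_seed_matches(MIR, subseq) if x.type == "7mer-1a"]
        assert m, "A opposite position 1 without an m8 match is a 7mer-1a"

    def test_strongest_type_reported_per_register(self):
        # an 8mer register must not also be reported as 7mer at that register
        subseq = embed("CGUACGUA")
        matches = find_seed_matches(MIR, subseq)
        regs = [m.site_end for m in matches]
        assert len(regs) == len(set(regs))

    def test_gu_not_counted(self):
        # replace the C opposite m8 (G) with U: G:U wobble must not count as m8
        subseq = embed("UGUACGUC")  # no A at 1a either -> nothing canonical
        assert find_seed_matches(MIR, subseq) == []

    def test_random_sequences_against_string_oracle(self, rng):
        """Every reported match is confirmed by direct reverse-complement
        string comparison; planted 8mers are never missed."""
        site8 = revcomp(MIR.sequence[1:8]) + "A"
        rc2_8 = revcomp(MIR.sequence[1:8])
        rc2_7 = revcomp(MIR.sequence[1:7])
        for trial in range(10_000):
            subseq = "".join(rng.choice(list("ACGU"), 61))
            if trial % 5 == 0:  # plant an 8mer at a random position
                k = int(rng.integers(0, 61 - 8))
                subseq = subseq[:k] + site8 + subseq[k + 8 :]
            found = {(m.site_end, m.type) for m in find_seed_matches(MIR, subseq)}
            expected = set()
            for r in range(7, 62):
                a1 = subseq[r - 1] == "A"
                m8 = r >= 8 and subseq[r - 8 : r - 1] == rc2_8
                if m8 and a1:
                    expected.add((r, "8mer-1a"))
                elif m8:
                    expected.add((r, "7mer-m8"))
                elif a1 and subseq[r - 7 : r - 1] == rc2_7:
                    expected.add((r, "7mer-1a"))
            assert found == expected


class TestSeedChangeFilter:
    def test_loss_detected(self):
        wt = find_seed_matches(MIR, embed("CGUACGUC"))
        assert seed_change_filter(wt, []) is True

    def test_identical_both_alleles(self):
        wt = find_seed_matches(MIR, embed("CGUACGUA"))
        assert seed_change_filter(wt, list(wt)) is False

    def test_type_change_same_register(self):
        wt = find_seed_matches(MIR, embed("UGUACGUA"))  # 7mer-1a
        mt = find_seed_matches(MIR, embed("CGUACGUA"))  # 8mer-1a
        assert seed_change_filter(wt, mt) is True


class TestScanDuplex:
    def test_perfect_complement_strong_site(self):
        subseq = embed(revcomp(MIR.sequence), 15)
        sites = scan_duplex(MIR, subseq)
        assert sites
        best = min(sites, key=lambda s: s.energy)
        assert best.energy < -11
        assert best.score >= DEFAULT_PARAMS.score_min

    def test_no_complementarity_no_sites(self):
        assert scan_duplex(MIR, "A" * 61) == []

    def test_reported_sites_respect_cutoffs(self, rng):
        subseq = "".join(rng.choice(list("ACGU"), 61))
        for s in scan_duplex(MIR, subseq):
            assert s.score >= DEFAULT_PARAMS.score_min
            assert s.energy <= DEFAULT_PARAMS.energy_relaxed


def _site(reg, energy):
    from utrvar.mirna import DuplexResult

    return DuplexResult(register=reg, score=50.0, energy=energy,
                        target_span=(reg - 7, reg), columns=[])


class TestStrongestDifferingSite:
    def test_retains_most_different_register(self):
        wt = [_site(1, -15.0), _site(2, -18.0)]
        mt = [_site(1, -15.0), _site(2, -12.0)]
        dgw, dgm, reg, *_ = strongest_differing_site(wt, mt)
        assert (dgw, dgm, reg) == (-18.0, -12.0, 2)

    def test_lost_site(self):
        dgw, dgm, reg, *_ = strongest_differing_site([_site(1, -15.0)], [])
        assert (dgw, dgm, reg) == (-15.0, None, 1)

    def test_identical_lists_emit_nothing(self):
        wt = [_site(1, -15.0)]
        assert strongest_differing_site(wt, list(wt)) is None


class TestClassification:
    @pytest.mark.parametrize(
        "dgw, dgm, expected",
        [
            (None, -16.70, "create"),
            (-11.01, None, "destroy"),
            (-16.10, -10.65, "alter"),
            (-9.0, -10.0, None),
            (None, -9.0, None),
            (-10.0, None, None),
        ],
    )
    def test_classes(self, dgw, dgm, expected):
        assert classify_site_change(dgw, dgm) == expected

    def test_both_absent_rejected(self):
        with pytest.raises(ValueError):
            classify_site_change(None, None)


class TestLogRatio:
    def test_halving_energy(self):
        assert log_ratio(-20.0, -10.0) == pytest.approx(-1.0)

    def test_no_change(self):
        assert log_ratio(-10.0, -10.0) == 0.0

    def test_published_energy_pair(self):
        assert log_ratio(-16.10, -10.65) == pytest.approx(
            math.log2(10.65 / 16.10), abs=1e-9
        )
        assert log_ratio(-16.10, -10.65) == pytest.approx(-0.596, abs=5e-4)

    def test_undefined_for_nonnegative(self):
        assert log_ratio(1.0, -5.0) is None
        assert log_ratio(-5.0, 0.0) is None


def _change(cls, lr=None, snv_pos=150, tid="T"):
    snv = SnvRecord(tid, snv_pos, "A", "G", utr_label="3")
    return SiteChange(
        snv=snv, mirna_id="mir-x", gene="G1", cls=cls, dg_wt=-15.0, dg_snv=-12.0, lr=lr
    )


class TestAlterMeanFilter:
    def test_strictly_above_mean(self):
        changes = [_change("alter", lr=v) for v in (0.2, -0.6, 1.0)]
        retained, mu = alter_mean_filter(changes)
        assert mu == pytest.approx(0.6)
        assert [c.lr for c in retained] == [1.0]

    def test_all_equal_retains_nothing(self):
        changes = [_change("alter", lr=0.5) for _ in range(3)]
        retained, mu = alter_mean_filter(changes)
        assert retained == [] and mu == pytest.approx(0.5)

    def test_matches_one_line_oracle(self, rng):
        lrs = rng.normal(size=50)
        changes = [_change("alter", lr=float(v)) for v in lrs]
        retained, mu = alter_mean_filter(changes)
        expected = [float(v) for v in lrs if abs(v) > np.abs(lrs).mean()]
        assert [c.lr for c in retained] == expected


class TestClipFilter:
    def test_destroy_inside_cluster_passes(self):
        sc = _change("destroy")
        clusters = [ClipCluster("T", 100, 200, 3)]
        assert clip_filter(sc, clusters) is True and sc.clip_pass is True

    def test_low_bc_fails(self):
        sc = _change("alter")
        assert clip_filter(sc, [ClipCluster("T", 100, 200, 1)]) is False

    def test_create_passes_through(self):
        sc = _change("create")
        assert clip_filter(sc, []) is True
        assert sc.clip_pass is None  # not applicable


class TestExpressionFilter:
    def test_membership(self):
        sc = _change("alter")
        assert expression_filter(sc, {"mir-x", "mir-y"}) is True
        assert expression_filter(sc, {"mir-y"}) is False

    def test_empty_set_fails_all(self, caplog):
        sc = _change("alter")
        assert expression_filter(sc, set()) is False


class TestCascadeProperties:
    def test_stage_counts_non_increasing(self, mirna_result):
        c = mirna_result.stage_counts
        assert (
            c["screen_pairs"]
            >= c["seed_change"]
            >= c["classified"]
            >= c["clip_pass"]
            >= c["lr_pass"]
            >= c["expressed"]
        )

    def test_classification_trichotomy(self, mirna_result):
        from utrvar.mirna import ENERGY_THRESHOLD

        assert mirna_result.all_changes
        for sc in mirna_result.all_changes:
            if sc.cls == "create":
                assert sc.dg_wt is None and sc.dg_snv <= ENERGY_THRESHOLD
            elif sc.cls == "destroy":
                assert sc.dg_snv is None and sc.dg_wt <= ENERGY_THRESHOLD
            else:
                assert sc.dg_wt is not None and sc.dg_snv is not None
                assert min(sc.dg_wt, sc.dg_snv) <= ENERGY_THRESHOLD
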