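"""Mate-pair orientation classification, summaries, scaffold selection, links."""

import pytest

from bacpool import matepair as mp
from bacpool import simulate as sim
from bacpool.model import SeqRecord


class TestClassifyOrientation:
    def test_rf(self):
        call = mp.classify_orientation((1000, 1150, "-"), (6850, 7000, "+"))
        assert call.orientation == "RF" and call.insert_size == 6000

    def test_fr(self):
        call = mp.classify_orientation((1000, 1150, "+"), (1250, 1400, "-"))
        assert call.orientation == "FR" and call.insert_size == 400

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_ff_rr(self, strand):
        call = mp.classify_orientation((100, 250, strand), (900, 1050, strand))
        assert call.orientation == "FF_RR"

    def test_mate_order_irrelevant(self):
        a = mp.classify_orientation((1000, 1150, "-"), (6850, 7000, "+"))
        b = mp.classify_orientation((6850, 7000, "+"), (1000, 1150, "-"))
        assert a == b

    def test_different_contigs_error(self):
        with pytest.raises(ValueError):
            mp.classify_orientation((0, 100, "+"), (0, 100, "-"), same_contig=False)


class TestSelectValidationPairs:
    def _pair(self, **kw):
        base = dict(
            pair_id="p", contig1="c1", contig2="c1",
            mate1=(0, 150, "-"), mate2=(5_000, 5_150, "+"),
            identity1=100.0, identity2=100.0, aligned1=150, aligned2=150,
            hit_count1=1, hit_count2=1,
        )
        base.update(kw)
        return mp.MappedPair(**base)

    def test_clean_pair_kept(self):
        assert mp.select_validation_pairs([self._pair()]) == [self._pair()]

    def test_imperfect_identity_rejected(self):
        assert mp.select_validation_pairs([self._pair(identity2=99.9)]) == []

    def test_multimapper_rejected(self):
        assert mp.select_validation_pairs([self._pair(hit_count1=2)]) == []

    def test_short_read_rejected(self):
        assert mp.select_validation_pairs(
            [self._pair(mate1=(0, 100, "-"), aligned1=100)]) == []

    def test_cross_contig_rejected(self):
        assert mp.select_validation_pairs([self._pair(contig2="c2")]) == []


class TestOrientationSummary:
    def test_table_regime(self):
        calls = (
            [mp.OrientationCall("RF", 6000)] * 990
            + [mp.OrientationCall("FR", 400)] * 3
            + [mp.OrientationCall("FF_RR", 5000)] * 7
        )
        s = mp.orientation_summary(calls)
        assert s["RF"]["percent"] == pytest.approx(99.0)
        assert s["FR"]["percent"] == pytest.approx(0.3)
        assert s["FF_RR"]["percent"] == pytest.approx(0.7)
        assert sum(v["percent"] for v in s.values()) == pytest.approx(100.0)

    def test_all_rf(self):
        s = mp.orientation_summary([mp.OrientationCall("RF", 6000)] * 10)
        assert s["RF"]["percent"] == 100.0 and s["FR"]["percent"] == 0.0
        assert s["FR"]["median_insert"] is None

    def test_median_insert(self):
        calls = [mp.OrientationCall("RF", x) for x in (5999, 6000, 6001)]
        assert mp.orientation_summary(calls)["RF"]["median_insert"] == 6000

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mp.orientation_summary([])


class TestClassifierClosure:
    def test_truth_recovered_for_all_pairs(self):
        """Simulated mate pairs classify back to their truth class, always."""
        ref = SeqRecord("r", sim.simulate_clone(60_000, 0.0, seed=13).insert)
        cfg = sim.SimConfig(seed=29, mp_orientation_mix=(0.98, 0.01, 0.01))
        mps = sim.simulate_mate_pairs(ref, 5_000, cfg)
        agree = sum(
            mp.classify_orientation(m.mate1, m.mate2).orientation == m.truth_class
            for m in mps
        )
        assert agree == len(mps)


class TestSelectScaffoldPairs:
    def _pair(self, **kw):
        base = dict(
            pair_id="p", contig1="c1", contig2="c2",
            mate1=(0, 150, "-"), mate2=(300, 450, "+"),
            identity1=100.0, identity2=100.0, aligned1=150, aligned2=150,
        )
        base.update(kw)
        return mp.MappedPair(**base)

    def test_full_length_perfect_kept(self):
        pools = {"c1": "pool1", "c2": "pool1"}
        assert len(mp.select_scaffold_pairs([self._pair()], 150, pools)) == 1

    def test_partial_alignment_rejected(self):
        pools = {"c1": "pool1", "c2": "pool1"}
        assert mp.select_scaffold_pairs([self._pair(aligned1=148)], 150, pools) == []

    def test_cross_pool_rejected(self):
        pools = {"c1": "pool1", "c2": "pool2"}
        assert mp.select_scaffold_pairs([self._pair()], 150, pools) == []

    def test_monotone_in_identity_threshold(self):
        pairs = [self._pair(identity1=ident) for ident in (100.0, 99.5, 98.0)]
        strict = mp.select_scaffold_pairs(pairs, 150)
        assert {p.pair_id for p in strict} <= {p.pair_id for p in pairs}


class TestSspaceTab:
    def test_worked_example(self, tmp_path):
        link = mp.ScaffoldLink("c1", "c2", (0, 150, "-"), (300, 450, "+"))
        out = tmp_path / "t.tab"
        mp.write_sspace_tab([link], out)
        assert out.read_text() == "c1\t1\t150\tc2\t301\t450\n"

    def test_empty(self, tmp_path):
        out = tmp_path / "t.tab"
        mp.write_sspace_tab([], out)
        assert out.read_text() == ""

    def test_deterministic(self, tmp_path):
        links = [
            mp.ScaffoldLink("c2", "c1", (10, 160, "-"), (5, 155, "+")),
            mp.ScaffoldLink("c1", "c2", (0, 150, "-"), (300, 450, "+")),
        ]
        a, b = tmp_path / "a.tab", tmp_path / "b.tab"
        mp.write_sspace_tab(links, a)
        mp.write_sspace_tab(list(links), b)
        assert a.read_text() == b.read_text()

    def test_unknown_contig_errors(self, tmp_path):
        link = mp.ScaffoldLink("c1", "ghost", (0, 150, "-"), (300, 450, "+"))
        with pytest.raises(ValueError):
            mp.write_sspace_tab([link], tmp_path / "t.tab", {"c1", "c2"})


class TestBundleLinks:
    def _links(self, n, contig_a="c1", contig_b="c2"):
        return [
            mp.ScaffoldLink(contig_a, contig_b, (9_000 + i, 9_150 + i, "-"),
                            (100 + i, 250 + i, "+"))
            for i in range(n)
        ]

    def test_k_threshold(self):
        lengths = {"c1": 10_000, "c2": 10_000}
        assert len(mp.bundle_links(self._links(12), lengths)) == 1
        assert len(mp.bundle_links(self._links(9), lengths)) == 0

    def test_gap_estimate_from_split_reference(self):
        """Mate pairs spanning a known 500 bp gap estimate it within ±200 bp."""
        ref = SeqRecord("r", sim.simulate_clone(40_000, 0.0, seed=41).insert)
        gap, cut = 500, 20_000
        len1, len2 = cut, len(ref.sequence) - cut - gap
        cfg = sim.SimConfig(seed=53, mp_insert_min=6_000, mp_insert_max=7_000,
                            mp_orientation_mix=(1.0, 0.0, 0.0))
        mps = sim.simulate_mate_pairs(ref, 3_000, cfg)
        links = []
        for m in mps:
            left, right = sorted((m.mate1, m.mate2))
            if left[1] <= cut and right[0] >= cut + gap:
                links.append(mp.ScaffoldLink(
                    "left", "right", left,
                    (right[0] - cut - gap, right[1] - cut - gap, right[2])))
        assert len(links) >= 10
        bundles = mp.bundle_links(links, {"left": len1, "right": len2},
                                  min_links=10, insert_range=(6_000, 7_000))
        assert len(bundles) == 1
        assert bundles[0].gap_estimate == pytest.approx(gap, abs=200)


def test_mapped_pairs_tsv_round_trip(tmp_path):
    pairs = [
        mp.MappedPair("p1", "c1", "c2", (0, 150, "-"), (300, 450, "+"),
                      100.0, 99.5, 150, 148, 1, 2),
    ]
    path = tmp_path / "m.tsv"
    mp.write_mapped_pairs_tsv(pairs, path)
    back = mp.read_mapped_pairs_tsv(path)
    assert back == pairs
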