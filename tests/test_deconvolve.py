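"""BES scoring S = b − d_s, pool deconvolution and pool-vs-singleton pairing."""

import pytest

from _hitgen import all_hits
from bacpool import deconvolve as dc
from bacpool import simulate as sim
from bacpool.model import AlignmentHit, SeqRecord


def _hit(bes="b1", contig="c1", start=100, end=600, b=200.0, identity=99.0):
    return AlignmentHit(bes, contig, 0, end - start, start, end, "+",
                        identity, end - start, b)


class TestEdgeDistance:
    def test_near_right_edge(self):
        assert dc.edge_distance(_hit(start=95_000, end=95_500), 100_000) == 4_500

    def test_at_left_edge(self):
        assert dc.edge_distance(_hit(start=0, end=500), 100_000) == 0

    def test_middle(self):
        assert dc.edge_distance(_hit(start=400, end=600), 1_000) == 400

    def test_outside_contig_errors(self):
        with pytest.raises(ValueError):
            dc.edge_distance(_hit(start=400, end=600), 500)


class TestScoreBesHits:
    def _query(self, length=600):
        return dc.BesQuery("b1", "A", "forward", "A" * length)

    def test_single_hit_assigned(self):
        asn = dc.score_bes_hits(self._query(), [_hit(start=50, end=550, b=200.0)],
                                {"c1": 10_000})
        assert asn is not None
        assert asn.score == 200.0 - 50
        assert asn.d_s == 50

    def test_highest_s_wins_not_highest_bitscore(self):
        h1 = _hit(contig="c1", start=10, end=510, b=180.0)    # S = 170
        h2 = _hit(contig="c2", start=60, end=560, b=200.0)    # S = 140
        asn = dc.score_bes_hits(self._query(), [h1, h2], {"c1": 10_000, "c2": 10_000})
        assert asn.contig_id == "c1" and asn.score == 170.0

    @pytest.mark.parametrize("length,expected_none", [(120, True), (121, False),
                                                      (1000, True), (999, False)])
    def test_length_filter_bounds(self, length, expected_none):
        """Only BES with 120 < length < X (default 1000) are scored."""
        q = self._query(length)
        asn = dc.score_bes_hits(q, [_hit(start=0, end=100, b=50.0)], {"c1": 10_000})
        assert (asn is None) == expected_none

    def test_proxy_bypasses_length_filter(self):
        q = dc.BesQuery("v1", "B", "forward", "A" * 120, "vector_end_proxy")
        asn = dc.score_bes_hits(q, [_hit(bes="v1", start=0, end=100, b=50.0)],
                                {"c1": 10_000})
        assert asn is not None

    def test_tie_breaking_chain(self):
        # equal S: higher b wins
        h1 = _hit(contig="c1", start=0, end=500, b=100.0)   # S=100
        h2 = _hit(contig="c2", start=50, end=550, b=150.0)  # S=100
        asn = dc.score_bes_hits(self._query(), [h1, h2], {"c1": 10_000, "c2": 10_000})
        assert asn.contig_id == "c2"
        # equal S and b: lexicographic contig id
        h3 = _hit(contig="c3", start=0, end=500, b=100.0)
        asn = dc.score_bes_hits(self._query(), [h1, h3], {"c1": 10_000, "c3": 10_000})
        assert asn.contig_id == "c1"

    def test_unknown_contig_errors(self):
        with pytest.raises(ValueError):
            dc.score_bes_hits(self._query(), [_hit(contig="ghost")], {"c1": 10_000})

    def test_exhaustive_oracle_small_instances(self):
        """Brute force max of S over <= 20 hits equals score_bes_hits."""
        import numpy as np

        rng = np.random.default_rng(3)
        lengths = {f"c{i}": int(rng.integers(2_000, 50_000)) for i in range(5)}
        for _ in range(50):
            n = int(rng.integers(1, 21))
            hits = []
            for _ in range(n):
                contig = f"c{int(rng.integers(0, 5))}"
                L = lengths[contig]
                start = int(rng.integers(0, L - 600))
                hits.append(_hit(contig=contig, start=start, end=start + 600,
                                 b=float(rng.integers(50, 1200))))
            asn = dc.score_bes_hits(self._query(), hits, lengths)
            best = max(h.bit_score - dc.edge_distance(h, lengths[h.subject_id]) for h in hits)
            assert asn.score == best

    def test_s_monotonicity(self):
        base = dc.score_bes_hits(self._query(), [_hit(start=100, end=600, b=200.0)],
                                 {"c1": 10_000})
        higher_b = dc.score_bes_hits(self._query(), [_hit(start=100, end=600, b=250.0)],
                                     {"c1": 10_000})
        closer = dc.score_bes_hits(self._query(), [_hit(start=50, end=550, b=200.0)],
                                   {"c1": 10_000})
        assert higher_b.score > base.score
        assert closer.score > base.score


class TestDeconvolutePool:
    def _setup(self):
        queries, assignments = [], {}
        for i, clone in enumerate("ABCD"):
            for end, contig_end in (("forward", "f"), ("reverse", "r")):
                q = dc.BesQuery(f"{clone}_{end}", clone, end, "A" * 600)
                queries.append(q)
                assignments[q.bes_id] = dc.BesAssignment(
                    q.bes_id, f"ctg{i}", 0, 600, "+", 0, 100.0, 1)
        return queries, assignments

    def test_all_clones_anchored_no_conflicts(self):
        queries, assignments = self._setup()
        rep = dc.deconvolute_pool(queries, assignments, list("ABCD"),
                                  [f"ctg{i}" for i in range(5)])
        assert rep.anchored == list("ABCD")
        assert rep.conflicts == []
        assert rep.unassigned_contigs == ["ctg4"]

    def test_proxy_anchoring(self):
        vector = SeqRecord("vec", "ACGT" * 100)
        fwd, rev = dc.vector_end_proxies(vector, "B")
        assert len(fwd.sequence) == 120 and len(rev.sequence) == 120
        assignments = {
            fwd.bes_id: dc.BesAssignment(fwd.bes_id, "ctg1", 0, 120, "+", 0, 50.0, 1),
            rev.bes_id: dc.BesAssignment(rev.bes_id, "ctg1", 880, 1000, "-", 0, 50.0, 1),
        }
        rep = dc.deconvolute_pool([fwd, rev], assignments, ["B"], ["ctg1"])
        assert rep.anchored == ["B"] and rep.proxy_anchored == ["B"]

    def test_conflict_reported_not_resolved(self):
        qa = dc.BesQuery("A_f", "A", "forward", "A" * 600)
        qb = dc.BesQuery("B_f", "B", "forward", "A" * 600)
        assignments = {
            "A_f": dc.BesAssignment("A_f", "ctg1", 0, 600, "+", 0, 10.0, 1),
            "B_f": dc.BesAssignment("B_f", "ctg1", 100, 700, "+", 100, 5.0, 1),
        }
        rep = dc.deconvolute_pool([qa, qb], assignments, ["A", "B"], ["ctg1"])
        assert rep.conflicts == [("ctg1", ("A", "B"))]


class TestDeconvolutionRecovery:
    def test_truth_contigs_recover_clones(self):
        """On a synthetic pool with truth contigs, every BES lands on its clone."""
        pool = sim.simulate_pool("pd", 4, 40_000, 0.5, seed=91, repeat_unit_length=2000)
        contigs = [SeqRecord(c.clone_id, c.insert) for c in pool.clones]
        lengths = {c.id: len(c) for c in contigs}
        queries = []
        for c in pool.clones:
            queries.append(dc.BesQuery(f"{c.clone_id}_For", c.clone_id, "forward", c.bes_forward))
            queries.append(dc.BesQuery(f"{c.clone_id}_Rev", c.clone_id, "reverse", c.bes_reverse))
        hits = all_hits([SeqRecord(q.bes_id, q.sequence) for q in queries], contigs)
        assignments = dc.assign_bes(queries, hits, lengths)
        correct = sum(
            1 for q in queries
            if assignments[q.bes_id] is not None
            and assignments[q.bes_id].contig_id == q.clone_id
        )
        assert correct == len(queries)
        rep = dc.deconvolute_pool(queries, assignments,
                                  [c.clone_id for c in pool.clones], list(lengths))
        assert len(rep.anchored) == 4 and rep.conflicts == []


class TestPairPoolToSingletons:
    def test_dominant_singleton_wins(self):
        hits = [AlignmentHit("pc1", "sA_1", 0, 9_900, 0, 9_900, "+", 99.0, 9_900, 18_000.0)]
        out = dc.pair_pool_to_singletons({"pc1": 10_000}, {"sA_1": "A"}, hits)
        (p,) = out
        assert p.singleton == "A" and p.paired and not p.shared
        assert p.aligned_fraction == pytest.approx(0.99)

    def test_split_contig_flagged_shared(self):
        hits = [
            AlignmentHit("pc1", "sA_1", 0, 6_000, 0, 6_000, "+", 99.0, 6_000, 6_000.0),
            AlignmentHit("pc1", "sB_1", 6_000, 10_000, 0, 4_000, "+", 99.0, 4_000, 4_000.0),
        ]
        out = dc.pair_pool_to_singletons({"pc1": 10_000}, {"sA_1": "A", "sB_1": "B"}, hits)
        (p,) = out
        # brute-force summed score: A=6000 > B=4000
        assert p.singleton == "A" and p.shared

    def test_no_hits_unpaired(self):
        out = dc.pair_pool_to_singletons({"pc1": 10_000}, {}, [])
        (p,) = out
        assert p.singleton is None and not p.paired
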