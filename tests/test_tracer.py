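"""tracer: graph construction, score propagation, seed-and-extend,
chain assignment, prior refinement, gap filling, and full tracing."""

import numpy as np
import pytest

from catrace import tracer as trc
from catrace.ca_cluster import CaCandidate
from catrace.constants import AA_INDEX, N_AA, ONE_TO_THREE


def _profile(letter, purity=1.0):
    p = np.full(N_AA, (1.0 - purity) / N_AA)
    p[AA_INDEX[ONE_TO_THREE[letter]]] += purity
    return p / p.sum()


def _cand(pos, letter="A", purity=1.0, score=0.9):
    return CaCandidate(position=np.asarray(pos, dtype=np.float64),
                       ca_score=score, bb_score=score,
                       aa_profile=_profile(letter, purity))


def _line_cands(seq, spacing=3.8, purity=1.0):
    return [_cand((i * spacing, 0.0, 0.0), letter, purity)
            for i, letter in enumerate(seq)]


def _zigzag(n):
    """Non-collinear, shift-detectable positions with 2-6 A steps."""
    rng = np.random.default_rng(7)
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        step = rng.normal(0, 1, 3)
        step *= rng.uniform(3.2, 4.4) / np.linalg.norm(step)
        pts.append(pts[-1] + step)
    return [np.asarray(p) for p in pts]


def _prior_from_points(points, chain_id="A", aa="ALA"):
    from catrace.struct_codec import Chain, Residue, StructureModel
    residues = [Residue(i + 1, aa, {"CA": np.asarray(p)})
                for i, p in enumerate(points)]
    return StructureModel([Chain(chain_id, residues)])


class TestBuildGraph:
    def test_chain_edges_and_bounds(self):
        cands = _line_cands("AAAA")
        g = trc.build_graph(cands)
        assert g.edges == {(0, 1), (1, 2), (2, 3)}
        assert g.dist[(0, 1)] == pytest.approx(3.8)

    def test_link_range_inclusive(self):
        for d, expect in [(1.9, 0), (2.0, 1), (6.0, 1), (6.1, 0)]:
            g = trc.build_graph([_cand((0, 0, 0)), _cand((d, 0, 0))])
            assert len(g.edges) == expect, d

    def test_degree_pruning_drops_worst_edge(self):
        # hub 0 with three spokes; the 5.5 A edge is farthest from 3.8 A
        cands = [_cand((0, 0, 0)), _cand((3.8, 0, 0)),
                 _cand((-3.0, 0, 0)), _cand((0, 5.5, 0))]
        g = trc.build_graph(cands)
        assert g.edges == {(0, 1), (0, 2)}
        assert max(len(g.neighbors(k)) for k in range(4)) <= 2

    def test_all_degrees_capped_at_two(self):
        rng = np.random.default_rng(0)
        cands = [_cand(rng.uniform(0, 12, 3)) for _ in range(30)]
        g = trc.build_graph(cands)
        assert all(len(g.neighbors(k)) <= 2 for k in range(30))

    def test_empty_and_singleton(self):
        assert trc.build_graph([]).edges == set()
        assert trc.build_graph([_cand((0, 0, 0))]).edges == set()


class TestHopSets:
    def test_exact_hop_levels_on_path_graph(self):
        g = trc.TraceGraph(n=5, edges={(0, 1), (1, 2), (2, 3), (3, 4)}).finalize()
        hs = g.hop_sets(3)
        assert hs[0][2] == [2]
        assert sorted(hs[1][2]) == [1, 3]
        assert sorted(hs[2][2]) == [0, 4]
        assert hs[3][0] == [3]
        assert hs[3][2] == []


class TestScoreMatrix:
    def test_values_and_padding(self):
        cands = [_cand((0, 0, 0), "A"), _cand((4, 0, 0), "G")]
        S = trc.initial_score_matrix(cands, ["AG", "A"])
        assert S.shape == (2, 2, 2)
        assert S[0, 0, 0] == 1.0 and S[0, 0, 1] == 0.0
        assert S[0, 1, 1] == 1.0 and S[0, 1, 0] == 0.0
        np.testing.assert_array_equal(S[1, 1], 0.0)  # beyond sequence 1

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="unknown residue letter"):
            trc.initial_score_matrix([_cand((0, 0, 0))], ["AX"])

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            trc.initial_score_matrix([_cand((0, 0, 0))], [])


def _brute_propagate(S, adj, hops, decay):
    """Direct evaluation of the propagation formula via per-node BFS."""
    n_seq, lmax, n = S.shape

    def exactly_h(k, h):
        level = {k: 0}
        frontier = [k]
        for _ in range(h):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in level:
                        level[v] = level[u] + 1
                        nxt.append(v)
            frontier = nxt
        return [v for v, lv in level.items() if lv == h]

    E = S.astype(np.float64).copy()
    for i in range(n_seq):
        for j in range(lmax):
            for k in range(n):
                for h in range(1, hops + 1):
                    nb = exactly_h(k, h)
                    if not nb:
                        continue
                    left = max(S[i, j - h, kp] for kp in nb) if j - h >= 0 else 0.0
                    right = max(S[i, j + h, kp] for kp in nb) if j + h < lmax else 0.0
                    E[i, j, k] += decay ** h * 0.5 * (left + right)
    return E


class TestPropagateScores:
    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            edges = {(a, b) for a in range(n) for b in range(a + 1, n)
                     if rng.random() < 0.35}
            g = trc.TraceGraph(n=n, edges=edges).finalize()
            adj = [g.neighbors(k) for k in range(n)]
            S = rng.random((2, 5, n))
            E = trc.propagate_scores(S, g, hops=3, decay=0.5)
            ref = _brute_propagate(S, adj, 3, 0.5)
            np.testing.assert_allclose(E, ref, atol=1e-9)

    def test_isolated_node_unchanged(self):
        g = trc.TraceGraph(n=2, edges=set()).finalize()
        S = np.random.default_rng(1).random((1, 4, 2))
        E = trc.propagate_scores(S, g)
        np.testing.assert_array_equal(E, S)

    def test_zero_decay_is_identity(self):
        g = trc.TraceGraph(n=3, edges={(0, 1), (1, 2)}).finalize()
        S = np.random.default_rng(2).random((1, 4, 3))
        np.testing.assert_array_equal(trc.propagate_scores(S, g, decay=0.0), S)


class TestSeedAndExtend:
    def test_recovers_clean_line(self):
        seq = "AGVLKAGVLK"
        cands = _line_cands(seq, purity=0.9)
        g = trc.build_graph(cands)
        S = trc.initial_score_matrix(cands, [seq])
        E = trc.propagate_scores(S, g)
        frags = trc.seed_and_extend(E, g, [seq], cands)
        best = frags[0]
        assert best.seq_index == 0
        assert best.start == 0
        assert best.cand_ids == list(range(len(seq)))

    def test_no_candidate_or_slot_reuse(self):
        seq = "AGVLKAGVLK"
        cands = _line_cands(seq, purity=0.6) + _line_cands(seq[::-1], purity=0.6)
        for c in cands[len(seq):]:
            c.position = c.position + np.array([0.0, 30.0, 0.0])
        g = trc.build_graph(cands)
        E = trc.propagate_scores(trc.initial_score_matrix(cands, [seq]), g)
        frags = trc.seed_and_extend(E, g, [seq], cands)
        seen_c: set[int] = set()
        seen_s: set[tuple[int, int]] = set()
        for f in frags:
            for j, k in zip(f.residues(), f.cand_ids):
                assert k not in seen_c
                assert (f.seq_index, j) not in seen_s
                seen_c.add(k)
                seen_s.add((f.seq_index, j))

    def test_extension_respects_threshold(self):
        seq = "AGV"
        cands = _line_cands(seq, purity=1.0)
        # make the third residue's profile flat: E there ~ small
        cands[2].aa_profile = np.full(N_AA, 1.0 / N_AA)
        g = trc.build_graph(cands)
        E = trc.propagate_scores(trc.initial_score_matrix(cands, [seq]), g,
                                 hops=0)
        frags = trc.seed_and_extend(E, g, [seq], cands,
                                    config=trc.TracerConfig(extend_threshold=0.2))
        best = frags[0]
        assert 2 not in list(best.residues())

    def test_empty_candidates(self):
        E = np.zeros((1, 4, 0))
        g = trc.TraceGraph(n=0, edges=set()).finalize()
        assert trc.seed_and_extend(E, g, ["AGVL"], []) == []


class TestMergeFragments:
    def test_consistent_overlap_merges(self):
        E = np.ones((1, 6, 6))
        f1 = trc.Fragment(0, 0, [0, 1, 2], score=1.0)
        f2 = trc.Fragment(0, 2, [2, 3, 4], score=1.0)
        merged = trc._merge_fragments([f1, f2], E)
        assert len(merged) == 1
        assert merged[0].start == 0
        assert merged[0].cand_ids == [0, 1, 2, 3, 4]

    def test_conflicting_overlap_kept_apart(self):
        E = np.ones((1, 6, 6))
        f1 = trc.Fragment(0, 0, [0, 1, 2], score=1.0)
        f2 = trc.Fragment(0, 2, [5, 3, 4], score=1.0)  # residue 2 -> 5 != 2
        assert len(trc._merge_fragments([f1, f2], E)) == 2


class TestAssignChains:
    def test_two_copies_disjoint(self):
        seq = "AAAA"
        f1 = trc.Fragment(0, 0, [0, 1], score=1.0)
        f2 = trc.Fragment(0, 0, [2, 3], score=0.9)
        asg = trc.assign_chains([f1, f2], [seq], copies=[2])
        placed = sorted(tuple(sorted(i.placed.values())) for i in asg.instances)
        assert placed == [(0, 1), (2, 3)]

    def test_candidate_conflict_skipped(self):
        f1 = trc.Fragment(0, 0, [0, 1], score=1.0)
        f2 = trc.Fragment(0, 2, [1, 2], score=0.9)  # reuses candidate 1
        asg = trc.assign_chains([f1, f2], ["AAAA"], copies=[1])
        assert asg.used_cands == {0, 1}

    def test_spatial_coherence_prefers_nearby_instance(self):
        pos = [(0, 0, 0), (3.8, 0, 0),          # f1 near origin
               (7.6, 0, 0), (11.4, 0, 0),       # f3 near origin
               (100, 0, 0), (103.8, 0, 0)]      # f2 far away
        cands = [_cand(p) for p in pos]
        f1 = trc.Fragment(0, 0, [0, 1], score=1.0)
        f2 = trc.Fragment(0, 0, [4, 5], score=0.9)
        f3 = trc.Fragment(0, 2, [2, 3], score=0.8)
        asg = trc.assign_chains([f1, f2, f3], ["AAAA"], copies=[2],
                                candidates=cands)
        near = next(i for i in asg.instances if 0 in i.placed.values())
        assert sorted(near.placed) == [0, 1, 2, 3]
        assert sorted(near.placed.values()) == [0, 1, 2, 3]


class TestRefineWithPrior:
    def test_off_by_one_registration_corrected(self):
        pts = _zigzag(6)
        cands = [_cand(p) for p in pts]
        prior = _prior_from_points(pts)  # residue j (0-based) at pts[j]
        inst = trc.ChainInstance("A", 0, {j + 1: j for j in range(4)})  # +1 shift
        asg = trc.Assignment(instances=[inst], used_cands=set(range(4)))
        E = np.ones((1, 6, 6))
        trc.refine_with_prior(asg, cands, E, prior, ["A"])
        assert inst.placed == {j: j for j in range(4)}

    def test_correct_registration_untouched(self):
        pts = _zigzag(6)
        cands = [_cand(p) for p in pts]
        prior = _prior_from_points(pts)
        inst = trc.ChainInstance("A", 0, {j: j for j in range(4)})
        asg = trc.Assignment(instances=[inst], used_cands=set(range(4)))
        trc.refine_with_prior(asg, cands, np.ones((1, 6, 6)), prior, ["A"])
        assert inst.placed == {j: j for j in range(4)}

    def test_no_prior_is_noop(self):
        inst = trc.ChainInstance("A", 0, {0: 0})
        asg = trc.Assignment(instances=[inst], used_cands={0})
        out = trc.refine_with_prior(asg, [], np.ones((1, 2, 1)), None, ["A"])
        assert out.instances[0].placed == {0: 0}


class TestFillGaps:
    def test_exact_length_path_filled(self):
        cands = _line_cands("AAAAA")
        g = trc.build_graph(cands)
        inst = trc.ChainInstance("A", 0, {0: 0, 4: 4})
        asg = trc.Assignment(instances=[inst], used_cands={0, 4})
        trc.fill_gaps(asg, cands, g, np.ones((1, 5, 5)))
        assert inst.placed == {j: j for j in range(5)}
        assert asg.used_cands == set(range(5))

    def test_wrong_length_gap_left_open(self):
        cands = _line_cands("AAAAA")
        g = trc.build_graph(cands)
        # gap of 2 residues but the only connecting path has 3 candidates
        inst = trc.ChainInstance("A", 0, {0: 0, 3: 4})
        asg = trc.Assignment(instances=[inst], used_cands={0, 4})
        trc.fill_gaps(asg, cands, g, np.ones((1, 4, 5)))
        assert sorted(inst.placed) == [0, 3]

    def test_best_scoring_path_chosen(self):
        # diamond: two length-1 paths between anchors, E prefers candidate 2
        pos = [(0, 0, 0), (3.8, 1.5, 0), (3.8, -1.5, 0), (7.6, 0, 0)]
        cands = [_cand(p) for p in pos]
        g = trc.build_graph(cands)
        assert {(0, 1), (0, 2), (1, 3), (2, 3)} <= g.edges
        E = np.ones((1, 3, 4))
        E[0, 1, 1] = 0.4
        E[0, 1, 2] = 0.9
        inst = trc.ChainInstance("A", 0, {0: 0, 2: 3})
        asg = trc.Assignment(instances=[inst], used_cands={0, 3})
        trc.fill_gaps(asg, cands, g, E)
        assert inst.placed[1] == 2


class TestEvictAndComplete:
    def test_prior_outlier_evicted(self):
        pts = _zigzag(5)
        cands = [_cand(p) for p in pts] + [_cand((60.0, 0.0, 0.0))]
        prior = _prior_from_points(pts)
        inst = trc.ChainInstance("A", 0, {0: 0, 1: 1, 2: 5, 3: 3, 4: 4})
        asg = trc.Assignment(instances=[inst], used_cands={0, 1, 5, 3, 4})
        trc.evict_prior_outliers(asg, cands, prior, ["A"])
        assert 2 not in inst.placed
        assert 5 not in asg.used_cands
        assert sorted(inst.placed) == [0, 1, 3, 4]

    def test_prior_guided_completion_places_missing_residue(self):
        pts = _zigzag(5)
        cands = [_cand(p) for p in pts]
        prior = _prior_from_points(pts)
        inst = trc.ChainInstance("A", 0, {0: 0, 1: 1, 3: 3, 4: 4})
        asg = trc.Assignment(instances=[inst], used_cands={0, 1, 3, 4})
        trc.prior_guided_completion(asg, cands, prior, ["A"], [5])
        assert inst.placed.get(2) == 2

    def test_completion_respects_link_invariant(self):
        pts = _zigzag(5)
        # replace candidate 2 with one sitting on the prior position of
        # residue 2 but too close to the residue-1 candidate
        bad = pts[1] + 0.5 * (pts[2] - pts[1]) / np.linalg.norm(pts[2] - pts[1])
        cands = [_cand(p) for p in [pts[0], pts[1], bad, pts[3], pts[4]]]
        prior = _prior_from_points([pts[0], pts[1], bad, pts[3], pts[4]])
        inst = trc.ChainInstance("A", 0, {0: 0, 1: 1, 3: 3, 4: 4})
        asg = trc.Assignment(instances=[inst], used_cands={0, 1, 3, 4})
        trc.prior_guided_completion(asg, cands, prior, ["A"], [5])
        assert 2 not in inst.placed


class TestExtendTermini:
    def test_extends_to_both_ends(self):
        cands = _line_cands("AAAAA")
        g = trc.build_graph(cands)
        inst = trc.ChainInstance("A", 0, {2: 2})
        asg = trc.Assignment(instances=[inst], used_cands={2})
        trc.extend_termini(asg, cands, g, np.ones((1, 5, 5)), [5])
        assert sorted(inst.placed) == [0, 1, 2, 3, 4]


@pytest.fixture(scope="module")
def traced(sim_bundle):
    seqs = {cid: s for cid, s in sim_bundle["seqs"].items()}
    return trc.trace(sim_bundle["cands"], seqs, prior=sim_bundle["prior"])


class TestTraceEndToEnd:
    def test_high_completeness(self, sim_bundle, traced):
        n_true = sim_bundle["struct"].n_residues
        assert traced.placed_count() >= 0.9 * n_true

    def test_chain_ids_match_sequences(self, sim_bundle, traced):
        assert {cid for cid, _ in traced.chains} == set(sim_bundle["seqs"])

    def test_consecutive_ca_distances_physical(self, traced):
        for _, residues in traced.chains:
            placed = [r for r in residues if r.cand_id is not trc.GAP]
            for a, b in zip(placed, placed[1:]):
                if b.res_index == a.res_index + 1:
                    d = np.linalg.norm(b.coord - a.coord)
                    assert 2.0 <= d <= 6.0

    def test_each_candidate_used_once(self, traced):
        ids = [r.cand_id for _, res in traced.chains for r in res
               if r.cand_id is not trc.GAP]
        assert len(ids) == len(set(ids))

    def test_model_writes_as_pdb(self, traced, tmp_path):
        from catrace.struct_codec import read_structure
        path = tmp_path / "model.pdb"
        trc.write_model(traced, path)
        rt = read_structure(path)
        assert rt.n_residues == traced.placed_count()
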