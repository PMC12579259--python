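"""Backbone tracing and sequence registration.

Stages: build a connectivity graph over Calpha candidates (edges at
2-6 A, max degree 2 after pruning toward the ideal 3.8 A spacing);
construct a chain x residue x candidate score matrix from amino-acid
profiles; enhance it by decayed N-hop connectivity propagation; seed
high-score cells and extend bidirectionally along sequence and graph;
greedily assign conflict-free fragments to chain instances; refine
registrations against an optional predicted-structure prior; fill
intra-chain gaps by bidirectional exact-length path search; and emit a
CA-only backbone model.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .ca_cluster import CaCandidate
from .constants import AA_INDEX, ONE_TO_THREE
from .struct_codec import Chain, Residue, StructureModel, write_structure

GAP = None  # sentinel candidate id for unmodeled residues

_IDEAL_CA_CA = 3.8


@dataclass
class TracerConfig:
    link_min: float = 2.0
    link_max: float = 6.0
    hops: int = 3               # propagation depth H
    decay: float = 0.5          # propagation decay gamma
    seed_top_frac: float = 0.01  # seeds: top fraction of E cells...
    seed_min: float = 0.5        # ...but never below this score
    extend_threshold: float = 0.2
    prior_max_dev: float = 5.0  # A; reject steps deviating more from the prior
    shift_window: int = 2       # +/- registration shifts tested in refinement
    shift_max_e_loss: float = 0.1  # shift must not cost >10% of mean E
    max_gap: int = 12           # longest gap attempted by path search


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------

@dataclass
class TraceGraph:
    """Symmetric candidate connectivity graph with max degree 2."""

    n: int
    edges: set[tuple[int, int]]          # (a, b) with a < b
    dist: dict[tuple[int, int], float] = field(default_factory=dict)

    def neighbors(self, k: int) -> list[int]:
        return self._adj[k]

    def finalize(self) -> "TraceGraph":
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        self._adj = adj
        return self

    def hop_sets(self, max_h: int) -> list[list[list[int]]]:
        """hop_sets()[h][k] = nodes exactly h hops from k (h from 0)."""
        out = []
        for k in range(self.n):
            level = {k: 0}
            frontier = deque([k])
            while frontier:
                u = frontier.popleft()
                if level[u] >= max_h:
                    continue
                for v in self._adj[u]:
                    if v not in level:
                        level[v] = level[u] + 1
                        frontier.append(v)
            per_h = [[] for _ in range(max_h + 1)]
            for v, h in level.items():
                per_h[h].append(v)
            out.append(per_h)
        # transpose to [h][k]
        return [[out[k][h] for k in range(self.n)] for h in range(max_h + 1)]


def build_graph(candidates: list[CaCandidate],
                config: TracerConfig | None = None) -> TraceGraph:
    """Edges at 2-6 A; prune any node above degree 2 by dropping its edge
    whose length is farthest from 3.8 A (ties: the longer edge)."""
    cfg = config or TracerConfig()
    n = len(candidates)
    edges: set[tuple[int, int]] = set()
    dist: dict[tuple[int, int], float] = {}
    if n > 1:
        pos = np.array([c.position for c in candidates])
        d = cdist(pos, pos)
        for a in range(n):
            for b in range(a + 1, n):
                if cfg.link_min <= d[a, b] <= cfg.link_max:
                    edges.add((a, b))
                    dist[(a, b)] = float(d[a, b])
    degree = np.zeros(n, dtype=int)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    # badness: distance from ideal spacing, ties broken toward longer edges
    def badness(e):
        return (abs(dist[e] - _IDEAL_CA_CA), dist[e])

    changed = True
    while changed:
        changed = False
        for k in np.argsort(-degree):
            if degree[k] <= 2:
                continue
            incident = [e for e in edges if k in e]
            worst = max(incident, key=badness)
            edges.remove(worst)
            a, b = worst
            degree[a] -= 1
            degree[b] -= 1
            changed = True
            break
    return TraceGraph(n=n, edges=edges, dist=dist).finalize()


# ---------------------------------------------------------------------------
# score matrix
# ---------------------------------------------------------------------------

def initial_score_matrix(candidates: list[CaCandidate],
                         sequences: list[str]) -> np.ndarray:
    """S[i, j, k] = candidate k's profile probability of residue j of
    sequence i.  Shape (n_seqs, max length, n_candidates); rows beyond a
    sequence's length are zero."""
    if not sequences:
        raise ValueError("sequences must be non-empty")
    n_seq = len(sequences)
    lmax = max(len(s) for s in sequences)
    n = len(candidates)
    S = np.zeros((n_seq, lmax, n), dtype=np.float64)
    if n == 0:
        return S
    profiles = np.array([c.aa_profile for c in candidates])  # (n, 20)
    for i, seq in enumerate(sequences):
        for j, letter in enumerate(seq):
            three = ONE_TO_THREE.get(letter.upper())
            if three is None:
                raise ValueError(f"unknown residue letter {letter!r} in sequence {i}")
            S[i, j] = profiles[:, AA_INDEX[three]]
    return S


def propagate_scores(S: np.ndarray, graph: TraceGraph, hops: int = 3,
                     decay: float = 0.5) -> np.ndarray:
    """Decayed N-hop connectivity enhancement.

    E[i,j,k] = S[i,j,k] + sum_{h=1..H} decay^h * 0.5 * (
        max_{k' at exactly h hops from k} S[i, j-h, k'] +
        max_{k' at exactly h hops from k} S[i, j+h, k'] ),
    with out-of-range sequence offsets contributing 0.
    """
    E = S.astype(np.float64).copy()
    if graph.n == 0 or hops < 1 or decay == 0.0:
        return E
    n_seq, lmax, n = S.shape
    hop_sets = graph.hop_sets(hops)
    for h in range(1, hops + 1):
        # per-candidate max over its exact-h neighborhood, per (i, j)
        Mh = np.zeros((n_seq, lmax, n), dtype=np.float64)
        any_nb = np.zeros(n, dtype=bool)
        for k in range(n):
            nb = hop_sets[h][k]
            if nb:
                any_nb[k] = True
                Mh[:, :, k] = S[:, :, nb].max(axis=2)
        term = np.zeros_like(E)
        term[:, h:, :] += 0.5 * Mh[:, :lmax - h, :]   # j-h in range
        term[:, :lmax - h, :] += 0.5 * Mh[:, h:, :]   # j+h in range
        term[:, :, ~any_nb] = 0.0
        E += (decay ** h) * term
    return E


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """A contiguous registration: residues [start, start+len) of sequence
    ``seq_index`` mapped to candidate ids."""

    seq_index: int
    start: int
    cand_ids: list[int]
    score: float = 0.0

    @property
    def stop(self) -> int:
        return self.start + len(self.cand_ids)

    def residues(self):
        return range(self.start, self.stop)


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid fit of P onto Q: returns (R, t, rmsd) with
    mapping x -> R @ x + t."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


class _PriorIndex:
    """Per-sequence lookup of prior Calpha coordinates by 0-based residue."""

    def __init__(self, prior: StructureModel | None, seq_ids: list[str]):
        self.maps: list[dict[int, np.ndarray]] = [dict() for _ in seq_ids]
        if prior is None:
            return
        by_id = {ch.chain_id: ch for ch in prior.chains}
        for i, sid in enumerate(seq_ids):
            ch = by_id.get(sid)
            if ch is None:
                continue
            for r in ch.residues:
                if "CA" in r.atoms:
                    self.maps[i][r.seq_index - 1] = np.asarray(r.atoms["CA"], dtype=np.float64)


def _prior_step_ok(frag_res: list[int], frag_pos: np.ndarray, i: int,
                   new_j: int, new_pos: np.ndarray, prior_idx: _PriorIndex,
                   max_dev: float) -> bool:
    """Accept an extension step unless it lands > max_dev from the prior's
    corresponding residue after superposing the fragment on the prior."""
    m = prior_idx.maps[i]
    if new_j not in m:
        return True
    js = [j for j in frag_res if j in m]
    if len(js) < 3:
        return True
    P = np.array([frag_pos[frag_res.index(j)] for j in js])
    Q = np.array([m[j] for j in js])
    R, t, _ = _kabsch(P, Q)
    return float(np.linalg.norm(R @ new_pos + t - m[new_j])) <= max_dev


def seed_and_extend(E: np.ndarray, graph: TraceGraph, sequences: list[str],
                    candidates: list[CaCandidate],
                    prior: StructureModel | None = None,
                    seq_ids: list[str] | None = None,
                    config: TracerConfig | None = None) -> list[Fragment]:
    """Seed top-scoring cells and extend bidirectionally.

    Seeds are E cells in the top ``seed_top_frac`` (never below
    ``seed_min``), visited in descending order, skipping cells whose
    candidate or (sequence, residue) slot is already inside a fragment.
    Extension steps move to the graph neighbor maximizing E at the next
    residue, require the score to clear ``extend_threshold``, and -- when a
    prior is supplied -- must stay within ``prior_max_dev`` of the prior's
    corresponding residue after fragment superposition.  Overlapping
    fragments with consistent registration are merged; fragments are
    scored by mean E and returned ranked.
    """
    cfg = config or TracerConfig()
    n_seq, lmax, n = E.shape
    if n == 0:
        return []
    prior_idx = _PriorIndex(prior, seq_ids or [str(i) for i in range(n_seq)])
    pos = np.array([c.position for c in candidates])
    flat = E.reshape(-1)
    n_top = max(1, int(round(flat.size * cfg.seed_top_frac)))
    thresh = max(cfg.seed_min, np.partition(flat, -n_top)[-n_top])
    seed_cells = np.argwhere(E >= thresh)
    order = np.argsort(-E[tuple(seed_cells.T)])
    seed_cells = seed_cells[order]

    frags: list[Fragment] = []
    used_cand: set[int] = set()
    used_slot: set[tuple[int, int]] = set()
    seq_lens = [len(s) for s in sequences]
    for i, j, k in seed_cells:
        i, j, k = int(i), int(j), int(k)
        if j >= seq_lens[i] or k in used_cand or (i, j) in used_slot:
            continue
        res = [j]
        ids = [k]
        # extend both directions; alternate until both stall
        for direction in (+1, -1):
            cur_j, cur_k = (res[-1], ids[-1]) if direction > 0 else (res[0], ids[0])
            while True:
                nxt_j = cur_j + direction
                if nxt_j < 0 or nxt_j >= seq_lens[i] or (i, nxt_j) in used_slot:
                    break
                choices = [k2 for k2 in graph.neighbors(cur_k)
                           if k2 not in used_cand and k2 not in ids]
                if not choices:
                    break
                k2 = max(choices, key=lambda c: E[i, nxt_j, c])
                if E[i, nxt_j, k2] < cfg.extend_threshold:
                    break
                if not _prior_step_ok(res, pos[ids], i, nxt_j, pos[k2],
                                      prior_idx, cfg.prior_max_dev):
                    break
                if direction > 0:
                    res.append(nxt_j)
                    ids.append(k2)
                else:
                    res.insert(0, nxt_j)
                    ids.insert(0, k2)
                cur_j, cur_k = nxt_j, k2
        frag = Fragment(seq_index=i, start=res[0], cand_ids=ids)
        frag.score = float(np.mean([E[i, jj, kk] for jj, kk in zip(frag.residues(), ids)]))
        frags.append(frag)
        used_cand.update(ids)
        used_slot.update((i, jj) for jj in frag.residues())

    frags = _merge_fragments(frags, E)
    frags.sort(key=lambda f: -f.score)
    return frags


def _merge_fragments(frags: list[Fragment], E: np.ndarray) -> list[Fragment]:
    """Merge overlapping/adjacent fragments of the same sequence whose
    shared residues map to the same candidates."""
    changed = True
    while changed:
        changed = False
        for a in range(len(frags)):
            for b in range(a + 1, len(frags)):
                fa, fb = frags[a], frags[b]
                if fa.seq_index != fb.seq_index:
                    continue
                lo, hi = (fa, fb) if fa.start <= fb.start else (fb, fa)
                if hi.start > lo.stop:
                    continue  # disjoint with a gap; leave for gap filling
                overlap = range(hi.start, min(lo.stop, hi.stop))
                if any(lo.cand_ids[j - lo.start] != hi.cand_ids[j - hi.start]
                       for j in overlap):
                    continue
                ids = list(lo.cand_ids) + hi.cand_ids[len(overlap):]
                merged = Fragment(fa.seq_index, lo.start, ids)
                merged.score = float(np.mean(
                    [E[fa.seq_index, jj, kk]
                     for jj, kk in zip(merged.residues(), ids)]))
                frags = [f for idx, f in enumerate(frags) if idx not in (a, b)]
                frags.append(merged)
                changed = True
                break
            if changed:
                break
    return frags


# ---------------------------------------------------------------------------
# chain assignment
# ---------------------------------------------------------------------------

@dataclass
class ChainInstance:
    """One physical copy of a sequence; maps residue j -> candidate id."""

    instance_id: str
    seq_index: int
    placed: dict[int, int] = field(default_factory=dict)


@dataclass
class Assignment:
    instances: list[ChainInstance]
    used_cands: set[int] = field(default_factory=set)


def assign_chains(fragments: list[Fragment], sequences: list[str],
                  copies: list[int] | None = None,
                  candidates: list[CaCandidate] | None = None,
                  instance_ids: list[str] | None = None) -> Assignment:
    """Greedy conflict-free fragment-to-instance assignment.

    Fragments are visited in descending score; a fragment is accepted on
    an instance of its sequence iff none of its residues is already
    booked there and none of its candidates is used anywhere.  Among
    admissible instances the one with the best spatial coherence (lowest
    mean distance to the instance's placed candidates) wins; empty
    instances rank after occupied ones.
    """
    copies = copies or [1] * len(sequences)
    instances: list[ChainInstance] = []
    ids_given = list(instance_ids) if instance_ids else None
    next_ord = 0
    for i, c in enumerate(copies):
        for _ in range(c):
            iid = (ids_given[next_ord] if ids_given
                   else chr(ord("A") + next_ord % 26) + ("" if next_ord < 26 else str(next_ord // 26)))
            instances.append(ChainInstance(iid, i))
            next_ord += 1
    asg = Assignment(instances=instances)
    pos = (np.array([c.position for c in candidates])
           if candidates else None)
    for frag in sorted(fragments, key=lambda f: -f.score):
        if any(k in asg.used_cands for k in frag.cand_ids):
            continue
        options = []
        for inst in instances:
            if inst.seq_index != frag.seq_index:
                continue
            if any(j in inst.placed for j in frag.residues()):
                continue
            if inst.placed and pos is not None:
                inst_pos = pos[list(inst.placed.values())]
                frag_pos = pos[frag.cand_ids]
                coherence = float(cdist(frag_pos, inst_pos).mean())
                options.append((0, coherence, inst))
            else:
                options.append((1, 0.0, inst))
        if not options:
            continue
        options.sort(key=lambda o: (o[0], o[1]))
        inst = options[0][2]
        for j, k in zip(frag.residues(), frag.cand_ids):
            inst.placed[j] = k
        asg.used_cands.update(frag.cand_ids)
    return asg


# ---------------------------------------------------------------------------
# prior refinement and gap filling
# ---------------------------------------------------------------------------

def _contiguous_runs(placed: dict[int, int]) -> list[list[int]]:
    """Maximal runs of consecutive placed residue indices."""
    runs = []
    for j in sorted(placed):
        if runs and j == runs[-1][-1] + 1:
            runs[-1].append(j)
        else:
            runs.append([j])
    return runs


def refine_with_prior(asg: Assignment, candidates: list[CaCandidate],
                      E: np.ndarray, prior: StructureModel | None,
                      seq_ids: list[str],
                      config: TracerConfig | None = None) -> Assignment:
    """Test +/-shift_window registration shifts per contiguous run; adopt
    the shift minimizing Calpha RMSD to the superposed prior provided it
    keeps residues in range, creates no conflicts, and costs at most
    ``shift_max_e_loss`` of the run's mean E."""
    cfg = config or TracerConfig()
    if prior is None:
        return asg
    prior_idx = _PriorIndex(prior, seq_ids)
    pos = np.array([c.position for c in candidates]) if candidates else np.zeros((0, 3))
    lmax = E.shape[1]
    for inst in asg.instances:
        pmap = prior_idx.maps[inst.seq_index]
        if not pmap:
            continue
        for run in _contiguous_runs(inst.placed):
            ids = [inst.placed[j] for j in run]
            base_e = float(np.mean([E[inst.seq_index, j, k] for j, k in zip(run, ids)]))
            best = (0, np.inf)
            for shift in range(-cfg.shift_window, cfg.shift_window + 1):
                res2 = [j + shift for j in run]
                if res2[0] < 0 or res2[-1] >= lmax:
                    continue
                if shift != 0 and any(
                        j in inst.placed and j not in run for j in res2):
                    continue
                js = [j for j in res2 if j in pmap]
                if len(js) < 3:
                    continue
                P = np.array([pos[ids[res2.index(j)]] for j in js])
                Q = np.array([pmap[j] for j in js])
                _, _, rmsd = _kabsch(P, Q)
                e2 = float(np.mean([E[inst.seq_index, j, k]
                                    for j, k in zip(res2, ids)]))
                if e2 < base_e * (1.0 - cfg.shift_max_e_loss):
                    continue
                if rmsd < best[1] - 1e-12:
                    best = (shift, rmsd)
            shift = best[0]
            if shift != 0:
                for j in run:
                    del inst.placed[j]
                for j, k in zip(run, ids):
                    inst.placed[j + shift] = k
    return asg


def fill_gaps(asg: Assignment, candidates: list[CaCandidate],
              graph: TraceGraph, E: np.ndarray,
              prior: StructureModel | None = None,
              seq_ids: list[str] | None = None,
              config: TracerConfig | None = None) -> Assignment:
    """Fill intra-chain gaps with exact-length unassigned candidate paths.

    For each gap of g residues between placed anchors, enumerate simple
    paths of g unassigned candidates connecting the anchor candidates
    along graph edges (depth-first, both directions implicit in the
    search); keep the path with maximal summed E.  With a prior, partial
    paths deviating more than ``prior_max_dev`` from the instance-superposed
    prior positions are pruned.  Iterates until no gap can be filled.
    """
    cfg = config or TracerConfig()
    prior_idx = _PriorIndex(prior, seq_ids or [str(i) for i in range(E.shape[0])])
    pos = np.array([c.position for c in candidates]) if candidates else np.zeros((0, 3))

    def prior_transform(inst: ChainInstance):
        """Rigid map from candidate space onto the prior, fit on placed residues."""
        pmap = prior_idx.maps[inst.seq_index]
        js = [j for j in inst.placed if j in pmap]
        if len(js) < 3:
            return None
        P = np.array([pos[inst.placed[j]] for j in js])
        Q = np.array([pmap[j] for j in js])
        R, t, _ = _kabsch(P, Q)
        return R, t, pmap

    progress = True
    while progress:
        progress = False
        for inst in asg.instances:
            runs = _contiguous_runs(inst.placed)
            if len(runs) < 2:
                continue
            ptrans = prior_transform(inst)
            for ra, rb in zip(runs[:-1], runs[1:]):
                j1, j2 = ra[-1], rb[0]
                g = j2 - j1 - 1
                if g < 1 or g > cfg.max_gap:
                    continue
                k1, k2 = inst.placed[j1], inst.placed[j2]
                best_path, best_score = None, -np.inf
                stack = [(k1, [])]
                while stack:
                    cur, path = stack.pop()
                    if len(path) == g:
                        if k2 in graph.neighbors(cur):
                            sc = sum(E[inst.seq_index, j1 + 1 + idx, kk]
                                     for idx, kk in enumerate(path))
                            if sc > best_score:
                                best_score, best_path = sc, list(path)
                        continue
                    for nxt in graph.neighbors(cur):
                        if nxt in asg.used_cands or nxt in path or nxt == k2:
                            continue
                        if ptrans is not None:
                            R, t, pmap = ptrans
                            jj = j1 + 1 + len(path)
                            if jj in pmap and np.linalg.norm(
                                    R @ pos[nxt] + t - pmap[jj]) > cfg.prior_max_dev:
                                continue
                        stack.append((nxt, path + [nxt]))
                if best_path is not None:
                    for idx, kk in enumerate(best_path):
                        inst.placed[j1 + 1 + idx] = kk
                    asg.used_cands.update(best_path)
                    progress = True
    return asg


def evict_prior_outliers(asg: Assignment, candidates: list[CaCandidate],
                         prior: StructureModel | None, seq_ids: list[str],
                         config: TracerConfig | None = None) -> Assignment:
    """Unplace residues that disagree with the prior.

    Per instance: superpose the placed residues onto the prior, evict the
    worst-deviating residue while it exceeds ``prior_max_dev``, refit, and
    repeat.  Evicted candidates return to the unassigned pool so gap
    filling can re-place them consistently.
    """
    cfg = config or TracerConfig()
    if prior is None:
        return asg
    prior_idx = _PriorIndex(prior, seq_ids)
    pos = np.array([c.position for c in candidates]) if candidates else np.zeros((0, 3))
    for inst in asg.instances:
        pmap = prior_idx.maps[inst.seq_index]
        while True:
            js = [j for j in sorted(inst.placed) if j in pmap]
            if len(js) < 4:
                break
            P = pos[[inst.placed[j] for j in js]]
            Q = np.array([pmap[j] for j in js])
            R, t, _ = _kabsch(P, Q)
            dev = np.linalg.norm(P @ R.T + t - Q, axis=1)
            worst = int(np.argmax(dev))
            if dev[worst] <= cfg.prior_max_dev:
                break
            j = js[worst]
            asg.used_cands.discard(inst.placed[j])
            del inst.placed[j]
    return asg


def prior_guided_completion(asg: Assignment, candidates: list[CaCandidate],
                            prior: StructureModel | None, seq_ids: list[str],
                            seq_lens: list[int],
                            config: TracerConfig | None = None) -> Assignment:
    """Place remaining residues directly from the prior.

    Voxel quantization can leave the degree-pruned graph without the true
    consecutive edges, which stalls graph-constrained gap filling.  When a
    prior is available, superpose each instance onto it, map every still
    unplaced residue's prior position back into the map frame, and accept
    the nearest unassigned candidate within ``prior_max_dev`` provided the
    2-6 A consecutive-distance invariant holds against already placed
    sequence neighbors.  Iterates until no placement succeeds.
    """
    cfg = config or TracerConfig()
    if prior is None or not candidates:
        return asg
    prior_idx = _PriorIndex(prior, seq_ids)
    pos = np.array([c.position for c in candidates])
    progress = True
    while progress:
        progress = False
        for inst in asg.instances:
            pmap = prior_idx.maps[inst.seq_index]
            js = [j for j in sorted(inst.placed) if j in pmap]
            if len(js) < 3:
                continue
            P = pos[[inst.placed[j] for j in js]]
            Q = np.array([pmap[j] for j in js])
            R, t, _ = _kabsch(P, Q)
            for j in range(seq_lens[inst.seq_index]):
                if j in inst.placed or j not in pmap:
                    continue
                target = R.T @ (pmap[j] - t)  # prior position in map frame
                free = [k for k in range(len(candidates))
                        if k not in asg.used_cands]
                if not free:
                    continue
                d = np.linalg.norm(pos[free] - target, axis=1)
                order = np.argsort(d)
                for oi in order:
                    if d[oi] > cfg.prior_max_dev:
                        break
                    k = free[int(oi)]
                    ok = True
                    for nb in (j - 1, j + 1):
                        if nb in inst.placed:
                            step = float(np.linalg.norm(pos[k] - pos[inst.placed[nb]]))
                            if not cfg.link_min <= step <= cfg.link_max:
                                ok = False
                                break
                    if ok:
                        inst.placed[j] = k
                        asg.used_cands.add(k)
                        progress = True
                        break
    return asg


def extend_termini(asg: Assignment, candidates: list[CaCandidate],
                   graph: TraceGraph, E: np.ndarray, seq_lens: list[int],
                   prior: StructureModel | None = None,
                   seq_ids: list[str] | None = None,
                   config: TracerConfig | None = None) -> Assignment:
    """Extend each instance's outermost placed residues toward the chain
    termini with the same step rule as fragment extension."""
    cfg = config or TracerConfig()
    prior_idx = _PriorIndex(prior, seq_ids or [str(i) for i in range(E.shape[0])])
    pos = np.array([c.position for c in candidates]) if candidates else np.zeros((0, 3))
    for inst in asg.instances:
        if not inst.placed:
            continue
        for direction in (-1, +1):
            while True:
                j = (min if direction < 0 else max)(inst.placed)
                nxt = j + direction
                if nxt < 0 or nxt >= seq_lens[inst.seq_index] or nxt in inst.placed:
                    break
                cur_k = inst.placed[j]
                choices = [k for k in graph.neighbors(cur_k)
                           if k not in asg.used_cands]
                if not choices:
                    break
                k2 = max(choices, key=lambda c: E[inst.seq_index, nxt, c])
                if E[inst.seq_index, nxt, k2] < cfg.extend_threshold:
                    break
                frag_res = sorted(inst.placed)
                if not _prior_step_ok(frag_res, pos[[inst.placed[r] for r in frag_res]],
                                      inst.seq_index, nxt, pos[k2], prior_idx,
                                      cfg.prior_max_dev):
                    break
                inst.placed[nxt] = k2
                asg.used_cands.add(k2)
    return asg


# ---------------------------------------------------------------------------
# backbone model
# ---------------------------------------------------------------------------

@dataclass
class PlacedResidue:
    res_index: int              # 1-based residue number within the chain
    aa_type: str                # three-letter code
    cand_id: int | None         # GAP when unmodeled
    coord: np.ndarray | None    # world (x, y, z) Calpha position


@dataclass
class BackboneModel:
    """Per chain instance, the full residue range with placements/GAPs."""

    chains: list[tuple[str, list[PlacedResidue]]]

    def placed_count(self) -> int:
        return sum(1 for _, res in self.chains for r in res if r.cand_id is not GAP)

    def to_structure(self) -> StructureModel:
        chains = []
        for cid, residues in self.chains:
            rs = [Residue(r.res_index, r.aa_type, {"CA": np.asarray(r.coord)})
                  for r in residues if r.cand_id is not GAP]
            if rs:
                chains.append(Chain(cid, rs))
        return StructureModel(chains)


def assignment_to_model(asg: Assignment, candidates: list[CaCandidate],
                        sequences: list[str]) -> BackboneModel:
    chains = []
    for inst in asg.instances:
        seq = sequences[inst.seq_index]
        residues = []
        for j, letter in enumerate(seq):
            k = inst.placed.get(j)
            residues.append(PlacedResidue(
                res_index=j + 1,
                aa_type=ONE_TO_THREE[letter.upper()],
                cand_id=k if k is not None else GAP,
                coord=None if k is None else np.asarray(candidates[k].position)))
        chains.append((inst.instance_id, residues))
    return BackboneModel(chains=chains)


def write_model(model: BackboneModel, path) -> None:
    """Write the CA-only backbone model as a PDB file; GAPs are omitted."""
    write_structure(model.to_structure(), path)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def trace(candidates: list[CaCandidate], sequences: dict[str, str],
          prior: StructureModel | None = None,
          config: TracerConfig | None = None) -> BackboneModel:
    """Full tracing stage from candidates + per-chain sequences.

    ``sequences`` maps chain id to one-letter sequence; identical
    sequences under different ids become copies (instances) of one
    sequence row.
    """
    cfg = config or TracerConfig()
    seq_ids = list(sequences)
    uniq: list[str] = []
    copies: list[int] = []
    seq_row: dict[str, int] = {}
    inst_ids_by_row: dict[int, list[str]] = {}
    for cid in seq_ids:
        s = sequences[cid]
        if s not in seq_row:
            seq_row[s] = len(uniq)
            uniq.append(s)
            copies.append(0)
        row = seq_row[s]
        copies[row] += 1
        inst_ids_by_row.setdefault(row, []).append(cid)
    inst_ids = [cid for row in range(len(uniq)) for cid in inst_ids_by_row[row]]
    # prior chains must be addressed per sequence row: point each row at
    # a chain id holding that sequence (first copy wins for scoring; gap
    # filling/refinement superpose per instance anyway)
    row_prior_ids = [inst_ids_by_row[row][0] for row in range(len(uniq))]

    graph = build_graph(candidates, cfg)
    S = initial_score_matrix(candidates, uniq)
    E = propagate_scores(S, graph, hops=cfg.hops, decay=cfg.decay)
    frags = seed_and_extend(E, graph, uniq, candidates, prior=prior,
                            seq_ids=row_prior_ids, config=cfg)
    asg = assign_chains(frags, uniq, copies=copies, candidates=candidates,
                        instance_ids=inst_ids)
    asg = refine_with_prior(asg, candidates, E, prior, row_prior_ids, cfg)
    asg = evict_prior_outliers(asg, candidates, prior, row_prior_ids, cfg)
    asg = fill_gaps(asg, candidates, graph, E, prior=prior,
                    seq_ids=row_prior_ids, config=cfg)
    seq_lens = [len(s) for s in uniq]
    asg = extend_termini(asg, candidates, graph, E, seq_lens, prior=prior,
                         seq_ids=row_prior_ids, config=cfg)
    asg = fill_gaps(asg, candidates, graph, E, prior=prior,
                    seq_ids=row_prior_ids, config=cfg)
    asg = prior_guided_completion(asg, candidates, prior, row_prior_ids,
                                  seq_lens, cfg)
    return assignment_to_model(asg, candidates, uniq)
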