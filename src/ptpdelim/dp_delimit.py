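"""Maximum-likelihood delimitation search by dynamic programming.

The search visits all inner nodes in post-order.  Each node ``u`` carries an
array with one entry per possible count ``i`` of informative speciation
edges inside its subtree.  Entry 0 is the null model for the subtree (one
coalescent process); an entry ``i > 0`` is built from child entries ``j``
and ``k`` with ``i = j + k + 2`` (the +2 being u's two out-edges; +1/+0 when
an out-edge is below the minimum informative length and occupies no slot).
A candidate pair is scored by the likelihood restricted to the subtree plus
the smallest edge set S that must be speciation once the subtree contains
speciation edges — the edges incident to the path from the root down to u.
The best-scoring pair per entry is kept with backpointers (greedy: groupings
outside S and the subtree are not explored).

At the tree root S is empty, so each root entry's score is the exact model
log-likelihood of its backtracked delimitation; the entry minimizing AICc is
selected and the delimitation recovered by backtracking.

Both models run through the same recursion: the multi-rate score adds
per-process log-likelihoods (additive across subtrees), the single-rate
score carries pooled coalescent sufficient statistics (edge count and
length sum, also additive) and fits one rate at scoring time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core_model import (
    DEFAULT_MINBR,
    Delimitation,
    Model,
    ScoredDelimitation,
    aicc,
    score_delimitation,
)
from .tree_io import Tree

_NEG_INF = -math.inf


@dataclass
class DPTable:
    """Per-node DP arrays indexed by i = informative speciation edges in T_u.

    ``score[i]`` is −inf for invalid entries.  ``coal_loglik`` is the summed
    log-likelihood of completed coalescent processes inside the subtree
    (multi-rate); ``coal_n``/``coal_len`` are the pooled sufficient
    statistics of the same edges (single-rate); ``n_species`` counts the
    delimited species (coalescent subtrees, singletons included) inside the
    subtree; ``spec_sum``/``spec_count`` cover the
    informative speciation edges inside the subtree; ``back_j``/``back_k``
    are the chosen child entries (−1 for entry 0).
    """

    score: np.ndarray
    coal_loglik: np.ndarray
    coal_n: np.ndarray
    coal_len: np.ndarray
    n_species: np.ndarray
    spec_sum: np.ndarray
    spec_count: np.ndarray
    back_j: np.ndarray
    back_k: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.score > _NEG_INF


def _exp_ll(n: np.ndarray | int, total: np.ndarray | float):
    """Vectorized n·ln(n/Σℓ) − n with the empty-set convention ll = 0."""
    n_arr = np.asarray(n, dtype=float)
    t_arr = np.asarray(total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n_arr * (np.log(n_arr) - np.log(t_arr)) - n_arr
    return np.where(n_arr == 0, 0.0, out)


def compute_dp(
    tree: Tree, method: Model = "multi", minbr: float = DEFAULT_MINBR
) -> list[DPTable]:
    """Fill the per-node score arrays; returns one table per node id."""
    tree.require_rooted()
    nn = len(tree.nodes)
    # static subtree accumulators over informative edges
    sub_n = [0] * nn
    sub_len = [0.0] * nn
    for node in tree.nodes:
        for c in node.children:
            length = c.parent_edge_length
            inf_edge = length >= minbr
            sub_n[node.id] = sub_n[node.id] + sub_n[c.id] + (1 if inf_edge else 0)
            sub_len[node.id] = sub_len[node.id] + sub_len[c.id] + (length if inf_edge else 0.0)
    # S(u): informative edges incident to the path root..u, excluding T_u's
    # edges; S(root) is empty, S(child) = S(u) + u's two informative out-edges
    s_n = [0] * nn
    s_len = [0.0] * nn
    for node in reversed(tree.nodes):  # pre-order
        if node.children:
            extra_n = s_n[node.id]
            extra_len = s_len[node.id]
            for c in node.children:
                if c.parent_edge_length >= minbr:
                    extra_n += 1
                    extra_len += c.parent_edge_length
            for c in node.children:
                s_n[c.id] = extra_n
                s_len[c.id] = extra_len

    tables: list[DPTable | None] = [None] * nn
    for node in tree.nodes:
        size = sub_n[node.id] + 1
        tab = DPTable(
            score=np.full(size, _NEG_INF),
            coal_loglik=np.zeros(size),
            coal_n=np.zeros(size, dtype=np.int64),
            coal_len=np.zeros(size),
            n_species=np.zeros(size, dtype=np.int64),
            spec_sum=np.zeros(size),
            spec_count=np.zeros(size, dtype=np.int64),
            back_j=np.full(size, -1, dtype=np.int64),
            back_k=np.full(size, -1, dtype=np.int64),
        )
        # entry 0: the whole subtree is one coalescent process
        n0, l0 = sub_n[node.id], sub_len[node.id]
        tab.coal_loglik[0] = float(_exp_ll(n0, l0)) if n0 else 0.0
        tab.coal_n[0] = n0
        tab.coal_len[0] = l0
        tab.n_species[0] = 1
        tab.score[0] = _entry_score(
            method, tab.coal_loglik[0], n0, l0,
            s_n[node.id], s_len[node.id] + 0.0, 0, 0.0,
        )
        if node.children:
            v, w = node.children
            tv, tw = tables[v.id], tables[w.id]
            assert tv is not None and tw is not None
            lv = v.parent_edge_length
            lw = w.parent_edge_length
            iv, av = (1, lv) if lv >= minbr else (0, 0.0)
            iw, aw = (1, lw) if lw >= minbr else (0, 0.0)
            _combine(tab, tv, tw, iv, av, iw, aw,
                     s_n[node.id], s_len[node.id], method)
        tables[node.id] = tab
    return tables  # type: ignore[return-value]


def _entry_score(
    method: Model,
    coal_ll,
    coal_n,
    coal_len,
    spec_n,
    spec_len,
    sub_spec_n,
    sub_spec_len,
):
    """Heuristic score of an entry: coalescent term + speciation fit."""
    tot_spec_n = spec_n + sub_spec_n
    tot_spec_len = spec_len + sub_spec_len
    spec_ll = _exp_ll(tot_spec_n, tot_spec_len)
    if method == "multi":
        return coal_ll + spec_ll
    return _exp_ll(coal_n, coal_len) + spec_ll


def _combine(tab, tv, tw, iv, av, iw, aw, s_n, s_len, method):
    """Fill entries i = j + k + iv + iw from the two child tables."""
    kw = np.arange(len(tw.score))
    for j in range(len(tv.score)):
        if not tv.valid[j]:
            continue
        lo = j + iv + iw
        # index 0 is reserved for the single-process null entry; when both
        # out-edges are uninformative a (0,0) combination would collide
        ks = slice(1, None) if lo == 0 else slice(None)
        # candidate accumulators for all admissible k at once
        cll = tv.coal_loglik[j] + tw.coal_loglik[ks]
        cn = tv.coal_n[j] + tw.coal_n[ks]
        clen = tv.coal_len[j] + tw.coal_len[ks]
        ssum = tv.spec_sum[j] + tw.spec_sum[ks] + av + aw
        scnt = tv.spec_count[j] + tw.spec_count[ks] + iv + iw
        cand = np.asarray(
            _entry_score(method, cll, cn, clen, s_n, s_len, scnt, ssum)
        )
        cand = np.where(tw.valid[ks], cand, _NEG_INF)
        if cand.size == 0:
            continue
        start = max(lo, 1)
        sl = slice(start, start + cand.size)
        better = cand > tab.score[sl]  # strict: ties keep the smallest j
        if not better.any():
            continue
        tab.score[sl] = np.where(better, cand, tab.score[sl])
        for arr, src in (
            (tab.coal_loglik, cll),
            (tab.coal_len, clen),
            (tab.spec_sum, ssum),
        ):
            arr[sl] = np.where(better, src, arr[sl])
        tab.coal_n[sl] = np.where(better, cn, tab.coal_n[sl])
        tab.spec_count[sl] = np.where(better, scnt, tab.spec_count[sl])
        tab.n_species[sl] = np.where(
            better, tv.n_species[j] + tw.n_species[ks], tab.n_species[sl]
        )
        tab.back_j[sl] = np.where(better, j, tab.back_j[sl])
        tab.back_k[sl] = np.where(better, kw[ks], tab.back_k[sl])


@dataclass(frozen=True)
class MLResult:
    best: ScoredDelimitation
    root_profile: dict[int, float]  # root entry i -> AICc
    method: Model
    minbr: float
    n_ignored: int


_TIE_TOL = 1e-9


def select_and_backtrack(
    tree: Tree,
    tables: list[DPTable],
    method: Model = "multi",
    minbr: float = DEFAULT_MINBR,
) -> MLResult:
    """Pick the root entry minimizing AICc and recover its delimitation.

    At the root the stored score is the exact model log-likelihood, so AICc
    can be evaluated per entry without backtracking first.  Near-exact AICc
    ties (within 1e-9) are resolved toward fewer species (smaller i).  The
    returned score is recomputed from scratch as a guard.
    """
    root_tab = tables[tree.root.id]
    n_obs = int(root_tab.coal_n[0])  # informative edge total (entry 0 pools all)
    n_ignored = tree.n_edges - n_obs
    profile: dict[int, float] = {}
    for i in range(len(root_tab.score)):
        if not root_tab.valid[i]:
            continue
        ll = float(root_tab.score[i])
        spec_n = int(root_tab.spec_count[i])
        if method == "multi":
            p = (1 if spec_n else 0) + int(root_tab.n_species[i])
        else:
            p = (1 if spec_n else 0) + (1 if root_tab.coal_n[i] else 0)
        profile[i] = aicc(ll, p, n_obs)
    best_aicc = min(profile.values())
    best_i = min(i for i, a in profile.items() if a <= best_aicc + _TIE_TOL)

    roots: set[int] = set()
    _backtrack(tree.root.id, best_i, tables, tree, roots)
    delim = Delimitation(frozenset(roots))
    scored = score_delimitation(tree, delim, method, minbr)
    if profile[best_i] < math.inf and abs(scored.aicc - profile[best_i]) > 1e-6:
        raise AssertionError(
            f"backtracked delimitation rescored to {scored.aicc}, "
            f"root entry said {profile[best_i]}"
        )
    return MLResult(scored, profile, method, minbr, n_ignored)


def _backtrack(node_id, entry, tables, tree, roots: set[int]) -> None:
    stack = [(node_id, entry)]
    while stack:
        nid, e = stack.pop()
        if e == 0:
            roots.add(nid)
            continue
        tab = tables[nid]
        v, w = tree.nodes[nid].children
        stack.append((v.id, int(tab.back_j[e])))
        stack.append((w.id, int(tab.back_k[e])))


def ml_delimit(
    tree: Tree, method: Model = "multi", minbr: float = DEFAULT_MINBR
) -> MLResult:
    """Run the full DP search: tables, AICc selection, backtracking."""
    tables = compute_dp(tree, method, minbr)
    return select_and_backtrack(tree, tables, method, minbr)


# ---------------------------------------------------------------------------
# exhaustive oracles (small trees)


def count_delimitations(tree: Tree) -> int:
    """|Ω| by the recursion D(tip) = 1, D(u) = 1 + D(v)·D(w)."""
    tree.require_rooted()
    counts: dict[int, int] = {}
    for node in tree.nodes:
        if node.is_tip:
            counts[node.id] = 1
        else:
            v, w = node.children
            counts[node.id] = 1 + counts[v.id] * counts[w.id]
    return counts[tree.root.id]


def enumerate_delimitations(
    tree: Tree, cap: int = 10**6
) -> Iterator[Delimitation]:
    """Yield every delimitation exactly once (root-set encoding)."""
    tree.require_rooted()
    total = count_delimitations(tree)
    if total > cap:
        raise ValueError(
            f"{total} delimitations exceed the enumeration cap {cap}; "
            "use MCMC sampling instead"
        )

    def gen(node) -> Iterator[frozenset[int]]:
        yield frozenset({node.id})
        if node.children:
            v, w = node.children
            for a in gen(v):
                for b in gen(w):
                    yield a | b

    for roots in gen(tree.root):
        yield Delimitation(roots)


def brute_force_best(
    tree: Tree,
    method: Model = "multi",
    minbr: float = DEFAULT_MINBR,
    cap: int = 10**6,
) -> ScoredDelimitation:
    """Global AICc optimum by exhaustive scan; ties toward fewer species."""
    best: ScoredDelimitation | None = None
    for delim in enumerate_delimitations(tree, cap):
        s = score_delimitation(tree, delim, method, minbr)
        if best is None:
            best = s
            continue
        if s.aicc < best.aicc - _TIE_TOL:
            best = s
        elif s.aicc <= best.aicc + _TIE_TOL:
            if (s.delimitation.n_species, sorted(s.delimitation.coalescent_roots)) < (
                best.delimitation.n_species,
                sorted(best.delimitation.coalescent_roots),
            ):
                best = s
    assert best is not None
    return best
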