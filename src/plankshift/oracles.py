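"""Slow, independent reference implementations used for validation.

These deliberately avoid the optimized code paths: the alignment oracle
enumerates every overlap alignment explicitly, and the likelihood oracle
sums over all internal-state assignments instead of pruning. They are
practical only at toy sizes and exist so the fast implementations can be
checked against first principles.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from numba import njit

from .identity import _SCALE, AlignmentParams, AlignmentResult, encode
from .placement import BackboneTree, GTRModel, _EigenModel, _LEAF_PARTIAL


@njit(cache=False)
def _better(s, m, c, bs, bm, bc):  # pragma: no cover - numba
    """Lexicographic preference: score, then matches, then fewer columns."""
    if s != bs:
        return s > bs
    if m != bm:
        return m > bm
    return c < bc


@njit(cache=False)
def _enum_core(q, r, i, j, score, matches, cols, ms, mm, gp, strict, best):
    """Recursively extend an alignment core from cell (i, j).

    The core is the paid, column-counted stretch between the free leading
    and trailing end-runs. A core may legally stop at any cell on the last
    row or last column (the rest is a free trailing run in one sequence),
    so every such cell records a candidate.
    """
    n, m = len(q), len(r)
    if i == n or j == m:
        if _better(score, matches, cols, best[0], best[1], best[2]):
            best[0], best[1], best[2] = score, matches, cols
    if i < n and j < m:
        qi, rj = q[i], r[j]
        if strict:
            inter = qi == rj and (qi & (qi - 1)) == 0
        else:
            inter = (qi & rj) != 0
        s = score + (ms if inter else mm)
        mt = matches + (1 if inter else 0)
        _enum_core(q, r, i + 1, j + 1, s, mt, cols + 1, ms, mm, gp, strict, best)
    if i < n:
        _enum_core(q, r, i + 1, j, score + gp, matches, cols + 1, ms, mm, gp, strict, best)
    if j < m:
        _enum_core(q, r, i, j + 1, score + gp, matches, cols + 1, ms, mm, gp, strict, best)


@njit(cache=False)
def _enum_all(q, r, ms, mm, gp, strict):  # pragma: no cover - numba
    best = np.zeros(3, dtype=np.int64)  # empty alignment: (0, 0, 0)
    n, m = len(q), len(r)
    # a free leading run lies along the first row or the first column, so
    # cores start from any cell on those two edges
    for i0 in range(n + 1):
        _enum_core(q, r, i0, 0, 0, 0, 0, ms, mm, gp, strict, best)
    for j0 in range(1, m + 1):
        _enum_core(q, r, 0, j0, 0, 0, 0, ms, mm, gp, strict, best)
    return best[0], best[1], best[2]


def exhaustive_overlap(
    query: str, reference: str, params: AlignmentParams | None = None
) -> AlignmentResult:
    """Best overlap alignment by exhaustive enumeration (lengths <= ~10).

    Terminal gaps are free and uncounted; among equal-score alignments the
    one with more matches, then fewer columns, is preferred — the same
    deterministic rule the dynamic program uses.
    """
    params = params or AlignmentParams()
    ms, mm, gp = params.scaled()
    s, mt, c = _enum_all(
        encode(query.upper()), encode(reference.upper()),
        ms, mm, gp, not params.ambiguity_intersect,
    )
    return AlignmentResult(score=s / _SCALE, matches=int(mt), columns=int(c))


def enumeration_loglik(
    tree: BackboneTree, alignment: Mapping[str, str], model: GTRModel
) -> float:
    """Tree log-likelihood by brute-force summation over every assignment of
    states to internal nodes, per site and rate category. Exponential in the
    number of internal nodes; for 3-5 leaf trees only."""
    import itertools

    em = _EigenModel.from_model(model)
    leaves = tree.leaves
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    n_sites = len(next(iter(alignment.values())))
    P = {
        v: em.transition(tree.blen[v])
        for v in range(tree.n_nodes) if tree.parent[v] >= 0
    }
    leaf_part = {
        v: [_LEAF_PARTIAL[alignment[tree.names[v]].upper()[s]] for s in range(n_sites)]
        for v in leaves
    }
    total = 0.0
    for s in range(n_sites):
        site_like = 0.0
        for c, (rate_w) in enumerate(em.weights):
            cat_like = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, states))
                term = em.pi[st[tree.root]]
                for v in internals:
                    for ch in tree.children[v]:
                        if ch in st:
                            term *= P[ch][c][st[v], st[ch]]
                        else:
                            # leaf: marginalize over its (possibly ambiguous) state
                            term *= float(P[ch][c][st[v]] @ leaf_part[ch][s])
                cat_like += term
            site_like += rate_w * cat_like
        total += np.log(site_like)
    return float(total)
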