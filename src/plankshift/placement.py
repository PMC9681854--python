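"""Simplified evolutionary placement of query sequences on a fixed backbone tree.

Implements Felsenstein's pruning algorithm under a GTR model with
discrete-Gamma rate variation (plus an optional invariant-site category),
and places each pre-aligned query MOTU by attaching it at the midpoint of
every backbone edge, optimizing only the pendant branch length, and ranking
edges by log-likelihood. Likelihood weight ratios follow the jplace
convention: normalized exponentiated log-likelihood differences across all
candidate edges.

This is a deliberate simplification of the published evolutionary-placement
algorithms (no distal-position optimization, no heuristic preplacement); it
is adequate for clade-level assignment of short V9 amplicons.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .types import FormatError, IUPAC_DNA

_BASES = "ACGT"
# exchangeability order follows the usual GTR convention
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

PENDANT_BOUNDS = (1e-8, 2.0)


# ---------------------------------------------------------------------------
# substitution model


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability discrete-Gamma bins.

    The Gamma has mean 1 (shape == rate); category means are computed from
    the incomplete-gamma function so the mixture mean is exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1 / shape)
    # mean of X over [lo, hi) for X~Gamma(shape, 1/shape):
    # E[X; lo<=X<hi] = P(Gamma(shape+1) in [lo*shape, hi*shape)) / shape * shape
    upper = gammainc(shape + 1, edges[1:] * shape)
    lower = gammainc(shape + 1, edges[:-1] * shape)
    rates = (upper - lower) * k
    return rates


@dataclass
class GTRModel:
    """General time-reversible model with Gamma rate variation.

    ``exchangeabilities`` are the six symmetric rates (AC, AG, AT, CG, CT,
    GT); TVM is the special case with AG == CT. The rate matrix is scaled so
    the expected substitution rate, averaged over the rate-category mixture
    (including a zero-rate invariant category of weight ``p_invariant``),
    equals 1 — branch lengths are then in expected substitutions per site.
    """

    exchangeabilities: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.base_frequencies, dtype=float)
        if ex.shape != (6,) or np.any(ex < 0) or not np.any(ex > 0):
            raise ValueError("need 6 non-negative exchangeabilities, not all zero")
        if fr.shape != (4,) or np.any(fr <= 0):
            raise ValueError("need 4 positive base frequencies")
        if not np.isclose(fr.sum(), 1.0, atol=1e-8):
            raise ValueError("base frequencies must sum to 1")
        if not 0 <= self.p_invariant < 1:
            raise ValueError("p_invariant must be in [0, 1)")
        self.exchangeabilities = ex
        self.base_frequencies = fr / fr.sum()

    def rate_matrix(self) -> np.ndarray:
        """Frequency-scaled rate matrix Q with rows summing to 0, mean rate 1
        across the category mixture."""
        ex = self.exchangeabilities
        pi = self.base_frequencies
        R = np.zeros((4, 4))
        for k, pair in enumerate(EXCHANGE_ORDER):
            i, j = _BASES.index(pair[0]), _BASES.index(pair[1])
            R[i, j] = R[j, i] = ex[k]
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(pi, np.diag(Q))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (zero mean rate)")
        # the invariant category contributes rate 0; rescale the variable
        # categories so the mixture mean stays 1
        return Q / (mean_rate * (1.0 - self.p_invariant))

    def category_rates_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-category relative rates and weights (invariant class first
        when ``p_invariant > 0``)."""
        rates = discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
        weights = np.full(self.n_rate_categories, 1.0 / self.n_rate_categories)
        if self.p_invariant > 0:
            rates = np.concatenate([[0.0], rates])
            weights = np.concatenate(
                [[self.p_invariant], (1 - self.p_invariant) * weights]
            )
        return rates, weights

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via its symmetrized form (stable for
        reversible models): returns (eigenvalues, U, U^-1) with
        P(t) = U diag(exp(lambda t)) U^-1."""
        Q = self.rate_matrix()
        pi = self.base_frequencies
        sq = np.sqrt(pi)
        S = (Q * sq[None, :]) / sq[:, None]
        lam, V = np.linalg.eigh((S + S.T) / 2)
        U = V / sq[:, None]
        Uinv = V.T * sq[None, :]
        return lam, U, Uinv


@dataclass
class _EigenModel:
    """Precomputed pieces for fast transition probabilities."""

    lam: np.ndarray
    U: np.ndarray
    Uinv: np.ndarray
    pi: np.ndarray
    rates: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_model(cls, model: GTRModel) -> "_EigenModel":
        lam, U, Uinv = model.eigen()
        rates, weights = model.category_rates_weights()
        return cls(lam, U, Uinv, np.asarray(model.base_frequencies), rates, weights)

    def transition(self, t: float) -> np.ndarray:
        """P(t * rate_c) for every rate category: shape (ncat, 4, 4)."""
        if t < 0:
            raise ValueError("negative branch length")
        ex = np.exp(self.lam[None, :] * (t * self.rates)[:, None])  # (ncat, 4)
        P = np.einsum("ij,cj,jk->cik", self.U, ex, self.Uinv)
        return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# backbone tree


@dataclass
class BackboneTree:
    """Rooted binary backbone with stable jplace-style edge numbers.

    Nodes are stored in postorder (root last). ``edge_num[v]`` numbers the
    edge above node ``v`` in postorder visiting order (root: -1), the
    convention jplace files use.
    """

    children: list[list[int]]
    parent: np.ndarray
    blen: np.ndarray
    names: list[str | None]
    edge_num: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]  # type: ignore[misc]

    def edge_nodes(self) -> list[int]:
        """Nodes carrying a (numbered) parent edge, in edge-number order."""
        order = [v for v in range(self.n_nodes) if v != self.root]
        return sorted(order, key=lambda v: self.edge_num[v])

    def node_of_edge(self, edge_id: int) -> int:
        for v in range(self.n_nodes):
            if self.edge_num[v] == edge_id:
                return v
        raise KeyError(f"no edge {edge_id}")

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "BackboneTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = []
        parent = np.full(len(nodes), -1, dtype=int)
        blen = np.zeros(len(nodes))
        names: list[str | None] = []
        edge_num = np.full(len(nodes), -1, dtype=int)
        counter = 0
        for i, nd in enumerate(nodes):
            kids = [index[id(c)] for c in nd.child_nodes()]
            if len(kids) not in (0, 2):
                raise FormatError("backbone tree must be binary")
            children.append(kids)
            names.append(nd.taxon.label if nd.taxon else None)
            for c in nd.child_nodes():
                parent[index[id(c)]] = i
            if nd.parent_node is not None:
                if nd.edge.length is None or not np.isfinite(nd.edge.length):
                    raise FormatError("every backbone edge needs a finite length")
                blen[i] = float(nd.edge.length)
                edge_num[i] = counter
                counter += 1
        leaf_labels = [n for n, ch in zip(names, children) if not ch]
        if len(set(leaf_labels)) != len(leaf_labels) or None in leaf_labels:
            raise FormatError("leaf names must be present and unique")
        return cls(children, parent, blen, names, edge_num)

    @classmethod
    def from_newick(cls, newick: str) -> "BackboneTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    def to_newick(self, edge_numbers: bool = False) -> str:
        def fmt(v: int) -> str:
            if self.children[v]:
                core = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
                label = self.names[v] or ""
            else:
                core = ""
                label = self.names[v]
            s = f"{core}{label}"
            if self.parent[v] >= 0:
                s += f":{self.blen[v]:.10g}"
                if edge_numbers:
                    s += "{%d}" % self.edge_num[v]
            return s

        return fmt(self.root) + ";"


def read_tree(path: str | os.PathLike) -> BackboneTree:
    with open(path) as fh:
        return BackboneTree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# pruning likelihood

_LEAF_PARTIAL = {}
for _c, _bases in IUPAC_DNA.items():
    _LEAF_PARTIAL[_c] = np.array(
        [1.0 if b in _bases else 0.0 for b in _BASES]
    )
_LEAF_PARTIAL["-"] = np.ones(4)
_LEAF_PARTIAL["."] = np.ones(4)
_LEAF_PARTIAL["?"] = np.ones(4)


def _encode_alignment(seqs: Mapping[str, str], names: Sequence[str]) -> np.ndarray:
    """(n_leaves, n_sites, 4) partial-likelihood tensor; gaps = missing."""
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise FormatError("alignment rows have unequal lengths")
    (L,) = lengths
    if L == 0:
        raise FormatError("zero-length alignment")
    out = np.empty((len(names), L, 4))
    for i, name in enumerate(names):
        if name not in seqs:
            raise FormatError(f"leaf {name!r} has no aligned sequence")
        s = seqs[name].upper()
        for j, ch in enumerate(s):
            try:
                out[i, j] = _LEAF_PARTIAL[ch]
            except KeyError:
                raise FormatError(
                    f"sequence {name!r}: invalid character {ch!r}"
                ) from None
    return out


def _compress(leaf_tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Site-pattern compression: unique columns and their multiplicities."""
    n, L, _ = leaf_tensor.shape
    flat = leaf_tensor.transpose(1, 0, 2).reshape(L, n * 4)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    weights = np.bincount(inverse, minlength=len(uniq)).astype(float)
    patterns = uniq.reshape(len(uniq), n, 4).transpose(1, 0, 2)
    return patterns, weights


def _down_partials(
    tree: BackboneTree, em: _EigenModel, leaf_patterns: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Postorder conditional likelihoods.

    Returns (down, scale, P) where ``down[v]`` has shape (ncat, npat, 4),
    ``scale[v]`` is the per-pattern log scaling absorbed below v, and
    ``P[v]`` the transition matrices of v's parent edge.
    """
    ncat = len(em.rates)
    npat = leaf_patterns.shape[1]
    N = tree.n_nodes
    down = np.ones((N, ncat, npat, 4))
    scale = np.zeros((N, npat))
    P = np.zeros((N, ncat, 4, 4))
    leaf_row = {v: i for i, v in enumerate(tree.leaves)}
    for v in range(N):
        if tree.parent[v] >= 0:
            P[v] = em.transition(tree.blen[v])
        if not tree.children[v]:
            down[v] = leaf_patterns[leaf_row[v]][None, :, :]
            continue
        for c in tree.children[v]:
            # (ncat, npat, 4) x (ncat, 4, 4) -> message from child c
            msg = np.einsum("cxy,cpy->cpx", P[c], down[c])
            down[v] = down[v] * msg
            scale[v] += scale[c]
        m = down[v].max(axis=(0, 2))  # per-pattern
        m = np.where(m > 0, m, 1.0)
        down[v] /= m[None, :, None]
        scale[v] += np.log(m)
    return down, scale, P


def tree_loglik(
    tree: BackboneTree, alignment: Mapping[str, str], model: GTRModel
) -> float:
    """Log-likelihood of the reference alignment on the backbone.

    Felsenstein pruning over compressed site patterns with the
    discrete-Gamma (+ invariant) rate mixture and per-node scaling.
    """
    em = _EigenModel.from_model(model)
    leaf_tensor = _encode_alignment(alignment, tree.leaf_names)
    patterns, weights = _compress(leaf_tensor)
    down, scale, _ = _down_partials(tree, em, patterns)
    root = tree.root
    site = np.einsum("x,cpx->cp", em.pi, down[root])
    site = np.einsum("c,cp->p", em.weights, site)
    return float(np.dot(weights, np.log(site) + scale[root]))


# ---------------------------------------------------------------------------
# placement


@dataclass(frozen=True)
class Placement:
    """One candidate attachment of a query on a backbone edge."""

    query_id: str
    edge_id: int
    pendant_length: float
    log_likelihood: float
    like_weight_ratio: float
    at_bound: bool = False


def _up_conditionals(
    tree: BackboneTree,
    em: _EigenModel,
    down: np.ndarray,
    scale: np.ndarray,
    P: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Preorder 'rest of tree' conditionals.

    ``up[v]`` is the conditional likelihood, evaluated at v's parent, of all
    data outside the subtree of v (no prior applied); ``upscale[v]`` its
    per-pattern log scaling.
    """
    N = tree.n_nodes
    ncat, npat = down.shape[1], down.shape[2]
    up = np.ones((N, ncat, npat, 4))
    upscale = np.zeros((N, npat))
    for v in range(N - 1, -1, -1):  # preorder = reverse postorder
        kids = tree.children[v]
        if not kids:
            continue
        # conditional of everything above v, transported from v's parent to v
        if tree.parent[v] >= 0:
            above_v = np.einsum("cxy,cpy->cpx", P[v], up[v])
            above_sc = upscale[v]
        else:
            above_v = np.ones((ncat, npat, 4))
            above_sc = np.zeros(npat)
        for c in kids:
            acc = above_v.copy()
            sc = above_sc.copy()
            for s in kids:
                if s == c:
                    continue
                msg = np.einsum("cxy,cpy->cpx", P[s], down[s])
                acc = acc * msg
                sc = sc + scale[s]
            m = acc.max(axis=(0, 2))
            m = np.where(m > 0, m, 1.0)
            up[c] = acc / m[None, :, None]
            upscale[c] = sc + np.log(m)
    return up, upscale


def place_query(
    tree: BackboneTree,
    alignment: Mapping[str, str],
    model: GTRModel,
    query: str,
    query_id: str = "query",
    pendant_bounds: tuple[float, float] = PENDANT_BOUNDS,
) -> list[Placement]:
    """Place one pre-aligned query on every backbone edge, best edge first.

    The query is attached at each edge midpoint on a pendant branch whose
    length is optimized by bounded one-dimensional likelihood maximization;
    ``like_weight_ratio`` normalizes the per-edge maxima to sum to 1.
    """
    names = tree.leaf_names
    widths = {len(s) for s in alignment.values()}
    if len(widths) != 1 or len(query) not in widths:
        raise FormatError(
            f"query {query_id!r}: length {len(query)} does not match the "
            f"reference alignment width"
        )
    if all(ch in "-.?" for ch in query.upper()):
        raise FormatError(f"query {query_id!r} is unplaceable: no non-gap columns")
    em = _EigenModel.from_model(model)
    leaf_tensor = _encode_alignment(alignment, names)
    qrow = _encode_alignment({"q": query}, ["q"])[0]
    patterns, weights = _compress(
        np.concatenate([leaf_tensor, qrow[None]], axis=0)
    )
    qpat = patterns[-1]  # (npat, 4)
    patterns = patterns[:-1]
    down, scale, P = _down_partials(tree, em, patterns)
    up, upscale = _up_conditionals(tree, em, down, scale, P)

    results: list[tuple[int, float, float, bool]] = []
    lo, hi = pendant_bounds
    for v in tree.edge_nodes():
        half = em.transition(tree.blen[v] / 2.0)
        dmid = np.einsum("cxy,cpy->cpx", half, down[v])
        umid = np.einsum("cxy,cpy->cpx", half, up[v])
        base = dmid * umid * em.pi[None, None, :]  # (ncat, npat, 4)
        const = scale[v] + upscale[v]

        def negll(t: float) -> float:
            Pq = em.transition(t)
            qp = np.einsum("cxy,py->cpx", Pq, qpat)
            site = np.einsum("c,cpx,cpx->p", em.weights, base, qp)
            site = np.maximum(site, 1e-300)
            return -float(np.dot(weights, np.log(site) + const))

        res = minimize_scalar(
            negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-7},
        )
        t_opt = float(res.x)
        at_bound = t_opt <= lo * 1.01 or t_opt >= hi * (1 - 1e-6)
        # the bounded optimizer never lands exactly on a bound; evaluate them
        ll_opt = -negll(t_opt)
        for b in (lo, hi):
            llb = -negll(b)
            if llb > ll_opt:
                t_opt, ll_opt, at_bound = b, llb, True
        results.append((int(tree.edge_num[v]), t_opt, ll_opt, at_bound))

    lls = np.array([r[2] for r in results])
    w = np.exp(lls - lls.max())
    w = w / w.sum()
    placements = [
        Placement(
            query_id=query_id, edge_id=e, pendant_length=t,
            log_likelihood=ll, like_weight_ratio=float(wi), at_bound=ab,
        )
        for (e, t, ll, ab), wi in zip(results, w)
    ]
    placements.sort(key=lambda p: (-p.log_likelihood, p.edge_id))
    return placements


def place_all(
    tree: BackboneTree,
    alignment: Mapping[str, str],
    model: GTRModel,
    queries: Mapping[str, str],
) -> dict[str, list[Placement]]:
    return {
        qid: place_query(tree, alignment, model, seq, query_id=qid)
        for qid, seq in queries.items()
    }


def placements_per_clade(
    placements: Mapping[str, list[Placement]],
    edge_to_clade: Mapping[int, str],
    labels: Mapping[str, str] | None = None,
):
    """Contingency table of best-edge clades by lifestyle label.

    ``edge_to_clade`` maps edge ids to named backbone clades (missing edges
    count as "unassigned"); ``labels`` maps query ids to a lifestyle call
    (default: all "putative_planktonic").
    """
    import pandas as pd

    rows: dict[tuple[str, str], int] = {}
    for qid, plist in placements.items():
        if not plist:
            continue
        best = plist[0]
        clade = edge_to_clade.get(best.edge_id, "unassigned")
        label = labels.get(qid, "unknown") if labels is not None else "putative_planktonic"
        rows[(clade, label)] = rows.get((clade, label), 0) + 1
    df = pd.DataFrame(
        [(c, l, n) for (c, l), n in sorted(rows.items())],
        columns=["clade", "label", "n_motus"],
    )
    return df


# ---------------------------------------------------------------------------
# jplace

JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio", "pendant_length"]


def write_jplace(
    placements: Mapping[str, list[Placement]],
    tree: BackboneTree,
    path: str | os.PathLike,
    invocation: str = "plankshift place",
) -> None:
    """Write placements as a jplace v3 document."""
    doc = {
        "version": 3,
        "tree": tree.to_newick(edge_numbers=True),
        "fields": JPLACE_FIELDS,
        "placements": [
            {
                "p": [
                    [p.edge_id, p.log_likelihood, p.like_weight_ratio, p.pendant_length]
                    for p in plist
                ],
                "n": [qid],
            }
            for qid, plist in placements.items()
        ],
        "metadata": {"invocation": invocation},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_jplace(path: str | os.PathLike) -> dict[str, list[Placement]]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != 3 or doc.get("fields") != JPLACE_FIELDS:
        raise FormatError(f"{path}: not a jplace v3 file with expected fields")
    out: dict[str, list[Placement]] = {}
    for entry in doc["placements"]:
        (qid,) = entry["n"]
        out[qid] = [
            Placement(
                query_id=qid, edge_id=int(e), pendant_length=float(t),
                log_likelihood=float(ll), like_weight_ratio=float(w),
            )
            for e, ll, w, t in entry["p"]
        ]
    return out


# ---------------------------------------------------------------------------
# model estimation on a fixed topology


def estimate_model(
    tree: BackboneTree,
    alignment: Mapping[str, str],
    init: GTRModel | None = None,
    estimate_frequencies: bool = False,
    maxiter: int = 400,
) -> GTRModel:
    """Estimate GTR exchangeabilities and Gamma shape by direct maximization
    of :func:`tree_loglik` on the fixed backbone (Nelder-Mead on a log/softmax
    parameterization). Base frequencies default to their empirical values.
    """
    from scipy.optimize import minimize

    if init is None:
        counts = np.zeros(4)
        for s in alignment.values():
            for ch, k in zip("ACGT", range(4)):
                counts[k] += s.upper().count(ch)
        freqs = (counts + 1.0) / (counts.sum() + 4.0)
        init = GTRModel(base_frequencies=tuple(freqs))

    def unpack(x: np.ndarray) -> GTRModel:
        ex = np.exp(np.concatenate([x[:5], [0.0]]))  # GT fixed to 1
        shape = float(np.exp(x[5]))
        if estimate_frequencies:
            f = np.exp(np.concatenate([x[6:9], [0.0]]))
            f = f / f.sum()
        else:
            f = init.base_frequencies
        return GTRModel(
            exchangeabilities=tuple(ex), base_frequencies=tuple(f),
            gamma_shape=shape, n_rate_categories=init.n_rate_categories,
            p_invariant=init.p_invariant,
        )

    x0 = np.concatenate(
        [
            np.log(np.asarray(init.exchangeabilities[:5]) / init.exchangeabilities[5]),
            [np.log(init.gamma_shape)],
            np.log(np.asarray(init.base_frequencies[:3]) / init.base_frequencies[3])
            if estimate_frequencies
            else [],
        ]
    )

    def neg(x: np.ndarray) -> float:
        try:
            return -tree_loglik(tree, alignment, unpack(x))
        except (ValueError, FloatingPointError):
            return 1e12

    res = minimize(neg, x0, method="Nelder-Mead", options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
    return unpack(res.x)
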