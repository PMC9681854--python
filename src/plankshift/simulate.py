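"""Synthetic TARA-like worlds with known ground truth.

The generator is the stand-in for the study's raw data: a station network
spanning a wide distance-to-coast gradient, a clade-structured V9 reference
database, and MOTUs whose station occupancy follows a logistic
distance-decay model — passively advected benthic taxa decay away from the
coast (beta1 < 0) while holoplanktonic taxa are flat or increasing
(beta1 >= 0). A configurable fraction of the Globothalamea MOTUs receives
planktonic-type occupancy: these are the "putative planktonic" targets the
downstream classifier must recover.

Everything is deterministic given the spec's seed; each operation draws
from its own spawned substream so stages stay reproducible in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import io as psio
from .placement import BackboneTree, GTRModel, _EigenModel
from .types import (
    BENTHIC_CATEGORIES,
    CLADE_CATEGORIES,
    LIFESTYLE_BENTHIC,
    LIFESTYLE_PLANKTONIC,
    OccurrenceTable,
    PLANKTONIC_CATEGORIES,
    ReferenceRecord,
    SampleRecord,
    TARGET_CATEGORY,
)

_BASES = np.array(list("ACGT"))

#: TARA-style size fraction labels (µm).
DEFAULT_SIZE_FRACTIONS = ["0.8-5", "5-20", "20-180", "180-2000"]


@dataclass(frozen=True)
class OccupancyPrior:
    """Uniform prior box for a MOTU's logistic occupancy coefficients.

    beta0 is the log-odds of presence at the coast; beta1 the change in
    log-odds per km of distance to coast.
    """

    beta0_low: float
    beta0_high: float
    beta1_low: float
    beta1_high: float

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        return (
            float(rng.uniform(self.beta0_low, self.beta0_high)),
            float(rng.uniform(self.beta1_low, self.beta1_high)),
        )


# Planktonic occupancy: flat-to-increasing with distance (beta1 >= 0).
PLANKTONIC_PRIOR = OccupancyPrior(-1.5, 0.5, 0.0, 0.002)
# Benthic occupancy: common near shore, decaying offshore (beta1 < 0).
BENTHIC_PRIOR = OccupancyPrior(1.0, 3.0, -0.006, -0.0015)

DEFAULT_OCCUPANCY = {
    "Spinose": PLANKTONIC_PRIOR,
    "Non-Spinose": PLANKTONIC_PRIOR,
    "Microperforates": PLANKTONIC_PRIOR,
    "Basal": PLANKTONIC_PRIOR,
    "Monothalamea": BENTHIC_PRIOR,
    "Tubothalamea": BENTHIC_PRIOR,
    "Globothalamea": BENTHIC_PRIOR,
}

DEFAULT_MOTUS_PER_CATEGORY = {
    "Spinose": 30,
    "Non-Spinose": 30,
    "Microperforates": 30,
    "Basal": 30,
    "Monothalamea": 20,
    "Tubothalamea": 20,
    "Globothalamea": 120,
}


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of one synthetic world; the seed makes it reproducible."""

    n_stations: int = 150
    distance_range: tuple[float, float] = (1.0, 2000.0)
    size_fractions: tuple[str, ...] = tuple(DEFAULT_SIZE_FRACTIONS)
    n_motus_per_category: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOTUS_PER_CATEGORY)
    )
    occupancy_params: Mapping[str, OccupancyPrior] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    #: prior used for the planktonic-type fraction of Globothalamea MOTUs
    putative_planktonic_prior: OccupancyPrior = PLANKTONIC_PRIOR
    putative_planktonic_fraction: float = 0.30
    count_mean: float = 50.0
    count_dispersion: float = 0.5  # negative-binomial size parameter
    seq_length: int = 130
    n_refs_per_category: int = 5
    ref_divergence: float = 0.02  # per-site substitution prob. ancestor->ref
    motu_divergence: float = 0.02  # per-site substitution prob. ancestor->MOTU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_range[0] <= 0:
            raise ValueError("km_min must be > 0 (log-uniform distances)")
        if self.distance_range[1] <= self.distance_range[0]:
            raise ValueError("distance_range must be increasing")
        if not 0 <= self.putative_planktonic_fraction <= 1:
            raise ValueError("putative_planktonic_fraction must be in [0, 1]")
        missing = [c for c in self.n_motus_per_category if c not in self.occupancy_params]
        if missing:
            raise ValueError(f"occupancy_params missing categories: {missing}")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50 nt")


@dataclass(frozen=True)
class MotuTruth:
    """Generator ground truth for one MOTU."""

    lifestyle: str  # planktonic | benthic
    beta0: float
    beta1: float
    source_category: str


@dataclass
class SyntheticWorld:
    """A complete generated dataset plus its ground truth."""

    spec: WorldSpec
    metadata: list[SampleRecord]
    reference_db: list[ReferenceRecord]
    ancestors: dict[str, str]
    motu_sequences: dict[str, str]
    occurrence: OccurrenceTable
    truth: dict[str, MotuTruth]
    #: station x MOTU presence draws (stations in metadata station order)
    presence_truth: dict[str, np.ndarray]
    station_order: list[str]


def _rngs(spec: WorldSpec, n: int) -> list[np.random.Generator]:
    """Fixed-order substreams: stations, references, motus, counts, ..."""
    ss = np.random.SeedSequence(spec.seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# stations


def gen_stations(spec: WorldSpec) -> list[SampleRecord]:
    """Station network: distances log-uniform over the range, one sample per
    size fraction per station."""
    if spec.n_stations < 2:
        raise ValueError("need at least 2 stations")
    rng = _rngs(spec, 1)[0]
    lo, hi = spec.distance_range
    dist = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_stations))
    lat = rng.uniform(-65, 65, size=spec.n_stations)
    lon = rng.uniform(-180, 180, size=spec.n_stations)
    records = []
    for i in range(spec.n_stations):
        st = f"ST{i + 1:04d}"
        for frac in spec.size_fractions:
            records.append(
                SampleRecord(
                    sample_id=f"{st}_{frac}",
                    station_id=st,
                    depth_zone="SRF",
                    size_fraction=frac,
                    latitude=round(float(lat[i]), 4),
                    longitude=round(float(lon[i]), 4),
                    distance_to_coast=round(float(dist[i]), 3),
                )
            )
    return records


# ---------------------------------------------------------------------------
# reference database


def expected_within_identity(rate: float) -> float:
    """Expected per-site identity of two sequences independently mutated
    from a common ancestor at per-site substitution probability ``rate``
    (a substitution replaces the base by one of the three others uniformly)."""
    return (1 - rate) ** 2 + rate**2 / 3 + 2 * rate * (1 - rate) * 0.0


WITHIN_IDENTITY_FLOOR = 0.95
BETWEEN_IDENTITY_CEIL = 0.80


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to a uniformly chosen different base."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    idx = np.flatnonzero(hit)
    if len(idx):
        shift = rng.integers(1, 4, size=len(idx))
        out[idx] = (out[idx] + shift) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def gen_reference_db(
    spec: WorldSpec,
) -> tuple[list[ReferenceRecord], dict[str, str]]:
    """Clade-structured references: one random ancestor per category,
    references by per-site substitution from it.

    Raises if the configured divergence would push the expected
    within-category identity below the 0.95 band floor (the between-category
    band sits near random-sequence identity and is rate-independent).
    """
    for rate in (spec.ref_divergence, spec.motu_divergence):
        if expected_within_identity(rate) < WITHIN_IDENTITY_FLOOR:
            raise ValueError(
                f"divergence {rate} gives expected within-category identity "
                f"{expected_within_identity(rate):.3f} < {WITHIN_IDENTITY_FLOOR}; "
                "identity bands would overlap"
            )
    rng = _rngs(spec, 2)[1]
    categories = [c for c in CLADE_CATEGORIES if c in spec.n_motus_per_category]
    ancestors: dict[str, str] = {}
    records: list[ReferenceRecord] = []
    for cat in categories:
        anc = rng.integers(0, 4, size=spec.seq_length)
        ancestors[cat] = _to_str(anc)
        for k in range(spec.n_refs_per_category):
            seq = _mutate(anc, spec.ref_divergence, rng)
            ref_id = f"REF_{cat.replace('-', '')}_{k + 1:03d}"
            taxonomy = (
                "Eukaryota", "TSAR", "Rhizaria", "Retaria", "Foraminifera",
                cat, f"{cat}_family", f"{cat}_genus", f"{cat}_sp{k + 1}", ref_id,
            )
            records.append(
                ReferenceRecord(
                    ref_id=ref_id, sequence=_to_str(seq),
                    taxonomy=taxonomy, clade_category=cat,
                )
            )
    return records, ancestors


# ---------------------------------------------------------------------------
# the world


def gen_motu_world(spec: WorldSpec) -> SyntheticWorld:
    """Generate a full world: stations, references, MOTUs, counts, truth.

    Per MOTU, presence at station s is Bernoulli(expit(beta0 + beta1 * d_s));
    conditional on presence the station's samples receive over-dispersed
    negative-binomial reads, with one sample bumped by +1 so presence always
    implies a nonzero station count. Size fractions carry no occupancy
    signal by default.
    """
    from scipy.special import expit

    metadata = gen_stations(spec)
    reference_db, ancestors = gen_reference_db(spec)
    _, _, rng_motu, rng_counts = _rngs(spec, 4)

    station_order: list[str] = []
    for rec in metadata:
        if rec.station_id not in station_order:
            station_order.append(rec.station_id)
    st_index = {s: i for i, s in enumerate(station_order)}
    distances = np.zeros(len(station_order))
    for rec in metadata:
        distances[st_index[rec.station_id]] = rec.distance_to_coast
    samples_of_station: dict[str, list[int]] = {s: [] for s in station_order}
    for j, rec in enumerate(metadata):
        samples_of_station[rec.station_id].append(j)

    motu_ids: list[str] = []
    motu_sequences: dict[str, str] = {}
    truth: dict[str, MotuTruth] = {}
    presence_truth: dict[str, np.ndarray] = {}
    counts = np.zeros((sum(spec.n_motus_per_category.values()), len(metadata)), dtype=np.int64)

    categories = [c for c in CLADE_CATEGORIES if c in spec.n_motus_per_category]
    m = 0
    for cat in categories:
        anc = np.array([list("ACGT").index(c) for c in ancestors[cat]])
        n_cat = spec.n_motus_per_category[cat]
        for k in range(n_cat):
            motu_id = f"M{m + 1:04d}"
            seq = _mutate(anc, spec.motu_divergence, rng_motu)
            motu_sequences[motu_id] = _to_str(seq)
            if cat == TARGET_CATEGORY and rng_motu.random() < spec.putative_planktonic_fraction:
                prior = spec.putative_planktonic_prior
                lifestyle = LIFESTYLE_PLANKTONIC
            else:
                prior = spec.occupancy_params[cat]
                lifestyle = (
                    LIFESTYLE_PLANKTONIC if cat in PLANKTONIC_CATEGORIES
                    else LIFESTYLE_BENTHIC
                )
            b0, b1 = prior.draw(rng_motu)
            p = expit(b0 + b1 * distances)
            present = (rng_motu.random(len(station_order)) < p).astype(np.int8)
            presence_truth[motu_id] = present
            truth[motu_id] = MotuTruth(
                lifestyle=lifestyle, beta0=b0, beta1=b1, source_category=cat
            )
            motu_ids.append(motu_id)
            nb_n = spec.count_dispersion
            per_sample_mean = spec.count_mean / max(len(spec.size_fractions), 1)
            nb_p = nb_n / (nb_n + per_sample_mean)
            for s, flag in zip(station_order, present):
                if not flag:
                    continue
                cols = samples_of_station[s]
                draws = rng_counts.negative_binomial(nb_n, nb_p, size=len(cols))
                seed_sample = rng_counts.integers(0, len(cols))
                draws[seed_sample] += 1
                counts[m, cols] = draws
            m += 1

    occurrence = OccurrenceTable(
        motu_ids, [r.sample_id for r in metadata], counts
    )
    return SyntheticWorld(
        spec=spec, metadata=metadata, reference_db=reference_db,
        ancestors=ancestors, motu_sequences=motu_sequences,
        occurrence=occurrence, truth=truth, presence_truth=presence_truth,
        station_order=station_order,
    )


def write_world(world: SyntheticWorld, outdir: str | os.PathLike) -> None:
    """Write metadata.tsv, reference.fasta, reference_taxonomy.tsv,
    motus.fasta, occurrence.tsv and truth.tsv into ``outdir``."""
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    d = os.fspath(outdir)
    psio.write_metadata(world.metadata, os.path.join(d, "metadata.tsv"))
    psio.write_reference_db(
        world.reference_db,
        os.path.join(d, "reference.fasta"),
        os.path.join(d, "reference_taxonomy.tsv"),
    )
    psio.write_fasta(world.motu_sequences, os.path.join(d, "motus.fasta"))
    psio.write_occurrence_table(world.occurrence, os.path.join(d, "occurrence.tsv"))
    rows = [
        {
            "motu_id": mid, "lifestyle": t.lifestyle, "beta0": t.beta0,
            "beta1": t.beta1, "source_category": t.source_category,
        }
        for mid, t in world.truth.items()
    ]
    pd.DataFrame(rows).to_csv(os.path.join(d, "truth.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# tree + alignment fixture for the placement stage


def gen_tree_and_alignment(
    n_leaves: int,
    seq_length: int,
    model: GTRModel,
    seed: int,
    n_queries: int = 0,
    query_pendant: float = 0.05,
    branch_mean: float = 0.1,
) -> tuple[BackboneTree, dict[str, str], dict[str, int]]:
    """Random bifurcating backbone with simulated sequences.

    Branch lengths are exponential with mean ``branch_mean``; sequences are
    simulated site-wise along the tree (root from the model's equilibrium
    frequencies, children through the transition probabilities of the rate
    matrix exponential, each site in a random Gamma rate category). When
    ``n_queries > 0``, extra query sequences are simulated from the midpoint
    of random edges on a pendant branch; the returned map records each
    query's true edge id.

    Returns (tree, alignment including queries as ``Q###`` rows, truth map
    query_id -> edge_id).
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    em = _EigenModel.from_model(model)

    # random topology by repeated joining; newick with exponential lengths
    subtrees = [f"L{i + 1:03d}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b1 = rng.exponential(branch_mean)
        b2 = rng.exponential(branch_mean)
        merged = f"({subtrees[i]}:{b1:.8f},{subtrees[j]}:{b2:.8f})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
    tree = BackboneTree.from_newick(subtrees[0] + ";")

    # choose query edges up front: edges with queries are simulated in two
    # halves so the query's lineage really branches at the edge midpoint of
    # the realized history
    edge_nodes = tree.edge_nodes()
    queries_on: dict[int, list[str]] = {}
    truth: dict[str, int] = {}
    for q in range(n_queries):
        v = edge_nodes[rng.integers(0, len(edge_nodes))]
        qid = f"Q{q + 1:03d}"
        queries_on.setdefault(v, []).append(qid)
        truth[qid] = int(tree.edge_num[v])

    # site-wise simulation down the tree
    ncat = len(em.rates)
    site_cat = rng.choice(ncat, p=em.weights, size=seq_length)
    states = np.zeros((tree.n_nodes, seq_length), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(4, p=em.pi, size=seq_length)

    def evolve(parent_states: np.ndarray, t: float) -> np.ndarray:
        P = em.transition(t)  # (ncat, 4, 4)
        rows = P[site_cat, parent_states]  # (L, 4)
        rows = rows / rows.sum(axis=1, keepdims=True)
        u = rng.random(seq_length)
        return (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)

    query_states: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes - 2, -1, -1):  # preorder below root
        if v in queries_on:
            mid = evolve(states[tree.parent[v]], tree.blen[v] / 2.0)
            states[v] = evolve(mid, tree.blen[v] / 2.0)
            for qid in queries_on[v]:
                query_states[qid] = evolve(mid, query_pendant)
        else:
            states[v] = evolve(states[tree.parent[v]], tree.blen[v])

    alignment = {tree.names[v]: _to_str(states[v]) for v in tree.leaves}
    for qid in sorted(query_states):
        alignment[qid] = _to_str(query_states[qid])
    return tree, alignment, truth
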