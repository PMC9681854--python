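"""Readers and writers for the tabular and sequence formats the pipeline touches.

TSV (tab-separated, UTF-8, '.' decimal) is the canonical tabular dialect;
every reader takes ``sep`` so comma-separated input works too. All
writer/reader pairs round-trip exactly on valid data, and malformed input is
rejected with a :class:`~plankshift.types.FormatError` naming the offending
record.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CLADE_CATEGORIES,
    Assignment,
    FormatError,
    OccurrenceTable,
    ReferenceRecord,
    SampleRecord,
    validate_dna,
)

N_TAXONOMY_RANKS = 10

#: Default clade-category mapping: a taxonomy rank value -> category.
#: Synthetic reference sets (and curated paths that name the clades
#: directly) map each category name to itself; curated databases with
#: different rank spellings supply their own mapping.
DEFAULT_CLADE_MAP: dict[str, str] = {c: c for c in CLADE_CATEGORIES}

METADATA_COLUMNS = [
    "sample_id",
    "station_id",
    "depth_zone",
    "size_fraction",
    "latitude",
    "longitude",
    "distance_to_coast",
]


# ---------------------------------------------------------------------------
# occurrence table


def read_occurrence_table(path: str | os.PathLike, sep: str = "\t") -> OccurrenceTable:
    """Read a MOTU x sample count table (first column MOTU ids, header samples)."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    motu_ids = [str(m) for m in df.index]
    sample_ids = [str(s) for s in df.columns]
    for axis, ids in (("MOTU", motu_ids), ("sample", sample_ids)):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()]
        if len(dup):
            raise FormatError(f"{path}: duplicated {axis} id {dup.iloc[0]!r}")
    counts = np.empty((len(motu_ids), len(sample_ids)), dtype=np.int64)
    for i, motu in enumerate(motu_ids):
        for j, sample in enumerate(sample_ids):
            cell = df.iat[i, j]
            try:
                val = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at MOTU {motu!r}, "
                    f"sample {sample!r}"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count at MOTU {motu!r}, sample {sample!r}"
                )
            counts[i, j] = val
    return OccurrenceTable(motu_ids, sample_ids, counts)


def write_occurrence_table(
    table: OccurrenceTable, path: str | os.PathLike, sep: str = "\t"
) -> None:
    df = pd.DataFrame(table.counts, index=table.motu_ids, columns=table.sample_ids)
    df.index.name = "motu_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path: str | os.PathLike, sep: str = "\t") -> list[SampleRecord]:
    """Read sample metadata; distance parsed as float km and validated >= 0."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        station = row["station_id"]
        if pd.isna(station) or str(station) == "":
            raise FormatError(f"{path}: sample {sid!r} has no station_id")
        try:
            dist = float(row["distance_to_coast"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: sample {sid!r}: bad distance_to_coast "
                f"{row['distance_to_coast']!r}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=sid,
                station_id=str(station),
                depth_zone=str(row["depth_zone"]),
                size_fraction=str(row["size_fraction"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                distance_to_coast=dist,
            )
        )
    return records


def write_metadata(
    records: Iterable[SampleRecord], path: str | os.PathLike, sep: str = "\t"
) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=METADATA_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> validated DNA string mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = validate_dna(str(rec.seq), name=f"FASTA record {rec.id!r}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# reference database


def derive_clade_category(
    taxonomy: tuple[str, ...], clade_map: Mapping[str, str], *, ref_id: str
) -> str:
    """Find the clade category named by a 10-rank taxonomy path.

    Exactly one rank value must map through ``clade_map``; zero or
    conflicting matches are format errors (the category partition over
    references must be total).
    """
    hits = {clade_map[r] for r in taxonomy if r in clade_map}
    if not hits:
        raise FormatError(
            f"reference {ref_id!r}: no taxonomy rank maps to a clade category "
            f"(path {list(taxonomy)!r})"
        )
    if len(hits) > 1:
        raise FormatError(
            f"reference {ref_id!r}: taxonomy maps to multiple categories {sorted(hits)!r}"
        )
    (category,) = hits
    if category not in CLADE_CATEGORIES:
        raise FormatError(
            f"reference {ref_id!r}: unknown clade {category!r} in mapping"
        )
    return category


def read_reference_db(
    fasta_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    clade_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[ReferenceRecord]:
    """Join reference FASTA with its 10-rank taxonomy TSV on sequence id.

    The taxonomy file has a ``ref_id`` column followed by ten rank columns
    (``rank1`` .. ``rank10``). Every FASTA id must have a taxonomy row.
    """
    clade_map = DEFAULT_CLADE_MAP if clade_map is None else dict(clade_map)
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(taxonomy_path, sep=sep, dtype=str).fillna("")
    if "ref_id" not in df.columns:
        raise FormatError(f"{taxonomy_path}: missing 'ref_id' column")
    rank_cols = [c for c in df.columns if c != "ref_id"]
    if len(rank_cols) != N_TAXONOMY_RANKS:
        raise FormatError(
            f"{taxonomy_path}: expected {N_TAXONOMY_RANKS} rank columns, "
            f"found {len(rank_cols)}"
        )
    tax = {str(r["ref_id"]): tuple(str(r[c]) for c in rank_cols) for _, r in df.iterrows()}
    records = []
    for ref_id, seq in seqs.items():
        if ref_id not in tax:
            raise FormatError(
                f"{fasta_path}: FASTA id {ref_id!r} missing from taxonomy table"
            )
        taxonomy = tax[ref_id]
        category = derive_clade_category(taxonomy, clade_map, ref_id=ref_id)
        records.append(
            ReferenceRecord(
                ref_id=ref_id, sequence=seq, taxonomy=taxonomy,
                clade_category=category,
            )
        )
    return records


def write_reference_db(
    records: Iterable[ReferenceRecord],
    fasta_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    sep: str = "\t",
) -> None:
    records = list(records)
    write_fasta({r.ref_id: r.sequence for r in records}, fasta_path)
    rank_cols = [f"rank{i}" for i in range(1, N_TAXONOMY_RANKS + 1)]
    df = pd.DataFrame(
        [[r.ref_id, *r.taxonomy] for r in records], columns=["ref_id", *rank_cols]
    )
    df.to_csv(taxonomy_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# assignments


def write_assignments(
    assignments: Iterable[Assignment], path: str | os.PathLike, sep: str = "\t"
) -> None:
    rows = [
        {
            "motu_id": a.motu_id,
            "best_ref_id": "" if a.best_ref_id is None else a.best_ref_id,
            "identity": a.identity,
            "category": "" if a.clade_category is None else a.clade_category,
            "assigned": a.assigned,
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows, columns=["motu_id", "best_ref_id", "identity", "category", "assigned"]
    ).to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_presence(presence, dirpath: str | os.PathLike, sep: str = "\t") -> None:
    """Write a StationPresence as presence.tsv (MOTU x station 0/1 matrix)
    plus stations.tsv (station_id, distance_to_coast)."""
    d = os.fspath(dirpath)
    df = pd.DataFrame(
        presence.presence, index=presence.motu_ids, columns=presence.station_ids
    )
    df.index.name = "motu_id"
    df.to_csv(os.path.join(d, "presence.tsv"), sep=sep)
    pd.DataFrame(
        {
            "station_id": presence.station_ids,
            "distance_to_coast": presence.station_distance,
        }
    ).to_csv(os.path.join(d, "stations.tsv"), sep=sep, index=False)


def read_presence(dirpath: str | os.PathLike, sep: str = "\t"):
    """Read the presence.tsv / stations.tsv pair back to a StationPresence."""
    from .occurrence import StationPresence

    d = os.fspath(dirpath)
    df = pd.read_csv(os.path.join(d, "presence.tsv"), sep=sep, index_col=0)
    st = pd.read_csv(os.path.join(d, "stations.tsv"), sep=sep)
    if list(df.columns) != [str(s) for s in st["station_id"]]:
        raise FormatError(f"{d}: stations.tsv does not match presence.tsv columns")
    return StationPresence(
        motu_ids=[str(m) for m in df.index],
        station_ids=[str(s) for s in df.columns],
        presence=df.to_numpy(dtype=np.int8),
        station_distance=st["distance_to_coast"].to_numpy(dtype=float),
    )


def write_fits(fits, path: str | os.PathLike, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "motu_id": f.motu_id, "beta0": f.beta0, "beta1": f.beta1,
                "se_beta1": f.se_beta1, "converged": f.converged,
                "estimable": f.estimable, "penalized": f.penalized,
                "trend": "" if f.trend is None else f.trend,
            }
            for f in fits
        ]
    ).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_fits(path: str | os.PathLike, sep: str = "\t"):
    from .occurrence import LogisticFit

    df = pd.read_csv(
        path, sep=sep, dtype={"motu_id": str, "trend": str},
        float_precision="round_trip",
    )
    out = []
    for _, r in df.iterrows():
        trend = r["trend"]
        trend = None if (pd.isna(trend) or trend == "") else str(trend)
        out.append(
            LogisticFit(
                motu_id=str(r["motu_id"]), beta0=float(r["beta0"]),
                beta1=float(r["beta1"]), se_beta1=float(r["se_beta1"]),
                converged=bool(r["converged"]), estimable=bool(r["estimable"]),
                penalized=bool(r["penalized"]), trend=trend,
            )
        )
    return out


def read_assignments(path: str | os.PathLike, sep: str = "\t") -> list[Assignment]:
    df = pd.read_csv(
        path, sep=sep,
        dtype={"motu_id": str, "best_ref_id": str, "category": str},
        float_precision="round_trip",
    )
    out = []
    for _, row in df.iterrows():
        assigned = bool(row["assigned"]) if not isinstance(row["assigned"], str) \
            else row["assigned"].strip().lower() == "true"
        cat = row["category"]
        cat = None if (pd.isna(cat) or cat == "") else str(cat)
        ref = row["best_ref_id"]
        ref = None if (pd.isna(ref) or ref == "") else str(ref)
        out.append(
            Assignment(
                motu_id=str(row["motu_id"]), best_ref_id=ref,
                identity=float(row["identity"]),
                clade_category=cat if assigned else None, assigned=assigned,
            )
        )
    return out
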