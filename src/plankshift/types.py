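"""Domain types shared by every pipeline stage.

The pipeline classifies 18S V9 metabarcoding MOTUs (molecular operational
taxonomic units) of foraminifera into seven clade categories — four
holoplanktonic (Spinose, Non-Spinose, Microperforates, Basal) and three
benthic (Monothalamea, Tubothalamea, Globothalamea) — and then asks which
Globothalamea MOTUs behave like plankton in their spatial occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The seven clade categories used for MOTU classification.
CLADE_CATEGORIES: tuple[str, ...] = (
    "Spinose",
    "Non-Spinose",
    "Microperforates",
    "Basal",
    "Globothalamea",
    "Tubothalamea",
    "Monothalamea",
)

#: Categories whose members spend their whole life cycle in the water column.
PLANKTONIC_CATEGORIES: frozenset[str] = frozenset(
    {"Spinose", "Non-Spinose", "Microperforates", "Basal"}
)

#: Benthic categories used as the "benthic" training class.
BENTHIC_CATEGORIES: frozenset[str] = frozenset({"Monothalamea", "Tubothalamea"})

#: The clade whose MOTUs are the unlabeled prediction targets.
TARGET_CATEGORY: str = "Globothalamea"

LIFESTYLE_PLANKTONIC = "planktonic"
LIFESTYLE_BENTHIC = "benthic"


class FormatError(ValueError):
    """Malformed input file or record; the message names the offender."""


def lifestyle_of(category: str) -> str | None:
    """Map a clade category to a lifestyle training label.

    Returns ``"planktonic"`` for the four holoplanktonic categories,
    ``"benthic"`` for Monothalamea/Tubothalamea, and ``None`` for
    Globothalamea (the unlabeled targets) or unknown categories.
    """
    if category in PLANKTONIC_CATEGORIES:
        return LIFESTYLE_PLANKTONIC
    if category in BENTHIC_CATEGORIES:
        return LIFESTYLE_BENTHIC
    return None


@dataclass(frozen=True)
class SampleRecord:
    """One sequencing sample: a station, depth zone and size fraction."""

    sample_id: str
    station_id: str
    depth_zone: str
    size_fraction: str
    latitude: float
    longitude: float
    distance_to_coast: float  # km, >= 0

    def __post_init__(self) -> None:
        if not self.station_id:
            raise FormatError(f"sample {self.sample_id!r}: missing station_id")
        d = self.distance_to_coast
        if not np.isfinite(d) or d < 0:
            raise FormatError(
                f"sample {self.sample_id!r}: distance_to_coast must be finite "
                f"and non-negative, got {d!r}"
            )


@dataclass
class OccurrenceTable:
    """MOTU x sample read-count matrix, the pipeline's central table.

    ``counts[i, j]`` is the number of reads of ``motu_ids[i]`` in
    ``sample_ids[j]``. Ids are opaque, case-sensitive strings and keep
    their input order.
    """

    motu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        for axis, ids in (("MOTU", self.motu_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {axis} id {i!r}")
                seen.add(i)
        if self.counts.shape != (len(self.motu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.motu_ids)} MOTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at MOTU {self.motu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def motu_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.motu_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}


# IUPAC nucleotide codes and the base sets they denote.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def validate_dna(seq: str, *, name: str = "sequence") -> str:
    """Upper-case and validate an IUPAC DNA string; reject empty/invalid."""
    if not seq:
        raise FormatError(f"{name}: empty sequence")
    up = seq.upper()
    bad = set(up) - IUPAC_DNA.keys()
    if bad:
        raise FormatError(
            f"{name}: non-IUPAC character(s) {sorted(bad)!r}"
        )
    return up


@dataclass(frozen=True)
class ReferenceRecord:
    """A clade-labeled reference barcode with its 10-rank taxonomy path."""

    ref_id: str
    sequence: str
    taxonomy: tuple[str, ...]
    clade_category: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_dna(self.sequence, name=f"reference {self.ref_id!r}")
        )
        if self.clade_category not in CLADE_CATEGORIES:
            raise FormatError(
                f"reference {self.ref_id!r}: unknown clade category "
                f"{self.clade_category!r}"
            )


@dataclass(frozen=True)
class Assignment:
    """Best reference hit for one MOTU, with the >= threshold decision."""

    motu_id: str
    best_ref_id: str | None
    identity: float
    clade_category: str | None
    assigned: bool

    def __post_init__(self) -> None:
        if not self.assigned and self.clade_category is not None:
            raise ValueError(
                f"{self.motu_id}: unassigned MOTU cannot carry a clade category"
            )
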