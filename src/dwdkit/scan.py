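"""Scanning WD40 proteins for the 16-residue DWD motif.

The DWD motif is the signature by which a WD40-repeat protein binds DDB1 and
acts as a CUL4-RING E3 ligase substrate receptor.  It is a hard position-class
consensus over 16 positions::

    [IFVL][IFVL][AGST][AGST][AGST] x [DE] x x [IFVL] x [IFVL][WY][DE][IFVL][RK]

Hydrophobic residues (I/F/V/L) sit at positions 1, 2, 10, 12 and 15; small
residues (A/G/S/T) at 3-5; the highly conserved anchors are Asp/Glu at 7 and
14, Trp/Tyr at 13, and the DDB1-facing Arg/Lys at 16.  ``x`` positions accept
any standard residue.  The unknown residue X never matches any position
(conservative detection).  Occurrences within one protein are numbered D1, D2,
D3, ... from the N-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import AMINO_ACIDS, DomainAnnotation, ProteinRecord
from .wd40 import RepeatRegion

MOTIF_LENGTH = 16

#: position -> allowed residues for the constrained positions (1-based keys
#: in the comment, 0-based in the dict).
_CONSTRAINED = {
    0: "IFVL",
    1: "IFVL",
    2: "AGST",
    3: "AGST",
    4: "AGST",
    6: "DE",
    9: "IFVL",
    11: "IFVL",
    12: "WY",
    13: "DE",
    14: "IFVL",
    15: "RK",
}


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of 16 allowed-residue sets (position classes).

    ``x`` positions accept the full 20-letter alphabet; no position accepts X.
    """

    position_classes: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.position_classes) != MOTIF_LENGTH:
            raise ValueError("a DWD motif pattern has exactly 16 positions")
        for i, cls in enumerate(self.position_classes):
            if "X" in cls:
                raise ValueError(f"position {i + 1}: X may not match")

    @classmethod
    def default(cls) -> "MotifPattern":
        classes = tuple(
            frozenset(_CONSTRAINED.get(i, AMINO_ACIDS)) for i in range(MOTIF_LENGTH)
        )
        return cls(position_classes=classes)

    def matches(self, window: str) -> bool:
        """Plain per-position check of one 16-mer (reference semantics)."""
        if len(window) != MOTIF_LENGTH:
            return False
        return all(c in cls for c, cls in zip(window, self.position_classes))

    def lookup_tables(self) -> np.ndarray:
        """(16, 128) boolean ASCII lookup used by the vectorized scanner."""
        tab = np.zeros((MOTIF_LENGTH, 128), dtype=bool)
        for i, cls in enumerate(self.position_classes):
            for c in cls:
                tab[i, ord(c)] = True
        return tab


#: The canonical DWD motif pattern.
DWD_MOTIF = MotifPattern.default()
_DEFAULT_TABLES = DWD_MOTIF.lookup_tables()


@dataclass(frozen=True)
class MotifHit:
    """One DWD motif occurrence: 0-based start and D1/D2/... ordinal."""

    protein_id: str
    start: int
    motif_seq: str
    ordinal: str


@dataclass
class DWDRecord:
    """A WD40 protein plus its motif hits, other-domain annotations and
    (once assigned) generic type A-K or PP."""

    protein_id: str
    species: str
    hits: list
    repeat_region: RepeatRegion
    other_domains: list
    protein_length: int
    dwd_type: Optional[str] = None

    @property
    def n_motifs(self) -> int:
        return len(self.hits)


def scan_motifs(
    sequence: str,
    pattern: MotifPattern = DWD_MOTIF,
    region: Optional[tuple[int, int]] = None,
    protein_id: str = "",
) -> list[MotifHit]:
    """Report every window of ``sequence`` matching ``pattern``.

    Overlapping matches are all reported, in ascending start order, with
    ordinals D1, D2, ... assigned in that order.  If ``region`` (0-based
    half-open) is given, only windows fully inside it are scanned.

    Sequences shorter than 16 yield an empty list.
    """
    n = len(sequence)
    if n < MOTIF_LENGTH:
        return []
    tables = (
        _DEFAULT_TABLES if pattern is DWD_MOTIF else pattern.lookup_tables()
    )
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n_win = n - MOTIF_LENGTH + 1
    valid = np.ones(n_win, dtype=bool)
    for k in range(MOTIF_LENGTH):
        valid &= tables[k][codes[k : k + n_win]]
    starts = np.nonzero(valid)[0]
    if region is not None:
        lo, hi = region
        starts = starts[(starts >= lo) & (starts + MOTIF_LENGTH <= hi)]
    return [
        MotifHit(
            protein_id=protein_id,
            start=int(s),
            motif_seq=sequence[s : s + MOTIF_LENGTH],
            ordinal=f"D{k + 1}",
        )
        for k, s in enumerate(starts)
    ]


def assemble_dwd(
    protein: ProteinRecord,
    region: RepeatRegion,
    hits: Sequence[MotifHit],
    other_domains: Sequence[DomainAnnotation] = (),
    wd40_names: frozenset = frozenset({"WD40"}),
) -> Optional[DWDRecord]:
    """Bundle a WD40-confirmed protein with its motif hits into a DWDRecord.

    Returns None when there are no hits (WD40 but not DWD).  Ordinals are
    recomputed in start order; other-domain annotations are filtered to
    non-WD40 names.  Hits referencing another protein are an error.
    """
    for h in hits:
        if h.protein_id and h.protein_id != protein.id:
            raise ValueError(
                f"hit on {h.protein_id!r} passed to assemble_dwd({protein.id!r})"
            )
    if not hits:
        return None
    lowered = {n.lower() for n in wd40_names}
    ordered = sorted(hits, key=lambda h: h.start)
    renumbered = [
        replace(h, protein_id=protein.id, ordinal=f"D{k + 1}")
        for k, h in enumerate(ordered)
    ]
    return DWDRecord(
        protein_id=protein.id,
        species=protein.species,
        hits=renumbered,
        repeat_region=region,
        other_domains=[
            d for d in other_domains if d.domain_name.lower() not in lowered
        ],
        protein_length=len(protein),
    )


def write_hits_tsv(records: Sequence[DWDRecord], path) -> None:
    """Motif-hit table: protein_id, species, ordinal, start_1based, motif_seq."""
    import pandas as pd

    rows = [
        (r.protein_id, r.species, h.ordinal, h.start + 1, h.motif_seq)
        for r in records
        for h in r.hits
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "species", "ordinal", "start_1based", "motif_seq"]
    ).to_csv(path, sep="\t", index=False)
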