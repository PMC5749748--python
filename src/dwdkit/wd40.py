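"""WD40 repeat protein detection.

WD40 proteins fold into beta-propellers built from several copies of 40-60
residue repeats that typically end with the Trp-Asp (WD) dipeptide.  They are
the search space within which DWD motifs are sought (DWDs are a subset of
WD40 proteins).

Two routes are provided: a naive built-in heuristic that chains WD dipeptide
end-anchors at repeat-like spacings, and ingestion of precomputed external
annotations (e.g. WDSP or InterPro runs supplied as TSV).  The naive detector
is a deliberate, transparent simplification of profile-based homology search;
it carries no statistical scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io import DomainAnnotation, ProteinRecord


@dataclass(frozen=True)
class RepeatRegion:
    """Detected WD40 repeat units on one protein (0-based half-open), plus the
    hull interval spanning them."""

    protein_id: str
    repeat_units: tuple
    region_span: tuple

    @property
    def n_units(self) -> int:
        return len(self.repeat_units)


def _wd_anchor_ends(sequence: str) -> list[int]:
    """0-based exclusive end positions of every 'WD' dipeptide."""
    return [i + 2 for i in range(len(sequence) - 1) if sequence[i : i + 2] == "WD"]


def _longest_chain(ends: Sequence[int], min_len: int, max_len: int) -> list[int]:
    """Maximum-length subsequence of anchor ends with successive spacing in
    [min_len, max_len]; ties resolved to the lexicographically smallest chain
    (hence leftmost start).  O(A^2) DP over anchors."""
    n = len(ends)
    if n == 0:
        return []
    # best[i]: (chain length ending at i, chain tuple) -- chains are short, so
    # carrying the tuple keeps tie-breaking exact and simple.
    best: list[tuple[int, tuple]] = [(1, (ends[i],)) for i in range(n)]
    for i in range(n):
        for j in range(i):
            gap = ends[i] - ends[j]
            if min_len <= gap <= max_len:
                cand_len = best[j][0] + 1
                cand = (cand_len, best[j][1] + (ends[i],))
                if cand_len > best[i][0] or (
                    cand_len == best[i][0] and cand[1] < best[i][1]
                ):
                    best[i] = cand
    top = max(b[0] for b in best)
    return list(min(b[1] for b in best if b[0] == top))


def detect_wd40_naive(
    protein: ProteinRecord,
    min_len: int = 40,
    max_len: int = 60,
    min_repeats: int = 4,
) -> Optional[RepeatRegion]:
    """Detect WD40 repeats by chaining WD dipeptide end-anchors.

    All positions where ``sequence[i:i+2] == "WD"`` become candidate repeat
    ends; the longest chain of anchors with successive spacing in
    ``[min_len, max_len]`` is found by dynamic programming (equivalent to
    exhaustive enumeration over anchor subsets).  If it has at least
    ``min_repeats`` units it is reported, ties broken by leftmost start.

    The first unit of a chain is the ``min_len`` residues ending at its anchor
    (clipped at 0); each later unit spans from the previous anchor end to its
    own.  Returns None when no qualifying chain exists.
    """
    ends = _wd_anchor_ends(protein.sequence)
    chain = _longest_chain(ends, min_len, max_len)
    if len(chain) < min_repeats:
        return None
    units = [(max(0, chain[0] - min_len), chain[0])]
    units += [(chain[k - 1], chain[k]) for k in range(1, len(chain))]
    return RepeatRegion(
        protein_id=protein.id,
        repeat_units=tuple(units),
        region_span=(units[0][0], units[-1][1]),
    )


def resolve_wd40(
    protein: ProteinRecord,
    annotations: Iterable[DomainAnnotation] = (),
    mode: str = "naive",
    wd40_names: frozenset = frozenset({"WD40"}),
    min_len: int = 40,
    max_len: int = 60,
    min_repeats: int = 4,
) -> Optional[RepeatRegion]:
    """Resolve the repeat region via the configured route.

    mode='annotation': rows whose domain_name is in ``wd40_names``
    (case-insensitive) become repeat units verbatim; none -> None.
    mode='annotation_else_naive': fall back to the naive detector when no
    annotation rows exist.  mode='naive': heuristic only.
    """
    if mode not in {"naive", "annotation", "annotation_else_naive"}:
        raise ValueError(f"unknown WD40 resolution mode {mode!r}")
    if mode == "naive":
        return detect_wd40_naive(protein, min_len, max_len, min_repeats)
    lowered = {n.lower() for n in wd40_names}
    units = sorted(
        (a.start, a.end)
        for a in annotations
        if a.protein_id == protein.id and a.domain_name.lower() in lowered
    )
    for s, e in units:
        if not (0 <= s < e <= len(protein)):
            raise ValueError(
                f"{protein.id}: malformed WD40 annotation interval [{s}, {e})"
            )
    if units:
        return RepeatRegion(
            protein_id=protein.id,
            repeat_units=tuple(units),
            region_span=(units[0][0], units[-1][1]),
        )
    if mode == "annotation_else_naive":
        return detect_wd40_naive(protein, min_len, max_len, min_repeats)
    return None


def write_repeats_tsv(regions: Sequence[RepeatRegion], path) -> None:
    import pandas as pd

    rows = [
        (r.protein_id, s, e) for r in regions for (s, e) in r.repeat_units
    ]
    pd.DataFrame(rows, columns=["protein_id", "unit_start", "unit_end"]).to_csv(
        path, sep="\t", index=False
    )
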