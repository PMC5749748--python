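"""Generic DWD type classification (Types A-K, plus PP for partial proteins).

A DWD's type is determined by three features: (i) the position of its DWD
motif within the protein, (ii) the number of DWD motifs, and (iii) the
presence/absence and arrangement of other (non-WD40) domains relative to the
repeat-region hull.

Default rule set, applied with this precedence:

1. flagged partial protein -> ``PP``;
2. other domains present and >= 2 motifs -> ``K``;
3. other domains present: ``H`` when domains flank the hull on both sides,
   ``J`` when >= 2 distinct domain names sit on one side, ``I`` when a domain
   nests inside the hull, ``F`` for a single N-terminal domain, ``G`` for a
   single C-terminal one (evaluated in that order; a domain's side is decided
   by its midpoint relative to the hull);
4. no other domains, >= 2 motifs -> ``E``;
5. otherwise ``A``/``B``/``C``/``D`` by quartile of motif start / protein
   length: [0, .25) -> A, [.25, .5) -> B, [.5, .75) -> C, [.75, 1] -> D.

The rule table is an explicit reconstruction of a scheme whose published
definition is schematic; the quartile boundaries and label names are
overridable via JSON so users can match an alternative convention exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .scan import DWDRecord

ALL_LABELS = tuple("ABCDEFGHIJK") + ("PP",)


@dataclass(frozen=True)
class TypeRule:
    """Total, deterministic mapping from DWD architecture to a type label."""

    position_bins: tuple = (0.25, 0.5, 0.75)
    position_labels: tuple = ("A", "B", "C", "D")
    multi_motif_label: str = "E"
    n_terminal_label: str = "F"
    c_terminal_label: str = "G"
    both_sides_label: str = "H"
    nested_label: str = "I"
    multi_domain_label: str = "J"
    domains_and_multi_motif_label: str = "K"
    partial_label: str = "PP"

    def __post_init__(self) -> None:
        if len(self.position_labels) != len(self.position_bins) + 1:
            raise ValueError("need one more position label than bin boundary")
        if list(self.position_bins) != sorted(self.position_bins):
            raise ValueError("position_bins must be sorted")

    def to_json(self, path) -> None:
        d = {
            "position_bins": list(self.position_bins),
            "position_labels": list(self.position_labels),
            "multi_motif_label": self.multi_motif_label,
            "n_terminal_label": self.n_terminal_label,
            "c_terminal_label": self.c_terminal_label,
            "both_sides_label": self.both_sides_label,
            "nested_label": self.nested_label,
            "multi_domain_label": self.multi_domain_label,
            "domains_and_multi_motif_label": self.domains_and_multi_motif_label,
            "partial_label": self.partial_label,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "TypeRule":
        d = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TypeRule key(s): {sorted(unknown)}")
        for key in ("position_bins", "position_labels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


DEFAULT_RULES = TypeRule()


def _domain_side(domain, hull) -> str:
    """'N', 'C' or 'nested', by domain midpoint relative to the repeat hull."""
    mid = (domain.start + domain.end) / 2.0
    hs, he = hull
    if mid < hs:
        return "N"
    if mid >= he:
        return "C"
    return "nested"


def classify(
    record: DWDRecord, rules: TypeRule = DEFAULT_RULES, is_partial: bool = False
) -> str:
    """Assign one type label to a DWDRecord (total and deterministic)."""
    if is_partial:
        return rules.partial_label
    domains = record.other_domains
    if domains:
        if record.n_motifs >= 2:
            return rules.domains_and_multi_motif_label
        hull = record.repeat_region.region_span
        sides = [_domain_side(d, hull) for d in domains]
        n_names = {d.domain_name for d, s in zip(domains, sides) if s == "N"}
        c_names = {d.domain_name for d, s in zip(domains, sides) if s == "C"}
        if n_names and c_names:
            return rules.both_sides_label
        if len(n_names) >= 2 or len(c_names) >= 2:
            return rules.multi_domain_label
        if "nested" in sides:
            return rules.nested_label
        if n_names:
            return rules.n_terminal_label
        return rules.c_terminal_label
    if record.n_motifs >= 2:
        return rules.multi_motif_label
    rel = record.hits[0].start / record.protein_length
    for bound, label in zip(rules.position_bins, rules.position_labels):
        if rel < bound:
            return label
    return rules.position_labels[-1]


@dataclass
class TypeDistribution:
    """Counts per label; fractions over non-PP labels; PP reported separately."""

    counts: dict
    fractions: dict
    pp_count: int


def type_distribution(
    records: Sequence[DWDRecord], rules: TypeRule = DEFAULT_RULES
) -> TypeDistribution:
    """Label counts and fractions for a set of classified DWDRecords.

    Records whose ``dwd_type`` is unset are classified on the fly with the
    default (non-partial) predicate.  Fractions sum to 1 over non-PP labels.
    """
    counts: dict = {}
    for r in records:
        label = r.dwd_type if r.dwd_type is not None else classify(r, rules)
        counts[label] = counts.get(label, 0) + 1
    pp = counts.pop(rules.partial_label, 0)
    total = sum(counts.values())
    fractions = {
        k: (v / total if total else 0.0) for k, v in sorted(counts.items())
    }
    return TypeDistribution(
        counts=dict(sorted(counts.items())), fractions=fractions, pp_count=pp
    )
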