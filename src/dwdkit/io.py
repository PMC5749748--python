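"""Readers and writers for on-disk artifacts: FASTA proteomes, domain-annotation
TSV, tabular reports and Newick trees.

All coordinates in memory are 0-based, half-open.  Conversion to the 1-based
inclusive convention that biologists read happens only in report writers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Legal residue alphabet: the 20 standard amino acids plus X (unknown).
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a species tag — the atom of every stage.

    Parameters
    ----------
    id : str
        Unique identifier within a proteome pool.
    species : str
        Species tag; carried per record so multi-species pools can be merged.
    sequence : str
        Upper-case amino-acid string over ``ACDEFGHIKLMNPQRSTVWYX``.
    """

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain interval on a protein, 0-based half-open."""

    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: invalid interval "
                f"[{self.start}, {self.end})"
            )


def _split_header(header: str) -> tuple[str, str]:
    """Parse ``id|species ...`` headers; without a ``|`` the species falls back
    to the whole header."""
    first_token = header.split()[0] if header.split() else header
    if "|" in first_token:
        pid, species = first_token.split("|", 1)
        species = species.split("|", 1)[0]
        return pid, species
    return first_token, header.strip()


def read_fasta(path: str | Path, species_parser=None) -> list[ProteinRecord]:
    """Read a (possibly multi-species) FASTA file into ProteinRecords.

    The species tag is parsed from the header: by default the token after the
    first ``|`` (e.g. ``>AT1G01010|A_thaliana``), else the whole header.  A
    custom ``species_parser(header) -> (id, species)`` may be supplied.

    Raises on duplicate ids and on illegal residue characters (with the
    offending line number).  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    parser = species_parser or _split_header
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, species = parser(rec.description)
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET_SET
        if bad:
            lineno = _find_bad_residue_line(path, rec.description)
            raise ValueError(
                f"{path}: illegal residue character(s) {sorted(bad)!r} in "
                f"record {pid!r} (near line {lineno})"
            )
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(id=pid, species=species, sequence=seq))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def _find_bad_residue_line(path: Path, description: str) -> int:
    """Locate the first sequence line with an out-of-alphabet character in the
    record with the given header (best-effort, for error messages only)."""
    in_target = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_target = line[1:].strip() == description
            elif in_target:
                if set(line.strip().upper()) - _ALPHABET_SET:
                    return lineno
    return -1


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write ProteinRecords as FASTA with ``>id|species`` headers."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.species}", description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta-2line")


def read_domain_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Read a 4-column domain-annotation TSV (header required):
    ``protein_id  domain_name  start  end`` with 0-based half-open coordinates.

    Invalid intervals raise with the 1-based file row number.  Unknown
    protein_ids are not checked here; the join to proteins happens downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_name": str})
    required = ["protein_id", "domain_name", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out: list[DomainAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                DomainAnnotation(
                    protein_id=str(row.protein_id),
                    domain_name=str(row.domain_name),
                    start=int(row.start),
                    end=int(row.end),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_domain_tsv(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.domain_name, a.start, a.end) for a in annotations],
        columns=["protein_id", "domain_name", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick

_NEWICK_META = re.compile(r"[\s(),:;\[\]']")


def _quote_label(label: str) -> str:
    if _NEWICK_META.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_to_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        name = node.taxon.label if node.taxon is not None else (node.label or "")
        s = _quote_label(name)
    else:
        inner = ",".join(_node_to_newick(c) for c in node.child_nodes())
        label = node.label if node.label is not None else ""
        s = f"({inner}){label}"
    if node.edge is not None and node.edge.length is not None and node.parent_node is not None:
        s += f":{node.edge.length:.6f}"
    return s


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree as Newick: branch lengths to 6 decimals, integer
    bootstrap supports (stored as internal ``node.label``) as internal node
    labels, leaf names quoted when they contain Newick metacharacters."""
    text = _node_to_newick(tree.seed_node) + ";\n"
    Path(path).write_text(text)


def newick_string(tree: dendropy.Tree) -> str:
    return _node_to_newick(tree.seed_node) + ";"


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick file; internal node labels (bootstrap supports) are kept
    on ``node.label``."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def read_newick_string(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def to_one_based(start: int) -> int:
    """Report-boundary converter: 0-based start -> 1-based position."""
    return start + 1
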