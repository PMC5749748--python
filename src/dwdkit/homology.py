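"""Characterization of query DWDs against a reference DWD database.

In the original survey this step was BLASTp of every identified DWD against
an annotated A. thaliana DWD database; here the comparison is an exact
affine-gap global alignment (Gotoh dynamic programming) under BLOSUM62 with
BLAST-default gap costs (open 11, extend 1 per residue: a gap of length L
costs ``11 + L``).  This is deterministic and dependency-free, and makes
"percent similarity" well defined: the BLAST "positives" percentage, i.e.
100 x (identities + positive-scoring substitutions) / alignment length.

Among co-optimal alignments the DP maximizes, lexicographically, (score,
identities, positives, aligned columns), so reported percentages are unique
and reproducible.  Queries are assigned to the group of their best-hit
reference when similarity and coverage thresholds are met; per-group
orthology is the percentage of reference members with at least one assigned
query homolog.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io import ALPHABET, ProteinRecord, read_fasta

_MAX_LEN = 4000  # packed-int field widths in the DP kernel bound this

_ENC = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENC[ord(_c)] = _i


def _blosum_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Dense substitution matrix over this package's 21-letter alphabet."""
    m = substitution_matrices.load(name)
    sub = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            sub[i, j] = int(m[a][b])
    return sub


_B62 = _blosum_matrix()

# packed objective: value = score<<36 | identities<<24 | positives<<12 | pairs
_S_SCORE = 36
_S_ID = 24
_S_POS = 12
_NEG = np.int64(-(1 << 60))


def _encode(seq: str) -> np.ndarray:
    codes = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains characters outside the alphabet")
    return codes.astype(np.int64)


def _gotoh_py(a, b, sub, go, ge):
    """Affine-gap global DP on packed int64 tuples (numba-compiled below)."""
    la = a.size
    lb = b.size
    open_cost = np.int64(go + ge) << _S_SCORE
    ext_cost = np.int64(ge) << _S_SCORE
    M = np.full((la + 1, lb + 1), _NEG, dtype=np.int64)
    X = np.full((la + 1, lb + 1), _NEG, dtype=np.int64)  # a-residue vs gap
    Y = np.full((la + 1, lb + 1), _NEG, dtype=np.int64)  # gap vs b-residue
    M[0, 0] = 0
    for i in range(1, la + 1):
        X[i, 0] = -(np.int64(go + i * ge) << _S_SCORE)
    for j in range(1, lb + 1):
        Y[0, j] = -(np.int64(go + j * ge) << _S_SCORE)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            bj = b[j - 1]
            s = sub[ai, bj]
            delta = (s << _S_SCORE) + 1  # +1 aligned pair
            if ai == bj:
                delta += np.int64(1) << _S_ID
            if s > 0:
                delta += np.int64(1) << _S_POS
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + delta

            x = M[i - 1, j] - open_cost
            if X[i - 1, j] - ext_cost > x:
                x = X[i - 1, j] - ext_cost
            if Y[i - 1, j] - open_cost > x:
                x = Y[i - 1, j] - open_cost
            X[i, j] = x

            y = M[i, j - 1] - open_cost
            if Y[i, j - 1] - ext_cost > y:
                y = Y[i, j - 1] - ext_cost
            if X[i, j - 1] - open_cost > y:
                y = X[i, j - 1] - open_cost
            Y[i, j] = y
    best = M[la, lb]
    if X[la, lb] > best:
        best = X[la, lb]
    if Y[la, lb] > best:
        best = Y[la, lb]
    return best


try:  # jit the kernel; the pure-Python body stays the reference semantics
    from numba import njit

    _gotoh = njit(cache=False)(_gotoh_py)
except ImportError:  # pragma: no cover
    _gotoh = _gotoh_py


@dataclass(frozen=True)
class AlignmentStats:
    """Unpacked result of one global alignment."""

    score: int
    identities: int
    positives: int
    aligned_columns: int  # columns with a residue in both sequences
    alignment_length: int  # total columns including gap columns

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.alignment_length

    @property
    def percent_similarity(self) -> float:
        return 100.0 * self.positives / self.alignment_length


def align_stats(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentStats:
    """Global affine-gap alignment statistics for two sequences.

    A gap of length L costs ``gap_open + L * gap_extend``.  Identities count
    equal residues in aligned columns; positives count aligned columns with a
    positive substitution score (identities included when their diagonal score
    is positive, as under BLOSUM62 for all standard residues).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) > _MAX_LEN or len(b) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} are not supported")
    sub = _B62 if matrix == "BLOSUM62" else _blosum_matrix(matrix)
    packed = int(_gotoh(_encode(a), _encode(b), sub, gap_open, gap_extend))
    pairs = packed & 0xFFF
    positives = (packed >> _S_POS) & 0xFFF
    identities = (packed >> _S_ID) & 0xFFF
    score = packed >> _S_SCORE
    return AlignmentStats(
        score=score,
        identities=identities,
        positives=positives,
        aligned_columns=pairs,
        alignment_length=len(a) + len(b) - pairs,
    )


def global_align_percent(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[float, float]:
    """(percent_identity, percent_similarity) of the global alignment."""
    st = align_stats(a, b, matrix, gap_open, gap_extend)
    return st.percent_identity, st.percent_similarity


# ---------------------------------------------------------------------------
# Reference database and the similarity matrix


@dataclass
class ReferenceDB:
    """Reference DWD set with group labels (e.g. G1..G15)."""

    records: list
    group_of: dict

    def __post_init__(self) -> None:
        missing = [r.id for r in self.records if r.id not in self.group_of]
        if missing:
            raise ValueError(f"reference record(s) without group: {missing}")
        if not self.records:
            raise ValueError("reference database is empty")

    @property
    def groups(self) -> list:
        return sorted(set(self.group_of.values()))

    @classmethod
    def from_files(cls, fasta_path, groups_path) -> "ReferenceDB":
        import pandas as pd

        records = read_fasta(fasta_path)
        df = pd.read_csv(groups_path, sep="\t", dtype=str)
        if not {"protein_id", "group"} <= set(df.columns):
            raise ValueError(f"{groups_path}: need columns protein_id, group")
        group_of = dict(zip(df["protein_id"], df["group"]))
        return cls(records=records, group_of=group_of)


@dataclass
class SimilarityMatrix:
    """Query x reference percent-similarity matrix, with the identity and
    shorter-sequence coverage values kept alongside for group assignment."""

    query_ids: list
    ref_ids: list
    similarity: np.ndarray  # percent, [0, 100]
    identity: np.ndarray  # percent, [0, 100]
    coverage: np.ndarray  # aligned columns / shorter length, [0, 1]

    def row(self, query_id: str) -> np.ndarray:
        return self.similarity[self.query_ids.index(query_id)]

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows, cols = self.query_ids, self.ref_ids
        if set(rows) & set(cols):  # disambiguate shared ids across namespaces
            rows = [f"query:{r}" for r in rows]
            cols = [f"ref:{c}" for c in cols]
        pd.DataFrame(
            np.round(self.similarity, 1), index=rows, columns=cols
        ).to_csv(path, sep="\t", index_label="query_id")


def build_similarity_matrix(
    queries: Sequence[ProteinRecord],
    refdb: ReferenceDB,
    reference_order: Optional[Sequence[str]] = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> SimilarityMatrix:
    """Align every query against every reference.

    Column order follows ``reference_order`` when provided (e.g. the
    phylogenetic arrangement of the reference proteins), else database order.
    """
    if not queries:
        raise ValueError("no query sequences")
    ref_by_id = {r.id: r for r in refdb.records}
    ref_ids = list(reference_order) if reference_order else [r.id for r in refdb.records]
    q_ids = [q.id for q in queries]
    sim = np.zeros((len(queries), len(ref_ids)))
    idn = np.zeros_like(sim)
    cov = np.zeros_like(sim)
    for i, q in enumerate(queries):
        for j, rid in enumerate(ref_ids):
            st = align_stats(q.sequence, ref_by_id[rid].sequence, "BLOSUM62", gap_open, gap_extend)
            sim[i, j] = st.percent_similarity
            idn[i, j] = st.percent_identity
            cov[i, j] = st.aligned_columns / min(
                len(q.sequence), len(ref_by_id[rid].sequence)
            )
    return SimilarityMatrix(
        query_ids=q_ids, ref_ids=ref_ids, similarity=sim, identity=idn, coverage=cov
    )


UNASSIGNED = "unassigned"


def assign_group(
    query_id: str,
    refdb: ReferenceDB,
    matrix: SimilarityMatrix,
    min_similarity: float = 40.0,
    min_coverage: float = 0.5,
) -> tuple[str, Optional[str]]:
    """Best-hit group assignment for one query.

    Returns ``(group_label, best_ref_id)``; ``(UNASSIGNED, None)`` when the
    best hit fails the similarity or coverage threshold.  Ties on similarity
    are broken by higher identity, then lexicographically smaller reference id.
    """
    i = matrix.query_ids.index(query_id)
    order = sorted(
        range(len(matrix.ref_ids)),
        key=lambda j: (-matrix.similarity[i, j], -matrix.identity[i, j], matrix.ref_ids[j]),
    )
    j = order[0]
    if matrix.similarity[i, j] >= min_similarity and matrix.coverage[i, j] >= min_coverage:
        rid = matrix.ref_ids[j]
        return refdb.group_of[rid], rid
    return UNASSIGNED, None


def assign_all(
    queries: Sequence[ProteinRecord],
    refdb: ReferenceDB,
    matrix: SimilarityMatrix,
    min_similarity: float = 40.0,
    min_coverage: float = 0.5,
) -> dict:
    """{query_id: (group, best_ref_id)} over all queries."""
    return {
        q.id: assign_group(q.id, refdb, matrix, min_similarity, min_coverage)
        for q in queries
    }


def group_orthology_fraction(refdb: ReferenceDB, assignments: dict) -> dict:
    """Per group: 100 x (reference members with >= 1 assigned query homolog)
    / group size.  ``assignments`` maps query_id -> (group, best_ref_id)."""
    hit_refs = {rid for (_, rid) in assignments.values() if rid is not None}
    out = {}
    for g in refdb.groups:
        members = [r for r, grp in refdb.group_of.items() if grp == g]
        if not members:
            import warnings

            warnings.warn(f"group {g} is empty; excluded", stacklevel=2)
            continue
        covered = sum(1 for m in members if m in hit_refs)
        out[g] = 100.0 * covered / len(members)
    return out
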