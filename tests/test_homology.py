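import numpy as np
import pytest
from Bio.Align import substitution_matrices

from dwdkit.homology import (
    ReferenceDB,
    UNASSIGNED,
    align_stats,
    assign_all,
    assign_group,
    build_similarity_matrix,
    global_align_percent,
    group_orthology_fraction,
)
from dwdkit.io import ProteinRecord
from dwdkit.synthetic import random_sequence
from oracles import brute_align

_B62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"


def test_identity_alignment_is_100():
    assert global_align_percent("ACDEFG", "ACDEFG") == (100.0, 100.0)


def test_empty_sequence_errors():
    with pytest.raises(ValueError):
        global_align_percent("", "ACD")


def test_symmetry(rng):
    for _ in range(100):
        a = random_sequence(rng, int(rng.integers(5, 60)))
        b = random_sequence(rng, int(rng.integers(5, 60)))
        assert global_align_percent(a, b) == global_align_percent(b, a)


def test_brute_force_alignment_oracle(rng):
    """Exact equality of (score, identities, positives, aligned columns)
    with exhaustive alignment enumeration on short random pairs."""
    for _ in range(200):
        a = random_sequence(rng, int(rng.integers(1, 7)))
        b = random_sequence(rng, int(rng.integers(1, 7)))
        st = align_stats(a, b)
        exp = brute_align(a, b, _B62)
        assert (st.score, st.identities, st.positives, st.aligned_columns) == exp


def test_score_matches_biopython_global_aligner(rng):
    """Independent cross-check of the optimal score against Biopython's
    PairwiseAligner under the same gap convention."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _B62
    aligner.open_gap_score = -12  # first gap column: open 11 + extend 1
    aligner.extend_gap_score = -1
    for _ in range(50):
        a = random_sequence(rng, int(rng.integers(3, 40)))
        b = random_sequence(rng, int(rng.integers(3, 40)))
        assert align_stats(a, b).score == aligner.score(a, b)


def test_planted_divergence_identity(rng):
    """A query mutated at ~10% of sites (no gaps) aligns at ~90% identity."""
    ref = random_sequence(rng, 400)
    q = list(ref)
    k = 40
    for i in rng.choice(len(ref), size=k, replace=False):
        q[i] = _AA[(_AA.index(q[i]) + 1 + int(rng.integers(0, 19))) % 20]
    n_changed = sum(1 for x, y in zip(ref, q) if x != y)
    st = align_stats("".join(q), ref)
    assert st.percent_identity == pytest.approx(
        100 * (400 - n_changed) / 400, abs=1.0
    )


def _refdb(rng, n_groups=3, per_group=3, length=120):
    records, group_of = [], {}
    for g in range(n_groups):
        for m in range(per_group):
            rid = f"R{g}{m}"
            records.append(
                ProteinRecord(id=rid, species="Ref", sequence=random_sequence(rng, length))
            )
            group_of[rid] = f"G{g + 1}"
    return ReferenceDB(records=records, group_of=group_of)


def test_similarity_matrix_range_and_identity(rng):
    db = _refdb(rng)
    queries = [ProteinRecord(id="q", species="Q", sequence=db.records[0].sequence)]
    m = build_similarity_matrix(queries, db)
    assert m.similarity.shape == (1, 9)
    assert ((m.similarity >= 0) & (m.similarity <= 100)).all()
    assert m.similarity[0, 0] == 100.0
    assert m.coverage[0, 0] == 1.0


def test_assign_group_identical_query(rng):
    db = _refdb(rng)
    q = ProteinRecord(id="q", species="Q", sequence=db.records[4].sequence)  # G2
    m = build_similarity_matrix([q], db)
    group, rid = assign_group("q", db, m)
    assert group == "G2" and rid == "R11"


def test_assign_group_random_query_unassigned(rng):
    """Unrelated random queries fail the similarity/coverage thresholds."""
    db = _refdb(rng, length=200)
    queries = [
        ProteinRecord(id=f"q{i}", species="Q", sequence=random_sequence(rng, 200))
        for i in range(20)
    ]
    m = build_similarity_matrix(queries, db)
    assigned = [
        assign_group(q.id, db, m)[0] for q in queries
    ]
    assert assigned.count(UNASSIGNED) >= 18  # empirical null: nearly all


def test_assign_group_tie_broken_by_identity():
    a = ProteinRecord(id="RA", species="Ref", sequence="ACDEFGHIKL")
    b = ProteinRecord(id="RB", species="Ref", sequence="ACDEFGHIKL")
    db = ReferenceDB(records=[a, b], group_of={"RA": "G1", "RB": "G2"})
    q = ProteinRecord(id="q", species="Q", sequence="ACDEFGHIKL")
    m = build_similarity_matrix([q], db)
    m.identity[0, 1] = 99.0  # force RB below RA on the secondary key
    assert assign_group("q", db, m)[0] == "G1"


def test_orthology_fraction_formula(rng):
    """9 reference members, 7 with homologs -> 77.8%."""
    records = [
        ProteinRecord(id=f"R{i}", species="Ref", sequence=random_sequence(rng, 50))
        for i in range(9)
    ]
    db = ReferenceDB(records=records, group_of={f"R{i}": "G7" for i in range(9)})
    assignments = {f"q{i}": ("G7", f"R{i}") for i in range(7)}
    frac = group_orthology_fraction(db, assignments)
    assert frac["G7"] == pytest.approx(77.8, abs=0.05)


def test_orthology_fraction_extremes(rng):
    db = _refdb(rng, n_groups=2, per_group=2, length=30)
    none = group_orthology_fraction(db, {"q": (UNASSIGNED, None)})
    assert set(none.values()) == {0.0}
    every = group_orthology_fraction(
        db, {f"q{i}": ("G?", r.id) for i, r in enumerate(db.records)}
    )
    assert set(every.values()) == {100.0}


def test_homolog_family_recovery(rng):
    """Queries generated by mutating references at 20% of sites are assigned
    back to the generating family."""
    db = _refdb(rng, n_groups=5, per_group=2, length=200)
    queries, want = [], []
    for j, ref in enumerate(db.records):
        q = list(ref.sequence)
        for i in rng.choice(len(q), size=40, replace=False):
            q[i] = _AA[int(rng.integers(0, 20))]
        queries.append(ProteinRecord(id=f"q{j}", species="Q", sequence="".join(q)))
        want.append(db.group_of[ref.id])
    m = build_similarity_matrix(queries, db)
    got = [assign_group(q.id, db, m)[0] for q in queries]
    assert got == want
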