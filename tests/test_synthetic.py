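import math

import numpy as np
import pytest

from dwdkit.io import ProteinRecord, read_fasta
from dwdkit.scan import scan_motifs
from dwdkit.synthetic import (
    SimConfig,
    evolve_family,
    generate_dataset,
    generate_wd40_backbone,
    plant_motif,
    random_sequence,
)
from dwdkit.wd40 import detect_wd40_naive
from oracles import brute_scan


def test_backbone_construction(rng):
    seq = generate_wd40_backbone(rng, 4, 44)
    assert len(seq) == 176
    assert all(seq[e - 2 : e] == "WD" for e in (44, 88, 132, 176))


def test_backbone_parameter_validation(rng):
    with pytest.raises(ValueError):
        generate_wd40_backbone(rng, 3, 44)
    with pytest.raises(ValueError):
        generate_wd40_backbone(rng, 4, 61)


def test_backbone_always_passes_naive_detector(rng):
    for _ in range(50):
        n, L = int(rng.integers(4, 9)), int(rng.integers(40, 61))
        prot = ProteinRecord(
            id="p", species="s", sequence=generate_wd40_backbone(rng, n, L)
        )
        region = detect_wd40_naive(prot)
        assert region is not None and region.n_units >= n


def test_backbone_deterministic():
    a = generate_wd40_backbone(np.random.default_rng(5), 5, 42)
    b = generate_wd40_backbone(np.random.default_rng(5), 5, 42)
    assert a == b


def test_plant_then_scan_hits_planted_window(rng):
    seq = random_sequence(rng, 100)
    planted = plant_motif(rng, seq, 0)
    assert 0 in {h.start for h in scan_motifs(planted)}
    # position 16 (1-based) of the planted window is the DDB1-facing Arg/Lys
    assert planted[15] in "RK"


def test_plant_twice_disjoint_gives_two_hits(rng):
    seq = random_sequence(rng, 200)
    seq = plant_motif(rng, seq, 10)
    seq = plant_motif(rng, seq, 60)
    starts = {h.start for h in scan_motifs(seq)}
    assert {10, 60} <= starts


def test_plant_out_of_range_errors(rng):
    with pytest.raises(ValueError):
        plant_motif(rng, "A" * 20, 10)


def test_evolve_zero_branch_lengths_identity(rng):
    anc = random_sequence(rng, 200)
    tree = "((A:0.0,B:0.0):0.0,C:0.0);"
    leaves = evolve_family(rng, anc, tree)
    assert set(leaves) == {"A", "B", "C"}
    assert all(s == anc for s in leaves.values())


def test_evolve_negative_branch_errors(rng):
    with pytest.raises(ValueError):
        evolve_family(rng, "ACDE", "(A:-0.1,B:0.1,C:0.1);")


def test_evolve_divergence_matches_binomial_expectation(rng):
    """Two leaves at total path length t differ at a site with probability
    1 - (per-site no-change)^2 adjusted for back/parallel substitution; for
    small per-branch p the expected differing fraction is close to
    1 - exp(-t).  Checked within 3 binomial standard errors at 10,000 sites."""
    n_sites = 10_000
    anc = random_sequence(rng, n_sites)
    t_half = 0.05
    leaves = evolve_family(rng, anc, f"(A:{t_half},B:{t_half},C:0.0);")
    diff = sum(1 for x, y in zip(leaves["A"], leaves["B"]) if x != y)
    p_branch = 1 - math.exp(-t_half)
    # A==B if both branches unchanged, or both changed to the same residue
    p_diff = 1 - ((1 - p_branch) ** 2 + p_branch**2 / 19)
    se = math.sqrt(p_diff * (1 - p_diff) / n_sites)
    assert abs(diff / n_sites - p_diff) <= 3 * se
    # and close to the 1 - exp(-t) approximation stated for the model
    assert abs(diff / n_sites - (1 - math.exp(-2 * t_half))) < 0.02


def test_evolve_protects_motif_windows(rng):
    anc = random_sequence(rng, 400)
    anc = plant_motif(rng, anc, 100)
    leaves = evolve_family(
        rng, anc, "(A:0.3,B:0.3,C:0.3);", motif_intervals=[(100, 116)]
    )
    for seq in leaves.values():
        assert seq[100:116] == anc[100:116]


def test_evolve_deterministic(rng):
    anc = random_sequence(rng, 300)
    a = evolve_family(np.random.default_rng(9), anc, "(A:0.1,B:0.2,C:0.05);")
    b = evolve_family(np.random.default_rng(9), anc, "(A:0.1,B:0.2,C:0.05);")
    assert a == b


def test_dataset_dwd_fraction_zero(tmp_path):
    ds = generate_dataset(
        SimConfig(seed=1, n_wd40_per_species=20, dwd_fraction=0.0), tmp_path
    )
    assert all(not t.is_dwd for t in ds.truth)
    assert all(not t.motif_intervals for t in ds.truth)


def test_dataset_byte_identical_given_seed(tmp_path):
    cfg = dict(seed=99, n_wd40_per_species=15)
    d1 = generate_dataset(SimConfig(**cfg), tmp_path / "a")
    d2 = generate_dataset(SimConfig(**cfg), tmp_path / "b")
    for sp in d1.fasta_paths:
        assert d1.fasta_paths[sp].read_bytes() == d2.fasta_paths[sp].read_bytes()
    assert d1.truth_path.read_bytes() == d2.truth_path.read_bytes()
    assert d1.domains_path.read_bytes() == d2.domains_path.read_bytes()


def test_planted_truth_closure(small_dataset):
    """Noise-free: every ground-truth motif interval is found by the scanner
    and no interval extends past the sequence end."""
    by_id = {p.id: p for p in small_dataset.proteins}
    for gt in small_dataset.truth:
        seq = by_id[gt.protein_id].sequence
        assert gt.seq_length == len(seq)
        found = {h.start for h in scan_motifs(seq)}
        assert found == {s for s, _ in gt.motif_intervals}


def test_motif_count_distribution_multinomial(tmp_path):
    """Empirical 1/2/3-motif family fractions within 3 standard errors of
    the configured (0.76, 0.21, 0.03)."""
    cfg = SimConfig(
        seed=31,
        species_tree="(A:0.0,B:0.0,C:0.0);",
        n_wd40_per_species=2000,
        dwd_fraction=1.0,
        other_domain_prob=0.0,
    )
    ds = generate_dataset(cfg, tmp_path)
    fams = {}
    for t in ds.truth:
        fams[t.family_id] = len(t.motif_intervals)
    counts = np.bincount(list(fams.values()), minlength=4)[1:4]
    n = counts.sum()
    for obs, p in zip(counts / n, (0.76, 0.21, 0.03)):
        se = math.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= 3 * se


def test_false_positive_rate_closed_form(rng):
    """P(uniform random 16-mer matches) = (4/20)^8 * (2/20)^4 = 2.56e-10, so
    one million random windows should contain essentially no hits."""
    assert (4 / 20) ** 8 * (2 / 20) ** 4 == pytest.approx(2.56e-10)
    seq = random_sequence(rng, 1_000_000 + 15)
    hits = scan_motifs(seq)
    assert len(hits) <= 2


def test_motif_survival_under_noise_matches_closed_form(rng):
    """With per-site in-motif substitution probability mu (uniform among the
    19 alternatives), a planted motif still matches iff every constrained
    position stays in class: survival = (1-mu+mu*3/19)^8 * (1-mu+mu/19)^4.
    Checked within 3 SE over 2,000 planted motifs."""
    from dwdkit.synthetic import _CODE, _mutate, random_motif
    from dwdkit.scan import DWD_MOTIF

    mu = 0.15
    p_surv = (1 - mu + mu * 3 / 19) ** 8 * (1 - mu + mu * 1 / 19) ** 4
    n = 2000
    survived = 0
    ones = np.ones(16, dtype=bool)
    for _ in range(n):
        codes = np.array([_CODE[c] for c in random_motif(rng)])
        mutated = _mutate(rng, codes, 0.0, mu, ones)
        window = "".join("ACDEFGHIKLMNPQRSTVWY"[c] for c in mutated)
        survived += DWD_MOTIF.matches(window)
    se = math.sqrt(p_surv * (1 - p_surv) / n)
    assert abs(survived / n - p_surv) <= 3 * se


def test_simconfig_validation_and_json(tmp_path):
    with pytest.raises(ValueError):
        SimConfig(motif_count_probs=(0.5, 0.4, 0.2))
    with pytest.raises(ValueError):
        SimConfig(dwd_fraction=1.5)
    cfg = SimConfig(seed=3, dwd_fraction=0.4)
    p = tmp_path / "cfg.json"
    cfg.to_json(p)
    assert SimConfig.from_json(p) == cfg
    import json

    d = json.loads(p.read_text())
    d["bogus"] = 1
    p.write_text(json.dumps(d))
    with pytest.raises(ValueError, match="bogus"):
        SimConfig.from_json(p)


def test_fasta_files_readable_and_match_truth(small_dataset):
    for sp, path in small_dataset.fasta_paths.items():
        recs = read_fasta(path)
        assert all(r.species == sp for r in recs)
        assert len(recs) == small_dataset.config.n_wd40_per_species
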