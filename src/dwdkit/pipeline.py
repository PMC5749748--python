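"""Pipeline orchestration: detect -> scan -> classify -> characterize ->
phylo -> stats, as a library layer the CLI wraps thinly.

Every stage is a pure function of (inputs, config, seed); all randomness
funnels through one seeded generator per run and every intermediate result is
written to the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import DEFAULT_RULES, TypeRule
from .classify import classify as classify_record
import dwdkit.homology as _homology
import dwdkit.phylogeny as _phylo
import dwdkit.scan as _scan
import dwdkit.stats as _stats
import dwdkit.synthetic as _synthetic
import dwdkit.wd40 as _wd40
from .io import (
    ProteinRecord,
    read_domain_tsv,
    read_fasta,
    write_newick,
)

log = logging.getLogger("dwdkit")


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {where} key(s): {sorted(unknown)}")


@dataclass
class RunConfig:
    """Single JSON config for all stages; unknown keys are rejected."""

    inputs: list = field(default_factory=list)  # FASTA paths
    domains: Optional[str] = None  # domain-annotation TSV
    refdb_fasta: Optional[str] = None
    refdb_groups: Optional[str] = None
    reference_species: Optional[str] = None
    outdir: str = "dwd_out"
    # detector
    detector_mode: str = "naive"
    min_len: int = 40
    max_len: int = 60
    min_repeats: int = 4
    wd40_names: list = field(default_factory=lambda: ["WD40"])
    # scan
    region_only: bool = False
    # classify
    rules_path: Optional[str] = None
    partial_rule: str = "none"  # none | missing_start_met
    # homology
    min_similarity: float = 40.0
    min_coverage: float = 0.5
    gap_open: int = 11
    gap_extend: int = 1
    # phylo
    n_reps: int = 1000
    k_groups: int = 15
    seed: int = 0
    representative: str = "D1"
    # simulate
    sim: Optional[dict] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        _check_keys(d, set(cls.__dataclass_fields__), "RunConfig")
        if d.get("sim") is not None:
            _check_keys(
                d["sim"], set(_synthetic.SimConfig.__dataclass_fields__), "sim"
            )
        return cls(**d)

    def to_json(self, path) -> None:
        from dataclasses import asdict

        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def sim_config(self) -> _synthetic.SimConfig:
        d = dict(self.sim or {})
        for key in ("motif_count_probs", "placement_weights"):
            if key in d:
                d[key] = tuple(d[key])
        d.setdefault("seed", self.seed)
        return _synthetic.SimConfig(**d)


@dataclass
class PipelineResult:
    proteins: list
    regions: dict  # protein_id -> RepeatRegion
    records: list  # classified DWDRecord
    stats: list  # SpeciesStats
    assignments: Optional[dict] = None
    orthology: Optional[dict] = None
    tree: Optional[object] = None
    groups: Optional[dict] = None


def load_inputs(config: RunConfig) -> tuple[list, list]:
    proteins: list = []
    seen = set()
    for p in config.inputs:
        for rec in read_fasta(p):
            if rec.id in seen:
                raise ValueError(f"duplicate protein id across inputs: {rec.id!r}")
            seen.add(rec.id)
            proteins.append(rec)
    annotations = read_domain_tsv(config.domains) if config.domains else []
    return proteins, annotations


def stage_detect(proteins, annotations, config: RunConfig) -> dict:
    regions = {}
    for prot in proteins:
        region = _wd40.resolve_wd40(
            prot,
            annotations,
            mode=config.detector_mode,
            wd40_names=frozenset(config.wd40_names),
            min_len=config.min_len,
            max_len=config.max_len,
            min_repeats=config.min_repeats,
        )
        if region is not None:
            regions[prot.id] = region
    return regions


def stage_scan(proteins, regions, annotations, config: RunConfig) -> list:
    by_id = {p.id: p for p in proteins}
    ann_by_id: dict = {}
    for a in annotations:
        ann_by_id.setdefault(a.protein_id, []).append(a)
    records = []
    for pid in sorted(regions):
        prot = by_id[pid]
        region = regions[pid]
        scan_region = region.region_span if config.region_only else None
        hits = _scan.scan_motifs(prot.sequence, region=scan_region, protein_id=pid)
        rec = _scan.assemble_dwd(
            prot,
            region,
            hits,
            ann_by_id.get(pid, ()),
            wd40_names=frozenset(config.wd40_names),
        )
        if rec is not None:
            records.append(rec)
    return records


def _is_partial(protein: ProteinRecord, rule: str) -> bool:
    if rule == "missing_start_met":
        return not protein.sequence.startswith("M")
    return False


def stage_classify(records, proteins, config: RunConfig) -> None:
    rules = (
        TypeRule.from_json(config.rules_path)
        if config.rules_path
        else DEFAULT_RULES
    )
    by_id = {p.id: p for p in proteins}
    for rec in records:
        rec.dwd_type = classify_record(
            rec, rules, is_partial=_is_partial(by_id[rec.protein_id], config.partial_rule)
        )


def _representative_motif(record, which: str = "D1") -> str:
    for h in record.hits:
        if h.ordinal == which:
            return h.motif_seq
    return record.hits[0].motif_seq


def _derive_refdb(records, proteins, config: RunConfig):
    """Build a reference DWD database from the reference species: its DWDs,
    grouped by cutting its D1-motif NJ tree into k groups (mirrors using an
    annotated model species as the characterization reference)."""
    ref_sp = config.reference_species
    species = sorted({r.species for r in records})
    if ref_sp is None:
        ref_sp = species[0]
    ref_records = [r for r in records if r.species == ref_sp]
    if len(ref_records) < 4:
        raise ValueError(
            f"reference species {ref_sp!r} has too few DWDs ({len(ref_records)})"
        )
    by_id = {p.id: p for p in proteins}
    aln = _phylo.MotifAlignment(
        names=tuple(r.protein_id for r in ref_records),
        rows=tuple(_representative_motif(r, config.representative) for r in ref_records),
    )
    tree = _phylo.neighbor_joining(_phylo.p_distance_matrix(aln))
    k = min(config.k_groups, len(ref_records))
    groups = _phylo.cut_tree_groups(tree, k)
    refdb = _homology.ReferenceDB(
        records=[by_id[r.protein_id] for r in ref_records],
        group_of={r.protein_id: groups[r.protein_id] for r in ref_records},
    )
    return refdb, ref_sp


def stage_characterize(records, proteins, config: RunConfig, outdir: Path):
    if config.refdb_fasta:
        if not config.refdb_groups:
            raise ValueError("refdb_fasta given without refdb_groups")
        refdb = _homology.ReferenceDB.from_files(
            config.refdb_fasta, config.refdb_groups
        )
        ref_sp = None
    else:
        refdb, ref_sp = _derive_refdb(records, proteins, config)
    by_id = {p.id: p for p in proteins}
    ref_ids = {r.id for r in refdb.records}
    queries = [
        by_id[r.protein_id]
        for r in records
        if r.protein_id not in ref_ids and (ref_sp is None or r.species != ref_sp)
    ]
    if not queries:
        raise ValueError("no query DWDs to characterize")
    matrix = _homology.build_similarity_matrix(
        queries, refdb, gap_open=config.gap_open, gap_extend=config.gap_extend
    )
    assignments = _homology.assign_all(
        queries, refdb, matrix, config.min_similarity, config.min_coverage
    )
    orthology = _homology.group_orthology_fraction(refdb, assignments)

    matrix.to_tsv(outdir / "similarity_matrix.tsv")
    import pandas as pd

    pd.DataFrame(
        [(q, g, r or "") for q, (g, r) in sorted(assignments.items())],
        columns=["query_id", "group", "best_ref_id"],
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, round(v, 1)) for g, v in sorted(orthology.items())],
        columns=["group", "pct_members_with_homolog"],
    ).to_csv(outdir / "group_orthology.tsv", sep="\t", index=False)
    return assignments, orthology


def stage_phylo(records, config: RunConfig, outdir: Path):
    if len(records) < 4:
        log.warning("fewer than 4 DWDs; skipping phylogeny")
        return None, None
    aln = _phylo.MotifAlignment(
        names=tuple(r.protein_id for r in records),
        rows=tuple(_representative_motif(r, config.representative) for r in records),
    )
    tree = _phylo.bootstrap_support(aln, n_reps=config.n_reps, seed=config.seed)
    write_newick(tree, outdir / "dwd_motif_tree.nwk")
    k = min(config.k_groups, len(records))
    groups = _phylo.cut_tree_groups(tree, k)
    import pandas as pd

    pd.DataFrame(
        sorted(groups.items()), columns=["protein_id", "group"]
    ).to_csv(outdir / "tree_groups.tsv", sep="\t", index=False)
    return tree, groups


def stage_stats(records, regions, proteins, outdir: Path) -> list:
    by_species_wd40: dict = {}
    by_id = {p.id: p for p in proteins}
    for pid in regions:
        sp = by_id[pid].species
        by_species_wd40[sp] = by_species_wd40.get(sp, 0) + 1
    recs_by_sp: dict = {}
    for r in records:
        recs_by_sp.setdefault(r.species, []).append(r)
    stats = [
        _stats.compute_species_stats(sp, by_species_wd40.get(sp, 0), recs_by_sp.get(sp, []))
        for sp in sorted(by_species_wd40)
    ]
    _stats.aggregate_report(stats, outdir, all_records=records)
    _stats.write_type_distribution_tsv(
        {s.species: s.type_distribution for s in stats},
        outdir / "type_distribution.tsv",
    )
    return stats


def run_all(config: RunConfig, force: bool = False) -> PipelineResult:
    """Run every stage in order, writing all intermediates to the outdir."""
    outdir = Path(config.outdir)
    existing = (
        [p for p in outdir.iterdir() if p.name != "run.log"]
        if outdir.exists()
        else []
    )
    if existing and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    proteins, annotations = load_inputs(config)
    log.info("loaded %d proteins from %d file(s)", len(proteins), len(config.inputs))

    regions = stage_detect(proteins, annotations, config)
    _wd40.write_repeats_tsv(
        [regions[pid] for pid in sorted(regions)], outdir / "wd40_repeats.tsv"
    )
    log.info("WD40-confirmed proteins: %d", len(regions))

    records = stage_scan(proteins, regions, annotations, config)
    _scan.write_hits_tsv(records, outdir / "motif_hits.tsv")
    log.info("DWD proteins: %d (%d motif hits)", len(records),
             sum(r.n_motifs for r in records))

    stage_classify(records, proteins, config)
    import pandas as pd

    pd.DataFrame(
        [(r.protein_id, r.species, r.n_motifs, r.dwd_type) for r in records],
        columns=["protein_id", "species", "n_motifs", "dwd_type"],
    ).to_csv(outdir / "dwd_types.tsv", sep="\t", index=False)

    assignments = orthology = None
    n_species = len({r.species for r in records})
    if config.refdb_fasta or n_species > 1:
        assignments, orthology = stage_characterize(records, proteins, config, outdir)
        log.info("characterized %d queries against reference DB", len(assignments))

    tree, groups = stage_phylo(records, config, outdir)
    stats = stage_stats(records, regions, proteins, outdir)
    log.info("wrote reports to %s", outdir)
    return PipelineResult(
        proteins=proteins,
        regions=regions,
        records=records,
        stats=stats,
        assignments=assignments,
        orthology=orthology,
        tree=tree,
        groups=groups,
    )


def run_simulate(config: RunConfig, outdir=None):
    """Generate a synthetic dataset from config.sim (seeded)."""
    sim = config.sim_config()
    return _synthetic.generate_dataset(sim, outdir or Path(config.outdir))
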