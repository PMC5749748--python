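"""Per-species summary statistics of a DWD survey: WD40 and DWD counts, the
DWD/WD40 ratio, and the distribution of motif multiplicities (D1-only /
two / three-or-more motifs per protein)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .classify import TypeDistribution, type_distribution
from .scan import DWDRecord


@dataclass
class SpeciesStats:
    """Summary for one species.

    ``dwd_ratio`` is 100 * n_dwd / n_wd40 (None when n_wd40 == 0);
    ``motif_count_fractions`` are the fractions of DWDs with exactly 1, 2 and
    3-or-more motifs (None when there are no DWDs).
    """

    species: str
    n_wd40: int
    n_dwd: int
    dwd_ratio: Optional[float]
    motif_count_fractions: Optional[tuple]
    type_distribution: TypeDistribution

    def __post_init__(self) -> None:
        if self.n_dwd > self.n_wd40:
            raise ValueError("n_dwd cannot exceed n_wd40")


def _motif_fractions(records: Sequence[DWDRecord]) -> Optional[tuple]:
    if not records:
        return None
    one = sum(1 for r in records if r.n_motifs == 1)
    two = sum(1 for r in records if r.n_motifs == 2)
    three = sum(1 for r in records if r.n_motifs >= 3)
    n = len(records)
    return (one / n, two / n, three / n)


def compute_species_stats(
    species: str, n_wd40: int, records: Sequence[DWDRecord]
) -> SpeciesStats:
    """Counts, ratio and motif-count fractions for one species' DWD records."""
    n_dwd = len(records)
    return SpeciesStats(
        species=species,
        n_wd40=n_wd40,
        n_dwd=n_dwd,
        dwd_ratio=(100.0 * n_dwd / n_wd40) if n_wd40 > 0 else None,
        motif_count_fractions=_motif_fractions(records),
        type_distribution=type_distribution(records),
    )


def _pool(stats: Sequence[SpeciesStats], all_records: Sequence[DWDRecord]) -> SpeciesStats:
    n_wd40 = sum(s.n_wd40 for s in stats)
    return compute_species_stats("POOLED", n_wd40, list(all_records))


def aggregate_report(
    stats: Sequence[SpeciesStats],
    outdir,
    all_records: Sequence[DWDRecord] = (),
) -> dict:
    """Write the per-species table (TSV, fractions as percent to 1 decimal)
    plus a machine-readable JSON; a pooled row is appended when the full
    record pool is supplied.  Returns the JSON-shaped dict."""
    import pandas as pd

    if not stats:
        raise ValueError("need at least one species")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = list(stats)
    if all_records:
        rows = rows + [_pool(stats, all_records)]

    def fmt(x):
        return "" if x is None else f"{x:.1f}"

    table = []
    payload = []
    for s in rows:
        f = s.motif_count_fractions
        table.append(
            {
                "species": s.species,
                "n_wd40": s.n_wd40,
                "n_dwd": s.n_dwd,
                "dwd_ratio_pct": fmt(s.dwd_ratio),
                "pct_1_motif": fmt(100 * f[0]) if f else "",
                "pct_2_motifs": fmt(100 * f[1]) if f else "",
                "pct_3plus_motifs": fmt(100 * f[2]) if f else "",
            }
        )
        payload.append(
            {
                "species": s.species,
                "n_wd40": s.n_wd40,
                "n_dwd": s.n_dwd,
                "dwd_ratio_pct": s.dwd_ratio,
                "motif_count_fractions": list(f) if f else None,
                "type_counts": s.type_distribution.counts,
                "type_fractions": s.type_distribution.fractions,
                "pp_count": s.type_distribution.pp_count,
            }
        )
    pd.DataFrame(table).to_csv(outdir / "species_stats.tsv", sep="\t", index=False)
    out = {"species": payload}
    (outdir / "species_stats.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n"
    )
    return out


def write_type_distribution_tsv(
    per_species: dict, path
) -> None:
    """per_species: {species: TypeDistribution} -> long-format TSV."""
    import pandas as pd

    rows = []
    for sp in sorted(per_species):
        td = per_species[sp]
        for label in sorted(td.counts):
            rows.append(
                (sp, label, td.counts[label], round(100 * td.fractions[label], 1))
            )
        if td.pp_count:
            rows.append((sp, "PP", td.pp_count, ""))
    pd.DataFrame(
        rows, columns=["species", "dwd_type", "count", "pct_of_non_pp"]
    ).to_csv(path, sep="\t", index=False)
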