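"""Candidate-marker prioritization.

Orders markers lexicographically by the selection factors used to pick
a genotyping shortlist: case-group homozygosity first (homozygous markers
breed true), then the haplotype-diversity class in the configured
population group (preferred > neutral > avoided), then gene and
chromosome marker density (genes and chromosomes carrying more candidate
loci are better supported), with (chrom, pos) as the final deterministic
tie-break.  A weighted-sum mode is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .haplodiv import DiversityRecord
from .poplevel import CandidateMarker

_CLASS_ORDER = {"preferred": 0, "neutral": 1, "avoided": 2}
_MISSING_CLASS = 3  # markers without a diversity record sort last


@dataclass
class RankingConfig:
    shortlist_size: int = 13
    diversity_group: str = "YC-ZC"  # which population group's class ranks
    mode: str = "lexicographic"  # or "weighted"
    weights: dict = field(
        default_factory=lambda: {
            "homozygous": 4.0, "diversity": 2.0, "gene": 1.0, "chrom": 0.5,
        }
    )


@dataclass
class RankedMarker:
    marker: CandidateMarker
    diversity_class: str
    diversity_by_group: dict
    gene_marker_count: int
    chrom_marker_count: int
    rank: int
    score_breakdown: dict


def rank_markers(
    markers: Sequence[CandidateMarker],
    diversity: Sequence[DiversityRecord],
    config: RankingConfig | None = None,
    per_gene: pd.DataFrame | None = None,
    per_chrom: pd.DataFrame | None = None,
) -> list[RankedMarker]:
    """Total-order ranking of markers; deterministic under input permutation.

    A marker lacking a diversity record for the configured group is demoted
    to the end (never silently dropped).
    """
    config = config or RankingConfig()
    by_locus: dict[str, dict[str, DiversityRecord]] = {}
    for rec in diversity:
        by_locus.setdefault(rec.focal_locus_id, {})[rec.population] = rec

    gene_counts = (
        dict(zip(per_gene["gene_id"], per_gene["n_total"]))
        if per_gene is not None
        else _count(markers, lambda m: m.gene_id)
    )
    chrom_counts = (
        dict(zip(per_chrom["chrom"], per_chrom["n_markers"]))
        if per_chrom is not None
        else _count(markers, lambda m: m.chrom)
    )

    entries = []
    for m in markers:
        recs = by_locus.get(m.locus_id, {})
        rec = recs.get(config.diversity_group)
        cls = rec.cls if rec is not None else None
        gcount = gene_counts.get(m.gene_id, 0) if m.gene_id else 0
        ccount = chrom_counts.get(m.chrom, 0)
        entries.append((m, cls, recs, gcount, ccount))

    def sort_key(entry):
        m, cls, _, gcount, ccount = entry
        cls_rank = _CLASS_ORDER.get(cls, _MISSING_CLASS)
        if config.mode == "weighted":
            w = config.weights
            score = (
                w["homozygous"] * m.homozygous_case
                + w["diversity"] * (2 - min(cls_rank, 2))
                + w["gene"] * gcount
                + w["chrom"] * ccount
            )
            demoted = cls_rank == _MISSING_CLASS
            return (demoted, -score, m.chrom, m.pos)
        return (
            not m.homozygous_case,
            cls_rank,
            -gcount,
            -ccount,
            m.chrom,
            m.pos,
        )

    ordered = sorted(entries, key=sort_key)
    ranked = []
    for rank, (m, cls, recs, gcount, ccount) in enumerate(ordered, start=1):
        ranked.append(
            RankedMarker(
                marker=m,
                diversity_class=cls if cls is not None else "missing",
                diversity_by_group={p: r.n_haplotypes for p, r in recs.items()},
                gene_marker_count=gcount,
                chrom_marker_count=ccount,
                rank=rank,
                score_breakdown={
                    "homozygous_case": m.homozygous_case,
                    "diversity_class": cls,
                    "gene_marker_count": gcount,
                    "chrom_marker_count": ccount,
                },
            )
        )
    return ranked


def shortlist(ranked: Sequence[RankedMarker], size: int | None = None) -> list[RankedMarker]:
    size = size if size is not None else RankingConfig().shortlist_size
    return list(ranked[:size])


def _count(markers, key):
    out: dict = {}
    for m in markers:
        k = key(m)
        if k:
            out[k] = out.get(k, 0) + 1
    return out


def ranked_to_frame(ranked: Sequence[RankedMarker]) -> pd.DataFrame:
    rows = []
    for r in ranked:
        m = r.marker
        row = {
            "rank": r.rank,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "homozygous_case": m.homozygous_case,
            "diversity_class": r.diversity_class,
            "gene_id": m.gene_id if m.gene_id else ".",
            "gene_marker_count": r.gene_marker_count,
            "chrom_marker_count": r.chrom_marker_count,
        }
        for group, n in sorted(r.diversity_by_group.items()):
            row[f"n_haplotypes_{group}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def circos_tracks(ranked: Sequence[RankedMarker]) -> dict[str, pd.DataFrame]:
    """Plain-text track tables (chrom, start, end, value) for external plotting.

    One track per selection factor, mirroring the seven-circle layout:
    homozygosity (0/1), gene marker count, and per-group haplotype counts.
    """
    tracks: dict[str, list[dict]] = {"homozygous": [], "gene_count": []}
    groups = sorted({g for r in ranked for g in r.diversity_by_group})
    for g in groups:
        tracks[f"haplotypes_{g}"] = []
    for r in ranked:
        m = r.marker
        base = {"chrom": m.chrom, "start": m.pos - 1, "end": m.pos}
        tracks["homozygous"].append({**base, "value": int(m.homozygous_case)})
        tracks["gene_count"].append({**base, "value": r.gene_marker_count})
        for g in groups:
            tracks[f"haplotypes_{g}"].append(
                {**base, "value": r.diversity_by_group.get(g, 0)}
            )
    return {name: pd.DataFrame(rows) for name, rows in tracks.items()}
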