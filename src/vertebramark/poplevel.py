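"""Population-level (fixed) genotypes and differential candidate-marker screening.

A population-level genotype exists at a locus when every member of the
population carries the same non-missing genotype there (heterozygous fixed
genotypes count).  Candidate markers are loci where the case population and
the pooled control group both carry fixed genotypes that differ from each
other -- the fixation-contrast screen that yields breeding markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_core import (
    MISSING,
    ConfigurationError,
    GeneInterval,
    GenotypeMatrix,
    SampleManifest,
)


@dataclass(frozen=True)
class PopulationGenotype:
    locus_id: str
    population: str
    fixed_genotype: tuple[int, int] | None  # sorted allele pair, None if not fixed
    n_informative: int


@dataclass
class CandidateMarker:
    chrom: str
    pos: int
    ref: str
    alt: str
    case_genotype: tuple[int, int]
    control_genotype: tuple[int, int]
    homozygous_case: bool
    gene_id: str | None = None
    relation: str = "none"  # inside | within_5kb | none

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def _fixed_per_locus(matrix: GenotypeMatrix, sample_idx: np.ndarray):
    """Per-locus fixed genotype over the given sample columns.

    Returns ``(fixed_mask, genotype_pairs)`` where ``genotype_pairs`` is an
    (L, 2) sorted allele-pair array valid only where ``fixed_mask`` holds.
    Any missing call, or any genotype difference, disqualifies fixation.
    """
    sub = np.sort(matrix.alleles[:, sample_idx, :], axis=2)  # unordered pairs
    any_missing = (sub == MISSING).any(axis=(1, 2))
    same = (sub == sub[:, :1, :]).all(axis=(1, 2))
    fixed = same & ~any_missing
    return fixed, sub[:, 0, :].astype(np.int8)


def population_level_genotypes(
    matrix: GenotypeMatrix, manifest: SampleManifest, population: str
) -> list[PopulationGenotype]:
    """Fixed genotype per locus for one population (None where not fixed)."""
    samples = manifest.samples_of(population)
    if len(samples) < 2:
        raise ConfigurationError(
            f"population {population!r} needs >=2 samples, has {len(samples)}"
        )
    idx = matrix.sample_index(samples)
    fixed, pairs = _fixed_per_locus(matrix, idx)
    n_nonmissing = (~(matrix.alleles[:, idx] == MISSING).any(axis=2)).sum(axis=1)
    out = []
    for i, locus_id in enumerate(matrix.loci["locus_id"]):
        gt = (int(pairs[i, 0]), int(pairs[i, 1])) if fixed[i] else None
        out.append(
            PopulationGenotype(locus_id, population, gt, int(n_nonmissing[i]))
        )
    return out


def fixed_locus_ids(
    matrix: GenotypeMatrix, manifest: SampleManifest, population: str
) -> set[str]:
    """Locus ids carrying a population-level genotype in ``population``."""
    samples = manifest.samples_of(population)
    if len(samples) < 2:
        raise ConfigurationError(
            f"population {population!r} needs >=2 samples, has {len(samples)}"
        )
    fixed, _ = _fixed_per_locus(matrix, matrix.sample_index(samples))
    return set(matrix.loci.loc[fixed, "locus_id"])


def shared_locus_counts(pop_sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Venn-region counts over populations' fixed-locus sets.

    Returns one count per non-empty population subset: the number of loci
    fixed in exactly that subset of populations (regions are disjoint and
    sum to the union size).  Per-population totals are the sums of the
    regions containing that population.
    """
    if len(pop_sets) < 2:
        raise ConfigurationError("need >=2 populations for shared-locus counts")
    pops = list(pop_sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(pops) + 1):
        for subset in combinations(pops, r):
            inside = set.intersection(*(pop_sets[p] for p in subset))
            outside = set.union(
                set(), *(pop_sets[p] for p in pops if p not in subset)
            )
            regions[frozenset(subset)] = len(inside - outside)
    return regions


def population_totals(regions: dict[frozenset, int]) -> dict[str, int]:
    pops = set().union(*regions)
    return {
        p: sum(n for subset, n in regions.items() if p in subset) for p in pops
    }


def screen_candidate_markers(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    case_population: str,
    control_populations: Sequence[str],
    pool_controls: bool = True,
) -> list[CandidateMarker]:
    """Loci fixed in case and control groups with differing genotypes.

    The control populations are pooled into one group before fixation is
    assessed (``pool_controls=False`` instead requires fixation on the same
    genotype within each control population separately).  Markers come out
    sorted by (chrom, pos); the matrix is already in that order.
    """
    case_samples = manifest.samples_of(case_population)
    control_samples = manifest.samples_of_group(sorted(control_populations))
    if not case_samples or not control_samples:
        raise ConfigurationError("case and control groups must be non-empty")
    if set(case_samples) & set(control_samples):
        raise ConfigurationError("case and control sample sets overlap")

    case_fixed, case_gt = _fixed_per_locus(matrix, matrix.sample_index(case_samples))

    if pool_controls:
        ctrl_fixed, ctrl_gt = _fixed_per_locus(
            matrix, matrix.sample_index(control_samples)
        )
    else:
        per_pop = [
            _fixed_per_locus(matrix, matrix.sample_index(manifest.samples_of(p)))
            for p in sorted(control_populations)
        ]
        ctrl_fixed = np.logical_and.reduce([f for f, _ in per_pop])
        ctrl_gt = per_pop[0][1]
        for f, gt in per_pop[1:]:
            ctrl_fixed &= (gt == ctrl_gt).all(axis=1)

    differs = (case_gt != ctrl_gt).any(axis=1)
    hit = case_fixed & ctrl_fixed & differs

    markers = []
    for i in np.flatnonzero(hit):
        row = matrix.loci.iloc[i]
        cg = (int(case_gt[i, 0]), int(case_gt[i, 1]))
        markers.append(
            CandidateMarker(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                case_genotype=cg,
                control_genotype=(int(ctrl_gt[i, 0]), int(ctrl_gt[i, 1])),
                homozygous_case=cg[0] == cg[1],
            )
        )
    return markers


def eligible_locus_count(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    case_population: str,
    control_populations: Sequence[str],
) -> int:
    """Size of the screening pool: loci fixed in both case and pooled control."""
    case_fixed, _ = _fixed_per_locus(
        matrix, matrix.sample_index(manifest.samples_of(case_population))
    )
    ctrl_fixed, _ = _fixed_per_locus(
        matrix,
        matrix.sample_index(manifest.samples_of_group(sorted(control_populations))),
    )
    return int((case_fixed & ctrl_fixed).sum())


def annotate_marker_genes(
    markers: Sequence[CandidateMarker],
    genes: Sequence[GeneInterval],
    flank: int = 5000,
) -> tuple[list[CandidateMarker], pd.DataFrame, pd.DataFrame]:
    """Attach gene context and tally per-gene / per-chromosome marker counts.

    Relation is ``inside`` when the marker position falls in the gene
    interval, ``within_5kb`` when the distance to the interval is <= flank
    (inclusive boundary), else ``none``.  Gene counts are reported
    separately per relation.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    gene_counts: dict[str, dict[str, int]] = {}
    chrom_counts: dict[str, int] = {}
    for m in markers:
        p0 = m.pos - 1  # 0-based point
        tree = trees.get(m.chrom)
        best: tuple[int, str, str] | None = None  # (distance, gene_id, relation)
        if tree is not None:
            for iv in tree.overlap(p0 - flank, p0 + flank + 1):
                g: GeneInterval = iv.data
                if g.start <= p0 < g.end:
                    cand = (0, g.gene_id, "inside")
                else:
                    dist = g.start - p0 if p0 < g.start else p0 - (g.end - 1)
                    if dist > flank:
                        continue
                    cand = (dist, g.gene_id, "within_5kb")
                if best is None or cand < best:
                    best = cand
        if best is not None:
            m.gene_id, m.relation = best[1], best[2]
            rec = gene_counts.setdefault(best[1], {"inside": 0, "within_5kb": 0})
            rec[best[2]] += 1
        else:
            m.gene_id, m.relation = None, "none"
        chrom_counts[m.chrom] = chrom_counts.get(m.chrom, 0) + 1

    per_gene = pd.DataFrame(
        [
            {"gene_id": g, "n_inside": c["inside"], "n_within_5kb": c["within_5kb"],
             "n_total": c["inside"] + c["within_5kb"]}
            for g, c in gene_counts.items()
        ]
    ).sort_values("n_total", ascending=False, ignore_index=True) if gene_counts else pd.DataFrame(
        columns=["gene_id", "n_inside", "n_within_5kb", "n_total"]
    )
    per_chrom = pd.DataFrame(
        sorted(chrom_counts.items()), columns=["chrom", "n_markers"]
    )
    return list(markers), per_gene, per_chrom


def markers_to_frame(markers: Sequence[CandidateMarker]) -> pd.DataFrame:
    def fmt(gt: tuple[int, int]) -> str:
        return f"{gt[0]}/{gt[1]}"

    return pd.DataFrame(
        [
            {
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "case_genotype": fmt(m.case_genotype),
                "control_genotype": fmt(m.control_genotype),
                "homozygous_case": m.homozygous_case,
                "gene_id": m.gene_id if m.gene_id else ".",
                "relation": m.relation,
            }
            for m in markers
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "case_genotype", "control_genotype",
            "homozygous_case", "gene_id", "relation",
        ],
    )
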