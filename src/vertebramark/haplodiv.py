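"""Haplotype-diversity counting around candidate markers.

For each focal marker the phased calls of all loci within a +/-5 kb flank
are turned into two allele strings per diploid; the haplotype diversity of
the marker in a population is the number of distinct strings.  Markers in
the lowest quartile of diversity are preferred for breeding (their local
haplotype background is nearly uniform, so the marker tags a stable
haplotype), the highest quartile is avoided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, SampleManifest

log = logging.getLogger(__name__)


class PhasingError(ValueError):
    """Raised when a window contains unphased heterozygous calls."""


@dataclass
class HaplotypeWindow:
    focal_locus_id: str
    member_locus_ids: list[str]  # sorted by position, includes focal
    strings: list[str]  # contributing haplotype strings (missing-free)
    n_dropped: int  # strings dropped for containing a missing allele


@dataclass(frozen=True)
class DiversityRecord:
    focal_locus_id: str
    population: str
    n_haplotypes: int
    n_strings: int
    cls: str = "neutral"  # preferred | neutral | avoided


def extract_window_haplotypes(
    matrix: GenotypeMatrix,
    focal_locus_id: str,
    population_samples: Sequence[str],
    flank: int = 5000,
) -> HaplotypeWindow:
    """Two phased allele strings per sample over loci within the flank.

    Strings containing a missing allele are dropped from counting (the
    partner string is kept).  Unphased heterozygous member calls raise
    :class:`PhasingError` -- phase the input (or simulate truth-phased
    data) first; homozygous calls are phase-unambiguous and accepted.
    """
    ids = matrix.loci["locus_id"]
    focal_rows = np.flatnonzero(ids == focal_locus_id)
    if len(focal_rows) != 1:
        raise KeyError(f"focal locus {focal_locus_id!r} not found")
    focal = focal_rows[0]
    chrom = matrix.loci["chrom"].iloc[focal]
    pos = matrix.loci["pos"].iloc[focal]
    member = np.flatnonzero(
        (matrix.loci["chrom"] == chrom).to_numpy()
        & (np.abs(matrix.loci["pos"].to_numpy() - pos) <= flank)
    )

    idx = matrix.sample_index(population_samples)
    al = matrix.alleles[np.ix_(member, idx)]  # (M, n, 2)
    het = al[:, :, 0] != al[:, :, 1]
    unphased_het = het & ~matrix.phased[np.ix_(member, idx)] & ~(al == MISSING).any(axis=2)
    if unphased_het.any():
        m, s = np.argwhere(unphased_het)[0]
        raise PhasingError(
            f"unphased heterozygous call at {ids.iloc[member[m]]} in sample "
            f"{population_samples[s]}; phase the VCF before haplotype counting"
        )

    strings: list[str] = []
    n_dropped = 0
    for s in range(len(idx)):
        for h in (0, 1):
            hap = al[:, s, h]
            if (hap == MISSING).any():
                n_dropped += 1
                continue
            strings.append("".join(str(int(a)) for a in hap))
    if n_dropped:
        log.debug(
            "window %s: dropped %d strings with missing alleles",
            focal_locus_id, n_dropped,
        )
    return HaplotypeWindow(
        focal_locus_id=focal_locus_id,
        member_locus_ids=list(ids.iloc[member]),
        strings=strings,
        n_dropped=n_dropped,
    )


def haplotype_diversity(window: HaplotypeWindow, population: str) -> DiversityRecord | None:
    """Distinct-string count; None (with a warning) when nothing contributes."""
    if not window.strings:
        log.warning("window %s: no contributing strings", window.focal_locus_id)
        return None
    return DiversityRecord(
        focal_locus_id=window.focal_locus_id,
        population=population,
        n_haplotypes=len(set(window.strings)),
        n_strings=len(window.strings),
    )


def diversity_for_markers(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    focal_locus_ids: Sequence[str],
    population_groups: dict[str, Sequence[str]],
    flank: int = 5000,
) -> list[DiversityRecord]:
    """Diversity records for each focal locus in each population group.

    ``population_groups`` maps a group label (e.g. ``"YC-ZC"``) to the
    populations pooled into it; pooled groups count over the union of the
    member populations' strings.
    """
    records: list[DiversityRecord] = []
    for label, pops in population_groups.items():
        samples = manifest.samples_of_group(list(pops))
        for locus_id in focal_locus_ids:
            window = extract_window_haplotypes(matrix, locus_id, samples, flank=flank)
            rec = haplotype_diversity(window, label)
            if rec is not None:
                records.append(rec)
    return records


def diversity_quartiles(records: Sequence[DiversityRecord]) -> list[DiversityRecord]:
    """Classify records of one population into diversity quartile classes.

    ``avoided`` when the count is at or above the upper quartile,
    ``preferred`` at or below the lower quartile (type-7 empirical
    quartiles, inclusive ties); on degenerate distributions where a record
    qualifies for both, ``avoided`` wins (conservative marker selection).
    """
    if len(records) < 4:
        raise ValueError("quartile classification needs >=4 records")
    counts = np.array([r.n_haplotypes for r in records], dtype=float)
    q1 = float(np.quantile(counts, 0.25))
    q3 = float(np.quantile(counts, 0.75))
    out = []
    for r in records:
        if r.n_haplotypes >= q3:
            cls = "avoided"
        elif r.n_haplotypes <= q1:
            cls = "preferred"
        else:
            cls = "neutral"
        out.append(DiversityRecord(r.focal_locus_id, r.population,
                                   r.n_haplotypes, r.n_strings, cls))
    return out


def diversity_to_frame(records: Sequence[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": r.focal_locus_id,
                "population": r.population,
                "n_haplotypes": r.n_haplotypes,
                "n_strings": r.n_strings,
                "class": r.cls,
            }
            for r in records
        ],
        columns=["locus_id", "population", "n_haplotypes", "n_strings", "class"],
    )


def diversity_summary(records: Sequence[DiversityRecord]) -> pd.DataFrame:
    """Median and quartiles of diversity per population group."""
    frame = diversity_to_frame(records)
    rows = []
    for pop, sub in frame.groupby("population"):
        c = sub["n_haplotypes"]
        rows.append(
            {
                "population": pop,
                "n_loci": len(sub),
                "q1": float(c.quantile(0.25)),
                "median": float(c.median()),
                "q3": float(c.quantile(0.75)),
                "max": int(c.max()),
            }
        )
    return pd.DataFrame(rows)
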