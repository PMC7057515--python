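"""Genotype-score phenotype prediction.

The predictor works from a reference panel of genotyped animals with known
phenotypes.  At each marker locus the *major genotype* of each phenotype
group is the strictly most frequent genotype in that group; loci where the
two groups' major genotypes exist and differ are *discriminative*.  A query
animal is then scored for each phenotype: every discriminative locus where
its genotype equals a group's major genotype adds a weight to that group's
score -- +3 when the genotype probability is >= 0.9, +2 when >= 0.8,
+1 otherwise.  The phenotype with the higher score is called when the
score difference strictly exceeds a threshold; otherwise "unknown".

Major genotypes are computed on the panel only; query cohorts never update
them (panel/query separation is an explicit API boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    MISSING,
    ConfigurationError,
    GenotypeMatrix,
    probability_grid,
)

log = logging.getLogger(__name__)

UNKNOWN = "unknown"


@dataclass(frozen=True)
class MajorGenotype:
    locus_id: str
    group: str
    genotype: tuple[int, int] | None  # None on tie or all-missing
    support_count: int


@dataclass
class ScoreCard:
    sample_id: str
    labels: tuple[str, str]
    scores: dict[str, int]
    audit: list[dict] = field(default_factory=list, repr=False)

    @property
    def diff(self) -> int:
        a, b = self.labels
        return abs(self.scores[a] - self.scores[b])


def major_genotype(
    calls: Sequence[tuple[int, int]], locus_id: str, group: str
) -> MajorGenotype:
    """Strict plurality genotype of one phenotype group at one locus.

    Missing calls are excluded; a tie for the top count makes the locus
    unusable for this group (genotype None).
    """
    counts: dict[tuple[int, int], int] = {}
    for a1, a2 in calls:
        if a1 == MISSING or a2 == MISSING:
            continue
        pair = (a1, a2) if a1 <= a2 else (a2, a1)
        counts[pair] = counts.get(pair, 0) + 1
    if not counts:
        log.warning("locus %s group %s: all calls missing", locus_id, group)
        return MajorGenotype(locus_id, group, None, 0)
    best = max(counts.values())
    winners = [g for g, c in counts.items() if c == best]
    if len(winners) > 1:
        return MajorGenotype(locus_id, group, None, best)
    return MajorGenotype(locus_id, group, winners[0], best)


def _group_majors(
    matrix: GenotypeMatrix, groups: dict[str, Sequence[str]], locus_ids: Sequence[str]
) -> dict[str, dict[str, MajorGenotype]]:
    id_to_row = {lid: i for i, lid in enumerate(matrix.loci["locus_id"])}
    out: dict[str, dict[str, MajorGenotype]] = {g: {} for g in groups}
    for group, samples in groups.items():
        idx = matrix.sample_index(samples)
        for lid in locus_ids:
            row = id_to_row.get(lid)
            if row is None:
                raise KeyError(f"locus {lid!r} not in panel matrix")
            calls = [tuple(matrix.alleles[row, j]) for j in idx]
            out[group][lid] = major_genotype(calls, lid, group)
    return out


def discriminative_loci(
    matrix: GenotypeMatrix,
    groups: dict[str, Sequence[str]],
    candidate_loci: Sequence[str],
) -> tuple[list[str], dict[str, dict[str, MajorGenotype]]]:
    """Loci where both phenotype groups have major genotypes that differ.

    Returns the surviving loci (in candidate order) and the major-genotype
    table.  Zero survivors is an error: prediction is impossible.
    """
    if len(groups) != 2 or any(len(s) == 0 for s in groups.values()):
        raise ConfigurationError("need exactly two non-empty phenotype groups")
    majors = _group_majors(matrix, groups, candidate_loci)
    ga, gb = list(groups)
    selected = [
        lid
        for lid in candidate_loci
        if majors[ga][lid].genotype is not None
        and majors[gb][lid].genotype is not None
        and majors[ga][lid].genotype != majors[gb][lid].genotype
    ]
    if not selected:
        raise ConfigurationError(
            "no discriminative loci survive; prediction impossible"
        )
    return selected, majors


def probability_weight(probability: float | None) -> int:
    """Scoring weight: 3 when p >= 0.9, 2 when p >= 0.8, 1 for the rest.

    An unavailable probability falls in the "rest" bucket (weight 1) with
    a logged warning at the call site.
    """
    if probability is None or np.isnan(probability):
        return 1
    if probability >= 0.9:
        return 3
    if probability >= 0.8:
        return 2
    return 1


def score_individual(
    query: GenotypeMatrix,
    sample_id: str,
    loci: Sequence[str],
    majors: dict[str, dict[str, MajorGenotype]],
    match_neither: str = "zero",
) -> ScoreCard:
    """Score one query sample for both phenotypes over discriminative loci.

    A locus contributes its weight to the group whose major genotype equals
    the sample's genotype.  When the genotype matches neither major (or the
    call is missing) nothing is added (``match_neither="zero"``); the
    alternatives ``"split"`` (half weight to each, floor-rounded) and
    ``"opposite"`` are selectable for sensitivity analysis.
    """
    labels = tuple(majors)
    if len(labels) != 2:
        raise ConfigurationError("majors table must have exactly two groups")
    j = query.sample_index([sample_id])[0]
    id_to_row = {lid: i for i, lid in enumerate(query.loci["locus_id"])}
    probs = probability_grid(query)

    scores = {labels[0]: 0, labels[1]: 0}
    audit = []
    for lid in loci:
        row = id_to_row.get(lid)
        entry = {"locus_id": lid, "matched": None, "weight": 0}
        if row is None:
            entry["matched"] = "absent_from_query"
            audit.append(entry)
            continue
        a1, a2 = query.alleles[row, j]
        if a1 == MISSING or a2 == MISSING:
            entry["matched"] = "missing"
            audit.append(entry)
            continue
        gt = (int(a1), int(a2)) if a1 <= a2 else (int(a2), int(a1))
        p = probs[row, j]
        p_val = None if np.isnan(p) else float(p)
        if p_val is None:
            log.warning(
                "locus %s sample %s: no genotype probability; weight 1",
                lid, sample_id,
            )
        w = probability_weight(p_val)
        matched = [g for g in labels if majors[g][lid].genotype == gt]
        if len(matched) == 1:
            scores[matched[0]] += w
            entry.update(matched=matched[0], weight=w, probability=p_val)
        elif not matched:
            if match_neither == "split":
                for g in labels:
                    scores[g] += w // 2
            elif match_neither == "opposite":
                pass  # no sensible opposite for a two-sided non-match
            entry.update(matched="neither", weight=0, probability=p_val)
        audit.append(entry)
    return ScoreCard(sample_id=sample_id, labels=labels, scores=scores, audit=audit)


def call_phenotype(card: ScoreCard, diff_threshold: int) -> str:
    """Label of the larger score when diff strictly exceeds the threshold.

    Equal scores are always "unknown".
    """
    if diff_threshold < 0:
        raise ConfigurationError("diff threshold must be >= 0")
    a, b = card.labels
    if card.diff > diff_threshold:
        return a if card.scores[a] > card.scores[b] else b
    return UNKNOWN


def predict_cohort(
    panel: GenotypeMatrix,
    panel_groups: dict[str, Sequence[str]],
    query: GenotypeMatrix,
    candidate_loci: Sequence[str],
    diff_threshold: int,
    match_neither: str = "zero",
) -> pd.DataFrame:
    """End-to-end prediction for every query sample.

    Output columns: sample_id, one score column per phenotype label, diff,
    call.
    """
    loci, majors = discriminative_loci(panel, panel_groups, candidate_loci)
    labels = tuple(panel_groups)
    rows = []
    for sample in query.samples:
        card = score_individual(query, sample, loci, majors, match_neither)
        rows.append(
            {
                "sample_id": sample,
                f"score_{labels[0]}": card.scores[labels[0]],
                f"score_{labels[1]}": card.scores[labels[1]],
                "diff": card.diff,
                "call": call_phenotype(card, diff_threshold),
            }
        )
    return pd.DataFrame(rows)
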