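"""Confusion tables, prediction metrics and inter-run genotype concordance.

Two cohort-level metrics summarise predictor performance:

* *accuracy of prediction* -- of the animals predicted to carry a
  phenotype, the percentage whose observed phenotype matches (a precision
  analogue; "unknown" calls are excluded because they predict nothing).
* *representative capacity* -- of the animals observed to carry a
  phenotype, the percentage correctly called (a recall analogue; animals
  left "unknown" count against it).

Both are reported as percentages rounded half-up to 2 decimals; a metric
whose denominator is zero is absent (None), never 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .io_core import ConfigurationError

UNKNOWN = "unknown"


@dataclass
class ConfusionTable:
    """Predicted-label rows (plus an unknown row) x observed-label columns."""

    labels: tuple[str, str]
    grid: pd.DataFrame  # index: labels + unknown; columns: labels

    def predicted_total(self, label: str) -> int:
        return int(self.grid.loc[label].sum())

    def observed_total(self, label: str) -> int:
        return int(self.grid[label].sum())

    def correct(self, label: str) -> int:
        return int(self.grid.loc[label, label])

    @property
    def grand_total(self) -> int:
        return int(self.grid.to_numpy().sum())


def build_confusion(
    calls: Mapping[str, str], observed: Mapping[str, str]
) -> ConfusionTable:
    """Cross-tabulate predicted calls (incl. unknown) against observed labels."""
    if set(calls) != set(observed):
        raise ConfigurationError("calls and observed must cover the same samples")
    missing = [s for s, lab in observed.items() if lab is None or lab == ""]
    if missing:
        raise ConfigurationError(f"samples without observed label: {missing[:5]}")
    labels = tuple(sorted(set(observed.values())))
    if len(labels) != 2:
        raise ConfigurationError(f"expected two observed labels, got {labels}")
    rows = list(labels) + [UNKNOWN]
    grid = pd.DataFrame(0, index=rows, columns=list(labels), dtype=int)
    for sample, call in calls.items():
        row = call if call in labels else UNKNOWN
        grid.loc[row, observed[sample]] += 1
    return ConfusionTable(labels=labels, grid=grid)


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def accuracy_of_prediction(table: ConfusionTable, label: str) -> float | None:
    """100 x correct / predicted-as-label; absent when nothing was predicted."""
    predicted = table.predicted_total(label)
    if predicted == 0:
        return None
    return _round2(100.0 * table.correct(label) / predicted)


def representative_capacity(table: ConfusionTable, label: str) -> float | None:
    """100 x correct / observed-as-label; absent when the label never occurs."""
    observed = table.observed_total(label)
    if observed == 0:
        return None
    return _round2(100.0 * table.correct(label) / observed)


def metric_report(table: ConfusionTable) -> dict:
    """Both metrics for both labels plus the raw grid, JSON-serialisable."""
    return {
        "labels": list(table.labels),
        "confusion": {
            str(row): {str(col): int(table.grid.loc[row, col]) for col in table.grid.columns}
            for row in table.grid.index
        },
        "accuracy_of_prediction": {
            lab: accuracy_of_prediction(table, lab) for lab in table.labels
        },
        "representative_capacity": {
            lab: representative_capacity(table, lab) for lab in table.labels
        },
        "grand_total": table.grand_total,
    }


def evaluate_calls(calls: pd.DataFrame, truth: Mapping[str, str]) -> dict:
    """Convenience: metric report from a predict_cohort output frame."""
    call_map = dict(zip(calls["sample_id"], calls["call"]))
    table = build_confusion(call_map, {s: truth[s] for s in call_map})
    return metric_report(table)


def genotype_concordance(
    calls_run1: pd.DataFrame,
    calls_run2: pd.DataFrame,
    min_concordance: float = 1.0,
) -> pd.DataFrame:
    """Per-locus fraction of identical non-missing calls between two runs.

    Inputs are long-format frames with columns locus_id, sample_id,
    genotype (string such as "0/1"; missing encoded as "./.").  Loci whose
    concordance falls below ``min_concordance`` are flagged for exclusion,
    mirroring the cross-platform genotype check that removes unreliable
    markers before validation.
    """
    merged = calls_run1.merge(
        calls_run2, on=["locus_id", "sample_id"], suffixes=("_1", "_2")
    )
    if merged.empty:
        raise ConfigurationError("no overlapping sample-locus calls between runs")

    def norm(gt: str) -> str | None:
        if "." in gt:
            return None
        alleles = sorted(gt.replace("|", "/").split("/"))
        return "/".join(alleles)

    merged["g1"] = merged["genotype_1"].map(norm)
    merged["g2"] = merged["genotype_2"].map(norm)
    usable = merged.dropna(subset=["g1", "g2"])
    rows = []
    for locus, sub in usable.groupby("locus_id", sort=True):
        frac = float((sub["g1"] == sub["g2"]).mean())
        rows.append(
            {
                "locus_id": locus,
                "n_compared": len(sub),
                "concordance": frac,
                "excluded": frac < min_concordance,
            }
        )
    return pd.DataFrame(rows)
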