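"""Replicate-level co-expression quantification (mean % ± SEM).

Immunocytochemistry-style count tables record, per imaged field: total
DAPI-stained cells, reference-positive cells (typically BRN3+ RGCs),
and cells double-positive for a subtype marker and the reference.  Each
row yields a co-expression percentage — relative to the reference-
positive population (how subtype markers are reported against BRN3) or
to the total DAPI population (how ipRGC percentages are reported) — and
rows are aggregated to mean ± SEM across technical replicates, with a
biological-replicate-level option.

SEM uses the sample (n-1) standard deviation, the convention for error
bars.  Rows with a zero denominator are excluded with a warning, never
imputed, and the reported n reflects the exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UsageError, ValidationError
from .qpcr import BRN3_GENES, SubtypeCall

COUNT_COLUMNS = ("biological_replicate", "image", "total",
                 "reference_positive", "double_positive")
DENOMINATOR_MODES = ("reference_positive", "total_dapi")


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Check CountTable column presence and count sanity."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValidationError(f"count table missing columns: {missing}")
    for col in ("total", "reference_positive", "double_positive"):
        vals = counts[col]
        if (vals < 0).any() or not np.allclose(vals, vals.astype(int)):
            raise ValidationError(f"column {col!r} must hold non-negative integers")
    if (counts["double_positive"] > counts["reference_positive"]).any():
        raise ValidationError("double_positive exceeds reference_positive")
    if (counts["reference_positive"] > counts["total"]).any():
        raise ValidationError("reference_positive exceeds total")
    return counts


def coexpression_fraction(row: Mapping[str, float],
                          mode: str = "reference_positive") -> float:
    """Percentage of double-positive cells for one replicate row."""
    if mode not in DENOMINATOR_MODES:
        raise UsageError(f"unknown denominator mode {mode!r}")
    denom = row["reference_positive"] if mode == "reference_positive" else row["total"]
    if denom <= 0:
        raise DegenerateInputError("zero denominator for co-expression fraction")
    return 100.0 * row["double_positive"] / denom


def aggregate_sem(percentages: Sequence[float]) -> tuple[float, float]:
    """Mean and SEM (sample sd / sqrt(n)) of per-replicate percentages."""
    arr = np.asarray(list(percentages), dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("SEM undefined for fewer than 2 replicates")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass
class MarkerQuant:
    """mean % ± SEM for one marker, with the replicate bookkeeping."""

    marker: str
    mean: float
    sem: float
    n_technical: int
    n_biological: int
    denominator: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 100.0) or self.sem < 0:
            raise ValidationError("percentages must lie in [0, 100], SEM >= 0")

    def formatted(self) -> str:
        return format_mean_sem(self.mean, self.sem)


def format_mean_sem(mean: float, sem: float) -> str:
    """The reporting shape used in figure legends: ``25.95% ± 0.46%``."""
    return f"{mean:.2f}% ± {sem:.2f}%"


def quantify_marker(counts: pd.DataFrame, marker: str = "marker",
                    mode: str = "reference_positive",
                    level: str = "technical") -> MarkerQuant:
    """Aggregate a marker's count table to mean ± SEM.

    ``level`` selects the SEM divisor: ``technical`` treats every image
    as a replicate (the figure-legend convention, n = images);
    ``biological`` first averages images within each biological
    replicate, then takes SEM across those means.
    """
    counts = validate_count_table(counts)
    if level not in ("technical", "biological"):
        raise UsageError(f"unknown replicate level {level!r}")
    rows: list[tuple[str, float]] = []
    excluded = 0
    for _, row in counts.iterrows():
        try:
            rows.append((row["biological_replicate"],
                         coexpression_fraction(row, mode)))
        except DegenerateInputError:
            excluded += 1
            warnings.warn(
                f"excluding image {row['image']!r}: zero denominator")
    if level == "technical":
        values = [p for _, p in rows]
    else:
        by_bio = pd.DataFrame(rows, columns=["bio", "pct"]).groupby("bio")["pct"]
        values = list(by_bio.mean())
    mean, sem = aggregate_sem(values)
    return MarkerQuant(marker, mean, sem, len(rows),
                       counts["biological_replicate"].nunique(), mode, excluded)


def subtype_summary(calls: Iterable[SubtypeCall],
                    grouping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-label prevalence among BRN3+ cells and among all cells.

    When ``grouping`` maps cell ids to replicate groups, prevalences are
    computed per group and reported as mean ± SEM across groups;
    otherwise single pooled percentages with SEM = NaN.
    """
    calls = list(calls)
    if not calls:
        raise UsageError("no subtype calls to summarise")
    if grouping is not None:
        unknown = [c.cell_id for c in calls if c.cell_id not in grouping]
        if unknown:
            raise UsageError(f"cells missing from grouping: {unknown[:5]}")

    labels = sorted({lab for c in calls for lab in c.labels})
    df = pd.DataFrame({
        "cell": [c.cell_id for c in calls],
        "brn3": [any(g in c.detected for g in BRN3_GENES) for c in calls],
        **{lab: [lab in c.labels for c in calls] for lab in labels},
    })
    df["group"] = [grouping[c] for c in df["cell"]] if grouping is not None else "all"

    records = []
    for lab in labels:
        pct_all, pct_brn3 = [], []
        for _, g in df.groupby("group"):
            pct_all.append(100.0 * g[lab].mean())
            brn3 = g[g["brn3"]]
            if len(brn3):
                pct_brn3.append(100.0 * brn3[lab].mean())
        def _agg(vals: list[float]) -> tuple[float, float]:
            if len(vals) >= 2:
                return aggregate_sem(vals)
            return (float(vals[0]) if vals else 0.0, float("nan"))
        mean_all, sem_all = _agg(pct_all)
        mean_brn3, sem_brn3 = _agg(pct_brn3)
        records.append({"label": lab,
                        "pct_of_all": mean_all, "sem_of_all": sem_all,
                        "pct_of_brn3": mean_brn3, "sem_of_brn3": sem_brn3,
                        "n_groups": df["group"].nunique()})
    return pd.DataFrame(records)
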