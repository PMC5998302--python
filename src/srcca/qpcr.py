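"""Single-cell qRT-PCR pipeline: well filtering, Ct handling, BRN3B-sorted
heatmaps, and combinatorial RGC-subtype calling.

Microfluidic single-cell capture annotates every chamber as containing
zero cells, one cell, more than one cell, or debris; only one-cell wells
enter the analysis.  Ct values (qPCR cycle threshold; lower = more
transcript) are turned into a simple expression score
``max(LOD - Ct, 0)`` against a limit-of-detection cycle (default 40), so
"no amplification" (the NaN sentinel) scores zero and a gene counts as
detected exactly when its score is positive.

Subtype labels are assigned combinatorially from detected genes; a cell
may satisfy several rules and every label carries a trace of the genes
that fired it.  BRN3 positivity means detection of any assayed POU4F
isoform (the BRN3 antibody is pan-isoform), falling back to POU4F2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import HeatmapMatrix
from .errors import (
    ConfigError,
    EmptyResultError,
    GeneLookupError,
    UsageError,
    ValidationError,
)

WELL_CATEGORIES = ("zero_cell", "one_cell", "multi_cell", "debris")
DEFAULT_LOD = 40.0
BRN3_GENES = ("POU4F1", "POU4F2", "POU4F3")


@dataclass
class CtMatrix:
    """Gene-by-well Ct values with capture-site annotations.

    NaN is the no-amplification sentinel.  All finite Ct values must lie
    in [0, lod].
    """

    values: np.ndarray
    gene_ids: list[str]
    well_ids: list[str]
    annotations: dict[str, str]
    lod: float = DEFAULT_LOD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.well_ids = [str(w) for w in self.well_ids]
        if self.values.shape != (len(self.gene_ids), len(self.well_ids)):
            raise ValidationError("Ct matrix shape does not match ids")
        if self.lod <= 0:
            raise UsageError("limit of detection must be > 0")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValidationError("negative Ct values")
        if np.any(finite > self.lod):
            raise ValidationError(f"Ct values above the LOD ({self.lod})")
        missing = [w for w in self.well_ids if w not in self.annotations]
        if missing:
            raise ValidationError(f"wells without annotations: {missing[:5]}")
        bad = {w: a for w, a in self.annotations.items()
               if a not in WELL_CATEGORIES}
        if bad:
            raise ValidationError(f"unknown well annotations: {bad}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise GeneLookupError(gene) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.well_ids)

    @classmethod
    def read(cls, ct_path: str | Path, wells_path: str | Path,
             sep: str = "\t", lod: float = DEFAULT_LOD) -> "CtMatrix":
        """Read a wide genes-x-wells Ct table plus a two-column
        (well, annotation) table."""
        df = pd.read_csv(ct_path, sep=sep, index_col=0)
        ann = pd.read_csv(wells_path, sep=sep, header=None,
                          names=["well", "annotation"])
        return cls(df.to_numpy(dtype=float), [str(g) for g in df.index],
                   [str(w) for w in df.columns],
                   dict(zip(ann["well"].astype(str), ann["annotation"])), lod)


def filter_wells(ct: CtMatrix) -> tuple[CtMatrix, dict[str, int]]:
    """Keep only one-cell wells; report removals per capture category."""
    removed = {cat: 0 for cat in WELL_CATEGORIES if cat != "one_cell"}
    keep: list[int] = []
    for i, w in enumerate(ct.well_ids):
        cat = ct.annotations[w]
        if cat == "one_cell":
            keep.append(i)
        else:
            removed[cat] += 1
    if not keep:
        raise EmptyResultError("no one-cell wells on this plate")
    wells = [ct.well_ids[i] for i in keep]
    return CtMatrix(ct.values[:, keep], list(ct.gene_ids), wells,
                    {w: "one_cell" for w in wells}, ct.lod), removed


def ct_to_expression(ct, lod: float = DEFAULT_LOD):
    """Expression score ``max(lod - Ct, 0)``; NaN (no amplification) -> 0.

    Accepts scalars or arrays.  A gene is "detected" iff its score > 0.
    """
    if lod <= 0:
        raise UsageError("limit of detection must be > 0")
    arr = np.asarray(ct, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValidationError("negative Ct values")
    score = np.where(np.isnan(arr), 0.0, np.maximum(lod - arr, 0.0))
    return float(score) if np.isscalar(ct) or arr.ndim == 0 else score


def expression_scores(ct: CtMatrix) -> pd.DataFrame:
    """Gene-by-well expression-score table for a Ct matrix."""
    return pd.DataFrame(ct_to_expression(ct.values, ct.lod),
                        index=ct.gene_ids, columns=ct.well_ids)


def sort_and_heatmap(ct: CtMatrix, sort_gene: str = "POU4F2",
                     panel: Sequence[str] | None = None) -> HeatmapMatrix:
    """Expression-score heatmap with wells sorted by a gene, high to low.

    Values are expression scores, not Z scores (the convention for Ct
    heatmaps).  If the sort gene never amplified, input order is kept
    and a warning is emitted.
    """
    scores = ct_to_expression(ct.values, ct.lod)
    if sort_gene not in ct._gene_index:
        raise GeneLookupError(sort_gene)
    key = scores[ct._gene_index[sort_gene]]
    if np.all(key == 0):
        warnings.warn(f"sort gene {sort_gene!r} undetected in every well; "
                      "keeping input well order")
        order = np.arange(len(ct.well_ids))
    else:
        order = np.lexsort((np.array(ct.well_ids, dtype=object).astype(str), -key))
    genes = list(panel) if panel is not None else list(ct.gene_ids)
    for g in genes:
        if g not in ct._gene_index:
            raise GeneLookupError(g)
    rows = [ct._gene_index[g] for g in genes]
    return HeatmapMatrix(sort_gene, genes, [ct.well_ids[i] for i in order],
                         scores[np.ix_(rows, order)])


# ---------------------------------------------------------------------------
# combinatorial subtype calling

#: label -> (requires_brn3, any-of gene groups, forbid_brn3)
#: A rule fires when the BRN3 requirement holds and at least one gene of
#: each group is detected.
SUBTYPE_RULES: dict[str, dict] = {
    "ON-OFF DS": {"brn3": True, "genes": [("CARTPT", "CDH6")]},
    "ON DS": {"brn3": True, "genes": [("FSTL4",)]},
    "alpha": {"brn3": True, "genes": [("SPP1", "CALB2")], "record": ("KCNG4",)},
    "ipRGC-BRN3+": {"brn3": True, "genes": [("OPN4",)]},
    "ipRGC-BRN3-": {"brn3": False, "forbid_brn3": True, "genes": [("OPN4",)]},
    "PV": {"genes": [("PVALB",)]},
    "W3B": {"genes": [("SDK2",)]},
    "J": {"genes": [("JAM2",)]},
}


@dataclass
class SubtypeCall:
    """Combinatorial subtype assignment for one cell (multi-label)."""

    cell_id: str
    detected: frozenset[str]
    labels: list[str]
    trace: dict[str, list[str]]   # label -> genes that fired the rule

    @property
    def unclassified(self) -> bool:
        return not self.labels


def _rule_genes(rules: Mapping[str, dict]) -> set[str]:
    need: set[str] = set()
    for rule in rules.values():
        for group in rule["genes"]:
            need.update(group)
        need.update(rule.get("record", ()))
    return need


def call_subtypes(ct: CtMatrix | pd.DataFrame,
                  rules: Mapping[str, dict] = SUBTYPE_RULES,
                  brn3_genes: Sequence[str] = BRN3_GENES) -> list[SubtypeCall]:
    """Assign RGC-subtype labels per cell from detected genes.

    ``ct`` may be a (filtered) :class:`CtMatrix` or a gene-by-cell
    expression-score DataFrame.  Rules are combinatorial (BRN3 with
    CART or CDH6 -> ON-OFF DS, BRN3 with FSTL4 -> ON DS, ...); multiple
    labels per cell are allowed and each label's trace records the genes
    that fired.  Rule genes never assayed raise a configuration error.
    """
    scores = expression_scores(ct) if isinstance(ct, CtMatrix) else ct
    assayed = set(scores.index)
    missing = sorted(g for g in _rule_genes(rules) if g not in assayed)
    if missing:
        raise ConfigError(f"rule genes never assayed: {missing}")
    brn3_assayed = [g for g in brn3_genes if g in assayed]
    if not brn3_assayed:
        raise ConfigError(
            f"no BRN3 isoform assayed (looked for {list(brn3_genes)})")

    detected_df = scores > 0
    calls: list[SubtypeCall] = []
    for cell in scores.columns:
        det = frozenset(detected_df.index[detected_df[cell]])
        brn3_hits = [g for g in brn3_assayed if g in det]
        labels: list[str] = []
        trace: dict[str, list[str]] = {}
        for label, rule in rules.items():
            if rule.get("brn3") and not brn3_hits:
                continue
            if rule.get("forbid_brn3") and brn3_hits:
                continue
            fired: list[str] = []
            ok = True
            for group in rule["genes"]:
                hits = [g for g in group if g in det]
                if not hits:
                    ok = False
                    break
                fired.extend(hits)
            if not ok:
                continue
            if rule.get("brn3"):
                fired = brn3_hits + fired
            fired.extend(g for g in rule.get("record", ()) if g in det)
            labels.append(label)
            trace[label] = fired
        calls.append(SubtypeCall(str(cell), det, labels, trace))
    return calls


def calls_to_frame(calls: Iterable[SubtypeCall]) -> pd.DataFrame:
    rows = [{"cell_id": c.cell_id,
             "labels": ";".join(c.labels) if c.labels else "unclassified",
             "detected": ";".join(sorted(c.detected))} for c in calls]
    return pd.DataFrame(rows)
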