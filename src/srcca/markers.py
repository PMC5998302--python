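"""Multi-target SRCCA marker-discovery workflows.

Combining the ranked lists of several target genes isolates genes that
track a whole cell class rather than a single marker:

* :func:`core_signature` — intersect the top-N lists of the four classic
  pan-RGC markers (BRN3B, ISL1, SNCG, RBPMS) to obtain a core RGC
  signature.
* :func:`subtype_candidates` — the same logic seeded with FSTL4, BRN3B
  and SNCG to nominate direction-selective (DS) RGC markers.
* :func:`specificity_contrast` — check that a candidate's companion list
  shares next to nothing with the lists of progenitor / RPE /
  photoreceptor genes ("minimal overlap" verdict).
* :func:`validate_candidate` — per-cell co-detection check that a
  candidate (e.g. DCX) co-occurs with its subtype panel but not with
  panels of other classes.

All outputs are candidate lists and audit reports, not biological claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import RankedGeneList, VennResult, combine_lists, srcca_rank, top_n
from .errors import ConfigError, DegenerateInputError, UsageError
from .expression_io import ExpressionMatrix
from .panels import MarkerPanel, default_aliases, resolve_symbol

PAN_RGC_TARGETS = ("BRN3B", "ISL1", "SNCG", "RBPMS")
DS_TARGETS = ("FSTL4", "BRN3B", "SNCG")


def _resolve_target(symbol: str, m: ExpressionMatrix,
                    aliases: Mapping[str, Sequence[str]]) -> str:
    for gid in resolve_symbol(symbol, aliases):
        if m.has_gene(gid):
            return gid
    raise ConfigError(
        f"target {symbol!r} (candidates "
        f"{resolve_symbol(symbol, aliases)}) not present in matrix"
    )


@dataclass
class SignatureResult:
    """A combined-SRCCA gene signature plus its audit trail."""

    targets: dict[str, str]          # display symbol -> matrix id
    n: int
    lists: dict[str, RankedGeneList]  # keyed by display symbol
    venn: VennResult

    @property
    def core(self) -> frozenset[str]:
        return self.venn.core


def _signature(m: ExpressionMatrix, targets: Sequence[str], n: int,
               aliases: Mapping[str, Sequence[str]] | None) -> SignatureResult:
    aliases = default_aliases() if aliases is None else aliases
    resolved = {t: _resolve_target(t, m, aliases) for t in targets}
    lists = {t: srcca_rank(m, gid) for t, gid in resolved.items()}
    sets = {t: top_n(lst, n) for t, lst in lists.items()}
    return SignatureResult(resolved, n, lists, combine_lists(sets))


def core_signature(m: ExpressionMatrix,
                   targets: Sequence[str] = PAN_RGC_TARGETS,
                   n: int = 200,
                   aliases: Mapping[str, Sequence[str]] | None = None
                   ) -> SignatureResult:
    """Full intersection of the top-``n`` SRCCA lists of pan-RGC targets.

    Each target is excluded from its own ranked list, so targets never
    appear in the core set; the per-target lists are retained for audit.
    """
    return _signature(m, targets, n, aliases)


def subtype_candidates(m: ExpressionMatrix,
                       targets: Sequence[str] = DS_TARGETS,
                       n: int = 1000,
                       aliases: Mapping[str, Sequence[str]] | None = None
                       ) -> SignatureResult:
    """DS-RGC candidate genes: intersection of top-``n`` lists for
    FSTL4 + pan-RGC co-targets."""
    return _signature(m, targets, n, aliases)


@dataclass
class PanelContrast:
    """Per-gene overlap of a target's SRCCA list with one panel's lists."""

    panel: str
    overlap_counts: dict[str, int]          # panel symbol -> |target_top_n ∩ gene_top_n|
    coexpression: dict[str, float]          # panel symbol -> fraction of
    unresolved: list[str]                   #   target-positive cells also positive
    minimal_overlap: bool


@dataclass
class SpecificityReport:
    """Specificity evidence for one candidate gene against marker panels."""

    candidate: str
    n: int
    threshold: float
    contrasts: list[PanelContrast]

    @property
    def minimal_overlap(self) -> bool:
        return all(c.minimal_overlap for c in self.contrasts)


def _positive(m: ExpressionMatrix, gene_id: str, detection_threshold: float,
              detection_quantile: float | None) -> np.ndarray:
    row = m.gene_row(gene_id)
    if detection_quantile is not None:
        return row > np.quantile(row, detection_quantile)
    return row > detection_threshold


def _detection_fractions(m: ExpressionMatrix, candidate_id: str,
                         gene_ids: Iterable[str],
                         detection_threshold: float,
                         detection_quantile: float | None = None
                         ) -> dict[str, float]:
    cand = _positive(m, candidate_id, detection_threshold, detection_quantile)
    if not cand.any():
        raise DegenerateInputError(
            f"candidate {candidate_id!r} detected in zero cells")
    out = {}
    for gid in gene_ids:
        out[gid] = float(
            _positive(m, gid, detection_threshold, detection_quantile)[cand].mean())
    return out


def specificity_contrast(m: ExpressionMatrix, target: str,
                         negative_panels: Sequence[MarkerPanel],
                         n: int = 200,
                         overlap_threshold: float = 0.05,
                         detection_threshold: float = 0.0,
                         aliases: Mapping[str, Sequence[str]] | None = None
                         ) -> SpecificityReport:
    """Overlap of a target's top-``n`` list with each negative-panel
    gene's own top-``n`` list.

    The panel earns a "minimal overlap" verdict when every resolved panel
    gene overlaps the target list in at most ``overlap_threshold * n``
    genes (default 5%).  Panel genes absent from the matrix are recorded
    as unresolved and excluded from the verdict.
    """
    aliases = default_aliases() if aliases is None else aliases
    target_id = _resolve_target(target, m, aliases)
    target_set = set(top_n(srcca_rank(m, target_id), n))
    contrasts: list[PanelContrast] = []
    for panel in negative_panels:
        resolved, unresolved = panel.resolve(m.gene_ids)
        if not resolved:
            raise ConfigError(f"panel {panel.name!r}: no gene resolves in matrix")
        counts: dict[str, int] = {}
        coexpr: dict[str, float] = {}
        for sym, gids in resolved.items():
            gid = gids[0]
            try:
                other = set(top_n(srcca_rank(m, gid), n))
                counts[sym] = len(target_set & other)
            except DegenerateInputError:
                unresolved.append(sym)
                continue
            cand = m.gene_row(target_id) > detection_threshold
            coexpr[sym] = float((m.gene_row(gid) > detection_threshold)[cand].mean()) \
                if cand.any() else 0.0
        verdict = bool(counts) and all(c <= overlap_threshold * n
                                       for c in counts.values())
        contrasts.append(PanelContrast(panel.name, counts, coexpr,
                                       unresolved, verdict))
    return SpecificityReport(target_id, n, overlap_threshold, contrasts)


@dataclass
class CandidateValidation:
    """Per-cell co-detection of a candidate with subtype vs other panels."""

    candidate: str
    subtype_fractions: dict[str, float]
    other_fractions: dict[str, dict[str, float]]
    margin: float
    passed: bool


def validate_candidate(m: ExpressionMatrix, candidate: str,
                       subtype_panel: MarkerPanel,
                       other_panels: Sequence[MarkerPanel],
                       detection_threshold: float = 0.0,
                       margin: float = 0.2,
                       detection_quantile: float | None = None,
                       aliases: Mapping[str, Sequence[str]] | None = None
                       ) -> CandidateValidation:
    """Fractions of candidate-positive cells positive for each panel gene.

    The candidate passes when its mean co-detection with the subtype
    panel exceeds the mean co-detection with every other panel by at
    least ``margin``.

    Positivity is ``expression > detection_threshold`` (default 0, the
    natural cut on zero-inflated TPM data).  For data without a sparse
    off-state, ``detection_quantile`` switches to a per-gene quantile
    cut (e.g. 0.75 marks the top quarter of cells positive).
    """
    aliases = default_aliases() if aliases is None else aliases
    cand_id = _resolve_target(candidate, m, aliases)

    def fractions(panel: MarkerPanel) -> dict[str, float]:
        resolved, _ = panel.resolve(m.gene_ids)
        if not resolved:
            raise ConfigError(f"panel {panel.name!r}: no gene resolves in matrix")
        ids = {sym: gids[0] for sym, gids in resolved.items()}
        raw = _detection_fractions(m, cand_id, ids.values(), detection_threshold,
                                   detection_quantile)
        return {sym: raw[gid] for sym, gid in ids.items()}

    sub = fractions(subtype_panel)
    others = {p.name: fractions(p) for p in other_panels}
    sub_mean = float(np.mean(list(sub.values())))
    passed = all(sub_mean >= float(np.mean(list(f.values()))) + margin
                 for f in others.values())
    return CandidateValidation(cand_id, sub, others, margin, passed)


@dataclass(frozen=True)
class Recovery:
    precision: float | None   # None when the result set is empty (undefined)
    recall: float


def marker_recovery(result: Iterable[str], truth: Iterable[str]) -> Recovery:
    """Precision/recall of a recovered gene set against a planted truth set."""
    result = set(result)
    truth = set(truth)
    if not truth:
        raise UsageError("truth set must be non-empty")
    hits = len(result & truth)
    precision = hits / len(result) if result else None
    return Recovery(precision, hits / len(truth))
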