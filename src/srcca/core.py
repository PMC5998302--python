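"""Spearman rank-correlation analysis (SRCCA) primitives.

SRCCA ranks every gene in a single-cell expression matrix by its Spearman
correlation (rho) against a chosen target gene across cells, from high to
low.  Because rho depends only on cross-cell ranks it is invariant to any
strictly monotone per-gene transform, so the same ranking is obtained on
TPM and log2(TPM+1) values.

The module also provides the downstream pieces of the workflow: top-N
extraction, Z-scored heatmap matrices with cells ordered by target
expression, and Venn-style combination of several ranked lists into
disjoint membership regions plus the full-intersection "core" set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateInputError, UsageError
from .expression_io import ExpressionMatrix


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average-tie ranks.

    Raises :class:`DegenerateInputError` if either vector is constant
    (the correlation is undefined; the caller decides how to exclude).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UsageError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman rho undefined for constant input")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass
class RankedGeneList:
    """SRCCA output for one target: genes ordered by rho, high to low.

    The target itself is excluded; genes with undefined rho (constant
    across cells) are listed in ``excluded`` instead of being ranked.
    Ties in rho are broken lexicographically by gene id so lists are
    deterministic across platforms.
    """

    target_gene: str
    genes: list[str]
    rho: np.ndarray
    n_cells: int
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.genes) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "rho": self.rho, "rank": self.ranks})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, target_gene: str = "", n_cells: int = 0
                 ) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t")
        return cls(target_gene or Path(path).stem, list(df["gene"].astype(str)),
                   df["rho"].to_numpy(), n_cells)


def srcca_rank(m: ExpressionMatrix, target: str) -> RankedGeneList:
    """Rank every non-constant gene by Spearman rho against ``target``.

    Vectorised: cross-cell average-tie ranks are computed once for the
    whole matrix, then rho is the Pearson correlation of each rank row
    with the target's rank row.
    """
    tvec = m.gene_row(target)  # raises GeneLookupError with candidates
    if m.n_cells < 3:
        raise UsageError("SRCCA needs at least 3 cells")
    if np.ptp(tvec) == 0:
        raise DegenerateInputError(f"target gene {target!r} is constant across cells")

    ranks = scipy.stats.rankdata(m.values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks * ranks).sum(axis=1))
    tr = scipy.stats.rankdata(tvec)
    tr -= tr.mean()
    tnorm = np.sqrt(tr @ tr)

    constant = norms == 0
    excluded = [g for g, c in zip(m.gene_ids, constant) if c and g != target]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks @ tr) / (norms * tnorm)

    keep = ~constant & np.array([g != target for g in m.gene_ids])
    genes = np.array(m.gene_ids, dtype=object)[keep]
    rho = rho[keep]
    # rho descending, ties broken lexicographically by gene id
    order = np.lexsort((genes.astype(str), -rho))
    return RankedGeneList(target, [str(g) for g in genes[order]], rho[order],
                          m.n_cells, excluded)


def top_n(ranked: RankedGeneList, n: int) -> list[str]:
    """First ``n`` genes of a ranked list (errors rather than truncating)."""
    if n < 1:
        raise UsageError("n must be >= 1")
    if n > len(ranked.genes):
        raise UsageError(
            f"requested top {n} but list for {ranked.target_gene!r} has only "
            f"{len(ranked.genes)} entries"
        )
    return list(ranked.genes[:n])


@dataclass
class HeatmapMatrix:
    """Gene rows, Z-scored; cell columns ordered by target expression.

    Rows are standardised with the population standard deviation; rows
    constant across cells are emitted as zeros and listed in
    ``constant_genes``.
    """

    target_gene: str
    genes: list[str]
    cells: list[str]
    values: np.ndarray
    constant_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def heatmap_zscore(m: ExpressionMatrix, target: str,
                   genes: Sequence[str]) -> HeatmapMatrix:
    """Z-score selected genes with cells ranked by target expression.

    Cells are ordered from highest to lowest target expression (ties by
    cell id) — the display convention for target-anchored single-cell
    heatmaps.
    """
    genes = list(genes)
    if not genes:
        raise UsageError("empty gene set for heatmap")
    tvec = m.gene_row(target)
    for g in genes:
        m.gene_row(g)  # existence check with nearest-alias message
    order = np.lexsort((np.array(m.cell_ids, dtype=object).astype(str), -tvec))
    cells = [m.cell_ids[i] for i in order]
    sub = np.vstack([m.gene_row(g)[order] for g in genes])
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)  # population sd
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (sub - mean) / sd
    z[constant] = 0.0
    return HeatmapMatrix(target, genes, cells, z,
                         [g for g, c in zip(genes, constant) if c])


@dataclass
class VennResult:
    """Disjoint region memberships of >= 2 named gene sets.

    ``regions`` maps each non-empty combination of set names (a sorted
    tuple) to the genes belonging to exactly those sets.  The region
    keyed by all names is the full-intersection ``core``.
    """

    set_names: list[str]
    regions: dict[tuple[str, ...], frozenset[str]]

    @property
    def core(self) -> frozenset[str]:
        return self.regions.get(tuple(sorted(self.set_names)), frozenset())

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return frozenset(out)

    def region(self, *names: str) -> frozenset[str]:
        return self.regions.get(tuple(sorted(names)), frozenset())

    def to_json(self) -> str:
        payload = {
            "sets": self.set_names,
            "regions": {"&".join(k): sorted(v) for k, v in self.regions.items() if v},
            "core": sorted(self.core),
        }
        return json.dumps(payload, indent=2)


def combine_lists(named_sets: Mapping[str, Iterable[str]]) -> VennResult:
    """Partition the union of named gene sets into exclusive Venn regions."""
    names = [str(k) for k in named_sets]
    if len(names) != len(set(names)):
        raise UsageError("duplicate set names")
    if len(names) < 2:
        raise UsageError("need at least 2 named sets")
    sets = {str(k): frozenset(str(g) for g in v) for k, v in named_sets.items()}
    regions: dict[tuple[str, ...], set[str]] = {}
    for gene in frozenset().union(*sets.values()):
        key = tuple(sorted(k for k in names if gene in sets[k]))
        regions.setdefault(key, set()).add(gene)
    return VennResult(names, {k: frozenset(v) for k, v in regions.items()})
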