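"""Seeded generators for synthetic retinal-culture data with planted truth.

Three generators emulate the data types of a ~day-70 hPSC retinal
culture so every pipeline stage can be exercised without any download:

* :func:`generate_mosaic` — a gene-by-cell count matrix over a mixed
  population (retinal progenitors, RPE, photoreceptors, RGCs with
  subtypes) on a zero-inflated negative-binomial background, with
  planted gene modules (a pan-RGC module containing the four classic
  targets, a DS module containing FSTL4 and a DCX-like candidate,
  negative-panel modules for the non-RGC populations).
* :func:`generate_qpcr_plate` — a microfluidic qPCR plate: Ct values
  derived from planted single-cell subtype identities, plus planted
  zero-cell / multi-cell / debris capture sites.
* :func:`generate_icc_counts` — immunocytochemistry-style count tables
  with binomial double-positive counts at a known true proportion.

Counts are negative binomial with mean ``base * fold`` in the owning
population (fold default 8x), a per-cell log-normal library-size factor,
and post-sampling dropout (zero inflation).  The same seed always
reproduces bit-identical output.

The four pan-RGC targets are planted with heterogeneous coverage —
POU4F2 and SNCG across all RGCs, ISL1 and RBPMS across non-DS RGCs —
mirroring the partially overlapping marker expression observed in real
RGC cultures; this heterogeneity is what makes the multi-target
intersection informative rather than redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression_io import ExpressionMatrix, GeneLengthTable, log_transform, tpm_normalize
from .qpcr import CtMatrix

# ---------------------------------------------------------------------------
# mosaic configuration

POPULATIONS = ("progenitor", "rpe", "photoreceptor", "rgc")
RGC_SUBTYPES = ("ds_on_off", "ds_on", "alpha", "iprgc", "pv", "w3b", "j", "other")

PAN_TARGETS = ("POU4F2", "ISL1", "SNCG", "RBPMS")
#: targets elevated only in non-DS RGCs (partial marker coverage)
PARTIAL_COVERAGE_TARGETS = ("ISL1", "RBPMS")
DS_SEED_GENES = ("FSTL4", "DCX")
NEGATIVE_SEEDS = {
    "progenitor": ("VSX2", "LHX2", "PAX6", "SIX6"),
    "rpe": ("MITF", "RPE65", "PMEL", "TYR"),
    "photoreceptor": ("CRX", "RCVRN", "NRL", "OTX2"),
}
SUBTYPE_MARKERS = {
    "ds_on_off": ("CARTPT", "CDH6"),
    "alpha": ("SPP1", "KCNG4", "CALB2"),
    "iprgc": ("OPN4",),
    "pv": ("PVALB",),
    "w3b": ("SDK2",),
    "j": ("JAM2",),
}


def _check_props(props: Mapping[str, float], what: str) -> None:
    if any(v < 0 for v in props.values()):
        raise ConfigError(f"{what} proportions must be >= 0")
    if not math.isclose(sum(props.values()), 1.0, abs_tol=1e-9):
        raise ConfigError(f"{what} proportions must sum to 1 (got "
                          f"{sum(props.values()):.6f})")


@dataclass
class MosaicConfig:
    """Study conditions for the synthetic single-cell mosaic.

    Defaults are desk-scale (500 cells x 3,000 genes, seconds to
    generate); :meth:`paper_scale` approximates a multi-plate
    microfluidic capture of a day-70 culture.
    """

    n_cells: int = 500
    n_genes: int = 3000
    population_props: dict[str, float] = field(default_factory=lambda: {
        "progenitor": 0.40, "rpe": 0.10, "photoreceptor": 0.20, "rgc": 0.30})
    subtype_props: dict[str, float] = field(default_factory=lambda: {
        "ds_on_off": 0.20, "ds_on": 0.25, "alpha": 0.18, "iprgc": 0.04,
        "pv": 0.05, "w3b": 0.05, "j": 0.05, "other": 0.18})
    n_pan_module: int = 150
    n_ds_module: int = 148
    n_negative_module: int = 12
    fold_change: float = 8.0
    dispersion: float = 0.4          # NB var = mu + dispersion * mu^2
    dropout: float = 0.2             # zero-inflation probability at low expression
    dropout_midpoint: float = 40.0   # counts scale of the dropout decay
    libsize_sigma: float = 0.3       # log-normal library-size spread
    background_log_mean: float = math.log(5.0)
    background_log_sigma: float = 1.2
    marker_log_mean: float = math.log(8.0)
    marker_log_sigma: float = 0.4
    seed: int = 42

    def __post_init__(self) -> None:
        _check_props(self.population_props, "population")
        _check_props(self.subtype_props, "RGC subtype")
        if set(self.population_props) != set(POPULATIONS):
            raise ConfigError(f"populations must be exactly {POPULATIONS}")
        if set(self.subtype_props) != set(RGC_SUBTYPES):
            raise ConfigError(f"RGC subtypes must be exactly {RGC_SUBTYPES}")
        if min(self.n_cells, self.n_genes, self.n_pan_module,
               self.n_ds_module, self.n_negative_module) <= 0:
            raise ConfigError("size parameters must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must lie in [0, 1)")
        if self.dropout_midpoint <= 0:
            raise ConfigError("dropout_midpoint must be > 0")
        if self.dispersion <= 0 or self.fold_change <= 0 or self.libsize_sigma < 0:
            raise ConfigError("dispersion/fold_change/libsize_sigma must be positive")
        structured = (self.n_pan_module + self.n_ds_module
                      + 3 * self.n_negative_module
                      + sum(len(v) for v in SUBTYPE_MARKERS.values()))
        if structured >= self.n_genes:
            raise ConfigError("n_genes too small for the configured modules")

    @classmethod
    def paper_scale(cls, **overrides) -> "MosaicConfig":
        """A capture-scale preset: a few hundred cells, genome-wide genes."""
        base = dict(n_cells=288, n_genes=20000, n_pan_module=150,
                    n_ds_module=148)
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthLabels:
    """Planted per-cell identities and per-gene module memberships."""

    cell_population: dict[str, str]
    cell_subtype: dict[str, str]          # "none" for non-RGC cells
    gene_module: dict[str, str]
    target_ids: dict[str, str] = field(default_factory=dict)

    def genes_in_module(self, module: str) -> frozenset[str]:
        return frozenset(g for g, m in self.gene_module.items() if m == module)

    def cells_in(self, population: str | None = None,
                 subtype: str | None = None) -> frozenset[str]:
        return frozenset(
            c for c in self.cell_population
            if (population is None or self.cell_population[c] == population)
            and (subtype is None or self.cell_subtype[c] == subtype))

    @property
    def pan_truth(self) -> frozenset[str]:
        """Planted pan-RGC module minus the target genes themselves."""
        return self.genes_in_module("pan_rgc") - set(PAN_TARGETS)

    @property
    def ds_truth(self) -> frozenset[str]:
        """Planted DS module minus the FSTL4 target."""
        return self.genes_in_module("ds") - {"FSTL4"}

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cells = pd.DataFrame({
            "cell_id": list(self.cell_population),
            "population": list(self.cell_population.values()),
            "subtype": [self.cell_subtype[c] for c in self.cell_population]})
        genes = pd.DataFrame({"gene_id": list(self.gene_module),
                              "module": list(self.gene_module.values())})
        return cells, genes


def _gene_layout(config: MosaicConfig) -> dict[str, str]:
    """Assign every gene id to exactly one module."""
    module: dict[str, str] = {}
    for i in range(config.n_pan_module):
        name = PAN_TARGETS[i] if i < 4 else f"PANRGC{i + 1:03d}"
        module[name] = "pan_rgc"
    for i in range(config.n_ds_module):
        name = DS_SEED_GENES[i] if i < 2 else f"DS{i + 1:03d}"
        module[name] = "ds"
    for sub, genes in SUBTYPE_MARKERS.items():
        for g in genes:
            module[g] = f"subtype_{sub}"
    for pop, seeds in NEGATIVE_SEEDS.items():
        prefix = {"progenitor": "PRG", "rpe": "RPE", "photoreceptor": "PHR"}[pop]
        for i in range(config.n_negative_module):
            name = seeds[i] if i < len(seeds) else f"{prefix}{i + 1:03d}"
            module[name] = pop
    n_bg = config.n_genes - len(module)
    for i in range(n_bg):
        module[f"BG{i + 1:04d}"] = "background"
    return module


def generate_mosaic(config: MosaicConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[ExpressionMatrix, TruthLabels]:
    """Draw a zero-inflated NB count mosaic with planted modules.

    ``seed`` overrides ``config.seed``.  Marker genes of a module have
    their mean multiplied by ``config.fold_change`` in the owning
    population/subtype.
    """
    config = config or MosaicConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    cell_ids = [f"C{i + 1:04d}" for i in range(config.n_cells)]
    pops = rng.choice(POPULATIONS, size=config.n_cells,
                      p=[config.population_props[p] for p in POPULATIONS])
    subs = np.where(
        pops == "rgc",
        rng.choice(RGC_SUBTYPES, size=config.n_cells,
                   p=[config.subtype_props[s] for s in RGC_SUBTYPES]),
        "none")

    gene_module = _gene_layout(config)
    gene_ids = list(gene_module)

    is_rgc = pops == "rgc"
    is_ds = np.isin(subs, ("ds_on_off", "ds_on"))
    coverage_masks: dict[str, np.ndarray] = {
        "pan_rgc": is_rgc,
        "ds": is_ds,
        "progenitor": pops == "progenitor",
        "rpe": pops == "rpe",
        "photoreceptor": pops == "photoreceptor",
        "background": np.zeros(config.n_cells, dtype=bool),
    }
    for sub in SUBTYPE_MARKERS:
        coverage_masks[f"subtype_{sub}"] = subs == sub

    elevated = np.zeros((config.n_genes, config.n_cells), dtype=bool)
    for i, g in enumerate(gene_ids):
        if g in PARTIAL_COVERAGE_TARGETS:
            elevated[i] = is_rgc & ~is_ds
        else:
            elevated[i] = coverage_masks[gene_module[g]]

    background = np.array([gene_module[g] == "background" for g in gene_ids])
    base = np.where(
        background,
        rng.lognormal(config.background_log_mean, config.background_log_sigma,
                      config.n_genes),
        rng.lognormal(config.marker_log_mean, config.marker_log_sigma,
                      config.n_genes))
    libfactor = rng.lognormal(0.0, config.libsize_sigma, config.n_cells)

    mu = base[:, None] * libfactor[None, :]
    mu = np.where(elevated, mu * config.fold_change, mu)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    if config.dropout > 0:
        # zero inflation decays with expected expression: lowly expressed
        # transcripts drop out at rate ~pi, abundant ones are rarely lost
        p_drop = config.dropout * np.exp(-mu / config.dropout_midpoint)
        counts[rng.random(counts.shape) < p_drop] = 0.0

    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, "counts")
    truth = TruthLabels(dict(zip(cell_ids, pops)),
                        dict(zip(cell_ids, subs)),
                        gene_module,
                        {"BRN3B": "POU4F2", "ISL1": "ISL1",
                         "SNCG": "SNCG", "RBPMS": "RBPMS", "FSTL4": "FSTL4"})
    return matrix, truth


def generate_gene_lengths(gene_ids: Sequence[str], seed: int = 0
                          ) -> GeneLengthTable:
    """Log-normal effective transcript lengths (median ~2 kb)."""
    rng = np.random.default_rng(seed)
    lengths = rng.lognormal(math.log(2000.0), 0.5, len(gene_ids))
    return GeneLengthTable(dict(zip(gene_ids, lengths)))


def mosaic_log_tpm(matrix: ExpressionMatrix,
                   lengths: GeneLengthTable | None = None,
                   seed: int = 0) -> ExpressionMatrix:
    """counts -> TPM -> log2(TPM+1), generating lengths when not given."""
    if lengths is None:
        lengths = generate_gene_lengths(matrix.gene_ids, seed)
    return log_transform(tpm_normalize(matrix, lengths))


# ---------------------------------------------------------------------------
# qPCR plate generator

PLATE_PANEL = ("POU4F1", "POU4F2", "POU4F3", "ISL1", "SNCG", "RBPMS",
               "CARTPT", "CDH6", "FSTL4", "SPP1", "CALB2", "KCNG4",
               "OPN4", "PVALB", "SDK2", "JAM2")

_PAN_PROFILE = ("POU4F1", "POU4F2", "POU4F3", "ISL1", "SNCG", "RBPMS")
#: planted identity -> (expressed genes, rule labels expected at zero noise)
PLATE_PROFILES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "on_off_ds": (_PAN_PROFILE + ("CARTPT", "CDH6"), ("ON-OFF DS",)),
    "on_ds": (_PAN_PROFILE + ("FSTL4",), ("ON DS",)),
    "alpha": (_PAN_PROFILE + ("SPP1", "KCNG4", "CALB2"), ("alpha",)),
    "iprgc_brn3_pos": (_PAN_PROFILE + ("OPN4",), ("ipRGC-BRN3+",)),
    "iprgc_brn3_neg": (("SNCG", "RBPMS", "OPN4"), ("ipRGC-BRN3-",)),
    "pv": (_PAN_PROFILE + ("PVALB",), ("PV",)),
    "w3b": (_PAN_PROFILE + ("SDK2",), ("W3B",)),
    "j": (_PAN_PROFILE + ("JAM2",), ("J",)),
    "other_rgc": (_PAN_PROFILE, ()),
}


@dataclass
class PlateConfig:
    """Conditions for a synthetic single-cell qPCR run."""

    n_wells: int = 96
    n_bad_wells: int = 12            # planted zero-cell/multi-cell/debris sites
    panel: tuple[str, ...] = PLATE_PANEL
    subtype_props: dict[str, float] = field(default_factory=lambda: {
        "on_off_ds": 0.15, "on_ds": 0.15, "alpha": 0.15,
        "iprgc_brn3_pos": 0.10, "iprgc_brn3_neg": 0.10,
        "pv": 0.10, "w3b": 0.10, "j": 0.10, "other_rgc": 0.05})
    lod: float = 40.0
    gain: float = 2.5                # cycles per log2 expression unit
    ct_noise_sd: float = 0.5         # cycle noise on detected genes
    dropout: float = 0.05            # per-gene detection failure
    expr_log_mean: float = math.log(30.0)
    expr_log_sigma: float = 0.3

    def __post_init__(self) -> None:
        if not self.panel:
            raise ConfigError("assayed-gene panel must not be empty")
        _check_props(self.subtype_props, "plate subtype")
        unknown = set(self.subtype_props) - set(PLATE_PROFILES)
        if unknown:
            raise ConfigError(f"unknown planted identities: {sorted(unknown)}")
        if self.n_bad_wells < 0 or self.n_bad_wells >= self.n_wells:
            raise ConfigError("n_bad_wells must lie in [0, n_wells)")
        if self.lod <= 0 or self.gain <= 0 or self.ct_noise_sd < 0:
            raise ConfigError("lod/gain/ct_noise_sd must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must lie in [0, 1)")


@dataclass
class PlateTruth:
    """Planted identity per well; expected labels under the calling rules."""

    well_identity: dict[str, str]       # one-cell wells -> planted identity
    expected_labels: dict[str, tuple[str, ...]]  # well -> rule labels (zero noise)


def generate_qpcr_plate(config: PlateConfig | None = None, seed: int = 0
                        ) -> tuple[CtMatrix, dict[str, str], PlateTruth]:
    """Simulate a capture plate: Ct matrix, annotations, planted truth.

    A detected gene's Ct is ``lod - gain*log2(1 + expression) + noise``
    clipped to (0, lod]; undetected genes carry the NaN sentinel.
    Planted bad wells cycle through zero_cell / multi_cell / debris:
    empty and debris sites never amplify, multi-cell sites carry the
    summed material of two cells.
    """
    config = config or PlateConfig()
    rng = np.random.default_rng(seed)
    wells = [f"W{i + 1:04d}" for i in range(config.n_wells)]
    bad_idx = set(rng.choice(config.n_wells, size=config.n_bad_wells,
                             replace=False).tolist())
    bad_cats = ("zero_cell", "multi_cell", "debris")

    identities = list(config.subtype_props)
    probs = [config.subtype_props[k] for k in identities]

    def _expression(identity: str) -> np.ndarray:
        expressed, _ = PLATE_PROFILES[identity]
        expr = np.zeros(len(config.panel))
        for i, g in enumerate(config.panel):
            if g in expressed:
                expr[i] = rng.lognormal(config.expr_log_mean,
                                        config.expr_log_sigma)
        return expr

    values = np.full((len(config.panel), config.n_wells), np.nan)
    annotations: dict[str, str] = {}
    well_identity: dict[str, str] = {}
    expected: dict[str, tuple[str, ...]] = {}
    n_bad_seen = 0
    for j, well in enumerate(wells):
        if j in bad_idx:
            cat = bad_cats[n_bad_seen % len(bad_cats)]
            n_bad_seen += 1
            annotations[well] = cat
            if cat == "multi_cell":
                expr = (_expression(str(rng.choice(identities, p=probs)))
                        + _expression(str(rng.choice(identities, p=probs))))
            else:
                continue
        else:
            annotations[well] = "one_cell"
            identity = str(rng.choice(identities, p=probs))
            well_identity[well] = identity
            expected[well] = PLATE_PROFILES[identity][1]
            expr = _expression(identity)
        detected = expr > 0
        if config.dropout > 0:
            detected &= rng.random(expr.shape) >= config.dropout
        ct = config.lod - config.gain * np.log2(1.0 + expr)
        if config.ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, config.ct_noise_sd, ct.shape)
        ct = np.clip(ct, 0.1, config.lod)
        values[detected, j] = ct[detected]

    ct_matrix = CtMatrix(values, list(config.panel), wells, annotations,
                         config.lod)
    return ct_matrix, annotations, PlateTruth(well_identity, expected)


# ---------------------------------------------------------------------------
# ICC count tables


def generate_icc_counts(true_proportion: float, n_images: int = 36,
                        cells_per_image: int = 200, seed: int = 0,
                        n_biological: int = 3,
                        reference_rate: float = 0.3) -> pd.DataFrame:
    """Binomial double-positive counts at a known co-expression rate.

    Each image draws a Poisson total-cell count, a binomial
    reference-positive (e.g. BRN3+) count, and a binomial
    double-positive count at ``true_proportion``.
    """
    if not (0.0 <= true_proportion <= 1.0):
        raise ConfigError("true_proportion must lie in [0, 1]")
    if not (0.0 <= reference_rate <= 1.0):
        raise ConfigError("reference_rate must lie in [0, 1]")
    if n_images < 1 or cells_per_image < 1 or n_biological < 1:
        raise ConfigError("n_images/cells_per_image/n_biological must be >= 1")
    rng = np.random.default_rng(seed)
    per_bio = max(1, n_images // n_biological)
    rows = []
    for i in range(n_images):
        total = max(int(rng.poisson(cells_per_image)), 1)
        ref = int(rng.binomial(total, reference_rate))
        double = int(rng.binomial(ref, true_proportion)) if ref else 0
        rows.append({"biological_replicate": f"B{min(i // per_bio, n_biological - 1) + 1}",
                     "image": f"img{i + 1:03d}", "total": total,
                     "reference_positive": ref, "double_positive": double})
    return pd.DataFrame(rows)
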