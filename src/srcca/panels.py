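"""Marker panels and alias resolution.

Marker genes are referred to in the literature by protein or common names
(BRN3B, CART, melanopsin, JAM-B...) that rarely match the gene symbols in
an expression matrix (POU4F2, CARTPT, OPN4, JAM2).  A :class:`MarkerPanel`
carries display symbols plus an alias map; :func:`resolve_symbol` turns a
display symbol into the matrix ids it may stand for.  Unresolved symbols
are always reported, never silently dropped.

Default panels and aliases ship as an editable YAML config
(``srcca/data/panels.yaml``) so mis-mappings can be overridden without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError

ROLES = ("pan_rgc_targets", "subtype_panel", "negative_panel")


@dataclass
class MarkerPanel:
    """A named gene set with a role and a display-symbol alias map."""

    name: str
    role: str
    genes: list[str]
    aliases: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"panel {self.name!r} is empty")
        if self.role not in ROLES:
            raise ConfigError(f"panel {self.name!r}: unknown role {self.role!r}")
        self.aliases = {k: ([v] if isinstance(v, str) else list(v))
                        for k, v in self.aliases.items()}

    def resolve(self, matrix_genes: Iterable[str]
                ) -> tuple[dict[str, list[str]], list[str]]:
        """Map each panel symbol to its matrix ids.

        Returns ``(resolved, unresolved)`` where ``resolved`` maps a
        display symbol to the matrix gene ids it resolves to (possibly
        several, e.g. BRN3 -> the POU4F family) and ``unresolved`` lists
        symbols with no id present in the matrix.
        """
        present = set(matrix_genes)
        resolved: dict[str, list[str]] = {}
        unresolved: list[str] = []
        for sym in self.genes:
            ids = [g for g in resolve_symbol(sym, self.aliases) if g in present]
            if ids:
                resolved[sym] = ids
            else:
                unresolved.append(sym)
        return resolved, unresolved


def resolve_symbol(symbol: str, aliases: Mapping[str, Sequence[str]]) -> list[str]:
    """Candidate matrix ids for a display symbol (itself, plus aliases)."""
    upper = {k.upper(): v for k, v in aliases.items()}
    hit = upper.get(symbol.upper())
    if hit is None:
        return [symbol]
    return [hit] if isinstance(hit, str) else list(hit)


def default_config_path() -> Path:
    return Path(str(resources.files("srcca").joinpath("data/panels.yaml")))


def load_panels(path: str | Path | None = None
                ) -> tuple[dict[str, MarkerPanel], dict[str, list[str]]]:
    """Load panels + alias table from YAML (the shipped defaults if None)."""
    path = Path(path) if path is not None else default_config_path()
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "panels" not in raw:
        raise ConfigError(f"{path}: expected a mapping with a 'panels' key")
    aliases = {k: ([v] if isinstance(v, str) else list(v))
               for k, v in (raw.get("aliases") or {}).items()}
    panels: dict[str, MarkerPanel] = {}
    for entry in raw["panels"]:
        try:
            panel = MarkerPanel(entry["name"], entry["role"],
                                list(entry["genes"]), aliases)
        except KeyError as exc:
            raise ConfigError(f"{path}: panel entry missing key {exc}") from exc
        if panel.name in panels:
            raise ConfigError(f"{path}: duplicate panel name {panel.name!r}")
        panels[panel.name] = panel
    return panels, aliases


def default_aliases() -> dict[str, list[str]]:
    return load_panels()[1]


def default_panels() -> dict[str, MarkerPanel]:
    return load_panels()[0]
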