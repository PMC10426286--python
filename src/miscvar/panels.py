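"""Disease gene-panel registry — the first stage of the candidate cascade.

Five panels are recognized: inborn errors of immunity (IEI), Kawasaki
disease (KD), severe COVID-19 (COVID19), MIS-C (MISC) and MIS-A (MISA).
Symbols are uppercase-normalized; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

PANEL_NAMES: tuple[str, ...] = ("IEI", "KD", "COVID19", "MISC", "MISA")

_PANEL_ALIASES = {
    "IEI": "IEI",
    "KD": "KD",
    "KAWASAKI": "KD",
    "COVID19": "COVID19",
    "COVID-19": "COVID19",
    "MISC": "MISC",
    "MIS-C": "MISC",
    "MISA": "MISA",
    "MIS-A": "MISA",
}


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def normalize_panel_name(name: str) -> str:
    try:
        return _PANEL_ALIASES[name.strip().upper()]
    except KeyError:
        raise ValueError(
            f"unknown panel name {name!r}; expected one of {PANEL_NAMES}"
        ) from None


@dataclass(frozen=True)
class GenePanel:
    """A named disease gene set."""

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.name not in PANEL_NAMES:
            raise ValueError(f"unknown panel name {self.name!r}")
        if not self.genes:
            raise ValueError(f"panel {self.name} has no genes")
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )


@dataclass
class PanelRegistry:
    """Collection of gene panels with cached union-panel membership."""

    panels: dict[str, GenePanel]
    _union: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name, panel in self.panels.items():
            if name != panel.name:
                raise ValueError(f"registry key {name!r} != panel name {panel.name!r}")
        self._union = frozenset().union(*(p.genes for p in self.panels.values())) \
            if self.panels else frozenset()

    @property
    def union_genes(self) -> frozenset[str]:
        return self._union

    def membership(self, gene: str) -> frozenset[str]:
        """Panel names containing *gene*; empty set means off-panel."""
        g = normalize_symbol(gene)
        return frozenset(
            name for name, panel in self.panels.items() if g in panel.genes
        )


def load_panels(path: str | Path) -> PanelRegistry:
    """Load a panel registry from a two-column (panel, gene) TSV.

    A header line ``panel<TAB>gene`` is optional. Duplicate (panel, gene)
    pairs are de-duplicated; an unrecognized panel name raises ValueError.
    """
    genes_by_panel: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            raw_panel, raw_gene = parts
            if lineno == 1 and raw_panel.strip().lower() == "panel":
                continue
            panel = normalize_panel_name(raw_panel)
            genes_by_panel.setdefault(panel, set()).add(normalize_symbol(raw_gene))
    return PanelRegistry(
        panels={
            name: GenePanel(name=name, genes=frozenset(genes), provenance=str(path))
            for name, genes in genes_by_panel.items()
        }
    )


def membership(registry: PanelRegistry, gene: str) -> frozenset[str]:
    return registry.membership(gene)


def multi_panel_genes(registry: PanelRegistry, genes: Iterable[str]) -> set[str]:
    """Subset of *genes* belonging to two or more panels."""
    return {
        normalize_symbol(g)
        for g in genes
        if len(registry.membership(g)) >= 2
    }
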