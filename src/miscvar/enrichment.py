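"""Gene-set over-representation, PPI edge enrichment, and pathway classification.

The interactome is a user-supplied scored edge list (any STRING-style
export works); edges below the confidence threshold (default 0.4, "medium
confidence") are dropped up front. Because the published edge counts and
enrichment p-values depend on the database version behind such an export,
these statistics are implemented generically:

* edge enrichment of a gene selection against either a *density* null
  (expected edges = rho * k(k-1)/2 with rho the background edge density,
  binomial upper-tail p) or a *degree-weighted permutation* null (nodes
  resampled with probability proportional to degree, add-one permutation
  p-value), the latter because STRING's own null is degree-corrected;
* term over-representation by the hypergeometric upper tail with
  Benjamini–Hochberg step-up q-values;
* the four-way classification of pathway labels into study-only,
  literature-only, shared, and combined-only sets;
* export of the pathway x gene membership matrix consumed by
  chord-diagram renderers (genes enriching no pathway are omitted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_SCORE_THRESHOLD = 0.4


@dataclass
class Interactome:
    """Background PPI network: scored undirected edges over gene symbols."""

    graph: nx.Graph
    score_threshold: float = DEFAULT_SCORE_THRESHOLD

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    ) -> "Interactome":
        g = nx.Graph()
        for a, b, score in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"confidence score {score} outside [0, 1]")
            if score >= score_threshold:
                g.add_edge(a, b, score=score)
            else:  # keep the node vocabulary even when the edge is dropped
                g.add_node(a)
                g.add_node(b)
        return cls(graph=g, score_threshold=score_threshold)

    @classmethod
    def from_tsv(
        cls, path: str | Path, score_threshold: float = DEFAULT_SCORE_THRESHOLD
    ) -> "Interactome":
        """Load a 3-column TSV (geneA, geneB, combined_score in [0,1])."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["a", "b", "score"], dtype={"a": str, "b": str})
        if isinstance(df.iloc[0]["score"], str):  # tolerate a header line
            df = df.iloc[1:]
        return cls.from_edges(
            (str(r.a), str(r.b), float(r.score)) for r in df.itertuples()
        )

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def density(self) -> float:
        return nx.density(self.graph)


@dataclass
class TermMap:
    """Flat term -> gene-set mapping over a background universe (no DAG)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term}: genes {sorted(stray)} outside universe"
                )

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "TermMap":
        """Load a GMT file (term <TAB> description <TAB> gene...).

        Without an explicit universe, the union of all term gene sets is used.
        """
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                terms[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
        uni = frozenset(universe) if universe is not None else frozenset().union(
            *(g for _, g in terms.values())
        )
        return cls(terms=terms, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    label: str
    overlap: int
    term_size: int
    expected: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class PathwayClassification:
    """Four disjoint pathway-label sets: S\\L, L\\S, S∩L, and C\\(S∪L)."""

    study_only: frozenset[str]
    literature_only: frozenset[str]
    shared: frozenset[str]
    combined_only: frozenset[str]


def subgraph_stats(inter: Interactome, genes: Iterable[str]) -> tuple[int, int]:
    """(node count, edge count) of the selection-induced subgraph."""
    selected = set(genes) & inter.nodes
    sub = inter.graph.subgraph(selected)
    return sub.number_of_nodes(), sub.number_of_edges()


def edge_enrichment(
    inter: Interactome,
    genes: Iterable[str],
    null: str = "density",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """(observed edges, expected edges, p-value) for a gene selection.

    ``null="density"`` — exact: expected = rho*k(k-1)/2 with rho the
    background density, p the binomial upper tail at the observed count.
    ``null="degree_permute"`` — Monte Carlo: k nodes redrawn (without
    replacement) with probability proportional to degree, expected is the
    permutation mean, p = (1 + #{draws >= observed}) / (n_perm + 1).
    """
    selected = sorted(set(genes) & inter.nodes)
    k = len(selected)
    if k < 2:
        raise ValueError("need at least 2 selected nodes present in the interactome")
    observed = inter.graph.subgraph(selected).number_of_edges()
    n_pairs = k * (k - 1) // 2

    if null == "density":
        rho = inter.density()
        expected = rho * n_pairs
        p = float(sps.binom.sf(observed - 1, n_pairs, rho))
        return observed, expected, p
    if null == "degree_permute":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        nodes = sorted(inter.nodes)
        deg = np.array([inter.graph.degree(n) for n in nodes], dtype=float)
        if deg.sum() == 0:
            raise ValueError("degree-weighted null undefined on an edgeless background")
        weights = deg / deg.sum()
        draws = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            pick = rng.choice(len(nodes), size=k, replace=False, p=weights)
            draws[i] = inter.graph.subgraph([nodes[j] for j in pick]).number_of_edges()
        expected = float(draws.mean())
        p = float((1 + np.sum(draws >= observed)) / (n_perm + 1))
        return observed, expected, p
    raise ValueError(f"unknown null model {null!r}")


def sample_null_selection(
    inter: Interactome, k: int, seed: int | np.random.Generator
) -> list[str]:
    """Draw k nodes from the degree-weighted null (the permutation null itself)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = sorted(inter.nodes)
    deg = np.array([inter.graph.degree(n) for n in nodes], dtype=float)
    weights = deg / deg.sum()
    pick = rng.choice(len(nodes), size=k, replace=False, p=weights)
    return [nodes[j] for j in pick]


def overrepresentation(
    term_map: TermMap, genes: Iterable[str], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation with BH step-up q-values.

    The selection is intersected with the universe; each term's p-value is
    the upper tail of drawing its observed overlap when sampling
    |selection| genes from the universe. Results are ordered by
    (q, p, term id); "significant" means q <= alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    selection = set(genes) & term_map.universe
    m = len(term_map.universe)
    n_draw = len(selection)
    rows = []
    for term, (label, term_genes) in term_map.terms.items():
        if not term_genes:
            continue
        overlap = len(selection & term_genes)
        big_k = len(term_genes)
        p = float(sps.hypergeom.sf(overlap - 1, m, big_k, n_draw))
        expected = n_draw * big_k / m if m else 0.0
        rows.append((term, label, overlap, big_k, expected, p))
    if not rows:
        return []
    pvals = [r[5] for r in rows]
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    results = [
        EnrichmentResult(term, label, overlap, size, expected, p, float(q))
        for (term, label, overlap, size, expected, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results


def classify_pathways(
    study: Iterable[str], literature: Iterable[str], combined: Iterable[str]
) -> PathwayClassification:
    """Partition pathway labels by which gene source identified them."""
    s, l, c = frozenset(study), frozenset(literature), frozenset(combined)
    return PathwayClassification(
        study_only=s - l,
        literature_only=l - s,
        shared=s & l,
        combined_only=c - (s | l),
    )


def chord_matrix(
    genes: Iterable[str], pathway_map: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Binary pathway x gene membership matrix for chord-diagram rendering.

    Rows are pathway labels, columns genes, both sorted; a gene belonging
    to no pathway does not appear.
    """
    gene_list = sorted(set(genes))
    pathways = {label: set(members) for label, members in pathway_map.items()}
    kept = [g for g in gene_list if any(g in mem for mem in pathways.values())]
    data = {
        label: [1 if g in members else 0 for g in kept]
        for label, members in sorted(pathways.items())
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=kept)
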