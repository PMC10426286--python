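"""Accessors for the packaged study fixtures.

Three plain-text tables ship with the package:

* ``candidate_variants.tsv`` — the published 50-variant candidate table
  (gene, carriers, transcript, HGVS change, effect, panel label, gnomAD and
  ABraOM AFs, inheritance pattern, dbSNP id) for the 30-patient cohort;
* ``gene_panels.tsv`` — a panel registry reverse-engineered from that
  table's Gene Panel column (each gene assigned at least its printed
  panel);
* ``pathway_gene_sets.tsv`` — the curated pathway x gene-source table:
  16 major pathways, each with the gene lists contributed by the present
  study, by the prior literature, and by the combined analysis.

The per-predictor verdicts of the candidate variants were not published —
only that each variant was called damaging by at least one of the 13
predictors — so :func:`synthetic_verdicts` fabricates a deterministic,
synthetic verdict profile per variant key that honors that property.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PREDICTORS, Cohort, Verdict, read_variant_table
from .panels import PanelRegistry, load_panels

STUDY_N_PATIENTS = 30


def study_roster(n_patients: int = STUDY_N_PATIENTS) -> tuple[str, ...]:
    return tuple(f"P{i}" for i in range(1, n_patients + 1))


def _data_path(name: str) -> Path:
    return Path(resources.files("miscvar").joinpath("data", name))


def variant_table_path() -> Path:
    return _data_path("candidate_variants.tsv")


def panel_table_path() -> Path:
    return _data_path("gene_panels.tsv")


def pathway_table_path() -> Path:
    return _data_path("pathway_gene_sets.tsv")


def synthetic_verdicts(key: tuple[str, str, str]) -> dict[str, Verdict]:
    """Deterministic synthetic predictor verdicts for a truth variant.

    Seeded from a stable hash of the variant key; between one and four of
    the 13 predictors are damaging (the published selection rule requires
    at least one), the rest tolerated or unknown.
    """
    digest = hashlib.md5("|".join(key).encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
    n_damaging = int(rng.integers(1, 5))
    order = rng.permutation(len(PREDICTORS))
    verdicts = {}
    for rank, idx in enumerate(order):
        if rank < n_damaging:
            v = Verdict.DAMAGING
        else:
            v = Verdict.TOLERATED if rng.random() < 0.7 else Verdict.UNKNOWN
        verdicts[PREDICTORS[idx]] = v
    return verdicts


def load_study_cohort(
    roster: Sequence[str] | None = None, with_verdicts: bool = True
) -> Cohort:
    """The packaged candidate-variant table as a cohort.

    With ``with_verdicts=True`` every variant receives its synthetic
    predictor profile (>=1 damaging), so the cohort passes the predictor
    stage exactly as the published candidates did.
    """
    cohort = read_variant_table(variant_table_path(), roster or study_roster())
    if with_verdicts:
        for key, ann in cohort.annotations.items():
            ann.predictor_verdicts = synthetic_verdicts(key)
    return cohort


def load_study_panels() -> PanelRegistry:
    return load_panels(panel_table_path())


def load_pathway_table() -> pd.DataFrame:
    return pd.read_csv(pathway_table_path(), sep="\t", dtype=str)


def _split_genes(cell: str) -> frozenset[str]:
    if cell.strip() in {"-", ""}:
        return frozenset()
    return frozenset(g.strip() for g in cell.split(",") if g.strip())


def pathway_gene_sets(source: str = "study") -> dict[str, frozenset[str]]:
    """Pathway label -> gene set for one gene source.

    ``source`` is one of ``study``, ``literature``, ``combined``; pathways
    with no genes from that source are omitted.
    """
    column = {
        "study": "StudyGenes",
        "literature": "LiteratureGenes",
        "combined": "CombinedGenes",
    }[source]
    df = load_pathway_table()
    out = {}
    for _, row in df.iterrows():
        genes = _split_genes(row[column])
        if genes:
            out[row["Pathway"]] = genes
    return out


def pathway_labels(source: str = "study") -> frozenset[str]:
    """Pathway labels identified by one gene source (study/literature/combined)."""
    return frozenset(pathway_gene_sets(source))
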