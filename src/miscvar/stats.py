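"""Cohort-level aggregation of the retained candidate variants.

These are the desk-scale summary operations: distinct-variant and gene
counts, carrier unions per variant / gene set, genes-per-patient tallies,
shared-carrier gene pairs, and the two descriptive-table conventions used
when printing (percentages truncated — not rounded — to one decimal, and
quartiles by linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import VariantKey
from .prioritize import CandidateSet

#: Complement-system gene set used for the pathway carrier count: the
#: complement pathway's present-study genes plus CFHR3, which the same
#: pathway table lists among the present-study complement-family findings.
COMPLEMENT_GENES: frozenset[str] = frozenset(
    {"C6", "C8A", "CD46", "CFB", "CFHR1", "CFHR3", "CFHR5", "FCN3", "MASP2"}
)


@dataclass
class CohortSummary:
    n_variants: int
    n_genes: int
    n_patients_with_cv: int
    pct_patients_with_cv: float
    genes_per_patient: dict[str, int]
    carriers_per_variant: dict[VariantKey, int]


def truncated_percent(numerator: int, denominator: int) -> float:
    """100*num/den truncated (not rounded) to one decimal: 29/30 -> 96.6."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    return (1000 * numerator // denominator) / 10.0


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation between order statistics."""
    if len(values) == 0:
        raise ValueError("median_iqr requires a non-empty list")
    arr = np.asarray(values, dtype=float)
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def carriers(cands: CandidateSet, gene: str, cdna_change: str) -> int:
    """Number of distinct patients carrying the (gene, cdna_change) variant."""
    matched = [
        rec for rec, _ in cands.variants
        if rec.gene == gene and rec.cdna_change == cdna_change
    ]
    if not matched:
        raise KeyError((gene, cdna_change))
    pooled: set[str] = set()
    for rec in matched:
        pooled |= rec.carriers
    return len(pooled)


def genes_per_patient(cands: CandidateSet, patient: str) -> int:
    """Distinct genes in which *patient* carries a retained variant."""
    if patient not in cands.per_patient:
        raise KeyError(patient)
    return len({key[0] for key in cands.per_patient[patient]})


def pathway_carriers(cands: CandidateSet, genes: Iterable[str]) -> int:
    """Distinct patients carrying a retained variant in any listed gene."""
    wanted = set(genes)
    hit: set[str] = set()
    for rec, _ in cands.variants:
        if rec.gene in wanted:
            hit |= rec.carriers
    return len(hit)


def cooccurring_gene_pairs(
    cands: CandidateSet, min_shared: int = 1
) -> list[tuple[str, str, int]]:
    """Unordered gene pairs whose carrier sets share >= min_shared patients.

    Returned in lexicographic order as (gene_a, gene_b, shared_count) with
    gene_a < gene_b.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    gene_carriers: dict[str, set[str]] = {}
    for rec, _ in cands.variants:
        gene_carriers.setdefault(rec.gene, set()).update(rec.carriers)
    genes = sorted(gene_carriers)
    out = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            shared = len(gene_carriers[ga] & gene_carriers[gb])
            if shared >= min_shared:
                out.append((ga, gb, shared))
    return out


def summarize(cands: CandidateSet, roster: Sequence[str]) -> CohortSummary:
    """All headline cohort aggregates, computed deterministically."""
    keys = cands.keys
    all_carriers: set[str] = set()
    carriers_per_variant: dict[VariantKey, int] = {}
    for rec, _ in cands.variants:
        carriers_per_variant[rec.key] = len(rec.carriers)
        all_carriers |= rec.carriers
    n_with_cv = len(all_carriers & set(roster))
    return CohortSummary(
        n_variants=len(keys),
        n_genes=len(cands.genes),
        n_patients_with_cv=n_with_cv,
        pct_patients_with_cv=truncated_percent(n_with_cv, len(roster)),
        genes_per_patient={p: genes_per_patient(cands, p) for p in roster},
        carriers_per_variant=carriers_per_variant,
    )
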