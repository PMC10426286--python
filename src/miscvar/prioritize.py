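"""The candidate-variant cascade: panel -> allele frequency -> predictor consensus.

A variant is retained iff

1. its gene belongs to at least one active disease panel,
2. every population allele frequency reported for it (gnomAD, ExAC,
   1000 Genomes, ABraOM) is at or below the threshold (default 5%,
   inclusive) — a variant absent from all four databases passes, absence
   implying rarity, and
3. at least ``min_damaging_predictors`` (default 1) of the 13 in-silico
   predictors call it damaging; an ``unknown`` verdict never counts.

The three filters are conjunctive, so the retained set is order-free; the
audit attributes each removal to the first failing stage in the fixed order
panel -> AF -> predictor. Clinical-significance labels are carried through
as annotations, never used to exclude, and no zygosity/inheritance-model
filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .cohort import AnnotationBundle, Cohort, VariantKey, VariantRecord
from .panels import PANEL_NAMES, PanelRegistry

STAGES = ("panel", "af", "predictor")


@dataclass(frozen=True)
class CascadeConfig:
    af_threshold: float = 0.05
    min_damaging_predictors: int = 1
    active_panels: frozenset[str] = frozenset(PANEL_NAMES)

    def __post_init__(self) -> None:
        if not 0.0 < self.af_threshold <= 1.0:
            raise ValueError("af_threshold must be in (0, 1]")
        if self.min_damaging_predictors < 1:
            raise ValueError("min_damaging_predictors must be >= 1")
        unknown = self.active_panels - set(PANEL_NAMES)
        if unknown:
            raise ValueError(f"unknown panels in active_panels: {sorted(unknown)}")


@dataclass
class CandidateSet:
    """Variants surviving the cascade, with inverse indices and an audit."""

    variants: list[tuple[VariantRecord, AnnotationBundle]]
    per_patient: dict[str, set[VariantKey]]
    per_gene: dict[str, set[VariantKey]]
    audit: dict[str, int] = field(default_factory=lambda: dict.fromkeys(STAGES, 0))

    @property
    def keys(self) -> set[VariantKey]:
        return {rec.key for rec, _ in self.variants}

    @property
    def genes(self) -> set[str]:
        return {rec.gene for rec, _ in self.variants}

    def record(self, key: VariantKey) -> tuple[VariantRecord, AnnotationBundle]:
        for rec, ann in self.variants:
            if rec.key == key:
                return rec, ann
        raise KeyError(key)


def af_pass(ann: AnnotationBundle, threshold: float) -> bool:
    """True iff every reported population AF is <= threshold (inclusive).

    A variant with no reported AF passes: absence from the population
    databases is itself evidence of rarity.
    """
    return all(af <= threshold for af in ann.reported_afs().values())


def predictor_pass(ann: AnnotationBundle, min_damaging: int) -> bool:
    """True iff at least *min_damaging* predictors call the variant damaging."""
    return ann.n_damaging() >= min_damaging


def prioritize_cohort(
    cohort: Cohort, registry: PanelRegistry, cfg: CascadeConfig | None = None
) -> CandidateSet:
    """Run the full cascade over a cohort.

    Output variants are ordered by (gene, cdna_change); the audit maps each
    stage to the number of records it removed, stages applied in the fixed
    order panel -> AF -> predictor.

    Raises KeyError if a record lacks an annotation bundle.
    """
    cfg = cfg or CascadeConfig()
    retained: list[tuple[VariantRecord, AnnotationBundle]] = []
    audit = dict.fromkeys(STAGES, 0)
    for rec in cohort.records:
        if rec.key not in cohort.annotations:
            raise KeyError(f"variant {rec.key} has no annotation bundle")
        ann = cohort.annotations[rec.key]
        if not (registry.membership(rec.gene) & cfg.active_panels):
            audit["panel"] += 1
        elif not af_pass(ann, cfg.af_threshold):
            audit["af"] += 1
        elif not predictor_pass(ann, cfg.min_damaging_predictors):
            audit["predictor"] += 1
        else:
            retained.append((rec, ann))
    retained.sort(key=lambda pair: (pair[0].gene, pair[0].cdna_change, pair[0].transcript))

    per_patient: dict[str, set[VariantKey]] = {p: set() for p in cohort.patients}
    per_gene: dict[str, set[VariantKey]] = {}
    for rec, _ in retained:
        per_gene.setdefault(rec.gene, set()).add(rec.key)
        for patient in rec.carriers:
            per_patient[patient].add(rec.key)
    return CandidateSet(
        variants=retained, per_patient=per_patient, per_gene=per_gene, audit=audit
    )


def as_candidate_set(cohort: Cohort) -> CandidateSet:
    """Wrap an already-filtered cohort as a CandidateSet (no stages applied)."""
    retained = [(rec, cohort.annotations[rec.key]) for rec in cohort.records]
    retained.sort(key=lambda pair: (pair[0].gene, pair[0].cdna_change, pair[0].transcript))
    per_patient: dict[str, set[VariantKey]] = {p: set() for p in cohort.patients}
    per_gene: dict[str, set[VariantKey]] = {}
    for rec, _ in retained:
        per_gene.setdefault(rec.gene, set()).add(rec.key)
        for patient in rec.carriers:
            per_patient[patient].add(rec.key)
    return CandidateSet(variants=retained, per_patient=per_patient, per_gene=per_gene)


def candidate_cohort(cands: CandidateSet, roster: Iterable[str]) -> Cohort:
    """Repackage a candidate set as a cohort (e.g. to re-run the cascade)."""
    return Cohort(
        patients=tuple(roster),
        records=[rec for rec, _ in cands.variants],
        annotations={rec.key: ann for rec, ann in cands.variants},
    )
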