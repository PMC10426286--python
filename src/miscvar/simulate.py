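"""Deterministic synthetic-cohort generator.

Emulates the analysis inputs end to end without any downloads: the 50
published candidate variants are embedded with their printed carriers in a
30-patient cohort, surrounded by decoy variants each constructed to fail
exactly one known cascade stage —

* *common-AF* decoys sit in a panel gene with a damaging verdict but carry
  at least one population AF above 5%;
* *benign* decoys sit in a panel gene with rare AFs but no damaging
  verdict among the 13 predictors;
* *off-panel* decoys are rare and damaging but in a gene outside every
  panel.

Because every decoy fails by construction, the cascade must recover exactly
the embedded truth set for any seed — the backbone correctness property of
the whole pipeline. All randomness flows through a single seeded generator
per call; identical specs yield byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures
from .cohort import (
    PREDICTORS,
    AnnotationBundle,
    Cohort,
    Effect,
    VariantKey,
    VariantRecord,
    Verdict,
    write_cohort_vcf,
    write_variant_table,
)
from .enrichment import Interactome

DECOY_STAGES = ("af", "predictor", "panel")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated cohort.

    Defaults mirror the cohort being emulated: 30 patients aged 0-17 years
    with a median age near 6, and 200 decoys split evenly across the three
    failure modes.
    """

    seed: int
    n_patients: int = 30
    n_decoys: int = 200
    decoy_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # (common-AF, benign, off-panel)
    age_min: int = 0
    age_max: int = 17
    age_median: float = 6.0

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if abs(sum(self.decoy_mix) - 1.0) > 1e-9:
            raise ValueError("decoy_mix fractions must sum to 1")


@dataclass
class TruthTable:
    """Embedded truth: candidate keys vs decoy keys with their failure stage."""

    true_keys: set[VariantKey]
    decoy_keys: dict[VariantKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.true_keys & set(self.decoy_keys)
        if overlap:
            raise ValueError(f"decoy keys collide with truth keys: {overlap}")


def _decoy_counts(n_decoys: int, mix: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n_decoys across the three modes."""
    raw = [n_decoys * f for f in mix]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(3), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: n_decoys - sum(counts)]:
        counts[i] += 1
    return counts


def _verdicts(rng: np.random.Generator, n_damaging: int) -> dict[str, Verdict]:
    order = rng.permutation(len(PREDICTORS))
    verdicts: dict[str, Verdict] = {}
    for rank, idx in enumerate(order):
        if rank < n_damaging:
            v = Verdict.DAMAGING
        else:
            v = Verdict.TOLERATED if rng.random() < 0.7 else Verdict.UNKNOWN
        verdicts[PREDICTORS[idx]] = v
    return verdicts


def build_cohort(spec: SyntheticSpec) -> tuple[Cohort, TruthTable]:
    """Assemble the in-memory cohort: truth variants plus seeded decoys."""
    rng = np.random.default_rng(spec.seed)
    roster = tuple(f"P{i}" for i in range(1, spec.n_patients + 1))
    registry = fixtures.load_study_panels()
    panel_genes = sorted(registry.union_genes)

    truth_cohort = fixtures.load_study_cohort(roster=roster)
    records = list(truth_cohort.records)
    annotations = dict(truth_cohort.annotations)
    truth = TruthTable(true_keys=truth_cohort.variant_keys())

    counts = _decoy_counts(spec.n_decoys, spec.decoy_mix)
    serial = 0
    for stage, n in zip(DECOY_STAGES, counts):
        for _ in range(n):
            serial += 1
            if stage == "panel":
                gene = f"DECOY{serial:04d}"
                assert gene not in registry.union_genes, "off-panel decoy collides with a panel gene"
            else:
                gene = panel_genes[int(rng.integers(len(panel_genes)))]
            cdna = f"c.{90000 + serial}A>G"
            n_carriers = int(rng.integers(1, 4))
            carriers = frozenset(
                roster[i] for i in rng.choice(spec.n_patients, n_carriers, replace=False)
            )
            if stage == "af":
                af_gnomad = float(np.round(rng.uniform(0.051, 0.5), 4))
                n_damaging = int(rng.integers(1, 4))
            else:
                af_gnomad = float(np.round(rng.uniform(0.0, 0.04), 4))
                n_damaging = 0 if stage == "predictor" else int(rng.integers(1, 4))
            rec = VariantRecord(
                gene=gene,
                transcript=f"NM_9{serial:05d}.1",
                cdna_change=cdna,
                effect=Effect.MISSENSE,
                carriers=carriers,
                rsid=None,
                panel_label=None if stage == "panel" else "IEI",
            )
            records.append(rec)
            annotations[rec.key] = AnnotationBundle(
                af_gnomad=af_gnomad,
                af_exac=float(np.round(rng.uniform(0.0, 0.04), 4))
                if rng.random() < 0.5 else None,
                predictor_verdicts=_verdicts(rng, n_damaging),
            )
            truth.decoy_keys[rec.key] = stage
    cohort = Cohort(patients=roster, records=records, annotations=annotations)
    return cohort, truth


def generate_ages(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Integer ages in [age_min, age_max] whose median concentrates near 6.

    Drawn from a gamma(2.5, scale=3) — a right-skewed shape typical of
    pediatric admission-age distributions, median ~6.5 before flooring —
    then floored and clipped to the cohort's printed age range.
    """
    raw = rng.gamma(shape=2.5, scale=3.0, size=spec.n_patients)
    return np.clip(np.floor(raw), spec.age_min, spec.age_max).astype(int)


@dataclass
class GeneratedCohort:
    cohort: Cohort
    truth: TruthTable
    ages: np.ndarray
    vcf_path: Path | None = None
    table_path: Path | None = None
    truth_path: Path | None = None


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path | None = None) -> GeneratedCohort:
    """Generate the cohort; optionally write VCF + table + truth JSON.

    Output files are byte-identical across runs with the same spec. The
    seed is recorded in the VCF header for provenance.
    """
    cohort, truth = build_cohort(spec)
    ages = generate_ages(spec, np.random.default_rng(spec.seed + 1))
    result = GeneratedCohort(cohort=cohort, truth=truth, ages=ages)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.vcf_path = out / "cohort.vcf"
        result.table_path = out / "cohort.tsv"
        result.truth_path = out / "truth.json"
        write_cohort_vcf(
            cohort, result.vcf_path,
            header_meta={"miscvar_seed": str(spec.seed), "miscvar_n_decoys": str(spec.n_decoys)},
        )
        write_variant_table(
            cohort.records, cohort.annotations, result.table_path, extended=True
        )
        result.truth_path.write_text(
            json.dumps(
                {
                    "seed": spec.seed,
                    "true_keys": sorted(list(k) for k in truth.true_keys),
                    "decoy_keys": {
                        "|".join(k): stage for k, stage in sorted(truth.decoy_keys.items())
                    },
                    "ages": ages.tolist(),
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
    return result


def generate_toy_interactome(seed: int, n_nodes: int, density: float) -> Interactome:
    """Seeded Erdos–Renyi background with scores uniform in [0.4, 1.0].

    Scores start at the medium-confidence threshold, so thresholding is a
    no-op and the realized density is the requested Bernoulli density.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.4, 1.0))))
    inter = Interactome.from_edges(edges)
    for node in nodes:  # isolated nodes stay part of the background
        inter.graph.add_node(node)
    return inter
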