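"""Domain types and readers/writers for cohort variant data.

A cohort is a fixed roster of patients plus a collection of annotated
variant records. A variant is identified at the transcript level by the
triple ``(gene, transcript, cdna_change)`` — HGVS c./n. notation compared by
plain string equality, never by genomic coordinates. Two on-disk forms are
supported:

* a tab-separated variant table mirroring the published candidate-variant
  layout (``Gene, Patient, Transcript, Variant, Effect, GenePanel,
  AF_gnomAD, AF_ABraOM, Inheritance, dbSNP``, with optional extra
  annotation columns), and
* a minimal VCF v4.2 dialect in which all annotations live in INFO keys and
  carriers are read off the per-patient genotype columns.

All allele frequencies are stored internally as fractions in [0, 1];
the table dialect prints percent strings ("3.83%") and uses "N/A" for a
missing value and "<0.01%" for a below-resolution bound (parsed as 0.0001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The 13 in-silico pathogenicity predictors whose verdicts annotate each variant.
PREDICTORS: tuple[str, ...] = (
    "CADD",
    "BayesDel_addAF",
    "DANN",
    "DEOGEN2",
    "EIGEN",
    "FATHMM-MKL",
    "LIST-S2",
    "M-CAP",
    "MutationAssessor",
    "MutationTaster",
    "SIFT",
    "Polyphen-2",
    "PrimateAI",
)

#: Variant key: (gene, transcript, cdna_change).
VariantKey = tuple[str, str, str]


class Effect(str, Enum):
    """Molecular consequence classes observed in the candidate table."""

    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    DELETION = "deletion"
    REGULATORY = "regulatory"


_EFFECT_ALIASES = {
    "missense": Effect.MISSENSE,
    "frameshift": Effect.FRAMESHIFT,
    "stop gain": Effect.STOP_GAINED,
    "stop gained": Effect.STOP_GAINED,
    "stop_gained": Effect.STOP_GAINED,
    "splice donor": Effect.SPLICE_DONOR,
    "splice_donor": Effect.SPLICE_DONOR,
    "splice acceptor": Effect.SPLICE_ACCEPTOR,
    "splice_acceptor": Effect.SPLICE_ACCEPTOR,
    "deletion": Effect.DELETION,
    "regulatory": Effect.REGULATORY,
}

_EFFECT_LABELS = {
    Effect.MISSENSE: "Missense",
    Effect.FRAMESHIFT: "Frameshift",
    Effect.STOP_GAINED: "Stop gained",
    Effect.SPLICE_DONOR: "Splice donor",
    Effect.SPLICE_ACCEPTOR: "Splice acceptor",
    Effect.DELETION: "Deletion",
    Effect.REGULATORY: "Regulatory",
}


def parse_effect(label: str) -> Effect:
    try:
        return _EFFECT_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized effect label: {label!r}") from None


class Verdict(str, Enum):
    """Three-valued in-silico predictor call."""

    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """One transcript-level variant with its carrier patients.

    ``panel_label`` carries the free-text panel annotation of the table
    dialect (e.g. "IEI/Covid-19"); panel membership used by the cascade
    always comes from a :class:`~miscvar.panels.PanelRegistry`, not from
    this label.
    """

    gene: str
    transcript: str
    cdna_change: str
    effect: Effect
    carriers: frozenset[str]
    rsid: str | None = None
    panel_label: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")

    @property
    def key(self) -> VariantKey:
        return (self.gene, self.transcript, self.cdna_change)


@dataclass
class AnnotationBundle:
    """Population allele frequencies, predictor verdicts and clinical labels.

    Each AF is a fraction in [0, 1] or ``None`` when the variant is absent
    from that database. ``predictor_verdicts`` maps each of the 13
    predictors to a :class:`Verdict`; predictors not scored are ``unknown``.
    """

    af_gnomad: float | None = None
    af_exac: float | None = None
    af_1kg: float | None = None
    af_abraom: float | None = None
    predictor_verdicts: dict[str, Verdict] = field(default_factory=dict)
    clinical_significance: str | None = None
    inheritance: str | None = None

    def __post_init__(self) -> None:
        full = {p: Verdict.UNKNOWN for p in PREDICTORS}
        for name, verdict in self.predictor_verdicts.items():
            if name not in full:
                raise ValueError(f"unknown predictor: {name!r}")
            full[name] = Verdict(verdict)
        self.predictor_verdicts = full
        for label, af in self.reported_afs().items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{label} allele frequency {af} outside [0, 1]")

    def reported_afs(self) -> dict[str, float]:
        """Mapping of database label -> AF, restricted to reported values."""
        pairs = {
            "gnomAD": self.af_gnomad,
            "ExAC": self.af_exac,
            "1KG": self.af_1kg,
            "ABraOM": self.af_abraom,
        }
        return {k: v for k, v in pairs.items() if v is not None}

    def n_damaging(self) -> int:
        return sum(1 for v in self.predictor_verdicts.values() if v is Verdict.DAMAGING)


@dataclass
class Cohort:
    """Patient roster, variant records, and per-variant annotations."""

    patients: tuple[str, ...]
    records: list[VariantRecord]
    annotations: dict[VariantKey, AnnotationBundle]
    skipped_records: int = 0

    def __post_init__(self) -> None:
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("patient roster contains duplicates")
        roster = set(self.patients)
        keys = {r.key for r in self.records}
        for rec in self.records:
            stray = rec.carriers - roster
            if stray:
                raise ValueError(
                    f"carriers {sorted(stray)} of variant {rec.key} not in roster"
                )
        for key in self.annotations:
            if key not in keys:
                raise ValueError(f"annotation for unknown variant key {key}")

    def variant_keys(self) -> set[VariantKey]:
        return {r.key for r in self.records}


# ---------------------------------------------------------------------------
# Allele-frequency cell codec (table dialect)
# ---------------------------------------------------------------------------

#: Fraction substituted for a "<0.01%" below-resolution cell (the printed bound).
BELOW_RESOLUTION_AF = 0.0001


def parse_af_cell(cell: str) -> float | None:
    """Parse a percent cell: '3.83%' -> 0.0383, 'N/A' -> None, '<0.01%' -> 1e-4."""
    text = cell.strip().rstrip("*").strip()
    if text in {"", "N/A", "NA", "-", "nan"}:
        return None
    bounded = text.startswith("<")
    if bounded:
        text = text[1:].strip()
    if not text.endswith("%"):
        raise ValueError(f"malformed allele-frequency cell: {cell!r}")
    try:
        value = float(text[:-1]) / 100.0
    except ValueError:
        raise ValueError(f"malformed allele-frequency cell: {cell!r}") from None
    # "<X%" cells carry the bound itself ("<0.01%" -> 0.0001)
    return value


def format_af_cell(af: float | None) -> str:
    if af is None:
        return "N/A"
    return f"{af * 100:.6g}%"


# ---------------------------------------------------------------------------
# Tabular reader / writer
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "Gene",
    "Patient",
    "Transcript",
    "Variant",
    "Effect",
    "GenePanel",
    "AF_gnomAD",
    "AF_ABraOM",
    "Inheritance",
    "dbSNP",
)

_NA_STRINGS = {"", "N/A", "NA", "-", "nan", "None"}


def _opt(cell: object) -> str | None:
    text = str(cell).strip()
    return None if text in _NA_STRINGS else text


def _parse_verdict_cell(cell: object) -> dict[str, Verdict]:
    text = str(cell).strip()
    if text in _NA_STRINGS:
        return {}
    out: dict[str, Verdict] = {}
    for item in text.split(","):
        name, _, verdict = item.strip().partition("=")
        out[name] = Verdict(verdict)
    return out


def read_variant_table(path: str | Path, roster: Sequence[str]) -> Cohort:
    """Read a tab-separated variant table into a :class:`Cohort`.

    Rows sharing a ``(Gene, Transcript, Variant)`` key are merged by
    unioning their carrier lists. Optional columns ``AF_ExAC``, ``AF_1KG``,
    ``Predictors`` (comma list of predictor=verdict) and ``ClinSig`` are
    parsed when present, so the tabular form can carry everything the VCF
    dialect does.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks columns {missing}")

    merged: dict[VariantKey, VariantRecord] = {}
    annotations: dict[VariantKey, AnnotationBundle] = {}
    roster_set = set(roster)
    for idx, row in df.iterrows():
        gene = row["Gene"].strip().upper()
        transcript = row["Transcript"].strip()
        cdna = "".join(row["Variant"].split())  # printed HGVS may embed spaces
        carriers = frozenset(
            p.strip() for p in row["Patient"].split(",") if p.strip()
        )
        stray = carriers - roster_set
        if stray:
            raise ValueError(
                f"row {idx + 2} of {path}: carriers {sorted(stray)} not in roster"
            )
        try:
            af_gnomad = parse_af_cell(row["AF_gnomAD"])
            af_abraom = parse_af_cell(row["AF_ABraOM"])
            af_exac = parse_af_cell(row["AF_ExAC"]) if "AF_ExAC" in row else None
            af_1kg = parse_af_cell(row["AF_1KG"]) if "AF_1KG" in row else None
        except ValueError as exc:
            raise ValueError(f"row {idx + 2} of {path}: {exc}") from None
        record = VariantRecord(
            gene=gene,
            transcript=transcript,
            cdna_change=cdna,
            effect=parse_effect(row["Effect"]),
            carriers=carriers,
            rsid=_opt(row["dbSNP"]),
            panel_label=_opt(row["GenePanel"]),
        )
        key = record.key
        if key in merged:
            merged[key] = replace(
                merged[key], carriers=merged[key].carriers | carriers
            )
        else:
            merged[key] = record
            annotations[key] = AnnotationBundle(
                af_gnomad=af_gnomad,
                af_exac=af_exac,
                af_1kg=af_1kg,
                af_abraom=af_abraom,
                predictor_verdicts=_parse_verdict_cell(row.get("Predictors", "")),
                clinical_significance=_opt(row.get("ClinSig", "")),
                inheritance=_opt(row["Inheritance"]),
            )
    return Cohort(
        patients=tuple(roster), records=list(merged.values()), annotations=annotations
    )


def write_variant_table(
    records: Iterable[VariantRecord],
    annotations: Mapping[VariantKey, AnnotationBundle],
    path: str | Path,
    extended: bool = False,
) -> None:
    """Write records in the tabular layout, sorted by (gene, cdna_change).

    With ``extended=True`` the optional ``AF_ExAC``, ``AF_1KG``,
    ``Predictors`` and ``ClinSig`` columns are included, making the file a
    lossless mirror of the VCF dialect.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (r.gene, r.cdna_change, r.transcript)):
        ann = annotations[rec.key]
        row = {
            "Gene": rec.gene,
            "Patient": ", ".join(sorted(rec.carriers, key=_patient_sort_key)),
            "Transcript": rec.transcript,
            "Variant": rec.cdna_change,
            "Effect": _EFFECT_LABELS[rec.effect],
            "GenePanel": rec.panel_label or "N/A",
            "AF_gnomAD": format_af_cell(ann.af_gnomad),
            "AF_ABraOM": format_af_cell(ann.af_abraom),
            "Inheritance": ann.inheritance or "N/A",
            "dbSNP": rec.rsid or "N/A",
        }
        if extended:
            row["AF_ExAC"] = format_af_cell(ann.af_exac)
            row["AF_1KG"] = format_af_cell(ann.af_1kg)
            row["Predictors"] = ",".join(
                f"{p}={v.value}" for p, v in ann.predictor_verdicts.items()
            )
            row["ClinSig"] = ann.clinical_significance or "N/A"
        rows.append(row)
    columns = list(_REQUIRED_COLUMNS) + (
        ["AF_ExAC", "AF_1KG", "Predictors", "ClinSig"] if extended else []
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def _patient_sort_key(pid: str) -> tuple:
    digits = "".join(ch for ch in pid if ch.isdigit())
    return (int(digits) if digits else 0, pid)


# ---------------------------------------------------------------------------
# Minimal VCF dialect
# ---------------------------------------------------------------------------
#
# The annotation vocabulary (INFO key PRED holding a comma list of
# predictor=verdict pairs) embeds '=' inside an INFO value, which strict
# htslib-based parsers reject; the dialect is therefore read and written by
# this module directly. The contract is bit-exact only for files produced by
# :func:`write_cohort_vcf` / the synthetic generator.

_VCF_REQUIRED_INFO = ("GENE", "TX", "HGVSC", "EFFECT")


def _info_dict(info_field: str) -> dict[str, str]:
    out = {}
    for item in info_field.split(";"):
        if not item or item == ".":
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def read_cohort_vcf(path: str | Path) -> Cohort:
    """Read the minimal VCF dialect into a :class:`Cohort`.

    The roster is the VCF sample columns, in order. A record lacking any of
    the required INFO keys (GENE, TX, HGVSC, EFFECT) is skipped with a
    logged warning; the number of skipped records is available as
    ``Cohort.skipped_records``. Multi-allelic sites are split into one
    logical record per ALT allele (annotations are site-level in this
    dialect and are shared across the split records).
    """
    patients: tuple[str, ...] = ()
    merged: dict[VariantKey, VariantRecord] = {}
    annotations: dict[VariantKey, AnnotationBundle] = {}
    skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                patients = tuple(line.split("\t")[9:])
                continue
            fields = line.split("\t")
            info = _info_dict(fields[7])
            missing = [k for k in _VCF_REQUIRED_INFO if k not in info]
            if missing:
                skipped += 1
                logger.warning(
                    "skipping VCF record at %s:%s — missing INFO %s",
                    fields[0], fields[1], missing,
                )
                continue
            alts = fields[4].split(",")
            genotypes = fields[9:]
            for alt_index in range(1, len(alts) + 1):
                carriers = frozenset(
                    pid
                    for pid, gt in zip(patients, genotypes)
                    if str(alt_index) in gt.split(":", 1)[0].replace("|", "/").split("/")
                )
                suffix = "" if alt_index == 1 else f"#alt{alt_index}"
                verdicts = {}
                if info.get("PRED"):
                    for item in info["PRED"].split(","):
                        name, _, verdict = item.partition("=")
                        verdicts[name] = Verdict(verdict)
                record = VariantRecord(
                    gene=info["GENE"],
                    transcript=info["TX"],
                    cdna_change=info["HGVSC"] + suffix,
                    effect=Effect(info["EFFECT"]),
                    carriers=carriers,
                    rsid=info.get("RSID") or (None if fields[2] == "." else fields[2]),
                    panel_label=info.get("PANEL") or None,
                )
                merged[record.key] = record
                annotations[record.key] = AnnotationBundle(
                    af_gnomad=float(info["AF_GNOMAD"]) if "AF_GNOMAD" in info else None,
                    af_exac=float(info["AF_EXAC"]) if "AF_EXAC" in info else None,
                    af_1kg=float(info["AF_1KG"]) if "AF_1KG" in info else None,
                    af_abraom=float(info["AF_ABRAOM"]) if "AF_ABRAOM" in info else None,
                    predictor_verdicts=verdicts,
                    clinical_significance=info.get("CLNSIG") or None,
                )
    return Cohort(
        patients=patients,
        records=list(merged.values()),
        annotations=annotations,
        skipped_records=skipped,
    )


def write_cohort_vcf(
    cohort: Cohort, path: str | Path, header_meta: Mapping[str, str] | None = None
) -> None:
    """Write a cohort in the minimal VCF dialect (deterministic ordering).

    Genomic coordinates are synthetic placeholders on a fictitious contig;
    variant identity is transcript-level throughout.
    """
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=chrSim>"]
    for key, value in (header_meta or {}).items():
        lines.append(f"##{key}={value}")
    for info_id, desc in (
        ("GENE", "Gene symbol"),
        ("TX", "Transcript accession"),
        ("HGVSC", "HGVS c./n. change"),
        ("EFFECT", "Molecular consequence"),
        ("RSID", "dbSNP identifier"),
        ("AF_GNOMAD", "gnomAD aggregated allele frequency"),
        ("AF_EXAC", "ExAC allele frequency"),
        ("AF_1KG", "1000 Genomes allele frequency"),
        ("AF_ABRAOM", "ABraOM allele frequency"),
        ("PRED", "Comma list of predictor=verdict"),
        ("CLNSIG", "Clinical significance label"),
        ("PANEL", "Printed gene-panel label"),
    ):
        lines.append(
            f'##INFO=<ID={info_id},Number=1,Type=String,Description="{desc}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.patients)
    )
    ordered = sorted(
        cohort.records, key=lambda r: (r.gene, r.cdna_change, r.transcript)
    )
    for pos, rec in enumerate(ordered, start=1):
        ann = cohort.annotations[rec.key]
        info = [
            f"GENE={rec.gene}",
            f"TX={rec.transcript}",
            f"HGVSC={rec.cdna_change}",
            f"EFFECT={rec.effect.value}",
        ]
        if rec.rsid:
            info.append(f"RSID={rec.rsid}")
        for info_key, af in (
            ("AF_GNOMAD", ann.af_gnomad),
            ("AF_EXAC", ann.af_exac),
            ("AF_1KG", ann.af_1kg),
            ("AF_ABRAOM", ann.af_abraom),
        ):
            if af is not None:
                info.append(f"{info_key}={af!r}")
        info.append(
            "PRED="
            + ",".join(f"{p}={v.value}" for p, v in ann.predictor_verdicts.items())
        )
        if ann.clinical_significance:
            info.append(f"CLNSIG={ann.clinical_significance}")
        if rec.panel_label:
            info.append(f"PANEL={rec.panel_label}")
        gts = ["0/1" if p in rec.carriers else "0/0" for p in cohort.patients]
        lines.append(
            "\t".join(
                [
                    "chrSim",
                    str(pos),
                    rec.rsid or ".",
                    "A",
                    "T",
                    ".",
                    "PASS",
                    ";".join(info),
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
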