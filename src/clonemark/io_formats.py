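"""External representations: variant tables, SEG files, manifests, reports.

All readers validate strictly and return typed records; downstream modules
never touch files. Coordinates on disk are 1-based inclusive (VCF/MAF
convention); window arithmetic elsewhere is 0-based half-open and converts
here. Chromosome names are normalized to the no-"chr" form internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .contexts import BASES, ContextError, collapse_snv

VARIANT_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "gene",
    "effect",
    "t_depth",
    "t_alt",
    "n_depth",
    "n_alt",
    "context",
]

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]

SAMPLE_ROLES = ("T", "LN", "D", "N")
EFFECTS = ("nonsynonymous", "synonymous", "other")
VARIANT_TYPES = ("SNV", "indel")


class FormatError(ValueError):
    """The file does not match the expected layout (missing columns etc.)."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if not chrom:
        raise ValidationError("empty chromosome name")
    return chrom


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class VariantRecord:
    """One candidate somatic variant in one tumor sample (tumor/normal counts)."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_type: str
    gene: str
    effect: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int
    context: str | None = None  # 3-mer, SNVs only

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(
                f"{self._loc()}: unknown variant_type {self.variant_type!r}"
            )
        if self.effect not in EFFECTS:
            raise ValidationError(f"{self._loc()}: unknown effect {self.effect!r}")
        for name in ("t_depth", "t_alt", "n_depth", "n_alt", "pos"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValidationError(f"{self._loc()}: {name}={v!r} must be a non-negative integer")
        if self.t_alt > self.t_depth:
            raise ValidationError(
                f"{self._loc()}: t_alt={self.t_alt} exceeds t_depth={self.t_depth}"
            )
        if self.n_alt > self.n_depth:
            raise ValidationError(
                f"{self._loc()}: n_alt={self.n_alt} exceeds n_depth={self.n_depth}"
            )
        if self.variant_type == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValidationError(f"{self._loc()}: SNV alleles must be single bases")
            if self.context is not None:
                try:
                    collapse_snv(self.ref, self.alt, self.context)
                except ContextError as exc:
                    raise ValidationError(f"{self._loc()}: {exc}") from exc
        else:
            if any(b not in BASES for b in (self.ref + self.alt).upper()):
                raise ValidationError(f"{self._loc()}: non-DNA indel alleles")

    def _loc(self) -> str:
        return f"{self.patient_id}/{self.sample_id} {self.chrom}:{self.pos}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact identity used for mutation sharing: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SegRecord:
    """One copy-ratio segment, 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: bad interval"
            )


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    role: str  # T | LN | D | N


@dataclass
class CohortManifest:
    """One patient's samples and input files.

    Exactly one matched normal (role N) per patient; at least one T and one D.
    """

    patient_id: str
    samples: list[SampleEntry]
    variant_file: str
    seg_file: str
    interval_months: int | None = None
    pathological_diagnosis: str | None = None

    def __post_init__(self) -> None:
        roles = [s.role for s in self.samples]
        ids = [s.sample_id for s in self.samples]
        for r in roles:
            if r not in SAMPLE_ROLES:
                raise ValidationError(f"{self.patient_id}: unknown role {r!r}")
        if roles.count("N") != 1:
            raise ValidationError(f"{self.patient_id}: exactly one normal sample required")
        if "T" not in roles or "D" not in roles:
            raise ValidationError(f"{self.patient_id}: need at least one T and one D sample")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"{self.patient_id}: duplicate sample_ids")

    def tumor_samples(self) -> list[SampleEntry]:
        return [s for s in self.samples if s.role != "N"]

    def sample_with_role(self, role: str) -> SampleEntry:
        matches = [s for s in self.samples if s.role == role]
        if not matches:
            raise KeyError(f"{self.patient_id}: no sample with role {role}")
        return matches[0]


# ---------------------------------------------------------------------------
# variant IO


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_variants(
    path: str | Path,
    dialect: str = "tsv",
    *,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
    patient_id: str | None = None,
) -> list[VariantRecord]:
    """Read candidate variant calls from a TSV table or a VCF.

    The TSV dialect is header-driven and canonical. The VCF dialect maps the
    per-sample AD (allelic depth) fields of a MuTect-style tumor/normal pair
    and needs ``tumor_sample`` / ``normal_sample`` names (from the manifest).
    Validation failures name the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        if tumor_sample is None or normal_sample is None:
            raise ValueError("VCF dialect requires tumor_sample and normal_sample names")
        return _read_variants_vcf(path, tumor_sample, normal_sample, patient_id or "NA")
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, VARIANT_COLUMNS, path)
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            records.append(
                VariantRecord(
                    patient_id=row.patient_id,
                    sample_id=row.sample_id,
                    chrom=normalize_chrom(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref.upper(),
                    alt=row.alt.upper(),
                    variant_type=row.variant_type,
                    gene=row.gene,
                    effect=row.effect,
                    t_depth=int(row.t_depth),
                    t_alt=int(row.t_alt),
                    n_depth=int(row.n_depth),
                    n_alt=int(row.n_alt),
                    context=(row.context or None),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return records


def _read_variants_vcf(
    path: Path, tumor_sample: str, normal_sample: str, patient_id: str
) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise FormatError(f"{path}: sample {name!r} not present in VCF header")
    ti, ni = samples.index(tumor_sample), samples.index(normal_sample)
    records: list[VariantRecord] = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record {v.CHROM}:{v.POS} lacks per-sample AD")
        for alt in v.ALT:
            is_snv = len(v.REF) == 1 and len(alt) == 1
            t_ref, t_alt = int(ad[ti][0]), int(max(ad[ti][1], 0))
            n_ref, n_alt = int(ad[ni][0]), int(max(ad[ni][1], 0))
            records.append(
                VariantRecord(
                    patient_id=patient_id,
                    sample_id=tumor_sample,
                    chrom=normalize_chrom(v.CHROM),
                    pos=int(v.POS),
                    ref=v.REF.upper(),
                    alt=alt.upper(),
                    variant_type="SNV" if is_snv else "indel",
                    gene=str(v.INFO.get("GENE", "NA")),
                    effect=str(v.INFO.get("EFFECT", "other")),
                    t_depth=t_ref + t_alt,
                    t_alt=t_alt,
                    n_depth=n_ref + n_alt,
                    n_alt=n_alt,
                    context=(v.INFO.get("CTX") if is_snv else None),
                )
            )
    return records


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        d["context"] = d["context"] or ""
        rows.append(d)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG IO

_SEG_ALIASES = {
    "id": "sample_id",
    "sample": "sample_id",
    "chromosome": "chrom",
    "loc.start": "start",
    "loc.end": "end",
    "seg.mean": "log2_ratio",
    "log2": "log2_ratio",
}


def read_seg(path: str | Path) -> list[SegRecord]:
    """Read a SEG-style TSV, validate, and sort by (sample, chrom, start).

    Overlapping segments within one sample/chromosome are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [_SEG_ALIASES.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns]
    _require_columns(df, SEG_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SegRecord(
                    sample_id=str(row.sample_id),
                    chrom=normalize_chrom(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    log2_ratio=float(row.log2_ratio),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    records.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    prev: SegRecord | None = None
    for s in records:
        if (
            prev is not None
            and s.sample_id == prev.sample_id
            and s.chrom == prev.chrom
            and s.start <= prev.end
        ):
            raise ValidationError(
                f"{path}: overlapping segments in {s.sample_id} {s.chrom}: "
                f"{prev.start}-{prev.end} and {s.start}-{s.end}"
            )
        prev = s
    return records


def write_seg(records: Iterable[SegRecord], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest IO


def read_manifest(path: str | Path) -> list[CohortManifest]:
    """Read a cohort manifest (YAML or JSON list of patients)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return []
    if not isinstance(data, list):
        raise FormatError(f"{path}: manifest must be a list of patients")
    manifests = []
    for entry in data:
        try:
            manifests.append(
                CohortManifest(
                    patient_id=entry["patient_id"],
                    samples=[SampleEntry(s["sample_id"], s["role"]) for s in entry["samples"]],
                    variant_file=entry["variant_file"],
                    seg_file=entry["seg_file"],
                    interval_months=entry.get("interval_months"),
                    pathological_diagnosis=entry.get("pathological_diagnosis"),
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: manifest entry missing field {exc}") from exc
    return manifests


def write_manifest(manifests: Iterable[CohortManifest], path: str | Path) -> None:
    data = []
    for m in manifests:
        entry = {
            "patient_id": m.patient_id,
            "samples": [{"sample_id": s.sample_id, "role": s.role} for s in m.samples],
            "variant_file": m.variant_file,
            "seg_file": m.seg_file,
        }
        if m.interval_months is not None:
            entry["interval_months"] = m.interval_months
        if m.pathological_diagnosis is not None:
            entry["pathological_diagnosis"] = m.pathological_diagnosis
        data.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# report IO

REPORT_SCHEMA_VERSION = "1.0"


def write_report(verdicts: Sequence[Mapping], path: str | Path, *, extra: Mapping | None = None) -> dict:
    """Serialize per-patient verdicts (plus per-stage evidence) as JSON."""
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_patients": len(verdicts),
        "verdicts": list(verdicts),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return doc


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if "schema_version" not in doc or "verdicts" not in doc:
        raise FormatError(f"{path}: not a clonemark report")
    return doc
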