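"""Per-patient LM-vs-SPT verdict and the cohort pipeline.

The primary rule mirrors the clonal dichotomy: any trunk or T&D-shared
branch mutation makes the esophageal and lung tumors clonally related
(verdict "metastasis"); none makes them independent ("primary"). Copy-number
similarity, spectra concordance and signature-1 dominance are recorded as
advisory evidence and never override the mutation-sharing rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import SignatureCatalog, synthetic_signature_catalog
from .clonality import (
    MutationPartition,
    compare_baf,
    partition_mutations,
    td_shared_count,
)
from .filtering import FilterConfig, filter_callset
from .io_formats import (
    CohortManifest,
    SegRecord,
    VariantRecord,
    read_seg,
    read_variants,
    write_report,
)
from .scna import TOY_GENOME, cosine_similarity, scna_analysis
from .signatures import fit_signatures, spectra_chisq, spectrum


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_shared: int = 1  # trunk + T&D branch mutations needed for "metastasis"
    baf_tau: float = 0.05
    n_perm: int = 500
    alpha: float = 0.05
    seed: int = 0
    genome: dict[str, int] = field(default_factory=lambda: dict(TOY_GENOME))
    weight_floor: float = 0.06
    cosine_related_threshold: float = 0.8
    cosine_independent_threshold: float = 0.6
    spectra_alpha: float = 0.05


@dataclass
class ClonalityVerdict:
    patient_id: str
    verdict: str  # "metastasis" | "primary"
    td_shared_count: int
    trunk_fraction: float
    td_cosine: float | None
    tln_cosine: float | None
    spectra_p: float | None
    concordant_evidence: dict[str, bool] = field(default_factory=dict)

    @property
    def n_concordant(self) -> int:
        return sum(self.concordant_evidence.values())

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def classify_patient(
    partition: MutationPartition,
    t_sample: str,
    d_sample: str,
    config: PipelineConfig | None = None,
    *,
    td_cosine: float | None = None,
    tln_cosine: float | None = None,
    spectra_p: float | None = None,
    sig1_dominant_t: bool | None = None,
    sig1_dominant_d: bool | None = None,
    patient_id: str = "NA",
) -> ClonalityVerdict:
    """Apply the verdict rule to one patient's stage outputs."""
    if partition is None:
        raise ValueError("classify_patient requires a mutation partition")
    cfg = config or PipelineConfig()
    shared = td_shared_count(partition, t_sample, d_sample)
    verdict = "metastasis" if shared >= cfg.min_shared else "primary"
    related = verdict == "metastasis"
    evidence: dict[str, bool] = {}
    if td_cosine is not None:
        evidence["scna_cosine_high"] = td_cosine >= cfg.cosine_related_threshold
        evidence["scna_cosine_low"] = td_cosine <= cfg.cosine_independent_threshold
        evidence["scna_concordant"] = (
            evidence["scna_cosine_high"] if related else evidence["scna_cosine_low"]
        )
    if spectra_p is not None:
        evidence["spectra_not_different"] = spectra_p >= cfg.spectra_alpha
        evidence["spectra_concordant"] = (
            evidence["spectra_not_different"] if related else not evidence["spectra_not_different"]
        )
    if sig1_dominant_t is not None and sig1_dominant_d is not None:
        evidence["signature1_dominant_both"] = bool(sig1_dominant_t and sig1_dominant_d)
    return ClonalityVerdict(
        patient_id=patient_id,
        verdict=verdict,
        td_shared_count=shared,
        trunk_fraction=partition.trunk_fraction,
        td_cosine=td_cosine,
        tln_cosine=tln_cosine,
        spectra_p=spectra_p,
        concordant_evidence=evidence,
    )


# ---------------------------------------------------------------------------
# cohort pipeline


@dataclass
class PatientResult:
    verdict: ClonalityVerdict
    partition: MutationPartition
    exposures: dict[str, dict[str, float]]
    baf_statistic: float | None
    n_input: int
    n_passing: int


@dataclass
class CohortReport:
    verdicts: list[ClonalityVerdict]
    failures: dict[str, str]
    results: dict[str, PatientResult]

    def verdict_of(self, patient_id: str) -> str:
        for v in self.verdicts:
            if v.patient_id == patient_id:
                return v.verdict
        raise KeyError(patient_id)

    def write(self, path: str | Path) -> dict:
        return write_report(
            [v.as_dict() for v in self.verdicts],
            path,
            extra={"failed_patients": self.failures},
        )


def analyze_patient(
    manifest: CohortManifest,
    variants: Sequence[VariantRecord],
    levels,
    config: PipelineConfig,
    catalog: SignatureCatalog,
) -> PatientResult:
    """Run filter -> clonality -> spectra/signatures -> verdict for one
    patient, given the cohort-level focal-SCNA level table (region x sample;
    recurrent regions are a cohort quantity, so they are called once in
    :func:`run_pipeline` and shared by every patient)."""
    tumor_ids = [s.sample_id for s in manifest.tumor_samples()]
    t_id = manifest.sample_with_role("T").sample_id
    d_id = manifest.sample_with_role("D").sample_id
    by_sample: dict[str, list[VariantRecord]] = {sid: [] for sid in tumor_ids}
    for v in variants:
        if v.sample_id in by_sample:
            by_sample[v.sample_id].append(v)

    filtered: dict[str, list[VariantRecord]] = {}
    n_pass = 0
    for sid in tumor_ids:
        callset = filter_callset(by_sample[sid], config.filter)
        filtered[sid] = callset.passing
        n_pass += len(callset.passing)
    nonsyn = {
        sid: [r for r in recs if r.effect == "nonsynonymous"]
        for sid, recs in filtered.items()
    }
    if all(len(v) == 0 for v in nonsyn.values()):
        raise ValueError(f"{manifest.patient_id}: no variants survive filtering")
    partition = partition_mutations({sid: nonsyn[sid] for sid in tumor_ids})

    baf = compare_baf(filtered[t_id], filtered[d_id], tau=config.baf_tau)

    spec_t = spectrum([r for r in filtered[t_id] if r.variant_type == "SNV"])
    spec_d = spectrum([r for r in filtered[d_id] if r.variant_type == "SNV"])
    _, _, spectra_p = spectra_chisq(spec_t, spec_d)
    exp_t = fit_signatures(spec_t, catalog, config.weight_floor)
    exp_d = fit_signatures(spec_d, catalog, config.weight_floor)

    ln_ids = [s.sample_id for s in manifest.samples if s.role == "LN"]
    have = lambda sid: levels is not None and len(levels) and sid in levels.columns
    td_cos = cosine_similarity(levels, t_id, d_id) if have(t_id) and have(d_id) else None
    tln_cos = (
        cosine_similarity(levels, t_id, ln_ids[0])
        if ln_ids and have(t_id) and have(ln_ids[0])
        else None
    )

    verdict = classify_patient(
        partition,
        t_id,
        d_id,
        config,
        td_cosine=td_cos,
        tln_cosine=tln_cos,
        spectra_p=spectra_p,
        sig1_dominant_t=exp_t.dominant() == "S1",
        sig1_dominant_d=exp_d.dominant() == "S1",
        patient_id=manifest.patient_id,
    )
    return PatientResult(
        verdict=verdict,
        partition=partition,
        exposures={t_id: exp_t.weights, d_id: exp_d.weights},
        baf_statistic=baf.shared_cluster_statistic,
        n_input=len(variants),
        n_passing=n_pass,
    )


def run_pipeline(
    manifests: Sequence[CohortManifest],
    config: PipelineConfig | None = None,
    *,
    data_dir: str | Path | None = None,
    data: Mapping[str, tuple[Sequence[VariantRecord], Sequence[SegRecord]]] | None = None,
    catalog: SignatureCatalog | None = None,
) -> CohortReport:
    """Run the whole cohort. Inputs come either from ``data`` (in-memory,
    keyed by patient_id) or from files next to ``data_dir``. Focal SCNA
    regions are recurrent across the cohort, so the permutation analysis
    runs once over all samples; the level table is then shared by every
    patient. A stage error marks that patient failed and the cohort
    continues.
    """
    cfg = config or PipelineConfig()
    catalog = catalog or synthetic_signature_catalog()
    loaded: dict[str, tuple[Sequence[VariantRecord], Sequence[SegRecord]]] = {}
    failures: dict[str, str] = {}
    for manifest in manifests:
        try:
            if data is not None:
                loaded[manifest.patient_id] = data[manifest.patient_id]
            else:
                base = Path(data_dir) if data_dir is not None else Path(".")
                loaded[manifest.patient_id] = (
                    read_variants(base / manifest.variant_file, "tsv"),
                    read_seg(base / manifest.seg_file),
                )
        except Exception as exc:  # noqa: BLE001 - per-patient fault isolation
            failures[manifest.patient_id] = str(exc)

    levels = None
    all_segs = [s for variants, segs in loaded.values() for s in segs]
    if all_segs:
        _, _, levels = scna_analysis(
            all_segs, cfg.genome, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha
        )
    verdicts: list[ClonalityVerdict] = []
    results: dict[str, PatientResult] = {}
    for manifest in manifests:
        if manifest.patient_id not in loaded:
            continue
        variants, _ = loaded[manifest.patient_id]
        try:
            res = analyze_patient(manifest, variants, levels, cfg, catalog)
        except Exception as exc:  # noqa: BLE001 - per-patient fault isolation
            failures[manifest.patient_id] = str(exc)
            continue
        results[manifest.patient_id] = res
        verdicts.append(res.verdict)
    return CohortReport(verdicts=verdicts, failures=failures, results=results)
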