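"""Synthetic multi-tumor cohorts with known clonal ground truth.

Each patient carries an esophageal tumor (T), a regional lymph-node
metastasis (LN), a distant lung tumor (D) and a matched normal (N). Under
the *related* regime (lung metastasis) all three tumors descend from one
clone: a trunk mutation set, drawn as a controllable fraction of the
patient's mutation burden, is present in every tumor, a T&LN branch and
per-sample private sets make up the rest, and every mutation's trinucleotide
context is sampled from an ageing-dominated signature mixture. Under the
*independent* regime (second primary) T and LN still share a clone but D's
mutation set is disjoint and drawn from a tobacco-flavoured, C>A-dominated
mixture. Read counts are binomial at Poisson depths; copy-number profiles
share a controllable fraction of focal aberrations between clonally related
tumors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import SignatureCatalog, synthetic_signature_catalog
from .contexts import BASES, CONTEXT_96_LABELS, class_of, reverse_complement
from .io_formats import (
    CohortManifest,
    SampleEntry,
    SegRecord,
    VariantRecord,
    write_manifest,
    write_seg,
    write_variants,
)
from .scna import TOY_GENOME, WINDOW_SIZE

RELATED = "related"
INDEPENDENT = "independent"

LEVEL_LOG2_MIDPOINT = {2: 1.2, 1: 0.5, 0: 0.0, -1: -0.7, -2: -1.6}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Cohort-generator knobs; defaults emulate the study conditions.

    ``mutations_per_tumor_range`` bounds the per-patient distinct somatic
    mutation budget (each tumor carries its trunk share plus privates, so
    per-tumor counts land inside the range); ``trunk_fraction_range``
    controls |trunk| / |union|, spanning the 12%-70% band seen in clonally
    related tumor trios.
    """

    n_patients: int = 20
    fraction_spt: float = 0.5
    trunk_fraction_range: tuple[float, float] = (0.12, 0.705)
    mutations_per_tumor_range: tuple[int, int] = (30, 120)
    mean_depth: int = 150
    tumor_purity: float = 0.8
    signature_mix_related: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.8, "S5": 0.2}
    )
    signature_mix_independent_D: dict[str, float] = field(
        default_factory=lambda: {"S4": 0.5, "S29": 0.3, "S1": 0.2}
    )
    n_focal_regions: int = 100
    shared_scna_fraction_related: float = 0.8
    shared_scna_fraction_independent: float = 0.05
    seed: int = 7
    # secondary knobs
    genome: dict[str, int] = field(default_factory=lambda: dict(TOY_GENOME))
    p_aberrant: float = 0.4  # per-tumor P(level != 0), i.e. P(0)=0.6
    scna_noise_sd: float = 0.1
    region_length: int = 20_000
    background_segment_length: int = 50_000
    ccf_trunk: float = 1.0
    ccf_branch: float = 0.8
    ccf_private: float = 0.6
    branch_share_of_nontrunk: float = 0.25
    indel_fraction: float = 0.05
    effect_probs: tuple[float, float, float] = (0.75, 0.20, 0.05)  # nonsyn, syn, other
    normal_alt_rate: float = 0.001

    def validate(self) -> None:
        lo_f, hi_f = self.trunk_fraction_range
        lo_m, hi_m = self.mutations_per_tumor_range
        if not (0 <= lo_f <= hi_f <= 1):
            raise ConfigError("trunk_fraction_range must be ordered within [0, 1]")
        if not (1 <= lo_m <= hi_m):
            raise ConfigError("mutations_per_tumor_range must be ordered and >= 1")
        if round(hi_f * lo_m) < 1 and hi_f > 0:
            raise ConfigError(
                "mutation budget lower bound too small for the requested trunk fraction"
            )
        if not (0 < self.tumor_purity <= 1):
            raise ConfigError("tumor_purity must be in (0, 1]")
        if not (0 <= self.fraction_spt <= 1):
            raise ConfigError("fraction_spt must be in [0, 1]")
        for mix in (self.signature_mix_related, self.signature_mix_independent_D):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6 or any(w < 0 for w in mix.values()):
                raise ConfigError(f"signature mixture must be nonnegative and sum to 1, got {total}")
        for frac in (
            self.shared_scna_fraction_related,
            self.shared_scna_fraction_independent,
            self.p_aberrant,
        ):
            if not (0 <= frac <= 1):
                raise ConfigError("SCNA fractions must be in [0, 1]")
        # independent-regime category probabilities must stay nonnegative
        q, s_rel, s_ind = self.p_aberrant, self.shared_scna_fraction_related, self.shared_scna_fraction_independent
        c0 = 2 * q * s_ind / (1 + s_ind)
        pa = q * (1 - s_rel) / (1 + s_rel)
        if q - c0 - pa < -1e-9:
            raise ConfigError("incompatible shared-SCNA fractions")


@dataclass
class PatientTruth:
    patient_id: str
    label: str  # related | independent
    trunk_fraction_drawn: float
    variant_origin: dict[str, str]  # "chrom:pos:ref:alt" -> origin set name
    region_category: list[str]  # per focal region
    region_levels: dict[str, list[int]]  # sample -> true level per region


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def labels(self) -> dict[str, str]:
        return {pid: t.label for pid, t in self.patients.items()}

    def to_json(self, path: str | Path) -> None:
        doc = {pid: asdict(t) for pid, t in self.patients.items()}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def focal_region_layout(
    genome: Mapping[str, int], n_regions: int, region_length: int = 20_000
) -> list[tuple[str, int, int]]:
    """Deterministic, well-separated focal-region coordinates (0-based
    half-open, aligned to 1-kb windows)."""
    chroms = sorted(genome, key=lambda c: (len(c), c))
    per = [n_regions // len(chroms)] * len(chroms)
    for i in range(n_regions % len(chroms)):
        per[i] += 1
    regions = []
    for chrom, n in zip(chroms, per):
        L = genome[chrom]
        for r in range(n):
            center = int((r + 1) * L / (n + 1))
            start = (center // WINDOW_SIZE) * WINDOW_SIZE
            end = min(start + region_length, L)
            regions.append((chrom, start, end))
    return regions


# ---------------------------------------------------------------------------
# mutation generation


def _sample_snv_alleles(rng: np.random.Generator, p96: np.ndarray):
    idx = int(rng.choice(96, p=p96))
    label = CONTEXT_96_LABELS[idx]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    context = five + ref + three
    if rng.random() < 0.5:  # report on the purine strand
        ref, alt, context = reverse_complement(ref), reverse_complement(alt), reverse_complement(context)
    return ref, alt, context


def _sample_indel_alleles(rng: np.random.Generator):
    base = BASES[int(rng.integers(4))]
    ins = BASES[int(rng.integers(4))]
    if rng.random() < 0.5:
        return base, base + ins, None  # insertion
    return base + ins, base, None  # deletion


def _gene_for(chrom: str, pos: int) -> str:
    return f"G{chrom}_{pos // 100_000:03d}"


def _scna_categories(config: SimulationConfig, truth_label: str) -> dict[str, float]:
    """Per-region category probabilities.

    Categories name the tumor set carrying a common aberration; per-tumor
    marginal aberration probability is ``p_aberrant`` in both regimes, and
    the fraction of a clonal pair's aberrant-region union that is shared
    equals the configured sharing fraction.
    """
    q = config.p_aberrant
    s_rel = config.shared_scna_fraction_related
    if truth_label == RELATED:
        c = 3 * q * s_rel / (1 + 2 * s_rel)
        p = q * (1 - s_rel) / (1 + 2 * s_rel)
        cats = {"clonal_all": c, "private_T": p, "private_LN": p, "private_D": p}
    else:
        s_ind = config.shared_scna_fraction_independent
        c0 = 2 * q * s_ind / (1 + s_ind)
        pa = q * (1 - s_rel) / (1 + s_rel)
        c1 = q - c0 - pa
        pd_ = q - c0
        cats = {
            "clonal_all": c0,
            "clonal_TLN": max(c1, 0.0),
            "private_T": pa,
            "private_LN": pa,
            "private_D": pd_,
        }
    cats["neutral"] = 1.0 - sum(cats.values())
    return cats


_CATEGORY_SAMPLES = {
    "clonal_all": ("T", "LN", "D"),
    "clonal_TLN": ("T", "LN"),
    "private_T": ("T",),
    "private_LN": ("LN",),
    "private_D": ("D",),
    "neutral": (),
}


def simulate_patient(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str,
    truth_label: str,
    catalog: SignatureCatalog | None = None,
) -> tuple[list[VariantRecord], list[SegRecord], PatientTruth]:
    """Generate one patient's variant rows, copy-ratio segments and truth."""
    config.validate()
    if truth_label not in (RELATED, INDEPENDENT):
        raise ConfigError(f"unknown truth label {truth_label!r}")
    catalog = catalog or synthetic_signature_catalog()
    p_related = catalog.mixture(config.signature_mix_related)
    p_indep = catalog.mixture(config.signature_mix_independent_D)
    roles = {"T": f"{patient_id}_T", "LN": f"{patient_id}_LN", "D": f"{patient_id}_D"}

    lo_m, hi_m = config.mutations_per_tumor_range
    f = float(rng.uniform(*config.trunk_fraction_range))

    # origin -> (present roles, context mixture)
    plan: list[tuple[str, tuple[str, ...], np.ndarray, int]] = []
    if truth_label == RELATED:
        U = int(rng.integers(lo_m, hi_m + 1))
        k = int(round(f * U))
        rest = U - k
        b = rng.binomial(rest, config.branch_share_of_nontrunk)
        priv = rng.multinomial(rest - b, [1 / 3] * 3)
        plan = [
            ("trunk", ("T", "LN", "D"), p_related, k),
            ("branch_TLN", ("T", "LN"), p_related, int(b)),
            ("private_T", ("T",), p_related, int(priv[0])),
            ("private_LN", ("LN",), p_related, int(priv[1])),
            ("private_D", ("D",), p_related, int(priv[2])),
        ]
    else:
        U_a = int(rng.integers(lo_m, hi_m + 1))
        k = int(round(f * U_a))
        priv = rng.multinomial(U_a - k, [0.5, 0.5])
        n_d = int(rng.integers(lo_m, hi_m + 1))
        plan = [
            ("shared_TLN", ("T", "LN"), p_related, k),
            ("private_T", ("T",), p_related, int(priv[0])),
            ("private_LN", ("LN",), p_related, int(priv[1])),
            ("private_D", ("D",), p_indep, n_d),
        ]

    ccf_of = {
        "trunk": config.ccf_trunk,
        "branch_TLN": config.ccf_branch,
        "shared_TLN": config.ccf_branch,
        "private_T": config.ccf_private,
        "private_LN": config.ccf_private,
        "private_D": config.ccf_private,
    }
    chroms = sorted(config.genome, key=lambda c: (len(c), c))
    chrom_p = np.array([config.genome[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    used_pos: set[tuple[str, int]] = set()
    variants: list[VariantRecord] = []
    origin_of: dict[str, str] = {}
    for origin, present, p96, count in plan:
        for _ in range(count):
            while True:
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
                pos = int(rng.integers(2, config.genome[chrom]))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    break
            if rng.random() < config.indel_fraction:
                ref, alt, context = _sample_indel_alleles(rng)
                vtype = "indel"
            else:
                ref, alt, context = _sample_snv_alleles(rng, p96)
                vtype = "SNV"
            effect = ("nonsynonymous", "synonymous", "other")[
                int(rng.choice(3, p=config.effect_probs))
            ]
            gene = _gene_for(chrom, pos)
            origin_of[f"{chrom}:{pos}:{ref}:{alt}"] = origin
            p_alt = config.tumor_purity * ccf_of[origin] / 2.0
            for role in present:
                t_depth = int(rng.poisson(config.mean_depth))
                t_alt = int(rng.binomial(t_depth, p_alt)) if t_depth else 0
                n_depth = int(rng.poisson(config.mean_depth))
                n_alt = int(rng.binomial(n_depth, config.normal_alt_rate)) if n_depth else 0
                variants.append(
                    VariantRecord(
                        patient_id=patient_id,
                        sample_id=roles[role],
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        variant_type=vtype,
                        gene=gene,
                        effect=effect,
                        t_depth=t_depth,
                        t_alt=t_alt,
                        n_depth=n_depth,
                        n_alt=n_alt,
                        context=context,
                    )
                )

    # ------------------------------------------------------------------ SCNA
    regions = focal_region_layout(config.genome, config.n_focal_regions, config.region_length)
    cats = _scna_categories(config, truth_label)
    names = list(cats.keys())
    probs = np.array([cats[n] for n in names])
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    region_category: list[str] = []
    region_levels: dict[str, list[int]] = {roles[r]: [] for r in ("T", "LN", "D")}
    for _ in regions:
        cat = names[int(rng.choice(len(names), p=probs))]
        region_category.append(cat)
        level = int(rng.choice([-2, -1, 1, 2])) if cat != "neutral" else 0
        carriers = _CATEGORY_SAMPLES[cat]
        for role in ("T", "LN", "D"):
            region_levels[roles[role]].append(level if role in carriers else 0)

    segs: list[SegRecord] = []
    for role in ("T", "LN", "D"):
        sid = roles[role]
        levels = region_levels[sid]
        for chrom in chroms:
            L = config.genome[chrom]
            marks = sorted(
                (start, end, levels[i])
                for i, (c, start, end) in enumerate(regions)
                if c == chrom
            )
            cursor = 0
            intervals: list[tuple[int, int, int | None]] = []
            for start, end, level in marks:
                pos0 = cursor
                while pos0 < start:
                    nxt = min(pos0 + config.background_segment_length, start)
                    intervals.append((pos0, nxt, None))
                    pos0 = nxt
                intervals.append((start, end, level))
                cursor = end
            while cursor < L:
                nxt = min(cursor + config.background_segment_length, L)
                intervals.append((cursor, nxt, None))
                cursor = nxt
            for s0, e0, level in intervals:
                if level is not None and level != 0:
                    # focal aberration: midpoint log2 perturbed by sigma=0.1
                    # (amplitude variation from purity/subclonality)
                    log2 = LEVEL_LOG2_MIDPOINT[level] + float(
                        rng.normal(0.0, config.scna_noise_sd)
                    )
                else:
                    # neutral background: a segment mean averages marker-level
                    # noise over its ~1-kb windows, so its sd shrinks by
                    # sqrt(n_windows)
                    n_markers = max((e0 - s0) / WINDOW_SIZE, 1.0)
                    log2 = float(
                        rng.normal(0.0, config.scna_noise_sd / np.sqrt(n_markers))
                    )
                segs.append(
                    SegRecord(sample_id=sid, chrom=chrom, start=s0 + 1, end=e0, log2_ratio=round(log2, 4))
                )

    truth = PatientTruth(
        patient_id=patient_id,
        label=truth_label,
        trunk_fraction_drawn=f,
        variant_origin=origin_of,
        region_category=region_category,
        region_levels=region_levels,
    )
    return variants, segs, truth


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    catalog: SignatureCatalog | None = None,
) -> tuple[list[CohortManifest], dict[str, tuple[list[VariantRecord], list[SegRecord]]], GroundTruth]:
    """Generate a cohort; optionally write manifest + per-patient files.

    The related/independent split is deterministic (round(fraction_spt * n)
    independent patients, assigned to the tail of the cohort), and the whole
    run is reproducible from ``config.seed``.
    """
    config.validate()
    catalog = catalog or synthetic_signature_catalog()
    n = config.n_patients
    n_ind = int(round(config.fraction_spt * n))
    labels = [RELATED] * (n - n_ind) + [INDEPENDENT] * n_ind
    root = np.random.default_rng(config.seed)
    streams = root.spawn(n) if n else []
    manifests: list[CohortManifest] = []
    data: dict[str, tuple[list[VariantRecord], list[SegRecord]]] = {}
    truth = GroundTruth()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, (label, rng) in enumerate(zip(labels, streams), start=1):
        pid = f"P{i:02d}"
        variants, segs, ptruth = simulate_patient(config, rng, pid, label, catalog)
        data[pid] = (variants, segs)
        truth.patients[pid] = ptruth
        variant_file = f"{pid}.variants.tsv"
        seg_file = f"{pid}.seg.tsv"
        manifests.append(
            CohortManifest(
                patient_id=pid,
                samples=[
                    SampleEntry(f"{pid}_T", "T"),
                    SampleEntry(f"{pid}_LN", "LN"),
                    SampleEntry(f"{pid}_D", "D"),
                    SampleEntry(f"{pid}_N", "N"),
                ],
                variant_file=variant_file,
                seg_file=seg_file,
            )
        )
        if out_path is not None:
            write_variants(variants, out_path / variant_file)
            write_seg(segs, out_path / seg_file)
    if out_path is not None:
        write_manifest(manifests, out_path / "manifest.yaml")
        truth.to_json(out_path / "truth.json")
        with open(out_path / "genome.tsv", "w") as fh:
            for chrom in sorted(config.genome, key=lambda c: (len(c), c)):
                fh.write(f"{chrom}\t{config.genome[chrom]}\n")
    return manifests, data, truth
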