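"""Mutation spectra, chi-square contrasts, signature refitting, and
recurrence-based candidate gene listing.

The 6-class spectrum is the strand-collapsed substitution distribution;
the 96-context profile adds flanking bases. A tumor's 96-profile is refit
as a nonnegative mixture over the reference catalog by nonnegative least
squares with iterative removal of weights below a floor (6% by default,
the convention of the widely used refitting tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import SignatureCatalog
from .contexts import (
    CLASS_OF_CONTEXT,
    CONTEXT_96_LABELS,
    CONTEXT_INDEX,
    SUBSTITUTION_CLASSES,
    collapse_snv,
)
from .io_formats import VariantRecord


@dataclass
class SpectrumProfile:
    """Counts over the 6 substitution classes and the 96 contexts."""

    counts96: np.ndarray  # int, length 96

    def __post_init__(self) -> None:
        self.counts96 = np.asarray(self.counts96)
        if self.counts96.shape != (96,) or (self.counts96 < 0).any():
            raise ValueError("counts96 must be a nonnegative length-96 vector")

    @property
    def counts6(self) -> np.ndarray:
        return np.array(
            [self.counts96[i * 16 : (i + 1) * 16].sum() for i in range(6)]
        )

    @property
    def total(self) -> int:
        return int(self.counts96.sum())

    def by_class(self) -> dict[str, int]:
        return dict(zip(SUBSTITUTION_CLASSES, (int(c) for c in self.counts6)))


def spectrum(callset: Iterable[VariantRecord]) -> SpectrumProfile:
    """Strand-collapsed spectrum of a sample's SNVs (indels are rejected)."""
    counts = np.zeros(96, dtype=int)
    for r in callset:
        if r.variant_type != "SNV":
            raise ValueError(f"spectrum needs SNVs; got {r.variant_type} at {r.chrom}:{r.pos}")
        if r.context is None:
            raise ValueError(f"SNV at {r.chrom}:{r.pos} lacks a trinucleotide context")
        label = collapse_snv(r.ref, r.alt, r.context)
        counts[CONTEXT_INDEX[label]] += 1
    return SpectrumProfile(counts)


def spectra_chisq(
    profile_a: SpectrumProfile | np.ndarray,
    profile_b: SpectrumProfile | np.ndarray,
    pool_expected_below: float = 1.0,
) -> tuple[float, int, float]:
    """Pearson chi-square contrast of two 6-class spectra.

    Classes with zero counts in both profiles are dropped; classes whose
    expected count falls below ``pool_expected_below`` are pooled into a
    single "other" class so the asymptotic test stays valid on small
    callsets. Returns (statistic, df, two-sided p).
    """
    a = profile_a.counts6 if isinstance(profile_a, SpectrumProfile) else np.asarray(profile_a)
    b = profile_b.counts6 if isinstance(profile_b, SpectrumProfile) else np.asarray(profile_b)
    a = a.astype(float)
    b = b.astype(float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("cannot contrast a spectrum with zero total mutations")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    table = np.vstack([a, b])
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    small = expected.min(axis=0) < pool_expected_below
    if small.any() and (~small).any():
        pooled = np.column_stack([table[:, ~small], table[:, small].sum(axis=1)])
        table = pooled
    if table.shape[1] < 2:
        return 0.0, 0, 1.0
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


@dataclass
class SignatureExposure:
    """Nonnegative signature weights; `weights` sum to at most 1."""

    weights: dict[str, float]
    residual: float

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        if sum(self.weights.values()) > 1 + 1e-6:
            raise ValueError("weights must sum to at most 1")

    def dominant(self) -> str | None:
        if not self.weights:
            return None
        return max(self.weights, key=lambda s: (self.weights[s], s))


def fit_signatures(
    profile: SpectrumProfile | np.ndarray,
    catalog: SignatureCatalog,
    weight_floor: float = 0.06,
) -> SignatureExposure:
    """Refit a 96-context profile against the catalog.

    The normalized profile m (sum 1) is decomposed as min ||m - S w||_2 with
    w >= 0 (NNLS); weights contributing less than ``weight_floor`` of the
    total are zeroed and the remaining signatures are refit, iterating until
    the support is stable. Because the catalog columns are unit-sum, the
    fitted weights already sum to (approximately) the explained fraction of
    the profile; they are scaled down only if the sum exceeds 1.
    """
    m = profile.counts96 if isinstance(profile, SpectrumProfile) else np.asarray(profile, dtype=float)
    m = m.astype(float)
    if m.sum() <= 0:
        raise ValueError("empty mutation profile")
    m = m / m.sum()
    S = catalog.values
    names = catalog.signatures
    support = np.arange(S.shape[1])
    w = None
    for _ in range(S.shape[1]):
        w, _rnorm = optimize.nnls(S[:, support], m)
        total = w.sum()
        if total == 0:
            break
        keep = w / total >= weight_floor
        if keep.all():
            break
        support = support[keep]
        if support.size == 0:
            w = np.array([])
            break
    weights = {}
    if w is not None and w.size:
        total = w.sum()
        scale = 1.0 / total if total > 1.0 else 1.0
        fitted = S[:, support] @ w
        residual = float(np.linalg.norm(m - fitted))
        for idx, wi in zip(support, w):
            if wi > 0:
                weights[names[idx]] = float(wi * scale)
    else:
        residual = float(np.linalg.norm(m))
    return SignatureExposure(weights=weights, residual=residual)


@dataclass(frozen=True)
class SmgCandidate:
    gene: str
    n_patients_mutated: int
    samples: tuple[str, ...]


def smg_candidates(
    cohort_callsets: Mapping[str, Iterable[VariantRecord]],
    min_patients: int = 2,
    cosmic_genes: set[str] | None = None,
) -> list[SmgCandidate]:
    """Recurrence-based candidate gene list: genes non-silently mutated in at
    least ``min_patients`` patients, optionally restricted to a known cancer
    gene set. This is a recurrence listing, not a background-model SMG test.
    """
    gene_patients: dict[str, set[str]] = {}
    gene_samples: dict[str, set[str]] = {}
    for patient, records in cohort_callsets.items():
        for r in records:
            if r.effect == "synonymous":
                continue
            gene_patients.setdefault(r.gene, set()).add(patient)
            gene_samples.setdefault(r.gene, set()).add(r.sample_id)
    out = []
    for gene, patients in gene_patients.items():
        if len(patients) < min_patients:
            continue
        if cosmic_genes is not None and gene not in cosmic_genes:
            continue
        out.append(
            SmgCandidate(
                gene=gene,
                n_patients_mutated=len(patients),
                samples=tuple(sorted(gene_samples[gene])),
            )
        )
    out.sort(key=lambda c: (-c.n_patients_mutated, c.gene))
    return out
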