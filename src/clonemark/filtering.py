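"""High-confidence somatic variant filtering for tumor/normal pairs.

SNVs pass when tumor and normal coverage are both at least 10, the tumor
variant-allele fraction exceeds 10%, the normal VAF is below 2%, and at
least 3 tumor reads carry the variant allele. The VAF bounds are strict
inequalities (a tumor VAF of exactly 0.10 fails); the depth and alt-read
bounds are inclusive. Indels additionally require absence from a supplied
germline set and zero alt reads in the normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import VariantRecord


class ZeroDepthError(ValueError):
    """VAF is undefined at zero depth."""


@dataclass(frozen=True)
class FilterConfig:
    min_depth_tumor: int = 10
    min_depth_normal: int = 10
    min_vaf_tumor: float = 0.10
    max_vaf_normal: float = 0.02
    min_alt_reads: int = 3

    def __post_init__(self) -> None:
        if min(self.min_depth_tumor, self.min_depth_normal, self.min_alt_reads) < 0:
            raise ValueError("depth/alt-read thresholds must be >= 0")
        if self.min_vaf_tumor < 0 or self.max_vaf_normal < 0:
            raise ValueError("VAF thresholds must be >= 0")
        if self.min_vaf_tumor <= self.max_vaf_normal:
            raise ValueError("min_vaf_tumor must exceed max_vaf_normal")


@dataclass
class FilteredCallset:
    passing: list[VariantRecord] = field(default_factory=list)
    rejected: list[tuple[VariantRecord, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.passing) + len(self.rejected)


def vaf(record: VariantRecord, compartment: str = "tumor") -> float:
    """Variant-allele fraction (alt reads / depth) in one compartment."""
    if compartment == "tumor":
        alt, depth = record.t_alt, record.t_depth
    elif compartment == "normal":
        alt, depth = record.n_alt, record.n_depth
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    if depth == 0:
        raise ZeroDepthError(f"{compartment} depth is 0 at {record.chrom}:{record.pos}")
    return alt / depth


def _snv_reason(r: VariantRecord, cfg: FilterConfig) -> str | None:
    # reasons are checked in a fixed order; the first failure is reported
    if r.t_depth == 0 or r.n_depth == 0:
        return "zero_depth"
    if r.t_depth < cfg.min_depth_tumor:
        return "tumor_depth"
    if r.n_depth < cfg.min_depth_normal:
        return "normal_depth"
    if not vaf(r, "tumor") > cfg.min_vaf_tumor:
        return "tumor_vaf"
    if not vaf(r, "normal") < cfg.max_vaf_normal:
        return "normal_vaf"
    if r.t_alt < cfg.min_alt_reads:
        return "alt_reads"
    return None


def filter_snvs(records: Iterable[VariantRecord], config: FilterConfig | None = None) -> FilteredCallset:
    """Apply the high-confidence SNV criteria record by record."""
    cfg = config or FilterConfig()
    out = FilteredCallset()
    for r in records:
        if r.variant_type != "SNV":
            raise TypeError(f"filter_snvs given a {r.variant_type} record at {r.chrom}:{r.pos}")
        reason = _snv_reason(r, cfg)
        if reason is None:
            out.passing.append(r)
        else:
            out.rejected.append((r, reason))
    return out


def filter_indels(
    records: Iterable[VariantRecord],
    config: FilterConfig | None = None,
    germline_set: frozenset | set | None = None,
) -> FilteredCallset:
    """High-confidence somatic indels.

    Germline filtering is represented by the caller-supplied key set (the
    upstream realignment/germline steps are out of scope); beyond that an
    indel needs tumor and normal coverage >= 10 and zero normal alt reads, a
    conservative stand-in for somatic status since no tumor-VAF rule is
    defined for indels.
    """
    cfg = config or FilterConfig()
    germline = germline_set or frozenset()
    out = FilteredCallset()
    for r in records:
        if r.variant_type != "indel":
            raise TypeError(f"filter_indels given a {r.variant_type} record at {r.chrom}:{r.pos}")
        if r.key in germline:
            out.rejected.append((r, "germline"))
        elif r.t_depth < cfg.min_depth_tumor:
            out.rejected.append((r, "tumor_depth"))
        elif r.n_depth < cfg.min_depth_normal:
            out.rejected.append((r, "normal_depth"))
        elif r.n_alt != 0:
            out.rejected.append((r, "normal_alt"))
        else:
            out.passing.append(r)
    return out


def filter_callset(
    records: Sequence[VariantRecord],
    config: FilterConfig | None = None,
    germline_set: frozenset | set | None = None,
) -> FilteredCallset:
    """Route SNVs and indels to their respective criteria; preserve totals."""
    snvs = [r for r in records if r.variant_type == "SNV"]
    indels = [r for r in records if r.variant_type == "indel"]
    a = filter_snvs(snvs, config)
    b = filter_indels(indels, config, germline_set)
    return FilteredCallset(passing=a.passing + b.passing, rejected=a.rejected + b.rejected)
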