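"""GISTIC-like focal somatic copy-number analysis on 1-kb windows.

Copy-ratio segments are rasterized onto fixed 1-kb windows; per-window
G-scores fold the frequency and amplitude of gain (or loss) across samples
into one average of positive (negative) log2 parts. Significance comes from
a permutation null that circularly shifts each sample's window vector within
each chromosome, preserving the marginal distribution and spatial
autocorrelation. Runs of significant windows become focal regions; each
region gets a 5-tier copy-aberration level per sample from its mean log2
ratio (thresholds 0.9 / 0.1 / -0.1 / -1.3), and pairs of samples are
compared by the cosine of their numeric level vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SegRecord, ValidationError

WINDOW_SIZE = 1000

#: toy genome used by the simulator and tests; real sizes come from a TSV
TOY_GENOME: dict[str, int] = {"1": 10_000_000, "2": 10_000_000, "3": 10_000_000}

LEVEL_NAMES = {2: "high_amp", 1: "low_amp", 0: "neutral", -1: "low_del", -2: "high_del"}


def read_genome(path) -> dict[str, int]:
    """Chromosome sizes from a two-column TSV (chrom, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {str(c).removeprefix("chr"): int(l) for c, l in zip(df.chrom, df.length)}


@dataclass
class WindowGrid:
    """Per-sample log2 copy-ratio vectors over fixed windows.

    Windows are 0-based half-open and concatenated across chromosomes in
    ``chrom_order``; windows with no segment coverage are NaN (missing),
    never zero.
    """

    genome: dict[str, int]
    window_size: int
    chrom_order: tuple[str, ...]
    chrom_slices: dict[str, slice]
    samples: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_windows), NaN = missing

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def window_coords(self, idx: int) -> tuple[str, int, int]:
        """(chrom, start, end) of window ``idx``, 0-based half-open."""
        for chrom in self.chrom_order:
            sl = self.chrom_slices[chrom]
            if sl.start <= idx < sl.stop:
                w = idx - sl.start
                start = w * self.window_size
                return chrom, start, min(start + self.window_size, self.genome[chrom])
        raise IndexError(idx)


def _grid_layout(genome: Mapping[str, int], window_size: int):
    chrom_order = tuple(sorted(genome, key=lambda c: (len(c), c)))
    slices = {}
    offset = 0
    for chrom in chrom_order:
        n = -(-genome[chrom] // window_size)
        slices[chrom] = slice(offset, offset + n)
        offset += n
    return chrom_order, slices, offset


def segments_to_windows(
    segs: Sequence[SegRecord],
    genome: Mapping[str, int],
    window_size: int = WINDOW_SIZE,
) -> WindowGrid:
    """Rasterize segments: each window takes the length-weighted mean of the
    segments overlapping it; uncovered windows are missing (NaN)."""
    genome = dict(genome)
    chrom_order, slices, n_windows = _grid_layout(genome, window_size)
    samples = tuple(sorted({s.sample_id for s in segs}))
    weighted = np.zeros((len(samples), n_windows))
    covered = np.zeros((len(samples), n_windows))
    sidx = {s: i for i, s in enumerate(samples)}
    for seg in segs:
        if seg.chrom not in genome:
            raise ValidationError(f"segment on unknown chromosome {seg.chrom!r}")
        L = genome[seg.chrom]
        start0, end0 = seg.start - 1, seg.end  # to 0-based half-open
        if end0 > L:
            raise ValidationError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} beyond chromosome length {L}"
            )
        base = slices[seg.chrom].start
        i = sidx[seg.sample_id]
        first, last = start0 // window_size, (end0 - 1) // window_size
        for w in range(first, last + 1):
            ws, we = w * window_size, (w + 1) * window_size
            ov = min(end0, we) - max(start0, ws)
            weighted[i, base + w] += ov * seg.log2_ratio
            covered[i, base + w] += ov
    with np.errstate(invalid="ignore"):
        values = np.where(covered > 0, weighted / np.maximum(covered, 1), np.nan)
    return WindowGrid(
        genome=genome,
        window_size=window_size,
        chrom_order=chrom_order,
        chrom_slices=slices,
        samples=samples,
        values=values,
    )


def g_scores(grid: WindowGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (g_amp, g_del): average positive / negative log2 parts.

    Missing samples are excluded from the per-window denominator; windows
    missing in every sample score 0.
    """
    v = grid.values
    mask = ~np.isnan(v)
    n_eff = mask.sum(axis=0)
    pos = np.where(mask, np.maximum(v, 0.0), 0.0).sum(axis=0)
    neg = np.where(mask, np.maximum(-v, 0.0), 0.0).sum(axis=0)
    denom = np.maximum(n_eff, 1)
    return pos / denom, neg / denom


@dataclass
class PermutationResult:
    n_perm: int
    p_amp: np.ndarray
    p_del: np.ndarray
    g_amp: np.ndarray
    g_del: np.ndarray
    alpha: float = 0.05

    @property
    def sig_amp(self) -> np.ndarray:
        return self.p_amp < self.alpha

    @property
    def sig_del(self) -> np.ndarray:
        return self.p_del < self.alpha


def permutation_null(
    grid: WindowGrid,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> PermutationResult:
    """Permutation null for per-window G-scores.

    Each permutation independently circularly shifts every sample's window
    vector (and its missingness mask) by a uniform offset within each
    chromosome; per-window p-values are (1 + #{null G >= observed G}) /
    (1 + n_perm), evaluated at that window, separately for amplification
    and deletion.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = grid.values
    n_samples, n_windows = v.shape
    mask = ~np.isnan(v)
    pos = np.where(mask, np.maximum(v, 0.0), 0.0)
    neg = np.where(mask, np.maximum(-v, 0.0), 0.0)
    obs_amp, obs_del = g_scores(grid)

    chrom_slices = [grid.chrom_slices[c] for c in grid.chrom_order]
    exceed_amp = np.zeros(n_windows, dtype=np.int64)
    exceed_del = np.zeros(n_windows, dtype=np.int64)
    null_pos = np.empty(n_windows)
    null_neg = np.empty(n_windows)
    null_n = np.empty(n_windows)
    complete = bool(mask.all())  # no missing data: denominators are constant
    for _ in range(n_perm):
        null_pos[:] = 0.0
        null_neg[:] = 0.0
        null_n[:] = float(n_samples) if complete else 0.0
        for i in range(n_samples):
            for sl in chrom_slices:
                width = sl.stop - sl.start
                off = int(rng.integers(width))
                null_pos[sl] += np.roll(pos[i, sl], off)
                null_neg[sl] += np.roll(neg[i, sl], off)
                if not complete:
                    null_n[sl] += np.roll(mask[i, sl], off)
        denom = np.maximum(null_n, 1)
        exceed_amp += (null_pos / denom) >= obs_amp
        exceed_del += (null_neg / denom) >= obs_del
    p_amp = (1 + exceed_amp) / (1 + n_perm)
    p_del = (1 + exceed_del) / (1 + n_perm)
    return PermutationResult(
        n_perm=n_perm, p_amp=p_amp, p_del=p_del, g_amp=obs_amp, g_del=obs_del, alpha=alpha
    )


@dataclass(frozen=True)
class FocalRegion:
    """A run of significant windows in one direction.

    Coordinates are 0-based half-open on the window grid's genome;
    ``windows`` is the slice into the concatenated window axis.
    """

    chrom: str
    start: int
    end: int
    direction: str  # "amp" | "del"
    g_score: float
    p_value: float
    windows: tuple[int, int]  # [first, last+1) global window indices
    peak: tuple[int, int]  # peak window sub-run, same indexing
    is_peak: bool = True


def _runs(flags: np.ndarray, lo: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((lo + start, lo + i))
            start = None
    if start is not None:
        runs.append((lo + start, lo + len(flags)))
    return runs


def call_regions(perm: PermutationResult, grid: WindowGrid) -> list[FocalRegion]:
    """Maximal runs of contiguous significant windows become focal regions.

    Within each region the window of maximal G-score, extended contiguously
    while G stays >= 95% of that maximum, forms the peak.
    """
    regions: list[FocalRegion] = []
    for direction, sig, g, p in (
        ("amp", perm.sig_amp, perm.g_amp, perm.p_amp),
        ("del", perm.sig_del, perm.g_del, perm.p_del),
    ):
        for chrom in grid.chrom_order:
            sl = grid.chrom_slices[chrom]
            for lo, hi in _runs(sig[sl], sl.start):
                gseg = g[lo:hi]
                apex = int(np.argmax(gseg))
                thresh = 0.95 * gseg[apex]
                p0 = apex
                while p0 > 0 and gseg[p0 - 1] >= thresh:
                    p0 -= 1
                p1 = apex
                while p1 < len(gseg) - 1 and gseg[p1 + 1] >= thresh:
                    p1 += 1
                start = (lo - sl.start) * grid.window_size
                end = min((hi - sl.start) * grid.window_size, grid.genome[chrom])
                regions.append(
                    FocalRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        direction=direction,
                        g_score=float(gseg[apex]),
                        p_value=float(p[lo:hi].min()),
                        windows=(lo, hi),
                        peak=(lo + p0, lo + p1 + 1),
                    )
                )
    return regions


def classify_level(mean_log2: float) -> int:
    """5-tier copy-aberration level from a region's mean log2 ratio.

    Boundary values (0.9, -1.3, +/-0.1) fall in the less extreme tier.
    """
    m = mean_log2
    if np.isnan(m):
        raise ValueError("cannot classify a missing mean log2 ratio")
    if m > 0.9:
        return 2
    if m > 0.1:
        return 1
    if m >= -0.1:
        return 0
    if m >= -1.3:
        return -1
    return -2


def classify_levels(regions: Sequence[FocalRegion], grid: WindowGrid) -> pd.DataFrame:
    """Region x sample numeric levels (NaN where all windows are missing)."""
    rows = []
    index = []
    for r in regions:
        lo, hi = r.windows
        sub = grid.values[:, lo:hi]
        cnt = (~np.isnan(sub)).sum(axis=1)
        sums = np.nansum(sub, axis=1)
        means = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
        rows.append(
            [classify_level(m) if not np.isnan(m) else np.nan for m in means]
        )
        index.append(f"{r.direction}:{r.chrom}:{r.start}-{r.end}")
    return pd.DataFrame(rows, index=index, columns=list(grid.samples), dtype=float)


def cosine_similarity(levels: pd.DataFrame, sample_a: str, sample_b: str) -> float:
    """Cosine of two samples' level vectors over regions non-missing in both.

    Returns 0.0 when either restricted vector is all-zero (no aberrations to
    compare); raises when no region is observed in both samples.
    """
    a = levels[sample_a].to_numpy(dtype=float)
    b = levels[sample_b].to_numpy(dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    if not keep.any():
        raise ValueError(f"no focal region observed in both {sample_a} and {sample_b}")
    a, b = a[keep], b[keep]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def scna_analysis(
    segs: Sequence[SegRecord],
    genome: Mapping[str, int],
    n_perm: int = 500,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    window_size: int = WINDOW_SIZE,
) -> tuple[WindowGrid, list[FocalRegion], pd.DataFrame]:
    """Convenience pipeline: windows -> permutation -> regions -> levels."""
    grid = segments_to_windows(segs, genome, window_size)
    perm = permutation_null(grid, n_perm=n_perm, seed=seed, alpha=alpha)
    regions = call_regions(perm, grid)
    levels = classify_levels(regions, grid)
    return grid, regions, levels
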