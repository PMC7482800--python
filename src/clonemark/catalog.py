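"""Reference mutational-signature catalogs (96 contexts x K signatures).

A catalog column is a probability distribution over the 96 trinucleotide
context classes; tumor profiles are modeled as nonnegative mixtures of the
columns. `read_signature_catalog` loads a COSMIC-v2-style TSV; because that
matrix cannot be redistributed here, `synthetic_signature_catalog` builds a
deterministic synthetic stand-in with the same shape and the qualitative
features the rest of the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import CONTEXT_96_LABELS, SUBSTITUTION_CLASSES
from .io_formats import FormatError, ValidationError


@dataclass(frozen=True)
class SignatureCatalog:
    """96 x K nonnegative matrix; every column sums to one."""

    matrix: pd.DataFrame  # index = CONTEXT_96_LABELS, columns = signature names

    def __post_init__(self) -> None:
        m = self.matrix
        if list(m.index) != list(CONTEXT_96_LABELS):
            raise ValidationError("catalog rows must be the 96 context labels in order")
        if (m.values < 0).any():
            raise ValidationError("catalog entries must be nonnegative")
        sums = m.values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("catalog columns must sum to 1")

    @property
    def signatures(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def mixture(self, weights: dict[str, float]) -> np.ndarray:
        """Probability vector over the 96 contexts for a signature mixture."""
        total = sum(weights.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        p = np.zeros(96)
        for sig, w in weights.items():
            if sig not in self.matrix.columns:
                raise KeyError(f"unknown signature {sig!r}")
            if w < 0:
                raise ValueError("mixture weights must be nonnegative")
            p += w * self.matrix[sig].to_numpy()
        return p / p.sum()


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Load a 96-row signature matrix TSV (first column = context labels).

    Columns within 1e-3 of unit sum are renormalized; anything further off
    is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"{path}: expected 96 context rows, found {df.shape[0]}")
    if set(df.index) != set(CONTEXT_96_LABELS):
        raise FormatError(f"{path}: context labels do not match the conventional 96")
    df = df.loc[list(CONTEXT_96_LABELS)]
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError(f"{path}: negative catalog entries")
    sums = vals.sum(axis=0)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        names = [c for c, b in zip(df.columns, bad) if b]
        raise ValidationError(f"{path}: columns not summing to 1: {names}")
    df = df / sums
    return SignatureCatalog(df)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    catalog.matrix.to_csv(path, sep="\t", index_label="context")


# class-level profiles for the named signatures the cohort generator uses;
# remaining signatures get seeded Dirichlet class profiles
_NAMED_CLASS_PROFILES = {
    # age-associated, CpG-deamination C>T dominated
    "S1": {"C>A": 0.03, "C>G": 0.03, "C>T": 0.78, "T>A": 0.04, "T>C": 0.08, "T>G": 0.04},
    # tobacco smoking, C>A dominated
    "S4": {"C>A": 0.62, "C>G": 0.07, "C>T": 0.14, "T>A": 0.07, "T>C": 0.07, "T>G": 0.03},
    # flat, clock-like
    "S5": {"C>A": 0.14, "C>G": 0.10, "C>T": 0.28, "T>A": 0.12, "T>C": 0.26, "T>G": 0.10},
    # tobacco chewing, C>A dominated
    "S29": {"C>A": 0.70, "C>G": 0.09, "C>T": 0.10, "T>A": 0.05, "T>C": 0.04, "T>G": 0.02},
}


def synthetic_signature_catalog(n_signatures: int = 30, seed: int = 20_200_96) -> SignatureCatalog:
    """Deterministic synthetic stand-in for a 30-signature reference catalog.

    This is NOT the published COSMIC v2 matrix (which cannot be shipped
    here); it is a synthetic catalog with the same 96 x 30 shape whose named
    columns reproduce the qualitative structure the analyses need: S1 is
    C>T-dominated with CpG (NCG-context) enrichment, S4 and S29 are
    C>A-dominated, S5 is flat. The remaining columns are random but fixed
    distributions, mutually distinct so that nonnegative refitting is
    well-posed.
    """
    if n_signatures < 1:
        raise ValueError("n_signatures must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"S{i}" for i in range(1, n_signatures + 1)]
    cols = {}
    for name in names:
        if name in _NAMED_CLASS_PROFILES:
            class_w = _NAMED_CLASS_PROFILES[name]
        else:
            w = rng.dirichlet(np.full(6, 0.8))
            class_w = dict(zip(SUBSTITUTION_CLASSES, w))
        col = np.zeros(96)
        for ci, cls in enumerate(SUBSTITUTION_CLASSES):
            within = rng.dirichlet(np.full(16, 0.6))
            if name == "S1" and cls == "C>T":
                # CpG enrichment: boost N[C>T]G contexts (3' base G)
                boost = np.array([4.0 if k % 4 == 2 else 1.0 for k in range(16)])
                within = within * boost
                within = within / within.sum()
            col[ci * 16 : (ci + 1) * 16] = class_w[cls] * within
        cols[name] = col / col.sum()
    df = pd.DataFrame(cols, index=list(CONTEXT_96_LABELS))
    return SignatureCatalog(df)
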