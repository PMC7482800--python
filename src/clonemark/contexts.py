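"""Trinucleotide-context machinery for mutation spectra.

Single-base substitutions are strand-collapsed to the pyrimidine frame, giving
six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) and, with one flanking
base on each side, 96 context classes in the conventional order
A[C>A]A ... T[T>G]T.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_context_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTION_CLASSES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


CONTEXT_96_LABELS: tuple[str, ...] = _build_context_labels()
CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_96_LABELS)}

#: index of the substitution class for each of the 96 contexts
CLASS_OF_CONTEXT: tuple[int, ...] = tuple(i // 16 for i in range(96))


class ContextError(ValueError):
    """Raised when an SNV's trinucleotide context is malformed."""


def collapse_snv(ref: str, alt: str, context: str) -> str:
    """Return the pyrimidine-frame 96-context label for one SNV.

    ``context`` is the 3-mer centered on the reference base on the reported
    strand; purine-reference SNVs are reverse-complemented so that e.g. a
    G>A call is counted as C>T.
    """
    ref = ref.upper()
    alt = alt.upper()
    context = context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ContextError(f"not an SNV: ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ContextError(f"ref and alt are identical: {ref!r}")
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ContextError(f"invalid trinucleotide context {context!r}")
    if context[1] != ref:
        raise ContextError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if ref in PURINES:
        ref, alt, context = (
            reverse_complement(ref),
            reverse_complement(alt),
            reverse_complement(context),
        )
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CONTEXT_INDEX:  # pragma: no cover - defensive
        raise ContextError(f"unmapped context {label!r}")
    return label


def class_of(label: str) -> str:
    """Substitution class (e.g. ``"C>T"``) of a 96-context label."""
    return label[2:5]
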