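"""The 96-channel trinucleotide substitution convention.

Single-base substitutions are collapsed onto the pyrimidine strand, giving six
substitution types (C>A, C>G, C>T, T>A, T>C, T>G), each observed in one of 16
flanking-base contexts: 6 x 16 = 96 channels.  Channel order follows the COSMIC
convention: substitution type varies slowest, then the 5' base, then the 3' base,
so the catalog begins A[C>A]A, A[C>A]C, ... and ends T[T>G]T.

This module is the single source of truth for channel ordering; every spectrum,
signature catalog and simulator indexes through it.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

N_CHANNELS = len(CHANNELS)  # 96

_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_name(ref: str, alt: str, context: str) -> str:
    """Map an SNV (ref, alt, trinucleotide context) to its channel label.

    ``context`` is the reference 3-mer centered on the mutated base.  Purine
    reference alleles are reverse-complemented onto the pyrimidine strand.
    Raises ``ValueError`` if the context middle base disagrees with ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    if context[1] != ref:
        raise ValueError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref not in PYRIMIDINES:
        ref, alt = complement(ref), complement(alt)
        context = reverse_complement(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_index(ref: str, alt: str, context: str) -> int:
    """0-based channel index for an SNV; see :func:`channel_name`."""
    return _CHANNEL_INDEX[channel_name(ref, alt, context)]
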