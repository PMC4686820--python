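"""Pyrimidine-collapsed trinucleotide channel encoding.

Every somatic SNV is mapped to one of 96 channels: the six substitution
types written with a pyrimidine reference base (C>A, C>G, C>T, T>A, T>C,
T>G) crossed with the 16 combinations of 5' and 3' flanking bases.
Mutations whose reference base is a purine are reverse-complemented first,
so the encoding is invariant under strand flips of (ref, alt, flanks).

Channel order is the COSMIC-style lexicographic one: substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank A,C,G,T, then 3' flank
A,C,G,T.  ``channel = sub_index*16 + flank5_index*4 + flank3_index``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"),
                 ("T", "A"), ("T", "C"), ("T", "G")]
_SUB_INDEX = {pair: i for i, pair in enumerate(SUBSTITUTIONS)}

N_CHANNELS = 96

CHANNEL_LABELS = [
    f"{f5}[{ref}>{alt}]{f3}"
    for (ref, alt) in SUBSTITUTIONS
    for f5 in BASES
    for f3 in BASES
]
CHANNEL_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

# integer-code complement: A(0)<->T(3), C(1)<->G(2)
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)

# substitution-pair lookup on integer codes; -1 marks ref==alt (invalid)
_SUB_CODE = np.full((4, 4), -1, dtype=np.int8)
for (r, a), k in _SUB_INDEX.items():
    _SUB_CODE[BASE_INDEX[r], BASE_INDEX[a]] = k


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def encode_channel(ref: str, alt: str, flank5: str, flank3: str) -> int:
    """Channel index 0-95 of a substitution in its trinucleotide context.

    Purine-reference mutations are reverse-complemented (ref, alt and both
    flanks together) before lookup, so e.g. G>A with context C_T encodes
    identically to C>T with context A_G.

    Raises ``ValueError`` for non-ACGT bases or ref == alt.
    """
    for b in (ref, alt, flank5, flank3):
        if b not in BASE_INDEX:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    sub = _SUB_INDEX[(ref, alt)]
    return sub * 16 + BASE_INDEX[flank5] * 4 + BASE_INDEX[flank3]


def decode_channel(channel: int) -> tuple[str, str, str, str]:
    """Inverse of :func:`encode_channel`: (ref, alt, flank5, flank3)."""
    if not 0 <= channel < N_CHANNELS:
        raise ValueError(f"channel {channel} outside 0-95")
    sub, rem = divmod(channel, 16)
    f5, f3 = divmod(rem, 4)
    ref, alt = SUBSTITUTIONS[sub]
    return ref, alt, BASES[f5], BASES[f3]


def encode_channels_codes(ref: np.ndarray, alt: np.ndarray,
                          flank5: np.ndarray, flank3: np.ndarray) -> np.ndarray:
    """Vectorised channel encoding on integer base codes (A=0,C=1,G=2,T=3).

    Returns int16 channel indices; entries with ref == alt raise.
    """
    ref = np.asarray(ref, dtype=np.int8)
    alt = np.asarray(alt, dtype=np.int8)
    flank5 = np.asarray(flank5, dtype=np.int8)
    flank3 = np.asarray(flank3, dtype=np.int8)
    purine = (ref == 0) | (ref == 2)  # A or G reference: collapse
    r = np.where(purine, _COMP_CODE[ref], ref)
    a = np.where(purine, _COMP_CODE[alt], alt)
    f5 = np.where(purine, _COMP_CODE[flank3], flank5)
    f3 = np.where(purine, _COMP_CODE[flank5], flank3)
    sub = _SUB_CODE[r, a]
    if np.any(sub < 0):
        raise ValueError("ref == alt in vectorised channel encoding")
    return (sub.astype(np.int16) * 16 + f5.astype(np.int16) * 4
            + f3.astype(np.int16))


def context_index_codes(flank5: np.ndarray, center: np.ndarray,
                        flank3: np.ndarray) -> np.ndarray:
    """Strand-collapsed trinucleotide *context* index (0-31) per position.

    The context part of a channel ignores the alternate allele: pyrimidine
    center (C or T) x 16 flank pairs.  Purine centers are collapsed by
    reverse complement, so each genomic position has exactly one context
    index regardless of strand.
    """
    center = np.asarray(center, dtype=np.int8)
    flank5 = np.asarray(flank5, dtype=np.int8)
    flank3 = np.asarray(flank3, dtype=np.int8)
    purine = (center == 0) | (center == 2)
    c = np.where(purine, _COMP_CODE[center], center)
    f5 = np.where(purine, _COMP_CODE[flank3], flank5)
    f3 = np.where(purine, _COMP_CODE[flank5], flank3)
    # c is 1 (C) or 3 (T) after collapse -> 0/1
    return ((c == 3).astype(np.int16) * 16 + f5.astype(np.int16) * 4
            + f3.astype(np.int16))


def channel_context_index(channel: int) -> int:
    """Context index (0-31) of a channel's (flank5, ref, flank3) triple."""
    sub, rem = divmod(int(channel), 16)
    return (1 if sub >= 3 else 0) * 16 + rem


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """ACGT(N) string to int8 codes; non-ACGT bases map to -1."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    raw = np.frombuffer(seq, dtype=np.uint8)
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[raw]


CODES_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
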