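"""Low-level DNA sequence utilities: 2-bit encoding, reverse complement,
collapsed substitution-type notation and triplet-context collapsing.

Bases are encoded A=0, C=1, G=2, T=3 so that the Watson-Crick complement
of code ``b`` is ``3 - b``.  ``N`` (or any non-ACGT symbol) encodes to 255
and is treated as missing by every consumer.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
N_CODE = 255

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.full(256, ord("N"), dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _DECODE[_i] = ord(_b)

#: The six strand-collapsed substitution classes, in the conventional order
#: used for bacterial mutation spectra (two transitions, four transversions).
SIX_TYPES = (
    "C:G>T:A",
    "A:T>G:C",
    "A:T>T:A",
    "G:C>T:A",
    "A:T>C:G",
    "G:C>C:G",
)

# (ref, alt) on the top strand -> collapsed pair notation.  Transitions at
# G:C pairs are written C:G>T:A (the C-strand view); transversions at G:C
# pairs are written from the G strand, matching common usage.
PAIR_NOTATION = {
    ("A", "G"): "A:T>G:C",
    ("T", "C"): "A:T>G:C",
    ("A", "T"): "A:T>T:A",
    ("T", "A"): "A:T>T:A",
    ("A", "C"): "A:T>C:G",
    ("T", "G"): "A:T>C:G",
    ("C", "T"): "C:G>T:A",
    ("G", "A"): "C:G>T:A",
    ("C", "A"): "G:C>T:A",
    ("G", "T"): "G:C>T:A",
    ("C", "G"): "G:C>C:G",
    ("G", "C"): "G:C>C:G",
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGTN string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array; 255 (N) stays 255."""
    out = codes[::-1].copy()
    acgt = out != N_CODE
    out[acgt] = 3 - out[acgt]
    return out


def pair_notation(ref: str, alt: str) -> str:
    """Collapsed pair notation of a substitution seen on either strand."""
    try:
        return PAIR_NOTATION[(ref.upper(), alt.upper())]
    except KeyError:
        raise ValueError(f"not a substitution: {ref!r}->{alt!r}") from None


def collapse_context(triplet: str, focal: str | None = None) -> str:
    """Collapse a top-strand triplet with its reverse complement.

    A context and its reverse complement are the same context; the
    representative is the orientation whose focal (middle) base is C or A,
    so e.g. 5'CGA3' (a G-centred triplet) collapses to 5'TCG3'.
    """
    triplet = triplet.upper()
    if len(triplet) != 3:
        raise ValueError("context must be a triplet")
    mid = focal or triplet[1]
    if mid in ("C", "A"):
        return triplet
    return revcomp(triplet)


def collapsed_context_ints(codes: np.ndarray, circular: bool) -> np.ndarray:
    """Per-site collapsed triplet as an integer in [0, 64); -1 at edges.

    Sites whose top-strand base is C or A use the top-strand triplet
    directly; G or T sites use its reverse complement, so a context and its
    reverse complement share one integer (the focal-C/A representation).
    The integer is base-4 positional: 16*left + 4*focal + right.
    """
    left = np.roll(codes, 1)
    right = np.roll(codes, -1)
    fwd = left.astype(np.int16) * 16 + codes * 4 + right
    rev = (3 - right.astype(np.int16)) * 16 + (3 - codes) * 4 + (3 - left)
    use_rc = (codes == G) | (codes == T)
    out = np.where(use_rc, rev, fwd)
    if not circular:
        out[0] = -1
        out[-1] = -1
    return out


def context_int_to_str(ci: int) -> str:
    """Decode a collapsed-context integer back to its triplet string."""
    return BASES[ci // 16] + BASES[(ci // 4) % 4] + BASES[ci % 4]


def gc_fraction(seq: str) -> float:
    """Observed G+C fraction of a sequence."""
    codes = encode(seq)
    return float(np.isin(codes, (C, G)).mean())
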