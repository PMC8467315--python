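"""Low-level DNA sequence utilities shared across the package.

Sequences are plain Python strings over the uppercase alphabet ``ACGT``
(IUPAC degenerate codes are accepted only where a pattern is expected,
e.g. a PAM such as ``TTTV``).
"""

from __future__ import annotations

import re

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide code -> set of concrete bases it matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_ACGT_RE = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_acgt(seq: str, what: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising ``ValueError`` if it is empty or
    contains characters outside A/C/G/T."""
    s = seq.upper()
    if not s or not _ACGT_RE.match(s):
        raise ValueError(f"{what} must be non-empty and contain only A/C/G/T: {seq!r}")
    return s


def gc_fraction(seq: str) -> float:
    """G+C fraction of a pure-ACGT sequence, in [0, 1]."""
    s = validate_acgt(seq)
    return (s.count("G") + s.count("C")) / len(s)


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC degenerate pattern (e.g. ``TTTV``) into a regex
    character-class string (``TTT[ACG]``)."""
    out = []
    for ch in pattern.upper():
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}") from None
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` exactly (same length)."""
    if len(seq) != len(pattern):
        return False
    return re.fullmatch(iupac_to_regex(pattern), seq.upper()) is not None


def random_seq(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random ACGT sequence of ``length`` with expected G+C fraction ``gc``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorised comparison (uint8 ASCII)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
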