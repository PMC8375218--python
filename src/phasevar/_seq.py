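"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(a: str, b: str) -> bool:
    """True if base b is the Watson-Crick complement of base a."""
    return b == a.translate(_COMPLEMENT)


def revcomp_iupac(motif: str) -> str:
    """Reverse complement of a degenerate IUPAC motif."""
    return motif.upper().translate(IUPAC_COMPLEMENT)[::-1]
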