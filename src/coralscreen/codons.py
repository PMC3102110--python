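"""Standard genetic code tables and frame translation.

The screen is pinned to the standard nuclear code: 61 sense codons, the
three stops TAA/TAG/TGA, no alternative code support. Codon order in
``SENSE_CODONS`` is the lexicographic (T,C,A,G-free) alphabetical order
used consistently by the rate-matrix code, so index i in any 61-vector or
61x61 matrix always refers to ``SENSE_CODONS[i]``.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid of each sense codon, aligned with SENSE_CODONS
AMINO_ACIDS: tuple[str, ...] = tuple(CODON_TABLE[c] for c in SENSE_CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a purine-purine or pyrimidine-pyrimidine change."""
    return (a, b) in _TRANSITIONS


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """Translate one codon: '*' for stops, 'X' for codons containing N."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def translate_frame(seq: str, frame: int) -> str:
    """Translate ``seq`` in one of the six reading frames.

    ``frame`` is +1/+2/+3 for the forward strand or -1/-2/-3 for the
    reverse complement; the magnitude gives the 1-based offset of the
    first codon. Trailing partial codons are dropped, stops are rendered
    '*', and codons containing N are rendered 'X'.
    """
    if abs(frame) not in (1, 2, 3):
        raise ValueError(f"frame must be in +-1..3, got {frame}")
    s = seq.upper()
    if frame < 0:
        s = reverse_complement(s)
    s = s[abs(frame) - 1 :]
    n = len(s) - len(s) % 3
    return "".join(translate_codon(s[i : i + 3]) for i in range(0, n, 3))


def split_codons(cds: str) -> list[str]:
    """Split an in-frame CDS into codons; length must be divisible by 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
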