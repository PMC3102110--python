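"""Global protein alignment and back-translation to codon alignments.

The two validated ORF proteins are aligned globally (Needleman-Wunsch
with affine gaps, BLOSUM62, ClustalW-like default penalties) and the
alignment is threaded back onto the nucleotide ORFs, one codon per
residue column — the Pal2Nal route. Codons containing N are masked to
gaps in both rows so downstream estimation sees only unambiguous
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import split_codons, translate_codon
from .io_core import AlignmentConfig

GAP = "---"


@dataclass
class CodonAlignment:
    """Gap-synchronized codon strings for two ORFs."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows must have equal length")

    @property
    def n_sites(self) -> int:
        """Number of ungapped codon columns."""
        return sum(
            1 for ca, cb in zip(self.codons_a, self.codons_b) if ca != GAP and cb != GAP
        )

    def ungapped(self, row: int) -> str:
        codons = self.codons_a if row == 0 else self.codons_b
        return "".join(c for c in codons if c != GAP)


def align_proteins_global(
    p1: str, p2: str, cfg: AlignmentConfig | None = None
) -> tuple[str, str, float]:
    """Optimal global alignment of two stop-free proteins.

    Affine gap cost open + k*extend (defaults 10 + 0.1k, a ClustalW-like
    emulation), BLOSUM62. Biopython's traceback is deterministic, so
    repeated calls give identical alignments.
    """
    cfg = cfg or AlignmentConfig()
    if not p1 or not p2:
        raise ValueError("align_proteins_global requires non-empty inputs")
    if "*" in p1 or "*" in p2:
        raise ValueError("internal stop codons are not allowed here")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    aln = aligner.align(p1, p2)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def back_translate(gapped_a: str, gapped_b: str, orf_a: str, orf_b: str) -> CodonAlignment:
    """Thread the gapped protein alignment back onto the nucleotide ORFs.

    Each residue column becomes its source codon; protein gaps become
    '---'. Columns where either codon contains N are masked to gaps in
    both rows. A residue that does not translate from its codon raises a
    frame-drift error naming the offending codon.
    """
    if len(gapped_a) != len(gapped_b):
        raise ValueError("gapped proteins must have equal length")
    ca = split_codons(orf_a.upper())
    cb = split_codons(orf_b.upper())
    if len(ca) != len(gapped_a.replace("-", "")) or len(cb) != len(gapped_b.replace("-", "")):
        raise ValueError("ungapped protein length must equal ORF length / 3")
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for col, (ra, rb) in enumerate(zip(gapped_a, gapped_b)):
        if ra == "-":
            cod_a = GAP
        else:
            cod_a = ca[ia]
            if translate_codon(cod_a) != ra:
                raise ValueError(
                    f"frame drift at column {col}: codon {cod_a} does not encode {ra!r}"
                )
            ia += 1
        if rb == "-":
            cod_b = GAP
        else:
            cod_b = cb[ib]
            if translate_codon(cod_b) != rb:
                raise ValueError(
                    f"frame drift at column {col}: codon {cod_b} does not encode {rb!r}"
                )
            ib += 1
        if "N" in cod_a or "N" in cod_b:
            out_a.append(GAP)
            out_b.append(GAP)
        else:
            out_a.append(cod_a)
            out_b.append(cod_b)
    return CodonAlignment(codons_a=out_a, codons_b=out_b)


def trim_terminal_stop(orf: str) -> str:
    """Drop a trailing stop codon, if present, before alignment."""
    codons = split_codons(orf.upper())
    if codons and translate_codon(codons[-1]) == "*":
        codons = codons[:-1]
    return "".join(codons)


def build_codon_alignment(
    orf_a: str, orf_b: str, cfg: AlignmentConfig | None = None
) -> CodonAlignment:
    """Protein-align two ORFs and back-translate (the Pal2Nal route)."""
    orf_a = trim_terminal_stop(orf_a)
    orf_b = trim_terminal_stop(orf_b)
    p1 = "".join(translate_codon(c) for c in split_codons(orf_a))
    p2 = "".join(translate_codon(c) for c in split_codons(orf_b))
    # X (from N codons) aligns like any residue; masking happens on
    # back-translation
    ga, gb, _ = align_proteins_global(p1, p2, cfg)
    return back_translate(ga, gb, orf_a, orf_b)
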