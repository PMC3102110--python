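"""Reciprocal-best-hit ortholog pairing by six-frame translated search.

An internal Smith-Waterman search over all 6x6 reading-frame pairs stands
in for tBLASTx: every query/target transcript is translated in all six
frames and the best local protein alignment (BLOSUM62, affine gaps) is
taken as the hit. Raw scores are converted to bit scores with the
Karlin-Altschul transform, bits = (lambda*raw - ln K) / ln 2, using
configurable constants (defaults are the gapped-BLOSUM62 values). A pair
of transcripts is kept when each is the other's highest-scoring match and
both bit scores clear the cutoff (default 300 bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import translate_frame
from .io_core import PairingConfig, TranscriptRecord

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class TranslatedHit:
    """Best translated local alignment between two transcripts.

    Nucleotide intervals are 1-based inclusive on the original (input
    strand) sequences; for negative frames the interval still refers to
    the forward coordinates and the strand is carried by the frame sign.
    """

    query_id: str
    subject_id: str
    query_frame: int
    subject_frame: int
    raw_score: float
    bit_score: float
    query_nt_interval: tuple[int, int]
    subject_nt_interval: tuple[int, int]
    query_aln: str  # gapped protein alignment, query row
    subject_aln: str
    query_prot_interval: tuple[int, int]  # 1-based on the frame translation
    subject_prot_interval: tuple[int, int]


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _protein_aligner(cfg: PairingConfig, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _matrix(cfg.matrix)
    # gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


def bit_score(raw: float, karlin_lambda: float, karlin_k: float) -> float:
    """Karlin-Altschul normalized score in bits."""
    return (karlin_lambda * raw - math.log(karlin_k)) / math.log(2)


def e_value(raw: float, m: int, n: int, karlin_lambda: float, karlin_k: float) -> float:
    """Karlin-Altschul expected number of chance hits for search space m*n."""
    return m * n * karlin_k * math.exp(-karlin_lambda * raw)


def local_align_protein(
    a: str,
    b: str,
    cfg: PairingConfig | None = None,
) -> tuple[float, tuple[str, str], tuple[tuple[int, int], tuple[int, int]]]:
    """Optimal Smith-Waterman local alignment of two protein strings.

    Returns (score, (gapped_a, gapped_b), ((a_start, a_end), (b_start,
    b_end))) with 1-based inclusive residue intervals. An all-negative
    comparison returns score 0 with empty alignment. Stops ('*') score
    the matrix's stop penalty; residues outside the matrix alphabet are
    an error.
    """
    cfg = cfg or PairingConfig()
    if not a or not b:
        raise ValueError("local_align_protein requires non-empty inputs")
    alphabet = set(str(_matrix(cfg.matrix).alphabet))
    bad = (set(a) | set(b)) - alphabet
    if bad:
        raise ValueError(f"residue(s) {sorted(bad)} outside matrix alphabet")
    aligner = _protein_aligner(cfg)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, ("", ""), ((0, 0), (0, 0))
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    ia = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    ib = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return float(score), (str(aln[0]), str(aln[1])), (ia, ib)


def _prot_to_nt_interval(
    prot_interval: tuple[int, int], frame: int, seq_len: int
) -> tuple[int, int]:
    """Map a 1-based protein interval in a reading frame to 1-based
    inclusive forward-strand nucleotide coordinates."""
    p1, p2 = prot_interval
    off = abs(frame)
    s = off + 3 * (p1 - 1)
    e = off + 3 * p2 - 1
    if frame > 0:
        return s, e
    return seq_len - e + 1, seq_len - s + 1


def six_frame_translations(seq: str) -> dict[int, str]:
    return {f: translate_frame(seq, f) for f in FRAMES}


def translated_best_hit(
    query: TranscriptRecord,
    targets: list[TranscriptRecord],
    cfg: PairingConfig | None = None,
    target_frames: dict[str, dict[int, str]] | None = None,
) -> TranslatedHit | None:
    """Best translated hit of ``query`` against ``targets``.

    Maximizes the raw Smith-Waterman score over all 6x6 frame pairs and
    all targets; ties go to the lexicographically smallest subject ID,
    then to the earliest frame pair in a fixed frame order. Returns None
    when the best bit score is below ``cfg.min_bitscore``.
    """
    cfg = cfg or PairingConfig()
    if not targets:
        raise ValueError("targets must be non-empty")
    aligner = _protein_aligner(cfg)
    qframes = six_frame_translations(query.seq)
    best: tuple[float, str, int, int] | None = None
    for target in sorted(targets, key=lambda t: t.id):
        if target.id == query.id and target.species == query.species:
            continue
        tframes = (
            target_frames[target.id] if target_frames is not None else six_frame_translations(target.seq)
        )
        for qf in FRAMES:
            qp = qframes[qf]
            if not qp:
                continue
            for tf in FRAMES:
                tp = tframes[tf]
                if not tp:
                    continue
                score = aligner.score(qp, tp)
                if best is None or score > best[0]:
                    best = (score, target.id, qf, tf)
    if best is None:
        return None
    raw, subject_id, qf, tf = best
    bits = bit_score(raw, cfg.karlin_lambda, cfg.karlin_k)
    if bits < cfg.min_bitscore:
        return None
    subject = next(t for t in targets if t.id == subject_id)
    tframes = (
        target_frames[subject_id] if target_frames is not None else six_frame_translations(subject.seq)
    )
    _, (qaln, saln), (qi, si) = local_align_protein(qframes[qf], tframes[tf], cfg)
    return TranslatedHit(
        query_id=query.id,
        subject_id=subject_id,
        query_frame=qf,
        subject_frame=tf,
        raw_score=raw,
        bit_score=bits,
        query_nt_interval=_prot_to_nt_interval(qi, qf, len(query.seq)),
        subject_nt_interval=_prot_to_nt_interval(si, tf, len(subject.seq)),
        query_aln=qaln,
        subject_aln=saln,
        query_prot_interval=qi,
        subject_prot_interval=si,
    )


def reciprocal_best_hits(
    set_a: list[TranscriptRecord],
    set_b: list[TranscriptRecord],
    cfg: PairingConfig | None = None,
) -> list[tuple[str, str, TranslatedHit, TranslatedHit]]:
    """Reciprocal best translated hits between two transcript sets.

    A pair (a, b) is kept iff a's best hit over set_b is b, b's best hit
    over set_a is a, and both bit scores are >= cfg.min_bitscore. Output
    is sorted by the ID from set_a.
    """
    cfg = cfg or PairingConfig()
    if not set_a or not set_b:
        raise ValueError("both transcript sets must be non-empty")
    frames_a = {r.id: six_frame_translations(r.seq) for r in set_a}
    frames_b = {r.id: six_frame_translations(r.seq) for r in set_b}
    best_a = {r.id: translated_best_hit(r, set_b, cfg, frames_b) for r in set_a}
    best_b = {r.id: translated_best_hit(r, set_a, cfg, frames_a) for r in set_b}
    pairs = []
    for a_id in sorted(best_a):
        hit_ab = best_a[a_id]
        if hit_ab is None:
            continue
        hit_ba = best_b.get(hit_ab.subject_id)
        if hit_ba is not None and hit_ba.subject_id == a_id:
            pairs.append((a_id, hit_ab.subject_id, hit_ab, hit_ba))
    return pairs
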