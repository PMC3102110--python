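"""Reading-frame validation and annotation of reciprocal best-hit pairs.

After pairing, every putative ortholog pair runs through a cascade of
checks before any rate is estimated: the unknown-strand partner is
oriented against the known-strand member; the longest and second-longest
stop-codon-free protein stretches (LSCFPS, 2nd LSCFPS) are parsed from
the translated hit alignment; for annotated sequences the frame is
accepted only when the LSCFPS's best reference-protein hit is the same
protein as the nucleotide-level hit, while non-annotated (candidate
taxonomically-restricted) pairs are accepted only when both members'
reading frames lie on the forward strand of the oriented sequences;
finally, pairs matching the mitochondrial reference are removed. A pair
is never dropped silently — it is either validated or carries a
rejection code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Align import PairwiseAligner

from .codons import reverse_complement, translate_codon, split_codons
from .io_core import PairingConfig, TranscriptRecord, ValidationConfig
from .pairing import TranslatedHit, bit_score, e_value, local_align_protein


@dataclass
class ValidatedPair:
    """One ortholog pair that survived (or failed) the validation cascade."""

    id_a: str
    id_b: str
    orf_a: str = ""
    orf_b: str = ""
    protein_a: str = ""
    protein_b: str = ""
    annotation: str = ""  # annotated | trg
    annotation_hit: str | None = None
    annotation_evalue: float = float("inf")
    strand_b: str = "+"  # strand of b relative to its input orientation
    frame_a: int = 0
    frame_b: int = 0
    # 1-based inclusive forward-strand coordinates of the ORFs on the
    # (oriented) transcripts
    orf_a_interval: tuple[int, int] = (0, 0)
    orf_b_interval: tuple[int, int] = (0, 0)
    rejection: str | None = None  # unorientable | no ORF | frame mismatch |
    #                               orientation | short ORF | mitochondrial


def _nt_aligner(cfg: ValidationConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = cfg.nt_match
    aligner.mismatch_score = cfg.nt_mismatch
    aligner.open_gap_score = -(cfg.nt_gap_open + cfg.nt_gap_extend)
    aligner.extend_gap_score = -cfg.nt_gap_extend
    return aligner


def nt_local_score(a: str, b: str, cfg: ValidationConfig) -> float:
    return float(_nt_aligner(cfg).score(a, b))


def orient_partner(
    a: TranscriptRecord, b: TranscriptRecord, cfg: ValidationConfig | None = None
) -> tuple[TranscriptRecord, str]:
    """Orient ``b`` onto the forward strand using the known-strand ``a``.

    Returns (oriented record, strand) where strand is '+' if b was kept
    and '-' if it was reverse-complemented. Neither strand reaching
    ``cfg.min_nt_score`` is an orientation failure.
    """
    cfg = cfg or ValidationConfig()
    if not a.orientation_known:
        raise ValueError("orient_partner requires a record with known orientation")
    fwd = nt_local_score(a.seq, b.seq, cfg)
    rc = reverse_complement(b.seq)
    rev = nt_local_score(a.seq, rc, cfg)
    if max(fwd, rev) < cfg.min_nt_score:
        raise OrientationError(f"no strand of {b.id} aligns to {a.id} above threshold")
    if fwd >= rev:
        return replace(b, orientation_known=True), "+"
    return replace(b, seq=rc, orientation_known=True), "-"


class OrientationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# LSCFPS extraction


def stop_free_runs(protein: str) -> list[tuple[str, int, int]]:
    """Maximal '*'-free runs as (run, start, end), 1-based inclusive,
    ranked by length descending; equal lengths rank the 5'-most first."""
    runs: list[tuple[str, int, int]] = []
    start = None
    for i, ch in enumerate(protein + "*"):
        if ch != "*" and start is None:
            start = i
        elif ch == "*" and start is not None:
            runs.append((protein[start:i], start + 1, i))
            start = None
    runs.sort(key=lambda r: (-len(r[0]), r[1]))
    return runs


def extract_lscfps(
    hit: TranslatedHit, side: str = "query"
) -> tuple[tuple[str, int, int], tuple[str, int, int] | None]:
    """Longest and second-longest stop-codon-free protein stretches of
    one side of a translated hit.

    Intervals are 1-based positions in that side's frame translation.
    An alignment that is entirely stops has no ORF.
    """
    if side == "query":
        aligned, interval = hit.query_aln, hit.query_prot_interval
    else:
        aligned, interval = hit.subject_aln, hit.subject_prot_interval
    ungapped = aligned.replace("-", "")
    runs = stop_free_runs(ungapped)
    if not runs:
        raise NoOrfError(f"alignment of {hit.query_id}/{hit.subject_id} is entirely stops")
    offset = interval[0] - 1
    shifted = [(run, s + offset, e + offset) for run, s, e in runs]
    return shifted[0], (shifted[1] if len(shifted) > 1 else None)


class NoOrfError(ValueError):
    pass


def best_frame_hit_by_orf(
    a: TranscriptRecord, b: TranscriptRecord, pcfg: PairingConfig | None = None
) -> TranslatedHit | None:
    """Best frame pair for one transcript pair, judged by ORF content.

    All 6x6 frame alignments are computed and the pair maximizing the
    combined length of the longest stop-free runs (query + subject
    side) wins, with raw score and frame order as deterministic
    tie-breaks. A raw-score maximum can land on an out-of-frame
    alignment of two nearly identical transcripts (stop-stop columns
    still score positively), whereas the longest stop-codon-free
    stretch singles out the true reading frame.
    """
    from .pairing import FRAMES, _prot_to_nt_interval, bit_score, six_frame_translations

    pcfg = pcfg or PairingConfig()
    qframes = six_frame_translations(a.seq)
    sframes = six_frame_translations(b.seq)
    best = None
    best_key = None
    for qf in FRAMES:
        qp = qframes[qf]
        if not qp:
            continue
        for sf in FRAMES:
            sp = sframes[sf]
            if not sp:
                continue
            score, (qaln, saln), (qi, si) = local_align_protein(qp, sp, pcfg)
            if score <= 0:
                continue
            runs_q = stop_free_runs(qaln.replace("-", ""))
            runs_s = stop_free_runs(saln.replace("-", ""))
            orf_len = (len(runs_q[0][0]) if runs_q else 0) + (
                len(runs_s[0][0]) if runs_s else 0
            )
            key = (orf_len, score)
            if best_key is None or key > best_key:
                best_key = key
                best = TranslatedHit(
                    query_id=a.id,
                    subject_id=b.id,
                    query_frame=qf,
                    subject_frame=sf,
                    raw_score=score,
                    bit_score=bit_score(score, pcfg.karlin_lambda, pcfg.karlin_k),
                    query_nt_interval=_prot_to_nt_interval(qi, qf, len(a.seq)),
                    subject_nt_interval=_prot_to_nt_interval(si, sf, len(b.seq)),
                    query_aln=qaln,
                    subject_aln=saln,
                    query_prot_interval=qi,
                    subject_prot_interval=si,
                )
    return best


def orf_from_run(seq: str, frame: int, prot_interval: tuple[int, int]) -> str:
    """In-frame nucleotide substring encoding a protein run located at
    1-based ``prot_interval`` of the given frame translation."""
    s = seq.upper() if frame > 0 else reverse_complement(seq.upper())
    off = abs(frame) - 1
    p1, p2 = prot_interval
    return s[off + 3 * (p1 - 1) : off + 3 * p2]


# ---------------------------------------------------------------------------
# Annotation


def classify_annotation(
    query: str,
    protein_ref: list[TranscriptRecord],
    vcfg: ValidationConfig | None = None,
    pcfg: PairingConfig | None = None,
    is_nucleotide: bool = True,
) -> tuple[str, str | None, float, float]:
    """Best reference-protein hit of a query and its annotation class.

    Nucleotide queries are searched in all six frames (the BLASTx
    analog); protein queries directly (the BLASTp analog). The E-value
    uses the Karlin-Altschul formula E = m*n*K*exp(-lambda*raw) with m
    the total residue count of the reference. Returns (class, hit ID,
    bit score, E-value); class is 'annotated' iff E < cfg.annot_evalue
    (strict), else 'trg'.
    """
    vcfg = vcfg or ValidationConfig()
    pcfg = pcfg or PairingConfig()
    if not protein_ref:
        return "trg", None, 0.0, float("inf")
    if is_nucleotide:
        from .pairing import six_frame_translations

        queries = [p for p in six_frame_translations(query).values() if p]
    else:
        queries = [query]
    m = sum(len(r.seq) for r in protein_ref)
    best_raw, best_id, best_n = 0.0, None, 1
    for ref in sorted(protein_ref, key=lambda r: r.id):
        for q in queries:
            score, _, _ = local_align_protein(q, ref.seq, pcfg)
            if score > best_raw:
                best_raw, best_id, best_n = score, ref.id, len(q)
    if best_id is None:
        return "trg", None, 0.0, float("inf")
    bits = bit_score(best_raw, pcfg.karlin_lambda, pcfg.karlin_k)
    ev = e_value(best_raw, m, best_n, pcfg.karlin_lambda, pcfg.karlin_k)
    cls = "annotated" if ev < vcfg.annot_evalue else "trg"
    return cls, (best_id if cls == "annotated" else None), bits, ev


# ---------------------------------------------------------------------------
# Frame validation


def _protein_of(orf: str) -> str:
    return "".join(translate_codon(c) for c in split_codons(orf))


def validate_frame(
    a: TranscriptRecord,
    b_oriented: TranscriptRecord,
    strand_b: str,
    protein_ref: list[TranscriptRecord],
    vcfg: ValidationConfig | None = None,
    pcfg: PairingConfig | None = None,
) -> ValidatedPair:
    """Run the frame-acceptance rules for one oriented pair.

    The pair's translated hit is recomputed on the oriented sequences
    (so frame signs reflect true strands); member a's nucleotide-level
    annotation decides the rule applied:

    * annotated: accept the LSCFPS (else the 2nd LSCFPS) of member a
      whose best protein-level reference hit is the same reference ID as
      the nucleotide-level hit; member b contributes its corresponding
      stop-free stretch of the alignment.
    * non-annotated: accept only when both members' reading frames lie
      on the forward strand of the oriented sequences.
    """
    vcfg = vcfg or ValidationConfig()
    pcfg = pcfg or PairingConfig()
    out = ValidatedPair(id_a=a.id, id_b=b_oriented.id, strand_b=strand_b)

    pair_cfg = replace(pcfg, min_bitscore=0.0)
    hit = best_frame_hit_by_orf(a, b_oriented, pair_cfg)
    if hit is None:
        out.rejection = "no ORF"
        return out

    annot_cls, annot_hit, _, annot_ev = classify_annotation(
        a.seq, protein_ref, vcfg, pcfg, is_nucleotide=True
    )
    out.annotation = annot_cls
    out.annotation_hit = annot_hit
    out.annotation_evalue = annot_ev

    try:
        runs_a = extract_lscfps(hit, "query")
        runs_b = extract_lscfps(hit, "subject")
    except NoOrfError:
        out.rejection = "no ORF"
        return out

    if annot_cls == "annotated":
        chosen_a = None
        for run in (runs_a[0], runs_a[1]):
            if run is None:
                continue
            _, run_hit, _, run_ev = classify_annotation(
                run[0], protein_ref, vcfg, pcfg, is_nucleotide=False
            )
            if run_hit == annot_hit and run_ev < vcfg.annot_evalue:
                chosen_a = run
                break
        if chosen_a is None:
            out.rejection = "frame mismatch"
            return out
        chosen_b = runs_b[0]
    else:
        if hit.query_frame < 0 or hit.subject_frame < 0:
            out.rejection = "orientation"
            return out
        chosen_a, chosen_b = runs_a[0], runs_b[0]

    orf_a = orf_from_run(a.seq, hit.query_frame, (chosen_a[1], chosen_a[2]))
    orf_b = orf_from_run(b_oriented.seq, hit.subject_frame, (chosen_b[1], chosen_b[2]))
    if len(orf_a) < 3 * vcfg.min_orf_codons or len(orf_b) < 3 * vcfg.min_orf_codons:
        out.rejection = "short ORF"
        return out
    out.orf_a, out.orf_b = orf_a, orf_b
    out.protein_a, out.protein_b = _protein_of(orf_a), _protein_of(orf_b)
    out.frame_a, out.frame_b = hit.query_frame, hit.subject_frame
    from .pairing import _prot_to_nt_interval

    out.orf_a_interval = _prot_to_nt_interval(
        (chosen_a[1], chosen_a[2]), hit.query_frame, len(a.seq)
    )
    out.orf_b_interval = _prot_to_nt_interval(
        (chosen_b[1], chosen_b[2]), hit.subject_frame, len(b_oriented.seq)
    )
    return out


def filter_mitochondrial(
    pairs: list[tuple[ValidatedPair, TranscriptRecord, TranscriptRecord]],
    mito: list[TranscriptRecord],
    cfg: ValidationConfig | None = None,
) -> tuple[list[ValidatedPair], list[str]]:
    """Remove pairs whose full transcript (either member, either strand)
    aligns to the mitochondrial reference at >= cfg.mito_min_bits."""
    cfg = cfg or ValidationConfig()
    kept: list[ValidatedPair] = []
    removed: list[str] = []
    aligner = _nt_aligner(cfg)
    mito_seqs = [m.seq for m in mito]

    def hits_mito(seq: str) -> bool:
        for ms in mito_seqs:
            for s in (seq, reverse_complement(seq)):
                raw = float(aligner.score(s, ms))
                if bit_score(raw, cfg.nt_lambda, cfg.nt_k) >= cfg.mito_min_bits:
                    return True
        return False

    for vp, rec_a, rec_b in pairs:
        if vp.rejection is None and (hits_mito(rec_a.seq) or hits_mito(rec_b.seq)):
            vp.rejection = "mitochondrial"
            removed.append(vp.id_a)
        kept.append(vp)
    return [p for p in kept if p.rejection is None], removed
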