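"""Synthetic two-species transcriptome bundles with known ground truth.

Every stage of the screen is exercised by data generated here: pairs of
coding sequences diverged under the same GY94 M0 codon model the
estimator fits (each descendant evolves t/2 so the total path length is
t), wrapped in EST-like transcripts with random UTRs and an unknown
strand for the second species; a protein reference containing only the
translated ancestors of non-TRG genes (so ~12% of genes are
taxonomically restricted by construction); a mitochondrial decoy
sequence with segments embedded in a chosen subset of transcripts; GO
assignments over a small synthetic ontology with optionally planted
fast-evolving categories; and six expression clusters.

Randomness uses one master seed; per-gene streams are derived with a
counter-based ``numpy.random.SeedSequence([master, stream, index])``
scheme so any subset of genes is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, reverse_complement, translate_codon, split_codons
from .dnds import build_Q, frequencies_from_nt, transition_matrix, N_CODONS
from .io_core import GoOntology, SimulateConfig, TranscriptRecord, write_fasta, write_tsv

CLUSTERS = ("I", "II", "III", "IV", "V", "VI")
# relative cluster sizes follow the published developmental synexpression
# cluster sizes (prawnchip .. planula/polyp/adult)
CLUSTER_WEIGHTS = np.array([567, 110, 159, 77, 43, 205], dtype=float)


@dataclass
class GeneTruth:
    """Ground-truth evolutionary parameters for one simulated gene."""

    gene_id: str
    omega_true: float
    kappa_true: float
    t_true: float  # expected substitutions per codon over the whole path
    n_codons: int
    is_trg: bool
    go_terms: set[str] = field(default_factory=set)
    expr_cluster: str = "I"
    strand_b: str = "+"
    mito_decoy: bool = False

    def __post_init__(self) -> None:
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")
        if self.n_codons < 30:
            raise ValueError("n_codons must be >= 30")


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), int(index)]))


def _gene_index(gene_id: str) -> int:
    """Stable per-gene counter for the seeding scheme."""
    import zlib

    return zlib.crc32(gene_id.encode()) & 0x7FFFFFFF


def default_codon_frequencies() -> np.ndarray:
    """F3x4 frequencies from nucleotide frequencies (A,C,G,T) =
    (0.3, 0.2, 0.2, 0.3) at all three positions, stops removed."""
    nt = np.array([[0.3, 0.2, 0.2, 0.3]] * 3)
    return frequencies_from_nt(nt)


def sample_gene_params(
    n_genes: int,
    seed: int,
    cfg: SimulateConfig | None = None,
) -> list[GeneTruth]:
    """Draw per-gene evolutionary parameters from the default mixture.

    omega is a two-component lognormal mixture (88% low, median ~0.23;
    12% high, median ~0.50, a minority of which exceed 1); by default
    the high component coincides with the TRG label so lineage-specific
    genes are genuinely faster, mirroring the screen's headline
    contrast. t is gamma-distributed around 0.12 substitutions per
    codon; expression clusters are assigned independently of omega.
    """
    cfg = cfg or SimulateConfig()
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= cfg.low_weight <= 1:
        raise ValueError("mixture weights must lie in [0, 1]")
    rng = _rng(seed, 0)
    width = len(str(max(n_genes - 1, 1)))
    truths: list[GeneTruth] = []
    cluster_p = CLUSTER_WEIGHTS / CLUSTER_WEIGHTS.sum()
    for i in range(n_genes):
        is_trg = bool(rng.random() < cfg.trg_prob)
        if cfg.couple_trg_omega:
            high = is_trg
        else:
            high = bool(rng.random() >= cfg.low_weight)
        if high:
            omega = float(rng.lognormal(math.log(cfg.high_median), cfg.high_sigma))
        else:
            omega = float(rng.lognormal(math.log(cfg.low_median), cfg.low_sigma))
        t = float(rng.gamma(cfg.t_shape, cfg.t_mean / cfg.t_shape))
        t = max(t, 1e-3)
        n_codons = int(rng.integers(cfg.n_codons_min, cfg.n_codons_max + 1))
        truths.append(
            GeneTruth(
                gene_id=f"g{str(i).zfill(width)}",
                omega_true=omega,
                kappa_true=cfg.kappa,
                t_true=t,
                n_codons=n_codons,
                is_trg=is_trg,
                expr_cluster=str(rng.choice(CLUSTERS, p=cluster_p)),
                strand_b="-" if rng.random() < 0.5 else "+",
            )
        )
    return truths


def simulate_codon_pair(
    g: GeneTruth, pi: np.ndarray, seed: int
) -> tuple[str, str, str]:
    """Simulate a pair of coding sequences diverged under GY94 M0.

    Ancestral codons are i.i.d. from pi; each descendant evolves
    independently for t/2 under the scaled rate matrix. Returns
    (cds_a, cds_b, ancestor); sequences have no internal stops by
    construction of the state space.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(
            f"pi must cover exactly the {N_CODONS} sense codons (stop codons excluded)"
        )
    model = build_Q(g.kappa_true, g.omega_true, pi)
    P = transition_matrix(model, g.t_true / 2.0)
    # guard rounding: renormalize rows
    P = P / P.sum(axis=1, keepdims=True)
    rng = _rng(seed, 1, _gene_index(g.gene_id))
    anc_idx = rng.choice(N_CODONS, size=g.n_codons, p=pi / pi.sum())
    child = np.empty((2, g.n_codons), dtype=int)
    for which in range(2):
        u = rng.random(g.n_codons)
        cum = np.cumsum(P, axis=1)
        child[which] = np.array(
            [np.searchsorted(cum[a], x) for a, x in zip(anc_idx, u)]
        )
    codons = np.array(SENSE_CODONS)
    cds_a = "".join(codons[child[0]])
    cds_b = "".join(codons[child[1]])
    ancestor = "".join(codons[anc_idx])
    return cds_a, cds_b, ancestor


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def make_transcripts(
    cds_a: str,
    cds_b: str,
    g: GeneTruth,
    utr_range: tuple[int, int],
    seed: int,
    species_a: str = "A",
    species_b: str = "B",
    mito_segment: str = "",
) -> tuple[TranscriptRecord, TranscriptRecord]:
    """Wrap a CDS pair into EST-like transcripts.

    Random UTRs (length uniform in ``utr_range``) flank both ends. The
    species-A transcript is forward with known orientation; the
    species-B transcript is reverse-complemented iff the gene's truth
    strand is '-' and its orientation is unknown. A non-empty
    ``mito_segment`` is embedded in the species-A 3' UTR to create a
    mitochondrial decoy.
    """
    rng = _rng(seed, 2, _gene_index(g.gene_id))
    lo, hi = utr_range

    def utr() -> str:
        return _random_nt(rng, int(rng.integers(lo, hi + 1)))

    seq_a = utr() + cds_a + utr() + mito_segment
    rec_a = TranscriptRecord(
        id=f"{g.gene_id}_a", seq=seq_a, species=species_a, orientation_known=True
    )
    seq_b = utr() + cds_b + utr()
    if g.strand_b == "-":
        seq_b = reverse_complement(seq_b)
    rec_b = TranscriptRecord(
        id=f"{g.gene_id}_b", seq=seq_b, species=species_b, orientation_known=False
    )
    return rec_a, rec_b


def build_references(
    truths: list[GeneTruth],
    ancestors: list[str],
    seed: int,
    mito_length: int = 6000,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Protein reference (translated ancestors of non-TRG genes only)
    and a random mitochondrial reference sequence."""
    proteins = []
    for g, anc in zip(truths, ancestors):
        if g.is_trg:
            continue
        prot = "".join(translate_codon(c) for c in split_codons(anc))
        proteins.append(
            TranscriptRecord(id=f"ref_{g.gene_id}", seq=prot, species="reference")
        )
    rng = _rng(seed, 3)
    mito = [TranscriptRecord(id="mito_synthetic", seq=_random_nt(rng, mito_length), species="mito")]
    return proteins, mito


# ---------------------------------------------------------------------------
# Synthetic ontology and GO assignment


def make_ontology(seed: int = 0, leaves_per_branch: int = 4) -> tuple[GoOntology, str]:
    """A small synthetic two-namespace GO-like DAG and its OBO text.

    Layout per namespace: one root, three mid-level terms, and
    ``leaves_per_branch`` leaves per mid-level term; one leaf per
    namespace gets a second parent to exercise diamond propagation.
    Term IDs use a synthetic GO:9xxxxxx range.
    """
    terms: dict[str, tuple[str, str, int]] = {}
    parents: dict[str, set[str]] = {}
    stanzas: list[str] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"GO:9{counter[0]:06d}"

    for ns_i, ns in enumerate(("biological_process", "molecular_function")):
        root = new_id()
        terms[root] = (f"synthetic {ns} root", ns, 0)
        parents[root] = set()
        stanzas.append(f"[Term]\nid: {root}\nname: synthetic {ns} root\nnamespace: {ns}\n")
        mids = []
        for m in range(3):
            mid = new_id()
            terms[mid] = (f"{ns} branch {m}", ns, 1)
            parents[mid] = {root}
            stanzas.append(
                f"[Term]\nid: {mid}\nname: {ns} branch {m}\nnamespace: {ns}\nis_a: {root}\n"
            )
            mids.append(mid)
        for m, mid in enumerate(mids):
            for l in range(leaves_per_branch):
                leaf = new_id()
                ps = {mid}
                # one diamond per namespace: first leaf of branch 1 also
                # hangs under branch 0
                if m == 1 and l == 0:
                    ps.add(mids[0])
                terms[leaf] = (f"{ns} leaf {m}.{l}", ns, 2)
                parents[leaf] = ps
                lines = [f"[Term]", f"id: {leaf}", f"name: {ns} leaf {m}.{l}", f"namespace: {ns}"]
                lines += [f"is_a: {p}" for p in sorted(ps)]
                stanzas.append("\n".join(lines) + "\n")
    obo = "format-version: 1.2\nontology: synthetic-go\n\n" + "\n".join(stanzas)
    return GoOntology(terms=terms, parents=parents), obo


def assign_go(
    truths: list[GeneTruth],
    ontology: GoOntology,
    planted: list[tuple[str, float]] | None = None,
    seed: int = 0,
    terms_per_gene: float = 2.0,
    planted_size: int = 20,
    cfg: SimulateConfig | None = None,
) -> dict[str, set[str]]:
    """Assign GO leaf terms to genes; optionally plant enriched terms.

    Background terms are drawn at random (Poisson number per gene). For
    each planted (term, effect) with effect > 1, ``planted_size`` member
    genes are chosen and their true omega redrawn from a lognormal whose
    median is effect x the low-component median — so the term is
    genuinely enriched for elevated omega. effect <= 1 plants the
    membership but leaves omega at its background draw (a true null).
    Truths are modified in place.
    """
    cfg = cfg or SimulateConfig()
    planted = planted or []
    for term, _ in planted:
        if term not in ontology.terms:
            raise ValueError(f"planted term {term} absent from ontology")
    rng = _rng(seed, 4)
    leaves = sorted(
        t for t in ontology.terms
        if all(t not in ontology.parents[o] for o in ontology.terms)
    )
    # planted terms receive only their chosen members, so the planted
    # category is exactly the gene set whose omega carries the effect
    planted_terms = {t for t, _ in planted}
    background = [t for t in leaves if t not in planted_terms]
    mapping: dict[str, set[str]] = {g.gene_id: set() for g in truths}
    for g in truths:
        k = min(rng.poisson(terms_per_gene), len(background))
        if k:
            picks = rng.choice(len(background), size=k, replace=False)
            mapping[g.gene_id].update(background[i] for i in picks)
    by_id = {g.gene_id: g for g in truths}
    ids = sorted(by_id)
    for term, effect in planted:
        size = min(planted_size, len(ids))
        members = rng.choice(len(ids), size=size, replace=False)
        for i in members:
            gid = ids[i]
            mapping[gid].add(term)
            if effect > 1:
                by_id[gid].omega_true = float(
                    rng.lognormal(math.log(effect * cfg.low_median), cfg.high_sigma)
                )
    for g in truths:
        g.go_terms = set(mapping[g.gene_id])
    return mapping


# ---------------------------------------------------------------------------
# Full bundle


def generate_bundle(
    cfg: SimulateConfig,
    seed: int,
    out_dir: str | Path,
    planted: list[tuple[str, float]] | None = None,
) -> dict:
    """Generate and write a complete synthetic input bundle.

    Writes speciesA.fasta, speciesB.fasta, proteins.fasta, mito.fasta,
    ontology.obo, go_map.tsv, clusters.tsv and truth.tsv under
    ``out_dir`` and returns the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pi = default_codon_frequencies()
    truths = sample_gene_params(cfg.n_genes, seed, cfg)
    ontology, obo_text = make_ontology(seed)
    go_map = assign_go(truths, ontology, planted, seed, cfg=cfg)

    rng = _rng(seed, 5)
    n_decoys = int(round(cfg.mito_decoy_frac * cfg.n_genes))
    decoy_ids = set(
        rng.choice([g.gene_id for g in truths], size=n_decoys, replace=False)
    ) if n_decoys else set()

    cds_pairs = {}
    ancestors = []
    for g in truths:
        cds_a, cds_b, anc = simulate_codon_pair(g, pi, seed)
        cds_pairs[g.gene_id] = (cds_a, cds_b)
        ancestors.append(anc)
    proteins, mito = build_references(truths, ancestors, seed, cfg.mito_length)

    recs_a, recs_b = [], []
    mito_seq = mito[0].seq
    for g in truths:
        g.mito_decoy = g.gene_id in decoy_ids
        segment = ""
        if g.mito_decoy:
            start = int(rng.integers(0, len(mito_seq) - cfg.mito_decoy_len))
            segment = mito_seq[start : start + cfg.mito_decoy_len]
        ra, rb = make_transcripts(
            *cds_pairs[g.gene_id], g, (cfg.utr_min, cfg.utr_max), seed, mito_segment=segment
        )
        recs_a.append(ra)
        recs_b.append(rb)

    write_fasta(out / "speciesA.fasta", recs_a)
    write_fasta(out / "speciesB.fasta", recs_b)
    write_fasta(out / "proteins.fasta", proteins)
    write_fasta(out / "mito.fasta", mito)
    (out / "ontology.obo").write_text(obo_text)
    # interchange tables are keyed by the species-A transcript ID, the
    # join key the screen itself uses
    write_tsv(
        out / "go_map.tsv",
        pd.DataFrame(
            [(f"{g}_a", t) for g in sorted(go_map) for t in sorted(go_map[g])],
            columns=["gene_id", "term_id"],
        ),
    )
    write_tsv(
        out / "clusters.tsv",
        pd.DataFrame(
            [(f"{g.gene_id}_a", g.expr_cluster) for g in truths], columns=["gene_id", "cluster"]
        ),
    )
    write_tsv(
        out / "truth.tsv",
        pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "omega_true": g.omega_true,
                    "kappa_true": g.kappa_true,
                    "t_true": g.t_true,
                    "n_codons": g.n_codons,
                    "is_trg": g.is_trg,
                    "expr_cluster": g.expr_cluster,
                    "strand_b": g.strand_b,
                    "mito_decoy": g.mito_decoy,
                    "go_terms": ";".join(sorted(g.go_terms)),
                }
                for g in truths
            ]
        ),
    )
    return {
        "truths": truths,
        "transcripts_a": recs_a,
        "transcripts_b": recs_b,
        "proteins": proteins,
        "mito": mito,
        "ontology": ontology,
        "go_map": go_map,
        "cds_pairs": cds_pairs,
        "out_dir": out,
    }
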