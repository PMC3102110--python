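"""Readers/writers and configuration for the evolutionary screen.

FASTA parsing is done with a deliberately small reader so that malformed
input can be reported with a line number and duplicate IDs rejected at
parse time (the screen's identifiers key every downstream table). OBO
parsing is delegated to obonet/networkx.

All interchange tables are TSV with a header row; '#'-prefixed lines are
comments. Coordinates in interchange tables are 1-based, inclusive, with
an explicit strand column (+/-).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
import yaml


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One nucleotide transcript.

    ``orientation_known`` is True when the library it came from was
    directionally cloned (the 5'->3' strand is known); transcripts from
    the other species start with unknown strand.
    """

    id: str
    seq: str
    species: str = ""
    orientation_known: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")


def read_fasta(
    path: str | Path,
    species: str = "",
    orientation_known: bool = False,
) -> list[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords, preserving file order.

    Sequences are uppercased; the description after the first whitespace
    of the header is retained separately. Duplicate IDs, headerless
    sequence data and empty records raise :class:`FastaParseError` with
    the line number.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []
    cur_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        if not cur_seq:
            raise FastaParseError(f"line {cur_line}: record {cur_id!r} has empty sequence")
        records.append(
            TranscriptRecord(cur_id, "".join(cur_seq).upper(), species, orientation_known, cur_desc)
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                parts = head.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise FastaParseError(f"line {lineno}: duplicate ID {cur_id!r}")
                seen.add(cur_id)
                cur_seq = []
                cur_line = lineno
            else:
                if cur_id is None:
                    raise FastaParseError(f"line {lineno}: sequence before first header")
                cur_seq.append(line)
    flush()
    return records


def write_fasta(path: str | Path, records: list[TranscriptRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene Ontology


@dataclass
class GoOntology:
    """A parsed GO DAG restricted to is_a/part_of edges.

    ``terms`` maps a term ID to (name, namespace, depth) where depth is
    the shortest is_a/part_of path from the namespace root (root depth 0).
    """

    terms: dict[str, tuple[str, str, int]]
    parents: dict[str, set[str]]

    def namespace(self, term: str) -> str:
        return self.terms[term][1]

    def depth(self, term: str) -> int:
        return self.terms[term][2]

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


_GO_RELATIONS = ("is_a", "part_of")


def parse_obo(path: str | Path, include_part_of: bool = True) -> GoOntology:
    """Parse an OBO 1.2 ontology into a :class:`GoOntology`.

    Obsolete terms are excluded (obonet drops them). is_a edges and,
    optionally, part_of edges are kept; other relationship types are
    ignored. A cyclic graph or a parent reference to a term without a
    stanza is an error.
    """
    graph = obonet.read_obo(path)
    keep = _GO_RELATIONS if include_part_of else ("is_a",)
    parents: dict[str, set[str]] = {}
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key in keep:
            if parent not in graph.nodes or "name" not in graph.nodes[parent]:
                raise ValueError(f"term {child} references missing parent {parent}")
            parents.setdefault(child, set()).add(parent)
            sub.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("ontology parent graph is cyclic")

    # depth = shortest path to the namespace root (a term with no parents)
    depths: dict[str, int] = {}
    # edges run child -> parent, so parents come last in topological
    # order; walk it backwards to have parent depths ready
    for node in reversed(list(nx.topological_sort(nx.DiGraph(sub)))):
        ps = parents.get(node, ())
        depths[node] = 0 if not ps else 1 + min(depths[p] for p in ps)

    terms = {
        node: (data.get("name", ""), data.get("namespace", ""), depths.get(node, 0))
        for node, data in graph.nodes(data=True)
        if "name" in data
    }
    return GoOntology(terms=terms, parents={t: parents.get(t, set()) for t in terms})


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a gene->GO TSV (columns: gene_id, term_id) into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def write_tsv(path: str | Path, df: pd.DataFrame, comment: str | None = None) -> None:
    """Write a TSV with an optional '#' comment header, deterministically."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PairingConfig:
    min_bitscore: float = 300.0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041


@dataclass
class ValidationConfig:
    annot_evalue: float = 1e-5
    min_orf_codons: int = 30
    min_nt_score: float = 40.0
    mito_min_bits: float = 50.0
    nt_match: float = 1.0
    nt_mismatch: float = -2.0
    nt_gap_open: float = 2.5
    nt_gap_extend: float = 2.5
    nt_lambda: float = 1.28
    nt_k: float = 0.46


@dataclass
class AlignmentConfig:
    gap_open: float = 10.0
    gap_extend: float = 0.1


@dataclass
class DndsConfig:
    freq_model: str = "F3x4"  # F3x4 | F1x4 | equal
    max_dn: float = 1.0
    max_ds: float = 1.0
    omega_cap: float = 99.0


@dataclass
class GoScanConfig:
    min_n: int = 5
    max_frac: float = 0.25
    fdr_q: float = 0.10
    include_part_of: bool = True
    exact_max_n: int = 12


@dataclass
class StatsConfig:
    bin_width: float = 0.1
    pool_above: float = 1.8


@dataclass
class ExpressionConfig:
    min_nt_bits: float = 50.0


@dataclass
class SimulateConfig:
    n_genes: int = 40
    n_codons_min: int = 200
    n_codons_max: int = 500
    trg_prob: float = 0.12
    low_weight: float = 0.88
    low_median: float = 0.23
    low_sigma: float = 0.6
    high_median: float = 0.50
    high_sigma: float = 0.8
    couple_trg_omega: bool = True
    kappa: float = 2.0
    t_mean: float = 0.12
    t_shape: float = 4.0
    utr_min: int = 0
    utr_max: int = 300
    mito_length: int = 6000
    mito_decoy_frac: float = 0.05
    mito_decoy_len: int = 200
    couple_clusters: bool = False


@dataclass
class InputPaths:
    species_a: str = ""
    species_b: str = ""
    species_a_label: str = "A"
    species_b_label: str = "B"
    proteins: str = ""
    mito: str = ""
    ontology: str = ""
    go_map: str = ""
    clusters: str = ""


@dataclass
class PipelineConfig:
    """All tunables of the screen; loadable from one YAML file."""

    seed: int = 1
    out_dir: str = "screen_out"
    inputs: InputPaths = field(default_factory=InputPaths)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    dnds: DndsConfig = field(default_factory=DndsConfig)
    go: GoScanConfig = field(default_factory=GoScanConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__!r} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {path or 'root'}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or dataclasses.is_dataclass(
            getattr(f, "default_factory", None)
        ):
            sub_cls = f.default_factory  # type: ignore[union-attr]
            kwargs[name] = _from_dict(sub_cls, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "inputs": InputPaths,
    "pairing": PairingConfig,
    "validation": ValidationConfig,
    "alignment": AlignmentConfig,
    "dnds": DndsConfig,
    "go": GoScanConfig,
    "stats": StatsConfig,
    "expression": ExpressionConfig,
    "simulate": SimulateConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    unknown = set(data) - set(_SECTION_TYPES) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if "out_dir" in data:
        kwargs["out_dir"] = str(data.pop("out_dir"))
    for name, value in data.items():
        kwargs[name] = _from_dict(_SECTION_TYPES[name], value, f"{name}.")
    cfg = PipelineConfig(**kwargs)
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    if cfg.pairing.min_bitscore < 0:
        raise ValueError("pairing.min_bitscore must be >= 0")
    if not 0 < cfg.go.max_frac <= 1:
        raise ValueError("go.max_frac must be in (0, 1]")
    if cfg.go.min_n < 1:
        raise ValueError("go.min_n must be >= 1")
    if cfg.stats.bin_width <= 0:
        raise ValueError("stats.bin_width must be > 0")
    if cfg.dnds.freq_model not in ("F3x4", "F1x4", "equal"):
        raise ValueError(f"unknown dnds.freq_model {cfg.dnds.freq_model!r}")
    if cfg.simulate.utr_min > cfg.simulate.utr_max or cfg.simulate.utr_min < 0:
        raise ValueError("simulate.utr_min/utr_max invalid")
    if not 0 <= cfg.simulate.trg_prob <= 1:
        raise ValueError("simulate.trg_prob must be a probability")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
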