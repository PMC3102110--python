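"""Stage-by-stage orchestration of the evolutionary screen.

Each stage reads its inputs from disk, writes a TSV under the output
directory and appends its entering/leaving counts to the run log, so the
log itself is the count-summary table of the run and any stage can be
re-run in isolation. Stage order: pairing -> validation -> rates ->
stats -> goscan -> expression. Given the same configuration and seed,
repeated runs produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_align, dnds, expression, framecheck, goscan, rate_stats
from .io_core import (
    PipelineConfig,
    TranscriptRecord,
    parse_obo,
    read_fasta,
    read_go_map,
    read_tsv,
    write_tsv,
)
from .pairing import reciprocal_best_hits

STAGES = ("pairing", "validation", "rates", "stats", "goscan", "expression")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.rows: list[dict] = []

    def count(self, stage: str, label: str, value) -> None:
        self.rows.append({"stage": stage, "count": label, "value": value})

    def flush(self) -> None:
        write_tsv(self.path, pd.DataFrame(self.rows, columns=["stage", "count", "value"]))


def _load_inputs(cfg: PipelineConfig):
    a = read_fasta(cfg.inputs.species_a, cfg.inputs.species_a_label, orientation_known=True)
    b = read_fasta(cfg.inputs.species_b, cfg.inputs.species_b_label, orientation_known=False)
    if not a or not b:
        raise ValueError("no sequences in species input FASTA")
    return a, b


def stage_pairing(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    set_a, set_b = _load_inputs(cfg)
    log.count("pairing", "transcripts_a", len(set_a))
    log.count("pairing", "transcripts_b", len(set_b))
    pairs = reciprocal_best_hits(set_a, set_b, cfg.pairing)
    rows = []
    for a_id, b_id, hab, hba in pairs:
        rows.append(
            {
                "id_a": a_id,
                "id_b": b_id,
                "frame_a": hab.query_frame,
                "frame_b": hab.subject_frame,
                "raw_score": hab.raw_score,
                "bit_score": round(hab.bit_score, 4),
                "a_start": hab.query_nt_interval[0],
                "a_end": hab.query_nt_interval[1],
                "a_strand": "+" if hab.query_frame > 0 else "-",
                "b_start": hab.subject_nt_interval[0],
                "b_end": hab.subject_nt_interval[1],
                "b_strand": "+" if hab.subject_frame > 0 else "-",
                "bit_score_ba": round(hba.bit_score, 4),
            }
        )
    write_tsv(
        out / "pairs.tsv",
        pd.DataFrame(rows, columns=[
            "id_a", "id_b", "frame_a", "frame_b", "raw_score", "bit_score",
            "a_start", "a_end", "a_strand", "b_start", "b_end", "b_strand",
            "bit_score_ba",
        ]),
        comment="reciprocal best translated hits; coordinates 1-based inclusive, strand +/-",
    )
    log.count("pairing", "reciprocal_best_pairs", len(pairs))


def stage_validation(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    set_a, set_b = _load_inputs(cfg)
    by_a = {r.id: r for r in set_a}
    by_b = {r.id: r for r in set_b}
    proteins = read_fasta(cfg.inputs.proteins, "reference") if cfg.inputs.proteins else []
    mito = read_fasta(cfg.inputs.mito, "mito") if cfg.inputs.mito else []
    pairs = read_tsv(out / "pairs.tsv")
    log.count("validation", "pairs_in", len(pairs))

    validated: list[framecheck.ValidatedPair] = []
    triples = []
    for _, row in pairs.iterrows():
        a = by_a[row["id_a"]]
        b = by_b[row["id_b"]]
        try:
            b_oriented, strand = framecheck.orient_partner(a, b, cfg.validation)
        except framecheck.OrientationError:
            vp = framecheck.ValidatedPair(id_a=a.id, id_b=b.id, rejection="unorientable")
            validated.append(vp)
            continue
        vp = framecheck.validate_frame(
            a, b_oriented, strand, proteins, cfg.validation, cfg.pairing
        )
        validated.append(vp)
        if vp.rejection is None:
            triples.append((vp, a, b_oriented))

    n_frame_ok = sum(1 for v in validated if v.rejection is None)
    log.count("validation", "frame_validated", n_frame_ok)
    kept, removed = framecheck.filter_mitochondrial(triples, mito, cfg.validation)
    log.count("validation", "mitochondrial_removed", len(removed))
    log.count("validation", "pairs_out", len(kept))
    for code in ("unorientable", "no ORF", "frame mismatch", "orientation", "short ORF"):
        log.count(
            "validation", f"rejected_{code.replace(' ', '_')}",
            sum(1 for v in validated if v.rejection == code),
        )

    rows = []
    for vp in validated:
        rows.append(
            {
                "id_a": vp.id_a,
                "id_b": vp.id_b,
                "strand_b": vp.strand_b,
                "frame_a": vp.frame_a,
                "frame_b": vp.frame_b,
                "orf_a_start": vp.orf_a_interval[0],
                "orf_a_end": vp.orf_a_interval[1],
                "orf_b_start": vp.orf_b_interval[0],
                "orf_b_end": vp.orf_b_interval[1],
                "annotation": vp.annotation,
                "annotation_hit": vp.annotation_hit or "",
                "orf_a": vp.orf_a,
                "orf_b": vp.orf_b,
                "rejection": vp.rejection or "",
            }
        )
    write_tsv(
        out / "validated.tsv",
        pd.DataFrame(rows),
        comment="frame-validated pairs; ORF coordinates 1-based inclusive on oriented transcripts; strand +/-",
    )


def stage_rates(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    validated = read_tsv(out / "validated.tsv")
    ok = validated[validated["rejection"].isna() | (validated["rejection"] == "")]
    log.count("rates", "pairs_in", len(ok))
    rows = []
    estimates = []
    for _, row in ok.iterrows():
        aln = codon_align.build_codon_alignment(row["orf_a"], row["orf_b"], cfg.alignment)
        est = dnds.fit_m0(aln, cfg.dnds, pair_id=(row["id_a"], row["id_b"]))
        estimates.append(est)
        rows.append(
            {
                "id_a": row["id_a"],
                "id_b": row["id_b"],
                "annotation": row["annotation"],
                "n_sites": est.n_sites,
                "t": round(est.t_hat, 6),
                "kappa": round(est.kappa_hat, 6),
                "omega": round(est.omega_hat, 6),
                "dN": round(est.dN, 6),
                "dS": round(est.dS, 6),
                "lnL": round(est.lnL, 4),
                "dN_ng": round(est.dN_ng, 6),
                "dS_ng": round(est.dS_ng, 6),
                "omega_ng": round(est.omega_ng, 6) if np.isfinite(est.omega_ng) else est.omega_ng,
                "status": est.status,
            }
        )
    table = pd.DataFrame(rows)
    kept, excluded = dnds.apply_filters(estimates, cfg.dnds)
    reason_by_id = {est.pair_id[0]: reason for est, reason in excluded}
    if len(table):
        table["filter_reason"] = [reason_by_id.get(i, "") for i in table["id_a"]]
    write_tsv(out / "rates.tsv", table, comment="per-pair M0 and NG86 estimates")
    kept_ids = {est.pair_id[0] for est in kept}
    write_tsv(
        out / "rates_filtered.tsv",
        table[table["id_a"].isin(kept_ids)] if len(table) else table,
        comment="pairs surviving the dN<=1, dS<=1, omega!=99 filters",
    )
    log.count("rates", "excluded_ds_gt_1", sum("ds_gt_1" in r for _, r in excluded))
    log.count("rates", "excluded_dn_gt_1", sum("dn_gt_1" in r for _, r in excluded))
    log.count("rates", "excluded_omega_sentinel", sum("omega_sentinel" in r for _, r in excluded))
    log.count("rates", "pairs_out", len(kept))


def stage_stats(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    table = read_tsv(out / "rates_filtered.tsv")
    log.count("stats", "pairs_in", len(table))
    summary = rate_stats.summarize_screen(table)
    write_tsv(out / "summary.tsv", rate_stats.summary_table(summary))
    hist = rate_stats.bin_omega(table, cfg.stats.bin_width, cfg.stats.pool_above)
    write_tsv(out / "omega_hist.tsv", hist)
    log.count("stats", "n_omega_gt1", summary.n_gt1)
    log.count("stats", "n_trg", summary.n_trg)
    for stat, p in summary.pvalues.items():
        log.count("stats", f"mwu_p_{stat}", p)


def stage_goscan(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    if not cfg.inputs.ontology or not cfg.inputs.go_map:
        log.count("goscan", "skipped_no_inputs", 1)
        return
    table = read_tsv(out / "rates_filtered.tsv")
    ontology = parse_obo(cfg.inputs.ontology, cfg.go.include_part_of)
    gene_go = read_go_map(cfg.inputs.go_map)
    stat_values = {
        "dS": dict(zip(table["id_a"], table["dS"])),
        "dN": dict(zip(table["id_a"], table["dN"])),
        "omega": dict(zip(table["id_a"], table["omega"])),
    }
    gene_go = {g: ts for g, ts in gene_go.items() if g in stat_values["omega"]}
    suffix = {"biological_process": "bp", "molecular_function": "mf"}
    for namespace, tag in suffix.items():
        result = goscan.scan_namespace(gene_go, ontology, namespace, stat_values, cfg.go)
        goscan.export_scan(
            result, out / f"go_scan_{tag}.tsv", out / f"go_dendrogram_{tag}.nwk"
        )
        log.count("goscan", f"categories_{tag}", len(result.categories))
        log.count(
            "goscan", f"passing_fdr_{tag}",
            int(result.table["passes_fdr"].sum()) if len(result.table) else 0,
        )


def stage_expression(cfg: PipelineConfig, out: Path, log: _Log) -> None:
    if not cfg.inputs.clusters:
        log.count("expression", "skipped_no_inputs", 1)
        return
    table = read_tsv(out / "rates_filtered.tsv")
    clusters = read_tsv(cfg.inputs.clusters)
    assignment = expression.map_to_clusters(
        list(table["id_a"]), clusters, cfg.expression, cfg.validation
    )
    df = table[table["id_a"].isin(assignment)].copy()
    df["cluster"] = [assignment[g] for g in df["id_a"]]
    order = sorted(df["cluster"].unique())
    ctable = expression.cluster_table(
        df.rename(columns={"id_a": "gene_id"}), order
    )
    write_tsv(out / "clusters_summary.tsv", ctable)
    log.count("expression", "mapped", len(df))
    counts = ctable[["n_conserved", "n_trg"]].to_numpy().T
    nonzero = counts.sum(axis=0) > 0
    try:
        chi2, dof, p = expression.trg_chisq(counts[:, nonzero])
        log.count("expression", "trg_chisq_p", p)
    except ValueError as exc:
        log.count("expression", "trg_chisq_skipped", str(exc))
    try:
        pos = df[df["omega"] > 0]
        log.count("expression", "anova_excluded_zero_omega", len(df) - len(pos))
        anova = expression.twoway_anova_log_omega(pos)
        write_tsv(out / "anova.tsv", anova)
    except ValueError as exc:
        log.count("expression", "anova_skipped", str(exc))


_STAGE_FUNCS = {
    "pairing": stage_pairing,
    "validation": stage_validation,
    "rates": stage_rates,
    "stats": stage_stats,
    "goscan": stage_goscan,
    "expression": stage_expression,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the screen (or a subset of stages) and return the output dir."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.tsv")
    if (out / "run_log.tsv").exists() and set(stages) != set(STAGES):
        prev = read_tsv(out / "run_log.tsv")
        log.rows = [r for _, r in prev.iterrows() if r["stage"] not in stages]
        log.rows = [dict(r) for r in log.rows]
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, out, log)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            log.flush()
            raise StageError(stage, exc) from exc
    log.flush()
    return out
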