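"""Mapping orthologs onto developmental expression clusters.

Orthologs are joined to synexpression clusters (the six developmental
clusters I-VI) either through a precomputed gene->cluster table or by
best nucleotide local alignment against the cluster sequences. Two
questions are asked of the mapped set: are taxonomically-restricted
genes overrepresented in any cluster (Pearson chi-square on the 2xK
membership table), and do log10 dN/dS ratios differ by cluster and
annotation class (two-way ANOVA with interaction, Type II sums of
squares).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .framecheck import _nt_aligner
from .io_core import ExpressionConfig, TranscriptRecord, ValidationConfig
from .pairing import bit_score


def map_to_clusters(
    ortholog_seqs: dict[str, str] | list[str],
    clusters: pd.DataFrame | dict[str, list[TranscriptRecord]],
    cfg: ExpressionConfig | None = None,
    vcfg: ValidationConfig | None = None,
) -> dict[str, str]:
    """Assign each ortholog to at most one expression cluster.

    With a table (columns gene_id, cluster) the join is on gene ID.
    With cluster sequences, each ortholog is assigned to the cluster of
    its best nucleotide local alignment with bit score >=
    ``cfg.min_nt_bits``; score ties go to the lower cluster label.
    """
    cfg = cfg or ExpressionConfig()
    vcfg = vcfg or ValidationConfig()
    if isinstance(clusters, pd.DataFrame):
        table = dict(zip(clusters.iloc[:, 0].astype(str), clusters.iloc[:, 1].astype(str)))
        ids = ortholog_seqs if isinstance(ortholog_seqs, list) else list(ortholog_seqs)
        return {g: table[g] for g in ids if g in table}
    if not isinstance(ortholog_seqs, dict):
        raise ValueError("cluster sequences require ortholog id->sequence mapping")
    aligner = _nt_aligner(vcfg)
    out: dict[str, str] = {}
    for gid, seq in ortholog_seqs.items():
        best: tuple[float, str] | None = None
        for label in sorted(clusters):
            for rec in clusters[label]:
                raw = float(aligner.score(seq, rec.seq))
                bits = bit_score(raw, vcfg.nt_lambda, vcfg.nt_k)
                if bits >= cfg.min_nt_bits and (best is None or bits > best[0]):
                    best = (bits, label)
        if best is not None:
            out[gid] = best[1]
    return out


def cluster_table(assignments: pd.DataFrame, cluster_order: list[str]) -> pd.DataFrame:
    """Per-cluster membership counts and mean dN/dS by annotation class.

    ``assignments`` needs columns: gene_id, cluster, annotation, omega.
    """
    rows = []
    for label in cluster_order:
        sub = assignments[assignments["cluster"] == label]
        cons = sub[sub["annotation"] == "annotated"]
        trg = sub[sub["annotation"] == "trg"]
        rows.append(
            {
                "cluster": label,
                "n_mapped": len(sub),
                "n_conserved": len(cons),
                "n_trg": len(trg),
                "mean_omega_conserved": float(cons["omega"].mean()) if len(cons) else float("nan"),
                "mean_omega_trg": float(trg["omega"].mean()) if len(trg) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def trg_chisq(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2xK table of
    conserved vs TRG counts per cluster; df = K - 1."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2xK count table")
    expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count; pool or drop empty clusters")
    res = chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def twoway_anova_log_omega(records: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of log10 dN/dS on cluster and annotation.

    ``records`` needs columns: omega (> 0; zeros must be excluded and
    counted upstream), cluster, annotation. Fits the full model with
    interaction by least squares and reports Type II sums of squares,
    F and P per term.
    """
    df = records.copy()
    if (df["omega"] <= 0).any():
        raise ValueError("omega must be > 0 for the log transform; exclude zeros upstream")
    for factor in ("cluster", "annotation"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than two levels")
    df["log_omega"] = np.log10(df["omega"].astype(float))
    model = smf.ols("log_omega ~ C(cluster) * C(annotation)", data=df).fit()
    import warnings

    with warnings.catch_warnings():
        # sparse cells (e.g. clusters with no TRG member) make the
        # interaction rank-deficient; the corresponding F is NaN
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(cluster)": "cluster",
            "C(annotation)": "annotation",
            "C(cluster):C(annotation)": "cluster:annotation",
            "Residual": "residual",
        }
    )
    table.index.name = "factor"
    return table.reset_index()
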