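"""Summary statistics contrasting conserved and lineage-specific genes.

The screen's headline comparison: after filtering, orthologs are split
by annotation status (annotated = conserved across taxa vs non-annotated
= presumably taxonomically restricted) and by whether the fitted dN/dS
exceeds 1; medians of dS, dN and dN/dS per class are compared with
Mann-Whitney U tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


def mwu(
    x: list[float] | np.ndarray,
    y: list[float] | np.ndarray,
    alternative: str = "two_sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Mann-Whitney U test of x against y.

    Midranks for ties; the P-value is exact (full enumeration) when
    n_x + n_y <= ``exact_max_n`` and there are no ties, otherwise the
    normal approximation with tie and continuity correction is used.
    ``alternative`` 'greater' tests whether x ranks higher than y.
    Returns (U of x, P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mwu requires non-empty samples")
    alt = {"two_sided": "two-sided", "greater": "greater"}[alternative]
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) + len(y) <= exact_max_n and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScreenSummary:
    """Counts, percentages and class contrasts in the shape of the
    published count-summary table."""

    n_total: int
    n_annotated: int
    n_trg: int
    n_gt1: int
    n_gt1_annotated: int
    n_gt1_trg: int
    medians: dict[str, dict[str, float]] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def n_lt1(self) -> int:
        return self.n_total - self.n_gt1

    def percentages(self) -> dict[str, float]:
        return {
            "pct_gt1_all": percent(self.n_gt1, self.n_total),
            "pct_gt1_of_trg": percent(self.n_gt1_trg, self.n_trg),
            "pct_gt1_of_annotated": percent(self.n_gt1_annotated, self.n_annotated),
            "pct_lt1_of_annotated": percent(
                self.n_annotated - self.n_gt1_annotated, self.n_annotated
            ),
            "pct_trg_of_all": percent(self.n_trg, self.n_total),
            "pct_annotated_of_all": percent(self.n_annotated, self.n_total),
        }


def percent(part: int, whole: int, digits: int = 0) -> float:
    """Percentage rounded half-up to ``digits`` (matching the integer
    rendering of the published table)."""
    if whole == 0:
        return float("nan")
    value = 100.0 * part / whole
    shift = 10**digits
    return math.floor(value * shift + 0.5) / shift


def summarize_screen(table: pd.DataFrame) -> ScreenSummary:
    """Summarize a filtered screen table.

    ``table`` needs columns: annotation ('annotated'|'trg'), omega, dN,
    dS. Computes class counts split at omega = 1, per-class medians and
    two-sided MWU P-values for dS, dN and omega between classes.
    """
    ann = table[table["annotation"] == "annotated"]
    trg = table[table["annotation"] == "trg"]
    summary = ScreenSummary(
        n_total=len(table),
        n_annotated=len(ann),
        n_trg=len(trg),
        n_gt1=int((table["omega"] > 1).sum()),
        n_gt1_annotated=int((ann["omega"] > 1).sum()),
        n_gt1_trg=int((trg["omega"] > 1).sum()),
    )
    for stat in ("dS", "dN", "omega"):
        summary.medians[stat] = {
            "annotated": float(ann[stat].median()) if len(ann) else float("nan"),
            "trg": float(trg[stat].median()) if len(trg) else float("nan"),
            "all": float(table[stat].median()) if len(table) else float("nan"),
        }
        if len(ann) and len(trg):
            _, p = mwu(trg[stat].to_numpy(), ann[stat].to_numpy(), "two_sided")
            summary.pvalues[stat] = p
        else:
            summary.pvalues[stat] = float("nan")
    return summary


def summary_table(summary: ScreenSummary) -> pd.DataFrame:
    """Render a ScreenSummary as the published-table-shaped TSV frame;
    percentages are recomputed from counts, never stored."""
    rows = [
        {
            "orthologs": "filtered",
            "n": summary.n_total,
            "pct_all": 100.0,
            "annotated": summary.n_annotated,
            "annotated_pct": percent(summary.n_annotated, summary.n_total),
            "non_annotated": summary.n_trg,
            "non_annotated_pct": percent(summary.n_trg, summary.n_total),
        },
        {
            "orthologs": "dnds_lt_1",
            "n": summary.n_lt1,
            "pct_all": percent(summary.n_lt1, summary.n_total),
            "annotated": summary.n_annotated - summary.n_gt1_annotated,
            "annotated_pct": percent(
                summary.n_annotated - summary.n_gt1_annotated, summary.n_annotated
            ),
            "non_annotated": summary.n_trg - summary.n_gt1_trg,
            "non_annotated_pct": percent(summary.n_trg - summary.n_gt1_trg, summary.n_trg),
        },
        {
            "orthologs": "dnds_gt_1",
            "n": summary.n_gt1,
            "pct_all": percent(summary.n_gt1, summary.n_total),
            "annotated": summary.n_gt1_annotated,
            "annotated_pct": percent(summary.n_gt1_annotated, summary.n_annotated),
            "non_annotated": summary.n_gt1_trg,
            "non_annotated_pct": percent(summary.n_gt1_trg, summary.n_trg),
        },
    ]
    return pd.DataFrame(rows)


def bin_omega(
    omegas: dict[str, list[float]] | pd.DataFrame,
    width: float = 0.1,
    pool_above: float = 1.8,
) -> pd.DataFrame:
    """Histogram of dN/dS per class with the tail pooled.

    Bins are half-open [k*width, (k+1)*width); all values strictly
    greater than ``pool_above`` are pooled into a final bin. Returns a
    frame with bin edges, per-class counts and per-class percentages.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if isinstance(omegas, pd.DataFrame):
        omegas = {
            cls: grp["omega"].tolist() for cls, grp in omegas.groupby("annotation")
        }
    n_bins = int(math.floor(pool_above / width + 1e-9)) + 1
    edges = [round(k * width, 10) for k in range(n_bins + 1)]
    rows = []
    for k in range(n_bins):
        rows.append({"bin_low": edges[k], "bin_high": edges[k + 1], "pooled": False})
    rows.append({"bin_low": pool_above, "bin_high": float("inf"), "pooled": True})
    df = pd.DataFrame(rows)
    for cls, values in omegas.items():
        counts = np.zeros(len(df), dtype=int)
        for v in values:
            if v > pool_above:
                counts[-1] += 1
            else:
                k = int(math.floor(v / width + 1e-9))
                k = min(k, n_bins - 1)
                counts[k] += 1
        df[f"count_{cls}"] = counts
        total = counts.sum()
        df[f"pct_{cls}"] = 100.0 * counts / total if total else 0.0
    return df


def neutral_ds_proxy(n_generations: float, mu: float) -> float:
    """Expected neutral synonymous divergence: generations since the
    species split (divergence time / generation time, counting both
    lineages' mutation input via a shared per-generation rate) times the
    per-site per-generation mutation rate."""
    if n_generations < 0 or mu < 0:
        raise ValueError("inputs must be non-negative")
    return n_generations * mu
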