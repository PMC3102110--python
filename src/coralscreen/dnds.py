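"""Pairwise dN/dS estimation under the Goldman-Yang M0 codon model.

Two estimators are provided for every codon alignment:

* ``fit_m0`` — maximum likelihood under the one-ratio (M0) GY94 model.
  The rate from codon i to codon j is 0 if they differ at more than one
  position, and otherwise proportional to pi_j, multiplied by kappa for
  transitions and by omega for nonsynonymous changes; Q is scaled so the
  expected number of substitutions per codon per unit time is 1. The
  pairwise likelihood treats one sequence as drawn from the stationary
  distribution and the other as its descendant at distance t, which by
  reversibility equals the two-descendant parameterization with total
  path length t.

* ``ng86`` — Nei-Gojobori (1986) counting with Jukes-Cantor correction,
  kept as an independent, likelihood-free cross-check.

dS and dN are derived from the ML fit with the mutational-opportunity
site convention: synonymous/nonsynonymous site fractions are computed
from the fitted model with omega set to 1, so that dN/dS equals the
fitted omega exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .codons import AMINO_ACIDS, CODON_INDEX, SENSE_CODONS, STOP_CODONS, is_transition, translate_codon
from .io_core import DndsConfig

N_CODONS = len(SENSE_CODONS)

OMEGA_SENTINEL = 99.0
BOUNDS_T = (1e-6, 50.0)
BOUNDS_KAPPA = (1e-3, 99.0)
BOUNDS_OMEGA = (1e-4, 99.0)


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-nucleotide-difference structure over the 61 sense codons.

    Returns boolean (61, 61) arrays: differ-at-one-position, is-transition
    (for those), is-synonymous (for those).
    """
    one = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(one)
    syn = np.zeros_like(one)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            one[i, j] = True
            ts[i, j] = is_transition(ci[p], cj[p])
            syn[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return one, ts, syn


_ONE_DIFF, _IS_TS, _IS_SYN = _pair_structure()


@dataclass
class CodonModel:
    """GY94 M0 model: kappa, omega, codon frequencies and the scaled Q."""

    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric eigendecomposition of Q using reversibility.

        With D = diag(sqrt(pi)), S = D Q D^-1 is symmetric; returns
        (eigenvalues, D^-1 U, U^T D) so that P(t) = (D^-1 U) exp(w t)
        (U^T D).
        """
        if self._eig is None:
            d = np.sqrt(self.pi)
            S = (self.Q * d[:, None]) / d[None, :]
            S = 0.5 * (S + S.T)  # symmetrize away rounding noise
            w, U = np.linalg.eigh(S)
            self._eig = (w, U / d[:, None], U.T * d[None, :])
        return self._eig


def build_Q(kappa: float, omega: float, pi: np.ndarray, scale: bool = True) -> CodonModel:
    """Build the GY94 rate matrix for (kappa, omega, pi).

    With ``scale`` (the default) Q is normalized so the expected number
    of substitutions per codon per unit time is 1; ``scale=False`` keeps
    the raw q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous].
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have length {N_CODONS}")
    if np.any(pi <= 0):
        raise ValueError("pi must have strictly positive entries (mask upstream)")
    if not math.isclose(float(pi.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("pi must sum to 1")
    R = np.where(_ONE_DIFF, pi[None, :], 0.0)
    R = np.where(_IS_TS, R * kappa, R)
    R = np.where(_ONE_DIFF & ~_IS_SYN, R * omega, R)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    if scale:
        mean_rate = -float(pi @ np.diag(R))
        if mean_rate > 0:
            R = R / mean_rate
    return CodonModel(kappa=kappa, omega=omega, pi=pi, Q=R)


def transition_matrix(model: CodonModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt), row-stochastic."""
    if t < 0:
        raise ValueError("t must be non-negative")
    w, L, R = model.eig()
    P = (L * np.exp(w * t)[None, :]) @ R
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Codon frequencies


def _position_nt_counts(codon_lists: list[list[str]]) -> np.ndarray:
    """(3, 4) nucleotide counts per codon position with +1 pseudocount."""
    counts = np.ones((3, 4))  # pseudocount keeps every sense codon representable
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for codons in codon_lists:
        for c in codons:
            for p, nt in enumerate(c):
                if nt in order:
                    counts[p, order[nt]] += 1
    return counts


def f3x4_frequencies(codon_lists: list[list[str]]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts."""
    counts = _position_nt_counts(codon_lists)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return frequencies_from_nt(freqs)


def f1x4_frequencies(codon_lists: list[list[str]]) -> np.ndarray:
    counts = _position_nt_counts(codon_lists).sum(axis=0, keepdims=True)
    freqs = np.repeat(counts / counts.sum(), 3).reshape(4, 3).T
    return frequencies_from_nt(freqs)


def frequencies_from_nt(pos_freqs: np.ndarray) -> np.ndarray:
    """Codon frequencies as products of per-position nucleotide
    frequencies (rows of ``pos_freqs``, order ACGT), with stop codons
    removed and the rest renormalized."""
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    pi = np.array(
        [
            pos_freqs[0, order[c[0]]] * pos_freqs[1, order[c[1]]] * pos_freqs[2, order[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


# ---------------------------------------------------------------------------
# ML fit


@dataclass
class RateEstimate:
    """Estimates for one ortholog pair (ML primary, NG86 companion)."""

    t_hat: float
    kappa_hat: float
    omega_hat: float
    dN: float
    dS: float
    lnL: float
    dN_ng: float
    dS_ng: float
    omega_ng: float
    n_sites: int
    status: str = "ok"  # ok | ds_saturated | dn_saturated | omega_sentinel
    pair_id: tuple[str, str] | None = None


def pair_codon_counts(codons_a: list[str], codons_b: list[str]) -> np.ndarray:
    """(61, 61) table of aligned sense-codon pairs; gap or N columns are
    dropped (complete deletion)."""
    N = np.zeros((N_CODONS, N_CODONS))
    for ca, cb in zip(codons_a, codons_b):
        ia = CODON_INDEX.get(ca)
        ib = CODON_INDEX.get(cb)
        if ia is not None and ib is not None:
            N[ia, ib] += 1
    return N


def _site_flux(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Unnormalized synonymous (A) and nonsynonymous-at-omega-1 (B)
    substitution fluxes for the model's mutational opportunity."""
    R = np.where(_ONE_DIFF, pi[None, :], 0.0)
    R = np.where(_IS_TS, R * kappa, R)
    flux = pi[:, None] * R
    A = float(flux[_IS_SYN & _ONE_DIFF].sum())
    B = float(flux[~_IS_SYN & _ONE_DIFF].sum())
    return A, B


def _ds_dn_from_fit(t: float, kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    A, B = _site_flux(kappa, pi)
    rho_s = A / (A + omega * B)  # fraction of substitutions that are synonymous
    p_s1 = A / (A + B)  # synonymous site fraction (omega = 1)
    dS = t * rho_s / (3.0 * p_s1)
    dN = t * (1.0 - rho_s) / (3.0 * (1.0 - p_s1))
    return dS, dN


def log_likelihood(counts: np.ndarray, model: CodonModel, t: float) -> float:
    P = transition_matrix(model, t)
    with np.errstate(divide="ignore"):
        logjoint = np.log(np.clip(model.pi[:, None] * P, 1e-300, None))
    return float((counts * logjoint).sum())


def alignment_frequencies(codons_a: list[str], codons_b: list[str], freq_model: str) -> np.ndarray:
    sense = [
        [c for c in codons if c in CODON_INDEX]
        for codons in (codons_a, codons_b)
    ]
    if freq_model == "F3x4":
        return f3x4_frequencies(sense)
    if freq_model == "F1x4":
        return f1x4_frequencies(sense)
    if freq_model == "equal":
        return equal_frequencies()
    raise ValueError(f"unknown freq_model {freq_model!r}")


def fit_m0(aln, cfg: DndsConfig | None = None, pair_id: tuple[str, str] | None = None) -> RateEstimate:
    """Fit (t, kappa, omega) by maximum likelihood on one codon alignment.

    Multi-start bounded quasi-Newton optimization in log-parameter space
    (starts at t in {0.01, 0.2, 1}); omega hitting its upper bound, or
    identical sequences, yield the omega sentinel (99) instead of an
    unbounded ratio.
    """
    cfg = cfg or DndsConfig()
    codons_a, codons_b = aln.codons_a, aln.codons_b
    counts = pair_codon_counts(codons_a, codons_b)
    n_used = int(counts.sum())
    if n_used < 1:
        raise ValueError("no ungapped codon columns to fit")
    pi = alignment_frequencies(codons_a, codons_b, cfg.freq_model)

    dn_ng, ds_ng, omega_ng, status_ng = _ng86_summary(codons_a, codons_b)

    n_diff = n_used - int(np.trace(counts))
    if n_diff == 0:
        model = build_Q(1.0, 1.0, pi)
        lnl = log_likelihood(counts, model, BOUNDS_T[0])
        return RateEstimate(
            t_hat=BOUNDS_T[0], kappa_hat=1.0, omega_hat=OMEGA_SENTINEL,
            dN=0.0, dS=0.0, lnL=lnl, dN_ng=dn_ng, dS_ng=ds_ng,
            omega_ng=omega_ng, n_sites=n_used, status="omega_sentinel",
            pair_id=pair_id,
        )

    lo = np.log([BOUNDS_T[0], BOUNDS_KAPPA[0], BOUNDS_OMEGA[0]])
    hi = np.log([BOUNDS_T[1], BOUNDS_KAPPA[1], BOUNDS_OMEGA[1]])

    def neg_lnl(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        model = build_Q(kappa, omega, pi)
        return -log_likelihood(counts, model, t)

    omega0 = min(max(omega_ng if np.isfinite(omega_ng) and omega_ng > 0 else 0.3, 0.01), 10.0)
    best = None
    for t0 in (0.01, 0.2, 1.0):
        x0 = np.log([t0, 2.0, omega0])
        res = minimize(
            neg_lnl, x0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    t_hat, kappa_hat, omega_hat = (float(v) for v in np.exp(best.x))
    lnl = -float(best.fun)
    dS, dN = _ds_dn_from_fit(t_hat, kappa_hat, omega_hat, pi)

    status = "ok"
    if omega_hat >= BOUNDS_OMEGA[1] * (1 - 1e-4):
        status = "omega_sentinel"
        omega_hat = OMEGA_SENTINEL
    elif status_ng != "ok":
        status = status_ng
    return RateEstimate(
        t_hat=t_hat, kappa_hat=kappa_hat, omega_hat=omega_hat,
        dN=dN, dS=dS, lnL=lnl, dN_ng=dn_ng, dS_ng=ds_ng,
        omega_ng=omega_ng, n_sites=n_used, status=status, pair_id=pair_id,
    )


# ---------------------------------------------------------------------------
# NG86 counting


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one sense codon: at each position, the
    fraction of the three single-nucleotide changes that are synonymous.
    Changes creating a stop codon count as nonsynonymous."""
    aa = translate_codon(codon)
    s = 0.0
    for p in range(3):
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _codon_syn_sites(c) for c in SENSE_CODONS}


def count_codon_pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways; pathways passing
    through a stop codon are excluded (if all are blocked, every pathway
    is used with steps through stops counted as nonsynonymous)."""
    diffs = [p for p in range(3) if ca[p] != cb[p]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = ca
        sd = nd = 0.0
        blocked = False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nd += 1.0
            elif translate_codon(cur) == translate_codon(nxt) and cur not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((blocked, sd, nd))
    open_paths = [(s, n) for b, s, n in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction; undefined (inf) at p >= 3/4."""
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln) -> tuple[float, float, float, float, float, float, float]:
    """Nei-Gojobori 1986 estimates on a codon alignment.

    Returns (dN, dS, omega, Sd, Nd, S_sites, N_sites). Saturation
    (p >= 3/4) yields inf for the corresponding distance; dS of zero
    with dN > 0 yields omega = inf.
    """
    sd = nd = 0.0
    s_sites = n_sites = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue
        s_a, s_b = _SYN_SITES[ca], _SYN_SITES[cb]
        s_sites += (s_a + s_b) / 2.0
        n_sites += 3.0 - (s_a + s_b) / 2.0
        dsd, dnd = count_codon_pair_differences(ca, cb)
        sd += dsd
        nd += dnd
    if s_sites == 0 or n_sites == 0:
        raise ValueError("degenerate alignment: no countable sites")
    p_s = sd / s_sites
    p_n = nd / n_sites
    ds = jukes_cantor(p_s)
    dn = jukes_cantor(p_n)
    if ds == 0.0:
        omega = float("inf") if dn > 0 else float("nan")
    else:
        omega = dn / ds
    return dn, ds, omega, sd, nd, s_sites, n_sites


def _ng86_summary(codons_a: list[str], codons_b: list[str]) -> tuple[float, float, float, str]:
    class _A:  # lightweight view for ng86
        pass

    a = _A()
    a.codons_a, a.codons_b = codons_a, codons_b
    try:
        dn, ds, omega, *_ = ng86(a)
    except ValueError:
        return float("nan"), float("nan"), float("nan"), "ok"
    status = "ok"
    if math.isinf(ds):
        status = "ds_saturated"
    elif math.isinf(dn):
        status = "dn_saturated"
    return dn, ds, omega, status


# ---------------------------------------------------------------------------
# Paper filters


def apply_filters(
    estimates: list[RateEstimate], cfg: DndsConfig | None = None
) -> tuple[list[RateEstimate], list[tuple[RateEstimate, str]]]:
    """Exclude unreliable pairs: dN > 1, dS > 1, and omega-sentinel (99)
    estimates; every exclusion carries its reason(s)."""
    cfg = cfg or DndsConfig()
    kept: list[RateEstimate] = []
    excluded: list[tuple[RateEstimate, str]] = []
    for est in estimates:
        reasons = []
        if est.dS > cfg.max_ds:
            reasons.append("ds_gt_1")
        if est.dN > cfg.max_dn:
            reasons.append("dn_gt_1")
        if est.status == "omega_sentinel" or est.omega_hat >= OMEGA_SENTINEL:
            reasons.append("omega_sentinel")
        if reasons:
            excluded.append((est, ",".join(reasons)))
        else:
            kept.append(est)
    return kept, excluded
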