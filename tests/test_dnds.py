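"""GY94 M0 machinery and NG86 counting.

NG86 is checked against an independent pathway-enumeration oracle over
all 61x61 sense-codon pairs; the ML estimator is checked for parameter
recovery on data simulated under its own model and for exact agreement
of dN/dS with the fitted omega (mutational-opportunity convention).
"""

import itertools
import math

import numpy as np
import pytest

from coralscreen.codon_align import CodonAlignment
from coralscreen.codons import CODON_INDEX, SENSE_CODONS, STOP_CODONS, CODON_TABLE
from coralscreen.dnds import (
    N_CODONS,
    apply_filters,
    build_Q,
    count_codon_pair_differences,
    equal_frequencies,
    fit_m0,
    jukes_cantor,
    ng86,
    pair_codon_counts,
    transition_matrix,
    RateEstimate,
)
from coralscreen.io_core import DndsConfig
from coralscreen.synthetic import GeneTruth, default_codon_frequencies, simulate_codon_pair


def _aln(seq_a: str, seq_b: str) -> CodonAlignment:
    split = lambda s: [s[i : i + 3] for i in range(0, len(s), 3)]
    return CodonAlignment(split(seq_a), split(seq_b))


class TestBuildQ:
    def test_synonymous_transition_rate_unscaled(self):
        pi = equal_frequencies()
        m = build_Q(2.0, 0.5, pi, scale=False)
        i, j = CODON_INDEX["TTT"], CODON_INDEX["TTC"]
        assert m.Q[i, j] == pytest.approx(2.0 / 61)  # kappa * pi_j, synonymous
        # nonsynonymous transversion TTT->TTA (F->L): omega * pi_j
        assert m.Q[i, CODON_INDEX["TTA"]] == pytest.approx(0.5 / 61)
        # multi-position change has rate zero
        assert m.Q[i, CODON_INDEX["AAA"]] == 0.0

    def test_omega_zero_kills_nonsynonymous_rates(self):
        pi = equal_frequencies()
        m = build_Q(2.0, 0.0, pi)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i != j and CODON_TABLE[ci] != CODON_TABLE[cj]:
                    assert m.Q[i, j] == 0.0

    def test_rows_sum_to_zero_and_reversibility(self):
        pi = default_codon_frequencies()
        m = build_Q(3.0, 0.7, pi)
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-12
        flux = pi[:, None] * m.Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_zero_frequency_rejected(self):
        pi = equal_frequencies()
        pi[0] = 0.0
        pi[1] += 1.0 / 61
        with pytest.raises(ValueError, match="positive"):
            build_Q(2.0, 0.5, pi)


class TestTransitionMatrix:
    def test_identity_at_t_zero(self):
        m = build_Q(2.0, 0.5, default_codon_frequencies())
        assert np.abs(transition_matrix(m, 0.0) - np.eye(N_CODONS)).max() < 1e-12

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_row_stochastic(self, t):
        m = build_Q(2.0, 0.5, default_codon_frequencies())
        P = transition_matrix(m, t)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_semigroup_property(self):
        m = build_Q(2.0, 0.5, default_codon_frequencies())
        P1, P2, P3 = (transition_matrix(m, t) for t in (0.3, 0.5, 0.8))
        assert np.abs(P1 @ P2 - P3).max() < 1e-8

    def test_rows_approach_stationary_distribution(self):
        pi = default_codon_frequencies()
        m = build_Q(2.0, 0.5, pi)
        P = transition_matrix(m, 500.0)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_negative_time_rejected(self):
        m = build_Q(2.0, 0.5, default_codon_frequencies())
        with pytest.raises(ValueError):
            transition_matrix(m, -0.1)


# ---------------------------------------------------------------------------
# NG86


def oracle_codon_pair(ca: str, cb: str):
    """Independent pathway enumeration: average syn/nonsyn steps over
    all orders of the differing positions, stop-free pathways only."""
    diffs = [p for p in range(3) if ca[p] != cb[p]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, through_stop = ca, 0, 0, False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                nd += 1
            elif CODON_TABLE.get(cur) == CODON_TABLE.get(nxt) and cur not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((through_stop, sd, nd))
    valid = [(s, n) for blocked, s, n in results if not blocked] or [
        (s, n) for _, s, n in results
    ]
    return (sum(s for s, _ in valid) / len(valid), sum(n for _, n in valid) / len(valid))


class TestNg86:
    def test_identical_sequences_have_zero_distances(self):
        aln = _aln("TTTAAAGGG", "TTTAAAGGG")
        dn, ds, omega, sd, nd, *_ = ng86(aln)
        assert (dn, ds, sd, nd) == (0.0, 0.0, 0.0, 0.0)
        assert math.isnan(omega)

    def test_hand_counted_synonymous_example(self):
        # TTT->TTC is synonymous; S sites = 1/3 + 1/3 + 1 = 5/3, pS = 0.6
        aln = _aln("TTTAAAGGG", "TTCAAAGGG")
        dn, ds, omega, sd, nd, s_sites, n_sites = ng86(aln)
        assert sd == 1.0 and nd == 0.0
        assert s_sites == pytest.approx(5.0 / 3.0)
        assert ds == pytest.approx(jukes_cantor(0.6))
        assert dn == 0.0

    def test_pathway_counts_match_oracle_on_all_codon_pairs(self):
        for ca in SENSE_CODONS:
            for cb in SENSE_CODONS:
                assert count_codon_pair_differences(ca, cb) == pytest.approx(
                    oracle_codon_pair(ca, cb)
                ), (ca, cb)

    def test_saturation_flagged_as_infinite(self):
        assert math.isinf(jukes_cantor(0.8))

    def test_concordance_with_m0_at_low_divergence(self):
        # equal frequencies and kappa=1 are NG86's implicit assumptions
        pi = equal_frequencies()
        deltas = []
        for i in range(7):
            g = GeneTruth(
                f"g{i}", omega_true=0.4, kappa_true=1.0, t_true=0.08,
                n_codons=1500, is_trg=False,
            )
            a, b, _ = simulate_codon_pair(g, pi, seed=400 + i)
            aln = _aln(a, b)
            est = fit_m0(aln, DndsConfig(freq_model="equal"))
            deltas.append(abs(est.omega_ng - est.omega_hat))
        assert np.median(deltas) <= 0.1


# ---------------------------------------------------------------------------
# M0 fit


class TestFitM0:
    def test_parameter_recovery_single_long_pair(self):
        pi = default_codon_frequencies()
        g = GeneTruth("g0", omega_true=0.5, kappa_true=2.0, t_true=0.2, n_codons=3000, is_trg=False)
        a, b, _ = simulate_codon_pair(g, pi, seed=7)
        est = fit_m0(_aln(a, b))
        assert est.t_hat == pytest.approx(0.2, rel=0.15)
        assert est.omega_hat == pytest.approx(0.5, rel=0.20)
        assert est.status == "ok"

    def test_dn_ds_ratio_equals_fitted_omega(self):
        pi = default_codon_frequencies()
        for i, om in enumerate((0.2, 0.8, 1.5)):
            g = GeneTruth("g0", omega_true=om, kappa_true=2.0, t_true=0.15, n_codons=500, is_trg=False)
            a, b, _ = simulate_codon_pair(g, pi, seed=50 + i)
            est = fit_m0(_aln(a, b))
            if est.status == "ok":
                assert est.dN / est.dS == pytest.approx(est.omega_hat, abs=1e-6)

    def test_identical_sequences_yield_sentinel(self):
        seq = "ATGAAACCCGGGTTTCTG" * 10
        est = fit_m0(_aln(seq, seq))
        assert est.status == "omega_sentinel"
        assert est.t_hat == pytest.approx(1e-6)
        assert est.dS == 0.0 and est.dN == 0.0
        assert est.omega_hat == 99.0

    def test_optimum_beats_perturbed_t(self):
        pi = default_codon_frequencies()
        g = GeneTruth("g0", omega_true=0.5, kappa_true=2.0, t_true=0.2, n_codons=800, is_trg=False)
        a, b, _ = simulate_codon_pair(g, pi, seed=9)
        aln = _aln(a, b)
        est = fit_m0(aln)
        from coralscreen.dnds import alignment_frequencies, log_likelihood

        pi_fit = alignment_frequencies(aln.codons_a, aln.codons_b, "F3x4")
        model = build_Q(est.kappa_hat, est.omega_hat, pi_fit)
        for factor in (0.9, 1.1):
            assert log_likelihood(
                pair_codon_counts(aln.codons_a, aln.codons_b), model, est.t_hat * factor
            ) <= est.lnL + 1e-9

    def test_estimator_bias_shrinks_with_length(self):
        pi = default_codon_frequencies()
        biases = []
        for n_codons, n_rep in ((500, 6), (5000, 6)):
            errs = []
            for i in range(n_rep):
                g = GeneTruth(
                    "g0", omega_true=0.5, kappa_true=2.0, t_true=0.2,
                    n_codons=n_codons, is_trg=False,
                )
                a, b, _ = simulate_codon_pair(g, pi, seed=1000 * n_codons + i)
                errs.append(fit_m0(_aln(a, b)).omega_hat - 0.5)
            biases.append(abs(np.mean(errs)))
        assert biases[1] <= biases[0] + 0.02


class TestFilters:
    def _est(self, dn, ds, omega=0.5, status="ok"):
        return RateEstimate(
            t_hat=0.1, kappa_hat=2.0, omega_hat=omega, dN=dn, dS=ds, lnL=-10.0,
            dN_ng=dn, dS_ng=ds, omega_ng=omega, n_sites=100, status=status,
        )

    def test_ds_above_one_excluded(self):
        kept, excluded = apply_filters([self._est(0.2, 1.3)])
        assert not kept and excluded[0][1] == "ds_gt_1"

    def test_dn_above_one_excluded(self):
        kept, excluded = apply_filters([self._est(1.2, 0.3)])
        assert not kept and "dn_gt_1" in excluded[0][1]

    def test_omega_sentinel_excluded(self):
        kept, excluded = apply_filters([self._est(0.0, 0.0, omega=99.0, status="omega_sentinel")])
        assert not kept and "omega_sentinel" in excluded[0][1]

    def test_typical_pair_kept(self):
        kept, excluded = apply_filters([self._est(0.0091, 0.0426)])
        assert len(kept) == 1 and not excluded
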