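"""MethScore / PsiScore formulas, replicate handling and group comparison."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snoridr import (
    classify_highly_modified,
    compare_conditions,
    meth_score,
    norm_u_count,
    psi_score,
    score_sites,
)
from snoridr.end_profiles import CleavageProfile, EndCountProfile


def bonds_from(values):
    c = np.concatenate([[0], np.asarray(values)])
    return CleavageProfile("r", c)


def profile5(counts):
    n5 = np.concatenate([[0], np.asarray(counts)])
    return EndCountProfile("r", n5, np.zeros_like(n5))


class TestMethScore:
    @pytest.mark.parametrize(
        "window,expected",
        [((10, 10, 0, 10, 10), 1.0), ((10, 10, 10, 10, 10), 0.0), ((10, 10, 5, 10, 10), 0.5)],
    )
    def test_worked_examples(self, window, expected):
        res = meth_score(bonds_from(window), position=3)
        assert res.score == pytest.approx(expected)
        assert res.mu == pytest.approx(10.0)

    def test_clamped_to_unit_interval(self):
        res = meth_score(bonds_from((1, 1, 50, 1, 1)), position=3)
        assert res.score == 0.0

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            meth_score(bonds_from((1, 2, 3)), position=9)

    def test_window_out_of_bounds_is_na(self):
        res = meth_score(bonds_from((10, 10, 10, 10, 10)), position=1)
        assert math.isnan(res.score) and res.reason == "window_out_of_bounds"

    def test_zero_neighbor_mean_is_na(self):
        res = meth_score(bonds_from((0, 0, 5, 0, 0)), position=3)
        assert math.isnan(res.score) and res.reason == "zero_neighbor_mean"

    @given(scale=st.integers(min_value=1, max_value=1000))
    def test_invariant_to_global_scaling(self, scale):
        base = np.array([8, 12, 3, 9, 11])
        s1 = meth_score(bonds_from(base), 3).score
        s2 = meth_score(bonds_from(base * scale), 3).score
        assert s1 == pytest.approx(s2)

    def test_weighted_variant_close_to_plain(self):
        res_p = meth_score(bonds_from((8, 12, 3, 9, 11)), 3)
        res_w = meth_score(bonds_from((8, 12, 3, 9, 11)), 3, weighted=True)
        assert res_w.score == pytest.approx(res_p.score, abs=0.05)


class TestNormUCount:
    def test_worked_example(self):
        # U at position 6 of an 11-nt window sequence, count 20 over flat
        # A/C/G background of 2
        seq = "ACGACUGCAGC"
        counts = [2] * 11
        counts[5] = 20
        table = norm_u_count(profile5(counts), seq)
        assert table.set_index("position").loc[6, "norm_u"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        seq = "ACGACUGCAGC"
        counts = [2] * 11
        counts[5] = 0
        table = norm_u_count(profile5(counts), seq)
        assert table.set_index("position").loc[6, "norm_u"] == 0.0

    def test_poly_u_window_is_na(self):
        seq = "U" * 41 + "ACGACG"
        table = norm_u_count(profile5([1] * len(seq)), seq).set_index("position")
        assert math.isnan(table.loc[20, "norm_u"])
        assert table.loc[20, "reason"] == "no_background"

    def test_window_expansion_recovers_sparse_background(self):
        # only 2 non-U inside the 10-nt window, 3rd within the 2x cap
        seq = "UUUUUAUUUUCUUUUUUUGUUUUU"
        counts = [1] * len(seq)
        table = norm_u_count(profile5(counts), seq).set_index("position")
        assert table.loc[12, "norm_u"] == pytest.approx(1.0)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError, match="even"):
            norm_u_count(profile5([1] * 20), "ACGU" * 5, window=7)


class TestPsiScore:
    def make_table(self, values):
        return pd.DataFrame({"position": range(1, len(values) + 1),
                             "raw": values, "norm_u": values, "reason": [None] * len(values)})

    def test_baseline_identity_scores_zero(self):
        table = self.make_table([5.0] * 12)
        out = psi_score(table)
        assert (out["score"] == 0.0).all()

    def test_zero_norm_u_scores_one(self):
        table = self.make_table([5.0] * 12 + [0.0])
        out = psi_score(table)
        assert out["score"].iloc[-1] == 1.0

    def test_too_few_uridines_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            psi_score(self.make_table([1.0] * 5))

    def test_invariant_to_global_scaling(self):
        vals = [4.0, 5.0, 6.0, 5.5, 4.5, 5.2, 4.8, 5.1, 4.9, 5.0, 2.0, 0.5]
        a = psi_score(self.make_table(vals))["score"]
        b = psi_score(self.make_table([v * 7 for v in vals]))["score"]
        assert np.allclose(a, b, equal_nan=True)


class TestScoreSites:
    SITES = pd.DataFrame({"position": [10, 20], "mod_type": ["Nm", "Nm"], "true_fraction": [0.9, 0.2]})

    def test_identical_replicates_mean_is_value(self):
        rep = pd.Series({10: 0.8, 20: 0.3})
        out = score_sites(self.SITES, {"WT": [rep, rep, rep]}, "Nm")
        assert out["score"].tolist() == pytest.approx([0.8, 0.3])
        assert (out["n_replicates"] == 3).all()

    def test_na_replicate_dropped_and_flagged(self):
        reps = [pd.Series({10: 0.8, 20: 0.3}), pd.Series({10: 0.6, 20: math.nan})]
        out = score_sites(self.SITES, {"WT": reps}, "Nm").set_index("position")
        assert out.loc[20, "score"] == pytest.approx(0.3)
        assert out.loc[20, "n_replicates"] == 1
        assert bool(out.loc[20, "incomplete"])

    def test_unknown_mod_type_rejected(self):
        with pytest.raises(ValueError, match="mod_type"):
            score_sites(self.SITES, {}, "m6A")


class TestHighlyModified:
    def test_strict_threshold(self):
        assert classify_highly_modified(0.81) == True  # noqa: E712
        assert classify_highly_modified(0.8) == False  # noqa: E712

    def test_na_propagates(self):
        assert classify_highly_modified(math.nan) is pd.NA

    def test_vectorized(self):
        out = classify_highly_modified(np.array([0.9, 0.5, math.nan]))
        assert out.tolist()[:2] == [True, False]
        assert out.isna().iloc[2]


def exact_rank_sum_p(x, y):
    """Independent oracle: full enumeration of the rank-sum null."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array([ranks[list(comb)].sum() - n * (n + 1) / 2
                   for comb in combinations(range(len(pooled)), n)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestCompareConditions:
    def test_identical_groups_not_significant(self):
        v = [0.1, 0.5, 0.9, 0.3, 0.7]
        res = compare_conditions(v, v)
        assert res.pvalue > 0.9
        assert res.stars == "ns"

    def test_total_separation_small_n_exact(self):
        a = [0.91, 0.92, 0.93, 0.94, 0.95]
        b = [0.11, 0.12, 0.13, 0.14, 0.15]
        res = compare_conditions(a, b)
        assert res.method == "exact"
        # complete separation: p = 2 / C(10, 5)
        assert res.pvalue == pytest.approx(2 / 252)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            n, m = rng.integers(3, 9, size=2)
            a, b = rng.normal(0, 1, n), rng.normal(0.8, 1, m)
            res = compare_conditions(a, b)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(exact_rank_sum_p(a, b))

    def test_na_scores_dropped(self):
        a = pd.Series([0.9, 0.8, math.nan, 0.7])
        b = pd.Series([0.2, 0.1, 0.3, 0.25])
        res = compare_conditions(a, b)
        assert res.n_dropped == 1
        assert res.summary_a.n == 3

    def test_box_summary_recomputable(self, rng):
        v = rng.uniform(0, 1, 40)
        res = compare_conditions(v, rng.uniform(0, 1, 40))
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert res.summary_a.median == pytest.approx(med)
        assert res.summary_a.q1 == pytest.approx(q1)
        assert res.summary_a.whisker_hi <= q3 + 1.5 * (q3 - q1)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_conditions([0.1, 0.2], [0.3, 0.4, 0.5])


class TestRecoveryInvariants:
    """Simulation-level properties of the score estimators."""

    @staticmethod
    def _mae_at_depth(depth):
        from snoridr import SimulationConfig, bond_profile, count_ends, gen_reference, gen_sites, simulate_rms

        cfg = SimulationConfig(seed=17, ref_length=1500, depth=depth, propensity_sd=0.0,
                               n_nm_sites=14, n_psi_sites=0)
        ref = gen_reference(cfg)
        sites = gen_sites(ref, cfg)
        aln, _ = simulate_rms(ref, sites, cfg)
        bonds = bond_profile(count_ends(aln, len(ref.seq)))
        errs = [abs(meth_score(bonds, int(p)).score - f)
                for p, f in zip(sites["position"], sites["true_fraction"])]
        return float(np.mean(errs))

    def test_error_decreases_monotonically_with_depth(self):
        maes = [self._mae_at_depth(d) for d in (100, 1000, 10000)]
        assert maes[0] > maes[1] > maes[2]

    def test_unmodified_positions_score_low_under_null(self):
        from snoridr import SimulationConfig, bond_profile, count_ends, gen_reference, gen_sites, simulate_rms

        cfg = SimulationConfig(seed=18, ref_length=1000, depth=500, propensity_sd=0.0,
                               n_nm_sites=0, n_psi_sites=0)
        ref = gen_reference(cfg)
        aln, _ = simulate_rms(ref, gen_sites(ref, cfg), cfg)
        bonds = bond_profile(count_ends(aln, len(ref.seq)))
        scores = [meth_score(bonds, p).score for p in range(50, 950, 7)]
        assert np.nanmean(scores) <= 0.1

    def test_psi_score_invariant_to_rate_rescaling(self):
        # deterministic count profile: scaling (u_rate, bg_rate) jointly
        # cancels in the NormUcount baseline normalization
        seq = ("ACGU" * 30)
        site_pos = 48 + 4  # a U position
        def scores(u_rate, bg_rate, f=0.6):
            counts = [u_rate if b == "U" else bg_rate for b in seq]
            counts[site_pos - 1] = u_rate * (1 - f)
            table = norm_u_count(profile5(counts), seq)
            return psi_score(table).set_index("position")["score"]

        a = scores(10.0, 1.0)
        b = scores(30.0, 3.0)
        assert np.allclose(a, b, equal_nan=True)
        assert a.loc[site_pos] == pytest.approx(0.6, abs=1e-9)
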