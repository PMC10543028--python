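"""Per-gene significance pipeline, enrichment, signatures and survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from slide2rx.transcriptome_eval import (
    hallmark_enrichment,
    holm_sidak,
    hr_concordance,
    per_gene_correlation,
    signature_score,
    significant_genes,
    subsample_significant_counts,
    survival_association,
)


def _frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


class TestPerGeneCorrelation:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(0)
        a = _frame(rng.normal(size=(5, 8)))
        out = per_gene_correlation(a, a)
        assert np.allclose(out["r"], 1.0)
        assert np.allclose(out["p"], 0.0)

    def test_negated_prediction_gives_r_minus_one(self):
        rng = np.random.default_rng(1)
        a = _frame(rng.normal(size=(3, 6)))
        out = per_gene_correlation(-a, a)
        assert np.allclose(out["r"], -1.0)

    def test_hand_computed_four_sample_case(self):
        pred = _frame([[1, 2, 3, 4]])
        actual = _frame([[1, 2, 4, 3]])
        out = per_gene_correlation(pred, actual)
        assert out["r"].iloc[0] == pytest.approx(0.8)
        # p from the t transform with n-2 = 2 dof, two-sided
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(t, 2))

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(2)
        pred = _frame(rng.normal(size=(10, 12)))
        actual = _frame(rng.normal(size=(10, 12)))
        out = per_gene_correlation(pred, actual)
        for i in range(10):
            r, p = stats.pearsonr(pred.iloc[i], actual.iloc[i])
            assert out["r"].iloc[i] == pytest.approx(r)
            assert out["p"].iloc[i] == pytest.approx(p)

    def test_zero_variance_gene_reported_missing(self):
        pred = _frame([[1, 1, 1, 1], [1, 2, 3, 4]])
        actual = _frame([[1, 2, 3, 4], [1, 2, 3, 4]])
        out = per_gene_correlation(pred, actual)
        assert np.isnan(out["r"].iloc[0]) and np.isnan(out["p"].iloc[0])
        assert out["r"].iloc[1] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        a = _frame(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="4"):
            per_gene_correlation(a, a)


def _holm_sidak_oracle(pvals, alpha=0.05):
    """Naive step-down: sort, adjust with 1-(1-p)^(m-j+1), running max."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, val)
        adj_sorted[i] = min(running, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    reject = np.zeros(m, bool)
    for i, idx in enumerate(order):
        if adj_sorted[i] < alpha:
            reject[idx] = True
        else:
            break
    return adj, reject


class TestHolmSidak:
    def test_two_pvalue_worked_example(self):
        out = holm_sidak([0.01, 0.04])
        assert out["p_adj"].iloc[0] == pytest.approx(1 - 0.99**2)
        assert out["p_adj"].iloc[1] == pytest.approx(0.04)
        assert out["reject"].all()

    def test_single_p_unchanged(self):
        out = holm_sidak([0.03])
        assert out["p_adj"].iloc[0] == pytest.approx(0.03)

    def test_all_ones_never_rejected(self):
        out = holm_sidak([1.0] * 5)
        assert not out["reject"].any()
        assert (out["p_adj"] == 1.0).all()

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        out = holm_sidak(p)
        assert (out["p_adj"].to_numpy() >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=20)
    )
    def test_matches_naive_step_down_oracle(self, pvals):
        out = holm_sidak(pvals)
        adj, reject = _holm_sidak_oracle(pvals)
        assert np.allclose(out["p_adj"].to_numpy(), adj, atol=1e-10)
        assert np.array_equal(out["reject"].to_numpy(), reject)


class TestSignificancePipeline:
    def test_null_predictions_control_family_error(self):
        # independent pred/actual: the fraction of genes ever declared
        # significant stays at or below alpha in expectation
        declared = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pred = _frame(rng.normal(size=(100, 20)))
            actual = _frame(rng.normal(size=(100, 20)))
            declared.append(significant_genes(pred, actual).n_significant / 100)
        assert np.mean(declared) <= 0.05

    def test_constant_genes_excluded_from_correction(self):
        rng = np.random.default_rng(4)
        pred = _frame(np.vstack([np.ones((1, 10)), rng.normal(size=(4, 10))]))
        actual = _frame(rng.normal(size=(5, 10)))
        rep = significant_genes(pred, actual)
        assert np.isnan(rep.table["p_adj"].iloc[0])
        assert not rep.table["significant"].iloc[0]


class TestSubsampling:
    def test_full_cohort_subsets_have_zero_sem(self):
        rng = np.random.default_rng(5)
        actual = _frame(rng.normal(size=(20, 12)))
        pred = actual + 0.1 * _frame(rng.normal(size=(20, 12)))
        out = subsample_significant_counts(pred, actual, subset_size=12, reps=5, seed=0)
        assert out["sem"] == 0.0
        assert len(set(out["counts"])) == 1

    def test_single_rep_sem_missing(self):
        rng = np.random.default_rng(6)
        a = _frame(rng.normal(size=(5, 10)))
        out = subsample_significant_counts(a, a, subset_size=8, reps=1, seed=0)
        assert np.isnan(out["sem"])

    def test_cohort_smaller_than_subset_rejected(self):
        a = _frame(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="200"):
            subsample_significant_counts(a, a, subset_size=200)

    def test_recovers_planted_gene_count(self):
        # 30 planted genes at high SNR among 100: subset counts near 30
        rng = np.random.default_rng(7)
        actual = rng.normal(size=(100, 250))
        pred = rng.normal(size=(100, 250))
        pred[:30] = actual[:30] + 0.45 * rng.normal(size=(30, 250))
        out = subsample_significant_counts(
            _frame(pred), _frame(actual), subset_size=200, reps=5, seed=1
        )
        assert abs(out["mean"] - 30) <= 10


class TestEnrichment:
    def test_disjoint_set_has_p_one(self):
        out = hallmark_enrichment(
            ["g1", "g2"], {"set": ["g8", "g9"]}, [f"g{i}" for i in range(10)]
        )
        assert out.loc["set", "p"] == pytest.approx(1.0)

    def test_degenerate_whole_background_set_flagged(self):
        bg = ["g0", "g1", "g2"]
        out = hallmark_enrichment(bg, {"all": bg}, bg)
        assert out.loc["all", "degenerate"]
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_hypergeometric_tail_by_enumeration(self):
        # background 20, hallmark 5, significant 10, overlap 5
        from math import comb

        bg = [f"g{i}" for i in range(20)]
        hall = bg[:5]
        sig = bg[:5] + bg[10:15]
        out = hallmark_enrichment(sig, {"h": hall}, bg)
        p_exact = sum(
            comb(5, k) * comb(15, 10 - k) for k in range(5, 6)
        ) / comb(20, 10)
        assert out.loc["h", "p"] == pytest.approx(p_exact)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hallmark_enrichment(["g1"], {"s": ["g1"]}, [])


class TestSignatureScore:
    def test_hand_ranked_toy_table(self):
        # two genes over three patients with ranks (1,2,3) and (3,1,2)
        expr = _frame([[1.0, 2.0, 3.0], [30.0, 10.0, 20.0]])
        s = signature_score(expr, ["g0", "g1"])
        assert np.allclose(s.to_numpy(), [0.5, 0.25, 0.75])

    def test_top_patient_scores_one(self):
        expr = _frame([[1, 5, 3], [2, 9, 4]])
        s = signature_score(expr, ["g0", "g1"])
        assert s["s1"] == pytest.approx(1.0)

    def test_single_gene_signature_is_normalized_rank(self):
        expr = _frame([[4.0, 1.0, 2.0, 3.0]])
        s = signature_score(expr, ["g0"])
        assert np.allclose(s.to_numpy(), [1.0, 0.0, 1 / 3, 2 / 3])

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        expr = _frame(rng.normal(size=(4, 7)))
        s1 = signature_score(expr, ["g0", "g2"])
        s2 = signature_score(np.exp(expr * 2.0), ["g0", "g2"])
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_missing_signature_rejected(self):
        expr = _frame(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="absent|present"):
            signature_score(expr, ["nope"])


def _simulate_survival(scores, beta, seed, censor=0.3, index=None):
    rng = np.random.default_rng(seed)
    hazard = np.exp(beta * scores)
    times = rng.exponential(1.0 / hazard) * 365
    event = rng.random(len(scores)) >= censor
    return pd.DataFrame(
        {"time": np.maximum(times, 0.5), "event": event.astype(int)},
        index=index if index is not None else [f"p{i}" for i in range(len(scores))],
    )


class TestSurvival:
    def test_null_scores_give_small_z_most_of_the_time(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            scores = pd.Series(rng.random(80), index=[f"p{i}" for i in range(80)])
            surv = _simulate_survival(np.zeros(80), 0.0, seed)
            out = survival_association(scores, surv)
            hits += abs(out["z"]) < 2
        assert hits >= 9

    def test_recovers_planted_log_hazard_ratio(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.normal(size=500), index=[f"p{i}" for i in range(500)])
        surv = _simulate_survival(scores.to_numpy(), 1.0, 9)
        out = survival_association(scores, surv)
        assert out["log_hr"] == pytest.approx(1.0, abs=0.2)

    def test_covariate_scaling_identity(self):
        rng = np.random.default_rng(10)
        scores = pd.Series(rng.normal(size=120), index=[f"p{i}" for i in range(120)])
        surv = _simulate_survival(scores.to_numpy(), 0.8, 10)
        b1 = survival_association(scores, surv)["log_hr"]
        b2 = survival_association(scores * 4.0, surv)["log_hr"]
        assert b2 == pytest.approx(b1 / 4.0, rel=1e-3)

    def test_no_events_rejected(self):
        scores = pd.Series(np.arange(12.0), index=[f"p{i}" for i in range(12)])
        surv = pd.DataFrame(
            {"time": np.ones(12), "event": np.zeros(12, int)}, index=scores.index
        )
        with pytest.raises(ValueError, match="events"):
            survival_association(scores, surv)


class TestHRConcordance:
    def _cohorts(self, flip=False):
        actual, predicted, surv = {}, {}, {}
        for c, beta in zip("abcd", [0.5, 1.0, -0.5, 1.5]):
            rng = np.random.default_rng(ord(c))
            s = pd.Series(rng.normal(size=150), index=[f"{c}{i}" for i in range(150)])
            actual[c] = s
            predicted[c] = -s if flip else s + 0.05 * rng.normal(size=150)
            surv[c] = _simulate_survival(s.to_numpy(), beta, ord(c), index=s.index)
        return actual, predicted, surv

    def test_identical_scores_give_correlation_one(self):
        actual, _, surv = self._cohorts()
        assert hr_concordance(actual, actual, surv) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        actual, predicted, surv = self._cohorts(flip=True)
        assert hr_concordance(actual, predicted, surv) == pytest.approx(-1.0, abs=1e-6)

    def test_too_few_cohorts_rejected(self):
        actual, predicted, surv = self._cohorts()
        with pytest.raises(ValueError, match="3 cohorts"):
            hr_concordance(
                {"a": actual["a"]}, {"a": predicted["a"]}, {"a": surv["a"]}
            )
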