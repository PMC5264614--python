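"""epiQTL association, marker filtering, linkage and the KW scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afsmqtl import (
    FULL_CMCGG,
    FULL_MCCGG,
    HEMI,
    NO_CALL,
    UNMETHYLATED,
    MarkerRecord,
    RunConfig,
    associate,
    classify_and_filter_markers,
    kruskal_marker,
    pairwise_linkage,
    scan_qtl_epi,
    score_methylation,
    segregation_test,
)


class TestScoring:
    def test_state_to_score_mapping(self):
        got = score_methylation([FULL_MCCGG, FULL_CMCGG, HEMI, UNMETHYLATED, NO_CALL])
        np.testing.assert_array_equal(got[:4], [1.0, 1.0, 2 / 3, 0.0])
        assert np.isnan(got[4])

    def test_scale_invariance_of_r(self, rng):
        # any a > 0 in the {a, 2a/3, 0} scale yields the same correlation
        states = rng.choice([FULL_MCCGG, HEMI, UNMETHYLATED], size=50)
        scores = score_methylation(list(states))
        trait = rng.normal(size=50)
        base = associate(scores, trait)
        scaled = associate(7.3 * scores, trait)
        assert scaled.r == pytest.approx(base.r)
        assert scaled.p == pytest.approx(base.p)


class TestAssociate:
    def test_perfect_collinearity(self):
        x = np.tile([0.0, 2 / 3, 1.0], 10)
        res = associate(x, 2.0 * x + 1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-100 and res.significant

    def test_overlap_below_twenty_non_evaluable(self, rng):
        x = np.concatenate([rng.random(19), np.full(10, np.nan)])
        y = np.concatenate([rng.random(19), rng.random(10)])
        y[:0] = np.nan
        res = associate(x, y)
        assert res.n_overlap == 19 and not res.significant
        assert "overlap" in res.reason

    def test_zero_variance_non_evaluable(self):
        res = associate(np.ones(30), np.arange(30.0))
        assert res.reason == "zero variance" and not res.significant

    def test_matches_textbook_pearson_t_test(self, rng):
        """(r, t, p) agree with scipy.stats.pearsonr and the closed-form t."""
        for _ in range(20):
            n = int(rng.integers(20, 60))
            x = rng.choice([0.0, 2 / 3, 1.0], size=n)
            y = rng.normal(size=n)
            res = associate(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            t_ref = r_ref * math.sqrt((n - 2) / (1 - r_ref**2))
            assert res.r == pytest.approx(r_ref)
            assert res.t == pytest.approx(t_ref)
            assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_sign_symmetry(self, rng):
        x = rng.choice([0.0, 2 / 3, 1.0], size=40)
        y = rng.normal(size=40)
        pos = associate(x, y)
        neg = associate(x, -y)
        assert neg.r == pytest.approx(-pos.r)
        assert neg.p == pytest.approx(pos.p)

    def test_missing_entries_pairwise_complete(self, rng):
        x = rng.choice([0.0, 1.0], size=40)
        y = rng.normal(size=40)
        x[5], y[7] = np.nan, np.nan
        res = associate(x, y)
        mask = ~(np.isnan(x) | np.isnan(y))
        r_ref, _ = stats.pearsonr(x[mask], y[mask])
        assert res.n_overlap == int(mask.sum())
        assert res.r == pytest.approx(r_ref)


def scores_frame(X, samples=None):
    samples = samples or [f"F{i}" for i in range(X.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [("s", i) for i in range(X.shape[0])], names=["scaffold", "position"]
    )
    return pd.DataFrame(X, index=idx, columns=samples)


class TestScanQtlEpi:
    def test_planted_effect_recovered_as_top_hit(self, rng):
        X = rng.choice([0.0, 2 / 3, 1.0], size=(200, 186))
        y = 2.0 * X[0] + rng.normal(0, 0.5, 186)
        scores = scores_frame(X)
        traits = pd.DataFrame({"CTIG": y}, index=scores.columns)
        out = scan_qtl_epi(scores, traits)
        best = out.loc[out["p"].idxmin()]
        assert best["site"] == "s:0" and best["significant"]

    def test_all_missing_site_yields_no_rows(self, rng):
        X = rng.choice([0.0, 1.0], size=(3, 30))
        X[1] = np.nan
        scores = scores_frame(X)
        traits = pd.DataFrame({"T": rng.normal(size=30)}, index=scores.columns)
        out = scan_qtl_epi(scores, traits)
        assert "s:1" not in set(out["site"])

    def test_repeatable_requires_two_trials_of_a_family(self, rng):
        X = rng.choice([0.0, 2 / 3, 1.0], size=(50, 186))
        noise = rng.normal(0, 0.4, size=(3, 186))
        traits = pd.DataFrame(
            {
                "CTIF1": 2.0 * X[0] + noise[0],
                "CTIF2": 2.0 * X[0] + noise[1],
                "SRY1": 2.0 * X[1] + noise[2],
            },
            index=[f"F{i}" for i in range(186)],
        )
        out = scan_qtl_epi(scores_frame(X), traits)
        by = out.set_index(["site", "trait_code"])
        assert by.loc[("s:0", "CTIF1"), "repeatable"]
        assert by.loc[("s:0", "CTIF2"), "repeatable"]
        # significant in one trial of one family only -> not repeatable
        assert not by.loc[("s:1", "SRY1"), "repeatable"]


def marker(progeny, in_female=True, in_male=False, support=5, mid="m"):
    return MarkerRecord(mid, in_female, in_male, np.asarray(progeny, dtype=float),
                        support)


class TestMarkerFiltering:
    def test_perfect_one_to_one_retained(self):
        m = marker([1.0] * 93 + [0.0] * 93)
        kept, _ = classify_and_filter_markers([m])
        assert len(kept) == 1
        assert kept.iloc[0]["marker_type"] == "lm_ll"
        assert kept.iloc[0]["seg_chi2"] == pytest.approx(0.0)

    def test_low_call_rate_removed(self):
        calls = [1.0] * 46 + [0.0] * 45 + [np.nan] * 95  # 49% called
        _, dropped = classify_and_filter_markers([marker(calls)])
        assert dropped.iloc[0]["reason"] == "call rate"

    def test_distorted_segregation_removed(self):
        m = marker([1.0] * 150 + [0.0] * 36)
        chi2_ref, p_ref = stats.chisquare([150, 36], [93, 93])
        assert p_ref < 0.01
        kept, dropped = classify_and_filter_markers([m])
        assert kept.empty
        assert dropped.iloc[0]["reason"] == "segregation distortion"
        assert dropped.iloc[0]["seg_p"] == pytest.approx(p_ref)

    def test_three_to_one_expectation_for_hk(self):
        m = marker([1.0] * 140 + [0.0] * 46, in_female=True, in_male=True)
        assert m.marker_type == "hk_hk"
        chi2, p = segregation_test(m)
        chi2_ref, p_ref = stats.chisquare([140, 46], [139.5, 46.5])
        assert chi2 == pytest.approx(chi2_ref) and p == pytest.approx(p_ref)
        kept, _ = classify_and_filter_markers([m])
        assert len(kept) == 1

    def test_progeny_only_marker_inconsistent(self):
        m = marker([1.0] * 93 + [0.0] * 93, in_female=False, in_male=False)
        _, dropped = classify_and_filter_markers([m])
        assert dropped.iloc[0]["reason"] == "absent in both parents"

    def test_single_read_marker_removed(self):
        m = marker([1.0] * 93 + [0.0] * 93, support=1)
        _, dropped = classify_and_filter_markers([m])
        assert dropped.iloc[0]["reason"] == "read support"


class TestPairwiseLinkage:
    def test_lod_zero_at_half_recombination(self):
        a = marker([1.0, 0.0] * 50, mid="a")
        b = marker([1.0, 1.0, 0.0, 0.0] * 25, mid="b")  # exactly 50% mismatch
        res = pairwise_linkage(a, b)
        assert res.rf == pytest.approx(0.5)
        assert res.lod == pytest.approx(0.0)

    def test_complete_cosegregation_closed_form(self):
        calls = [1.0, 0.0] * 50
        res = pairwise_linkage(marker(calls, mid="a"), marker(calls, mid="b"))
        assert res.rf == 0.0
        assert res.lod == pytest.approx(100 * math.log10(2))
        assert res.groupable

    def test_high_rf_not_groupable(self):
        a = marker([1.0] * 55 + [0.0] * 45, mid="a")
        b = marker([0.0] * 45 + [1.0] * 55, mid="b")  # 90 mismatches of 100
        res = pairwise_linkage(a, b)
        assert res.rf == 0.5 and not res.groupable

    def test_rf_point45_not_groupable(self):
        n = 100
        calls_a = np.array([1.0, 0.0] * 50)
        calls_b = calls_a.copy()
        calls_b[:45] = 1.0 - calls_b[:45]  # 45 recombinants
        res = pairwise_linkage(marker(calls_a, mid="a"), marker(calls_b, mid="b"))
        assert res.rf == pytest.approx(0.45)
        assert not res.groupable

    def test_lod_decreasing_in_rf(self):
        lods = []
        base = np.array([1.0, 0.0] * 50)
        for n_rec in (0, 10, 20, 30, 40, 50):
            other = base.copy()
            other[:n_rec] = 1.0 - other[:n_rec]
            lods.append(pairwise_linkage(marker(base, mid="a"),
                                         marker(other, mid="b")).lod)
        assert all(x > y for x, y in zip(lods, lods[1:]))

    def test_few_informative_progeny_non_evaluable(self):
        a = marker([1.0] * 5 + [np.nan] * 95, mid="a")
        b = marker([1.0] * 100, mid="b")
        res = pairwise_linkage(a, b)
        assert np.isnan(res.rf) and "informative" in res.reason

    def test_phase_type_mismatch_non_evaluable(self):
        a = marker([1.0, 0.0] * 50, mid="a")
        b = marker([1.0, 0.0] * 50, in_female=True, in_male=True, mid="b")
        assert "phase" in pairwise_linkage(a, b).reason


def brute_ranks(values):
    """Average ranks (1-based) computed by direct comparison."""
    v = list(values)
    ranks = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def brute_h(y, groups):
    """Tie-corrected Kruskal-Wallis H from first principles."""
    n = len(y)
    ranks = brute_ranks(y)
    h = 0.0
    for g in set(groups):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        rsum = sum(ranks[i] for i in idx)
        h += rsum**2 / len(idx)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for x in y:
        ties[x] = ties.get(x, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


class TestKruskalWallis:
    def test_identical_trait_values_give_null(self):
        h, p = kruskal_marker([1, 1, 0, 0, 1, 0], [3.0] * 6)
        assert h == 0.0 and p == 1.0

    def test_single_genotype_class_non_evaluable(self):
        h, p = kruskal_marker([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(h) and np.isnan(p)

    def test_h_matches_first_principles(self, rng):
        for _ in range(20):
            g = rng.integers(0, 2, size=12).astype(float)
            if len(set(g)) < 2 or min((g == 0).sum(), (g == 1).sum()) < 2:
                continue
            y = rng.choice([1.0, 2.0, 3.0, 5.0], size=12)
            if np.ptp(y) == 0:
                continue
            h, _ = kruskal_marker(g, y)
            assert h == pytest.approx(brute_h(list(y), list(g)))

    def test_two_group_case_equals_rank_sum_permutation(self, rng):
        """H-based and rank-sum-based exact permutation tests coincide (n <= 8)."""
        for _ in range(5):
            n1, n2 = 4, 4
            y = rng.choice([1.0, 2.0, 3.0, 4.0, 6.0], size=n1 + n2)
            if np.ptp(y) == 0:
                continue
            labels = [0] * n1 + [1] * n2
            h_obs = brute_h(list(y), labels)
            ranks = brute_ranks(y)
            w_obs = sum(ranks[:n1])
            e_w = n1 * (n1 + n2 + 1) / 2.0
            n = n1 + n2
            h_count = w_count = total = 0
            for subset in itertools.combinations(range(n), n1):
                perm_labels = [0 if i in subset else 1 for i in range(n)]
                h_perm = brute_h(list(y), perm_labels)
                w_perm = sum(ranks[i] for i in subset)
                h_count += h_perm >= h_obs - 1e-12
                w_count += abs(w_perm - e_w) >= abs(w_obs - e_w) - 1e-12
                total += 1
            assert h_count == w_count  # identical exact tests
            # and the implementation's H agrees with the brute-force H
            h_impl, _ = kruskal_marker([float(l) for l in labels], y)
            assert h_impl == pytest.approx(h_obs)
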