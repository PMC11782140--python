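"""Residualization, Mann-Whitney testing and Bonferroni correction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resteeg.exceptions import DataError
from resteeg.io import FeatureTable, SubjectMeta
from resteeg.stats import (
    bonferroni_adjust,
    build_ec_minus_eo,
    group_difference_report,
    mann_whitney_u,
    residualize,
)


def make_metas(n_ad, n_hc, seed=0):
    rng = np.random.default_rng(seed)
    metas = []
    for i in range(n_ad):
        metas.append(SubjectMeta(f"AD{i:02d}", "AD", float(rng.uniform(55, 85)),
                                 "F" if rng.random() < 0.5 else "M",
                                 int(rng.integers(1, 6)), "R"))
    for i in range(n_hc):
        metas.append(SubjectMeta(f"HC{i:02d}", "HC", float(rng.uniform(55, 85)),
                                 "F" if rng.random() < 0.5 else "M",
                                 int(rng.integers(1, 6)), "R"))
    return metas


def table_from(metas, values: dict):
    index = pd.Index([m.subject_id for m in metas], name="subject_id")
    return FeatureTable(pd.DataFrame(values, index=index))


class TestResidualize:
    def test_feature_linear_in_age_residualizes_to_zero(self):
        metas = make_metas(5, 5)
        ages = np.array([m.age for m in metas])
        table = table_from(metas, {"relpower_alpha_O1_EC": 2 * ages + 1})
        resid = residualize(table, metas)
        np.testing.assert_allclose(resid.df.to_numpy(), 0.0, atol=1e-9)

    def test_constant_covariates_reduce_to_demeaning(self):
        metas = [SubjectMeta(f"s{i}", "AD" if i < 3 else "HC", 70.0, "M", 3, "R")
                 for i in range(6)]
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        table = table_from(metas, {"tbr_thetabeta_F3_EC": vals})
        with pytest.warns(UserWarning, match="collinear"):
            resid = residualize(table, metas)
        np.testing.assert_allclose(
            resid.df.to_numpy().ravel(), vals - vals.mean(), atol=1e-9
        )

    def test_matches_normal_equations_oracle(self):
        metas = make_metas(8, 8, seed=3)
        rng = np.random.default_rng(4)
        y = rng.standard_normal((16, 3))
        table = table_from(metas, {f"relpower_alpha_O{i+1}_EC": y[:, i] for i in range(2)}
                           | {"tbr_thetabeta_F3_EC": y[:, 2]})
        resid = residualize(table, metas)
        # independent oracle: closed-form normal equations
        x = np.column_stack([
            np.ones(16),
            [m.age for m in metas],
            [1.0 if m.sex == "F" else 0.0 for m in metas],
            [float(m.education) for m in metas],
        ])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(resid.df.to_numpy(), y - x @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self):
        metas = make_metas(10, 10, seed=5)
        rng = np.random.default_rng(6)
        table = table_from(metas, {"plv_theta_F3-O1_EC": rng.standard_normal(20)})
        resid = residualize(table, metas).df.to_numpy().ravel()
        for cov in ([m.age for m in metas],
                    [1.0 if m.sex == "F" else 0.0 for m in metas],
                    [float(m.education) for m in metas]):
            assert abs(np.corrcoef(resid, cov)[0, 1]) < 1e-8

    def test_too_few_subjects_rejected(self):
        metas = make_metas(2, 1)
        table = table_from(metas, {"tbr_thetabeta_F3_EC": [1.0, 2.0, 3.0]})
        with pytest.raises(DataError):
            residualize(table, metas)


def exhaustive_mw_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of relabelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum(np.sum(xi > ys) + 0.5 * np.sum(xi == ys) for xi in xs)

    u_obs = u_of(range(n1))
    center = n1 * n2 / 2
    dev = abs(u_obs - center)
    us = [u_of(c) for c in combinations(range(n1 + n2), n1)]
    p = np.mean([abs(u - center) >= dev - 1e-12 for u in us])
    return u_obs, p


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_give_central_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 9 / 2

    def test_identical_constant_samples_give_p_one(self):
        u, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 3, 5, 7], [2, 4, 6, 8]),
            ([1, 2, 3, 4], [5, 6, 7, 8]),
            ([10, 30, 20, 50], [15, 25, 35, 5]),
        ],
    )
    def test_matches_exhaustive_enumeration(self, x, y):
        u, p = mann_whitney_u(x, y)
        u_oracle, p_oracle = exhaustive_mw_oracle(x, y)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_orientation_sums_to_n1n2(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(7), rng.standard_normal(9)
        u1, _ = mann_whitney_u(x, y)
        u2, _ = mann_whitney_u(y, x)
        assert u1 + u2 == pytest.approx(63.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_p_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(15) + 0.5
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        np.testing.assert_allclose(
            bonferroni_adjust([0.01, 0.2, 0.001], 28), [0.28, 1.0, 0.028]
        )

    def test_family_of_one_is_identity(self):
        np.testing.assert_allclose(bonferroni_adjust([0.03], 1), [0.03])

    def test_flag_count_non_increasing_in_family_size(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 0.2, size=10)
        flags = [np.sum(bonferroni_adjust(p, fam) < 0.05) for fam in (10, 20, 40)]
        assert flags[0] >= flags[1] >= flags[2]


class TestGroupDifferenceReport:
    def _tables(self, metas, effect=2.0, seed=0):
        rng = np.random.default_rng(seed)
        n = len(metas)
        is_ad = np.array([m.group == "AD" for m in metas])
        ec = {
            "plv_theta_F3-O1_EC": rng.standard_normal(n) + effect * is_ad,
            "plv_theta_T3-C4_EC": rng.standard_normal(n),
        }
        eo = {
            "plv_theta_F3-O1_EO": rng.standard_normal(n),
            "plv_theta_T3-C4_EO": rng.standard_normal(n),
        }
        idx = pd.Index([m.subject_id for m in metas], name="subject_id")
        return {
            "EC": FeatureTable(pd.DataFrame(ec, index=idx)),
            "EO": FeatureTable(pd.DataFrame(eo, index=idx)),
        }

    def test_ec_effect_flagged_only_in_ec(self):
        metas = make_metas(15, 15, seed=7)
        results, report = group_difference_report(self._tables(metas), metas)
        by = {(r["metric"], r["item"], r["condition"]): r["significant"]
              for _, r in report.iterrows()}
        assert by[("plv", "F3-O1", "EC")]
        assert not by[("plv", "F3-O1", "EO")]
        assert not by[("plv", "T3-C4", "EO")]

    def test_builds_ec_minus_eo_features(self):
        metas = make_metas(10, 10, seed=8)
        _, report = group_difference_report(self._tables(metas), metas)
        assert (report["condition"] == "ECminusEO").sum() == 2

    def test_family_is_metric_band_condition_block(self):
        metas = make_metas(10, 10, seed=9)
        results, _ = group_difference_report(self._tables(metas), metas)
        for r in results:
            assert r.family_size == 2  # two PLV-theta features per condition

    def test_subject_missing_one_condition_excluded(self):
        metas = make_metas(10, 10, seed=10)
        tables = self._tables(metas)
        tables["EO"] = FeatureTable(tables["EO"].df.iloc[:-1])
        with pytest.warns(UserWarning, match="excluded"):
            diff = build_ec_minus_eo(tables["EC"], tables["EO"])
        assert len(diff.subjects) == 19

    def test_shuffled_labels_rarely_flag(self):
        # permutation sanity: relabelled groups behave like the null
        metas = make_metas(12, 12, seed=11)
        rng = np.random.default_rng(12)
        counts = 0
        for rep in range(10):
            shuffled_groups = rng.permutation([m.group for m in metas])
            shuffled = [
                SubjectMeta(m.subject_id, g, m.age, m.sex, m.education, m.handedness)
                for m, g in zip(metas, shuffled_groups)
            ]
            _, report = group_difference_report(
                self._tables(shuffled, effect=0.0, seed=rep), shuffled
            )
            counts += int(report["significant"].sum())
        assert counts <= 2
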