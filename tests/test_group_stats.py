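"""Paired contrasts, quantile grouping and behavior correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsnet import ContrastDesign, build_feature_table, contrast_report, paired_t, pearson, quantile_split
from nirsnet.network import ROI_ORDER

EDGES = [f"wpco_{a}-{b}" for a, b in itertools.combinations(ROI_ORDER, 2)]


def paired_t_loop_oracle(x, y):
    """Textbook formula computed with explicit loops."""
    n = len(x)
    d = [x[i] - y[i] for i in range(n)]
    md = sum(d) / n
    var = sum((v - md) ** 2 for v in d) / (n - 1)
    return md / math.sqrt(var / n)


def pearson_loop_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    vx = sum((v - mx) ** 2 for v in x)
    vy = sum((v - my) ** 2 for v in y)
    return cov / math.sqrt(vx * vy)


class TestPairedT:
    def test_hand_computed_difference(self):
        """d = [1, 2, 3] gives t = 2*sqrt(3), df = 2."""
        res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2 * math.sqrt(3))
        assert res.df == 2
        assert not res.degenerate

    def test_identical_vectors_degenerate(self):
        res = paired_t(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t == 0.0 and res.degenerate and math.isnan(res.p)

    def test_sign_antisymmetry(self, rng):
        x, y = rng.standard_normal((2, 12))
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 9))
            res = paired_t(x, y)
            assert res.t == pytest.approx(paired_t_loop_oracle(x, y), abs=1e-10)

    def test_constant_nonzero_difference_infinite(self):
        res = paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert math.isinf(res.t) and res.t > 0 and res.degenerate


class TestQuantileSplit:
    def test_study_grouping_sizes(self, rng):
        scores = pd.Series(rng.standard_normal(31), index=[f"S{i:02d}" for i in range(31)])
        high, low = quantile_split(scores, 0.27)
        assert len(high) == len(low) == 9  # ceil(0.27 * 31)
        assert not set(high) & set(low)
        assert min(scores[high]) > max(scores[low])

    def test_ceil_rounding_at_n_100(self, rng):
        scores = pd.Series(rng.standard_normal(100))
        high, low = quantile_split(scores, 0.27)
        assert len(high) == len(low) == 27

    def test_all_equal_scores_split_by_id_order(self):
        ids = [f"S{i:02d}" for i in range(31)]
        scores = pd.Series(1.0, index=ids)
        high, low = quantile_split(scores, 0.27)
        assert len(high) == len(low) == 9
        assert not set(high) & set(low)
        assert low == ids[:9]  # deterministic tie-break by id

    def test_overlapping_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="overlap"):
            quantile_split(pd.Series(rng.standard_normal(3)), 0.5)
        quantile_split(pd.Series(rng.standard_normal(4)), 0.5)  # boundary ok

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(
        seed=st.integers(0, 2**20),
        scale=st.floats(0.1, 50),
        shift=st.floats(-100, 100),
    )
    def test_invariant_under_affine_transform(self, seed, scale, shift):
        r = np.random.default_rng(seed)
        scores = pd.Series(r.standard_normal(20))
        assert quantile_split(scores, 0.27) == quantile_split(scale * scores + shift, 0.27)


class TestPearson:
    def test_perfect_linear_relations(self, rng):
        x = rng.standard_normal(10)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_printed_toy_vectors(self):
        """x=[1,2,3,4], y=[2,1,4,3] has r = 0.6 by the covariance formula."""
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        r, _ = pearson(np.array(x), np.array(y))
        assert r == pytest.approx(0.6)
        assert r == pytest.approx(pearson_loop_oracle(x, y))

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 15))
            assert pearson(x, y)[0] == pytest.approx(
                pearson_loop_oracle(list(x), list(y)), abs=1e-10
            )

    def test_p_from_t_transform(self, rng):
        from scipy import stats as sps

        x, y = rng.standard_normal((2, 20))
        r, p = pearson(x, y)
        t = r * math.sqrt((20 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 18), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(seed=st.integers(0, 2**20), a=st.floats(0.01, 20), b=st.floats(-10, 10))
    def test_invariant_under_positive_affine(self, seed, a, b):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 12))
        assert pearson(a * x + b, y)[0] == pytest.approx(pearson(x, y)[0], abs=1e-9)


def feature_table_from_edges(edge_values: dict[str, np.ndarray], n: int) -> pd.DataFrame:
    """FeatureTable with near/far rows for n subjects from per-edge arrays."""
    rows = []
    for cond in ("near", "far"):
        for i in range(n):
            rows.append(
                {
                    "subject": f"S{i:02d}",
                    "condition": cond,
                    **{e: edge_values[(cond, e)][i] for e in EDGES},
                }
            )
    return build_feature_table(rows)


class TestContrastReport:
    def test_identical_conditions_all_t_zero(self, rng):
        vals = {("near", e): rng.uniform(0, 1, 8) for e in EDGES}
        vals.update({("far", e): vals[("near", e)] for e in EDGES})
        features = feature_table_from_edges(vals, 8)
        rep = contrast_report(features, ContrastDesign(kind="distance", feature_set="wpco"))
        assert (rep["stat"] == 0.0).all()
        assert rep["degenerate"].all()

    def test_planted_edge_difference_detected(self, rng):
        """One shifted edge comes out significant; the report has 45 rows."""
        n = 31
        vals = {}
        for e in EDGES:
            base = 0.3 + 0.05 * rng.standard_normal(n)
            vals[("near", e)] = base
            shift = 0.08 if e == "wpco_LOFA-ROFA" else 0.0
            vals[("far", e)] = base + 0.03 * rng.standard_normal(n) + shift
        rep = contrast_report(
            feature_table_from_edges(vals, n),
            ContrastDesign(kind="distance", feature_set="wpco"),
        )
        assert len(rep) == 45
        hit = rep.set_index("feature").loc["wpco_LOFA-ROFA"]
        assert hit["p"] < 0.05
        assert (rep["df"] == 30).all()

    def test_prior_split_rank_matched(self, rng):
        n = 31
        vals = {(c, e): rng.uniform(0, 1, n) for c in ("near", "far") for e in EDGES}
        features = feature_table_from_edges(vals, n)
        behavior = pd.DataFrame(
            {
                "subject_id": [f"S{i:02d}" for i in range(n)],
                "prior_score": rng.standard_normal(n),
                "performance_near": rng.standard_normal(n),
                "performance_far": rng.standard_normal(n),
            }
        )
        rep = contrast_report(
            features, ContrastDesign(kind="prior", feature_set="wpco"), behavior
        )
        assert (rep["df"] == 8).all()  # groups of 9, rank-matched pairs

    def test_performance_correlation_mode(self, rng):
        n = 20
        vals = {(c, e): rng.uniform(0, 1, n) for c in ("near", "far") for e in EDGES}
        # make one edge track performance perfectly
        perf = rng.standard_normal(n)
        vals[("far", "wpco_LIPFG-RIPFG")] = 0.5 + 0.1 * (perf - perf.min()) / np.ptp(perf)
        features = feature_table_from_edges(vals, n)
        behavior = pd.DataFrame(
            {
                "subject_id": [f"S{i:02d}" for i in range(n)],
                "prior_score": rng.standard_normal(n),
                "performance_near": rng.standard_normal(n),
                "performance_far": perf,
            }
        )
        rep = contrast_report(
            features, ContrastDesign(kind="performance", feature_set="wpco"), behavior
        ).set_index("feature")
        assert rep.loc["wpco_LIPFG-RIPFG", "estimate"] == pytest.approx(1.0)
        assert rep.loc["wpco_LIPFG-RIPFG", "p"] < 1e-6

    def test_q_values_present_and_ordered(self, rng):
        n = 10
        vals = {(c, e): rng.uniform(0, 1, n) for c in ("near", "far") for e in EDGES}
        rep = contrast_report(
            feature_table_from_edges(vals, n),
            ContrastDesign(kind="distance", feature_set="wpco"),
        )
        ok = rep["p"].notna()
        assert (rep.loc[ok, "q"] >= rep.loc[ok, "p"] - 1e-12).all()

    def test_missing_cells_rejected(self, rng):
        vals = {(c, e): rng.uniform(0, 1, 6) for c in ("near", "far") for e in EDGES}
        features = feature_table_from_edges(vals, 6).drop(index=("S03", "far"))
        with pytest.raises(ValueError, match="missing|matched"):
            contrast_report(features, ContrastDesign(kind="distance", feature_set="wpco"))
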