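import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bilacc.errors import DegenerateError, ShapeError
from bilacc.stats import (
    cohort_descriptives,
    delta_table,
    run_correlation_analysis,
    spearman_rho,
)


def make_table(n=6, seed=0, coupled=True):
    """Tiny cohort table with acceleration monotone in the scores if coupled."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        u = (i + 1) / (n + 1)
        for session, shift in (("T1", 0.0), ("T2", 0.1)):
            acc = 3.0 * (u + shift) if coupled else rng.uniform(0.5, 3.0)
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "session": session,
                    "affected_side": "left",
                    "mean_left": acc,
                    "mean_right": acc * 1.5,
                    "mean_affected": acc,
                    "mean_unaffected": acc * 1.5,
                    "n_selected": 10,
                    "asymmetry_index": 0.2,
                    "mas": int(round(15 * min(u + shift, 1.0))),
                    "mal_aou": round(5 * min(u + shift, 1.0), 2),
                    "mal_qom": round(5 * min(u + shift, 1.0), 2),
                }
            )
    return pd.DataFrame(rows)


class TestSpearmanRho:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_example_hand_ranked(self):
        # x-ranks [1, 2.5, 2.5, 4], y-ranks [1, 3, 2, 4]: Pearson of ranks
        # is 4.5 / sqrt(4.5 * 5) = 3/sqrt(10).
        res = spearman_rho([1, 2, 2, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(3.0 / np.sqrt(10.0))

    def test_matches_scipy_cross_check(self, rng):
        for _ in range(10):
            x = rng.integers(0, 6, size=18).astype(float)  # heavy ties
            y = rng.normal(size=18)
            if np.ptp(x) == 0:
                continue
            res = spearman_rho(x, y)
            ref_rho, ref_p = sps.spearmanr(x, y)
            assert res.rho == pytest.approx(ref_rho, abs=1e-12)
            assert res.p_value == pytest.approx(ref_p, abs=1e-9)
            assert res.method == "t-approximation"

    def test_exact_permutation_matches_enumeration_n5(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 3.5, 1.0, 2.5]
        res = spearman_rho(x, y)
        assert res.method == "exact-permutation"
        # independent brute force: rank by hand with plain python, enumerate 120 perms
        def ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            r = [0.0] * len(v)
            for rank, i in enumerate(order, start=1):
                r[i] = float(rank)
            return r  # no ties in this example

        def pearson(a, b):
            n = len(a)
            ma, mb = sum(a) / n, sum(b) / n
            num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
            den = (
                sum((ai - ma) ** 2 for ai in a) * sum((bi - mb) ** 2 for bi in b)
            ) ** 0.5
            return num / den

        rx, ry = ranks(x), ranks(y)
        obs = pearson(rx, ry)
        count = sum(
            1
            for perm in itertools.permutations(ry)
            if abs(pearson(rx, list(perm))) >= abs(obs) - 1e-12
        )
        assert res.rho == pytest.approx(obs)
        assert res.p_value == pytest.approx(count / 120.0)

    def test_degenerate_constant_input(self):
        with pytest.raises(DegenerateError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_pairs(self):
        with pytest.raises(ShapeError):
            spearman_rho([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_invariance_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y).rho == pytest.approx(base.rho)
        assert spearman_rho(x, y**3).rho == pytest.approx(base.rho)
        assert spearman_rho(y, x).rho == pytest.approx(base.rho)
        assert spearman_rho(x, -y).rho == pytest.approx(-base.rho)


class TestCohortDescriptives:
    def test_single_row(self):
        t = make_table(n=1)
        d = cohort_descriptives(t[t.session == "T1"])
        row = d.loc[("mas", "T1")]
        assert row["median"] == row["q1"] == row["q3"]

    def test_linear_interpolation_quantiles(self):
        t = make_table(n=5)
        t.loc[t.session == "T1", "mean_affected"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        d = cohort_descriptives(t)
        row = d.loc[("mean_affected", "T1")]
        assert (row["median"], row["q1"], row["q3"]) == (3.0, 2.0, 4.0)

    def test_matches_sort_oracle(self, rng):
        t = make_table(n=18, coupled=False, seed=3)
        d = cohort_descriptives(t)
        vals = np.sort(t[t.session == "T2"]["mean_affected"].to_numpy())
        assert d.loc[("mean_affected", "T2"), "median"] == pytest.approx(np.median(vals))


class TestDeltaTable:
    def test_identical_sessions_zero_deltas(self):
        t = make_table(n=4)
        t.loc[t.session == "T2", ["mean_affected", "mas", "mal_aou", "mal_qom"]] = (
            t.loc[t.session == "T1", ["mean_affected", "mas", "mal_aou", "mal_qom"]].to_numpy()
        )
        d = delta_table(t)
        assert (d.drop(columns="patient_id").to_numpy() == 0).all()

    def test_t2_minus_t1_sign(self):
        t = make_table(n=1)
        t.loc[t.session == "T1", "mas"] = 3
        t.loc[t.session == "T2", "mas"] = 8
        assert delta_table(t)["delta_mas"].iloc[0] == 5

    def test_incomplete_patient_excluded(self):
        t = make_table(n=4)
        t = t[~((t.patient_id == "p2") & (t.session == "T2"))]
        d = delta_table(t)
        assert len(d) == 3
        assert "p2" not in set(d.patient_id)


class TestCorrelationGrid:
    def test_nine_cells(self):
        g = run_correlation_analysis(make_table(n=8))
        assert len(g) == 9
        assert set(g["contrast"]) == {"T1", "T2", "delta"}
        assert set(g["score"]) == {"mas", "mal_aou", "mal_qom"}

    def test_perfect_coupling_gives_rho_one(self):
        g = run_correlation_analysis(make_table(n=8, coupled=True))
        cell = g[(g.score == "mas") & (g.contrast == "T1")].iloc[0]
        assert cell["rho"] == pytest.approx(1.0)

    def test_degenerate_cell_reported_not_fatal(self):
        t = make_table(n=6)
        t["mal_qom"] = 2.5  # constant score
        g = run_correlation_analysis(t)
        cell = g[(g.score == "mal_qom") & (g.contrast == "T1")].iloc[0]
        assert cell["method"] == "degenerate"
        assert np.isnan(cell["rho"])
        assert len(g) == 9
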