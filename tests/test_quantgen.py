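"""Variance components: REML vs the balanced expected-mean-squares oracle,
degenerate inputs, heritability arithmetic, BH adjustment, and line means."""

import numpy as np
import pandas as pd
import pytest

from metabosysgen import quantgen as qg
from metabosysgen.synthetic import SimulationConfig, simulate_panel


def balanced_table(rng, n_lines=12, n_reps=3, s_line=1.0, s_lxs=0.5, s_e=1.0, sex_shift=0.7):
    rows = []
    a = np.sqrt(s_line) * rng.standard_normal(n_lines)
    b = np.sqrt(s_lxs) * rng.standard_normal((n_lines, 2))
    for l in range(n_lines):
        for si, sex in enumerate(("F", "M")):
            for r in range(n_reps):
                y = a[l] + (sex_shift if sex == "M" else 0.0) + b[l, si]
                y += np.sqrt(s_e) * rng.standard_normal()
                rows.append(("L%02d" % l, sex, r + 1, "m1", y))
    return pd.DataFrame(rows, columns=["line", "sex", "replicate", "metabolite", "abundance"])


def ems_full(tbl):
    """Independent EMS oracle for the balanced two-way mixed design."""
    L = tbl["line"].nunique()
    S = 2
    r = int(len(tbl) / (L * S))
    grand = tbl["abundance"].mean()
    ml = tbl.groupby("line")["abundance"].mean()
    ms = tbl.groupby("sex")["abundance"].mean()
    mls = tbl.groupby(["line", "sex"])["abundance"].mean()
    msl = S * r * ((ml - grand) ** 2).sum() / (L - 1)
    msls = r * sum(
        (mls[l, s] - ml[l] - ms[s] + grand) ** 2 for l, s in mls.index
    ) / ((L - 1) * (S - 1))
    mse = sum(
        (row.abundance - mls[row.line, row.sex]) ** 2 for row in tbl.itertuples()
    ) / (L * S * (r - 1))
    return (msl - msls) / (S * r), (msls - mse) / r, mse


class TestFullModel:
    def test_reml_matches_ems_oracle_when_interior(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            tbl = balanced_table(rng, s_line=2.0, s_lxs=1.0, s_e=1.0)
            s2l, s2lxs, s2e = ems_full(tbl)
            if min(s2l, s2lxs, s2e) <= 0:
                continue
            vc = qg.fit_full_model(tbl, "m1")
            assert abs(vc.sigma2_L - s2l) < 1e-6
            assert abs(vc.sigma2_LxS - s2lxs) < 1e-6
            assert abs(vc.sigma2_e - s2e) < 1e-6

    def test_all_equal_observations_degenerate_to_zero(self):
        tbl = balanced_table(np.random.default_rng(1), s_line=0, s_lxs=0, s_e=0, sex_shift=0)
        tbl["abundance"] = 5.0
        vc = qg.fit_full_model(tbl, "m1")
        assert vc.sigma2_L == vc.sigma2_LxS == vc.sigma2_e == 0.0
        assert vc.H2 == 0.0

    def test_pure_line_signal_gives_zero_error_variance(self):
        rows = []
        for l, mean in enumerate((0.0, 5.0, 10.0, 15.0)):
            for sex in ("F", "M"):
                for r in range(3):
                    rows.append((f"L{l}", sex, r + 1, "m1", mean))
        tbl = pd.DataFrame(rows, columns=["line", "sex", "replicate", "metabolite", "abundance"])
        vc = qg.fit_full_model(tbl, "m1")
        assert vc.sigma2_e < 1e-6  # bounded variance-ratio search: ratio capped at 1e8
        assert vc.sigma2_e / vc.sigma2_L < 1e-7
        assert vc.p_L < 1e-6

    def test_requires_both_sexes_and_two_lines(self):
        tbl = balanced_table(np.random.default_rng(2))
        with pytest.raises(qg.ModelError):
            qg.fit_full_model(tbl[tbl["sex"] == "F"], "m1")
        with pytest.raises(qg.ModelError):
            qg.fit_full_model(tbl[tbl["line"] == "L00"], "m1")

    def test_unbalanced_data_still_fits(self):
        tbl = balanced_table(np.random.default_rng(3)).drop(index=[0, 7, 20])
        vc = qg.fit_full_model(tbl, "m1")
        assert 0 <= vc.H2 <= 1
        with pytest.raises(qg.ModelError):
            qg.fit_full_model(tbl, "m1", method="anova")


class TestReducedModel:
    def test_reml_matches_one_way_ems(self):
        rng = np.random.default_rng(4)
        tbl = balanced_table(rng, s_line=2.0, s_lxs=0.0, s_e=1.0)
        sub = tbl[tbl["sex"] == "F"]
        L = sub["line"].nunique()
        r = 3
        ml = sub.groupby("line")["abundance"].mean()
        msl = r * ml.var()
        mse = sub.groupby("line")["abundance"].var().mean()
        expect = (msl - mse) / r
        if expect > 0:
            vc = qg.fit_reduced_model(tbl, "m1", "F")
            assert abs(vc.sigma2_L - expect) < 1e-6
            assert abs(vc.sigma2_e - mse) < 1e-6

    def test_identical_replicates_give_zero_error(self):
        rows = [(f"L{l}", "F", r + 1, "m1", float(l)) for l in range(5) for r in range(3)]
        tbl = pd.DataFrame(rows, columns=["line", "sex", "replicate", "metabolite", "abundance"])
        vc = qg.fit_reduced_model(tbl, "m1", "F")
        assert vc.sigma2_e < 1e-8

    def test_null_line_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            rows = [
                (f"L{l}", "F", r + 1, "m1", rng.standard_normal())
                for l in range(10) for r in range(3)
            ]
            tbl = pd.DataFrame(rows, columns=["line", "sex", "replicate", "metabolite", "abundance"])
            ps.append(qg.fit_reduced_model(tbl, "m1", "F", method="anova").p_L)
        from scipy import stats
        _, p = stats.kstest(ps, "uniform")
        assert p > 0.01


class TestHeritability:
    @pytest.mark.parametrize(
        "components,expected",
        [((2.0, 1.0, 3.0), 0.5), ((0.0, 0.0, 5.0), 0.0), ((4.0, 0.0, 0.0), 1.0)],
    )
    def test_arithmetic(self, components, expected):
        assert qg.heritability(*components) == pytest.approx(expected)

    def test_negative_variance_rejected(self):
        with pytest.raises(qg.ModelError):
            qg.heritability(-1.0, 0.0, 1.0)


class TestBHAdjust:
    def test_hand_computed_example(self):
        q, flags = qg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_single_and_all_ones(self):
        q, _ = qg.bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)
        q, flags = qg.bh_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not flags.any()

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        q1, f1 = qg.bh_adjust(p)
        q2, f2 = qg.bh_adjust(p[perm])
        assert np.allclose(q1[perm], q2)
        assert (f1[perm] == f2).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qg.bh_adjust([0.5, 1.5])


class TestLineMeans:
    def test_mean_and_missing_handling(self):
        tbl = pd.DataFrame(
            {
                "line": ["A"] * 3 + ["B"] * 3,
                "sex": "F",
                "replicate": [1, 2, 3] * 2,
                "metabolite": "m1",
                "abundance": [1.0, 2.0, 3.0, 1.0, np.nan, 3.0],
            }
        )
        lm = qg.line_means(tbl, "F")
        assert lm.loc["A", "m1"] == pytest.approx(2.0)
        assert lm.loc["B", "m1"] == pytest.approx(2.0)

    def test_all_missing_cell_stays_missing(self):
        tbl = pd.DataFrame(
            {
                "line": ["A", "A", "B"],
                "sex": "F",
                "replicate": [1, 2, 1],
                "metabolite": "m1",
                "abundance": [np.nan, np.nan, 1.0],
            }
        )
        lm = qg.line_means(tbl, "F")
        assert np.isnan(lm.loc["A", "m1"]) if "A" in lm.index else True
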