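"""qPCR relative expression, dermal proportions, beta regression, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camovis.expression import (
    DERMAL_TISSUES,
    QpcrRecord,
    beta_regression,
    collapse_triplicates,
    dermal_proportion,
    dermal_proportion_table,
    expression_table,
    relative_expression,
    stage_contrast,
)
from camovis.simulate import (
    QpcrGenParams,
    ratios_for_dermal_proportion,
    simulate_qpcr,
)


class TestRelativeExpression:
    def test_equal_cp_unity(self):
        assert relative_expression(20, 20) == 1.0

    def test_one_cycle_halves(self):
        assert relative_expression(20, 21) == 0.5

    def test_two_cycles_quadruples(self):
        assert relative_expression(22, 20) == 4.0

    @given(st.integers(-10, 10))
    def test_integer_cycle_exact_powers(self, k):
        assert relative_expression(20, 20 + k) == 2.0 ** (-k)

    @pytest.mark.parametrize("cp", [0.0, 46.0, -1.0])
    def test_cp_range_enforced(self, cp):
        with pytest.raises(ValueError, match="Cp"):
            relative_expression(cp, 20)

    @pytest.mark.parametrize("e", [1.0, 2.5, 0.9])
    def test_efficiency_range_enforced(self, e):
        with pytest.raises(ValueError, match="efficiency"):
            relative_expression(20, 20, e_ref=e)


class TestCollapseTriplicates:
    def _rec(self, *cps):
        return QpcrRecord("s1", "larva", "head", "Arr-1", tuple(cps))

    def test_tight_triplicate(self):
        mean, sd, flag = collapse_triplicates(self._rec(20.0, 20.2, 20.1))
        assert mean == pytest.approx(20.1)
        assert not flag

    def test_spread_triplicate_flagged(self):
        mean, sd, flag = collapse_triplicates(self._rec(20.0, 21.5, 20.1))
        assert mean == pytest.approx(20.5333333, rel=1e-6)
        assert sd == pytest.approx(0.8386497, rel=1e-5)  # > 0.5 cycles
        assert flag

    def test_single_replicate(self):
        mean, sd, flag = collapse_triplicates(self._rec(19.7))
        assert (mean, sd, flag) == (19.7, 0.0, True)

    def test_no_usable_replicates(self):
        rec = QpcrRecord("s1", "larva", "head", "Arr-1", (float("nan"),))
        with pytest.raises(ValueError, match="no usable"):
            collapse_triplicates(rec)


class TestDermalProportion:
    def test_three_quarters(self):
        parts = {t: 1.0 for t in DERMAL_TISSUES}
        assert dermal_proportion(1.0, parts) == pytest.approx(0.75)

    def test_symmetric_half(self):
        parts = {t: 1.0 for t in DERMAL_TISSUES}
        assert dermal_proportion(3.0, parts) == pytest.approx(0.5)

    def test_missing_tissue_named(self):
        with pytest.raises(ValueError, match="claspers_or_genitalia"):
            dermal_proportion(1.0, {"thorax": 1.0, "abdomen": 1.0})

    def test_nonpositive_rejected(self):
        parts = {t: 1.0 for t in DERMAL_TISSUES}
        with pytest.raises(ValueError, match="positive"):
            dermal_proportion(0.0, parts)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 10.0))
    def test_scale_invariance(self, scale, head):
        parts = {t: 0.5 for t in DERMAL_TISSUES}
        p1 = dermal_proportion(head, parts)
        p2 = dermal_proportion(head * scale, {t: v * scale for t, v in parts.items()})
        assert p1 == pytest.approx(p2, rel=1e-9)


def _beta_sample(rng, mu, phi, n):
    return rng.beta(mu * phi, (1 - mu) * phi, n)


class TestBetaRegression:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "proportion": np.concatenate(
                    [_beta_sample(rng, 0.5, 20, 18), _beta_sample(rng, 0.2, 20, 18)]
                ),
                "stage": ["larva"] * 18 + ["adult"] * 18,
            }
        )
        fit = beta_regression(df)
        slope = fit.terms.loc["stage[larva]"]
        # |logit(0.5) - logit(0.2)| = 1.386
        assert abs(abs(slope["estimate"]) - 1.3862944) < 3 * slope["se"]

    def test_matches_statsmodels_oracle(self):
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(11)
        y = np.concatenate([_beta_sample(rng, 0.6, 15, 20), _beta_sample(rng, 0.3, 15, 20)])
        df = pd.DataFrame({"proportion": y, "stage": ["larva"] * 20 + ["adult"] * 20})
        fit = beta_regression(df)
        oracle = BetaModel.from_formula(
            "proportion ~ C(stage)", df, exog_precision=np.ones((40, 1))
        ).fit(disp=False)
        assert fit.diagnostics["loglik"] == pytest.approx(oracle.llf, abs=1e-5)
        assert fit.terms.loc["intercept", "estimate"] == pytest.approx(
            oracle.params.iloc[0], abs=1e-5
        )

    def test_intercept_only_reduction(self):
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(12)
        y = _beta_sample(rng, 0.4, 10, 30)
        df = pd.DataFrame({"proportion": y, "stage": ["larva"] * 30})
        fit = beta_regression(df, include_predictor=False)
        oracle = BetaModel.from_formula(
            "proportion ~ 1", df, exog_precision=np.ones((30, 1))
        ).fit(disp=False)
        assert fit.diagnostics["loglik"] == pytest.approx(oracle.llf, abs=1e-6)

    def test_degenerate_equal_proportions(self):
        df = pd.DataFrame(
            {"proportion": [0.5] * 20, "stage": ["larva"] * 10 + ["adult"] * 10}
        )
        fit = beta_regression(df)
        mu_hat = 1 / (1 + np.exp(-fit.terms.loc["intercept", "estimate"]))
        assert mu_hat == pytest.approx(0.5, abs=1e-6)
        assert fit.terms.loc["stage[larva]", "estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points(self):
        df = pd.DataFrame({"proportion": [0.4] * 4, "stage": ["larva", "adult"] * 2})
        with pytest.raises(ValueError, match="at least 6"):
            beta_regression(df)

    def test_boundary_rejected(self):
        df = pd.DataFrame(
            {"proportion": [0.0, 0.5, 0.5, 0.6, 0.4, 0.5], "stage": ["larva", "adult"] * 3}
        )
        with pytest.raises(ValueError, match="strictly inside"):
            beta_regression(df)


class TestStageContrast:
    def test_equal_means_zero_t(self):
        df = pd.DataFrame(
            {"ratio": [1.0, 2.0, 1.0, 2.0], "stage": ["larva", "larva", "adult", "adult"]}
        )
        assert fit_t(df) == pytest.approx(0.0, abs=1e-12)

    def test_equals_pooled_t_by_hand(self):
        rng = np.random.default_rng(13)
        la, ad = rng.lognormal(0, 0.5, 12), rng.lognormal(0.4, 0.5, 12)
        df = pd.DataFrame(
            {"ratio": np.concatenate([la, ad]), "stage": ["larva"] * 12 + ["adult"] * 12}
        )
        x, ydat = np.log10(la), np.log10(ad)
        sp2 = (x.var(ddof=1) * 11 + ydat.var(ddof=1) * 11) / 22
        t_hand = (x.mean() - ydat.mean()) / np.sqrt(sp2 * (1 / 12 + 1 / 12))
        assert fit_t(df) == pytest.approx(t_hand, rel=1e-10)

    def test_adult_excess_strongly_negative(self):
        # 10x adult excess, sign convention larva - adult
        df = pd.DataFrame(
            {
                "ratio": [1.0, 1.1, 0.9, 1.0, 10.0, 11.0, 9.0, 10.0],
                "stage": ["larva"] * 4 + ["adult"] * 4,
            }
        )
        assert fit_t(df) < -10

    def test_nonpositive_rejected(self):
        df = pd.DataFrame({"ratio": [1.0, 0.0], "stage": ["larva", "adult"]})
        with pytest.raises(ValueError, match="> 0"):
            stage_contrast(df)


def fit_t(df):
    return stage_contrast(df).terms.loc["stage[larva]", "t"]


class TestTableHelpers:
    def test_noise_free_generator_inversion(self):
        qpcr = simulate_qpcr(QpcrGenParams(replicate_sd=0.0), seed=0)
        ratios = expression_table(qpcr)
        np.testing.assert_allclose(ratios["ratio"], 1.0)

    def test_dermal_proportion_round_trip(self):
        tissue_ratios = ratios_for_dermal_proportion(0.75)
        params = QpcrGenParams(
            replicate_sd=0.0,
            true_ratios={
                ("Arr-1", stage, tissue): r
                for stage in ("larva", "adult")
                for tissue, r in tissue_ratios.items()
            },
            genes=("Arr-1",),
        )
        qpcr = simulate_qpcr(params, seed=0)
        props = dermal_proportion_table(expression_table(qpcr))
        np.testing.assert_allclose(props["proportion"], 0.75, rtol=1e-9)

    def test_missing_reference_gene_errors(self):
        qpcr = simulate_qpcr(QpcrGenParams(), seed=0)
        with pytest.raises(ValueError, match="reference gene missing"):
            expression_table(qpcr[qpcr["gene"] != "spectrin"])
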