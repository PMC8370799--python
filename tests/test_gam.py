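import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from seepbef.gam import (
    GAMSpec, SmoothTerm, backward_select, bef_spec, classify_shape, fit_gam,
    select_family_link, select_knots, smooth_estimate,
)


def single_smooth(y, x, k=6, **spec_kw):
    data = pd.DataFrame({"y": y, "x": x})
    return fit_gam(GAMSpec("y", None, (SmoothTerm("x", k=k),), **spec_kw), data)


def grouped_frame(rng, n_per=40, signal=None):
    n = 3 * n_per
    act = np.repeat(["active", "transition", "background"], n_per)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    if signal is not None:
        y = y + signal(x, act)
    return pd.DataFrame({
        "activity": act, "tax_PC1": x, "tax_PC2": rng.normal(size=n),
        "oceanographic_PC1": rng.normal(size=n), "oceanographic_PC2": rng.normal(size=n),
        "terrain_PC1": rng.normal(size=n), "tpi": rng.normal(size=n), "y": y,
    })


class TestFitBasics:
    def test_exact_linear_response_degenerates_to_line(self, rng):
        x = rng.normal(size=80)
        fit = single_smooth(2.0 * x - 1.0, x)
        assert fit.terms["edf"].iloc[0] == pytest.approx(1.0, abs=0.1)
        assert fit.adj_r2 >= 0.999

    def test_identity_link_decomposition(self, rng):
        x = rng.normal(size=60)
        y = np.sin(x) + 0.2 * rng.normal(size=60)
        fit = single_smooth(y, x)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-10)

    def test_deterministic_for_fixed_data(self, rng):
        x = rng.normal(size=50)
        y = np.sin(2 * x) + 0.3 * rng.normal(size=50)
        f1 = single_smooth(y, x)
        f2 = single_smooth(y, x)
        np.testing.assert_array_equal(f1.coef, f2.coef)
        assert f1.aic == f2.aic

    def test_edf_bounded_by_basis_dimension(self, rng):
        x = rng.normal(size=80)
        fit = single_smooth(np.sin(3 * x) + 0.1 * rng.normal(size=80), x, k=6)
        assert fit.terms["edf"].iloc[0] <= 5.0 + 1e-8  # k - 1 after centering

    def test_by_factor_smooths_are_separate_terms(self, rng):
        df = grouped_frame(rng)
        fit = fit_gam(bef_spec("y", "tax"), df)
        by_terms = [t for t in fit.terms["term"] if t.startswith("s(tax_PC1)")]
        assert sorted(by_terms) == [
            "s(tax_PC1):active", "s(tax_PC1):background", "s(tax_PC1):transition"]

    def test_small_group_rejected(self, rng):
        df = grouped_frame(rng, n_per=10)
        df = df[~((df.activity == "active") & (df.index < 6))]
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_gam(bef_spec("y", "tax"), df)

    def test_k_larger_than_group_rejected(self, rng):
        df = grouped_frame(rng, n_per=6)
        with pytest.raises(ValueError, match="exceeds"):
            fit_gam(bef_spec("y", "tax", k=8), df)

    def test_collinear_smooths_rejected(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        data = pd.DataFrame({"y": y, "x": x, "x2": x})
        spec = GAMSpec("y", None, (SmoothTerm("x", k=5), SmoothTerm("x2", k=5)))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_gam(spec, data)

    def test_gamma_log_family_fits_positive_response(self, rng):
        x = rng.normal(size=100)
        mu = np.exp(0.5 * x)
        y = rng.gamma(shape=8.0, scale=mu / 8.0)
        fit = single_smooth(y, x, family="gamma", link="log")
        assert (fit.fitted > 0).all()
        assert np.corrcoef(np.log(fit.fitted), 0.5 * x)[0, 1] > 0.9

    def test_gamma_rejects_nonpositive_response(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="positive"):
            single_smooth(np.r_[-1.0, np.abs(rng.normal(size=29))], x,
                          family="gamma", link="log")


class TestSelection:
    def test_strong_model_survives_backward_selection(self, rng):
        sig = lambda x, act: 2.0 * np.sin(2 * x)
        df = grouped_frame(rng, signal=sig)
        spec = GAMSpec("y", "activity", (SmoothTerm("tax_PC1", k=6),))
        full = fit_gam(spec, df)
        fit, trace = backward_select(full, df)
        assert fit.has_term("s(tax_PC1)")
        assert all(step["action"] != "drop" for step in trace)

    def test_noise_covariate_is_dropped(self, rng):
        sig = lambda x, act: 2.0 * np.sin(2 * x)
        df = grouped_frame(rng, signal=sig)
        spec = GAMSpec("y", "activity", (SmoothTerm("tax_PC1", k=6),
                                         SmoothTerm("tpi", k=6)))
        fit, trace = backward_select(fit_gam(spec, df), df)
        assert not fit.has_term("s(tpi)")
        assert fit.has_term("s(tax_PC1)")

    def test_selection_trace_replays_to_same_model(self, rng):
        df = grouped_frame(rng)
        full = fit_gam(bef_spec("y", "tax", k=4), df)
        f1, t1 = backward_select(full, df)
        f2, t2 = backward_select(full, df)
        assert [s["term"] for s in t1] == [s["term"] for s in t2]
        assert [t.name for t in f1.spec.smooths] == [t.name for t in f2.spec.smooths]

    def test_backward_never_worsens_aic_beyond_tolerance(self, rng):
        df = grouped_frame(rng)
        full = fit_gam(bef_spec("y", "tax", k=4), df)
        fit, _ = backward_select(full, df, aic_tol=2.0)
        assert fit.aic <= full.aic + 2.0

    def test_single_knot_candidate_is_chosen(self, rng):
        x = rng.normal(size=50)
        spec = GAMSpec("y", None, (SmoothTerm("x", k=6),))
        data = pd.DataFrame({"y": np.sin(x), "x": x})
        new_spec, chosen = select_knots(spec, data, k_candidates=(4,))
        assert chosen == {"s(x)": 4}
        assert new_spec.smooths[0].k == 4

    def test_oversized_knot_candidates_excluded(self, rng):
        df = grouped_frame(rng, n_per=7)
        spec = GAMSpec("y", "activity", (SmoothTerm("tax_PC1", by="active", k=4),))
        _, chosen = select_knots(spec, df, k_candidates=(4, 9))
        assert chosen["s(tax_PC1):active"] == 4  # k=9 > 7 observations

    def test_out_of_range_knot_candidates_rejected(self, rng):
        df = grouped_frame(rng)
        spec = GAMSpec("y", "activity", (SmoothTerm("tax_PC1", k=4),))
        with pytest.raises(ValueError):
            select_knots(spec, df, k_candidates=(2, 4))

    def test_family_selection_single_candidate_unconditional(self, rng):
        x = rng.normal(size=60)
        spec = GAMSpec("y", None, (SmoothTerm("x", k=5),))
        data = pd.DataFrame({"y": x + rng.normal(size=60), "x": x})
        fam, link, _ = select_family_link((("gaussian", "identity"),), spec, data)
        assert (fam, link) == ("gaussian", "identity")

    def test_family_selection_rejects_empty_candidates(self, rng):
        spec = GAMSpec("y", None, (SmoothTerm("x", k=5),))
        with pytest.raises(ValueError):
            select_family_link((), spec, pd.DataFrame({"y": [1.0], "x": [0.0]}))

    def test_gaussian_data_prefers_gaussian(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            x = rng.normal(size=100)
            y = 5.0 + x + 0.5 * rng.normal(size=100)  # positive-shifted gaussian
            spec = GAMSpec("y", None, (SmoothTerm("x", k=5),))
            fam, link, _ = select_family_link(
                (("gaussian", "identity"), ("gamma", "log")),
                spec, pd.DataFrame({"y": y, "x": x}))
            wins += (fam, link) == ("gaussian", "identity")
        assert wins >= 18


class TestShapes:
    def test_linear_truth_is_monotone_increasing(self, rng):
        x = rng.normal(size=80)
        fit = single_smooth(x + 0.3 * rng.normal(size=80), x)
        assert classify_shape(fit, "s(x)").label == "monotone_increasing"

    def test_negative_quadratic_is_unimodal_with_peak(self, rng):
        x = rng.normal(size=100)
        y = -((x - 0.2) ** 2) + 0.3 * rng.normal(size=100)
        fit = single_smooth(y, x)
        call = classify_shape(fit, "s(x)")
        assert call.label == "unimodal"
        assert call.extremum == pytest.approx(0.2, abs=0.15)

    def test_dropped_or_insignificant_term_is_null(self, rng):
        df = grouped_frame(rng)
        full = fit_gam(bef_spec("y", "tax", k=4), df)
        fit, _ = backward_select(full, df)
        assert classify_shape(fit, "s(tax_PC1):active").label == "null"

    def test_small_grid_rejected(self, rng):
        x = rng.normal(size=50)
        fit = single_smooth(x, x)
        with pytest.raises(ValueError):
            classify_shape(fit, "s(x)", grid_size=5)

    def test_smooth_estimate_has_intervals(self, rng):
        x = rng.normal(size=60)
        fit = single_smooth(np.sin(x) + 0.2 * rng.normal(size=60), x)
        sm = smooth_estimate(fit, "s(x)", grid_size=50)
        assert len(sm) == 50
        assert (sm["hi"] >= sm["lo"]).all()
        assert (sm["se"] >= 0).all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_fit_agrees_with_mgcv_oracle(tmp_path, rng):
    """Cross-check against mgcv on one dataset: the fitted curves must be
    close and the smooth must be judged significant by both."""
    n = 150
    x = np.sort(rng.uniform(-2, 2, size=n))
    y = np.sin(1.5 * x) + 0.3 * rng.normal(size=n)
    fit = single_smooth(y, x, k=6)
    df = pd.DataFrame({"x": x, "y": y})
    df.to_csv(tmp_path / "d.csv", index=False)
    rcode = textwrap.dedent(f"""
        suppressMessages(library(mgcv))
        d <- read.csv("{tmp_path}/d.csv")
        m <- gam(y ~ s(x, k = 6, bs = "cr"), data = d, method = "GCV.Cp")
        out <- data.frame(fitted = fitted(m))
        write.csv(out, "{tmp_path}/fit.csv", row.names = FALSE)
        cat(summary(m)$s.pv[1])
    """)
    res = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True,
                         timeout=120)
    assert res.returncode == 0, res.stderr
    mgcv_fit = pd.read_csv(tmp_path / "fit.csv")["fitted"].to_numpy()
    rmse = np.sqrt(np.mean((fit.fitted - mgcv_fit) ** 2))
    assert rmse <= 0.1 * y.std()
    mgcv_p = float(res.stdout.strip().split()[-1])
    assert fit.terms["p"].iloc[0] < 0.001 and mgcv_p < 0.001
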