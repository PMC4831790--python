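import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import tumorhet as th
from tumorhet.diffexpr import _rebind
from tumorhet.lmm import AliasingWarning


def balanced_design(n_pat=2, n_foci=2, n_punch=3):
    pat, foc = [], []
    for i in range(n_pat):
        for j in range(n_foci):
            for k in range(n_punch):
                pat.append(f"P{i}")
                foc.append(f"F{j}")
    return np.array(pat), np.array(foc)


def simulate_y(rng, pat, foc, sP, sF, sIT, mean=0.0):
    pats = {p: rng.normal(0, sP) for p in set(pat)}
    focs = {(p, f): rng.normal(0, sF) for p, f in set(zip(pat, foc))}
    return (
        mean
        + np.array([pats[p] for p in pat])
        + np.array([focs[(p, f)] for p, f in zip(pat, foc)])
        + rng.normal(0, sIT, len(pat))
    )


def grid_oracle(model, method="REML", grid_max=3.0, n=25):
    """Dense grid over sigmas + generic Nelder-Mead polish of the exact
    (restricted) likelihood; independent of the fitting path."""
    grid = np.linspace(0.0, grid_max, n)
    best, best_s = -np.inf, None
    for sP in grid:
        for sF in grid:
            for sIT in np.linspace(0.05, grid_max, n):
                ll = model.loglike((sP, sF, sIT), method)
                if ll > best:
                    best, best_s = ll, (sP, sF, sIT)
    res = optimize.minimize(
        lambda s: -model.loglike(np.abs(s), method),
        x0=np.asarray(best_s), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    return max(best, -res.fun)


class TestCriterion:
    def test_reduces_to_ols_when_random_variances_zero(self):
        rng = np.random.default_rng(21)
        pat, foc = balanced_design()
        y = rng.normal(2.0, 1.3, len(pat))
        X = np.ones((len(y), 1))
        m = th.NestedLMM(y, X, pat, foc)
        s = 0.9
        n = len(y)
        r = y - y.mean()
        # ML: independent Gaussian log-likelihood at sd s
        expected_ml = -0.5 * (
            n * np.log(2 * np.pi) + n * np.log(s**2) + (r @ r) / s**2
        )
        assert th.reml_criterion((0, 0, s), m, "ML") == pytest.approx(
            expected_ml, abs=1e-10
        )
        # REML: residual variant with n-p degrees and the design-term
        expected_reml = -0.5 * (
            (n - 1) * np.log(2 * np.pi)
            + n * np.log(s**2)
            + np.log(n / s**2)
            + (r @ r) / s**2
        )
        assert th.reml_criterion((0, 0, s), m, "REML") == pytest.approx(
            expected_reml, abs=1e-10
        )

    def test_scale_identity(self):
        # scaling (y, all sigmas) by c shifts the criterion analytically
        rng = np.random.default_rng(22)
        pat, foc = balanced_design(3, 2, 3)
        y = simulate_y(rng, pat, foc, 0.5, 0.7, 0.4)
        X = np.ones((len(y), 1))
        c = 2.0
        m1 = th.NestedLMM(y, X, pat, foc)
        m2 = th.NestedLMM(c * y, X, pat, foc)
        s = (0.5, 0.7, 0.4)
        s2 = tuple(c * v for v in s)
        n, p = len(y), 1
        ll1 = m1.loglike(s, "ML")
        ll2 = m2.loglike(s2, "ML")
        assert ll2 == pytest.approx(ll1 - n * np.log(c), abs=1e-8)
        llr1 = m1.loglike(s, "REML")
        llr2 = m2.loglike(s2, "REML")
        assert llr2 == pytest.approx(llr1 - (n - p) * np.log(c), abs=1e-8)

    def test_random_probe_optimality(self):
        rng = np.random.default_rng(23)
        pat, foc = balanced_design(3, 2, 3)
        y = simulate_y(rng, pat, foc, 0.4, 0.8, 0.5)
        m = th.NestedLMM(y, np.ones((len(y), 1)), pat, foc)
        fit = m.fit("REML")
        probes = rng.uniform(0, 2.5, size=(1000, 3)) + [0, 0, 0.02]
        best_probe = max(m.loglike(s, "REML") for s in probes)
        assert fit.llf >= best_probe - 1e-8


class TestFit:
    def test_constant_response_degenerate(self):
        pat, foc = balanced_design()
        y = np.full(len(pat), 4.2)
        m = th.NestedLMM(y, np.ones((len(y), 1)), pat, foc)
        fit = m.fit("REML")
        assert fit.sigma_P < 1e-6 and fit.sigma_F < 1e-6
        assert fit.sigma_IT < 1e-6
        assert fit.params.iloc[0] == pytest.approx(4.2, abs=1e-8)
        assert np.isfinite(fit.llf)

    def test_grid_oracle_equivalence_balanced_fixture(self):
        rng = np.random.default_rng(24)
        pat, foc = balanced_design(2, 2, 3)
        y = simulate_y(rng, pat, foc, 0.6, 1.0, 0.5, mean=5.0)
        m = th.NestedLMM(y, np.ones((len(y), 1)), pat, foc)
        fit = m.fit("REML")
        oracle = grid_oracle(m, "REML")
        assert fit.llf == pytest.approx(oracle, abs=1e-4)

    def test_shift_invariance_of_sigmas(self):
        rng = np.random.default_rng(25)
        pat, foc = balanced_design(3, 2, 3)
        y = simulate_y(rng, pat, foc, 0.5, 0.8, 0.4)
        X = np.ones((len(y), 1))
        f1 = th.NestedLMM(y, X, pat, foc).fit("REML")
        f2 = th.NestedLMM(y + 100.0, X, pat, foc).fit("REML")
        assert f2.sigma_P == pytest.approx(f1.sigma_P, abs=1e-5)
        assert f2.sigma_F == pytest.approx(f1.sigma_F, abs=1e-5)
        assert f2.sigma_IT == pytest.approx(f1.sigma_IT, abs=1e-5)
        assert f2.params.iloc[0] == pytest.approx(f1.params.iloc[0] + 100.0,
                                                  abs=1e-5)

    def test_parameter_recovery_median(self, study_design):
        tum = study_design
        pat = tum["patient_id"].to_numpy()
        foc = tum["focus_id"].to_numpy()
        rng = np.random.default_rng(26)
        X = np.ones((len(pat), 1))
        base = th.NestedLMM(np.zeros(len(pat)), X, pat, foc)
        est = []
        for _ in range(60):
            y = simulate_y(rng, pat, foc, 0.5, 1.0, 0.5)
            f = _rebind(base, y).fit("REML")
            est.append((f.sigma_P, f.sigma_F, f.sigma_IT))
        med = np.median(np.asarray(est), axis=0)
        np.testing.assert_allclose(med, [0.5, 1.0, 0.5], atol=0.1)

    def test_rank_deficient_design_rejected(self):
        pat, foc = balanced_design()
        X = np.column_stack([np.ones(len(pat)), np.ones(len(pat))])
        with pytest.raises(ValueError, match="rank"):
            th.NestedLMM(np.zeros(len(pat)), X, pat, foc)

    def test_single_punch_per_focus_aliasing_warning(self):
        pat = np.repeat([f"P{i}" for i in range(4)], 3)
        foc = np.array([f"F{j}" for j in range(3)] * 4)  # 1 punch per focus
        with pytest.warns(AliasingWarning, match="sigma_F and sigma_IT"):
            th.NestedLMM(np.zeros(12), np.ones((12, 1)), pat, foc)

    def test_summary_mentions_components(self):
        rng = np.random.default_rng(27)
        pat, foc = balanced_design()
        y = simulate_y(rng, pat, foc, 0.3, 0.5, 0.4)
        fit = th.NestedLMM(y, np.ones((len(y), 1)), pat, foc).fit()
        s = fit.summary()
        assert "sigma_F" in s and "REML" in s


class TestLRT:
    def _fits(self, lam):
        rng = np.random.default_rng(28)
        pat, foc = balanced_design(3, 2, 3)
        y = simulate_y(rng, pat, foc, 0.4, 0.8, 0.5)
        m = th.NestedLMM(y, np.ones((len(y), 1)), pat, foc)
        full = m.fit("REML")
        red = m.fit("REML", include_focus=False)
        red.llf = full.llf - lam / 2.0  # exact statistic for the check
        return full, red

    def test_zero_statistic_gives_p_one(self):
        full, red = self._fits(0.0)
        assert th.lrt_focus_variance(full, red, "chisq1") == pytest.approx(1.0)
        assert th.lrt_focus_variance(full, red, "mixture_half") == 1.0

    def test_chi2_quantile(self):
        full, red = self._fits(3.841458820694124)
        assert th.lrt_focus_variance(full, red, "chisq1") == pytest.approx(
            0.05, abs=1e-6
        )
        assert th.lrt_focus_variance(full, red, "mixture_half") == pytest.approx(
            0.025, abs=1e-6
        )

    def test_mismatched_designs_rejected(self):
        rng = np.random.default_rng(29)
        pat, foc = balanced_design(3, 2, 3)
        y = simulate_y(rng, pat, foc, 0.4, 0.8, 0.5)
        m1 = th.NestedLMM(y, np.ones((len(y), 1)), pat, foc)
        X2 = np.column_stack([np.ones(len(y)), rng.normal(size=len(y))])
        m2 = th.NestedLMM(y, X2, pat, foc)
        full = m1.fit("REML")
        red = m2.fit("REML", include_focus=False)
        with pytest.raises(ValueError, match="fixed design"):
            th.lrt_focus_variance(full, red)

    def test_negative_statistic_clipped(self):
        full, red = self._fits(-2.0)
        assert th.lrt_focus_variance(full, red, "chisq1") == 1.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_against_lme4_reference(tmp_path, study_design):
    """Independent cross-check: variance components from lme4's REML fit."""
    tum = study_design
    rng = np.random.default_rng(30)
    y = simulate_y(rng, tum["patient_id"].to_numpy(),
                   tum["focus_id"].to_numpy(), 0.5, 1.0, 0.5, mean=8.0)
    df = pd.DataFrame({
        "y": y,
        "patient": tum["patient_id"].to_numpy(),
        "focus": [f"{p}_{f}" for p, f in zip(tum["patient_id"],
                                             tum["focus_id"])],
    })
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "m <- lmer(y ~ 1 + (1|patient) + (1|focus), data=d, REML=TRUE)\n"
        "v <- as.data.frame(VarCorr(m))\n"
        "cat(v$sdcor[v$grp=='patient'], v$sdcor[v$grp=='focus'],\n"
        "    v$sdcor[v$grp=='Residual'], fixef(m)[1], sep='\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
        timeout=300,
    )
    assert out.returncode == 0, out.stderr
    sP_r, sF_r, sIT_r, beta_r = (float(v) for v in out.stdout.split())
    fit = th.NestedLMM(
        y, np.ones((len(y), 1)), tum["patient_id"], tum["focus_id"]
    ).fit("REML")
    assert fit.sigma_P == pytest.approx(sP_r, abs=2e-3)
    assert fit.sigma_F == pytest.approx(sF_r, abs=2e-3)
    assert fit.sigma_IT == pytest.approx(sIT_r, abs=2e-3)
    assert fit.params.iloc[0] == pytest.approx(beta_r, abs=1e-3)
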