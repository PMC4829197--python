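"""Tests of the MCMC fitter against independent oracles, and of the
convergence diagnostics against frozen reference values.

The strongest check is the quadrature oracle: for the Gaussian
likelihood with a Gamma prior on the residual precision, delta can be
integrated out analytically, leaving a 3-D integral over (A, B, C)
that brute-force grid quadrature evaluates to high accuracy.  The
diagnostics are frozen against R coda (geweke.diag / heidel.diag) run
once on the same seeded chains.
"""

import numpy as np
import pytest
from scipy.special import gammaln

from balanceprior import (
    BalancingPriorSpec,
    MCMCConfig,
    ModelSpec,
    fit_model,
    geweke,
    heidelberger_welch,
    load_fit_summary,
    posterior_predictive_interval,
    save_fit,
)
from balanceprior.core_model import ImbalancedDataset, StructuralModel

from conftest import TRUE_EMAX, make_emax_pair


def quadrature_posterior_mean(ds, weights, a0=0.001, b0=0.001, prior_prec=1e-6,
                              A_rng=(0.5, 6, 70), B_rng=(5, 20, 70), C_rng=(0.5, 120, 240),
                              check_edges=True):
    """Brute-force posterior means of (A, B, C) for the weighted Emax
    model with delta marginalised analytically:

        p(y | theta) ~ (b0 + WRSS/2) ** -(a0 + sum(w)/2)
    """
    x, y, w = ds.x, ds.y, weights
    A = np.linspace(*A_rng)
    B = np.linspace(*B_rng)
    C = np.linspace(*C_rng)
    AA, BB = np.meshgrid(A, B, indexing="ij")
    lp = np.empty((len(A), len(B), len(C)))
    sw = w.sum()
    for k, c in enumerate(C):
        mu = AA[..., None] + BB[..., None] * x[None, None, :] / (c + x[None, None, :])
        wrss = np.sum(w[None, None, :] * (y[None, None, :] - mu) ** 2, axis=-1)
        lp[:, :, k] = -(a0 + sw / 2) * np.log(b0 + wrss / 2)
    lp += -0.5 * prior_prec * (
        AA[..., None] ** 2 + BB[..., None] ** 2 + C[None, None, :] ** 2
    )
    p = np.exp(lp - lp.max())
    p /= p.sum()
    means = (
        float((p.sum(axis=(1, 2)) * A).sum()),
        float((p.sum(axis=(0, 2)) * B).sum()),
        float((p.sum(axis=(0, 1)) * C).sum()),
    )
    edge = p[:, :, -1].sum() + p[:, :, 0].sum() + p[0].sum() + p[-1].sum()
    if check_edges:
        assert edge < 1e-4, "posterior mass escapes the quadrature box"
    return means


class TestFitModel:
    def test_power_mode_matches_quadrature_oracle(self, emax_pair, short_mcmc):
        ds, prior = emax_pair
        fit = fit_model(ds, ModelSpec(mode="power"), prior, short_mcmc)
        ref = quadrature_posterior_mean(ds, prior.weights)
        for p, r in zip(("A", "B", "C"), ref):
            assert fit.mean[p] == pytest.approx(r, rel=0.05), p

    def test_conventional_mode_matches_quadrature_oracle(self, emax_pair, short_mcmc):
        """The unweighted posterior carries a heavy (B, C) ridge cut off
        only by the vague prior, so no finite quadrature box holds all
        its mass; instead both the grid and the MCMC draws are truncated
        to the same box and their conditional means compared."""
        ds, _ = emax_pair
        fit = fit_model(ds, ModelSpec(mode="conventional"), None, short_mcmc)
        box = dict(A_rng=(0.2, 7, 70), B_rng=(4, 26, 70), C_rng=(0.5, 400, 400))
        ref = quadrature_posterior_mean(ds, np.ones(ds.n), check_edges=False, **box)
        draws = fit.step_chains.reshape(-1, 4)
        keep = np.ones(len(draws), bool)
        for j, rng_ in enumerate((box["A_rng"], box["B_rng"], box["C_rng"])):
            keep &= (draws[:, j] >= rng_[0]) & (draws[:, j] <= rng_[1])
        assert keep.mean() > 0.95
        for j, (p, r) in enumerate(zip(("A", "B", "C"), ref)):
            assert draws[keep, j].mean() == pytest.approx(r, rel=0.05), p

    def test_recovery_on_balanced_data(self, balanced_dataset, short_mcmc):
        """With a well-conditioned design the conventional posterior mean
        recovers the generating parameters."""
        fit = fit_model(balanced_dataset, ModelSpec(mode="conventional"), None, short_mcmc)
        for p in ("A", "B", "C"):
            tol = 3 * np.hypot(fit.se[p], fit.mcse[p])
            assert abs(fit.mean[p] - TRUE_EMAX.params[p]) < tol, p

    def test_conventional_close_to_nonlinear_least_squares(self, balanced_dataset, short_mcmc):
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            lambda x, A, B, C: A + B * x / (C + x),
            balanced_dataset.x,
            balanced_dataset.y,
            p0=[2, 10, 10],
        )
        fit = fit_model(balanced_dataset, ModelSpec(mode="conventional"), None, short_mcmc)
        for p, ref in zip(("A", "B", "C"), popt):
            assert abs(fit.mean[p] - ref) < 4 * fit.se[p], p

    def test_unit_weights_equal_conventional(self, emax_pair, short_mcmc):
        ds, _ = emax_pair
        unit = BalancingPriorSpec.from_multiplier(ds.is_minority, 1.0)
        f_pow = fit_model(ds, ModelSpec(mode="power"), unit, short_mcmc)
        f_conv = fit_model(ds, ModelSpec(mode="conventional"), None, short_mcmc)
        for p in ("A", "B", "C"):
            tol = 4 * np.hypot(f_pow.mcse[p], f_conv.mcse[p])
            assert abs(f_pow.mean[p] - f_conv.mean[p]) < tol, p

    def test_latent_mode_close_to_conventional(self, emax_pair, short_mcmc):
        """The literal two-layer model adds <= 1e-6 extra variance, so its
        exact (marginalised) posterior is indistinguishable from the
        conventional one."""
        ds, prior = emax_pair
        f_lat = fit_model(ds, ModelSpec(mode="latent"), prior, short_mcmc)
        f_conv = fit_model(ds, ModelSpec(mode="conventional"), None, short_mcmc)
        for p in ("A", "B", "C"):
            tol = 4 * np.hypot(f_lat.mcse[p], f_conv.mcse[p])
            assert abs(f_lat.mean[p] - f_conv.mean[p]) < tol, p

    def test_latent_gibbs_freezes_at_initialisation(self, emax_pair):
        """Single-site Gibbs on the literal two-layer model cannot leave its
        starting point: the latent precisions pin the conditional updates.
        Started at the generating values it reports them back almost
        unchanged, with tiny within-chain spread."""
        ds, prior = emax_pair
        mcmc = MCMCConfig(n_burn=3000, n_sample=3000, thin=10, seed=5)
        init = [2.0, 10.0, 10.0]
        fit = fit_model(ds, ModelSpec(mode="latent_gibbs"), prior, mcmc, init=init)
        for p, v in zip(("A", "B", "C"), init):
            assert abs(fit.mean[p] - v) / v < 0.02, p
            assert fit.se[p] < 0.05 * v, p

    def test_truncation_keeps_A_nonnegative(self, short_mcmc):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 25, 120)
        y = 0.05 + 5 * x / (8 + x) + rng.normal(0, 0.3, 120)
        mask = np.zeros(120, bool)
        mask[:5] = True
        ds = ImbalancedDataset.from_arrays(x, y, mask)
        fit = fit_model(ds, ModelSpec(mode="conventional", truncate_A=True), None, short_mcmc)
        assert np.all(fit.chains[:, 0] >= 0)

    def test_seed_determinism_and_chain_length(self, emax_pair):
        ds, prior = emax_pair
        mcmc = MCMCConfig(n_burn=3200, n_sample=3200, thin=10, n_walkers=16, seed=3)
        f1 = fit_model(ds, ModelSpec(mode="power"), prior, mcmc)
        f2 = fit_model(ds, ModelSpec(mode="power"), prior, mcmc)
        assert np.array_equal(f1.chains, f2.chains)
        assert len(f1.chains) == mcmc.n_retained

    def test_mismatched_tau_length_rejected(self, emax_pair, short_mcmc):
        ds, _ = emax_pair
        bad = BalancingPriorSpec(phi=1e6, tau_int=np.full(ds.n + 1, 1e6))
        with pytest.raises(ValueError, match="mismatch"):
            fit_model(ds, ModelSpec(mode="power"), bad, short_mcmc)

    def test_fit_roundtrip_serialisation(self, emax_pair, short_mcmc, tmp_path):
        ds, prior = emax_pair
        fit = fit_model(ds, ModelSpec(mode="power"), prior, short_mcmc)
        save_fit(fit, tmp_path / "fit")
        means, ses, echo = load_fit_summary(tmp_path / "fit")
        for p in ("A", "B", "C"):
            assert means[p] == pytest.approx(fit.mean[p], rel=1e-6)
            assert ses[p] == pytest.approx(fit.se[p], rel=1e-6)
        assert echo["model"]["mode"] == "power"


# frozen chains; reference z / verdicts computed once with R coda
def _oracle_chains():
    rng = np.random.default_rng(123)
    n = 2000
    out = {}
    out["white"] = rng.standard_normal(n)
    ar = np.zeros(n)
    e = rng.standard_normal(n)
    for i in range(1, n):
        ar[i] = 0.6 * ar[i - 1] + e[i]
    out["ar1"] = ar
    out["trend"] = rng.standard_normal(n) + np.linspace(0, 3, n)
    shift = rng.standard_normal(n)
    shift[: n // 2] += 1.5
    out["shift_half"] = shift
    ar2 = np.zeros(n)
    e2 = rng.standard_normal(n)
    for i in range(1, n):
        ar2[i] = 0.3 * ar2[i - 1] + e2[i]
    out["ar1_mild"] = ar2 + 5.0
    return out


# (coda geweke z, coda stationarity, coda halfwidth)
CODA_REFERENCE = {
    "white": (1.381, True, False),
    "ar1": (0.991, True, False),
    "trend": (-12.920, False, False),
    "shift_half": (18.183, True, False),
    "ar1_mild": (-0.552, True, True),
}


class TestGeweke:
    def test_matches_coda_reference(self):
        chains = _oracle_chains()
        for name, (z_ref, *_rest) in CODA_REFERENCE.items():
            z = geweke(chains[name])
            assert z == pytest.approx(z_ref, abs=0.25), name

    def test_iid_normal_null(self):
        rng = np.random.default_rng(77)
        assert abs(geweke(rng.standard_normal(10_000))) < 3

    def test_trend_detected(self):
        rng = np.random.default_rng(78)
        x = rng.standard_normal(5000) + np.linspace(0, 4, 5000)
        assert abs(geweke(x)) > 3

    def test_constant_chain_defined_as_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert geweke(np.ones(500)) == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="100"):
            geweke(np.arange(50))
        with pytest.raises(ValueError, match="overlap"):
            geweke(np.random.default_rng(0).standard_normal(500), 0.6, 0.5)


class TestHeidelbergerWelch:
    def test_matches_coda_reference(self):
        chains = _oracle_chains()
        for name, (_z, st_ref, hw_ref) in CODA_REFERENCE.items():
            st, hw = heidelberger_welch(chains[name])
            assert st == st_ref, name
            assert hw == hw_ref, name

    def test_stationary_chain_with_offset_passes_both(self):
        rng = np.random.default_rng(5)
        st, hw = heidelberger_welch(rng.standard_normal(2000) + 10.0)
        assert st and hw

    def test_persistent_mean_shift_fails_stationarity(self):
        # the shift must outlast the 40% initial discards to fail
        rng = np.random.default_rng(123)
        x = rng.standard_normal(2000)
        x[:1400] += 2.0
        st, _ = heidelberger_welch(x)
        assert not st

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="100"):
            heidelberger_welch(np.arange(20))


@pytest.fixture(scope="module")
def fit(balanced_dataset, short_mcmc):
    return fit_model(balanced_dataset, ModelSpec(mode="conventional"), None, short_mcmc)


class TestPosteriorPredictiveInterval:

    def test_interval_orders_and_collapse(self, fit):
        grid = np.linspace(2, 25, 8)
        wide = posterior_predictive_interval(fit, grid, level=0.95, n_draws=4000, seed=1)
        assert (wide["lower"] <= wide["median"]).all()
        assert (wide["median"] <= wide["upper"]).all()
        narrow = posterior_predictive_interval(fit, grid, level=1e-6, n_draws=4000, seed=1)
        assert np.allclose(narrow["lower"], narrow["median"], atol=5e-3)
        assert np.allclose(narrow["upper"], narrow["median"], atol=5e-3)

    def test_calibration_on_fresh_replicates(self, fit):
        """~95% of fresh observations from the generating process fall
        inside the 95% predictive band."""
        rng = np.random.default_rng(9)
        grid = rng.uniform(2, 25, 2000)
        y_new = TRUE_EMAX.predict(grid) + rng.normal(0, 0.25, 2000)
        band = posterior_predictive_interval(fit, grid, level=0.95, n_draws=4000, seed=2)
        cover = np.mean((y_new >= band["lower"]) & (y_new <= band["upper"]))
        assert cover == pytest.approx(0.95, abs=0.03)

    def test_too_few_draws_rejected(self, fit):
        with pytest.raises(ValueError, match="100"):
            posterior_predictive_interval(fit, [5.0], n_draws=10)
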