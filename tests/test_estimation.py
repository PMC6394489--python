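"""Likelihood machinery: joint density, Laplace vs quadrature, LRT,
empirical Bayes, dataset handling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import roots_hermite

import trastupk as tp
from trastupk import _engine
from trastupk.estimation import LikelihoodModel, ModelConfig

THETA = {"cl": 0.127, "vc": 2.62, "q": 0.544, "vp": 2.97,
         "vmax": 8.81, "km": 8.92}
OMEGA = {"cl": 0.401, "vc": 0.246, "vp": 0.495, "km": 1.39}
SIGMA = (0.197, 1.38)


def toy_records(dv=(60.0, 35.0), times=(2.0, 21.0)):
    rows = [{"ID": 1, "TIME": 0.0, "AMT": 528.0, "RATE": 528.0 / 0.0625,
             "EVID": 1, "DV": np.nan, "MDV": 1}]
    rows += [{"ID": 1, "TIME": t, "AMT": 0.0, "RATE": 0.0, "EVID": 0,
              "DV": v, "MDV": 0} for t, v in zip(times, dv)]
    return pd.DataFrame(rows)


def agq_neg2ll(records, theta, omega, sigma, eta_on, n_nodes=11):
    """Adaptive Gauss-Hermite marginal -2 log-likelihood (oracle).

    Centers the quadrature at the joint-density mode with curvature
    scaling; exact up to polynomial order 2*n_nodes-1 after adaptation.
    """
    d = len(eta_on)
    x, w = roots_hermite(n_nodes)

    def neg_joint(eta):
        return -tp.subject_loglik(records, theta, omega, sigma, eta,
                                  eta_on=eta_on)

    from scipy.optimize import minimize
    mode = minimize(neg_joint, np.zeros(d), method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12,
                             "maxiter": 4000}).x
    h = 1e-4
    H = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            ei = np.eye(d)[i] * h
            ej = np.eye(d)[j] * h
            H[i, j] = (neg_joint(mode + ei + ej) - neg_joint(mode + ei - ej)
                       - neg_joint(mode - ei + ej)
                       + neg_joint(mode - ei - ej)) / (4 * h * h)
    L = np.linalg.cholesky(np.linalg.inv(H))
    nodes = [x] * d
    total = 0.0
    l0 = -neg_joint(mode)
    import itertools
    for combo in itertools.product(range(n_nodes), repeat=d):
        z = np.array([x[c] for c in combo])
        eta = mode + math.sqrt(2.0) * (L @ z)
        lw = sum(math.log(w[c]) for c in combo) + float(z @ z)
        total += math.exp((-neg_joint(eta) - l0) + lw)
    logdetL = float(np.sum(np.log(np.diag(L))))
    log_lik = l0 + d / 2.0 * math.log(2.0) + logdetL + math.log(total)
    return -2.0 * log_lik


class TestSubjectLoglik:
    def test_no_observations_returns_prior_density(self):
        rows = pd.DataFrame([{"ID": 1, "TIME": 0.0, "AMT": 100.0,
                              "RATE": 0.0, "EVID": 1, "DV": np.nan,
                              "MDV": 1}])
        eta = [0.2]
        got = tp.subject_loglik(rows, THETA, OMEGA, SIGMA, eta,
                                eta_on=("cl",))
        expected = (-0.5 * math.log(2 * math.pi) - math.log(0.401)
                    - 0.5 * (0.2 / 0.401) ** 2)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_density_maximal_when_prediction_equals_dv(self):
        """With additive-only error, perturbing DV away from the model
        prediction can only lower the joint density."""
        sigma = (0.0, 1.0)
        base = toy_records()
        # model predictions at the sample times with eta = 0
        obs_t = np.array([2.0, 21.0])
        f = _engine.simulate_conc(obs_t, np.array([0.0]), np.array([528.0]),
                                  np.array([0.0625]), *[THETA[k] for k in
                                  ("cl", "vc", "q", "vp", "vmax", "km")], 0.1)
        rec = toy_records(dv=tuple(f))
        l_star = tp.subject_loglik(rec, THETA, OMEGA, sigma, [0.0],
                                   eta_on=("cl",))
        for shift in (-2.0, -0.5, 0.5, 2.0):
            rec2 = toy_records(dv=tuple(f + shift))
            assert tp.subject_loglik(rec2, THETA, OMEGA, sigma, [0.0],
                                     eta_on=("cl",)) < l_star


class TestLaplaceVsQuadrature:
    @pytest.mark.parametrize("eta_on", [("cl",), ("cl", "vc")])
    def test_laplace_matches_agq_within_tenth(self, eta_on):
        """Laplace -2LL agrees with 11-node adaptive Gauss-Hermite to
        within 0.1 on a small subject."""
        rec = toy_records()
        data = tp.PKDataset(rec)
        lap = -2.0 * tp.marginal_loglik(data, THETA, OMEGA, SIGMA,
                                        eta_on=eta_on)
        agq = agq_neg2ll(rec, THETA, OMEGA, SIGMA, eta_on)
        assert lap == pytest.approx(agq, abs=0.1)

    def test_omega_to_zero_limit_equals_fixed_effects(self):
        rec = toy_records()
        data = tp.PKDataset(rec)
        tiny = {"cl": 1e-4, "vc": 1e-4, "vp": 1e-4, "km": 1e-4}
        lap = -2.0 * tp.marginal_loglik(data, THETA, tiny, SIGMA,
                                        eta_on=("cl", "vc"))
        cfg = ModelConfig(theta_init=dict(THETA), estimate_theta=(),
                          eta_on=(), omega_init=tiny, estimate_omega=False,
                          sigma_init=SIGMA, estimate_sigma=())
        fixed = LikelihoodModel(data, cfg).ofv(np.zeros(0))
        assert lap == pytest.approx(fixed, abs=1e-3)

    def test_duplicating_subjects_doubles_the_loglik(self):
        rec = toy_records()
        rec2 = pd.concat([rec, rec.assign(ID=2)], ignore_index=True)
        one = tp.marginal_loglik(tp.PKDataset(rec), THETA, OMEGA, SIGMA)
        two = tp.marginal_loglik(tp.PKDataset(rec2), THETA, OMEGA, SIGMA)
        assert two == pytest.approx(2 * one, rel=1e-10)


class TestLRT:
    def test_critical_value_at_p_001(self):
        assert tp.lrt(10.83, 0.0, 1) == pytest.approx(0.001, rel=0.01)

    def test_no_improvement_gives_p_one(self):
        assert tp.lrt(100.0, 100.0, 1) == 1.0

    def test_negative_improvement_warns(self):
        with pytest.warns(UserWarning, match="fits worse"):
            assert tp.lrt(100.0, 101.0, 1) == 1.0

    def test_published_nonlinear_cl_decision(self):
        """An OFV drop of 871 points over 2 df is overwhelming evidence
        for the Michaelis-Menten pathway."""
        assert tp.lrt(871.0, 0.0, 2) < 1e-100


class TestEmpiricalBayes:
    def test_no_observations_mode_is_zero(self):
        """With no data the posterior mode of eta is the prior mode."""
        eta_idx = np.array([0], dtype=np.int64)
        om_inv = np.array([[1.0 / 0.401 ** 2]])
        eta, val, H, conv = _engine.eta_mode(
            np.array([0.3]), np.empty(0), np.empty(0), np.array([0.0]),
            np.array([100.0]), np.array([0.0]),
            np.array([0.127, 2.62, 0.544, 2.97, 8.81, 8.92]), eta_idx,
            om_inv, 2 * math.log(0.401), 0.2, 1.0)
        assert conv and abs(eta[0]) < 1e-6

    def test_omega_to_zero_shrinks_mode_to_zero(self):
        rec = toy_records()
        data = tp.PKDataset(rec)
        tiny = {"cl": 1e-3, "vc": 1e-3, "vp": 1e-3, "km": 1e-3}
        ebe = tp.empirical_bayes(data, THETA, tiny, SIGMA, eta_on=("cl",))
        assert abs(ebe["eta_cl"].iloc[0]) < 1e-4

    def test_rich_subject_eta_recovered(self, pp, spec):
        """A subject simulated with known eta gets an EBE near the truth."""
        true_eta = 0.35
        times = np.arange(1.0, 64.0, 3.0)
        sp = tp.subject_from_covariates(tp.TYPICAL_BC, pp,
                                        (true_eta, 0.0, 0.0, 0.0))
        f = _engine.simulate_conc(times, np.array([0.0, 21.0, 42.0]),
                                  np.array([528.0, 396.0, 396.0]),
                                  np.array([0.0625, 0.0208, 0.0208]),
                                  sp.cl, sp.vc, sp.q, sp.vp, sp.vmax, sp.km,
                                  0.1)
        rng = np.random.default_rng(11)
        dv = tp.apply_residual_error(f, pp, rng)
        rows = [{"ID": 1, "TIME": t, "AMT": a, "RATE": a / d if d else 0.0,
                 "EVID": 1, "DV": np.nan, "MDV": 1}
                for t, a, d in [(0.0, 528.0, 0.0625), (21.0, 396.0, 0.0208),
                                (42.0, 396.0, 0.0208)]]
        rows += [{"ID": 1, "TIME": t, "AMT": 0.0, "RATE": 0.0, "EVID": 0,
                  "DV": v, "MDV": 0} for t, v in zip(times, dv)]
        data = tp.PKDataset(pd.DataFrame(rows).sort_values(["TIME", "EVID"]))
        ebe = tp.empirical_bayes(data, THETA, OMEGA, SIGMA, eta_on=("cl",))
        assert ebe["eta_cl"].iloc[0] == pytest.approx(true_eta, abs=0.15)


class TestFit:
    def test_refit_at_optimum_is_stationary(self, pp, spec):
        design = tp.StudyDesign(n_subjects=15, seed=21)
        data, _, _ = tp.generate_dataset(design, pp, spec)
        cfg = ModelConfig(theta_init=dict(THETA), estimate_theta=("cl",),
                          eta_on=("cl",), omega_init={"cl": 0.4, "vc": 0.2,
                                                      "vp": 0.4, "km": 1.0},
                          estimate_omega=False, sigma_init=SIGMA,
                          estimate_sigma=())
        res = tp.fit(data, cfg, maxiter=60)
        cfg2 = ModelConfig(theta_init=dict(res.theta),
                           estimate_theta=("cl",), eta_on=("cl",),
                           omega_init=cfg.omega_init, estimate_omega=False,
                           sigma_init=SIGMA, estimate_sigma=())
        res2 = tp.fit(data, cfg2, maxiter=60)
        assert abs(res2.ofv - res.ofv) < 0.01


class TestPKDataset:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing required column"):
            tp.PKDataset(pd.DataFrame({"ID": [1], "TIME": [0.0]}))

    def test_subject_without_dose_rejected(self):
        df = pd.DataFrame([
            {"ID": 1, "TIME": 1.0, "AMT": 0.0, "EVID": 0, "DV": 5.0,
             "MDV": 0}])
        with pytest.raises(ValueError, match="no dose"):
            tp.PKDataset(df)

    def test_subject_without_observation_rejected(self):
        df = pd.DataFrame([
            {"ID": 1, "TIME": 0.0, "AMT": 100.0, "EVID": 1, "DV": np.nan,
             "MDV": 1}])
        with pytest.raises(ValueError, match="no observation"):
            tp.PKDataset(df)

    def test_drop_blq_counts_and_prunes(self):
        df = toy_records(dv=(60.0, 0.05))
        data = tp.PKDataset(df)
        out, n = data.drop_blq()
        assert n == 1
        assert (out.df["EVID"] == 0).sum() == 1

    def test_csv_roundtrip_with_missing_dots(self, tmp_path, small_dataset):
        data, _ = small_dataset
        path = tmp_path / "data.csv"
        tp.write_nonmem_csv(data, path)
        assert "." in path.read_text().splitlines()[1]
        back = tp.read_nonmem_csv(path)
        assert back.n_subjects == data.n_subjects
        np.testing.assert_allclose(
            back.df["DV"].dropna(), data.df["DV"].dropna(), rtol=1e-12)
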