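"""Tests for MAP/Laplace fitting, MCMC, empirical Bayes and model comparison."""

import math

import numpy as np
import pytest

from prefshift.data import ParticipantDataset, Trial
from prefshift.inference import (
    MODELS,
    ChainConfig,
    ModelSpec,
    PriorSpec,
    compare_models,
    effective_sample_size,
    empirical_bayes_refit,
    fit_perturbation_model,
    map_fit,
    mcmc_fit,
)
from prefshift.models import ku_policy_arrays

from conftest import make_pair


def ku_dataset(m, u, thetas, rng, pid="p", phase=1):
    """Synthetic self-trial dataset from a random-preference agent."""
    trials = []
    for i, th in enumerate(thetas):
        pi = float(ku_policy_arrays(th, m, u))
        trials.append(
            Trial(phase=phase, index=i, role="self", pair=make_pair(float(th)),
                  choice=int(rng.random() < pi))
        )
    return ParticipantDataset(pid, trials)


def two_phase_ku_dataset(m1, m3, u, rng, n=60, pid="p"):
    thetas1 = rng.uniform(-9, 0, n)
    thetas3 = rng.uniform(-9, 0, n // 2)
    ds = ku_dataset(m1, u, thetas1, rng, pid=pid, phase=1)
    for i, th in enumerate(thetas3):
        pi = float(ku_policy_arrays(th, m3, u))
        ds.trials.append(
            Trial(phase=3, index=n + i, role="self", pair=make_pair(float(th)),
                  choice=int(rng.random() < pi))
        )
    return ds


class TestMapFit:
    def test_ku_recovery(self, rng):
        """Median recovered taste mode across replicates lands near truth."""
        est = []
        for _ in range(20):
            ds = ku_dataset(-4.0, 1.0, rng.uniform(-9, 0, 60), rng)
            est.append(map_fit("ku", ds).params["m"])
        assert abs(np.median(est) + 4.0) < 0.5

    def test_all_delayed_flags_boundary(self):
        trials = [
            Trial(phase=1, index=i, role="self", pair=make_pair(th), choice=1)
            for i, th in enumerate(np.linspace(-9, 0, 30))
        ]
        f = map_fit("ku", ParticipantDataset("p", trials))
        assert f.boundary
        assert not f.converged

    def test_kt_symmetric_toy_reaches_analytic_optimum(self):
        """Two identical trials with opposite choices: the optimum puts the
        policy at exactly 0.5 and the log-likelihood at -2 ln 2, which a grid
        search over (k, ln T) cannot beat."""
        trials = [
            Trial(phase=1, index=0, role="self", pair=make_pair(-4.0), choice=1),
            Trial(phase=1, index=1, role="self", pair=make_pair(-4.0), choice=0),
        ]
        ds = ParticipantDataset("p", trials)
        f = map_fit("kt", ds)
        assert f.loglik == pytest.approx(-2 * math.log(2), abs=1e-6)
        # independent grid-search oracle
        spec = MODELS["kt"]
        best = max(
            spec.loglik(np.array([k, lT]), ds)
            for k in np.linspace(-8, 0, 81)
            for lT in np.linspace(-3, 3, 61)
        )
        assert f.loglik >= best - 1e-6

    def test_bic_identity(self, simulated_participant):
        for model in ("kt", "ku", "ps"):
            f = map_fit(model, simulated_participant)
            assert f.bic == pytest.approx(f.recompute_bic())


@pytest.fixture(scope="module")
def gaussian_model():
    """Conjugate toy: unit-variance Gaussian likelihood on the mean."""
    return ModelSpec(
        name="gauss",
        t_names=("mu",),
        n_names=("mu",),
        loglik=lambda x, y: float(-0.5 * np.sum((y - x[0]) ** 2)),
        to_natural=lambda x: {"mu": float(x[0])},
        bounds_lo=(-50.0,),
        bounds_hi=(50.0,),
        start=lambda y: np.array([float(np.mean(y))]),
        n_trials=lambda y: len(y),
    )


class TestMcmc:

    def test_conjugate_posterior_median(self, gaussian_model, rng):
        y = rng.normal(2.0, 1.0, size=40)
        cfg = ChainConfig(iterations=4000, warmup=500, thin=2)
        f = mcmc_fit(gaussian_model, y, chain_cfg=cfg, seed=3)
        post_sd = 1.0 / math.sqrt(len(y))
        mc_err = 3 * post_sd / math.sqrt(min(f.ess["mu"], len(f.samples)))
        assert f.params["mu"] == pytest.approx(float(np.mean(y)), abs=4 * mc_err)
        assert f.converged

    def test_fixed_seed_reproducible(self, gaussian_model, rng):
        y = rng.normal(0.0, 1.0, size=20)
        cfg = ChainConfig(iterations=500, warmup=100, thin=1)
        a = mcmc_fit(gaussian_model, y, chain_cfg=cfg, seed=11)
        b = mcmc_fit(gaussian_model, y, chain_cfg=cfg, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_ess_of_iid_chain(self, rng):
        n = 2000
        ess = effective_sample_size(rng.standard_normal(n))
        assert 0.8 * n <= ess <= 1.2 * n

    def test_agrees_with_map_on_identified_data(self, rng):
        ds = ku_dataset(-4.0, 1.0, np.linspace(-8, -1, 80), rng)
        fm = map_fit("ku", ds)
        fc = mcmc_fit(
            "ku", ds, chain_cfg=ChainConfig(iterations=3000, warmup=500, thin=3),
            seed=0,
        )
        sd = math.sqrt(fc.samples[:, 0].var())
        assert abs(fc.params["m"] - fm.params["m"]) < max(0.5 * sd, 0.1)


@pytest.fixture(scope="module")
def small_population():
    rng = np.random.default_rng(5)
    datasets, fits = [], []
    for i in range(14):
        m = rng.normal(-4.5, 1.5)
        ds = ku_dataset(m, 1.0, rng.uniform(-9, 0, 60), rng, pid=f"p{i}")
        datasets.append(ds)
        fits.append(map_fit("ku", ds, seed=i))
    return datasets, fits


class TestEmpiricalBayes:

    def test_shrinkage(self, small_population):
        datasets, fits = small_population
        refits, priors = empirical_bayes_refit(fits, datasets, "ku", seed=0)
        v1 = np.var([f.params["m"] for f in fits])
        v3 = np.var([f.params["m"] for f in refits])
        assert v3 <= v1 + 1e-9
        assert priors.means is not None

    def test_excluded_participants_reappear(self, small_population):
        datasets, fits = small_population
        # force one fit to be flagged: it must still be refit in stage 3
        fits = list(fits)
        fits[0].converged = False
        refits, _ = empirical_bayes_refit(fits, datasets, "ku", seed=0)
        assert len(refits) == len(datasets)
        assert refits[0].participant_id == datasets[0].participant_id

    def test_too_few_converged_raises(self, small_population):
        datasets, fits = small_population
        bad = []
        for f in fits:
            import copy
            g = copy.copy(f)
            g.converged = False
            bad.append(g)
        with pytest.raises(ValueError):
            empirical_bayes_refit(bad, datasets, "ku", seed=0)

    def test_prior_covers_generating_hyperparameter(self):
        """The stage-2 prior mean for the taste mode brackets the generating
        population mean across replicate small populations."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            datasets, fits = [], []
            for i in range(12):
                m = rng.normal(-4.5, 1.0)
                ds = ku_dataset(m, 1.0, rng.uniform(-9, 0, 60), rng, pid=f"p{i}")
                datasets.append(ds)
                fits.append(map_fit("ku", ds, seed=i))
            _, priors = empirical_bayes_refit(fits, datasets, "ku", seed=0)
            ci = 2 * priors.sds[0] / math.sqrt(12)
            if abs(priors.means[0] + 4.5) < 2 * priors.sds[0]:
                hits += 1
        assert hits >= 8


class TestCompareModels:
    def test_identical_fits_tie(self, rng):
        ds = ku_dataset(-4.0, 1.0, rng.uniform(-9, 0, 40), rng)
        a = map_fit("ku", ds)
        b = map_fit("ku", ds)
        cmp_ = compare_models([a], [b])
        assert cmp_.frac_a_better == 0.5
        assert cmp_.total_delta_bic == pytest.approx(0.0, abs=1e-9)
        assert cmp_.wilcoxon_p == 1.0

    def test_mismatched_participants_raise(self, rng):
        d1 = ku_dataset(-4.0, 1.0, rng.uniform(-9, 0, 20), rng, pid="a")
        d2 = ku_dataset(-4.0, 1.0, rng.uniform(-9, 0, 20), rng, pid="b")
        with pytest.raises(ValueError):
            compare_models([map_fit("ku", d1)], [map_fit("ku", d2)])


class TestPerturbationModel:
    def test_jump_detected_by_bic(self, rng):
        ds = two_phase_ku_dataset(-6.0, -3.0, 0.8, rng)
        fp = fit_perturbation_model(ds)
        f0 = map_fit("ku_static", ds)
        assert f0.bic - fp.bic > 6  # strong evidence for the perturbation

    def test_no_jump_prefers_static_model(self, rng):
        wins = 0
        for i in range(10):
            r = np.random.default_rng(50 + i)
            ds = two_phase_ku_dataset(-5.0, -5.0, 0.8, r)
            fp = fit_perturbation_model(ds)
            f0 = map_fit("ku_static", ds)
            if f0.bic <= fp.bic:
                wins += 1
        assert wins >= 8  # parameter penalty favours the static model

    def test_recovered_jump_tracks_injected_jump(self, rng):
        jumps = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        rec = []
        for j in jumps:
            est = []
            for i in range(5):
                r = np.random.default_rng(int(1000 + 100 * j + i))
                ds = two_phase_ku_dataset(-5.0, -5.0 + j, 0.8, r, n=80)
                f = fit_perturbation_model(ds)
                est.append(f.params["m3"] - f.params["m1"])
            rec.append(np.median(est))
        slope = np.polyfit(jumps, rec, 1)[0]
        assert 0.7 < slope < 1.3

    def test_missing_phase_raises(self, rng):
        ds = ku_dataset(-4.0, 1.0, rng.uniform(-9, 0, 20), rng)
        with pytest.raises(ValueError):
            fit_perturbation_model(ds)
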