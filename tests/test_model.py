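import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist
from scipy.stats import halfnorm, norm

from varscreen import (
    PriorSpec, SamplerConfig, assign_fclass, bayes_factor, build_model_data,
    classify_variants, functional_thresholds, log_joint, prior_for_variant,
    sample_posterior,
)
from varscreen.constants import ABN_ANCHOR_ID, ETA_ABN_ANCHOR, WT_ID
from varscreen.model import bf_from_posterior_probability

L = ETA_ABN_ANCHOR


# ---------------------------------------------------------------------------
# priors

class TestPriorForVariant:
    @pytest.mark.parametrize("annotation, expected", [
        ({"agvgd_class": "C65", "protein_position": 2600}, (15.00, 3.48)),
        ({"agvgd_class": "C35", "protein_position": 30}, (5.38, 2.57)),
        ({"agvgd_class": "C15", "protein_position": 3280}, (3.76, 9.00)),
        ({"agvgd_class": "C0", "protein_position": 2481}, (1.43, 73.1)),
        ({"agvgd_class": "C65", "protein_position": 1500}, (1.64, 120.44)),
        ({"agvgd_class": "", "protein_position": 41}, (1.64, 120.44)),
        ({"nonsense": True, "protein_position": 100}, (387, 1.07)),
    ])
    def test_align_gvgd_categories(self, annotation, expected):
        assert prior_for_variant(annotation, "align_gvgd") == expected

    def test_domain_boundaries_are_inside(self):
        for pos in (10, 40, 2481, 3186, 3269, 3305):
            params = prior_for_variant(
                {"agvgd_class": "C65", "protein_position": pos},
                "align_gvgd")
            assert params == (15.00, 3.48)

    def test_noninformative_always_flat(self):
        assert prior_for_variant({"agvgd_class": "C65",
                                  "protein_position": 2600}) == (1.0, 1.0)

    def test_missing_grade_inside_domain_raises(self):
        with pytest.raises(ValueError, match="Align-GVGD"):
            prior_for_variant({"agvgd_class": "", "protein_position": 2600},
                              "align_gvgd")


# ---------------------------------------------------------------------------
# joint density vs independently coded oracle

def toy_data():
    obs = pd.DataFrame({
        "variant_id": [WT_ID, WT_ID, "P1", "P1", "U1", "U1"],
        "batch": [1, 2, 1, 2, 1, 2],
        "drug": "niraparib",
        "replicate": [1, 1, 1, 1, 1, 1],
        "f": [0.1, -0.2, -2.3, -2.6, -1.0, -1.4],
    })
    ann = pd.DataFrame({
        "variant_id": [WT_ID, "P1", "U1"],
        "label": ["benign", "pathogenic", "unknown"],
        "protein_position": [0, 2700, 1500],
        "agvgd_class": ["", "C65", ""],
        "nonsense": False,
    })
    return obs, ann


def oracle_log_joint(state, obs, priors, pi_ab=(1.0, 1.0)):
    """Straight sum of log densities, coded independently of the
    implementation: explicit loops, scipy distributions only."""
    lp = 0.0
    idx = {"P1": 0, "U1": 1, WT_ID: 2}  # sorted variant order
    for _, row in obs.iterrows():
        b = int(row["batch"]) - 1
        eta_v = state["eta"][idx[row["variant_id"]]]
        mu = state["beta"][b] + state["tau"][b] * eta_v
        lp += norm.logpdf(row["f"], mu, state["tau"][b] * state["psi"])
    for b in range(2):
        lp += norm.logpdf(state["beta"][b], state["kappa1"], state["lambda1"])
        lp += norm.logpdf(state["tau"][b], state["kappa2"], state["lambda2"])
    # P1 is labelled pathogenic: abnormal component, no mixture
    lp += norm.logpdf(state["eta"][idx["P1"]], state["eta_abn"],
                      state["sigma1"])
    # U1 is unknown: indicator marginalized
    pi = state["pi"][idx["U1"]]
    lp += math.log(
        pi * norm.pdf(state["eta"][idx["U1"]], state["eta_abn"],
                      state["sigma1"])
        + (1 - pi) * norm.pdf(state["eta"][idx["U1"]], priors.eta_nor,
                              state["sigma2"]))
    lp += beta_dist.logpdf(pi, *pi_ab)
    lp += norm.logpdf(state["kappa1"], 0, 5)
    lp += norm.logpdf(state["kappa2"], 1, 5)
    for name in ("psi", "sigma1", "sigma2", "lambda1", "lambda2"):
        lp += halfnorm.logpdf(state[name], scale=5)
    lp += norm.logpdf(state["eta_abn"], L, 5)
    return lp


@pytest.mark.parametrize("state_seed", [0, 1, 2, 3, 4])
def test_log_joint_matches_oracle(state_seed):
    obs, ann = toy_data()
    data = build_model_data(obs, ann)
    priors = PriorSpec(eta_nor=0.0)
    rng = np.random.default_rng(state_seed)
    state = {
        "eta": np.array([rng.normal(-2.5, 0.5), rng.normal(-1, 0.5), 0.0]),
        "beta": rng.normal(0, 0.3, 2),
        "tau": rng.uniform(0.7, 1.3, 2),
        "psi": rng.uniform(0.1, 0.6),
        "sigma1": rng.uniform(0.1, 0.6),
        "sigma2": rng.uniform(0.1, 0.6),
        "lambda1": rng.uniform(0.1, 0.6),
        "lambda2": rng.uniform(0.1, 0.6),
        "kappa1": rng.normal(0, 0.5),
        "kappa2": rng.normal(1, 0.5),
        "eta_abn": rng.normal(L, 0.3),
        "pi": np.array([0.0, rng.uniform(0.05, 0.95), 0.0]),
    }
    got = log_joint(state, data, priors, mode="training")
    want = oracle_log_joint(state, obs, priors)
    assert got == pytest.approx(want, abs=1e-10)


def test_log_joint_standard_normal_likelihood_term():
    """One observation at f=0 for the wild-type anchor with unit batch
    effects and psi=1 contributes exactly log N(0; 0, 1)."""
    obs = pd.DataFrame({
        "variant_id": [WT_ID], "batch": [1], "drug": "d",
        "replicate": [1], "f": [0.0]})
    ann = pd.DataFrame({"variant_id": [WT_ID], "label": ["benign"]})
    data = build_model_data(obs, ann)
    priors = PriorSpec(eta_nor=0.0)
    state = {
        "eta": np.array([0.0]), "beta": np.array([0.0]),
        "tau": np.array([1.0]), "psi": 1.0, "sigma1": 1.0, "sigma2": 1.0,
        "lambda1": 1.0, "lambda2": 1.0, "kappa1": 0.0, "kappa2": 1.0,
        "eta_abn": L, "pi": np.array([0.5]),
    }
    base = log_joint(state, data, priors, mode="training")
    # remove the likelihood term by moving the observation's density to 1:
    # recompute all prior terms with an explicit sum
    prior_terms = (
        norm.logpdf(state["beta"][0], 0.0, 1.0)
        + norm.logpdf(state["tau"][0], 1.0, 1.0)
        + norm.logpdf(0.0, 0, 5) + norm.logpdf(1.0, 1, 5)
        + 5 * halfnorm.logpdf(1.0, scale=5)
        + norm.logpdf(L, L, 5)
    )
    assert base - prior_terms == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)),
                                               abs=1e-12)
    assert base - prior_terms == pytest.approx(-0.9189, abs=1e-4)


def test_log_joint_rejects_invalid_scales():
    obs, ann = toy_data()
    data = build_model_data(obs, ann)
    priors = PriorSpec(eta_nor=0.0)
    state = {
        "eta": np.zeros(3), "beta": np.zeros(2), "tau": np.ones(2),
        "psi": 0.3, "sigma1": 0.3, "sigma2": 0.3, "lambda1": 0.3,
        "lambda2": 0.3, "kappa1": 0.0, "kappa2": 1.0, "eta_abn": L,
        "pi": np.full(3, 0.5),
    }
    for bad in ({"tau": np.array([1.0, -0.1])}, {"psi": 0.0},
                {"sigma1": -1.0}):
        assert log_joint({**state, **bad}, data, priors) == -np.inf


def test_mixture_term_symmetric_at_equidistant_eta():
    """When eta_v sits midway between the component centres with equal
    sds and pi=0.5, both components contribute equally: the mixture term
    equals the single-component density (log weight cancels)."""
    obs = pd.DataFrame({
        "variant_id": ["U1"], "batch": [1], "drug": "d", "replicate": [1],
        "f": [-1.26]})
    ann = pd.DataFrame({"variant_id": ["U1"], "label": ["unknown"],
                        "protein_position": [1500], "agvgd_class": [""],
                        "nonsense": [False]})
    data = build_model_data(obs, ann)
    priors = PriorSpec(eta_nor=0.0, eta_abn_fixed=L)
    mid = L / 2
    state = {
        "eta": np.array([mid]), "beta": np.array([0.0]),
        "tau": np.array([1.0]), "psi": 0.3, "sigma1": 0.4, "sigma2": 0.4,
        "lambda1": 0.3, "lambda2": 0.3, "kappa1": 0.0, "kappa2": 1.0,
        "eta_abn": L, "pi": np.array([0.5]),
    }
    lp_mid = log_joint(state, data, priors, mode="full")
    # replace the mixture with a pure abnormal-component density by
    # setting pi -> 1: the two must agree since both components have the
    # same density at the midpoint
    lp_pure = log_joint({**state, "pi": np.array([1.0 - 1e-12])}, data,
                        priors, mode="full")
    assert lp_mid == pytest.approx(lp_pure, abs=1e-9)


# ---------------------------------------------------------------------------
# Bayes factor: odds arithmetic and quadrature oracle

class TestBfArithmetic:
    def test_posterior_099_noninformative_gives_99(self):
        bf, clamped = bf_from_posterior_probability(0.99, 0.5)
        assert bf == pytest.approx(99.0)
        assert not clamped

    def test_no_evidence_gives_unity(self):
        for p0 in (0.5, 0.2, 0.9):
            bf, _ = bf_from_posterior_probability(p0, p0)
            assert bf == pytest.approx(1.0)

    def test_extreme_probabilities_clamped(self):
        assert bf_from_posterior_probability(1.0, 0.5) == (1e8, True)
        assert bf_from_posterior_probability(0.0, 0.5) == (1e-8, True)


def one_variant_fixture():
    f_obs = np.array([-1.6, -1.9, -1.3])
    globals_ = dict(beta=np.array([0.1]), tau=np.array([1.1]), psi=0.35,
                    sigma1=0.4, sigma2=0.35, kappa1=0.0, kappa2=1.0,
                    lambda1=0.3, lambda2=0.3)
    eta_abn = L
    eta_nor = 0.0
    return f_obs, globals_, eta_abn, eta_nor


def quadrature_p_abnormal(f_obs, g, eta_abn, eta_nor, p0):
    """2-D integration over the variant effect and the two-valued mixture
    indicator, everything else fixed."""

    def lik(eta):
        mu = g["beta"][0] + g["tau"][0] * eta
        return float(np.prod(norm.pdf(f_obs, mu, g["tau"][0] * g["psi"])))

    span = (-8.0, 4.0)
    num = p0 * quad(lambda e: norm.pdf(e, eta_abn, g["sigma1"]) * lik(e),
                    *span)[0]
    den = (1 - p0) * quad(lambda e: norm.pdf(e, eta_nor, g["sigma2"]) * lik(e),
                          *span)[0]
    return num / (num + den)


def test_one_variant_bf_matches_quadrature():
    f_obs, g, eta_abn, eta_nor = one_variant_fixture()
    obs = pd.DataFrame({
        "variant_id": "Q", "batch": 1, "drug": "d",
        "replicate": [1, 2, 3], "f": f_obs})
    ann = pd.DataFrame({"variant_id": ["Q"], "label": ["unknown"],
                        "protein_position": [1500], "agvgd_class": [""],
                        "nonsense": [False]})
    data = build_model_data(obs, ann)
    priors = PriorSpec(eta_nor=eta_nor, eta_abn_fixed=eta_abn,
                       pi_fixed_at_mean=True)
    config = SamplerConfig(chains=4, warmup=200, draws=2000, seed=3)
    draws = sample_posterior(data, priors, config, mode="full",
                             fixed_params=g)
    bf = bayes_factor(draws, "Q")
    p_star = quadrature_p_abnormal(f_obs, g, eta_abn, eta_nor, p0=0.5)
    bf_star = (p_star / (1 - p_star)) / (0.5 / 0.5)
    assert bf.value == pytest.approx(bf_star, rel=0.05)


def test_posterior_p_abnormal_monotone_in_prior_mean():
    """On fixed data, raising the prior probability of abnormality never
    lowers the posterior probability (checked on the quadrature oracle,
    including the Align-GVGD C65 prior mean)."""
    f_obs, g, eta_abn, eta_nor = one_variant_fixture()
    p65 = 15.00 / (15.00 + 3.48)
    means = [0.05, 0.2, 0.5, p65, 0.95]
    ps = [quadrature_p_abnormal(f_obs, g, eta_abn, eta_nor, p0)
          for p0 in means]
    assert all(b >= a for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# fClass mapping

class TestAssignFclass:
    @pytest.mark.parametrize("bf, expected", [
        (0.003, 1),      # boundary inclusive
        (0.0029, 1),
        (0.0031, 2),
        (0.053, 2),      # boundary inclusive
        (0.054, 3),
        (1.0, 3),
        (18.69, 3),
        (18.7, 4),       # boundary inclusive on the abnormal side
        (349.9, 4),
        (350.0, 5),
        (785.0, 5),
    ])
    def test_mapping(self, bf, expected):
        assert assign_fclass(bf) == expected

    def test_invalid_bf_rejected(self):
        for bad in (0.0, -1.0, float("nan")):
            with pytest.raises(ValueError):
                assign_fclass(bad)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=-8, max_value=8),
           st.floats(min_value=-8, max_value=8))
    def test_monotone_in_bf(self, a, b):
        lo, hi = sorted((10.0 ** a, 10.0 ** b))
        assert assign_fclass(lo) <= assign_fclass(hi)


# ---------------------------------------------------------------------------
# functional thresholds

class TestFunctionalThresholds:
    def make_cls(self, etas):
        return pd.DataFrame({
            "variant_id": list(etas), "eta_mean": list(etas.values())})

    def test_published_style_thresholds(self):
        cls = self.make_cls({"b1": -0.2, "R18H": -1.38,
                             "C2535X": -2.17, "p2": -3.0})
        labels = pd.Series({"b1": "benign", "R18H": "benign",
                            "C2535X": "pathogenic", "p2": "pathogenic"})
        th = functional_thresholds(cls, labels)
        assert th.higher == pytest.approx(-1.38)
        assert th.lower == pytest.approx(-2.17)
        assert th.separating

    def test_zones(self):
        cls = self.make_cls({"b": -1.0, "p": -2.5, "q_hi": -0.1,
                             "q_mid": -1.7, "q_lo": -3.2})
        labels = pd.Series({"b": "benign", "p": "pathogenic"})
        th = functional_thresholds(cls, labels)
        zones = th.zones.set_index("variant_id")["zone"]
        assert zones["q_hi"] == "normal"
        assert zones["q_mid"] == "intermediate"
        assert zones["q_lo"] == "abnormal"

    def test_nonseparating_flagged_not_raised(self):
        cls = self.make_cls({"b": -2.5, "p": -1.0})
        labels = pd.Series({"b": "benign", "p": "pathogenic"})
        th = functional_thresholds(cls, labels)
        assert not th.separating

    def test_single_class_raises(self):
        cls = self.make_cls({"b": -1.0})
        labels = pd.Series({"b": "benign"})
        with pytest.raises(ValueError):
            functional_thresholds(cls, labels)


# ---------------------------------------------------------------------------
# sampler contract

@pytest.fixture(scope="module")
def small_fit(request):
    from conftest import make_recovery_observations, make_recovery_truth
    truth = make_recovery_truth(seed=0, n_unknown=10)
    obs = make_recovery_observations(truth, seed=0)
    data = build_model_data(obs, truth)
    priors = PriorSpec(eta_nor=0.0)
    config = SamplerConfig(chains=4, warmup=250, draws=600, seed=5)
    draws = sample_posterior(data, priors, config, mode="training")
    return truth, obs, data, priors, config, draws


def test_fixed_seed_reproducible(small_fit):
    truth, obs, data, priors, config, draws = small_fit
    again = sample_posterior(data, priors, config, mode="training")
    for name in draws.params:
        assert np.array_equal(draws.params[name], again.params[name])


def test_anchors_constant_across_draws(small_fit):
    *_, draws = small_fit
    wt = draws.eta(WT_ID)
    ab = draws.eta(ABN_ANCHOR_ID)
    assert np.all(wt == 0.0)
    assert np.allclose(ab, L)


def test_rhat_below_contract_threshold(small_fit):
    *_, draws = small_fit
    assert draws.rhat_table.max() < 1.1


def test_classification_table_invariants(small_fit):
    *_, draws = small_fit
    cls = classify_variants(draws)
    assert (cls["ci_low"] <= cls["eta_mean"]).all()
    assert (cls["eta_mean"] <= cls["ci_high"]).all()
    assert (cls["bayes_factor"] > 0).all()
    for _, row in cls.iterrows():
        assert assign_fclass(row["bayes_factor"]) == row["fclass"]


def test_observation_order_does_not_change_inference(small_fit):
    """Exchangeability: permuting observation rows leaves the posterior
    unchanged up to Monte Carlo error."""
    truth, obs, data, priors, config, draws = small_fit
    shuffled = obs.sample(frac=1.0, random_state=1).reset_index(drop=True)
    data2 = build_model_data(shuffled, truth)
    draws2 = sample_posterior(data2, priors, config, mode="training")
    cls1 = classify_variants(draws).set_index("variant_id")
    cls2 = classify_variants(draws2).set_index("variant_id")
    diff = (np.log10(cls1["bayes_factor"])
            - np.log10(cls2["bayes_factor"]).reindex(cls1.index))
    assert np.abs(diff).max() < 0.5
    assert np.abs(cls1["eta_mean"] - cls2["eta_mean"]).max() < 0.1


def test_empty_data_rejected():
    obs, ann = toy_data()
    data = build_model_data(obs, ann)
    data.f = np.empty(0)
    with pytest.raises(ValueError):
        sample_posterior(data, PriorSpec(eta_nor=0.0))


def test_full_mode_requires_fixed_eta_abn():
    obs, ann = toy_data()
    data = build_model_data(obs, ann)
    with pytest.raises(ValueError, match="eta_abn"):
        sample_posterior(data, PriorSpec(eta_nor=0.0),
                         SamplerConfig(chains=2, warmup=10, draws=10),
                         mode="full")
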