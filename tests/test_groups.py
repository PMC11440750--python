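import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfblup import groups, popstruct, simdata
from mfblup.errors import DataError, ValidationError
from mfblup.pedigree import Pedigree
from tests.conftest import brute_force_group_fractions


def flat_pedigree(years, pop="P"):
    n = len(years)
    return Pedigree(pd.DataFrame({
        "id": np.arange(1, n + 1), "sire": 0, "dam": 0,
        "year": years, "flock": "f", "pop": pop}))


# ----------------------------------------------------------------------
# Group assignment
# ----------------------------------------------------------------------
def test_assign_groups_two_cohorts():
    ped = flat_pedigree([1960, 1963, 1965, 1969])
    gd = groups.assign_groups(ped)
    assert gd.n_groups == 2
    assert gd.groups == [("P", (1960, 1964)), ("P", (1965, 1969))]


def test_assign_groups_interval_equals_span():
    ped = flat_pedigree([1960, 1969])
    gd = groups.assign_groups(ped, interval_years=10)
    assert gd.n_groups == 1


def test_assign_groups_counting_oracle(small_sim):
    _, pop = small_sim
    ped = pop.pedigree
    gd = groups.assign_groups(ped, interval_years=5)
    expected = 0
    for p in ped.df["pop"].unique():
        yrs = ped.df.loc[ped.df["pop"] == p, "year"]
        span = yrs.max() - yrs.min() + 1
        expected += 1 if span <= 5 else int(np.ceil(span / 5))
    assert gd.n_groups == expected
    # every unknown parent maps to exactly one group
    for _, row in ped.df.iterrows():
        idx = gd.group_of(str(row["pop"]), int(row["year"]))
        assert 0 <= idx < gd.n_groups


def test_groupdef_yaml_roundtrip(tmp_path):
    gd = groups.GroupDefinition([("A", (2000, 2004)), ("A", (2005, 2009)), ("B", (2000, 2009))])
    gd.to_yaml(tmp_path / "g.yaml")
    back = groups.GroupDefinition.from_yaml(tmp_path / "g.yaml")
    assert back.groups == gd.groups


def test_groupdef_rejects_gapped_intervals():
    with pytest.raises(ValidationError):
        groups.GroupDefinition([("A", (2000, 2004)), ("A", (2006, 2009))])


# ----------------------------------------------------------------------
# Group fractions
# ----------------------------------------------------------------------
def test_group_fractions_founder_and_half():
    ped = Pedigree(pd.DataFrame({
        "id": [1, 2], "sire": [0, 1], "dam": [0, 0],
        "year": [2000, 2006], "flock": "f", "pop": "P"}))
    gd = groups.assign_groups(ped)
    Q = groups.group_fractions(ped, gd).frame()
    assert gd.n_groups == 2
    # founder: unit vector on its own cohort group
    assert Q.iloc[0].tolist() == [1.0, 0.0]
    # known sire (cohort-1 pure) + unknown dam (offspring cohort group)
    assert Q.iloc[1].tolist() == [0.5, 0.5]


def test_group_fractions_rows_sum_to_one_and_match_oracle(small_sim):
    _, pop = small_sim
    sub = Pedigree(pop.pedigree.df.iloc[:50].reset_index(drop=True))
    gd = groups.assign_groups(pop.pedigree)
    Q = groups.group_fractions(sub, gd)
    assert np.allclose(Q.values.sum(axis=1), 1.0)
    assert np.allclose(Q.values, brute_force_group_fractions(sub, gd), atol=1e-12)


# ----------------------------------------------------------------------
# Base allele frequencies
# ----------------------------------------------------------------------
def test_base_frequencies_single_population_is_mean():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(20, 15)).astype(np.int8)
    g = popstruct.GenotypeSet(calls, np.arange(1, 21), [f"M{j}" for j in range(15)])
    P, _ = groups.base_allele_frequencies(g, np.ones((20, 1)), labels=["P"])
    assert np.allclose(P.loc["P"], calls.mean(axis=0) / 2)


def test_base_frequencies_purebred_blocks():
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
    Q = np.zeros((30, 2))
    Q[:18, 0] = 1.0
    Q[18:, 1] = 1.0
    g = popstruct.GenotypeSet(calls, np.arange(1, 31), [f"M{j}" for j in range(10)])
    P, _ = groups.base_allele_frequencies(g, Q, labels=["A", "B"])
    assert np.allclose(P.loc["A"], calls[:18].mean(axis=0) / 2)
    assert np.allclose(P.loc["B"], calls[18:].mean(axis=0) / 2)


def test_base_frequencies_admixed_normal_equations_oracle():
    rng = np.random.default_rng(2)
    calls = rng.integers(0, 3, size=(40, 8)).astype(np.int8)
    mix = rng.dirichlet([2, 2, 2], size=40)
    g = popstruct.GenotypeSet(calls, np.arange(1, 41), [f"M{j}" for j in range(8)])
    P, _ = groups.base_allele_frequencies(g, mix)
    for j in range(8):
        want = np.linalg.solve(mix.T @ mix, mix.T @ calls[:, j].astype(float)) / 2
        assert np.allclose(P.iloc[:, j], np.clip(want, 0, 1), atol=1e-10)


def test_base_frequencies_unrepresented_population_raises():
    calls = np.ones((5, 3), dtype=np.int8)
    Q = np.zeros((5, 2))
    Q[:, 0] = 1.0
    g = popstruct.GenotypeSet(calls, np.arange(1, 6), ["a", "b", "c"])
    with pytest.raises(DataError, match="B"):
        groups.base_allele_frequencies(g, Q, labels=["A", "B"])


# ----------------------------------------------------------------------
# Γ entry formulas
# ----------------------------------------------------------------------
@pytest.mark.parametrize("p, expected", [
    ([0.5, 0.5, 0.5], 0.0),
    ([0.0, 1.0, 0.0], 2.0),
    ([0.2, 0.8], 0.72),
])
def test_gamma_ancestral_values(p, expected):
    assert groups.gamma_ancestral(p) == pytest.approx(expected)


def test_gamma_between_values():
    assert groups.gamma_between([0.2, 0.8], [0.8, 0.2]) == pytest.approx(-0.72)
    assert groups.gamma_between([0.5, 0.5], [0.1, 0.9]) == pytest.approx(0.0)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
@settings(deadline=None, max_examples=50)
def test_gamma_self_consistency(p):
    assert groups.gamma_between(p, p) == pytest.approx(groups.gamma_ancestral(p))
    assert 0.0 <= groups.gamma_ancestral(p) <= 2.0


@pytest.mark.parametrize("dF, g0, expected", [
    (0.01, 0.5, 0.0075),
    (0.02, 0.0, 0.02),
    (0.02, 2.0, 0.0),
])
def test_delta_f_gamma(dF, g0, expected):
    assert groups.delta_f_gamma(dF, g0) == pytest.approx(expected)


# ----------------------------------------------------------------------
# Inbreeding trend
# ----------------------------------------------------------------------
def test_resolve_delta_f_replacement_rule():
    resolved, used = groups.resolve_delta_f(np.array([-0.001, 0.002, 0.004]), c=0.0)
    assert np.allclose(resolved, [0.003, 0.002, 0.004])
    assert not used


def test_resolve_delta_f_keeps_large_c():
    resolved, used = groups.resolve_delta_f(np.array([0.002]), c=0.005, c_tol=1e-3)
    assert used and resolved[0] == pytest.approx(0.007)


def test_trend_fit_noiseless_interpolation():
    # f_i = 0.001 * t_i within one pure population: exact recovery
    n = 30
    years = 2000 + np.arange(n) % 10
    ped = Pedigree(pd.DataFrame({
        "id": np.arange(1, n + 3), "sire": [0, 0] + [1] * n, "dam": [0, 0] + [2] * n,
        "year": [1999, 1999] + list(years), "flock": "f", "pop": "P"}))
    f = np.r_[0.0, 0.0, 0.001 * (years - 1999)]
    fit = groups.fit_inbreeding_trend(ped, np.ones((n + 2, 1)), populations=["P"],
                                      inbreeding=f)
    assert fit.d[0] == pytest.approx(0.001, abs=1e-12)
    assert fit.delta_f[0] == pytest.approx(0.001, abs=1e-12)


def test_trend_fit_matches_lstsq_oracle():
    rng = np.random.default_rng(3)
    n = 200
    Q = rng.dirichlet([3, 3], size=n)
    years = rng.integers(2000, 2020, size=n)
    sire = np.r_[0, 0, np.full(n - 2, 1)]
    dam = np.r_[0, 0, np.full(n - 2, 2)]
    ped = Pedigree(pd.DataFrame({
        "id": np.arange(1, n + 1), "sire": sire, "dam": dam,
        "year": np.r_[1999, 1999, years[2:]], "flock": "f", "pop": "P"}))
    f = rng.random(n) * 0.05
    fit = groups.fit_inbreeding_trend(ped, Q, populations=["A", "B"], inbreeding=f)
    both = np.arange(n) >= 2
    t = (ped.df["year"].to_numpy() - ped.df["year"].min()).astype(float)[both]
    # rows of Q sum to one, so the shared slope is collinear with the
    # per-population slopes and the estimator fits c = 0
    X = np.hstack([Q[both], t[:, None] * Q[both]])
    beta = np.linalg.lstsq(X, f[both], rcond=None)[0]
    assert fit.c == 0.0
    assert np.allclose(np.r_[fit.b, fit.d], beta, atol=1e-8)


def test_trend_fit_requires_fully_pedigreed_animals():
    ped = flat_pedigree([2000, 2001, 2002])
    with pytest.raises(DataError):
        groups.fit_inbreeding_trend(ped, np.ones((3, 1)), inbreeding=np.zeros(3))


# ----------------------------------------------------------------------
# Trend Γ construction
# ----------------------------------------------------------------------
def test_build_gamma_trend_block():
    gd = groups.GroupDefinition(
        [("P", (2000, 2004)), ("P", (2005, 2009)), ("P", (2010, 2014))])
    gm = groups.build_gamma_trend(gd, {"P": 0.48}, {}, {"P": 0.001})
    want = np.array([[0.48, 0.48, 0.48], [0.48, 0.49, 0.49], [0.48, 0.49, 0.50]])
    assert np.allclose(gm.matrix, want, atol=1e-12)
    d = np.diag(gm.matrix)
    assert np.all(np.diff(d) >= 0)  # monotone along the diagonal


def test_build_gamma_trend_degenerate_cases():
    gd = groups.GroupDefinition([("P", (2000, 2004)), ("P", (2005, 2009))])
    flat = groups.build_gamma_trend(gd, {"P": 0.3}, {}, {"P": 0.0})
    assert np.allclose(flat.matrix, 0.3)
    single = groups.GroupDefinition([("P", (2000, 2009))], interval_years=10)
    gm = groups.build_gamma_trend(single, {"P": 0.42}, {}, {"P": 0.01})
    assert gm.matrix.shape == (1, 1) and gm.matrix[0, 0] == pytest.approx(0.42)


def test_build_gamma_trend_between_blocks():
    gd = groups.GroupDefinition(
        [("A", (2000, 2004)), ("A", (2005, 2009)), ("B", (2000, 2009))])
    gm = groups.build_gamma_trend(gd, {"A": 0.5, "B": 0.6}, {("A", "B"): 0.4},
                                  {"A": 0.001, "B": 0.0})
    M = gm.values
    assert M.loc["A|2000-2004", "B|2000-2009"] == 0.4
    assert M.loc["B|2000-2009", "A|2005-2009"] == 0.4
    assert np.allclose(gm.matrix, gm.matrix.T)


# ----------------------------------------------------------------------
# GLS Γ
# ----------------------------------------------------------------------
def test_gamma_gls_collapses_to_pooled_ancestral():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 3, size=(25, 40)).astype(np.int8)
    g = popstruct.GenotypeSet(calls, np.arange(1, 26), [f"M{j}" for j in range(40)])
    gm = groups.estimate_gamma_gls(g, np.ones((25, 1)), labels=["only"])
    pooled = calls.mean(axis=0) / 2
    assert gm.matrix[0, 0] == pytest.approx(groups.gamma_ancestral(pooled))


def test_gamma_gls_recovers_simulated_bases():
    cfg = simdata.SimConfig(
        n_populations=3, population_names=["A", "B", "C"], drift_F=[0.02, 0.05, 0.01],
        n_markers=2000, seed=8)
    freqs = simdata.simulate_founder_frequencies(cfg)
    rng = np.random.default_rng(0)
    per_pop = 250
    calls = np.vstack([
        rng.binomial(2, freqs.loc[p], size=(per_pop, cfg.n_markers)) for p in cfg.population_names
    ]).astype(np.int8)
    Q = np.kron(np.eye(3), np.ones((per_pop, 1)))
    g = popstruct.GenotypeSet(calls, np.arange(1, 3 * per_pop + 1),
                              [f"M{j}" for j in range(cfg.n_markers)])
    gm = groups.estimate_gamma_gls(g, Q, labels=cfg.population_names)
    for i, p in enumerate(cfg.population_names):
        truth = groups.gamma_ancestral(freqs.loc[p].to_numpy())
        assert gm.matrix[i, i] == pytest.approx(truth, abs=0.05)


def test_gamma_gls_small_group_has_larger_replicate_variance():
    cfg = simdata.SimConfig(n_populations=2, population_names=["big", "small"],
                            drift_F=[0.02, 0.02], n_markers=500, seed=1)
    diags = {"big": [], "small": []}
    for seed in range(8):
        freqs = simdata.simulate_founder_frequencies(cfg.replace(seed=seed))
        rng = np.random.default_rng(seed + 100)
        calls = np.vstack([
            rng.binomial(2, freqs.loc["big"], size=(400, 500)),
            rng.binomial(2, freqs.loc["small"], size=(2, 500)),
        ]).astype(np.int8)
        Q = np.zeros((402, 2)); Q[:400, 0] = 1; Q[400:, 1] = 1
        g = popstruct.GenotypeSet(calls, np.arange(1, 403), [f"M{j}" for j in range(500)])
        gm = groups.estimate_gamma_gls(g, Q, labels=["big", "small"])
        truth = {p: groups.gamma_ancestral(freqs.loc[p].to_numpy()) for p in ("big", "small")}
        diags["big"].append(gm.matrix[0, 0] - truth["big"])
        diags["small"].append(gm.matrix[1, 1] - truth["small"])
    assert np.var(diags["small"]) > np.var(diags["big"])


def test_gamma_gls_reports_representation(small_dataset):
    _, _, ds, gd = small_dataset
    Q = groups.group_fractions(ds.pedigree, gd)
    gm = groups.estimate_gamma_gls(ds.genotypes, Q)
    assert set(gm.representation) == set(gd.labels)
    assert sum(gm.representation.values()) == pytest.approx(ds.genotypes.n_animals)


# ----------------------------------------------------------------------
# Γ validation
# ----------------------------------------------------------------------
def test_check_gamma_passthrough_and_projection():
    ok = groups.GammaMatrix(pd.DataFrame(np.eye(3) * 0.5))
    assert groups.check_gamma(ok) is ok
    bad = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.warns(UserWarning, match="projected"):
        fixed = groups.check_gamma(groups.GammaMatrix(bad))
    w, U = np.linalg.eigh(bad.to_numpy())
    want = (U * np.clip(w, 0, None)) @ U.T
    assert np.allclose(fixed.matrix, want, atol=1e-12)
    assert np.linalg.eigvalsh(fixed.matrix).min() >= -1e-10


def test_check_gamma_rejects_asymmetric():
    with pytest.raises(ValidationError):
        groups.GammaMatrix(pd.DataFrame([[1.0, 0.2], [0.3, 1.0]]))


def test_gamma_csv_roundtrip(tmp_path):
    gm = groups.GammaMatrix(
        pd.DataFrame([[0.5, 0.4], [0.4, 0.6]], index=["a", "b"], columns=["a", "b"]),
        method="trend")
    gm.to_csv(tmp_path / "g.csv")
    back = groups.GammaMatrix.from_csv(tmp_path / "g.csv")
    assert back.method == "trend"
    assert np.allclose(back.matrix, gm.matrix)
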