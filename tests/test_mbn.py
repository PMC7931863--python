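"""Conditional-Gaussian scoring, constraints, search and parameters."""

import itertools

import networkx as nx
import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_cohort, random_cg_cohort
from vambn.mbn import (
    EdgeConstraints,
    MbnNode,
    bootstrap_edges,
    build_constraints,
    fit_parameters,
    local_score,
    loglik,
    tabu_search,
    total_score,
)

# ---------------------------------------------------------------------------
# independent brute-force scorer (statsmodels OLS, explicit partitioning)
# ---------------------------------------------------------------------------


def brute_force_score(node, parents, cohort):
    N = cohort.n
    disc = sorted(p for p in parents
                  if cohort.node(p).kind != "gaussian_code")
    cont = sorted(p for p in parents
                  if cohort.node(p).kind == "gaussian_code")
    cards = [cohort.node(p).n_levels for p in disc]
    configs = list(itertools.product(*[range(c) for c in cards])) or [()]
    logl = 0.0
    if cohort.node(node).kind == "gaussian_code":
        for cfg in configs:
            sel = np.ones(N, dtype=bool)
            for p, v in zip(disc, cfg):
                sel &= cohort.values[p].to_numpy() == v
            n_c = int(sel.sum())
            if n_c == 0:
                continue
            y = cohort.values[node].to_numpy(dtype=float)[sel]
            Xd = sm.add_constant(
                cohort.values[cont].to_numpy(dtype=float)[sel], has_constant="add")
            res = sm.OLS(y, Xd).fit()
            sigma2 = max(float(res.ssr) / n_c, 1e-10)
            logl += (-0.5 * n_c * (np.log(sigma2) + np.log(2 * np.pi) + 1)
                     + n_c * np.log(n_c / N))
        n_par = len(configs) * (2 + len(cont))
    else:
        L = cohort.node(node).n_levels
        for cfg in configs:
            sel = np.ones(N, dtype=bool)
            for p, v in zip(disc, cfg):
                sel &= cohort.values[p].to_numpy() == v
            n_c = int(sel.sum())
            if n_c == 0:
                continue
            yv = cohort.values[node].to_numpy()[sel]
            for lev in range(L):
                k = int((yv == lev).sum())
                if k:
                    logl += k * np.log(k / n_c)
        n_par = len(configs) * (L - 1)
    return logl - 0.5 * np.log(N) * n_par


def test_parentless_gaussian_score_has_closed_form():
    r = np.random.default_rng(0)
    y = r.normal(2.0, 1.3, 500)
    co = make_cohort({"Y": y}, [("Y", "gaussian_code", 0)])
    s = local_score(co.columns[0], set(), co)
    sig2 = y.var()
    expect = -250 * (np.log(sig2) + np.log(2 * np.pi) + 1) - np.log(500) / 2 * 2
    assert s == pytest.approx(expect, rel=1e-12)


def test_duplicating_subjects_doubles_unpenalized_loglik():
    co = random_cg_cohort(1, n=100)
    node = co.node("G2")
    parents = {"G1", "D1"}

    def unpenalized(cohort):
        n_par = 3 * (1 + 1 + 1)  # 3 configs x (intercept, slope, variance)
        return (local_score(node, parents, cohort)
                + 0.5 * np.log(cohort.n) * n_par)

    double = make_cohort(
        {c.name: np.concatenate([co.values[c.name]] * 2) for c in co.columns},
        [(c.name, c.kind, c.n_levels) for c in co.columns],
    )
    assert unpenalized(double) == pytest.approx(2 * unpenalized(co), rel=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_local_score_matches_brute_force_on_random_cohorts(seed):
    co = random_cg_cohort(seed, n=200)
    nodes = {c.name: c for c in co.columns}
    parent_sets = [
        ("G1", set()), ("G1", {"D1"}), ("G1", {"G2", "D2"}),
        ("G2", {"G1", "D1", "D2"}), ("D1", set()), ("D1", {"D2"}),
        ("D2", {"D1"}),
    ]
    for child, parents in parent_sets:
        a = local_score(nodes[child], parents, co)
        b = brute_force_score(child, parents, co)
        assert a == pytest.approx(b, rel=1e-8)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def _role_nodes():
    roles = ["baseline_demographic", "medical_history", "imaging",
             "clinical_outcome", "nonmotor_assessment", "biomarker",
             "treatment", "other"]
    return [MbnNode(f"z_{r}", "gaussian_code", module=r, visit=1, role=r)
            for r in roles]


def test_backwards_in_time_edges_are_blacklisted():
    nodes = [MbnNode("z_m_v1", "gaussian_code", "m", 1, "clinical_outcome"),
             MbnNode("z_m_v2", "gaussian_code", "m", 2, "clinical_outcome")]
    cons = build_constraints(nodes)
    assert ("z_m_v2", "z_m_v1") in cons.blacklist
    assert ("z_m_v1", "z_m_v2") not in cons.blacklist


def test_edges_into_baseline_demographics_are_blacklisted():
    nodes = _role_nodes()
    cons = build_constraints(nodes)
    for nd in nodes:
        if nd.role != "baseline_demographic":
            assert (nd.name, "z_baseline_demographic") in cons.blacklist


def test_blacklist_matches_exhaustive_rule_enumeration():
    """Independent re-statement of the role rules, pair by pair."""
    nodes = _role_nodes()
    cons = build_constraints(nodes)
    into_imaging = {"imaging", "clinical_outcome", "baseline_demographic",
                    "biomarker", "treatment"}
    for p in nodes:
        for c in nodes:
            if p.name == c.name:
                continue
            expected = (
                c.role in ("baseline_demographic", "treatment")
                or (c.role == "medical_history" and p.role not in
                    {"baseline_demographic", "biomarker", "medical_history"})
                or (p.role == "imaging" and c.role != "imaging")
                or (c.role == "imaging" and p.role not in into_imaging)
                or (c.role == "biomarker" and p.role not in
                    {"biomarker", "baseline_demographic"})
            )
            assert ((p.name, c.name) in cons.blacklist) == expected, \
                (p.role, c.role)


def test_gaussian_parent_of_discrete_child_is_blacklisted():
    nodes = [MbnNode("z", "gaussian_code", "m", 1, "other"),
             MbnNode("d", "standalone_categorical", "m", 1, "other", 2)]
    cons = build_constraints(nodes)
    assert ("z", "d") in cons.blacklist


def test_forced_structure_and_indicator_chains():
    nodes = [
        MbnNode("z_m_v1", "gaussian_code", "m", 1, "clinical_outcome"),
        MbnNode("z_m_v2", "gaussian_code", "m", 2, "clinical_outcome"),
        MbnNode("s_m_v1", "component_label", "m", 1, "clinical_outcome", 2),
        MbnNode("aux_m_v1", "auxiliary", "m", 1, None, 2),
        MbnNode("aux_m_v2", "auxiliary", "m", 2, None, 2),
        MbnNode("vm_v1", "visit_missing", None, 1, None, 2),
        MbnNode("vm_v2", "visit_missing", None, 2, None, 2),
    ]
    cons = build_constraints(nodes)
    assert ("s_m_v1", "z_m_v1") in cons.whitelist
    assert ("aux_m_v1", "z_m_v1") in cons.whitelist
    assert ("aux_m_v1", "aux_m_v2") in cons.whitelist
    assert ("vm_v1", "vm_v2") in cons.whitelist
    assert not (cons.blacklist & cons.whitelist)


def test_whitelist_cycle_is_rejected():
    with pytest.raises(ValueError, match="cycle"):
        EdgeConstraints(whitelist={("a", "b"), ("b", "a")})


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def _enumerate_best(cohort, whitelist=frozenset()):
    names = [c.name for c in cohort.columns]
    cand = [(p, c) for p in names for c in names if p != c]
    best = None
    for r in range(len(cand) + 1):
        for sub in itertools.combinations(cand, r):
            g = nx.DiGraph(list(sub))
            g.add_nodes_from(names)
            if not nx.is_directed_acyclic_graph(g):
                continue
            if not set(whitelist) <= set(sub):
                continue
            sc = total_score(set(sub), cohort)
            if best is None or sc > best[0]:
                best = (sc, set(sub))
    return best


def test_tabu_attains_exhaustive_optimum_on_chain():
    r = np.random.default_rng(3)
    n = 1000
    x = r.standard_normal(n)
    y = 1.5 * x + 0.4 * r.standard_normal(n)
    z = -2.0 * y + 0.6 * r.standard_normal(n)
    co = make_cohort({"X": x, "Y": y, "Z": z},
                     [("X", "gaussian_code", 0), ("Y", "gaussian_code", 0),
                      ("Z", "gaussian_code", 0)])
    model = tabu_search(co, EdgeConstraints(), max_iter=25)
    best_score, _ = _enumerate_best(co)
    assert model.score == pytest.approx(best_score, rel=1e-12)


def test_independent_nodes_yield_empty_graph_plus_whitelist():
    r = np.random.default_rng(4)
    n = 2000
    co = make_cohort(
        {k: r.standard_normal(n) for k in "ABC"},
        [(k, "gaussian_code", 0) for k in "ABC"],
    )
    wl = {("A", "B")}
    model = tabu_search(co, EdgeConstraints(whitelist=set(wl)), max_iter=25)
    assert model.dag == wl


def test_whitelisted_edge_is_always_present():
    co = random_cg_cohort(7, n=150)
    wl = {("D2", "D1")}
    cons = build_constraints(list(co.columns), extra_whitelist=set(wl))
    model = tabu_search(co, cons, max_iter=20)
    assert wl <= model.dag


def test_tabu_rejects_nonpositive_iteration_budget():
    co = random_cg_cohort(0, n=50)
    with pytest.raises(ValueError):
        tabu_search(co, EdgeConstraints(), max_iter=0)


def test_total_score_decomposes_over_nodes():
    co = random_cg_cohort(2, n=150)
    dag = {("G1", "G2"), ("D1", "G1")}
    total = total_score(dag, co)
    parts = sum(
        local_score(c, {p for p, ch in dag if ch == c.name}, co)
        for c in co.columns
    )
    assert total == pytest.approx(parts, rel=1e-12)


# ---------------------------------------------------------------------------
# parameters & likelihood
# ---------------------------------------------------------------------------

def test_linear_regression_parameters_are_recovered():
    r = np.random.default_rng(11)
    n = 2000
    x = r.standard_normal(n)
    y = 2.0 * x + 1.0 + 0.5 * r.standard_normal(n)
    co = make_cohort({"X": x, "Y": y},
                     [("X", "gaussian_code", 0), ("Y", "gaussian_code", 0)])
    model = fit_parameters({("X", "Y")}, co)
    ent = model.gaussian_params["Y"]["table"][()]
    assert 1.9 <= ent["slopes"]["X"] <= 2.1
    assert 0.9 <= ent["intercept"] <= 1.1


def test_cpt_uses_add_one_smoothing():
    vals = np.array([1] * 30 + [0] * 70)
    co = make_cohort({"B": vals}, [("B", "standalone_categorical", 2)])
    model = fit_parameters(set(), co)
    probs = model.cpt["B"]["table"][()]
    assert probs[1] == pytest.approx(31 / 102)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_parameters_recovered_from_own_simulated_data():
    from vambn.simulate import sample_codes

    co = random_cg_cohort(5, n=500)
    dag = {("G1", "G2"), ("D1", "G1"), ("D2", "G2")}
    gen = fit_parameters(dag, co)
    big = sample_codes(gen, 100_000, seed=17)
    refit = fit_parameters(dag, big)
    for node in ("G1", "G2"):
        for cfg, ent in gen.gaussian_params[node]["table"].items():
            ref = refit.gaussian_params[node]["table"][cfg]
            for key in ("intercept", "variance"):
                assert ref[key] == pytest.approx(ent[key], rel=0.05, abs=0.02)
            for p, b in ent["slopes"].items():
                assert ref["slopes"][p] == pytest.approx(b, rel=0.05, abs=0.02)


def test_loglik_closed_form_and_identity_with_score():
    co = make_cohort({"Y": np.zeros(1)}, [("Y", "gaussian_code", 0)])
    model = fit_parameters(set(), co)
    model.gaussian_params["Y"]["table"][()]["variance"] = 1.0
    model.gaussian_params["Y"]["table"][()]["intercept"] = 0.0
    assert loglik(model, co)[0] == pytest.approx(-0.5 * np.log(2 * np.pi))

    co2 = random_cg_cohort(9, n=300)
    dag = {("G1", "G2")}
    model2 = fit_parameters(dag, co2)
    # total data log-likelihood at the MLE equals the sum of unpenalized
    # Gaussian local-score terms minus the partition-share terms
    ll = loglik(model2, co2).sum()
    manual = 0.0
    for c in co2.columns:
        if c.is_gaussian:
            parents = {p for p, ch in dag if ch == c.name}
            n_par = 2 + len(parents)
            s = local_score(c, parents, co2) + 0.5 * np.log(co2.n) * n_par
            manual += s  # no discrete parents: no partition-share term
        else:
            # discrete nodes: smoothed CPT vs empirical frequencies
            yv = co2.values[c.name].to_numpy()
            probs = model2.cpt[c.name]["table"][()]
            manual += sum(np.log(probs[v]) for v in yv)
    assert ll == pytest.approx(manual, rel=1e-6)


def test_loglik_respects_subject_permutation():
    co = random_cg_cohort(10, n=80)
    model = fit_parameters({("G1", "G2")}, co)
    base = loglik(model, co)
    perm = np.random.default_rng(1).permutation(co.n)
    shuffled = make_cohort(
        {c.name: co.values[c.name].to_numpy()[perm] for c in co.columns},
        [(c.name, c.kind, c.n_levels) for c in co.columns],
    )
    assert np.allclose(loglik(model, shuffled), base[perm])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_edge_frequencies():
    r = np.random.default_rng(21)
    n = 500
    x = r.standard_normal(n)
    y = 2.0 * x + r.standard_normal(n)  # r ~ 0.9
    w = r.integers(0, 2, n)
    co = make_cohort(
        {"X": x, "Y": y, "W": w},
        [("X", "gaussian_code", 0), ("Y", "gaussian_code", 0),
         ("W", "standalone_categorical", 2)],
    )
    cons = EdgeConstraints(blacklist={("X", "W"), ("Y", "W"), ("W", "X")},
                           whitelist={("W", "Y")})
    freqs = bootstrap_edges(co, cons, n_boot=100, seed=5)
    assert freqs[("W", "Y")] == 1.0
    for e in cons.blacklist:
        assert freqs.get(e, 0.0) == 0.0
    strong = freqs.get(("X", "Y"), 0.0) + freqs.get(("Y", "X"), 0.0)
    assert strong >= 0.9  # the X-Y dependence appears in some orientation
    r1 = bootstrap_edges(co, cons, n_boot=10, seed=9)
    r2 = bootstrap_edges(co, cons, n_boot=10, seed=9)
    assert r1 == r2
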