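import numpy as np
import pandas as pd
import pytest

from vambn.data_io import VariableSpec
from vambn.mbn import EncodedCohort, MbnNode


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


def make_real_slice(n, mean, sd, seed, name="y"):
    """Single real-variable slice with a full mask."""
    r = np.random.default_rng(seed)
    X = np.empty((n, 1), dtype=object)
    X[:, 0] = r.normal(mean, sd, n)
    return X, np.ones((n, 1), dtype=bool), [VariableSpec(name, "real", "m", (1,))]


def make_mixed_slice(n, seed, missing_frac=0.0):
    """Five-variable slice covering every supported type."""
    r = np.random.default_rng(seed)
    specs = [
        VariableSpec("a", "real", "m", (1,)),
        VariableSpec("b", "positive", "m", (1,)),
        VariableSpec("c", "count", "m", (1,)),
        VariableSpec("d", "categorical", "m", (1,), ("x", "y", "z")),
        VariableSpec("e", "ordinal", "m", (1,), ("1", "2", "3", "4")),
    ]
    f = r.standard_normal(n)
    X = np.empty((n, 5), dtype=object)
    X[:, 0] = 2.0 * f + 0.5 * r.standard_normal(n)
    X[:, 1] = np.exp(0.5 * f + 0.2 * r.standard_normal(n))
    X[:, 2] = r.poisson(np.exp(1.0 + 0.3 * f)).astype(float)
    X[:, 3] = np.array(["x", "y", "z"])[
        (f[:, None] > np.array([-0.5, 0.7])).sum(axis=1)]
    X[:, 4] = np.array(["1", "2", "3", "4"])[
        (f[:, None] > np.array([-0.8, 0.0, 0.8])).sum(axis=1)]
    mask = r.random((n, 5)) >= missing_frac
    mask[0] = True  # keep at least one fully observed row
    return X, mask, specs


def make_cohort(columns: dict, names_kinds: list) -> EncodedCohort:
    """Build an EncodedCohort from plain arrays.

    names_kinds: list of (name, kind, n_levels) tuples.
    """
    nodes = [
        MbnNode(name, kind, module="m", role="other", n_levels=nl)
        for name, kind, nl in names_kinds
    ]
    df = pd.DataFrame({name: columns[name] for name, _, _ in names_kinds})
    return EncodedCohort(list(range(len(df))), nodes, df)


@pytest.fixture(scope="session")
def small_fit():
    """A small study and a fully fitted model, shared across tests."""
    from vambn.hivae import HivaeConfig
    from vambn.pipeline import fit_vambn
    from vambn.synthetic import GeneratorSpec, generate_study

    bundle = generate_study(GeneratorSpec(n_subjects=150, n_visits=2, seed=31))
    model = fit_vambn(bundle.table, bundle.groups, seed=5,
                      hivae_config=HivaeConfig(epochs=60), max_iter=25)
    return bundle, model


@pytest.fixture(scope="session")
def transfer_setup():
    """Two linked studies, source-study VAEs and a source network for the
    extra feature, plus the target cohort encoded with the source VAEs."""
    from vambn.data_io import MissingnessNodes
    from vambn.hivae import HivaeConfig, fit_hivae
    from vambn.mbn import assemble_cohort, fit_parameters
    from vambn.synthetic import (
        ExtraFeatureSpec,
        GeneratorSpec,
        generate_two_studies,
    )

    spec = GeneratorSpec(n_subjects=400, n_visits=2, seed=41,
                         mcar_rate=0.0, dropout_base=-30.0,
                         mnar_base=-30.0)
    a, b = generate_two_studies(spec, ExtraFeatureSpec(noise_sd=1.0))
    hivaes = {}
    groups_b = {g.name: g for g in b.groups}
    for name in ("demographics", "extra"):
        X, m, _, vars_ = b.table.module_stack(name)
        hivaes[name] = fit_hivae(X, m, vars_,
                                 HivaeConfig(epochs=200, seed=13))
    cohort_b = assemble_cohort(
        b.table, [groups_b["demographics"], groups_b["extra"]],
        hivaes, MissingnessNodes())
    source_mbn = fit_parameters(
        {("z_demographics_v1", "z_extra_v1")}, cohort_b)
    groups_a = {g.name: g for g in a.groups}
    cohort_a = assemble_cohort(
        a.table, [groups_a["demographics"]],
        {"demographics": hivaes["demographics"]}, MissingnessNodes())
    return a, b, hivaes, source_mbn, cohort_a


def random_cg_cohort(seed, n=200):
    """Random 4-node conditional-Gaussian cohort (2 Gaussian, 2 discrete)."""
    r = np.random.default_rng(seed)
    d1 = r.integers(0, 3, n)
    d2 = r.integers(0, 2, n)
    g1 = 0.5 * d1 + r.standard_normal(n)
    g2 = 0.8 * g1 - 0.6 * d2 + r.standard_normal(n)
    return make_cohort(
        {"G1": g1, "G2": g2, "D1": d1, "D2": d2},
        [("G1", "gaussian_code", 0), ("G2", "gaussian_code", 0),
         ("D1", "standalone_categorical", 3),
         ("D2", "standalone_categorical", 2)],
    )
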