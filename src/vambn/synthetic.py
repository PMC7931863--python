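"""Ground-truth generator for longitudinal heterogeneous study data.

Emulates the data regime the model targets — a few hundred subjects, a
handful of variable modules followed over several visits, mixed
continuous/count/categorical/ordinal variables, a randomized treatment arm
with an effect on a motor-outcome score, and realistic missingness
(cell-level MCAR, outcome-dependent monotone dropout, and block-wise MNAR
on the laboratory panel).

Each module-visit has a latent standardized factor following
linear-Gaussian structural equations along a known admissible DAG;
observed variables are type-specific emissions of their module factor.
The returned truth bundle (true DAG, factors, pre-missingness table)
makes every downstream stage testable end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import (
    ColumnSpec,
    HeterogeneousTable,
    ModuleGroup,
    VariableSpec,
    expected_columns,
)
from .mbn import MbnNode, build_constraints, z_name


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableGen:
    """Emission of one observed variable from its module factor.

    loading is the correlation with the factor (continuous/ordinal),
    loc/scale place the variable on its natural range; counts use a
    log-linear Poisson emission exp(loc + scale * f).
    """

    name: str
    vtype: str
    levels: tuple = ()
    loading: float = 0.9
    loc: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class ModuleGen:
    name: str
    role: str
    visits: tuple
    variables: tuple
    encoded: bool = True


def default_modules(n_visits: int = 5) -> tuple:
    """SP513-shaped default: demographics, history, two motor-score modules,
    a sleepiness module, a laboratory panel and a randomized treatment arm."""
    all_v = tuple(range(1, n_visits + 1))
    lab_v = tuple(t for t in (1, 3, 5) if t <= n_visits)
    return (
        ModuleGen("demographics", "baseline_demographic", (1,), (
            VariableGen("age", "real", loc=62.0, scale=9.0),
            VariableGen("weight", "positive", loc=4.33, scale=0.12),
            VariableGen("sex", "categorical", ("F", "M"), loading=0.6),
        )),
        ModuleGen("history", "medical_history", (1,), (
            VariableGen("comorbidities", "count", loc=0.9, scale=0.5),
            VariableGen("cardio_hx", "categorical", ("no", "yes"), loading=0.8),
            VariableGen("duration", "positive", loc=0.7, scale=0.6),
        )),
        ModuleGen("updrs2", "clinical_outcome", all_v, (
            VariableGen("u2_total", "count", loc=2.3, scale=0.4),
            VariableGen("u2_adl", "real", loc=12.0, scale=4.0),
            VariableGen("u2_speech", "ordinal", ("0", "1", "2", "3"),
                        loading=0.85),
        )),
        ModuleGen("updrs3", "clinical_outcome", all_v, (
            VariableGen("u3_total", "count", loc=3.1, scale=0.35),
            VariableGen("u3_motor", "real", loc=25.0, scale=8.0),
            VariableGen("u3_gait", "ordinal", ("0", "1", "2", "3"),
                        loading=0.85),
        )),
        ModuleGen("ess", "nonmotor_assessment", all_v, (
            VariableGen("ess_total", "count", loc=2.0, scale=0.4),
            VariableGen("ess_vas", "real", loc=40.0, scale=12.0),
            VariableGen("ess_doze", "ordinal", ("0", "1", "2", "3"),
                        loading=0.85),
        )),
        ModuleGen("labs", "biomarker", lab_v, (
            VariableGen("hemoglobin", "positive", loc=4.95, scale=0.07),
            VariableGen("creatinine", "positive", loc=-0.11, scale=0.15),
            VariableGen("alt", "positive", loc=3.2, scale=0.3),
        )),
        ModuleGen("treatment", "treatment", (1,), (
            VariableGen("arm", "categorical", ("placebo", "drug")),
        ), encoded=False),
    )


def default_edges(n_visits: int = 5) -> dict:
    """True module-level DAG with path coefficients (standardized scale)."""
    e: dict = {
        (("demographics", 1), ("history", 1)): 0.6,
        (("demographics", 1), ("updrs3", 1)): 0.5,
        (("demographics", 1), ("labs", 1)): 0.5,
        (("history", 1), ("ess", 1)): 0.6,
    }
    for t in range(1, n_visits):
        e[(("updrs2", t), ("updrs2", t + 1))] = 0.75
        e[(("updrs3", t), ("updrs3", t + 1))] = 0.75
        e[(("ess", t), ("ess", t + 1))] = 0.75
    for t in range(1, n_visits + 1):
        e[(("updrs2", t), ("updrs3", t))] = 0.6
    lab_v = [t for t in (1, 3, 5) if t <= n_visits]
    for a, b in zip(lab_v[:-1], lab_v[1:]):
        e[(("labs", a), ("labs", b))] = 0.7
    return e


@dataclass(frozen=True)
class GeneratorSpec:
    n_subjects: int = 550
    n_visits: int = 5
    modules: tuple = None
    edges: dict = None  # (parent_key, child_key) -> coefficient
    treatment_effect: float = 0.5  # standardized shift on updrs3, visits >= 2
    outcome_module: str = "updrs3"
    noise_sd: float = 0.5  # structural residual before standardization
    mcar_rate: float = 0.02  # cell-level
    dropout_base: float = -3.0  # per-visit hazard logit at average severity
    dropout_slope: float = 1.0  # hazard increase per sd of outcome factor
    mnar_module: str = "labs"
    mnar_base: float = -2.9  # block-missingness logit at average factor
    mnar_slope: float = 1.0
    seed: int = 20260921

    def __post_init__(self):
        if self.modules is None:
            object.__setattr__(self, "modules",
                               default_modules(self.n_visits))
        if self.edges is None:
            object.__setattr__(self, "edges", default_edges(self.n_visits))


@dataclass
class StudyBundle:
    table: HeterogeneousTable
    groups: list
    truth: dict  # true_edges, factors, pre_missingness, params


# ---------------------------------------------------------------------------
# admissibility
# ---------------------------------------------------------------------------

def _spec_nodes(spec: GeneratorSpec) -> list[MbnNode]:
    nodes = []
    for m in spec.modules:
        for t in m.visits:
            if m.encoded:
                nodes.append(MbnNode(z_name(m.name, t), "gaussian_code",
                                     m.name, t, m.role))
            else:
                for v in m.variables:
                    nodes.append(MbnNode(f"{v.name}_v{t}",
                                         "standalone_categorical", m.name, t,
                                         m.role, len(v.levels)))
    return nodes


def _node_name(spec: GeneratorSpec, key) -> str:
    mod, t = key
    m = next(mm for mm in spec.modules if mm.name == mod)
    if m.encoded:
        return z_name(mod, t)
    return f"{m.variables[0].name}_v{t}"


def check_admissible(spec: GeneratorSpec) -> set:
    """True edges as node-name pairs; raises if any violates the constraints."""
    nodes = _spec_nodes(spec)
    cons = build_constraints(nodes)
    edges = {(_node_name(spec, a), _node_name(spec, b)) for a, b in spec.edges}
    for t in range(2, spec.n_visits + 1):
        edges.add((_node_name(spec, ("treatment", 1)),
                   _node_name(spec, (spec.outcome_module, t))))
    by_name = {n.name: n for n in nodes}
    for p, c in sorted(edges):
        if (p, c) in cons.blacklist:
            pn, cn = by_name[p], by_name[c]
            if pn.visit is not None and cn.visit is not None and pn.visit > cn.visit:
                why = "temporal order (no edges backwards in time)"
            elif cn.role in ("baseline_demographic", "treatment"):
                why = f"edges into {cn.role} modules"
            elif cn.role == "medical_history":
                why = "medical history may only depend on baseline/biomarkers"
            elif pn.role == "imaging" or cn.role == "imaging":
                why = "imaging direction rules"
            elif cn.role == "biomarker":
                why = "biomarkers accept only biomarker/baseline parents"
            else:
                why = "discrete-child restriction"
            raise ValueError(f"true edge {p}->{c} violates constraint: {why}")
    return edges


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _topo_keys(spec: GeneratorSpec) -> list:
    keys = [(m.name, t) for m in spec.modules for t in m.visits if m.encoded]
    parents = {k: [] for k in keys}
    for (a, b), _ in spec.edges.items():
        if b in parents:
            parents[b].append(a)
    out, placed = [], set()
    while len(out) < len(keys):
        for k in keys:
            if k in placed:
                continue
            if all(p in placed or p not in parents for p in parents[k]):
                out.append(k)
                placed.add(k)
    return out


def _emit(var: VariableGen, f: np.ndarray, rng) -> np.ndarray:
    n = f.shape[0]
    lam = var.loading
    resid = np.sqrt(max(1.0 - lam * lam, 1e-12))
    if var.vtype in ("real", "positive"):
        u = lam * f + resid * rng.standard_normal(n)
        x = var.loc + var.scale * u
        vals = np.exp(x) if var.vtype == "positive" else x
        return np.array([float(v) for v in vals], dtype=object)
    if var.vtype == "count":
        lograte = np.clip(var.loc + var.scale * f, -20, 20)
        return np.array([float(v) for v in rng.poisson(np.exp(lograte))],
                        dtype=object)
    u = lam * f + resid * rng.standard_normal(n)
    if var.vtype == "ordinal":
        cuts = np.array([-0.8, 0.0, 0.8])[: len(var.levels) - 1]
        idx = (u[:, None] > cuts[None, :]).sum(axis=1)
        return np.array([var.levels[i] for i in idx], dtype=object)
    # categorical: binary via threshold on u, multi-level via softmax draw
    L = len(var.levels)
    if L == 2:
        idx = (u > 0).astype(int)
    else:
        logits = np.linspace(-1, 1, L)[None, :] * u[:, None]
        pr = np.exp(logits - logits.max(axis=1, keepdims=True))
        pr /= pr.sum(axis=1, keepdims=True)
        idx = (rng.random((n, 1)) > pr.cumsum(axis=1)).sum(axis=1)
    return np.array([var.levels[i] for i in idx], dtype=object)


def generate_study(spec: GeneratorSpec) -> StudyBundle:
    """Draw one study: factors, emissions, then MCAR -> dropout -> MNAR."""
    true_edges = check_admissible(spec)  # raises if inadmissible
    n = spec.n_subjects
    rng_f = np.random.default_rng([spec.seed, 1])
    rng_e = np.random.default_rng([spec.seed, 2])
    rng_m = np.random.default_rng([spec.seed, 3])

    arm = (rng_f.random(n) < 0.5).astype(np.int64)
    factors: dict = {}
    for key in _topo_keys(spec):
        sys = np.zeros(n)
        has_parent = False
        for (a, b), beta in spec.edges.items():
            if b == key and a in factors:
                sys += beta * factors[a]
                has_parent = True
        total = sys + spec.noise_sd * rng_f.standard_normal(n) \
            if has_parent else rng_f.standard_normal(n)
        f = (total - total.mean()) / total.std()
        if key[0] == spec.outcome_module and key[1] >= 2:
            f = f + spec.treatment_effect * arm
        factors[key] = f

    groups = [
        ModuleGroup(
            m.name, m.role,
            tuple(
                VariableSpec(v.name, v.vtype, m.name, m.visits, v.levels)
                for v in m.variables
            ),
            encoded=m.encoded,
        )
        for m in spec.modules
    ]
    cols = expected_columns(groups)
    values = np.empty((n, len(cols)), dtype=object)
    for j, c in enumerate(cols):
        if c.var.module == "treatment":
            values[:, j] = np.array(
                [c.var.levels[a] for a in arm], dtype=object)
            continue
        vg = next(v for m in spec.modules for v in m.variables
                  if m.name == c.var.module and v.name == c.var.name)
        values[:, j] = _emit(vg, factors[(c.var.module, c.visit)], rng_e)

    full_mask = np.ones((n, len(cols)), dtype=bool)
    pre = HeterogeneousTable(
        [f"S{i+1:05d}" for i in range(n)],
        pd.DataFrame(values.copy(), columns=[c.name for c in cols]),
        full_mask.copy(), list(cols),
    )

    mask = full_mask.copy()
    # 1) cell-level MCAR (never on the treatment arm)
    for j, c in enumerate(cols):
        if c.var.module == "treatment":
            continue
        mask[:, j] &= rng_m.random(n) >= spec.mcar_rate
    # 2) MAR dropout: hazard at visit t rises with the previous outcome factor
    dropped = np.zeros(n, dtype=bool)
    for t in range(2, spec.n_visits + 1):
        sev = factors.get((spec.outcome_module, t - 1), np.zeros(n))
        hazard = 1.0 / (1.0 + np.exp(-(spec.dropout_base
                                       + spec.dropout_slope * sev)))
        dropped |= rng_m.random(n) < hazard
        for j, c in enumerate(cols):
            if c.visit >= t and c.var.module != "treatment":
                mask[dropped, j] = False
    # 3) block-wise MNAR on the designated module, driven by its own factor
    mnar_mod = next((m for m in spec.modules if m.name == spec.mnar_module),
                    None)
    if mnar_mod is not None:
        for t in mnar_mod.visits:
            f = factors[(spec.mnar_module, t)]
            p = 1.0 / (1.0 + np.exp(-(spec.mnar_base + spec.mnar_slope * f)))
            hit = rng_m.random(n) < p
            for j, c in enumerate(cols):
                if c.var.module == spec.mnar_module and c.visit == t:
                    mask[hit, j] = False

    masked_values = values.copy()
    masked_values[~mask] = None
    table = HeterogeneousTable(
        list(pre.subject_ids),
        pd.DataFrame(masked_values, columns=[c.name for c in cols]),
        mask, list(cols),
    )
    fdf = pd.DataFrame({z_name(m, t): f for (m, t), f in factors.items()})
    fdf["arm"] = arm
    truth = {
        "true_edges": true_edges,
        "factors": fdf,
        "pre_missingness": pre,
        "params": {"edges": dict(spec.edges),
                   "treatment_effect": spec.treatment_effect},
    }
    return StudyBundle(table, groups, truth)


# ---------------------------------------------------------------------------
# linked study pair for feature transfer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtraFeatureSpec:
    """A feature module observed only in study B.

    parents maps (module, visit) keys shared by both studies to linear
    coefficients on their factors; the feature value is the linear
    combination plus Gaussian noise and is emitted unchanged as a single
    real variable, so its true conditional mean given the parent factors is
    exactly the linear form.
    """

    name: str = "extra"
    variable: str = "y_extra"
    parents: dict = field(
        default_factory=lambda: {("demographics", 1): 3.0})
    noise_sd: float = 1.0
    visit: int = 1


def generate_two_studies(
    spec: GeneratorSpec, extra: ExtraFeatureSpec
) -> tuple[StudyBundle, StudyBundle]:
    """Two studies with a shared structural backbone; B also measures the
    extra feature. B's truth bundle records the feature's generating law."""
    for key in extra.parents:
        if key not in {(m.name, t) for m in spec.modules for t in m.visits}:
            raise ValueError(f"extra-feature parent {key} not in shared modules")
    a = generate_study(replace(spec, seed=spec.seed))
    b = generate_study(replace(spec, seed=spec.seed + 1))

    rng = np.random.default_rng([spec.seed, 77])
    n = spec.n_subjects
    y = np.zeros(n)
    for key, beta in extra.parents.items():
        y += beta * b.truth["factors"][z_name(*key)].to_numpy()
    y = y + extra.noise_sd * rng.standard_normal(n)

    var = VariableSpec(extra.variable, "real", extra.name, (extra.visit,))
    grp = ModuleGroup(extra.name, "other", (var,))
    b.groups.append(grp)
    col = ColumnSpec(var, extra.visit)
    b.table.columns.append(col)
    b.table.values[col.name] = [float(v) for v in y]
    b.table.mask = np.concatenate(
        [b.table.mask, np.ones((n, 1), dtype=bool)], axis=1)
    b.truth["extra"] = {
        "module": extra.name, "variable": extra.variable,
        "parents": dict(extra.parents), "noise_sd": extra.noise_sd,
        "values": y,
        "conditional_mean": {
            z_name(*k): beta for k, beta in extra.parents.items()},
    }
    return a, b
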