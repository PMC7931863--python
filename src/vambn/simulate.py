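"""Virtual-patient simulation, do-calculus interventions, feature transfer.

Ancestral sampling walks the Bayesian network in topological order
(discrete nodes from their CPT rows, Gaussian nodes from the fitted linear
regression given the drawn parents) and then decodes the module codes back
to the raw variable space through the per-module VAEs. An ideal
intervention do(X = x) deletes X's incoming edges and clamps its value
before sampling, which leaves every non-descendant's distribution
untouched. Feature transfer clamps the (mapped) parents of a node of study
B's model to values observed in study A and draws the node — counterfactual
addition of a feature B measured but A did not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ColumnSpec, HeterogeneousTable, ModuleGroup, expected_columns
from .hivae import LatentCode, decode
from .mbn import EncodedCohort, MbnModel, s_name, z_name

#: Gaussian draws are truncated this many residual sd's from the local mean,
#: keeping decoder inputs inside the code range the VAEs were trained on.
TRUNCATION_SD = 6.0


@dataclass(frozen=True)
class Intervention:
    """Clamped node values: floats for Gaussian nodes, level indices for
    discrete ones."""

    targets: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# node-level ancestral sampling
# ---------------------------------------------------------------------------

def _draw_nodes(model: MbnModel, n: int, rng, clamp: dict) -> pd.DataFrame:
    g = model.graph()
    for t in clamp:  # do-calculus: delete incoming edges of clamped nodes
        for p in list(g.predecessors(t)):
            g.remove_edge(p, t)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as e:
        raise ValueError("model graph contains a cycle") from e
    out: dict[str, np.ndarray] = {}
    for name in order:
        node = model.node(name)
        if name in clamp:
            if node.is_gaussian:
                out[name] = np.full(n, float(clamp[name]))
            else:
                v = int(clamp[name])
                if not 0 <= v < node.n_levels:
                    raise ValueError(
                        f"clamp value {v} outside levels of {name!r}"
                    )
                out[name] = np.full(n, v, dtype=np.int64)
            continue
        if node.is_gaussian:
            gp = model.gaussian_params[name]
            mean = np.zeros(n)
            var = np.zeros(n)
            cfg_vals = [out[p] for p in gp["disc_parents"]]
            for cfg, ent in gp["table"].items():
                sel = np.ones(n, dtype=bool)
                for pv, cv in zip(cfg_vals, cfg):
                    sel &= pv == cv
                if not sel.any():
                    continue
                m = np.full(int(sel.sum()), float(ent["intercept"]))
                for p, b in ent["slopes"].items():
                    m += b * out[p][sel]
                mean[sel] = m
                var[sel] = ent["variance"]
            sd = np.sqrt(var)
            draw = mean + sd * rng.standard_normal(n)
            out[name] = np.clip(draw, mean - TRUNCATION_SD * sd,
                                mean + TRUNCATION_SD * sd)
        else:
            tab = model.cpt[name]
            vals = np.zeros(n, dtype=np.int64)
            cfg_vals = [out[p] for p in tab["disc_parents"]]
            u = rng.random(n)
            for cfg, probs in tab["table"].items():
                sel = np.ones(n, dtype=bool)
                for pv, cv in zip(cfg_vals, cfg):
                    sel &= pv == cv
                if not sel.any():
                    continue
                cum = np.cumsum(probs)
                vals[sel] = np.searchsorted(cum, u[sel], side="right")
            out[name] = np.clip(vals, 0, node.n_levels - 1)
    return pd.DataFrame({c.name: out[c.name] for c in model.columns})


def sample_codes(
    model: MbnModel, n: int, seed: int = 0,
    intervention: Intervention | None = None,
) -> EncodedCohort:
    """Draw `n` subjects at the node (code) level, without decoding."""
    if n < 1:
        raise ValueError("n must be >= 1")
    clamp = dict(intervention.targets) if intervention else {}
    for t in clamp:
        node = model.node(t)  # raises KeyError for unknown targets
        if node.kind in ("auxiliary", "visit_missing"):
            raise ValueError(
                f"intervening on missingness node {t!r} is not allowed"
            )
    rng = np.random.default_rng(seed)
    vals = _draw_nodes(model, n, rng, clamp)
    return EncodedCohort([f"VP{i+1:06d}" for i in range(n)],
                         list(model.columns), vals)


# ---------------------------------------------------------------------------
# decoding drawn codes into a raw-space table
# ---------------------------------------------------------------------------

def decode_cohort(
    codes: EncodedCohort,
    hivaes: dict,
    groups: list[ModuleGroup],
    seed: int = 0,
    mode: str = "sample",
) -> HeterogeneousTable:
    """Decode node-level draws into a wide heterogeneous table.

    Subjects whose auxiliary / missing-visit indicators were drawn 1 get
    the corresponding module-visit blocks masked in the output.
    """
    rng = np.random.default_rng(seed)
    cols: list[ColumnSpec] = expected_columns(groups)
    n = codes.n
    values = np.empty((n, len(cols)), dtype=object)
    mask = np.ones((n, len(cols)), dtype=bool)
    colnames = [c.name for c in cols]
    node_names = {c.name for c in codes.columns}

    for g in groups:
        if g.encoded:
            model = hivaes[g.name]
            L = model.config.latent_dim
            for t in g.visits:
                zcols = ([z_name(g.name, t)] if L == 1 else
                         [z_name(g.name, t) + f"_d{d}" for d in range(L)])
                z = codes.values[zcols].to_numpy(dtype=np.float64)
                if s_name(g.name, t) in node_names:
                    s = codes.values[s_name(g.name, t)].to_numpy(np.int64) + 1
                else:
                    s = np.ones(n, dtype=np.int64)
                lcs = [LatentCode(z[i], int(s[i])) for i in range(n)]
                dec = decode(model, lcs, mode, rng)
                for jj, v in enumerate(model.specs):
                    j = colnames.index(v.column_name(t))
                    values[:, j] = dec[:, jj]
        else:
            for v in g.variables:
                for t in v.visits:
                    nd = f"{v.name}_v{t}"
                    idx = codes.values[nd].to_numpy(dtype=np.int64)
                    j = colnames.index(v.column_name(t))
                    values[:, j] = [v.levels[i] for i in idx]

    # apply drawn missingness indicators
    vm_by_visit = {}
    for c in codes.columns:
        if c.kind == "visit_missing":
            vm_by_visit[c.visit] = codes.values[c.name].to_numpy(np.int64)
    for c in codes.columns:
        blocks = []
        if c.kind == "auxiliary":
            blocks.append(((c.module, c.visit),
                           codes.values[c.name].to_numpy(np.int64)))
        for (mod, t), ind in blocks:
            for j, col in enumerate(cols):
                if col.var.module == mod and col.visit == t:
                    mask[ind == 1, j] = False
    for t, ind in vm_by_visit.items():
        for j, col in enumerate(cols):
            if col.visit == t:
                mask[ind == 1, j] = False
    values[~mask] = None
    vdf = pd.DataFrame(values, columns=colnames)
    return HeterogeneousTable(list(codes.subjects), vdf, mask, cols)


def sample_cohort(
    model: MbnModel, hivaes: dict, groups: list[ModuleGroup],
    n: int, seed: int = 0, mode: str = "sample",
) -> HeterogeneousTable:
    """Simulate a virtual cohort: ancestral MBN draws, then VAE decoding."""
    codes = sample_codes(model, n, seed)
    return decode_cohort(codes, hivaes, groups, seed=seed + 1, mode=mode)


def intervene(
    model: MbnModel, hivaes: dict, groups: list[ModuleGroup],
    intervention: Intervention, n: int, seed: int = 0, mode: str = "sample",
) -> HeterogeneousTable:
    """Simulate under do(X = x): clamp targets, delete their incoming edges."""
    codes = sample_codes(model, n, seed, intervention)
    return decode_cohort(codes, hivaes, groups, seed=seed + 1, mode=mode)


# ---------------------------------------------------------------------------
# counterfactual feature transfer between studies
# ---------------------------------------------------------------------------

def transfer_feature(
    source_mbn: MbnModel,
    source_hivaes: dict,
    target_cohort: EncodedCohort,
    feature_node: str,
    parent_map: dict,
    n_draws: int = 100,
    seed: int = 0,
    mode: str = "sample",
):
    """Counterfactually add a feature of the source study to target subjects.

    For each target subject the parents of `feature_node` in the source
    model are clamped to the subject's values of the mapped target columns
    (the target must have been encoded with the *source* study's VAEs so
    the code spaces agree) and `n_draws` values of the feature are drawn
    from its local conditional. Gaussian module codes are decoded through
    the source VAE of their module; the result is an object array of shape
    (n_subjects, n_draws, n_module_variables). Discrete features return an
    integer array (n_subjects, n_draws) of level indices.
    """
    node = source_mbn.node(feature_node)
    parents = sorted(source_mbn.parents(feature_node))
    missing = [p for p in parents if p not in parent_map]
    if missing:
        raise ValueError(f"unmapped parents of {feature_node!r}: {missing}")
    for p in parents:
        if parent_map[p] not in target_cohort.values.columns:
            raise ValueError(
                f"target cohort lacks column {parent_map[p]!r} for parent {p!r}"
            )
    rng = np.random.default_rng(seed)
    n = target_cohort.n

    if node.is_gaussian:
        gp = source_mbn.gaussian_params[feature_node]
        cfg_vals = [
            target_cohort.values[parent_map[p]].to_numpy(np.int64)
            for p in gp["disc_parents"]
        ]
        mean = np.zeros(n)
        var = np.zeros(n)
        for cfg, ent in gp["table"].items():
            sel = np.ones(n, dtype=bool)
            for pv, cv in zip(cfg_vals, cfg):
                sel &= pv == cv
            if not sel.any():
                continue
            m = np.full(int(sel.sum()), float(ent["intercept"]))
            for p, b in ent["slopes"].items():
                m += b * target_cohort.values[parent_map[p]].to_numpy(
                    np.float64)[sel]
            mean[sel] = m
            var[sel] = ent["variance"]
        sd = np.sqrt(var)
        zdraws = mean[:, None] + sd[:, None] * rng.standard_normal((n, n_draws))
        zdraws = np.clip(zdraws, (mean - TRUNCATION_SD * sd)[:, None],
                         (mean + TRUNCATION_SD * sd)[:, None])
        module = node.module
        model = source_hivaes[module]
        if model.config.latent_dim != 1:
            raise ValueError("feature transfer supports latent_dim=1 modules")
        flat = zdraws.reshape(-1, 1)
        lcs = [LatentCode(flat[i], 1) for i in range(flat.shape[0])]
        dec = decode(model, lcs, mode, rng)
        return dec.reshape(n, n_draws, model.n_variables)

    tab = source_mbn.cpt[feature_node]
    cfg_vals = [
        target_cohort.values[parent_map[p]].to_numpy(np.int64)
        for p in tab["disc_parents"]
    ]
    out = np.zeros((n, n_draws), dtype=np.int64)
    u = rng.random((n, n_draws))
    for cfg, probs in tab["table"].items():
        sel = np.ones(n, dtype=bool)
        for pv, cv in zip(cfg_vals, cfg):
            sel &= pv == cv
        if not sel.any():
            continue
        cum = np.cumsum(probs)
        out[sel] = np.searchsorted(cum, u[sel], side="right")
    return np.clip(out, 0, node.n_levels - 1)
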