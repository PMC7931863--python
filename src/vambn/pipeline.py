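"""End-to-end model fitting: per-module VAEs, encoding, network learning.

The two-step training mirrors the model's likelihood factorization: first
each module's VAE is fitted (optionally with a 3-fold cross-validated grid
search over learning rate and minibatch size), then the Bayesian network
structure and parameters are learned on the encoded cohort under the
causal constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import (
    HeterogeneousTable,
    MissingnessNodes,
    ModuleGroup,
    build_missingness_nodes,
)
from .hivae import (
    HivaeConfig,
    HivaeModel,
    fit_hivae,
    reconstruction_loglik,
    select_hyperparameters,
)
from .mbn import (
    EdgeConstraints,
    EncodedCohort,
    MbnModel,
    assemble_cohort,
    build_constraints,
    loglik,
    tabu_search,
)


def substream(seed: int, label: str) -> int:
    """Stable named sub-seed so parallel module order cannot matter."""
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) % (2**31)
    return int((seed * 1000003 + h) % (2**31))


@dataclass
class VambnModel:
    """A fitted model: per-module VAEs plus the network over their codes."""

    hivaes: dict  # module name -> HivaeModel
    mbn: MbnModel
    cohort: EncodedCohort
    constraints: EdgeConstraints
    missing: MissingnessNodes
    groups: list


def fit_vambn(
    table: HeterogeneousTable,
    groups: list[ModuleGroup],
    seed: int = 0,
    hivae_config: HivaeConfig | None = None,
    select_grid: list | None = None,
    whitelist: set = frozenset(),
    max_iter: int = 50,
    epsilons: dict | None = None,
    dp: "object | None" = None,
) -> VambnModel:
    """Two-step training: VAE per module, then constrained network learning.

    Pass ``select_grid`` (e.g. ``hivae.DEFAULT_GRID``) to choose learning
    rate and batch size per module by 3-fold cross-validation. Pass a
    ``privacy.DpConfig`` as ``dp`` to train every module VAE with DP-SGD;
    per-module epsilon values are then written into ``epsilons``.
    """
    base = hivae_config
    hivaes: dict[str, HivaeModel] = {}
    for g in groups:
        if not g.encoded:
            continue
        X, m, _, vars_ = table.module_stack(g.name)
        sub = substream(seed, f"hivae:{g.name}")
        if base is None:
            # fixed optimization budget per module (~4000 gradient steps),
            # whatever the stacked row count of the module
            cfg = HivaeConfig(seed=sub)
            steps_per_epoch = int(np.ceil(X.shape[0] / cfg.batch_size))
            cfg = replace(cfg, epochs=int(
                np.clip(np.ceil(4000 / steps_per_epoch), 20, 400)))
        else:
            cfg = replace(base, seed=sub)
        if select_grid:
            chosen = select_hyperparameters(
                X, m, vars_, [replace(c, seed=sub, epochs=cfg.epochs)
                              for c in select_grid],
                seed=sub,
            )
            cfg = replace(chosen, seed=sub)
        if dp is not None:
            from .privacy import dp_fit_hivae

            hivaes[g.name], eps = dp_fit_hivae(X, m, vars_, cfg, dp)
            if epsilons is not None:
                epsilons[g.name] = eps
        else:
            hivaes[g.name] = fit_hivae(X, m, vars_, cfg)
    missing = build_missingness_nodes(table, groups)
    cohort = assemble_cohort(table, groups, hivaes, missing)
    constraints = build_constraints(
        cohort.columns, extra_whitelist=set(whitelist),
        collapsed=missing.collapsed,
    )
    mbn = tabu_search(cohort, constraints, max_iter=max_iter,
                      seed=substream(seed, "tabu"))
    return VambnModel(hivaes, mbn, cohort, constraints, missing, groups)


def missingness_like(table: HeterogeneousTable, groups: list[ModuleGroup],
                     reference: MissingnessNodes) -> MissingnessNodes:
    """Indicators for a new table restricted to the reference's node set,
    so held-out subjects can be scored under a model fitted elsewhere."""
    out = MissingnessNodes(collapsed=set(reference.collapsed))
    for t in reference.visit_missing:
        mods = [g.name for g in groups if t in g.visits]
        vm = np.ones(table.n_subjects, dtype=np.int64)
        for m in mods:
            vm &= table.block_missing(m, t)
        out.visit_missing[t] = vm
    for (m, t) in reference.aux:
        out.aux[(m, t)] = table.block_missing(m, t)
    return out


def holdout_loglik(
    train: HeterogeneousTable,
    test: HeterogeneousTable,
    groups: list[ModuleGroup],
    seed: int = 0,
    hivae_config: HivaeConfig | None = None,
    max_iter: int = 50,
    whitelist: set = frozenset(),
) -> dict:
    """Fit on the training split only; score both splits per subject.

    Returns per-subject network log-likelihoods and per-subject VAE
    reconstruction log-likelihoods (averaged over modules) for both
    splits — the overfitting diagnostic: a large train-test gap flags a
    model that memorized its subjects.
    """
    train_ids = set(train.subject_ids)
    if train_ids & set(test.subject_ids):
        raise ValueError("train and test splits overlap")
    model = fit_vambn(train, groups, seed=seed, hivae_config=hivae_config,
                      max_iter=max_iter, whitelist=whitelist)
    out = {}
    for label, tab in (("train", train), ("test", test)):
        miss = missingness_like(tab, groups, model.missing)
        cohort = assemble_cohort(tab, groups, model.hivaes, miss)
        out[f"mbn_{label}"] = loglik(model.mbn, cohort)
        recs = []
        for g in groups:
            if not g.encoded:
                continue
            X, m, rows, _ = tab.module_stack(g.name)
            rr = reconstruction_loglik(model.hivaes[g.name], X, m)
            per_subj = np.zeros(tab.n_subjects)
            for r, (i, _t) in zip(rr, rows):
                per_subj[i] += r
            recs.append(per_subj)
        out[f"hivae_{label}"] = np.mean(recs, axis=0)
    out["model"] = model
    return out


def save_vambn(model: VambnModel, outdir, meta: dict | None = None) -> None:
    """Write a fitted model as a directory of JSON/YAML artifacts."""
    import json
    import os

    from .data_io import write_config
    from .hivae import save_model
    from .mbn import save_mbn

    os.makedirs(outdir, exist_ok=True)
    save_mbn(model.mbn, os.path.join(outdir, "mbn.json"))
    for name, hm in model.hivaes.items():
        save_model(hm, os.path.join(outdir, f"hivae_{name}.json"))
    write_config(model.groups, os.path.join(outdir, "groups.yaml"))
    doc = {
        "schema_version": 1,
        "modules": sorted(model.hivaes),
        "aux_keys": sorted([list(k) for k in model.missing.aux]),
        "collapsed": sorted([list(k) for k in model.missing.collapsed]),
        "visit_missing": sorted(model.missing.visit_missing),
        "whitelist": sorted(model.constraints.whitelist),
        **(meta or {}),
    }
    with open(os.path.join(outdir, "meta.json"), "w") as fh:
        json.dump(doc, fh, indent=1)


def load_vambn(outdir) -> VambnModel:
    import json
    import os

    import yaml

    from .data_io import parse_config
    from .hivae import load_model
    from .mbn import load_mbn

    with open(os.path.join(outdir, "meta.json")) as fh:
        meta = json.load(fh)
    with open(os.path.join(outdir, "groups.yaml")) as fh:
        groups = parse_config(yaml.safe_load(fh))
    hivaes = {m: load_model(os.path.join(outdir, f"hivae_{m}.json"))
              for m in meta["modules"]}
    mbn = load_mbn(os.path.join(outdir, "mbn.json"))
    missing = MissingnessNodes(
        aux={tuple(k): None for k in meta["aux_keys"]},
        visit_missing={t: None for t in meta["visit_missing"]},
        collapsed={tuple(k) for k in meta["collapsed"]},
    )
    constraints = EdgeConstraints(
        whitelist={tuple(e) for e in meta["whitelist"]})
    return VambnModel(hivaes, mbn, None, constraints, missing, groups)


def split_table(table: HeterogeneousTable, test_fraction: float = 0.2,
                seed: int = 0) -> tuple[HeterogeneousTable, HeterogeneousTable]:
    """Random subject-level split into train and test tables."""
    rng = np.random.default_rng(seed)
    n = table.n_subjects
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    te, tr = np.sort(order[:n_test]), np.sort(order[n_test:])

    def subset(idx):
        return HeterogeneousTable(
            [table.subject_ids[i] for i in idx],
            table.values.iloc[idx].reset_index(drop=True),
            table.mask[idx],
            list(table.columns),
        )

    return subset(tr), subset(te)
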