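"""Modular Bayesian network over per-module VAE codes.

Nodes are the Gaussian module embeddings z(module, visit), the categorical
mixture labels s (when K > 1), standalone categorical variables (e.g. a
treatment arm), and the binary missingness indicators. The network is a
conditional-Gaussian Bayesian network: a discrete node may never be the
child of a Gaussian one, so the likelihood decomposes into per-partition
linear models and multinomial tables and can be scored in closed form.

Structure learning is a BIC-scored tabu search under a blacklist encoding
causal role constraints (baseline only outgoing, no edges backwards in
time, ...) and a whitelist of forced edges (auxiliary indicators onto their
module nodes, indicator chains over visits, empirically known edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import HeterogeneousTable, MissingnessNodes, ModuleGroup
from .hivae import HivaeModel, encode

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-10

GAUSSIAN_KINDS = ("gaussian_code",)
DISCRETE_KINDS = ("component_label", "standalone_categorical", "auxiliary",
                  "visit_missing")
#: kinds carrying module content, subject to the causal role rules
CONTENT_KINDS = ("gaussian_code", "component_label", "standalone_categorical")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MbnNode:
    name: str
    kind: str
    module: str | None = None
    visit: int | None = None
    role: str | None = None
    n_levels: int = 0  # discrete nodes only

    def __post_init__(self):
        if self.kind in DISCRETE_KINDS and self.n_levels < 2:
            raise ValueError(f"discrete node {self.name!r} needs n_levels >= 2")

    @property
    def is_gaussian(self) -> bool:
        return self.kind in GAUSSIAN_KINDS


@dataclass
class EncodedCohort:
    """The MBN's training table: one fully observed row per subject.

    Gaussian columns hold embeddings (missing blocks carry the encoder's
    deterministic fill code; their auxiliary indicator records the fact),
    discrete columns hold 0-based level indices.
    """

    subjects: list
    columns: list[MbnNode]
    values: pd.DataFrame

    def node(self, name: str) -> MbnNode:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def resample(self, rng) -> "EncodedCohort":
        idx = rng.integers(0, self.n, size=self.n)
        return EncodedCohort(
            [self.subjects[i] for i in idx],
            self.columns,
            self.values.iloc[idx].reset_index(drop=True),
        )


@dataclass
class EdgeConstraints:
    blacklist: set = field(default_factory=set)
    whitelist: set = field(default_factory=set)

    def __post_init__(self):
        self.blacklist -= self.whitelist
        g = nx.DiGraph(list(self.whitelist))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("whitelist edges form a cycle")


@dataclass
class MbnModel:
    columns: list  # list[MbnNode]
    dag: set  # directed edges (parent, child) over node names
    gaussian_params: dict = field(default_factory=dict)
    cpt: dict = field(default_factory=dict)
    score: float = float("nan")

    def node(self, name: str) -> MbnNode:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def parents(self, name: str) -> set:
        return {p for p, c in self.dag if c == name}

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(c.name for c in self.columns)
        g.add_edges_from(self.dag)
        return g


# ---------------------------------------------------------------------------
# node naming helpers
# ---------------------------------------------------------------------------

def z_name(module: str, visit: int) -> str:
    return f"z_{module}_v{visit}"


def s_name(module: str, visit: int) -> str:
    return f"s_{module}_v{visit}"


def aux_name(module: str, visit: int) -> str:
    return f"aux_{module}_v{visit}"


def vm_name(visit: int) -> str:
    return f"vm_v{visit}"


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def assemble_cohort(
    table: HeterogeneousTable,
    groups: list[ModuleGroup],
    hivaes: dict,
    missing: MissingnessNodes,
) -> EncodedCohort:
    """Build the MBN training table from encoded modules and indicators.

    Mixture labels s are added only for modules with K > 1 (a constant
    label carries no information). Standalone groups contribute one
    categorical node per variable and visit; their rare missing cells are
    filled with the most frequent observed level.
    """
    cols: list[MbnNode] = []
    data: dict[str, np.ndarray] = {}
    n = table.n_subjects
    for g in groups:
        if g.encoded:
            model: HivaeModel = hivaes[g.name]
            X, m, rows, _ = table.module_stack(g.name)
            codes = encode(model, X, m)
            visits = sorted({t for _, t in rows})
            per_visit = {t: [c for c, (_, tt) in zip(codes, rows) if tt == t]
                         for t in visits}
            for t in visits:
                cs = per_visit[t]
                for d in range(model.config.latent_dim):
                    suffix = f"_d{d}" if model.config.latent_dim > 1 else ""
                    nm = z_name(g.name, t) + suffix
                    cols.append(MbnNode(nm, "gaussian_code", g.name, t, g.role))
                    data[nm] = np.array([c.z[d] for c in cs])
                if model.config.n_components > 1:
                    nm = s_name(g.name, t)
                    cols.append(MbnNode(nm, "component_label", g.name, t,
                                        g.role, model.config.n_components))
                    data[nm] = np.array([c.s - 1 for c in cs], dtype=np.int64)
        else:
            for v in g.variables:
                for t in v.visits:
                    j = [c.name for c in table.columns].index(v.column_name(t))
                    idx = np.zeros(n, dtype=np.int64)
                    lut = {lab: k for k, lab in enumerate(v.levels)}
                    obs = table.mask[:, j]
                    vals = [lut[x] for x in table.values.iloc[:, j][obs]]
                    fill = int(np.bincount(vals).argmax()) if vals else 0
                    for i in range(n):
                        idx[i] = lut[table.values.iat[i, j]] if obs[i] else fill
                    nm = f"{v.name}_v{t}"
                    cols.append(MbnNode(nm, "standalone_categorical", g.name,
                                        t, g.role, len(v.levels)))
                    data[nm] = idx
    for (m_, t), ind in sorted(missing.aux.items()):
        nm = aux_name(m_, t)
        cols.append(MbnNode(nm, "auxiliary", m_, t, None, 2))
        data[nm] = ind.astype(np.int64)
    for t, ind in sorted(missing.visit_missing.items()):
        nm = vm_name(t)
        cols.append(MbnNode(nm, "visit_missing", None, t, None, 2))
        data[nm] = ind.astype(np.int64)
    df = pd.DataFrame({c.name: data[c.name] for c in cols})
    return EncodedCohort(list(table.subject_ids), cols, df)


# ---------------------------------------------------------------------------
# edge constraints
# ---------------------------------------------------------------------------

def build_constraints(
    nodes: list[MbnNode],
    extra_whitelist: set | None = None,
    collapsed: set | None = None,
) -> EdgeConstraints:
    """Derive the blacklist/whitelist from node roles, visits and kinds.

    Blacklisted are edges that would (1) enter a baseline-demographic or
    treatment module (both are exogenous), (2) enter medical history from
    anything but baseline, history or biomarkers, (3) leave imaging toward
    another module kind, (4) enter imaging from modules that cannot
    plausibly drive it (history, non-motor, other), (5) enter a biomarker
    module from outside {biomarker, baseline}, (6) point backwards in time,
    or make a discrete node the child of a Gaussian one. Whitelisted
    (forced) are mixture labels and auxiliary indicators onto their own
    module node, indicator chains between consecutive visits, the
    visit-missing node onto module nodes whose auxiliary indicator was
    collapsed into it, and any caller-supplied, empirically known edges.
    """
    by_name = {nd.name: nd for nd in nodes}
    white: set = set(extra_whitelist or ())
    for e in white:
        if e[0] not in by_name or e[1] not in by_name:
            raise ValueError(f"whitelist edge {e} references unknown node")

    # forced parents: s and aux onto their own module-visit gaussian node(s)
    for nd in nodes:
        if nd.kind == "component_label":
            for tgt in nodes:
                if (tgt.kind == "gaussian_code" and tgt.module == nd.module
                        and tgt.visit == nd.visit):
                    white.add((nd.name, tgt.name))
        elif nd.kind == "auxiliary":
            for tgt in nodes:
                if (tgt.kind == "gaussian_code" and tgt.module == nd.module
                        and tgt.visit == nd.visit):
                    white.add((nd.name, tgt.name))
    for m, t in collapsed or ():
        if vm_name(t) in by_name:
            for tgt in nodes:
                if (tgt.kind == "gaussian_code" and tgt.module == m
                        and tgt.visit == t):
                    white.add((vm_name(t), tgt.name))

    # indicator chains over consecutive available visits
    aux_by_mod: dict = {}
    for nd in nodes:
        if nd.kind == "auxiliary":
            aux_by_mod.setdefault(nd.module, []).append(nd)
    for mods in aux_by_mod.values():
        mods.sort(key=lambda nd: nd.visit)
        for a, b in zip(mods[:-1], mods[1:]):
            white.add((a.name, b.name))
    vms = sorted((nd for nd in nodes if nd.kind == "visit_missing"),
                 key=lambda nd: nd.visit)
    for a, b in zip(vms[:-1], vms[1:]):
        white.add((a.name, b.name))

    into_imaging_ok = ("imaging", "clinical_outcome", "baseline_demographic",
                       "biomarker", "treatment")
    black: set = set()
    for p in nodes:
        for c in nodes:
            if p.name == c.name:
                continue
            e = (p.name, c.name)
            if p.is_gaussian and c.kind in DISCRETE_KINDS:
                black.add(e)
                continue
            if (p.visit is not None and c.visit is not None
                    and p.visit > c.visit):
                black.add(e)
                continue
            if p.kind in CONTENT_KINDS and c.kind in CONTENT_KINDS:
                if c.role in ("baseline_demographic", "treatment"):
                    black.add(e)
                elif (c.role == "medical_history" and p.role not in
                        ("baseline_demographic", "biomarker", "medical_history")):
                    black.add(e)
                elif p.role == "imaging" and c.role != "imaging":
                    black.add(e)
                elif c.role == "imaging" and p.role not in into_imaging_ok:
                    black.add(e)
                elif (c.role == "biomarker" and p.role not in
                        ("biomarker", "baseline_demographic")):
                    black.add(e)
    return EdgeConstraints(blacklist=black, whitelist=white)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _partition_ids(cohort: EncodedCohort, disc_parents: list[str]):
    """Map each row to a discrete-parent configuration id."""
    if not disc_parents:
        return np.zeros(cohort.n, dtype=np.int64), 1, [()]
    cards = [cohort.node(p).n_levels for p in disc_parents]
    vals = [cohort.values[p].to_numpy(dtype=np.int64) for p in disc_parents]
    ids = np.ravel_multi_index(vals, cards)
    n_configs = int(np.prod(cards))
    configs = [tuple(np.unravel_index(i, cards)) for i in range(n_configs)]
    configs = [tuple(int(x) for x in cfg) for cfg in configs]
    return ids, n_configs, configs


def _split_parents(cohort: EncodedCohort, parents) -> tuple[list, list]:
    disc = sorted(p for p in parents if cohort.node(p).kind in DISCRETE_KINDS)
    cont = sorted(p for p in parents if cohort.node(p).is_gaussian)
    return disc, cont


def local_score(node: MbnNode, parents, cohort: EncodedCohort) -> float:
    """BIC-penalized local log-likelihood of `node` given `parents`.

    Gaussian nodes: rows are partitioned by the configuration c of the
    discrete parents; within each partition a linear regression on the
    continuous parents is fitted by maximum likelihood, contributing
    -n_c/2 (log sigma_c^2 + log 2 pi + 1) + n_c log(n_c / N); empty
    partitions contribute 0. Discrete nodes use the multinomial maximum
    log-likelihood per configuration. The penalty is (log N / 2) times the
    parameter count (per-configuration intercept+slopes+variance for
    Gaussian children, cardinality-1 per configuration for discrete ones).
    Higher is better.
    """
    disc, cont = _split_parents(cohort, parents)
    if node.kind in DISCRETE_KINDS and cont:
        raise ValueError(
            f"discrete node {node.name!r} cannot have Gaussian parents {cont}"
        )
    N = cohort.n
    ids, n_configs, _ = _partition_ids(cohort, disc)
    logl = 0.0
    if node.is_gaussian:
        y = cohort.values[node.name].to_numpy(dtype=np.float64)
        Xc = (cohort.values[cont].to_numpy(dtype=np.float64)
              if cont else np.empty((N, 0)))
        k_reg = 1 + len(cont)
        for cid in np.unique(ids):
            sel = ids == cid
            n_c = int(sel.sum())
            yc = y[sel]
            design = np.concatenate([np.ones((n_c, 1)), Xc[sel]], axis=1)
            if n_c >= 1:
                beta, *_ = np.linalg.lstsq(design, yc, rcond=None)
                rss = float(np.sum((yc - design @ beta) ** 2))
                sigma2 = max(rss / n_c, _VAR_FLOOR)
                if n_c <= k_reg:
                    warnings.warn(
                        f"degenerate partition for {node.name} "
                        f"(n={n_c} <= {k_reg} regressors)"
                    )
                logl += (-0.5 * n_c * (np.log(sigma2) + _LOG2PI + 1.0)
                         + n_c * np.log(n_c / N))
        n_par = n_configs * (k_reg + 1)
    else:
        yv = cohort.values[node.name].to_numpy(dtype=np.int64)
        L = node.n_levels
        for cid in np.unique(ids):
            sel = ids == cid
            n_c = int(sel.sum())
            counts = np.bincount(yv[sel], minlength=L)
            nz = counts > 0
            logl += float(np.sum(counts[nz] * np.log(counts[nz] / n_c)))
        n_par = n_configs * (L - 1)
    return logl - 0.5 * np.log(N) * n_par


def total_score(dag: set, cohort: EncodedCohort) -> float:
    """Decomposable BIC of a DAG: sum of local scores over nodes."""
    out = 0.0
    for c in cohort.columns:
        out += local_score(c, {p for p, ch in dag if ch == c.name}, cohort)
    return out


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def _admissible_pairs(cohort: EncodedCohort, constraints: EdgeConstraints):
    names = [c.name for c in cohort.columns]
    kinds = {c.name: c for c in cohort.columns}
    out = []
    for p in names:
        for c in names:
            if p == c or (p, c) in constraints.blacklist:
                continue
            if kinds[p].is_gaussian and kinds[c].kind in DISCRETE_KINDS:
                continue
            out.append((p, c))
    return out


def tabu_search(
    cohort: EncodedCohort,
    constraints: EdgeConstraints,
    max_iter: int = 100,
    tabu_len: int = 100,
    seed: int = 0,
) -> MbnModel:
    """BIC-scored structure search with a tabu list.

    Starts from the whitelist-only graph and repeatedly applies the best
    admissible add/delete/reverse move (ties broken lexicographically),
    even when it worsens the score, while forbidding the inverses of the
    last `tabu_len` moves — the escape mechanism that distinguishes tabu
    search from a plain hill climber. Stops after `max_iter` successive
    moves without improving the best score, then refits parameters on the
    best structure found. Whitelist edges are never removed; blacklisted
    edges and moves breaking acyclicity or the discrete-child restriction
    are never considered. Deterministic for fixed inputs.
    """
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    del seed  # the search itself is deterministic; kept for API symmetry
    nodes = {c.name: c for c in cohort.columns}
    cache: dict = {}

    def ls(child: str, parents: frozenset) -> float:
        key = (child, parents)
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[key] = local_score(nodes[child], set(parents), cohort)
        return cache[key]

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(constraints.whitelist)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("whitelist edges form a cycle")

    def parents_of(c):
        return frozenset(g.predecessors(c))

    current = sum(ls(c, parents_of(c)) for c in nodes)
    best_dag, best_score = set(g.edges()), current
    pairs = _admissible_pairs(cohort, constraints)
    rev_ok = {(p, c) for (p, c) in pairs}
    tabu: list = []
    stall = 0
    while stall < max_iter:
        moves = []  # (delta, order_key, op, edge)
        for p, c in pairs:
            if g.has_edge(p, c):
                continue
            if ("add", (p, c)) in tabu:
                continue
            if nx.has_path(g, c, p):
                continue  # would create a cycle
            pc = parents_of(c)
            delta = ls(c, pc | {p}) - ls(c, pc)
            moves.append((delta, ("add", p, c), "add", (p, c)))
        for p, c in sorted(g.edges()):
            if (p, c) in constraints.whitelist:
                continue
            if ("del", (p, c)) not in tabu:
                pc = parents_of(c)
                delta = ls(c, pc - {p}) - ls(c, pc)
                moves.append((delta, ("del", p, c), "del", (p, c)))
            if (c, p) in rev_ok and ("rev", (p, c)) not in tabu:
                g.remove_edge(p, c)
                cyc = nx.has_path(g, p, c)
                g.add_edge(p, c)
                if not cyc:
                    pc, pp = parents_of(c), parents_of(p)
                    delta = (ls(c, pc - {p}) - ls(c, pc)
                             + ls(p, pp | {c}) - ls(p, pp))
                    moves.append((delta, ("rev", p, c), "rev", (p, c)))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1]))
        delta, _, op, (p, c) = moves[0]
        if op == "add":
            g.add_edge(p, c)
            tabu.append(("del", (p, c)))
        elif op == "del":
            g.remove_edge(p, c)
            tabu.append(("add", (p, c)))
        else:
            g.remove_edge(p, c)
            g.add_edge(c, p)
            tabu.append(("rev", (c, p)))
        tabu = tabu[-tabu_len:]
        current += delta
        if current > best_score + 1e-9:
            best_score, best_dag = current, set(g.edges())
            stall = 0
        else:
            stall += 1
    model = fit_parameters(best_dag, cohort)
    model.score = best_score
    return model


# ---------------------------------------------------------------------------
# parameter fitting & likelihood
# ---------------------------------------------------------------------------

def fit_parameters(dag: set, cohort: EncodedCohort) -> MbnModel:
    """Maximum-likelihood local parameters for a fixed DAG.

    Gaussian nodes: per discrete-parent configuration, an OLS regression on
    the continuous parents with residual variance RSS/n_c. Partitions with
    fewer rows than regression parameters fall back to the partition mean
    and the pooled residual variance (flagged). Discrete nodes: CPTs from
    relative frequencies with add-one smoothing, uniform for unseen
    configurations.
    """
    g = nx.DiGraph(list(dag))
    g.add_nodes_from(c.name for c in cohort.columns)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("dag contains a cycle")
    model = MbnModel(list(cohort.columns), set(dag))
    for node in cohort.columns:
        parents = set(g.predecessors(node.name))
        disc, cont = _split_parents(cohort, parents)
        if node.kind in DISCRETE_KINDS and cont:
            raise ValueError(
                f"discrete node {node.name!r} has Gaussian parents {cont}"
            )
        ids, n_configs, configs = _partition_ids(cohort, disc)
        if node.is_gaussian:
            y = cohort.values[node.name].to_numpy(dtype=np.float64)
            Xc = (cohort.values[cont].to_numpy(dtype=np.float64)
                  if cont else np.empty((cohort.n, 0)))
            k_reg = 1 + len(cont)
            entries, pooled_rss, pooled_n = {}, 0.0, 0
            for cid, cfg in enumerate(configs):
                sel = ids == cid
                n_c = int(sel.sum())
                if n_c == 0:
                    entries[cfg] = None
                    continue
                design = np.concatenate([np.ones((n_c, 1)), Xc[sel]], axis=1)
                if n_c <= k_reg:  # underdetermined: mean-only fallback
                    beta = np.zeros(k_reg)
                    beta[0] = y[sel].mean()
                    rss = float(np.sum((y[sel] - beta[0]) ** 2))
                    entries[cfg] = {"intercept": beta[0],
                                    "slopes": dict(zip(cont, beta[1:])),
                                    "variance": None, "flag": "pooled"}
                else:
                    beta, *_ = np.linalg.lstsq(design, y[sel], rcond=None)
                    rss = float(np.sum((y[sel] - design @ beta) ** 2))
                    var = rss / n_c
                    if var < 1e-8:
                        # an (almost) constant partition — e.g. the fill
                        # code of a missing block — carries no variance
                        # information; fall back to the pooled estimate
                        entries[cfg] = {"intercept": float(beta[0]),
                                        "slopes": {p: float(b) for p, b in
                                                   zip(cont, beta[1:])},
                                        "variance": None,
                                        "flag": "degenerate"}
                    else:
                        entries[cfg] = {"intercept": float(beta[0]),
                                        "slopes": {p: float(b) for p, b in
                                                   zip(cont, beta[1:])},
                                        "variance": var, "flag": None}
                pooled_rss += rss
                pooled_n += n_c
            pooled_var = max(pooled_rss / max(pooled_n, 1), 1e-6)
            for cfg, ent in entries.items():
                if ent is None:
                    entries[cfg] = {"intercept": float(np.mean(y)),
                                    "slopes": {p: 0.0 for p in cont},
                                    "variance": pooled_var, "flag": "empty"}
                elif ent["variance"] is None:
                    ent["variance"] = pooled_var
            model.gaussian_params[node.name] = {
                "disc_parents": disc, "cont_parents": cont, "table": entries,
            }
        else:
            yv = cohort.values[node.name].to_numpy(dtype=np.int64)
            L = node.n_levels
            table = {}
            for cid, cfg in enumerate(configs):
                sel = ids == cid
                counts = np.bincount(yv[sel], minlength=L).astype(np.float64)
                table[cfg] = (counts + 1.0) / (counts.sum() + L)
            model.cpt[node.name] = {"disc_parents": disc, "table": table}
    return model


def loglik(model: MbnModel, cohort: EncodedCohort) -> np.ndarray:
    """Per-subject log-likelihood under the fitted local distributions."""
    out = np.zeros(cohort.n)
    for node in cohort.columns:
        if node.is_gaussian:
            gp = model.gaussian_params[node.name]
            y = cohort.values[node.name].to_numpy(dtype=np.float64)
            m = np.zeros(cohort.n)
            v = np.zeros(cohort.n)
            ids, _, configs = _partition_ids(cohort, gp["disc_parents"])
            by_id = {cid: gp["table"][cfg] for cid, cfg in enumerate(configs)}
            for cid in np.unique(ids):
                sel = ids == cid
                ent = by_id[int(cid)]
                mu = np.full(int(sel.sum()), ent["intercept"])
                for p, b in ent["slopes"].items():
                    mu += b * cohort.values[p].to_numpy(dtype=np.float64)[sel]
                m[sel] = mu
                v[sel] = ent["variance"]
            out += -0.5 * (np.log(v) + _LOG2PI + (y - m) ** 2 / v)
        else:
            tab = model.cpt[node.name]
            yv = cohort.values[node.name].to_numpy(dtype=np.int64)
            ids, _, configs = _partition_ids(cohort, tab["disc_parents"])
            by_id = {cid: tab["table"][cfg] for cid, cfg in enumerate(configs)}
            for cid in np.unique(ids):
                sel = ids == cid
                out[sel] += np.log(by_id[int(cid)][yv[sel]])
    return out


def bootstrap_edges(
    cohort: EncodedCohort,
    constraints: EdgeConstraints,
    n_boot: int = 100,
    seed: int = 0,
    max_iter: int = 50,
) -> dict:
    """Non-parametric bootstrap of structure learning.

    Resamples subjects with replacement `n_boot` times, reruns the tabu
    search on each resample, and returns the inclusion fraction of every
    directed edge that ever appeared. Whitelisted edges are forced in every
    run (frequency 1); blacklisted edges can never appear.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    freqs: dict = {}
    for _ in range(n_boot):
        res = cohort.resample(rng)
        model = tabu_search(res, constraints, max_iter=max_iter)
        for e in model.dag:
            freqs[e] = freqs.get(e, 0) + 1
    return {e: k / n_boot for e, k in sorted(freqs.items())}


# ---------------------------------------------------------------------------
# DAG import/export
# ---------------------------------------------------------------------------

def write_edge_list(edges, path, freqs: dict | None = None) -> None:
    """parent<TAB>child<TAB>frequency text format."""
    with open(path, "w") as fh:
        for p, c in sorted(edges):
            f = 1.0 if freqs is None else freqs.get((p, c), 0.0)
            fh.write(f"{p}\t{c}\t{f}\n")


def read_edge_list(path) -> set:
    out = set()
    with open(path) as fh:
        for line in fh:
            if line.strip():
                p, c, *_ = line.rstrip("\n").split("\t")
                out.add((p, c))
    return out


def save_mbn(model: MbnModel, path) -> None:
    """JSON serialization of the network structure and local parameters."""
    import json

    doc = {
        "columns": [c.__dict__ for c in model.columns],
        "dag": sorted(model.dag),
        "score": model.score,
        "gaussian_params": {
            name: {
                "disc_parents": gp["disc_parents"],
                "cont_parents": gp["cont_parents"],
                "table": [
                    {"config": list(cfg), **ent}
                    for cfg, ent in gp["table"].items()
                ],
            }
            for name, gp in model.gaussian_params.items()
        },
        "cpt": {
            name: {
                "disc_parents": tab["disc_parents"],
                "table": [
                    {"config": list(cfg), "probs": probs.tolist()}
                    for cfg, probs in tab["table"].items()
                ],
            }
            for name, tab in model.cpt.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_mbn(path) -> MbnModel:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    cols = [MbnNode(**c) for c in doc["columns"]]
    model = MbnModel(cols, {tuple(e) for e in doc["dag"]},
                     score=doc["score"])
    for name, gp in doc["gaussian_params"].items():
        model.gaussian_params[name] = {
            "disc_parents": gp["disc_parents"],
            "cont_parents": gp["cont_parents"],
            "table": {
                tuple(ent.pop("config")): ent for ent in gp["table"]
            },
        }
    for name, tab in doc["cpt"].items():
        model.cpt[name] = {
            "disc_parents": tab["disc_parents"],
            "table": {
                tuple(ent["config"]): np.asarray(ent["probs"])
                for ent in tab["table"]
            },
        }
    return model


def write_graphml(model: MbnModel, path, freqs: dict | None = None) -> None:
    """Graph-interchange file loadable by common network viewers."""
    g = nx.DiGraph()
    for c in model.columns:
        g.add_node(c.name, kind=c.kind, module=c.module or "",
                   visit=-1 if c.visit is None else int(c.visit))
    for e in sorted(model.dag):
        g.add_edge(*e, frequency=1.0 if freqs is None else freqs.get(e, 0.0))
    nx.write_graphml(g, path)
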