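"""Validation battery: are simulated patients statistically realistic?

Compares cohorts (real, decoded-real, virtual) on marginal summaries,
correlation structure (Frobenius distance of Pearson correlation
matrices), agreement of learned network structures (sensitivity and
specificity over the constraint-admissible edge universe, whitelist
excluded), group-difference effect sizes (ANOVA eta-squared, Mann-Whitney
rank-biserial), and train/test log-likelihood of the fitted model.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import HeterogeneousTable

_NUMERIC = ("real", "positive", "count")


def _numeric_frame(table: HeterogeneousTable) -> pd.DataFrame:
    cols = {}
    for j, c in enumerate(table.columns):
        if c.var.vtype in _NUMERIC:
            v = np.full(table.n_subjects, np.nan)
            obs = table.mask[:, j]
            v[obs] = [float(x) for x in table.values.iloc[:, j][obs]]
            cols[c.name] = v
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# marginal summaries
# ---------------------------------------------------------------------------

def _summary(v: np.ndarray) -> dict:
    v = v[~np.isnan(v)]
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "variance": float(v.var()),
        "median": float(np.median(v)),
        "q1": float(np.quantile(v, 0.25)),
        "q3": float(np.quantile(v, 0.75)),
    }


def compare_marginals(real: HeterogeneousTable,
                      decoded: HeterogeneousTable,
                      virtual: HeterogeneousTable) -> dict:
    """Per-variable summary statistics for each cohort (observed cells only).

    Numeric variables get mean/variance/median/quartiles; discrete ones get
    level frequencies. Variables absent from any cohort are skipped with a
    warning.
    """
    cohorts = {"real": real, "decoded": decoded, "virtual": virtual}
    names = [c.name for c in real.columns]
    out: dict = {}
    for name in names:
        per = {}
        skip = False
        for label, tab in cohorts.items():
            cols = [c.name for c in tab.columns]
            if name not in cols:
                warnings.warn(f"variable {name!r} absent from {label} cohort")
                skip = True
                break
            j = cols.index(name)
            obs = tab.mask[:, j]
            vals = tab.values.iloc[:, j][obs]
            if tab.columns[j].var.vtype in _NUMERIC:
                v = np.array([float(x) for x in vals])
                per[label] = _summary(v) if v.size else {"n": 0}
            else:
                levels = tab.columns[j].var.levels
                n_obs = max(len(vals), 1)
                per[label] = {
                    "n": int(len(vals)),
                    "frequencies": {
                        lev: float((vals == lev).sum() / n_obs)
                        for lev in levels
                    },
                }
        if not skip:
            out[name] = per
    return out


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def correlation_distance(a: HeterogeneousTable,
                         b: HeterogeneousTable) -> tuple[float, float, float]:
    """Frobenius norms of the two Pearson correlation matrices and the
    relative error ||C_b - C_a||_F / ||C_a||_F.

    Computed on the numeric variables shared by both cohorts with
    pairwise-complete observations; zero-variance variables are excluded
    with a warning. Cohort `a` is the designated original.
    """
    fa, fb = _numeric_frame(a), _numeric_frame(b)
    shared = [c for c in fa.columns if c in fb.columns]
    keep = []
    for c in shared:
        if np.nanstd(fa[c].to_numpy()) == 0 or np.nanstd(fb[c].to_numpy()) == 0:
            warnings.warn(f"zero-variance variable {c!r} excluded")
        else:
            keep.append(c)
    if len(keep) < 2:
        raise ValueError("need at least two shared numeric variables")
    ca = fa[keep].corr(method="pearson").to_numpy()
    cb = fb[keep].corr(method="pearson").to_numpy()
    ca = np.nan_to_num(ca)
    cb = np.nan_to_num(cb)
    na = float(np.linalg.norm(ca))
    nb = float(np.linalg.norm(cb))
    rel = float(np.linalg.norm(cb - ca) / na)
    return na, nb, rel


# ---------------------------------------------------------------------------
# structure agreement
# ---------------------------------------------------------------------------

def structure_agreement(reference_dag: set, candidate_dag: set,
                        whitelist: set, universe: set | None = None,
                        nodes: set | None = None) -> tuple[float, float]:
    """Sensitivity/specificity of a candidate DAG against a reference.

    Whitelisted (forced) edges are excluded from both positives and
    negatives — they carry no information about recovery. The edge universe
    defaults to all ordered pairs over the node set; passing the
    constraint-admissible pairs excludes impossible-by-construction edges
    from the negatives.
    """
    if nodes is not None:
        for e in reference_dag | candidate_dag:
            if e[0] not in nodes or e[1] not in nodes:
                raise ValueError(f"edge {e} references node outside the node set")
    if universe is None:
        if nodes is None:
            nodes = {x for e in reference_dag | candidate_dag | set(whitelist)
                     for x in e}
        universe = {(p, c) for p in nodes for c in nodes if p != c}
    universe = set(universe) - set(whitelist)
    pos = (set(reference_dag) & universe)
    neg = universe - pos
    cand = set(candidate_dag) & universe
    tp = len(cand & pos)
    tn = len(neg - cand)
    sens = tp / len(pos) if pos else 1.0
    spec = tn / len(neg) if neg else 1.0
    return sens, spec


# ---------------------------------------------------------------------------
# group effects
# ---------------------------------------------------------------------------

def group_effects(table: HeterogeneousTable, grouping: str, outcome: str,
                  test: str = "anova") -> tuple[float, float, float]:
    """Test a group difference on an outcome variable.

    Returns (statistic, p, effect size): ANOVA with eta-squared, or
    Mann-Whitney U with the signed rank-biserial correlation
    r = 2 U1 / (n1 n2) - 1 (U1 for the first level; +1 means complete
    separation with the first group larger). Rows missing either cell are
    dropped.
    """
    cols = [c.name for c in table.columns]
    jg, jo = cols.index(grouping), cols.index(outcome)
    ok = table.mask[:, jg] & table.mask[:, jo]
    g = np.array([str(x) for x in table.values.iloc[:, jg][ok]])
    y = np.array([float(x) for x in table.values.iloc[:, jo][ok]])
    levels = [lev for lev in dict.fromkeys(g)]
    samples = [y[g == lev] for lev in levels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if test == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*samples)
        gm = y.mean()
        ss_b = sum(len(s) * (s.mean() - gm) ** 2 for s in samples)
        ss_t = float(((y - gm) ** 2).sum())
        eta2 = ss_b / ss_t if ss_t > 0 else 0.0
        if not np.isfinite(f):  # identical constant groups
            f, p = 0.0, 1.0
        return float(f), float(p), float(eta2)
    if test == "mann_whitney":
        if len(samples) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        u1, p = stats.mannwhitneyu(samples[0], samples[1],
                                   alternative="two-sided")
        r = 2.0 * u1 / (len(samples[0]) * len(samples[1])) - 1.0
        return float(u1), float(p), float(r)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)


def plot_marginals(real: HeterogeneousTable, virtual: HeterogeneousTable,
                   variables: list, path) -> None:
    """Overlay density histograms of selected variables (real vs virtual)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fr, fv = _numeric_frame(real), _numeric_frame(virtual)
    k = len(variables)
    fig, axes = plt.subplots(1, k, figsize=(4 * k, 3), squeeze=False)
    for ax, v in zip(axes[0], variables):
        ax.hist(fr[v].dropna(), bins=30, alpha=0.5, density=True, label="real")
        ax.hist(fv[v].dropna(), bins=30, alpha=0.5, density=True,
                label="virtual")
        ax.set_title(v)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
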