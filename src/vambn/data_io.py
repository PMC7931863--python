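"""Study-table I/O and missingness bookkeeping.

A study is a wide CSV (one row per subject) plus a configuration file that
assigns every data column to a *module* (a predefined group of variables,
e.g. demographics or a clinical score) measured at one or more *visits*.
Variables carry one of five statistical types: ``real``, ``positive``
(strictly positive continuous), ``count``, ``categorical`` or ``ordinal``.

Missing cells are tracked in a boolean mask. Block-wise missingness — a
subject lacking a whole module at a visit, or a whole visit — is turned
into binary indicator nodes for the Bayesian network: *auxiliary* nodes per
module-visit block and *missing-visit* nodes per visit. Indicators are only
introduced for blocks with more than five affected subjects, and an
auxiliary indicator identical to its visit indicator is collapsed into it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VTYPES = ("real", "positive", "count", "categorical", "ordinal")
ROLES = (
    "baseline_demographic",
    "medical_history",
    "imaging",
    "clinical_outcome",
    "nonmotor_assessment",
    "biomarker",
    "treatment",
    "other",
)

#: accepted spellings of a missing cell in CSV input (case-insensitive)
NA_STRINGS = {"", "na", "nan"}


class ConfigurationError(ValueError):
    """The study configuration is inconsistent with itself or the CSV."""


class DataError(ValueError):
    """A data cell violates its declared variable type."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One study variable: its type, category levels and visit schedule."""

    name: str
    vtype: str
    module: str
    visits: tuple[int, ...]
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise ConfigurationError(
                f"variable {self.name!r}: unknown vtype {self.vtype!r}"
            )
        discrete = self.vtype in ("categorical", "ordinal")
        if discrete and not self.levels:
            raise ConfigurationError(
                f"variable {self.name!r}: {self.vtype} requires levels"
            )
        if not discrete and self.levels:
            raise ConfigurationError(
                f"variable {self.name!r}: levels only allowed for "
                "categorical/ordinal variables"
            )
        if list(self.visits) != sorted(set(self.visits)) or not self.visits:
            raise ConfigurationError(
                f"variable {self.name!r}: visits must be strictly increasing"
            )

    def column_name(self, visit: int) -> str:
        """CSV column for this variable at `visit`."""
        if len(self.visits) == 1:
            return self.name
        return f"{self.name}_V{visit}"


@dataclass(frozen=True)
class ModuleGroup:
    """A named group of variables sharing a causal role class.

    ``encoded`` is False for standalone categorical nodes (e.g. a treatment
    arm) that enter the Bayesian network directly instead of through a VAE.
    """

    name: str
    role: str
    variables: tuple[VariableSpec, ...]
    encoded: bool = True

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(
                f"module {self.name!r}: unknown role {self.role!r}"
            )
        for v in self.variables:
            if v.module != self.name:
                raise ConfigurationError(
                    f"variable {v.name!r} declares module {v.module!r} but "
                    f"sits in group {self.name!r}"
                )
        if not self.encoded:
            for v in self.variables:
                if v.vtype not in ("categorical", "ordinal"):
                    raise ConfigurationError(
                        f"standalone module {self.name!r}: variable "
                        f"{v.name!r} must be categorical/ordinal"
                    )

    @property
    def visits(self) -> tuple[int, ...]:
        out: set[int] = set()
        for v in self.variables:
            out.update(v.visits)
        return tuple(sorted(out))


@dataclass(frozen=True)
class ColumnSpec:
    """A single table column: a variable observed at one visit."""

    var: VariableSpec
    visit: int

    @property
    def name(self) -> str:
        return self.var.column_name(self.visit)


@dataclass
class HeterogeneousTable:
    """Subjects x variables with a per-cell observation mask.

    ``values`` is an object-dtype DataFrame (floats for numeric variables,
    level labels for discrete ones, ``None`` where unobserved). ``mask`` is
    True exactly where a cell is observed.
    """

    subject_ids: list
    values: pd.DataFrame
    mask: np.ndarray
    columns: list[ColumnSpec]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def specs(self) -> list[VariableSpec]:
        return [c.var for c in self.columns]

    def column_index(self, module: str, visit: int) -> list[int]:
        return [
            j
            for j, c in enumerate(self.columns)
            if c.var.module == module and c.visit == visit
        ]

    def block_missing(self, module: str, visit: int) -> np.ndarray:
        """Per-subject indicator: all of `module`'s variables at `visit` unobserved."""
        idx = self.column_index(module, visit)
        if not idx:
            raise KeyError(f"no columns for module {module!r} at visit {visit}")
        return (~self.mask[:, idx]).all(axis=1).astype(np.int64)

    def module_stack(self, module: str):
        """Stack a module's per-visit blocks into one (subject, visit)-row slice.

        Returns ``(X, mask, rows)`` where ``X`` is an object array of shape
        (n_subjects * n_visits, n_module_vars), column order follows the
        module's variable order, and ``rows`` lists (subject_index, visit).
        Used to train one VAE per module across all its visits.
        """
        vars_ = sorted(
            {c.var.name: c.var for c in self.columns if c.var.module == module}.values(),
            key=lambda v: [c.var.name for c in self.columns].index(v.name),
        )
        visits = sorted({c.visit for c in self.columns if c.var.module == module})
        blocks, masks, rows = [], [], []
        colnames = [c.name for c in self.columns]
        for t in visits:
            idx = [colnames.index(v.column_name(t)) for v in vars_ if t in v.visits]
            if len(idx) != len(vars_):
                raise ConfigurationError(
                    f"module {module!r}: variables measured at different "
                    f"visit sets are not supported (visit {t})"
                )
            blocks.append(self.values.iloc[:, idx].to_numpy(dtype=object))
            masks.append(self.mask[:, idx])
            rows.extend((i, t) for i in range(self.n_subjects))
        X = np.concatenate(blocks, axis=0)
        m = np.concatenate(masks, axis=0)
        return X, m, rows, vars_


@dataclass
class MissingnessNodes:
    """Binary indicator nodes describing block-wise missingness."""

    aux: dict = field(default_factory=dict)  # (module, visit) -> int array
    visit_missing: dict = field(default_factory=dict)  # visit -> int array
    collapsed: set = field(default_factory=set)  # (module, visit) keys


# ---------------------------------------------------------------------------
# configuration & loading
# ---------------------------------------------------------------------------

def parse_config(config: dict) -> list[ModuleGroup]:
    """Build module groups from a parsed configuration mapping."""
    if "modules" not in config:
        raise ConfigurationError("configuration lacks a 'modules' list")
    groups = []
    for m in config["modules"]:
        vars_ = tuple(
            VariableSpec(
                name=v["name"],
                vtype=v["vtype"],
                module=m["name"],
                visits=tuple(int(t) for t in v["visits"]),
                levels=tuple(str(x) for x in v.get("levels", ())),
            )
            for v in m["variables"]
        )
        groups.append(
            ModuleGroup(
                name=m["name"],
                role=m["role"],
                variables=vars_,
                encoded=bool(m.get("encoded", True)),
            )
        )
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate module names in configuration")
    return groups


def expected_columns(groups: list[ModuleGroup]) -> list[ColumnSpec]:
    """Canonical column order: (module order, visit, variable order)."""
    cols = []
    for g in groups:
        for t in g.visits:
            for v in g.variables:
                if t in v.visits:
                    cols.append(ColumnSpec(v, t))
    return cols


def _parse_cell(raw, col: ColumnSpec, row_label):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s.lower() in NA_STRINGS:
        return None
    v = col.var
    if v.vtype in ("categorical", "ordinal"):
        if s not in v.levels:
            raise DataError(
                f"row {row_label!r}, column {col.name!r}: value {s!r} is not "
                f"among declared levels {list(v.levels)}"
            )
        return s
    try:
        x = float(s)
    except ValueError as e:
        raise DataError(
            f"row {row_label!r}, column {col.name!r}: {s!r} is not numeric"
        ) from e
    if v.vtype == "positive" and x <= 0:
        raise DataError(
            f"row {row_label!r}, column {col.name!r}: positive variable has "
            f"non-positive value {x}"
        )
    if v.vtype == "count" and (x < 0 or x != int(x)):
        raise DataError(
            f"row {row_label!r}, column {col.name!r}: count variable has "
            f"value {x}"
        )
    return x


def load_study(table_path, config_path) -> tuple[HeterogeneousTable, list[ModuleGroup]]:
    """Read a wide study CSV and its configuration.

    The first CSV column is the subject identifier. Every other column must
    be declared exactly once by the configuration; multi-visit variables use
    ``NAME_V<visit>`` columns. Empty cells and the strings NA/NaN (any case)
    are treated as missing.
    """
    with open(config_path) as fh:
        groups = parse_config(yaml.safe_load(fh))
    cols = expected_columns(groups)

    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    subject_col = df.columns[0]
    declared = {c.name for c in cols}
    present = set(df.columns[1:])
    missing = sorted(declared - present)
    if missing:
        raise ConfigurationError(
            f"configured columns absent from CSV: {missing}"
        )
    extra = sorted(present - declared)
    if extra:
        raise ConfigurationError(f"CSV columns not declared in config: {extra}")

    subject_ids = df[subject_col].tolist()
    n = len(subject_ids)
    values = np.empty((n, len(cols)), dtype=object)
    mask = np.zeros((n, len(cols)), dtype=bool)
    for j, c in enumerate(cols):
        raw = df[c.name].to_numpy()
        for i in range(n):
            cell = _parse_cell(raw[i], c, subject_ids[i])
            values[i, j] = cell
            mask[i, j] = cell is not None
    vdf = pd.DataFrame(values, columns=[c.name for c in cols])
    return HeterogeneousTable(subject_ids, vdf, mask, cols), groups


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, float):
        return repr(x)  # round-trips exactly through float()
    return str(x)


def write_wide(table: HeterogeneousTable, path) -> None:
    """Write the wide CSV form readable by :func:`load_study`."""
    with open(path, "w") as fh:
        fh.write(",".join(["SUBJID"] + [c.name for c in table.columns]) + "\n")
        for i, sid in enumerate(table.subject_ids):
            cells = [str(sid)]
            for j in range(len(table.columns)):
                cells.append(_fmt(table.values.iat[i, j]) if table.mask[i, j] else "")
            fh.write(",".join(cells) + "\n")


def write_long(table: HeterogeneousTable, path) -> None:
    """Canonical long format: subject_id, module, visit, variable, value."""
    with open(path, "w") as fh:
        fh.write("subject_id,module,visit,variable,value\n")
        for i, sid in enumerate(table.subject_ids):
            for j, c in enumerate(table.columns):
                if table.mask[i, j]:
                    fh.write(
                        f"{sid},{c.var.module},{c.visit},{c.var.name},"
                        f"{_fmt(table.values.iat[i, j])}\n"
                    )


def write_config(groups: list[ModuleGroup], path) -> None:
    doc = {
        "modules": [
            {
                "name": g.name,
                "role": g.role,
                "encoded": g.encoded,
                "variables": [
                    {
                        "name": v.name,
                        "vtype": v.vtype,
                        "visits": list(v.visits),
                        **({"levels": list(v.levels)} if v.levels else {}),
                    }
                    for v in g.variables
                ],
            }
            for g in groups
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# missingness nodes
# ---------------------------------------------------------------------------

#: minimum number of affected subjects before an indicator node is introduced
MISSINGNESS_THRESHOLD = 5


def build_missingness_nodes(
    table: HeterogeneousTable, groups: list[ModuleGroup]
) -> MissingnessNodes:
    """Construct auxiliary and missing-visit indicator nodes.

    The auxiliary indicator for (module, visit) is 1 for a subject iff every
    variable of that module at that visit is unobserved. The missing-visit
    indicator for visit t is 1 iff all modules measured at t are unobserved.
    Indicators with at most :data:`MISSINGNESS_THRESHOLD` affected subjects
    are dropped, and an auxiliary indicator that equals its visit indicator
    subject-for-subject is collapsed into the visit node.
    """
    out = MissingnessNodes()
    visits = sorted({c.visit for c in table.columns})
    block = {}
    for g in groups:
        for t in g.visits:
            block[(g.name, t)] = table.block_missing(g.name, t)

    for t in visits:
        mods = [k for k in block if k[1] == t]
        vm = np.ones(table.n_subjects, dtype=np.int64)
        for k in mods:
            vm &= block[k]
        if vm.sum() > MISSINGNESS_THRESHOLD:
            out.visit_missing[t] = vm

    for (m, t), ind in sorted(block.items()):
        if ind.sum() <= MISSINGNESS_THRESHOLD:
            continue
        vm = out.visit_missing.get(t)
        if vm is not None and np.array_equal(ind, vm):
            out.collapsed.add((m, t))
        else:
            out.aux[(m, t)] = ind
    return out
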