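"""Decomposable log-linear graphical models over categorical cohort variables.

Provides contingency-table construction, iterative-proportional-fitting (IPF)
estimation restricted to decomposable (chordal) undirected graphs, backward
stepwise edge elimination under a penalized log-likelihood
``H(j, k) = -2 logL(j) + k * z(j)`` or a chi-square deletion test,
conditional imputation of a missing variable, and junction-tree forward
sampling of synthetic datasets.

Restricting to decomposable models keeps IPF exact (it converges to the
closed-form clique/separator product) and makes direct junction-tree
sampling possible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import VARIABLE_LEVELS, PatientRecord, cohort_to_frame

__all__ = [
    "GM_VARIABLES",
    "MODEL_ORDER",
    "ContingencyTable",
    "GraphModel",
    "NonDecomposableError",
    "build_table",
    "complete_cases",
    "fit_decomposable",
    "stepwise_select",
    "fit_four_models",
    "impute_missing",
    "simulate_syn",
    "synd_to_cohort",
]

logger = logging.getLogger(__name__)

#: Default variable set of the cohort graphical model.
GM_VARIABLES = ("age_group", "stage", "her2", "adherence", "followup", "exitus")

#: Fixed label order; also the tie-break order during subset selection.
MODEL_ORDER = ("GMK1", "GMTEST", "GMAIC", "GMBIC")

_IPF_TOL = 1e-10
_IPF_MAX_CYCLES = 2000


class NonDecomposableError(ValueError):
    """The candidate graph is not chordal, so the model class excludes it."""


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of categorical variables; counts sum to N."""

    variables: tuple[str, ...]
    levels: tuple[tuple, ...]
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    def axis(self, variable: str) -> int:
        return self.variables.index(variable)


def complete_cases(
    cohort: Sequence[PatientRecord] | pd.DataFrame,
    variables: Sequence[str] = GM_VARIABLES,
) -> pd.DataFrame:
    """Rows of the cohort with every listed variable observed."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    mask = np.ones(len(frame), dtype=bool)
    for var in variables:
        mask &= frame[var].notna().to_numpy()
    return frame.loc[mask].reset_index(drop=True)


def build_table(
    cohort: Sequence[PatientRecord] | pd.DataFrame,
    variables: Sequence[str] = GM_VARIABLES,
) -> ContingencyTable:
    """Exact cross-tabulation of the cohort over ``variables``.

    Raises on an empty cohort or on any missing value; callers wanting the
    complete-case table should filter with :func:`complete_cases` first.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if len(frame) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    variables = tuple(variables)
    levels = tuple(tuple(VARIABLE_LEVELS[v]) for v in variables)
    shape = tuple(len(lv) for lv in levels)
    idx = np.empty((len(frame), len(variables)), dtype=np.intp)
    for j, (var, lv) in enumerate(zip(variables, levels)):
        lookup = {value: i for i, value in enumerate(lv)}
        column = frame[var].tolist()
        for i, value in enumerate(column):
            if value is None or (isinstance(value, float) and value != value):
                raise ValueError(f"missing value for {var!r} in row {i}")
            try:
                idx[i, j] = lookup[value]
            except KeyError:
                raise ValueError(f"unknown level {value!r} for variable {var!r}")
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple(idx.T), 1)
    return ContingencyTable(variables=variables, levels=levels, counts=counts)


def _junction_tree(cliques: list[tuple[str, ...]]):
    """Maximum-weight spanning tree (Kruskal, deterministic tie-break).

    Returns edges as (i, j, separator) triples over clique indices; cliques
    in different connected components of the variable graph get joined by
    empty separators, yielding a single sampling tree.
    """
    m = len(cliques)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    candidates = sorted(
        ((i, j) for i in range(m) for j in range(i + 1, m)),
        key=lambda ij: (-len(set(cliques[ij[0]]) & set(cliques[ij[1]])), ij),
    )
    edges = []
    for i, j in candidates:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            sep = tuple(sorted(set(cliques[i]) & set(cliques[j])))
            edges.append((i, j, sep))
        if len(edges) == m - 1:
            break
    return edges


@dataclass(frozen=True)
class GraphModel:
    """A fitted decomposable log-linear model.

    ``probs`` is the fitted joint cell-probability array in the table's
    variable order; ``cliques`` and ``jt_edges`` describe the junction tree
    used for sampling; ``n_params`` is the model dimension z(j) computed by
    inclusion-exclusion over cliques and separators.
    """

    variables: tuple[str, ...]
    levels: tuple[tuple, ...]
    edges: tuple[tuple[str, str], ...]
    probs: np.ndarray
    loglik: float
    n_params: int
    penalty: float | None
    criterion: str
    cliques: tuple[tuple[str, ...], ...]
    jt_edges: tuple[tuple[int, int, tuple[str, ...]], ...]
    n: int

    def criterion_value(self, k: float) -> float:
        return -2.0 * self.loglik + k * self.n_params

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": list(self.variables),
            "levels": [list(lv) for lv in self.levels],
            "edges": [list(e) for e in self.edges],
            "loglik": self.loglik,
            "n_params": self.n_params,
            "penalty": self.penalty,
            "criterion": self.criterion,
            "n": self.n,
            "probs": self.probs.ravel().tolist(),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_json(cls, path: str | Path) -> "GraphModel":
        with open(path) as handle:
            payload = json.load(handle)
        variables = tuple(payload["variables"])
        levels = tuple(tuple(lv) for lv in payload["levels"])
        shape = tuple(len(lv) for lv in levels)
        edges = tuple(_canonical_edge(*e) for e in payload["edges"])
        cliques, jt_edges = _graph_structure(variables, edges)
        return cls(
            variables=variables,
            levels=levels,
            edges=edges,
            probs=np.asarray(payload["probs"], dtype=float).reshape(shape),
            loglik=float(payload["loglik"]),
            n_params=int(payload["n_params"]),
            penalty=payload["penalty"],
            criterion=payload["criterion"],
            cliques=cliques,
            jt_edges=jt_edges,
            n=int(payload["n"]),
        )


def _graph_structure(variables, edges):
    graph = nx.Graph()
    graph.add_nodes_from(variables)
    graph.add_edges_from(edges)
    if not nx.is_chordal(graph):
        raise NonDecomposableError(f"graph with edges {sorted(edges)} is not chordal")
    cliques = sorted(tuple(sorted(c)) for c in nx.find_cliques(graph))
    jt_edges = tuple(_junction_tree(cliques))
    return tuple(cliques), jt_edges


def _model_dimension(levels_of, cliques, jt_edges) -> int:
    dim = 0
    for clique in cliques:
        dim += int(np.prod([levels_of[v] for v in clique])) - 1
    for _, _, sep in jt_edges:
        dim -= int(np.prod([levels_of[v] for v in sep], initial=1)) - 1
    return dim


def _ipf(table: ContingencyTable, cliques) -> np.ndarray:
    target = table.counts / table.n
    p = np.full(table.shape, 1.0 / table.counts.size)
    other_axes = []
    for clique in cliques:
        other_axes.append(
            tuple(i for i, v in enumerate(table.variables) if v not in clique)
        )
    for _ in range(_IPF_MAX_CYCLES):
        for axes in other_axes:
            emp = target.sum(axis=axes, keepdims=True)
            cur = p.sum(axis=axes, keepdims=True)
            ratio = np.divide(emp, cur, out=np.zeros_like(emp), where=cur > 0)
            p = p * ratio
        diff = 0.0
        for axes in other_axes:
            diff = max(
                diff,
                float(
                    np.abs(p.sum(axis=axes) - target.sum(axis=axes)).max()
                ),
            )
        if diff < _IPF_TOL:
            break
    else:  # pragma: no cover - IPF on decomposable models converges fast
        logger.warning("IPF did not reach tol %.0e after %d cycles", _IPF_TOL, _IPF_MAX_CYCLES)
    return p


def fit_decomposable(
    table: ContingencyTable,
    edges: Iterable[tuple[str, str]],
    criterion: str = "custom",
    penalty: float | None = None,
) -> GraphModel:
    """Fit the decomposable model with the given edge set by IPF.

    Raises :class:`NonDecomposableError` if the graph is not chordal.
    """
    edges = tuple(sorted({_canonical_edge(u, v) for u, v in edges}))
    cliques, jt_edges = _graph_structure(table.variables, edges)
    probs = _ipf(table, cliques)
    counts = table.counts
    mask = counts > 0
    loglik = float(np.sum(counts[mask] * np.log(probs[mask])))
    levels_of = {v: len(lv) for v, lv in zip(table.variables, table.levels)}
    n_params = _model_dimension(levels_of, cliques, jt_edges)
    return GraphModel(
        variables=table.variables,
        levels=table.levels,
        edges=edges,
        probs=probs,
        loglik=loglik,
        n_params=n_params,
        penalty=penalty,
        criterion=criterion,
        cliques=cliques,
        jt_edges=jt_edges,
        n=table.n,
    )


def _removable_edges(variables, edges):
    """Edges whose deletion keeps the graph chordal, lexicographically sorted."""
    removable = []
    for edge in sorted(edges):
        graph = nx.Graph()
        graph.add_nodes_from(variables)
        graph.add_edges_from(e for e in edges if e != edge)
        if nx.is_chordal(graph):
            removable.append(edge)
    return removable


def stepwise_select(
    table: ContingencyTable,
    penalty: float | None = None,
    alpha: float | None = None,
    criterion: str = "custom",
) -> GraphModel:
    """Backward stepwise edge elimination from the saturated model.

    Exactly one of ``penalty`` (k in H = -2 logL + k z) or ``alpha``
    (chi-square deletion-test level) must be given.  At each step only
    deletions that keep the graph decomposable are candidates; the tie-break
    is the lexicographically smallest edge.
    """
    if (penalty is None) == (alpha is None):
        raise ValueError("specify exactly one of penalty= or alpha=")
    all_edges = tuple(
        _canonical_edge(u, v) for u, v in combinations(sorted(table.variables), 2)
    )
    current = fit_decomposable(table, all_edges, criterion=criterion, penalty=penalty)
    while current.edges:
        best_edge = None
        best_model = None
        if penalty is not None:
            best_gain = 1e-9  # require a strict decrease beyond float noise
            for edge in _removable_edges(table.variables, current.edges):
                cand = fit_decomposable(
                    table,
                    (e for e in current.edges if e != edge),
                    criterion=criterion,
                    penalty=penalty,
                )
                gain = current.criterion_value(penalty) - cand.criterion_value(penalty)
                if gain > best_gain:
                    best_gain, best_edge, best_model = gain, edge, cand
        else:
            best_p = alpha
            for edge in _removable_edges(table.variables, current.edges):
                cand = fit_decomposable(
                    table,
                    (e for e in current.edges if e != edge),
                    criterion=criterion,
                    penalty=penalty,
                )
                dev = max(2.0 * (current.loglik - cand.loglik), 0.0)
                df = max(current.n_params - cand.n_params, 1)
                p_value = float(stats.chi2.sf(dev, df))
                if p_value > best_p:
                    best_p, best_edge, best_model = p_value, edge, cand
        if best_edge is None:
            break
        current = best_model
    return current


def fit_four_models(
    table: ContingencyTable, alpha: float = 0.05
) -> dict[str, GraphModel]:
    """The four stepwise fits: k=1, deletion test, AIC (k=2), BIC (k=log N)."""
    n = table.n
    return {
        "GMK1": stepwise_select(table, penalty=1.0, criterion="GMK1"),
        "GMTEST": stepwise_select(table, alpha=alpha, criterion="GMTEST"),
        "GMAIC": stepwise_select(table, penalty=2.0, criterion="GMAIC"),
        "GMBIC": stepwise_select(table, penalty=math.log(n) if n > 0 else 0.0, criterion="GMBIC"),
    }


def impute_missing(
    cohort: Sequence[PatientRecord],
    model: GraphModel,
    target: str = "adherence",
    seed: int | None = 0,
) -> tuple[list[PatientRecord], int]:
    """Fill the missing ``target`` values by draws from the model conditional.

    For each record with a missing target, the conditional distribution of
    the target given the record's other model variables is read off the
    fitted joint by normalization; a zero-probability covariate combination
    falls back to the target's fitted marginal (logged).  Returns the new
    cohort (records without missingness untouched) and the number imputed.
    """
    if target not in model.variables:
        raise ValueError(f"model does not include target variable {target!r}")
    rng = np.random.default_rng(seed)
    t_axis = model.variables.index(target)
    levels = model.levels[t_axis]
    marginal = model.probs.sum(
        axis=tuple(i for i in range(len(model.variables)) if i != t_axis)
    )
    marginal = marginal / marginal.sum()
    level_index = {
        v: {value: i for i, value in enumerate(lv)}
        for v, lv in zip(model.variables, model.levels)
    }
    n_fallback = 0
    out: list[PatientRecord] = []
    for rec in cohort:
        value = getattr(rec, target)
        if value is not None:
            out.append(rec)
            continue
        frame_row = {
            "age_group": rec.age_group,
            "stage": rec.stage,
            "her2": rec.her2,
            "adherence": rec.adherence,
            "followup": rec.followup,
            "exitus": rec.exitus,
        }
        index = tuple(
            slice(None) if v == target else level_index[v][frame_row[v]]
            for v in model.variables
        )
        cond = model.probs[index]
        total = cond.sum()
        if total <= 0:
            cond = marginal
            n_fallback += 1
        else:
            cond = cond / total
        drawn = levels[rng.choice(len(levels), p=cond)]
        out.append(_replace_field(rec, target, drawn))
    if n_fallback:
        logger.info(
            "impute_missing: %d record(s) used the marginal fallback", n_fallback
        )
    return out, sum(1 for a, b in zip(cohort, out) if a is not b)


def _replace_field(rec: PatientRecord, field: str, value) -> PatientRecord:
    import dataclasses

    return dataclasses.replace(rec, **{field: value})


def simulate_syn(
    model: GraphModel, n: int, seed: int | None = 0, chunk: int = 200_000
) -> pd.DataFrame:
    """Forward-sample ``n`` records over the model's junction tree.

    The root clique is drawn from its fitted marginal, then every adjacent
    clique from its conditional given the separator, walking the tree
    breadth-first.  Returns a DataFrame over the model's variables with
    level values (not indices).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    variables = model.variables
    n_vars = len(variables)
    var_axis = {v: i for i, v in enumerate(variables)}
    sizes = np.array([len(lv) for lv in model.levels])
    rng = np.random.default_rng(seed)

    # breadth-first clique order over the (single, possibly separator-empty) tree
    adjacency: dict[int, list[tuple[int, tuple[str, ...]]]] = {
        i: [] for i in range(len(model.cliques))
    }
    for i, j, sep in model.jt_edges:
        adjacency[i].append((j, sep))
        adjacency[j].append((i, sep))
    order: list[tuple[int, int | None, tuple[str, ...]]] = []
    seen: set[int] = set()
    for root in range(len(model.cliques)):
        if root in seen:
            continue
        queue = [(root, None, ())]
        while queue:
            node, parent, sep = queue.pop(0)
            if node in seen:
                continue
            seen.add(node)
            order.append((node, parent, sep))
            for nxt, nsep in sorted(adjacency[node]):
                if nxt not in seen:
                    queue.append((nxt, node, nsep))

    values = np.zeros((n, n_vars), dtype=np.int64)
    assigned: set[str] = set()
    for node, parent, _ in order:
        clique = model.cliques[node]
        new_vars = [v for v in clique if v not in assigned]
        if not new_vars:
            continue
        cond_vars = [v for v in clique if v in assigned]
        marg_axes = tuple(i for i, v in enumerate(variables) if v not in clique)
        marg = model.probs.sum(axis=marg_axes)
        # reorder to (cond_vars..., new_vars...)
        kept = [v for v in variables if v in clique]
        perm = [kept.index(v) for v in cond_vars + new_vars]
        marg = np.transpose(marg, perm)
        n_cond = int(np.prod([sizes[var_axis[v]] for v in cond_vars], initial=1))
        n_new = int(np.prod([sizes[var_axis[v]] for v in new_vars]))
        flat = marg.reshape(n_cond, n_new)
        row_sums = flat.sum(axis=1, keepdims=True)
        cond_table = np.divide(
            flat, row_sums, out=np.full_like(flat, 1.0 / n_new), where=row_sums > 0
        )
        if cond_vars:
            cond_idx = np.zeros(n, dtype=np.int64)
            for v in cond_vars:
                cond_idx = cond_idx * sizes[var_axis[v]] + values[:, var_axis[v]]
        else:
            cond_idx = np.zeros(n, dtype=np.int64)
        new_draw = np.empty(n, dtype=np.int64)
        for row in np.unique(cond_idx):
            members = np.flatnonzero(cond_idx == row)
            new_draw[members] = rng.choice(n_new, size=members.size, p=cond_table[row])
        new_sizes = [sizes[var_axis[v]] for v in new_vars]
        unravelled = np.unravel_index(new_draw, new_sizes)
        for v, col in zip(new_vars, unravelled):
            values[:, var_axis[v]] = col
        assigned.update(new_vars)

    data = {}
    for j, v in enumerate(variables):
        lv = np.asarray(model.levels[j], dtype=object)
        data[v] = lv[values[:, j]]
    frame = pd.DataFrame(data)
    if "followup" in frame.columns:
        frame["followup"] = frame["followup"].astype(int)
    return frame


def synd_to_cohort(
    synd: pd.DataFrame,
    reference: Sequence[PatientRecord],
    seed: int | None = 0,
    id_prefix: str = "Y",
) -> list[PatientRecord]:
    """Attach exact ages and diagnosis years to a synthetic categorical dataset.

    The graphical model carries only the age group, so (age_dx, year_dx)
    pairs are resampled within each age group from the reference cohort's
    empirical joint distribution.
    """
    rng = np.random.default_rng(seed)
    pools: dict[str, np.ndarray] = {}
    for rec in reference:
        pools.setdefault(rec.age_group, []).append((rec.age_dx, rec.year_dx))
    pools = {g: np.asarray(pairs) for g, pairs in pools.items()}
    n = len(synd)
    width = max(len(str(n)), 1)
    groups = synd["age_group"].to_numpy()
    age_dx = np.empty(n, dtype=np.int64)
    year_dx = np.empty(n, dtype=np.int64)
    for group in sorted(pools):
        members = np.flatnonzero(groups == group)
        if members.size == 0:
            continue
        pick = rng.integers(0, len(pools[group]), size=members.size)
        age_dx[members] = pools[group][pick, 0]
        year_dx[members] = pools[group][pick, 1]
    missing_groups = set(groups) - set(pools)
    if missing_groups:
        raise ValueError(
            f"reference cohort has no members in age group(s) {sorted(missing_groups)}"
        )
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"{id_prefix}{i + 1:0{width}d}",
                age_dx=int(age_dx[i]),
                stage=synd["stage"].iloc[i],
                her2=synd["her2"].iloc[i],
                adherence=synd["adherence"].iloc[i],
                followup=int(synd["followup"].iloc[i]),
                exitus=synd["exitus"].iloc[i],
                year_dx=int(year_dx[i]),
            )
        )
    return records
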