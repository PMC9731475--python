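"""Discrete Bayesian network for daily collision-likelihood inference.

Networks here are small (about a dozen nodes, at most three states each),
so inference is exact: the full joint is materialised as a dense array by
broadcasting CPTs together, and posteriors come from conditioning slices of
that array.  Parameters are learned from complete data by smoothed counting
and from incomplete data by EM; model quality is assessed by stratified
K-fold cross-validation on the likelihood node and ROC/AUC on the
probability of its highest state.

The likelihood node's training label is derived from observation data as
the proximity-weighted product of location risk and observed count, summed
over zones, then discretised.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .data import ZoneMap

__all__ = [
    "NodeSpec",
    "NetworkStructure",
    "BayesNet",
    "CPTSet",
    "LikelihoodLabelSpec",
    "derive_likelihood_label",
    "discretise_node",
    "build_network",
    "learn_cpts",
    "infer",
    "crossvalidate",
    "roc_auc",
    "influence_strength",
]


@dataclass(frozen=True)
class NodeSpec:
    """A discrete node: ordered states (at most three, e.g. low/medium/high)
    and how raw values map onto them."""

    name: str
    states: tuple[str, ...] = ("low", "medium", "high")
    discretisation: str = "quantile"  # quantile | fixed | categorical
    cutpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            warnings.warn(f"node {self.name!r} is degenerate with {len(self.states)} state(s)")
        if len(self.states) > 3:
            raise ValueError(f"node {self.name!r}: at most three states are supported")
        if self.discretisation not in ("quantile", "fixed", "categorical"):
            raise ValueError(f"unknown discretisation {self.discretisation!r}")
        if self.discretisation == "fixed" and self.cutpoints is None:
            raise ValueError(f"node {self.name!r}: fixed discretisation needs cutpoints")


@dataclass
class NetworkStructure:
    nodes: list[NodeSpec]
    edges: list[tuple[str, str]]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkStructure":
        doc = yaml.safe_load(Path(path).read_text())
        nodes = [
            NodeSpec(
                n["name"],
                tuple(n.get("states", ("low", "medium", "high"))),
                n.get("discretisation", "quantile"),
                tuple(n["cutpoints"]) if n.get("cutpoints") else None,
            )
            for n in doc["nodes"]
        ]
        edges = [(e["parent"], e["child"]) for e in doc["edges"]]
        return cls(nodes, edges)


@dataclass
class BayesNet:
    """A validated structure: acyclicity proven, topological order cached."""

    structure: NetworkStructure
    order: list[str] = field(init=False)
    parents: dict[str, list[str]] = field(init=False)
    node_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        names = [n.name for n in self.structure.nodes]
        if not names:
            raise ValueError("network has no nodes")
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        known = set(names)
        for p, c in self.structure.edges:
            if p not in known or c not in known:
                raise ValueError(f"dangling edge ({p!r} -> {c!r}): endpoint not a declared node")
        self.parents = {n: [] for n in names}
        for p, c in self.structure.edges:
            self.parents[c].append(p)
        self.order = self._toposort(names)
        self.node_index = {n: i for i, n in enumerate(names)}

    def _toposort(self, names: list[str]) -> list[str]:
        children: dict[str, list[str]] = {n: [] for n in names}
        indeg = {n: 0 for n in names}
        for p, c in self.structure.edges:
            children[p].append(c)
            indeg[c] += 1
        queue = [n for n in names if indeg[n] == 0]
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(names):
            cycle = sorted(n for n in names if n not in order)
            raise ValueError(f"structure contains a cycle involving: {', '.join(cycle)}")
        return order

    def spec(self, name: str) -> NodeSpec:
        return self.structure.nodes[self.node_index[name]]

    def card(self, name: str) -> int:
        return len(self.spec(name).states)


def build_network(structure: NetworkStructure) -> BayesNet:
    """Validate a structure (acyclic, no dangling edges) into a BayesNet."""
    return BayesNet(structure)


# ---------------------------------------------------------------------------
# Likelihood label and discretisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LikelihoodLabelSpec:
    """How to turn per-zone observations into the likelihood training label.

    raw score = location_weight(z) * observed(z) * (1 / proximity(z)),
    summed over zones (mode="sum"); mode="single" uses only the named zone.
    The raw score is then discretised (tertiles by default).
    """

    mode: str = "sum"
    zone: str | None = None
    n_states: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "single"):
            raise ValueError("mode must be 'sum' or 'single'")
        if self.mode == "single" and self.zone is None:
            raise ValueError("single-zone mode needs a zone")


def derive_likelihood_label(
    row: Mapping[str, float] | pd.Series,
    zone_map: ZoneMap,
    spec: LikelihoodLabelSpec = LikelihoodLabelSpec(),
) -> float:
    """Raw likelihood score for one day from its per-zone observed counts.

    Rows carry ``observed_<zone>`` columns.  A day with no observations
    scores 0 and will land in the lowest state.
    """
    zones = [spec.zone] if spec.mode == "single" else zone_map.zone_ids()
    raw = 0.0
    for z in zones:
        entry = zone_map.get(z)
        if entry is None:
            raise KeyError(f"zone {z!r} missing from zone map")
        obs = float(row.get(f"observed_{z}", 0.0) if hasattr(row, "get") else row[f"observed_{z}"])
        raw += entry.location_weight * obs * (1.0 / entry.proximity)
    return raw


def discretise_node(values: Sequence[float] | np.ndarray, node_spec: NodeSpec) -> np.ndarray:
    """Map numeric values to state indices under the node's discretisation.

    quantile mode derives tertile (generally ``len(states)``-tile) cutpoints
    from the values given — callers pass training data only.  Ties exactly at
    a cutpoint go to the lower state.
    """
    vals = np.asarray(values, dtype=float)
    k = len(node_spec.states)
    if node_spec.discretisation == "categorical":
        return vals.astype(int)
    if node_spec.discretisation == "fixed":
        cuts = np.asarray(node_spec.cutpoints, dtype=float)
    else:
        if np.all(vals == vals[0]):
            warnings.warn(f"node {node_spec.name!r}: constant values collapse to a single state")
            return np.zeros(len(vals), dtype=int)
        qs = np.quantile(vals, [i / k for i in range(1, k)])
        cuts = np.asarray(qs, dtype=float)
    # value <= cut -> lower state
    return np.searchsorted(cuts, vals, side="left").clip(0, k - 1)


def discretise_cases(
    net: BayesNet, frame: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Discretise a raw feature frame into per-node state indices.

    ``columns`` maps node name -> frame column (defaults to same name).
    """
    columns = columns or {}
    out = {}
    for node in net.order:
        col = columns.get(node, node)
        out[node] = discretise_node(frame[col].to_numpy(), net.spec(node))
    return pd.DataFrame(out, index=frame.index)


# ---------------------------------------------------------------------------
# Parameters: CPTs, counting and EM
# ---------------------------------------------------------------------------


class CPTSet:
    """Per-node conditional probability tables.

    Each table is a dense array of shape (card(parent1), ..., card(node));
    the last axis sums to one for every parent-state combination.
    """

    def __init__(self, net: BayesNet, tables: Mapping[str, np.ndarray]):
        self.net = net
        self.tables = {n: np.asarray(t, dtype=float) for n, t in tables.items()}
        for n, t in self.tables.items():
            rows = t.reshape(-1, t.shape[-1])
            if np.any(t < 0):
                raise ValueError(f"CPT for {n!r} has negative entries")
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {n!r} do not sum to 1")

    def to_json(self, path: str | Path) -> None:
        doc = {n: t.tolist() for n, t in self.tables.items()}
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, net: BayesNet, path: str | Path) -> "CPTSet":
        doc = json.loads(Path(path).read_text())
        return cls(net, {n: np.asarray(t) for n, t in doc.items()})

    def joint(self) -> np.ndarray:
        """The full joint as a dense array over nodes in topological order."""
        order = self.net.order
        axis = {n: i for i, n in enumerate(order)}
        shape = [self.net.card(n) for n in order]
        joint = np.ones(shape)
        for n in order:
            pars = self.net.parents[n]
            t = self.tables[n]
            # reorder CPT axes (parents..., node) into joint axis order,
            # then broadcast across the remaining axes
            src_axes = [axis[p] for p in pars] + [axis[n]]
            t_sorted = np.transpose(t, np.argsort(src_axes))
            sl: list = [np.newaxis] * len(order)
            for a in sorted(src_axes):
                sl[a] = slice(None)
            joint = joint * t_sorted[tuple(sl)]
        return joint


def _count_tables(net: BayesNet, cases: pd.DataFrame, alpha: float) -> dict[str, np.ndarray]:
    tables = {}
    for n in net.order:
        pars = net.parents[n]
        shape = [net.card(p) for p in pars] + [net.card(n)]
        counts = np.full(shape, float(alpha))
        cols = cases[pars + [n]].to_numpy(int) if len(cases) else np.empty((0, len(pars) + 1), int)
        for rowvals in cols:
            counts[tuple(rowvals)] += 1.0
        denom = counts.sum(axis=-1, keepdims=True)
        if np.any(denom == 0):
            raise ValueError(f"node {n!r}: zero counts with alpha=0 leave CPT rows undefined")
        tables[n] = counts / denom
    return tables


def _soft_count_tables(net: BayesNet, exp_counts: dict[str, np.ndarray], alpha: float) -> dict[str, np.ndarray]:
    tables = {}
    for n, counts in exp_counts.items():
        c = counts + alpha
        denom = c.sum(axis=-1, keepdims=True)
        if np.any(denom == 0):
            raise ValueError(f"node {n!r}: zero expected counts with alpha=0")
        tables[n] = c / denom
    return tables


def _case_loglik_and_posterior(joint: np.ndarray, net: BayesNet, case: Mapping[str, float]):
    """P(observed part) and posterior over the missing nodes of one case."""
    order = net.order
    sl: list = [slice(None)] * len(order)
    missing = []
    for i, nname in enumerate(order):
        v = case[nname]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing.append(i)
        else:
            sl[i] = int(v)
    sub = joint[tuple(sl)]
    p_obs = float(np.sum(sub))
    return p_obs, missing, sub


def learn_cpts(
    net: BayesNet,
    cases: pd.DataFrame,
    alpha: float = 1.0,
    max_em_iters: int = 100,
    tol: float = 1e-6,
) -> CPTSet:
    """Maximum-likelihood CPTs with additive-alpha smoothing.

    Complete data: closed-form smoothed counting.  Cases with missing entries
    (NaN): EM — expected counts from posteriors over the missing nodes,
    iterated until the log-likelihood gain drops below ``tol`` or
    ``max_em_iters`` is reached.  The log-likelihood trace is attached to the
    returned CPTSet as ``em_loglik`` (non-decreasing by construction).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if len(cases) == 0 and alpha == 0:
        raise ValueError("zero cases with alpha=0: CPTs undefined")

    complete = len(cases) == 0 or not cases.isna().any().any()
    if complete:
        cpts = CPTSet(net, _count_tables(net, cases.astype(int) if len(cases) else cases, alpha))
        cpts.em_loglik = []  # type: ignore[attr-defined]
        return cpts

    # EM: initialise from complete rows (or uniform if none)
    complete_rows = cases.dropna()
    if len(complete_rows):
        tables = _count_tables(net, complete_rows.astype(int), max(alpha, 1.0))
    else:
        tables = {
            n: np.full(
                [net.card(p) for p in net.parents[n]] + [net.card(n)],
                1.0 / net.card(n),
            )
            for n in net.order
        }
    cpts = CPTSet(net, tables)

    order = net.order
    axis = {n: i for i, n in enumerate(order)}
    trace: list[float] = []
    for _ in range(max_em_iters):
        joint = cpts.joint()
        exp_counts = {
            n: np.zeros([net.card(p) for p in net.parents[n]] + [net.card(n)]) for n in order
        }
        loglik = 0.0
        for _, case in cases.iterrows():
            p_obs, missing, sub = _case_loglik_and_posterior(joint, net, case)
            if p_obs <= 0:
                loglik += -np.inf
                continue
            loglik += float(np.log(p_obs))
            post = sub / p_obs  # array over missing axes (in joint order)
            miss_names = [order[i] for i in missing]
            for n in order:
                fam = net.parents[n] + [n]
                fam_idx = []
                for f in fam:
                    if f in miss_names:
                        fam_idx.append(("m", miss_names.index(f)))
                    else:
                        fam_idx.append(("o", int(case[f])))
                # marginalise posterior onto the missing family members
                keep = [mi for kind, mi in fam_idx if kind == "m"]
                if keep:
                    post_arr = np.asarray(post)
                    drop = tuple(i for i in range(post_arr.ndim) if i not in keep)
                    marg = post_arr.sum(axis=drop) if drop else post_arr
                    # marg axes correspond to sorted(keep); family may repeat order
                    marg = np.transpose(marg, np.argsort(np.argsort(keep)))
                else:
                    marg = 1.0
                # scatter-add into expected counts
                _scatter_add(exp_counts[n], fam_idx, marg)
        trace.append(loglik)
        new_tables = _soft_count_tables(net, exp_counts, alpha)
        new_cpts = CPTSet(net, new_tables)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            cpts = new_cpts
            break
        cpts = new_cpts
    cpts.em_loglik = trace  # type: ignore[attr-defined]
    return cpts


def _scatter_add(target: np.ndarray, fam_idx, marg) -> None:
    """Add a (possibly scalar) posterior block into the indexed slice of target."""
    sl = []
    for kind, v in fam_idx:
        sl.append(slice(None) if kind == "m" else v)
    target[tuple(sl)] += marg


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def infer(
    net: BayesNet,
    cpts: CPTSet,
    evidence: Mapping[str, int | str],
    query: str,
) -> np.ndarray:
    """Exact posterior over ``query`` given ``evidence`` (state index or name)."""
    joint = cpts.joint()
    order = net.order
    sl: list = [slice(None)] * len(order)
    for name, state in evidence.items():
        if name not in net.node_index:
            raise KeyError(f"unknown evidence node {name!r}")
        idx = state if isinstance(state, (int, np.integer)) else net.spec(name).states.index(state)
        if not (0 <= idx < net.card(name)):
            raise ValueError(f"invalid state {state!r} for node {name!r}")
        sl[order.index(name)] = int(idx)
    sub = joint[tuple(sl)]
    remaining = [n for n in order if n not in evidence]
    q_axis = remaining.index(query) if query in remaining else None
    if q_axis is None:  # evidence on the query node itself -> point mass
        out = np.zeros(net.card(query))
        ev = evidence[query]
        idx = ev if isinstance(ev, (int, np.integer)) else net.spec(query).states.index(ev)
        out[int(idx)] = 1.0
        return out
    axes = tuple(i for i in range(sub.ndim) if i != q_axis)
    marg = sub.sum(axis=axes) if axes else sub
    total = marg.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    return marg / total


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def crossvalidate(
    net: BayesNet,
    cases: pd.DataFrame,
    K: int = 2,
    seed: int = 0,
    target: str = "Likelihood",
    alpha: float = 1.0,
) -> dict:
    """Stratified K-fold CV on the target node.

    Per fold: CPTs re-learned on the training cases (structure fixed), each
    test case's target predicted as the argmax posterior given all other
    nodes as evidence; ties break toward the lower state.  Returns per-fold
    accuracies, their mean, and pooled scores P(target = highest state) for
    ROC analysis (scores/predictions/labels are aligned with each other, in
    canonical case order).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if len(cases) < K:
        raise ValueError("need at least K cases")
    # canonical (content-sorted) order: identical discrete rows are
    # interchangeable, so folds become invariant to input case order
    canon = np.lexsort(tuple(cases[n].to_numpy() for n in reversed(net.order)))
    cases = cases.iloc[canon].reset_index(drop=True)
    y = cases[target].to_numpy(int)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed % (2**31))
    others = [n for n in net.order if n != target]
    fold_acc: list[float] = []
    scores = np.zeros(len(cases))
    preds = np.zeros(len(cases), dtype=int)
    hi = net.card(target) - 1
    for tr, te in skf.split(cases, y):
        train = cases.iloc[tr]
        present = set(np.unique(train[target].to_numpy(int)))
        if len(present) < net.card(target):
            warnings.warn(f"a fold is missing target state(s); alpha={alpha} smoothing covers them")
        cpts = learn_cpts(net, train, alpha=alpha)
        correct = 0
        for i in te:
            ev = {n: int(cases.iloc[i][n]) for n in others}
            post = infer(net, cpts, ev, target)
            pred = int(np.argmax(post))  # np.argmax takes the first (lower) max
            preds[i] = pred
            scores[i] = float(post[hi])
            correct += int(pred == y[i])
        fold_acc.append(correct / len(te))
    return {
        "fold_accuracy": fold_acc,
        "mean_accuracy": float(np.mean(fold_acc)),
        "scores_high": scores,
        "predictions": preds,
        "labels": y,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) from a threshold sweep and the trapezoid AUC.

    AUC equals the probability that a random positive outscores a random
    negative (ties count one half).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or (~y).all():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def influence_strength(net: BayesNet, cpts: CPTSet, edge: tuple[str, str]) -> float:
    """Arc strength of parent -> child in [0, 1].

    Maximum total-variation distance between the child's conditional
    distributions as the parent's state varies, maximised over the
    configurations of the child's other parents.
    """
    parent, child = edge
    pars = net.parents[child]
    if parent not in pars:
        raise ValueError(f"{parent!r} is not a parent of {child!r}")
    t = cpts.tables[child]
    p_axis = pars.index(parent)
    other_axes = [i for i in range(len(pars)) if i != p_axis]
    other_cards = [t.shape[i] for i in other_axes]
    best = 0.0
    for combo in itertools.product(*[range(c) for c in other_cards]) if other_cards else [()]:
        sl: list = [slice(None)] * (len(pars) + 1)
        for ax, v in zip(other_axes, combo):
            sl[ax] = v
        block = t[tuple(sl)]  # (parent states, child states)
        for i in range(block.shape[0]):
            for j in range(i + 1, block.shape[0]):
                tv = 0.5 * float(np.abs(block[i] - block[j]).sum())
                best = max(best, tv)
    return best
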