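"""Discrete Bayesian networks: scoring, hill-climbing search, CPT fitting.

Structure learning is score-based greedy hill climbing from the empty
graph: at each step the single arc addition, deletion or reversal with
the largest score improvement is applied, subject to acyclicity, until no
single-arc operation improves the score.  The default score is the BIC
for multinomial data,

    score(G) = sum_i [ log L(X_i | Pa_i) - (ln n)/2 * (r_i - 1) * q_i ],

with ``r_i`` the child cardinality and ``q_i`` the number of joint parent
configurations.  BIC is decomposable (the search only rescores the
families an operation touches) and score-equivalent (Markov-equivalent
DAGs receive identical scores), so the learned orientation within an
equivalence class is a tie-break artifact, never evidence.  A BDeu
(Bayesian Dirichlet equivalent uniform) score is available as an option.

Parameter learning is Bayesian: each conditional probability table row is
the posterior mean under a symmetric Dirichlet prior whose total weight
is spread uniformly over the family's cells.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .dataset import DiscreteDataset
from .graphs import DagStructure

__all__ = [
    "ScoreConfig",
    "Cpt",
    "BayesianNetwork",
    "family_score",
    "network_score",
    "hill_climb",
    "fit_parameters",
    "joint_probability",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Structure-learning configuration.

    score_name
        ``"bic"`` (default) or ``"bdeu"``.
    equivalent_sample_size
        Dirichlet prior weight of the BDeu score (ignored by BIC).
    improvement_epsilon
        Minimal score gain for a search step to be taken; strictly
        positive so the search terminates.
    """

    score_name: str = "bic"
    equivalent_sample_size: float = 1.0
    improvement_epsilon: float = 1e-9

    def __post_init__(self):
        if self.score_name not in ("bic", "bdeu"):
            raise ValueError(f"unknown score {self.score_name!r}")
        if self.improvement_epsilon <= 0:
            raise ValueError("improvement_epsilon must be > 0")
        if self.equivalent_sample_size <= 0:
            raise ValueError("equivalent_sample_size must be > 0")


# -- counting and local scores -------------------------------------------


def _family_counts(
    codes: np.ndarray, cards: np.ndarray, child: int, parents: tuple[int, ...]
) -> np.ndarray:
    """Contingency counts, shape ``(q, r)``: one row per parent config."""
    n = codes.shape[0]
    r = int(cards[child])
    q = 1
    idx = np.zeros(n, dtype=np.int64)
    for p in parents:
        idx = idx * cards[p] + codes[:, p]
        q *= int(cards[p])
    joint = idx * r + codes[:, child]
    return np.bincount(joint, minlength=q * r).reshape(q, r)


def _score_counts(counts: np.ndarray, n: int, cfg: ScoreConfig) -> float:
    q, r = counts.shape
    if cfg.score_name == "bic":
        rows = counts.sum(axis=1, keepdims=True)
        nz = counts > 0
        ll = float(
            (
                counts[nz]
                * (np.log(counts[nz]) - np.log(np.broadcast_to(rows, counts.shape)[nz]))
            ).sum()
        )
        penalty = 0.5 * math.log(n) * (r - 1) * q if n > 0 else 0.0
        return ll - penalty
    # BDeu marginal likelihood
    ess = cfg.equivalent_sample_size
    a_row = ess / q
    a_cell = ess / (q * r)
    rows = counts.sum(axis=1)
    return float(
        (gammaln(a_row) - gammaln(a_row + rows)).sum()
        + (gammaln(a_cell + counts) - gammaln(a_cell)).sum()
    )


def family_score(
    ds: DiscreteDataset,
    child: str,
    parents,
    cfg: ScoreConfig | None = None,
) -> float:
    """Decomposable local score of ``child`` given ``parents``.

    Deterministic in its inputs.  A child with a single declared level has
    zero free parameters; this degenerate case is scored but flagged with
    a warning.
    """
    cfg = cfg or ScoreConfig()
    parents = tuple(parents)
    if child in parents:
        raise ValueError(f"{child!r} cannot be its own parent")
    codes, card_map = ds.codes()
    names = ds.variables
    cards = np.array([card_map[v] for v in names], dtype=np.int64)
    index = {v: i for i, v in enumerate(names)}
    if card_map[child] < 2:
        warnings.warn(
            f"variable {child!r} has a single level; family score has zero "
            "free parameters",
            UserWarning,
            stacklevel=2,
        )
    counts = _family_counts(
        codes, cards, index[child], tuple(index[p] for p in parents)
    )
    return _score_counts(counts, ds.n, cfg)


def network_score(
    ds: DiscreteDataset, dag: DagStructure, cfg: ScoreConfig | None = None
) -> float:
    """Sum of family scores over all nodes (decomposability)."""
    if set(dag.nodes) != set(ds.variables):
        raise ValueError("DAG nodes do not match dataset variables")
    cfg = cfg or ScoreConfig()
    return sum(
        family_score(ds, v, sorted(dag.parents(v)), cfg) for v in ds.variables
    )


# -- hill climbing --------------------------------------------------------


class _ScoreCache:
    """Family-score memo over integer-coded data."""

    def __init__(self, codes, cards, n, cfg):
        self.codes = codes
        self.cards = cards
        self.n = n
        self.cfg = cfg
        self._memo: dict = {}

    def __call__(self, child: int, parents: frozenset) -> float:
        key = (child, parents)
        val = self._memo.get(key)
        if val is None:
            counts = _family_counts(
                self.codes, self.cards, child, tuple(sorted(parents))
            )
            val = self._memo[key] = _score_counts(counts, self.n, self.cfg)
        return val


def _has_path(start: int, goal: int, children: dict) -> bool:
    stack = [start]
    seen = set()
    while stack:
        x = stack.pop()
        if x == goal:
            return True
        if x in seen:
            continue
        seen.add(x)
        stack.extend(children[x])
    return False


def hill_climb(
    ds: DiscreteDataset, cfg: ScoreConfig | None = None
) -> DagStructure:
    """Greedy score search from the empty graph.

    At each iteration every admissible single-arc operation — additions
    first, then deletions, then reversals, each enumerated in
    lexicographic (parent, child) order — is scored, and the first
    operation attaining the largest improvement above
    ``improvement_epsilon`` is applied.  The fixed enumeration order makes
    the search fully deterministic.  The result is locally optimal: no
    single-arc operation improves its score.
    """
    cfg = cfg or ScoreConfig()
    if ds.n == 0:
        raise ValueError("cannot learn a structure from an empty dataset")
    names = ds.variables
    k = len(names)
    order = sorted(range(k), key=lambda i: names[i])
    if k <= 1:
        return DagStructure.from_arcs(names, ())

    codes, card_map = ds.codes()
    cards = np.array([card_map[v] for v in names], dtype=np.int64)
    fam = _ScoreCache(codes, cards, ds.n, cfg)

    parents: dict[int, frozenset] = {i: frozenset() for i in range(k)}
    children: dict[int, set] = {i: set() for i in range(k)}
    eps = cfg.improvement_epsilon

    while True:
        best_delta = eps
        best_op = None
        # additions
        for p in order:
            for c in order:
                if p == c or p in parents[c] or c in parents[p]:
                    continue
                if _has_path(c, p, children):
                    continue  # would create a cycle
                delta = fam(c, parents[c] | {p}) - fam(c, parents[c])
                if delta > best_delta:
                    best_delta, best_op = delta, ("add", p, c)
        # deletions
        for p in order:
            for c in order:
                if p not in parents[c]:
                    continue
                delta = fam(c, parents[c] - {p}) - fam(c, parents[c])
                if delta > best_delta:
                    best_delta, best_op = delta, ("delete", p, c)
        # reversals
        for p in order:
            for c in order:
                if p not in parents[c]:
                    continue
                children[p].discard(c)
                cyclic = _has_path(p, c, children)
                children[p].add(c)
                if cyclic:
                    continue
                delta = (
                    fam(p, parents[p] | {c})
                    - fam(p, parents[p])
                    + fam(c, parents[c] - {p})
                    - fam(c, parents[c])
                )
                if delta > best_delta:
                    best_delta, best_op = delta, ("reverse", p, c)
        if best_op is None:
            break
        op, p, c = best_op
        if op == "add":
            parents[c] |= {p}
            children[p].add(c)
        elif op == "delete":
            parents[c] -= {p}
            children[p].discard(c)
        else:
            parents[c] -= {p}
            children[p].discard(c)
            parents[p] |= {c}
            children[c].add(p)

    arcs = [
        (names[p], names[c]) for c in range(k) for p in parents[c]
    ]
    return DagStructure.from_arcs(names, arcs)


# -- parameter learning ---------------------------------------------------


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table of one node.

    ``table`` has one row per joint parent configuration (mixed-radix
    order, first parent most significant) and one column per child level;
    every row sums to 1.
    """

    child: str
    parents: tuple[str, ...]
    child_levels: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: np.ndarray

    def __post_init__(self):
        tab = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", tab)
        q = int(np.prod([len(l) for l in self.parent_levels], initial=1))
        if tab.shape != (q, len(self.child_levels)):
            raise ValueError(
                f"CPT for {self.child!r}: table shape {tab.shape} does not "
                f"match {q} parent configurations x "
                f"{len(self.child_levels)} levels"
            )
        if (tab < -1e-12).any() or (tab > 1 + 1e-12).any():
            raise ValueError(f"CPT for {self.child!r}: entries outside [0, 1]")
        if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT for {self.child!r}: rows do not sum to 1")

    def row_index(self, assignment: dict) -> int:
        idx = 0
        for p, lv in zip(self.parents, self.parent_levels):
            idx = idx * len(lv) + lv.index(assignment[p])
        return idx

    def probability(self, assignment: dict) -> float:
        row = self.row_index(assignment)
        col = self.child_levels.index(assignment[self.child])
        return float(self.table[row, col])


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG plus one CPT per node — the full factored joint distribution."""

    structure: DagStructure
    cpts: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.cpts) != set(self.structure.nodes):
            raise ValueError("CPTs do not cover the node set exactly")
        for node, cpt in self.cpts.items():
            if frozenset(cpt.parents) != self.structure.parents(node):
                raise ValueError(
                    f"CPT parents for {node!r} disagree with the structure"
                )

    def to_json(self) -> str:
        payload = {
            "nodes": sorted(self.structure.nodes),
            "arcs": sorted(map(list, self.structure.arcs)),
            "cpts": {
                node: {
                    "parents": list(cpt.parents),
                    "child_levels": list(cpt.child_levels),
                    "parent_levels": [list(l) for l in cpt.parent_levels],
                    "table": cpt.table.tolist(),
                }
                for node, cpt in sorted(self.cpts.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def fit_parameters(
    ds: DiscreteDataset,
    dag: DagStructure,
    prior_weight: float = 1.0,
) -> BayesianNetwork:
    """Posterior-mean CPTs under a symmetric Dirichlet prior.

    ``prior_weight`` is the total equivalent sample size per family,
    spread uniformly over its ``q * r`` cells, so every row — including
    rows for parent configurations never observed — is well defined
    (an unobserved configuration yields the uniform row).
    """
    if set(dag.nodes) != set(ds.variables):
        raise ValueError("DAG nodes do not match dataset variables")
    if prior_weight <= 0:
        raise ValueError("prior_weight must be > 0")
    codes, card_map = ds.codes()
    names = ds.variables
    cards = np.array([card_map[v] for v in names], dtype=np.int64)
    index = {v: i for i, v in enumerate(names)}
    cpts = {}
    for node in names:
        pars = tuple(sorted(dag.parents(node)))
        counts = _family_counts(
            codes, cards, index[node], tuple(index[p] for p in pars)
        )
        alpha = prior_weight / counts.size
        post = counts + alpha
        table = post / post.sum(axis=1, keepdims=True)
        cpts[node] = Cpt(
            child=node,
            parents=pars,
            child_levels=tuple(ds.levels[node]),
            parent_levels=tuple(tuple(ds.levels[p]) for p in pars),
            table=table,
        )
    return BayesianNetwork(structure=dag, cpts=cpts)


def joint_probability(bn: BayesianNetwork, assignment: dict) -> float:
    """Probability of one full assignment: the product of its CPT entries.

    Partial assignments are rejected; marginalisation is out of scope.
    """
    missing = set(bn.structure.nodes) - set(assignment)
    if missing:
        raise ValueError(
            f"assignment must cover every node; missing {sorted(missing)}"
        )
    prob = 1.0
    for node, cpt in bn.cpts.items():
        prob *= cpt.probability(assignment)
    return prob
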