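"""Performance measures, the logistic comparator, and the scenario grid.

The simulation study measures how well structure learning recovers the
generating missing-data structure:

* **validity** — fraction of replicates whose learned structure equals
  the generating one.  The default comparison is at the CPDAG level (the
  statistically identifiable target); skeleton and exact-DAG modes are
  available.
* **simulation consistency** — per variable pair, the fraction of
  replicates whose relation status (present/absent) matches the truth.
* **robustness** — the spread of validity across the missing rates of
  one mechanism, reported as the sample standard deviation (the sample
  variance is exposed alongside).

The comparator is the classical missing-indicator logistic regression:
regress the indicator on the fully observed variables and test the
coefficients.  Its validity counts a replicate correct when the global
likelihood-ratio test decision matches the truth (no relation under
MCAR, some relation under MAR).  A per-coefficient Wald mode — correct
when the set of significant predictors equals the truly related set —
is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bn import ScoreConfig, hill_climb
from .dataset import DiscreteDataset
from .graphs import DagStructure, Pair, cpdag, skeleton
from .simulate import (
    INDICATOR,
    ScenarioSpec,
    generate_scenario,
    true_structure_arcs,
)

__all__ = [
    "validity",
    "simulation_consistency",
    "robustness",
    "LogisticFit",
    "logistic_fit",
    "logistic_validity",
    "ContingencyTable2x2",
    "chi_square_2x2",
    "ScenarioResult",
    "PerformanceTable",
    "run_scenario",
    "run_experiment",
    "default_scenarios",
]


# -- structure-recovery measures -----------------------------------------


def _representative(dag: DagStructure, mode: str):
    if mode == "cpdag":
        return cpdag(dag)
    if mode == "skeleton":
        return skeleton(dag)
    if mode == "dag":
        return dag.arcs
    raise ValueError(f"unknown comparison mode {mode!r}")


def validity(
    learned: list[DagStructure],
    truth: DagStructure,
    mode: str = "cpdag",
) -> float:
    """Fraction of learned structures that coincide with the true one."""
    if not learned:
        raise ValueError("need at least one learned structure")
    if any(dag.nodes != truth.nodes for dag in learned):
        raise ValueError("structures are over different node sets")
    target = _representative(truth, mode)
    hits = sum(_representative(dag, mode) == target for dag in learned)
    return hits / len(learned)


def simulation_consistency(
    learned: list[DagStructure],
    pair,
    truth: DagStructure,
    directed: bool = False,
) -> float:
    """Fraction of replicates whose relation status for ``pair`` is true.

    By default the status is skeleton presence/absence; ``directed=True``
    matches the exact oriented arc instead (orientation within an
    equivalence class is a search artifact, so directed mode mainly
    probes the tie-breaking behaviour).
    """
    if not learned:
        raise ValueError("need at least one learned structure")
    if directed:
        p, c = tuple(pair)
        if p not in truth.nodes or c not in truth.nodes:
            raise ValueError(f"unknown pair {pair!r}")
        status = (p, c) in truth.arcs
        hits = sum(((p, c) in dag.arcs) == status for dag in learned)
    else:
        pr = Pair(pair)
        if not pr <= truth.nodes:
            raise ValueError(f"unknown pair {pair!r}")
        status = pr in skeleton(truth)
        hits = sum((pr in skeleton(dag)) == status for dag in learned)
    return hits / len(learned)


def robustness(validities, kind: str = "sd") -> float:
    """Spread of validity across the missing rates of one mechanism.

    ``kind="sd"`` (default) is the sample standard deviation of the
    per-rate validities; ``kind="var"`` the sample variance.
    """
    vals = np.asarray(list(validities), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 validities")
    var = float(np.var(vals, ddof=1))
    if kind == "var":
        return var
    if kind == "sd":
        return float(np.sqrt(var))
    raise ValueError(f"unknown kind {kind!r}")


# -- logistic comparator --------------------------------------------------


@dataclass(frozen=True)
class LogisticFit:
    """Missing-indicator logistic regression summary."""

    params: dict
    llf_full: float
    llf_null: float
    lr_stat: float
    lr_df: int
    lr_pvalue: float
    wald_pvalues: dict
    separation: bool = False
    dropped: tuple = ()


def _design(ds: DiscreteDataset, predictors):
    """Aggregated dummy design: one row per covariate pattern."""
    codes, cards = ds.codes()
    names = ds.variables
    index = {v: i for i, v in enumerate(names)}
    cols, colnames, dropped = [], [], []
    for var in predictors:
        levels = ds.levels[var]
        observed = np.unique(codes[:, index[var]])
        if observed.size < 2:
            dropped.append(var)
            continue
        for li in range(1, len(levels)):
            cols.append(codes[:, index[var]] == li)
            colnames.append(f"{var}[{levels[li]}]")
    return cols, colnames, dropped


def logistic_fit(
    ds: DiscreteDataset,
    indicator: str = INDICATOR,
    predictors=None,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of the indicator.

    Observations are aggregated by covariate pattern and fitted as a
    binomial GLM (iteratively reweighted least squares).  The global
    likelihood-ratio statistic is 2(l_full - l_null) against the
    intercept-only model, referred to a chi-square with one degree of
    freedom per dummy column.  Constant predictors are dropped with a
    warning; (quasi-)separation is flagged rather than fatal.
    """
    if indicator not in ds.variables:
        raise ValueError(f"unknown indicator {indicator!r}")
    if len(ds.levels[indicator]) != 2:
        raise ValueError(f"indicator {indicator!r} must be binary")
    predictors = tuple(
        predictors
        if predictors is not None
        else (v for v in ds.variables if v != indicator)
    )
    if not predictors:
        raise ValueError("need at least one predictor")
    codes, _ = ds.codes()
    y = codes[:, ds.variables.index(indicator)]

    cols, colnames, dropped = _design(ds, predictors)
    if dropped:
        warnings.warn(
            f"constant predictors dropped: {dropped}", UserWarning, stacklevel=2
        )
    if not cols:
        raise ValueError("all predictors are constant")

    # aggregate rows by covariate pattern for a fast, stable IRLS fit
    pattern = np.zeros(ds.n, dtype=np.int64)
    for col in cols:
        pattern = pattern * 2 + col
    order = np.unique(pattern)
    pos = np.searchsorted(order, pattern)
    n_pat = order.size
    successes = np.bincount(pos, weights=y, minlength=n_pat)
    totals = np.bincount(pos, minlength=n_pat).astype(float)
    first = np.full(n_pat, -1, dtype=np.int64)
    seen = np.zeros(n_pat, dtype=bool)
    for i, p in enumerate(pos):
        if not seen[p]:
            seen[p] = True
            first[p] = i
    exog = np.column_stack(
        [np.ones(n_pat)] + [col.astype(float)[first] for col in cols]
    )
    endog = np.column_stack([successes, totals - successes])

    def _fit(x):
        model = sm.GLM(endog, x, family=sm.families.Binomial())
        return model.fit(maxiter=maxiter, tol=tol)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = _fit(exog)
        null = _fit(exog[:, :1])
    separation = bool(np.abs(full.params[1:]).max(initial=0.0) > 15.0)
    if separation:
        warnings.warn(
            "possible (quasi-)separation: some coefficient estimates are "
            "extreme",
            UserWarning,
            stacklevel=2,
        )
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    df = len(colnames)
    names = ["intercept"] + colnames
    return LogisticFit(
        params=dict(zip(names, map(float, full.params))),
        llf_full=float(full.llf),
        llf_null=float(null.llf),
        lr_stat=float(lr),
        lr_df=df,
        lr_pvalue=float(stats.chi2.sf(lr, df)),
        wald_pvalues=dict(zip(names, map(float, full.pvalues))),
        separation=separation,
        dropped=tuple(dropped),
    )


def logistic_validity(
    fits: list[LogisticFit],
    truth_related,
    alpha: float = 0.05,
    rule: str = "global_lr",
) -> float:
    """Fraction of replicates where the test decision matches the truth.

    ``truth_related`` names the variables genuinely related to the
    indicator (empty under MCAR).  Under the default ``global_lr`` rule a
    replicate is correct when the global LR test at ``alpha`` rejects iff
    the truth is non-empty.  Under ``wald_exact`` the set of predictors
    with a Wald p-value below ``alpha`` must equal the related set.
    """
    if not fits:
        raise ValueError("need at least one fit")
    related = frozenset(truth_related)
    hits = 0
    for fit in fits:
        if rule == "global_lr":
            reject = fit.lr_pvalue < alpha
            hits += reject == bool(related)
        elif rule == "wald_exact":
            significant = frozenset(
                name.split("[", 1)[0]
                for name, p in fit.wald_pvalues.items()
                if name != "intercept" and p < alpha
            )
            hits += significant == related
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return hits / len(fits)


# -- contingency statistics ----------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A labelled 2x2 table of non-negative counts."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self):
        tab = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", tab)
        if tab.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (tab < 0).any():
            raise ValueError("counts must be non-negative")
        if tab.sum() == 0:
            raise ValueError("grand total must be positive")

    @classmethod
    def from_counts(cls, a, b, c, d, **kw) -> "ContingencyTable2x2":
        return cls(np.array([[a, b], [c, d]]), **kw)


def chi_square_2x2(
    table: ContingencyTable2x2, continuity: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default.

    Returns ``(statistic, p_value)`` with the p-value from the 1-df
    chi-square reference distribution.  A zero row or column marginal
    leaves the statistic undefined and raises.
    """
    tab = table.counts
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square statistic undefined")
    stat, p, _, _ = stats.chi2_contingency(tab, correction=continuity)
    return float(stat), float(p)


# -- scenario experiments -------------------------------------------------


@dataclass
class ScenarioResult:
    """Structure-recovery and comparator summary of one scenario."""

    spec: ScenarioSpec
    truth: DagStructure
    validity: float
    validity_dag: float
    logistic_validity: float | None
    pair_consistency: dict
    structures: list = field(default_factory=list, repr=False)
    lr_pvalues: list = field(default_factory=list, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "mechanism": self.spec.mechanism,
            "missing_rate": self.spec.missing_rate,
            "n": self.spec.n,
            "reps": self.spec.reps,
            "validity": self.validity,
            "validity_dag": self.validity_dag,
            "logistic_validity": self.logistic_validity,
            "pair_consistency": {
                " -- ".join(sorted(pr)): v
                for pr, v in sorted(
                    self.pair_consistency.items(), key=lambda kv: sorted(kv[0])
                )
            },
        }


@dataclass
class PerformanceTable:
    """Results of a scenario grid plus per-mechanism robustness."""

    scenarios: list

    def per_mechanism(self, mechanism: str) -> list:
        return [
            s
            for s in self.scenarios
            if s.spec.mechanism == mechanism.upper()
        ]

    def robustness(self, mechanism: str, kind: str = "sd") -> float:
        vals = [s.validity for s in self.per_mechanism(mechanism)]
        return robustness(vals, kind=kind)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scenarios:
            row = {
                "mechanism": s.spec.mechanism,
                "missing_rate": s.spec.missing_rate,
                "validity": s.validity,
                "logistic_validity": s.logistic_validity,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"scenarios": [s.to_json_dict() for s in self.scenarios]}
        robust = {}
        for mech in ("MCAR", "MAR"):
            if len(self.per_mechanism(mech)) >= 2:
                robust[mech] = {
                    "sd": self.robustness(mech, "sd"),
                    "var": self.robustness(mech, "var"),
                }
        out["robustness"] = robust
        return out


def run_scenario(
    spec: ScenarioSpec,
    cfg: ScoreConfig | None = None,
    logistic: bool = True,
    keep_structures: bool = True,
) -> ScenarioResult:
    """Generate, learn and score one scenario.

    Per replicate: draw a realization, learn the structure by hill
    climbing, and (optionally) fit the logistic comparator.  Fully
    deterministic given ``spec.seed``.
    """
    cfg = cfg or ScoreConfig()
    truth = DagStructure.from_arcs(
        ("tumor_type", "operation", "twoweeks", INDICATOR),
        true_structure_arcs(spec.mechanism),
    )
    structures = []
    lr_pvalues = []
    for j in range(spec.reps):
        ds = generate_scenario(spec, j)
        structures.append(hill_climb(ds, cfg))
        if logistic:
            fit = logistic_fit(ds, INDICATOR)
            lr_pvalues.append(fit.lr_pvalue)
    val = validity(structures, truth, mode="cpdag")
    val_dag = validity(structures, truth, mode="dag")
    log_val = None
    if logistic:
        related = () if spec.mechanism == "MCAR" else ("operation",)
        correct = [
            (p < 0.05) == bool(related) for p in lr_pvalues
        ]
        log_val = sum(correct) / len(correct)
    pairs = {
        Pair(pr): simulation_consistency(structures, pr, truth)
        for pr in combinations(sorted(truth.nodes), 2)
    }
    return ScenarioResult(
        spec=spec,
        truth=truth,
        validity=val,
        validity_dag=val_dag,
        logistic_validity=log_val,
        pair_consistency=pairs,
        structures=structures if keep_structures else [],
        lr_pvalues=lr_pvalues,
    )


def default_scenarios(
    reps: int = 1000,
    n: int = 2000,
    master_seed: int = 0,
    rates=(0.05, 0.10, 0.15, 0.20),
) -> list[ScenarioSpec]:
    """The 8-scenario grid: {MCAR, MAR} x four missing rates.

    Per-scenario seeds are derived deterministically from the master
    seed and the scenario's position in the grid.
    """
    specs = []
    for mi, mech in enumerate(("MCAR", "MAR")):
        for ri, rate in enumerate(rates):
            seed = (master_seed * 131 + mi * 17 + ri + 1) % (2**31)
            specs.append(
                ScenarioSpec(
                    mechanism=mech,
                    missing_rate=rate,
                    n=n,
                    reps=reps,
                    seed=seed,
                )
            )
    return specs


def run_experiment(
    specs,
    cfg: ScoreConfig | None = None,
    logistic: bool = True,
) -> PerformanceTable:
    """Run a scenario grid and assemble the performance table."""
    results = [
        run_scenario(spec, cfg, logistic=logistic, keep_structures=False)
        for spec in specs
    ]
    return PerformanceTable(scenarios=results)
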