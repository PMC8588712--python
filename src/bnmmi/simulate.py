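"""Synthetic clinical datasets with controlled missingness mechanisms.

The generator emulates a tumor-surgery cohort with three binary
variables linked in a chain:

    tumor_type -> operation -> twoweeks

* ``tumor_type``: 0 benign, 1 malignant; P(malignant) = 0.58.
* ``operation``: 0 no surgery, 1 surgery; P(op | benign) = 0.89,
  P(op | malignant) = 0.62.
* ``twoweeks``: 0 discharged within two weeks, 1 later;
  P(fast discharge | op) = 0.51, P(fast discharge | no op) = 0.65.

A hospital-fee variable is then subjected to missingness.  Only its
missing indicator ``missing_fee`` matters to mechanism identification,
so the latent fee values are never generated:

* MCAR: the indicator is i.i.d. Bernoulli(p), independent of everything.
* MAR: the non-operation group's missing rate ``p1`` is a fixed multiple
  (default 2.5) of the operation group's ``p2``; given the overall rate p
  the pair solves  p1 = ratio * p2  and  p1 * P(no op) + p2 * P(op) = p.

``P(no op)`` in that calibration is the theoretical marginal implied by
the generator parameters (0.2666 at the defaults), not the realised
sample fraction, so ``(p1, p2)`` are constants of the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import DiscreteDataset

__all__ = [
    "GeneratorParams",
    "ScenarioSpec",
    "DEFAULT_PARAMS",
    "generate_complete",
    "solve_mar_rates",
    "impose_mcar",
    "impose_mar",
    "generate_scenario",
    "true_structure_arcs",
    "to_raw_with_missing",
    "operation_marginal",
]

BINARY = ("0", "1")

#: Variable names of the complete generator output, in column order.
CHAIN_VARIABLES = ("tumor_type", "operation", "twoweeks")

#: Default name of the appended missing indicator.
INDICATOR = "missing_fee"


@dataclass(frozen=True)
class GeneratorParams:
    """Binomial parameters of the tumor_type -> operation -> twoweeks chain."""

    p_malignant: float = 0.58
    p_op_given_benign: float = 0.89
    p_op_given_malignant: float = 0.62
    p_fast_discharge_given_op: float = 0.51
    p_fast_discharge_given_noop: float = 0.65

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


DEFAULT_PARAMS = GeneratorParams()


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: a mechanism at one overall missing rate."""

    mechanism: str  # "MCAR" | "MAR"
    missing_rate: float
    n: int = 2000
    reps: int = 10_000
    seed: int = 0
    mar_ratio: float = 2.5
    params: GeneratorParams = DEFAULT_PARAMS

    def __post_init__(self):
        if self.mechanism.upper() not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        object.__setattr__(self, "mechanism", self.mechanism.upper())
        if not 0.0 < self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in (0, 1)")
        if self.mar_ratio < 1.0:
            raise ValueError("mar_ratio must be >= 1")
        if self.n < 1 or self.reps < 1:
            raise ValueError("n and reps must be >= 1")

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def operation_marginal(params: GeneratorParams = DEFAULT_PARAMS) -> float:
    """Theoretical P(operation = 1) under the chain parameters."""
    return (
        params.p_malignant * params.p_op_given_malignant
        + (1 - params.p_malignant) * params.p_op_given_benign
    )


def _frame(columns: dict) -> DiscreteDataset:
    frame = pd.DataFrame(
        {k: v.astype(np.int8).astype(str) for k, v in columns.items()},
        dtype=object,
    )
    return DiscreteDataset(frame, {k: BINARY for k in columns})


def generate_complete(
    params: GeneratorParams = DEFAULT_PARAMS,
    n: int = 2000,
    seed=None,
) -> DiscreteDataset:
    """Draw ``n`` i.i.d. records from the three-variable chain.

    ``seed`` may be an int, a seed sequence, or a ``numpy`` Generator.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    t = rng.random(n) < params.p_malignant
    p_op = np.where(t, params.p_op_given_malignant, params.p_op_given_benign)
    o = rng.random(n) < p_op
    p_fast = np.where(
        o, params.p_fast_discharge_given_op, params.p_fast_discharge_given_noop
    )
    w = rng.random(n) >= p_fast  # twoweeks = 1 means discharge after 2 weeks
    return _frame({"tumor_type": t, "operation": o, "twoweeks": w})


def solve_mar_rates(
    overall_rate: float, ratio: float, p_noop: float
) -> tuple[float, float]:
    """Group missing rates ``(p1, p2)`` from the overall rate.

    Solves  p1 = ratio * p2  subject to
    ``p1 * p_noop + p2 * (1 - p_noop) = overall_rate`` in closed form:
    ``p2 = overall_rate / (ratio * p_noop + 1 - p_noop)``.
    """
    if not 0.0 < overall_rate < 1.0:
        raise ValueError("overall_rate must lie in (0, 1)")
    if ratio < 1.0:
        raise ValueError("ratio must be >= 1")
    if not 0.0 < p_noop < 1.0:
        raise ValueError("p_noop must lie in (0, 1)")
    p2 = overall_rate / (ratio * p_noop + (1.0 - p_noop))
    p1 = ratio * p2
    if p1 > 1.0:
        raise ValueError(
            f"infeasible rates: non-operation missing rate p1 = {p1:.4f} > 1"
        )
    return p1, p2


def impose_mcar(
    ds: DiscreteDataset,
    rate: float,
    seed=None,
    indicator: str = INDICATOR,
) -> DiscreteDataset:
    """Append an indicator drawn i.i.d. Bernoulli(rate).

    Independent of every column, so the true missing-data structure has
    the indicator isolated.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = _as_rng(seed)
    m = rng.random(ds.n) < rate
    frame = ds.frame.copy()
    frame[indicator] = m.astype(np.int8).astype(str)
    levels = dict(ds.levels)
    levels[indicator] = BINARY
    return DiscreteDataset(frame, levels, ds.missing_marker)


def impose_mar(
    ds: DiscreteDataset,
    overall_rate: float,
    ratio: float = 2.5,
    seed=None,
    indicator: str = INDICATOR,
    p_noop: float | None = None,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> DiscreteDataset:
    """Append an indicator whose rate depends on ``operation``.

    Rows with operation = 0 miss at rate ``p1``, rows with operation = 1
    at ``p2 = p1 / ratio``; see :func:`solve_mar_rates`.  ``p_noop``
    defaults to the theoretical no-operation marginal of ``params``.
    """
    if "operation" not in ds.variables:
        raise ValueError("dataset has no 'operation' variable")
    if p_noop is None:
        p_noop = 1.0 - operation_marginal(params)
    p1, p2 = solve_mar_rates(overall_rate, ratio, p_noop)
    rng = _as_rng(seed)
    op = (ds.frame["operation"] == "1").to_numpy()
    m = rng.random(ds.n) < np.where(op, p2, p1)
    frame = ds.frame.copy()
    frame[indicator] = m.astype(np.int8).astype(str)
    levels = dict(ds.levels)
    levels[indicator] = BINARY
    return DiscreteDataset(frame, levels, ds.missing_marker)


def generate_scenario(
    spec: ScenarioSpec, realization: int = 0
) -> DiscreteDataset:
    """One realization of a scenario: chain draw plus imposed missingness.

    Each realization uses an independent, reproducible RNG stream derived
    from ``(spec.seed, realization)``, so realizations are identical
    whether generated sequentially or independently.
    """
    rng = np.random.default_rng([spec.seed, realization])
    ds = generate_complete(spec.params, spec.n, rng)
    if spec.mechanism == "MCAR":
        return impose_mcar(ds, spec.missing_rate, rng)
    return impose_mar(
        ds, spec.missing_rate, spec.mar_ratio, rng, params=spec.params
    )


def true_structure_arcs(mechanism: str) -> frozenset:
    """Generating arcs of a scenario (over the prepared variable set)."""
    arcs = {("tumor_type", "operation"), ("operation", "twoweeks")}
    if mechanism.upper() == "MAR":
        arcs.add(("operation", INDICATOR))
    elif mechanism.upper() != "MCAR":
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return frozenset(arcs)


def to_raw_with_missing(
    ds: DiscreteDataset,
    indicator: str = INDICATOR,
    value_var: str = "fee",
    observed_label: str = "recorded",
) -> DiscreteDataset:
    """Rewrite the indicator as a raw variable with actual missing cells.

    Produces the form a raw extract would take — a ``fee`` column that is
    ``observed_label`` where recorded and missing otherwise — so the full
    pipeline (preparation included) can be exercised end to end.
    """
    if indicator not in ds.variables:
        raise ValueError(f"dataset has no {indicator!r} variable")
    frame = ds.frame.drop(columns=[indicator]).copy()
    mask = (ds.frame[indicator] == "1").to_numpy()
    frame[value_var] = np.where(mask, ds.missing_marker, observed_label)
    levels = {v: ds.levels[v] for v in frame.columns if v in ds.levels}
    levels[value_var] = (observed_label,)
    return DiscreteDataset(frame, levels, ds.missing_marker)
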