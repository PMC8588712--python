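"""Credibility assessment and missing-mechanism identification.

After the missing-data structure is learned, two questions remain: is the
structure believable, and what does it say about the mechanism?

Credibility is assessed by a nonparametric bootstrap: the prepared data
are resampled with replacement N times, the structure is relearned on
each replicate, and each relation (unordered variable pair) of the
original structure must reappear in at least a threshold fraction
(default 90%) of replicate skeletons.  An expert-specified structure, if
available, is compared relation-by-relation against the same replicates.

The decision rule is then:

* structure not credible  ->  INCONCLUSIVE (identification is temporarily
  impossible; the structure cannot be trusted to characterise the
  dependence relations),
* credible, indicator isolated  ->  MCAR,
* credible, indicator connected  ->  not MCAR; MAR and MNAR cannot be
  told apart because the missing values themselves are unobserved.

Everything here operates on skeletons: arc orientation within a
Markov-equivalence class is not identifiable, so it never influences a
verdict.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .bn import ScoreConfig, hill_climb
from .dataset import DiscreteDataset, make_missing_indicator
from .graphs import DagStructure, Pair, skeleton

__all__ = [
    "Verdict",
    "CredibilityReport",
    "ExpertComparison",
    "MechanismVerdict",
    "bootstrap_replicates",
    "relation_frequencies",
    "assess_credibility",
    "compare_with_expert",
    "identify_mechanism",
    "run_identification",
]


class Verdict(str, enum.Enum):
    MCAR = "MCAR"
    NOT_MCAR_MAR_OR_MNAR = "NOT_MCAR_MAR_OR_MNAR"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class CredibilityReport:
    """Bootstrap support for the originally learned relations."""

    n_replicates: int
    threshold: float
    relation_frequency: dict
    original_relations: frozenset
    credible: bool
    failing_relations: frozenset = frozenset()

    def to_json_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "threshold": self.threshold,
            "credible": self.credible,
            "relation_frequency": {
                " -- ".join(sorted(pr)): freq
                for pr, freq in sorted(
                    self.relation_frequency.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "original_relations": sorted(
                " -- ".join(sorted(pr)) for pr in self.original_relations
            ),
            "failing_relations": sorted(
                " -- ".join(sorted(pr)) for pr in self.failing_relations
            ),
        }


@dataclass(frozen=True)
class ExpertComparison:
    """Per-pair agreement between bootstrap structures and expertise.

    ``consistency`` maps each unordered pair to the percentage (0-100) of
    replicates whose skeleton agrees with the expert structure on the
    presence/absence of that relation; inconsistency is the complement.
    """

    n_replicates: int
    consistency: dict
    inconsistency: dict

    def to_json_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "consistency_percent": {
                " -- ".join(sorted(pr)): v
                for pr, v in sorted(
                    self.consistency.items(), key=lambda kv: sorted(kv[0])
                )
            },
        }


@dataclass(frozen=True)
class MechanismVerdict:
    """The identification outcome plus its supporting evidence."""

    verdict: Verdict
    indicator: str
    incident_relations: frozenset
    credibility: CredibilityReport | None

    def to_json_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "indicator": self.indicator,
            "incident_relations": sorted(
                " -- ".join(sorted(pr)) for pr in self.incident_relations
            ),
            "credibility": (
                self.credibility.to_json_dict() if self.credibility else None
            ),
        }


def bootstrap_replicates(
    ds: DiscreteDataset,
    n_replicates: int,
    cfg: ScoreConfig | None = None,
    seed=None,
    _indices=None,
) -> list[DagStructure]:
    """Relearn the structure on ``n_replicates`` with-replacement resamples.

    Reproducible: the same seed yields the same replicate list.
    ``_indices`` (testing hook) supplies explicit row-index arrays instead
    of random resampling.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if ds.n < 2:
        raise ValueError("need at least 2 rows to bootstrap")
    cfg = cfg or ScoreConfig()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if _indices is not None:
        index_arrays = [np.asarray(ix) for ix in _indices]
        if len(index_arrays) != n_replicates:
            raise ValueError("_indices length must equal n_replicates")
    else:
        index_arrays = [
            rng.integers(0, ds.n, size=ds.n) for _ in range(n_replicates)
        ]
    return [hill_climb(ds.take(ix), cfg) for ix in index_arrays]


def relation_frequencies(replicates: list[DagStructure]) -> dict:
    """Skeleton-presence frequency of every unordered node pair.

    Covers all pairs of the common node set, including pairs that never
    occur (frequency 0).  Invariant under permutation of the replicates.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    nodes = replicates[0].nodes
    if any(rep.nodes != nodes for rep in replicates):
        raise ValueError("replicates are over different node sets")
    counts = {Pair(p): 0 for p in combinations(sorted(nodes), 2)}
    for rep in replicates:
        for pr in skeleton(rep):
            counts[pr] += 1
    n = len(replicates)
    return {pr: c / n for pr, c in counts.items()}


def assess_credibility(
    original: DagStructure,
    freqs: dict,
    threshold: float = 0.9,
    n_replicates: int | None = None,
) -> CredibilityReport:
    """Judge the original structure by bootstrap support.

    Credible iff every skeleton relation of ``original`` reappears with
    frequency >= ``threshold``.  An empty structure is vacuously credible.
    Only reproducibility of the learned relations is required; replicates
    are free to contain extra relations.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    relations = skeleton(original)
    failing = frozenset(
        pr for pr in relations if freqs.get(pr, 0.0) < threshold
    )
    return CredibilityReport(
        n_replicates=n_replicates if n_replicates is not None else 0,
        threshold=threshold,
        relation_frequency=dict(freqs),
        original_relations=relations,
        credible=not failing,
        failing_relations=failing,
    )


def compare_with_expert(
    replicates: list[DagStructure], expert: DagStructure
) -> ExpertComparison:
    """Real-study consistency of bootstrap structures with expertise.

    For each unordered pair, consistency% is the percentage of replicates
    whose skeleton agrees with the expert structure on whether the
    relation is present; inconsistency% is its complement.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if expert.nodes != replicates[0].nodes:
        raise ValueError("expert structure is over a different node set")
    freqs = relation_frequencies(replicates)
    expert_skel = skeleton(expert)
    consistency = {}
    for pr, freq in freqs.items():
        agree = freq if pr in expert_skel else 1.0 - freq
        consistency[pr] = 100.0 * agree
    inconsistency = {pr: 100.0 - v for pr, v in consistency.items()}
    return ExpertComparison(
        n_replicates=len(replicates),
        consistency=consistency,
        inconsistency=inconsistency,
    )


def identify_mechanism(
    original: DagStructure,
    indicator: str,
    report: CredibilityReport,
) -> MechanismVerdict:
    """Apply the identification rule to a learned structure.

    INCONCLUSIVE when the credibility assessment failed; otherwise MCAR
    iff no skeleton relation touches the indicator, else not-MCAR
    (MAR or MNAR — not further distinguishable).  The verdict depends
    only on the indicator's skeleton adjacencies and the credibility
    flag, never on arc orientation.
    """
    if indicator not in original.nodes:
        raise ValueError(f"indicator {indicator!r} not in the structure")
    incident = original.incident_pairs(indicator)
    if not report.credible:
        verdict = Verdict.INCONCLUSIVE
    elif incident:
        verdict = Verdict.NOT_MCAR_MAR_OR_MNAR
    else:
        verdict = Verdict.MCAR
    return MechanismVerdict(
        verdict=verdict,
        indicator=indicator,
        incident_relations=incident,
        credibility=report,
    )


@dataclass(frozen=True)
class IdentificationResult:
    """Everything the end-to-end pipeline produced."""

    prepared: DiscreteDataset
    indicator: str
    structure: DagStructure
    replicates: list
    report: CredibilityReport
    verdict: MechanismVerdict
    expert_comparison: ExpertComparison | None = None


def run_identification(
    ds: DiscreteDataset,
    source_variable: str | None = None,
    *,
    n_bootstrap: int = 10_000,
    threshold: float = 0.9,
    cfg: ScoreConfig | None = None,
    seed=None,
    expert: DagStructure | None = None,
    indicator_name: str | None = None,
) -> IdentificationResult:
    """The full pipeline: prepare, learn, bootstrap, identify.

    ``ds`` is the raw dataset with (at most) one incompletely observed
    variable; ``source_variable`` defaults to the variable that actually
    has missing cells.  A dataset with no missing cells at all is handled
    degenerately: a warning is issued and an all-zero indicator is
    analysed, which yields an MCAR verdict with empty evidence.
    """
    cfg = cfg or ScoreConfig()
    missing_vars = ds.variables_with_missing()
    if source_variable is None:
        if len(missing_vars) == 1:
            source_variable = missing_vars[0]
        elif not missing_vars:
            warnings.warn(
                "dataset has no missing cells; mechanism identification is "
                "degenerate (trivially MCAR)",
                UserWarning,
                stacklevel=2,
            )
            source_variable = ds.variables[-1]
        # >1 missing variables: fall through, make_missing_indicator raises
        else:
            source_variable = missing_vars[0]
    prepared, spec = make_missing_indicator(
        ds, source_variable, indicator_name=indicator_name
    )
    indicator = spec.indicator_variable
    structure = hill_climb(prepared, cfg)
    replicates = bootstrap_replicates(prepared, n_bootstrap, cfg, seed=seed)
    freqs = relation_frequencies(replicates)
    report = assess_credibility(
        structure, freqs, threshold=threshold, n_replicates=n_bootstrap
    )
    verdict = identify_mechanism(structure, indicator, report)
    comparison = (
        compare_with_expert(replicates, expert) if expert is not None else None
    )
    return IdentificationResult(
        prepared=prepared,
        indicator=indicator,
        structure=structure,
        replicates=replicates,
        report=report,
        verdict=verdict,
        expert_comparison=comparison,
    )
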