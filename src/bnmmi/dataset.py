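"""Categorical datasets and missing-indicator preparation.

The unit of data every stage of the pipeline consumes is a
:class:`DiscreteDataset`: a rectangular table of named categorical
variables with explicit per-variable level sets and a reserved token
marking missing cells.  Preparation for mechanism identification replaces
the one incompletely observed variable by its dichotomous missing
indicator (0 = observed, 1 = missing), yielding a complete dataset on
which network structure learning operates.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiscreteDataset",
    "MissingIndicatorSpec",
    "ParseError",
    "MultivariateMissingError",
    "DegenerateIndicatorWarning",
    "read_table",
    "write_table",
    "make_missing_indicator",
]

#: Tokens mapped to the missing marker when reading delimited text.
DEFAULT_MISSING_TOKENS = ("NA", "")


class ParseError(ValueError):
    """Raised for malformed delimited input (ragged rows, empty file)."""


class MultivariateMissingError(ValueError):
    """Raised when more than one variable contains missing cells.

    Only univariate missingness is supported: the missing-indicator
    construction and the downstream mechanism-identification rule are
    defined for exactly one incompletely observed variable.
    """


class DegenerateIndicatorWarning(UserWarning):
    """Issued when an indicator is requested for a fully observed variable."""


@dataclass(frozen=True)
class MissingIndicatorSpec:
    """Record of a missing-indicator replacement.

    The coding is fixed: indicator = 0 where the source variable was
    observed, 1 where it was absent.
    """

    source_variable: str
    indicator_variable: str
    coding: tuple[int, int] = (0, 1)


@dataclass
class DiscreteDataset:
    """Named categorical variables with level sets and a missing marker.

    Parameters
    ----------
    frame
        ``(n, k)`` table of string labels; missing cells hold
        ``missing_marker``.
    levels
        Mapping of variable name to its ordered tuple of category labels.
        Omitted variables get data-driven levels: the sorted distinct
        observed labels.
    missing_marker
        Reserved token for missing cells; must not collide with any level.
    """

    frame: pd.DataFrame
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    missing_marker: str = "?"

    def __post_init__(self) -> None:
        self.frame = self.frame.astype(object)
        inferred: dict[str, tuple[str, ...]] = {}
        for var in self.frame.columns:
            col = self.frame[var]
            declared = self.levels.get(var)
            if declared is None:
                observed = sorted(set(col) - {self.missing_marker})
                inferred[var] = tuple(observed)
            else:
                declared = tuple(str(v) for v in declared)
                if self.missing_marker in declared:
                    raise ValueError(
                        f"missing marker {self.missing_marker!r} collides with "
                        f"a declared level of {var!r}"
                    )
                bad = set(col) - set(declared) - {self.missing_marker}
                if bad:
                    raise ValueError(
                        f"variable {var!r} contains labels outside its "
                        f"declared levels: {sorted(bad)}"
                    )
                inferred[var] = declared
        self.levels = inferred

    # -- basic accessors -------------------------------------------------

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    def cardinality(self, var: str) -> int:
        return len(self.levels[var])

    def missing_mask(self, var: str) -> np.ndarray:
        return (self.frame[var] == self.missing_marker).to_numpy()

    def variables_with_missing(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if self.missing_mask(v).any())

    @property
    def is_complete(self) -> bool:
        return not self.variables_with_missing()

    # -- fast-path integer view ------------------------------------------

    def codes(self) -> tuple[np.ndarray, dict[str, int]]:
        """Integer-coded view ``(n, k)`` plus per-variable cardinalities.

        Level labels are mapped to their position in the declared level
        order.  Only defined for complete datasets.
        """
        missing = self.variables_with_missing()
        if missing:
            raise ValueError(
                f"dataset is not complete: missing cells in {list(missing)}"
            )
        cols = []
        for var in self.variables:
            cat = pd.Categorical(self.frame[var], categories=self.levels[var])
            cols.append(np.asarray(cat.codes, dtype=np.int64))
        codes = (
            np.column_stack(cols)
            if cols
            else np.empty((self.n, 0), dtype=np.int64)
        )
        cards = {v: self.cardinality(v) for v in self.variables}
        return codes, cards

    def equals(self, other: "DiscreteDataset") -> bool:
        return (
            self.variables == other.variables
            and self.levels == other.levels
            and self.frame.reset_index(drop=True).equals(
                other.frame.reset_index(drop=True)
            )
        )

    def take(self, indices: np.ndarray) -> "DiscreteDataset":
        """Row subset / resample (used by the bootstrap)."""
        sub = self.frame.iloc[np.asarray(indices)].reset_index(drop=True)
        return DiscreteDataset(sub, dict(self.levels), self.missing_marker)


# -- delimited text I/O ---------------------------------------------------


def read_table(
    path,
    *,
    delimiter: str = ",",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    declared_levels: dict[str, tuple[str, ...]] | None = None,
    missing_marker: str = "?",
) -> DiscreteDataset:
    """Read a delimited text file with header into a :class:`DiscreteDataset`.

    Any cell equal to one of ``missing_tokens`` is mapped to the missing
    marker.  Ragged rows raise :class:`ParseError` naming the offending
    line number (1-based, header = line 1).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = list(reader)
    if not rows:
        raise ParseError(f"{path}: empty file (no header row)")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        raise ParseError(f"{path}: duplicate column names in header")
    records = []
    tokens = set(missing_tokens)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, "
                f"expected {len(header)}"
            )
        records.append(
            [missing_marker if cell in tokens else cell for cell in row]
        )
    frame = pd.DataFrame(records, columns=header, dtype=object)
    return DiscreteDataset(
        frame, dict(declared_levels or {}), missing_marker=missing_marker
    )


def write_table(
    ds: DiscreteDataset,
    path,
    *,
    delimiter: str = ",",
    missing_token: str = "NA",
) -> None:
    """Write a dataset as delimited text; missing cells get ``missing_token``.

    ``read_table(write_table(ds))`` with matching dialect reproduces the
    dataset (up to declared-but-unobserved levels, which delimited text
    cannot carry).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(ds.variables)
        for _, row in ds.frame.iterrows():
            writer.writerow(
                [
                    missing_token if cell == ds.missing_marker else cell
                    for cell in row
                ]
            )


# -- preparation ----------------------------------------------------------


def make_missing_indicator(
    ds: DiscreteDataset,
    var: str,
    *,
    indicator_name: str | None = None,
) -> tuple[DiscreteDataset, MissingIndicatorSpec]:
    """Replace ``var`` by its dichotomous missing indicator.

    The returned dataset drops ``var`` and appends an indicator variable
    (levels ``"0"``/``"1"``) equal to 1 exactly where ``var`` was missing;
    it is complete by construction.  No rows are dropped: the method
    analyses the full updated dataset, not the complete cases.

    Raises
    ------
    MultivariateMissingError
        If any *other* variable also contains missing cells.
    """
    if var not in ds.variables:
        raise KeyError(f"unknown variable {var!r}")
    others = [v for v in ds.variables_with_missing() if v != var]
    if others:
        raise MultivariateMissingError(
            f"variables {others} also contain missing cells; only "
            "univariate missingness is supported"
        )
    name = indicator_name or f"{var}_missing"
    if name in ds.variables:
        raise ValueError(f"indicator name {name!r} already present")
    mask = ds.missing_mask(var)
    if not mask.any():
        warnings.warn(
            f"variable {var!r} has no missing cells; indicator is "
            "identically zero",
            DegenerateIndicatorWarning,
            stacklevel=2,
        )
    frame = ds.frame.drop(columns=[var]).copy()
    frame[name] = np.where(mask, "1", "0")
    levels = {v: ds.levels[v] for v in frame.columns if v in ds.levels}
    levels[name] = ("0", "1")
    out = DiscreteDataset(frame, levels, ds.missing_marker)
    return out, MissingIndicatorSpec(source_variable=var, indicator_variable=name)
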