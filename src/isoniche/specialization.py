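"""Individual specialization indices from serial isotope series.

The isotopic niche of a sampled population decomposes into the width of
each individual's own diet series and the spread between individuals
(Roughgarden-style within/between decomposition):

* INW_i  — individual niche width: variance of individual *i*'s delta
  values along its whisker (‰²);
* BINW   — between-individual niche width: variance of the per-individual
  mean delta values across the population (‰²), computed once for the
  whole sampled population;
* TNW    — total niche width, mean(INW) + BINW;
* SI_i   — specialization index, INW_i / (INW_i + BINW) ∈ [0, 1].

An individual restricted to a narrow slice of the population niche has a
small SI. The conventional classification is specialist (SI < 0.2),
generalist (SI > 0.5), intermediate otherwise (boundary values fall in the
intermediate class). Indices are computed per element: NSI from δ15N
(trophic level) and CSI from δ13C (feeding area), never pooled.

The ``between-means`` dialect above is the default because it makes the
TNW decomposition exact; a ``total-variance`` dialect (variance of all
pooled segment values) is retained for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    InsufficientDataError,
    UndefinedIndexError,
)

CLASS_LABELS = ("specialist", "intermediate", "generalist")

#: Response name per element column, the field's usual shorthand.
INDEX_NAMES = {"d15N": "NSI", "d13C": "CSI"}


def individual_niche_width(series: Sequence[float], ddof: int = 1) -> float:
    """Variance (‰²) of one individual's delta values along its whisker."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"individual niche width needs >= 2 values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise DomainError("non-finite delta value in series")
    return float(np.var(arr, ddof=ddof))


def between_individual_niche_width(
    all_series: Mapping[str, Sequence[float]],
    dialect: str = "between-means",
    ddof: int = 1,
) -> float:
    """Between-individual niche width (‰²) for the whole sampled population.

    ``between-means`` (default): variance of per-individual mean values.
    ``total-variance``: variance of all pooled segment values.
    """
    if len(all_series) < 2:
        raise InsufficientDataError(
            "between-individual niche width needs >= 2 individuals"
        )
    if dialect == "between-means":
        means = np.array([np.mean(np.asarray(v, dtype=float))
                          for v in all_series.values()])
        return float(np.var(means, ddof=ddof))
    if dialect == "total-variance":
        pooled = np.concatenate(
            [np.asarray(v, dtype=float) for v in all_series.values()]
        )
        return float(np.var(pooled, ddof=ddof))
    raise DomainError(f"unknown BINW dialect {dialect!r}")


def specialization_index(inw: float, binw: float) -> float:
    """SI = INW / (INW + BINW), in [0, 1]."""
    if inw < 0 or binw < 0:
        raise DomainError("niche widths must be non-negative")
    total = inw + binw
    if total == 0:
        raise UndefinedIndexError("INW + BINW = 0; index undefined")
    return inw / total


def classify(si: float,
             thresholds: tuple[float, float] = (0.2, 0.5)) -> str:
    """Three-way class: specialist (SI < lo), generalist (SI > hi),
    intermediate otherwise; boundary values are intermediate."""
    lo, hi = thresholds
    if not 0.0 <= si <= 1.0:
        raise DomainError(f"SI {si} outside [0, 1]")
    if si < lo:
        return "specialist"
    if si > hi:
        return "generalist"
    return "intermediate"


def population_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per class per element.

    ``results`` must have columns ``element``, ``class`` with one row per
    (individual, element). Proportions are count/total per element,
    rounded for display at 0.1%.
    """
    if results.empty:
        raise InsufficientDataError("no specialization results to summarize")
    rows = []
    for element, grp in results.groupby("element", sort=True):
        total = len(grp)
        counts = grp["class"].value_counts()
        for label in CLASS_LABELS:
            n = int(counts.get(label, 0))
            rows.append(
                {
                    "element": element,
                    "class": label,
                    "n": n,
                    "proportion": n / total,
                    "percent": round(100.0 * n / total, 1),
                }
            )
    return pd.DataFrame(rows)


class SpecializationModel:
    """Niche-width decomposition and specialization indices for a sampled
    population, one index per element.

    Parameters
    ----------
    data
        Tidy per-segment table with one row per (individual, segment):
        an id column and one delta column per element.
    id_col, element_cols
        Column names; by default ``individual_id`` and both of
        ``d15N``/``d13C`` (whichever are present).
    dialect
        BINW dialect, ``between-means`` (default) or ``total-variance``.
    ddof
        Variance divisor correction (1 → divisor n−1, the default; 0 →
        divisor n). With only a few segments per whisker this choice is
        material.
    thresholds
        (specialist, generalist) SI cut points.

    Examples
    --------
    >>> model = SpecializationModel.from_dataframe(segments)
    >>> res = model.fit()
    >>> res.per_individual.head()
    >>> res.population_summary()
    """

    def __init__(
        self,
        data: pd.DataFrame,
        id_col: str = "individual_id",
        element_cols: Sequence[str] | None = None,
        dialect: str = "between-means",
        ddof: int = 1,
        thresholds: tuple[float, float] = (0.2, 0.5),
    ) -> None:
        if element_cols is None:
            element_cols = [c for c in ("d15N", "d13C") if c in data.columns]
        if not element_cols:
            raise DomainError("no element columns found in data")
        missing = [c for c in (id_col, *element_cols)
                   if c not in data.columns]
        if missing:
            raise DomainError(f"missing column(s): {', '.join(missing)}")
        if dialect not in ("between-means", "total-variance"):
            raise DomainError(f"unknown BINW dialect {dialect!r}")
        self.data = data
        self.id_col = id_col
        self.element_cols = list(element_cols)
        self.dialect = dialect
        self.ddof = ddof
        self.thresholds = thresholds

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs):
        return cls(data, **kwargs)

    def fit(self) -> "SpecializationResults":
        rows = []
        decompositions = {}
        for col in self.element_cols:
            series = {
                str(ind): grp[col].to_numpy(dtype=float)
                for ind, grp in self.data.groupby(self.id_col, sort=True)
            }
            binw = between_individual_niche_width(
                series, dialect=self.dialect, ddof=self.ddof
            )
            inws = {}
            for ind, vals in series.items():
                inws[ind] = individual_niche_width(vals, ddof=self.ddof)
            tnw = float(np.mean(list(inws.values()))) + binw
            decompositions[col] = NicheDecomposition(
                element=col, INW=dict(inws), BINW=binw, TNW=tnw,
                dialect=self.dialect,
            )
            for ind, vals in series.items():
                si = specialization_index(inws[ind], binw)
                rows.append(
                    {
                        "individual_id": ind,
                        "element": col,
                        "index": INDEX_NAMES.get(col, f"SI[{col}]"),
                        "n_segments": len(vals),
                        "INW": inws[ind],
                        "BINW": binw,
                        "TNW": tnw,
                        "SI": si,
                        "class": classify(si, self.thresholds),
                    }
                )
        per_individual = pd.DataFrame(rows)
        return SpecializationResults(self, per_individual, decompositions)


@dataclass(frozen=True)
class NicheDecomposition:
    """INW per individual, BINW and TNW for one element (all ‰²)."""

    element: str
    INW: dict[str, float]
    BINW: float
    TNW: float
    dialect: str


class SpecializationResults:
    """Fitted niche decomposition: per-individual indices and classes."""

    def __init__(self, model: SpecializationModel,
                 per_individual: pd.DataFrame,
                 decompositions: dict[str, NicheDecomposition]) -> None:
        self.model = model
        self.per_individual = per_individual
        self.decompositions = decompositions

    def population_summary(self) -> pd.DataFrame:
        return population_summary(self.per_individual)

    def pivot(self, value: str = "SI") -> pd.DataFrame:
        """Wide table: one row per individual, one column per index."""
        return self.per_individual.pivot(
            index="individual_id", columns="index", values=value
        )

    def summary(self) -> str:
        lines = ["Specialization index decomposition",
                 f"  dialect: {self.model.dialect}  "
                 f"variance ddof: {self.model.ddof}  "
                 f"thresholds: <{self.model.thresholds[0]} specialist, "
                 f">{self.model.thresholds[1]} generalist"]
        for col, dec in self.decompositions.items():
            name = INDEX_NAMES.get(col, col)
            sub = self.per_individual[self.per_individual["element"] == col]
            lines.append(
                f"  {name} ({col}): n={sub['individual_id'].nunique()}  "
                f"BINW={dec.BINW:.3f}  TNW={dec.TNW:.3f}  "
                f"median SI={sub['SI'].median():.3f}"
            )
            summ = population_summary(sub)
            for _, r in summ.iterrows():
                lines.append(
                    f"    {r['class']:>12}: n={r['n']:>3}  "
                    f"{r['percent']:5.1f}%"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<SpecializationResults: "
                f"{self.per_individual['individual_id'].nunique()} "
                f"individuals, elements={self.model.element_cols}>")
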