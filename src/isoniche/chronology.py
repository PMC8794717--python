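"""Whisker growth chronology and segment planning.

A vibrissa archives assimilated diet sequentially: material at the base is
the newest, material toward the tip the oldest. Growth follows a von
Bertalanffy curve

    L(t) = L_inf * (1 - exp(-k * (t - t0)))

either evaluated continuously or stepped daily,
``L_{d+1} = L_d + (L_inf - L_d) * (1 - exp(-k))``, whose closed form
coincides with the continuous curve at integer days. Inverting the curve
dates any position along the whisker relative to the collection date, and
a mass-density profile converts a target segment mass (tin-capsule
analytical window, typically 0.2-0.5 mg) into cut lengths. Plans alternate
isotope segments with fixed-duration buffer cuts that restore independence
between consecutive samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal, Sequence

import numpy as np

from .exceptions import DomainError, InfeasiblePlanError, StateError

Mode = Literal["continuous", "daily-discrete"]


@dataclass(frozen=True)
class GrowthModel:
    """Von Bertalanffy whisker growth: asymptote ``L_inf`` (mm), rate ``k``
    (per day), nominal zero-length age ``t0`` (days)."""

    L_inf: float
    k: float
    t0: float = 0.0
    mode: Mode = "continuous"

    def __post_init__(self) -> None:
        if not self.L_inf > 0:
            raise DomainError("L_inf must be positive")
        if not self.k > 0:
            raise DomainError("k must be positive")
        if self.mode not in ("continuous", "daily-discrete"):
            raise DomainError(f"unknown mode {self.mode!r}")


def length_at_age(t: float, model: GrowthModel) -> float:
    """Whisker length (mm) at age ``t`` days.

    In daily-discrete mode ``t`` must be a non-negative integer day count
    from ``t0``; the daily recursion telescopes to the continuous curve
    evaluated at integer days.
    """
    if model.mode == "daily-discrete":
        if t < model.t0 or not float(t - model.t0).is_integer():
            raise DomainError(
                "daily-discrete mode requires an integer day >= t0"
            )
    elif t < model.t0:
        raise DomainError(f"age {t} precedes t0={model.t0}")
    return model.L_inf * (1.0 - math.exp(-model.k * (t - model.t0)))


def age_at_length(l: float, model: GrowthModel) -> float:
    """Age (days) at which the whisker reached length ``l`` mm.

    Continuous mode inverts the growth curve exactly; daily-discrete mode
    returns the smallest integer day on which length >= ``l``.
    """
    if l < 0 or l >= model.L_inf:
        raise DomainError(
            f"length {l} outside [0, L_inf={model.L_inf}) domain"
        )
    t = model.t0 - math.log(1.0 - l / model.L_inf) / model.k
    if model.mode == "daily-discrete":
        d = math.ceil(t - model.t0 - 1e-12)
        return model.t0 + max(d, 0)
    return t


@dataclass(frozen=True)
class WhiskerRecord:
    """Observed whisker geometry for one individual.

    ``observed_length`` is the cut length measured to the nearest 0.5 mm;
    the intradermal portion (position-dependent, supplied by config) is
    added to give the estimated total grown length.
    """

    individual_id: str
    observed_length: float
    intradermal_length: float
    collection_date: date
    position_label: str = "A"

    def __post_init__(self) -> None:
        if not self.observed_length > 0 or self.intradermal_length < 0:
            raise DomainError("whisker lengths must be positive")

    @property
    def estimated_total_length(self) -> float:
        return self.observed_length + self.intradermal_length


def _age_below_base(d_from_base: float, whisker: WhiskerRecord,
                    model: GrowthModel) -> float:
    """Days before collection at which material ``d_from_base`` mm below
    the base lay at the growing tip."""
    total = whisker.estimated_total_length
    if total >= model.L_inf:
        raise DomainError(
            f"estimated total length {total} mm is not below "
            f"L_inf={model.L_inf} mm"
        )
    if d_from_base < 0 or d_from_base > total:
        raise DomainError(
            f"position {d_from_base} mm outside [0, {total}] mm"
        )
    return age_at_length(total, model) - age_at_length(total - d_from_base,
                                                       model)


def date_of_position(d_from_base: float, whisker: WhiskerRecord,
                     model: GrowthModel) -> date:
    """Deposition date of material ``d_from_base`` mm from the whisker base.

    The base holds material deposited on the collection date; deeper
    positions are older. Sub-day remainders are truncated toward the
    collection date (whole-day dates, deterministic tie-break).
    """
    days_back = _age_below_base(d_from_base, whisker, model)
    return whisker.collection_date - timedelta(days=int(days_back + 1e-9))


@dataclass(frozen=True)
class DensityModel:
    """Linear mass density of a whisker, used to turn segment masses into
    cut lengths.

    ``uniform``: constant density, either given directly (``linear_density``
    mg/mm) or derived as total mass / length. ``linear-taper``: density
    varies linearly from base to tip with base:tip ratio ``taper_ratio``,
    scaled to the same mean density.
    """

    profile: Literal["uniform", "linear-taper"] = "uniform"
    linear_density: float | None = 0.30  # mg/mm
    total_mass_mg: float | None = None
    taper_ratio: float = 1.0

    def _mean_density(self, whisker_length: float) -> float:
        if self.total_mass_mg is not None:
            return self.total_mass_mg / whisker_length
        if self.linear_density is None:
            raise DomainError("density model needs linear_density or "
                              "total_mass_mg")
        return self.linear_density

    def _endpoints(self, whisker_length: float) -> tuple[float, float]:
        mean = self._mean_density(whisker_length)
        if self.profile == "uniform":
            return mean, mean
        r = self.taper_ratio
        if r <= 0:
            raise DomainError("taper_ratio must be positive")
        base = 2.0 * mean * r / (1.0 + r)
        tip = 2.0 * mean / (1.0 + r)
        return base, tip

    def mass_between(self, a: float, b: float, whisker_length: float) -> float:
        """Mass (mg) of the cut between ``a`` and ``b`` mm from the base."""
        if not 0 <= a <= b <= whisker_length:
            raise DomainError("cut outside whisker")
        rho_b, rho_t = self._endpoints(whisker_length)
        slope = (rho_t - rho_b) / whisker_length
        return rho_b * (b - a) + slope * (b * b - a * a) / 2.0

    def length_for_mass(self, mass: float, start: float,
                        whisker_length: float) -> float:
        """Length of a cut starting at ``start`` mm from the base that
        contains ``mass`` mg."""
        if mass <= 0:
            raise DomainError("mass must be positive")
        rho_b, rho_t = self._endpoints(whisker_length)
        slope = (rho_t - rho_b) / whisker_length
        rho_s = rho_b + slope * start
        if abs(slope) < 1e-12:
            length = mass / rho_s
        else:
            # solve rho_s*x + slope*x^2/2 = mass for x > 0
            disc = rho_s * rho_s + 2.0 * slope * mass
            if disc < 0:
                raise InfeasiblePlanError("density profile cannot supply "
                                          "the requested mass")
            length = (-rho_s + math.sqrt(disc)) / slope
        if start + length > whisker_length + 1e-9:
            raise InfeasiblePlanError(
                f"cut of {length:.2f} mm from {start:.2f} mm exceeds whisker"
            )
        return length


@dataclass(frozen=True)
class Segment:
    """One planned cut. ``start_mm`` is nearer the base (newer material);
    ``start_date <= end_date`` is the chronological deposition window."""

    role: Literal["isotope", "buffer"]
    start_mm: float
    end_mm: float
    est_mass_mg: float
    start_date: date
    end_date: date
    duration_days: float


@dataclass
class SegmentPlan:
    """Ordered, contiguous cuts from the base toward the tip."""

    whisker: WhiskerRecord
    segments: list[Segment] = field(default_factory=list)

    @property
    def isotope_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "isotope"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "individual_id": self.whisker.individual_id,
                    "role": s.role,
                    "start_mm": s.start_mm,
                    "end_mm": s.end_mm,
                    "est_mass_mg": s.est_mass_mg,
                    "start_date": s.start_date,
                    "end_date": s.end_date,
                    "duration_days": s.duration_days,
                }
                for s in self.segments
            ]
        )


def plan_segments(
    whisker: WhiskerRecord,
    model: GrowthModel,
    density: DensityModel,
    n_isotope: int = 3,
    mass_window: tuple[float, float] = (0.2, 0.5),
    buffer_days_target: float = 11.3,
    target_mass: float | None = None,
) -> SegmentPlan:
    """Plan ``n_isotope`` isotope segments separated by fixed-duration
    buffer cuts, working greedily from the base toward the tip.

    Each isotope segment is cut to the mass target (default: midpoint of
    ``mass_window``); each buffer spans ``buffer_days_target`` days of
    growth, so its physical length shrinks toward the base of older
    (slower-growing) whiskers.
    """
    if n_isotope < 1:
        raise DomainError("n_isotope must be >= 1")
    lo, hi = mass_window
    if not 0 < lo < hi:
        raise DomainError("invalid mass window")
    if target_mass is None:
        target_mass = (lo + hi) / 2.0
    if not lo <= target_mass <= hi:
        raise DomainError("target mass outside mass window")

    total = whisker.estimated_total_length
    plan = SegmentPlan(whisker)
    pos = 0.0

    def _dated(role: str, a: float, b: float, mass: float) -> Segment:
        dur = (_age_below_base(b, whisker, model)
               - _age_below_base(a, whisker, model))
        return Segment(
            role=role,
            start_mm=a,
            end_mm=b,
            est_mass_mg=mass,
            start_date=date_of_position(b, whisker, model),
            end_date=date_of_position(a, whisker, model),
            duration_days=dur,
        )

    for i in range(n_isotope):
        try:
            seg_len = density.length_for_mass(target_mass, pos, total)
        except InfeasiblePlanError as exc:
            raise InfeasiblePlanError(
                f"whisker {whisker.individual_id}: too short for isotope "
                f"segment {i + 1} of {n_isotope} ({exc})"
            ) from exc
        end = pos + seg_len
        mass = density.mass_between(pos, end, total)
        if not lo - 1e-9 <= mass <= hi + 1e-9:
            raise InfeasiblePlanError(
                f"segment mass {mass:.3f} mg outside window [{lo}, {hi}]"
            )
        plan.segments.append(_dated("isotope", pos, end, mass))
        pos = end
        if i < n_isotope - 1:
            # buffer: fixed duration of growth, variable length
            age_here = _age_below_base(pos, whisker, model)
            target_len_remaining = total - pos
            older_age = (age_at_length(total, model) - age_here
                         - buffer_days_target)
            if older_age <= model.t0:
                raise InfeasiblePlanError(
                    f"whisker {whisker.individual_id}: too short for buffer "
                    f"{i + 1} ({buffer_days_target} days of growth predate "
                    "the whisker)"
                )
            older_len = length_at_age(older_age, model)
            buf_end = total - older_len
            if buf_end > total or buf_end <= pos:
                raise InfeasiblePlanError(
                    f"whisker {whisker.individual_id}: buffer {i + 1} "
                    f"infeasible (needs {buf_end - pos:.2f} mm of "
                    f"{target_len_remaining:.2f} mm remaining)"
                )
            mass = density.mass_between(pos, buf_end, total)
            plan.segments.append(_dated("buffer", pos, buf_end, mass))
            pos = buf_end
    if pos > total + 1e-9:
        raise InfeasiblePlanError(
            f"plan needs {pos:.2f} mm but whisker has {total:.2f} mm "
            f"(shortfall {pos - total:.2f} mm)"
        )
    return plan


def segment_durations(plan: SegmentPlan) -> np.ndarray:
    """Days of growth represented by each isotope segment, base outward."""
    segs = plan.isotope_segments
    if not segs:
        raise StateError("plan has no isotope segments")
    if any(s.start_date is None or s.end_date is None for s in segs):
        raise StateError("plan is undated")
    return np.array([s.duration_days for s in segs])
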