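"""Synthetic populations with known niche-variance structure.

The generator emulates the structure of a whisker-isotope specialization
study — ~71 individuals, three analyzed segments per whisker, covariates
(sex, age class, mass, site, competition level) — with a fully known
truth model so every pipeline stage can be validated:

* individual mean delta values μ_i ~ Normal(population mean, σ_B²);
* a true specialization index per individual linked to covariates on the
  logit scale (plus unexplained individual variation, so covariates
  explain only part of the spread, as in real data);
* within-individual variance σ²_W,i = σ_B² · SI_i / (1 − SI_i), so the
  asymptotic index σ²_W,i/(σ²_W,i + σ_B²) equals the configured truth;
* segment values x_ij ~ Normal(μ_i, σ_W,i) plus independent additive
  analytical noise.

Truth tables never leak into the pipeline-facing covariate/segment
tables. All generation is seeded; unseeded generation is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, JoinError
from .specialization import SpecializationModel

_ELEMENTS = ("N", "C")


@dataclass(frozen=True)
class GeneratorConfig:
    """Simulation parameters; defaults emulate the study conditions of a
    71-devil, 3-segment winter sampling campaign.

    ``si_link_*`` are (intercept, per-kg mass slope, lowered-competition
    offset) on the logit scale; ``si_logit_sd_*`` adds individual logit
    noise so covariates explain only part of the true-SI variation.
    """

    n_individuals: int = 71
    n_segments: int = 3
    mean_d15N: float = 7.4  # ‰
    mean_d13C: float = -22.5  # ‰
    sigma_B_N: float = 1.3  # ‰ between-individual sd of means
    sigma_B_C: float = 2.8  # ‰
    si_link_N: tuple[float, float, float] = (1.2, -0.25, -0.5)
    si_link_C: tuple[float, float, float] = (-2.0, 0.0, 0.0)
    si_logit_sd_N: float = 0.8
    si_logit_sd_C: float = 2.0
    mass_mean: float = 8.0  # kg
    mass_sd: float = 1.8  # kg
    prop_female: float = 0.5
    prop_adult: float = 0.7
    sites: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")
    lowered_sites: tuple[str, ...] = ("S6", "S7")
    noise_sd: float = 0.1  # ‰ analytical noise per capsule
    n_missing_mass: int = 1
    ar1_rho: float = 0.0  # optional along-whisker autocorrelation
    # whisker geometry for the chronology stage
    whisker_length_mean: float = 45.0  # mm, observed
    whisker_length_sd: float = 3.0
    intradermal_mm: float = 5.0
    collection_start: date = date(2018, 8, 1)
    collection_stop: date = date(2018, 10, 4)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_segments < 2:
            raise ConfigError("need >= 2 individuals and >= 2 segments")
        if not (self.sigma_B_N > 0 and self.sigma_B_C > 0):
            raise ConfigError("sigma_B must be positive")
        if self.noise_sd < 0 or self.si_logit_sd_N < 0 \
                or self.si_logit_sd_C < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not set(self.lowered_sites) <= set(self.sites):
            raise ConfigError("lowered_sites must be a subset of sites")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must lie in (-1, 1)")
        if self.n_missing_mass >= self.n_individuals:
            raise ConfigError("cannot blank the mass of every individual")


@dataclass
class SyntheticPopulation:
    """Pipeline-facing tables plus the withheld truth table."""

    config: GeneratorConfig
    covariates: pd.DataFrame
    segments: pd.DataFrame
    whiskers: pd.DataFrame
    truth: pd.DataFrame


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _true_si(config: GeneratorConfig, element: str, mass: np.ndarray,
             lowered: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    b0, b_mass, b_comp = getattr(config, f"si_link_{element}")
    sd = getattr(config, f"si_logit_sd_{element}")
    logit = b0 + b_mass * mass + b_comp * lowered.astype(float)
    logit = logit + rng.normal(0.0, sd, size=mass.size)
    si = _logistic(logit)
    if not np.all((si > 0) & (si < 1)):
        raise ConfigError("link parameters force true SI outside (0, 1)")
    return si


def _segment_values(mu: np.ndarray, sigma_w: np.ndarray, m: int,
                    noise_sd: float, rho: float,
                    rng: np.random.Generator) -> np.ndarray:
    n = mu.size
    if rho == 0.0:
        diet = rng.normal(0.0, 1.0, size=(n, m)) * sigma_w[:, None]
    else:
        # stationary AR(1) along the whisker, marginal sd = sigma_w
        z = np.empty((n, m))
        z[:, 0] = rng.normal(0.0, 1.0, size=n)
        innov_sd = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + rng.normal(0.0, innov_sd, size=n)
        diet = z * sigma_w[:, None]
    noise = rng.normal(0.0, noise_sd, size=(n, m))
    return mu[:, None] + diet + noise


def simulate_population(
    config: GeneratorConfig, seed: int | None = None
) -> SyntheticPopulation:
    """Draw one synthetic population; byte-identical under the same seed."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigError("a seed is required (unseeded generation refused)")
    rng = np.random.default_rng(seed)
    n, m = config.n_individuals, config.n_segments
    width = max(3, len(str(n)))
    ids = np.array([f"D{str(i + 1).zfill(width)}" for i in range(n)])

    sex = np.where(rng.random(n) < config.prop_female, "F", "M")
    age = np.where(rng.random(n) < config.prop_adult, "adult", "yearling")
    mass = rng.normal(config.mass_mean, config.mass_sd, size=n)
    while np.any(mass <= 0):  # truncate at zero, redraw the offenders
        bad = mass <= 0
        mass[bad] = rng.normal(config.mass_mean, config.mass_sd,
                               size=int(bad.sum()))
    site = rng.choice(np.array(config.sites), size=n)
    lowered = np.isin(site, config.lowered_sites)
    competition = np.where(lowered, "lowered", "normal")

    truth_cols: dict[str, np.ndarray] = {"individual_id": ids}
    seg_frames = []
    for element, col, mean, sigma_b in (
        ("N", "d15N", config.mean_d15N, config.sigma_B_N),
        ("C", "d13C", config.mean_d13C, config.sigma_B_C),
    ):
        si = _true_si(config, element, mass, lowered, rng)
        sigma_w = sigma_b * np.sqrt(si / (1.0 - si))
        mu = rng.normal(mean, sigma_b, size=n)
        vals = _segment_values(mu, sigma_w, m, config.noise_sd,
                               config.ar1_rho, rng)
        truth_cols[f"mu_{col}"] = mu
        truth_cols[f"sigma_W_{col}"] = sigma_w
        truth_cols[f"SI_true_{element}"] = si
        seg_frames.append(vals)

    capsule_mass = np.clip(
        rng.normal(0.32, 0.08, size=(n, m)), 0.2, 0.5
    )
    segments = pd.DataFrame(
        {
            "individual_id": np.repeat(ids, m),
            "segment_id": np.tile(
                np.array([f"seg{j + 1}" for j in range(m)]), n
            ),
            "d15N": seg_frames[0].ravel(),
            "d13C": seg_frames[1].ravel(),
            "mass_mg": capsule_mass.ravel(),
        }
    )

    mass_recorded = mass.copy()
    if config.n_missing_mass:
        blank = rng.choice(n, size=config.n_missing_mass, replace=False)
        mass_recorded[blank] = np.nan
    covariates = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sex,
            "age_class": age,
            "mass": mass_recorded,
            "competition": competition,
            "site": site,
        }
    )

    span = (config.collection_stop - config.collection_start).days
    coll_offsets = rng.integers(0, span + 1, size=n)
    whiskers = pd.DataFrame(
        {
            "individual_id": ids,
            "observed_length": np.round(
                rng.normal(config.whisker_length_mean,
                           config.whisker_length_sd, size=n) * 2
            ) / 2.0,  # measured to the nearest 0.5 mm
            "intradermal_length": config.intradermal_mm,
            "collection_date": [
                config.collection_start + timedelta(days=int(o))
                for o in coll_offsets
            ],
            "position_label": rng.choice(list("ABCDEF"), size=n),
        }
    )

    truth = pd.DataFrame(truth_cols)
    truth["mass"] = mass  # actual mass, even where the record is blank
    return SyntheticPopulation(config, covariates, segments, whiskers, truth)


# ---------------------------------------------------------------------------
# targets of the estimator

def expected_si(sigma_w: float, sigma_b: float) -> float:
    """Asymptotic (many-segment) target σ²_W / (σ²_W + σ²_B)."""
    if sigma_w < 0 or not sigma_b > 0:
        raise ConfigError("sigma_w must be >= 0 and sigma_b > 0")
    return sigma_w**2 / (sigma_w**2 + sigma_b**2)


def expected_si_estimate(
    sigma_w: float,
    sigma_b: float,
    n_segments: int,
    noise_sd: float = 0.0,
    mean_sigma_w2: float | None = None,
    ddof: int = 1,
) -> float:
    """Expected value of the finite-segment SI estimator, by quadrature.

    The sample INW is a scaled chi-square, INW ~ σ²_eff · χ²_{m−d}/(m−d)
    with σ²_eff = σ²_W + noise², and the between-means BINW concentrates on
    σ²_B + mean(σ²_eff)/m; the expectation of INW/(INW + BINW) is computed
    under that law. Sampling noise of BINW itself (O(1/n_individuals)) is
    neglected, so this is the large-population expectation.
    """
    if n_segments - ddof < 1:
        raise ConfigError("need n_segments - ddof >= 1")
    s2 = sigma_w**2 + noise_sd**2
    pop_s2 = s2 if mean_sigma_w2 is None else mean_sigma_w2 + noise_sd**2
    binw = sigma_b**2 + pop_s2 / n_segments
    dof = n_segments - ddof
    law = stats.gamma(a=dof / 2.0, scale=2.0 * s2 / dof)
    return float(law.expect(lambda v: v / (v + binw)))


def estimate_si(population: SyntheticPopulation) -> pd.DataFrame:
    """Run the specialization estimator on a synthetic population and
    return one row per individual with NSI, CSI and the covariates."""
    res = SpecializationModel.from_dataframe(population.segments).fit()
    wide = res.pivot("SI").reset_index()
    return wide.merge(population.covariates, on="individual_id",
                      validate="1:1")


def recovery_report(truth: pd.DataFrame,
                    estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-element bias and RMSE of estimated SI against the truth table.

    ``estimates`` must carry ``individual_id`` plus ``NSI``/``CSI``
    columns (as produced by :func:`estimate_si`).
    """
    if set(truth["individual_id"]) != set(estimates["individual_id"]):
        raise JoinError("truth and estimate tables cover different "
                        "individuals")
    joined = truth.merge(estimates, on="individual_id", validate="1:1")
    rows = []
    for element, est_col in (("N", "NSI"), ("C", "CSI")):
        err = joined[est_col] - joined[f"SI_true_{element}"]
        rows.append(
            {
                "element": element,
                "index": est_col,
                "n": len(joined),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
            }
        )
    return pd.DataFrame(rows)


def replicate_driver_recovery(
    config: GeneratorConfig,
    n_replicates: int,
    seed: int,
    response: str = "NSI",
) -> pd.DataFrame:
    """Replicate the generate → estimate → select pipeline and record, per
    replicate, whether the AICc-top model retained mass and the sign of
    its mass coefficient, plus the mean estimated and true SI."""
    from .drivers import DriverSelection

    root = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        pop = simulate_population(config,
                                  seed=int(root.integers(0, 2**31 - 1)))
        est = estimate_si(pop)
        sel = DriverSelection.from_dataframe(est, response=response)
        fit = sel.fit(check_normality=False)
        retained = "mass" in fit.top.terms
        coef = fit.top.params.get("mass", np.nan)
        element = "N" if response == "NSI" else "C"
        rows.append(
            {
                "replicate": r,
                "mass_retained": retained,
                "mass_coefficient": float(coef),
                "top_model": fit.top.label,
                "top_is_null": fit.top.label == "1 (null)",
                "mean_si_est": float(est[response].mean()),
                "mean_si_true": float(
                    pop.truth[f"SI_true_{element}"].mean()
                ),
            }
        )
    return pd.DataFrame(rows)
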