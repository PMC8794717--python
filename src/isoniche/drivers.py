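"""Drivers of specialization: all-subsets Gaussian linear models ranked
by AICc.

Candidate models regress a specialization index (NSI, or log-transformed
CSI when raw residuals fail the normality screen) on individual and
environmental covariates. Every subset of the main effects is fitted
(interactions only when both parents are present — the marginality rule),
models are ranked by the small-sample Akaike criterion

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1),

where the Gaussian log-likelihood uses the ML variance estimator RSS/n and
``k`` counts the mean parameters plus one for the residual variance.
Models within ΔAICc < 2 of the best have substantial support; Akaike
weights exp(-Δ/2) are reported both normalized over the full candidate set
and renormalized over the supported subset. Each supported model is also
compared against the intercept-only null with a nested-model F test, and
residual normality is screened with a simulation-based quantile-plot
envelope calibrated to 95% simultaneous coverage.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CollinearityError,
    DomainError,
    InsufficientDataError,
    MarginalityError,
    NestingError,
)

logger = logging.getLogger(__name__)

DEFAULT_TERMS = ("age_class", "competition", "mass", "sex", "site")
DEFAULT_INTERACTIONS = (("mass", "competition"),)


# ---------------------------------------------------------------------------
# design matrices

def _is_categorical(col: pd.Series) -> bool:
    return (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool)


def _encode_term(df: pd.DataFrame, term: str) -> pd.DataFrame:
    col = df[term]
    if _is_categorical(col):
        levels = sorted(map(str, col.dropna().unique()))
        if len(levels) < 2:
            # constant factor carries no information; encode nothing
            return pd.DataFrame(index=df.index)
        ref = levels[0]  # treatment coding, alphabetical reference
        block = {}
        for lv in levels[1:]:
            block[f"{term}[{lv}]"] = (col.astype(str) == lv).astype(float)
        return pd.DataFrame(block, index=df.index)
    return pd.DataFrame({term: col.astype(float)}, index=df.index)


def build_design_matrix(
    data: pd.DataFrame,
    terms: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Treatment-coded design matrix with an intercept.

    Categorical terms expand to indicator columns with the alphabetically
    first level as reference; interaction columns are elementwise products
    of the parent blocks and require both parents among ``terms``
    (marginality). Raises :class:`CollinearityError` naming the aliased
    columns when the matrix is rank deficient.
    """
    for a, b in interactions:
        if a not in terms or b not in terms:
            raise MarginalityError(
                f"interaction {a}:{b} requires both main effects in the model"
            )
    blocks = {t: _encode_term(data, t) for t in terms}
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        X = pd.concat([X, blocks[t]], axis=1)
    for a, b in interactions:
        for ca in blocks[a].columns:
            for cb in blocks[b].columns:
                X[f"{ca}:{cb}"] = blocks[a][ca] * blocks[b][cb]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        aliased = _aliased_columns(X)
        raise CollinearityError(
            f"design matrix is rank deficient; aliased column(s): "
            f"{', '.join(aliased)}"
        )
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    from scipy.linalg import qr

    arr = X.to_numpy(dtype=float)
    _, r, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [X.columns[i] for i in sorted(piv[rank:])]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class ModelFit:
    """One fitted Gaussian linear model.

    ``k`` counts the estimated mean parameters plus one for the residual
    variance; ``loglik`` is the maximized Gaussian log-likelihood with the
    ML variance RSS/n.
    """

    response: str
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    params: pd.Series
    n: int
    k: int
    rss: float
    loglik: float
    aicc: float
    r2: float
    residuals: np.ndarray
    fitted: np.ndarray

    @property
    def k_mean(self) -> int:
        return self.k - 1

    @property
    def label(self) -> str:
        parts = list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(parts) if parts else "1 (null)"


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood with ML variance RSS/n."""
    if rss <= 0:
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1)."""
    if n - k - 1 <= 0:
        raise DomainError(f"AICc undefined for n={n}, k={k} (n <= k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_ols(
    X: pd.DataFrame,
    y: Sequence[float],
    response: str = "y",
    terms: tuple[str, ...] = (),
    interactions: tuple[tuple[str, str], ...] = (),
) -> ModelFit:
    """Ordinary least squares with the AICc bookkeeping used for ranking."""
    yv = np.asarray(y, dtype=float)
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    if n <= p:
        raise InsufficientDataError(
            f"underdetermined fit: n={n} rows for {p} parameters"
        )
    beta, *_ = np.linalg.lstsq(arr, yv, rcond=None)
    fitted = arr @ beta
    resid = yv - fitted
    rss = float(resid @ resid)
    tss = float(((yv - yv.mean()) ** 2).sum())
    k = p + 1
    ll = gaussian_loglik(rss, n)
    if not math.isfinite(ll):
        crit = -math.inf  # perfect fit dominates any ranking
    elif n - k - 1 <= 0:
        crit = math.nan  # too few rows for the small-sample correction
    else:
        crit = aicc(ll, k, n)
    return ModelFit(
        response=response,
        terms=tuple(terms),
        interactions=tuple(interactions),
        params=pd.Series(beta, index=X.columns),
        n=n,
        k=k,
        rss=rss,
        loglik=ll,
        aicc=crit,
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        residuals=resid,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# candidate sets and ranking

def all_subsets(
    full_terms: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
) -> list[tuple[tuple[str, ...], tuple[tuple[str, str], ...]]]:
    """All-subsets candidate list: every subset of the main effects, plus
    interaction-bearing variants only when both parents are present.

    Ordering is deterministic: by number of main effects, then
    alphabetically, then by interaction count.
    """
    terms = sorted(full_terms)
    out = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            feasible = [ix for ix in interactions
                        if ix[0] in subset and ix[1] in subset]
            for ri in range(len(feasible) + 1):
                for ixs in itertools.combinations(feasible, ri):
                    out.append((subset, ixs))
    return out


@dataclass
class ModelTable:
    """Ranked candidate set with ΔAICc, Akaike weights and support flags."""

    fits: list[ModelFit]
    frame: pd.DataFrame
    delta_support: float = 2.0

    @property
    def top(self) -> ModelFit:
        return self.fits[0]

    @property
    def supported(self) -> list[ModelFit]:
        flags = self.frame["support"].to_numpy()
        return [f for f, s in zip(self.fits, flags) if s]


def rank_models(fits: Sequence[ModelFit],
                delta_support: float = 2.0) -> ModelTable:
    """Sort by AICc, compute Δ, full-set and supported-subset weights."""
    if not fits:
        raise InsufficientDataError("no fitted models to rank")
    responses = {f.response for f in fits}
    if len(responses) > 1:
        raise NestingError(
            f"cannot rank models with mixed responses: {sorted(responses)}"
        )
    if len({f.n for f in fits}) > 1:
        raise NestingError("cannot rank models fitted to different n")
    order = sorted(fits, key=lambda f: (f.aicc, f.k, f.label))
    delta = np.array([f.aicc - order[0].aicc for f in order])
    rel = np.exp(-delta / 2.0)
    weights = rel / rel.sum()
    support = delta < delta_support
    w_support = np.where(support, rel, 0.0)
    if w_support.sum() > 0:
        w_support = w_support / w_support.sum()
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "model": [f.label for f in order],
            "df": [f.k for f in order],
            "logLik": [f.loglik for f in order],
            "AICc": [f.aicc for f in order],
            "delta_AICc": delta,
            "weight": weights,
            "weight_supported": w_support,
            "support": support,
            "R2": [f.r2 for f in order],
        }
    )
    return ModelTable(fits=list(order), frame=frame,
                      delta_support=delta_support)


def compare_to_null(top: ModelFit, null: ModelFit) -> tuple[float, float]:
    """Nested-model F test of ``top`` against ``null`` (same rows).

    F = [(RSS0 - RSS1)/(p1 - p0)] / [RSS1/(n - p1)] with p the number of
    mean parameters; returns (F, p-value).
    """
    if top.n != null.n or top.response != null.response:
        raise NestingError("models are fitted to different data")
    if not set(null.params.index) <= set(top.params.index):
        raise NestingError(
            f"null model ({null.label}) is not nested in {top.label}"
        )
    df1 = top.k_mean - null.k_mean
    df2 = top.n - top.k_mean
    if df1 == 0:
        return 0.0, 1.0
    f = ((null.rss - top.rss) / df1) / (top.rss / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


# ---------------------------------------------------------------------------
# residual normality screen

@dataclass(frozen=True)
class EnvelopeResult:
    """Outcome of the quantile-plot envelope normality screen."""

    passed: bool
    fraction_inside: float
    n_sim: int
    lower: np.ndarray
    upper: np.ndarray
    observed: np.ndarray


def envelope_normality_check(
    residuals: Sequence[float],
    n_sim: int = 500,
    seed: int | np.random.Generator | None = None,
    global_level: float = 0.95,
    calibrate: bool = True,
) -> EnvelopeResult:
    """Simulation envelope for the normal quantile plot of residuals.

    ``n_sim`` normal samples of the same size, scaled to the residual
    standard deviation, give per-order-statistic envelopes. With
    ``calibrate=True`` (default) the envelope is widened rank-by-rank until
    a fraction ``global_level`` of the simulated samples lies entirely
    inside — a simultaneous (global) envelope, so a well-specified model
    passes in ≈95% of datasets. ``calibrate=False`` gives raw pointwise
    2.5%/97.5% bands, which are anti-conservative as a joint check.

    The check passes iff every observed order statistic lies inside.
    """
    res = np.sort(np.asarray(residuals, dtype=float))
    n = res.size
    if n < 3:
        raise InsufficientDataError("envelope check needs >= 3 residuals")
    if n_sim < 100:
        logger.warning("n_sim=%d is small; envelope will be noisy", n_sim)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sd = float(res.std(ddof=1))
    sims = np.sort(rng.standard_normal((n_sim, n)) * sd, axis=1)
    col_sorted = np.sort(sims, axis=0)
    if calibrate:
        # rank depth of each simulated curve; trim the most extreme k per
        # side such that >= global_level of curves stay fully inside
        ranks = np.argsort(np.argsort(sims, axis=0), axis=0) + 1
        depth = np.minimum(ranks, n_sim + 1 - ranks).min(axis=1)
        k = 0
        while k + 1 < n_sim // 2 and np.mean(depth > k + 1) >= global_level:
            k += 1
        lower = col_sorted[k]
        upper = col_sorted[n_sim - 1 - k]
    else:
        alpha = 1.0 - global_level
        lower = np.quantile(sims, alpha / 2.0, axis=0)
        upper = np.quantile(sims, 1.0 - alpha / 2.0, axis=0)
    inside = (res >= lower) & (res <= upper)
    return EnvelopeResult(
        passed=bool(inside.all()),
        fraction_inside=float(inside.mean()),
        n_sim=n_sim,
        lower=lower,
        upper=upper,
        observed=res,
    )


def transform_response(y: Sequence[float], kind: str = "identity",
                       ids: Sequence | None = None) -> np.ndarray:
    """Elementwise response transform; ``log`` requires strictly positive
    values and names the offending ids otherwise."""
    arr = np.asarray(y, dtype=float)
    if kind == "identity":
        return arr
    if kind == "log":
        bad = np.where(~(arr > 0))[0]
        if bad.size:
            names = ([str(ids[i]) for i in bad] if ids is not None
                     else [str(i) for i in bad])
            raise DomainError(
                "log transform requires positive values; offending: "
                + ", ".join(names)
            )
        return np.log(arr)
    raise DomainError(f"unknown transform {kind!r}")


# ---------------------------------------------------------------------------
# the modelling object

class DriverSelection:
    """All-subsets AICc selection of specialization drivers.

    Parameters
    ----------
    data
        One row per individual: the response column plus covariates.
    response
        Name of the response column (e.g. ``NSI`` or ``CSI``).
    terms, interactions
        Full main-effect set and optional interactions (fitted only in
        models containing both parents).
    transform
        ``identity`` or ``log`` applied to the response before fitting.
    delta_support
        ΔAICc support threshold (default 2).

    Rows with missing values in the response or any covariate are dropped
    (listwise deletion) with a logged count.

    Examples
    --------
    >>> sel = DriverSelection.from_dataframe(df, response="NSI")
    >>> res = sel.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        terms: Sequence[str] = DEFAULT_TERMS,
        interactions: Sequence[tuple[str, str]] = DEFAULT_INTERACTIONS,
        transform: str = "identity",
        delta_support: float = 2.0,
        id_col: str | None = "individual_id",
    ) -> None:
        cols = [response, *terms]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise DomainError(f"missing column(s): {', '.join(missing)}")
        complete = data.dropna(subset=cols).reset_index(drop=True)
        self.n_dropped = len(data) - len(complete)
        if self.n_dropped:
            logger.info("dropped %d row(s) with missing data (n=%d)",
                        self.n_dropped, len(complete))
        self.data = complete
        self.response = response
        self.terms = tuple(terms)
        self.interactions = tuple(tuple(ix) for ix in interactions)
        self.transform = transform
        self.delta_support = delta_support
        self.id_col = id_col if id_col in complete.columns else None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kw):
        return cls(data, response, **kw)

    def _response_vector(self) -> np.ndarray:
        ids = (self.data[self.id_col] if self.id_col is not None else None)
        return transform_response(
            self.data[self.response], self.transform, ids=ids
        )

    def fit(
        self,
        check_normality: bool = True,
        auto_log: bool = False,
        n_sim: int = 500,
        seed: int | np.random.Generator | None = None,
    ) -> "DriverSelectionResults":
        """Fit the full candidate set and rank by AICc.

        With ``auto_log=True`` the candidate set is refitted on the
        log response when the top raw model fails the envelope screen,
        mirroring the usual workflow for a right-skewed index.
        """
        y = self._response_vector()
        fits = []
        self.aliased_candidates: list[str] = []
        name = (self.response if self.transform == "identity"
                else f"{self.transform}({self.response})")
        for terms, ixs in all_subsets(self.terms, self.interactions):
            try:
                X = build_design_matrix(self.data, terms, ixs)
            except CollinearityError as exc:
                # e.g. competition fully determined by site: the joint
                # model is aliased and leaves the candidate set
                label = " + ".join(list(terms)
                                   + [f"{a}:{b}" for a, b in ixs])
                self.aliased_candidates.append(label)
                logger.warning("dropping aliased candidate %s (%s)",
                               label, exc)
                continue
            fits.append(fit_ols(X, y, response=name, terms=terms,
                                interactions=ixs))
        table = rank_models(fits, self.delta_support)
        envelope = None
        if check_normality:
            envelope = envelope_normality_check(
                table.top.residuals, n_sim=n_sim, seed=seed
            )
            if auto_log and not envelope.passed \
                    and self.transform == "identity":
                logger.info(
                    "%s: top model failed the quantile-envelope screen; "
                    "refitting candidate set on log(%s)",
                    self.response, self.response,
                )
                relog = DriverSelection(
                    self.data, self.response, self.terms, self.interactions,
                    transform="log", delta_support=self.delta_support,
                    id_col=self.id_col or "individual_id",
                )
                return relog.fit(check_normality=True, auto_log=False,
                                 n_sim=n_sim, seed=seed)
        null = next(f for f in table.fits
                    if not f.terms and not f.interactions)
        comparisons = {}
        for fitted in table.supported:
            comparisons[fitted.label] = compare_to_null(fitted, null)
        return DriverSelectionResults(self, table, null, comparisons,
                                      envelope)


class DriverSelectionResults:
    """Ranked candidate set with support weights, null comparisons and
    the residual-normality screen of the top model."""

    def __init__(self, model: DriverSelection, table: ModelTable,
                 null: ModelFit,
                 null_comparisons: dict[str, tuple[float, float]],
                 envelope: EnvelopeResult | None) -> None:
        self.model = model
        self.table = table
        self.null = null
        self.null_comparisons = null_comparisons
        self.envelope = envelope

    @property
    def top(self) -> ModelFit:
        return self.table.top

    @property
    def frame(self) -> pd.DataFrame:
        out = self.table.frame.copy()
        out["p_vs_null"] = [
            self.null_comparisons.get(lbl, (np.nan, np.nan))[1]
            for lbl in out["model"]
        ]
        return out

    def supported_frame(self) -> pd.DataFrame:
        f = self.frame
        return f[f["support"]].reset_index(drop=True)

    def summary(self) -> str:
        f = self.supported_frame()
        lines = [
            f"AICc model selection for {self.top.response} "
            f"(n={self.top.n}, {len(self.table.fits)} candidate models, "
            f"{self.model.n_dropped} row(s) dropped for missing data)",
            f"Supported models (delta AICc < {self.table.delta_support:g}):",
        ]
        for _, r in f.iterrows():
            lines.append(
                f"  {int(r['rank'])}. {r['model']:<50} df={int(r['df'])} "
                f"logLik={r['logLik']:8.3f} dAICc={r['delta_AICc']:5.2f} "
                f"w={r['weight_supported']:.3f} p_vs_null={r['p_vs_null']:.4g}"
            )
        top = self.top
        lines.append(f"Top model coefficients (R2={top.r2:.3f}):")
        for name, val in top.params.items():
            lines.append(f"  {name:<28} {val: .4f}")
        if self.envelope is not None:
            lines.append(
                "Residual normality (95% global quantile envelope): "
                + ("pass" if self.envelope.passed
                   else f"FAIL ({self.envelope.fraction_inside:.1%} inside)")
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<DriverSelectionResults: top={self.top.label!r}, "
                f"n={self.top.n}>")
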