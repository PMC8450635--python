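"""Weighted Poisson and binomial GLMs linking parasitism to diversity,
Wald inference with significance codes, and the amplification/dilution
classification rule.

Two model objects mirror the two parasitism indices:

* :class:`OccurrenceCountModel` — per-period counts of analytical
  (certainty 1–3) parasitized host occurrences regressed on the SQS
  diversity predictors and period midpoint age; Poisson family, log link,
  rows weighted by log10 of the period's reported specimen total.
* :class:`PrevalenceModel` — per-occurrence prevalence (k infested of n
  examined) regressed on the period-level diversity predictors and the
  record's best age; binomial family, logit link, rows weighted by
  log10(n).

Both are built from data via ``from_records`` and their ``fit()`` returns
a :class:`GLMFit` results object carrying estimates, standard errors,
Wald z and p, significance codes and deviance, with a ``summary()``
table.  Fitting is iteratively reweighted least squares via statsmodels
with variance weights, relative tolerance 1e-8, at most 100 iterations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import ParasitismOccurrence
from .sqs import DiversityTable
from .timescale import Timescale, load_timescale

log = logging.getLogger(__name__)

DIVERSITY_PREDICTORS = ("S_mean", "lambda_3t", "mu_3t")
DEFAULT_OCCURRENCE_PREDICTORS = DIVERSITY_PREDICTORS + ("midpoint_ma",)
DEFAULT_PREVALENCE_PREDICTORS = DIVERSITY_PREDICTORS + ("best_age_ma",)


@dataclass(frozen=True)
class ModelSpec:
    """Response kind, predictor list, family and weighting of one fit."""

    response: str  # "count" or "proportion"
    predictors: tuple[str, ...]
    weighted: bool = True

    @property
    def family(self) -> str:
        return "poisson_log" if self.response == "count" else "binomial_logit"

    def __post_init__(self) -> None:
        if self.response not in ("count", "proportion"):
            raise ValueError(f"unknown response kind {self.response!r}")


def sig_code(p: float) -> str:
    """Star codes: *** p<0.001, ** p<0.01, * p<0.05, # p<0.10."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "#"
    return ""


@dataclass
class GLMFit:
    """Results of one weighted GLM fit."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    deviance: float
    converged: bool
    n_rows: int
    flags: tuple[str, ...] = ()
    dropped_rows: tuple = ()
    group: str = "all"

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.zvalues
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=z.index)

    @property
    def codes(self) -> pd.Series:
        return self.pvalues.map(sig_code)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: term, estimate, SE, z, p, code."""
        return wald_summary(self)

    def summary_text(self) -> str:
        header = (
            f"{self.spec.family} GLM ({self.group}), n={self.n_rows}, "
            f"deviance={self.deviance:.4g}, converged={self.converged}"
        )
        if self.flags:
            header += f", flags={';'.join(self.flags)}"
        return header + "\n" + self.summary().to_string(index=False)


def wald_summary(fit: GLMFit) -> pd.DataFrame:
    """Wald coefficient table with two-sided normal p and star codes."""
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "z": fit.zvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "code": fit.codes.to_numpy(),
        }
    )


def fit_glm(
    spec: ModelSpec,
    data: pd.DataFrame,
    group: str = "all",
) -> GLMFit:
    """Maximize the weighted GLM log-likelihood.

    ``data`` must hold the predictor columns, a ``weight`` column when the
    spec is weighted, and the response: a ``count`` column for Poisson or
    ``k``/``n`` columns for binomial (successes of trials).  The binomial
    likelihood for k of n with an extra weight w is fitted as a
    proportion response with variance weights n*w.  Rank-deficient
    designs and non-convergence yield a flagged fit, never silent output.
    """
    missing = [c for c in spec.predictors if c not in data.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    n_params = len(spec.predictors) + 1
    if len(data) < n_params + 1:
        raise ValueError(
            f"{len(data)} rows cannot support {n_params} parameters "
            f"(need at least {n_params + 1})"
        )
    exog = sm.add_constant(
        data[list(spec.predictors)].astype(float), has_constant="add"
    )
    exog = exog.rename(columns={"const": "Intercept"})

    w = (
        data["weight"].to_numpy(dtype=float)
        if spec.weighted
        else np.ones(len(data))
    )
    if spec.weighted and np.any(w <= 0):
        raise ValueError("weights must be positive for weighted fits")

    flags: list[str] = []
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        flags.append("rank_deficient")
        nan = pd.Series(np.nan, index=exog.columns)
        return GLMFit(
            spec=spec, params=nan, bse=nan, deviance=float("nan"),
            converged=False, n_rows=len(data), flags=tuple(flags), group=group,
        )

    if spec.response == "count":
        endog = data["count"].to_numpy(dtype=float)
        family = sm.families.Poisson()
        var_weights = w
    else:
        k = data["k"].to_numpy(dtype=float)
        n = data["n"].to_numpy(dtype=float)
        endog = k / n
        family = sm.families.Binomial()
        var_weights = n * w

    try:
        model = sm.GLM(endog, exog, family=family, var_weights=var_weights)
        res = model.fit(method="IRLS", maxiter=100, tol=1e-8)
        converged = bool(getattr(res, "converged", True))
        if not converged:
            flags.append("not_converged")
        return GLMFit(
            spec=spec,
            params=pd.Series(res.params, index=exog.columns),
            bse=pd.Series(res.bse, index=exog.columns),
            deviance=float(res.deviance),
            converged=converged,
            n_rows=len(data),
            flags=tuple(flags),
            group=group,
        )
    except (PerfectSeparationError, ValueError) as exc:
        log.warning("fit_glm: %s", exc)
        flags.append("perfect_separation")
        nan = pd.Series(np.nan, index=exog.columns)
        return GLMFit(
            spec=spec, params=nan, bse=nan, deviance=float("nan"),
            converged=False, n_rows=len(data), flags=tuple(flags), group=group,
        )


def _period_specimen_totals(
    records: list[ParasitismOccurrence],
) -> pd.Series:
    rows = [
        (r.period, r.n_specimens)
        for r in records
        if r.n_specimens is not None
    ]
    if not rows:
        return pd.Series(dtype=float)
    df = pd.DataFrame(rows, columns=["period", "n"])
    return df.groupby("period")["n"].sum()


class OccurrenceCountModel:
    """Poisson GLM of per-period parasitized-occurrence counts.

    Construct with :meth:`from_records`, which bins the analytical
    records per period, joins the diversity predictors, computes
    log10 specimen-total weights, and drops (with a log entry) any
    period missing a predictor.  When some period with occurrences has
    no reported specimens at all, the fit falls back to unweighted mode
    and is annotated accordingly.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: tuple[str, ...] = DEFAULT_OCCURRENCE_PREDICTORS,
        weighted: bool = True,
        group: str = "all",
        dropped: tuple = (),
    ) -> None:
        self.data = data
        self.spec = ModelSpec("count", tuple(predictors), weighted=weighted)
        self.group = group
        self.dropped = dropped

    @classmethod
    def from_records(
        cls,
        records: list[ParasitismOccurrence],
        diversity: DiversityTable,
        timescale: Timescale | None = None,
        predictors: tuple[str, ...] = DEFAULT_OCCURRENCE_PREDICTORS,
        host_class: str | None = None,
        group: str = "all",
    ) -> "OccurrenceCountModel":
        ts = timescale or load_timescale()
        recs = [
            r
            for r in records
            if host_class is None or r.host_class == host_class
        ]
        counts = pd.Series(
            [sum(r.period == p.name for r in recs) for p in ts.periods],
            index=[p.name for p in ts.periods],
            name="count",
        )
        div = diversity.frame.set_index("period")
        frame = div.join(counts)
        totals = _period_specimen_totals(recs)
        frame["specimens"] = totals.reindex(frame.index).fillna(0.0)

        div_cols = [c for c in predictors if c in div.columns]
        complete = frame.dropna(subset=div_cols)
        dropped = tuple(sorted(set(frame.index) - set(complete.index)))
        if dropped:
            log.info(
                "OccurrenceCountModel: dropped periods with missing "
                "predictors: %s", dropped,
            )
        weighted = bool((complete["specimens"] > 0).all()) and len(complete) > 0
        data = complete.copy()
        if weighted:
            w = np.log10(data["specimens"].to_numpy(dtype=float))
            if (w <= 0).any():
                weighted = False
            else:
                # relative precision weights: the absolute scale of
                # log10(specimens) carries no information, so normalize to
                # mean 1 to keep Wald variances on the observation scale
                data["weight"] = w / w.mean()
        if not weighted:
            log.info(
                "OccurrenceCountModel: fitting unweighted "
                "(inadequate sample-size data)"
            )
        return cls(
            data.reset_index(),
            predictors=predictors,
            weighted=weighted,
            group=group,
            dropped=dropped,
        )

    def fit(self) -> GLMFit:
        fit = fit_glm(self.spec, self.data, group=self.group)
        fit.dropped_rows = self.dropped
        if not self.spec.weighted:
            fit.flags = fit.flags + ("unweighted",)
        return fit


class PrevalenceModel:
    """Binomial GLM of per-occurrence prevalence (k infested of n).

    Each prevalence-eligible record is joined to its period's diversity
    predictors; the record's own best age enters as ``best_age_ma``.
    Rows in periods with missing predictors are dropped and recorded.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: tuple[str, ...] = DEFAULT_PREVALENCE_PREDICTORS,
        weighted: bool = True,
        group: str = "all",
        dropped: tuple = (),
        min_rows: int = 20,
    ) -> None:
        if len(data) < min_rows:
            raise ValueError(
                f"prevalence model needs at least {min_rows} rows, got {len(data)}"
            )
        self.data = data
        self.spec = ModelSpec("proportion", tuple(predictors), weighted=weighted)
        self.group = group
        self.dropped = dropped

    @classmethod
    def from_records(
        cls,
        records: list[ParasitismOccurrence],
        diversity: DiversityTable,
        predictors: tuple[str, ...] = DEFAULT_PREVALENCE_PREDICTORS,
        host_class: str | None = None,
        group: str = "all",
        min_rows: int = 20,
    ) -> "PrevalenceModel":
        recs = [
            r
            for r in records
            if (host_class is None or r.host_class == host_class)
            and r.n_specimens is not None
            and r.n_infested is not None
        ]
        rows = pd.DataFrame(
            {
                "record_id": [r.record_id for r in recs],
                "period": [r.period for r in recs],
                "k": [r.n_infested for r in recs],
                "n": [r.n_specimens for r in recs],
                "best_age_ma": [r.best_age_ma for r in recs],
            }
        )
        div = diversity.frame.set_index("period")
        div_cols = [c for c in predictors if c in div.columns]
        joined = rows.join(div[div_cols], on="period")
        complete = joined.dropna(subset=div_cols)
        dropped = tuple(
            sorted(set(joined.loc[joined.index.difference(complete.index), "period"]))
        )
        if dropped:
            log.info(
                "PrevalenceModel: dropped records in periods with missing "
                "predictors: %s", dropped,
            )
        data = complete.copy()
        w = np.log10(data["n"].to_numpy(dtype=float))
        data["weight"] = w / w.mean()  # relative precision weights, mean 1
        return cls(
            data.reset_index(drop=True),
            predictors=predictors,
            group=group,
            dropped=dropped,
            min_rows=min_rows,
        )

    def fit(self) -> GLMFit:
        fit = fit_glm(self.spec, self.data, group=self.group)
        fit.dropped_rows = self.dropped
        return fit


@dataclass
class HypothesisCall:
    """Amplification/dilution verdict for one host group."""

    group: str
    call: str  # "amplification" | "dilution" | "unclear"
    notes: tuple[str, ...] = field(default_factory=tuple)


def classify_support(
    coef_table: pd.DataFrame,
    group: str = "all",
    alpha: float = 0.05,
    marginal: float = 0.10,
    diversity_term: str = "S_mean",
    origination_term: str = "lambda_3t",
    extinction_term: str = "mu_3t",
) -> HypothesisCall:
    """Classify a coefficient table as amplification, dilution or unclear.

    Default rule (configurable through the term names and thresholds):

    * amplification — diversity coefficient significant and positive, or
      origination positive AND extinction negative with either significant;
    * dilution — diversity coefficient significant and negative, or
      extinction significant and positive;
    * unclear — no term reaches the marginal threshold (p < 0.10), or
      the signed pattern matches no rule.

    Mechanism notes always list every signed term at or below the
    marginal threshold.
    """
    tab = coef_table.set_index("term")

    def est(term: str) -> float:
        return float(tab.loc[term, "estimate"]) if term in tab.index else float("nan")

    def pval(term: str) -> float:
        return float(tab.loc[term, "p"]) if term in tab.index else float("nan")

    notes = []
    for term in tab.index:
        if term == "Intercept":
            continue
        p = pval(term)
        if not math.isnan(p) and p < marginal:
            sign = "+" if est(term) > 0 else "-"
            qual = "marginal " if p >= alpha else ""
            notes.append(f"({sign}) {qual}{term} (p={p:.3g})")

    s, ps = est(diversity_term), pval(diversity_term)
    lam, plam = est(origination_term), pval(origination_term)
    mu, pmu = est(extinction_term), pval(extinction_term)

    call = "unclear"
    if not math.isnan(ps) and ps < alpha:
        call = "amplification" if s > 0 else "dilution"
    elif (
        not math.isnan(lam)
        and not math.isnan(mu)
        and lam > 0
        and mu < 0
        and (plam < alpha or pmu < alpha)
    ):
        call = "amplification"
    elif not math.isnan(pmu) and pmu < alpha and mu > 0:
        call = "dilution"
    if not notes:
        call = "unclear"
        notes = ["no significant relationships"]
    return HypothesisCall(group=group, call=call, notes=tuple(notes))
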