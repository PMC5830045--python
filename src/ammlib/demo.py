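"""Worked analyses and the demo library fixture.

Two small, fully self-contained analyses exercise the library container
end to end:

* a one-factor ordinary least-squares fit of plant weight on a two-level
  treatment group (the classic Dobson plant-weight data, 10 control and
  10 treated plants), with the complete summary surface -- coefficients,
  standard errors, t and F tests, residual quantiles, R-squared -- computed
  in closed form from the normal equations;
* a conjugate beta-binomial update for an orchard-infestation probability:
  a Beta(alpha, beta) prior combined with y infested apples out of n
  sampled yields a Beta(alpha + y, beta + n - y) posterior.

:func:`build_demo_library` replays the full worked sequence -- creating a
library, inserting and removing datasets and models, and linking models
to their data and priors through metadata -- and is the shared fixture for
search, subsetting and archiving.  External estimator outputs (the
occupancy models for the chorus-frog data) are represented by inert
synthetic placeholder payloads; no occupancy estimation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .archive import register_structured_type
from .core import AmLibrary, OpaquePayload, make_record
from .simulate import CovariateSpec, simulate_covariates, specs_from_mapping

__all__ = [
    "OlsResult",
    "BetaParams",
    "BinomialObservation",
    "ols_fit",
    "beta_binomial_update",
    "beta_pdf",
    "plant_weight_data",
    "apple_infestation_data",
    "demo_covariate_specs",
    "build_demo_library",
]


# -- canonical fixture data --------------------------------------------------

#: Plant dry weights for 10 control plants (Dobson 1990, via the classic
#: two-group weight experiment).
PLANT_CTL = (4.17, 5.58, 5.18, 6.11, 4.50, 4.61, 5.17, 4.53, 5.33, 5.14)

#: Plant dry weights for 10 plants under the treatment.
PLANT_TRT = (4.81, 4.17, 4.41, 3.59, 5.87, 3.83, 6.03, 4.89, 4.32, 4.69)


def plant_weight_data() -> pd.DataFrame:
    """The 20-row plant-weight table: columns ``weight`` and ``group``."""
    weight = np.array(PLANT_CTL + PLANT_TRT, dtype=float)
    group = pd.Categorical(["Ctl"] * 10 + ["Trt"] * 10,
                           categories=["Ctl", "Trt"])
    return pd.DataFrame({"weight": weight, "group": group})


def apple_infestation_data() -> pd.DataFrame:
    """The orchard sample: n = 100 apples inspected, y = 25 infested."""
    return pd.DataFrame({"n": [100], "y": [25]})


def demo_covariate_specs() -> list[CovariateSpec]:
    """The seven uncorrelated covariates simulated in the demo sequence."""
    return specs_from_mapping({
        "unif1": {"dist": "runif", "min": 0, "max": 10, "seed": 334, "round": 0},
        "unif2": {"dist": "runif", "min": 0, "max": 10, "seed": 668, "round": 0},
        "norm1": {"dist": "normal", "mean": 10, "sd": 2, "seed": 10, "round": 1},
        "norm2": {"dist": "normal", "mean": 50, "sd": 10, "seed": 15, "round": 2},
        "beta1": {"dist": "rbeta", "shape1": 2, "shape2": 1, "seed": 1002},
        "binom1": {"dist": "bin", "size": 20, "prob": 0.5, "seed": 561},
        "bern1": {"dist": "bernoulli", "size": 1, "prob": 0.5, "seed": 6},
    })


# -- ordinary least squares --------------------------------------------------


@dataclass
class OlsResult:
    """Full summary surface of a one-factor least-squares fit.

    The model is ``y_i = beta0 + beta1 * x_i + eps_i`` with ``x_i`` the
    indicator of the second factor level, so ``beta0`` is the first-level
    mean and ``beta1`` the level-2 minus level-1 effect.
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    residuals: np.ndarray
    residual_summary: dict[str, float]  # min, q1, median, q3, max
    residual_se: float
    df_resid: int
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    f_p_value: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OlsResult):
            return NotImplemented
        scalars = ("terms", "coefficients", "standard_errors", "t_values",
                   "p_values", "residual_summary", "residual_se", "df_resid",
                   "r_squared", "adj_r_squared", "f_statistic", "f_df",
                   "f_p_value")
        return (all(getattr(self, f) == getattr(other, f) for f in scalars)
                and np.array_equal(self.residuals, other.residuals))

    def summary(self) -> str:
        """A transcript-style text rendering of the fit."""
        rs = self.residual_summary
        lines = [
            "Residuals:",
            "     Min       1Q   Median       3Q      Max",
            (f"{rs['min']:8.4f} {rs['q1']:8.4f} {rs['median']:8.4f} "
             f"{rs['q3']:8.4f} {rs['max']:8.4f}"),
            "",
            "Coefficients:",
            f"{'':14s}{'Estimate':>10s}{'Std. Error':>12s}"
            f"{'t value':>9s}{'Pr(>|t|)':>10s}",
        ]
        for term in self.terms:
            lines.append(
                f"{term:14s}{self.coefficients[term]:10.4f}"
                f"{self.standard_errors[term]:12.4f}"
                f"{self.t_values[term]:9.3f}"
                f"{self.p_values[term]:10.3g}")
        lines += [
            "",
            (f"Residual standard error: {self.residual_se:.4f} "
             f"on {self.df_resid} degrees of freedom"),
            (f"Multiple R-squared: {self.r_squared:.5g},  "
             f"Adjusted R-squared: {self.adj_r_squared:.5g}"),
            (f"F-statistic: {self.f_statistic:.4g} on {self.f_df[0]} and "
             f"{self.f_df[1]} DF,  p-value: {self.f_p_value:.3g}"),
        ]
        return "\n".join(lines)


def _factor_levels(group: Sequence) -> tuple[list[str], np.ndarray]:
    if isinstance(group, pd.Series) and isinstance(group.dtype, pd.CategoricalDtype):
        group = group.array
    if isinstance(group, pd.Categorical):
        levels = [str(c) for c in group.categories if c in set(group)]
        labels = [str(g) for g in group]
    else:
        labels = [str(g) for g in group]
        levels = list(dict.fromkeys(labels))  # first-appearance order
    codes = np.array([levels.index(g) for g in labels])
    return levels, codes


def ols_fit(response: Sequence[float], group: Sequence) -> OlsResult:
    """Closed-form least squares of a response on a two-level factor.

    Estimates come straight from the normal equations
    ``(X'X) beta = X'y`` with ``X = [1, 1{group = level2}]``; the summary
    statistics (standard errors, t tests, the residual five-number
    summary, sigma-hat, R-squared and the overall F test) follow in
    closed form.  p-values use the t and F distributions.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim != 1:
        raise ValueError("response must be a 1-d numeric vector")
    levels, codes = _factor_levels(group)
    n = y.size
    if len(codes) != n:
        raise ValueError("response and group lengths differ")
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if len(levels) < 2:
        raise np.linalg.LinAlgError(
            f"group factor has a single level ({levels[0]!r}); "
            f"the design is rank-deficient")
    if len(levels) > 2:
        raise ValueError(f"group must have exactly two levels, got {levels}")
    p = 2
    if n <= p:
        raise ValueError(f"insufficient data: n = {n} <= {p} coefficients")

    X = np.column_stack([np.ones(n), (codes == 1).astype(float)])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        raise ValueError("response has zero variance; the fit is undefined")
    df_resid = n - p
    sigma2 = sse / df_resid
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    f_stat = ((sst - sse) / (p - 1)) / (sse / df_resid)
    f_p = float(stats.f.sf(f_stat, p - 1, df_resid))

    terms = ("(Intercept)", f"group{levels[1]}")
    q1, med, q3 = np.quantile(resid, [0.25, 0.5, 0.75])
    return OlsResult(
        terms=terms,
        coefficients=dict(zip(terms, map(float, beta))),
        standard_errors=dict(zip(terms, map(float, se))),
        t_values=dict(zip(terms, map(float, tvals))),
        p_values=dict(zip(terms, map(float, pvals))),
        residuals=resid,
        residual_summary={"min": float(resid.min()), "q1": float(q1),
                          "median": float(med), "q3": float(q3),
                          "max": float(resid.max())},
        residual_se=float(np.sqrt(sigma2)),
        df_resid=df_resid,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        f_statistic=float(f_stat),
        f_df=(p - 1, df_resid),
        f_p_value=f_p,
    )


# -- conjugate beta-binomial updating ----------------------------------------


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta distribution; both strictly positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta shape parameters must be strictly positive, "
                f"got alpha={self.alpha}, beta={self.beta}")

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class BinomialObservation:
    """y successes out of n independent trials (0 <= y <= n)."""

    y: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 0 or not 0 <= self.y <= self.n:
            raise ValueError(
                f"need 0 <= y <= n, got y={self.y}, n={self.n}")


def beta_binomial_update(prior: BetaParams,
                         obs: BinomialObservation) -> BetaParams:
    """Conjugate posterior: Beta(alpha + y, beta + n - y).

    With a Beta prior on a binomial success probability, Bayes' theorem
    has this closed form; the posterior concentrates as n grows, which is
    the uncertainty reduction that iterative monitoring buys.
    """
    return BetaParams(prior.alpha + obs.y, prior.beta + obs.n - obs.y)


def beta_pdf(p, params: BetaParams) -> np.ndarray:
    """Beta density at probabilities *p* (each must lie in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return stats.beta.pdf(p, params.alpha, params.beta)


# -- archive support for the result types ------------------------------------

register_structured_type(
    "OlsResult", OlsResult,
    lambda r: {"terms": list(r.terms),
               "coefficients": r.coefficients,
               "standard_errors": r.standard_errors,
               "t_values": r.t_values,
               "p_values": r.p_values,
               "residuals": [float(v) for v in r.residuals],
               "residual_summary": r.residual_summary,
               "residual_se": r.residual_se,
               "df_resid": r.df_resid,
               "r_squared": r.r_squared,
               "adj_r_squared": r.adj_r_squared,
               "f_statistic": r.f_statistic,
               "f_df": list(r.f_df),
               "f_p_value": r.f_p_value},
    lambda d: OlsResult(
        terms=tuple(d["terms"]),
        coefficients=d["coefficients"],
        standard_errors=d["standard_errors"],
        t_values=d["t_values"],
        p_values=d["p_values"],
        residuals=np.array(d["residuals"], dtype=float),
        residual_summary=d["residual_summary"],
        residual_se=d["residual_se"],
        df_resid=d["df_resid"],
        r_squared=d["r_squared"],
        adj_r_squared=d["adj_r_squared"],
        f_statistic=d["f_statistic"],
        f_df=tuple(d["f_df"]),
        f_p_value=d["f_p_value"]),
)

register_structured_type(
    "BetaParams", BetaParams,
    lambda b: {"alpha": b.alpha, "beta": b.beta},
    lambda d: BetaParams(d["alpha"], d["beta"]),
)


# -- the demo library --------------------------------------------------------

_DESCRIPTION_FINAL = ("This AM Model Library stores analysis inputs (data) "
                      "and analysis outputs (models) associated with the "
                      "ammlib demo sequence.")


def build_demo_library() -> AmLibrary:
    """Replay the worked demo sequence and return the resulting library.

    The script creates a library, inserts five datasets (plant weights,
    an updated plant table reusing the original's metadata, the apple
    sample, a simulated covariate table, and a placeholder for external
    detection-history data), removes two of them, then inserts five
    models (the plant OLS fit, two synthetic occupancy-model
    placeholders, and the two Bayesian apple models linked by a "prior"
    key) and removes one.  Final state: models [plant.model, frog.model1,
    frog.model2, apple.m1]; data [plant.data, apple.data, frog.data].
    """
    lib = AmLibrary("This AM Model Library stores models and data.",
                    {"owner": "me", "email": "me@somewhere.com"})
    lib.set_description(_DESCRIPTION_FINAL)
    lib.edit_info({"date.created": None, "owner": "Me",
                   "organization": "My Organization"})

    # datasets -------------------------------------------------------
    plant = plant_weight_data()
    lib.insert(data={"plant.data": make_record(
        "data", plant,
        {"comment": "Plant dataset from the lm helpfile.", "taxa": "plants"})})
    lib.meta("data", "plant.data", {
        "url": "https://stat.ethz.ch/R-manual/R-devel/library/stats/html/lm.html",
        "group": ("The column named 'group' identifies which group a sample "
                  "belongs to, where Ctl = control group and Trt = treatment "
                  "group."),
        "weight": ("The column named 'weight' provides total biomass of the "
                   "sample, in grams."),
    })

    # a new year's data reusing last year's metadata verbatim
    extra = pd.DataFrame({
        "group": pd.Categorical(["Ctl", "Trt"], categories=["Ctl", "Trt"]),
        "weight": [4.50, 3.83]})
    updated = pd.concat([plant[["group", "weight"]], extra],
                        ignore_index=True)
    lib.insert(data={"updated.plant.data": make_record(
        "data", updated, lib.meta("data", "plant.data"))})

    lib.insert(data={
        "apple.data": make_record(
            "data", apple_infestation_data(),
            {"comment": "Apple infestation dataset for Bayesian analysis."}),
        "sim.data": make_record(
            "data", simulate_covariates(demo_covariate_specs(), n=10,
                                        add_year=True),
            {"comment": "Simulated covariate dataset."}),
    })

    frog_frame = OpaquePayload.build(
        "unmarkedFrameOccu", "unmarked",
        note=("synthetic placeholder for chorus-frog detection histories "
              "produced by an external occupancy toolkit"))
    lib.insert(data={"frog.data": make_record(
        "data", frog_frame,
        {"comment": "Chorus frog dataset from the package unmarked.",
         "taxa": "Chorus Frog",
         "url": ("http://www.rdocumentation.org/packages/unmarked/"
                 "versions/0.11-0/topics/occu")})})

    # prune: the simulated covariates by index, the updated table by name
    lib.remove("data", 4)
    lib.remove("data", "updated.plant.data")

    # models ---------------------------------------------------------
    checked_out = lib.get("data", "plant.data")
    fit = ols_fit(checked_out["weight"], checked_out["group"])
    lib.insert(models={"plant.model": make_record(
        "model", fit,
        {"comment": "Analysis from lm helpfile", "data": "plant.data"},
        payload_class="OlsResult")})

    placeholder = ("synthetic placeholder for a fitted single-season "
                   "occupancy model from an external toolkit")
    lib.insert(models={
        "frog.model1": make_record(
            "model",
            OpaquePayload.build("unmarkedFitOccu", "unmarked",
                                note=placeholder, formula="~obsvar1 ~ sitevar1"),
            {"comment": ("Occupancy as a function of sitevar1 and detection "
                         "as a function of obsvar1."),
             "data": "frog.data"}),
        "frog.model2": make_record(
            "model",
            OpaquePayload.build("unmarkedFitOccu", "unmarked",
                                note=placeholder, formula="~1 ~ 1"),
            {"comment": ("Occupancy as a function of no covariates and "
                         "detection as a function of no covariates"),
             "data": "frog.data"}),
    })

    prior = BetaParams(2, 3)
    obs = BinomialObservation(y=25, n=100)
    posterior = beta_binomial_update(prior, obs)
    lib.insert(models={
        "apple.m1": make_record(
            "model",
            {"distribution": "beta",
             "parameters": {"alpha": prior.alpha, "beta": prior.beta}},
            {"comment": "Bayes model 1 for apple infestation"}),
        "apple.m2": make_record(
            "model",
            {"distribution": "beta",
             "posteriors": {"alpha": posterior.alpha, "beta": posterior.beta}},
            {"comment": "Bayes model 2 for apple infestation",
             "prior": "apple.m1", "data": "apple.data"}),
    })
    lib.remove("model", "apple.m2")
    return lib
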