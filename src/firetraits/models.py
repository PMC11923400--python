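"""Trait-environment models: quadratic-logit fire-response curves and
linear leaf-trait models.

Two model classes, in the statsmodels mould (a model object built from
data whose ``fit()`` returns a results object):

``FireResponseModel``
    Binomial GLM with logit link for a binary fire-response strategy
    (resprouting or postfire seeding) against x = log10(fires per
    century), as a raw (non-orthogonal) quadratic polynomial, optionally
    with a woody/herbaceous main effect and its interactions with both
    polynomial terms. Treatment coding with herbaceous as the reference
    level, so the intercept is the herbaceous logit at F = 1 fire per
    century. Fitted by IRLS; results carry Wald 95 % CIs, odds ratios
    exp(beta), the Tjur coefficient of discrimination, fitted probability
    curves with CI bands, and the location of the quadratic peak
    F* = 10^(-b1 / (2 b2)).

``LeafTraitModel``
    OLS of a log10-transformed leaf trait (LMA or leaf N) on a strategy
    indicator, growth form and their interaction; results carry 95 % CIs,
    R^2 / adjusted R^2, and estimated-marginal-mean pairwise contrasts
    with Tukey (studentized range) or Bonferroni adjustment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FireResponseModel", "FireResponseResults",
    "LeafTraitModel", "LeafTraitResults", "EmmContrast",
    "fit_logistic_quadratic", "odds_ratios", "tjur_r2", "predict_curve",
    "quadratic_peak", "fit_leaf_trait_lm", "emm_pairwise",
]

_Z95 = stats.norm.ppf(0.975)


def tjur_r2(fitted_probs, outcomes) -> float:
    """Tjur coefficient of discrimination.

    The absolute difference between the mean fitted probability of the
    TRUE outcomes and the mean fitted probability of the FALSE outcomes.
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes required")
    return float(abs(p[y].mean() - p[~y].mean()))


# --------------------------------------------------------------------------
# binomial GLM with quadratic logit
# --------------------------------------------------------------------------

class FireResponseModel:
    """Quadratic-logit binomial model of a fire-response strategy.

    Parameters
    ----------
    endog : array of bool
        Strategy outcome per species (True = has the strategy).
    fires_per_century : array of float
        Mean fire frequency F per species; must be positive (the
        predictor is x = log10 F).
    growth_form : array of str, optional
        "woody" / "herbaceous" per species. When given, a woody dummy
        (herbaceous = reference) enters the model; with
        ``interaction=True`` its interactions with x and x^2 enter too.
    """

    def __init__(self, endog, fires_per_century, growth_form=None,
                 interaction: bool = True):
        y = np.asarray(endog, dtype=bool)
        F = np.asarray(fires_per_century, dtype=float)
        if (~np.isfinite(F)).any() or (F <= 0).any():
            raise ValueError("fires_per_century must be finite and positive")
        if y.all() or not y.any():
            raise ValueError("response has a single class; model not identifiable")
        x = np.log10(F)
        cols = {"intercept": np.ones_like(x), "log10_fires": x,
                "log10_fires_sq": x**2}
        if growth_form is not None:
            gf = np.asarray(growth_form, dtype=object)
            bad = set(gf) - {"woody", "herbaceous"}
            if bad:
                raise ValueError(f"unknown growth forms: {sorted(bad)}")
            w = (gf == "woody").astype(float)
            cols["woody"] = w
            if interaction:
                cols["log10_fires:woody"] = x * w
                cols["log10_fires_sq:woody"] = x**2 * w
        self.endog = y
        self.x = x
        self.exog = pd.DataFrame(cols)
        self.has_group = growth_form is not None
        self.interaction = interaction and self.has_group

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, response: str = "resprouter",
                       freq_col: str = "fires_per_century",
                       group_col: str | None = "growth_form",
                       interaction: bool = True) -> "FireResponseModel":
        cols = [response, freq_col] + ([group_col] if group_col else [])
        sub = table.dropna(subset=cols)
        return cls(
            sub[response].astype(bool).to_numpy(),
            sub[freq_col].to_numpy(),
            sub[group_col].to_numpy() if group_col else None,
            interaction=interaction,
        )

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "FireResponseResults":
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        glm = sm.GLM(self.endog.astype(float), self.exog,
                     family=sm.families.Binomial())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", PerfectSeparationWarning)
            res = glm.fit(maxiter=maxiter, tol=tol, tol_criterion="deviance")
        converged = bool(res.converged)
        # quasi-complete separation: flagged by IRLS or visible as runaway
        # coefficients / standard errors
        separation = bool(
            any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
            or np.any(np.abs(res.params) > 30) or np.any(res.bse > 1e3))
        return FireResponseResults(self, res, converged and not separation,
                                   separation)


@dataclasses.dataclass
class FireResponseResults:
    """Fitted quadratic-logit model; statsmodels GLM results underneath."""

    model: FireResponseModel
    _res: object
    converged: bool
    separation_flag: bool = False

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def cov_params(self) -> pd.DataFrame:
        return self._res.cov_params()

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        ci.columns = ["low", "high"]
        return ci

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues)

    @property
    def tjur_r2(self) -> float:
        return tjur_r2(self.fittedvalues, self.model.endog)

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with exponentiated Wald 95 % CI bounds, full precision."""
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "odds_ratio": np.exp(self.params.to_numpy()),
            "or_low": np.exp(ci["low"].to_numpy()),
            "or_high": np.exp(ci["high"].to_numpy()),
        }).set_index("term")

    def _curve_coefs(self, group: str = "herbaceous") -> tuple[float, float, float]:
        p = self.params
        b0, b1, b2 = p["intercept"], p["log10_fires"], p["log10_fires_sq"]
        if group == "woody":
            if not self.model.has_group:
                raise ValueError("model has no growth-form term")
            b0 = b0 + p["woody"]
            if self.model.interaction:
                b1 = b1 + p["log10_fires:woody"]
                b2 = b2 + p["log10_fires_sq:woody"]
        elif group != "herbaceous":
            raise ValueError(f"unknown group {group!r}")
        return float(b0), float(b1), float(b2)

    def predict_curve(self, fires_per_century, group: str = "herbaceous",
                      alpha: float = 0.05) -> pd.DataFrame:
        """Fitted probability over an F grid with a CI band.

        The band is Wald on the logit scale, then transformed, so it always
        contains the point estimate and stays inside (0, 1).
        """
        F = np.asarray(fires_per_century, dtype=float)
        if (F <= 0).any():
            raise ValueError("F grid must be positive")
        x = np.log10(F)
        X = np.zeros((len(x), len(self.params)))
        idx = {t: i for i, t in enumerate(self.params.index)}
        X[:, idx["intercept"]] = 1.0
        X[:, idx["log10_fires"]] = x
        X[:, idx["log10_fires_sq"]] = x**2
        if group == "woody":
            X[:, idx["woody"]] = 1.0
            if self.model.interaction:
                X[:, idx["log10_fires:woody"]] = x
                X[:, idx["log10_fires_sq:woody"]] = x**2
        eta = X @ self.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov_params.to_numpy(), X))
        z = stats.norm.ppf(1 - alpha / 2)
        expit = lambda v: 1.0 / (1.0 + np.exp(-v))
        return pd.DataFrame({
            "fires_per_century": F,
            "probability": expit(eta),
            "ci_low": expit(eta - z * se),
            "ci_high": expit(eta + z * se),
        })

    def peak(self, group: str = "herbaceous") -> dict:
        """Location of the fitted curve's maximum over F.

        For a concave quadratic (b2 < 0) the peak is at
        x* = -b1 / (2 b2), i.e. F* = 10^x*; otherwise the curve is
        monotone (or a valley) and no peak is reported.
        """
        _, b1, b2 = self._curve_coefs(group)
        if b2 < 0:
            x_star = -b1 / (2 * b2)
            return {"has_peak": True, "x_star": x_star,
                    "peak_fires_per_century": 10.0**x_star}
        return {"has_peak": False, "x_star": None,
                "peak_fires_per_century": None}

    def summary(self) -> pd.DataFrame:
        """Coefficient table mirroring the usual GLM report layout."""
        ci = self.conf_int()
        orr = self.odds_ratios()
        tab = pd.DataFrame({
            "coefficient": self.params,
            "ci_low": ci["low"],
            "ci_high": ci["high"],
            "odds_ratio": orr["odds_ratio"],
            "or_ci_low": orr["or_low"],
            "or_ci_high": orr["or_high"],
            "p": self.pvalues,
        })
        tab.attrs["nobs"] = self.nobs
        tab.attrs["tjur_r2"] = self.tjur_r2
        tab.attrs["converged"] = self.converged
        return tab


# --------------------------------------------------------------------------
# linear leaf-trait models
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EmmContrast:
    contrast: str
    estimate: float     # log10-scale difference
    se: float
    df: int
    t: float
    p_adjusted: float
    adjust: str


class LeafTraitModel:
    """OLS of log10(leaf trait) on strategy x growth form (treatment coding,
    herbaceous and strategy-absent as references)."""

    def __init__(self, trait_values, strategy, growth_form,
                 strategy_name: str = "strategy"):
        v = np.asarray(trait_values, dtype=float)
        if (v <= 0).any() or (~np.isfinite(v)).any():
            raise ValueError("trait values must be positive and finite")
        s = np.asarray(strategy, dtype=bool).astype(float)
        gf = np.asarray(growth_form, dtype=object)
        bad = set(gf) - {"woody", "herbaceous"}
        if bad:
            raise ValueError(f"unknown growth forms: {sorted(bad)}")
        w = (gf == "woody").astype(float)
        self.endog = np.log10(v)
        self.exog = pd.DataFrame({
            "intercept": np.ones_like(s),
            strategy_name: s,
            "woody": w,
            f"{strategy_name}:woody": s * w,
        })
        self.strategy_name = strategy_name
        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            aliased = self._aliased_terms()
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    def _aliased_terms(self) -> list[str]:
        X = self.exog.to_numpy()
        names = list(self.exog.columns)
        aliased, kept = [], []
        for j, name in enumerate(names):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(name)
        return aliased

    @classmethod
    def from_dataframe(cls, profiles: pd.DataFrame, trait: str = "mean_lma",
                       strategy: str = "resprouter",
                       group_col: str = "growth_form") -> "LeafTraitModel":
        sub = profiles.dropna(subset=[trait, strategy, group_col])
        sub = sub[sub[group_col].isin(["woody", "herbaceous"])]
        return cls(sub[trait].to_numpy(), sub[strategy].astype(bool).to_numpy(),
                   sub[group_col].to_numpy(), strategy_name=strategy)

    def fit(self) -> "LeafTraitResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return LeafTraitResults(self, res)


@dataclasses.dataclass
class LeafTraitResults:
    model: LeafTraitModel
    _res: object

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    @property
    def df_resid(self) -> int:
        return int(self._res.df_resid)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        ci.columns = ["low", "high"]
        return ci

    def cell_means(self) -> pd.DataFrame:
        """Estimated marginal means of the four strategy x growth-form cells."""
        rows = []
        for gf, w in (("herbaceous", 0.0), ("woody", 1.0)):
            for strat, s in ((False, 0.0), (True, 1.0)):
                L = np.array([1.0, s, w, s * w])
                est = float(L @ self.params.to_numpy())
                se = float(np.sqrt(L @ self._res.cov_params().to_numpy() @ L))
                rows.append({"growth_form": gf, "strategy": strat,
                             "emmean": est, "se": se})
        return pd.DataFrame(rows)

    def emm_pairwise(self, adjust: str = "tukey",
                     family: str = "within_group") -> list[EmmContrast]:
        """Pairwise contrasts of cell means, strategy-present minus absent.

        ``family="within_group"`` compares the two strategy means inside
        each growth form (two separate families of two means each, as when
        contrasts are conditioned on the group); ``family="all"`` treats
        all four cell means as one family. Tukey uses the studentized-range
        distribution over the family's means; Bonferroni multiplies the
        unadjusted p by the number of contrasts in the family.
        """
        if adjust not in {"tukey", "bonferroni", "none"}:
            raise ValueError(f"unknown adjustment {adjust!r}")
        if family not in {"within_group", "all"}:
            raise ValueError(f"unknown family {family!r}")
        cov = self._res.cov_params().to_numpy()
        beta = self.params.to_numpy()
        df = self.df_resid

        def one(gf_w: float, label: str, k_means: int, n_contrasts: int):
            # L for (strategy TRUE - strategy FALSE) at given growth form
            L = np.array([0.0, 1.0, 0.0, gf_w])
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se
            if adjust == "tukey" and k_means > 2:
                p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2),
                                                     k_means, df))
            else:
                p = float(2 * stats.t.sf(abs(t), df))
                if adjust == "bonferroni":
                    p = min(1.0, p * n_contrasts)
            return EmmContrast(contrast=label, estimate=est, se=se, df=df,
                               t=t, p_adjusted=p, adjust=adjust)

        name = self.model.strategy_name
        if family == "within_group":
            k_means, n_con = 2, 1
        else:
            k_means, n_con = 4, 2
        return [
            one(0.0, f"herbaceous: {name} TRUE - FALSE", k_means, n_con),
            one(1.0, f"woody: {name} TRUE - FALSE", k_means, n_con),
        ]

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        tab = pd.DataFrame({
            "estimate": self.params,
            "ci_low": ci["low"],
            "ci_high": ci["high"],
            "p": self.pvalues,
        })
        tab.attrs["nobs"] = self.nobs
        tab.attrs["rsquared"] = self.rsquared
        tab.attrs["rsquared_adj"] = self.rsquared_adj
        return tab


# --------------------------------------------------------------------------
# functional wrappers (the pipeline surface)
# --------------------------------------------------------------------------

def fit_logistic_quadratic(table: pd.DataFrame, response: str = "resprouter",
                           interaction: bool = True,
                           group_col: str | None = "growth_form"
                           ) -> FireResponseResults:
    return FireResponseModel.from_dataframe(
        table, response=response, group_col=group_col, interaction=interaction
    ).fit()


def odds_ratios(fit: FireResponseResults) -> pd.DataFrame:
    if not fit.converged:
        raise ValueError("fit did not converge; odds ratios unreliable")
    return fit.odds_ratios()


def predict_curve(fit: FireResponseResults, fires_per_century,
                  group: str = "herbaceous") -> pd.DataFrame:
    return fit.predict_curve(fires_per_century, group=group)


def quadratic_peak(fit: FireResponseResults, group: str = "herbaceous") -> dict:
    return fit.peak(group)


def fit_leaf_trait_lm(profiles: pd.DataFrame, trait: str = "mean_lma",
                      strategy: str = "resprouter") -> LeafTraitResults:
    return LeafTraitModel.from_dataframe(profiles, trait=trait,
                                         strategy=strategy).fit()


def emm_pairwise(fit: LeafTraitResults, adjust: str = "tukey",
                 family: str = "within_group") -> list[EmmContrast]:
    return fit.emm_pairwise(adjust=adjust, family=family)
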