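"""Body-mass accounting and AICc multimodel inference.

For capital breeders, mass gained over the foraging season is the proxy
for foraging success: the gain rate is expressed as percent of initial
mass per day, and mothers weighed a few days after giving birth have
their parturition-day mass back-estimated from the average lactation mass
loss (4.1 kg per day).

The inference layer is information-theoretic: candidate (mixed) linear
models are compared with the small-sample Akaike criterion

    AICc = -2 LL + 2K + 2K(K+1)/(n - K - 1),

delta-AICc, Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2) and the
evidence ratio between two models; goodness of fit of mixed models is
summarised by marginal / conditional R² (variance explained by fixed
effects alone vs fixed plus random effects).  Model fitting itself is a
pluggable backend behind :func:`fit_candidates` — by default statsmodels
MixedLM with full ML (so likelihoods are comparable across fixed-effect
structures) or OLS when no grouping is given — and everything downstream
consumes only (LL, K, n, variance components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CandidateModel",
    "SelectionTable",
    "parturition_mass",
    "mass_gain_rate",
    "aicc",
    "delta_and_weights",
    "evidence_ratio",
    "r2_glmm",
    "median_mad",
    "fit_candidates",
    "build_selection_table",
]

#: Average maternal mass loss during lactation, kg per day.
LACTATION_LOSS_KG_PER_DAY = 4.1


# ---------------------------------------------------------------------------
# body mass


def parturition_mass(
    measured_mass: float, days_postpartum: float, rate: float = LACTATION_LOSS_KG_PER_DAY
) -> float:
    """Back-estimate mass on the day of parturition from a later weighing."""
    if days_postpartum < 0:
        raise ValueError("days_postpartum must be >= 0")
    return measured_mass + rate * days_postpartum


def mass_gain_rate(initial: float, final: float, days: float) -> float:
    """Daily mass gain as percent of initial mass: 100·(final−initial)/(initial·days)."""
    if days <= 0:
        raise ValueError("days must be positive")
    if initial <= 0:
        raise ValueError("initial mass must be positive")
    return 100.0 * (final - initial) / (initial * days)


# ---------------------------------------------------------------------------
# information criteria


def aicc(ll: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def delta_and_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """ΔAICc from the best model and normalised Akaike weights."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    rel = np.exp(-delta / 2.0)
    return delta, rel / rel.sum()


def evidence_ratio(w_i: float | None = None, w_j: float | None = None, delta: float | None = None) -> float:
    """Evidence ratio between two models: w_i/w_j, equivalently exp(Δ/2).

    ``delta`` is the AICc difference of model j above model i.
    """
    if delta is not None:
        return float(np.exp(delta / 2.0))
    if w_i is None or w_j is None:
        raise ValueError("provide either delta or both weights")
    if w_j <= 0 or w_i <= 0:
        raise ValueError("weights must be positive")
    return float(w_i / w_j)


def r2_glmm(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R² of a mixed model from variance components."""
    parts = (var_fixed, var_random, var_resid)
    if any(v < 0 for v in parts):
        raise ValueError("variance components must be >= 0")
    total = sum(parts)
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random) / total


def median_mad(values) -> tuple[float, float]:
    """Sample median and raw median absolute deviation (no 1.4826 scaling)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


# ---------------------------------------------------------------------------
# candidate models


@dataclass
class CandidateModel:
    """One fitted candidate: everything AICc ranking and R² need."""

    label: str
    formula: str
    k: int                      # fixed coefficients + variance parameters
    ll: float                   # maximised (ML) log-likelihood
    n: int
    var_fixed: float
    var_random: float
    var_resid: float
    failed: bool = False
    message: str = ""

    @property
    def aicc(self) -> float:
        return aicc(self.ll, self.k, self.n)

    @property
    def r2(self) -> tuple[float, float]:
        return r2_glmm(self.var_fixed, self.var_random, self.var_resid)


def fit_candidates(
    data: pd.DataFrame,
    specs: dict[str, str],
    response: str,
    group: str | None = None,
) -> list[CandidateModel]:
    """Fit every candidate fixed-effect structure in ``specs``.

    ``specs`` maps a display label to a right-hand-side formula (patsy
    syntax, e.g. ``"Bm + Sn + Sx + Bm:Sx"``; ``"1"`` is the intercept-only
    model).  With ``group`` set, a random intercept per group is added and
    the model is fitted by full ML; otherwise an ordinary linear model is
    fitted.  K counts fixed coefficients plus the residual variance plus
    (if present) the random-intercept variance.  A model that fails to fit
    is returned flagged rather than aborting the set.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if group is not None and group not in data.columns:
        raise ValueError(f"grouping column {group!r} not in data")
    out: list[CandidateModel] = []
    for label, rhs in specs.items():
        formula = f"{response} ~ {rhs}"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if group is not None:
                    model = smf.mixedlm(formula, data=data, groups=data[group])
                    try:
                        fit = model.fit(reml=False, maxiter=500)
                    except (np.linalg.LinAlgError, ValueError):
                        fit = model.fit(reml=False, maxiter=1000, method="powell")
                    n_fixed = len(fit.fe_params)
                    var_random = float(fit.cov_re.iloc[0, 0])
                    var_resid = float(fit.scale)
                    fitted_fixed = np.asarray(model.exog @ fit.fe_params)
                    k = n_fixed + 2  # + random-intercept variance + residual variance
                    ll = float(fit.llf)
                else:
                    fit = smf.ols(formula, data=data).fit()
                    n_fixed = len(fit.params)
                    var_random = 0.0
                    var_resid = float(fit.ssr / fit.nobs)  # ML residual variance
                    fitted_fixed = np.asarray(fit.fittedvalues)
                    k = n_fixed + 1  # + residual variance
                    ll = float(fit.llf)
            var_fixed = float(np.var(fitted_fixed, ddof=1)) if len(fitted_fixed) > 1 else 0.0
            out.append(
                CandidateModel(
                    label=label, formula=formula, k=k, ll=ll, n=int(fit.nobs),
                    var_fixed=var_fixed, var_random=var_random, var_resid=var_resid,
                )
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            out.append(
                CandidateModel(
                    label=label, formula=formula, k=0, ll=float("nan"), n=len(data),
                    var_fixed=0.0, var_random=0.0, var_resid=0.0,
                    failed=True, message=str(exc),
                )
            )
    return out


#: The standard candidate set over body mass (Bm), season (Sn) and sex (Sx)
#: used for home-range and core-area model selection.
HOME_RANGE_CANDIDATES: dict[str, str] = {
    "Bm + Sn + Sx + Bm*Sx": "Bm + Sn + Sx + Bm:Sx",
    "Bm + Sn + Sx": "Bm + Sn + Sx",
    "Sn + Sx": "Sn + Sx",
    "Bm + Sn + Sx + Sn*Sx + Bm*Sx": "Bm + Sn + Sx + Sn:Sx + Bm:Sx",
    "Bm + Sn + Sx + Sn*Sx": "Bm + Sn + Sx + Sn:Sx",
    "Sn + Sx + Sn*Sx": "Sn + Sx + Sn:Sx",
    "Sn": "Sn",
    "Bm + Sn": "Bm + Sn",
    "Bm + Sx + Bm*Sx": "Bm + Sx + Bm:Sx",
    "Bm + Sx": "Bm + Sx",
    "Sx": "Sx",
    "~": "1",
    "Bm": "Bm",
}


# ---------------------------------------------------------------------------
# selection tables


@dataclass
class SelectionTable:
    """AICc ranking of a candidate set.

    ``table`` columns: Model, K, AICc, dAICc, w, LL, rank — AICc
    ascending.  ``evidence_ratio_next`` is the ER of the top model against
    the runner-up.
    """

    table: pd.DataFrame

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]

    @property
    def evidence_ratio_next(self) -> float:
        if len(self.table) < 2:
            return float("nan")
        return evidence_ratio(delta=float(self.table["dAICc"].iloc[1]))

    def er(self, label_i: str, label_j: str) -> float:
        t = self.table.set_index("Model")
        return evidence_ratio(w_i=float(t.loc[label_i, "w"]), w_j=float(t.loc[label_j, "w"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_selection_table(models: list[CandidateModel]) -> SelectionTable:
    """Rank fitted candidates by AICc; failed fits are dropped."""
    ok = [m for m in models if not m.failed]
    if not ok:
        raise ValueError("no successfully fitted models")
    a = np.array([m.aicc for m in ok])
    delta, w = delta_and_weights(a)
    df = pd.DataFrame({
        "Model": [m.label for m in ok],
        "K": [m.k for m in ok],
        "AICc": a,
        "dAICc": delta,
        "w": w,
        "LL": [m.ll for m in ok],
    })
    df = df.sort_values(["AICc", "K", "Model"], kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    return SelectionTable(table=df)
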