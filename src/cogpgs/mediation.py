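"""Mediation of the polygenic-score effect on cognitive decline by binary
amyloid status.

Point estimates come from three regressions on complete subjects:

    (i)   logistic:  Aβ  ~ score + covariates            -> a
    (ii)  OLS:       slope ~ score + covariates          -> c   (total)
    (iii) OLS:       slope ~ score + Aβ + covariates     -> c', b

The indirect (mediated) effect is the difference c − c' and the proportion
mediated (c − c')/c.  Uncertainty comes from a subject-level percentile
bootstrap (resampling whole subjects with replacement, never observations
within a subject — the slope outcome is already one row per subject).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import ScoreSet


def _as_binary(ab_status: pd.Series) -> pd.Series:
    s = pd.Series(ab_status)
    if s.dtype == object:
        mapped = s.map({"positive": 1.0, "negative": 0.0})
        if mapped.isna().any() and not s.isna().any():
            raise ValueError("amyloid status strings must be positive/negative")
        s = mapped
    return s.astype(float)


def _standardize(x: pd.Series) -> pd.Series:
    v = x.to_numpy(dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("predictor has zero variance")
    return pd.Series((v - v.mean()) / sd, index=x.index, name=x.name)


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(X.T @ X, X.T @ y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(X, y, rcond=None)[0]


@dataclass
class MediationResult:
    """Mediation paths with bootstrap confidence intervals.

    ``a`` is on the log-odds scale (per SD of score); ``b``, ``c``,
    ``c_prime`` and ``indirect`` are in units of the (transformed) outcome
    per SD of score.  ``proportion_mediated`` is (c − c')/c, undefined
    (NaN, CI suppressed) when the total effect is numerically zero.
    """

    a: float
    a_p: float
    b: float
    b_p: float
    c: float
    c_p: float
    c_prime: float
    c_prime_p: float
    indirect: float
    proportion_mediated: float
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float] | None
    n_boot: int
    seed: int
    n: int

    def __post_init__(self) -> None:
        if abs(self.indirect - (self.c - self.c_prime)) > 1e-12:
            raise ValueError("indirect effect must equal c - c' exactly")

    @property
    def significant_indirect(self) -> bool:
        lo, hi = self.ci_indirect
        return not (lo <= 0.0 <= hi)

    def summary(self) -> str:
        """Text path diagram: score -> amyloid -> cognitive slope."""
        pm = (
            f"{100 * self.proportion_mediated:.1f}%"
            if np.isfinite(self.proportion_mediated)
            else "undefined"
        )
        lines = [
            "             Aβ status",
            f"      a={self.a:+.3f} /      \\ b={self.b:+.3f}",
            "            /        \\",
            f"  score ----------------> slope",
            f"      c  = {self.c:+.4f} (p={self.c_p:.3g})   total",
            f"      c' = {self.c_prime:+.4f} (p={self.c_prime_p:.3g})   direct",
            f"      c-c' = {self.indirect:+.4f} "
            f"[95% CI {self.ci_indirect[0]:+.4f}, {self.ci_indirect[1]:+.4f}]"
            f"   mediated ({pm} mediation)",
            f"      n={self.n}, bootstraps={self.n_boot}, seed={self.seed}",
        ]
        return "\n".join(lines)


def mediate(
    score,
    ab_status: pd.Series,
    slope: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Difference-method mediation with percentile bootstrap CIs.

    ``score`` is a ScoreSet or Series (standardized internally); ``slope``
    is the (inverse-normal-transformed) per-subject outcome; ``ab_status``
    a binary mediator with both classes present.  Identical seeds give
    bit-identical CIs.
    """
    if isinstance(score, ScoreSet):
        z = score.scores
    else:
        z = pd.Series(score)
    df = pd.DataFrame({"z": z, "ab": _as_binary(ab_status), "y": pd.Series(slope)})
    cov_cols: list[str] = []
    if covariates is not None and len(covariates.columns):
        df = df.join(covariates, how="inner")
        cov_cols = list(covariates.columns)
    df = df.dropna()
    n = len(df)
    if n < len(cov_cols) + 4:
        raise ValueError("too few complete subjects for mediation")
    classes = df["ab"].unique()
    if len(classes) < 2:
        raise ValueError("mediator has a single class; mediation undefined")
    df["z"] = _standardize(df["z"])

    C = df[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((n, 0))
    ones = np.ones((n, 1))
    zv = df["z"].to_numpy()[:, None]
    ab = df["ab"].to_numpy()[:, None]
    y = df["y"].to_numpy(dtype=float)
    X_total = np.hstack([ones, zv, C])            # column 1 -> c
    X_direct = np.hstack([ones, zv, ab, C])       # column 1 -> c', column 2 -> b

    # path a: logistic mediator model (reported, not used in c - c')
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit = sm.Logit(df["ab"].to_numpy(), X_total).fit(disp=0, maxiter=200)
        a, a_p = float(logit.params[1]), float(logit.pvalues[1])
    except Exception:
        warnings.warn("mediator model did not fit (separation?); path a missing")
        a, a_p = float("nan"), float("nan")

    fit_total = sm.OLS(y, X_total).fit()
    fit_direct = sm.OLS(y, X_direct).fit()
    c, c_p = float(fit_total.params[1]), float(fit_total.pvalues[1])
    c_prime, cp_p = float(fit_direct.params[1]), float(fit_direct.pvalues[1])
    b, b_p = float(fit_direct.params[2]), float(fit_direct.pvalues[2])
    indirect = c - c_prime
    c_defined = abs(c) > 1e-8
    pm = indirect / c if c_defined else float("nan")
    if not c_defined:
        warnings.warn("total effect ~ 0: proportion mediated undefined")

    rng = np.random.default_rng(seed)
    boot_ind = np.empty(n_boot)
    boot_pm = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        cb = _ols_beta(X_total[idx], y[idx])[1]
        cpb = _ols_beta(X_direct[idx], y[idx])[1]
        boot_ind[i] = cb - cpb
        boot_pm[i] = (cb - cpb) / cb if abs(cb) > 1e-8 else np.nan
    ci_ind = tuple(np.percentile(boot_ind, [2.5, 97.5]))
    ci_pm = None
    if c_defined:
        ok = np.isfinite(boot_pm)
        if ok.sum() >= max(10, n_boot // 2):
            ci_pm = tuple(np.percentile(boot_pm[ok], [2.5, 97.5]))

    return MediationResult(
        a=a,
        a_p=a_p,
        b=b,
        b_p=b_p,
        c=c,
        c_p=c_p,
        c_prime=c_prime,
        c_prime_p=cp_p,
        indirect=indirect,
        proportion_mediated=pm,
        ci_indirect=(float(ci_ind[0]), float(ci_ind[1])),
        ci_proportion=(
            (float(ci_pm[0]), float(ci_pm[1])) if ci_pm is not None else None
        ),
        n_boot=n_boot,
        seed=seed,
        n=n,
    )
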