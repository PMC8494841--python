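"""Longitudinal trajectories and covariate-adjusted association tests.

Stage one fits a linear mixed model to the longitudinal cognitive outcome
(``score ~ 1 + time`` with correlated random intercept and slope per
subject, maximum likelihood) and extracts the per-subject conditional modes
(BLUPs).  Stage two rank-based inverse-normal transforms the extracted
intercepts/slopes and regresses them on a standardized polygenic score plus
covariates by OLS, with Bonferroni control over the score-threshold family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .scoring import ScoreSet


@dataclass
class RandomEffects:
    """Mixed-model output: fixed effects, variance components and
    per-subject conditional intercepts/slopes.

    ``effects`` is indexed by subject with columns ``intercept``/``slope``
    (fixed effect + conditional deviation, i.e. the subject-specific line)
    and ``intercept_dev``/``slope_dev`` (the conditional modes themselves).
    """

    effects: pd.DataFrame = field(repr=False)
    fixed_intercept: float
    fixed_slope: float
    se_fixed_slope: float
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_residual: float
    converged: bool
    n_subjects: int
    n_observations: int
    n_excluded_subjects: int = 0

    def __post_init__(self) -> None:
        if self.var_residual < -1e-12:
            raise ValueError("residual variance must be non-negative")
        if self.converged and not np.isfinite(
            self.effects[["intercept", "slope"]].to_numpy()
        ).all():
            raise ValueError("non-finite conditional modes in a converged fit")


def fit_trajectories(
    data: pd.DataFrame,
    outcome: str = "score",
    subject_col: str = "subject_id",
    time_col: str = "time_years",
    min_visits: int = 3,
) -> RandomEffects:
    """Fit ``outcome ~ 1 + time`` with correlated random intercept and slope
    per subject by maximum likelihood and return the conditional modes.

    Subjects with fewer than ``min_visits`` observations are excluded with a
    warning.  Degenerate noise-free data (every subject exactly on a line)
    are detected and solved in closed form — the ML limit with zero residual
    variance, where the conditional modes equal each subject's own
    least-squares line.  Non-convergence is flagged on the result, never
    silently ignored.
    """
    df = data[[subject_col, time_col, outcome]].dropna()
    counts = df.groupby(subject_col, sort=False)[outcome].size()
    keep = counts.index[counts >= min_visits]
    n_excl = int((counts < min_visits).sum())
    if n_excl:
        warnings.warn(f"excluded {n_excl} subjects with <{min_visits} visits")
    df = df[df[subject_col].isin(keep)]
    if df.empty:
        raise ValueError("no subjects with enough visits")
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to model")

    subjects = pd.unique(df[subject_col])
    # per-subject OLS lines; doubles as the noise-free closed form
    coefs = np.empty((len(subjects), 2))
    max_resid = 0.0
    for i, s in enumerate(subjects):
        sub = df[df[subject_col] == s]
        t = sub[time_col].to_numpy(dtype=float)
        ys = sub[outcome].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(t), t])
        b, *_ = np.linalg.lstsq(X, ys, rcond=None)
        coefs[i] = b
        max_resid = max(max_resid, float(np.abs(ys - X @ b).max()))

    scale_ref = max(1.0, float(np.std(y)))
    if max_resid < 1e-8 * scale_ref:
        # exact-fit limit: ML residual variance is zero and the conditional
        # modes coincide with the per-subject lines
        fi, fs = coefs.mean(axis=0)
        cov = np.cov(coefs.T, ddof=0) if len(subjects) > 1 else np.zeros((2, 2))
        cov = np.atleast_2d(cov)
        eff = pd.DataFrame(
            {
                "intercept": coefs[:, 0],
                "slope": coefs[:, 1],
                "intercept_dev": coefs[:, 0] - fi,
                "slope_dev": coefs[:, 1] - fs,
            },
            index=pd.Index(subjects, name=subject_col),
        )
        se_fs = float(np.sqrt(cov[1, 1] / len(subjects))) if len(subjects) > 1 else 0.0
        return RandomEffects(
            effects=eff,
            fixed_intercept=float(fi),
            fixed_slope=float(fs),
            se_fixed_slope=se_fs,
            var_intercept=float(cov[0, 0]),
            var_slope=float(cov[1, 1]),
            cov_intercept_slope=float(cov[0, 1]),
            var_residual=0.0,
            converged=True,
            n_subjects=len(subjects),
            n_observations=len(df),
            n_excluded_subjects=n_excl,
        )

    model_df = pd.DataFrame(
        {
            "y": y,
            "time": df[time_col].to_numpy(dtype=float),
            "subject": df[subject_col].to_numpy(),
        }
    )
    md = sm.MixedLM.from_formula(
        "y ~ time", groups="subject", re_formula="~time", data=model_df
    )
    res = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "cg", "powell"):
            try:
                res = md.fit(reml=False, method=method, maxiter=2000)
            except Exception:
                continue
            if getattr(res, "converged", False):
                converged = True
                break
    if res is None:
        raise RuntimeError("mixed-model fit failed under every optimizer")
    if not converged:
        warnings.warn("mixed model did not converge; estimates flagged")

    fe = res.fe_params
    fi, fs = float(fe["Intercept"]), float(fe["time"])
    re = res.random_effects
    rows = []
    for s in subjects:
        r = re[s]
        rows.append((float(r.iloc[0]), float(r.iloc[1])))
    dev = np.array(rows)
    eff = pd.DataFrame(
        {
            "intercept": fi + dev[:, 0],
            "slope": fs + dev[:, 1],
            "intercept_dev": dev[:, 0],
            "slope_dev": dev[:, 1],
        },
        index=pd.Index(subjects, name=subject_col),
    )
    cov_re = np.asarray(res.cov_re)
    return RandomEffects(
        effects=eff,
        fixed_intercept=fi,
        fixed_slope=fs,
        se_fixed_slope=float(res.bse_fe["time"]),
        var_intercept=float(cov_re[0, 0]),
        var_slope=float(cov_re[1, 1]),
        cov_intercept_slope=float(cov_re[0, 1]),
        var_residual=float(res.scale),
        converged=converged,
        n_subjects=len(subjects),
        n_observations=len(df),
        n_excluded_subjects=n_excl,
    )


def int_transform(values) -> np.ndarray:
    """Rank-based inverse normal transformation with the Blom offset.

    Maps value of rank r (average ranks for ties) among n observations to
    Φ⁻¹((r − 3/8) / (n + 1/4)).  Strictly monotone in the input, hence
    invariant to any strictly increasing transform of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values cannot be rank-transformed")
    r = stats.rankdata(x, method="average")
    c = 3.0 / 8.0
    return stats.norm.ppf((r - c) / (x.size - 2 * c + 1))


@dataclass(frozen=True)
class AssociationResult:
    """One covariate-adjusted association test."""

    predictor: str
    outcome: str
    beta: float
    se: float
    p: float
    p_bonferroni: float
    family_size: int
    n: int
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")


def bonferroni(p: float, m: int) -> float:
    """Family-wise corrected p-value: min(1, p*m)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * m)


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    rank = np.linalg.matrix_rank(A / norms, tol=1e-8)
    if rank < A.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(A / norms, j, axis=1)
            if np.linalg.matrix_rank(sub, tol=1e-8) == rank:
                bad.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _predictor_series(predictor, name: str | None) -> tuple[pd.Series, str]:
    if isinstance(predictor, ScoreSet):
        s = predictor.scores
        label = name or predictor.label
    else:
        s = pd.Series(predictor)
        label = name or (s.name or "score")
    z = s.to_numpy(dtype=float)
    sd = z.std(ddof=1)
    if sd == 0:
        raise ValueError("predictor has zero variance")
    return pd.Series((z - z.mean()) / sd, index=s.index, name=label), label


def _assemble(
    predictor_z: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None,
    extra: dict[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.Series, int]:
    frames = {"__pred__": predictor_z}
    if extra:
        frames.update(extra)
    df = pd.DataFrame(frames)
    if covariates is not None and len(covariates.columns):
        df = df.join(covariates, how="inner")
    df = df.join(outcome.rename("__y__"), how="inner")
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subjects with missing data")
    if len(df) < df.shape[1] + 1:
        raise ValueError("too few complete subjects for the design")
    y = df.pop("__y__")
    X = sm.add_constant(df, has_constant="add")
    _check_full_rank(X)
    return X, y, n_dropped


def associate(
    scoreset,
    effects: RandomEffects,
    target: str,
    covariates: pd.DataFrame | None = None,
    family_size: int = 7,
    baseline_scores: pd.Series | None = None,
    predictor_name: str | None = None,
) -> AssociationResult:
    """OLS of the inverse-normal-transformed conditional ``target``
    (``"intercept"`` or ``"slope"``) on the standardized score plus
    covariates.

    The baseline test score, when supplied, enters as a covariate only for
    the slope target — for the intercept it is essentially the outcome
    itself.  Returns the score coefficient with its Bonferroni-corrected
    p-value at the given family size.
    """
    if target not in ("intercept", "slope"):
        raise ValueError("target must be 'intercept' or 'slope'")
    z, label = _predictor_series(scoreset, predictor_name)
    raw = effects.effects[target]
    out = pd.Series(int_transform(raw), index=raw.index)
    cov = covariates.copy() if covariates is not None else pd.DataFrame(index=raw.index)
    if baseline_scores is not None and target == "slope":
        cov = cov.join(baseline_scores.rename("baseline_score"), how="inner")
    X, y, _ = _assemble(z, out, cov)
    fit = sm.OLS(y, X).fit()
    p = float(fit.pvalues["__pred__"])
    return AssociationResult(
        predictor=label,
        outcome=target,
        beta=float(fit.params["__pred__"]),
        se=float(fit.bse["__pred__"]),
        p=p,
        p_bonferroni=bonferroni(p, family_size),
        family_size=family_size,
        n=int(fit.nobs),
        covariates=tuple(c for c in X.columns if c not in ("const", "__pred__")),
    )


def interaction_test(
    scoreset,
    effects: RandomEffects,
    target: str,
    ab_status: pd.Series,
    covariates: pd.DataFrame | None = None,
    family_size: int = 1,
    baseline_scores: pd.Series | None = None,
) -> AssociationResult:
    """Test the score x amyloid-status product term.

    Both main effects accompany the product term; the returned result is
    the coefficient test for the interaction.  A single-class amyloid
    vector makes the design rank deficient and raises.
    """
    if target not in ("intercept", "slope"):
        raise ValueError("target must be 'intercept' or 'slope'")
    z, label = _predictor_series(scoreset, None)
    ab = pd.Series(ab_status).astype(float)
    inter = (z * ab.reindex(z.index)).rename("__inter__")
    raw = effects.effects[target]
    out = pd.Series(int_transform(raw), index=raw.index)
    cov = covariates.copy() if covariates is not None else pd.DataFrame(index=raw.index)
    if baseline_scores is not None and target == "slope":
        cov = cov.join(baseline_scores.rename("baseline_score"), how="inner")
    X, y, _ = _assemble(z, out, cov, extra={"ab_status": ab, "__inter__": inter})
    fit = sm.OLS(y, X).fit()
    p = float(fit.pvalues["__inter__"])
    return AssociationResult(
        predictor=f"{label} x ab_status",
        outcome=target,
        beta=float(fit.params["__inter__"]),
        se=float(fit.bse["__inter__"]),
        p=p,
        p_bonferroni=bonferroni(p, family_size),
        family_size=family_size,
        n=int(fit.nobs),
        covariates=tuple(
            c for c in X.columns if c not in ("const", "__pred__", "__inter__")
        ),
    )
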