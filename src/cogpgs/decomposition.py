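"""Heuristic decomposition of a polygenic score into amyloid-dependent and
amyloid-independent variant subsets.

The scan works in three passes.  A leave-one-out pass rebuilds the score
n times with one variant removed (weights fixed, denominator reflecting the
reduced count) and records the p-value of the logistic score -> amyloid
association: removal of an amyloid-independent variant sharpens the
association (p drops), removal of an amyloid-dependent variant weakens it
(p rises).  A nested pass ranks variants by that leave-one-out p-value
(ascending for the independent side, descending for the dependent side) and
evaluates the top-k score for every k against the cognitive slope, with and
without amyloid adjustment, plus a bootstrap mediation significance flag.
Selection then returns the largest k whose score still behaves as fully
independent (no significant mediation, association survives amyloid
adjustment) or fully dependent (association lost under adjustment); a final
refinement pass tags dependent-set variants whose removal restores the
adjusted association as "partial".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import GenotypeMatrix
from .mediation import _as_binary, _standardize, mediate
from .scoring import ScoreSet, score, standardize_scores


@dataclass(frozen=True)
class AbAssociation:
    """Logistic association between a predictor and binary amyloid status."""

    beta: float
    p: float
    separation: bool = False


def _logit_assoc(
    predictor: pd.Series, ab_status: pd.Series, covariates: pd.DataFrame | None
) -> AbAssociation:
    df = pd.DataFrame({"z": predictor, "ab": _as_binary(ab_status)})
    cov_cols: list[str] = []
    if covariates is not None and len(covariates.columns):
        df = df.join(covariates, how="inner")
        cov_cols = list(covariates.columns)
    df = df.dropna()
    if df["ab"].nunique() < 2:
        raise ValueError("amyloid status has a single class")
    df["z"] = _standardize(df["z"])
    X = sm.add_constant(df[["z"] + cov_cols], has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(df["ab"], X).fit(disp=0, maxiter=200)
        beta = float(fit.params["z"])
        se = float(fit.bse["z"])
        if abs(beta) > 15 or se > 100:
            return AbAssociation(beta=beta, p=float("nan"), separation=True)
        return AbAssociation(beta=beta, p=float(fit.pvalues["z"]))
    except Exception:
        return AbAssociation(beta=float("nan"), p=float("nan"), separation=True)


def prs_ab_association(
    scoreset, ab_status: pd.Series, covariates: pd.DataFrame | None = None
) -> AbAssociation:
    """Logistic regression of amyloid status on the standardized score plus
    covariates; quasi-complete separation is flagged and p set to missing."""
    z = scoreset.scores if isinstance(scoreset, ScoreSet) else pd.Series(scoreset)
    return _logit_assoc(z, ab_status, covariates)


def per_variant_ab_association(
    dosage: pd.Series, ab_status: pd.Series, covariates: pd.DataFrame | None = None
) -> AbAssociation:
    """Single-variant version with the dosage standardized; monomorphic
    variants (zero variance) raise."""
    return _logit_assoc(pd.Series(dosage), ab_status, covariates)


def loo_scan(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    ab_status: pd.Series,
    covariates: pd.DataFrame | None = None,
    ploidy: int = 2,
) -> pd.DataFrame:
    """Leave-one-out table: for each variant v, the amyloid association of
    the score rebuilt from the remaining n-1 variants (same weights,
    denominator using n-1).

    Output columns: ``id, beta_loo, p_loo, p_full, delta, candidate,
    flagged`` where delta = p_loo - p_full and candidate is "independent"
    when removal lowered the p-value, else "dependent".
    """
    if len(records) < 3:
        raise ValueError("leave-one-out scan needs at least 3 variants")
    full = standardize_scores(score(genotypes, records, ploidy=ploidy))
    p_full = prs_ab_association(full, ab_status, covariates).p
    rows = []
    for i in range(len(records)):
        reduced = records.drop(index=records.index[i]).reset_index(drop=True)
        vid = records.iloc[i]["id"]
        raw = score(genotypes, reduced, ploidy=ploidy)
        if raw.scores.std(ddof=1) == 0:
            warnings.warn(f"reduced score without {vid} has zero variance; flagged")
            rows.append((vid, np.nan, np.nan, True))
            continue
        res = prs_ab_association(standardize_scores(raw), ab_status, covariates)
        rows.append((vid, res.beta, res.p, res.separation))
    out = pd.DataFrame(rows, columns=["id", "beta_loo", "p_loo", "flagged"])
    out["p_full"] = p_full
    out["delta"] = out["p_loo"] - p_full
    out["candidate"] = np.where(out["delta"] < 0, "independent", "dependent")
    out.loc[out["p_loo"].isna(), "candidate"] = "unclassified"
    return out[["id", "beta_loo", "p_loo", "p_full", "delta", "candidate", "flagged"]]


def _ranked_ids(loo_table: pd.DataFrame, order: str) -> list[str]:
    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    tab = loo_table.dropna(subset=["p_loo"]).copy()
    if tab["p_loo"].duplicated().any():
        warnings.warn("ties in leave-one-out p; broken by (|beta|, id)")
    tab["absb"] = tab["beta_loo"].abs()
    tab = tab.sort_values(
        ["p_loo", "absb", "id"],
        ascending=[order == "ascending", False, True],
        kind="mergesort",
    )
    return list(tab["id"])


def rank_and_nest(
    loo_table: pd.DataFrame,
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    ab_status: pd.Series,
    slope: pd.Series,
    covariates: pd.DataFrame | None = None,
    order: str = "ascending",
    ploidy: int = 2,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested-score scan: build the top-k score for k = 1..n in the chosen
    leave-one-out p-value order and test each against the (transformed)
    slope, unadjusted and amyloid-adjusted, plus a bootstrap mediation
    significance flag for the indirect effect through amyloid.
    """
    ranked = _ranked_ids(loo_table, order)
    rec_by_id = records.set_index("id", drop=False)
    ab = _as_binary(ab_status)
    rows = []
    for k in range(1, len(ranked) + 1):
        ids = ranked[:k]
        sub = rec_by_id.loc[ids].reset_index(drop=True)
        raw = score(genotypes, sub, ploidy=ploidy)
        if raw.scores.std(ddof=1) == 0:
            rows.append(
                {
                    "k": k, "variants": ",".join(ids), "beta_unadj": np.nan,
                    "p_unadj": np.nan, "beta_adj": np.nan, "p_adj": np.nan,
                    "indirect": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                    "mediation_significant": False,
                }
            )
            continue
        z = standardize_scores(raw).scores
        med = mediate(z, ab, slope, covariates, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "k": k,
                "variants": ",".join(ids),
                "beta_unadj": med.c,
                "p_unadj": med.c_p,
                "beta_adj": med.c_prime,
                "p_adj": med.c_prime_p,
                "indirect": med.indirect,
                "ci_lo": med.ci_indirect[0],
                "ci_hi": med.ci_indirect[1],
                "mediation_significant": med.significant_indirect,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["order"] = order
    return out


def select_independent(nested: pd.DataFrame, alpha: float = 0.05) -> int | None:
    """Largest k whose score shows no significant amyloid mediation while
    remaining associated with the slope both unadjusted and adjusted."""
    if nested.attrs.get("order", "ascending") != "ascending":
        raise ValueError("independent selection expects the ascending-order scan")
    ok = (
        ~nested["mediation_significant"].astype(bool)
        & (nested["p_unadj"] < alpha)
        & (nested["p_adj"] < alpha)
    )
    return _largest_qualifying(nested, ok)


def select_dependent(nested: pd.DataFrame, alpha: float = 0.05) -> int | None:
    """Largest k whose score is associated with the slope unadjusted but
    loses the association when adjusting for amyloid."""
    if nested.attrs.get("order", "descending") != "descending":
        raise ValueError("dependent selection expects the descending-order scan")
    ok = (nested["p_unadj"] < alpha) & (nested["p_adj"] >= alpha)
    return _largest_qualifying(nested, ok)


def _largest_qualifying(nested: pd.DataFrame, ok: pd.Series) -> int | None:
    ks = nested.loc[ok.fillna(False), "k"]
    if ks.empty:
        warnings.warn("no nested model satisfies the selection conditions")
        return None
    k_sel = int(ks.max())
    qualifying = set(ks)
    gaps = [k for k in range(1, k_sel) if k not in qualifying]
    if gaps:
        warnings.warn(
            f"non-contiguous qualification below selected k={k_sel}: "
            f"failing k values {gaps}"
        )
    return k_sel


def refine_partial(
    dependent_ids: list[str],
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    ab_status: pd.Series,
    slope: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    ploidy: int = 2,
) -> dict[str, str]:
    """Split the selected dependent set into fully and partially dependent
    variants: removing a *partial* variant restores significance of the
    amyloid-adjusted slope association of the remaining set."""
    if len(dependent_ids) < 2:
        warnings.warn("dependent set of size <2: refinement skipped")
        return {v: "dependent" for v in dependent_ids}
    rec_by_id = records.set_index("id", drop=False)
    labels = {}
    for v in dependent_ids:
        rest = [u for u in dependent_ids if u != v]
        sub = rec_by_id.loc[rest].reset_index(drop=True)
        raw = score(genotypes, sub, ploidy=ploidy)
        if raw.scores.std(ddof=1) == 0:
            labels[v] = "dependent"
            continue
        z = standardize_scores(raw).scores
        df = pd.DataFrame({"z": z, "ab": _as_binary(ab_status), "y": pd.Series(slope)})
        if covariates is not None and len(covariates.columns):
            df = df.join(covariates, how="inner")
        df = df.dropna()
        X = sm.add_constant(df.drop(columns="y"), has_constant="add")
        p_adj = float(sm.OLS(df["y"], X).fit().pvalues["z"])
        labels[v] = "partial" if p_adj < alpha else "dependent"
    return labels


@dataclass
class DecompositionResult:
    """Full decomposition output: per-variant classes, both nested scans and
    the selected model sizes."""

    per_variant: pd.DataFrame = field(repr=False)
    scan_ascending: pd.DataFrame = field(repr=False)
    scan_descending: pd.DataFrame = field(repr=False)
    k_independent: int | None
    k_dependent: int | None
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.per_variant)
        if self.k_independent is not None and self.k_independent > n:
            raise ValueError("k_independent exceeds variant count")
        if self.k_dependent is not None and self.k_dependent > n:
            raise ValueError("k_dependent exceeds variant count")


def decompose(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    ab_status: pd.Series,
    slope: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    ploidy: int = 2,
    scan_n_boot: int = 200,
    seed: int = 0,
) -> DecompositionResult:
    """Run the full decomposition of one score's variant set.

    Variants in the selected ascending top-k_I are labelled independent;
    variants in the selected descending top-k_D are labelled dependent or
    partial (after refinement, with priority over the independent label if
    the two selections overlap); all remaining variants keep their
    leave-one-out candidate label, so the classes partition the set.
    """
    loo = loo_scan(records, genotypes, ab_status, covariates, ploidy=ploidy)
    common = dict(
        records=records, genotypes=genotypes, ab_status=ab_status, slope=slope,
        covariates=covariates, ploidy=ploidy, n_boot=scan_n_boot, seed=seed,
    )
    scan_asc = rank_and_nest(loo, order="ascending", **common)
    scan_desc = rank_and_nest(loo, order="descending", **common)
    k_i = select_independent(scan_asc, alpha=alpha)
    k_d = select_dependent(scan_desc, alpha=alpha)

    asc_ids = _ranked_ids(loo, "ascending")
    desc_ids = _ranked_ids(loo, "descending")
    classes = dict(zip(loo["id"], loo["candidate"]))
    if k_i:
        for v in asc_ids[:k_i]:
            classes[v] = "independent"
    part_labels: dict[str, str] = {}
    if k_d:
        part_labels = refine_partial(
            desc_ids[:k_d], records, genotypes, ab_status, slope,
            covariates, alpha=alpha, ploidy=ploidy,
        )
        classes.update(part_labels)

    tab = loo.copy()
    tab["rank_ascending"] = tab["id"].map({v: i + 1 for i, v in enumerate(asc_ids)})
    tab["rank_descending"] = tab["id"].map({v: i + 1 for i, v in enumerate(desc_ids)})
    tab["class"] = tab["id"].map(classes)
    return DecompositionResult(
        per_variant=tab,
        scan_ascending=scan_asc,
        scan_descending=scan_desc,
        k_independent=k_i,
        k_dependent=k_d,
        alpha=alpha,
        seed=seed,
    )
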