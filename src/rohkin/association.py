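"""Case-control association of genomic inbreeding with disease risk.

The full-cohort model is a maximum-likelihood logistic regression of the
binary outcome (gallbladder cancer status) on F_ROH together with the
standard confounder set: age and age^2 (age mean-centred before squaring),
biological sex, education (categorical, with an explicit "missing" level),
BMI category (normal <= 25, overweight 25-30, obesity > 30 kg/m^2),
Aymara-Quechua and Mapuche-Huilliche ancestry proportions, and genetic risk
of gallstone disease (a weighted six-variant polygenic risk score).

Scaling conventions: F_ROH and the ancestry proportions enter as
percentages, so their odds ratios are per one percentage point; the PRS
enters as log2(score), so its odds ratio is per doubling of the implied
gallstone-disease risk.  Wald 95% confidence intervals are reported.
Interactions of F_ROH with sex, age, PRS and ancestry can be added, and the
full model can be refitted within strata (sex; age below/at-or-above 60;
PRS below/above its median) to give stratum-specific odds ratios per 1%
F_ROH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_io import EDUCATION_LEVELS, GenotypeMatrix, MISSING, validate_cohort

logger = logging.getLogger(__name__)

ANCESTRY_CATEGORIES = (
    "European",
    "Aymara-Quechua",
    "Aymara-Quechua-European",
    "Mapuche-Huilliche",
    "Mapuche-Huilliche-European",
    "Other admixture",
)

INTERACTION_TERMS = ("sex", "age", "prs", "ancestry")


# ---------------------------------------------------------------------------
# Polygenic risk score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PRSWeights:
    """Effect-allele weights of a polygenic risk score.

    ``variants`` maps variant id -> (effect_allele, weight).  The default
    score for gallstone disease uses six variants; any non-empty set is
    accepted.  Missing genotypes are imputed with the cohort mean dosage of
    the variant.
    """

    variants: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("a PRS needs at least one variant")
        for vid, allele, w in self.variants:
            if not np.isfinite(w):
                raise ValueError(f"variant {vid}: weight must be finite")

    @classmethod
    def from_tsv(cls, path) -> "PRSWeights":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "effect_allele": str})
        return cls(tuple(zip(df["id"], df["effect_allele"], df["weight"].astype(float))))


def compute_prs(g: GenotypeMatrix, weights: PRSWeights) -> np.ndarray:
    """Per-sample weighted dosage score.

    Dosage counts copies of the effect allele; variants absent from ``g``
    are skipped with a log message (at least one must overlap).  A missing
    dosage is replaced by the variant's cohort mean dosage.
    """
    by_id = {vid: j for j, vid in enumerate(g.variants["id"])}
    score = np.zeros(g.n_samples)
    n_used = 0
    for vid, allele, w in weights.variants:
        j = by_id.get(vid)
        if j is None:
            logger.warning("PRS variant %s absent from genotype data; skipped", vid)
            continue
        dos = g.calls[:, j].astype(float)
        dos[g.calls[:, j] == MISSING] = np.nan
        if g.variants.loc[j, "allele_b"] == allele:
            pass
        elif g.variants.loc[j, "allele_a"] == allele:
            dos = 2.0 - dos
        else:
            logger.warning("PRS variant %s: effect allele %s matches neither allele; skipped",
                           vid, allele)
            continue
        mean = np.nanmean(dos)
        dos = np.where(np.isnan(dos), mean, dos)
        score += w * dos
        n_used += 1
    if n_used == 0:
        raise ValueError("no PRS variant overlaps the genotype data")
    return score


# ---------------------------------------------------------------------------
# Ancestry categories
# ---------------------------------------------------------------------------


def ancestry_category(
    aymara_quechua_prop: float, mapuche_huilliche_prop: float, european_prop: float
) -> str:
    """Six-way ancestry category from individual ancestry proportions.

    Rules are applied in order: European > 0.70; Aymara-Quechua > 0.70;
    Aymara-Quechua 0.35-0.70; Mapuche-Huilliche > 0.70; Mapuche-Huilliche
    0.35-0.70; otherwise "Other admixture".
    """
    aq, mh, eur = aymara_quechua_prop, mapuche_huilliche_prop, european_prop
    for prop in (aq, mh, eur):
        if not 0.0 <= prop <= 1.0:
            raise ValueError("ancestry proportions must lie in [0, 1]")
    if eur > 0.70:
        return "European"
    if aq > 0.70:
        return "Aymara-Quechua"
    if 0.35 <= aq <= 0.70:
        return "Aymara-Quechua-European"
    if mh > 0.70:
        return "Mapuche-Huilliche"
    if 0.35 <= mh <= 0.70:
        return "Mapuche-Huilliche-European"
    return "Other admixture"


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Fitted logistic model: per-term odds ratios with Wald 95% CIs."""

    terms: list[str]
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n: int
    converged: bool
    stratum: str = "all"
    log_likelihood: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        finite = (
            np.isfinite(self.odds_ratios)
            & np.isfinite(self.ci_low)
            & np.isfinite(self.ci_high)
        )
        ok = (self.ci_low <= self.odds_ratios + 1e-12) & (
            self.odds_ratios <= self.ci_high + 1e-12
        )
        if not np.all(ok | ~finite):
            raise ValueError("confidence bounds must bracket the odds ratio")

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {
            "or": float(self.odds_ratios[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p_values[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "or": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


def design_matrix(
    cohort: pd.DataFrame, interactions: list[str] | None = None
) -> pd.DataFrame:
    """Build the model design matrix (without intercept) from a cohort table.

    Columns: froh_pct; sex_female; age_c, age_c_sq (centred years);
    education dummies vs the "secondary" baseline; BMI category dummies vs
    normal; aymara_quechua_pctpt / mapuche_huilliche_pctpt (percentage
    points); log2_prs; plus any requested froh x covariate interactions.
    """
    X = pd.DataFrame(index=cohort.index)
    X["froh_pct"] = cohort["f_roh"] * 100.0
    X["sex_female"] = (cohort["sex"] == "female").astype(float)
    age_c = cohort["age"] - cohort["age"].mean()
    X["age_c"] = age_c
    X["age_c_sq"] = age_c**2
    for level in EDUCATION_LEVELS:
        if level == "secondary":
            continue
        X[f"edu_{level}"] = (cohort["education"] == level).astype(float)
    X["bmi_overweight"] = ((cohort["bmi"] > 25) & (cohort["bmi"] <= 30)).astype(float)
    X["bmi_obesity"] = (cohort["bmi"] > 30).astype(float)
    X["aymara_quechua_pctpt"] = cohort["aymara_quechua_pct"] * 100.0
    X["mapuche_huilliche_pctpt"] = cohort["mapuche_huilliche_pct"] * 100.0
    X["log2_prs"] = np.log2(cohort["gsd_prs"])
    for term in interactions or []:
        if term == "sex":
            X["froh_x_female"] = X["froh_pct"] * X["sex_female"]
        elif term == "age":
            X["froh_x_age"] = X["froh_pct"] * X["age_c"]
        elif term == "prs":
            X["froh_x_log2prs"] = X["froh_pct"] * X["log2_prs"]
        elif term == "ancestry":
            X["froh_x_aymara"] = X["froh_pct"] * X["aymara_quechua_pctpt"]
            X["froh_x_mapuche"] = X["froh_pct"] * X["mapuche_huilliche_pctpt"]
        else:
            raise ValueError(
                f"unknown interaction {term!r}; choose from {INTERACTION_TERMS}"
            )
    return X


def _fit_logistic(
    y: np.ndarray, X: pd.DataFrame, n: int, stratum: str
) -> AssociationResult:
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    converged = True
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=False, maxiter=200, method="newton")
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=False, maxiter=500, method="bfgs")
        converged = bool(fit.mle_retvals.get("converged", False))
    if not converged:
        logger.warning("logistic fit did not converge (stratum=%s); "
                       "possible separation -- interpret with care", stratum)
    params = fit.params
    ci = fit.conf_int()
    return AssociationResult(
        terms=list(Xc.columns),
        odds_ratios=np.exp(np.asarray(params)),
        ci_low=np.exp(np.asarray(ci)[:, 0]),
        ci_high=np.exp(np.asarray(ci)[:, 1]),
        p_values=np.asarray(fit.pvalues),
        n=n,
        converged=converged,
        stratum=stratum,
        log_likelihood=float(fit.llf),
    )


def fit_gbc_model(
    cohort: pd.DataFrame,
    interactions: list[str] | None = None,
    stratum_label: str = "all",
) -> AssociationResult:
    """Fit the full-cohort logistic model (see module docstring).

    With ``interactions``, F_ROH x covariate product terms are added and a
    likelihood-ratio test of all interaction terms against the main-effects
    model is stored in ``result.extra['lrt_interactions']``.
    """
    validate_cohort(cohort)
    y = cohort["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic model undefined")
    X = design_matrix(cohort, interactions)
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        logger.info("dropping constant columns: %s", const_cols)
        X = X.drop(columns=const_cols)
    result = _fit_logistic(y, X, len(cohort), stratum_label)
    if interactions:
        base = _fit_logistic(y, design_matrix(cohort, None).drop(
            columns=const_cols, errors="ignore"), len(cohort), stratum_label)
        df_diff = len(result.terms) - len(base.terms)
        lr = 2.0 * (result.log_likelihood - base.log_likelihood)
        result.extra["lrt_interactions"] = {
            "statistic": float(lr),
            "df": int(df_diff),
            "p": float(stats.chi2.sf(max(lr, 0.0), df_diff)) if df_diff > 0 else np.nan,
        }
    return result


STRATA = ("sex", "age60", "prs_median")


def stratified_or(
    cohort: pd.DataFrame,
    stratify_by: str,
    age_cutoff: float = 60.0,
    prs_cutoff: float | None = None,
) -> dict[str, AssociationResult]:
    """Refit the full model within strata; keyed results per stratum.

    ``stratify_by`` is one of ``sex`` (male/female), ``age60`` (age below vs
    at-or-above ``age_cutoff`` years) or ``prs_median`` (PRS at-or-below vs
    above ``prs_cutoff``, defaulting to the cohort median score).  Strata
    that lack one of the outcome classes are skipped with a warning.
    """
    if stratify_by == "sex":
        masks = {
            "male": cohort["sex"] == "male",
            "female": cohort["sex"] == "female",
        }
    elif stratify_by == "age60":
        masks = {
            f"age<{age_cutoff:g}": cohort["age"] < age_cutoff,
            f"age>={age_cutoff:g}": cohort["age"] >= age_cutoff,
        }
    elif stratify_by == "prs_median":
        cut = float(cohort["gsd_prs"].median()) if prs_cutoff is None else prs_cutoff
        masks = {
            f"prs<={cut:g}": cohort["gsd_prs"] <= cut,
            f"prs>{cut:g}": cohort["gsd_prs"] > cut,
        }
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}; choose from {STRATA}")
    out: dict[str, AssociationResult] = {}
    for label, mask in masks.items():
        sub = cohort.loc[mask]
        if len(sub) == 0 or sub["outcome"].nunique() < 2:
            logger.warning("stratum %s lacks both outcome classes; skipped", label)
            continue
        out[label] = fit_gbc_model(sub.reset_index(drop=True), stratum_label=label)
    return out


def forest_table(results: list[AssociationResult], term: str = "froh_pct") -> pd.DataFrame:
    """Rows (label, OR, CI bounds, p) for one term across fitted models,
    ready for a forest plot; order follows the input list."""
    rows = []
    for res in results:
        if term not in res.terms:
            continue
        t = res.term(term)
        if t["ci_low"] > t["or"] or t["or"] > t["ci_high"]:
            raise ValueError(f"malformed CI for stratum {res.stratum}")
        rows.append(
            {
                "label": res.stratum,
                "or": t["or"],
                "ci_low": t["ci_low"],
                "ci_high": t["ci_high"],
                "p": t["p"],
            }
        )
    return pd.DataFrame(rows, columns=["label", "or", "ci_low", "ci_high", "p"])
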