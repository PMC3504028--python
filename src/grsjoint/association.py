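"""Case-control logistic association models, HWE QC and descriptive statistics.

All disease models are prospective logistic regressions fitted to the
case-control sample by maximum likelihood (valid for odds ratios under
case-control sampling).  The additive genetic model enters as the 0/1/2
effect-allele dosage; covariate adjustment follows the study convention of
age + sex + BMI.  Confidence intervals are Wald, ``exp(beta ± 1.96 se)``, and
p-values are two-sided Wald z tests; model log-likelihoods are exposed so
nested models can be compared by likelihood ratio.

The statsmodels-style surface is :class:`SnpAssociationModel` /
:class:`GrsAssociationModel`, whose ``fit()`` returns results objects with
``summary()`` tables; the underlying operations are also available as plain
functions (:func:`fit_logistic`, :func:`single_snp_assoc`, :func:`grs_assoc`,
:func:`hwe_chi2`, :func:`table1_descriptives`, :func:`direction_consistency`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConvergenceError, FitError, SeparationError
from .panel import GenotypeMatrix, SnpDescriptor

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile
SEPARATION_BETA = 15.0
ADJUSTMENT = ("age", "sex", "bmi")


@dataclass
class AssocResult:
    """One fitted model term on the odds-ratio scale."""

    term: str
    beta: float
    se: float
    or_value: float
    ci95: tuple
    p_value: float
    n_used: int
    model: str

    @classmethod
    def from_estimate(cls, term, beta, se, n_used, model):
        return cls(
            term=term,
            beta=float(beta),
            se=float(se),
            or_value=float(np.exp(beta)),
            ci95=(float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))),
            p_value=float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan"),
            n_used=int(n_used),
            model=model,
        )

    @classmethod
    def reference(cls, term, n_used, model):
        """The reference-category row: OR fixed at 1.00, no interval."""
        return cls(
            term=term, beta=0.0, se=float("nan"), or_value=1.0,
            ci95=(float("nan"), float("nan")), p_value=float("nan"),
            n_used=int(n_used), model=model,
        )


@dataclass
class LogisticFit:
    """Per-term results plus the quantities needed for likelihood-ratio tests."""

    results: list
    llf: float
    n_used: int
    params: pd.Series
    model: str

    def term(self, name: str) -> AssocResult:
        for r in self.results:
            if r.term == name:
                return r
        raise KeyError(name)


@dataclass
class HweResult:
    """Hardy-Weinberg goodness-of-fit for one SNP's genotype counts."""

    rsid: str
    counts: tuple  # (n homozygous effect, n heterozygous, n homozygous other)
    chi2: float
    p_value: float
    excluded: bool


def fit_logistic(outcome, design: pd.DataFrame, model_desc: str = "logistic") -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald per-term results.

    ``design`` must contain an intercept column (named ``const`` or
    ``intercept``).  Newton iterations run to relative tolerance 1e-8 within
    100 iterations; non-convergence and (quasi-)complete separation
    (|beta| > 15 or a statsmodels perfect-separation signal) raise.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise FitError("degenerate outcome: all participants share one status")
    X = design.astype(float)
    intercept_names = {"const", "intercept"}
    for col in X.columns:
        if col.lower() in intercept_names:
            continue
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"constant non-intercept column {col!r}")
    if not any(c.lower() in intercept_names for c in X.columns):
        raise ValueError("design must include an intercept column")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than model terms")

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge in 100 iterations")
    for name, val in res.params.items():
        # intercept magnitude is scale-dependent, not a separation signal
        if str(name).lower() in intercept_names:
            continue
        if abs(val) > SEPARATION_BETA:
            raise SeparationError(str(name))

    results = [
        AssocResult.from_estimate(name, res.params[name], res.bse[name], res.nobs, model_desc)
        for name in X.columns
    ]
    return LogisticFit(
        results=results, llf=float(res.llf), n_used=int(res.nobs),
        params=res.params, model=model_desc,
    )


def _adjustment_design(phenos: pd.DataFrame, covariates: Sequence[str] = ADJUSTMENT) -> pd.DataFrame:
    """Intercept + adjustment columns; drops sex in single-sex strata."""
    X = pd.DataFrame(index=phenos.index)
    X["const"] = 1.0
    for cov in covariates:
        if cov == "sex":
            male = (phenos["sex"] == "male").astype(float)
            if male.nunique() < 2:
                logger.info("single-sex stratum: dropping sex term")
                continue
            X["sex_male"] = male
        else:
            X[cov] = phenos[cov].astype(float)
    return X


def _status_vector(phenos: pd.DataFrame) -> np.ndarray:
    return (phenos["status"] == "case").to_numpy(dtype=float)


def single_snp_assoc(
    matrix: GenotypeMatrix,
    phenos: pd.DataFrame,
    rsid: str,
    covariates: Sequence[str] = ADJUSTMENT,
) -> AssocResult:
    """Additive per-allele association for one SNP, adjusted for age/sex/BMI.

    Participants missing this genotype are dropped for this SNP only.
    """
    dosage = pd.Series(matrix.column(rsid), index=matrix.participant_ids)
    merged = phenos.set_index("id")
    dose = dosage.reindex(merged.index)
    ok = dose.notna()
    merged, dose = merged[ok], dose[ok]
    if dose.nunique() < 2:
        raise ValueError(f"{rsid}: monomorphic in the analytic sample")
    X = _adjustment_design(merged.reset_index(drop=True), covariates)
    X.insert(1, "dosage", dose.to_numpy(dtype=float))
    fit = fit_logistic(_status_vector(merged), X, model_desc=f"status ~ {rsid} + age + sex + bmi")
    result = fit.term("dosage")
    result.term = rsid
    return result


class SnpAssociationModel:
    """Per-SNP additive logistic screen across a panel (statsmodels-style).

    Parameters
    ----------
    matrix, phenos : analytic-sample genotypes and phenotypes (ids aligned).
    panel : SNP descriptors; one additive model is fitted per panel SNP
        present in the matrix.
    """

    def __init__(self, matrix: GenotypeMatrix, phenos: pd.DataFrame,
                 panel: Sequence[SnpDescriptor], covariates: Sequence[str] = ADJUSTMENT):
        self.matrix = matrix
        self.phenos = phenos
        self.panel = list(panel)
        self.covariates = covariates

    def fit(self) -> "SnpAssociationResults":
        results = []
        for snp in self.panel:
            results.append(single_snp_assoc(self.matrix, self.phenos, snp.rsid, self.covariates))
        return SnpAssociationResults(results, self.panel)


class SnpAssociationResults:
    def __init__(self, results: list, panel: Sequence[SnpDescriptor]):
        self.results = results
        self.panel = list(panel)

    def summary(self) -> pd.DataFrame:
        rows = []
        by_rsid = {r.term: r for r in self.results}
        for snp in self.panel:
            r = by_rsid[snp.rsid]
            rows.append(
                {
                    "rsid": snp.rsid, "gene": snp.nearby_gene,
                    "effect_allele": snp.effect_allele, "other_allele": snp.other_allele,
                    "eaf": snp.effect_allele_freq, "or": r.or_value,
                    "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                    "p_value": r.p_value, "n": r.n_used,
                    "grs2": "Y" if snp.in_grs2 else "N",
                }
            )
        return pd.DataFrame(rows)

    def direction_consistency(self) -> tuple:
        return direction_consistency(self.results, self.panel)


def direction_consistency(assoc: Sequence[AssocResult], panel: Sequence[SnpDescriptor]) -> tuple:
    """Count SNPs whose estimated OR exceeds 1 for the literature risk allele.

    An OR of exactly 1 counts as inconsistent: directional consistency
    requires strict excess risk.  Returns ``(n_consistent, n_total)``.
    """
    by_term = {r.term: r for r in assoc}
    missing = [s.rsid for s in panel if s.rsid not in by_term]
    if missing:
        raise ValueError(f"no association result for panel SNP(s): {missing}")
    n_consistent = sum(1 for s in panel if by_term[s.rsid].or_value > 1.0)
    return n_consistent, len(panel)


# ---------------------------------------------------------------------------
# GRS association


def grs_assoc(
    grs_table: pd.DataFrame,
    phenos: pd.DataFrame,
    form: str = "continuous",
    covariates: Sequence[str] = ADJUSTMENT,
) -> "GrsAssociationResults":
    """Fit the score-disease model in continuous, quintile or tertile form."""
    return GrsAssociationModel(grs_table, phenos, form=form, covariates=covariates).fit()


class GrsAssociationModel:
    """Association of a genetic risk score with disease, adjusted for age/sex/BMI.

    ``form="continuous"`` fits one per-score-point (per risk allele) term on
    the weighted score.  ``form="quintile"``/``"tertile"`` fits k-1 category
    indicators against the lowest-score reference, and additionally an
    ordinal-coded model for the trend p-value; a k-1 df heterogeneity LRT is
    reported alongside, since either reading of a "trend over categories"
    p-value may be wanted.
    """

    def __init__(self, grs_table: pd.DataFrame, phenos: pd.DataFrame,
                 form: str = "continuous", covariates: Sequence[str] = ADJUSTMENT):
        if form not in ("continuous", "quintile", "tertile"):
            raise ValueError("form must be continuous/quintile/tertile")
        self.form = form
        self.covariates = covariates
        merged = phenos.set_index("id").join(
            grs_table[[c for c in ("score_name", "weighted_score", "quintile", "tertile")
                       if c in grs_table.columns]],
            how="inner",
        )
        if merged.empty:
            raise ValueError("no overlap between score table and phenotypes")
        self.data = merged.reset_index()
        self.score_name = str(grs_table["score_name"].iloc[0]) if "score_name" in grs_table else "GRS"

    def fit(self) -> "GrsAssociationResults":
        data = self.data
        y = _status_vector(data)
        X = _adjustment_design(data, self.covariates)
        desc = f"status ~ {self.score_name} ({self.form}) + age + sex + bmi"
        if self.form == "continuous":
            X.insert(1, "grs", data["weighted_score"].to_numpy(dtype=float))
            fit = fit_logistic(y, X, model_desc=desc)
            per_point = fit.term("grs")
            per_point.term = f"{self.score_name} per point"
            return GrsAssociationResults(
                form=self.form, score_name=self.score_name,
                results=[per_point], fit=fit,
            )

        col = self.form
        if col not in data.columns:
            raise ValueError(f"{col} labels missing from score table")
        cats = data[col].astype(int)
        k = int(cats.max())
        counts = cats.value_counts()
        if sorted(counts.index) != list(range(1, k + 1)) or (counts == 0).any():
            raise ValueError("empty score category after merging with phenotypes")
        Xcat = X.copy()
        for level in range(2, k + 1):
            Xcat[f"cat{level}"] = (cats == level).astype(float)
        fit = fit_logistic(y, Xcat, model_desc=desc)
        base_fit = fit_logistic(y, X, model_desc=desc + " [null]")
        het_chi2 = 2.0 * (fit.llf - base_fit.llf)
        het_p = float(stats.chi2.sf(het_chi2, df=k - 1))
        Xtrend = X.copy()
        Xtrend.insert(1, "trend", cats.to_numpy(dtype=float) - 1.0)
        trend_fit = fit_logistic(y, Xtrend, model_desc=desc + " [ordinal]")
        results = [AssocResult.reference(f"{self.score_name} {col[0].upper()}1", fit.n_used, desc)]
        for level in range(2, k + 1):
            r = fit.term(f"cat{level}")
            r.term = f"{self.score_name} {col[0].upper()}{level}"
            results.append(r)
        return GrsAssociationResults(
            form=self.form, score_name=self.score_name, results=results, fit=fit,
            trend_p=trend_fit.term("trend").p_value,
            heterogeneity_p=het_p,
        )


@dataclass
class GrsAssociationResults:
    form: str
    score_name: str
    results: list
    fit: LogisticFit
    trend_p: Optional[float] = None
    heterogeneity_p: Optional[float] = None

    @property
    def llf(self) -> float:
        return self.fit.llf

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "term": r.term, "or": r.or_value, "ci_low": r.ci95[0],
                "ci_high": r.ci95[1], "p_value": r.p_value, "n": r.n_used,
            }
            for r in self.results
        ]
        df = pd.DataFrame(rows)
        if self.trend_p is not None:
            df.attrs["trend_p"] = self.trend_p
            df.attrs["heterogeneity_p"] = self.heterogeneity_p
        return df


# ---------------------------------------------------------------------------
# Hardy-Weinberg QC


def hwe_chi2(counts, rsid: str = "", threshold: float = 1e-4) -> HweResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``counts`` is the genotype triple (effect-homozygote, heterozygote,
    other-homozygote).  Expected counts use the sample allele frequency;
    the ``excluded`` flag marks p below the QC threshold (default 1e-4).
    """
    n2, n1, n0 = (int(c) for c in counts)
    if min(n2, n1, n0) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n2 + n1 + n0
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n2 + n1) / (2 * n)
    expected = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
    observed = np.array([n2, n1, n0], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    chi2 = float(np.nansum(np.where(expected > 0, terms, 0.0)))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        rsid=rsid, counts=(n2, n1, n0), chi2=chi2, p_value=p_value,
        excluded=p_value < threshold,
    )


def genotype_counts(dosage: np.ndarray) -> tuple:
    """(n effect-homozygote, n heterozygote, n other-homozygote) ignoring missing."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    return (int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))


def hwe_screen(matrix: GenotypeMatrix, phenos: pd.DataFrame, threshold: float = 1e-4) -> list:
    """HWE test per SNP on control genotypes (the QC convention)."""
    controls = set(phenos.loc[phenos["status"] == "control", "id"])
    mask = np.array([pid in controls for pid in matrix.participant_ids])
    out = []
    for rsid in matrix.snp_ids:
        counts = genotype_counts(matrix.column(rsid)[mask])
        if sum(counts) == 0:
            continue
        out.append(hwe_chi2(counts, rsid=rsid, threshold=threshold))
    return out


# ---------------------------------------------------------------------------
# Descriptive statistics (study-population characteristics table)


def table1_descriptives(phenos: pd.DataFrame, composite: Optional[pd.Series] = None) -> pd.DataFrame:
    """Case/control descriptives with the study's test conventions.

    Age is summarised by medians and compared by Mann-Whitney (it is skewed);
    BMI and WHR by means and one-way ANOVA; categorical rows (sex, BMI class,
    WHR tertile, exercise, optional composite score) by chi-square.  Returns a
    long-format frame with columns ``variable, category, control, case,
    p_value``; percentages for categorical rows.
    """
    statuses = set(phenos["status"])
    if statuses != {"case", "control"}:
        raise ValueError("both cases and controls required for descriptives")
    ctrl = phenos[phenos["status"] == "control"]
    case = phenos[phenos["status"] == "case"]
    rows = []

    mw = stats.mannwhitneyu(ctrl["age"], case["age"], alternative="two-sided")
    rows.append(("Age (yrs) median", "", ctrl["age"].median(), case["age"].median(), mw.pvalue))
    for var in ("bmi", "whr"):
        f = stats.f_oneway(ctrl[var], case[var])
        label = {"bmi": "BMI (mean)", "whr": "WHR (mean)"}[var]
        rows.append((label, "", ctrl[var].mean(), case[var].mean(), f.pvalue))

    def _cat_rows(label, ctrl_cat, case_cat, order):
        table = np.array(
            [[int((ctrl_cat == c).sum()) for c in order],
             [int((case_cat == c).sum()) for c in order]]
        )
        keep = table.sum(axis=0) > 0
        chi2_p = stats.chi2_contingency(table[:, keep], correction=False)[1] if keep.sum() > 1 else 1.0
        for i, c in enumerate(order):
            rows.append(
                (label, str(c),
                 100.0 * table[0, i] / max(table[0].sum(), 1),
                 100.0 * table[1, i] / max(table[1].sum(), 1),
                 chi2_p if i == 0 else np.nan)
            )

    _cat_rows("Men (%)", ctrl["sex"], case["sex"], ["male"])
    bmi_class = pd.cut(
        phenos["bmi"], bins=[-np.inf, 25.0, 30.0 - 1e-12, np.inf],
        labels=["<=25", ">25-<30", ">=30"], right=True,
    )
    _cat_rows("BMI categories (%)", bmi_class[phenos["status"] == "control"],
              bmi_class[phenos["status"] == "case"], ["<=25", ">25-<30", ">=30"])
    cuts = np.quantile(phenos["whr"], [1 / 3, 2 / 3])
    whr_tert = 1 + (phenos["whr"] > cuts[0]).astype(int) + (phenos["whr"] > cuts[1]).astype(int)
    _cat_rows("WHR terciles (%)", whr_tert[phenos["status"] == "control"],
              whr_tert[phenos["status"] == "case"], [1, 2, 3])
    pa = np.where(phenos["exercise"], "Exercise", "No exercise")
    _cat_rows("PA (%)", pd.Series(pa)[phenos["status"].to_numpy() == "control"],
              pd.Series(pa)[phenos["status"].to_numpy() == "case"], ["No exercise", "Exercise"])
    if composite is not None:
        comp = pd.Series(np.asarray(composite), index=phenos.index)
        _cat_rows("Combined risk factors (%)", comp[phenos["status"] == "control"],
                  comp[phenos["status"] == "case"], [0, 1, 2, 3])

    return pd.DataFrame(rows, columns=["variable", "category", "control", "case", "p_value"])
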