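"""Gene-lifestyle joint effects and multiplicative interaction tests.

Lifestyle is discretised three ways, coexisting by design:

* BMI classes at the WHO boundaries — <=25, >25-<30, >=30 (a BMI of exactly
  25 falls in the lowest class, exactly 30 in the highest);
* WHR tertiles cut from the pooled analytic sample;
* the composite high-risk count 0-3: [BMI > 25] + [WHR > 0.85] + [no
  exercise] — note the fixed 0.85 WHR cut here, distinct from the tertiles.

The joint-effect table fits one logistic model with an indicator for every
(GRS tertile x lifestyle category) cell except the double-low reference, so
each cell's OR is against the same baseline.  The interaction test is a 1-df
likelihood-ratio comparison of the main-effects model (ordinal GRS code +
ordinal/binary lifestyle code + adjustments) against the same model plus the
single product of the two codes.

Adjustment sets follow the study's table footnotes: age + sex for the BMI and
composite panels, age + sex + BMI for the WHR and exercise panels; the
mapping is an argument because the source marks are ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssocResult, LogisticFit, _adjustment_design, _status_vector, fit_logistic
from .exceptions import FitError

HIGH_WHR_CUT = 0.85
HIGH_BMI_CUT = 25.0

ENV_CHOICES = ("bmi", "whr", "exercise", "composite")

#: Default covariate sets per lifestyle panel (study table footnote reading).
DEFAULT_ADJUSTMENT = {
    "bmi": ("age", "sex"),
    "composite": ("age", "sex"),
    "whr": ("age", "sex", "bmi"),
    "exercise": ("age", "sex", "bmi"),
}

ENV_LABELS = {
    "bmi": ["<=25", ">25-<30", ">=30"],
    "whr": ["T1", "T2", "T3"],
    "exercise": ["exercise", "no_exercise"],
    "composite": ["0", "1", "2", "3"],
}


@dataclass
class LifestyleCategories:
    """Discretised lifestyle exposures for one participant."""

    participant_id: str
    bmi_class: int  # 0: <=25, 1: >25-<30, 2: >=30
    whr_tertile: int  # 1-3
    high_whr: bool  # whr > 0.85
    exercise: bool
    composite: int  # 0-3


@dataclass
class JointEffectCell:
    """One cell of the cross-classified GRS x lifestyle odds-ratio grid."""

    grs_category: int
    env_category: str
    or_value: Optional[float]
    ci95: tuple
    n_cases: int
    n_controls: int
    is_reference: bool = False


def categorize_lifestyle(
    phenos: pd.DataFrame,
    whr_tertile_basis: str = "sample",
    whr_cuts: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Assign BMI class, WHR tertile, the fixed high-WHR flag and the composite.

    With ``whr_tertile_basis="sample"`` the tertile cuts are the pooled
    sample's 1/3 and 2/3 quantiles (ties to the lower tertile); pass
    ``whr_tertile_basis="fixed"`` with explicit ``whr_cuts`` instead.  The
    composite counts BMI > 25, WHR > 0.85, and no exercise participation.
    """
    bmi = phenos["bmi"].to_numpy(dtype=float)
    whr = phenos["whr"].to_numpy(dtype=float)
    exercise = phenos["exercise"].to_numpy(dtype=bool)

    bmi_class = np.where(bmi <= HIGH_BMI_CUT, 0, np.where(bmi < 30.0, 1, 2))
    if whr_tertile_basis == "sample":
        cuts = np.quantile(whr, [1 / 3, 2 / 3])
    elif whr_tertile_basis == "fixed":
        if whr_cuts is None or len(whr_cuts) != 2:
            raise ValueError("fixed basis requires two whr_cuts")
        cuts = np.asarray(whr_cuts, dtype=float)
    else:
        raise ValueError("whr_tertile_basis must be 'sample' or 'fixed'")
    whr_tertile = 1 + (whr > cuts[0]).astype(int) + (whr > cuts[1]).astype(int)
    high_whr = whr > HIGH_WHR_CUT
    composite = (bmi > HIGH_BMI_CUT).astype(int) + high_whr.astype(int) + (~exercise).astype(int)

    return pd.DataFrame(
        {
            "id": phenos["id"].to_numpy(),
            "bmi_class": bmi_class,
            "whr_tertile": whr_tertile,
            "high_whr": high_whr,
            "exercise": exercise,
            "composite": composite,
        }
    )


def lifestyle_records(cats: pd.DataFrame) -> list:
    return [
        LifestyleCategories(
            participant_id=str(r.id), bmi_class=int(r.bmi_class),
            whr_tertile=int(r.whr_tertile), high_whr=bool(r.high_whr),
            exercise=bool(r.exercise), composite=int(r.composite),
        )
        for r in cats.itertuples(index=False)
    ]


def _env_codes(cats: pd.DataFrame, env: str) -> np.ndarray:
    """Ordinal (or binary) lifestyle code, 0 = lowest-risk category."""
    if env == "bmi":
        return cats["bmi_class"].to_numpy(dtype=int)
    if env == "whr":
        return cats["whr_tertile"].to_numpy(dtype=int) - 1
    if env == "exercise":
        return (~cats["exercise"].to_numpy(dtype=bool)).astype(int)
    if env == "composite":
        return cats["composite"].to_numpy(dtype=int)
    raise ValueError(f"env must be one of {ENV_CHOICES}")


def _merge(grs_table: pd.DataFrame, cats: pd.DataFrame, phenos: pd.DataFrame) -> pd.DataFrame:
    merged = (
        phenos.merge(cats.drop(columns=["exercise"]), on="id", validate="one_to_one")
        .merge(grs_table[["tertile"]], left_on="id", right_index=True, validate="one_to_one")
    )
    if merged.empty:
        raise ValueError("no participants shared between scores, categories and phenotypes")
    return merged


class JointEffectsModel:
    """Cross-classified GRS-tertile x lifestyle odds-ratio grid with LRT.

    ``fit()`` returns :class:`JointEffectsResults` holding the cell grid
    (reference cell OR fixed at 1.00), cell case/control counts, and the 1-df
    likelihood-ratio interaction test.  Cells with no cases or no controls are
    reported with their counts and an undefined OR (their participants are
    left out of the joint fit), since sparse double-extreme cells are expected
    at small n.
    """

    def __init__(
        self,
        grs_table: pd.DataFrame,
        cats: pd.DataFrame,
        phenos: pd.DataFrame,
        env: str,
        adjust: Optional[Sequence[str]] = None,
    ):
        if env not in ENV_CHOICES:
            raise ValueError(f"env must be one of {ENV_CHOICES}")
        self.env = env
        self.adjust = tuple(adjust) if adjust is not None else DEFAULT_ADJUSTMENT[env]
        self.data = _merge(grs_table, cats, phenos)
        self.score_name = str(grs_table["score_name"].iloc[0]) if "score_name" in grs_table else "GRS"

    def fit(self) -> "JointEffectsResults":
        data = self.data
        env_code = _env_codes(data, self.env)
        grs_code = data["tertile"].to_numpy(dtype=int) - 1  # 0..2
        labels = ENV_LABELS[self.env]
        y = _status_vector(data)

        cells = {}
        degenerate = np.zeros(len(data), dtype=bool)
        for g in range(3):
            for e in range(len(labels)):
                sel = (grs_code == g) & (env_code == e)
                n_cases = int(y[sel].sum())
                n_controls = int(sel.sum() - n_cases)
                cells[(g, e)] = [n_cases, n_controls]
                if (g, e) != (0, 0) and sel.any() and (n_cases == 0 or n_controls == 0):
                    degenerate |= sel

        # one model, one indicator per non-reference cell, common baseline
        sub = data[~degenerate].reset_index(drop=True)
        sub_y = y[~degenerate]
        sub_g = grs_code[~degenerate]
        sub_e = env_code[~degenerate]
        X = _adjustment_design(sub, self.adjust)
        terms = []
        for g in range(3):
            for e in range(len(labels)):
                if (g, e) == (0, 0):
                    continue
                col = f"g{g + 1}x{labels[e]}"
                ind = ((sub_g == g) & (sub_e == e)).astype(float)
                if ind.sum() == 0:
                    continue  # empty cell: no indicator, reported as undefined
                X[col] = ind
                terms.append((g, e, col))
        desc = f"status ~ {self.score_name} tertile x {self.env} + {'+'.join(self.adjust)}"
        fit = fit_logistic(sub_y, X, model_desc=desc)

        grid = []
        for g in range(3):
            for e in range(len(labels)):
                n_cases, n_controls = cells[(g, e)]
                if (g, e) == (0, 0):
                    grid.append(JointEffectCell(g + 1, labels[e], 1.0, (np.nan, np.nan),
                                                n_cases, n_controls, is_reference=True))
                    continue
                match = [t for t in terms if t[:2] == (g, e)]
                if not match:
                    grid.append(JointEffectCell(g + 1, labels[e], None, (np.nan, np.nan),
                                                n_cases, n_controls))
                    continue
                r = fit.term(match[0][2])
                grid.append(JointEffectCell(g + 1, labels[e], r.or_value, r.ci95,
                                            n_cases, n_controls))

        lrt = lrt_interaction_from_codes(sub_y, sub_g, sub_e, _adjustment_design(sub, self.adjust))
        return JointEffectsResults(
            env=self.env, score_name=self.score_name, adjust=self.adjust,
            cells=grid, fit=fit, interaction=lrt, env_labels=labels,
        )


@dataclass
class JointEffectsResults:
    env: str
    score_name: str
    adjust: tuple
    cells: list
    fit: LogisticFit
    interaction: tuple  # (chi2, df, p)
    env_labels: list = field(default_factory=list)

    def grid(self) -> pd.DataFrame:
        """Wide OR grid: lifestyle categories in rows, GRS tertiles in columns."""
        frame = pd.DataFrame(index=self.env_labels, columns=[f"T{g}" for g in (1, 2, 3)], dtype=object)
        for c in self.cells:
            frame.loc[c.env_category, f"T{c.grs_category}"] = c.or_value
        frame.attrs["p_interaction"] = self.interaction[2]
        return frame

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "grs_tertile": c.grs_category, "env": c.env_category,
                "or": c.or_value, "ci_low": c.ci95[0], "ci_high": c.ci95[1],
                "n_cases": c.n_cases, "n_controls": c.n_controls,
                "reference": c.is_reference,
            }
            for c in self.cells
        ]
        df = pd.DataFrame(rows)
        df.attrs["p_interaction"] = self.interaction[2]
        return df


def joint_effect_table(
    grs_table: pd.DataFrame,
    cats: pd.DataFrame,
    phenos: pd.DataFrame,
    env: str,
    adjust: Optional[Sequence[str]] = None,
) -> JointEffectsResults:
    """Functional wrapper over :class:`JointEffectsModel`."""
    return JointEffectsModel(grs_table, cats, phenos, env=env, adjust=adjust).fit()


def lrt_interaction_from_codes(y, grs_code, env_code, adjust_design: pd.DataFrame) -> tuple:
    """1-df likelihood-ratio test for a GRS x lifestyle product term.

    Main-effects model: ordinal GRS code + ordinal/binary lifestyle code +
    adjustments; the full model adds their single product.  Returns
    ``(chi2, df, p)``; a full-model log-likelihood below the nested one by
    more than 1e-6 is a fit failure.
    """
    Xmain = adjust_design.copy()
    Xmain["grs_code"] = np.asarray(grs_code, dtype=float)
    Xmain["env_code"] = np.asarray(env_code, dtype=float)
    main = fit_logistic(y, Xmain, model_desc="main effects")
    Xfull = Xmain.copy()
    Xfull["grs_x_env"] = Xmain["grs_code"] * Xmain["env_code"]
    full = fit_logistic(y, Xfull, model_desc="main effects + interaction")
    chi2 = 2.0 * (full.llf - main.llf)
    if chi2 < -1e-6:
        raise FitError("full-model log-likelihood below nested model: fit failure")
    chi2 = max(chi2, 0.0)
    return chi2, 1, float(stats.chi2.sf(chi2, df=1))


def lrt_interaction(
    grs_table: pd.DataFrame,
    cats: pd.DataFrame,
    phenos: pd.DataFrame,
    env: str,
    adjust: Optional[Sequence[str]] = None,
) -> tuple:
    """Interaction LRT on the merged analytic sample (see module docstring)."""
    if env not in ENV_CHOICES:
        raise ValueError(f"env must be one of {ENV_CHOICES}")
    if adjust is None:
        adjust = DEFAULT_ADJUSTMENT[env]
    data = _merge(grs_table, cats, phenos)
    y = _status_vector(data)
    grs_code = data["tertile"].to_numpy(dtype=int) - 1
    env_code = _env_codes(data, env)
    return lrt_interaction_from_codes(y, grs_code, env_code, _adjustment_design(data, adjust))
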