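"""Synthetic case-control cohort generator.

Emulates the data-generating process the downstream analysis assumes:

* control genotypes in Hardy-Weinberg proportions at the panel's effect-allele
  frequencies (treated as control-population frequencies);
* case genotypes drawn retrospectively, with P(g | case) proportional to
  HWE(g) x OR^g per SNP — the genotype distribution implied by an additive
  logistic disease model with the published per-allele odds ratio;
* lifestyle covariates (BMI class, WHR tertile, exercise) sampled
  conditionally on status from the study's observed category margins, with
  continuous BMI/WHR drawn from truncated normals within the drawn category;
* an optional missing-genotype process, including deliberately "heavy-missing"
  participants so the >=4-missing exclusion rule can be exercised exactly.

SNPs are simulated independently across loci (no LD): the score construction
checks and assumes r² < 0.80 within loci, so independence is the simplest
structure satisfying the analysis's assumptions.

One root seed drives everything; each stage draws from its own spawned
substream, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypeMatrix, SnpDescriptor, load_panel

#: Lifestyle category margins by status, as observed in the study population.
#: Blocks: P(BMI class) over (<=25, >25-<30, >=30); P(WHR tertile) over
#: (T1, T2, T3); P(exercise participation).
DEFAULT_LIFESTYLE_MARGINS = {
    "control": {
        "bmi": (0.684, 0.273, 0.043),
        "whr": (0.429, 0.305, 0.266),
        "exercise": 0.364,
    },
    "case": {
        "bmi": (0.364, 0.493, 0.143),
        "whr": (0.189, 0.328, 0.483),
        "exercise": 0.387,
    },
}

#: Fraction male and median age by status, from the study descriptives.
DEFAULT_MALE_FRACTION = {"control": 0.2146, "case": 0.2676}
DEFAULT_AGE_MEDIAN = {"control": 53.16, "case": 58.57}

# Category bounds used when drawing continuous values inside a drawn class.
BMI_CLASS_BOUNDS = ((15.0, 25.0), (25.0, 30.0), (30.0, 45.0))
#: WHR tertile bounds; the upper cut is the fixed 0.85 "high WHR" threshold.
DEFAULT_WHR_CUTS = (0.81, 0.85)
WHR_RANGE = (0.60, 1.20)

#: Mean/SD anchors for the truncated normal draws (study means 23.7/26.4 for
#: BMI and 0.83/0.87 for WHR in controls/cases).
BMI_ANCHOR = {"control": (23.7, 3.0), "case": (26.4, 3.0)}
WHR_ANCHOR = {"control": (0.83, 0.05), "case": (0.87, 0.05)}
AGE_SD = 8.0
AGE_RANGE = (40.0, 75.0)

#: Seed of the canonical small cohort used throughout the test suite.
CANONICAL_SEED = 20121121


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 2,679 cases vs 3,322 controls,
    per-SNP odds ratios and effect-allele frequencies from the packaged panel,
    and the study's lifestyle category margins.
    """

    n_cases: int = 2679
    n_controls: int = 3322
    per_snp_or: Optional[dict] = None  # rsID -> OR; None = panel published ORs
    control_eaf: Optional[dict] = None  # rsID -> frequency; None = panel EAFs
    lifestyle_margins: dict = field(
        default_factory=lambda: {
            k: {kk: vv for kk, vv in v.items()} for k, v in DEFAULT_LIFESTYLE_MARGINS.items()
        }
    )
    grs_env_interaction_beta: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0,1)")
        for status, block in self.lifestyle_margins.items():
            for key in ("bmi", "whr"):
                probs = block[key]
                if any(p < 0 or p > 1 for p in probs):
                    raise ValueError(f"{status}/{key}: probabilities outside [0,1]")
                if abs(sum(probs) - 1.0) > 1e-6:
                    raise ValueError(f"{status}/{key}: margins must sum to 1, got {sum(probs)}")
            if not 0.0 <= block["exercise"] <= 1.0:
                raise ValueError(f"{status}/exercise probability outside [0,1]")

    def resolved_or(self, panel: Sequence[SnpDescriptor]) -> dict:
        ors = {s.rsid: s.published_or for s in panel}
        if self.per_snp_or:
            ors.update(self.per_snp_or)
        for rsid, val in ors.items():
            if val <= 0:
                raise ValueError(f"{rsid}: odds ratio must be positive, got {val}")
        return ors

    def resolved_eaf(self, panel: Sequence[SnpDescriptor]) -> dict:
        eafs = {s.rsid: s.effect_allele_freq for s in panel}
        if self.control_eaf:
            eafs.update(self.control_eaf)
        return eafs


def _participant_ids(config: SimulationConfig) -> tuple:
    n = config.n_cases + config.n_controls
    width = max(6, len(str(n)))
    ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    return ids, status


def case_genotype_probs(eaf: float, odds_ratio: float) -> np.ndarray:
    """Genotype distribution in cases under retrospective additive sampling.

    P(g | case) ∝ HWE(g; eaf) x OR^g.  For the additive model this stays
    binomial with effect-allele frequency p' = p·OR / (1 - p + p·OR).
    """
    p = eaf
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    w = hwe * odds_ratio ** np.arange(3)
    return w / w.sum()


def simulate_genotypes(config: SimulationConfig, panel: Optional[Sequence[SnpDescriptor]] = None) -> GenotypeMatrix:
    """Draw a case-control genotype matrix; deterministic under a fixed seed.

    Controls are HWE at the control frequency; cases are enriched per SNP
    according to the configured odds ratio.
    """
    if panel is None:
        panel = load_panel()
    ors = config.resolved_or(panel)
    eafs = config.resolved_eaf(panel)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    ids, status = _participant_ids(config)
    is_case = status == "case"
    dosage = np.empty((len(ids), len(panel)))
    for j, snp in enumerate(panel):
        p = eafs[snp.rsid]
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        case_probs = case_genotype_probs(p, ors[snp.rsid])
        dosage[is_case, j] = rng.choice(3, size=config.n_cases, p=case_probs)
        dosage[~is_case, j] = rng.choice(3, size=config.n_controls, p=hwe)
    return GenotypeMatrix(ids, [s.rsid for s in panel], dosage)


def _truncnorm_draw(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_phenotypes(
    config: SimulationConfig,
    grs_values: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Draw phenotypes conditional on status from the configured margins.

    Lifestyle is sampled conditionally on case/control status (the joint
    structure the stratified analyses consume) rather than through a
    structural disease model.  When ``grs_env_interaction_beta`` is non-zero
    and per-participant ``grs_values`` are supplied, case status is re-sampled
    from a prospective logistic model containing a GRS x no-exercise product
    term, so interaction detection can be exercised with a known effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    ids, status = _participant_ids(config)
    n = len(ids)
    frame = pd.DataFrame({"id": ids, "status": status})

    sex = np.empty(n, dtype=object)
    age = np.empty(n)
    bmi = np.empty(n)
    whr = np.empty(n)
    exercise = np.empty(n, dtype=bool)
    whr_bounds = (
        (WHR_RANGE[0], DEFAULT_WHR_CUTS[0]),
        (DEFAULT_WHR_CUTS[0], DEFAULT_WHR_CUTS[1]),
        (DEFAULT_WHR_CUTS[1], WHR_RANGE[1]),
    )
    for st in ("case", "control"):
        mask = status == st
        k = int(mask.sum())
        margins = config.lifestyle_margins[st]
        sex[mask] = np.where(rng.random(k) < DEFAULT_MALE_FRACTION[st], "male", "female")
        age[mask] = _truncnorm_draw(rng, *AGE_RANGE, DEFAULT_AGE_MEDIAN[st], AGE_SD, k)
        bmi_cat = rng.choice(3, size=k, p=np.asarray(margins["bmi"], dtype=float))
        whr_cat = rng.choice(3, size=k, p=np.asarray(margins["whr"], dtype=float))
        b = np.empty(k)
        w = np.empty(k)
        for c in range(3):
            sel = bmi_cat == c
            if sel.any():
                lo, hi = BMI_CLASS_BOUNDS[c]
                b[sel] = _truncnorm_draw(rng, lo, hi, *BMI_ANCHOR[st], int(sel.sum()))
            sel = whr_cat == c
            if sel.any():
                lo, hi = whr_bounds[c]
                w[sel] = _truncnorm_draw(rng, lo, hi, *WHR_ANCHOR[st], int(sel.sum()))
        bmi[mask] = b
        whr[mask] = w
        exercise[mask] = rng.random(k) < margins["exercise"]

    frame["age"] = age
    frame["sex"] = sex
    frame["bmi"] = bmi
    frame["whr"] = whr
    frame["exercise"] = exercise

    if config.grs_env_interaction_beta != 0.0 and grs_values is not None:
        frame = _resample_status_with_interaction(config, frame, np.asarray(grs_values, float))
    return frame


# Main-effect log-odds used when re-sampling status for interaction studies:
# a per-score-point effect of the size the study reports for the full-panel
# score, and a modest lifestyle main effect.
INTERACTION_GRS_BETA = np.log(1.08)
INTERACTION_ENV_BETA = np.log(1.10)


def _resample_status_with_interaction(config, frame, grs_values):
    if len(grs_values) != len(frame):
        raise ValueError("grs_values length must match cohort size")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    grs_c = grs_values - grs_values.mean()
    env = (~frame["exercise"].to_numpy()).astype(float)  # 1 = no exercise
    base = np.log(config.n_cases / config.n_controls)
    eta = (
        base
        + INTERACTION_GRS_BETA * grs_c
        + INTERACTION_ENV_BETA * env
        + config.grs_env_interaction_beta * grs_c * env
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    frame = frame.copy()
    frame["status"] = np.where(rng.random(len(frame)) < prob, "case", "control")
    return frame


def inject_missingness(
    matrix: GenotypeMatrix,
    rate: float = 0.0,
    n_heavy: int = 0,
    heavy_min: int = 4,
    seed: int = 0,
) -> GenotypeMatrix:
    """Blank genotypes at random, plus deterministic heavy-missing participants.

    ``n_heavy`` participants (chosen by the seeded RNG) each receive at least
    ``heavy_min`` missing genotypes, so the exclusion filter downstream has an
    exactly known number of casualties when ``rate`` is 0.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0,1)")
    if heavy_min > matrix.n_snps:
        raise ValueError("heavy_min exceeds number of SNPs")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[2])
    dosage = matrix.dosage.copy()
    if rate > 0:
        mask = rng.random(dosage.shape) < rate
        dosage[mask] = np.nan
    if n_heavy > 0:
        heavy_idx = rng.choice(matrix.n_participants, size=n_heavy, replace=False)
        for i in heavy_idx:
            cols = rng.choice(matrix.n_snps, size=heavy_min, replace=False)
            dosage[i, cols] = np.nan
    return GenotypeMatrix(list(matrix.participant_ids), list(matrix.snp_ids), dosage)


def simulate_cohort(
    config: SimulationConfig,
    panel: Optional[Sequence[SnpDescriptor]] = None,
    n_heavy: int = 0,
    heavy_min: int = 4,
):
    """Genotypes + phenotypes for one synthetic cohort (ids aligned).

    Returns ``(GenotypeMatrix, phenotype DataFrame)``.  Missingness (uniform
    ``config.missing_rate`` plus ``n_heavy`` heavy-missing participants) is
    applied after the clean draw.
    """
    if panel is None:
        panel = load_panel()
    genotypes = simulate_genotypes(config, panel)
    grs_values = None
    if config.grs_env_interaction_beta != 0.0:
        grs_values = np.nansum(genotypes.dosage, axis=1)
    phenos = simulate_phenotypes(config, grs_values=grs_values)
    if config.missing_rate > 0 or n_heavy > 0:
        genotypes = inject_missingness(
            genotypes, rate=config.missing_rate, n_heavy=n_heavy,
            heavy_min=heavy_min, seed=config.seed,
        )
    return genotypes, phenos


def canonical_fixture(seed: int = CANONICAL_SEED):
    """The rigged reference cohort: 6,075 participants, 74 with >=4 missing.

    2,679 cases and 3,396 controls are drawn at the panel defaults; exactly 74
    participants are given four missing genotypes each, so the >=4-missing
    exclusion leaves 6,001 for analysis.
    """
    config = SimulationConfig(n_cases=2679, n_controls=3396, seed=seed)
    panel = load_panel()
    return config, panel, *simulate_cohort(config, panel, n_heavy=74, heavy_min=4)
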