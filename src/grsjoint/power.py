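"""Self-contained numeric procedures: case-control power and the binomial sign test.

The power calculation treats the genetic exposure as a subject-level binary
trait: prevalence p0 in controls, and in cases the odds-transformed
prevalence p1 = p0/(1-p0)·OR / (1 + p0/(1-p0)·OR) implied by the per-exposure
odds ratio.  Power for the uncorrected two-proportion chi-square then follows
the classical normal approximation with the pooled-variance test statistic.
(Counting alleles instead of subjects — 2N trials per group — would give a
very different, much higher figure; the subject-level reading matches the
dichotomous-exposure power module of the PS program this procedure mirrors.)

The sign test is the exact binomial tail at p = 1/2; it defaults to the
one-sided tail P(X >= k), with the two-sided doubling available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .panel import SnpDescriptor


@dataclass(frozen=True)
class PowerSpec:
    """Design of one two-group binary-exposure comparison."""

    n_cases: int
    n_controls: int
    exposure_freq: float  # control-group prevalence of the risk exposure
    or_alt: float
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.exposure_freq < 1.0:
            raise ValueError("exposure_freq must lie in (0,1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def odds_transform(p0: float, odds_ratio: float) -> float:
    """Map a baseline prevalence through an odds ratio: odds' = odds x OR."""
    odds = p0 / (1.0 - p0) * odds_ratio
    return odds / (1.0 + odds)


def power_case_control(
    spec: PowerSpec,
    method: str = "analytic",
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Power of the uncorrected chi-square two-proportion comparison.

    ``method="analytic"`` uses the normal approximation with pooled variance
    under the null; ``method="simulation"`` draws ``reps`` binomial datasets
    and counts chi-square rejections at ``alpha``.  Rounding is left to the
    caller.
    """
    p0 = spec.exposure_freq
    p1 = odds_transform(p0, spec.or_alt)
    n1, n0 = spec.n_cases, spec.n_controls
    if method == "analytic":
        z_alpha = stats.norm.ppf(1.0 - spec.alpha / spec.sides)
        pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
        se0 = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n0))
        z = abs(p1 - p0) / se0
        power = stats.norm.cdf(z - z_alpha)
        if spec.sides == 2:
            power += stats.norm.cdf(-z - z_alpha)
        return float(power)
    if method == "simulation":
        if reps < 100:
            raise ValueError("simulation needs at least 100 replicates")
        rng = np.random.default_rng(seed)
        x1 = rng.binomial(n1, p1, size=reps).astype(float)
        x0 = rng.binomial(n0, p0, size=reps).astype(float)
        # Pearson chi-square on the 2x2 exposed/unexposed table, no correction
        a, b = x1, n1 - x1
        c, d = x0, n0 - x0
        n = float(n1 + n0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2 = np.nan_to_num(chi2)
        if spec.sides == 2:
            reject = chi2 > stats.chi2.ppf(1.0 - spec.alpha, df=1)
        else:
            z = np.sign(a / n1 - c / n0) * np.sqrt(chi2)
            reject = z > stats.norm.ppf(1.0 - spec.alpha)
        return float(reject.mean())
    raise ValueError("method must be 'analytic' or 'simulation'")


def sign_test(k_consistent: int, n_total: int, sides: int = 1) -> float:
    """Exact binomial sign test of directional consistency at p = 1/2.

    One-sided: P(X >= k).  Two-sided: 2·min(lower tail, upper tail), capped
    at 1.  Exact tail summation, no normal approximation.
    """
    if n_total < 1 or not 0 <= k_consistent <= n_total:
        raise ValueError("need 0 <= k <= n and n >= 1")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    upper = float(stats.binom.sf(k_consistent - 1, n_total, 0.5))
    if sides == 1:
        return upper
    lower = float(stats.binom.cdf(k_consistent, n_total, 0.5))
    return min(1.0, 2.0 * min(upper, lower))


def average_maf(panel: Sequence[SnpDescriptor]) -> float:
    """Mean minor-allele frequency over the panel, min(EAF, 1-EAF) per SNP."""
    if not panel:
        raise ValueError("empty panel")
    return float(np.mean([s.maf for s in panel]))
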