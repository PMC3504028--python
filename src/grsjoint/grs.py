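"""Genetic risk score construction.

The score is an unweighted risk-allele count: each SNP contributes 0, 1 or 2
according to its effect-allele dosage.  GRS1 sums all panel SNPs; GRS2 the
subset flagged as study-significant.  Missing genotypes are handled two ways:

* participants missing ``threshold`` (default 4) or more genotypes over the
  full panel are excluded from analysis entirely;
* for the rest, the attained count is rescaled to the full panel size,
  ``weighted = raw * S / (S - m)`` for S panel SNPs and m missing — the
  standard missing-genotype correction, which also makes non-integer quantile
  cutpoints meaningful.

Quantile categories (tertiles for the joint-effect tables, quintiles for the
dose-response table) are cut at the empirical quantiles of the pooled
analytic sample's weighted scores, ties going to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, SnpDescriptor, grs2_subset


@dataclass
class GrsResult:
    """Per-participant score record."""

    participant_id: str
    score_name: str  # "GRS1" | "GRS2"
    raw_score: int
    n_snps: int
    n_missing: int
    weighted_score: float
    quintile: Optional[int] = None
    tertile: Optional[int] = None


def compute_raw_grs(matrix: GenotypeMatrix, snp_subset: Sequence[str]) -> pd.DataFrame:
    """Sum non-missing dosages over ``snp_subset`` for every participant.

    Returns a frame indexed by participant id with columns ``raw_score`` and
    ``n_missing`` (both counted over the subset only).
    """
    snp_subset = list(snp_subset)
    if not snp_subset:
        raise ValueError("empty SNP subset")
    unknown = set(snp_subset) - set(matrix.snp_ids)
    if unknown:
        raise KeyError(f"subset SNPs not in matrix: {sorted(unknown)}")
    cols = [matrix.snp_ids.index(s) for s in snp_subset]
    sub = matrix.dosage[:, cols]
    raw = np.nansum(sub, axis=1).astype(int)
    n_missing = np.isnan(sub).sum(axis=1).astype(int)
    return pd.DataFrame(
        {"raw_score": raw, "n_missing": n_missing},
        index=pd.Index(matrix.participant_ids, name="id"),
    )


def compute_weighted_grs(raw_score: float, n_snps: int, n_missing: int) -> float:
    """Rescale an attained allele count to the full panel: raw * S / (S - m)."""
    if n_missing >= n_snps:
        raise ValueError("all subset genotypes missing; weighted score undefined")
    return raw_score * n_snps / (n_snps - n_missing)


def exclude_high_missing(
    matrix: GenotypeMatrix,
    phenos: pd.DataFrame,
    threshold: int = 4,
):
    """Drop participants missing ``threshold`` or more genotypes over the panel.

    A participant with exactly ``threshold`` missing genotypes is excluded;
    one with ``threshold - 1`` is retained.  Returns
    ``(filtered matrix, filtered phenotypes, n_excluded)``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    n_miss = matrix.missing_per_participant()
    keep = n_miss < threshold
    n_excluded = int((~keep).sum())
    filtered = matrix.subset_participants(keep)
    kept_ids = set(filtered.participant_ids)
    phenos_f = phenos[phenos["id"].isin(kept_ids)].reset_index(drop=True)
    return filtered, phenos_f, n_excluded


def assign_quantiles(scores: np.ndarray, k: int) -> np.ndarray:
    """Cut scores into k categories (1..k) at the sample (i/k)-quantiles.

    Boundaries come from the full vector passed in (the pooled analytic
    sample); a value tied with a boundary goes to the lower category.
    """
    scores = np.asarray(scores, dtype=float)
    if k not in (3, 5):
        raise ValueError("k must be 3 (tertiles) or 5 (quintiles)")
    if np.unique(scores).size < k:
        raise ValueError(f"fewer than {k} distinct score values; quantiles undefined")
    cuts = np.quantile(scores, [i / k for i in range(1, k)])
    labels = np.ones(scores.shape, dtype=int)
    for cut in cuts:
        labels += scores > cut
    return labels


def compute_grs(
    matrix: GenotypeMatrix,
    panel: Sequence[SnpDescriptor],
    score: str = "GRS1",
    quantiles: Sequence[int] = (3, 5),
) -> pd.DataFrame:
    """Full score table for one score definition over an analytic sample.

    Columns: ``score_name, raw_score, n_snps, n_missing, weighted_score`` and,
    per requested k, ``tertile`` / ``quintile`` cut on the pooled weighted
    scores.  Assumes the high-missingness exclusion has already been applied.
    """
    score = score.upper()
    if score == "GRS1":
        subset = [s.rsid for s in panel]
    elif score == "GRS2":
        subset = grs2_subset(panel)
    else:
        raise ValueError("score must be 'GRS1' or 'GRS2'")
    base = compute_raw_grs(matrix, subset)
    n_snps = len(subset)
    weighted = np.array(
        [
            compute_weighted_grs(r, n_snps, m)
            for r, m in zip(base["raw_score"], base["n_missing"])
        ]
    )
    out = base.assign(score_name=score, n_snps=n_snps, weighted_score=weighted)
    for k in quantiles:
        name = {3: "tertile", 5: "quintile"}[k]
        out[name] = assign_quantiles(weighted, k)
    return out


def grs_records(table: pd.DataFrame) -> list:
    """View a score table as :class:`GrsResult` objects."""
    return [
        GrsResult(
            participant_id=str(idx),
            score_name=row["score_name"],
            raw_score=int(row["raw_score"]),
            n_snps=int(row["n_snps"]),
            n_missing=int(row["n_missing"]),
            weighted_score=float(row["weighted_score"]),
            quintile=int(row["quintile"]) if "quintile" in row else None,
            tertile=int(row["tertile"]) if "tertile" in row else None,
        )
        for idx, row in table.iterrows()
    ]
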