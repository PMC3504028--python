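"""SNP panel, genotype and phenotype I/O, plus panel-level QC (allele sanity, LD).

File dialects
-------------
* SNP panel: TSV with header ``rsid  locus  gene  effect_allele  other_allele
  eaf  published_or  grs2`` (``grs2`` in {Y, N}).  A transcription of the study's
  36-SNP susceptibility panel ships with the package (``grsjoint/data/snp_panel.tsv``).
* Genotypes: either (a) a dosage TSV — participants in rows, rsID columns,
  integer counts of the effect allele in {0,1,2} with ``NA`` for missing — or
  (b) VCF 4.x with GT fields, biallelic records only.
* Phenotypes: TSV with header ``id  status  age  sex  bmi  whr  exercise``.

Dosages are always oriented to the panel's effect allele: a VCF record whose
REF equals the effect allele has its ALT count flipped (``2 - alt_count``).
Allele pairs that do not match the descriptor literally are refused — no
strand-flip guessing — because an A/T or C/G panel entry cannot be
disambiguated from its reverse complement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlleleMismatchError,
    GenotypeFileError,
    MonomorphicInputError,
    PanelError,
)

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = [
    "rsid", "locus", "gene", "effect_allele", "other_allele",
    "eaf", "published_or", "grs2",
]

PHENOTYPE_COLUMNS = ["id", "status", "age", "sex", "bmi", "whr", "exercise"]


@dataclass(frozen=True)
class SnpDescriptor:
    """One panel row: a GWAS-identified risk variant and its published effect.

    ``effect_allele`` is the allele reported to increase disease risk; dosage
    counts copies of it.  ``effect_allele_freq`` is the study-population
    frequency of that allele and ``published_or`` the literature per-allele
    odds ratio.  ``in_grs2`` marks membership in the restricted score built
    from the SNPs significant in the study itself.
    """

    rsid: str
    locus_index: int
    nearby_gene: str
    effect_allele: str
    other_allele: str
    effect_allele_freq: float
    published_or: float
    in_grs2: bool

    def __post_init__(self):
        if self.effect_allele not in _VALID_BASES:
            raise PanelError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_BASES:
            raise PanelError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise PanelError(f"{self.rsid}: effect and other allele are both {self.effect_allele}")
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise PanelError(
                f"{self.rsid}: effect-allele frequency {self.effect_allele_freq} outside (0,1)"
            )
        if not self.published_or > 0:
            raise PanelError(f"{self.rsid}: published OR {self.published_or} must be positive")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(EAF, 1-EAF)."""
        return min(self.effect_allele_freq, 1.0 - self.effect_allele_freq)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Case/control status and the covariates the study adjusts or stratifies on."""

    participant_id: str
    status: str  # "case" | "control"
    age: float
    sex: str  # "male" | "female"
    bmi: float
    whr: float
    exercise: bool

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"{self.participant_id}: status must be case/control")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.participant_id}: sex must be male/female")
        if not self.bmi > 0:
            raise ValueError(f"{self.participant_id}: bmi must be positive")
        if not 0 < self.whr < 2:
            raise ValueError(f"{self.participant_id}: whr {self.whr} outside (0,2)")
        if not self.age > 0:
            raise ValueError(f"{self.participant_id}: age must be positive")


@dataclass
class GenotypeMatrix:
    """Participants x SNPs effect-allele dosages; NaN encodes a missing genotype."""

    participant_ids: list
    snp_ids: list
    dosage: np.ndarray  # float array, entries in {0,1,2,NaN}

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.participant_ids) or m != len(self.snp_ids):
            raise ValueError("dosage shape inconsistent with id lists")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
            raise ValueError(f"non-missing dosages must be 0/1/2; found {bad[:5]}")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, rsid: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(rsid)
        except ValueError:
            raise KeyError(f"SNP {rsid} not in matrix") from None
        return self.dosage[:, j]

    def missing_per_participant(self) -> np.ndarray:
        return np.isnan(self.dosage).sum(axis=1)

    def subset_participants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            [self.participant_ids[i] for i in idx],
            list(self.snp_ids),
            self.dosage[idx, :].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.participant_ids, columns=self.snp_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Panel I/O


def packaged_panel_path() -> Path:
    """Path to the 36-SNP panel shipped with the package."""
    return Path(resources.files("grsjoint") / "data" / "snp_panel.tsv")


def load_panel(path=None) -> list:
    """Read a SNP panel TSV into validated :class:`SnpDescriptor` rows.

    With no argument the packaged 36-SNP study panel is loaded.  Raises
    :class:`PanelError` on duplicate rsIDs, invalid allele codes, frequencies
    outside (0,1), or an empty table.
    """
    if path is None:
        path = packaged_panel_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(PANEL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise PanelError(f"panel file missing columns: {sorted(missing_cols)}")
    if df.empty:
        raise PanelError("no panel rows")
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise PanelError(f"duplicate rsID(s): {dups}")
    panel = []
    for _, row in df.iterrows():
        flag = str(row["grs2"]).strip().upper()
        if flag not in ("Y", "N"):
            raise PanelError(f"{row['rsid']}: grs2 flag must be Y or N, got {row['grs2']!r}")
        panel.append(
            SnpDescriptor(
                rsid=row["rsid"],
                locus_index=int(row["locus"]),
                nearby_gene=row["gene"],
                effect_allele=str(row["effect_allele"]).strip().upper(),
                other_allele=str(row["other_allele"]).strip().upper(),
                effect_allele_freq=float(row["eaf"]),
                published_or=float(row["published_or"]),
                in_grs2=(flag == "Y"),
            )
        )
    n_grs2 = sum(s.in_grs2 for s in panel)
    logger.info("loaded panel: %d SNPs, %d flagged for GRS2", len(panel), n_grs2)
    return panel


def write_panel(panel: Sequence[SnpDescriptor], path) -> None:
    """Write descriptors back to the panel TSV dialect (round-trips with load_panel)."""
    rows = [
        {
            "rsid": s.rsid,
            "locus": s.locus_index,
            "gene": s.nearby_gene,
            "effect_allele": s.effect_allele,
            "other_allele": s.other_allele,
            "eaf": s.effect_allele_freq,
            "published_or": s.published_or,
            "grs2": "Y" if s.in_grs2 else "N",
        }
        for s in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def grs2_subset(panel: Sequence[SnpDescriptor]) -> list:
    return [s.rsid for s in panel if s.in_grs2]


# ---------------------------------------------------------------------------
# Genotype I/O


def read_genotypes(path, panel: Sequence[SnpDescriptor], format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes as effect-allele dosages oriented to the panel.

    ``format="tsv"`` expects the package's dosage dialect (already oriented);
    ``format="vcf"`` reads GT fields and orients each record by literal
    comparison of (REF, ALT) with the descriptor's allele pair.  SNPs absent
    from the panel are dropped with a warning; incompatible allele pairs and
    multi-allelic records are errors.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, panel)
    if format == "vcf":
        return _read_genotypes_vcf(path, panel)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path, panel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    known = {s.rsid for s in panel}
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"dropping {len(extra)} SNP(s) absent from panel: {extra}")
        df = df.drop(columns=extra)
    if df.shape[1] == 0:
        raise GenotypeFileError("no panel SNPs found in genotype file")
    return GenotypeMatrix.from_dataframe(df.astype(float))


def _read_genotypes_vcf(path, panel) -> GenotypeMatrix:
    import pysam

    by_rsid = {s.rsid: s for s in panel}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise GenotypeFileError("VCF has no sample columns")
        columns: dict[str, np.ndarray] = {}
        for rec in vcf:
            rsid = rec.id
            if rsid is None or rsid not in by_rsid:
                warnings.warn(f"dropping VCF record {rsid or rec.pos}: not in panel")
                continue
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeFileError(f"{rsid}: multi-allelic records are not supported")
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            desc = by_rsid[rsid]
            if (ref, alt) == (desc.other_allele, desc.effect_allele):
                flip = False
            elif (ref, alt) == (desc.effect_allele, desc.other_allele):
                flip = True
            else:
                raise AlleleMismatchError(
                    f"{rsid}: VCF alleles {ref}/{alt} incompatible with panel "
                    f"{desc.effect_allele}/{desc.other_allele}"
                )
            col = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                alt_count = float(sum(1 for a in gt if a == 1))
                col[i] = 2.0 - alt_count if flip else alt_count
            columns[rsid] = col
    if not columns:
        raise GenotypeFileError("no panel SNPs found in VCF")
    snp_ids = list(columns)
    dosage = np.column_stack([columns[s] for s in snp_ids])
    return GenotypeMatrix(samples, snp_ids, dosage)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write the dosage TSV dialect (integers, NA for missing)."""
    df = matrix.to_dataframe()
    out = df.where(df.isna(), df.astype("Int64").astype(str)).fillna("NA")
    out.index.name = "id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phenotype I/O


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV into a validated DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise GenotypeFileError(f"phenotype file missing columns: {sorted(missing_cols)}")
    df["exercise"] = df["exercise"].astype(int).astype(bool)
    validate_phenotypes(df)
    return df


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    out = phenos.copy()
    out["exercise"] = out["exercise"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def validate_phenotypes(phenos: pd.DataFrame) -> None:
    if not phenos["status"].isin(["case", "control"]).all():
        raise ValueError("status must be 'case' or 'control'")
    if not phenos["sex"].isin(["male", "female"]).all():
        raise ValueError("sex must be 'male' or 'female'")
    if (phenos["bmi"] <= 0).any() or (phenos["age"] <= 0).any():
        raise ValueError("age and bmi must be positive")
    if ((phenos["whr"] <= 0) | (phenos["whr"] >= 2)).any():
        raise ValueError("whr must lie in (0,2)")


def phenotype_records(phenos: pd.DataFrame) -> list:
    """View a phenotype frame as a list of :class:`PhenotypeRecord`."""
    return [
        PhenotypeRecord(
            participant_id=str(r.id), status=r.status, age=float(r.age), sex=r.sex,
            bmi=float(r.bmi), whr=float(r.whr), exercise=bool(r.exercise),
        )
        for r in phenos.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Linkage disequilibrium QC


def ld_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared dosage correlation between two SNPs (composite genotype r²).

    Computed on pairwise-complete entries.  This is the genotype-correlation
    estimator appropriate for unphased case-control dosages, not a
    haplotype-phase r².  Raises :class:`MonomorphicInputError` when either
    vector is constant on the complete pairs (r² undefined, which must not be
    confused with 0).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(d1) | np.isnan(d2))
    if ok.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete entries")
    a, b = d1[ok], d2[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MonomorphicInputError("r² undefined for a monomorphic dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def check_same_locus_ld(
    matrix: GenotypeMatrix,
    panel: Sequence[SnpDescriptor],
    threshold: float = 0.80,
) -> list:
    """List same-locus SNP pairs whose dosage r² meets/exceeds ``threshold``.

    The score construction assumes effectively independent loci; pairs at the
    same locus index with r² >= 0.80 would double-count a signal.  An empty
    list is a pass.  Monomorphic SNPs are skipped (their r² is undefined).
    """
    by_locus: dict[int, list[str]] = {}
    for s in panel:
        if s.rsid in matrix.snp_ids:
            by_locus.setdefault(s.locus_index, []).append(s.rsid)
    offending = []
    for rsids in by_locus.values():
        for i in range(len(rsids)):
            for j in range(i + 1, len(rsids)):
                try:
                    r2 = ld_r2(matrix.column(rsids[i]), matrix.column(rsids[j]))
                except MonomorphicInputError:
                    continue
                if r2 >= threshold:
                    offending.append((rsids[i], rsids[j], r2))
    return offending
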