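"""End-to-end pipeline driver and table renderers.

Stage order follows the analysis: panel load → HWE/LD QC → high-missingness
exclusion → GRS1/GRS2 construction → descriptives, per-SNP and GRS
association tables → joint-effect grids with interaction tests.  Every stage
appends a manifest entry with its input/output counts; given a fixed seed the
whole bundle is byte-reproducible.

Renderers mirror the five study-table layouts: characteristics (1), per-SNP
associations (2), GRS quintiles + continuous (3), and the GRS1/GRS2 joint
grids (4/5) with a P_interaction footer per lifestyle panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .association import SnpAssociationModel, grs_assoc, hwe_screen, table1_descriptives
from .grs import compute_grs, exclude_high_missing
from .joint import ENV_CHOICES, JointEffectsModel, categorize_lifestyle
from .panel import check_same_locus_ld, load_panel, read_genotypes, read_phenotypes
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

TABLE_STYLES = ("table1", "table2", "table3", "table4", "table5")


@dataclass
class PipelineConfig:
    """One reproducible run: either input files or a simulation block."""

    panel_path: Optional[str] = None  # None = packaged panel
    genotypes_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    genotype_format: str = "tsv"
    simulation: Optional[dict] = None  # kwargs for SimulationConfig (+ n_heavy/heavy_min)
    missing_threshold: int = 4
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        has_files = self.genotypes_path is not None and self.phenotypes_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("exactly one of (genotype+phenotype files | simulation block) required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns ``{"tables": ..., "manifest": ...}``.

    Tables are the rendered (tsv, text) pairs for the five study-table
    layouts; the manifest records per-stage counts and the seed.  When
    ``config.out_dir`` is set everything is also written to disk.
    """
    manifest = {"seed": config.seed, "version": __version__, "stages": []}

    def stage(name, **info):
        manifest["stages"].append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    panel = load_panel(config.panel_path)
    stage("load_panel", n_snps=len(panel), n_grs2=sum(s.in_grs2 for s in panel))

    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        n_heavy = sim_kwargs.pop("n_heavy", 0)
        heavy_min = sim_kwargs.pop("heavy_min", 4)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        matrix, phenos = simulate_cohort(sim, panel, n_heavy=n_heavy, heavy_min=heavy_min)
        stage("simulate", n_cases=sim.n_cases, n_controls=sim.n_controls, seed=sim.seed)
    else:
        matrix = read_genotypes(config.genotypes_path, panel, format=config.genotype_format)
        phenos = read_phenotypes(config.phenotypes_path)
        stage("read_inputs", n_participants=matrix.n_participants, n_snps=matrix.n_snps)

    hwe = hwe_screen(matrix, phenos)
    ld_pairs = check_same_locus_ld(matrix, panel)
    stage("qc", n_hwe_excluded=sum(h.excluded for h in hwe), n_ld_pairs=len(ld_pairs))

    matrix, phenos, n_excluded = exclude_high_missing(matrix, phenos, config.missing_threshold)
    stage("exclude_missing", n_excluded=n_excluded, n_retained=matrix.n_participants)

    grs = {name: compute_grs(matrix, panel, score=name) for name in ("GRS1", "GRS2")}
    stage("grs", **{f"{k.lower()}_mean_weighted": round(float(v["weighted_score"].mean()), 4)
                    for k, v in grs.items()})

    cats = categorize_lifestyle(phenos)
    table1 = table1_descriptives(phenos, composite=cats.set_index("id")["composite"]
                                 .reindex(phenos["id"]).to_numpy())
    stage("table1", n_rows=len(table1))

    snp_results = SnpAssociationModel(matrix, phenos, panel).fit()
    n_cons, n_tot = snp_results.direction_consistency()
    stage("table2", n_snps=n_tot, n_direction_consistent=n_cons)

    grs_results = {
        name: {
            "quintile": grs_assoc(grs[name], phenos, form="quintile"),
            "continuous": grs_assoc(grs[name], phenos, form="continuous"),
        }
        for name in ("GRS1", "GRS2")
    }
    stage("table3", n_models=4)

    joint = {
        name: {env: JointEffectsModel(grs[name], cats, phenos, env=env).fit()
               for env in ENV_CHOICES}
        for name in ("GRS1", "GRS2")
    }
    stage("joint", n_grids=sum(len(v) for v in joint.values()))

    tables = {
        "table1": render_table(table1, "table1"),
        "table2": render_table(snp_results, "table2"),
        "table3": render_table(grs_results, "table3"),
        "table4": render_table(joint["GRS1"], "table4"),
        "table5": render_table(joint["GRS2"], "table5"),
    }
    bundle = {"tables": tables, "manifest": manifest}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, (tsv, text) in tables.items():
            (out / f"{name}.tsv").write_text(tsv)
            (out / f"{name}.txt").write_text(text)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        stage("write_outputs", out_dir=str(out))
    return bundle


# ---------------------------------------------------------------------------
# Renderers


def _fmt_or(or_value, ci) -> str:
    if or_value is None or (isinstance(or_value, float) and or_value != or_value):
        return "NA"
    if ci[0] != ci[0]:  # reference cell: no interval
        return f"{or_value:.2f}"
    return f"{or_value:.2f} ({ci[0]:.2f}–{ci[1]:.2f})"


def _fmt_p(p) -> str:
    if p != p:
        return ""
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4g}"


def render_table(result, style: str):
    """Render a result set in one of the five study-table layouts.

    Returns ``(tsv, text)`` strings.  Raises ``TypeError``/``ValueError`` when
    the result type does not match the style or is empty.
    """
    if style not in TABLE_STYLES:
        raise ValueError(f"unknown table style {style!r}")
    return _RENDERERS[style](result)


def _render_table1(desc):
    if not isinstance(desc, pd.DataFrame) or desc.empty:
        raise TypeError("table1 style requires a non-empty descriptives frame")
    df = desc.copy()
    df["control"] = df["control"].map(lambda v: f"{v:.2f}")
    df["case"] = df["case"].map(lambda v: f"{v:.2f}")
    df["p_value"] = df["p_value"].map(_fmt_p)
    tsv = df.to_csv(sep="\t", index=False)
    text = df.to_string(index=False)
    return tsv, "Characteristics of the study population\n" + text


def _render_table2(snp_results):
    summary = getattr(snp_results, "summary", None)
    if summary is None:
        raise TypeError("table2 style requires per-SNP association results")
    df = snp_results.summary()
    if df.empty:
        raise ValueError("empty result")
    out = pd.DataFrame(
        {
            "rsID": df["rsid"], "Nearby Gene": df["gene"],
            "Effect allele": df["effect_allele"], "Other allele": df["other_allele"],
            "EAF": df["eaf"].map(lambda v: f"{v:.2f}"),
            "OR (95% CI)": [
                _fmt_or(o, (lo, hi)) for o, lo, hi in zip(df["or"], df["ci_low"], df["ci_high"])
            ],
            "P value": df["p_value"].map(_fmt_p),
            "GRS2": df["grs2"],
        }
    )
    tsv = out.to_csv(sep="\t", index=False)
    return tsv, "Association of panel SNPs with disease\n" + out.to_string(index=False)


def _render_table3(grs_results):
    if not isinstance(grs_results, dict) or not grs_results:
        raise TypeError("table3 style requires {score: {quintile, continuous}} results")
    scores = list(grs_results)
    rows = []
    quint = {s: grs_results[s]["quintile"] for s in scores}
    k = max(len(quint[s].results) for s in scores)
    for i in range(k):
        row = {"": f"Q{i + 1}"}
        for s in scores:
            r = quint[s].results[i]
            row[f"{s} OR (95% CI)"] = _fmt_or(r.or_value, r.ci95)
            row[f"{s} P value"] = ""
        rows.append(row)
    trend = {"": "Trend"}
    for s in scores:
        trend[f"{s} OR (95% CI)"] = ""
        trend[f"{s} P value"] = _fmt_p(quint[s].trend_p)
    rows.append(trend)
    cont = {"": "Continuous"}
    for s in scores:
        r = grs_results[s]["continuous"].results[0]
        cont[f"{s} OR (95% CI)"] = _fmt_or(r.or_value, r.ci95)
        cont[f"{s} P value"] = _fmt_p(r.p_value)
    rows.append(cont)
    out = pd.DataFrame(rows)
    tsv = out.to_csv(sep="\t", index=False)
    return tsv, "Association between the genetic risk scores and disease\n" + out.to_string(index=False)


def _render_joint(joint_results):
    if not isinstance(joint_results, dict) or not joint_results:
        raise TypeError("joint table style requires {env: JointEffectsResults}")
    blocks_tsv, blocks_text = [], []
    header = ["", "GRS T1", "GRS T2", "GRS T3"]
    for env, res in joint_results.items():
        cells = getattr(res, "cells", None)
        if cells is None:
            raise TypeError(f"{env}: not a joint-effects result")
        rows = []
        for label in res.env_labels:
            row = [label]
            for g in (1, 2, 3):
                cell = next(c for c in cells if c.grs_category == g and c.env_category == label)
                row.append(_fmt_or(cell.or_value, cell.ci95))
            rows.append(row)
        chi2, df, p = res.interaction
        footer = [f"P_interaction {env}", _fmt_p(p), "", ""]
        block = pd.DataFrame([header] + rows + [footer])
        blocks_tsv.append(block.to_csv(sep="\t", index=False, header=False))
        blocks_text.append(f"[{env}; adjusted for {'+'.join(res.adjust)}]\n"
                           + block.to_string(index=False, header=False))
    return "\n".join(blocks_tsv), "\n\n".join(blocks_text)


def _render_table4(res):
    tsv, text = _render_joint(res)
    return tsv, "Joint effects of lifestyle with GRS1 tertiles\n" + text


def _render_table5(res):
    tsv, text = _render_joint(res)
    return tsv, "Joint effects of lifestyle with GRS2 tertiles\n" + text


_RENDERERS = {
    "table1": _render_table1,
    "table2": _render_table2,
    "table3": _render_table3,
    "table4": _render_table4,
    "table5": _render_table5,
}
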