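"""End-to-end orchestration: simulate/load, normalize, link, score, report.

The pipeline is a pure function of (inputs, config, seed): each stage writes
its outputs before the next starts, stage toggles prune downstream sections,
and reruns with the same configuration produce byte-identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import to_relative
from .data_io import (
    AbundanceMatrix,
    read_abundance,
    read_alignment_hits,
    read_annotations,
    read_gene_abundance,
    read_hgt_events,
    read_sample_info,
    write_abundance,
)
from .host_link import link_pairs
from .interactions import (
    classify_change,
    concordance,
    correlate_pairs,
    project_direction,
    screen_differential,
    vote_trend,
)
from .lifestyle import compare_groups, lli_community, lli_shift
from .mobilome import (
    amg_reversal_filter,
    classify_phage_mediated,
    donor_recipient_roles,
    enzyme_trajectory,
    hgt_frequency_change,
)
from .synthetic_data import GENUS_PHYLUM, SimConfig, simulate_study

__all__ = ["RunConfig", "run_pipeline", "community_lli_by_sample", "community_lli_change"]

logger = logging.getLogger(__name__)

_STAGES = ("host_link", "lifestyle", "interactions", "mobilome")


@dataclass
class RunConfig:
    """Pipeline configuration: either a ``simulate`` block or input paths."""

    output_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None  # paths keyed like the simulate bundle files
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    relab_threshold: float = 0.2
    alpha: float = 0.05
    min_identity: float = 90.0
    max_evalue: float = 1e-5
    min_bitscore: float = 90.0
    min_n: int = 5
    bh_scope: str = "stratum"
    control_group: str = "CON"
    baseline_day: int = 0
    change_day: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        if cfg.simulate is None and cfg.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs' paths")
        if cfg.inputs:
            missing = [p for p in cfg.inputs.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input paths do not exist: {missing}")
        return cfg


def _as_fraction(m: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample relative fractions from a count or normalized matrix."""
    if m.unit == "relative_fraction":
        return m
    if m.unit == "read_count":
        return to_relative(m)
    vals = m.values
    colsums = vals.sum(axis=0)
    safe = np.where(colsums > 0, colsums, 1.0)
    return AbundanceMatrix(
        pd.DataFrame(vals / safe, index=m.data.index, columns=m.data.columns), "relative_fraction"
    )


def community_lli_by_sample(phage_m: AbundanceMatrix, phage_ann: pd.DataFrame) -> pd.Series:
    """Community LLI (virulent/temperate relative-abundance ratio) per sample.

    Phages with lifestyle 'unknown' are excluded.
    """
    rel = _as_fraction(phage_m)
    ls = phage_ann.set_index("taxon_id")["lifestyle"].reindex(rel.data.index)
    vir = rel.data.loc[(ls == "virulent").to_numpy()].sum(axis=0)
    tmp = rel.data.loc[(ls == "temperate").to_numpy()].sum(axis=0)
    out = {}
    for s in rel.sample_ids:
        if tmp[s] == 0:
            logger.warning("sample %s skipped: temperate total is zero", s)
            continue
        out[s] = lli_community(float(vir[s]), float(tmp[s]))
    return pd.Series(out, name="community_lli")


def community_lli_change(
    lli_by_sample: pd.Series,
    sample_info: pd.DataFrame,
    baseline_day: int = 0,
    change_day: int = 10,
) -> pd.DataFrame:
    """Per-group mean/median community LLI at two days and the percent change.

    The percent change is computed on the group mean (the "average LLI");
    the median is reported alongside.
    """
    meta = sample_info.set_index("sample_id")
    rows = []
    for g, sub in meta.groupby("group"):
        base = lli_by_sample.reindex(sub.index[sub["day"] == baseline_day]).dropna()
        post = lli_by_sample.reindex(sub.index[sub["day"] == change_day]).dropna()
        if base.empty or post.empty:
            continue
        mean0, mean1 = float(base.mean()), float(post.mean())
        rows.append(
            {
                "group": g,
                "mean_lli_baseline": mean0,
                "mean_lli_change_day": mean1,
                "median_lli_baseline": float(base.median()),
                "median_lli_change_day": float(post.median()),
                "percent_change_mean": (mean1 - mean0) / mean0 * 100.0,
                "log10_fold_change_median": lli_shift(float(base.median()), float(post.median())),
            }
        )
    return pd.DataFrame(rows)


def _load_inputs(cfg: RunConfig):
    from .synthetic_data import StudyBundle, SimTruth

    if cfg.simulate is not None:
        sim = SimConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
        return simulate_study(sim)
    paths = cfg.inputs
    return StudyBundle(
        phage_abundance=read_abundance(paths["phage_abundance"], paths.get("phage_unit", "normalized_1e10")),
        bacteria_abundance=read_abundance(paths["bacteria_abundance"], paths.get("bacteria_unit", "normalized_1e10")),
        sample_info=read_sample_info(paths["sample_info"]),
        phage_annotations=read_annotations(paths["phage_annotations"]),
        bacteria_annotations=read_annotations(paths["bacteria_annotations"]),
        enzyme_table=read_gene_abundance(paths["enzyme_table"]),
        ko_table=read_gene_abundance(paths["ko_table"]),
        hgt_events=read_hgt_events(paths["hgt_events"]),
        alignment_hits=read_alignment_hits(paths["alignment_hits"]),
        truth=None,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the stages in order and write outputs + report.json.

    Returns the run report as a dict. Stage failure retains prior outputs
    and marks the stage failed in the report.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("simulate", "inputs", "output_dir")
        },
        "stages": {},
        "headline": {},
        "warnings": [],
    }

    bundle = _load_inputs(cfg)
    meta = bundle.sample_info
    group_of = dict(zip(meta["sample_id"], meta["group"]))
    write_abundance(bundle.phage_abundance, outdir / "phage_abundance.tsv")
    write_abundance(bundle.bacteria_abundance, outdir / "bacteria_abundance.tsv")
    meta.to_csv(outdir / "sample_info.tsv", sep="\t", index=False)
    report["stages"]["data_io"] = {
        "status": "ok",
        "n_phage": len(bundle.phage_abundance.taxon_ids),
        "n_bacteria": len(bundle.bacteria_abundance.taxon_ids),
        "n_samples": len(meta),
    }

    pairs: list[tuple[str, str]] = []
    if cfg.stages.get("host_link", True):
        try:
            pairs = link_pairs(bundle.phage_annotations, bundle.bacteria_annotations, taxonomy=GENUS_PHYLUM)
            pd.DataFrame(pairs, columns=["phage_id", "bacterium_id"]).to_csv(
                outdir / "host_links.tsv", sep="\t", index=False
            )
            report["stages"]["host_link"] = {"status": "ok", "n_pairs": len(pairs)}
        except Exception as exc:  # stage isolation: keep prior outputs
            logger.exception("host_link stage failed")
            report["stages"]["host_link"] = {"status": "failed", "error": str(exc)}

    if cfg.stages.get("lifestyle", True):
        try:
            lli = community_lli_by_sample(bundle.phage_abundance, bundle.phage_annotations)
            lli_frame = lli.rename_axis("sample_id").reset_index()
            lli_frame = lli_frame.merge(meta[["sample_id", "group", "day"]], on="sample_id")
            lli_frame.to_csv(outdir / "lli.tsv", sep="\t", index=False, float_format="%.10g")
            change = community_lli_change(lli, meta, cfg.baseline_day, cfg.change_day)
            change.to_csv(outdir / "lli_change.tsv", sep="\t", index=False, float_format="%.10g")
            report["stages"]["lifestyle"] = {"status": "ok", "n_lli_records": len(lli_frame)}
            report["headline"]["community_lli_percent_change_mean"] = {
                r["group"]: r["percent_change_mean"] for _, r in change.iterrows()
            }
            day_change = meta[meta["day"].isin([cfg.baseline_day, cfg.change_day])]
            by_group = {
                g: lli.reindex(sub["sample_id"]).dropna().tolist()
                for g, sub in day_change[day_change["day"] == cfg.change_day].groupby("group")
            }
            comparison = compare_groups(by_group, key="community_lli_change_day", min_n=cfg.min_n, alpha=cfg.alpha)
            if comparison is not None:
                pd.DataFrame(comparison.pairwise).assign(key=comparison.key).to_csv(
                    outdir / "lli_group_comparison.tsv", sep="\t", index=False, float_format="%.10g"
                )
        except Exception as exc:
            logger.exception("lifestyle stage failed")
            report["stages"]["lifestyle"] = {"status": "failed", "error": str(exc)}

    if cfg.stages.get("interactions", True):
        try:
            strata = {
                g: meta.loc[meta["group"] == g, "sample_id"].tolist() for g in sorted(meta["group"].unique())
            }
            correlations = correlate_pairs(
                bundle.phage_abundance,
                bundle.bacteria_abundance,
                pairs,
                strata,
                alpha=cfg.alpha,
                bh_scope=cfg.bh_scope,
            )
            corr_frame = pd.DataFrame([dataclasses.asdict(r) for r in correlations])
            corr_frame.to_csv(outdir / "correlations.tsv", sep="\t", index=False, float_format="%.10g")
            n_sig = int(corr_frame["significant"].sum()) if len(corr_frame) else 0
            report["headline"]["n_significant_pairs"] = n_sig

            changes = []
            ctrl_abs = corr_frame.loc[corr_frame["stratum"] == cfg.control_group, "rho"].abs()
            for g in strata:
                if g == cfg.control_group or ctrl_abs.empty:
                    continue
                intv_abs = corr_frame.loc[corr_frame["stratum"] == g, "rho"].abs()
                if intv_abs.empty:
                    continue
                changes.append(dataclasses.asdict(classify_change(ctrl_abs, intv_abs, stratum=g, alpha=cfg.alpha)))
            pd.DataFrame(changes).to_csv(outdir / "changes.tsv", sep="\t", index=False, float_format="%.10g")

            dab = screen_differential(bundle.bacteria_abundance, group_of, alpha=cfg.alpha)
            dab.to_csv(outdir / "dab_screen.tsv", sep="\t", index=False, float_format="%.10g")

            votes, scores = _trend_votes(bundle, pairs, cfg)
            votes.to_csv(outdir / "votes.tsv", sep="\t", index=False)
            scores.to_csv(outdir / "concordance.tsv", sep="\t", index=False, float_format="%.10g")
            report["stages"]["interactions"] = {
                "status": "ok",
                "n_correlations": len(corr_frame),
                "n_significant": n_sig,
                "n_dab": len(dab),
            }
        except Exception as exc:
            logger.exception("interactions stage failed")
            report["stages"]["interactions"] = {"status": "failed", "error": str(exc)}

    if cfg.stages.get("mobilome", True):
        try:
            flagged = classify_phage_mediated(
                bundle.hgt_events, bundle.alignment_hits, cfg.min_identity, cfg.max_evalue
            )
            flagged.to_csv(outdir / "hgt_flags.tsv", sep="\t", index=False, float_format="%.10g")
            roles = donor_recipient_roles(flagged[flagged["phage_mediated"]])
            roles.to_csv(outdir / "hgt_roles.tsv", sep="\t", index=False)
            counts = flagged.loc[flagged["phage_mediated"], "group"].value_counts().to_dict()
            freq = {}
            base = counts.get(cfg.control_group, 0)
            for g, c in sorted(counts.items()):
                if g == cfg.control_group or base <= 0:
                    continue
                fold, pct = hgt_frequency_change(base, c)
                freq[g] = {"fold": fold, "percent_change": pct}
            report["headline"]["hgt_fold_change_vs_control"] = freq

            traj = enzyme_trajectory(bundle.enzyme_table, meta)
            traj.to_csv(outdir / "enzyme_trajectory.tsv", sep="\t", index=False, float_format="%.10g")
            selections = amg_reversal_filter(bundle.ko_table, meta, alpha=cfg.alpha)
            sel_frame = pd.DataFrame(
                [
                    {
                        "ko": s.ko,
                        "pathway": s.pathway,
                        "eval_day": s.eval_day,
                        "hfd_p": s.hfd_p,
                        "fuc_p": s.fuc_p,
                        "hfd_percent_change": s.hfd_percent_change,
                        "fuc_below_hfd": s.fuc_below_hfd,
                        "selected": s.selected,
                    }
                    for s in selections
                ]
            )
            sel_frame.to_csv(outdir / "amg_selection.tsv", sep="\t", index=False, float_format="%.10g")
            report["stages"]["mobilome"] = {
                "status": "ok",
                "n_events": len(flagged),
                "n_phage_mediated": int(flagged["phage_mediated"].sum()),
                "n_ko_selected": int(sel_frame["selected"].sum()) if len(sel_frame) else 0,
            }
        except Exception as exc:
            logger.exception("mobilome stage failed")
            report["stages"]["mobilome"] = {"status": "failed", "error": str(exc)}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    return report


def _trend_votes(bundle, pairs, cfg: RunConfig):
    """Per-project direction votes and phage-host concordance over projects."""
    meta = bundle.sample_info
    projects = sorted(meta["project_id"].unique())
    phage_dir: dict[str, dict[str, int]] = {}
    bact_dir: dict[str, dict[str, int]] = {}
    for proj in projects:
        sub = meta[meta["project_id"] == proj]
        ctrl = sub.loc[sub["group"] == cfg.control_group, "sample_id"].tolist()
        intv = sub.loc[sub["group"] != cfg.control_group, "sample_id"].tolist()
        if not ctrl or not intv:
            continue
        for taxon, store, matrix in (
            ("phage", phage_dir, bundle.phage_abundance),
            ("bact", bact_dir, bundle.bacteria_abundance),
        ):
            ids = {p for p, _ in pairs} if taxon == "phage" else {b for _, b in pairs}
            for tid in ids:
                if tid not in matrix.data.index:
                    continue
                d = project_direction(
                    matrix.data.loc[tid, ctrl].to_numpy(), matrix.data.loc[tid, intv].to_numpy()
                )
                if d is not None:
                    store.setdefault(tid, {})[proj] = d
    vote_rows = []
    score_rows = []
    for phage_id, host_id in pairs:
        directions = list(phage_dir.get(phage_id, {}).values())
        v = vote_trend(directions, phage_id=phage_id)
        vote_rows.append(dataclasses.asdict(v))
        c = concordance(phage_dir.get(phage_id, {}), bact_dir.get(host_id, {}), phage_id=phage_id)
        row = dataclasses.asdict(c)
        row["bacterium_id"] = host_id
        score_rows.append(row)
    return pd.DataFrame(vote_rows), pd.DataFrame(score_rows)
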