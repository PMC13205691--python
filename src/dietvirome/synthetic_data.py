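"""Synthetic diet-intervention study generator with recorded ground truth.

Emulates the design of a three-arm mouse diet study — control (CON),
high-fat diet (HFD) and HFD supplemented with fucoidan (FUC), six subjects
per group, fecal sampling on days 0/10/14/18 — and produces every table the
analysis pipeline consumes, plus a SimTruth record of what was planted:

* phage and bacterial abundance matrices with log-normal noise;
* linked phage-bacterium pairs sharing a Gaussian-copula latent factor so
  each pair's population Spearman correlation equals its planted value
  (rho_pearson = 2 sin(pi * rho_spearman / 6), exact under the log-normal
  marginals because Spearman is rank-invariant);
* per-(group, day) virulent relative-abundance fractions realized exactly
  per sample by rescaling the virulent block (correlation-planted phages
  are temperate, so the rescaling never touches them);
* diet-associated bacteria with planted fold effects in the HFD group;
* HGT events with alignment hits engineered so the identity/E-value screen
  recovers the planted phage-mediated labels exactly;
* HGT-enzyme gene tables following planted per-(class, group) monotone
  trends, and KO tables realizing planted HFD-up / FUC-down reversal
  effects.

A single global seed drives a per-table stream splitter (SeedSequence
spawning), so adding a table does not perturb earlier tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    AbundanceMatrix,
    AlignmentHit,
    validate_annotations,
    validate_gene_abundance,
    validate_hgt_events,
    validate_sample_info,
)

__all__ = ["SimConfig", "SimTruth", "StudyBundle", "simulate_study", "truth_report"]

GROUPS = ("CON", "HFD", "FUC")
DAYS = (0, 10, 14, 18)

#: Genus pool used for bacterial species names and phage host naming.
GENERA = [
    "Bacteroides",
    "Parabacteroides",
    "Prevotella",
    "Alistipes",
    "Akkermansia",
    "Lactobacillus",
    "Lactococcus",
    "Faecalibaculum",
    "Anaerotignum",
    "Roseburia",
    "Blautia",
    "Clostridium",
    "Amedibacterium",
    "Acutalibacter",
    "Enterococcus",
    "Escherichia",
]

GENUS_PHYLUM = {
    "Bacteroides": "Bacteroidetes",
    "Parabacteroides": "Bacteroidetes",
    "Prevotella": "Bacteroidetes",
    "Alistipes": "Bacteroidetes",
    "Akkermansia": "Verrucomicrobia",
    "Lactobacillus": "Firmicutes",
    "Lactococcus": "Firmicutes",
    "Faecalibaculum": "Firmicutes",
    "Anaerotignum": "Firmicutes",
    "Roseburia": "Firmicutes",
    "Blautia": "Firmicutes",
    "Clostridium": "Firmicutes",
    "Amedibacterium": "Firmicutes",
    "Acutalibacter": "Firmicutes",
    "Enterococcus": "Firmicutes",
    "Escherichia": "Proteobacteria",
}


def _default_virulent_fraction() -> dict:
    """Planted virulent relative-abundance fraction per (group, day).

    The control arm stays lytic-dominated at 0.7; the high-fat arm shifts
    toward lysogeny (0.7 at baseline to 0.5 from day 10 on); the fucoidan
    arm is intermediate, tracking the control more closely.
    """
    frac = {}
    for d in DAYS:
        frac[("CON", d)] = 0.7
        frac[("HFD", d)] = 0.7 if d == 0 else 0.5
        frac[("FUC", d)] = 0.7 if d == 0 else 0.65
    return frac


def _default_enzyme_trends() -> dict:
    """Only the fucoidan arm shows continuously increasing mobility enzymes."""
    trends = {}
    for cls in ("integrase", "recombinase", "transposase"):
        trends[(cls, "CON")] = "flat"
        trends[(cls, "HFD")] = "decreasing"
        trends[(cls, "FUC")] = "increasing"
    return trends


def _default_ko_effects() -> list[tuple[str, str, float, float]]:
    """(KO, pathway, HFD fold on days > 0, FUC fold on days > 0).

    The first five are amino-acid-metabolism orthologs planted with the
    reversal pattern (HFD up, FUC down); the rest are null controls.
    """
    reversal = [
        ("K14157", "Lysine degradation", 4.0, 0.4),
        ("K01582", "Lysine degradation", 4.0, 0.4),
        ("K01953", "Alanine, aspartate and glutamate metabolism", 3.0, 0.5),
        ("K12960", "Cysteine and methionine metabolism", 3.0, 0.5),
        ("K17103", "Glycerophospholipid metabolism", 3.0, 0.5),
    ]
    nulls = [(f"K9000{i}", "Null pathway", 1.0, 1.0) for i in range(1, 6)]
    return reversal + nulls


@dataclass
class SimConfig:
    """Planted parameters of a synthetic diet-intervention study."""

    groups: tuple[str, ...] = GROUPS
    n_subjects_per_group: int = 6
    days: tuple[int, ...] = DAYS
    n_phage: int = 200
    n_bacteria: int = 60
    n_linked_pairs: int = 12
    rho_planted: float = 0.8
    virulent_fraction: Mapping[tuple[str, int], float] = field(default_factory=_default_virulent_fraction)
    n_dab: int = 5
    dab_fold: float = 10.0
    hgt_gene_trend: Mapping[tuple[str, str], str] = field(default_factory=_default_enzyme_trends)
    n_hgt_events: int = 300
    phage_mediated_fraction: float = 476 / 7115  # observed study-wide proportion
    ko_effects: list[tuple[str, str, float, float]] = field(default_factory=_default_ko_effects)
    noise_sigma: float = 0.5
    gene_noise_sigma: float = 0.3
    n_projects: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_phage, self.n_bacteria, self.n_subjects_per_group, self.n_hgt_events) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.phage_mediated_fraction <= 1:
            raise ValueError("phage_mediated_fraction must lie in [0, 1]")
        if abs(self.rho_planted) > 0.999:
            raise ValueError("planted |rho| > 0.999 is not achievable under noise")
        for f in dict(self.virulent_fraction).values():
            if not 0 < f < 1:
                raise ValueError("virulent fractions must lie strictly in (0, 1)")
        if self.n_linked_pairs > min(self.n_phage // 2, self.n_bacteria):
            raise ValueError("n_linked_pairs exceeds available temperate phages or bacteria")
        if self.n_linked_pairs + self.n_dab > self.n_bacteria:
            raise ValueError("n_linked_pairs + n_dab exceeds n_bacteria")


@dataclass
class SimTruth:
    """Ground truth of a generated study, keyed by generated entity ids."""

    pair_rho: dict
    virulent_fraction: dict
    dab_taxa: dict  # taxon_id -> planted fold
    phage_mediated_event_ids: list
    ko_selected: list
    enzyme_trends: dict
    linked_pairs: list

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pair_rho": {f"{p}|{b}": r for (p, b), r in self.pair_rho.items()},
            "virulent_fraction": {f"{g}|{d}": f for (g, d), f in self.virulent_fraction.items()},
            "dab_taxa": self.dab_taxa,
            "phage_mediated_event_ids": self.phage_mediated_event_ids,
            "ko_selected": self.ko_selected,
            "enzyme_trends": {f"{c}|{g}": t for (c, g), t in self.enzyme_trends.items()},
            "linked_pairs": [list(p) for p in self.linked_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


@dataclass
class StudyBundle:
    phage_abundance: AbundanceMatrix
    bacteria_abundance: AbundanceMatrix
    sample_info: pd.DataFrame
    phage_annotations: pd.DataFrame
    bacteria_annotations: pd.DataFrame
    enzyme_table: pd.DataFrame
    ko_table: pd.DataFrame
    hgt_events: pd.DataFrame
    alignment_hits: list[AlignmentHit]
    truth: SimTruth

    def write(self, outdir: str | Path) -> None:
        from .data_io import write_abundance, write_alignment_hits, write_hgt_events

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_abundance(self.phage_abundance, outdir / "phage_abundance.tsv")
        write_abundance(self.bacteria_abundance, outdir / "bacteria_abundance.tsv")
        self.sample_info.to_csv(outdir / "sample_info.tsv", sep="\t", index=False)
        self.phage_annotations.to_csv(outdir / "phage_annotations.tsv", sep="\t", index=False)
        self.bacteria_annotations.to_csv(outdir / "bacteria_annotations.tsv", sep="\t", index=False)
        self.enzyme_table.to_csv(outdir / "enzyme_abundance.tsv", sep="\t", index=False)
        self.ko_table.to_csv(outdir / "ko_abundance.tsv", sep="\t", index=False)
        write_hgt_events(self.hgt_events, outdir / "hgt_events.tsv")
        write_alignment_hits(self.alignment_hits, outdir / "phage_hits.tsv")
        self.truth.to_json(outdir / "truth.json")


def _gauss_copula_r(rho_spearman: float) -> float:
    """Pearson correlation of the Gaussian latent giving the target Spearman."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def simulate_study(cfg: SimConfig) -> StudyBundle:
    """Generate a complete synthetic study bundle with recorded truth."""
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_ab = np.random.default_rng(streams[0])
    rng_hgt = np.random.default_rng(streams[1])
    rng_genes = np.random.default_rng(streams[2])
    rng_ko = np.random.default_rng(streams[3])
    rng_names = np.random.default_rng(streams[4])

    # ---- samples -----------------------------------------------------------
    rows = []
    for proj in range(1, cfg.n_projects + 1):
        for g in cfg.groups:
            for subj in range(1, cfg.n_subjects_per_group + 1):
                for d in cfg.days:
                    rows.append(
                        {
                            "sample_id": f"P{proj}_{g}_m{subj}_d{d}",
                            "subject_id": f"P{proj}_{g}_m{subj}",
                            "group": g,
                            "day": d,
                            "project_id": f"P{proj}",
                        }
                    )
    sample_info = validate_sample_info(pd.DataFrame(rows))
    samples = sample_info["sample_id"].tolist()
    n_samples = len(samples)
    group_of = dict(zip(sample_info["sample_id"], sample_info["group"]))
    day_of = dict(zip(sample_info["sample_id"], sample_info["day"]))

    # ---- taxa and annotations ---------------------------------------------
    n_temperate = cfg.n_phage // 2
    phage_ids = [f"vOTU{i:04d}" for i in range(1, cfg.n_phage + 1)]
    lifestyles = ["temperate"] * n_temperate + ["virulent"] * (cfg.n_phage - n_temperate)
    bact_ids = [f"bMAG{i:03d}" for i in range(1, cfg.n_bacteria + 1)]
    bact_genera = [GENERA[i % len(GENERA)] for i in range(cfg.n_bacteria)]

    # linked pairs: the first n_linked_pairs temperate phages, each named after
    # its host bacterium's genus so nomenclature matching re-derives the pair
    linked_pairs: list[tuple[str, str]] = []
    phage_names: dict[str, str] = {}
    for k in range(cfg.n_linked_pairs):
        phage_id, bact_id = phage_ids[k], bact_ids[k]
        genus = bact_genera[k]
        phage_names[phage_id] = f"s__{genus}_phage_{k + 1}"
        linked_pairs.append((phage_id, bact_id))
    # one crAssphage among the unlinked temperate block exercises the override
    crass_idx = cfg.n_linked_pairs
    if crass_idx < n_temperate:
        phage_names[phage_ids[crass_idx]] = f"s__crAssphage_sp{crass_idx}"
    for i, pid in enumerate(phage_ids):
        if pid not in phage_names:
            phage_names[pid] = f"s__uncultured_virus_{i + 1}"

    phage_ann = pd.DataFrame(
        {
            "taxon_id": phage_ids,
            "species_name": [phage_names[p] for p in phage_ids],
            "kingdom": "virus",
            "lifestyle": lifestyles,
            "host_genus": None,
            "host_phylum": None,
            "host_link_method": "none",
        }
    )
    bact_ann = pd.DataFrame(
        {
            "taxon_id": bact_ids,
            "species_name": [
                f"s__{g}_sp{i + 1}" for i, g in enumerate(bact_genera)
            ],
            "kingdom": "bacterium",
            "lifestyle": "unknown",  # lifestyle is a viral attribute
            "host_genus": None,
            "host_phylum": None,
            "host_link_method": "none",
        }
    )

    # ---- abundance matrices with copula-planted correlations ---------------
    sigma = cfg.noise_sigma
    r_latent = _gauss_copula_r(cfg.rho_planted)
    mu_phage = rng_ab.normal(math.log(50.0), 1.0, size=cfg.n_phage)
    mu_bact = rng_ab.normal(math.log(200.0), 1.0, size=cfg.n_bacteria)

    z_phage = rng_ab.standard_normal((cfg.n_phage, n_samples))
    z_bact = rng_ab.standard_normal((cfg.n_bacteria, n_samples))
    for k, (pid, bid) in enumerate(linked_pairs):
        i_p, i_b = phage_ids.index(pid), bact_ids.index(bid)
        shared = z_phage[i_p]
        z_bact[i_b] = r_latent * shared + math.sqrt(1 - r_latent**2) * z_bact[i_b]

    # diet-associated bacteria: planted fold effect in the HFD arm on days > 0,
    # drawn from bacteria outside the correlation-planted block
    dab_idx = list(range(cfg.n_linked_pairs, cfg.n_linked_pairs + cfg.n_dab))
    dab_taxa = {bact_ids[i]: cfg.dab_fold for i in dab_idx}
    log_effect = np.zeros((cfg.n_bacteria, n_samples))
    for i in dab_idx:
        for j, s in enumerate(samples):
            if group_of[s] == "HFD" and day_of[s] > 0:
                log_effect[i, j] = math.log(cfg.dab_fold)

    phage_vals = np.exp(mu_phage[:, None] + sigma * z_phage)
    bact_vals = np.exp(mu_bact[:, None] + sigma * z_bact + log_effect)

    # exact per-sample virulent fraction: rescale the virulent block only
    vir_mask = np.array([ls == "virulent" for ls in lifestyles])
    vf = dict(cfg.virulent_fraction)
    for j, s in enumerate(samples):
        f = vf[(group_of[s], day_of[s])]
        v_sum = phage_vals[vir_mask, j].sum()
        t_sum = phage_vals[~vir_mask, j].sum()
        phage_vals[vir_mask, j] *= f * t_sum / ((1.0 - f) * v_sum)

    phage_m = AbundanceMatrix(pd.DataFrame(phage_vals, index=phage_ids, columns=samples), "normalized_1e10")
    bact_m = AbundanceMatrix(pd.DataFrame(bact_vals, index=bact_ids, columns=samples), "normalized_1e10")

    # ---- HGT events and alignment hits -------------------------------------
    n_mediated = int(round(cfg.phage_mediated_fraction * cfg.n_hgt_events))
    mediated_flags = np.zeros(cfg.n_hgt_events, dtype=bool)
    mediated_flags[rng_hgt.choice(cfg.n_hgt_events, size=n_mediated, replace=False)] = True
    # role bias mirrors the study: Akkermansia/Bacteroides recipient-biased,
    # Amedibacterium donor-biased, Acutalibacter both
    donor_pool = ["Amedibacterium"] * 4 + ["Acutalibacter"] * 2 + ["Clostridium", "Roseburia"]
    recip_pool = ["Akkermansia"] * 3 + ["Bacteroides"] * 3 + ["Acutalibacter"] * 2 + ["Blautia"]
    ev_rows, hits = [], []
    phage_contigs = [f"phage_contig_{i}" for i in range(1, 21)]
    for i in range(cfg.n_hgt_events):
        gene_id = f"hgt_gene_{i + 1:04d}"
        flagged = bool(mediated_flags[i])
        contig = None
        identity = np.nan
        evalue = np.nan
        if flagged:
            contig = str(rng_hgt.choice(phage_contigs))
            identity = float(rng_hgt.uniform(92.0, 99.9))
            evalue = float(10 ** rng_hgt.uniform(-30.0, -6.0))
            hits.append(
                AlignmentHit(
                    gene_id, contig, round(identity, 3), int(rng_hgt.integers(250, 2000)),
                    int(rng_hgt.integers(0, 20)), int(rng_hgt.integers(0, 4)),
                    1, 500, 1, 500, evalue, float(rng_hgt.uniform(200, 2000)),
                )
            )
        elif rng_hgt.random() < 0.5:
            # decoy hit that fails the screen on identity or E-value
            if rng_hgt.random() < 0.5:
                bad_identity, bad_e = float(rng_hgt.uniform(60.0, 90.0)), float(10 ** rng_hgt.uniform(-30.0, -6.0))
            else:
                bad_identity, bad_e = float(rng_hgt.uniform(92.0, 99.0)), float(10 ** rng_hgt.uniform(-4.0, -1.0))
            hits.append(
                AlignmentHit(
                    gene_id, str(rng_hgt.choice(phage_contigs)), round(bad_identity, 3),
                    int(rng_hgt.integers(250, 2000)), int(rng_hgt.integers(0, 20)),
                    int(rng_hgt.integers(0, 4)), 1, 500, 1, 500, bad_e,
                    float(rng_hgt.uniform(50, 500)),
                )
            )
        ev_rows.append(
            {
                "event_id": f"hgt{i + 1:04d}",
                "donor_taxon": str(rng_hgt.choice(donor_pool)),
                "recipient_taxon": str(rng_hgt.choice(recip_pool)),
                "gene_id": gene_id,
                "amino_acid_identity": float(rng_hgt.uniform(80.0, 100.0)),
                "gene_cluster_coverage": float(rng_hgt.uniform(75.0, 100.0)),
                "alignment_length_bp": int(rng_hgt.integers(200, 5000)),
                "group": str(rng_hgt.choice(list(cfg.groups))),
                "phage_contig_id": contig,
                "phage_nt_identity": identity,
                "phage_e_value": evalue,
                "phage_mediated": flagged,
            }
        )
    hgt_events = validate_hgt_events(pd.DataFrame(ev_rows))
    mediated_ids = hgt_events.loc[hgt_events["phage_mediated"], "event_id"].tolist()

    # ---- HGT-enzyme trajectories --------------------------------------------
    trend_mult = {"increasing": [1.0, 2.0, 4.0, 8.0], "flat": [1.0] * 4, "decreasing": [8.0, 4.0, 2.0, 1.0]}
    trends = dict(cfg.hgt_gene_trend)
    gene_rows = []
    for (cls, g), trend in trends.items():
        mults = dict(zip(sorted(cfg.days), trend_mult[trend][: len(cfg.days)]))
        base = float(rng_genes.uniform(50, 150))
        for s in samples:
            if group_of[s] != g:
                continue
            val = base * mults[day_of[s]] * float(np.exp(rng_genes.normal(0, cfg.gene_noise_sigma)))
            gene_rows.append({"gene_key": cls, "pathway": None, "sample_id": s, "value": val})
    enzyme_table = validate_gene_abundance(pd.DataFrame(gene_rows))

    # ---- KO tables -----------------------------------------------------------
    ko_rows = []
    ko_selected = []
    for ko, pathway, hfd_fold, fuc_fold in cfg.ko_effects:
        base = float(rng_ko.uniform(20, 80))
        planted_reversal = hfd_fold > 1.0 and fuc_fold != 1.0 and fuc_fold * base < hfd_fold * base
        if planted_reversal:
            ko_selected.append(ko)
        for s in samples:
            g, d = group_of[s], day_of[s]
            mult = 1.0
            if d > 0 and g == "HFD":
                mult = hfd_fold
            elif d > 0 and g == "FUC":
                mult = fuc_fold
            val = base * mult * float(np.exp(rng_ko.normal(0, cfg.gene_noise_sigma)))
            ko_rows.append({"gene_key": ko, "pathway": pathway, "sample_id": s, "value": val})
    ko_table = validate_gene_abundance(pd.DataFrame(ko_rows))

    truth = SimTruth(
        pair_rho={pair: cfg.rho_planted for pair in linked_pairs},
        virulent_fraction=vf,
        dab_taxa=dab_taxa,
        phage_mediated_event_ids=mediated_ids,
        ko_selected=ko_selected,
        enzyme_trends=trends,
        linked_pairs=linked_pairs,
    )
    return StudyBundle(
        phage_abundance=phage_m,
        bacteria_abundance=bact_m,
        sample_info=sample_info,
        phage_annotations=validate_annotations(phage_ann),
        bacteria_annotations=validate_annotations(bact_ann),
        enzyme_table=enzyme_table,
        ko_table=ko_table,
        hgt_events=hgt_events,
        alignment_hits=hits,
        truth=truth,
    )


def truth_report(truth: SimTruth, outputs: Mapping) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth.

    ``outputs`` may contain:

    * ``pair_correlations``: list of PairCorrelation — scored as mean
      absolute rho error over planted pairs;
    * ``community_lli_change_sign``: mapping group -> sign of the day-0 to
      day-10 community LLI change — scored as agreement with the planted
      virulent-fraction change sign;
    * ``dab_called``: iterable of taxon ids from the differential screen —
      recall and precision against planted diet-associated taxa;
    * ``phage_mediated_ids``: iterable of event ids flagged phage-mediated —
      exact-match rate against the planted labels;
    * ``ko_selected``: iterable of selected KO ids — recall against the
      planted reversal set.
    """
    report: dict = {}
    if "pair_correlations" in outputs:
        errors = []
        for rec in outputs["pair_correlations"]:
            key = (rec.phage_id, rec.bacterium_id)
            if key in truth.pair_rho:
                errors.append(abs(rec.rho - truth.pair_rho[key]))
        report["rho_mean_abs_error"] = float(np.mean(errors)) if errors else None
        report["rho_n_pairs_scored"] = len(errors)
    if "community_lli_change_sign" in outputs:
        agree, total = 0, 0
        for g, sign in outputs["community_lli_change_sign"].items():
            f0 = truth.virulent_fraction.get((g, 0))
            f10 = truth.virulent_fraction.get((g, 10))
            if f0 is None or f10 is None:
                continue
            planted = (f10 / (1 - f10)) - (f0 / (1 - f0))
            planted_sign = 0 if planted == 0 else (1 if planted > 0 else -1)
            total += 1
            agree += int(sign == planted_sign)
        report["lli_sign_agreement"] = agree / total if total else None
    if "dab_called" in outputs:
        called = set(outputs["dab_called"])
        planted = set(truth.dab_taxa)
        report["dab_recall"] = len(called & planted) / len(planted) if planted else None
        report["dab_precision"] = len(called & planted) / len(called) if called else None
    if "phage_mediated_ids" in outputs:
        called = set(outputs["phage_mediated_ids"])
        planted = set(truth.phage_mediated_event_ids)
        report["phage_mediated_exact_match"] = float(called == planted)
    if "ko_selected" in outputs:
        called = set(outputs["ko_selected"])
        planted = set(truth.ko_selected)
        report["ko_recall"] = len(called & planted) / len(planted) if planted else None
    return report
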