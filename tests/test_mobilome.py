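"""HGT classification, signed log changes, trajectories, and the AMG filter."""

import math

import numpy as np
import pandas as pd
import pytest

from dietvirome.data_io import AlignmentHit
from dietvirome.mobilome import (
    amg_reversal_filter,
    classify_phage_mediated,
    crosskingdom_homolog_filter,
    donor_recipient_roles,
    enzyme_trajectory,
    hgt_frequency_change,
    signed_log10_change,
)


def _hit(query, identity, evalue, bit=500.0, subject="ctg1"):
    return AlignmentHit(query, subject, identity, 400, 2, 0, 1, 400, 1, 400, evalue, bit)


def _events(gene_ids):
    n = len(gene_ids)
    return pd.DataFrame(
        {
            "event_id": [f"e{i}" for i in range(n)],
            "donor_taxon": "GenusA",
            "recipient_taxon": "GenusB",
            "gene_id": gene_ids,
            "amino_acid_identity": 90.0,
            "gene_cluster_coverage": 80.0,
            "alignment_length_bp": 300,
            "group": "HFD",
            "phage_contig_id": None,
            "phage_nt_identity": np.nan,
            "phage_e_value": np.nan,
            "phage_mediated": False,
        }
    )


class TestClassifyPhageMediated:
    def test_passing_hit_flags_event(self):
        out = classify_phage_mediated(_events(["g1"]), [_hit("g1", 95.0, 1e-20)])
        assert out["phage_mediated"].tolist() == [True]
        assert out["phage_contig_id"].tolist() == ["ctg1"]

    def test_boundary_identity_not_flagged(self):
        out = classify_phage_mediated(_events(["g1"]), [_hit("g1", 90.0, 1e-20)])
        assert out["phage_mediated"].tolist() == [False]

    def test_boundary_evalue_not_flagged(self):
        out = classify_phage_mediated(_events(["g1"]), [_hit("g1", 95.0, 1e-5)])
        assert out["phage_mediated"].tolist() == [False]

    def test_best_hit_by_bitscore_recorded(self):
        hits = [_hit("g1", 92.0, 1e-10, bit=100, subject="a"), _hit("g1", 96.0, 1e-12, bit=900, subject="b")]
        out = classify_phage_mediated(_events(["g1"]), hits)
        assert out["phage_contig_id"].tolist() == ["b"]

    def test_matches_brute_force_filter(self, rng):
        genes = [f"g{i}" for i in range(40)]
        hits = [
            _hit(str(rng.choice(genes)), float(rng.uniform(80, 100)), float(10.0 ** rng.uniform(-12, -2)))
            for _ in range(120)
        ]
        out = classify_phage_mediated(_events(genes), hits)
        expected = {
            g: any(h.query_id == g and h.identity > 90 and h.e_value < 1e-5 for h in hits)
            for g in genes
        }
        assert out.set_index("gene_id")["phage_mediated"].to_dict() == expected

    def test_monotone_in_thresholds(self, rng):
        genes = [f"g{i}" for i in range(30)]
        hits = [
            _hit(str(rng.choice(genes)), float(rng.uniform(85, 100)), float(10.0 ** rng.uniform(-10, -3)))
            for _ in range(80)
        ]
        loose = classify_phage_mediated(_events(genes), hits, min_identity=85, max_evalue=1e-3)
        tight = classify_phage_mediated(_events(genes), hits, min_identity=95, max_evalue=1e-8)
        assert set(tight.loc[tight["phage_mediated"], "gene_id"]) <= set(
            loose.loc[loose["phage_mediated"], "gene_id"]
        )


class TestFrequencyChange:
    def test_eighty_percent_reduction(self):
        fold, pct = hgt_frequency_change(10, 2)
        assert fold == pytest.approx(0.2) and pct == pytest.approx(-80.0)

    def test_no_change(self):
        assert hgt_frequency_change(7, 7) == (1.0, 0.0)

    def test_fold_increase(self):
        fold, _ = hgt_frequency_change(4, 38)
        assert fold == pytest.approx(9.5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            hgt_frequency_change(0, 5)


class TestDonorRecipientRoles:
    def test_role_labels(self):
        ev = pd.DataFrame(
            {
                "donor_genus": ["A", "A", "A", "B", "C", "C", "C"],
                "recipient_genus": ["B", "B", "B", "B", "B", "A", "C"],
            }
        )
        roles = donor_recipient_roles(ev).set_index("genus")
        assert roles.loc["A", "role"] == "donor-biased"
        assert roles.loc["B", "role"] == "recipient-biased"
        assert roles.loc["C"].tolist() == [3, 1, "donor-biased"]

    def test_balanced(self):
        ev = pd.DataFrame({"donor_genus": ["X", "Y"], "recipient_genus": ["Y", "X"]})
        roles = donor_recipient_roles(ev)
        assert (roles["role"] == "balanced").all()

    def test_matches_brute_force_tally(self, rng):
        genera = list("ABCDE")
        ev = pd.DataFrame(
            {
                "donor_genus": rng.choice(genera, 60),
                "recipient_genus": rng.choice(genera, 60),
            }
        )
        roles = donor_recipient_roles(ev).set_index("genus")
        for g in genera:
            nd = int((ev["donor_genus"] == g).sum())
            nr = int((ev["recipient_genus"] == g).sum())
            if nd or nr:
                assert roles.loc[g, "n_donor"] == nd and roles.loc[g, "n_recipient"] == nr


class TestSignedLog10Change:
    def test_tenfold_difference(self):
        assert signed_log10_change(1, 11).value == pytest.approx(1.0)

    def test_symmetry(self):
        assert signed_log10_change(11, 1).value == pytest.approx(-1.0)

    def test_equal_zero(self):
        assert signed_log10_change(5, 5).value == 0.0

    def test_antisymmetric_both_conventions(self, rng):
        for conv in ("verbatim_difference", "stabilized"):
            for _ in range(20):
                a, b = rng.uniform(0, 50, 2)
                fwd = signed_log10_change(a, b, conv).value
                rev = signed_log10_change(b, a, conv).value
                assert fwd == pytest.approx(-rev)

    def test_stabilized_keeps_sign_for_small_differences(self):
        # verbatim convention flips sign for |diff| < 1; stabilized does not
        assert signed_log10_change(1.0, 1.5).value < 0
        assert signed_log10_change(1.0, 1.5, "stabilized").value > 0


def _meta(days=(0, 10, 14, 18), groups=("CON", "HFD", "FUC"), n=4):
    rows = [
        {"sample_id": f"{g}_m{i}_d{d}", "subject_id": f"{g}_m{i}", "group": g, "day": d, "project_id": "P1"}
        for g in groups
        for i in range(n)
        for d in days
    ]
    return pd.DataFrame(rows)


class TestEnzymeTrajectory:
    def _table(self, meta, per_day):
        rows = []
        for _, r in meta.iterrows():
            rows.append(
                {
                    "gene_key": "integrase",
                    "pathway": None,
                    "sample_id": r["sample_id"],
                    "value": per_day[r["day"]] if r["group"] == "FUC" else 1.0,
                }
            )
        return pd.DataFrame(rows)

    def test_strictly_increasing_flag(self):
        meta = _meta()
        traj = enzyme_trajectory(self._table(meta, {0: 1, 10: 2, 14: 3, 18: 4}), meta)
        fuc = traj[traj["group"] == "FUC"]
        assert fuc["continuously_increasing"].all()

    def test_tie_breaks_strictness(self):
        meta = _meta()
        traj = enzyme_trajectory(self._table(meta, {0: 1, 10: 2, 14: 2, 18: 3}), meta)
        fuc = traj[traj["group"] == "FUC"]
        assert not fuc["continuously_increasing"].any()

    def test_matches_brute_force_medians(self, rng):
        meta = _meta()
        rows = [
            {"gene_key": "transposase", "pathway": None, "sample_id": s, "value": float(rng.uniform(0, 10))}
            for s in meta["sample_id"]
        ]
        table = pd.DataFrame(rows)
        traj = enzyme_trajectory(table, meta, classes=("transposase",))
        merged = table.merge(meta, on="sample_id")
        for _, r in traj.iterrows():
            vals = merged[(merged["group"] == r["group"]) & (merged["day"] == r["day"])]["value"]
            assert r["median_abundance"] == pytest.approx(float(np.median(vals)))


class TestAMGReversalFilter:
    def _ko_table(self, meta, ko_values):
        rows = []
        for ko, (pathway, value_of) in ko_values.items():
            for _, r in meta.iterrows():
                rows.append(
                    {
                        "gene_key": ko,
                        "pathway": pathway,
                        "sample_id": r["sample_id"],
                        "value": value_of(r["group"], r["day"], int(r["subject_id"].split("m")[-1])),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_ko_not_selected(self):
        meta = _meta()
        table = self._ko_table(meta, {"K0001": ("pw", lambda g, d, i: 5.0 + 0.1 * i)})
        sels = amg_reversal_filter(table, meta)
        assert not any(s.selected for s in sels)

    def test_hand_computed_exact_wilcoxon_oracle(self):
        # n=4 vs 4, complete separation: exact two-sided rank-sum p = 2/C(8,4) = 1/35
        meta = _meta(n=4)

        def up(base, hfd_mult, fuc_mult):
            return lambda g, d, i: base + 0.01 * i + (
                0.0 if d == 0 else base * ((hfd_mult - 1) if g == "HFD" else (fuc_mult - 1) if g == "FUC" else 0)
            )

        table = self._ko_table(
            meta,
            {
                "K1": ("pw1", up(10.0, 5.0, 0.2)),   # reversal: selected
                "K2": ("pw1", up(10.0, 5.0, 1.0)),   # FUC unchanged: fails retention
                "K3": ("pw2", up(10.0, 0.2, 0.05)),  # HFD down: fails criterion (1)
            },
        )
        sels = amg_reversal_filter(table, meta)
        by_ko = {}
        for s in sels:
            by_ko.setdefault(s.ko, []).append(s)
        assert all(s.selected for s in by_ko["K1"])
        assert by_ko["K1"][0].hfd_p == pytest.approx(2 / 70)
        assert not any(s.selected for s in by_ko.get("K2", []))
        assert not any(s.selected for s in by_ko.get("K3", []))
        assert by_ko["K3"][0].hfd_p == pytest.approx(2 / 70)  # significant but wrong direction

    def test_planted_reversal_recovered_across_seeds(self):
        from dietvirome import SimConfig, simulate_study

        recalls = []
        for seed in range(50):
            b = simulate_study(
                SimConfig(seed=seed, n_phage=20, n_bacteria=16, n_linked_pairs=4, n_hgt_events=10)
            )
            sels = amg_reversal_filter(b.ko_table, b.sample_info)
            selected = {s.ko for s in sels if s.selected}
            planted = set(b.truth.ko_selected)
            recalls.append(len(selected & planted) / len(planted))
        assert float(np.mean(recalls)) >= 0.9

    def test_output_ordering(self, rng):
        meta = _meta()
        table = self._ko_table(
            meta,
            {
                "K10": ("pwA", lambda g, d, i: 10 + 0.01 * i + (40 if g == "HFD" and d > 0 else 0)),
                "K11": ("pwA", lambda g, d, i: 10 + 0.01 * i + (10 if g == "HFD" and d > 0 else 0)),
            },
        )
        sels = amg_reversal_filter(table, meta)
        kos = [s.ko for s in sels]
        assert kos.index("K10") < kos.index("K11")  # sorted by day-10 HFD up-regulation


class TestCrossKingdomHomologFilter:
    def test_first_passing_record_kept(self):
        hits = [_hit("q1", 95, 1e-10, bit=200, subject="a"), _hit("q1", 99, 1e-30, bit=900, subject="b")]
        kept = crosskingdom_homolog_filter(hits)
        assert len(kept) == 1 and kept[0].subject_id == "a"

    def test_boundary_bitscore_dropped(self):
        assert crosskingdom_homolog_filter([_hit("q1", 95, 1e-10, bit=90.0)]) == []

    def test_matches_brute_force(self, rng):
        hits = [
            _hit(f"q{rng.integers(8)}", 95.0, float(10.0 ** rng.uniform(-10, -2)), bit=float(rng.uniform(50, 150)))
            for _ in range(60)
        ]
        kept = crosskingdom_homolog_filter(hits)
        seen, expected = set(), []
        for h in hits:
            if h.e_value < 1e-5 and h.bit_score > 90 and h.query_id not in seen:
                seen.add(h.query_id)
                expected.append(h)
        assert kept == expected
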