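"""Simulator contracts: determinism, configured distributions, planted
effects, and cohort generation."""

import numpy as np
import pytest

from clonodiff.cdr3 import length_spectratype, modal_length_window
from clonodiff.diversity import diversity_profile
from clonodiff.errors import ConfigError
from clonodiff.io import read_airr_tsv, write_airr_tsv
from clonodiff.simulate import (
    CohortSimConfig,
    PlantedUsageShift,
    RepertoireSimConfig,
    default_igh_config,
    default_trb_config,
    simulate_cohort,
    simulate_repertoire,
    simulate_study,
)
from clonodiff.usage import usage_vector


class TestDeterminism:
    def test_identical_config_seed_gives_identical_bytes(self, tmp_path):
        cfg = default_trb_config(n_samples_per_group=2)
        blobs = []
        for run in range(2):
            samples, _, _ = simulate_study(cfg, seed=11)
            path = tmp_path / f"run{run}.tsv"
            write_airr_tsv(samples, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_sample_streams_are_order_independent(self):
        cfg = default_trb_config()
        a = simulate_repertoire(cfg, "ORR", seed=1, sample_index=5)
        b = simulate_repertoire(cfg, "ORR", seed=1, sample_index=5)
        assert [r.key for r in a.records] == [r.key for r in b.records]

    def test_different_seeds_differ(self):
        cfg = default_trb_config()
        a = simulate_repertoire(cfg, "ORR", seed=1, sample_index=0)
        b = simulate_repertoire(cfg, "ORR", seed=2, sample_index=0)
        assert {r.key for r in a.records} != {r.key for r in b.records}


class TestRepertoireShape:
    def test_output_passes_io_validation_roundtrip(self, tmp_path):
        cfg = default_igh_config(n_samples_per_group=2)
        samples, design, _ = simulate_study(cfg, seed=4)
        path = write_airr_tsv(samples, tmp_path / "igh.tsv")
        back = read_airr_tsv(path, "IGH")
        assert len(back) == 4
        assert {s.sample_id for s in back} == set(design.groups)

    def test_frequencies_normalized_and_reads_at_depth(self):
        cfg = default_trb_config()
        s = simulate_repertoire(cfg, "non_ORR", seed=9, sample_index=1)
        assert s.total_reads == cfg.total_reads_per_sample
        assert sum(s.frequencies()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "factory, window",
        [(default_trb_config, {14, 15, 16}), (default_igh_config, {19, 20, 21})],
    )
    def test_modal_window_matches_length_model(self, factory, window):
        samples, _, _ = simulate_study(factory(), seed=20)
        specs = [length_spectratype(s) for s in samples]
        assert set(modal_length_window(specs, 3)) == window

    def test_anchor_residues(self):
        trb = simulate_repertoire(default_trb_config(), "ORR", seed=2)
        assert all(r.cdr3_aa[0] == "C" and r.cdr3_aa[-1] == "F"
                   for r in trb.records)
        igh = simulate_repertoire(default_igh_config(), "ORR", seed=2)
        assert all(r.cdr3_aa[0] == "C" and r.cdr3_aa[-1] in "WF"
                   for r in igh.records)
        lasts = {r.cdr3_aa[-1] for r in igh.records}
        assert lasts == {"W", "F"}


class TestPlantedEffects:
    def test_usage_shift_raises_group_mean(self):
        """Across a handful of replicates the planted 3x gene is used about
        3x more in the target group (Dirichlet noise allows [2, 4.5])."""
        cfg = default_trb_config(n_samples_per_group=5)
        ratios = []
        for seed in range(8):
            samples, _, _ = simulate_study(cfg, seed=seed)
            mean = {
                g: np.mean([
                    usage_vector(s, "V").fractions.get("TRBV29-1", 0.0)
                    for s in samples if s.group == g
                ])
                for g in ("non_ORR", "ORR")
            }
            ratios.append(mean["ORR"] / mean["non_ORR"])
        assert 2.0 < np.mean(ratios) < 4.5

    def test_expansion_lowers_evenness_in_target_group(self):
        cfg = default_trb_config()
        lows = 0
        for seed in range(5):
            samples, _, _ = simulate_study(cfg, seed=seed)
            inv = {
                g: np.mean([
                    diversity_profile(s).inverse_simpson
                    for s in samples if s.group == g
                ])
                for g in ("non_ORR", "ORR")
            }
            lows += inv["ORR"] < inv["non_ORR"]
        assert lows >= 4

    def test_top_linked_genes_recover_prior_leaders(self):
        """Group-level pairing marginals recover the usage prior's two lead
        genes (as a set; the leaders' mutual order is within noise) in
        >=95% of runs."""
        from clonodiff.usage import group_pairing_matrix, top_linked_genes, vj_pairing_matrix

        cfg = default_trb_config()
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            samples, _, _ = simulate_study(cfg, seed=60_000 + seed)
            ok = True
            for group in ("non_ORR", "ORR"):
                matrices = [
                    vj_pairing_matrix(s) for s in samples if s.group == group
                ]
                gm = group_pairing_matrix(matrices, label=group)
                ok &= set(top_linked_genes(gm, "V", 2)) == {"TRBV20-1", "TRBV12-3"}
                ok &= set(top_linked_genes(gm, "J", 2)) == {"TRBJ2-7", "TRBJ2-1"}
            hits += ok
        assert hits / n_runs >= 0.95

    def test_no_plants_in_null_config(self):
        cfg = RepertoireSimConfig()
        assert cfg.planted_usage == ()
        assert cfg.planted_expansion is None


class TestConfigValidation:
    def test_bad_prior_rejected(self):
        with pytest.raises(ConfigError):
            RepertoireSimConfig(v_usage_prior={"TRBV2": 0.7, "TRBV9": 0.7})
        with pytest.raises(ConfigError):
            RepertoireSimConfig(v_usage_prior={"TRBV2": 1.5, "TRBV9": -0.5})

    def test_bad_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            RepertoireSimConfig(
                planted_usage=(PlantedUsageShift("TRBV2", 0.0, "ORR"),)
            )

    def test_unknown_locus_or_group_rejected(self):
        with pytest.raises(ConfigError):
            RepertoireSimConfig(locus="TRA")
        with pytest.raises(ConfigError):
            simulate_repertoire(default_trb_config(), "responders", seed=1)


class TestCohortSimulation:
    def test_exact_arm_allocation(self):
        patients = simulate_cohort(CohortSimConfig(), seed=6)
        assert sum(p.regimen == "TP" for p in patients) == 69
        assert sum(p.regimen == "FP" for p in patients) == 19

    def test_zero_censoring_all_events(self):
        patients = simulate_cohort(CohortSimConfig(censor_rate=0.0), seed=6)
        assert all(p.pfs_event and p.os_event for p in patients)

    def test_median_pfs_matches_exponential_model(self):
        """At large n the responder sample median is close to the
        configured 18.37-month exponential median."""
        cfg = CohortSimConfig(
            n_patients=10000,
            arm_sizes={"TP": 10000, "FP": 0},
            response_counts={"TP": {"PR": 60, "SD": 40}, "FP": {"PR": 1}},
            exact_counts=False,
        )
        patients = simulate_cohort(cfg, seed=12)
        resp = [p for p in patients if p.is_responder]
        nonresp = [p for p in patients if not p.is_responder]
        assert np.median([p.pfs_months for p in resp]) == pytest.approx(
            18.37, rel=0.05
        )
        assert np.median([p.pfs_months for p in nonresp]) == pytest.approx(
            8.07, rel=0.05
        )
        assert np.median([p.os_months for p in resp]) == pytest.approx(
            28.27, rel=0.05
        )
        assert np.median([p.os_months for p in nonresp]) == pytest.approx(
            22.33, rel=0.05
        )

    def test_os_not_shorter_than_pfs(self):
        patients = simulate_cohort(CohortSimConfig(), seed=8)
        assert all(p.os_months >= p.pfs_months for p in patients)

    def test_determinism(self):
        a = simulate_cohort(CohortSimConfig(censor_rate=0.3), seed=5)
        b = simulate_cohort(CohortSimConfig(censor_rate=0.3), seed=5)
        assert [(p.patient_id, p.best_response, p.pfs_months) for p in a] == [
            (p.patient_id, p.best_response, p.pfs_months) for p in b
        ]

    def test_arm_sizes_must_sum(self):
        with pytest.raises(ConfigError):
            CohortSimConfig(n_patients=88, arm_sizes={"TP": 60, "FP": 19})
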