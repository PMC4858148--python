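"""Determinism, count conservation and truth round-trips of the simulator."""

import numpy as np
import pytest

from circamir import hairpin_discovery as hp
from circamir.synthetic_data import (DECOY_SPECS, SimulationConfig,
                                     decoy_hairpin, make_reference,
                                     simulate_qpcr, simulate_reads)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(junk_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(fold_changes={"m": 0.0})
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=-1)


class TestMakeReference:
    def test_seed_determinism(self, small_config, reference):
        again = make_reference(small_config)
        assert again.genome == reference.genome
        assert again.catalog == reference.catalog
        assert [t.mirna for t in again.truth] == [t.mirna
                                                 for t in reference.truth]

    def test_catalog_size_and_headers(self, reference, small_config):
        assert len(reference.catalog) == small_config.n_conserved
        assert all(m.startswith("gga-miR-") for m in reference.catalog)
        assert all(set(s) <= set("ACGU") for s in reference.catalog.values())

    def test_matures_planted_at_recorded_loci(self, reference):
        for t in reference.truth:
            seg = reference.genome[t.locus[0]:t.locus[1]]
            assert seg == (t.mature if t.strand == "+"
                           else hp.revcomp(t.mature))

    def test_novel_true_pass_criteria_round_trip(self, reference, small_config):
        for t in reference.truth:
            if t.kind != "novel_true":
                continue
            cands = hp.extract_candidates(t.locus, t.strand, reference.genome,
                                          t.mature, small_config.flank)
            reports = [hp.evaluate_criteria(c.folded()) for c in cands]
            assert any(r.overall for r in reports)

    def test_decoys_fail_exactly_their_recorded_criterion(self, reference,
                                                          small_config):
        decoys = [t for t in reference.truth if t.kind == "novel_decoy"]
        assert decoys
        for t in decoys:
            assert not t.compliant
            cands = hp.extract_candidates(t.locus, t.strand, reference.genome,
                                          t.mature, small_config.flank)
            planted = next(c for c in cands if c.arm == "5p").folded()
            rep = hp.evaluate_criteria(planted)
            failed = {k for k, ok in rep.checks.items() if not ok}
            assert failed == {t.violated_criterion}

    def test_forced_15_pair_stem_decoy_violates_pair_criterion(self):
        """A stem held below 16 pairs is recorded (and measured) as a
        violation of the stem pair-count criterion."""
        built = decoy_hairpin("c2_stem_pairs", np.random.default_rng(0))
        cand = hp.HairpinCandidate(built.sequence, built.mature,
                                   built.mature_start, "5p").folded()
        rep = hp.evaluate_criteria(cand)
        assert rep.values["c2_stem_pairs"] < 16
        assert not rep.checks["c2_stem_pairs"] and not rep.overall

    def test_all_decoy_kinds_single_violation(self):
        rng = np.random.default_rng(1)
        for kind in DECOY_SPECS:
            built = decoy_hairpin(kind, rng)
            cand = hp.HairpinCandidate(built.sequence, built.mature,
                                       built.mature_start, "5p").folded()
            rep = hp.evaluate_criteria(cand)
            assert {k for k, ok in rep.checks.items() if not ok} == {kind}


class TestSimulateReads:
    def test_fastq_bytes_deterministic(self, reference, small_config):
        a = simulate_reads(reference, small_config, libraries=("serum_BO",))
        b = simulate_reads(reference, small_config, libraries=("serum_BO",))
        assert a.fastq["serum_BO"] == b.fastq["serum_BO"]

    def test_depth_and_count_conservation(self, reference, small_config,
                                          sim_reads):
        depth = small_config.depth_per_library
        n_junk = round(depth * small_config.junk_fraction)
        for lib, text in sim_reads.fastq.items():
            assert text.count("\n@") + 1 == depth
            assert sim_reads.true_counts[lib].sum() == depth - n_junk

    def test_zero_junk_maps_every_read(self):
        cfg = SimulationConfig(seed=5, depth_per_library=2_000, n_conserved=6,
                               n_novel_true=1, n_novel_decoy=0,
                               junk_fraction=0.0)
        ref = make_reference(cfg)
        reads = simulate_reads(ref, cfg, libraries=("serum_BO",))
        matures = {t.mature for t in ref.truth}
        seqs = reads.fastq["serum_BO"].split("\n")[1::4]
        assert len(seqs) == 2_000
        adapter = cfg.adapter
        for s in set(seqs):
            insert = s[:s.find(adapter[:8])]
            assert insert in matures

    def test_ao_means_track_fold_change_at_large_depth(self):
        """With dispersion off, empirical AO/BO RPM ratios sit on the
        planted fold-changes."""
        cfg = SimulationConfig(seed=11, depth_per_library=400_000,
                               n_conserved=10, n_novel_true=0,
                               n_novel_decoy=0, dispersion=0.0,
                               junk_fraction=0.0)
        ref = make_reference(cfg)
        reads = simulate_reads(ref, cfg, libraries=("serum_BO", "serum_AO"))
        tc = reads.true_counts
        for t in ref.truth:
            ratio = tc.loc[t.mirna, "serum_AO"] / tc.loc[t.mirna, "serum_BO"]
            assert abs(np.log2(ratio) - np.log2(t.fold_change)) < 0.35, t.mirna

    def test_depth_smaller_than_species_errors(self):
        cfg = SimulationConfig(seed=1, depth_per_library=10, n_conserved=20)
        ref = make_reference(cfg)
        with pytest.raises(ValueError):
            simulate_reads(ref, cfg)


class TestSimulateQpcr:
    def test_flat_pattern_zero_noise_equal_means(self):
        cfg = SimulationConfig(seed=2, qpcr_noise_sd=0.0,
                               qpcr_patterns={"m": "flat"})
        cq = simulate_qpcr(cfg)
        means = cq[cq.mirna == "m"].groupby("stage_week")["cq"].mean()
        assert means.nunique() == 1

    def test_panel_step_translates_to_relative_level(self):
        """Noise-free two-cycle Cq step at onset = 4-fold relative level."""
        cfg = SimulationConfig(seed=2, qpcr_noise_sd=0.0, qpcr_step_cq=2.0,
                               qpcr_patterns={"m": "panel"})
        cq = simulate_qpcr(cfg)
        from circamir import qpcr as q
        dcq = q.delta_cq(cq)
        prof = q.expression_profile(dcq, "m", baseline_stage=10)
        assert prof.levels[13] == pytest.approx(4.0)
        assert prof.levels[10] == 1.0
        assert all(prof.levels[w] == pytest.approx(4.0) for w in (14, 15, 16))

    def test_transient_returns_to_baseline(self):
        cfg = SimulationConfig(seed=2, qpcr_noise_sd=0.0, qpcr_step_cq=2.0,
                               qpcr_patterns={"m": "transient"})
        from circamir import qpcr as q
        prof = q.expression_profile(q.delta_cq(simulate_qpcr(cfg)), "m", 10)
        assert prof.levels[13] == pytest.approx(4.0)
        assert prof.levels[16] == pytest.approx(1.0)

    def test_replicates_below_two_error(self):
        with pytest.raises(ValueError):
            simulate_qpcr(SimulationConfig(seed=0), replicates=1)

    def test_u6_group_differences_stay_below_limit(self):
        """Reference stability across many seeds: max pairwise stage-mean
        U6 Cq difference < 0.6 with sd 0.15 and 6 replicates."""
        from circamir.qpcr import validate_reference
        ok = 0
        n = 300
        for seed in range(n):
            cfg = SimulationConfig(seed=seed, qpcr_noise_sd=0.15,
                                   qpcr_patterns={"m": "flat"})
            flag, _ = validate_reference(simulate_qpcr(cfg))
            ok += flag
        assert ok / n >= 0.99
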