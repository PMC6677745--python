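"""Generator determinism, planted-truth fidelity and model behaviour."""

import numpy as np
import pandas as pd
import pytest

from chromtraj.motifs import CONSENSUS, default_pwms, scan_sequence
from chromtraj.simulate import (
    FactorRules,
    OpeningModelParams,
    ScenarioConfig,
    default_factor_rules,
    fit_opening_model,
    generate_genome,
    opening_recovery_experiment,
    simulate_accessibility,
    simulate_binding,
    simulate_scenario,
    simulate_starr,
    write_fasta,
    write_scenario,
)
from chromtraj.starr import StarrCallSet, call_consensus_enhancers, overlap_fraction
from chromtraj.trajectories import assign_occupancy_codes


class TestGenerateGenome:
    cfg = ScenarioConfig(chrom_length=200_000,
                         motif_counts={"SoxOct": 100, "MORE": 100})

    def test_counts_match_config_exactly(self):
        _, truth = generate_genome(self.cfg, seed=3)
        assert truth["class"].value_counts().to_dict() == {"SoxOct": 100, "MORE": 100}

    def test_same_seed_identical_output(self):
        s1, t1 = generate_genome(self.cfg, seed=5)
        s2, t2 = generate_genome(self.cfg, seed=5)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_sequence_matches_consensus(self):
        seq, truth = generate_genome(self.cfg, seed=2)
        from chromtraj.motifs import reverse_complement
        for _, row in truth.head(50).iterrows():
            cons = CONSENSUS[row["class"]]
            planted = seq[row["start"]:row["end"]]
            if row["strand"] == "-":
                planted = reverse_complement(planted)
            matches = all(c == "N" or c == p for c, p in zip(cons, planted))
            assert matches, (cons, planted)

    def test_min_spacing_respected(self):
        _, truth = generate_genome(self.cfg, seed=4)
        starts, ends = truth["start"].to_numpy(), truth["end"].to_numpy()
        assert np.all(starts[1:] - ends[:-1] >= self.cfg.min_spacing)

    def test_infeasible_packing_rejected(self):
        cfg = ScenarioConfig(chrom_length=10_000, motif_counts={"MORE": 500})
        with pytest.raises(ValueError, match="pack"):
            generate_genome(cfg, seed=1)

    def test_scanning_recovers_planted_instances(self, small_scenario, small_genome):
        sc = small_scenario
        pwm_by_name = {p.name: p for p in default_pwms()}
        truth = sc.truth[sc.truth["class"] != "none"]
        recovered = 0
        for _, row in truth.iterrows():
            window = sc.sequence[max(0, row["center"] - 100): row["center"] + 100]
            if scan_sequence(window, pwm_by_name[row["class"]]):
                recovered += 1
        assert recovered / len(truth) >= 0.99

    def test_fasta_writer_roundtrip(self, tmp_path):
        seq, _ = generate_genome(self.cfg, seed=9)
        path = tmp_path / "g.fa"
        write_fasta(seq, path, "chr1")
        from pyfaidx import Fasta
        assert str(Fasta(str(path))["chr1"][:]) == seq


class TestSimulateBinding:
    def small_truth(self, seed=0, n=500, cls="SoxOct"):
        cfg = ScenarioConfig(chrom_length=400_000, motif_counts={cls: n})
        return generate_genome(cfg, seed)[1]

    def rules_with(self, p, cls="SoxOct"):
        return FactorRules(
            {("Oct4", "day1", cls): p}, {"Oct4": True},
        )

    def test_probability_one_binds_everything(self):
        truth = self.small_truth(n=100)
        binding, summits, _ = simulate_binding(
            truth, self.rules_with(1.0), ["Oct4"], ["day1"], seed=1
        )
        assert binding["pou_Oct4_day1"].all()
        assert len(summits[("Oct4", "day1")]) == 100

    def test_probability_zero_binds_nothing(self):
        truth = self.small_truth(n=100)
        binding, summits, _ = simulate_binding(
            truth, self.rules_with(0.0), ["Oct4"], ["day1"], seed=1
        )
        assert not binding["pou_Oct4_day1"].any()
        assert summits[("Oct4", "day1")] == []

    def test_bound_fraction_within_binomial_ci(self):
        truth = self.small_truth(n=500)
        binding, _, _ = simulate_binding(
            truth, self.rules_with(0.6), ["Oct4"], ["day1"], seed=11
        )
        frac = binding["pou_Oct4_day1"].mean()
        ci = 1.96 * np.sqrt(0.6 * 0.4 / 500)
        assert abs(frac - 0.6) < ci + 1e-9

    def test_missing_rule_is_an_error(self):
        truth = self.small_truth(n=10)
        with pytest.raises(KeyError, match="day5"):
            simulate_binding(truth, self.rules_with(0.5), ["Oct4"], ["day5"], seed=1)

    def test_defective_mutant_loses_soxoct_by_day5(self, small_scenario):
        """Late-stage codes at SoxOct loci end in 0 for the defective factor."""
        sc = small_scenario
        conditions = [
            ("day1", sc.pou_summits[("Oct4defSox2", "day1")]),
            ("day5", sc.pou_summits[("Oct4defSox2", "day5")]),
        ]
        trajs = assign_occupancy_codes(conditions)
        soxoct_centers = set(sc.truth.loc[sc.truth["class"] == "SoxOct", "center"])
        at_soxoct = [
            t for t in trajs
            if any(abs(t.locus.rep_pos - c) <= 30 for c in soxoct_centers)
        ]
        assert at_soxoct, "no SoxOct-locus trajectories found"
        late_bound = sum(t.code.endswith("1") for t in at_soxoct)
        assert late_bound / len(at_soxoct) < 0.1

    def test_sox2_blocked_by_incompetent_partner(self, small_scenario):
        sc = small_scenario
        b = sc.binding
        soxoct = (sc.truth["class"] == "SoxOct").to_numpy()
        oct4_bound = b["pou_Oct4_day1"].to_numpy() & soxoct
        def_bound = b["pou_Oct4defSox2_day1"].to_numpy() & soxoct
        cobind_oct4 = b["sox2_Oct4_day1"].to_numpy()[oct4_bound].mean()
        cobind_def = b["sox2_Oct4defSox2_day1"].to_numpy()[def_bound].mean()
        assert cobind_oct4 > 0.8
        assert cobind_def < 0.15


class TestSimulateAccessibility:
    truth = generate_genome(
        ScenarioConfig(chrom_length=800_000, motif_counts={"SoxOct": 2000}), seed=0
    )[1]

    def test_null_model_matches_baseline_logistic(self):
        params = OpeningModelParams(betaS=0.0, betaO=0.0, betaOS=0.0)
        n = len(self.truth)
        rng = np.random.default_rng(0)
        sox = rng.random(n) < 0.5
        pou = rng.random(n) < 0.5
        cond = simulate_accessibility(self.truth, sox, pou, params, seed=3)
        base = 1 / (1 + np.exp(2.0))
        ci = 1.96 * np.sqrt(base * (1 - base) / n)
        assert abs(cond.open_state.mean() - base) < ci + 1e-9

    def test_saturating_sox_effect_opens_all_bound(self):
        params = OpeningModelParams(betaS=30.0)
        n = len(self.truth)
        sox = np.zeros(n, bool); sox[:1000] = True
        cond = simulate_accessibility(self.truth, sox, np.zeros(n, bool), params, seed=4)
        assert cond.open_state[:1000].all()

    def test_open_loci_emit_higher_counts(self):
        n = len(self.truth)
        cond = simulate_accessibility(
            self.truth, np.ones(n, bool), np.ones(n, bool),
            OpeningModelParams(), seed=5,
        )
        assert cond.counts[cond.open_state].mean() > 5 * cond.counts[~cond.open_state].mean()

    def test_peaks_are_high_count_loci(self):
        n = len(self.truth)
        cond = simulate_accessibility(
            self.truth, np.ones(n, bool), np.zeros(n, bool),
            OpeningModelParams(), seed=6, peak_min_count=8,
        )
        assert len(cond.peaks) == int((cond.counts > 8).sum())

    def test_parameter_recovery_small(self):
        df = opening_recovery_experiment(OpeningModelParams(), n_loci=3000,
                                         n_seeds=10, seed=3)
        est = df.mean()
        for key, target in [("beta0", -2.0), ("betaS", 2.0),
                            ("betaO", 0.5), ("betaOS", 1.0)]:
            assert abs(est[key] - target) < 0.3
        assert (df["betaS"] > df["betaO"]).all()


from chromtraj.intervals import GenomicInterval as _GI

_ENHANCERS = [_GI("chr1", 1000 * i, 1000 * i + 300) for i in range(1, 41)]


class TestSimulateStarr:
    enhancers = _ENHANCERS

    def test_noiseless_roundtrip(self):
        reps, merged = simulate_starr(self.enhancers, 100_000, seed=1,
                                      sensitivity=1.0, fp_rate=0.0)
        out = call_consensus_enhancers(StarrCallSet(reps, merged))
        assert [(o.start, o.end) for o in out] == \
               [(e.start, e.end) for e in self.enhancers]

    def test_zero_sensitivity_empty_consensus(self):
        reps, merged = simulate_starr(self.enhancers, 100_000, seed=1,
                                      sensitivity=0.0, fp_rate=0.0)
        assert call_consensus_enhancers(StarrCallSet(reps, merged)) == []

    def test_recall_matches_binomial_tail_oracle(self):
        s = 0.8
        enhancers = [_GI("chr1", 1000 * i, 1000 * i + 300) for i in range(1, 201)]
        reps, merged = simulate_starr(enhancers, 1_000_000, seed=9,
                                      sensitivity=s, fp_rate=0.0)
        out = call_consensus_enhancers(StarrCallSet(reps, merged))
        recall = overlap_fraction(enhancers, out)
        # oracle: called in merged AND in >= 2 of 3 replicates, independently
        p_reps = 3 * s**2 * (1 - s) + s**3
        p_merged = 1 - (1 - s) ** 3
        expected = p_reps * p_merged
        ci = 1.96 * np.sqrt(expected * (1 - expected) / len(enhancers))
        assert abs(recall - expected) < ci


class TestScenario:
    def test_full_determinism(self, small_config):
        a = simulate_scenario(small_config, seed=21)
        b = simulate_scenario(small_config, seed=21)
        assert a.sequence == b.sequence
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.binding, b.binding)
        for key in a.atac:
            np.testing.assert_array_equal(a.atac[key].counts, b.atac[key].counts)

    def test_written_files_byte_identical(self, small_config, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_scenario(simulate_scenario(small_config, seed=8), d1)
        write_scenario(simulate_scenario(small_config, seed=8), d2)
        for f1 in sorted(d1.iterdir()):
            assert (d2 / f1.name).read_bytes() == f1.read_bytes()

    def test_config_yaml_roundtrip(self, small_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = ScenarioConfig.from_yaml(p)
        assert back == small_config

    def test_default_rules_cover_all_conditions(self):
        rules = default_factor_rules()
        for f in ("Oct4", "Oct4defSox2", "Oct6"):
            for d in ("day1", "day5"):
                for cls in ("SoxOct", "MORE", "MORE_plus1", "octamer",
                            "Sox_single", "none"):
                    assert 0 <= rules.pou_prob(f, d, cls) <= 1
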