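import numpy as np
import pytest
from scipy.stats import chi2

from srnase_evol import all_pairs_kaks
from srnase_evol.divergence import GENETIC_CODE
from srnase_evol.synth import (
    PipelineOutputs,
    SimulationConfig,
    conversion_recovery,
    recovery_metrics,
    simulate_dataset,
)


class TestDeterminism:
    def test_same_seed_is_byte_identical(self):
        config = SimulationConfig(seed=4, n_sequences=20, n_codons=60)
        a1, t1 = simulate_dataset(config)
        a2, t2 = simulate_dataset(config)
        assert [(r.id, r.residues) for r in a1.records] == [
            (r.id, r.residues) for r in a2.records
        ]
        assert t1.pss_positions == t2.pss_positions
        assert t1.substitutions == t2.substitutions
        assert t1.conversions == t2.conversions

    def test_different_seeds_differ(self):
        a1, _ = simulate_dataset(SimulationConfig(seed=4, n_sequences=20, n_codons=60))
        a2, _ = simulate_dataset(SimulationConfig(seed=5, n_sequences=20, n_codons=60))
        assert [r.residues for r in a1.records] != [r.residues for r in a2.records]


class TestAlignmentStructure:
    def test_no_internal_stop_codons(self, default_sim):
        _config, alignment, _truth = default_sim
        for record in alignment.records:
            for k in range(0, alignment.length, 3):
                assert GENETIC_CODE[record.residues[k : k + 3]] != "*"

    def test_clades_span_genera(self, default_sim):
        config, _alignment, truth = default_sim
        for clade in set(truth.clade_of.values()):
            members = [s for s, c in truth.clade_of.items() if c == clade]
            genera = {truth.genus_of[s] for s in members}
            assert len(genera) == min(config.n_genera, len(members))

    def test_zero_conversion_rate_yields_no_events(self):
        config = SimulationConfig(seed=3, n_sequences=20, n_codons=60,
                                  conversion_rate=0.0)
        _a, truth = simulate_dataset(config)
        assert truth.conversions == ()

    def test_conversion_tracts_within_alignment(self, default_sim):
        _config, alignment, truth = default_sim
        for ev in truth.conversions:
            assert 1 <= ev.tract_start <= ev.tract_end <= alignment.length


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"omega_background": 0.0},
            {"clade_depth": 0.3, "crown_depth": 0.2},
            {"n_pss": 500},
            {"conversion_rate": -0.1},
            {"n_sequences": 3, "n_clades": 5},
        ],
    )
    def test_infeasible_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestNeutralCalibration:
    def test_realized_dnds_near_one(self):
        # neutral evolution, no transition bias (the counting method's
        # assumption), low divergence, many codons to average out the
        # genealogy; pairs pooled over three replicate datasets
        ratios = []
        for seed in (5, 6, 7):
            config = SimulationConfig(
                seed=seed, omega_pss=1.0, omega_background=1.0, kappa=1.0,
                conversion_rate=0.0, n_sequences=16, n_codons=2500,
                crown_depth=0.02, clade_depth=0.008, n_clades=4, n_pss=1,
            )
            alignment, _truth = simulate_dataset(config)
            ratios.extend(
                p.ka / p.ks for p in all_pairs_kaks(alignment) if p.ks > 0
            )
        assert len(ratios) >= 50
        assert 0.9 <= float(np.mean(ratios)) <= 1.1


class TestPoissonConsistency:
    def test_branch_counts_match_branch_lengths(self):
        config = SimulationConfig(
            seed=9, omega_pss=1.0, omega_background=1.0, kappa=1.0,
            conversion_rate=0.0, n_sequences=24, n_codons=800,
            crown_depth=0.05, clade_depth=0.02, n_clades=4, n_pss=1,
        )
        _a, truth = simulate_dataset(config)
        # expected events per branch: 3 substitutions/codon per unit depth
        observed, expected = [], []
        small_obs = small_exp = 0.0
        for branch, (syn, nonsyn) in truth.branch_counts.items():
            mu = 3.0 * config.n_codons * truth.branch_lengths[branch]
            if mu >= 5.0:
                observed.append(syn + nonsyn)
                expected.append(mu)
            else:
                small_obs += syn + nonsyn
                small_exp += mu
        if small_exp > 0:
            observed.append(small_obs)
            expected.append(small_exp)
        observed = np.array(observed, dtype=float)
        expected = np.array(expected)
        x2 = float(((observed - expected) ** 2 / expected).sum())
        assert x2 < chi2.ppf(0.999, df=len(expected))


class TestRecoveryMetrics:
    def test_perfect_inference_scores_perfectly(self, default_sim, default_matrix):
        from srnase_evol import cluster_specificities
        from srnase_evol.io import ProbabilityTrack
        from srnase_evol.selection import call_pss

        config, alignment, truth = default_sim
        n = alignment.n_codons
        oracle_profile = call_pss(
            ProbabilityTrack(
                [0.99 if k + 1 in truth.pss_positions else 0.0 for k in range(n)],
                [0.99 if k + 1 in truth.pss_positions else 0.0 for k in range(n)],
                [False] * n,
            )
        )
        outputs = PipelineOutputs(
            run_id=truth.run_id,
            pss_profile=oracle_profile,
            partition=cluster_specificities(default_matrix),
            n_syn_mutations=float(truth.n_syn_total),
        )
        metrics = recovery_metrics(outputs, truth)
        assert metrics.pss_precision == 1.0 and metrics.pss_recall == 1.0
        assert metrics.pss_fpr == 0.0
        assert metrics.cluster_count_error == 0
        assert metrics.syn_count_relative_error == 0.0

    def test_empty_pss_gives_zero_recall(self, default_sim):
        from srnase_evol.io import ProbabilityTrack
        from srnase_evol.selection import call_pss

        _config, alignment, truth = default_sim
        n = alignment.n_codons
        empty = call_pss(ProbabilityTrack([0.0] * n, [0.0] * n, [False] * n))
        metrics = recovery_metrics(
            PipelineOutputs(run_id=truth.run_id, pss_profile=empty), truth
        )
        assert metrics.pss_recall == 0.0

    def test_run_id_mismatch_rejected(self, default_sim):
        _config, _alignment, truth = default_sim
        with pytest.raises(ValueError):
            recovery_metrics(PipelineOutputs(run_id="sim-999"), truth)

    def test_metrics_stable_across_reruns(self):
        config = SimulationConfig(seed=1, n_sequences=20, n_codons=60)
        results = []
        for _ in range(2):
            _a, truth = simulate_dataset(config)
            outputs = PipelineOutputs(run_id=truth.run_id)
            results.append(recovery_metrics(outputs, truth))
        assert results[0] == results[1]
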