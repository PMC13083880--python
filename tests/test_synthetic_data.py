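"""Simulator: determinism, planted structure, stationary behavior, templates."""

import numpy as np
import pytest

import chromdyn as cd
from chromdyn.synthetic_data import ConfigurationError


class TestConfigValidation:
    def test_non_stochastic_transition_rejected(self):
        cfg = cd.SimConfig(transition_truth=np.eye(4) * 0.9)
        with pytest.raises(ConfigurationError):
            cd.simulate_chromatin(cfg)

    def test_non_positive_background_rejected(self):
        with pytest.raises(ConfigurationError):
            cd.simulate_chromatin(cd.SimConfig(lambda_bg=0.0))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            cd.simulate_chromatin(cd.SimConfig(chrom_length=20_000))

    def test_invalid_cluster_count_rejected(self):
        cfg = cd.SimConfig(
            n_chroms=1, chrom_length=200_000, n_genes=10, n_clusters_truth=0,
            delayed_fraction=0.0,
        )
        bins, _, truth = cd.simulate_chromatin(cfg)
        with pytest.raises(ConfigurationError):
            cd.simulate_expression(cfg, truth, bins)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = cd.SimConfig(n_chroms=1, chrom_length=500_000, n_genes=60, seed=5)
        out1 = cd.simulate_chromatin(cfg)
        out2 = cd.simulate_chromatin(cfg)
        for cond in cfg.conditions:
            assert np.array_equal(
                out1[1][cond].counts, out2[1][cond].counts
            )
            assert np.array_equal(
                out1[2].state_paths[cond], out2[2].state_paths[cond]
            )
        g1, e1, d1, t1 = cd.simulate_expression(cfg, out1[2], out1[0])
        g2, e2, d2, t2 = cd.simulate_expression(cfg, out2[2], out2[0])
        assert e1.tpm.equals(e2.tpm)
        assert g1.equals(g2)
        assert t1.delayed_genes == t2.delayed_genes

    def test_different_seed_different_output(self):
        c1 = cd.SimConfig(n_chroms=1, chrom_length=500_000, seed=1)
        c2 = cd.SimConfig(n_chroms=1, chrom_length=500_000, seed=2)
        a = cd.simulate_chromatin(c1)[1]["WT_0h"].counts
        b = cd.simulate_chromatin(c2)[1]["WT_0h"].counts
        assert not np.array_equal(a, b)


class TestChromatinStructure:
    def test_zero_delayed_fraction_plants_nothing(self):
        cfg = cd.SimConfig(delayed_fraction=0.0, n_chroms=1, chrom_length=500_000)
        _, _, truth = cd.simulate_chromatin(cfg)
        assert truth.delayed_bins == {}

    def test_states_partition_and_counts_non_negative(self, default_sim):
        truth, cfg = default_sim["truth"], default_sim["cfg"]
        for cond in cfg.conditions:
            path = truth.state_paths[cond]
            assert path.shape == (default_sim["bins"].n_bins,)
            assert np.all((path >= 1) & (path <= cfg.n_states))
            counts = default_sim["counts"][cond].counts
            assert np.issubdtype(counts.dtype, np.integer)
            assert np.all(counts >= 0)

    def test_planted_bins_carry_delayed_codes(self, default_sim):
        """Every planted bin shows 4 at three slots and a target state in
        the wild type at 16 h; its code is one of the delayed codes."""
        truth, cfg = default_sim["truth"], default_sim["cfg"]
        wt0, wt1, ko0, ko1 = (truth.state_paths[c] for c in cfg.conditions)
        assert len(truth.delayed_bins) > 0
        for b, code in truth.delayed_bins.items():
            assert wt0[b] == 4 and ko0[b] == 4 and ko1[b] == 4
            assert wt1[b] in cfg.delayed_targets
            assert code == f"#4{wt1[b]}_44"
            assert code in cd.DELAYED_CODES

    def test_state_frequencies_match_stationary_oracle(self):
        """Empirical state frequencies agree with the chain's stationary
        distribution computed independently by eigen-decomposition, with
        standard errors adjusted for Markov autocorrelation."""
        cfg = cd.SimConfig(delayed_fraction=0.0, seed=21)
        bins, _, truth = cd.simulate_chromatin(cfg)
        A = cfg.transition_truth
        # independent oracle: solve pi A = pi as a linear system
        K = A.shape[0]
        M = np.vstack([A.T - np.eye(K), np.ones(K)])
        rhs = np.concatenate([np.zeros(K), [1.0]])
        pi = np.linalg.lstsq(M, rhs, rcond=None)[0]
        # integrated autocorrelation time from the eigenvalue spectrum
        lam2 = sorted(np.abs(np.linalg.eigvals(A)))[-2]
        inflation = (1 + lam2) / (1 - lam2)
        n = bins.n_bins
        for cond in cfg.conditions:
            freq = np.bincount(truth.state_paths[cond], minlength=K + 1)[1:] / n
            se = np.sqrt(pi * (1 - pi) * inflation / n)
            assert np.all(np.abs(freq - pi) < 3 * se)

    def test_flat_fold_multiplier_gives_background_presence_rate(self):
        """With fold_on = 1 the on/off draw is invisible: the call rate
        equals the false-positive rate of the binarization rule."""
        cfg = cd.SimConfig(fold_on=1.0, delayed_fraction=0.0, seed=4)
        bins, counts, _ = cd.simulate_chromatin(cfg)
        binary = cd.binarize(counts[cfg.conditions[0]], bins)
        assert binary.calls.mean() < 0.01


class TestExpressionStructure:
    def test_gene_anchors_inside_genome(self, default_sim):
        truth, bins = default_sim["truth"], default_sim["bins"]
        for gene, b in truth.gene_anchor.items():
            assert 0 <= b < bins.n_bins
        genes = default_sim["genes"]
        for _, g in genes.iterrows():
            assert 0 <= g["start"] <= g["end"] <= bins.chrom_sizes[g["chrom"]]

    def test_delayed_genes_anchor_on_delayed_windows(self, default_sim):
        truth = default_sim["truth"]
        centers = {s + w // 2 for s, w, _t in truth.delayed_windows}
        anchored = {truth.gene_anchor[g] for g in truth.delayed_genes}
        assert anchored == centers

    def test_template_distances_match_configured_separation(self):
        """Recompute pairwise template distances from the emitted truth:
        the minimum equals separation * sigma * sqrt(D)."""
        cfg = cd.SimConfig(
            n_chroms=1, chrom_length=1_000_000, n_genes=120,
            n_clusters_truth=6, cluster_separation=3.0, seed=12,
        )
        bins, _, truth = cd.simulate_chromatin(cfg)
        _, _, _, truth = cd.simulate_expression(cfg, truth, bins)
        T = truth.cluster_templates
        dists = [
            np.linalg.norm(T[i] - T[j])
            for i in range(len(T))
            for j in range(i + 1, len(T))
        ]
        target = cfg.cluster_separation * cfg.sigma_within * np.sqrt(4)
        assert min(dists) == pytest.approx(target, rel=1e-9)

    def test_standalone_trajectories_equidistant_templates(self):
        X, labels, T = cd.simulate_trajectories(1200, 6, 6, 3.0, seed=1)
        target = 3.0 * 0.5 * np.sqrt(6)
        for i in range(6):
            for j in range(i + 1, 6):
                assert np.linalg.norm(T[i] - T[j]) == pytest.approx(target)
        assert X.shape == (1200, 6)
        assert set(labels) == set(range(1, 7))

    def test_non_delayed_gene_has_symmetric_condition_law(self, default_sim):
        """Genes away from delayed windows get no genotype effect: their
        planted mean surface is baseline + template + offsets in both
        genotypes, so no systematic knockout attenuation exists."""
        truth = default_sim["truth"]
        degs = default_sim["degs"]
        ko_contrast = [k for k in degs if k.startswith("KO")][0]
        down = set(cd.deg_set(degs[ko_contrast], "down"))
        # delayed genes are strongly down in the knockout contrast;
        # non-delayed genes hit the threshold only at the false-positive
        # level plus template differences, never en masse
        assert set(truth.delayed_genes) <= down

    def test_replicate_count(self, default_sim):
        expr = default_sim["expression"]
        cfg = default_sim["cfg"]
        assert expr.tpm.shape[1] == len(cfg.conditions) * 3
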