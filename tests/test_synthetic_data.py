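"""Seeded generator: determinism, coalescent expectations, truth records."""

import numpy as np
import pytest

from divmig.demography import DemographicModelSpec, ModelSpecError
from divmig.popstats import k2p_distance
from divmig.synthetic_data import (
    SimulationConfig,
    simulate_host_symbiont_dataset,
    simulate_locus_alignments,
    simulate_snp_genotypes,
)

_TRANSVERSION_PAIRS = {
    frozenset(p) for p in (("A", "C"), ("A", "T"), ("G", "C"), ("G", "T"))
}


class TestDeterminism:
    def test_snp_genotypes_bitwise_reproducible(self, small_sim_config):
        g1, t1 = simulate_snp_genotypes(small_sim_config)
        g2, t2 = simulate_snp_genotypes(small_sim_config)
        assert np.array_equal(g1.genotypes, g2.genotypes)
        assert np.array_equal(t1.snp_tmrca, t2.snp_tmrca)

    def test_locus_alignments_reproducible(self, small_sim_config):
        a1 = simulate_locus_alignments(small_sim_config)
        a2 = simulate_locus_alignments(small_sim_config)
        assert [x.sequences for x in a1] == [x.sequences for x in a2]

    def test_host_symbiont_reproducible(self, small_sim_config):
        r1 = simulate_host_symbiont_dataset(small_sim_config)
        r2 = simulate_host_symbiont_dataset(small_sim_config)
        assert r1[0].sequences == r2[0].sequences
        assert r1[1] == r2[1]

    def test_different_seed_changes_output(self, small_sim_config, si_spec):
        other = SimulationConfig(
            model_spec=si_spec, n1=4, n2=4, num_snp_sites=300, num_loci=2,
            locus_length=60, theta_site=0.01, seed=124,
        )
        g1, _ = simulate_snp_genotypes(small_sim_config)
        g2, _ = simulate_snp_genotypes(other)
        assert not np.array_equal(g1.genotypes, g2.genotypes)


class TestSnpGenotypes:
    def test_config_validation(self, si_spec):
        with pytest.raises(ModelSpecError):
            SimulationConfig(model_spec=si_spec, n1=0)
        with pytest.raises(ModelSpecError):
            SimulationConfig(model_spec=si_spec, theta_site=-1.0)
        with pytest.raises(ModelSpecError):
            SimulationConfig(model_spec=si_spec, transfer_prob=1.5)
        with pytest.raises(ModelSpecError):
            SimulationConfig(model_spec=si_spec, inheritance_scalar=0.0)

    def test_all_sites_segregating(self, small_sim_config):
        g, _ = simulate_snp_genotypes(small_sim_config)
        counts = g.genotypes.sum(axis=0)
        assert (counts > 0).all()
        assert (counts < 2 * g.n_individuals).all()

    def test_deep_split_yields_no_shared_polymorphism(self):
        spec = DemographicModelSpec("SI", nu1=1.0, nu2=1.0, T_s=20.0)
        cfg = SimulationConfig(
            model_spec=spec, n1=4, n2=4, num_snp_sites=2000, seed=7
        )
        g, _ = simulate_snp_genotypes(cfg)
        c1 = g.genotypes[:4].sum(axis=0)
        c2 = g.genotypes[4:].sum(axis=0)
        shared = ((c1 > 0) & (c1 < 8) & (c2 > 0) & (c2 < 8)).sum()
        assert shared / 2000 < 0.01

    def test_single_population_watterson_ratios(self):
        # xi_i proportional to 1/i for an equilibrium population
        spec = DemographicModelSpec("SI", nu1=1.0, nu2=1.0, T_s=0.3)
        cfg = SimulationConfig(
            model_spec=spec, n1=4, n2=0, num_snp_sites=10_000, seed=13
        )
        g, _ = simulate_snp_genotypes(cfg)
        counts = g.genotypes.sum(axis=0)
        n_hap = 8
        harmonic = sum(1.0 / i for i in range(1, n_hap))
        n_sites = counts.size
        for i in (1, 2, 3):
            p = (1.0 / i) / harmonic
            observed = (counts == i).sum()
            se = np.sqrt(n_sites * p * (1 - p))
            assert abs(observed - n_sites * p) < 3 * se

    def test_2m_truth_records_migration_class(self):
        # accepted class fractions are length-weighted by segregating-site
        # ascertainment; the expectation follows from the per-class
        # expected total tree length
        from divmig.demography import EngineConfig, expected_afs

        spec = DemographicModelSpec(
            "IM2M", nu1=1, nu2=1, M12=5, M21=5, Me12=0.01, Me21=0.01, T_s=1, P=0.6
        )
        cfg = SimulationConfig(model_spec=spec, n1=3, n2=3, num_snp_sites=2000, seed=3)
        _, truth = simulate_snp_genotypes(cfg)
        assert truth.snp_migration_class is not None
        frac = 1.0 - truth.snp_migration_class.mean()
        neutral = DemographicModelSpec("IM", nu1=1, nu2=1, M12=5, M21=5, T_s=1)
        barrier = DemographicModelSpec("IM", nu1=1, nu2=1, M12=0.01, M21=0.01, T_s=1)
        cfg_e = EngineConfig(20000, 9)
        t_n = expected_afs(neutral, 6, 6, cfg_e).total()
        t_b = expected_afs(barrier, 6, 6, cfg_e).total()
        expected = 0.6 * t_n / (0.6 * t_n + 0.4 * t_b)
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / 2000)

    def test_population_exchange_symmetry(self):
        a = DemographicModelSpec("IM", nu1=2.0, nu2=0.5, M12=1.5, M21=0.3, T_s=0.5)
        b = DemographicModelSpec("IM", nu1=0.5, nu2=2.0, M12=0.3, M21=1.5, T_s=0.5)
        n_sites = 4000
        ca = SimulationConfig(model_spec=a, n1=3, n2=2, num_snp_sites=n_sites, seed=41)
        cb = SimulationConfig(model_spec=b, n1=2, n2=3, num_snp_sites=n_sites, seed=42)
        ga, _ = simulate_snp_genotypes(ca)
        gb, _ = simulate_snp_genotypes(cb)
        from divmig.spectra import afs_from_genotypes

        sa = afs_from_genotypes(ga).data / n_sites
        sb = afs_from_genotypes(gb).data.T / n_sites
        se = np.sqrt(sa * (1 - sa) / n_sites + sb * (1 - sb) / n_sites)
        z = np.where(se > 0, (sa - sb) / np.where(se == 0, 1, se), 0.0)
        assert np.abs(z).max() < 4.5


class TestLocusAlignments:
    def test_locus_length_validation(self, si_spec):
        with pytest.raises(ModelSpecError):
            SimulationConfig(model_spec=si_spec, locus_length=0)

    def test_mito_one_sequence_nuclear_two_per_individual(self, small_sim_config):
        nuc = simulate_locus_alignments(small_sim_config, mitochondrial=False)[0]
        mito = simulate_locus_alignments(small_sim_config, mitochondrial=True)[0]
        assert len(nuc) == 2 * 8
        assert len(mito) == 8
        assert sorted(set(nuc.copy_index)) == [0, 1]

    def test_infinite_tstv_ratio_gives_transitions_only(self, si_spec):
        cfg = SimulationConfig(
            model_spec=si_spec, n1=4, n2=4, num_loci=3, locus_length=200,
            theta_site=0.02, ts_tv_ratio=np.inf, seed=5,
        )
        for aln in simulate_locus_alignments(cfg):
            ref = aln.sequences[0]
            for seq in aln.sequences[1:]:
                for x, y in zip(ref, seq):
                    if x != y:
                        assert frozenset((x, y)) not in _TRANSVERSION_PAIRS

    def test_inheritance_scalar_quarters_diversity(self, si_spec):
        # mean within-population pairwise diversity scales with effective size
        def mean_pi(scalar, seed):
            cfg = SimulationConfig(
                model_spec=si_spec, n1=4, n2=1, num_loci=200, locus_length=300,
                theta_site=0.02, inheritance_scalar=scalar, seed=seed,
            )
            vals = []
            for aln in simulate_locus_alignments(cfg, mitochondrial=True):
                pop1 = aln.by_population("pop1").sequences
                diffs = [
                    sum(1 for x, y in zip(a, b) if x != y) / len(a)
                    for i, a in enumerate(pop1)
                    for b in pop1[i + 1:]
                ]
                vals.append(np.mean(diffs))
            return np.array(vals)

        quarter = mean_pi(0.25, 31)
        full = mean_pi(1.0, 32)
        ratio = quarter.mean() / full.mean()
        # delta-method SE of the ratio across 200 replicate loci
        se = ratio * np.sqrt(
            quarter.var() / (len(quarter) * quarter.mean() ** 2)
            + full.var() / (len(full) * full.mean() ** 2)
        )
        assert abs(ratio - 0.25) < 4 * se

    def test_within_population_diversity_matches_theta(self, si_spec):
        # under SI with nu = 1, E[pairwise difference per site] = theta_site
        cfg = SimulationConfig(
            model_spec=si_spec, n1=4, n2=1, num_loci=300, locus_length=200,
            theta_site=0.01, seed=77,
        )
        vals = []
        for aln in simulate_locus_alignments(cfg, mitochondrial=True):
            pop1 = aln.by_population("pop1").sequences
            diffs = [
                sum(1 for x, y in zip(a, b) if x != y) / len(a)
                for i, a in enumerate(pop1)
                for b in pop1[i + 1:]
            ]
            vals.append(np.mean(diffs))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # finite-sites multiple hits bias the raw difference slightly low
        assert abs(vals.mean() - 0.01) < max(4 * se, 0.0005)

    def test_deep_mito_split_gives_k2p_scale_divergence(self):
        spec = DemographicModelSpec("SI", nu1=0.2, nu2=0.2, T_s=9.0)
        cfg = SimulationConfig(
            model_spec=spec, n1=5, n2=5, num_loci=1, locus_length=518,
            theta_site=0.005, inheritance_scalar=0.25, seed=11,
        )
        aln = simulate_locus_alignments(cfg, mitochondrial=True)[0]
        p1 = aln.by_population("pop1").sequences
        p2 = aln.by_population("pop2").sequences
        between = np.mean([k2p_distance(a, b) for a in p1 for b in p2])
        within = np.mean(
            [k2p_distance(a, b) for i, a in enumerate(p1) for b in p1[i + 1:]]
        )
        assert between > 10 * within
        assert 0.01 < between < 0.5


class TestHostSymbiont:
    def test_zero_transfer_prob_means_full_concordance(self, si_spec):
        cfg = SimulationConfig(
            model_spec=si_spec, n1=6, n2=6, num_loci=1, locus_length=60,
            transfer_prob=0.0, seed=2,
        )
        _, labels, truth = simulate_host_symbiont_dataset(cfg)
        ids, pops = cfg.individual_ids()
        assert [labels[i] for i in ids] == pops
        assert not any(truth.symbiont_flipped)

    def test_full_transfer_prob_flips_everyone(self, si_spec):
        cfg = SimulationConfig(
            model_spec=si_spec, n1=6, n2=6, num_loci=1, locus_length=60,
            transfer_prob=1.0, seed=2,
        )
        _, labels, truth = simulate_host_symbiont_dataset(cfg)
        ids, pops = cfg.individual_ids()
        assert all(labels[i] != p for i, p in zip(ids, pops))
        assert all(truth.symbiont_flipped)

    def test_transfer_fraction_within_binomial_interval(self, si_spec):
        cfg = SimulationConfig(
            model_spec=si_spec, n1=500, n2=500, num_loci=1, locus_length=30,
            transfer_prob=0.15, seed=8,
        )
        _, _, truth = simulate_host_symbiont_dataset(cfg)
        frac = np.mean(truth.symbiont_flipped)
        half_width = 2.576 * np.sqrt(0.15 * 0.85 / 1000)  # binomial 99% interval
        assert abs(frac - 0.15) < half_width
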