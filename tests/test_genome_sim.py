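"""Unit and property tests for the population simulator."""

import dataclasses

import numpy as np
import pytest

from ssgwas import genome_sim as gs

from conftest import micro_config


class TestSpecs:
    def test_trait_variances(self):
        tr = gs.TraitSpec(h2=0.14, var_p=1.0)
        assert tr.var_e == pytest.approx(0.86, abs=1e-12)
        assert tr.var_a + tr.var_e == pytest.approx(tr.var_p)
        with pytest.raises(ValueError):
            gs.TraitSpec(h2=1.2)
        with pytest.raises(ValueError):
            gs.TraitSpec(h2=0.5, var_p=-1)

    def test_genome_layout(self, tiny_genome):
        g = tiny_genome
        assert g.n_markers == 150 and g.n_qtl == 30
        assert g.chrom_lengths.sum() == pytest.approx(60.0)
        # positions strictly increasing within each chromosome
        for c in range(1, g.n_chromosomes + 1):
            pos = g.pos_cm[g.chrom == c]
            assert np.all(np.diff(pos) > 0)
        assert np.all(g.n_alleles[~g.is_qtl] == 2)
        assert np.all((g.n_alleles[g.is_qtl] >= 2) & (g.n_alleles[g.is_qtl] <= 4))

    def test_genome_rejects_bad_maps(self):
        with pytest.raises(ValueError):
            gs.GenomeSpec(chrom_lengths=[10.0], chrom=[1, 1],
                          pos_cm=[5.0, 3.0], is_qtl=[False, False],
                          n_alleles=[2, 2])
        with pytest.raises(ValueError):
            gs.GenomeSpec(chrom_lengths=[10.0], chrom=[1], pos_cm=[4.0],
                          is_qtl=[True], n_alleles=[7])

    def test_historical_schedule_full_scale_lengths(self):
        hld = gs.PopSchedule.historical(ld="hld")
        lld = gs.PopSchedule.historical(ld="lld")
        assert len(gs.historical_size_path(hld)) == 3020
        assert len(gs.historical_size_path(lld)) == 2020
        path = gs.historical_size_path(hld)
        assert path[0] == 1000 and path[-1] == 200
        assert np.all(np.diff(path[1000:]) <= 0)

    def test_pedigree_must_be_sorted(self):
        with pytest.raises(ValueError):
            gs.Population(sire=np.array([2, 0]), dam=np.array([0, 0]),
                          sex=np.array([1, 2]), generation=np.zeros(2, int),
                          haps=np.zeros((2, 2, 1), np.uint8))


class TestMeiosisAndMutation:
    def test_no_mutation_offspring_alleles_parental(self, rng):
        genome = gs.GenomeSpec.random(rng, n_chromosomes=1, total_length=1.0,
                                      n_markers=20, n_qtl=5, mutation_rate=0.0)
        sched = gs.PopSchedule.historical(constant_size=2, n_constant=1,
                                          final_size=2, n_decline=0)
        pop = gs.simulate_historical(genome, sched, 7)
        assert pop.n_animals == 2
        # with mutation off, every allele must already exist in generation 0:
        # all loci start with alleles drawn from {0..k-1}; here simply check
        # codes stay within the allele sets
        assert np.all(pop.haps < genome.n_alleles[None, None, :])

    def test_gene_drop_without_recombination(self, rng):
        # chromosomes of (near) zero map length cannot recombine: each
        # transmitted chromosome equals one parental haplotype exactly
        L = 30
        genome = gs.GenomeSpec(
            chrom_lengths=[1e-9], chrom=np.ones(L, int),
            pos_cm=np.linspace(0, 1e-9, L, endpoint=False),
            is_qtl=np.zeros(L, bool), n_alleles=np.full(L, 2),
            mutation_rate=0.0)
        haps = rng.integers(0, 2, size=(2, 2, L)).astype(np.uint8)
        parents = np.array([0, 0, 1, 1, 0, 1])
        gam = gs._make_gametes(rng, haps, parents, genome)
        for g, p in zip(gam, parents):
            assert (np.array_equal(g, haps[p, 0]) or
                    np.array_equal(g, haps[p, 1]))

    def test_recombination_fraction_matches_haldane(self, rng):
        # two loci 20 cM apart: recombinant fraction 0.5(1-exp(-0.4))
        genome = gs.GenomeSpec(chrom_lengths=[20.0], chrom=[1, 1],
                               pos_cm=[0.0, 20.0], is_qtl=[False, False],
                               n_alleles=[2, 2], mutation_rate=0.0)
        haps = np.array([[[0, 0], [1, 1]]], dtype=np.uint8)  # one parent
        gam = gs._make_gametes(rng, haps, np.zeros(40000, int), genome)
        rec = (gam[:, 0] != gam[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-0.4))
        assert rec == pytest.approx(expected, abs=0.01)


class TestDrift:
    def test_frequency_martingale_without_mutation(self, rng):
        sizes = [100] * 20
        k = np.full(2000, 2)
        p = gs.simulate_locus_drift(rng, sizes, k, mutation_rate=0.0)
        # E[p_t] = p_0 = 0.5: mean over many loci stays put
        assert p[:, 0].mean() == pytest.approx(0.5, abs=0.01)

    def test_heterozygosity_decays_faster_in_longer_bottleneck(self, rng):
        k = np.full(1500, 2)
        sizes_long = np.linspace(100, 40, 120).round().astype(int)
        sizes_short = np.linspace(100, 40, 60).round().astype(int)
        p_long = gs.simulate_locus_drift(rng, sizes_long, k, 0.0)
        p_short = gs.simulate_locus_drift(rng, sizes_short, k, 0.0)
        het = lambda p: (2 * p[:, 0] * (1 - p[:, 0])).mean()
        assert het(p_long) < het(p_short)


class TestPanelAndEffects:
    def test_all_fixed_loci_rejected(self):
        genome = gs.GenomeSpec(chrom_lengths=[10.0], chrom=[1, 1],
                               pos_cm=[1.0, 2.0], is_qtl=[False, True],
                               n_alleles=[2, 3])
        pop = gs.Population(sire=np.zeros(4, int), dam=np.zeros(4, int),
                            sex=np.array([1, 2, 1, 2]),
                            generation=np.zeros(4, int),
                            haps=np.zeros((4, 2, 2), np.uint8))
        with pytest.raises(ValueError, match="segregating"):
            gs.select_segregating_loci(pop, genome, 0.0, 0, 1, 0)

    def test_maf_zero_accepts_every_polymorphic_marker(self, tiny_genome,
                                                       tiny_population):
        mk = tiny_genome.marker_index
        f = tiny_population.haps[:, :, mk].mean(axis=(0, 1))
        n_poly = int(((f > 0) & (f < 1)).sum())
        sub, _ = gs.select_segregating_loci(tiny_population, tiny_genome,
                                            0.0, n_poly, 1, 0)
        assert sub.n_markers == n_poly

    def test_effect_scaling_is_exact(self, tiny_genome, tiny_population):
        trait = gs.TraitSpec()
        sub, pop = gs.select_segregating_loci(tiny_population, tiny_genome,
                                              0.02, 50, 10, 1)
        eff = gs.assign_qtl_effects(sub, trait, pop, 2)
        tbv = gs.compute_tbv(pop, sub, eff)
        assert np.var(tbv) == pytest.approx(trait.var_a, abs=1e-9)

    def test_zero_heritability_gives_zero_effects(self, tiny_genome,
                                                  tiny_population):
        trait = gs.TraitSpec(h2=0.0)
        sub, pop = gs.select_segregating_loci(tiny_population, tiny_genome,
                                              0.02, 50, 10, 1)
        eff = gs.assign_qtl_effects(sub, trait, pop, 2)
        assert np.all(eff.effects == 0)

    def test_single_qtl_variance_matches_hwe_enumeration(self):
        # one biallelic QTL, effects (0, e): Var(tbv) = e^2 2p(1-p) under
        # binomially weighted genotype counts
        e, p = 0.7, 0.3
        genome = gs.GenomeSpec(chrom_lengths=[10.0], chrom=[1], pos_cm=[5.0],
                               is_qtl=[True], n_alleles=[2])
        rng = np.random.default_rng(0)
        n = 200_000
        haps = (rng.random((n, 2, 1)) < p).astype(np.uint8)
        pop = gs.Population(sire=np.zeros(n, int), dam=np.zeros(n, int),
                            sex=np.ones(n, int), generation=np.zeros(n, int),
                            haps=haps)
        table = gs.QTLEffectTable(np.array([[0.0, e, 0.0, 0.0]]), 1.0)
        tbv = gs.compute_tbv(pop, genome, table)
        assert np.var(tbv) == pytest.approx(e**2 * 2 * p * (1 - p), rel=0.02)


class TestPhenotypes:
    def _founders(self, rng, n=400):
        genome = gs.GenomeSpec.random(rng, n_chromosomes=2, total_length=20,
                                      n_markers=40, n_qtl=40)
        sched = gs.PopSchedule.historical(constant_size=n, n_constant=5,
                                          final_size=n, n_decline=0)
        pop = gs.simulate_historical(genome, sched, rng)
        trait = gs.TraitSpec()
        eff = gs.assign_qtl_effects(genome, trait, pop, rng)
        return genome, trait, eff, dataclasses.replace(
            pop, tbv=gs.compute_tbv(pop, genome, eff))

    def test_zero_residual_variance_phenotype_equals_tbv(self, rng):
        genome, _, eff, pop = self._founders(rng, n=100)
        trait = gs.TraitSpec(h2=1.0 - 1e-12)  # var_e ~ 0
        pop = gs.simulate_phenotypes(pop, trait, rng)
        f = pop.females
        assert np.allclose(pop.phenotype[f], pop.tbv[f], atol=1e-5)

    def test_males_have_no_records(self, rng):
        genome, trait, eff, pop = self._founders(rng, n=100)
        pop = gs.simulate_phenotypes(pop, trait, rng)
        assert np.all(np.isnan(pop.phenotype[pop.males]))
        assert np.all(~np.isnan(pop.phenotype[pop.females]))

    def test_offspring_phenotype_regresses_on_midparent_tbv(self, rng):
        # slope of offspring phenotype on mid-parent TBV ~ 1: the offspring
        # TBV is the mid-parent value plus Mendelian sampling noise
        genome, trait, eff, pop = self._founders(rng, n=1000)
        off = gs.simulate_expansion(pop, genome,
                                    gs.PopSchedule.expansion(1, 5), rng)
        new = off.generation == 1
        tbv = gs.compute_tbv(off, genome, eff)
        mid = 0.5 * (tbv[off.sire[new] - 1] + tbv[off.dam[new] - 1])
        phe = tbv[new] + rng.normal(0, np.sqrt(trait.var_e), new.sum())
        slope = np.polyfit(mid, phe, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.12)

    def test_realized_heritability(self, rng):
        # Var(tbv)/Var(phenotype) in unselected cohorts = h2 within 2 SE
        # over 10 replicates
        vals = []
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            genome, trait, eff, pop = self._founders(r, n=500)
            pop = gs.simulate_phenotypes(pop, trait, r)
            f = pop.females
            vals.append(np.var(pop.tbv[f]) / np.var(pop.phenotype[f]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.14) <= 2 * se + 1e-9


class TestExpansionAndSelection:
    def test_expansion_zero_generations_is_identity(self, tiny_genome,
                                                    tiny_population):
        out = gs.simulate_expansion(tiny_population, tiny_genome,
                                    gs.PopSchedule.expansion(0), 0)
        assert out is tiny_population

    def test_expansion_cohort_sizes_double(self, tiny_genome, tiny_population):
        out = gs.simulate_expansion(tiny_population, tiny_genome,
                                    gs.PopSchedule.expansion(3, 5), 0)
        n_dams0 = (tiny_population.sex == 2).sum()
        sizes = np.bincount(out.generation)[1:]
        assert sizes[0] == 5 * n_dams0
        assert sizes[1] == 5 * 2 * n_dams0
        assert sizes[2] == 5 * 4 * n_dams0

    def test_selection_zero_replacement_keeps_parents(self, rng):
        genome = gs.GenomeSpec.random(rng, 2, 20, 60, 20)
        sched = gs.PopSchedule.historical(constant_size=80, n_constant=5,
                                          final_size=80, n_decline=0)
        pop = gs.simulate_historical(genome, sched, rng)
        trait = gs.TraitSpec()
        eff = gs.assign_qtl_effects(genome, trait, pop, rng)
        sel = gs.simulate_selection(
            pop, trait, genome, eff,
            gs.PopSchedule.selection(3, 4, 20, 0.0), rng)
        for g in (1, 2, 3):
            cohort = sel.generation == g
            assert set(sel.sire[cohort]) <= set(sel.sire[sel.generation == 1])
            assert set(sel.dam[cohort]) == set(sel.dam[sel.generation == 1])

    def test_selection_response_is_positive(self):
        # truncation selection on EBV raises mean TBV (10 small replicates)
        gains = []
        for rep in range(10):
            r = np.random.default_rng(3000 + rep)
            genome = gs.GenomeSpec.random(r, 2, 40, 80, 40)
            pop = gs.simulate_historical(
                genome,
                gs.PopSchedule.historical(constant_size=120, n_constant=10,
                                          final_size=120, n_decline=0), r)
            trait = gs.TraitSpec(h2=0.4)
            eff = gs.assign_qtl_effects(genome, trait, pop, r)
            sel = gs.simulate_selection(
                pop, trait, genome, eff,
                gs.PopSchedule.selection(4, 6, 40, 0.3), r)
            gains.append(sel.tbv[sel.generation == 4].mean() -
                         sel.tbv[sel.generation == 1].mean())
        assert np.mean(gains) > 0

    def test_selection_insufficient_candidates_raises(self, rng):
        genome = gs.GenomeSpec.random(rng, 2, 20, 60, 20)
        pop = gs.simulate_historical(
            genome, gs.PopSchedule.historical(constant_size=30, n_constant=5,
                                              final_size=30, n_decline=0), rng)
        trait = gs.TraitSpec()
        eff = gs.assign_qtl_effects(genome, trait, pop, rng)
        with pytest.raises(ValueError, match="sires"):
            gs.simulate_selection(pop, trait, genome, eff,
                                  gs.PopSchedule.selection(2, 25, 25, 0.2),
                                  rng)
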