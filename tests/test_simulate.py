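"""Genome, meiosis, backcross, genotype-call and growth-curve simulation."""

import numpy as np
import pytest

from alecross import datasets
from alecross import filtering as flt
from alecross import growth as gr
from alecross import simulate as sim


class TestEvolvedGenome:
    def test_zero_rate_plants_only_causal_variants(self, yeast_parent, phenotype_model):
        spec0 = sim.GenomeSpec(yeast_parent.spec.chromosomes, 0.0, 50)
        evolved = sim.simulate_evolved_genome(yeast_parent, spec0, phenotype_model, seed=1)
        assert set(evolved.variants) == set(phenotype_model.causal_loci)
        assert all(v.causal for v in evolved.variants.values())
        mu, lag = sim.assign_phenotype(evolved, phenotype_model)
        assert (mu, lag) == (phenotype_model.mu_both, phenotype_model.lag_both)

    def test_neutral_count_matches_poisson_mean(self, yeast_spec, phenotype_model):
        # 12 Mbp x 1e-9 /bp/gen x 50 generations -> mean 0.6 mutations
        parent = sim.HaploidGenome(yeast_spec)
        mean = yeast_spec.total_bp * 1e-9 * 50
        counts = [
            len(sim.simulate_evolved_genome(parent, yeast_spec, phenotype_model,
                                            n_causal=0, seed=s).variants)
            for s in range(10_000)
        ]
        se = np.sqrt(mean / len(counts))
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_causal_collision_names_locus(self, yeast_spec, phenotype_model):
        chrom, pos = phenotype_model.causal_loci[0]
        parent = sim.HaploidGenome(yeast_spec).with_variants(
            [sim.Variant(chrom, pos, "A", "C")]
        )
        with pytest.raises(ValueError, match=f"{chrom}:{pos}"):
            sim.simulate_evolved_genome(parent, yeast_spec, phenotype_model, seed=0)


class TestPhenotypeLookup:
    def test_two_locus_table(self, phenotype_model, yeast_spec):
        a, b = phenotype_model.causal_loci
        base = sim.HaploidGenome(yeast_spec)
        va = sim.Variant(*a, "C", "T", causal=True)
        vb = sim.Variant(*b, "A", "G", causal=True)
        assert sim.assign_phenotype(base, phenotype_model)[0] == 0.0
        assert sim.assign_phenotype(base.with_variants([va]), phenotype_model)[0] == 0.060
        assert sim.assign_phenotype(base.with_variants([vb]), phenotype_model)[0] == 0.033
        assert sim.assign_phenotype(base.with_variants([va, vb]), phenotype_model)[0] == 0.130

    def test_flat_model_ignores_genotype(self, yeast_spec):
        model = sim.PhenotypeModel(
            mu_none=0.1, mu_gut1_only=0.1, mu_ubr2_only=0.1, mu_both=0.1
        )
        a, _ = model.causal_loci
        base = sim.HaploidGenome(yeast_spec)
        carrier = base.with_variants([sim.Variant(*a, "C", "T")])
        assert sim.assign_phenotype(base, model)[0] == sim.assign_phenotype(carrier, model)[0]


class TestMeiosis:
    def test_identical_parents_give_identical_spores(self, one_chrom_spec):
        parent = sim.HaploidGenome(one_chrom_spec).with_variants(
            [sim.Variant("c1", 1000, "C", "T")]
        )
        spores = sim.simulate_meiosis(parent, parent, sim.CrossConfig(), seed=0)
        assert all(set(s.variants) == set(parent.variants) for s in spores)

    def test_two_to_two_segregation_at_every_site(self, one_chrom_spec):
        parent = sim.HaploidGenome(one_chrom_spec)
        evolved = sim.plant_neutral_mutations(parent, 100, seed=1)
        cfg = sim.CrossConfig(recombination_rate=4.0)
        for seed in range(100):
            spores = sim.simulate_meiosis(evolved, parent, cfg, seed=seed)
            for locus in evolved.variants:
                assert sum(s.carries(locus) for s in spores) == 2

    def test_mismatched_specs_rejected(self, one_chrom_spec, two_chrom_spec):
        with pytest.raises(ValueError):
            sim.simulate_meiosis(
                sim.HaploidGenome(one_chrom_spec),
                sim.HaploidGenome(two_chrom_spec),
                sim.CrossConfig(),
                seed=0,
            )

    def test_bit_reproducible_given_seed(self, one_chrom_spec):
        parent = sim.HaploidGenome(one_chrom_spec)
        evolved = sim.plant_neutral_mutations(parent, 30, seed=5)
        cfg = sim.CrossConfig(recombination_rate=2.0)
        a = sim.simulate_meiosis(evolved, parent, cfg, seed=42)
        b = sim.simulate_meiosis(evolved, parent, cfg, seed=42)
        assert [set(s.variants) for s in a] == [set(s.variants) for s in b]


class TestBackcrossProgram:
    def test_unselected_retention_halves_per_round(self, yeast_parent, phenotype_model):
        per_round = np.zeros(3)
        reps = 25
        for rep in range(reps):
            evolved = sim.plant_neutral_mutations(yeast_parent, 300, seed=500 + rep)
            cfg = sim.CrossConfig(selection_rule="random", seed=rep)
            _, retention = sim.run_backcross_program(
                evolved, yeast_parent, cfg, phenotype_model
            )
            per_round += np.array(retention)
        per_round /= reps
        for k in (1, 2, 3):
            expected = sim.expected_neutral_retention(k)
            se = np.sqrt(expected * (1 - expected) / (reps * 300))
            # loci within a chromosome co-segregate, so allow a generous band
            assert abs(per_round[k - 1] - expected) < 10 * se

    def test_max_mu_selection_keeps_both_causal_loci(self, yeast_parent, phenotype_model):
        spec0 = sim.GenomeSpec(yeast_parent.spec.chromosomes, 0.0, 50)
        evolved = sim.simulate_evolved_genome(yeast_parent, spec0, phenotype_model, seed=3)
        for seed in range(25):
            cfg = sim.CrossConfig(seed=seed)  # max_mu, 28 screened, 3 rounds
            final, _ = sim.run_backcross_program(evolved, yeast_parent, cfg, phenotype_model)
            assert all(final.carries(l) for l in phenotype_model.causal_loci)
            assert sim.assign_phenotype(final, phenotype_model)[0] == phenotype_model.mu_both

    def test_zero_screened_segregants_rejected(self):
        with pytest.raises(ValueError):
            sim.CrossConfig(segregants_screened_per_round=0)


class TestGenotypeCalls:
    def test_noise_free_calls_equal_truth(self, one_chrom_spec):
        parent = sim.HaploidGenome(one_chrom_spec)
        evolved = sim.plant_neutral_mutations(parent, 20, seed=9)
        noise = sim.CallNoiseModel(mean_depth=85, depth_dispersion=0.0, base_error_rate=0.0)
        records = sim.simulate_genotype_calls(
            [parent, evolved], noise, seed=0, sample_names=["P", "E"]
        )
        assert len(records) == 20
        for rec in records:
            var = evolved.variants[(rec.chromosome, rec.position)]
            assert rec.call("P").allele == var.ref_allele
            assert rec.call("E").allele == var.alt_allele
            assert all(c.depth == 85 and c.quality == 255 for c in rec.calls)

    def test_half_error_rate_miscalls_half_the_sites(self, one_chrom_spec):
        parent = sim.HaploidGenome(one_chrom_spec)
        carrier = sim.plant_neutral_mutations(parent, 10_000, seed=11)
        noise = sim.CallNoiseModel(mean_depth=30, depth_dispersion=0.0, base_error_rate=0.5)
        records = sim.simulate_genotype_calls([carrier], noise, seed=1, sample_names=["S"])
        miscalls = sum(
            1
            for rec in records
            if rec.call("S").allele != carrier.variants[(rec.chromosome, rec.position)].alt_allele
        )
        n = len(records)
        assert abs(miscalls / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_het_artifact_and_cnv_regions(self, one_chrom_spec):
        parent = sim.HaploidGenome(one_chrom_spec)
        carrier = parent.with_variants(
            [sim.Variant("c1", 500, "C", "T"), sim.Variant("c1", 5000, "G", "A")]
        )
        noise = sim.CallNoiseModel(
            mean_depth=50,
            depth_dispersion=0.0,
            base_error_rate=0.0,
            het_artifact_regions=(("c1", 400, 600),),
            cnv_regions=(("c1", 4500, 5500),),
        )
        records = sim.simulate_genotype_calls([parent, carrier], noise, seed=0,
                                              sample_names=["P", "C"])
        by_pos = {r.position: r for r in records}
        assert by_pos[500].call("P").is_het and by_pos[500].call("C").is_het
        assert all(by_pos[5000].in_cnv.values())
        assert not any(by_pos[500].in_cnv.values())

    def test_trio_table_round_trips_through_cascade(self):
        """Genomes encoding the packaged trio variants, called without noise,
        filter and classify back to the same ten records."""
        fixture = datasets.trio_filtered_variants()
        chroms = {}
        for rec in fixture:
            chroms[rec.chromosome] = max(chroms.get(rec.chromosome, 0), rec.position + 1000)
        spec = sim.GenomeSpec(tuple(chroms.items()), 0.0, 50)
        roles = datasets.trio_roles()
        genomes = {}
        for name in roles.as_tuple():
            variants = [
                sim.Variant(rec.chromosome, rec.position, rec.ref_allele,
                            rec.call(name).allele)
                for rec in fixture
                if rec.call(name).allele != rec.ref_allele
            ]
            genomes[name] = sim.HaploidGenome(spec).with_variants(variants)
        noise = sim.CallNoiseModel(mean_depth=100, depth_dispersion=0.0, base_error_rate=0.0)
        called = sim.simulate_genotype_calls(
            list(genomes.values()), noise, seed=0, sample_names=list(genomes)
        )
        result = flt.run_cascade(called, flt.FilterConfig(), roles)
        expected = flt.run_cascade(fixture, flt.FilterConfig(), roles)
        key = lambda res: sorted(
            (r.chromosome, r.position, s.value)
            for r, s in zip(res.records, res.statuses)
        )
        assert key(result) == key(expected)
        assert len(result.records) == 10


class TestGrowthCurveSimulation:
    def test_zero_rate_curve_is_constant(self):
        curve = sim.simulate_growth_curve(0.0, lag=0.0, noise_sd=0.0, seed=0)
        od = curve.to_od().values
        assert np.allclose(od, od[0], rtol=1e-9)

    def test_od_g_od_round_trip(self):
        curve = sim.simulate_growth_curve(0.13, lag=5.0, noise_sd=0.0, seed=0)
        od = curve.to_od().values
        assert np.allclose(gr.g_to_od(gr.od_to_g(od)), od, rtol=1e-9)

    def test_mu_round_trip_with_large_cap(self):
        curve = sim.simulate_growth_curve(
            0.130, lag=0.0, od0=0.01, od_cap=10.0, noise_sd=0.0, seed=0
        )
        stats = gr.estimate_mu_max(curve)
        assert stats.mu_max == pytest.approx(0.130, abs=0.002)

    def test_cap_not_above_inoculum_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_growth_curve(0.1, lag=0.0, od0=0.5, od_cap=0.5)

    def test_bit_reproducible_given_seed(self):
        a = sim.simulate_growth_curve(0.06, 10.0, noise_sd=0.05, seed=3)
        b = sim.simulate_growth_curve(0.06, 10.0, noise_sd=0.05, seed=3)
        assert np.array_equal(a.values, b.values)


class TestSeedDerivation:
    def test_stage_seeds_distinct_and_stable(self):
        seeds = [sim.stage_seed(123, k) for k in range(10)]
        assert len(set(seeds)) == 10
        assert seeds == [sim.stage_seed(123, k) for k in range(10)]
        assert all(0 <= s < 2**31 for s in seeds)
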