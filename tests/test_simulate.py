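"""The Wright-Fisher admixture engine: reservoirs, generation mechanics,
lazy/materialised equivalence, sampling."""

import numpy as np
import pytest

from admixhist import synthdata as sd
from admixhist.scenarios import (
    AFRICAN,
    EUROPEAN,
    DemographyParams,
    ParameterVector,
    PulseProcess,
)
from admixhist.simulate import (
    AdmixedPopulation,
    InsufficientUnrelatedError,
    _GenerationRecord,
    _make_generation,
    build_reservoir,
    advance_generation,
    resolve_genotypes,
    run_simulation,
    sample_source,
    sample_unrelated,
    _grandparent_codes,
)


class TestReservoir:
    def test_empirical_frequency_matches_target(self):
        res = build_reservoir(np.array([0.5]), R=20_000,
                              rng=np.random.default_rng(0))
        f = res.haplotypes.mean()
        assert 0.49 <= f <= 0.51

    def test_monomorphic_frequency_warns_and_fixes_column(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            res = build_reservoir(np.array([1.0, 0.5]), R=50,
                                  rng=np.random.default_rng(1))
        assert np.all(res.haplotypes[:, 0] == 1)

    def test_invalid_frequency_errors(self):
        with pytest.raises(ValueError):
            build_reservoir(np.array([1.2]), R=10, rng=np.random.default_rng(2))

    def test_seeded_determinism(self):
        a = build_reservoir(np.full(20, 0.3), R=100, rng=np.random.default_rng(3))
        b = build_reservoir(np.full(20, 0.3), R=100, rng=np.random.default_rng(3))
        assert np.array_equal(a.haplotypes, b.haplotypes)


def _pulse_params(s_afr_0, s_pulse=0.0, demog=(100, 400, 0.5)):
    return ParameterVector(
        scenario="Afr2Pulses-Eur2Pulses",
        s_Afr_0=s_afr_0,
        african_process=PulseProcess(AFRICAN, 15, 5, s_pulse, s_pulse),
        european_process=PulseProcess(EUROPEAN, 17, 7, s_pulse, s_pulse),
        demography=DemographyParams(*demog),
    )


class TestEngineEquivalence:
    def test_lazy_and_materialised_genotypes_are_bit_identical(self, tiny_reservoirs):
        pv = _pulse_params(0.5, 0.2, demog=(50, 150, 0.5))
        full = run_simulation(pv, tiny_reservoirs,
                              np.random.default_rng(42), materialize=True)
        lazy = run_simulation(pv, tiny_reservoirs, np.random.default_rng(42))
        idx = np.arange(25)
        g_lazy, _ = resolve_genotypes(lazy, idx, tiny_reservoirs)
        assert np.array_equal(full.genotypes[idx], g_lazy)

    def test_seed_determinism_of_sampled_genotypes(self, tiny_reservoirs):
        pv = _pulse_params(0.3, 0.1, demog=(60, 200, 0.3))
        outs = []
        for _ in range(2):
            pop = run_simulation(pv, tiny_reservoirs, np.random.default_rng(5))
            g, _ = resolve_genotypes(pop, np.arange(10), tiny_reservoirs)
            outs.append(g)
        assert np.array_equal(outs[0], outs[1])


class TestAncestryDynamics:
    def test_single_source_founding_gives_pure_ancestry(self, tiny_reservoirs):
        pv = _pulse_params(1.0, 0.0)
        pop = run_simulation(pv, tiny_reservoirs, np.random.default_rng(8))
        _, dos = resolve_genotypes(pop, np.arange(20), tiny_reservoirs,
                                   with_ancestry=True)
        assert np.all(dos == 2)

    def test_founding_fraction_preserved_under_drift(self, tiny_reservoirs):
        # no post-founding gene flow: mean African genome fraction stays
        # near s_Afr,0 within Wright-Fisher drift error (N >= 2000)
        pv = _pulse_params(0.6, 0.0, demog=(1000, 2000, 0.5))
        pop = run_simulation(pv, tiny_reservoirs, np.random.default_rng(9))
        _, dos = resolve_genotypes(pop, np.arange(40), tiny_reservoirs,
                                   with_ancestry=True)
        assert dos.mean() / 2 == pytest.approx(0.6, abs=0.1)

    def test_single_european_pulse_halves_african_ancestry(self, tiny_reservoirs):
        pv = ParameterVector(
            scenario="Afr2Pulses-Eur2Pulses",
            s_Afr_0=1.0,
            african_process=PulseProcess(AFRICAN, 15, 5, 0.0, 0.0),
            european_process=PulseProcess(EUROPEAN, 10, 2, 0.5, 0.0),
            demography=DemographyParams(1000, 2000, 0.5),
        )
        pop = run_simulation(pv, tiny_reservoirs, np.random.default_rng(10))
        _, dos = resolve_genotypes(pop, np.arange(40), tiny_reservoirs,
                                   with_ancestry=True)
        assert dos.mean() / 2 == pytest.approx(0.5, abs=0.1)

    def test_ancestry_variance_narrows_with_generations(self, tiny_reservoirs):
        # with no post-founding gene flow, individual admixture fractions
        # homogenise: the g=20 variance is below the early-generation one
        pv = _pulse_params(0.5, 0.0, demog=(500, 500, 0.5))
        rng = np.random.default_rng(11)
        pop = run_simulation(pv, tiny_reservoirs, rng)
        _, dos20 = resolve_genotypes(pop, np.arange(100), tiny_reservoirs,
                                     with_ancestry=True)
        var20 = (dos20.mean(axis=1) / 2).var()
        # right after founding an individual's fraction is the mean of two
        # Bernoulli(0.5) parental labels (variance 0.125); by g=20 the
        # fractions have homogenised far below that
        assert var20 < 0.02 < 0.125


class TestGenerationMechanics:
    def test_offspring_equal_sum_of_two_gametes(self, tiny_reservoirs):
        pv = _pulse_params(0.5, 0.2, demog=(40, 100, 0.5))
        pop = run_simulation(pv, tiny_reservoirs, np.random.default_rng(13),
                             materialize=True)
        g = pop.genotypes
        assert g.min() >= 0 and g.max() <= 2
        assert np.array_equal(pop.haplotypes.sum(axis=1), g)

    def test_pure_drift_generation_decays_heterozygosity(self, tiny_reservoirs):
        # E[H'] = (1 - 1/(2N)) H under Wright-Fisher; N = 20 over many
        # replicate single generations
        from admixhist.sumstats import heterozygosity_stats

        pv = _pulse_params(0.5, 0.0, demog=(20, 100, 0.0))
        base = run_simulation(pv, tiny_reservoirs, np.random.default_rng(14),
                              materialize=True)
        base = AdmixedPopulation(g=base.g, N=20, records=base.records[:-1] + [
            _GenerationRecord(parent=base.records[-1].parent[:20],
                              src_gametes=base.records[-1].src_gametes,
                              src_pop=base.records[-1].src_pop)],
            sizes=base.sizes[:-1] + [20], haplotypes=base.haplotypes[:20],
            seg_seed=base.seg_seed)
        ratios = []
        h0 = heterozygosity_stats(base.genotypes)[0]
        for s in range(40):
            nxt = advance_generation(base, (0.0, 0.0, 1.0), tiny_reservoirs,
                                     np.random.default_rng(100 + s))
            ratios.append(heterozygosity_stats(nxt.genotypes)[0] / h0)
        expected = 1 - 1 / (2 * base.N)
        assert np.mean(ratios) == pytest.approx(expected, abs=0.02)

    def test_single_individual_population_cannot_avoid_selfing(self, tiny_reservoirs):
        with pytest.raises(ValueError, match="selfing"):
            _make_generation(1, (0.0, 0.0, 1.0), 1, tiny_reservoirs,
                             np.random.default_rng(15))

    def test_drift_with_no_previous_generation_errors(self, tiny_reservoirs):
        with pytest.raises(ValueError):
            _make_generation(10, (0.0, 0.0, 1.0), 0, tiny_reservoirs,
                             np.random.default_rng(16))


class TestSampling:
    def test_unrelated_sample_shares_no_grandparents(self, tiny_reservoirs):
        pv = _pulse_params(0.5, 0.1, demog=(200, 800, 0.5))
        rng = np.random.default_rng(17)
        pop = run_simulation(pv, tiny_reservoirs, rng)
        idx = sample_unrelated(pop, 20, rng)
        gp = _grandparent_codes(pop)
        seen = set()
        for o in idx:
            row = set(gp[o].tolist())
            assert not (row & seen)
            seen |= row

    def test_single_individual_sample_always_succeeds(self, tiny_reservoirs):
        pv = _pulse_params(0.5, 0.0, demog=(20, 100, 0.5))
        rng = np.random.default_rng(18)
        pop = run_simulation(pv, tiny_reservoirs, rng)
        assert sample_unrelated(pop, 1, rng).size == 1

    def test_sibling_population_has_no_unrelated_pair(self, tiny_reservoirs):
        # two individuals built from the same two parents (full sibs)
        pv = _pulse_params(0.5, 0.0, demog=(10, 100, 0.5))
        rng = np.random.default_rng(19)
        pop = run_simulation(pv, tiny_reservoirs, rng)
        rec = pop.records[-1]
        sib_parent = np.vstack([rec.parent[0], rec.parent[0]])  # full sibs
        rec2 = _GenerationRecord(parent=sib_parent,
                                 src_gametes=rec.src_gametes,
                                 src_pop=rec.src_pop)
        pop2 = AdmixedPopulation(g=pop.g, N=2, records=pop.records[:-1] + [rec2],
                                 sizes=pop.sizes[:-1] + [2],
                                 seg_seed=pop.seg_seed)
        with pytest.raises(InsufficientUnrelatedError):
            sample_unrelated(pop2, 2, rng)

    def test_source_sample_shapes_and_frequencies(self, tiny_reservoirs):
        rng = np.random.default_rng(20)
        res = tiny_reservoirs[AFRICAN]
        g = sample_source(res, n=60, rng=rng)
        assert g.shape == (60, res.L)
        assert set(np.unique(g)) <= {0, 1, 2}
        err = np.abs(g.mean(axis=0) / 2 - res.haplotypes.mean(axis=0))
        assert err.mean() < 0.05

    def test_source_sample_edge_cases(self, tiny_reservoirs):
        res = tiny_reservoirs[EUROPEAN]
        assert sample_source(res, n=0, rng=np.random.default_rng(0)).shape == (0, res.L)
        with pytest.raises(ValueError):
            sample_source(res, n=res.R, rng=np.random.default_rng(0))
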