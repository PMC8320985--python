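import math

import numpy as np
import pytest

from eorscode import ConstraintProfile, is_valid_codeword
from eorscode.eo import (
    C_MAX,
    C_MIN,
    EOParams,
    EquilibriumPool,
    Particle,
    decode_particle,
    eo_search,
    exponential_term,
    generation_rate,
    initialize_population,
    time_parameter,
    update_concentration,
)
from eorscode.oracle import build_conflict_graph, max_clique_exact


@pytest.fixture
def params():
    return EOParams(pop_size=10, t_max=20, seed=7)


class TestEOParams:
    def test_defaults(self):
        p = EOParams()
        assert (p.pop_size, p.t_max) == (50, 1000)
        assert (p.a1, p.a2, p.rp, p.v) == (2.0, 1.0, 0.5, 1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(pop_size=0), dict(t_max=-1), dict(rp=1.5), dict(a1=0), dict(v=-1)],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            EOParams(**kwargs)


class TestInitialization:
    def test_population_shape_and_bounds(self, params, small_profile):
        pop = initialize_population(params, small_profile)
        assert len(pop) == params.pop_size
        for p in pop:
            assert p.concentration.shape == (small_profile.n,)
            assert (p.concentration >= C_MIN).all()
            assert (p.concentration <= C_MAX).all()
            assert is_valid_codeword(p.decoded, small_profile)

    def test_seeded_determinism(self, params, small_profile):
        a = initialize_population(params, small_profile)
        b = initialize_population(params, small_profile)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.concentration, y.concentration)
            assert x.decoded == y.decoded

    def test_extreme_r_maps_to_bounds(self, small_profile):
        # r == 0 gives c_min, r == 1 gives c_max under the affine map
        assert C_MIN + (C_MAX - C_MIN) * 0.0 == C_MIN
        assert C_MIN + (C_MAX - C_MIN) * 1.0 == C_MAX


class TestTimeParameter:
    def test_endpoints(self, params):
        assert time_parameter(0, params) == 1.0
        assert time_parameter(params.t_max, params) == 0.0

    def test_midpoint(self):
        params = EOParams(t_max=1000, a2=1.0)
        assert time_parameter(500, params) == pytest.approx(math.sqrt(0.5))


class TestExponentialTerm:
    def test_zero_time_gives_zero(self, params):
        lam = np.array([0.3, 0.7])
        r = np.array([0.1, 0.9])
        np.testing.assert_allclose(
            exponential_term(lam, 0.0, params, r), np.zeros(2)
        )

    def test_sign_and_magnitude(self, params):
        lam = np.full(4, 0.5)
        r = np.full(4, 0.9)  # > 0.5 everywhere
        F = exponential_term(lam, 1.0, params, r)
        assert (F < 0).all()
        assert (np.abs(F) < params.a1).all()

    def test_closed_form_value(self):
        params = EOParams(a1=2.0)
        F = exponential_term(np.array([math.log(2)]), 1.0, params, np.array([0.9]))
        assert F[0] == pytest.approx(-1.0)


class TestGenerationRate:
    def setup_method(self):
        self.lam = np.array([0.2, 0.8])
        self.c = np.array([1.0, 2.0])
        self.c_eq = np.array([0.5, 2.5])
        self.F = np.array([-0.5, 0.3])
        self.params = EOParams()

    def test_gate_closed(self):
        R = generation_rate(self.lam, self.c, self.c_eq, self.F, 0.9, 0.2, self.params)
        np.testing.assert_array_equal(R, np.zeros(2))

    def test_zero_F(self):
        R = generation_rate(
            self.lam, self.c, self.c_eq, np.zeros(2), 0.9, 0.9, self.params
        )
        np.testing.assert_array_equal(R, np.zeros(2))

    def test_cancellation(self):
        c_eq = self.lam * self.c
        R = generation_rate(self.lam, self.c, c_eq, self.F, 0.9, 0.9, self.params)
        np.testing.assert_allclose(R, np.zeros(2))

    def test_open_gate_value(self):
        R = generation_rate(self.lam, self.c, self.c_eq, self.F, 1.0, 0.9, self.params)
        np.testing.assert_allclose(R, 0.5 * (self.c_eq - self.lam * self.c) * self.F)


class TestUpdateConcentration:
    def test_update_stays_in_bounds(self, small_profile):
        params = EOParams(pop_size=5, t_max=10, seed=3)
        rng = np.random.default_rng(3)
        pop = initialize_population(params, small_profile, rng)
        for p in pop:
            p.fitness_value = 1
        pool = EquilibriumPool.from_particles(pop)
        for it in range(1, 11):
            pop = [
                update_concentration(p, pool, it, params, rng, small_profile)
                for p in pop
            ]
            for p in pop:
                assert (p.concentration >= C_MIN).all()
                assert (p.concentration <= C_MAX).all()

    def test_fixed_point_identity(self):
        # c == c_eq and R == 0 leaves c unchanged in the update formula
        c = np.array([1.0, 2.0, 0.5])
        F = np.array([0.3, -0.7, 0.1])
        new_c = c + (c - c) * F + 0.0 * (1.0 - F)
        np.testing.assert_array_equal(new_c, c)

    def test_seeded_trajectory_reproducible(self, small_profile):
        def run():
            params = EOParams(pop_size=6, t_max=15, seed=11)
            rng = np.random.default_rng(11)
            pop = initialize_population(params, small_profile, rng)
            pool = EquilibriumPool.from_particles(pop)
            for it in range(1, 16):
                pop = [
                    update_concentration(p, pool, it, params, rng, small_profile)
                    for p in pop
                ]
            return np.stack([p.concentration for p in pop])

        np.testing.assert_array_equal(run(), run())


class TestEquilibriumPool:
    def test_picks_four_best_plus_average(self, small_profile):
        concs = [np.full(4, float(i)) for i in range(6)]
        particles = [
            Particle(c, decode_particle(c, small_profile), fitness_value=i)
            for i, c in enumerate(concs)
        ]
        pool = EquilibriumPool.from_particles(particles)
        assert len(pool.candidates) == 5
        got = sorted(c[0] for c in pool.best4)
        assert got == [2.0, 3.0, 4.0, 5.0]
        np.testing.assert_allclose(pool.avg, np.full(4, 3.5))


class TestDecodeParticle:
    def test_worked_repair_example(self):
        profile = ConstraintProfile(n=4, d=2, w=2)
        word = decode_particle(np.array([0.2, 1.6, 2.4, 3.7]), profile)
        assert word.bases == "TGCA"

    def test_identity_on_valid_integer_vector(self):
        profile = ConstraintProfile(n=4, d=2, w=2)
        word = decode_particle(np.array([0.0, 2.0, 1.0, 3.0]), profile)
        assert word.bases == "TGCA"

    def test_all_zero_vector_minimal_perturbation(self):
        profile = ConstraintProfile(n=4, d=1, w=2)
        word = decode_particle(np.zeros(4), profile)
        assert word.bases == "TCTC"
        # minimality: no valid word is closer to the all-zero vector
        from conftest import brute_force_valid_words

        def cost(w):
            return sum(dict(T=0, C=1, G=2, A=3)[c] for c in w)

        best = min(cost(w) for w in brute_force_valid_words(4, 2))
        assert cost(word.bases) == best

    @pytest.mark.parametrize("seed", range(5))
    def test_always_valid_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        for n, w in [(4, 2), (6, 3), (9, 4), (5, 0), (5, 5)]:
            profile = ConstraintProfile(n=n, d=1, w=w)
            conc = rng.uniform(0.0, 3.0, size=n)
            word = decode_particle(conc, profile)
            assert is_valid_codeword(word, profile)
            again = decode_particle(word.digits_array().astype(float), profile)
            assert again == word

    def test_shape_check(self):
        with pytest.raises(ValueError):
            decode_particle(np.zeros(3), ConstraintProfile(n=4, d=2))


class TestEOSearch:
    def test_result_is_valid_code(self):
        profile = ConstraintProfile(n=9, d=6, w=4)
        code = eo_search(profile, EOParams(pop_size=15, t_max=30, seed=5))
        assert code.is_valid_code()
        assert len(code) >= 1

    def test_zero_iterations(self, small_profile):
        code = eo_search(small_profile, EOParams(pop_size=10, t_max=0, seed=1))
        assert len(code) <= 1

    def test_monotone_growth(self, small_profile):
        trajectory = []
        eo_search(
            small_profile,
            EOParams(pop_size=10, t_max=25, seed=2),
            trajectory=trajectory,
        )
        sizes = [s for _, _, s in trajectory]
        assert sizes == sorted(sizes)

    def test_never_exceeds_exact_optimum(self, small_profile):
        optimum = len(max_clique_exact(build_conflict_graph(small_profile)))
        for seed in range(3):
            code = eo_search(small_profile, EOParams(pop_size=20, t_max=40, seed=seed))
            assert len(code) <= optimum

    def test_seeded_reproducibility(self, small_profile):
        params = EOParams(pop_size=12, t_max=20, seed=9)
        a = eo_search(small_profile, params)
        b = eo_search(small_profile, params)
        assert [w.bases for w in a.members] == [w.bases for w in b.members]
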