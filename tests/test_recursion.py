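import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdturnover.fitness import EpistasisScheme, FitnessScheme
from sdturnover.genome import N_GAMETES, Locus
from sdturnover.recursion import (
    DegenerateStateError,
    PopulationState,
    RecombinationRates,
    RecursionEngine,
    allele_frequency,
    gametic_disequilibrium,
    gametogenesis,
    next_generation,
    zygote_sex_ratio,
)
from sdturnover.scenarios import ScenarioSpec, initialize_ancestral
from .conftest import make_gamete

g = make_gamete
NEUTRAL = FitnessScheme()
NO_EPI = EpistasisScheme(epsilon=0.0)


# -- gametogenesis -------------------------------------------------------------


def test_gametogenesis_tight_linkage():
    """Without recombination only the two parental haplotypes are produced."""
    dist = gametogenesis(g(XY_SD=1, XY_SA=1), g(), RecombinationRates(0.0, 0.0, 0.0))
    assert dist[g(XY_SD=1, XY_SA=1)] == pytest.approx(0.5)
    assert dist[g()] == pytest.approx(0.5)
    assert np.count_nonzero(dist) == 2


def test_gametogenesis_recombinant_masses():
    """Parental haplotypes get (1-r)/2, recombinants r/2."""
    dist = gametogenesis(g(XY_SD=1, XY_SA=1), g(), RecombinationRates(0.1, 0.0, 0.0))
    assert dist[g(XY_SD=1, XY_SA=1)] == pytest.approx(0.45)
    assert dist[g()] == pytest.approx(0.45)
    assert dist[g(XY_SD=1)] == pytest.approx(0.05)
    assert dist[g(XY_SA=1)] == pytest.approx(0.05)


def test_gametogenesis_invisible_in_homozygotes():
    for r in (0.0, 0.2, 0.5):
        dist = gametogenesis(g(), g(), RecombinationRates(r, r, r))
        assert dist[g()] == pytest.approx(1.0)
        assert np.count_nonzero(dist) == 1


@given(
    m=st.integers(0, 127),
    p=st.integers(0, 127),
    r=st.floats(0.0, 0.5, allow_nan=False),
)
@settings(derandomize=True, max_examples=100)
def test_gametogenesis_mass_conserved(m, p, r):
    dist = gametogenesis(m, p, RecombinationRates(r, r / 2, r / 3))
    assert dist.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.min() >= 0.0


def test_epi_locus_segregates_half_half():
    dist = gametogenesis(g(EPI=1), g(), RecombinationRates())
    assert dist[g(EPI=1)] == pytest.approx(0.5)
    assert dist[g()] == pytest.approx(0.5)


# -- one-generation map --------------------------------------------------------


def _neutral_state(rng):
    """Random neutral state with identical pools and a male determiner."""
    freqs = rng.uniform(0.05, 0.45, size=7)
    pool = np.ones(N_GAMETES)
    bits = (np.arange(N_GAMETES)[:, None] >> np.arange(7)) & 1
    for locus in range(7):
        f = 0.0 if locus in (Locus.IA_SD, Locus.IIW_SD) else freqs[locus]
        pool = pool * np.where(bits[:, locus] == 1, f, 1 - f)
    egg = pool.copy()
    egg_bits = bits[:, Locus.XY_SD]
    egg = np.where(egg_bits == 1, 0.0, egg)
    egg /= egg.sum()
    return PopulationState(egg, pool / pool.sum())


def test_neutral_step_preserves_allele_frequencies(rng):
    """With s = 0 and eps = 0 the focal-allele frequencies are conserved."""
    for _ in range(3):
        state = _neutral_state(rng)
        before = {
            locus: allele_frequency(state, locus) for locus in (Locus.XY_SA, Locus.EPI)
        }
        nxt = next_generation(state, NEUTRAL, NO_EPI, RecombinationRates())
        for locus, p in before.items():
            assert allele_frequency(nxt, locus) == pytest.approx(p, abs=1e-12)


def test_ancestral_sex_ratio_and_y_transmission():
    """Y stays sperm-only and the zygote sex ratio stays exactly one half."""
    spec = ScenarioSpec(s_Y=0.03, s_new=0.02)
    state = initialize_ancestral(spec)
    engine = RecursionEngine(
        spec.fitness_scheme(), spec.epistasis_scheme(), spec.rates,
        spec.support(with_novel=False),
    )
    egg = engine._gather(state.egg)
    sperm = engine._gather(state.sperm)
    y_bit = (engine.support >> int(Locus.XY_SD)) & 1
    for _ in range(50):
        egg, sperm = engine.step_pools(egg, sperm)
        assert float(egg @ y_bit) == 0.0
        st_full = PopulationState(engine._scatter(egg), engine._scatter(sperm))
        assert zygote_sex_ratio(st_full) == pytest.approx(0.5, abs=1e-12)


def test_double_determiner_cross_gives_75_percent_males():
    """Y/+; A/+ males x wild-type females -> 3/4 of zygotes male."""
    egg = np.zeros(N_GAMETES)
    egg[g()] = 1.0
    sperm = gametogenesis(g(), g(XY_SD=1, IA_SD=1), RecombinationRates())
    assert zygote_sex_ratio(PopulationState(egg, sperm)) == pytest.approx(0.75)


@pytest.mark.parametrize("male", [make_gamete(XY_SD=1), make_gamete(IA_SD=1)])
def test_single_determiner_cross_gives_half_males(male):
    egg = np.zeros(N_GAMETES)
    egg[g()] = 1.0
    sperm = gametogenesis(g(), male, RecombinationRates())
    assert zygote_sex_ratio(PopulationState(egg, sperm)) == pytest.approx(0.5)


def test_all_female_population_is_degenerate():
    pool = np.zeros(N_GAMETES)
    pool[g()] = 1.0
    state = PopulationState(pool.copy(), pool.copy())
    with pytest.raises(DegenerateStateError):
        next_generation(state, NEUTRAL, NO_EPI, RecombinationRates())


def test_linkage_disequilibrium_decays_by_one_minus_r():
    """Neutral LD within a linkage group shrinks by (1-r) per generation.

    Uses a population with Y fixed on both copies, where the maternal-only W
    allele determines sex (Y/Y males, Y/Y; W/+ females), so the polymorphic
    I^A pair (A, SA^A) has no sex effect and the classic geometric decay
    holds exactly in both pools at every generation.
    """
    r = 0.07
    # joint distribution of the IA-group haplotype with coupling LD
    ia_joint = {(0, 0): 0.35, (0, 1): 0.15, (1, 1): 0.35, (1, 0): 0.15}
    egg = np.zeros(N_GAMETES)
    sperm = np.zeros(N_GAMETES)
    for (a, sa), weight in ia_joint.items():
        egg[g(XY_SD=1, IA_SD=a, IA_SA=sa, IIW_SD=1)] += 0.5 * weight  # W eggs
        egg[g(XY_SD=1, IA_SD=a, IA_SA=sa)] += 0.5 * weight
        sperm[g(IA_SD=a, IA_SA=sa, XY_SD=1)] += weight  # Y fixed everywhere
    state = PopulationState(egg, sperm)
    d = gametic_disequilibrium(state.egg, Locus.IA_SD, Locus.IA_SA)
    assert d != 0.0
    rates = RecombinationRates(r_XY=0.0, r_A=r, r_W=0.0)
    for _ in range(5):
        state = next_generation(state, NEUTRAL, NO_EPI, rates)
        for pool_t in (state.egg, state.sperm):
            d_next = gametic_disequilibrium(pool_t, Locus.IA_SD, Locus.IA_SA)
            assert d_next == pytest.approx((1 - r) * d, abs=1e-12)
        d = d_next


def test_cross_group_disequilibrium_halves_each_generation():
    """LD between unlinked non-SD loci (SA^A x EPI) decays by exactly 1/2."""
    joint = {(0, 0): 0.35, (0, 1): 0.15, (1, 1): 0.35, (1, 0): 0.15}
    egg = np.zeros(N_GAMETES)
    sperm = np.zeros(N_GAMETES)
    for (sa, epi), weight in joint.items():
        egg[g(IA_SA=sa, EPI=epi)] += weight
        sperm[g(IA_SA=sa, EPI=epi, XY_SD=1)] += 0.5 * weight
        sperm[g(IA_SA=sa, EPI=epi)] += 0.5 * weight
    state = PopulationState(egg, sperm)
    d = gametic_disequilibrium(state.egg, Locus.IA_SA, Locus.EPI)
    assert d != 0.0
    for _ in range(4):
        state = next_generation(state, NEUTRAL, NO_EPI, RecombinationRates())
        for pool_t in (state.egg, state.sperm):
            assert gametic_disequilibrium(
                pool_t, Locus.IA_SA, Locus.EPI
            ) == pytest.approx(0.5 * d, abs=1e-12)
        d *= 0.5


def test_sparse_support_matches_dense_dynamics():
    """Restricting to the scenario's reachable gamete subspace is exact."""
    spec = ScenarioSpec(transition="Y_to_A", s_Y=0.03, s_new=0.04, epsilon=0.05,
                        epi_type="dominance", epi_partner="SAY")
    state = initialize_ancestral(spec)
    scheme, epi = spec.fitness_scheme(), spec.epistasis_scheme()
    sparse = RecursionEngine(scheme, epi, spec.rates, spec.support(with_novel=False))
    dense = RecursionEngine(scheme, epi, spec.rates)
    s_state = sparse.run(state.copy(), 200)
    d_state = dense.run(state.copy(), 200)
    np.testing.assert_allclose(s_state.egg, d_state.egg, atol=1e-12)
    np.testing.assert_allclose(s_state.sperm, d_state.sperm, atol=1e-12)


def test_unclosed_support_is_rejected():
    # {all-+, Y-SA^Y} is not closed: recombination makes Y-+ and +-SA^Y
    with pytest.raises(ValueError, match="closed"):
        RecursionEngine(NEUTRAL, NO_EPI, RecombinationRates(), support=[0, 3])


def test_pools_stay_normalized_under_selection():
    spec = ScenarioSpec(s_Y=0.05, s_new=0.05, epsilon=0.05)
    state = initialize_ancestral(spec)
    engine = RecursionEngine(
        spec.fitness_scheme(), spec.epistasis_scheme(), spec.rates,
        spec.support(with_novel=False),
    )
    state = engine.run(state, 500)
    assert state.egg.sum() == pytest.approx(1.0, abs=1e-12)
    assert state.sperm.sum() == pytest.approx(1.0, abs=1e-12)
    assert state.egg.min() >= 0.0 and state.sperm.min() >= 0.0


# -- allele_frequency ----------------------------------------------------------


def test_allele_frequency_parent_of_origin_reads():
    spec = ScenarioSpec(s_Y=0.02, s_new=0.02)
    state = initialize_ancestral(spec)
    assert allele_frequency(state, Locus.XY_SD, "paternal", "males") == pytest.approx(1.0)
    assert allele_frequency(state, Locus.XY_SD, "maternal", "males") == 0.0
    assert allele_frequency(state, Locus.XY_SD, "maternal", "females") == 0.0
    assert allele_frequency(state, Locus.XY_SD, "paternal", "females") == 0.0
    assert allele_frequency(state, Locus.IA_SD) == 0.0  # novel allele absent
    assert allele_frequency(state, Locus.IIW_SA) == 0.0  # inert locus
    assert allele_frequency(state, Locus.XY_SA, "both", "all") == pytest.approx(0.25)


def test_allele_frequency_rejects_bad_arguments():
    state = initialize_ancestral(ScenarioSpec(s_Y=0.02, s_new=0.02))
    with pytest.raises(ValueError):
        allele_frequency(state, Locus.XY_SA, origin="paternal-ish")
    with pytest.raises(ValueError):
        allele_frequency(state, Locus.XY_SA, within_sex="hermaphrodites")
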