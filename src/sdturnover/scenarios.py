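"""Sex-determination transition scenarios.

A scenario starts from an ancestral male-heterogametic (XY) population in
which Y is fixed on the paternally inherited copy of males, runs a burn-in so
the SA and EPI allele frequencies approach equilibrium, introduces the novel
SD allele (A, a second male determiner, or W, a dominant female determiner)
at low frequency across all genotypes, runs to the horizon, and classifies
the outcome from the parent-of-origin frequency of the novel SD allele:

* Y->A: frequency of A among the paternally inherited copies of males;
* Y->W: frequency of W among the maternally inherited copies of females.

The read is rounded to 0 (ancestral system maintained) or 1 (turnover);
a tie at exactly 0.5 classifies as turnover.  The recursion itself is
deterministic, so a scenario maps to exactly one outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitness import EpistasisScheme, FitnessScheme, SALocusParams
from .genome import GAMETE_BITS, N_GAMETES, Locus
from .recursion import (
    PopulationState,
    RecombinationRates,
    RecursionEngine,
    TrajectoryRecorder,
    allele_frequency,
)

TRANSITIONS = ("Y_to_A", "Y_to_W")

#: epistasis partners compatible with each transition (the partner SA locus
#: must sit on a linkage group that segregates in the scenario)
ALLOWED_PARTNERS = {"Y_to_A": ("SAY", "SAA"), "Y_to_W": ("SAY", "SAW")}

#: default sex-specific dominance per SA locus (hM, hF)
DEFAULT_DOMINANCE = {"SAY": (0.6, 0.4), "SAA": (0.6, 0.4), "SAW": (0.4, 0.6)}

#: novel SD locus per transition
NOVEL_SD_LOCUS = {"Y_to_A": Locus.IA_SD, "Y_to_W": Locus.IIW_SD}

#: SA locus linked to the novel SD gene per transition
NOVEL_SA_LOCUS = {"Y_to_A": Locus.IA_SA, "Y_to_W": Locus.IIW_SA}

#: initial focal-allele frequency of segregating SA and EPI loci
INIT_SA_FREQ = 0.25


@dataclass(frozen=True)
class ScenarioSpec:
    """Full configuration of one transition simulation.

    ``s_Y`` is the male-benefit coefficient of SA^Y (sM = s_Y, sF = -s_Y);
    ``s_new`` is the coefficient of the SA locus linked to the novel SD gene,
    oriented to benefit the sex its linkage group determines (male benefit
    for SA^A, female benefit for SA^W).  The SA locus of the non-segregating
    linkage group is inert (s = 0, initial frequency 0).
    """

    transition: str = "Y_to_A"
    epi_type: str = "dominance"
    epi_partner: str = "SAY"
    s_Y: float = 0.02
    s_new: float = 0.02
    epsilon: float = 0.0
    burn_in: int = 10_000
    total_generations: int = 200_000
    intro_freq: float = 1e-4
    rates: RecombinationRates = field(default_factory=RecombinationRates)
    read_mode: str = "within_sex"  # or "pool"

    def __post_init__(self):
        if self.transition not in TRANSITIONS:
            raise ValueError(f"unknown transition {self.transition!r}")
        if self.epi_partner not in ALLOWED_PARTNERS[self.transition]:
            raise ValueError(
                f"partner {self.epi_partner!r} is not available in a "
                f"{self.transition} scenario (allowed: "
                f"{ALLOWED_PARTNERS[self.transition]})"
            )
        if not 0.0 < self.intro_freq < 1.0:
            raise ValueError(f"intro_freq must lie in (0, 1), got {self.intro_freq}")
        if not 0 <= self.burn_in < self.total_generations:
            raise ValueError("need 0 <= burn_in < total_generations")
        if self.read_mode not in ("within_sex", "pool"):
            raise ValueError(f"unknown read_mode {self.read_mode!r}")

    # -- derived configuration -------------------------------------------------

    def fitness_scheme(self) -> FitnessScheme:
        hM, hF = DEFAULT_DOMINANCE["SAY"]
        say = SALocusParams(sM=self.s_Y, sF=-self.s_Y, hM=hM, hF=hF)
        inert = SALocusParams()
        if self.transition == "Y_to_A":
            hM, hF = DEFAULT_DOMINANCE["SAA"]
            saa = SALocusParams(sM=self.s_new, sF=-self.s_new, hM=hM, hF=hF)
            return FitnessScheme(params_SAY=say, params_SAA=saa, params_SAW=inert)
        hM, hF = DEFAULT_DOMINANCE["SAW"]
        saw = SALocusParams(sM=-self.s_new, sF=self.s_new, hM=hM, hF=hF)
        return FitnessScheme(params_SAY=say, params_SAA=inert, params_SAW=saw)

    def epistasis_scheme(self) -> EpistasisScheme:
        return EpistasisScheme(
            epi_type=self.epi_type, partner=self.epi_partner, epsilon=self.epsilon
        )

    def segregating_loci(self, with_novel: bool = True):
        """Loci allowed to carry focal alleles at a given phase."""
        loci = {Locus.XY_SD, Locus.XY_SA, NOVEL_SA_LOCUS[self.transition], Locus.EPI}
        if with_novel:
            loci.add(NOVEL_SD_LOCUS[self.transition])
        return loci

    def support(self, with_novel: bool = True) -> np.ndarray:
        """Gamete indices whose focal alleles sit only at segregating loci."""
        allowed = np.zeros(7, dtype=bool)
        for locus in self.segregating_loci(with_novel):
            allowed[int(locus)] = True
        ok = ~(GAMETE_BITS.astype(bool) & ~allowed[None, :]).any(axis=1)
        return np.flatnonzero(ok)

    def to_dict(self) -> dict:
        return {
            "transition": self.transition,
            "epi_type": self.epi_type,
            "epi_partner": self.epi_partner,
            "s_Y": self.s_Y,
            "s_new": self.s_new,
            "epsilon": self.epsilon,
            "burn_in": self.burn_in,
            "total_generations": self.total_generations,
            "intro_freq": self.intro_freq,
            "rates": {
                "r_XY": self.rates.r_XY,
                "r_A": self.rates.r_A,
                "r_W": self.rates.r_W,
            },
            "read_mode": self.read_mode,
        }


def desk_profile(spec: ScenarioSpec) -> ScenarioSpec:
    """Shortened run lengths (burn-in 2,000; total 20,000) for quick studies."""
    return replace(spec, burn_in=2_000, total_generations=20_000)


@dataclass
class TransitionOutcome:
    """Binary turnover classification plus final allele frequencies."""

    outcome_bit: int
    read_frequency: float
    final_freqs: dict
    generations_run: int
    converged_early: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome_bit": self.outcome_bit,
            "read_frequency": self.read_frequency,
            "final_freqs": self.final_freqs,
            "generations_run": self.generations_run,
            "converged_early": self.converged_early,
        }


def _product_pool(freqs: dict) -> np.ndarray:
    """Linkage-equilibrium pool: independent per-locus focal frequencies."""
    pool = np.ones(N_GAMETES)
    for locus in Locus:
        f = freqs.get(locus, 0.0)
        bit = GAMETE_BITS[:, int(locus)]
        pool *= np.where(bit == 1, f, 1.0 - f)
    return pool


def initialize_ancestral(spec: ScenarioSpec) -> PopulationState:
    """Ancestral XY population at linkage equilibrium.

    Half of the sperm pool carries Y (so zygotes are 50% Y/+ males with Y
    strictly paternal), eggs never carry Y; the novel SD alleles are absent;
    segregating SA loci and EPI start at frequency 0.25 in both pools; the
    inert SA locus starts at 0.
    """
    sa_freqs = {
        locus: INIT_SA_FREQ
        for locus in spec.segregating_loci(with_novel=False)
        if locus != Locus.XY_SD
    }
    egg = _product_pool({**sa_freqs, Locus.XY_SD: 0.0})
    sperm = _product_pool({**sa_freqs, Locus.XY_SD: 0.5})
    return PopulationState(egg, sperm, generation=0)


def introduce_sd_allele(state: PopulationState, spec: ScenarioSpec) -> PopulationState:
    """Move a fraction ``intro_freq`` of every +-carrying gamete to its focal
    counterpart at the novel SD locus, in both pools (mutation across all
    genotypes present).  Pool mass is conserved and the relative proportions
    among the donor gamete types are unchanged.
    """
    locus = NOVEL_SD_LOCUS[spec.transition]
    bit = int(locus)
    bits = GAMETE_BITS[:, bit]
    pools = []
    for pool in (state.egg, state.sperm):
        if float(pool @ bits) > 0.0:
            raise ValueError(
                f"focal allele at {locus.name} already present before introduction"
            )
        new = pool.copy()
        donors = np.flatnonzero((bits == 0) & (pool > 0))
        moved = spec.intro_freq * pool[donors]
        new[donors] -= moved
        new[donors | (1 << bit)] += moved
        pools.append(new)
    return PopulationState(pools[0], pools[1], state.generation)


def classify_outcome(state: PopulationState, spec: ScenarioSpec) -> TransitionOutcome:
    """Read the parent-of-origin frequency of the novel SD allele and round.

    Y->A reads A among paternally inherited copies of males; Y->W reads W
    among maternally inherited copies of females.  ``read_mode='pool'``
    instead reads the plain sperm-pool (A) or egg-pool (W) frequency.
    """
    locus = NOVEL_SD_LOCUS[spec.transition]
    if spec.transition == "Y_to_A":
        origin, sex = "paternal", "males"
    else:
        origin, sex = "maternal", "females"
    if spec.read_mode == "pool":
        read = allele_frequency(state, locus, origin=origin, within_sex="all")
    else:
        read = allele_frequency(state, locus, origin=origin, within_sex=sex)
    final_freqs = {
        f"p_{name}": allele_frequency(state, locus, origin="both", within_sex="all")
        for name, locus in (
            ("Y", Locus.XY_SD),
            ("A", Locus.IA_SD),
            ("W", Locus.IIW_SD),
            ("SAY", Locus.XY_SA),
            ("SAA", Locus.IA_SA),
            ("SAW", Locus.IIW_SA),
            ("EPI", Locus.EPI),
        )
    }
    return TransitionOutcome(
        outcome_bit=int(read >= 0.5),
        read_frequency=read,
        final_freqs=final_freqs,
        generations_run=state.generation,
    )


def run_transition(
    spec: ScenarioSpec,
    trajectory_path=None,
    trajectory_every: int = 100,
    stop_when_converged: bool = False,
    convergence_tol: float = 1e-13,
    convergence_window: int = 100,
) -> TransitionOutcome:
    """Run one full scenario: init, burn-in, introduction, horizon, classify.

    Deterministic given ``spec``.  With ``stop_when_converged`` (off by
    default) the run ends early once the L-infinity change of both pools
    stays below ``convergence_tol`` for ``convergence_window`` consecutive
    generations.
    """
    scheme = spec.fitness_scheme()
    epi = spec.epistasis_scheme()
    recorder = TrajectoryRecorder() if trajectory_path is not None else None

    state = initialize_ancestral(spec)
    burn_engine = RecursionEngine(scheme, epi, spec.rates, spec.support(with_novel=False))
    state = burn_engine.run(state, spec.burn_in, recorder, trajectory_every)

    state = introduce_sd_allele(state, spec)
    engine = RecursionEngine(scheme, epi, spec.rates, spec.support(with_novel=True))

    remaining = spec.total_generations - spec.burn_in
    converged_early = False
    if not stop_when_converged:
        state = engine.run(state, remaining, recorder, trajectory_every)
    else:
        egg = engine._gather(state.egg)
        sperm = engine._gather(state.sperm)
        gen = state.generation
        quiet = 0
        for t in range(remaining):
            if recorder is not None and (gen - spec.burn_in) % trajectory_every == 0:
                recorder(gen, engine._scatter(egg), engine._scatter(sperm))
            new_egg, new_sperm = engine.step_pools(egg, sperm)
            delta = max(
                np.abs(new_egg - egg).max(), np.abs(new_sperm - sperm).max()
            )
            egg, sperm = new_egg, new_sperm
            gen += 1
            quiet = quiet + 1 if delta < convergence_tol else 0
            if quiet >= convergence_window:
                converged_early = True
                break
        state = PopulationState(engine._scatter(egg), engine._scatter(sperm), gen)

    if recorder is not None:
        recorder(state.generation, state.egg, state.sperm)
        recorder.write_tsv(trajectory_path)

    outcome = classify_outcome(state, spec)
    outcome.converged_early = converged_early
    outcome.generations_run = state.generation
    return outcome
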