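"""Deterministic two-sex gamete-frequency recursion.

The population is infinite with discrete non-overlapping generations.  Its
state is a pair of frequency vectors over the 128 gamete types: the egg pool
(maternally transmitted haplotypes) and the sperm pool (paternally
transmitted haplotypes).  One generation is

1. random mating: zygote genotype frequencies are the outer product of the
   egg and sperm pools;
2. sex assignment per zygote genotype;
3. viability selection within each sex (fitness-weighted, renormalized per
   sex, so each sex contributes half the gene pool regardless of the
   post-selection sex ratio);
4. gametogenesis with Mendelian segregation and recombination: within a
   two-locus linkage group the parental haplotypes each have mass (1-r)/2
   and the recombinants r/2; linkage groups assort independently.

The recursion is dense over the full 128-type space by default.  A
bit-closed ``support`` subset (all gamete types whose alleles vary only at a
subset of loci) gives numerically identical dynamics at a fraction of the
cost and is used by the scenario runner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitness import EpistasisScheme, FitnessScheme, fitness_tables
from .genome import GAMETE_BITS, N_GAMETES, Locus, male_mask

logger = logging.getLogger(__name__)

#: pool sums are renormalized every generation; a pre-normalization deviation
#: beyond this is logged as numerical drift
DRIFT_WARN = 1e-9
#: frequencies within this of zero from below are clipped to 0
NEG_CLIP = -1e-15


class DegenerateStateError(RuntimeError):
    """Raised when one sex has zero total zygote frequency."""


@dataclass(frozen=True)
class RecombinationRates:
    """Recombination fraction between the SD and SA locus of each group.

    The EPI group carries a single locus and has no rate; linkage groups
    assort independently of one another.
    """

    r_XY: float = 0.01
    r_A: float = 0.01
    r_W: float = 0.01

    def __post_init__(self):
        for name in ("r_XY", "r_A", "r_W"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {r}")


@dataclass
class PopulationState:
    """Egg- and sperm-pool gamete frequencies plus a generation counter."""

    egg: np.ndarray
    sperm: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.egg = np.asarray(self.egg, dtype=float)
        self.sperm = np.asarray(self.sperm, dtype=float)
        for name, pool in (("egg", self.egg), ("sperm", self.sperm)):
            if pool.shape != (N_GAMETES,):
                raise ValueError(f"{name} pool must have shape ({N_GAMETES},)")
            if pool.min() < NEG_CLIP:
                raise ValueError(f"{name} pool has negative frequencies")
            if abs(pool.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} pool must sum to 1, sums to {pool.sum()}")

    def copy(self) -> "PopulationState":
        return PopulationState(self.egg.copy(), self.sperm.copy(), self.generation)


def _pair_transition(r: float) -> np.ndarray:
    """(4, 4, 4) gamete table for one two-locus group.

    Axis order (maternal haplotype, paternal haplotype, offspring haplotype);
    a haplotype is coded sd_bit + 2 * sa_bit.
    """
    T = np.zeros((4, 4, 4))
    for m in range(4):
        msd, msa = m & 1, m >> 1
        for p in range(4):
            psd, psa = p & 1, p >> 1
            for (sd, sa), w in (
                ((msd, msa), (1 - r) / 2),
                ((psd, psa), (1 - r) / 2),
                ((msd, psa), r / 2),
                ((psd, msa), r / 2),
            ):
                T[m, p, sd + 2 * sa] += w
    return T


_T_EPI = np.zeros((2, 2, 2))
for _m in range(2):
    for _p in range(2):
        _T_EPI[_m, _p, _m] += 0.5
        _T_EPI[_m, _p, _p] += 0.5


def _group_codes(indices: np.ndarray):
    bits = GAMETE_BITS[indices]
    g_xy = bits[:, Locus.XY_SD] + 2 * bits[:, Locus.XY_SA]
    g_ia = bits[:, Locus.IA_SD] + 2 * bits[:, Locus.IA_SA]
    g_iiw = bits[:, Locus.IIW_SD] + 2 * bits[:, Locus.IIW_SA]
    g_epi = bits[:, Locus.EPI]
    return g_xy.astype(int), g_ia.astype(int), g_iiw.astype(int), g_epi.astype(int)


def gametogenesis(maternal: int, paternal: int, rates: RecombinationRates) -> np.ndarray:
    """Gamete-type distribution (length 128) produced by one genotype.

    Product across linkage groups of the per-group segregation masses:
    parental haplotypes (1-r)/2 each, recombinants r/2 each; the single-locus
    EPI group segregates 1/2-1/2.
    """
    idx = np.arange(N_GAMETES)
    g_xy, g_ia, g_iiw, g_epi = _group_codes(idx)
    mb = GAMETE_BITS[maternal]
    pb = GAMETE_BITS[paternal]
    m_codes = (
        int(mb[0] + 2 * mb[1]),
        int(mb[2] + 2 * mb[3]),
        int(mb[4] + 2 * mb[5]),
        int(mb[6]),
    )
    p_codes = (
        int(pb[0] + 2 * pb[1]),
        int(pb[2] + 2 * pb[3]),
        int(pb[4] + 2 * pb[5]),
        int(pb[6]),
    )
    tables = (
        _pair_transition(rates.r_XY),
        _pair_transition(rates.r_A),
        _pair_transition(rates.r_W),
        _T_EPI,
    )
    dist = np.ones(N_GAMETES)
    for g_codes, mc, pc, T in zip((g_xy, g_ia, g_iiw, g_epi), m_codes, p_codes, tables):
        dist *= T[mc, pc, g_codes]
    return dist


class RecursionEngine:
    """Precomputed one-generation map for fixed parameters.

    Parameters
    ----------
    scheme, epi, rates
        Fitness, epistasis and recombination configuration.
    support
        Optional subset of gamete indices the dynamics are restricted to.
        Must be closed under gametogenesis (true for any subset defined by
        fixing some loci to the non-focal allele); all state mass outside the
        support must be zero.
    """

    def __init__(
        self,
        scheme: FitnessScheme,
        epi: EpistasisScheme,
        rates: RecombinationRates,
        support=None,
    ):
        self.support = (
            np.arange(N_GAMETES) if support is None else np.asarray(sorted(support))
        )
        n = len(self.support)
        self.n = n
        g_xy, g_ia, g_iiw, g_epi = _group_codes(self.support)
        T_xy = _pair_transition(rates.r_XY)
        T_ia = _pair_transition(rates.r_A)
        T_iiw = _pair_transition(rates.r_W)
        G = (
            T_xy[g_xy[:, None, None], g_xy[None, :, None], g_xy[None, None, :]]
            * T_ia[g_ia[:, None, None], g_ia[None, :, None], g_ia[None, None, :]]
            * T_iiw[g_iiw[:, None, None], g_iiw[None, :, None], g_iiw[None, None, :]]
            * _T_EPI[g_epi[:, None, None], g_epi[None, :, None], g_epi[None, None, :]]
        )
        mass = G.sum(axis=2)
        if not np.allclose(mass, 1.0, atol=1e-12):
            raise ValueError("support is not closed under gametogenesis")
        self._G = np.ascontiguousarray(G.reshape(n * n, n))
        wf, wm = fitness_tables(scheme, epi, self.support)
        males = male_mask(self.support)
        # fitness masked by sex: zygotes of the other sex contribute nothing
        self._wfem = np.ascontiguousarray((wf * ~males).ravel())
        self._wmal = np.ascontiguousarray((wm * males).ravel())
        self._Z = np.empty((n, n))
        self._bf = np.empty(n * n)
        self._bm = np.empty(n * n)

    def _gather(self, pool: np.ndarray) -> np.ndarray:
        sub = pool[self.support]
        outside = pool.sum() - sub.sum()
        if outside > 1e-12:
            raise ValueError(
                f"state has frequency mass {outside:.3e} outside the engine support"
            )
        return sub.copy()

    def _scatter(self, sub: np.ndarray) -> np.ndarray:
        full = np.zeros(N_GAMETES)
        full[self.support] = sub
        return full

    def step_pools(self, egg: np.ndarray, sperm: np.ndarray):
        """One generation on support-indexed pools (in place safe, returns new)."""
        np.multiply(egg[:, None], sperm[None, :], out=self._Z)
        z = self._Z.reshape(-1)
        np.multiply(z, self._wfem, out=self._bf)
        np.multiply(z, self._wmal, out=self._bm)
        fem_mass = self._bf.sum()
        mal_mass = self._bm.sum()
        if fem_mass <= 0.0 or mal_mass <= 0.0:
            raise DegenerateStateError(
                "one sex has zero total zygote frequency; population cannot continue"
            )
        new_egg = self._bf @ self._G
        new_sperm = self._bm @ self._G
        new_egg /= fem_mass
        new_sperm /= mal_mass
        for pool in (new_egg, new_sperm):
            np.maximum(pool, 0.0, out=pool)
            total = pool.sum()
            if abs(total - 1.0) > DRIFT_WARN:
                logger.warning("pool normalization drift %.3e", total - 1.0)
            pool /= total
        return new_egg, new_sperm

    def run(
        self,
        state: PopulationState,
        generations: int,
        recorder=None,
        record_every: int = 100,
    ) -> PopulationState:
        """Advance ``state`` by ``generations`` steps.

        ``recorder``, if given, is called as ``recorder(gen, egg, sperm)`` with
        full 128-length pools at generation 0 of this stretch and every
        ``record_every`` generations thereafter.
        """
        egg = self._gather(state.egg)
        sperm = self._gather(state.sperm)
        gen0 = state.generation
        for t in range(generations):
            if recorder is not None and t % record_every == 0:
                recorder(gen0 + t, self._scatter(egg), self._scatter(sperm))
            egg, sperm = self.step_pools(egg, sperm)
        return PopulationState(self._scatter(egg), self._scatter(sperm), gen0 + generations)


def next_generation(
    state: PopulationState,
    scheme: FitnessScheme,
    epi: EpistasisScheme,
    rates: RecombinationRates,
) -> PopulationState:
    """One generation of the full dense recursion (convenience wrapper)."""
    engine = RecursionEngine(scheme, epi, rates)
    egg, sperm = engine.step_pools(state.egg.copy(), state.sperm.copy())
    return PopulationState(egg, sperm, state.generation + 1)


def allele_frequency(
    state: PopulationState,
    locus: Locus,
    origin: str = "both",
    within_sex: str = "all",
) -> float:
    """Focal-allele frequency at ``locus`` among designated copies.

    ``origin`` selects maternally inherited copies (the egg pool), paternally
    inherited copies (the sperm pool), or their average.  ``within_sex``
    restricts to male or female zygotes of the next random-mating round
    (zygotes are formed as egg x sperm to condition on sex).
    """
    if origin not in ("maternal", "paternal", "both"):
        raise ValueError(f"unknown origin {origin!r}")
    if within_sex not in ("males", "females", "all"):
        raise ValueError(f"unknown class {within_sex!r}")
    bit = GAMETE_BITS[:, int(locus)].astype(float)
    if within_sex == "all":
        p_mat = float(state.egg @ bit)
        p_pat = float(state.sperm @ bit)
    else:
        z = np.outer(state.egg, state.sperm)
        males = male_mask()
        mask = males if within_sex == "males" else ~males
        denom = float(z[mask].sum())
        if denom <= 0.0:
            raise DegenerateStateError(f"no zygote mass in class {within_sex!r}")
        p_mat = float((z * bit[:, None])[mask].sum()) / denom
        p_pat = float((z * bit[None, :])[mask].sum()) / denom
    if origin == "maternal":
        return p_mat
    if origin == "paternal":
        return p_pat
    return 0.5 * (p_mat + p_pat)


def zygote_sex_ratio(state: PopulationState) -> float:
    """Fraction of male zygotes under random union of the two pools."""
    z = np.outer(state.egg, state.sperm)
    return float(z[male_mask()].sum())


def gametic_disequilibrium(pool: np.ndarray, locus_a: Locus, locus_b: Locus) -> float:
    """D = p_ab - p_a * p_b between two loci within one gamete pool."""
    ba = GAMETE_BITS[:, int(locus_a)].astype(float)
    bb = GAMETE_BITS[:, int(locus_b)].astype(float)
    p_a = float(pool @ ba)
    p_b = float(pool @ bb)
    p_ab = float(pool @ (ba * bb))
    return p_ab - p_a * p_b


#: column order of the trajectory table
TRAJECTORY_COLUMNS = (
    "generation",
    "p_Y",
    "p_A",
    "p_W",
    "p_SAY",
    "p_SAA",
    "p_SAW",
    "p_EPI",
)

_TRAJ_LOCI = (
    Locus.XY_SD,
    Locus.IA_SD,
    Locus.IIW_SD,
    Locus.XY_SA,
    Locus.IA_SA,
    Locus.IIW_SA,
    Locus.EPI,
)


class TrajectoryRecorder:
    """Collects pooled focal-allele frequencies (origin=both, all zygotes)."""

    def __init__(self):
        self.rows = []

    def __call__(self, gen: int, egg: np.ndarray, sperm: np.ndarray):
        mean = 0.5 * (egg + sperm)
        freqs = [float(mean @ GAMETE_BITS[:, int(l)].astype(float)) for l in _TRAJ_LOCI]
        self.rows.append((gen, *freqs))

    def write_tsv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(TRAJECTORY_COLUMNS)
            for row in self.rows:
                w.writerow([row[0]] + [f"{v:.12g}" for v in row[1:]])
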