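"""Sex-specific viability and epistatic fitness effects.

Per SA locus, genotype fitness is 1 (no focal copy), 1 + h_sex * s_sex (one
copy) or 1 + s_sex (two copies), with sex-specific selection coefficients
(sM, sF) and dominance (hM, hF).  Sexual antagonism means sM * sF < 0.

Total viability is multiplicative over the three SA loci,

    w_female = w_SAY * w_SAA * w_SAW
    w_male   = w_SAY * w_SAA * w_SAW * w_EPI,

where the male-only epistasis factor is w_EPI = 1 + sigma * epsilon.  The
binary indicator sigma depends on the epistasis type and the copy numbers at
the EPI locus and its partner SA locus:

    dominance:      sigma = 1 iff both loci carry >= 1 focal copy
    overdominance:  sigma = 1 iff both loci are heterozygous
    coadaptation:   sigma = 1 iff both loci are +/+ or both focal-homozygous

Epistasis never enters female fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Locus, Sex, copy_counts

EPISTASIS_TYPES = ("dominance", "overdominance", "coadaptation")

#: sigma[epi_copies, sa_copies] for each epistasis type
SIGMA = {
    "dominance": np.array([[0, 0, 0], [0, 1, 1], [0, 1, 1]], dtype=np.int64),
    "overdominance": np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=np.int64),
    "coadaptation": np.array([[1, 0, 0], [0, 0, 0], [0, 0, 1]], dtype=np.int64),
}

#: epistasis-partner name -> the SA locus the EPI locus reads
PARTNER_LOCUS = {
    "SAY": Locus.XY_SA,
    "SAA": Locus.IA_SA,
    "SAW": Locus.IIW_SA,
}


@dataclass(frozen=True)
class SALocusParams:
    """Selection (sM, sF) and dominance (hM, hF) at one SA locus.

    An inert locus has sM = sF = 0; an active locus must be sexually
    antagonistic (sM * sF < 0).  Homozygote fitness 1 + s must stay positive,
    so s <= -1 is rejected.
    """

    sM: float = 0.0
    sF: float = 0.0
    hM: float = 0.5
    hF: float = 0.5

    def __post_init__(self):
        if self.sM <= -1.0 or self.sF <= -1.0:
            raise ValueError(
                f"selection coefficient <= -1 gives non-positive fitness "
                f"(sM={self.sM}, sF={self.sF})"
            )
        if not (0.0 <= self.hM <= 1.0 and 0.0 <= self.hF <= 1.0):
            raise ValueError(f"dominance must lie in [0,1] (hM={self.hM}, hF={self.hF})")
        active = self.sM != 0.0 or self.sF != 0.0
        if active and self.sM * self.sF >= 0.0:
            raise ValueError(
                f"active SA locus requires sM*sF<0 (sM={self.sM}, sF={self.sF})"
            )

    def table(self, sex: Sex) -> np.ndarray:
        """Fitness by focal copy number [0, 1, 2] for the given sex."""
        s = self.sM if sex == Sex.MALE else self.sF
        h = self.hM if sex == Sex.MALE else self.hF
        return np.array([1.0, 1.0 + h * s, 1.0 + s])


@dataclass(frozen=True)
class FitnessScheme:
    """SA parameters for the three SA loci (SA^Y, SA^A, SA^W)."""

    params_SAY: SALocusParams = field(default_factory=SALocusParams)
    params_SAA: SALocusParams = field(default_factory=SALocusParams)
    params_SAW: SALocusParams = field(default_factory=SALocusParams)

    def params_for(self, locus: Locus) -> SALocusParams:
        return {
            Locus.XY_SA: self.params_SAY,
            Locus.IA_SA: self.params_SAA,
            Locus.IIW_SA: self.params_SAW,
        }[locus]


@dataclass(frozen=True)
class EpistasisScheme:
    """Male-limited epistasis between the EPI locus and one SA locus."""

    epi_type: str = "dominance"
    partner: str = "SAY"
    epsilon: float = 0.0

    def __post_init__(self):
        if self.epi_type not in EPISTASIS_TYPES:
            raise ValueError(
                f"unknown epistasis type {self.epi_type!r}; "
                f"expected one of {EPISTASIS_TYPES}"
            )
        if self.partner not in PARTNER_LOCUS:
            raise ValueError(f"unknown epistasis partner {self.partner!r}")
        if self.epsilon < 0:
            raise ValueError(f"epistasis effect size must be >= 0, got {self.epsilon}")

    @property
    def partner_locus(self) -> Locus:
        return PARTNER_LOCUS[self.partner]


def locus_fitness(focal_copies: int, sex: Sex, params: SALocusParams) -> float:
    """Viability factor contributed by one SA locus."""
    if focal_copies not in (0, 1, 2):
        raise ValueError(f"focal copy number must be 0, 1 or 2, got {focal_copies}")
    return float(params.table(sex)[focal_copies])


def epistasis_sigma(epi_type: str, epi_copies: int, sa_copies: int) -> int:
    """Binary epistasis indicator for given EPI and partner-SA copy numbers."""
    if epi_type not in SIGMA:
        raise ValueError(f"unknown epistasis type {epi_type!r}")
    if epi_copies not in (0, 1, 2) or sa_copies not in (0, 1, 2):
        raise ValueError("copy numbers must be 0, 1 or 2")
    return int(SIGMA[epi_type][epi_copies, sa_copies])


def fitness_of(
    maternal: int,
    paternal: int,
    sex: Sex,
    scheme: FitnessScheme,
    epi: EpistasisScheme,
) -> float:
    """Viability of one zygote: product over SA loci, times w_EPI in males.

    Depends only on copy numbers, so it is invariant to swapping the maternal
    and paternal gametes.
    """
    from .genome import GAMETE_BITS

    bits_m = GAMETE_BITS[maternal]
    bits_p = GAMETE_BITS[paternal]
    w = 1.0
    for locus in (Locus.XY_SA, Locus.IA_SA, Locus.IIW_SA):
        copies = int(bits_m[locus]) + int(bits_p[locus])
        w *= locus_fitness(copies, sex, scheme.params_for(locus))
    if sex == Sex.MALE:
        epi_copies = int(bits_m[Locus.EPI]) + int(bits_p[Locus.EPI])
        sa_copies = int(bits_m[epi.partner_locus]) + int(bits_p[epi.partner_locus])
        w *= 1.0 + epistasis_sigma(epi.epi_type, epi_copies, sa_copies) * epi.epsilon
    return w


def fitness_tables(scheme: FitnessScheme, epi: EpistasisScheme, support=None):
    """Vectorized (n, n) viability matrices (w_female, w_male) over gamete pairs."""
    wf = np.ones_like(copy_counts(Locus.XY_SA, support), dtype=float)
    wm = np.ones_like(wf)
    for locus in (Locus.XY_SA, Locus.IA_SA, Locus.IIW_SA):
        copies = copy_counts(locus, support)
        params = scheme.params_for(locus)
        wf *= params.table(Sex.FEMALE)[copies]
        wm *= params.table(Sex.MALE)[copies]
    epi_copies = copy_counts(Locus.EPI, support)
    sa_copies = copy_counts(epi.partner_locus, support)
    wm *= 1.0 + SIGMA[epi.epi_type][epi_copies, sa_copies] * epi.epsilon
    return wf, wm
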