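"""Genome architecture and sex determination.

The model genome is haploid-gamete-centric: a gamete is one haplotype across
four independently assorting linkage groups.  Three groups (XY, I^A, II^W)
each carry one sex-determination (SD) locus and one sexually antagonistic (SA)
locus; the fourth carries a single epistasis (EPI) locus.  Every locus is
biallelic with a non-focal allele "+" (coded 0) and a focal allele (coded 1).

Gamete encoding
---------------
A gamete type is an integer in [0, 127].  Bit ``i`` (least-significant bit
first) holds the allele at locus ``i`` in the fixed order

    bit 0: XY.SD  (focal allele Y, male determiner)
    bit 1: XY.SA  (focal allele SA^Y)
    bit 2: IA.SD  (focal allele A, male determiner)
    bit 3: IA.SA  (focal allele SA^A)
    bit 4: IIW.SD (focal allele W, dominant female determiner)
    bit 5: IIW.SA (focal allele SA^W)
    bit 6: EPI    (focal allele EPI)

so e.g. gamete 5 = 0b0000101 carries Y and A and "+" everywhere else.  This
bijection is fixed so that trajectory/state files are comparable across runs.

Sex determination
-----------------
A zygote is female if it carries at least one W allele (W is epistatically
dominant over Y), else male if it carries at least one Y or A allele, else
female (the all-"+" ground state is female).  W/W genotypes cannot arise in
valid dynamics (W is never transmitted through males) but are representable
and classed female.
"""

from __future__ import annotations

from enum import Enum, IntEnum

import numpy as np

N_LOCI = 7
N_GAMETES = 1 << N_LOCI  # 128


class Locus(IntEnum):
    """Locus identifiers; the integer value is the gamete bit position."""

    XY_SD = 0
    XY_SA = 1
    IA_SD = 2
    IA_SA = 3
    IIW_SD = 4
    IIW_SA = 5
    EPI = 6


#: focal-allele symbol at each locus
FOCAL_ALLELE = {
    Locus.XY_SD: "Y",
    Locus.XY_SA: "SA^Y",
    Locus.IA_SD: "A",
    Locus.IA_SA: "SA^A",
    Locus.IIW_SD: "W",
    Locus.IIW_SA: "SA^W",
    Locus.EPI: "EPI",
}

#: two-locus linkage groups as (SD locus, SA locus, recombination-rate name)
LINKAGE_GROUPS = (
    (Locus.XY_SD, Locus.XY_SA, "r_XY"),
    (Locus.IA_SD, Locus.IA_SA, "r_A"),
    (Locus.IIW_SD, Locus.IIW_SA, "r_W"),
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: (128, 7) int8 array; GAMETE_BITS[g, l] is the allele of gamete g at locus l
GAMETE_BITS = (
    (np.arange(N_GAMETES)[:, None] >> np.arange(N_LOCI)[None, :]) & 1
).astype(np.int8)


def gamete_index(alleles) -> int:
    """Integer index of a gamete given its 7-tuple of allele indicators."""
    alleles = tuple(int(a) for a in alleles)
    if len(alleles) != N_LOCI or any(a not in (0, 1) for a in alleles):
        raise ValueError(f"need 7 allele indicators in {{0,1}}, got {alleles!r}")
    return sum(a << i for i, a in enumerate(alleles))


def gamete_alleles(index: int) -> tuple:
    """7-tuple of allele indicators for a gamete index."""
    if not 0 <= index < N_GAMETES:
        raise ValueError(f"gamete index out of range: {index}")
    return tuple(int(b) for b in GAMETE_BITS[index])


def sex_of(maternal: int, paternal: int) -> Sex:
    """Sex of the zygote formed by a maternal and a paternal gamete.

    Female if at least one W is present, else male if at least one Y or A is
    present, else female.  Total over all 128 x 128 ordered gamete pairs and
    symmetric in its arguments.
    """
    bits = GAMETE_BITS[maternal] | GAMETE_BITS[paternal]
    if bits[Locus.IIW_SD]:
        return Sex.FEMALE
    if bits[Locus.XY_SD] or bits[Locus.IA_SD]:
        return Sex.MALE
    return Sex.FEMALE


def male_mask(support=None) -> np.ndarray:
    """Boolean (n, n) matrix over (maternal, paternal) gamete pairs: True = male.

    ``support`` restricts both axes to a subset of gamete indices.
    """
    idx = np.arange(N_GAMETES) if support is None else np.asarray(support)
    bits = GAMETE_BITS[idx]
    combined = bits[:, None, :] | bits[None, :, :]
    has_w = combined[:, :, Locus.IIW_SD] == 1
    has_male = (combined[:, :, Locus.XY_SD] == 1) | (combined[:, :, Locus.IA_SD] == 1)
    return has_male & ~has_w


def copy_counts(locus: Locus, support=None) -> np.ndarray:
    """(n, n) matrix of focal-allele copy number (0/1/2) at ``locus``."""
    idx = np.arange(N_GAMETES) if support is None else np.asarray(support)
    b = GAMETE_BITS[idx, int(locus)].astype(np.int64)
    return b[:, None] + b[None, :]
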