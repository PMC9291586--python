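"""Independent individual-based Wright-Fisher simulator used as a test oracle.

Implements the same biology as the deterministic recursion — sex rule,
sex-specific SA viability, male-limited epistasis, Mendelian segregation with
recombination — but re-coded from first principles with per-genotype Python
loops, and with finite population size: each generation N zygotes are drawn
multinomially from the random-mating genotype distribution implied by the
fitness-weighted parental gamete pools.
"""

import itertools

import numpy as np

# bit order: XY.SD, XY.SA, IA.SD, IA.SA, IIW.SD, IIW.SA, EPI
_GROUPS = ((0, 1), (2, 3), (4, 5))  # (SD bit, SA bit) per two-locus group
_EPI_BIT = 6
_SA_BIT = {"SAY": 1, "SAA": 3, "SAW": 5}


def _bits(gamete):
    return [(gamete >> b) & 1 for b in range(7)]


def _sex(maternal, paternal):
    ab = [m | p for m, p in zip(_bits(maternal), _bits(paternal))]
    if ab[4]:
        return "female"
    return "male" if (ab[0] or ab[2]) else "female"


def _sa_fitness(copies, s, h):
    return [1.0, 1.0 + h * s, 1.0 + s][copies]


def _sigma(epi_type, epi_copies, sa_copies):
    if epi_type == "dominance":
        return 1 if (epi_copies >= 1 and sa_copies >= 1) else 0
    if epi_type == "overdominance":
        return 1 if (epi_copies == 1 and sa_copies == 1) else 0
    if epi_type == "coadaptation":
        return 1 if (epi_copies, sa_copies) in ((0, 0), (2, 2)) else 0
    raise ValueError(epi_type)


def _gamete_dist(maternal, paternal, r_by_group):
    """List of (gamete, prob): product over groups of segregation masses."""
    mb, pb = _bits(maternal), _bits(paternal)
    per_group = []
    for (sd, sa), r in zip(_GROUPS, r_by_group):
        opts = {}
        for (b1, b2), w in (
            ((mb[sd], mb[sa]), (1 - r) / 2),
            ((pb[sd], pb[sa]), (1 - r) / 2),
            ((mb[sd], pb[sa]), r / 2),
            ((pb[sd], mb[sa]), r / 2),
        ):
            key = (b1 << sd) | (b2 << sa)
            opts[key] = opts.get(key, 0.0) + w
        per_group.append(list(opts.items()))
    epi_opts = {}
    for b in (mb[_EPI_BIT], pb[_EPI_BIT]):
        key = b << _EPI_BIT
        epi_opts[key] = epi_opts.get(key, 0.0) + 0.5
    per_group.append(list(epi_opts.items()))
    dist = {}
    for combo in itertools.product(*per_group):
        gamete = 0
        prob = 1.0
        for part, w in combo:
            gamete |= part
            prob *= w
        dist[gamete] = dist.get(gamete, 0.0) + prob
    return list(dist.items())


class WrightFisherOracle:
    """Finite-N counterpart of the deterministic recursion.

    Parameters are plain scalars: selection coefficients per SA locus as
    (sM, sF, hM, hF) keyed "SAY"/"SAA"/"SAW", epistasis (type, partner,
    epsilon), recombination rates per group, and the gamete support to
    enumerate (any iterable of gamete indices closed under segregation).
    """

    def __init__(self, sa_params, epi_type, epi_partner, epsilon, rates, support):
        self.support = sorted(support)
        self.index = {gam: k for k, gam in enumerate(self.support)}
        n = len(self.support)
        self.n = n
        wf = np.zeros((n, n))
        wm = np.zeros((n, n))
        female = np.zeros((n, n), dtype=bool)
        self.G = np.zeros((n * n, n))
        partner_bit = _SA_BIT[epi_partner]
        for i, gm in enumerate(self.support):
            for j, gp in enumerate(self.support):
                mb, pb = _bits(gm), _bits(gp)
                w = 1.0
                wmale = 1.0
                for name, bit in _SA_BIT.items():
                    sM, sF, hM, hF = sa_params[name]
                    copies = mb[bit] + pb[bit]
                    w_f = _sa_fitness(copies, sF, hF)
                    w_m = _sa_fitness(copies, sM, hM)
                    w *= w_f
                    wmale *= w_m
                epi_copies = mb[_EPI_BIT] + pb[_EPI_BIT]
                sa_copies = mb[partner_bit] + pb[partner_bit]
                wmale *= 1.0 + _sigma(epi_type, epi_copies, sa_copies) * epsilon
                wf[i, j] = w
                wm[i, j] = wmale
                female[i, j] = _sex(gm, gp) == "female"
                for gam, prob in _gamete_dist(gm, gp, rates):
                    self.G[i * n + j, self.index[gam]] += prob
        self.wf = wf * female
        self.wm = wm * ~female

    def initial_counts(self, egg_freq, sperm_freq, N, rng):
        e = np.asarray([egg_freq[gam] for gam in self.support])
        s = np.asarray([sperm_freq[gam] for gam in self.support])
        z = np.outer(e / e.sum(), s / s.sum()).ravel()
        return rng.multinomial(N, z).reshape(self.n, self.n)

    def step(self, counts, N, rng):
        bf = (counts * self.wf).ravel()
        bm = (counts * self.wm).ravel()
        egg = bf @ self.G
        sperm = bm @ self.G
        egg /= egg.sum()
        sperm /= sperm.sum()
        z = np.outer(egg, sperm).ravel()
        return rng.multinomial(N, z / z.sum()).reshape(self.n, self.n)

    def allele_freq(self, counts, bit):
        """Pooled focal-allele frequency (both parental origins) among zygotes."""
        b = np.asarray([(gam >> bit) & 1 for gam in self.support], dtype=float)
        total = counts.sum()
        mat = (counts.sum(axis=1) @ b) / total
        pat = (counts.sum(axis=0) @ b) / total
        return 0.5 * (mat + pat)
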