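"""Forward-in-time simulation of a livestock population for GWAS method studies.

The simulated design mirrors a beef-cattle breeding program with a
sex-limited, low-heritability trait: a long historical phase (constant
size, then a gradual bottleneck that builds up linkage disequilibrium),
an exponential expansion of the number of dams, and a selection phase in
which parents are replaced by the candidates with the best pedigree-BLUP
breeding values.  Markers are biallelic SNPs; QTLs carry 2-4 alleles with
gamma-distributed additive effects.

Two simulators are provided:

* the full gene-dropping simulator (:func:`simulate_historical`,
  :func:`simulate_expansion`, :func:`simulate_selection`) which tracks
  haplotypes, pedigree and phenotypes and is the data generator for the
  WssGBLUP / Bayes C analyses; and
* a marginal allele-frequency drift simulator
  (:func:`simulate_locus_drift`) which reproduces the per-locus
  frequency distribution of the demographic schedule without linkage,
  used for the analytic true-QTL statistics where only marginal
  frequencies matter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "TraitSpec",
    "PopSchedule",
    "Population",
    "QTLEffectTable",
    "simulate_historical",
    "simulate_locus_drift",
    "historical_size_path",
    "select_segregating_loci",
    "assign_qtl_effects",
    "compute_tbv",
    "simulate_phenotypes",
    "simulate_expansion",
    "simulate_selection",
    "genotype_females",
    "marker_dosages",
    "BOVINE_AUTOSOME_MB",
]

# Physical lengths (Mb) of the 29 bovine autosomes, used only as relative
# proportions when distributing a configured total map length.
BOVINE_AUTOSOME_MB = np.array(
    [158.3, 137.1, 121.4, 120.8, 121.2, 119.5, 112.6, 113.4, 105.7, 104.3,
     107.3, 91.2, 84.2, 84.6, 85.3, 81.7, 75.2, 66.0, 64.1, 72.0,
     71.6, 61.4, 52.5, 62.7, 42.9, 51.7, 45.4, 46.3, 51.5]
)

MALE, FEMALE = 1, 2


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing to ``total``."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(exact - base)[::-1]
    base[order[:rem]] += 1
    return base


@dataclass
class GenomeSpec:
    """Map of marker and QTL loci over a set of autosomes.

    Loci are stored merged and sorted by (chromosome, position) so that a
    single recombination lattice covers markers and QTLs; ``is_qtl``
    distinguishes them.  Positions are in centimorgans.  The physical map
    used for window analyses assumes 1 cM = 1 Mb.
    """

    chrom_lengths: np.ndarray          # cM per chromosome
    chrom: np.ndarray                  # (L,) 1-based chromosome of each locus
    pos_cm: np.ndarray                 # (L,) position within chromosome
    is_qtl: np.ndarray                 # (L,) bool
    n_alleles: np.ndarray              # (L,) 2 for markers, 2..4 for QTLs
    mutation_rate: float = 1e-4

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=np.int16)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        self.is_qtl = np.asarray(self.is_qtl, dtype=bool)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.uint8)
        if not (len(self.chrom) == len(self.pos_cm) == len(self.is_qtl) == len(self.n_alleles)):
            raise ValueError("locus arrays must have equal length")
        order_ok = np.all(np.diff(self.chrom) >= 0)
        within = np.all(np.diff(self.pos_cm)[np.diff(self.chrom) == 0] > 0)
        if not (order_ok and within):
            raise ValueError("loci must be sorted with strictly increasing positions within chromosomes")
        if np.any(self.pos_cm < 0) or np.any(self.pos_cm > self.chrom_lengths[self.chrom - 1]):
            raise ValueError("locus position outside its chromosome")
        if np.any(self.n_alleles[~self.is_qtl] != 2):
            raise ValueError("markers must be biallelic")
        if np.any((self.n_alleles[self.is_qtl] < 2) | (self.n_alleles[self.is_qtl] > 4)):
            raise ValueError("QTLs must have 2-4 alleles")

    # -- derived views -------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def total_length(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def marker_index(self) -> np.ndarray:
        return np.nonzero(~self.is_qtl)[0]

    @property
    def qtl_index(self) -> np.ndarray:
        return np.nonzero(self.is_qtl)[0]

    @property
    def n_markers(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def mutation_mean_u(self) -> float:
        """Expected number of mutations per individual per generation
        (u = 2 L mu): every gene copy mutates with probability mu."""
        return 2.0 * self.n_loci * self.mutation_rate

    def recombination_fractions(self) -> np.ndarray:
        """Haldane recombination fraction between adjacent loci (0.5 across
        chromosome boundaries)."""
        d = np.diff(self.pos_cm) / 100.0  # Morgans
        rf = 0.5 * (1.0 - np.exp(-2.0 * d))
        rf[np.diff(self.chrom) != 0] = 0.5
        return rf

    def meiosis_layout(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cached geometry for the gamete sampler: global locus
        coordinates (chromosomes laid end to end), 0-based chromosome of
        each locus, and the first locus index of each chromosome."""
        if not hasattr(self, "_meiosis_cache"):
            offsets = np.concatenate([[0.0], np.cumsum(self.chrom_lengths)])
            gpos = self.pos_cm + offsets[self.chrom - 1]
            cmap = (self.chrom - 1).astype(np.int64)
            starts = np.searchsorted(self.chrom, np.arange(1, self.n_chromosomes + 1))
            starts = np.minimum(starts, max(self.n_loci - 1, 0))
            self._meiosis_cache = (gpos, cmap, starts.astype(np.int64))
        return self._meiosis_cache

    def mean_marker_spacing(self) -> float:
        """Average adjacent-marker distance in cM (total length / n markers)."""
        return self.total_length / self.n_markers

    # -- constructors --------------------------------------------------
    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        n_chromosomes: int = 29,
        total_length: float = 2333.0,
        n_markers: int = 735_293,
        n_qtl: int = 7_000,
        mutation_rate: float = 1e-4,
        chrom_weights: np.ndarray | None = None,
    ) -> "GenomeSpec":
        """Random genome: chromosome lengths proportional to the bovine
        autosomes, loci placed uniformly, per-chromosome counts
        proportional to length."""
        if chrom_weights is None:
            chrom_weights = BOVINE_AUTOSOME_MB[:n_chromosomes]
            if len(chrom_weights) < n_chromosomes:
                chrom_weights = np.ones(n_chromosomes)
        lengths = chrom_weights / chrom_weights.sum() * total_length
        nm = _largest_remainder(lengths, n_markers)
        nq = _largest_remainder(lengths, n_qtl)
        chrom, pos, isq = [], [], []
        for c in range(n_chromosomes):
            pm = np.sort(rng.uniform(0, lengths[c], nm[c]))
            pq = np.sort(rng.uniform(0, lengths[c], nq[c]))
            p = np.concatenate([pm, pq])
            q = np.concatenate([np.zeros(nm[c], bool), np.ones(nq[c], bool)])
            o = np.argsort(p, kind="stable")
            chrom.append(np.full(nm[c] + nq[c], c + 1))
            pos.append(p[o])
            isq.append(q[o])
        chrom = np.concatenate(chrom)
        pos = np.concatenate(pos)
        isq = np.concatenate(isq)
        nall = np.full(len(pos), 2, dtype=np.uint8)
        nall[isq] = rng.integers(2, 5, size=isq.sum())
        return cls(lengths, chrom, pos, isq, nall, mutation_rate)

    def subset(self, locus_index: np.ndarray) -> "GenomeSpec":
        locus_index = np.sort(np.asarray(locus_index))
        return GenomeSpec(
            self.chrom_lengths,
            self.chrom[locus_index],
            self.pos_cm[locus_index],
            self.is_qtl[locus_index],
            self.n_alleles[locus_index],
            self.mutation_rate,
        )


@dataclass
class TraitSpec:
    """Heritability / variance bookkeeping for the simulated trait."""

    h2: float = 0.14
    var_p: float = 1.0
    gamma_shape: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.h2 < 1:
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")
        if self.var_p <= 0:
            raise ValueError("var_p must be positive")

    @property
    def var_a(self) -> float:
        return self.h2 * self.var_p

    @property
    def var_e(self) -> float:
        return self.var_p - self.var_a

    @property
    def lam(self) -> float:
        """Mixed-model variance ratio sigma2_e / sigma2_a."""
        return self.var_e / self.var_a


@dataclass
class PopSchedule:
    """Demographic schedule for one simulation phase."""

    phase: Literal["historical", "expansion", "selection"]
    # historical
    n_constant: int = 0
    constant_size: int = 0
    n_decline: int = 0
    final_size: int = 0
    hld: bool = True
    # expansion
    n_generations: int = 0
    offspring_per_dam: int = 5
    # selection
    n_sires: int = 0
    n_dams: int = 0
    replacement_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.phase == "historical":
            if self.n_constant < 0 or self.n_decline < 0:
                raise ValueError("generation counts must be non-negative")
            if self.constant_size <= 0 or self.final_size <= 0:
                raise ValueError("population sizes must be positive")
            if self.final_size > self.constant_size:
                raise ValueError("historical size path must be non-increasing")
        elif self.phase == "expansion":
            if self.n_generations < 0 or self.offspring_per_dam <= 0:
                raise ValueError("invalid expansion schedule")
        elif self.phase == "selection":
            if self.n_generations < 0 or self.n_sires <= 0 or self.n_dams <= 0:
                raise ValueError("invalid selection schedule")
            if not 0 <= self.replacement_rate <= 1:
                raise ValueError("replacement_rate must be in [0, 1]")

    @classmethod
    def historical(cls, constant_size: int = 1000, n_constant: int = 1000,
                   final_size: int = 200, ld: str = "hld",
                   n_decline: int | None = None) -> "PopSchedule":
        """Historical phase; the bottleneck spans 2,020 (HLD) or 1,020 (LLD)
        generations at full scale unless ``n_decline`` is given."""
        hld = ld.lower() == "hld"
        if n_decline is None:
            n_decline = 2020 if hld else 1020
        return cls("historical", n_constant=n_constant, constant_size=constant_size,
                   n_decline=n_decline, final_size=final_size, hld=hld)

    @classmethod
    def expansion(cls, n_generations: int = 6, offspring_per_dam: int = 5) -> "PopSchedule":
        return cls("expansion", n_generations=n_generations,
                   offspring_per_dam=offspring_per_dam)

    @classmethod
    def selection(cls, n_generations: int = 15, n_sires: int = 240,
                  n_dams: int = 6000, replacement_rate: float = 0.2) -> "PopSchedule":
        return cls("selection", n_generations=n_generations, n_sires=n_sires,
                   n_dams=n_dams, replacement_rate=replacement_rate)


def historical_size_path(schedule: PopSchedule) -> np.ndarray:
    """Cohort sizes of every historical generation after generation zero."""
    if schedule.phase != "historical":
        raise ValueError("schedule is not historical")
    const = np.full(schedule.n_constant, schedule.constant_size, dtype=int)
    if schedule.n_decline:
        decline = np.linspace(schedule.constant_size, schedule.final_size,
                              schedule.n_decline + 1)[1:]
        decline = np.round(decline).astype(int)
    else:
        decline = np.empty(0, dtype=int)
    return np.concatenate([const, decline])


@dataclass
class Population:
    """Pedigree plus haplotypes, breeding values and phenotypes.

    Animal ids are 1-based row numbers; ``sire``/``dam`` are 0 for
    founders.  ``haps`` has shape (n, 2, L) over the merged locus order
    of the associated :class:`GenomeSpec`.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray          # 1 male, 2 female
    generation: np.ndarray
    haps: np.ndarray         # (n, 2, L) uint8 allele codes
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None
    genotyped: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sire)
        ids = np.arange(1, n + 1)
        if np.any(self.sire >= ids) or np.any(self.dam >= ids):
            raise ValueError("pedigree must be sorted: parents precede offspring")
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)
        if self.phenotype is None:
            self.phenotype = np.full(n, np.nan)

    @property
    def n_animals(self) -> int:
        return len(self.sire)

    @property
    def females(self) -> np.ndarray:
        return np.nonzero(self.sex == FEMALE)[0]

    @property
    def males(self) -> np.ndarray:
        return np.nonzero(self.sex == MALE)[0]

    def marker_haplotypes(self, genome: GenomeSpec) -> np.ndarray:
        return self.haps[:, :, genome.marker_index]

    def qtl_haplotypes(self, genome: GenomeSpec) -> np.ndarray:
        return self.haps[:, :, genome.qtl_index]

    def pedigree_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "id": np.arange(1, self.n_animals + 1),
            "sire": self.sire,
            "dam": self.dam,
            "sex": np.where(self.sex == MALE, "M", "F"),
            "generation": self.generation,
        })


@dataclass
class QTLEffectTable:
    """Additive allele effects per QTL, after scaling to the target
    additive variance."""

    effects: np.ndarray        # (Q, 4) effect per allele code; unused slots 0
    scale_factor: float

    @property
    def n_qtl(self) -> int:
        return self.effects.shape[0]


# ---------------------------------------------------------------------------
# meiosis and mutation
# ---------------------------------------------------------------------------

from numba import njit


@njit(cache=True)
def _gamete_walk(haps, parents, gpos, cmap, phase, ev_pos, ev_count):
    """Copy one gamete per parent, walking loci once and flipping the
    source haplotype at each crossover position."""
    m = parents.shape[0]
    L = gpos.shape[0]
    out = np.empty((m, L), dtype=np.uint8)
    base = 0
    for g in range(m):
        p = parents[g]
        e0 = base
        e1 = base + ev_count[g]
        base = e1
        ptr = e0
        cur_chrom = -1
        src = 0
        for l in range(L):
            c = cmap[l]
            if c != cur_chrom:
                cur_chrom = c
                src = phase[g, c]
                # events before a chromosome's first locus flip the whole
                # chromosome, which the random phase already absorbs
                while ptr < e1 and ev_pos[ptr] < gpos[l]:
                    ptr += 1
            else:
                while ptr < e1 and ev_pos[ptr] < gpos[l]:
                    src ^= 1
                    ptr += 1
            out[g, l] = haps[p, src, l]
    return out


def _make_gametes(rng: np.random.Generator, haps: np.ndarray,
                  parent_rows: np.ndarray, genome: GenomeSpec) -> np.ndarray:
    """One gamete per entry of ``parent_rows``.

    Crossover count per chromosome is Poisson with mean = map length in
    Morgans, positions uniform, no interference (Haldane); chromosomes
    assort independently.  Implemented as a genome-wide Poisson process
    on the concatenated map plus an independent random phase per
    chromosome.
    """
    m = len(parent_rows)
    gpos, cmap, _ = genome.meiosis_layout()
    total_morgans = genome.total_length / 100.0

    k = rng.poisson(total_morgans, size=m)
    K = int(k.sum())
    x = rng.uniform(0.0, genome.total_length, size=K)
    # sort positions within each gamete's block
    g_idx = np.repeat(np.arange(m), k)
    order = np.lexsort((x, g_idx))
    x = np.ascontiguousarray(x[order])
    phase = rng.integers(0, 2, size=(m, genome.n_chromosomes), dtype=np.uint8)
    return _gamete_walk(haps, np.asarray(parent_rows, dtype=np.int64),
                        gpos, cmap, phase, x, k.astype(np.int64))


def _apply_mutations(rng: np.random.Generator, haps: np.ndarray,
                     genome: GenomeSpec) -> None:
    """Recurrent mutation: each newborn carries Poisson(u) mutations,
    u = 2 L mu (i.e. rate mu per gene copy), each assigned to a random
    (locus, gamete); a mutated marker flips its allele, a mutated QTL
    draws a different allele uniformly."""
    n_mut = rng.poisson(haps.shape[0] * genome.mutation_mean_u)
    if n_mut == 0:
        return
    n = haps.shape[0]
    loci = rng.integers(0, genome.n_loci, size=n_mut)
    rows = rng.integers(0, n, size=n_mut)
    copies = rng.integers(0, 2, size=n_mut)
    k = genome.n_alleles[loci]
    cur = haps[rows, copies, loci]
    shift = rng.integers(1, k.astype(np.int64))
    haps[rows, copies, loci] = ((cur.astype(np.int64) + shift) % k).astype(np.uint8)


# ---------------------------------------------------------------------------
# historical phase
# ---------------------------------------------------------------------------

def simulate_historical(genome: GenomeSpec, schedule: PopSchedule,
                        seed: int | np.random.Generator) -> Population:
    """Run the historical phase and return its final generation.

    Random union of gametes each generation (each offspring draws a
    random sire and a random dam), equal sex probability, recurrent
    mutation at ``genome.mutation_rate``.  Only the final cohort is
    returned, as a founder population (sire = dam = 0).
    """
    rng = np.random.default_rng(seed)
    if schedule.phase != "historical":
        raise ValueError("schedule.phase must be 'historical'")
    sizes = historical_size_path(schedule)
    if np.any(sizes <= 0):
        raise ValueError("historical sizes must be positive")

    n0 = schedule.constant_size
    L = genome.n_loci
    # generation zero: every gene copy uniform over the allele set
    haps = (rng.integers(0, 2**16, size=(n0, 2, L)) % genome.n_alleles).astype(np.uint8)
    sex = _draw_sex(rng, n0)

    for size in sizes:
        males = np.nonzero(sex == MALE)[0]
        females = np.nonzero(sex == FEMALE)[0]
        if len(males) == 0 or len(females) == 0:
            raise RuntimeError("a historical generation lost one sex entirely")
        sires = males[rng.integers(0, len(males), size=size)]
        dams = females[rng.integers(0, len(females), size=size)]
        haps = np.stack([
            _make_gametes(rng, haps, sires, genome),
            _make_gametes(rng, haps, dams, genome),
        ], axis=1)
        _apply_mutations(rng, haps, genome)
        sex = _draw_sex(rng, size)

    n = haps.shape[0]
    return Population(
        sire=np.zeros(n, dtype=np.int32),
        dam=np.zeros(n, dtype=np.int32),
        sex=sex,
        generation=np.zeros(n, dtype=np.int16),
        haps=haps,
    )


def _draw_sex(rng: np.random.Generator, n: int) -> np.ndarray:
    """Equal sex probability, but guarantee at least one of each for n >= 2."""
    sex = np.where(rng.random(n) < 0.5, MALE, FEMALE).astype(np.int8)
    if n >= 2:
        if np.all(sex == MALE):
            sex[rng.integers(0, n)] = FEMALE
        elif np.all(sex == FEMALE):
            sex[rng.integers(0, n)] = MALE
    return sex


def simulate_locus_drift(rng: np.random.Generator, sizes: Sequence[int],
                         n_alleles: np.ndarray,
                         mutation_rate: float = 1e-4) -> np.ndarray:
    """Marginal Wright-Fisher drift of allele frequencies, locus by locus.

    Each generation the 2N gene copies of every locus are drawn
    multinomially from the previous frequencies; every copy then mutates
    with probability ``mutation_rate`` to a different allele of its
    locus (uniformly chosen), matching the per-individual Poisson(2 L mu)
    mutation load of the gene-dropping simulator.  Initial frequencies
    are equal over each locus's allele set.

    Returns the final frequencies, shape (L, 4).
    """
    n_alleles = np.asarray(n_alleles, dtype=np.int64)
    L = len(n_alleles)
    K = 4
    p = np.zeros((L, K))
    for j in range(K):
        p[:, j] = np.where(j < n_alleles, 1.0 / n_alleles, 0.0)
    for N in sizes:
        n2 = 2 * int(N)
        if n2 <= 0:
            raise ValueError("population sizes must be positive")
        counts = np.zeros((L, K), dtype=np.int64)
        remaining = np.full(L, n2, dtype=np.int64)
        prem = np.ones(L)
        for j in range(K - 1):
            with np.errstate(invalid="ignore", divide="ignore"):
                pj = np.where(prem > 1e-12, np.clip(p[:, j] / prem, 0.0, 1.0), 0.0)
            c = rng.binomial(remaining, pj)
            counts[:, j] = c
            remaining -= c
            prem -= p[:, j]
        counts[:, K - 1] = remaining
        if mutation_rate > 0:
            m_out = rng.binomial(counts, mutation_rate)
            counts -= m_out
            ev_loc, ev_src = np.nonzero(m_out)
            if len(ev_loc):
                reps = m_out[ev_loc, ev_src]
                loc = np.repeat(ev_loc, reps)
                src = np.repeat(ev_src, reps)
                kk = n_alleles[loc]
                tgt = (src + rng.integers(1, kk)) % kk
                np.add.at(counts, (loc, tgt), 1)
        p = counts / n2
    return p


# ---------------------------------------------------------------------------
# locus panel selection and QTL effects
# ---------------------------------------------------------------------------

def select_segregating_loci(pop: Population, genome: GenomeSpec,
                            maf_min: float, n_markers: int, n_qtl: int,
                            seed: int | np.random.Generator) -> tuple[GenomeSpec, Population]:
    """Sample the analysis panel from the last historical generation.

    Markers are drawn uniformly without replacement among loci with
    MAF >= ``maf_min``; QTLs among loci with at least two alleles still
    segregating.  Returns the restricted genome and population.
    """
    rng = np.random.default_rng(seed)
    mk = genome.marker_index
    qt = genome.qtl_index
    if len(mk):
        freq1 = pop.haps[:, :, mk].mean(axis=(0, 1))
        maf = np.minimum(freq1, 1.0 - freq1)
        elig_m = mk[maf >= maf_min]
    else:
        elig_m = mk
    seg = np.array([len(np.unique(pop.haps[:, :, q])) >= 2 for q in qt])
    elig_q = qt[seg] if len(qt) else qt
    if len(elig_m) < n_markers:
        raise ValueError(
            f"only {len(elig_m)} markers with MAF >= {maf_min}, need {n_markers}")
    if len(elig_q) < n_qtl:
        raise ValueError(
            f"only {len(elig_q)} segregating QTLs, need {n_qtl}")
    keep = np.sort(np.concatenate([
        rng.choice(elig_m, size=n_markers, replace=False),
        rng.choice(elig_q, size=n_qtl, replace=False),
    ]))
    sub = genome.subset(keep)
    newpop = replace(pop, haps=np.ascontiguousarray(pop.haps[:, :, keep]))
    return sub, newpop


def assign_qtl_effects(genome: GenomeSpec, trait: TraitSpec,
                       ref_pop: Population,
                       seed: int | np.random.Generator) -> QTLEffectTable:
    """Gamma-distributed additive allele effects, scaled to the target
    additive variance.

    Each allele of each QTL draws |effect| ~ Gamma(shape, 1) with an
    independent random sign; a single multiplicative factor then makes
    the variance of the summed QTL values over ``ref_pop`` equal
    ``trait.var_a`` exactly.
    """
    rng = np.random.default_rng(seed)
    Q = genome.n_qtl
    k = genome.n_alleles[genome.qtl_index].astype(int)
    eff = rng.gamma(trait.gamma_shape, 1.0, size=(Q, 4))
    eff *= np.where(rng.random((Q, 4)) < 0.5, -1.0, 1.0)
    eff[np.arange(4)[None, :] >= k[:, None]] = 0.0
    if trait.var_a == 0:
        return QTLEffectTable(np.zeros_like(eff), 0.0)
    table = QTLEffectTable(eff, 1.0)
    raw = compute_tbv(ref_pop, genome, table)
    v = float(np.var(raw))
    if v <= 0:
        raise ValueError("zero genetic variance in the reference cohort before scaling")
    s = np.sqrt(trait.var_a / v)
    return QTLEffectTable(eff * s, s)


def compute_tbv(pop: Population, genome: GenomeSpec,
                effects: QTLEffectTable) -> np.ndarray:
    """True breeding value: sum of the animal's QTL allele effects."""
    qh = pop.qtl_haplotypes(genome)  # (n, 2, Q)
    idx = np.arange(effects.n_qtl)
    return (effects.effects[idx, qh[:, 0, :]] +
            effects.effects[idx, qh[:, 1, :]]).sum(axis=1)


def qtl_genetic_values(pop: Population, genome: GenomeSpec,
                       effects: QTLEffectTable) -> np.ndarray:
    """Per-QTL genotypic value of every animal, shape (n, Q)."""
    qh = pop.qtl_haplotypes(genome)
    idx = np.arange(effects.n_qtl)
    return effects.effects[idx, qh[:, 0, :]] + effects.effects[idx, qh[:, 1, :]]


def simulate_phenotypes(pop: Population, trait: TraitSpec,
                        seed: int | np.random.Generator,
                        rows: np.ndarray | None = None) -> Population:
    """Phenotype = TBV + N(0, var_e); the trait is sex-limited, so only
    females receive records."""
    rng = np.random.default_rng(seed)
    if pop.tbv is None:
        raise ValueError("tbv must be computed before phenotypes")
    if rows is None:
        rows = np.arange(pop.n_animals)
    phe = pop.phenotype.copy()
    f = rows[pop.sex[rows] == FEMALE]
    phe[f] = pop.tbv[f] + rng.normal(0.0, np.sqrt(trait.var_e), size=len(f))
    return replace(pop, phenotype=phe)


# ---------------------------------------------------------------------------
# expansion phase
# ---------------------------------------------------------------------------

def simulate_expansion(founders: Population, genome: GenomeSpec,
                       schedule: PopSchedule,
                       seed: int | np.random.Generator) -> Population:
    """Exponential growth of the number of dams.

    The dams double every generation starting from all founder females;
    each generation produces ``offspring_per_dam`` times the number of
    dams, each offspring from a random dam and a random sire of the
    previous cohort (100% replacement, no selection).
    """
    rng = np.random.default_rng(seed)
    if schedule.phase != "expansion":
        raise ValueError("schedule.phase must be 'expansion'")
    if schedule.n_generations == 0:
        return founders

    sire = list(founders.sire)
    dam = list(founders.dam)
    sex = founders.sex.copy()
    gen = founders.generation.copy()
    haps = founders.haps

    prev_rows = np.arange(founders.n_animals)       # previous cohort
    dam_rows = prev_rows[founders.sex[prev_rows] == FEMALE]
    n_dams = len(dam_rows)

    for g in range(1, schedule.n_generations + 1):
        sire_pool = prev_rows[sex[prev_rows] == MALE]
        if len(sire_pool) == 0:
            raise RuntimeError("no males available in the expansion phase")
        n_off = schedule.offspring_per_dam * n_dams
        d = dam_rows[rng.integers(0, n_dams, size=n_off)]
        s = sire_pool[rng.integers(0, len(sire_pool), size=n_off)]
        new = np.stack([
            _make_gametes(rng, haps, s, genome),
            _make_gametes(rng, haps, d, genome),
        ], axis=1)
        off_sex = _draw_sex(rng, n_off)
        start = haps.shape[0]
        haps = np.concatenate([haps, new], axis=0)
        sire.extend(s + 1)
        dam.extend(d + 1)
        sex = np.concatenate([sex, off_sex])
        gen = np.concatenate([gen, np.full(n_off, gen.max() + 1, dtype=gen.dtype)])
        prev_rows = np.arange(start, start + n_off)
        # dams double each generation, sampled among the new females
        fem = prev_rows[off_sex == FEMALE]
        n_dams = min(2 * n_dams, len(fem)) if g < schedule.n_generations else n_dams
        if g < schedule.n_generations:
            dam_rows = rng.choice(fem, size=n_dams, replace=False)

    return Population(
        sire=np.asarray(sire, dtype=np.int32),
        dam=np.asarray(dam, dtype=np.int32),
        sex=sex,
        generation=gen,
        haps=haps,
    )


# ---------------------------------------------------------------------------
# selection phase
# ---------------------------------------------------------------------------

def simulate_selection(pop: Population, trait: TraitSpec, genome: GenomeSpec,
                       effects: QTLEffectTable, schedule: PopSchedule,
                       seed: int | np.random.Generator) -> Population:
    """Truncation selection on pedigree-BLUP breeding values.

    Founder parents (``n_sires`` males, ``n_dams`` females) are sampled
    from the last generation of ``pop``.  Each generation every dam is
    mated to a random selected sire and produces one offspring; 20% (by
    default) of sires and dams are then replaced by the top-EBV
    candidates of the newest cohort.  EBVs come from a pedigree BLUP of
    all female phenotypes recorded so far, using the true variance
    ratio.  Phenotypes (females only) are attached to each new cohort.
    """
    from .mixed_model import solve_mme
    from .relmat import build_Ainv, inbreeding

    rng = np.random.default_rng(seed)
    if schedule.phase != "selection":
        raise ValueError("schedule.phase must be 'selection'")

    last = pop.generation == pop.generation.max()
    males = np.nonzero(last & (pop.sex == MALE))[0]
    females = np.nonzero(last & (pop.sex == FEMALE))[0]
    if len(males) < schedule.n_sires or len(females) < schedule.n_dams:
        raise ValueError(
            f"need {schedule.n_sires} sires and {schedule.n_dams} dams, "
            f"have {len(males)} males and {len(females)} females")
    sires = rng.choice(males, size=schedule.n_sires, replace=False)
    dams = rng.choice(females, size=schedule.n_dams, replace=False)

    sire = pop.sire.copy()
    dam = pop.dam.copy()
    sex = pop.sex.copy()
    gen = pop.generation.copy()
    haps = pop.haps
    tbv = compute_tbv(pop, genome, effects) if pop.tbv is None else pop.tbv.copy()
    phe = pop.phenotype.copy()

    n_rep_s = int(round(schedule.replacement_rate * schedule.n_sires))
    n_rep_d = int(round(schedule.replacement_rate * schedule.n_dams))
    F_cache = None

    for g in range(1, schedule.n_generations + 1):
        n_off = len(dams)
        s = sires[rng.integers(0, len(sires), size=n_off)]
        new = np.stack([
            _make_gametes(rng, haps, s, genome),
            _make_gametes(rng, haps, dams, genome),
        ], axis=1)
        off_sex = _draw_sex(rng, n_off)
        start = haps.shape[0]
        haps = np.concatenate([haps, new], axis=0)
        sire = np.concatenate([sire, (s + 1).astype(np.int32)])
        dam = np.concatenate([dam, (dams + 1).astype(np.int32)])
        sex = np.concatenate([sex, off_sex])
        gen = np.concatenate([gen, np.full(n_off, gen.max() + 1, dtype=gen.dtype)])
        new_rows = np.arange(start, start + n_off)

        qh = haps[new_rows][:, :, genome.qtl_index]
        idx = np.arange(effects.n_qtl)
        new_tbv = (effects.effects[idx, qh[:, 0, :]] +
                   effects.effects[idx, qh[:, 1, :]]).sum(axis=1)
        tbv = np.concatenate([tbv, new_tbv])
        newphe = np.full(n_off, np.nan)
        f = off_sex == FEMALE
        newphe[f] = new_tbv[f] + rng.normal(0.0, np.sqrt(trait.var_e), size=f.sum())
        phe = np.concatenate([phe, newphe])

        if g == schedule.n_generations:
            break

        if n_rep_s == 0 and n_rep_d == 0:
            continue  # parents unchanged; no ranking needed
        # pedigree BLUP on all female records to date
        rec_rows = np.nonzero(~np.isnan(phe))[0]
        if len(rec_rows) == 0:
            ebv = np.zeros(len(sire))
        else:
            F_cache = inbreeding(sire, dam, known=F_cache)
            Ainv = build_Ainv(sire, dam, F=F_cache)
            res = solve_mme(
                y=phe[rec_rows],
                X=np.ones((len(rec_rows), 1)),
                rec_animal=rec_rows,
                Kinv=Ainv,
                lam=trait.lam,
            )
            ebv = res.a_hat

        cand_m = new_rows[off_sex == MALE]
        cand_f = new_rows[off_sex == FEMALE]
        if len(cand_m) < n_rep_s or len(cand_f) < n_rep_d:
            raise ValueError("not enough candidates to satisfy the replacement rate")
        if n_rep_s:
            keep = sires[np.argsort(ebv[sires])[n_rep_s:]]
            top = cand_m[np.argsort(ebv[cand_m])[::-1][:n_rep_s]]
            sires = np.concatenate([keep, top])
        if n_rep_d:
            keep = dams[np.argsort(ebv[dams])[n_rep_d:]]
            top = cand_f[np.argsort(ebv[cand_f])[::-1][:n_rep_d]]
            dams = np.concatenate([keep, top])

    return Population(sire=sire, dam=dam, sex=sex, generation=gen, haps=haps,
                      tbv=tbv, phenotype=phe)


def genotype_females(pop: Population, n: int, last_k_generations: int,
                     seed: int | np.random.Generator) -> Population:
    """Flag ``n`` randomly chosen females of the last ``last_k_generations``
    cohorts as genotyped."""
    rng = np.random.default_rng(seed)
    gmax = pop.generation.max()
    elig = np.nonzero((pop.sex == FEMALE) &
                      (pop.generation > gmax - last_k_generations))[0]
    if len(elig) < n:
        raise ValueError(f"only {len(elig)} eligible females, need {n}")
    chosen = rng.choice(elig, size=n, replace=False)
    flags = np.zeros(pop.n_animals, dtype=bool)
    flags[chosen] = True
    return replace(pop, genotyped=flags)


def marker_dosages(pop: Population, genome: GenomeSpec,
                   rows: np.ndarray | None = None) -> np.ndarray:
    """Allele-1 dosage (0/1/2) at the marker loci for ``rows``
    (default: the genotyped animals)."""
    if rows is None:
        rows = np.nonzero(pop.genotyped)[0]
    mh = pop.haps[rows][:, :, genome.marker_index]
    return mh.sum(axis=1, dtype=np.int16)
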