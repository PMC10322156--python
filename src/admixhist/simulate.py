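"""Forward-in-time, individual-centred Wright-Fisher admixture simulation.

The admixed population H of N_g diploid individuals is re-formed each
generation from a parental pool of 2*N_g parents drawn, in proportions
given by the contribution schedule, from two fixed source gamete
reservoirs and from H itself at the previous generation.  Source parents
are assembled anew every generation by pairing two different reservoir
gametes; each offspring draws a pair of distinct parents (parents are
returned to the pool after every draw, i.e. a parent may have several
offspring but no offspring is produced by selfing); every gamete is an
independent Mendelian draw of one allele per site (sites are unlinked
and mutation-free).

Two equivalent execution modes are provided.  The *materialised* mode
stores every generation's haplotypes, exactly as described above.  The
default *lazy* mode records only the pedigree (who descends from whom,
and which reservoir gametes founded each source parent) and resolves the
genotypes of sampled individuals afterwards by per-site backward
gene-dropping.  All Mendelian segregation choices in both modes come
from a counter-based hash keyed by (generation, child, gamete, site), so
for the same seed the two modes produce bit-identical genotypes; the
lazy mode is the same stochastic process evaluated only where needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .scenarios import (
    AFRICAN,
    EUROPEAN,
    GENERATIONS,
    ContributionSchedule,
    ParameterVector,
    build_schedule,
    population_size_at,
)

__all__ = [
    "GameteReservoir",
    "AdmixedPopulation",
    "SampleSet",
    "InsufficientUnrelatedError",
    "build_reservoir",
    "advance_generation",
    "run_simulation",
    "resolve_genotypes",
    "sample_unrelated",
    "sample_source",
]


class InsufficientUnrelatedError(RuntimeError):
    """No subset of the requested size without shared grandparents."""


@dataclass
class GameteReservoir:
    """Fixed pool of haploid genomes matching a site-frequency spectrum."""

    label: str
    haplotypes: np.ndarray  # (R, L) uint8 alleles in {0, 1}
    site_frequencies: np.ndarray  # (L,) generating frequencies

    @property
    def R(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def L(self) -> int:
        return self.haplotypes.shape[1]


def build_reservoir(
    frequencies: np.ndarray, R: int = 20_000, rng: Optional[np.random.Generator] = None,
    label: str = AFRICAN,
) -> GameteReservoir:
    """Draw R haploid genomes with i.i.d. Bernoulli(f_s) alleles per site.

    Frequencies of exactly 0 or 1 are accepted with a monomorphic-site
    warning; frequencies outside [0, 1] are an error.  The reservoir is
    fixed for the whole admixture process.
    """
    rng = np.random.default_rng() if rng is None else rng
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.ndim != 1 or freqs.size < 1:
        raise ValueError("frequencies must be a non-empty 1-D array")
    if np.any((freqs < 0) | (freqs > 1)) or not np.all(np.isfinite(freqs)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if np.any((freqs == 0) | (freqs == 1)):
        warnings.warn("monomorphic site(s): frequency exactly 0 or 1", stacklevel=2)
    haps = (rng.random((R, freqs.size)) < freqs).astype(np.uint8)
    return GameteReservoir(label=label, haplotypes=haps, site_frequencies=freqs)


# ---------------------------------------------------------------------------
# counter-based segregation bits (splitmix64 finalizer)

_U = np.uint64
_GOLD = _U(0x9E3779B97F4A7C15)
_M1 = _U(0xBF58476D1CE4E5B9)
_M2 = _U(0x94D049BB133111EB)


def _segregation_bits(seed: int, g: int, child: np.ndarray, copy: np.ndarray,
                      site: np.ndarray) -> np.ndarray:
    """Deterministic Mendelian choice bit for (g, child, gamete copy, site).

    The key packs the four coordinates uniquely into 64 bits and is
    mixed with the splitmix64 finalizer; the top bit is returned.  Two
    lineages that traverse the same gamete at the same site always see
    the same choice, which is what makes lazy backward gene-dropping
    exactly equivalent to forward simulation.
    """
    key = (
        np.asarray(site, dtype=np.uint64)
        | (np.asarray(copy, dtype=np.uint64) << _U(21))
        | (np.asarray(child, dtype=np.uint64) << _U(22))
        | (_U(g) << _U(44))
    )
    z = (key + _U(1)) * _GOLD + _U(seed)
    z = (z ^ (z >> _U(30))) * _M1
    z = (z ^ (z >> _U(27))) * _M2
    z = z ^ (z >> _U(31))
    return (z >> _U(63)).astype(np.uint8)


# ---------------------------------------------------------------------------
# population containers


@dataclass
class _GenerationRecord:
    """Pedigree bookkeeping for the individuals created at generation g."""

    parent: np.ndarray  # (N_g, 2) int64; >=0 -> admixed index at g-1, <0 -> -(k+1) into src tables
    src_gametes: np.ndarray  # (S_g, 2) int64 reservoir gamete ids
    src_pop: np.ndarray  # (S_g,) uint8, 0 = African, 1 = European


@dataclass
class AdmixedPopulation:
    """The admixed population after some number of generations.

    Holds the full pedigree (one record per generation) and, in
    materialised mode, the current generation's haplotypes.
    """

    g: int
    N: int
    records: list  # list[_GenerationRecord], index = generation
    sizes: list  # list[int], N at each generation
    haplotypes: Optional[np.ndarray] = None  # (N, 2, L) uint8 or None (lazy)
    seg_seed: int = 0

    @property
    def genotypes(self) -> np.ndarray:
        if self.haplotypes is None:
            raise ValueError("lazy population: use resolve_genotypes for samples")
        return self.haplotypes.sum(axis=1, dtype=np.uint8)

    def parent_identities(self, g: Optional[int] = None) -> np.ndarray:
        """(N_g, 2) parent identity codes at generation g (default: last).

        Admixed parents keep their index; source parents get unique
        synthetic negative ids, distinct across generations.
        """
        g = self.g if g is None else g
        rec = self.records[g]
        out = rec.parent.astype(np.int64).copy()
        src = out < 0
        # unique across generations: offset by generation tag
        out[src] = -((-out[src] - 1) + (g + 1) * 10_000_000) - 1
        return out


@dataclass
class SampleSet:
    """Sampled genotype matrices for the admixed and source populations."""

    admixed: np.ndarray  # (n, L) uint8 in {0,1,2}
    afr: np.ndarray  # (n_src, L)
    eur: np.ndarray  # (n_src, L)
    ancestry_dosage: Optional[np.ndarray] = None  # (n, L) count of African-origin alleles


# ---------------------------------------------------------------------------
# generation mechanics


def _apportion(total: int, shares: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of `total` among shares; ties and
    leftover go to the last (admixed) class."""
    quotas = np.asarray(shares, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    short = total - counts.sum()
    if short > 0:
        # stable sort descending by remainder, later index wins ties
        order = np.argsort(-(rem + np.arange(len(shares)) * 1e-15))
        for i in order[:short]:
            counts[i] += 1
    return counts.tolist()


def _distinct_pairs(R: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n rows of two distinct ids from range(R)."""
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    if R < 2:
        raise ValueError("need at least two reservoir gametes")
    a = rng.integers(0, R, size=n)
    b = rng.integers(0, R, size=n)
    while True:
        clash = a == b
        if not clash.any():
            break
        b[clash] = rng.integers(0, R, size=int(clash.sum()))
    return np.stack([a, b], axis=1).astype(np.int64)


def _make_generation(
    N_new: int,
    row: tuple[float, float, float],
    N_prev: int,
    reservoirs: dict,
    rng: np.random.Generator,
) -> _GenerationRecord:
    """Draw the parental pool and offspring parent assignments for one
    generation; pure pedigree bookkeeping, no genotype work."""
    s_afr, s_eur, h = row
    if h > 0 and N_prev == 0:
        raise ValueError("h_g > 0 with no previous admixed generation")
    nA, nE, nH = _apportion(2 * N_new, (s_afr, s_eur, h))
    srcA = _distinct_pairs(reservoirs[AFRICAN].R, nA, rng)
    srcE = _distinct_pairs(reservoirs[EUROPEAN].R, nE, rng)
    src_gametes = np.concatenate([srcA, srcE], axis=0)
    src_pop = np.concatenate(
        [np.zeros(nA, dtype=np.uint8), np.ones(nE, dtype=np.uint8)]
    )
    if nH > 0:
        adm_ids = rng.integers(0, N_prev, size=nH)
    else:
        adm_ids = np.empty(0, dtype=np.int64)
    P = nA + nE + nH
    # pool entry -> parent code (<0 source slot, >=0 admixed individual)
    pool_code = np.concatenate(
        [-(np.arange(nA + nE, dtype=np.int64) + 1), adm_ids.astype(np.int64)]
    )
    # identity for the no-selfing rule: source slots are all distinct
    # individuals; admixed slots with the same id are the same individual
    identity = np.concatenate(
        [np.arange(nA + nE, dtype=np.int64), (nA + nE) + adm_ids.astype(np.int64)]
    )
    if not (identity != identity[0]).any():
        raise ValueError("cannot pick two distinct parents without selfing")
    i = rng.integers(0, P, size=N_new)
    j = rng.integers(0, P, size=N_new)
    for _ in range(10_000):
        clash = identity[i] == identity[j]
        if not clash.any():
            break
        j[clash] = rng.integers(0, P, size=int(clash.sum()))
    else:
        raise ValueError("cannot pick two distinct parents without selfing")
    parent = np.stack([pool_code[i], pool_code[j]], axis=1)
    return _GenerationRecord(parent=parent, src_gametes=src_gametes, src_pop=src_pop)


def _materialize(
    rec: _GenerationRecord,
    g: int,
    hap_prev: Optional[np.ndarray],
    reservoirs: dict,
    seg_seed: int,
    L: int,
) -> np.ndarray:
    """Build the (N, 2, L) haplotypes of the generation-g individuals."""
    N = rec.parent.shape[0]
    haps = np.empty((N, 2, L), dtype=np.uint8)
    sites = np.arange(L, dtype=np.uint64)
    res = (reservoirs[AFRICAN].haplotypes, reservoirs[EUROPEAN].haplotypes)
    for c in (0, 1):
        pid = rec.parent[:, c]
        for o in range(N):
            bits = _segregation_bits(seg_seed, g, np.full(L, o, np.uint64),
                                     np.full(L, c, np.uint64), sites)
            p = pid[o]
            if p >= 0:
                haps[o, c] = hap_prev[p, bits, sites.astype(np.intp)]
            else:
                k = -p - 1
                gam = rec.src_gametes[k, bits]
                haps[o, c] = res[rec.src_pop[k]][gam, sites.astype(np.intp)]
    return haps


def advance_generation(
    pop: AdmixedPopulation,
    row: tuple[float, float, float],
    reservoirs: dict,
    rng: np.random.Generator,
    N_new: Optional[int] = None,
) -> AdmixedPopulation:
    """Advance a materialised population by one generation.

    `row` is the schedule row (s_Afr,g, s_Eur,g, h_g) for the new
    generation; `N_new` is the new reproductive size (default:
    unchanged).  Returns a new AdmixedPopulation at generation g+1 with
    haplotypes materialised.
    """
    if pop.haplotypes is None:
        raise ValueError("advance_generation requires a materialised population")
    g = pop.g + 1
    L = pop.haplotypes.shape[2]
    N_new = pop.N if N_new is None else int(N_new)
    rec = _make_generation(N_new, row, pop.N, reservoirs, rng)
    haps = _materialize(rec, g, pop.haplotypes, reservoirs, pop.seg_seed, L)
    return AdmixedPopulation(
        g=g,
        N=N_new,
        records=pop.records + [rec],
        sizes=pop.sizes + [N_new],
        haplotypes=haps,
        seg_seed=pop.seg_seed,
    )


def run_simulation(
    params: ParameterVector,
    reservoirs: dict,
    rng: np.random.Generator,
    materialize: bool = False,
) -> AdmixedPopulation:
    """Run the full 21-generation admixture process.

    Founds H at generation 0 with proportions (s_Afr,0, s_Eur,0) of
    source parents, then applies the schedule for g = 1..20 with the
    reproductive size trajectory N_g.  With ``materialize=False`` (the
    default) only the pedigree is stored; use :func:`resolve_genotypes`
    to obtain sampled genotypes.  Both modes consume the seedable stream
    identically and give bit-identical sampled genotypes.
    """
    if set(reservoirs) != {AFRICAN, EUROPEAN}:
        raise ValueError("reservoirs must map African and European labels")
    L = reservoirs[AFRICAN].L
    if reservoirs[EUROPEAN].L != L:
        raise ValueError("reservoirs must cover the same sites")
    schedule = build_schedule(params)
    seg_seed = int(rng.integers(0, 2**62))
    records: list[_GenerationRecord] = []
    sizes: list[int] = []
    hap_prev: Optional[np.ndarray] = None
    N_prev = 0
    for g in range(GENERATIONS):
        N_g = population_size_at(params.demography, g)
        row = (float(schedule.s_afr[g]), float(schedule.s_eur[g]), float(schedule.h[g]))
        rec = _make_generation(N_g, row, N_prev, reservoirs, rng)
        records.append(rec)
        sizes.append(N_g)
        if materialize:
            hap_prev = _materialize(rec, g, hap_prev, reservoirs, seg_seed, L)
        N_prev = N_g
    return AdmixedPopulation(
        g=GENERATIONS - 1,
        N=N_prev,
        records=records,
        sizes=sizes,
        haplotypes=hap_prev,
        seg_seed=seg_seed,
    )


def resolve_genotypes(
    pop: AdmixedPopulation,
    individuals: np.ndarray,
    reservoirs: dict,
    with_ancestry: bool = False,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Genotypes of chosen final-generation individuals by backward
    gene-dropping through the pedigree.

    For every (individual, gamete, site) lineage the walk follows the
    recorded parent of that gamete and uses the counter-based
    segregation bit to choose which of the parent's two copies it
    descends from, terminating at a reservoir gamete.  Returns the
    (n, L) genotype matrix and, if requested, the per-site count of
    African-origin alleles (true-ancestry instrumentation).
    """
    individuals = np.asarray(individuals, dtype=np.int64)
    n = individuals.size
    L = reservoirs[AFRICAN].L
    res = (reservoirs[AFRICAN].haplotypes, reservoirs[EUROPEAN].haplotypes)

    # flat lineage state: one entry per (sample row, copy, site)
    rows = np.repeat(np.arange(2 * n, dtype=np.int64), L)
    site = np.tile(np.arange(L, dtype=np.int64), 2 * n)
    cur_ind = np.repeat(np.repeat(individuals, 2), L)
    cur_copy = np.repeat(np.tile(np.array([0, 1], dtype=np.uint8), n), L)

    alleles = np.zeros(2 * n * L, dtype=np.uint8)
    origin = np.zeros(2 * n * L, dtype=np.uint8) if with_ancestry else None
    out_pos = np.arange(2 * n * L, dtype=np.int64)

    for g in range(pop.g, -1, -1):
        if cur_ind.size == 0:
            break
        rec = pop.records[g]
        bits = _segregation_bits(pop.seg_seed, g, cur_ind.astype(np.uint64),
                                 cur_copy.astype(np.uint64), site.astype(np.uint64))
        pid = rec.parent[cur_ind, cur_copy]
        is_src = pid < 0
        if is_src.any():
            k = (-pid[is_src] - 1)
            b = bits[is_src].astype(np.intp)
            gam = rec.src_gametes[k, b]
            pops = rec.src_pop[k]
            s = site[is_src]
            vals = np.where(
                pops == 0, res[0][gam, s], res[1][gam, s]
            ).astype(np.uint8)
            alleles[out_pos[is_src]] = vals
            if with_ancestry:
                origin[out_pos[is_src]] = (pops == 0).astype(np.uint8)
        keep = ~is_src
        cur_ind = pid[keep]
        cur_copy = bits[keep]
        site = site[keep]
        out_pos = out_pos[keep]
    if cur_ind.size:
        raise RuntimeError("unresolved lineages at generation 0")

    geno = alleles.reshape(2 * n, L).reshape(n, 2, L).sum(axis=1, dtype=np.uint8)
    dos = None
    if with_ancestry:
        dos = origin.reshape(n, 2, L).sum(axis=1, dtype=np.uint8)
    return geno, dos


# ---------------------------------------------------------------------------
# sampling


def _grandparent_codes(pop: AdmixedPopulation) -> np.ndarray:
    """(N, 4) array of grandparent identity codes per final-generation
    individual, remapped to a compact 0..K-1 range.

    Source parents contribute their own unique synthetic id (duplicated
    to fill both slots), so half-sibs through a shared source parent are
    also flagged.  Codes may repeat within a row; rows sharing any code
    share a grandparent.
    """
    g = pop.g
    rec = pop.records[g]
    rec_prev = pop.records[g - 1] if g >= 1 else None
    N = pop.N
    out = np.empty((N, 4), dtype=np.int64)
    # raw code spaces kept disjoint by offsets:
    #   admixed ids at g-2: [0, N_prev2)
    #   source slots at g-1: N_prev2 + k
    #   source slots at g:   N_prev2 + S_prev + k
    n_prev2 = pop.sizes[g - 2] if g >= 2 else 0
    s_prev = rec_prev.src_gametes.shape[0] if rec_prev is not None else 0
    for c in (0, 1):
        p = rec.parent[:, c]
        is_src = p < 0
        cols = out[:, 2 * c : 2 * c + 2]
        # source parent at g: its own unique id in both slots
        code_src = n_prev2 + s_prev + (-p - 1)
        cols[is_src, 0] = code_src[is_src]
        cols[is_src, 1] = code_src[is_src]
        adm = ~is_src
        if adm.any():
            q = rec_prev.parent[p[adm], :]  # (m, 2)
            qc = np.where(q < 0, n_prev2 + (-q - 1), q)
            cols[adm] = qc
    _, compact = np.unique(out, return_inverse=True)
    return compact.reshape(N, 4)


def sample_unrelated(
    pop: AdmixedPopulation, n: int, rng: np.random.Generator,
    max_tries: int = 40, relax: bool = False,
) -> np.ndarray:
    """Indices of n final-generation individuals sharing no grandparents.

    Greedy selection over randomized orders (alternating plain shuffles
    with orders preferring individuals whose grandparents are least
    shared) with a bounded retry budget.  With ``relax=True`` a fully
    unrelated subset is still preferred, but when the pedigree cannot
    support one (small reproductive sizes) the sample is completed with
    the individuals adding the fewest already-used grandparents instead
    of raising; otherwise InsufficientUnrelatedError is raised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > pop.N:
        raise InsufficientUnrelatedError(f"requested {n} > population size {pop.N}")
    gp = _grandparent_codes(pop)
    K = int(gp.max()) + 1
    # popularity-weighted degree for conflict-aware orderings
    degree = np.bincount(gp.ravel(), minlength=K)[gp].sum(axis=1).astype(float)

    best = np.empty(0, dtype=np.int64)
    best_used = np.zeros(K, dtype=bool)
    for attempt in range(max_tries):
        if attempt % 2 == 0:
            order = rng.permutation(pop.N)
        else:
            order = np.argsort(degree + rng.random(pop.N) * (degree.mean() + 1))
        chosen: list[int] = []
        used = np.zeros(K, dtype=bool)
        for o in order:
            row = gp[o]
            if not used[row].any():
                chosen.append(int(o))
                used[row] = True
                if len(chosen) == n:
                    return np.array(chosen, dtype=np.int64)
        if len(chosen) > len(best):
            best = np.array(chosen, dtype=np.int64)
            best_used = used
    if not relax:
        raise InsufficientUnrelatedError(
            f"no subset of {n} individuals without shared grandparents in {pop.N}"
        )
    mask = np.ones(pop.N, dtype=bool)
    mask[best] = False
    remaining = np.flatnonzero(mask)
    overlap = best_used[gp[remaining]].sum(axis=1) + rng.random(remaining.size)
    fill = remaining[np.argsort(overlap)][: n - len(best)]
    return np.concatenate([best, fill.astype(np.int64)])[:n]


def sample_source(
    reservoir: GameteReservoir, n: int = 60, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """n diploid genotypes formed from 2n distinct reservoir gametes."""
    rng = np.random.default_rng() if rng is None else rng
    if 2 * n > reservoir.R:
        raise ValueError(f"2n = {2*n} exceeds reservoir size {reservoir.R}")
    if n == 0:
        return np.empty((0, reservoir.L), dtype=np.uint8)
    ids = rng.choice(reservoir.R, size=2 * n, replace=False)
    return (
        reservoir.haplotypes[ids[:n]] + reservoir.haplotypes[ids[n:]]
    ).astype(np.uint8)
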