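"""Synthetic inputs for exercising the whole pipeline without downloads.

Three generators:

* source-population allele-frequency pairs under a Balding-Nichols
  model: an ancestral frequency per SNP, then each population's
  frequency drawn from Beta(p (1-F)/F, (1-p)(1-F)/F) where F is the
  target divergence (an Fst-like parameter), clipped to a minor-allele
  frequency floor (the study's SNP panels avoided singletons);
* pseudo-observed admixed datasets: a full simulator run under a known
  parameter vector, with unrelated admixed sampling, source sampling,
  and the generating truth retained;
* ancestry/ROH track fixtures with a controllable association between
  long-ROH placement and African ancestry.

Everything is seeded and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import roh as rohmod
from .roh import AFR, ASN, EUR, AncestryROHTrack, AncestrySegment, ROHInterval
from .scenarios import (
    AFRICAN,
    EUROPEAN,
    DemographyParams,
    ParameterVector,
    PriorSpec,
    PulseProcess,
    RecurringProcess,
    SCENARIOS,
    draw_parameters,
    parameter_record,
)
from .simulate import (
    GameteReservoir,
    SampleSet,
    build_reservoir,
    resolve_genotypes,
    run_simulation,
    sample_source,
    sample_unrelated,
)
from .sumstats import SUMMARY_NAMES, compute_summary_vector

__all__ = [
    "SourcePairSpec",
    "PseudoObservedSet",
    "DESK_SCALE",
    "generate_source_frequencies",
    "make_reservoirs",
    "generate_pseudo_observed",
    "exemplar_parameters",
    "build_reference_table",
    "generate_roh_fixture",
]

#: documented scaled-down mirror of the study's 60,000-SNP /
#: 20,000-gamete / 10,000-simulation configuration
DESK_SCALE = {
    "L": 5_000,
    "reservoir_size": 2_000,
    "n_admixed": 30,
    "n_source": 60,
    "sims_per_scenario": 500,
}


@dataclass(frozen=True)
class SourcePairSpec:
    """Specification of a synthetic two-source frequency panel."""

    L: int = 5_000
    divergence: float = 0.15
    maf_floor: float = 0.01
    ancestral_beta: tuple[float, float] = (0.8, 0.8)

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence must be in (0, 1)")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("MAF floor must be in (0, 0.5)")


@dataclass
class PseudoObservedSet:
    """A sampled dataset with its generating truth."""

    samples: SampleSet
    params: ParameterVector
    seed: int
    summary: Optional[np.ndarray] = None

    @property
    def true_ancestry_fraction(self) -> np.ndarray:
        """Per-individual realized African genome fraction (instrumented)."""
        if self.samples.ancestry_dosage is None:
            raise ValueError("dataset was generated without ancestry instrumentation")
        return self.samples.ancestry_dosage.mean(axis=1) / 2.0


def generate_source_frequencies(
    spec: SourcePairSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two per-site allele-frequency vectors at the target divergence."""
    p_anc = rng.beta(*spec.ancestral_beta, size=spec.L)
    p_anc = np.clip(p_anc, spec.maf_floor, 1.0 - spec.maf_floor)
    F = spec.divergence
    shape = (1.0 - F) / F
    fa = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    fb = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    lo, hi = spec.maf_floor, 1.0 - spec.maf_floor
    return np.clip(fa, lo, hi), np.clip(fb, lo, hi)


def make_reservoirs(
    freq_afr: np.ndarray,
    freq_eur: np.ndarray,
    R: int,
    rng: np.random.Generator,
) -> dict:
    """Build the fixed African/European gamete reservoirs."""
    return {
        AFRICAN: build_reservoir(freq_afr, R=R, rng=rng, label=AFRICAN),
        EUROPEAN: build_reservoir(freq_eur, R=R, rng=rng, label=EUROPEAN),
    }


def generate_pseudo_observed(
    params: ParameterVector,
    spec: SourcePairSpec,
    n: int,
    seed: int,
    reservoirs: Optional[dict] = None,
    n_source: int = 60,
    with_ancestry: bool = False,
    with_summary: bool = False,
    relax_unrelated: bool = False,
) -> PseudoObservedSet:
    """Simulate one dataset under known parameters and sample it.

    Builds reservoirs from a fresh frequency draw unless `reservoirs`
    is supplied; runs the admixture process; samples n unrelated
    admixed individuals and n_source diploids per source.  With
    ``relax_unrelated=True`` small reproductive sizes that cannot
    support a fully unrelated sample are completed with least-related
    individuals (as in reference-table builds) instead of raising.
    """
    rng = np.random.default_rng(seed)
    if reservoirs is None:
        fa, fe = generate_source_frequencies(spec, rng)
        R = DESK_SCALE["reservoir_size"]
        reservoirs = make_reservoirs(fa, fe, R, rng)
    pop = run_simulation(params, reservoirs, rng)
    idx = sample_unrelated(pop, n, rng, relax=relax_unrelated)
    geno, dosage = resolve_genotypes(pop, idx, reservoirs, with_ancestry=with_ancestry)
    afr = sample_source(reservoirs[AFRICAN], n=n_source, rng=rng)
    eur = sample_source(reservoirs[EUROPEAN], n=n_source, rng=rng)
    samples = SampleSet(admixed=geno, afr=afr, eur=eur, ancestry_dosage=dosage)
    summary = compute_summary_vector(samples) if with_summary else None
    return PseudoObservedSet(samples=samples, params=params, seed=seed, summary=summary)


def exemplar_parameters(scenario: str, s_afr_0: float = 0.5) -> ParameterVector:
    """A strong-signal parameter vector typical of its scenario.

    Pulse processes get two well-separated substantial pulses; recurring
    processes a multi-generation mid-history period with high initial
    intensity decaying to a sustained level — the regimes in which the
    four histories leave their most distinctive marks on the admixture
    pattern statistics.  Process timings are staggered so that combined
    African + European contributions stay feasible at every generation.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")

    def pulses(src, t1, t2, s1=0.5, s2=0.4):
        return PulseProcess(source=src, t_p1=t1, t_p2=t2, s_p1=s1, s_p2=s2)

    def recurring(src, t1, t2, s1=0.65, s2=0.3):
        return RecurringProcess(source=src, t_t1=t1, t_t2=t2,
                                s_t1=s1, s_t2=s2, u=0.25)

    afr_rec = "AfrRecurring" in scenario
    eur_rec = "EurRecurring" in scenario
    if not afr_rec and not eur_rec:
        afr = pulses(AFRICAN, 16, 8)
        eur = pulses(EUROPEAN, 14, 5)
    elif not afr_rec and eur_rec:
        afr = pulses(AFRICAN, 16, 3)
        eur = recurring(EUROPEAN, 7, 14)
    elif afr_rec and not eur_rec:
        afr = recurring(AFRICAN, 7, 14)
        eur = pulses(EUROPEAN, 16, 3)
    else:
        afr = recurring(AFRICAN, 9, 15, 0.6, 0.3)
        eur = recurring(EUROPEAN, 3, 9, 0.6, 0.3)
    return ParameterVector(
        scenario=scenario,
        s_Afr_0=s_afr_0,
        african_process=afr,
        european_process=eur,
        demography=DemographyParams(N0=500, N20=50_000, uN=0.25),
    )


def build_reference_table(
    scenarios: Sequence[str] = SCENARIOS,
    sims_per_scenario: int = DESK_SCALE["sims_per_scenario"],
    spec: SourcePairSpec = SourcePairSpec(),
    n: int = DESK_SCALE["n_admixed"],
    seed: int = 0,
    prior: Optional[PriorSpec] = None,
    reservoir_size: int = DESK_SCALE["reservoir_size"],
    n_source: int = DESK_SCALE["n_source"],
) -> pd.DataFrame:
    """Simulate a reference table: one row per simulation with the
    scenario label, the parameter columns and the 42 summary statistics.

    The gamete reservoirs are built once from one frequency draw and
    shared by all simulations of the table.
    """
    prior = PriorSpec() if prior is None else prior
    root = np.random.default_rng(seed)
    fa, fe = generate_source_frequencies(spec, root)
    reservoirs = make_reservoirs(fa, fe, reservoir_size, root)
    rows = []
    for scen in scenarios:
        for i in range(sims_per_scenario):
            rng = np.random.default_rng(root.integers(0, 2**31))
            params = draw_parameters(prior, scen, rng)
            pop = run_simulation(params, reservoirs, rng)
            # small drawn N20 cannot always support a fully unrelated
            # sample; prefer unrelated, fill with least-related
            idx = sample_unrelated(pop, n, rng, relax=True)
            geno, _ = resolve_genotypes(pop, idx, reservoirs)
            ss = SampleSet(
                admixed=geno,
                afr=sample_source(reservoirs[AFRICAN], n=n_source, rng=rng),
                eur=sample_source(reservoirs[EUROPEAN], n=n_source, rng=rng),
            )
            rec = parameter_record(params)
            rec.update(zip(SUMMARY_NAMES, compute_summary_vector(ss)))
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ancestry/ROH fixtures


def _ancestry_track(
    chrom_lengths: dict,
    afr_fraction: float,
    mean_segment_cm: float,
    rng: np.random.Generator,
    identical_haplotypes: bool,
    asn_fraction: float = 0.0,
) -> list:
    segs = []
    for chrom, L in chrom_lengths.items():
        hap_tracks = []
        n_haps = 1 if identical_haplotypes else 2
        for hap in range(n_haps):
            pos = 0.0
            track = []
            while pos < L:
                length = min(rng.exponential(mean_segment_cm) + 0.5, L - pos)
                u = rng.random()
                if u < asn_fraction:
                    lab = ASN
                elif u < asn_fraction + (1 - asn_fraction) * afr_fraction:
                    lab = AFR
                else:
                    lab = EUR
                track.append((pos, pos + length, lab))
                pos += length
            hap_tracks.append(track)
        if identical_haplotypes:
            hap_tracks.append(hap_tracks[0])
        for hap, track in enumerate(hap_tracks):
            for a, b, lab in track:
                segs.append(AncestrySegment(haplotype=hap, chrom=chrom,
                                            start=a, end=b, ancestry=lab))
    return segs


def generate_roh_fixture(
    n_individuals: int,
    rng: np.random.Generator,
    chrom_lengths: Optional[dict] = None,
    association: float = 0.0,
    afr_fraction: float = 0.5,
    n_long: int = 5,
    long_range: tuple[float, float] = (1.0, 3.0),
    n_medium: int = 3,
    n_short: int = 4,
    mean_segment_cm: float = 25.0,
    identical_haplotypes: bool = True,
    asn_fraction: float = 0.0,
) -> list:
    """A set of per-individual ancestry/ROH tracks.

    `association` in [0, 1] is the probability that a long ROH is
    forced fully inside homozygous-AFR ancestry; 0 gives the null
    (placement independent of ancestry), 1 the fully associated
    alternative.  Short and medium ROH are always placed uniformly.
    """
    if chrom_lengths is None:
        chrom_lengths = {f"chr{i+1}": 150.0 for i in range(10)}
    tracks = []
    for _ in range(n_individuals):
        segs = _ancestry_track(chrom_lengths, afr_fraction, mean_segment_cm, rng,
                               identical_haplotypes, asn_fraction)
        lengths = np.concatenate(
            [
                rng.uniform(*long_range, size=n_long),
                rng.uniform(rohmod.SHORT_MAX, rohmod.MEDIUM_MAX, size=n_medium),
                rng.uniform(0.05, rohmod.SHORT_MAX, size=n_short),
            ]
        )
        assoc = np.concatenate(
            [np.full(n_long, association), np.zeros(n_medium + n_short)]
        )
        rois = _place_roh(segs, chrom_lengths, lengths, assoc, rng)
        tracks.append(
            AncestryROHTrack(chrom_lengths=dict(chrom_lengths), segments=segs,
                             roh=rois)
        )
    return tracks


def _place_roh(track_segs, chrom_lengths, lengths, assoc_probs, rng):
    """Place ROH of the given lengths without overlap.

    assoc_probs[i] is the probability that ROH i is constrained fully
    inside homozygous-AFR ancestry; otherwise it is placed uniformly on
    the map (within a chromosome), with rejection for overlaps.
    """
    out = []
    chroms = list(chrom_lengths)
    offsets = np.concatenate([[0.0], np.cumsum([chrom_lengths[c] for c in chroms])])
    total = offsets[-1]
    if lengths.sum() > total:
        raise ValueError("requested total ROH length exceeds map length")
    tgt = []
    for ci, c in enumerate(chroms):
        hap0 = sorted(
            [s for s in track_segs if s.chrom == c and s.haplotype == 0],
            key=lambda s: s.start,
        )
        hap1 = {(s.start, s.end): s.ancestry
                for s in track_segs if s.chrom == c and s.haplotype == 1}
        for s in hap0:
            if s.ancestry == AFR and hap1.get((s.start, s.end)) == AFR:
                tgt.append((offsets[ci] + s.start, offsets[ci] + s.end))
    placed: list[tuple[float, float]] = []

    def overlaps(a, b):
        return any(a < e and s < b for s, e in placed)

    for l, p_assoc in zip(lengths, assoc_probs):
        assoc = rng.random() < p_assoc
        ok = False
        for _ in range(2_000):
            if assoc:
                fits = [(s, e) for s, e in tgt if e - s >= l]
                if not fits:
                    raise ValueError(
                        f"no homozygous AFR segment can hold an ROH of {l:.2f} cM"
                    )
                widths = np.array([e - s - l for s, e in fits]) + 1e-12
                j = rng.choice(len(fits), p=widths / widths.sum())
                start = fits[j][0] + rng.random() * max(fits[j][1] - fits[j][0] - l, 0)
            else:
                w = np.maximum([chrom_lengths[c] - l for c in chroms], 0)
                if w.sum() <= 0:
                    raise ValueError("ROH longer than every chromosome")
                ci = rng.choice(len(chroms), p=w / w.sum())
                start = offsets[ci] + rng.random() * (chrom_lengths[chroms[ci]] - l)
            if not overlaps(start, start + l):
                placed.append((start, start + l))
                ok = True
                break
        if not ok:
            raise ValueError("non-overlapping ROH placement infeasible")
        ci = int(np.searchsorted(offsets, placed[-1][0] + 1e-12, side="right") - 1)
        out.append(
            ROHInterval(chrom=chroms[ci], start=placed[-1][0] - offsets[ci],
                        end=placed[-1][0] - offsets[ci] + l)
        )
    return out
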