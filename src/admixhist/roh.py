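"""Runs of homozygosity (ROH) intersected with local-ancestry tracks.

ROH are classified by genetic length l (cM): short (l < 0.25), medium
(0.25 <= l < 1) and long (l >= 1); the implied time to the most recent
common ancestor of the underlying haplotypes is g = 100 / (2 l)
generations, so long ROH index common ancestors within the last ~50
generations.  Local ancestry is a per-haplotype partition of the genome
into AFR / EUR / ASN segments in cM coordinates.  Where informative
ancestry segments do not abut, each side is extended to the midpoint of
the gap before intersecting with ROH (the midpoint rule).

The ancestry-excess statistic of an individual is the AFR proportion of
their long-ROH content minus their genome-wide AFR proportion (both
computed over AFR + EUR content; ASN segments and ROH with heterozygous
ancestry are excluded).  Its significance is assessed by re-placing
each individual's long ROH uniformly at random on their own map
(lengths preserved, no overlaps) and recomputing the mean excess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AFR", "EUR", "ASN",
    "AncestrySegment",
    "ROHInterval",
    "AncestryROHTrack",
    "PermutationResult",
    "tmrca_from_length",
    "classify_length",
    "roh_ancestry_content",
    "ancestry_excess",
    "permutation_test",
]

AFR, EUR, ASN = "AFR", "EUR", "ASN"
_LABELS = (AFR, EUR, ASN)

#: class boundaries in cM; the boundary values 0.25 and 1 are assigned
#: to the larger class (medium and long respectively)
SHORT_MAX = 0.25
MEDIUM_MAX = 1.0


def tmrca_from_length(l: float) -> float:
    """Generations to the most recent common ancestor: g = 100 / (2 l)."""
    if not (l > 0):
        raise ValueError(f"ROH length must be positive, got {l}")
    return 100.0 / (2.0 * l)


def classify_length(l: float) -> str:
    if not (l > 0):
        raise ValueError("ROH length must be positive")
    if l < SHORT_MAX:
        return "short"
    if l < MEDIUM_MAX:
        return "medium"
    return "long"


@dataclass(frozen=True)
class AncestrySegment:
    haplotype: int  # 0 or 1
    chrom: str
    start: float  # cM, 0-based half-open
    end: float
    ancestry: str

    def __post_init__(self):
        if self.haplotype not in (0, 1):
            raise ValueError("haplotype must be 0 or 1")
        if not (self.start < self.end):
            raise ValueError("segment start must be < end")
        if self.ancestry not in _LABELS:
            raise ValueError(f"ancestry must be one of {_LABELS}")


@dataclass(frozen=True)
class ROHInterval:
    chrom: str
    start: float
    end: float

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError("ROH start must be < end")

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        return classify_length(self.length)


@dataclass
class AncestryROHTrack:
    """One individual's two haplotype ancestry tracks plus ROH calls."""

    chrom_lengths: dict  # chrom -> map length in cM
    segments: list  # list[AncestrySegment]
    roh: list  # list[ROHInterval]

    def __post_init__(self):
        for r in self.roh:
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"ROH on unknown chromosome {r.chrom}")
            if r.start < 0 or r.end > self.chrom_lengths[r.chrom]:
                raise ValueError("ROH outside map bounds")
        self._cache: dict = {}

    # -- midpoint-extended per-haplotype step functions -------------------

    def _hap_steps(self, chrom: str, hap: int) -> tuple[np.ndarray, np.ndarray]:
        """(breakpoints, labels) covering [0, L) for one haplotype.

        Consecutive informative segments are extended to meet at the
        midpoint of any gap; the first and last segments are extended to
        the chromosome edges.  labels[i] applies on
        [breakpoints[i], breakpoints[i+1]).
        """
        key = ("hap", chrom, hap)
        if key in self._cache:
            return self._cache[key]
        L = self.chrom_lengths[chrom]
        segs = sorted(
            (s for s in self.segments if s.chrom == chrom and s.haplotype == hap),
            key=lambda s: s.start,
        )
        if not segs:
            raise ValueError(f"no ancestry segments on {chrom} haplotype {hap}")
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError("overlapping ancestry segments on one haplotype")
        bps = [0.0]
        labels = []
        for i, s in enumerate(segs):
            labels.append(s.ancestry)
            if i + 1 < len(segs):
                bps.append((s.end + segs[i + 1].start) / 2.0)
        bps.append(L)
        # merge equal-label neighbours
        mb, ml = [bps[0]], [labels[0]]
        for i in range(1, len(labels)):
            if labels[i] == ml[-1]:
                continue
            mb.append(bps[i])
            ml.append(labels[i])
        mb.append(L)
        out = (np.asarray(mb), np.asarray(ml, dtype=object))
        self._cache[key] = out
        return out

    def _diploid_dosage(self, chrom: str) -> tuple[np.ndarray, dict, np.ndarray]:
        """(breakpoints, per-label dosage arrays, het indicator) for the
        diploid ancestry along one chromosome.

        dosage[label][i] in {0, 1, 2} counts haplotype copies with that
        label on [bp[i], bp[i+1]); het[i] is 1 where the two haplotype
        labels differ.
        """
        key = ("dip", chrom)
        if key in self._cache:
            return self._cache[key]
        b0, l0 = self._hap_steps(chrom, 0)
        b1, l1 = self._hap_steps(chrom, 1)
        bps = np.unique(np.concatenate([b0, b1]))
        mids = (bps[:-1] + bps[1:]) / 2.0
        lab0 = l0[np.searchsorted(b0, mids, side="right") - 1]
        lab1 = l1[np.searchsorted(b1, mids, side="right") - 1]
        dosage = {
            lab: (lab0 == lab).astype(int) + (lab1 == lab).astype(int)
            for lab in _LABELS
        }
        het = (lab0 != lab1).astype(int)
        out = (bps, dosage, het)
        self._cache[key] = out
        return out

    def global_ancestry_fraction(self, ancestry: str = AFR) -> float:
        """Genome-wide diploid fraction of `ancestry` among AFR + EUR content."""
        want = 0.0
        afr_eur = 0.0
        for chrom in self.chrom_lengths:
            bps, dosage, _ = self._diploid_dosage(chrom)
            widths = np.diff(bps)
            want += float((dosage[ancestry] * widths).sum())
            afr_eur += float(((dosage[AFR] + dosage[EUR]) * widths).sum())
        if afr_eur == 0:
            raise ValueError("no AFR/EUR ancestry on the map")
        return want / afr_eur


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    per_individual: np.ndarray


def roh_ancestry_content(track: AncestryROHTrack, roh: ROHInterval) -> dict:
    """Partition one ROH's length by diploid ancestry.

    Returns per-label cM lengths (an ROH stretch where both haplotypes
    carry the label contributes its full length; a stretch with two
    different labels contributes half to each), a heterozygous-ancestry
    flag (any stretch with unequal haplotype labels) and a spanning flag
    (the ROH crosses at least one ancestry breakpoint).
    """
    if roh.chrom not in track.chrom_lengths:
        raise ValueError(f"ROH on unknown chromosome {roh.chrom}")
    if roh.start < 0 or roh.end > track.chrom_lengths[roh.chrom]:
        raise ValueError("ROH outside map bounds")
    bps, dosage, het = track._diploid_dosage(roh.chrom)
    lo = np.clip(bps, roh.start, roh.end)
    widths = np.diff(lo)
    content = {lab: float((dosage[lab] * widths).sum()) / 2.0 for lab in _LABELS}
    het_flag = bool(((het * widths) > 0).any())
    inside = (bps > roh.start) & (bps < roh.end)
    spanning = False
    if inside.any():
        # breakpoint where the unordered label pair changes
        idx = np.where(inside)[0]
        for i in idx:
            left = {lab: dosage[lab][i - 1] for lab in _LABELS}
            right = {lab: dosage[lab][i] for lab in _LABELS}
            if left != right:
                spanning = True
                break
    return {"lengths": content, "heterozygous": het_flag, "spanning": spanning}


def _included_long_roh(track: AncestryROHTrack) -> list:
    """Long ROH retained for the excess statistic: heterozygous-ancestry
    ROH are excluded, as are ROH with any ASN content."""
    keep = []
    for r in track.roh:
        if r.size_class != "long":
            continue
        c = roh_ancestry_content(track, r)
        if c["heterozygous"]:
            continue
        if c["lengths"][ASN] > 0:
            continue
        keep.append((r, c))
    return keep


def ancestry_excess(
    tracks: Sequence[AncestryROHTrack], ancestry: str = AFR
) -> np.ndarray:
    """Per-individual ancestry excess in long ROH.

    excess_i = (ancestry content of individual i's long ROH / total
    retained long-ROH content) - (genome-wide diploid fraction of that
    ancestry).  Individuals with no retained long ROH are dropped with a
    warning; the returned array has one value per retained individual.
    """
    vals = []
    dropped = 0
    for t in tracks:
        kept = _included_long_roh(t)
        tot = sum(c["lengths"][AFR] + c["lengths"][EUR] for _, c in kept)
        if tot <= 0:
            dropped += 1
            continue
        want = sum(c["lengths"][ancestry] for _, c in kept)
        vals.append(want / tot - t.global_ancestry_fraction(ancestry))
    if dropped:
        warnings.warn(f"dropped {dropped} individual(s) with no retained long ROH",
                      stacklevel=2)
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# permutation machinery


class _TrackCache:
    """Concatenated-coordinate caches for fast uniform re-placement."""

    def __init__(self, track: AncestryROHTrack):
        self.chroms = list(track.chrom_lengths)
        lens = np.array([track.chrom_lengths[c] for c in self.chroms])
        self.offsets = np.concatenate([[0.0], np.cumsum(lens)])
        self.total = float(lens.sum())
        self.chrom_lens = lens
        # global piecewise-linear cumulative dosage in concat coordinates
        bps_all = [np.array([0.0])]
        cum_afr = [np.array([0.0])]
        cum_eur = [np.array([0.0])]
        a0 = e0 = 0.0
        for ci, c in enumerate(self.chroms):
            bps, dosage, _ = track._diploid_dosage(c)
            w = np.diff(bps)
            ca = a0 + np.cumsum(dosage[AFR] * w) / 2.0
            ce = e0 + np.cumsum(dosage[EUR] * w) / 2.0
            bps_all.append(bps[1:] + self.offsets[ci])
            cum_afr.append(ca)
            cum_eur.append(ce)
            a0, e0 = float(ca[-1]), float(ce[-1])
        self.bps = np.concatenate(bps_all)
        self.cum_afr = np.concatenate(cum_afr)
        self.cum_eur = np.concatenate(cum_eur)

    def content(self, starts: np.ndarray, ends: np.ndarray):
        afr = np.interp(ends, self.bps, self.cum_afr) - np.interp(
            starts, self.bps, self.cum_afr
        )
        eur = np.interp(ends, self.bps, self.cum_eur) - np.interp(
            starts, self.bps, self.cum_eur
        )
        return afr, eur

    def draw_starts(self, lengths: np.ndarray, size: int,
                    rng: np.random.Generator, cross_chromosome: bool = True,
                    chrom_of: Optional[np.ndarray] = None) -> np.ndarray:
        """(size, k) concat-coordinate starts, each ROH fitting within a
        chromosome; uniform over the allowed start space."""
        k = lengths.size
        if cross_chromosome:
            slack = self.chrom_lens[None, :] - lengths[:, None]
            feasible = slack >= -1e-9
            if np.any(~feasible.any(axis=1)):
                raise ValueError("an ROH is longer than every chromosome")
            # exact-fit chromosomes get an infinitesimal start window
            allowed = np.where(feasible, np.maximum(slack, 0.0) + 1e-12, 0.0)
            tot = allowed.sum(axis=1)  # (k,)
            u = rng.random((size, k)) * tot[None, :]
            cdf = np.cumsum(allowed, axis=1)
            ci = (u[..., None] > cdf[None, :, :-1]).sum(axis=2)
            within = u - np.concatenate(
                [np.zeros((k, 1)), cdf[:, :-1]], axis=1
            )[np.arange(k)[None, :], ci]
            within = np.minimum(within, np.maximum(slack, 0.0)[np.arange(k)[None, :], ci])
            return self.offsets[ci] + within
        # same-chromosome mode
        allowed = self.chrom_lens[chrom_of] - lengths
        if np.any(allowed <= 0):
            raise ValueError("an ROH does not fit on its own chromosome")
        return self.offsets[chrom_of][None, :] + rng.random((size, k)) * allowed[None, :]


def permutation_test(
    tracks: Sequence[AncestryROHTrack],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    ancestry: str = AFR,
    cross_chromosome: bool = True,
    max_batches: int = 200,
) -> PermutationResult:
    """Permutation test of ancestry excess in long ROH.

    The observed statistic is the mean per-individual ancestry excess.
    Each permutation re-places every individual's retained long ROH
    uniformly at random on that individual's own map (lengths preserved,
    non-overlap enforced by rejection; across chromosomes by default)
    and recomputes the same mean.  Two-sided p-value with the +1
    correction: p = (#{|null| >= |observed|} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    if not tracks:
        raise ValueError("empty track set")

    per_ind = []
    null_parts = []
    for t in tracks:
        kept = _included_long_roh(t)
        if not kept:
            continue
        cache = _TrackCache(t)
        glob = t.global_ancestry_fraction(ancestry)
        tot = sum(c["lengths"][AFR] + c["lengths"][EUR] for _, c in kept)
        want = sum(c["lengths"][ancestry] for _, c in kept)
        per_ind.append(want / tot - glob)

        lengths = np.array([r.length for r, _ in kept])
        chrom_of = np.array([cache.chroms.index(r.chrom) for r, _ in kept])
        k = lengths.size
        if lengths.sum() > cache.total:
            raise ValueError("total ROH length exceeds map length")
        starts = np.empty((0, k))
        batch = max(n_perm, 64)
        for _ in range(max_batches):
            need = n_perm - starts.shape[0]
            if need <= 0:
                break
            cand = cache.draw_starts(lengths, int(need * 1.5) + 8, rng,
                                     cross_chromosome, chrom_of)
            if k > 1:
                order = np.argsort(cand, axis=1)
                s_sorted = np.take_along_axis(cand, order, axis=1)
                l_sorted = np.take_along_axis(
                    np.broadcast_to(lengths, cand.shape), order, axis=1
                )
                ok = np.all(
                    s_sorted[:, 1:] >= s_sorted[:, :-1] + l_sorted[:, :-1] - 1e-12,
                    axis=1,
                )
                cand = cand[ok]
            starts = np.vstack([starts, cand])[: n_perm]
        if starts.shape[0] < n_perm:
            raise ValueError("non-overlapping ROH placement infeasible")
        afr, eur = cache.content(starts, starts + lengths[None, :])
        tot_p = afr + eur
        prop = (afr if ancestry == AFR else eur).sum(axis=1) / tot_p.sum(axis=1)
        null_parts.append(prop - glob)

    if not per_ind:
        raise ValueError("no individual with retained long ROH")
    observed = float(np.mean(per_ind))
    null = np.mean(np.stack(null_parts, axis=0), axis=0)
    p = (np.sum(np.abs(null) >= abs(observed) - 1e-15) + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed, null=null, p_value=float(p),
        per_individual=np.asarray(per_ind),
    )
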