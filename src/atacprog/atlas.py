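"""Cross-patient peak-atlas construction.

A cohort atlas is a globally disjoint, sorted set of genomic intervals built by
iteratively folding per-patient reproducible peak sets into a growing atlas.
Overlapping pairs are resolved by an overlap-fraction rule: if the overlap
fraction exceeds a threshold the two peaks are replaced by their intersection
(one unified peak); otherwise the overlapping portion is removed from both and
the disjoint remainders are kept as separate peaks.

Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator


class PeakInterval(NamedTuple):
    """A genomic interval, 0-based half-open. Requires ``end > start``."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "PeakInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "PeakInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _validate_interval(iv: PeakInterval) -> None:
    if iv.end <= iv.start or iv.start < 0:
        raise ValueError(f"malformed interval {iv!r}: need 0 <= start < end")


def canonicalize(intervals: Iterable[PeakInterval]) -> list[PeakInterval]:
    """Sort by (chrom, start) and union-merge any overlapping intervals."""
    ivs = sorted(intervals)
    for iv in ivs:
        _validate_interval(iv)
    out: list[PeakInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out.pop()
            iv = PeakInterval(iv.chrom, prev.start, max(prev.end, iv.end))
        out.append(iv)
    return out


@dataclass
class PeakSet:
    """A named, canonical (sorted, internally disjoint) set of peaks."""

    sample_id: str
    intervals: list[PeakInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = canonicalize(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)


@dataclass
class PeakAtlas:
    """Globally disjoint, sorted atlas with the contributing sample ids."""

    intervals: list[PeakInterval]
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def peak_ids(self) -> list[str]:
        return [iv.peak_id for iv in self.intervals]

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def assert_disjoint(self) -> None:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise AssertionError(f"atlas not disjoint: {a} overlaps {b}")


def overlap_fraction(
    a: PeakInterval, b: PeakInterval, denominator: str = "min"
) -> float:
    """Overlap fraction of two intervals.

    ``denominator='min'`` uses intersection / min(length) so that full
    containment always gives 1; ``'jaccard'`` uses intersection / union.
    """
    inter = a.intersection_length(b)
    if denominator == "min":
        return inter / min(a.length, b.length)
    if denominator == "jaccard":
        union = a.length + b.length - inter
        return inter / union
    raise ValueError(f"unknown denominator {denominator!r}")


def merge_pair(
    a: PeakInterval,
    b: PeakInterval,
    threshold: float = 0.75,
    denominator: str = "min",
) -> list[PeakInterval]:
    """Resolve two overlapping peaks into one unified or two disjoint peaks.

    If the overlap fraction is strictly greater than ``threshold`` the
    non-overlapping portions are removed, leaving the single intersection.
    Otherwise the overlapping portion is removed from both peaks and all
    nonempty remainders are returned.  A fraction exactly equal to the
    threshold is treated as not merged.
    """
    if not a.overlaps(b):
        raise ValueError(f"merge_pair requires overlapping intervals: {a}, {b}")
    f = overlap_fraction(a, b, denominator)
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if f > threshold:
        return [PeakInterval(a.chrom, lo, hi)]
    pieces: list[PeakInterval] = []
    for iv in (a, b):
        if iv.start < lo:
            pieces.append(PeakInterval(iv.chrom, iv.start, lo))
        if hi < iv.end:
            pieces.append(PeakInterval(iv.chrom, hi, iv.end))
    return sorted(pieces)


def reproducible_peaks(
    rep1: PeakSet, rep2: PeakSet, min_frac: float = 0.5
) -> PeakSet:
    """Reproducibility filter between replicate peak calls.

    Keeps each peak of ``rep1`` whose best overlap with any ``rep2`` peak has
    intersection / min(lengths) >= ``min_frac``, reported on the rep1
    coordinates.  The symmetric filter is ``reproducible_peaks(rep2, rep1)``.
    This is a simple overlap-fraction stand-in for a replicate-consistency
    (IDR-style) analysis.
    """
    by_chrom: dict[str, list[PeakInterval]] = {}
    for iv in rep2.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for iv in rep1.intervals:
        best = 0.0
        for other in by_chrom.get(iv.chrom, []):
            if other.start >= iv.end:
                break
            if iv.overlaps(other):
                best = max(best, overlap_fraction(iv, other, "min"))
        if best >= min_frac:
            kept.append(iv)
    return PeakSet(rep1.sample_id, kept)


class PeakAtlasBuilder(BaseEstimator):
    """Iterative cross-patient atlas builder.

    Patients are folded in, in the given order.  Each incoming peak is
    resolved against the current atlas peaks in coordinate order by repeated
    pairwise merges; products are re-checked for new overlaps until stable,
    and non-overlapping peaks are inserted directly.

    Parameters
    ----------
    threshold : float, default 0.75
        Overlap fraction above which (strictly) two peaks are unified.
    denominator : {'min', 'jaccard'}, default 'min'
        Denominator of the overlap fraction.
    min_patients : int or None, default None
        If set, post-filter the atlas to peaks overlapped by the original
        peak sets of at least this many patients.

    Attributes
    ----------
    atlas_ : PeakAtlas
        The disjoint, sorted atlas after :meth:`fit`.
    """

    def __init__(
        self,
        threshold: float = 0.75,
        denominator: str = "min",
        min_patients: int | None = None,
    ):
        self.threshold = threshold
        self.denominator = denominator
        self.min_patients = min_patients

    # -- incremental core ---------------------------------------------------

    def _init_state(self) -> None:
        self._chroms: dict[str, tuple[list[int], list[PeakInterval]]] = {}
        self._samples: list[str] = []

    def _insert_peak(self, peak: PeakInterval) -> None:
        _validate_interval(peak)
        starts, ivs = self._chroms.setdefault(peak.chrom, ([], []))
        pending = [peak]
        while pending:
            q = pending.pop(0)
            idx = self._first_overlap(starts, ivs, q)
            if idx is None:
                j = bisect.bisect_left(starts, q.start)
                starts.insert(j, q.start)
                ivs.insert(j, q)
            else:
                r = ivs.pop(idx)
                starts.pop(idx)
                products = merge_pair(q, r, self.threshold, self.denominator)
                pending = sorted(products) + pending

    @staticmethod
    def _first_overlap(
        starts: list[int], ivs: list[PeakInterval], q: PeakInterval
    ) -> int | None:
        """Index of the leftmost atlas interval overlapping q, else None."""
        j = bisect.bisect_right(starts, q.start)
        if j > 0 and ivs[j - 1].end > q.start:
            return j - 1
        if j < len(ivs) and ivs[j].start < q.end:
            return j
        return None

    def add_peak_set(self, peak_set: PeakSet) -> "PeakAtlasBuilder":
        if not hasattr(self, "_chroms"):
            self._init_state()
        for iv in peak_set.intervals:
            self._insert_peak(iv)
        self._samples.append(peak_set.sample_id)
        return self

    def current_atlas(self) -> PeakAtlas:
        intervals: list[PeakInterval] = []
        for chrom in sorted(self._chroms):
            intervals.extend(self._chroms[chrom][1])
        atlas = PeakAtlas(intervals, list(self._samples))
        atlas.assert_disjoint()
        return atlas

    # -- sklearn-style surface ----------------------------------------------

    def fit(self, peak_sets: Sequence[PeakSet], y=None) -> "PeakAtlasBuilder":
        self._init_state()
        for ps in peak_sets:
            self.add_peak_set(ps)
        atlas = self.current_atlas()
        if self.min_patients is not None:
            atlas = _filter_min_patients(atlas, peak_sets, self.min_patients)
        self.atlas_ = atlas
        return self


def _filter_min_patients(
    atlas: PeakAtlas, peak_sets: Sequence[PeakSet], k: int
) -> PeakAtlas:
    kept = []
    for iv in atlas.intervals:
        n = sum(
            any(iv.overlaps(p) for p in ps.intervals) for ps in peak_sets
        )
        if n >= k:
            kept.append(iv)
    return PeakAtlas(kept, list(atlas.provenance))


def build_atlas(
    peak_sets: Sequence[PeakSet],
    threshold: float = 0.75,
    denominator: str = "min",
    min_patients: int | None = None,
) -> PeakAtlas:
    """Build a disjoint cohort atlas from per-patient peak sets."""
    return PeakAtlasBuilder(threshold, denominator, min_patients).fit(peak_sets).atlas_


def qc_filter_patients(peak_sets: Sequence[PeakSet]) -> list[PeakSet]:
    """Drop patients in the bottom quartile of reproducible-peak counts.

    Patients whose peak count is strictly below the 25th percentile of all
    counts (linear interpolation) are excluded.  Requires >= 4 patients.
    """
    if len(peak_sets) < 4:
        raise ValueError("qc_filter_patients needs at least 4 patients")
    counts = np.array([len(ps) for ps in peak_sets], dtype=float)
    q25 = np.percentile(counts, 25)  # linear interpolation
    return [ps for ps, c in zip(peak_sets, counts) if c >= q25]


def saturation_curve(
    peak_sets: Sequence[PeakSet],
    n_resamples: int = 500,
    seed: int | None = None,
    threshold: float = 0.75,
    denominator: str = "min",
):
    """Mean cumulative atlas size as patients are added in random order.

    For each resample the patient order is permuted (sampling without
    replacement), the atlas is rebuilt incrementally and its size recorded at
    every prefix.  Returns ``(mean, sd)`` arrays of length ``len(peak_sets)``
    where entry ``i`` is the atlas size after ``i + 1`` patients.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if len(peak_sets) < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    n = len(peak_sets)
    sizes = np.empty((n_resamples, n), dtype=float)
    for r in range(n_resamples):
        order = rng.permutation(n)
        builder = PeakAtlasBuilder(threshold, denominator)
        builder._init_state()
        for j, idx in enumerate(order):
            builder.add_peak_set(peak_sets[idx])
            sizes[r, j] = sum(
                len(ivs) for _, ivs in builder._chroms.values()
            )
    return sizes.mean(axis=0), sizes.std(axis=0)
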