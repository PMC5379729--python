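"""w1–w5 window decomposition and averaged feature profiles.

Each called region with its flanks is divided into five windows: w1 (flank
upstream of the region), w2 (first ``edge`` bp of the region), w3 (the
variable-length middle), w4 (last ``edge`` bp) and w5 (downstream flank).
Per-base feature values — GC indicator, repeat-class coverage, or histone
signal — are binned within each window and averaged across regions, giving
a metagene-style curve over the concatenated windows.

w3 varies in length across regions, so it is rescaled to a fixed number of
bins by proportional per-base assignment (each base contributes to the bins
it fractionally overlaps, with weights summing to the window length); the
fixed windows are binned at ``fixed_bin_size`` bp per bin. Windows clipped
at chromosome boundaries, and empty middles of short regions, contribute
missing values that are excluded from the mean with count bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import Annotation, ChromSizes, GenomeRegion

__all__ = [
    "WindowScheme",
    "Windows",
    "WindowProfile",
    "make_windows",
    "gc_profile",
    "coverage_profile",
    "genome_mean_gc",
    "genome_mean_coverage",
]


@dataclass(frozen=True)
class WindowScheme:
    flank: int = 300
    edge: int = 300
    middle_bins: int = 300
    fixed_bin_size: int = 10  # bp per bin in w1/w2/w4/w5

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.edge <= 0:
            raise ValueError("flank and edge must be positive")
        if self.middle_bins <= 0 or self.fixed_bin_size <= 0:
            raise ValueError("middle_bins and fixed_bin_size must be positive")
        if self.flank % self.fixed_bin_size or self.edge % self.fixed_bin_size:
            raise ValueError("flank and edge must be multiples of fixed_bin_size")

    @property
    def flank_bins(self) -> int:
        return self.flank // self.fixed_bin_size

    @property
    def edge_bins(self) -> int:
        return self.edge // self.fixed_bin_size

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + 2 * self.edge_bins + self.middle_bins

    def segment_slices(self) -> dict[str, slice]:
        f, e, m = self.flank_bins, self.edge_bins, self.middle_bins
        return {
            "w1": slice(0, f),
            "w2": slice(f, f + e),
            "w3": slice(f + e, f + e + m),
            "w4": slice(f + e + m, f + 2 * e + m),
            "w5": slice(f + 2 * e + m, 2 * f + 2 * e + m),
        }


@dataclass(frozen=True)
class Windows:
    """The five windows of one region; w1/w5 clipped, w3 None when empty."""

    w1: GenomeRegion | None
    w2: GenomeRegion
    w3: GenomeRegion | None
    w4: GenomeRegion
    w5: GenomeRegion | None
    clipped: bool
    empty_middle: bool


def make_windows(
    region: GenomeRegion, scheme: WindowScheme, sizes: ChromSizes
) -> Windows:
    """Split one region (plus flanks) into w1..w5.

    w2..w4 tile the region exactly whenever the region is longer than
    2·edge; shorter regions get an empty middle (flagged) with w2/w4 still
    anchored to the region's ends (they then overlap). Flanks are clipped at
    chromosome boundaries and None when fully outside.
    """
    L = sizes[region.chrom]
    s, e = region.start, region.end
    f, d = scheme.flank, scheme.edge

    def maybe(chrom: str, a: int, b: int) -> GenomeRegion | None:
        a, b = max(a, 0), min(b, L)
        return GenomeRegion(chrom, a, b) if a < b else None

    w1 = maybe(region.chrom, s - f, s)
    w5 = maybe(region.chrom, e, e + f)
    w2 = GenomeRegion(region.chrom, s, min(s + d, e))
    w4 = GenomeRegion(region.chrom, max(e - d, s), e)
    empty_middle = region.length <= 2 * d
    w3 = None if empty_middle else GenomeRegion(region.chrom, s + d, e - d)
    clipped = (w1 is None or w1.length < f) or (w5 is None or w5.length < f)
    return Windows(w1, w2, w3, w4, w5, clipped, empty_middle)


def _bin_fixed(
    values: np.ndarray, expect_len: int, bin_size: int, align_right: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Bin a (possibly short) per-base value array into fixed-size bins.

    *values* may contain NaN (excluded bases). A clipped window is aligned
    to the region side: right for an upstream flank, left for a downstream
    one. Returns (bin means, contributing base counts).
    """
    full = np.full(expect_len, np.nan)
    if len(values):
        if align_right:
            full[expect_len - len(values):] = values
        else:
            full[: len(values)] = values
    full = full.reshape(-1, bin_size)
    counts = np.sum(~np.isnan(full), axis=1)
    sums = np.nansum(full, axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def _bin_rescaled(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Rescale a variable-length per-base array to *n_bins* proportional bins.

    Each base is spread over the bins it fractionally overlaps; per-bin
    values are weighted means with weights summing to the window length
    (NaN bases contribute no weight).
    """
    L = len(values)
    if L == 0:
        return np.full(n_bins, np.nan), np.zeros(n_bins)
    edges = np.linspace(0.0, L, n_bins + 1)
    # per-base values are piecewise constant on [i, i+1); the fractional
    # integral up to x is the linear interpolation of the prefix sum, so the
    # per-bin weighted sums are exact differences of interpolated prefixes
    valid = ~np.isnan(values)
    grid = np.arange(L + 1, dtype=float)
    cum_v = np.concatenate([[0.0], np.cumsum(np.where(valid, values, 0.0))])
    cum_w = np.concatenate([[0.0], np.cumsum(valid.astype(float))])
    wsum = np.diff(np.interp(edges, grid, cum_v))
    weight = np.diff(np.interp(edges, grid, cum_w))
    with np.errstate(invalid="ignore"):
        means = np.where(weight > 1e-12, wsum / np.maximum(weight, 1e-300), np.nan)
    return means, weight


@dataclass(frozen=True)
class WindowProfile:
    """Mean per-bin feature values over regions, concatenated w1|w2|w3|w4|w5."""

    feature: str
    values: np.ndarray  # (n_bins,) mean across regions; NaN where no data
    region_counts: np.ndarray  # (n_bins,) number of regions contributing
    n_regions: int
    scheme: WindowScheme
    genome_background: float | None = None

    def segment(self, name: str) -> np.ndarray:
        return self.values[self.scheme.segment_slices()[name]]


def _region_bins(
    per_base: dict[str, np.ndarray],
    region: GenomeRegion,
    scheme: WindowScheme,
    sizes: ChromSizes,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (values, has-data flags) for one region from per-base arrays."""
    win = make_windows(region, scheme, sizes)
    arr = per_base[region.chrom]

    def fetch(w: GenomeRegion | None) -> np.ndarray:
        if w is None:
            return np.array([])
        return arr[w.start : w.end]

    v1, c1 = _bin_fixed(fetch(win.w1), scheme.flank, scheme.fixed_bin_size, True)
    v2, c2 = _bin_fixed(fetch(win.w2), scheme.edge, scheme.fixed_bin_size, False)
    v3, c3 = _bin_rescaled(fetch(win.w3), scheme.middle_bins)
    v4, c4 = _bin_fixed(fetch(win.w4), scheme.edge, scheme.fixed_bin_size, True)
    v5, c5 = _bin_fixed(fetch(win.w5), scheme.flank, scheme.fixed_bin_size, False)
    values = np.concatenate([v1, v2, v3, v4, v5])
    has = np.concatenate([c1 > 0, c2 > 0, c3 > 0, c4 > 0, c5 > 0])
    return values, has


def _aggregate(
    feature: str,
    per_base: dict[str, np.ndarray],
    regions: Sequence[GenomeRegion],
    scheme: WindowScheme,
    sizes: ChromSizes,
    background: float | None,
) -> WindowProfile:
    if not regions:
        raise ValueError("no regions supplied")
    total = np.zeros(scheme.n_bins)
    counts = np.zeros(scheme.n_bins, dtype=int)
    for r in sorted(regions):
        values, has = _region_bins(per_base, r, scheme, sizes)
        total[has] += values[has]
        counts += has
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return WindowProfile(feature, means, counts, len(regions), scheme, background)


def _gc_array(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    vals = np.where((a == ord("G")) | (a == ord("C")), 1.0, 0.0)
    vals[(a == ord("N"))] = np.nan  # N excluded from the GC denominator
    return vals


def gc_profile(
    regions: Sequence[GenomeRegion],
    fasta: Mapping[str, str],
    scheme: WindowScheme,
    sizes: ChromSizes,
) -> WindowProfile:
    """Mean per-bin GC fraction across regions (N bases excluded)."""
    per_base = {c: _gc_array(fasta[c]) for c in {r.chrom for r in regions}}
    bg_vals = np.concatenate([_gc_array(s) for s in fasta.values()])
    background = float(np.nanmean(bg_vals))
    return _aggregate("GC", per_base, regions, scheme, sizes, background)


def _coverage_array(
    annots: Iterable[Annotation], label: str, chrom: str, length: int, signal: bool
) -> np.ndarray:
    vals = np.zeros(length)
    if signal:
        # mean of overlapping signal values per base, 0 where uncovered
        total = np.zeros(length)
        n = np.zeros(length)
        for a in annots:
            if a.region.chrom == chrom and a.label == label:
                s, e = max(a.region.start, 0), min(a.region.end, length)
                total[s:e] += a.value
                n[s:e] += 1
        covered = n > 0
        vals[covered] = total[covered] / n[covered]
    else:
        for a in annots:
            if a.region.chrom == chrom and a.label == label:
                vals[max(a.region.start, 0) : min(a.region.end, length)] = 1.0
    return vals


def coverage_profile(
    regions: Sequence[GenomeRegion],
    annots: Sequence[Annotation],
    label: str,
    scheme: WindowScheme,
    sizes: ChromSizes,
    signal: bool = False,
) -> WindowProfile:
    """Mean per-bin covered fraction (or mean signal) for one track label."""
    if label not in {a.label for a in annots}:
        raise ValueError(f"label {label!r} not present in track")
    per_base = {
        c: _coverage_array(annots, label, c, sizes[c], signal)
        for c in {r.chrom for r in regions}
    }
    background = genome_mean_coverage(annots, sizes, label, signal)
    return _aggregate(label, per_base, regions, scheme, sizes, background)


def genome_mean_gc(fasta: Mapping[str, str]) -> float:
    return float(np.nanmean(np.concatenate([_gc_array(s) for s in fasta.values()])))


def genome_mean_coverage(
    annots: Sequence[Annotation],
    sizes: ChromSizes,
    label: str,
    signal: bool = False,
) -> float:
    """Genome-wide mean of the feature (the flat reference segment)."""
    total_bp = sum(sizes.values())
    acc = 0.0
    for c in sizes:
        arr = _coverage_array(annots, label, c, sizes[c], signal)
        acc += float(arr.sum())
    return acc / total_bp
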