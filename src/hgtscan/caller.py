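"""The core HGT caller.

A focal-genome interval is a *non-mammal conserved region* when, base by
base, at least ``min_nonmammal_species`` distinct non-mammal species align to
it with identity at or above ``min_identity``, and the merged interval is
strictly longer than ``min_length``. Such a region is called a candidate HGT
region when at most ``max_mammal_support`` mammal species "support" it — a
mammal supports a region when the union of its qualifying alignments covers
strictly more than ``mammal_min_coverage`` of the region's length.

Threshold semantics are deliberately asymmetric and applied literally:
identity thresholds are inclusive (an identity of exactly 0.40 qualifies),
while the length and coverage thresholds are strict (a region of exactly
1000 bp, or mammal coverage of exactly 40%, does not pass).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .model import MAMMAL, NON_MAMMAL, AlignmentBlock, GenomeRegion, SpeciesPanel

__all__ = [
    "CallParams",
    "HGTRegion",
    "qualifying_blocks",
    "nonmammal_conserved_regions",
    "mammal_support",
    "call_hgt",
    "threshold_grid",
    "validate_calls",
    "evaluate_calls",
]


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the calling pipeline (defaults are the study's)."""

    min_identity: float = 0.40
    min_nonmammal_species: int = 2
    min_length: int = 1000  # strict: region length must exceed this
    max_mammal_support: int = 8
    mammal_min_coverage: float = 0.40  # strict: coverage must exceed this
    mammal_min_identity: float = 0.40
    merge_gap: int = 0
    support_mode: str = "depth"  # "depth" (per-base) or "region" (any-overlap)

    def __post_init__(self) -> None:
        for name in ("min_identity", "mammal_min_coverage", "mammal_min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.max_mammal_support < 0:
            raise ValueError("max_mammal_support must be ≥ 0")
        if self.min_nonmammal_species < 1:
            raise ValueError("min_nonmammal_species must be ≥ 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be ≥ 0")
        if self.support_mode not in ("depth", "region"):
            raise ValueError(f"unknown support_mode {self.support_mode!r}")


@dataclass(frozen=True)
class HGTRegion:
    """A called candidate region with its supporting species."""

    region: GenomeRegion
    #: (species_id, overlap-length-weighted mean identity), sorted by species
    nonmammal_supporters: tuple[tuple[str, float], ...]
    mammal_support_count: int
    mammal_supporters: tuple[str, ...]


def qualifying_blocks(
    blocks: Iterable[AlignmentBlock],
    panel: SpeciesPanel,
    clade: str,
    min_identity: float,
) -> list[AlignmentBlock]:
    """Blocks from species of *clade* with identity ≥ min_identity (inclusive)."""
    if clade not in (MAMMAL, NON_MAMMAL):
        raise ValueError(f"unknown clade {clade!r}")
    return [
        b
        for b in blocks
        if panel.clade_of(b.species_id) == clade and b.identity >= min_identity
    ]


def merge_intervals(
    intervals: Iterable[tuple[int, int]], gap: int = 0
) -> list[tuple[int, int]]:
    """Union of half-open intervals, bridging gaps of ≤ *gap* bp."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect_length(intervals: Sequence[tuple[int, int]], start: int, end: int) -> int:
    """Total overlap of sorted disjoint intervals with [start, end)."""
    total = 0
    for s, e in intervals:
        if e <= start:
            continue
        if s >= end:
            break
        total += min(e, end) - max(s, start)
    return total


def _species_unions(
    blocks: Iterable[AlignmentBlock],
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """chrom -> species -> merged sorted intervals."""
    per: dict[str, dict[str, list[tuple[int, int]]]] = {}
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for b in blocks:
        raw.setdefault(b.chrom, {}).setdefault(b.species_id, []).append((b.start, b.end))
    for chrom, by_sp in raw.items():
        per[chrom] = {sp: merge_intervals(ivs) for sp, ivs in by_sp.items()}
    return per


def _depth_regions(
    species_intervals: dict[str, list[tuple[int, int]]], min_depth: int
) -> list[tuple[int, int]]:
    """Maximal intervals where ≥ min_depth distinct species have coverage.

    Each species contributes its (already unioned) intervals once, so depth
    counts distinct species per base. Boundary sweep over +1/−1 events.
    """
    events: list[tuple[int, int]] = []
    for ivs in species_intervals.values():
        for s, e in ivs:
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    out: list[tuple[int, int]] = []
    depth = 0
    open_start: int | None = None
    i = 0
    n = len(events)
    while i < n:
        pos = events[i][0]
        while i < n and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= min_depth and open_start is None:
            open_start = pos
        elif depth < min_depth and open_start is not None:
            if pos > open_start:
                out.append((open_start, pos))
            open_start = None
    return out


def nonmammal_conserved_regions(
    blocks: Iterable[AlignmentBlock],
    panel: SpeciesPanel,
    params: CallParams,
) -> list[GenomeRegion]:
    """Maximal non-mammal conserved intervals, per the calling predicate.

    In the default ``depth`` mode the ≥2-species condition is enforced per
    base; in ``region`` mode any interval covered by at least one qualifying
    non-mammal block is kept when at least ``min_nonmammal_species`` distinct
    species overlap it anywhere (the laxer reading).
    """
    qual = qualifying_blocks(blocks, panel, NON_MAMMAL, params.min_identity)
    per_chrom = _species_unions(qual)
    regions: list[GenomeRegion] = []
    for chrom in sorted(per_chrom):
        if params.support_mode == "depth":
            ivs = _depth_regions(per_chrom[chrom], params.min_nonmammal_species)
        else:
            ivs = _depth_regions(per_chrom[chrom], 1)
        ivs = merge_intervals(ivs, params.merge_gap)
        for s, e in ivs:
            if e - s <= params.min_length:
                continue
            if params.support_mode == "region":
                n_sp = sum(
                    1
                    for sp_ivs in per_chrom[chrom].values()
                    if _intersect_length(sp_ivs, s, e) > 0
                )
                if n_sp < params.min_nonmammal_species:
                    continue
            regions.append(GenomeRegion(chrom, s, e))
    return sorted(regions)


def mammal_support(
    region: GenomeRegion,
    blocks: Iterable[AlignmentBlock],
    panel: SpeciesPanel,
    params: CallParams,
) -> tuple[int, tuple[str, ...]]:
    """Count mammal species whose qualifying coverage of *region* exceeds the cutoff.

    A mammal supports the region iff the union of its blocks with identity
    ≥ ``mammal_min_identity``, intersected with the region, covers strictly
    more than ``mammal_min_coverage`` × region length.
    """
    qual = qualifying_blocks(blocks, panel, MAMMAL, params.mammal_min_identity)
    per_chrom = _species_unions(qual)
    sp_ivs = per_chrom.get(region.chrom, {})
    cutoff = params.mammal_min_coverage * region.length
    supporters = sorted(
        sp
        for sp, ivs in sp_ivs.items()
        if _intersect_length(ivs, region.start, region.end) > cutoff
    )
    return len(supporters), tuple(supporters)


def _nonmammal_supporter_identities(
    region: GenomeRegion,
    qual_blocks: Sequence[AlignmentBlock],
) -> tuple[tuple[str, float], ...]:
    """Per non-mammal species, overlap-weighted mean identity inside the region."""
    acc: dict[str, tuple[float, int]] = {}
    for b in qual_blocks:
        ov = b.region.overlap(region)
        if ov == 0:
            continue
        wsum, w = acc.get(b.species_id, (0.0, 0))
        acc[b.species_id] = (wsum + b.identity * ov, w + ov)
    return tuple(
        (sp, wsum / w) for sp, (wsum, w) in sorted(acc.items())
    )


def call_hgt(
    blocks: Sequence[AlignmentBlock],
    panel: SpeciesPanel,
    params: CallParams | None = None,
) -> list[HGTRegion]:
    """Run the full calling pipeline; deterministic, sorted by (chrom, start)."""
    params = params or CallParams()
    panel.require_callable(params.min_nonmammal_species)
    conserved = nonmammal_conserved_regions(blocks, panel, params)
    qual_nm = qualifying_blocks(blocks, panel, NON_MAMMAL, params.min_identity)
    calls: list[HGTRegion] = []
    for region in conserved:
        count, supporters = mammal_support(region, blocks, panel, params)
        if count > params.max_mammal_support:
            continue
        nm = _nonmammal_supporter_identities(region, qual_nm)
        calls.append(HGTRegion(region, nm, count, supporters))
    return calls


def threshold_grid(
    blocks: Sequence[AlignmentBlock],
    panel: SpeciesPanel,
    identity_grid: Sequence[float],
    coverage_grid: Sequence[float],
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Sensitivity grid: rerun the caller over identity × mammal-coverage values.

    The identity axis sets both the non-mammal conservation identity and the
    mammal-support identity (the study varies one "similarity threshold");
    the coverage axis sets the mammal-support coverage cutoff. Returns one
    row per pair with the number of called regions and their total bases.
    """
    if not identity_grid or not coverage_grid:
        raise ValueError("identity_grid and coverage_grid must be non-empty")
    params = params or CallParams()
    rows = []
    for ident in identity_grid:
        for cov in coverage_grid:
            p = replace(
                params,
                min_identity=ident,
                mammal_min_identity=ident,
                mammal_min_coverage=cov,
            )
            calls = call_hgt(blocks, panel, p)
            rows.append(
                {
                    "identity": ident,
                    "coverage": cov,
                    "n_regions": len(calls),
                    "total_bases": sum(c.region.length for c in calls),
                }
            )
    return pd.DataFrame(rows)


def validate_calls(calls: Iterable[HGTRegion], params: CallParams) -> None:
    """Independent post-hoc validator of the HGTRegion invariants."""
    for c in calls:
        if len(c.nonmammal_supporters) < params.min_nonmammal_species:
            raise AssertionError(f"{c.region}: too few non-mammal supporters")
        if c.mammal_support_count > params.max_mammal_support:
            raise AssertionError(f"{c.region}: mammal support exceeds cap")
        if c.region.length <= params.min_length:
            raise AssertionError(f"{c.region}: region not longer than min_length")
        if c.mammal_support_count != len(c.mammal_supporters):
            raise AssertionError(f"{c.region}: supporter count mismatch")


def evaluate_calls(
    called: Sequence[GenomeRegion],
    truth: Sequence[GenomeRegion],
    min_jaccard: float = 0.5,
) -> dict:
    """Score called regions against planted truth.

    Greedy best-Jaccard matching; a truth region is recovered when its best
    unmatched call reaches *min_jaccard*. Returns precision, recall, and the
    per-truth-region Jaccard values.
    """
    pairs = sorted(
        (
            (t.jaccard(c), ti, ci)
            for ti, t in enumerate(truth)
            for ci, c in enumerate(called)
            if t.jaccard(c) > 0
        ),
        reverse=True,
    )
    matched_t: dict[int, float] = {}
    matched_c: set[int] = set()
    for j, ti, ci in pairs:
        if ti in matched_t or ci in matched_c:
            continue
        matched_t[ti] = j
        matched_c.add(ci)
    jaccards = [matched_t.get(ti, 0.0) for ti in range(len(truth))]
    n_rec = sum(1 for j in jaccards if j >= min_jaccard)
    n_tp_calls = sum(1 for j in matched_t.values() if j >= min_jaccard)
    return {
        "n_truth": len(truth),
        "n_called": len(called),
        "recall": n_rec / len(truth) if truth else float("nan"),
        "precision": n_tp_calls / len(called) if called else float("nan"),
        "jaccards": jaccards,
        "mean_jaccard": sum(jaccards) / len(jaccards) if jaccards else float("nan"),
    }
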