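"""Positional bias and composition-vs-background analyses of called regions.

The positional test asks whether called regions concentrate in the terminal
zones of chromosomes. Each chromosome contributes one paired observation:
the per-bp density of region midpoints in its two end zones minus the
density in its middle zone. A one-sided paired t-test (H1: end density
greater) with n_chromosomes − 1 degrees of freedom summarises the bias.

Composition analyses compare the per-base label make-up of the called
regions (foreground) against the whole genome (background), with overlaps
between labels resolved by an explicit priority order and unannotated bases
assigned a designated default label.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import merge_intervals, _intersect_length
from .model import Annotation, ChromSizes, GenomeRegion

#: chromatin-state priority (segmentation order of the 7-class scheme)
CHROMATIN_PRIORITY = (
    "Heterochrom",
    "Txn",
    "Enhancer",
    "Promoter",
    "Repressed",
    "Insulator",
    "Repetitive",
)

#: gene-biotype priority; non_gene is the default label for unannotated bases
GENE_PRIORITY = ("protein_coding", "lincRNA", "antisense", "other", "non_gene")

__all__ = [
    "ZonePartition",
    "EndBiasResult",
    "end_bias_test",
    "composition",
    "gene_overlap",
    "GeneOverlap",
    "CHROMATIN_PRIORITY",
    "GENE_PRIORITY",
]


@dataclass(frozen=True)
class ZonePartition:
    """Per-chromosome split into two end zones and one middle zone."""

    end_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.end_fraction < 0.5:
            raise ValueError(f"end_fraction {self.end_fraction} outside (0, 0.5)")

    def zones(self, length: int) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """((0, f·L), ((1−f)·L, L), middle) as half-open intervals."""
        cut = int(round(self.end_fraction * length))
        return (0, cut), (length - cut, length), (cut, length - cut)


@dataclass(frozen=True)
class EndBiasResult:
    t: float
    p: float
    table: pd.DataFrame  # per-chromosome end/middle counts and densities
    warning: str | None = None


def end_bias_test(
    regions: Sequence[GenomeRegion],
    sizes: ChromSizes,
    end_fraction: float = 0.10,
) -> EndBiasResult:
    """Paired one-sided t-test of end-zone vs middle-zone region density.

    Regions are assigned to zones by midpoint; densities are per bp of zone
    so unequal zone sizes do not bias the comparison. A zero-variance
    difference vector yields a degenerate result (p = NaN) with a warning
    rather than an error.
    """
    if len(sizes) < 2:
        raise ValueError("need at least 2 chromosomes for a paired test")
    if not regions:
        raise ValueError("no regions supplied")
    part = ZonePartition(end_fraction)
    rows = []
    for chrom in sizes:
        L = sizes[chrom]
        (e1s, e1e), (e2s, e2e), (ms, me) = part.zones(L)
        end_bp = (e1e - e1s) + (e2e - e2s)
        mid_bp = me - ms
        n_end = n_mid = 0
        for r in regions:
            if r.chrom != chrom:
                continue
            m = r.midpoint
            if e1s <= m < e1e or e2s <= m < e2e:
                n_end += 1
            else:
                n_mid += 1
        rows.append(
            {
                "chrom": chrom,
                "n_end": n_end,
                "n_mid": n_mid,
                "end_bp": end_bp,
                "mid_bp": mid_bp,
                "density_end": n_end / end_bp,
                "density_mid": n_mid / mid_bp,
            }
        )
    table = pd.DataFrame(rows)
    d = (table["density_end"] - table["density_mid"]).to_numpy()
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        msg = "zero variance in per-chromosome differences; p undefined"
        warnings.warn(msg, stacklevel=2)
        t = np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else np.nan)
        return EndBiasResult(float(t), float("nan"), table, msg)
    t = d.mean() * np.sqrt(n) / sd
    p = float(stats.t.sf(t, df=n - 1))
    return EndBiasResult(float(t), p, table, None)


def _label_bases(
    annots: Sequence[Annotation],
    priority: Sequence[str],
    default_label: str,
    chrom: str,
    length: int,
    restrict: Sequence[tuple[int, int]] | None,
) -> dict[str, int]:
    """Per-label base counts on one chromosome via a boundary sweep.

    Overlapping annotations of different labels are resolved by the priority
    list (first wins); bases under no annotation get *default_label*. With
    *restrict* (sorted disjoint intervals), only bases inside it are counted.
    """
    rank = {label: i for i, label in enumerate(priority)}
    events: list[tuple[int, int, int]] = []  # pos, +1/-1, rank
    for a in annots:
        if a.region.chrom != chrom:
            continue
        r = rank[a.label]
        s, e = max(a.region.start, 0), min(a.region.end, length)
        if s < e:
            events.append((s, 1, r))
            events.append((e, -1, r))
    events.sort()
    counts = {label: 0 for label in priority}
    active = np.zeros(len(priority), dtype=int)
    prev = 0
    i = 0
    nev = len(events)

    def add(x1: int, x2: int) -> None:
        if x2 <= x1:
            return
        span = (
            _intersect_length(restrict, x1, x2) if restrict is not None else x2 - x1
        )
        if span == 0:
            return
        nz = np.nonzero(active)[0]
        label = priority[nz[0]] if len(nz) else default_label
        counts[label] += span

    while i < nev:
        pos = events[i][0]
        add(prev, pos)
        while i < nev and events[i][0] == pos:
            active[events[i][2]] += events[i][1]
            i += 1
        prev = pos
    add(prev, length)
    return counts


def composition(
    regions: Sequence[GenomeRegion],
    annots: Sequence[Annotation],
    sizes: ChromSizes,
    priority: Sequence[str],
    default_label: str,
) -> pd.DataFrame:
    """Foreground (regions) vs background (whole genome) label fractions.

    Returns a DataFrame with columns label / foreground_fraction /
    background_fraction; each column sums to 1. Labels present in the track
    but absent from the priority list are an error (listed); the default
    label must be in the priority list.
    """
    if default_label not in priority:
        raise ValueError(f"default label {default_label!r} not in priority list")
    known = set(priority)
    unknown = sorted({a.label for a in annots} - known)
    if unknown:
        raise ValueError(f"track labels missing from priority list: {unknown}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    fg = {label: 0 for label in priority}
    bg = {label: 0 for label in priority}
    for chrom in sizes:
        L = sizes[chrom]
        chrom_annots = [a for a in annots if a.region.chrom == chrom]
        restrict = merge_intervals(by_chrom.get(chrom, []))
        if restrict:
            for label, n in _label_bases(
                chrom_annots, priority, default_label, chrom, L, restrict
            ).items():
                fg[label] += n
        for label, n in _label_bases(
            chrom_annots, priority, default_label, chrom, L, None
        ).items():
            bg[label] += n
    fg_total = sum(fg.values())
    bg_total = sum(bg.values())
    if fg_total == 0:
        raise ValueError("regions cover zero bases of the genome")
    return pd.DataFrame(
        {
            "label": list(priority),
            "foreground_fraction": [fg[l] / fg_total for l in priority],
            "background_fraction": [bg[l] / bg_total for l in priority],
        }
    )


@dataclass(frozen=True)
class GeneOverlap:
    gene_id: str
    biotype: str
    regions: tuple[GenomeRegion, ...]


def gene_overlap(
    regions: Sequence[GenomeRegion],
    genes: Sequence[Annotation],
) -> list[GeneOverlap]:
    """Genes with any (≥1 bp) overlap with the regions, each reported once.

    Gene annotations must carry unique ids (``name``); the label is the
    biotype. Output is sorted by gene id and independent of input order.
    """
    ids = [g.name for g in genes]
    if any(i is None for i in ids):
        raise ValueError("gene annotations must carry ids in their name field")
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids are not unique")
    by_chrom: dict[str, list[GenomeRegion]] = {}
    for r in sorted(regions):
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[GeneOverlap] = []
    # sweep per gene over start-sorted regions; regions ending before the
    # gene can never match later genes on the same sorted pass
    for g in sorted(genes, key=lambda a: (a.region.chrom, a.region.start, a.name)):
        cands = by_chrom.get(g.region.chrom, [])
        # only regions starting before the gene end can overlap it
        hi = bisect.bisect_left([r.start for r in cands], g.region.end)
        hits = tuple(r for r in cands[:hi] if r.end > g.region.start)
        if hits:
            out.append(GeneOverlap(g.name, g.label, hits))
    out.sort(key=lambda o: o.gene_id)
    return out
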