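"""Synthetic focal genome, species panel, alignment blocks and annotations.

The generator emulates the signal the caller is built to find: a handful of
planted regions that are well conserved in at least two non-mammal species
while only a few (or no) mammals align to them, embedded in a background
where most mammals carry high-identity alignments and non-mammals only
sparse, low-identity ones. Everything is deterministic under the seed.

Background alignment blocks are Poisson-count intervals per species per
chromosome with uniform starts and log-normal lengths; block identities are
drawn per clade (mammals high, non-mammals low) so that false positives are
possible but rare. Sequence sets for the phylogenetic stage are evolved with
a Jukes–Cantor single-parameter substitution process — only topology, not
branch-length realism, matters downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import (
    MAMMAL,
    NON_MAMMAL,
    AlignmentBlock,
    Annotation,
    ChromSizes,
    GenomeRegion,
    SpeciesPanel,
    write_alignment_blocks,
    write_bed,
    write_fasta,
)
from .phylo import PhyloTree, Topo, _attach, _remove

BASES = np.array(list("ACGT"))

#: chromHMM-style segmentation classes with genome-wide weights mirroring a
#: typical whole-genome background (heterochromatin-dominated).
CHROMATIN_CLASSES = {
    "Heterochrom": 0.723,
    "Txn": 0.202,
    "Enhancer": 0.037,
    "Promoter": 0.016,
    "Repressed": 0.013,
    "Insulator": 0.007,
    "Repetitive": 0.002,
}

GENE_BIOTYPES = {
    "protein_coding": 0.407,
    "lincRNA": 0.070,
    "antisense": 0.037,
    "other": 0.030,
}
GENE_FRACTION = sum(GENE_BIOTYPES.values())  # rest is non-gene

REPEAT_CLASSES = {
    "SINE": 0.13,
    "LINE": 0.20,
    "LTR": 0.08,
    "DNA": 0.03,
    "Simple_repeat": 0.02,
    "Low_complexity": 0.01,
}

HISTONE_MARKS = ("H3K4Me1", "H2A.Z", "H3K4Me3", "H3K9Ac", "H3K27Ac", "H3K27Me3")

__all__ = [
    "SimConfig",
    "PlantedRegion",
    "PlantedTruth",
    "make_panel",
    "simulate_genome",
    "plant_hgt_alignments",
    "simulate_transfer_sequences",
    "demo_species_tree",
    "write_dataset",
    "CHROMATIN_CLASSES",
    "GENE_BIOTYPES",
    "REPEAT_CLASSES",
    "HISTONE_MARKS",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_mammals: int = 41
    n_nonmammals: int = 12
    n_planted_hgt: int = 10
    planted_length: int = 1500
    hgt_nonmammal_identity: float = 0.60
    hgt_nonmammal_supporters: int = 2
    hgt_mammal_supporters: int = 0
    background_mammal_identity: float = 0.70
    background_block_rate: float = 0.2  # blocks per kb per species
    substitution_rate_per_branch: float = 0.02
    #: fraction of planted regions forced into terminal chromosome zones
    end_zone_plant_fraction: float = 0.0
    end_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "hgt_nonmammal_identity",
            "background_mammal_identity",
            "end_zone_plant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.hgt_nonmammal_supporters < 2:
            raise ValueError("hgt_nonmammal_supporters must be ≥ 2")
        if self.hgt_mammal_supporters < 0 or self.hgt_mammal_supporters > self.n_mammals:
            raise ValueError("hgt_mammal_supporters outside [0, n_mammals]")
        if self.hgt_nonmammal_supporters > self.n_nonmammals:
            raise ValueError("hgt_nonmammal_supporters exceeds panel size")
        if self.planted_length <= 0 or self.chrom_length <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class PlantedRegion:
    region: GenomeRegion
    nonmammal_supporters: tuple[str, ...]
    mammal_support_count: int


@dataclass(frozen=True)
class PlantedTruth:
    regions: tuple[PlantedRegion, ...]

    @property
    def intervals(self) -> list[GenomeRegion]:
        return [p.region for p in self.regions]

    def write(self, bed_path: str | Path, json_path: str | Path) -> None:
        with open(bed_path, "w") as fh:
            for i, p in enumerate(self.regions):
                fh.write(
                    f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\tplant{i}\n"
                )
        with open(json_path, "w") as fh:
            json.dump(
                [
                    {
                        "chrom": p.region.chrom,
                        "start": p.region.start,
                        "end": p.region.end,
                        "nonmammal_supporters": list(p.nonmammal_supporters),
                        "mammal_support_count": p.mammal_support_count,
                    }
                    for p in self.regions
                ],
                fh,
                indent=2,
                sort_keys=True,
            )
        # trailing newline keeps the sidecar diff-friendly
        with open(json_path, "a") as fh:
            fh.write("\n")


def make_panel(cfg: SimConfig) -> SpeciesPanel:
    clades = {f"mammal_{i:02d}": MAMMAL for i in range(1, cfg.n_mammals + 1)}
    clades.update(
        {f"nonmammal_{i:02d}": NON_MAMMAL for i in range(1, cfg.n_nonmammals + 1)}
    )
    return SpeciesPanel(clades)


def _chrom_names(cfg: SimConfig) -> list[str]:
    return [f"chr{i}" for i in range(1, cfg.n_chroms + 1)]


def simulate_genome(
    cfg: SimConfig,
) -> tuple[dict[str, str], ChromSizes, dict[str, list[Annotation]]]:
    """Uniform-random DNA plus gene / chromatin / repeat / histone tracks.

    Chromatin labels tile each chromosome completely; genes and repeats are
    non-overlapping intervals within their own track; histone marks are
    sparse intervals with log-normal signal values.
    """
    if cfg.chrom_length < 3 * cfg.planted_length:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small to host planted regions "
            f"of {cfg.planted_length} bp"
        )
    rng = np.random.default_rng(cfg.seed)
    chroms = _chrom_names(cfg)
    seqs = {
        c: "".join(BASES[rng.integers(0, 4, cfg.chrom_length)]) for c in chroms
    }
    sizes = ChromSizes({c: cfg.chrom_length for c in chroms})
    tracks: dict[str, list[Annotation]] = {
        "gene": [],
        "chromatin": [],
        "repeat": [],
        "histone": [],
    }
    gene_counter = 0
    chromatin_labels = list(CHROMATIN_CLASSES)
    chromatin_probs = np.array(list(CHROMATIN_CLASSES.values()))
    chromatin_probs /= chromatin_probs.sum()
    for c in chroms:
        L = cfg.chrom_length
        # chromatin: full segmentation with ~2 kb mean segment length
        pos = 0
        while pos < L:
            seg = int(rng.exponential(2000)) + 200
            end = min(pos + seg, L)
            label = chromatin_labels[rng.choice(len(chromatin_labels), p=chromatin_probs)]
            tracks["chromatin"].append(
                Annotation(GenomeRegion(c, pos, end), "chromatin", label)
            )
            pos = end
        # genes: alternate gene/gap so per-base biotype shares track the weights
        pos = int(rng.integers(0, 2000))
        biotypes = list(GENE_BIOTYPES)
        bio_probs = np.array(list(GENE_BIOTYPES.values()))
        bio_probs /= bio_probs.sum()
        while pos < L - 500:
            glen = int(rng.lognormal(np.log(4000), 0.5))
            end = min(pos + glen, L)
            gene_counter += 1
            biotype = biotypes[rng.choice(len(biotypes), p=bio_probs)]
            tracks["gene"].append(
                Annotation(
                    GenomeRegion(c, pos, end), "gene", biotype,
                    name=f"gene{gene_counter:05d}",
                )
            )
            gap = int(glen * (1.0 - GENE_FRACTION) / GENE_FRACTION)
            pos = end + max(gap, 200)
        # repeats: non-overlapping, class-weighted
        rep_labels = list(REPEAT_CLASSES)
        rep_probs = np.array(list(REPEAT_CLASSES.values()))
        target = rep_probs.sum() * L
        rep_probs /= rep_probs.sum()
        pos = int(rng.integers(0, 500))
        covered = 0
        while covered < target and pos < L - 100:
            rlen = int(rng.lognormal(np.log(300), 0.6)) + 20
            end = min(pos + rlen, L)
            label = rep_labels[rng.choice(len(rep_labels), p=rep_probs)]
            tracks["repeat"].append(
                Annotation(GenomeRegion(c, pos, end), "repeat", label)
            )
            covered += end - pos
            pos = end + int(rng.exponential(1000)) + 50
        # histone marks: sparse peaks with signal values
        for mark in HISTONE_MARKS:
            n_peaks = rng.poisson(L / 20_000)
            starts = np.sort(rng.integers(0, max(L - 2000, 1), n_peaks))
            for s in starts:
                width = int(rng.integers(200, 2000))
                tracks["histone"].append(
                    Annotation(
                        GenomeRegion(c, int(s), min(int(s) + width, L)),
                        "histone",
                        mark,
                        value=float(rng.lognormal(0.5, 0.5)),
                    )
                )
    return seqs, sizes, tracks


def _place_plants(cfg: SimConfig, rng: np.random.Generator) -> list[GenomeRegion]:
    """Non-overlapping planted regions, optionally forced into end zones."""
    chroms = _chrom_names(cfg)
    L = cfg.chrom_length
    plen = cfg.planted_length
    n_end = int(round(cfg.end_zone_plant_fraction * cfg.n_planted_hgt))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[GenomeRegion] = []
    attempts = 0
    i = 0
    while i < cfg.n_planted_hgt:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("cannot place planted regions; chromosome too crowded")
        c = chroms[int(rng.integers(len(chroms)))]
        if i < n_end:
            # midpoint inside a terminal zone of width end_fraction * L
            zone = int(cfg.end_fraction * L)
            if rng.integers(2) == 0:
                start = int(rng.integers(0, max(zone - plen, 1)))
            else:
                start = int(rng.integers(L - zone, L - plen))
        else:
            lo, hi = plen, L - 2 * plen
            if hi <= lo:
                raise ValueError("chrom_length too small for interior placement")
            start = int(rng.integers(lo, hi))
        end = start + plen
        # keep plants separated by at least one planted length so calls
        # cannot merge across plants
        if any(start - plen < e and end + plen > s for s, e in placed[c]):
            continue
        placed[c].append((start, end))
        out.append(GenomeRegion(c, start, end))
        i += 1
    return sorted(out)


def plant_hgt_alignments(
    cfg: SimConfig, sizes: ChromSizes
) -> tuple[list[AlignmentBlock], PlantedTruth]:
    """Alignment-block table with planted HGT signal plus its truth record.

    Each planted region receives full-length blocks at
    ``hgt_nonmammal_identity`` from exactly ``hgt_nonmammal_supporters``
    non-mammals, and (when requested) blocks from ``hgt_mammal_supporters``
    mammals at identity 0.5 covering 60% of the region — enough to count as
    mammal support under the default thresholds, which is what the spoiler
    (9-supporter) negative control exploits.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    panel = make_panel(cfg)
    mammals = sorted(panel.mammals)
    nonmammals = sorted(panel.non_mammals)
    if cfg.hgt_nonmammal_supporters > len(nonmammals):
        raise ValueError("requested non-mammal supporters exceed panel size")
    if cfg.hgt_mammal_supporters > len(mammals):
        raise ValueError("requested mammal supporters exceed panel size")

    blocks: list[AlignmentBlock] = []
    planted: list[PlantedRegion] = []
    for region in _place_plants(cfg, rng):
        nm_idx = rng.choice(len(nonmammals), cfg.hgt_nonmammal_supporters, replace=False)
        supporters = tuple(sorted(nonmammals[k] for k in nm_idx))
        for sp in supporters:
            blocks.append(
                AlignmentBlock(
                    sp, region.chrom, region.start, region.end,
                    cfg.hgt_nonmammal_identity,
                )
            )
        if cfg.hgt_mammal_supporters:
            m_idx = rng.choice(len(mammals), cfg.hgt_mammal_supporters, replace=False)
            cover = int(0.6 * region.length)
            for k in sorted(m_idx):
                blocks.append(
                    AlignmentBlock(
                        mammals[k], region.chrom, region.start,
                        region.start + cover, 0.5,
                    )
                )
        planted.append(PlantedRegion(region, supporters, cfg.hgt_mammal_supporters))

    # background: Poisson blocks per species per chromosome. Blocks that
    # would overlap a planted region are rejected — the planted signal is
    # precisely that mammals align *elsewhere* — which keeps the truth
    # record's support counts exact.
    plant_ivs: dict[str, list[tuple[int, int]]] = {}
    for p in planted:
        plant_ivs.setdefault(p.region.chrom, []).append((p.region.start, p.region.end))
    if cfg.background_block_rate > 0:
        for chrom, L in sizes.items():
            lam = cfg.background_block_rate * L / 1000.0
            for sp in mammals + nonmammals:
                n = rng.poisson(lam)
                if n == 0:
                    continue
                starts = rng.integers(0, L - 50, n)
                lens = np.clip(rng.lognormal(np.log(500), 0.6, n), 50, 5000).astype(int)
                if panel.clade_of(sp) == MAMMAL:
                    idents = np.clip(
                        rng.normal(cfg.background_mammal_identity, 0.05, n), 0.0, 1.0
                    )
                else:
                    idents = np.clip(rng.normal(0.20, 0.08, n), 0.02, 0.45)
                for s, ln, ident in zip(starts, lens, idents):
                    e = min(int(s) + int(ln), L)
                    if any(int(s) < pe and e > ps for ps, pe in plant_ivs.get(chrom, [])):
                        continue
                    blocks.append(AlignmentBlock(sp, chrom, int(s), e, float(ident)))
    blocks.sort()
    return blocks, PlantedTruth(tuple(planted))


def demo_species_tree() -> PhyloTree:
    """A small fixed vertebrate-style species tree for the phylogenetic stage.

    Two fish as the basal lineages (lamprey the designated outgroup), then
    reptile/bird, then the mammals with a primate pair — mirroring the
    clade structure the transfer scenario plays out on.
    """
    newick = (
        "(lamprey,(zebrafish,((chicken,lizard),"
        "((mouse,rat),(human,chimp)))));"
    )
    return PhyloTree.from_newick(newick)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor step: each site substitutes with probability *rate*."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits):
        # shift by 1..3 in base space: always a different base, uniform over the 3
        out[hits] = (out[hits] + rng.integers(1, 4, len(hits))) % 4
    return out


def simulate_transfer_sequences(
    species_tree: PhyloTree,
    donor: str,
    recipient: str,
    length: int = 2000,
    rate: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, str], PhyloTree]:
    """Sequence set with one planted transfer, plus the expected topology.

    Sequences evolve along the species-tree topology with per-branch
    substitution probability *rate*; the recipient's sequence is then
    replaced by a near-copy of the donor's (1% divergence), so a correct
    distance tree places recipient sister to donor. The expected topology is
    the species tree with the recipient leaf regrafted next to the donor.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    leaves = species_tree.leaves
    if donor not in leaves or recipient not in leaves:
        raise ValueError("donor and recipient must be leaves of the species tree")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, length)

    seqs: dict[str, np.ndarray] = {}

    def evolve(t: Topo, parent_seq: np.ndarray) -> None:
        seq = _mutate(parent_seq, rate, rng)
        if isinstance(t, str):
            seqs[t] = seq
        else:
            evolve(t[0], seq)
            evolve(t[1], seq)

    evolve(species_tree.topo, root)
    seqs[recipient] = _mutate(seqs[donor], 0.01, rng)
    out = {sp: "".join(BASES[s]) for sp, s in sorted(seqs.items())}

    # expected topology: recipient regrafted as donor's sister
    pruned = _remove(species_tree.topo, recipient)
    expected = PhyloTree(_attach(pruned, recipient, donor))
    return out, expected


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete synthetic dataset in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs, sizes, tracks = simulate_genome(cfg)
    blocks, truth = plant_hgt_alignments(cfg, sizes)
    panel = make_panel(cfg)
    paths = {
        "genome": outdir / "genome.fa",
        "sizes": outdir / "chrom.sizes",
        "panel": outdir / "panel.tsv",
        "blocks": outdir / "blocks.tsv",
        "genes": outdir / "genes.bed",
        "chromatin": outdir / "chromatin.bed",
        "repeats": outdir / "repeats.bed",
        "histone": outdir / "histone.bed",
        "truth_bed": outdir / "truth.bed",
        "truth_json": outdir / "truth.json",
    }
    write_fasta(seqs, paths["genome"])
    sizes.write(paths["sizes"])
    panel.write(paths["panel"])
    write_alignment_blocks(blocks, paths["blocks"])
    write_bed(tracks["gene"], paths["genes"])
    write_bed(tracks["chromatin"], paths["chromatin"])
    write_bed(tracks["repeat"], paths["repeats"])
    write_bed(tracks["histone"], paths["histone"])
    truth.write(paths["truth_bed"], paths["truth_json"])
    return paths
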