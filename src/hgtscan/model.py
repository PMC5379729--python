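"""Domain types and flat-file I/O for the HGT scan pipeline.

Coordinates are 0-based, half-open (BED convention) throughout the package.
Genome-browser style literals (1-based, inclusive) can be converted on ingest
with :func:`parse_region_literal`.

Alignment blocks are precomputed pairwise-alignment intervals between the
focal genome and one other species, each carrying an identity fraction.
Identity is defined here as *matched columns over focal-genome (non-gap)
bases*: every filtering threshold downstream is phrased relative to the focal
genome region, so identity and coverage share one coordinate system. Strand
is ignored: the caller uses only identity and length on the focal genome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MAMMAL = "mammal"
NON_MAMMAL = "non_mammal"
CLADES = (MAMMAL, NON_MAMMAL)

TRACKS = ("gene", "chromatin", "repeat", "histone")

__all__ = [
    "MAMMAL",
    "NON_MAMMAL",
    "CLADES",
    "TRACKS",
    "GenomeRegion",
    "AlignmentBlock",
    "SpeciesPanel",
    "ChromSizes",
    "Annotation",
    "read_alignment_blocks",
    "write_alignment_blocks",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "block_identity",
    "parse_region_literal",
]


@dataclass(frozen=True, order=True)
class GenomeRegion:
    """A half-open interval [start, end) on one chromosome of the focal genome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "GenomeRegion") -> int:
        """Overlap length in bp (0 if different chromosomes or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomeRegion") -> float:
        """Interval Jaccard: overlap / union length (0 across chromosomes)."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        union = self.length + other.length - ov
        return ov / union

    def __str__(self) -> str:  # 0-based half-open, explicit
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, order=True)
class AlignmentBlock:
    """One aligned interval between a focal-genome region and one species."""

    species_id: str
    chrom: str
    start: int
    end: int
    identity: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid block interval {self.chrom}:{self.start}-{self.end} "
                f"for species {self.species_id!r}"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(
                f"identity {self.identity} outside [0,1] for block "
                f"{self.species_id} {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def region(self) -> GenomeRegion:
        return GenomeRegion(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


class SpeciesPanel:
    """The species panel: each aligned species labelled mammal / non_mammal.

    The real study used 41 mammals and 12 non-mammals; those are defaults of
    the study, not constraints of the type — any panel with at least one
    mammal and two non-mammals can drive the caller.
    """

    def __init__(self, clades: Mapping[str, str]):
        for sp, clade in clades.items():
            if clade not in CLADES:
                raise ValueError(f"unknown clade {clade!r} for species {sp!r}")
        self._clades = dict(clades)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._clades)

    @property
    def mammals(self) -> tuple[str, ...]:
        return tuple(s for s, c in self._clades.items() if c == MAMMAL)

    @property
    def non_mammals(self) -> tuple[str, ...]:
        return tuple(s for s, c in self._clades.items() if c == NON_MAMMAL)

    def clade_of(self, species_id: str) -> str:
        return self._clades[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._clades

    def __len__(self) -> int:
        return len(self._clades)

    def require_callable(self, min_nonmammal: int = 2) -> None:
        """Raise unless the panel can support calling (≥min non-mammals, ≥1 mammal)."""
        if len(self.non_mammals) < min_nonmammal:
            raise ValueError(
                f"panel has {len(self.non_mammals)} non-mammal species; "
                f"need at least {min_nonmammal}"
            )
        if len(self.mammals) < 1:
            raise ValueError("panel has no mammal species")

    @classmethod
    def read(cls, path: str | Path) -> "SpeciesPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        _require_columns(df, ("species", "clade"), path)
        if df["species"].duplicated().any():
            dups = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValueError(f"duplicate species in panel {path}: {dups}")
        return cls(dict(zip(df["species"], df["clade"])))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species": list(self._clades), "clade": list(self._clades.values())}
        ).to_csv(path, sep="\t", index=False)


class ChromSizes(Mapping[str, int]):
    """Chromosome lengths (UCSC chrom.sizes style)."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length {length} for {chrom}")
        self._sizes = dict(sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @classmethod
    def read(cls, path: str | Path) -> "ChromSizes":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
                chrom, length = parts[0], int(parts[1])
                if chrom in sizes:
                    raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom}")
                sizes[chrom] = length
        return cls(sizes)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self._sizes.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class Annotation:
    """A typed genomic interval from one annotation track.

    ``label`` carries the class of interest (gene biotype, chromatin state,
    repeat class, histone mark); ``value`` is a signal level, 1.0 for
    presence/absence tracks; ``name`` is an optional stable identifier
    (e.g. a gene id).
    """

    region: GenomeRegion
    track: str
    label: str
    value: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.track not in TRACKS:
            raise ValueError(f"unknown track {self.track!r}; expected one of {TRACKS}")
        if not self.label:
            raise ValueError("annotation label must be non-empty")
        if self.value < 0:
            raise ValueError(f"negative annotation value {self.value}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_alignment_blocks(
    path: str | Path,
    panel: SpeciesPanel,
    sizes: ChromSizes | None = None,
) -> list[AlignmentBlock]:
    """Read a TSV of alignment blocks, validating every row against the panel.

    Expected header: ``species  chrom  start  end  identity``. Rows with an
    unknown species, an empty/inverted interval, an identity outside [0,1],
    or (when *sizes* is given) an end beyond the chromosome, are hard errors
    naming the offending row.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"species": str, "chrom": str, "start": int, "end": int, "identity": float},
        float_precision="round_trip",
    )
    _require_columns(df, ("species", "chrom", "start", "end", "identity"), path)
    blocks: list[AlignmentBlock] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        if row.species not in panel:
            raise ValueError(f"{path} line {idx}: unknown species {row.species!r}")
        try:
            block = AlignmentBlock(row.species, row.chrom, row.start, row.end, row.identity)
        except ValueError as exc:
            raise ValueError(f"{path} line {idx}: {exc}") from None
        if sizes is not None:
            if block.chrom not in sizes:
                raise ValueError(f"{path} line {idx}: unknown chromosome {block.chrom!r}")
            if block.end > sizes[block.chrom]:
                raise ValueError(
                    f"{path} line {idx}: block end {block.end} beyond "
                    f"{block.chrom} length {sizes[block.chrom]}"
                )
        blocks.append(block)
    return blocks


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["species", "chrom", "start", "end", "identity"])
        for b in blocks:
            writer.writerow([b.species_id, b.chrom, b.start, b.end, repr(b.identity)])


def read_bed(path: str | Path, track: str) -> list[Annotation]:
    """Read a BED6-compatible annotation file for one declared track.

    Columns: chrom, start, end, name, score, strand[, label]. The BED name
    column is the class label for most tracks; gene files may carry the gene
    id in the name column and the biotype in an optional 7th column.
    Score is the signal value (used for histone tracks); strand is ignored.
    """
    annots: list[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected ≥4 BED columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            value = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 1.0
            if len(parts) > 6 and parts[6]:
                label, gene_name = parts[6], name
            else:
                label, gene_name = name, (name if track == "gene" else None)
            try:
                annots.append(
                    Annotation(GenomeRegion(chrom, start, end), track, label, value, gene_name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return annots


def write_bed(annots: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annots:
            cols = [a.region.chrom, str(a.region.start), str(a.region.end),
                    a.name if a.name is not None else a.label, repr(a.value), "."]
            if a.name is not None and a.name != a.label:
                cols.append(a.label)
            fh.write("\t".join(cols) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def block_identity(focal_seq: str, other_seq: str) -> float:
    """Alignment identity relative to the focal genome.

    Both arguments are rows of one gapped pairwise alignment (equal length,
    ``-`` for gaps). Returns matched non-gap columns divided by the number of
    columns where the focal row has a base. Case-insensitive.
    """
    if len(focal_seq) != len(other_seq):
        raise ValueError(
            f"alignment rows differ in length ({len(focal_seq)} vs {len(other_seq)})"
        )
    focal = focal_seq.upper()
    other = other_seq.upper()
    denom = 0
    matches = 0
    for a, b in zip(focal, other):
        if a == "-":
            continue
        denom += 1
        if b != "-" and a == b:
            matches += 1
    if denom == 0:
        raise ValueError("focal alignment row contains no bases (all gaps)")
    return matches / denom


def parse_region_literal(text: str, one_based: bool = False) -> GenomeRegion:
    """Parse ``chrom:start-end`` into a region.

    With ``one_based=True`` the literal is interpreted as a 1-based inclusive
    genome-browser coordinate and converted to 0-based half-open.
    """
    try:
        chrom, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start, end = int(lo), int(hi)
    except ValueError:
        raise ValueError(f"cannot parse region literal {text!r}") from None
    if one_based:
        start -= 1
    return GenomeRegion(chrom, start, end)
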