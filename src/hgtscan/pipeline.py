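"""End-to-end orchestration: run all stages on one dataset, write the report bundle.

A run is fully determined by its inputs and configuration: the manifest
echoes the resolved parameters and the SHA-256 of every input file, and
repeated runs with identical config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .caller import CallParams, HGTRegion, call_hgt, evaluate_calls, threshold_grid, validate_calls
from .context import (
    CHROMATIN_PRIORITY,
    GENE_PRIORITY,
    composition,
    end_bias_test,
    gene_overlap,
)
from .model import (
    ChromSizes,
    GenomeRegion,
    SpeciesPanel,
    read_alignment_blocks,
    read_bed,
    read_fasta,
)
from .profiles import WindowScheme, coverage_profile, gc_profile
from .simulate import (
    HISTONE_MARKS,
    REPEAT_CLASSES,
    SimConfig,
    plant_hgt_alignments,
    simulate_genome,
    write_dataset,
)

logger = logging.getLogger("hgtscan")

__all__ = ["RunConfig", "run_pipeline", "simulate_and_run", "write_calls"]


@dataclass
class RunConfig:
    """Paths and parameters of one full pipeline run."""

    blocks: str
    panel: str
    chrom_sizes: str
    outdir: str
    genome: str | None = None
    genes: str | None = None
    chromatin: str | None = None
    repeats: str | None = None
    histone: str | None = None
    params: CallParams = field(default_factory=CallParams)
    scheme: WindowScheme = field(default_factory=WindowScheme)
    end_fraction: float = 0.10
    identity_grid: tuple[float, ...] = (0.4, 0.5, 0.6)
    coverage_grid: tuple[float, ...] = (0.4, 0.2, 0.0)
    seed: int = 0

    def input_paths(self) -> dict[str, str]:
        paths = {"blocks": self.blocks, "panel": self.panel, "chrom_sizes": self.chrom_sizes}
        for key in ("genome", "genes", "chromatin", "repeats", "histone"):
            if getattr(self, key) is not None:
                paths[key] = getattr(self, key)
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_calls(calls: Sequence[HGTRegion], bed_path: Path, json_path: Path) -> None:
    """BED of called regions plus a JSON sidecar with supporter detail."""
    with open(bed_path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                f"{c.region.chrom}\t{c.region.start}\t{c.region.end}\thgt{i:04d}\n"
            )
    payload = [
        {
            "chrom": c.region.chrom,
            "start": c.region.start,
            "end": c.region.end,
            "nonmammal_supporters": {sp: round(ident, 6) for sp, ident in c.nonmammal_supporters},
            "mammal_support_count": c.mammal_support_count,
            "mammal_supporters": list(c.mammal_supporters),
        }
        for c in calls
    ]
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _profile_frame(profiles: dict[str, "object"]) -> "object":
    import pandas as pd

    cols = {"bin": np.arange(next(iter(profiles.values())).values.size)}
    for name, prof in profiles.items():
        cols[name] = prof.values
        cols[f"{name}_n"] = prof.region_counts
    df = pd.DataFrame(cols)
    return df


def run_pipeline(cfg: RunConfig) -> dict:
    """Run call → grid → context → profiles; write the report bundle.

    Missing input files are reported (all of them, by name) before any
    computation. Returns a summary dict mirroring the manifest.
    """
    missing = [p for p in cfg.input_paths().values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = SpeciesPanel.read(cfg.panel)
    sizes = ChromSizes.read(cfg.chrom_sizes)
    blocks = read_alignment_blocks(cfg.blocks, panel, sizes)
    logger.info("loaded %d alignment blocks, %d species", len(blocks), len(panel))

    calls = call_hgt(blocks, panel, cfg.params)
    validate_calls(calls, cfg.params)
    regions = [c.region for c in calls]
    logger.info("called %d candidate HGT regions", len(calls))
    write_calls(calls, outdir / "calls.bed", outdir / "calls.json")

    grid = threshold_grid(blocks, panel, cfg.identity_grid, cfg.coverage_grid, cfg.params)
    grid.to_csv(outdir / "threshold_grid.tsv", sep="\t", index=False)

    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "params": asdict(cfg.params),
        "scheme": asdict(cfg.scheme),
        "end_fraction": cfg.end_fraction,
        "inputs": {k: _sha256(v) for k, v in sorted(cfg.input_paths().items())},
        "n_blocks": len(blocks),
        "n_regions": len(calls),
        "total_bases": sum(r.length for r in regions),
    }

    if regions and len(sizes) >= 2:
        bias = end_bias_test(regions, sizes, cfg.end_fraction)
        bias.table.to_csv(outdir / "end_bias.tsv", sep="\t", index=False)
        summary["end_bias"] = {"t": bias.t, "p": bias.p, "warning": bias.warning}

    if regions and cfg.genes:
        genes = read_bed(cfg.genes, "gene")
        comp = composition(regions, genes, sizes, GENE_PRIORITY, "non_gene")
        comp.to_csv(outdir / "gene_composition.tsv", sep="\t", index=False)
        overlaps = gene_overlap(regions, genes)
        summary["n_overlapping_genes"] = len(overlaps)
        with open(outdir / "gene_overlap.tsv", "w") as fh:
            fh.write("gene_id\tbiotype\tn_regions\n")
            for o in overlaps:
                fh.write(f"{o.gene_id}\t{o.biotype}\t{len(o.regions)}\n")

    if regions and cfg.chromatin:
        chromatin = read_bed(cfg.chromatin, "chromatin")
        comp = composition(
            regions, chromatin, sizes, CHROMATIN_PRIORITY, CHROMATIN_PRIORITY[0]
        )
        comp.to_csv(outdir / "chromatin_composition.tsv", sep="\t", index=False)

    profiles = {}
    if regions and cfg.genome:
        fasta = read_fasta(cfg.genome)
        profiles["GC"] = gc_profile(regions, fasta, cfg.scheme, sizes)
    if regions and cfg.repeats:
        repeats = read_bed(cfg.repeats, "repeat")
        present = {a.label for a in repeats}
        for cls in REPEAT_CLASSES:
            if cls in present:
                profiles[cls] = coverage_profile(regions, repeats, cls, cfg.scheme, sizes)
    if regions and cfg.histone:
        histone = read_bed(cfg.histone, "histone")
        present = {a.label for a in histone}
        for mark in HISTONE_MARKS:
            if mark in present:
                profiles[mark] = coverage_profile(
                    regions, histone, mark, cfg.scheme, sizes, signal=True
                )
    if profiles:
        _profile_frame(profiles).to_csv(
            outdir / "profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )
        summary["profiles"] = sorted(profiles)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def simulate_and_run(
    simcfg: SimConfig,
    params: CallParams | None = None,
    outdir: str | Path | None = None,
    min_jaccard: float = 0.99,
) -> dict:
    """Generate a synthetic dataset, run the caller, score against truth."""
    params = params or CallParams()
    if outdir is not None:
        paths = write_dataset(simcfg, outdir)
        cfg = RunConfig(
            blocks=str(paths["blocks"]),
            panel=str(paths["panel"]),
            chrom_sizes=str(paths["sizes"]),
            outdir=str(Path(outdir) / "report"),
            genome=str(paths["genome"]),
            genes=str(paths["genes"]),
            chromatin=str(paths["chromatin"]),
            repeats=str(paths["repeats"]),
            histone=str(paths["histone"]),
            params=params,
            seed=simcfg.seed,
        )
        run_pipeline(cfg)
        panel = SpeciesPanel.read(paths["panel"])
        sizes = ChromSizes.read(paths["sizes"])
        blocks = read_alignment_blocks(paths["blocks"], panel, sizes)
        with open(paths["truth_json"]) as fh:
            truth_regions = [
                GenomeRegion(t["chrom"], t["start"], t["end"]) for t in json.load(fh)
            ]
    else:
        _, sizes, _ = simulate_genome(simcfg)
        blocks, truth = plant_hgt_alignments(simcfg, sizes)
        panel = None
        truth_regions = truth.intervals
    if panel is None:
        from .simulate import make_panel

        panel = make_panel(simcfg)
    calls = call_hgt(blocks, panel, params)
    report = evaluate_calls([c.region for c in calls], truth_regions, min_jaccard)
    report["min_jaccard"] = min_jaccard
    return report
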