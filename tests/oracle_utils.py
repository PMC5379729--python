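"""Brute-force reference implementations shared by the test suite.

These deliberately avoid the package's interval algebra: per-base boolean
masks and explicit loops, correct by inspection at toy scale.
"""

import numpy as np

from hgtscan.model import MAMMAL, NON_MAMMAL, AlignmentBlock, GenomeRegion


def perbase_call(blocks, panel, params, chrom_len, chrom="chr1"):
    """Per-base reference caller: species masks → depth array → runs."""
    masks = {}
    for b in blocks:
        if b.chrom != chrom:
            continue
        if panel.clade_of(b.species_id) != NON_MAMMAL or b.identity < params.min_identity:
            continue
        m = masks.setdefault(b.species_id, np.zeros(chrom_len, dtype=bool))
        m[b.start : b.end] = True
    depth = np.zeros(chrom_len, dtype=int)
    for m in masks.values():
        depth += m
    ok = depth >= params.min_nonmammal_species
    edges = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
    regions = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > params.min_length:
            regions.append(GenomeRegion(chrom, int(s), int(e)))
    mmasks = {}
    for b in blocks:
        if (
            b.chrom == chrom
            and panel.clade_of(b.species_id) == MAMMAL
            and b.identity >= params.mammal_min_identity
        ):
            m = mmasks.setdefault(b.species_id, np.zeros(chrom_len, dtype=bool))
            m[b.start : b.end] = True
    out = []
    for r in regions:
        supporters = sorted(
            sp
            for sp, m in mmasks.items()
            if m[r.start : r.end].sum() > params.mammal_min_coverage * r.length
        )
        if len(supporters) <= params.max_mammal_support:
            out.append((r, supporters))
    return out


def random_blocks(rng, panel, chrom_len, n, chrom="chr1"):
    blocks = []
    species = list(panel.species)
    for _ in range(n):
        sp = species[rng.integers(len(species))]
        start = int(rng.integers(0, chrom_len - 100))
        length = int(rng.integers(100, 4000))
        blocks.append(
            AlignmentBlock(
                sp, chrom, start, min(start + length, chrom_len), float(rng.random())
            )
        )
    return blocks
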