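"""Seeded column shuffling and complementary fractional splits.

The workflow mirrors the site-resampling design used to probe how much
data strong bootstrap support requires: randomise column order of the
full (degenerate) supermatrix without replacement, then cut it into
complementary blocks (e.g. two 50% halves, three 33% thirds, or an
85%/15% pair). A single Fisher-Yates pass of a well-seeded generator is
distribution-identical to repeated re-shuffling, so one pass is done and
the seed recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import floor
from pathlib import Path

import numpy as np

from degenkit.matrix_io import NucMatrix


@dataclass(frozen=True)
class SubsampleSpec:
    """Seeded recipe for one shuffle-and-split replicate."""

    seed: int
    fractions: tuple[float, ...] = (0.5, 0.5)
    replicate_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        if not self.fractions:
            raise ValueError("fraction list must not be empty")
        if any(not (0.0 < f <= 1.0) for f in self.fractions):
            raise ValueError("each fraction must be in (0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng([self.seed, self.replicate_id])


def shuffle_columns(m: NucMatrix, seed) -> NucMatrix:
    """Permute column order uniformly at random; metadata follows.

    ``seed`` may be an int or a numpy Generator. The column multiset is
    unchanged; charsets, positions and codon triples are remapped through
    the permutation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(m.n_cols)
    return m.take(list(perm))


def complementary_split(m: NucMatrix, spec: SubsampleSpec) -> list[NucMatrix]:
    """Cut a (pre-shuffled) matrix into consecutive complementary blocks.

    Block i has ``floor(f_i * n)`` columns; remainder columns go to the
    last block. Blocks are disjoint and jointly exhaust the columns.
    """
    n = m.n_cols
    sizes = [floor(f * n) for f in spec.fractions]
    sizes[-1] += n - sum(sizes)
    out, start = [], 0
    for size in sizes:
        out.append(m.take(range(start, start + size)))
        start += size
    return out


def shuffle_and_split(m: NucMatrix, spec: SubsampleSpec) -> list[NucMatrix]:
    """Shuffle with the replicate's own generator, then split.

    (seed, fractions, replicate_id) fully determines the output.
    """
    return complementary_split(shuffle_columns(m, spec.rng()), spec)


def split_manifest(m: NucMatrix, spec: SubsampleSpec, blocks: list[NucMatrix]) -> dict:
    """Provenance record for one replicate: seed, fractions, column origins."""
    return {
        "seed": spec.seed,
        "replicate_id": spec.replicate_id,
        "fractions": list(spec.fractions),
        "n_cols": m.n_cols,
        "blocks": [
            {"n_cols": b.n_cols, "source_columns": [int(c) for c in b.origin]}
            for b in blocks
        ],
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))
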