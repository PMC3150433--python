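"""Per-taxon base composition, Euclidean distances, composition trees.

Compositional heterogeneity — differing A/C/G/T proportions among taxa
— is a classic source of nonphylogenetic signal, concentrated in
synonymous sites. The diagnostics here quantify it directly: per-taxon
nucleotide proportions (in percent, over determinate sites only), the
Euclidean distance matrix on those proportions treated as four
independent characters, and a clustering diagram built solely from
composition (UPGMA by default, neighbor joining on request). When taxa
cluster by shared composition rather than by phylogeny, the character
set is carrying misleading signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from degenkit.errors import DegenkitError
from degenkit.matrix_io import NucMatrix
from degenkit.support import SupportedTree, parse_tree

BASES = "ACGT"


@dataclass(frozen=True)
class CompositionVector:
    """A/C/G/T proportions (percent) for one taxon over counted sites."""

    taxon: str
    freq: tuple[float, float, float, float]
    n_counted: int

    @property
    def defined(self) -> bool:
        return self.n_counted > 0


def base_composition(m: NucMatrix) -> list[CompositionVector]:
    """One composition vector per taxon.

    Sites with any symbol outside {A,C,G,T} (ambiguity codes, N, gaps,
    missing) are excluded from both numerator and denominator. A taxon
    with zero countable sites gets an undefined (all-zero, n=0) vector.
    """
    out = []
    for taxon, row in zip(m.taxa, m.rows):
        counts = [row.count(b) for b in BASES]
        n = sum(counts)
        if n == 0:
            out.append(CompositionVector(taxon, (0.0, 0.0, 0.0, 0.0), 0))
        else:
            out.append(
                CompositionVector(taxon, tuple(100.0 * c / n for c in counts), n)
            )
    return out


def euclidean_matrix(
    vectors: list[CompositionVector],
) -> tuple[list[str], np.ndarray]:
    """Symmetric Euclidean distance matrix on percent compositions.

    Undefined vectors are excluded with a warning. Units are percent:
    two pure, disjoint compositions sit sqrt(2)*100 ~ 141.42 apart.
    """
    defined = [v for v in vectors if v.defined]
    dropped = [v.taxon for v in vectors if not v.defined]
    if dropped:
        warnings.warn(f"excluding taxa with no countable sites: {dropped}")
    if len(defined) < 2:
        raise DegenkitError("need at least 2 defined composition vectors")
    X = np.array([v.freq for v in defined], dtype=float)
    return [v.taxon for v in defined], squareform(pdist(X, metric="euclidean"))


def _linkage_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_newick(node.get_left(), labels)
    right = _linkage_newick(node.get_right(), labels)
    bl_l = node.dist - node.get_left().dist
    bl_r = node.dist - node.get_right().dist
    return f"({left}:{bl_l / 2:.6g},{right}:{bl_r / 2:.6g})"


def composition_tree(
    labels: list[str], d: np.ndarray, method: str = "upgma"
) -> SupportedTree:
    """Cluster taxa on the composition distance matrix.

    ``upgma`` (default) uses average linkage with scipy's deterministic
    lowest-index tie-breaking; ``nj`` uses scikit-bio neighbor joining.
    The newick string is attached as ``.newick`` on the returned tree.
    """
    d = np.asarray(d, dtype=float)
    if len(labels) < 3:
        raise DegenkitError("need at least 3 taxa to build a tree")
    if d.shape != (len(labels), len(labels)):
        raise DegenkitError("distance matrix shape does not match labels")
    if method == "upgma":
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        root = hierarchy.to_tree(Z)
        nwk = _linkage_newick(root, labels) + ";"
    elif method == "nj":
        from skbio import DistanceMatrix
        from skbio.tree import nj

        nwk = str(nj(DistanceMatrix(d, ids=labels)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return parse_tree(nwk)


def composition_table(vectors: list[CompositionVector]):
    """Composition vectors as a pandas DataFrame (percent units)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"taxon": v.taxon, "A": v.freq[0], "C": v.freq[1], "G": v.freq[2],
             "T": v.freq[3], "n_counted": v.n_counted}
            for v in vectors
        ]
    )


def write_phylip_distances(labels: list[str], d: np.ndarray, path) -> None:
    """Square PHYLIP-format distance matrix."""
    lines = [f" {len(labels)}"]
    for lab, drow in zip(labels, d):
        lines.append(lab + "  " + " ".join(f"{x:.6f}" for x in drow))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
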