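"""Bipartition-level bootstrap support accounting and per-gene utility.

A tree with bootstrap labels is decomposed into its informative
bipartitions ("nodes"). Candidate analyses are compared against a
reference topology by bipartition identity after restriction to shared
taxa: a candidate node is *strongly supporting* when it matches a
strongly supported reference node, *conflicting* when its support
reaches the reporting threshold but it matches no such node, and
*strongly conflicting* when that support is itself strong. Defaults
follow the conventions of multigene bootstrap studies: >=80% "strong",
>=50% reportable, >=75% for single-gene analyses.

The phylogenetic-utility statistic for a gene fragment is

    U = (G / (L x 10^-3)) * (T / (T - m))

with G the reference nodes the gene recovers at >=75% bootstrap, L the
fragment length in nucleotides, m the number of taxa with entirely
missing data for the fragment, and T the total taxon count (80 in the
study design this implements).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import dendropy
import numpy as np
from scipy import stats

from degenkit.errors import DegenkitError
from degenkit.matrix_io import MISSING, NucMatrix


class Bipartition:
    """Unordered split of a leaf set into two non-empty sides."""

    __slots__ = ("side_a", "side_b", "_key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]) -> None:
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides must be non-empty")
        if a & b:
            raise ValueError("sides must be disjoint")
        self.side_a, self.side_b = a, b
        self._key = frozenset((a, b))

    @property
    def leaves(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_informative(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) >= 2

    def restrict(self, taxa: Iterable[str]) -> "Bipartition | None":
        """Induced bipartition on a taxon subset (None if one side empties)."""
        t = frozenset(taxa)
        a, b = self.side_a & t, self.side_b & t
        if not a or not b:
            return None
        return Bipartition(a, b)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Bipartition) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"{{{a}}}|{{{b}}}"


class SupportedTree:
    """Leaf-labelled topology reduced to informative bipartitions + support."""

    def __init__(self, leaves: Iterable[str], clades: dict[Bipartition, float | None]):
        self.leaves = frozenset(leaves)
        self.clades = dict(clades)
        self.newick: str | None = None

    def support_of(self, b: Bipartition) -> float | None:
        return self.clades.get(b)


def parse_tree(newick: str) -> SupportedTree:
    """Parse newick text (or a path to it) into a SupportedTree.

    Internal-node labels are read as bootstrap percentages when numeric;
    trees without labels yield supports of None (absent, not zero).
    Unrooted semantics: mirror bipartitions are merged, keeping the
    maximum attached support.
    """
    text = newick
    p = Path(newick)
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as e:  # dendropy raises several parse error types
        raise DegenkitError(f"malformed newick: {e}") from e
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise DegenkitError("duplicate leaf label in tree")
    leaves = frozenset(labels)
    clades: dict[Bipartition, float | None] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        inside = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        outside = leaves - inside
        if not outside:
            continue
        b = Bipartition(inside, outside)
        if not b.is_informative:
            continue
        support = None
        if nd.label is not None:
            try:
                support = float(nd.label)
            except ValueError:
                support = None
        prev = clades.get(b)
        if b not in clades or (support is not None and (prev is None or support > prev)):
            clades[b] = support
    st = SupportedTree(leaves, clades)
    st.newick = text.strip()
    return st


@dataclass
class SupportComparison:
    """Counts from matching a candidate bootstrap analysis to a reference."""

    n_strong_match: int
    n_conflict: int
    n_strong_conflict: int
    thresholds: tuple[float, float]
    strong_matches: list[tuple[Bipartition, float]]
    conflicts: list[tuple[Bipartition, float]]


def classify_support(
    reference: SupportedTree,
    candidate: SupportedTree,
    strong: float = 80.0,
    report: float = 50.0,
) -> SupportComparison:
    """Count strongly supporting / conflicting candidate nodes.

    The reference is first restricted to the candidate's leaves. A
    candidate node is matched by bipartition identity against reference
    nodes whose own support is >= ``strong``; conflict means support
    >= ``report`` with no such match (strong conflict: >= ``strong``).
    """
    if not (candidate.leaves & reference.leaves):
        raise DegenkitError("candidate and reference share no leaves")
    if not candidate.leaves <= reference.leaves:
        raise DegenkitError("candidate leaves must be a subset of reference leaves")
    strong_ref: set[Bipartition] = set()
    for b, s in reference.clades.items():
        if s is None or s < strong:
            continue
        rb = b.restrict(candidate.leaves)
        if rb is not None and rb.is_informative:
            strong_ref.add(rb)
    strong_matches: list[tuple[Bipartition, float]] = []
    conflicts: list[tuple[Bipartition, float]] = []
    n_strong_conflict = 0
    for b, s in candidate.clades.items():
        if s is None:
            continue
        if b in strong_ref:
            if s >= strong:
                strong_matches.append((b, s))
        elif s >= report:
            conflicts.append((b, s))
            if s >= strong:
                n_strong_conflict += 1
    return SupportComparison(
        n_strong_match=len(strong_matches),
        n_conflict=len(conflicts),
        n_strong_conflict=n_strong_conflict,
        thresholds=(strong, report),
        strong_matches=sorted(strong_matches, key=lambda t: -t[1]),
        conflicts=sorted(conflicts, key=lambda t: -t[1]),
    )


def genes_supporting_nodes(
    reference: SupportedTree,
    single_gene_trees: Iterable[SupportedTree],
    threshold: float = 75.0,
) -> dict[Bipartition, int]:
    """Per reference node, how many gene analyses recover it at >= threshold.

    Each reference bipartition is restricted to the gene's taxon sample
    before matching, so genes missing taxa can still support a node.
    """
    counts: dict[Bipartition, int] = {b: 0 for b in reference.clades}
    for gt in single_gene_trees:
        if not gt.leaves <= reference.leaves:
            raise DegenkitError("gene-tree leaves must be a subset of reference leaves")
        for b in counts:
            rb = b.restrict(gt.leaves)
            if rb is None or not rb.is_informative:
                continue
            s = gt.clades.get(rb)
            if s is not None and s >= threshold:
                counts[b] += 1
    return counts


@dataclass(frozen=True)
class UtilityRecord:
    """Per-gene phylogenetic-utility statistic."""

    gene_id: str
    G: int
    L: int
    m: int
    utility: float


def utility(G: int, L: int, m: int, total_taxa: int = 80) -> float:
    """U = (G / (L x 1e-3)) * (total_taxa / (total_taxa - m))."""
    if L <= 0:
        raise ValueError("fragment length must be positive")
    if not (0 <= m < total_taxa):
        raise ValueError("missing-taxon count must satisfy 0 <= m < total taxa")
    return (G / (L * 1e-3)) * (total_taxa / (total_taxa - m))


def missing_taxon_count(m: NucMatrix, fragment: str) -> int:
    """Taxa whose sequence for the fragment is 100% missing symbols."""
    cols = m.charsets[fragment]
    return sum(1 for r in m.rows if all(r[c] in MISSING for c in cols))


def score_gene(
    gene_id: str,
    reference: SupportedTree,
    gene_tree: SupportedTree,
    length: int,
    missing: int,
    threshold: float = 75.0,
    total_taxa: int = 80,
) -> UtilityRecord:
    """UtilityRecord for one gene: count recovered reference nodes, score."""
    G = 0
    for b in reference.clades:
        rb = b.restrict(gene_tree.leaves)
        if rb is None or not rb.is_informative:
            continue
        s = gene_tree.clades.get(rb)
        if s is not None and s >= threshold:
            G += 1
    return UtilityRecord(gene_id, G, length, missing, utility(G, length, missing, total_taxa))


class TrendFit(NamedTuple):
    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float


def fit_utility_trend(records: list[UtilityRecord], rates) -> TrendFit:
    """OLS of utility on nonsynonymous rate with coefficient standard errors.

    ``rates`` is a RateTable (or any object with a ``rates`` mapping
    gene_id -> rate).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to fit a trend")
    rate_map = rates.rates if hasattr(rates, "rates") else dict(rates)
    x = np.array([rate_map[r.gene_id] for r in records], dtype=float)
    y = np.array([r.utility for r in records], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in rates")
    fit = stats.linregress(x, y)
    return TrendFit(fit.slope, fit.intercept, fit.stderr, fit.intercept_stderr)
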