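"""Synthetic in-frame codon alignments with known structure.

The generator emulates the statistical contrasts the toolkit exists to
detect in real protein-coding supermatrices: a conservative
nonsynonymous replacement process along a known tree, a much faster
synonymous process confined to within-family codon exchanges whose
third-position equilibrium frequencies differ between designated taxon
groups (shared compositional bias), per-fragment missing taxa, and
planted clean or staggered deletions.

The model is deliberately a two-layer approximation rather than a full
codon model: amino-acid states change at the nonsynonymous rate (branch
lengths are expected nonsynonymous substitutions per codon), and the
codon realising each amino acid is re-drawn within the family at
``syn_rate_multiplier`` times that rate, weighted by the lineage's
third-position bias. Each site carries a neutral third-position allele
that only synonymous events update; a nonsynonymous event re-uses it
whenever the new family allows, so with the synonymous process switched
off, third positions of fourfold codons are invariant across the tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from degenkit.degeneracy import STANDARD_CODE
from degenkit.errors import DegenkitError
from degenkit.matrix_io import NucMatrix

_FAMILIES = {
    fam: codons for fam, codons in STANDARD_CODE.families.items() if fam != "stop"
}
_FAMILY_NAMES = sorted(_FAMILIES)
_NT3_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class IndelPlanEntry:
    """A deletion to plant: fragment index, codon interval, bearer taxa."""

    fragment: int
    codon_start: int
    codon_end: int  # half-open, in codons
    taxa: tuple[str, ...]


@dataclass
class SimSpec:
    """Recipe for one synthetic supermatrix.

    ``newick`` carries the generating tree with branch lengths in
    expected nonsynonymous substitutions per codon; ``groups`` assigns
    taxa to compositional-bias groups and ``nt3_bias`` gives each group
    its target third-position A/C/G/T frequencies. ``missing_taxa`` maps
    fragment index to taxa rendered entirely missing ('?') there.
    """

    newick: str
    n_codons: int = 60
    n_fragments: int = 12
    syn_rate_multiplier: float = 10.0
    nt3_bias: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    missing_taxa: dict[int, tuple[str, ...]] = field(default_factory=dict)
    indel_plan: list[IndelPlanEntry] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.syn_rate_multiplier < 0:
            raise DegenkitError("syn_rate_multiplier must be non-negative")
        for g, f in self.nt3_bias.items():
            if abs(sum(f) - 1.0) > 1e-6:
                raise DegenkitError(f"bias frequencies for group {g!r} must sum to 1")
        for e in self.indel_plan:
            if not (0 <= e.codon_start < e.codon_end <= self.n_codons):
                raise DegenkitError("indel interval outside fragment")
            if not (0 <= e.fragment < self.n_fragments):
                raise DegenkitError("indel fragment index out of range")

    def to_json(self) -> str:
        d = asdict(self)
        d["indel_plan"] = [asdict(e) for e in self.indel_plan]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimSpec":
        d = json.loads(text)
        d["indel_plan"] = [IndelPlanEntry(**{**e, "taxa": tuple(e["taxa"])}) for e in d.get("indel_plan", [])]
        d["nt3_bias"] = {k: tuple(v) for k, v in d.get("nt3_bias", {}).items()}
        d["groups"] = {k: tuple(v) for k, v in d.get("groups", {}).items()}
        d["missing_taxa"] = {int(k): tuple(v) for k, v in d.get("missing_taxa", {}).items()}
        return cls(**d)


def fragment_name(i: int) -> str:
    return f"frag{i + 1:02d}"


def _codon_weights(codons: tuple[str, ...], bias: np.ndarray | None) -> np.ndarray:
    if bias is None:
        return np.full(len(codons), 1.0 / len(codons))
    w = np.array([bias[_NT3_INDEX[c[2]]] + 1e-6 for c in codons])
    return w / w.sum()


def simulate_alignment(spec: SimSpec) -> NucMatrix:
    """Evolve codon sequences along the tree; return an in-frame matrix.

    Deterministic given the spec's seed. Fragments are emitted as
    contiguous charsets frag01..fragNN; taxa listed in ``missing_taxa``
    get all-'?' rows for those fragments.
    """
    tree = dendropy.Tree.get(data=spec.newick, schema="newick")
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(taxa)) != len(taxa):
        raise DegenkitError("duplicate taxon label in tree")
    group_of = {t: g for g, members in spec.groups.items() for t in members}
    bias_of = {g: np.asarray(f, dtype=float) for g, f in spec.nt3_bias.items()}

    def node_bias(nd) -> np.ndarray | None:
        tips = {lf.taxon.label for lf in nd.leaf_iter()}
        gs = {group_of.get(t) for t in tips}
        if len(gs) == 1:
            (g,) = gs
            if g is not None and g in bias_of:
                return bias_of[g]
        return None

    rng = np.random.default_rng(spec.seed)
    tip_codons: dict[str, list[str]] = {t: [] for t in taxa}
    for _ in range(spec.n_fragments):
        root_state: list[str] = []
        for _ in range(spec.n_codons):
            fam = _FAMILY_NAMES[rng.integers(len(_FAMILY_NAMES))]
            codons = _FAMILIES[fam]
            root_state.append(codons[rng.integers(len(codons))])
        states = {tree.seed_node: (root_state, [c[2] for c in root_state])}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            b = nd.edge.length or 0.0
            p_ns = 1.0 - np.exp(-b)
            p_syn = 1.0 - np.exp(-spec.syn_rate_multiplier * b)
            bias = node_bias(nd)
            parent_codons, parent_pref = states[nd.parent_node]
            state = list(parent_codons)
            pref = list(parent_pref)
            ns_hits = rng.random(spec.n_codons) < p_ns
            syn_hits = rng.random(spec.n_codons) < p_syn
            for i in range(spec.n_codons):
                codon = state[i]
                fam = STANDARD_CODE.family_of[codon]
                if ns_hits[i]:
                    others = [f for f in _FAMILY_NAMES if f != fam]
                    fam = others[rng.integers(len(others))]
                    # re-use the neutral third-position allele if possible
                    cands = tuple(
                        c for c in _FAMILIES[fam] if c[2] == pref[i]
                    ) or _FAMILIES[fam]
                    w = _codon_weights(cands, bias if len(cands) > 1 else None)
                    codon = cands[rng.choice(len(cands), p=w)]
                if syn_hits[i] and len(_FAMILIES[fam]) > 1:
                    cands = _FAMILIES[fam]
                    w = _codon_weights(cands, bias)
                    codon = cands[rng.choice(len(cands), p=w)]
                    pref[i] = codon[2]
                state[i] = codon
            states[nd] = (state, pref)
        for t in taxa:
            lf = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label == t
            )
            tip_codons[t].append("".join(states[lf][0]))

    frag_len = 3 * spec.n_codons
    rows = []
    for t in taxa:
        parts = []
        for fi in range(spec.n_fragments):
            if t in spec.missing_taxa.get(fi, ()):
                parts.append("?" * frag_len)
            else:
                parts.append(tip_codons[t][fi])
        rows.append("".join(parts))
    charsets = {
        fragment_name(fi): tuple(range(fi * frag_len, (fi + 1) * frag_len))
        for fi in range(spec.n_fragments)
    }
    return NucMatrix(taxa, rows, charsets, fragments=tuple(charsets))


def inject_indels(m: NucMatrix, spec: SimSpec) -> NucMatrix:
    """Plant the planned deletions ('-' over whole codons) into the matrix.

    Raises if a planned deletion would overwrite an existing gap for the
    same taxon; different taxa may overlap (that is how staggered decoys
    for negative tests are planted: two entries with unequal bounds).
    """
    rows = [list(r) for r in m.rows]
    frag_len = 3 * spec.n_codons
    for e in spec.indel_plan:
        cols = range(e.fragment * frag_len + 3 * e.codon_start,
                     e.fragment * frag_len + 3 * e.codon_end)
        for t in e.taxa:
            ti = m.taxa.index(t)
            if any(rows[ti][c] == "-" for c in cols):
                raise DegenkitError(f"planned indel overlaps existing gap for {t}")
            for c in cols:
                rows[ti][c] = "-"
    out = m.take(range(m.n_cols), rows=["".join(r) for r in rows])
    return out


def default_spec(
    n_taxa: int = 24,
    seed: int = 0,
    n_fragments: int = 12,
    n_codons: int = 60,
    syn_rate_multiplier: float = 10.0,
    biased: bool = True,
) -> SimSpec:
    """Study-like conditions at desk scale.

    A random birth-death tree over ``n_taxa`` tips scaled to a root-tip
    depth of ~0.4 nonsynonymous substitutions per codon; two
    compositional groups interleaved across the tree (so bias crosscuts
    phylogeny) with GC-rich vs AT-rich third-position targets; one
    fragment with a quarter of the taxa missing.
    """
    import random as _random

    from dendropy.simulate import treesim

    taxon_ns = dendropy.TaxonNamespace([f"t{i + 1:02d}" for i in range(n_taxa)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxon_ns,
        rng=_random.Random(seed),
    )
    depth = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = 0.4 * edge.length / depth
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    taxa = [f"t{i + 1:02d}" for i in range(n_taxa)]
    groups = {"gc": tuple(taxa[0::2]), "at": tuple(taxa[1::2])}
    bias = (
        {"gc": (0.05, 0.45, 0.45, 0.05), "at": (0.45, 0.05, 0.05, 0.45)}
        if biased
        else {}
    )
    return SimSpec(
        newick=newick,
        n_codons=n_codons,
        n_fragments=n_fragments,
        syn_rate_multiplier=syn_rate_multiplier,
        nt3_bias=bias,
        groups=groups if biased else {},
        missing_taxa={0: tuple(taxa[: n_taxa // 4])},
        seed=seed,
    )
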