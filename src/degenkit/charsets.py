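"""Named character subsets and rate-based gene bins.

Builds the standard subsets used to dissect synonymous from
nonsynonymous signal in an in-frame supermatrix:

- ``nt1``/``nt2``/``nt3``: codon-position columns (frame-local per
  gene fragment).
- ``LRall1``/``noLRall1``: first-position columns that do / do not
  potentially encode leucine or arginine in any taxon — Leu and Arg are
  the only amino acids with synonymous variation at the first position.
- ``noLRall1nt2`` and ``LRall1nt3``: the complementary split of the
  whole matrix into a mostly-nonsynonymous and a synonymous-enriched
  half.
- degen1 variants and ``nt3_4foldsynon``.

Also bins gene fragments into contiguous rate classes of approximately
equal character counts, given a nonsynonymous-rate ranking table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from degenkit.degeneracy import (
    IUPAC_SETS,
    STANDARD_CODE,
    GeneticCode,
    degen1_matrix,
    fourfold_synon_matrix,
)
from degenkit.errors import CharsetError, FrameError
from degenkit.matrix_io import CharIndexSet, NucMatrix, extract_submatrix

NAMED_SETS = (
    "nt123",
    "nt1",
    "nt2",
    "nt3",
    "LRall1",
    "noLRall1",
    "LRall1nt3",
    "noLRall1nt2",
    "nt123_degen1",
    "nt3_degen1",
    "LRall1nt3_degen1",
    "nt3_4foldsynon",
)


@dataclass(frozen=True)
class RateTable:
    """Per-fragment nonsynonymous-rate ranking (rank 1 = fastest)."""

    ranks: dict[str, int]
    rates: dict[str, float]

    def __post_init__(self) -> None:
        rk = sorted(self.ranks.values())
        if rk != list(range(1, len(rk) + 1)):
            raise ValueError("ranks must be unique and contiguous from 1")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_rates(cls, rates: dict[str, float]) -> "RateTable":
        """Rank fragments by descending rate; ties broken by name."""
        order = sorted(rates, key=lambda n: (-rates[n], n))
        return cls({n: i + 1 for i, n in enumerate(order)}, dict(rates))

    @classmethod
    def from_tsv(cls, path, fragment_names: list[str] | None = None) -> "RateTable":
        """Read a two-column (fragment_id, rate) tab-separated table.

        An integer first column is taken as the rank itself (1 = fastest),
        optionally mapped onto ``fragment_names`` ordered by rank; a
        string first column is taken as fragment names with ranks derived
        from descending rate. A header row is detected and skipped.
        """
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        try:
            float(df.iloc[0, 1])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        first = df.iloc[:, 0].astype(str)
        rates_col = df.iloc[:, 1].astype(float)
        if first.str.fullmatch(r"\d+").all():
            ranks = first.astype(int).tolist()
            if fragment_names is None:
                names = [str(r) for r in ranks]
            else:
                names = [fragment_names[r - 1] for r in ranks]
            return cls(dict(zip(names, ranks)), dict(zip(names, rates_col)))
        return cls.from_rates(dict(zip(first, rates_col)))

    def by_rank(self) -> list[str]:
        return sorted(self.ranks, key=self.ranks.get)


def codon_position_columns(m: NucMatrix, pos: int) -> CharIndexSet:
    """All columns at codon position ``pos`` (1, 2 or 3)."""
    if pos not in (1, 2, 3):
        raise ValueError("pos must be 1, 2 or 3")
    if m.n_cols and not any(m.positions):
        raise FrameError("matrix carries no reading-frame information")
    idx = tuple(c for c in range(m.n_cols) if m.positions[c] == pos)
    return CharIndexSet(f"nt{pos}", idx)


def _codon_is_lr(column_codons: list[str], code: GeneticCode) -> bool:
    for codon in column_codons:
        sets = [IUPAC_SETS.get(s, frozenset()) for s in codon]
        if any(not s for s in sets):  # gap/missing codon never triggers
            continue
        for combo in itertools.product(*sets):
            if code.translate("".join(combo)) in ("L", "R"):
                return True
    return False


def lr_classify_columns(
    m: NucMatrix, code: GeneticCode = STANDARD_CODE
) -> tuple[CharIndexSet, CharIndexSet]:
    """Partition nt1 columns into LRall1 and noLRall1.

    A first-position column belongs to LRall1 iff at least one taxon's
    codon there has an ambiguity resolution translating to Leu or Arg
    ("potential synonymous change at nt1"). Orphan first-position columns
    detached from any codon fall to noLRall1.
    """
    nt1 = codon_position_columns(m, 1)
    lr: set[int] = set()
    for tri in m.codons:
        i, j, k = tri
        codons = [r[i] + r[j] + r[k] for r in m.rows]
        if _codon_is_lr(codons, code):
            lr.add(i)
    lrall1 = tuple(c for c in nt1 if c in lr)
    nolrall1 = tuple(c for c in nt1 if c not in lr)
    return CharIndexSet("LRall1", lrall1), CharIndexSet("noLRall1", nolrall1)


def build_named_set(m: NucMatrix, name: str) -> NucMatrix:
    """Build one of the named character-set matrices from a masked matrix.

    Degenerate variants apply the degeneracy transform on the full codon
    context first and slice afterwards; the two orders agree because the
    transform is local to each codon.
    """
    if name not in NAMED_SETS:
        raise CharsetError(f"unknown named set {name!r}; one of {NAMED_SETS}")
    if m.exclusion:
        raise CharsetError("apply_exclusion before building named sets")
    if name == "nt123":
        return m.take(range(m.n_cols))
    if name == "nt123_degen1":
        return degen1_matrix(m)
    if name == "nt3_4foldsynon":
        return fourfold_synon_matrix(m)
    if name in ("nt1", "nt2", "nt3"):
        return extract_submatrix(m, codon_position_columns(m, int(name[2])))
    if name in ("LRall1", "noLRall1"):
        lr, nolr = lr_classify_columns(m)
        return extract_submatrix(m, lr if name == "LRall1" else nolr)
    if name in ("LRall1nt3", "noLRall1nt2"):
        lr, nolr = lr_classify_columns(m)
        if name == "LRall1nt3":
            cols = sorted(set(lr) | set(codon_position_columns(m, 3)))
        else:
            cols = sorted(set(nolr) | set(codon_position_columns(m, 2)))
        return extract_submatrix(m, cols)
    if name in ("nt3_degen1", "LRall1nt3_degen1"):
        deg = degen1_matrix(m)
        base = "nt3" if name == "nt3_degen1" else "LRall1nt3"
        sub = build_named_set(deg, base) if base == "nt3" else None
        if sub is None:
            # LR membership must be judged on the raw codons, not the
            # degenerate ones, so compute columns on m and slice deg.
            lr, _ = lr_classify_columns(m)
            cols = sorted(set(lr) | set(codon_position_columns(m, 3)))
            sub = extract_submatrix(deg, cols)
        return sub
    raise AssertionError("unreachable")


def rate_bins(m: NucMatrix, rt: RateTable, k: int) -> list[CharIndexSet]:
    """Split fragments, in rank order, into k contiguous character bins.

    Split points are chosen to minimise the maximum deviation of bin
    character counts from total/k (ties toward earlier split points).
    Returns bins fastest-first; each carries its fragment names.
    """
    order = rt.by_rank()
    missing = [n for n in order if n not in m.charsets]
    if missing:
        raise CharsetError(f"fragments missing from matrix: {missing}")
    unranked = [n for n in m.fragments if n not in rt.ranks]
    if unranked:
        raise CharsetError(f"fragments without a rank: {unranked}")
    if k > len(order):
        raise ValueError("more bins than fragments")
    sizes = [len(m.charsets[n]) for n in order]
    total = sum(sizes)
    target = total / k
    best: tuple[float, tuple[int, ...]] | None = None
    for cuts in itertools.combinations(range(1, len(order)), k - 1):
        bounds = (0, *cuts, len(order))
        dev = max(
            abs(sum(sizes[a:b]) - target) for a, b in zip(bounds, bounds[1:])
        )
        key = (dev, cuts)
        if best is None or key < best:
            best = key
    bounds = (0, *best[1], len(order))
    bins = []
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        frags = tuple(order[a:b])
        cols = tuple(sorted(c for n in frags for c in m.charsets[n]))
        bins.append(CharIndexSet(f"ratebin{i + 1}", cols, fragments=frags))
    return bins


def explicit_bins(m: NucMatrix, rt: RateTable, rank_groups: list[tuple[int, int]]) -> list[CharIndexSet]:
    """Bins from explicit inclusive rank ranges, e.g. [(1, 37), (38, 68)]."""
    order = rt.by_rank()
    bins = []
    for i, (a, b) in enumerate(rank_groups):
        frags = tuple(order[a - 1 : b])
        cols = tuple(sorted(c for n in frags for c in m.charsets[n]))
        bins.append(CharIndexSet(f"ratebin{i + 1}", cols, fragments=frags))
    return bins
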