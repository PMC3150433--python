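"""Aligned nucleotide matrices with character-set metadata.

The central container is :class:`NucMatrix`: a taxa-labelled, column-aligned
nucleotide matrix carrying named character sets (typically one per gene
fragment of a concatenated supermatrix), an exclusion mask of ambiguously
aligned columns, and explicit codon bookkeeping (per-column codon position
and per-codon column triples) so that downstream codon-level operations
survive slicing, masking and shuffling without re-framing.

Coordinates are 0-based half-open internally; NEXUS I/O converts to and
from the format's 1-based inclusive ranges (including ``a-b\\3`` step
notation). NEXUS parsing is delegated to Bio.Nexus; EXSET statements,
which Bio.Nexus does not accept, are extracted by a small pre-pass using
the same range grammar.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Nexus import Nexus

from degenkit.errors import AlignmentError, CharsetError, FrameError

#: Symbols treated as missing data for composition and degeneracy purposes.
MISSING = frozenset("-?")

#: Valid matrix symbols: bases, IUPAC ambiguity, gap and missing.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")


@dataclass(frozen=True)
class CharIndexSet:
    """A named, strictly increasing set of 0-based column indices."""

    name: str
    indices: tuple[int, ...]
    fragments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        idx = self.indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            object.__setattr__(self, "indices", tuple(sorted(set(idx))))

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


class NucMatrix:
    """Aligned nucleotide matrix with charsets, exclusion mask and codon map.

    Parameters
    ----------
    taxa, rows
        Parallel sequences: unique taxon labels and equal-length sequence
        strings over ``ALPHABET``.
    charsets
        Map of set name to 0-based column indices.
    exclusion
        Columns flagged as ambiguously aligned, to be removed by
        :func:`apply_exclusion`.
    fragments
        Names of the charsets that are gene fragments. Fragments define the
        reading frame: within each fragment the first column is codon
        position 1. Fragments must be pairwise disjoint and a whole number
        of codons. When omitted, every charset that satisfies both
        requirements (greedily, in order) is taken as a fragment; with no
        charsets at all the whole matrix is treated as one in-frame block
        if its length allows.
    positions, codons
        Explicit per-column codon positions (1/2/3, 0 = unknown) and codon
        column triples. Normally derived from ``fragments``; slicing and
        masking operations pass them through so derived matrices keep codon
        provenance.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Sequence[str],
        charsets: Mapping[str, Iterable[int]] | None = None,
        exclusion: Iterable[int] = (),
        fragments: Sequence[str] | None = None,
        positions: Sequence[int] | None = None,
        codons: Sequence[tuple[int, int, int]] | None = None,
        origin: Sequence[int] | None = None,
    ) -> None:
        self.taxa = list(taxa)
        self.rows = [r.upper() for r in rows]
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon label")
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa and rows differ in length")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise AlignmentError("ragged rows: unequal sequence lengths")
            bad = set("".join(self.rows)) - ALPHABET
            if bad:
                raise AlignmentError(f"illegal symbols in matrix: {sorted(bad)}")
            self.n_cols = n
        else:
            self.n_cols = 0

        self.charsets: dict[str, tuple[int, ...]] = {}
        for name, idx in (charsets or {}).items():
            t = tuple(sorted(set(int(i) for i in idx)))
            if t and (t[0] < 0 or t[-1] >= self.n_cols):
                raise CharsetError(f"charset {name!r} index out of bounds")
            self.charsets[name] = t
        self.exclusion = tuple(sorted(set(int(i) for i in exclusion)))
        if self.exclusion and (self.exclusion[0] < 0 or self.exclusion[-1] >= self.n_cols):
            raise CharsetError("exclusion index out of bounds")

        if fragments is None:
            fragments = self._autodetect_fragments()
        else:
            self._validate_fragments(fragments)
        self.fragments = tuple(fragments)

        if positions is not None:
            self.positions = tuple(positions)
            self.codons = tuple(tuple(c) for c in (codons or ()))
        else:
            self.positions, self.codons = self._derive_frame()
        if len(self.positions) != self.n_cols:
            raise CharsetError("positions length must equal column count")
        self.origin = tuple(origin) if origin is not None else tuple(range(self.n_cols))

    # -- frame bookkeeping -------------------------------------------------

    def _validate_fragments(self, fragments: Sequence[str]) -> None:
        seen: set[int] = set()
        for name in fragments:
            if name not in self.charsets:
                raise CharsetError(f"fragment charset {name!r} not defined")
            cols = self.charsets[name]
            if len(cols) % 3 != 0:
                raise FrameError(f"fragment {name!r} has {len(cols)} columns, not a codon multiple")
            if seen & set(cols):
                raise CharsetError(f"fragment {name!r} overlaps another fragment")
            seen.update(cols)

    def _autodetect_fragments(self) -> list[str]:
        picked: list[str] = []
        seen: set[int] = set()
        for name, cols in self.charsets.items():
            if cols and len(cols) % 3 == 0 and not (seen & set(cols)):
                picked.append(name)
                seen.update(cols)
        return picked

    def _derive_frame(self) -> tuple[tuple[int, ...], tuple[tuple[int, int, int], ...]]:
        positions = [0] * self.n_cols
        codons: list[tuple[int, int, int]] = []
        if self.fragments:
            for name in self.fragments:
                cols = self.charsets[name]
                for k, c in enumerate(cols):
                    positions[c] = k % 3 + 1
                for k in range(0, len(cols), 3):
                    codons.append((cols[k], cols[k + 1], cols[k + 2]))
        elif self.n_cols % 3 == 0:
            positions = [(c % 3) + 1 for c in range(self.n_cols)]
            codons = [(c, c + 1, c + 2) for c in range(0, self.n_cols, 3)]
        return tuple(positions), tuple(codons)

    # -- basic access ------------------------------------------------------

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, c: int) -> str:
        return "".join(r[c] for r in self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NucMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.rows == other.rows
            and self.charsets == other.charsets
            and self.exclusion == other.exclusion
        )

    def __repr__(self) -> str:
        return (
            f"NucMatrix({len(self.taxa)} taxa x {self.n_cols} cols, "
            f"{len(self.charsets)} charsets, {len(self.exclusion)} excluded)"
        )

    # -- column selection core ---------------------------------------------

    def take(self, cols: Sequence[int], rows: Sequence[str] | None = None) -> "NucMatrix":
        """Column-select (and optionally reorder) into a new matrix.

        Charsets, exclusion, positions and codon triples are remapped
        through the selection; codons with any column dropped are detached.
        ``rows`` optionally overrides sequence content (used by masking).
        """
        cols = list(cols)
        if cols and (min(cols) < 0 or max(cols) >= self.n_cols):
            raise CharsetError("column index out of range")
        remap = {old: new for new, old in enumerate(cols)}
        src = rows if rows is not None else self.rows
        new_rows = ["".join(r[c] for c in cols) for r in src]
        new_charsets = {
            name: tuple(sorted(remap[c] for c in idx if c in remap))
            for name, idx in self.charsets.items()
        }
        new_excl = tuple(sorted(remap[c] for c in self.exclusion if c in remap))
        new_pos = tuple(self.positions[c] for c in cols)
        new_codons = tuple(
            tuple(remap[c] for c in tri)
            for tri in self.codons
            if all(c in remap for c in tri)
        )
        new_frags = tuple(n for n in self.fragments if new_charsets.get(n))
        m = NucMatrix(
            self.taxa,
            new_rows,
            new_charsets,
            new_excl,
            fragments=(),
            positions=new_pos,
            codons=new_codons,
            origin=tuple(self.origin[c] for c in cols),
        )
        m.fragments = new_frags
        return m


# -- operations ------------------------------------------------------------

_RANGE_RE = re.compile(r"(\d+)(?:\s*-\s*(\d+|\.))?(?:\s*\\\s*(\d+))?")


def _parse_nexus_ranges(text: str, n_cols: int) -> tuple[int, ...]:
    """Parse a NEXUS 1-based inclusive range list into 0-based indices."""
    out: set[int] = set()
    for tok in text.replace(",", " ").split():
        m = _RANGE_RE.fullmatch(tok)
        if not m:
            raise CharsetError(f"cannot parse range token {tok!r}")
        a = int(m.group(1))
        b = n_cols if m.group(2) in (".",) else int(m.group(2) or a)
        step = int(m.group(3) or 1)
        if a < 1 or b > n_cols:
            raise CharsetError(f"range {tok!r} out of bounds for {n_cols} columns")
        out.update(range(a - 1, b, step))
    return tuple(sorted(out))


_EXSET_RE = re.compile(
    r"^\s*EXSET\s+(?:\*\s*)?(?P<name>[\w.+-]+)\s*=\s*(?P<body>[^;]+);",
    re.IGNORECASE | re.MULTILINE,
)


def read_nexus(
    path,
    fragments: Sequence[str] | None = None,
    exclusion_charset: str | None = None,
) -> NucMatrix:
    """Read a NEXUS alignment with CHARSET (and optional EXSET) metadata.

    ``exclusion_charset`` names a charset to be interpreted as the
    exclusion mask instead of (or in addition to) EXSET statements, for
    files that publish their mask as an ordinary charset.
    """
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    exset_body = None
    m = _EXSET_RE.search(text)
    if m:
        exset_body = m.group("body")
        text = text[: m.start()] + text[m.end():]
    try:
        nex = Nexus.Nexus(io.StringIO(text))
    except Nexus.NexusError as e:
        raise AlignmentError(f"NEXUS parse failure: {e}") from e
    if nex.matrix is None or not nex.taxlabels:
        raise AlignmentError("no DATA/CHARACTERS matrix in NEXUS file")
    taxa = list(nex.taxlabels)
    rows = [str(nex.matrix[t]).upper() for t in taxa]
    charsets = {name: tuple(sorted(cols)) for name, cols in (nex.charsets or {}).items()}
    n_cols = len(rows[0]) if rows else 0
    exclusion: tuple[int, ...] = ()
    if exset_body is not None:
        exclusion = _parse_nexus_ranges(exset_body, n_cols)
    if exclusion_charset is not None:
        if exclusion_charset not in charsets:
            raise CharsetError(f"exclusion charset {exclusion_charset!r} not defined")
        exclusion = tuple(sorted(set(exclusion) | set(charsets.pop(exclusion_charset))))
    return NucMatrix(taxa, rows, charsets, exclusion, fragments=fragments)


def apply_exclusion(m: NucMatrix) -> NucMatrix:
    """Remove the masked columns; re-index all charsets.

    Exactly ``len(m.exclusion)`` columns are removed. When the mask splits
    a codon, the codon's surviving columns are set to ``N`` and detached
    from the codon map rather than silently re-framed, preserving codon
    semantics for downstream degeneracy operations.
    """
    if not m.exclusion:
        out = m.take(range(m.n_cols))
        return out
    excluded = set(m.exclusion)
    rows = None
    broken_cols: set[int] = set()
    for tri in m.codons:
        hit = sum(1 for c in tri if c in excluded)
        if 0 < hit < 3:
            broken_cols.update(c for c in tri if c not in excluded)
    if broken_cols:
        rows = []
        for r in m.rows:
            chars = list(r)
            for c in broken_cols:
                chars[c] = "N"
            rows.append("".join(chars))
    keep = [c for c in range(m.n_cols) if c not in excluded]
    # detach broken codons by pre-filtering the codon map
    survivors = tuple(tri for tri in m.codons if not any(c in excluded for c in tri))
    trimmed = m.take(range(m.n_cols), rows=rows)
    trimmed.codons = survivors
    out = trimmed.take(keep)
    out.exclusion = ()
    return out


def extract_submatrix(m: NucMatrix, cols: CharIndexSet | Iterable[int]) -> NucMatrix:
    """Slice the named columns out of the matrix, preserving taxon order.

    Original column indices are retained in ``origin`` for provenance.
    """
    idx = list(cols.indices if isinstance(cols, CharIndexSet) else cols)
    return m.take(idx)


def _compact_ranges(indices: Sequence[int]) -> str:
    """Render 0-based indices as compact NEXUS 1-based inclusive ranges."""
    parts: list[str] = []
    run_start = prev = None
    for i in indices:
        if run_start is None:
            run_start = prev = i
        elif i == prev + 1:
            prev = i
        else:
            parts.append(f"{run_start + 1}" if run_start == prev else f"{run_start + 1}-{prev + 1}")
            run_start = prev = i
    if run_start is not None:
        parts.append(f"{run_start + 1}" if run_start == prev else f"{run_start + 1}-{prev + 1}")
    return " ".join(parts)


def write_matrix(m: NucMatrix, path, format: str = "nexus", wrap: int = 70) -> None:
    """Write the matrix as NEXUS (with SETS block), FASTA or relaxed PHYLIP."""
    fmt = format.lower()
    out = []
    if fmt == "nexus":
        out.append("#NEXUS")
        out.append("BEGIN DATA;")
        out.append(f"DIMENSIONS NTAX={len(m.taxa)} NCHAR={m.n_cols};")
        out.append("FORMAT DATATYPE=DNA MISSING=? GAP=-;")
        out.append("MATRIX")
        width = max((len(t) for t in m.taxa), default=0) + 2
        for t, r in zip(m.taxa, m.rows):
            out.append(f"{t:<{width}}{r}")
        out.append(";")
        out.append("END;")
        if m.charsets or m.exclusion:
            out.append("BEGIN SETS;")
            for name, idx in m.charsets.items():
                if idx:
                    out.append(f"CHARSET {name} = {_compact_ranges(idx)};")
            if m.exclusion:
                out.append(f"EXSET * mask = {_compact_ranges(m.exclusion)};")
            out.append("END;")
    elif fmt == "fasta":
        for t, r in zip(m.taxa, m.rows):
            out.append(f">{t}")
            out.extend(r[i : i + wrap] for i in range(0, len(r), wrap) or [""])
    elif fmt == "phylip":
        out.append(f" {len(m.taxa)} {m.n_cols}")
        for t, r in zip(m.taxa, m.rows):
            if re.search(r"[\s():;,\[\]]", t):
                raise AlignmentError(f"taxon label {t!r} illegal for PHYLIP")
            out.append(f"{t}  {r}")
    else:
        raise ValueError(f"unknown format {format!r}")
    Path(path).write_text("\n".join(out) + "\n")
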