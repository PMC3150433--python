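"""Genetic-code-driven codon classification and degen1 recoding.

degen1 replaces every codon by the maximally degenerate IUPAC codon of
its synonymous family, so that only nonsynonymous differences between
sequences remain informative: His CAT/CAC both become CAY, all six Leu
codons become YTN, all six Arg codons MGN. Serine's two codon boxes
(TCN and AGY) are kept as separate families because no single
substitution interconverts them; their difference stays visible after
recoding. Met (ATG) and Trp (TGG) are untouched — the only determinate
third-position symbols that survive recoding.

The fourfold-synonymous mask is the complementary construction: it keeps
third-position states only for codons of the strictly fourfold amino
acids (Ala, Gly, Pro, Thr, Val), where third-position change is purely
synonymous, and degenerates everything else to N.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

from Bio.Data import CodonTable, IUPACData

from degenkit.errors import FrameError
from degenkit.matrix_io import NucMatrix

logger = logging.getLogger(__name__)

#: Base sets for every symbol a codon may contain.
IUPAC_SETS: dict[str, frozenset[str]] = {
    s.upper(): frozenset(b.upper() for b in bases)
    for s, bases in IUPACData.ambiguous_dna_values.items()
}
IUPAC_SETS["-"] = frozenset()
IUPAC_SETS["?"] = frozenset()

#: Reverse lookup: base set -> single IUPAC symbol.
SET_TO_IUPAC: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_SETS.items() if v and k not in ("X",)
}
SET_TO_IUPAC[frozenset("ACGT")] = "N"

_AA3 = IUPACData.protein_letters_1to3

#: Amino acids whose codon family is strictly fourfold degenerate.
STRICT_FOURFOLD_AA = frozenset({"Ala", "Gly", "Pro", "Thr", "Val"})

_KIND_BY_SIZE = {1: "nondegenerate", 2: "twofold", 3: "threefold", 4: "fourfold", 6: "sixfold"}


class GeneticCode:
    """A codon table plus the synonymous-family partition used by degen1.

    Families group codons that can interconvert by synonymous change:
    one family per amino acid, except serine which splits into ``Ser1``
    (TCN) and ``Ser2`` (AGY). Stop codons form the ``stop`` family.
    """

    def __init__(self, table_id: int = 1) -> None:
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.table: dict[str, str] = dict(tbl.forward_table)
        self.stop_codons = tuple(tbl.stop_codons)
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.table.items()):
            if aa == "S":
                key = "Ser1" if codon.startswith("TC") else "Ser2"
            else:
                key = _AA3[aa]
            fams.setdefault(key, []).append(codon)
        fams["stop"] = sorted(self.stop_codons)
        self.families: dict[str, tuple[str, ...]] = {k: tuple(v) for k, v in fams.items()}
        self.family_of: dict[str, str] = {
            c: fam for fam, codons in self.families.items() for c in codons
        }

    def translate(self, codon: str) -> str | None:
        """Amino acid (1-letter) for a sense codon, None for a stop."""
        return self.table.get(codon)


STANDARD_CODE = GeneticCode(1)

_REGISTRY: dict[str, GeneticCode] = {"standard": STANDARD_CODE}


def register_code(name: str, code: GeneticCode) -> None:
    """Register an alternate genetic code for later lookup by name."""
    _REGISTRY[name] = code


def get_code(name: str = "standard") -> GeneticCode:
    return _REGISTRY[name]


def classify_codon(c: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Degeneracy-family label for an unambiguous sense codon.

    Returns e.g. ``fourfold(Ala)``, ``twofold(Ser2)``, ``threefold(Ile)``,
    ``sixfold(Leu)``, ``nondegenerate(Trp)`` or ``stop``. Leucine and
    arginine count their full six-codon families; serine is reported per
    codon box. Raises ``ValueError`` for ambiguous or non-codon input —
    use :func:`degen1_codon` for total behaviour.
    """
    c = c.upper()
    fam = code.family_of.get(c)
    if fam is None:
        raise ValueError(f"{c!r} is not an unambiguous codon")
    if fam == "stop":
        return "stop"
    if fam in ("Leu", "Arg"):
        return f"sixfold({fam})"
    return f"{_KIND_BY_SIZE[len(code.families[fam])]}({fam})"


class DegenMap:
    """Total, idempotent codon -> degenerate-codon mapping.

    Every sense codon maps to the per-position IUPAC union over its
    family (CAT -> CAY, TTA -> YTN, AGA -> MGN, ...). Stop codons and
    codons containing gap/missing symbols map to NNN. Ambiguous codons
    are resolved conservatively: if every resolution lands on the same
    degenerate codon it is emitted, otherwise NNN — except that codons
    already equal to a family image (e.g. YTN itself) are fixed points,
    which makes the map idempotent.
    """

    def __init__(self, code: GeneticCode = STANDARD_CODE) -> None:
        self.code = code
        self.family_image: dict[str, str] = {}
        for fam, codons in code.families.items():
            if fam == "stop":
                continue
            img = "".join(
                SET_TO_IUPAC[frozenset(c[i] for c in codons)] for i in range(3)
            )
            self.family_image[fam] = img
        self._images = frozenset(self.family_image.values()) | {"NNN"}
        self._plain: dict[str, str] = {
            c: self.family_image[fam] if fam != "stop" else "NNN"
            for c, fam in code.family_of.items()
        }
        self._warned_stop = False

    def __call__(self, codon: str) -> str:
        return self.map(codon)

    @lru_cache(maxsize=4096)
    def _map_ambiguous(self, codon: str) -> str:
        sets = [IUPAC_SETS.get(s, frozenset()) for s in codon]
        if any(not s for s in sets):  # gap or missing symbol
            return "NNN"
        outputs = set()
        for combo in itertools.product(*sets):
            out = self._plain["".join(combo)]
            outputs.add(out)
            if len(outputs) > 1:
                return "NNN"
        return outputs.pop()

    def map(self, codon: str) -> str:
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError("codon must have length 3")
        if codon in self._images:  # fixed points: keeps the map idempotent
            return codon
        hit = self._plain.get(codon)
        if hit is not None:
            if hit == "NNN" and not self._warned_stop:
                logger.warning("stop codon %s degenerated to NNN", codon)
                self._warned_stop = True
            return hit
        return self._map_ambiguous(codon)


STANDARD_DEGEN = DegenMap(STANDARD_CODE)


def degen1_codon(c: str, dm: DegenMap = STANDARD_DEGEN) -> str:
    """degen1 image of a single codon (total over gaps and ambiguity)."""
    return dm.map(c)


def degen1_matrix(m: NucMatrix, dm: DegenMap = STANDARD_DEGEN) -> NucMatrix:
    """Apply degen1 codon-wise to every row; dimensions and charsets kept.

    Requires codon structure (an in-frame matrix or one carrying codon
    provenance from slicing). Columns outside any codon — orphans left by
    a partial-codon mask — are left untouched.
    """
    if m.n_cols and not m.codons:
        raise FrameError("matrix has no codon structure; cannot degenerate")
    new_rows = []
    for r in m.rows:
        chars = list(r)
        for i, j, k in m.codons:
            out = dm.map(r[i] + r[j] + r[k])
            chars[i], chars[j], chars[k] = out[0], out[1], out[2]
        new_rows.append("".join(chars))
    out = m.take(range(m.n_cols))
    out.rows = new_rows
    return out


def fourfold_synon_cell(c: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Third-position symbol if the codon is strictly fourfold, else N.

    A codon qualifies when every resolution of its first two positions
    yields an amino acid whose whole family is fourfold degenerate
    (Ala, Gly, Pro, Thr, Val). Leu/Arg/Ser codons are excluded even when
    they sit in a fourfold box, because their families are sixfold.
    """
    c = c.upper()
    s1, s2 = IUPAC_SETS.get(c[0], frozenset()), IUPAC_SETS.get(c[1], frozenset())
    if not s1 or not s2:
        return "N"
    for b1, b2 in itertools.product(s1, s2):
        aa = code.translate(b1 + b2 + "A")
        if aa is None or _AA3.get(aa) not in STRICT_FOURFOLD_AA:
            return "N"
    return c[2]


def fourfold_synon_matrix(m: NucMatrix, code: GeneticCode = STANDARD_CODE) -> NucMatrix:
    """nt3-only matrix keeping third positions of strictly fourfold codons.

    One column per codon; all other cells are N. Fragment charsets are
    carried over, re-indexed to the codon grid.
    """
    if m.n_cols and not m.codons:
        raise FrameError("matrix has no codon structure")
    cols3 = [tri[2] for tri in m.codons]
    new_rows = []
    for r in m.rows:
        cells = []
        for i, j, k in m.codons:
            cells.append(fourfold_synon_cell(r[i] + r[j] + r[k], code))
        new_rows.append("".join(cells))
    sliced = m.take(cols3)
    out = NucMatrix(
        m.taxa,
        new_rows,
        charsets=sliced.charsets,
        fragments=(),
        positions=tuple(3 for _ in cols3),
        codons=(),
        origin=sliced.origin,
    )
    out.fragments = sliced.fragments
    return out
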