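import itertools

import pytest

from degenkit.matrix_io import NucMatrix, read_nexus
from degenkit.synthgen import default_spec, simulate_alignment

SMALL_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=9;
FORMAT DATATYPE=DNA MISSING=? GAP=-;
MATRIX
t1 ATGGCAGGT
t2 ATGGCGGGA
;
END;
BEGIN SETS;
CHARSET g1 = 1-6;
CHARSET g2 = 7-9;
CHARSET nt3_by_hand = 3-9\\3;
EXSET * mask = 4-6;
END;
"""


@pytest.fixture
def small_nexus_path(tmp_path):
    p = tmp_path / "small.nex"
    p.write_text(SMALL_NEXUS)
    return p


@pytest.fixture
def small_matrix(small_nexus_path):
    return read_nexus(small_nexus_path, fragments=["g1", "g2"])


def make_matrix(rows, taxa=None, **kw):
    taxa = taxa or [f"t{i + 1}" for i in range(len(rows))]
    return NucMatrix(taxa, rows, **kw)


@pytest.fixture(scope="session")
def sim_matrix():
    """Unbiased 12-taxon simulated supermatrix (4 fragments x 30 codons)."""
    spec = default_spec(n_taxa=12, seed=11, n_fragments=4, n_codons=30, biased=False)
    spec.missing_taxa = {}
    return simulate_alignment(spec)


ALL_CODONS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
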