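import pytest

from rawrphylo.io_formats import Alignment, parse_newick


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        (
            ("a", "AC-GT"),
            ("b", "ACGGT"),
            ("c", "A--GT"),
        )
    )


@pytest.fixture
def quartet_tree():
    return parse_newick("((a,b),(c,d));")


@pytest.fixture
def quartet_alt_tree():
    return parse_newick("((a,c),(b,d));")


@pytest.fixture
def five_taxon_trees():
    """Two binary 5-leaf trees sharing exactly one of their two
    non-trivial bipartitions."""
    t1 = parse_newick("(((a,b),c),(d,e));")  # splits ab|cde, de|abc
    t2 = parse_newick("(((a,b),d),(c,e));")  # splits ab|cde, ce|abd
    return t1, t2
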