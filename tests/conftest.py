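import pytest

import clavis


@pytest.fixture(scope="session")
def syagrus():
    return clavis.load_fixture("syagrus_key")


@pytest.fixture(scope="session")
def syagrus_taxon_matrix(syagrus):
    return clavis.induce_matrix(syagrus, level="taxon")


@pytest.fixture(scope="session")
def syagrus_occurrence_matrix(syagrus):
    return clavis.induce_matrix(syagrus, level="occurrence")


@pytest.fixture(scope="session")
def clades():
    return clavis.load_fixture("clades")


@pytest.fixture(scope="session")
def regions():
    return clavis.load_fixture("regions")


TOY_CHARACTERS = """\
char_id\tlabel\tkind\tstates\tunits\tsymbol\tdescription
color\tflower color\tcategorical\tred,blue,white\t\t\t
size\tleaf size\tquantitative\t\tcm\t\t
hairy\tpubescence\tbinary\t\t\t\t
"""

TOY_KEY = """\
# root: 1
couplet\tslot\tstatement\tpredicates\ttarget
1\ta\tflowers red\tcolor=red\tC:2
1\tb\tflowers blue or white\tcolor in {blue,white}\tC:3
2\ta\tleaves small\tsize<5\tT:Genus alpha
2\tb\tleaves large\tsize>=5\tT:Genus beta
3\ta\tplant hairy\thairy=present\tT:Genus gamma
3\tb\tplant glabrous\thairy=absent\tT:Genus delta
"""


@pytest.fixture()
def toy_key():
    key = clavis.parse_key(TOY_CHARACTERS, TOY_KEY)
    key.require_valid()
    return key


def make_key(couplet_rows: str, characters: str = TOY_CHARACTERS):
    """Build a key from raw key.tsv rows (header added automatically)."""
    header = "couplet\tslot\tstatement\tpredicates\ttarget\n"
    return clavis.parse_key(characters, header + couplet_rows)
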