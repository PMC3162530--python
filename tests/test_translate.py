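import pytest

from exonweaver.errors import ConfigurationError
from exonweaver.translate import (
    STOP,
    UNKNOWN,
    codons_for,
    revcomp,
    translate_cds,
    translate_codon,
)


@pytest.mark.parametrize(
    "codon,table,expected",
    [
        ("ATG", 1, "M"),
        ("TAA", 1, STOP),
        ("ANG", 1, UNKNOWN),
        ("NNN", 1, UNKNOWN),
        ("atg", 1, "M"),
        ("TAA", 6, "Q"),  # ciliate code reads TAA as glutamine
        ("TGA", 1, STOP),
        ("CTG", 1, "L"),
    ],
)
def test_translate_codon(codon, table, expected):
    assert translate_codon(codon, table) == expected


def test_unsupported_table_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        translate_codon("ATG", 9999)


def test_translate_cds_drops_partial_codon():
    assert translate_cds("ATGAAAT") == "MK"


def test_codons_for_roundtrip():
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        for codon in codons_for(aa, 1):
            assert translate_codon(codon, 1) == aa


def test_revcomp():
    assert revcomp("ATGC") == "GCAT"
    assert revcomp(revcomp("ACGTN")) == "ACGTN"
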