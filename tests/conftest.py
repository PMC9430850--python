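import hypothesis
import pytest

from ntcascan.genome import AnnotatedGenome, GeneFeature

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def toy_genome() -> AnnotatedGenome:
    """500 bp genome with one gene per strand."""
    seq = ("ACGT" * 125)[:500]
    return AnnotatedGenome(
        id="toy",
        sequence=seq,
        features=[
            GeneFeature("geneA", 101, 400, "+"),
            GeneFeature("geneB", 451, 480, "-"),
        ],
    )


TOY_GENBANK = """\
LOCUS       toyrec                   120 bp    DNA     linear   BCT 01-JAN-2020
DEFINITION  toy two-gene record.
ACCESSION   toyrec
VERSION     toyrec.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..120
     CDS             11..40
                     /locus_tag="t0001"
                     /gene="alpha"
     CDS             complement(61..99)
                     /locus_tag="t0002"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture
def toy_genbank_path(tmp_path):
    path = tmp_path / "toy.gbk"
    path.write_text(TOY_GENBANK)
    return path
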