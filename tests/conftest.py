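import io

import pytest

from syntenylocus.domains import bundled_profiles
from syntenylocus.simulate import PanelSpec, generate_panel

TOY_GFF3 = """\
##gff-version 3
chr1\ttoy\tgene\t100\t1000\t.\t+\t.\tID=gene1;Name=ALPHA;biotype=protein_coding
chr1\ttoy\tmRNA\t100\t1000\t.\t+\t.\tID=tx1;Parent=gene1
chr1\ttoy\texon\t100\t300\t.\t+\t.\tID=tx1.e1;Parent=tx1
chr1\ttoy\texon\t600\t1000\t.\t+\t.\tID=tx1.e2;Parent=tx1
chr1\ttoy\tgene\t2000\t3000\t.\t-\t.\tID=gene2;Name=BETA;biotype=protein_coding
chr1\ttoy\tgene\t4000\t5000\t.\t+\t.\tID=gene3;Name=GAMMA;biotype=protein_coding
"""


@pytest.fixture
def toy_gff3_stream():
    return io.StringIO(TOY_GFF3)


@pytest.fixture(scope="session")
def profiles():
    """The bundled synthetic Methyltransf_2/Maf profiles."""
    return bundled_profiles()


@pytest.fixture(scope="session")
def small_panel():
    """10-species panel with the planted anchor/target/paralog arrangement."""
    return generate_panel(PanelSpec(seed=42))
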