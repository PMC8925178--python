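import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from genefam.core_io import bundled_gene_table


@pytest.fixture(scope="session")
def gene_table():
    """The bundled 65-member wheat VQ gene table."""
    return bundled_gene_table()
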