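import numpy as np
import pytest

from slimprints.msa_io import OrthologueAlignment


def make_alignment(query: str, *orthologues: str, query_id: str = "Q") -> OrthologueAlignment:
    """Alignment with the query first and orthologue rows named O1, O2, ..."""
    rows = [(query_id, query.upper())]
    rows += [(f"O{k + 1}", seq.upper()) for k, seq in enumerate(orthologues)]
    return OrthologueAlignment(query_id=query_id, rows=tuple(rows), query_row_index=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def aln_factory():
    return make_alignment
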