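import pytest

from svjunction.descriptors import descriptor_span, descriptor_to_structure
from svjunction.io.fixtures import load_fixture


@pytest.fixture(scope="session")
def bundle():
    return load_fixture()


@pytest.fixture(scope="session")
def case_structures(bundle):
    """case -> (structure, span) from the normalized descriptor."""
    out = {}
    for case in bundle.cases:
        row = bundle.case_row(case)
        ops = bundle.descriptor_ops(case)
        span = descriptor_span(ops)
        out[case] = (descriptor_to_structure(ops, span, contig=row.chromosome), span)
    return out


@pytest.fixture(scope="session")
def clean_structures(bundle):
    """case -> (structure, span) from the clean (orientation-faithful) descriptor."""
    out = {}
    for case in bundle.cases:
        row = bundle.case_row(case)
        ops = bundle.descriptor_ops(case, "clean")
        span = descriptor_span(ops)
        out[case] = (descriptor_to_structure(ops, span, contig=row.chromosome), span)
    return out
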