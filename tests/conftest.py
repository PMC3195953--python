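import pytest

from interolognet import FixtureSpec, InteractionRecord


SMALL_SPEC = FixtureSpec(
    species=((9606, 120), (10090, 60), (4932, 60)),
    background_edge_p=0.02,
    query_size=8,
    shell_size=15,
    planted_p_in=0.25,
    ortholog_coverage=0.8,
    human_overlap_fraction=0.3,
    n_go_terms=10,
    seed=0,
)


@pytest.fixture
def small_spec() -> FixtureSpec:
    """A fast three-species fixture specification for pipeline-level tests."""
    return SMALL_SPEC


def rec(a, b, tax_a=9606, tax_b=None, category="physical", source="dbX",
        method="two hybrid", pubmed=()):
    return InteractionRecord(
        id_a=a,
        id_b=b,
        taxid_a=tax_a,
        taxid_b=tax_a if tax_b is None else tax_b,
        category=category,
        source_db=source,
        detection_method=method,
        pubmed_ids=tuple(pubmed),
    )


@pytest.fixture
def mixed_records():
    return [
        rec("HSP90AA1", "AHSA1", pubmed=["15937123"]),
        rec("HSP90AA1", "CDC37", category="genetic"),
        rec("STI1", "HSP82", tax_a=4932),
        rec("HSP90AA1", "Hsp90aa1", tax_a=9606, tax_b=10090),
    ]
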