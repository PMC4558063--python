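from __future__ import annotations

import pytest

from tcscensus import GeneRecord


def make_genome(domain_lists, organism="orgA", replicon="chr1"):
    """Build a toy gene table from a list of domain tuples (() = non-IST)."""
    return [
        GeneRecord(
            organism_id=organism,
            replicon_id=replicon,
            position=i + 1,
            gene_id=f"g{i+1}",
            annotation="x",
            domains=tuple(doms),
        )
        for i, doms in enumerate(domain_lists)
    ]


@pytest.fixture
def toy_genome():
    """[HK, RR, x, x, HK]: one HK-RR pair plus one isolated HK."""
    return make_genome([("HK",), ("RR",), (), (), ("HK",)])
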