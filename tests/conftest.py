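import logging

import pytest

from metaborank.io import GeneSet, GeneSetCollection

logging.getLogger("metaborank").setLevel(logging.ERROR)


@pytest.fixture
def tiny_collection():
    """Three overlapping pathways over a 10-gene universe."""
    return GeneSetCollection(
        [
            GeneSet("P1", frozenset({"G1", "G2", "G3", "G4"})),
            GeneSet("P2", frozenset({"G3", "G4", "G5", "G6"})),
            GeneSet("P3", frozenset({"G7", "G8", "G9", "G10"})),
        ]
    )


def write(path, text):
    path.write_text(text)
    return str(path)
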