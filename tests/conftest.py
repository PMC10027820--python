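import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scanpathnet import ScanpathEntry, Scanpath, from_edges


@pytest.fixture
def worked_scanpath():
    """The canonical worked example: reading "Could humans live on Mars some
    day?" with fixation sequence could-humans-live-mars-day-could-humans."""
    keys = ["could", "humans", "live", "mars", "day", "could", "humans"]
    positions = [0, 1, 2, 4, 6, 0, 1]
    entries = tuple(
        ScanpathEntry(node_key=k, sentence_index=0, word_index=w, duration_ms=200.0)
        for k, w in zip(keys, positions)
    )
    return Scanpath(participant_id="p1", text_id="mars", entries=entries)


# The printed example adjacency matrix over 8 fixated words, read cell by
# cell as directed entries (row -> column). Off-diagonal sum is 14.
TABLE1_NODES = ("could", "human", "on", "mars", "day", "scientist", "this", "question")
TABLE1_DIRECTED_CELLS = [
    ("could", "human", 1),
    ("human", "on", 1),
    ("human", "mars", 1),
    ("human", "scientist", 1),
    ("on", "mars", 1),
    ("mars", "human", 1),
    ("mars", "day", 3),
    ("day", "mars", 3),
    ("scientist", "this", 1),
    ("this", "question", 1),
]

# The same table read as unique undirected transition counts (each pair once):
# this is the reading under which the word "mars" has degree 5.
TABLE1_UNDIRECTED_EDGES = [
    ("could", "human", 1),
    ("human", "on", 1),
    ("human", "mars", 1),
    ("human", "scientist", 1),
    ("on", "mars", 1),
    ("mars", "day", 3),
    ("scientist", "this", 1),
    ("this", "question", 1),
]


@pytest.fixture
def table1_directed():
    return from_edges(
        [(i, j, float(w)) for i, j, w in TABLE1_DIRECTED_CELLS], nodes=TABLE1_NODES
    )


@pytest.fixture
def table1_undirected():
    return from_edges(
        [(i, j, float(w)) for i, j, w in TABLE1_UNDIRECTED_EDGES], nodes=TABLE1_NODES
    )


def complete_graph(n: int) -> "ScanpathNetwork":
    return from_edges(
        [(str(i), str(j), 1.0) for i in range(n) for j in range(n) if i != j]
    )
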