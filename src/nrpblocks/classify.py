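"""Structure-type classification of decomposed molecules.

A decomposition is summarized by its block graph (occurrences connected by
cleaved bonds).  The type is read off that graph: a cycle makes the
structure cyclic, a node with more than two neighbours makes it branched,
both together branch-cyclic, and more than one branch point falls back to
``other`` (the downstream sequence notation cannot express it).  A block
lacking a C-terminus — e.g. Hpd or putrescine, terminated by amine groups
on both sides — marks the whole structure as a polyketide, refined to
linear or cyclic; there is no branched-polyketide type, so a branched
polyketide is ``other`` as well.
"""

from __future__ import annotations

import enum
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .decompose import BlockGraph

__all__ = ["SequenceType", "classify", "ClassificationError"]


class SequenceType(str, enum.Enum):
    LINEAR = "linear"
    CYCLIC = "cyclic"
    BRANCHED = "branched"
    BRANCH_CYCLIC = "branch-cyclic"
    LINEAR_POLYKETIDE = "linear-polyketide"
    CYCLIC_POLYKETIDE = "cyclic-polyketide"
    OTHER = "other"

    def __str__(self) -> str:
        return self.value


class ClassificationError(ValueError):
    """Block graph unsuitable for classification (e.g. disconnected)."""


def classify(block_graph: "BlockGraph") -> SequenceType:
    """Determine the :class:`SequenceType` of a connected block graph.

    For a connected graph a cycle exists iff ``|edges| >= |nodes|``; a
    branch point is any node with degree > 2 (each contributes
    ``degree - 2`` branches).  A single occurrence with no edges is
    linear (or linear-polyketide if it has no C-terminus).
    """
    g = block_graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise ClassificationError("empty block graph")
    import networkx as nx

    if not nx.is_connected(nx.Graph(g)):
        raise ClassificationError("disconnected block graph")

    cyclic = g.number_of_edges() >= g.number_of_nodes()
    branches = sum(max(0, d - 2) for _n, d in g.degree())
    polyketide = any(occ.c_termini == 0 for occ in block_graph.occurrences)

    if branches >= 2:
        return SequenceType.OTHER
    if branches == 1:
        if polyketide:
            return SequenceType.OTHER  # no branched-polyketide type exists
        return SequenceType.BRANCH_CYCLIC if cyclic else SequenceType.BRANCHED
    if polyketide:
        return (SequenceType.CYCLIC_POLYKETIDE if cyclic
                else SequenceType.LINEAR_POLYKETIDE)
    return SequenceType.CYCLIC if cyclic else SequenceType.LINEAR
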