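"""Family recommendation by Tanimoto similarity over block sets.

Two structures are compared as the *sets* of their building blocks:
``T(A, B) = |A n B| / (|A| + |B| - |A n B|)``.  Block identity is the
canonical generic SMILES of the block structure, not the acronym — two
containers may call the same monomer different names.  A simpler
text-substring model is kept alongside for historical parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .database import Container, SequenceRecord

__all__ = ["FamilyRecommendation", "tanimoto",
           "recommend_families_tanimoto", "recommend_families_text"]


@dataclass
class FamilyRecommendation:
    """Families suggested for a query, and where they came from."""

    families: list[str] = field(default_factory=list)
    source_sequence: str | None = None
    score: float | None = None  # Tanimoto score, or None for the text model


def tanimoto(blocks_a: Iterable[str], blocks_b: Iterable[str]) -> float:
    """Tanimoto similarity of two block sets; T(empty, empty) = 0."""
    a, b = set(blocks_a), set(blocks_b)
    union = len(a) + len(b) - len(a & b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _stored_block_set(record: "SequenceRecord",
                      container: "Container") -> set[str]:
    """Block identities of a stored sequence.

    Acronyms from the notation are mapped to block structures through the
    container; an acronym without a stored structure falls back to the
    acronym string itself (documented convention).
    """
    by_acr = {b.acronym: b.smiles for b in container.blocks if b.smiles}
    return {by_acr.get(a, a) for a in record.acronyms()}


def recommend_families_tanimoto(query_blocks: Iterable[str],
                                query_total: int,
                                container: "Container"
                                ) -> FamilyRecommendation:
    """Best-scoring stored sequence's families, ties broken by block count.

    The maximum T over all stored sequences is taken; among equal scores
    the sequence minimizing ``|total blocks(query) - total blocks(stored)|``
    wins (totals count repeats), remaining ties go to the first stored
    sequence.  A score of 0 recommends nothing.
    """
    qset = set(query_blocks)
    best: tuple[float, int, int] | None = None  # (score, -count_diff...) keyed
    best_record = None
    for pos, rec in enumerate(container.sequences):
        sset = _stored_block_set(rec, container)
        t = tanimoto(qset, sset)
        count_diff = abs(query_total - rec.total_blocks())
        key = (-t, count_diff, pos)
        if best is None or key < best:
            best = key
            best_record = rec
    if best_record is None or best is None or -best[0] <= 0.0:
        return FamilyRecommendation()
    return FamilyRecommendation(families=list(best_record.families),
                                source_sequence=best_record.name,
                                score=-best[0])


def _search_substring(name: str) -> str:
    """Query substring: the name with its final token dropped (if >= 2)."""
    tokens = name.split()
    if len(tokens) >= 2:
        return " ".join(tokens[:-1])
    return name


def recommend_families_text(query_name: str,
                            container: "Container") -> FamilyRecommendation:
    """Families of every stored sequence whose name contains the query
    substring (case-insensitive); e.g. 'pseudacyclin B' matches
    'pseudacyclin A' via the substring 'pseudacyclin'."""
    if not query_name.strip():
        raise ValueError("query name must be nonempty")
    s = _search_substring(query_name.strip()).lower()
    families: list[str] = []
    matched = None
    for rec in container.sequences:
        if s in rec.name.lower():
            matched = matched or rec.name
            for fam in rec.families:
                if fam not in families:
                    families.append(fam)
    return FamilyRecommendation(families=families, source_sequence=matched)
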