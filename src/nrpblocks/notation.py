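"""CycloBranch sequence notation: render and parse.

Linear and cyclic sequences are written ``[A]-[B]-[C]-[D]-[E]`` (for
cyclic types the last block is implicitly bonded to the first).  Singly
branched and branch-cyclic sequences insert the branch after its
attachment block: ``[A]\\([B]-[C]\\)[D]-[E]`` is the backbone A-D-E with
the branch B-C hanging off A.  Multiply branched structures (type
``other``) have no notation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .classify import SequenceType

__all__ = ["BlockSequence", "NotationError", "to_notation", "parse_notation"]

_FORBIDDEN = set("[]-\\()")


class NotationError(ValueError):
    """Malformed notation text or unrepresentable sequence."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass
class BlockSequence:
    """Ordered block acronyms plus topology flags.

    ``branch`` is ``(attachment position on backbone, acronyms ordered
    outward)``; it may only be present for branched/branch-cyclic/other
    types.  ``modifications`` holds up to three terminal-modification
    names (validated against the container, not here).
    """

    backbone: list[str]
    branch: tuple[int, list[str]] | None = None
    cyclic: bool = False
    type: SequenceType = SequenceType.LINEAR
    modifications: list[str] = field(default_factory=list)

    @property
    def total_blocks(self) -> int:
        return len(self.backbone) + (len(self.branch[1]) if self.branch else 0)

    @property
    def acronyms(self) -> list[str]:
        out = list(self.backbone)
        if self.branch:
            out += self.branch[1]
        return out


def _check_acronym(acr: str) -> str:
    if not acr:
        raise NotationError("empty acronym")
    bad = _FORBIDDEN & set(acr)
    if bad:
        raise NotationError(
            f"acronym {acr!r} contains illegal character(s) {sorted(bad)}")
    return acr


def to_notation(seq: BlockSequence) -> str:
    """Render *seq* as CycloBranch notation.

    Raises :class:`NotationError` for type ``other`` (unrepresentable)
    and for acronyms containing grammar characters.
    """
    if seq.type is SequenceType.OTHER:
        raise NotationError("type 'other' has no sequence notation")
    if not seq.backbone:
        raise NotationError("empty backbone")
    for acr in seq.acronyms:
        _check_acronym(acr)

    def blocks(acrs: list[str]) -> str:
        return "-".join(f"[{a}]" for a in acrs)

    if seq.branch is None:
        return blocks(seq.backbone)
    pos, branch = seq.branch
    if not (0 <= pos < len(seq.backbone)):
        raise NotationError(f"branch attachment {pos} outside backbone")
    if not branch:
        raise NotationError("empty branch")
    head = blocks(seq.backbone[: pos + 1])
    tail = blocks(seq.backbone[pos + 1:])
    return head + "\\(" + blocks(branch) + "\\)" + tail


_BLOCK_RE = re.compile(r"\[([^\[\]\\()-]+)\]")


def parse_notation(text: str) -> BlockSequence:
    """Parse notation text into an acronym skeleton.

    The cyclic flag and type cannot be recovered from the text alone (a
    cyclic sequence reads like a linear one); callers supply them from the
    stored record.  ``to_notation(parse_notation(t)) == t`` for every
    well-formed ``t``.
    """
    backbone: list[str] = []
    branch: tuple[int, list[str]] | None = None
    pos = 0
    n = len(text)
    current = backbone
    while pos < n:
        if text.startswith("\\(", pos):
            if branch is not None or current is not backbone:
                raise NotationError("more than one branch", pos)
            if not backbone:
                raise NotationError("branch before any backbone block", pos)
            branch = (len(backbone) - 1, [])
            current = branch[1]
            pos += 2
            continue
        if text.startswith("\\)", pos):
            if current is backbone:
                raise NotationError("unmatched branch close", pos)
            if not current:
                raise NotationError("empty branch", pos)
            current = backbone
            pos += 2
            # a backbone block may follow immediately (no dash)
            continue
        if text[pos] == "-":
            if pos == 0 or not current or text[pos - 1] == "(":
                raise NotationError("misplaced '-'", pos)
            pos += 1
            if pos >= n or text[pos] != "[":
                raise NotationError("expected '[' after '-'", pos)
            continue
        m = _BLOCK_RE.match(text, pos)
        if not m:
            raise NotationError(f"expected a block at {text[pos:pos + 8]!r}", pos)
        # blocks must be separated by '-', a branch marker, or start of text
        if pos > 0 and text[pos - 1] not in "-()":
            raise NotationError("missing separator before block", pos)
        current.append(m.group(1))
        pos = m.end()
    if current is not backbone:
        raise NotationError("unterminated branch", n)
    if not backbone:
        raise NotationError("no blocks found", 0)
    seq_type = SequenceType.BRANCHED if branch else SequenceType.LINEAR
    return BlockSequence(backbone=backbone, branch=branch, type=seq_type)
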