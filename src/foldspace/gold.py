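"""Deriving "gold" secondary structures from annotated base-pair lists.

Experimentally solved 3D structures yield lists of annotated base-base
interactions (e.g. from MC-Annotate).  Only cis Watson-Crick (cWC) pairs
over the canonical alphabet take part in secondary structure; lonely
pairs are thermodynamically unstable and removed; pseudoknots have no
unique nested resolution, so structures whose crossings cannot be
resolved by deleting a single pair are discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Set, Tuple

from .params import pair_type
from .sequence import RnaSequence, as_sequence
from .structures import SecondaryStructure

Pair = Tuple[int, int]


class GoldError(ValueError):
    pass


@dataclass
class Rejection:
    """Signaled (non-exception) outcome: the structure is unusable."""

    reason: str

    def __bool__(self):
        return False


@dataclass(frozen=True)
class AnnotatedPairList:
    """A sequence plus annotated base-base interactions.

    ``interactions`` holds 1-based ``(i, j, tag)`` with ``i < j``; the tag
    is the interaction class (e.g. ``"cWC"``, ``"stacking"``).
    """

    sequence: RnaSequence
    interactions: tuple

    def __post_init__(self):
        object.__setattr__(self, "sequence", as_sequence(self.sequence))
        n = len(self.sequence)
        norm = []
        for (i, j, tag) in self.interactions:
            if not (1 <= i <= n and 1 <= j <= n):
                raise GoldError(f"interaction ({i},{j}) outside 1..{n}")
            if i == j:
                raise GoldError(f"self-interaction at {i}")
            if i > j:
                i, j = j, i
            norm.append((i, j, tag))
        object.__setattr__(self, "interactions", tuple(norm))


def filter_canonical_cwc(apl: AnnotatedPairList) -> Set[Pair]:
    """Keep only cWC-tagged interactions whose bases pair canonically.

    Non-canonical pairs, base stackings and base-backbone interactions
    are not part of the secondary structure and are dropped.  A position
    engaged in several cWC pairs keeps none of them (no unique partner).
    """
    code = apl.sequence.code
    pairs = set()
    for (i, j, tag) in apl.interactions:
        if tag.lower() not in ("cwc", "cis watson-crick", "ww_cis", "+/+"):
            continue
        if pair_type(code[i - 1], code[j - 1]) == 0:
            continue
        pairs.add((i, j))
    used: dict = {}
    conflicted = set()
    for (i, j) in pairs:
        for pos in (i, j):
            if pos in used:
                conflicted.add(pos)
            used[pos] = True
    return {
        (i, j) for (i, j) in pairs if i not in conflicted and j not in conflicted
    }


def remove_lonely_pairs(pairs: Iterable[Pair]) -> Set[Pair]:
    """Iteratively remove pairs without a stacked neighbor (fixpoint)."""
    current = set(pairs)
    while True:
        lonely = {
            (i, j)
            for (i, j) in current
            if (i + 1, j - 1) not in current and (i - 1, j + 1) not in current
        }
        if not lonely:
            return current
        current -= lonely


def _crossing_pairs(pairs: Set[Pair]) -> Set[Pair]:
    crossing = set()
    ps = sorted(pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if i < k < j < l:
                crossing.add(ps[a])
                crossing.add(ps[b])
    return crossing


def apply_pseudoknot_policy(pairs: Iterable[Pair]):
    """Resolve crossings removable by deleting one pair; else reject.

    Returns ``(nested pair set, removed pair or None)`` on success, or a
    :class:`Rejection` when no single-pair deletion makes the set nested
    ("pseudoknots larger than one base pair").
    """
    current = set(pairs)
    crossing = _crossing_pairs(current)
    if not crossing:
        return current, None
    for cand in sorted(crossing):
        trial = current - {cand}
        if not _crossing_pairs(trial):
            return trial, cand
    return Rejection("pseudoknot larger than one base pair")


def build_gold_structure(apl: AnnotatedPairList):
    """Canonical-cWC filter, pseudoknot policy, lonely-pair removal.

    Lonely pairs are re-checked after any removal, so the pipeline is
    idempotent.  Returns a :class:`SecondaryStructure` or a
    :class:`Rejection`.
    """
    pairs = filter_canonical_cwc(apl)
    res = apply_pseudoknot_policy(pairs)
    if isinstance(res, Rejection):
        return res
    pairs, _removed = res
    pairs = remove_lonely_pairs(pairs)
    return SecondaryStructure.from_pairs(len(apl.sequence), pairs)


# ---------------------------------------------------------------------------
# input formats


def parse_pair_tsv(sequence, text: str) -> AnnotatedPairList:
    """TSV pair list: columns i, j, interaction class (header optional)."""
    rows = []
    for ln in text.splitlines():
        f = ln.split()
        if not f or ln.lstrip().startswith("#"):
            continue
        try:
            i, j = int(f[0]), int(f[1])
        except ValueError:
            continue  # header line
        tag = f[2] if len(f) > 2 else "cWC"
        rows.append((i, j, tag))
    return AnnotatedPairList(sequence=sequence, interactions=tuple(rows))


_MCA_LINE = re.compile(
    r"^\s*\w?(\d+)-\w?(\d+)\s*:\s*([ACGU])-([ACGU])\s+(.*)$", re.I
)


def parse_mc_annotate(sequence, text: str) -> AnnotatedPairList:
    """Permissive reader for MC-Annotate-style base-pair listings.

    Accepts lines of the form ``A12-A34 : G-C Ww/Ww pairing cis ...``;
    a pair is tagged ``cWC`` when the line reports a cis Watson-Crick/
    Watson-Crick edge contact, anything else keeps its raw description.
    """
    rows = []
    for ln in text.splitlines():
        m = _MCA_LINE.match(ln)
        if not m:
            continue
        i, j = int(m.group(1)), int(m.group(2))
        desc = m.group(5)
        if "Ww/Ww" in desc and "cis" in desc:
            tag = "cWC"
        else:
            tag = desc.strip() or "other"
        rows.append((i, j, tag))
    return AnnotatedPairList(sequence=sequence, interactions=tuple(rows))


def write_fasta_like(name: str, seq, structure: SecondaryStructure) -> str:
    """Header, sequence line, dot-bracket line."""
    seq = as_sequence(seq)
    return f">{name}\n{seq.seq}\n{structure.dotbracket}\n"
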