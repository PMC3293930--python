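"""Abstract shapes of secondary structures, levels 1-5.

A shape string describes the arrangement of helices: ``[`` ``]`` bracket a
helix (a maximal stack of base pairs, of any length), ``_`` marks a stretch
of unpaired bases (of any length).  The five abstraction levels retain
decreasing amounts of loop detail:

* level 1: every helix and every unpaired region;
* level 2: every helix, plus unpaired regions of bulges and internal loops
  (hairpin, multiloop and exterior strands are dropped);
* level 3: level 2 without the underscores (helix interruptions by bulges
  and internal loops still nest);
* level 4: helices separated only by a bulge are merged; internal-loop
  interruptions still nest;
* level 5: helices merged across bulges and internal loops; only the helix
  nesting produced by multiloops remains.

The fully unpaired structure maps to ``"_"`` at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structures import SecondaryStructure, StructureError, parse_dotbracket

LEVELS = (1, 2, 3, 4, 5)


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeString:
    """A shape at a given abstraction level."""

    level: int
    text: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ShapeError(f"shape level must be 1..5, got {self.level}")
        depth = 0
        for ch in self.text:
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
                if depth < 0:
                    raise ShapeError(f"unbalanced shape string {self.text!r}")
            elif ch != "_":
                raise ShapeError(f"invalid shape character {ch!r}")
        if depth != 0:
            raise ShapeError(f"unbalanced shape string {self.text!r}")
        if "__" in self.text:
            raise ShapeError(f"runs of underscores in {self.text!r}")

    def __str__(self) -> str:
        return self.text


def _merge(parts) -> str:
    """Concatenate shape fragments, collapsing adjacent underscores."""
    out = []
    for p in parts:
        if not p:
            continue
        if out and out[-1].endswith("_") and p.startswith("_"):
            p = p[1:]
            if not p:
                continue
        out.append(p)
    return "".join(out)


def shape_of(s: SecondaryStructure, level: int) -> ShapeString:
    """Abstract shape of structure ``s`` at the given level."""
    if level not in LEVELS:
        raise ShapeError(f"shape level must be 1..5, got {level}")
    loops = {loop.closing: loop for loop in s.loops()}

    def helix_str(pair) -> str:
        return "[" + inner_str(pair) + "]"

    def inner_str(pair) -> str:
        # follow the maximal stack down to the helix-terminating loop
        loop = loops[pair]
        while loop.kind == "stack":
            pair = loop.children[0]
            loop = loops[pair]
        if loop.kind == "hairpin":
            return "_" if level == 1 else ""
        if loop.kind in ("bulge_left", "bulge_right"):
            child = loop.children[0]
            if level >= 4:
                return inner_str(child)  # merged into one helix
            x = helix_str(child)
            if level >= 3:
                return x
            return ("_" + x) if loop.kind == "bulge_left" else (x + "_")
        if loop.kind == "internal":
            child = loop.children[0]
            if level == 5:
                return inner_str(child)
            x = helix_str(child)
            if level >= 3:
                return x
            return "_" + x + "_"
        # multiloop
        return _render_loop_body(loop)

    def _render_loop_body(loop) -> str:
        items = [(start, "_" if level == 1 else "") for (start, _e) in loop.runs]
        items += [(i, helix_str((i, j))) for (i, j) in loop.children]
        items.sort()
        return _merge(p for _, p in items)

    exterior = loops[None]
    text = _render_loop_body(exterior)
    if not text or text == "_":
        text = "_"
    return ShapeString(level=level, text=text)


# ---------------------------------------------------------------------------
# refinement across levels


def witness_structure(p: ShapeString) -> SecondaryStructure:
    """A canonical secondary structure mapping to shape ``p`` at its level.

    Helices are realized with two stacked pairs, hairpin loops with three
    unpaired bases, interrupting loops as 1x1 internal loops.
    """
    items, _ = _parse_items(p.text, 0)
    db = "".join(_witness_item(it) for it in items)
    if not db:
        db = "."
    return parse_dotbracket(db)


def _parse_items(text, k):
    """Parse a shape string into a list of '_' and nested bracket items."""
    items = []
    while k < len(text):
        ch = text[k]
        if ch == "_":
            items.append("_")
            k += 1
        elif ch == "[":
            sub, k2 = _parse_items(text, k + 1)
            if k2 >= len(text) or text[k2] != "]":
                raise ShapeError(f"unbalanced shape string {text!r}")
            items.append(sub)
            k = k2 + 1
        else:  # ']'
            break
    return items, k


def _witness_item(item) -> str:
    if item == "_":
        return "."
    # item is the content list of one bracket pair
    sub = item
    brackets = [x for x in sub if x != "_"]
    if not brackets:
        return "((...))"
    if len(brackets) == 1:
        lead = sub and sub[0] == "_"
        trail = sub and sub[-1] == "_"
        inner = _witness_item(brackets[0])
        if lead and trail:
            return "((." + inner + ".))"
        if lead:
            return "((." + inner + "))"
        if trail:
            return "((" + inner + ".))"
        # uninterrupted nesting: realize as a 1x1 internal loop
        return "((." + inner + ".))"
    return "((" + "".join(_witness_item(x) for x in sub) + "))"


def is_refinement(p: ShapeString, q: ShapeString) -> bool:
    """True iff every structure with shape ``p`` (at p.level) has shape
    ``q`` at q.level.  Requires ``p.level <= q.level``; equal levels are
    admitted only as an equality test."""
    if p.level > q.level:
        raise ShapeError(
            f"refinement requires p.level <= q.level, got {p.level} > {q.level}"
        )
    if p.level == q.level:
        if p.text == q.text:
            return True
        raise ShapeError(
            "same-level shapes can only be compared for equality; "
            f"{p.text!r} != {q.text!r}"
        )
    w = witness_structure(p)
    return shape_of(w, q.level).text == q.text
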