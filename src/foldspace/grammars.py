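"""Declarative grammar descriptions of the four folding-space models.

These mirror exactly the recurrences implemented in
:mod:`foldspace._dp`: nonterminals, productions with their evaluation
function labels, and the shared filters.  They exist so the structure of a
model (e.g. its nonterminal/function inventory) is inspectable data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Tuple

MODELS = ("NoDangle", "OverDangle", "MicroState", "MacroState")

_LABEL = re.compile(r"([a-z_]+[a-z0-9_]*'*)\s*\(")

_TERMINALS = {"BASE", "REGION", "REGION3", "REGION30", "LOC", "EMPTY"}


@dataclass(frozen=True)
class GrammarSpec:
    """A tree grammar: nonterminals and labelled productions."""

    name: str
    axiom: str
    productions: Dict[str, Tuple[str, ...]]
    filters: Tuple[str, ...] = ("stackpairing", "r3", "r30", "canonical_pairs")

    @property
    def nonterminals(self) -> Tuple[str, ...]:
        return tuple(self.productions)

    @property
    def functions(self) -> Tuple[str, ...]:
        seen = []
        for alts in self.productions.values():
            for alt in alts:
                for label in _LABEL.findall(alt):
                    if label not in seen:
                        seen.append(label)
        return tuple(seen)

    @property
    def n_nonterminals(self) -> int:
        return len(self.nonterminals)

    @property
    def n_functions(self) -> int:
        return len(self.functions)


_SHARED_CLOSED = {
    "closed": (
        "stack | hairpin | leftB | rightB | iloop | multiloop "
        "<with stackpairing>",
    ),
    "stack": ("sr(BASE, closed, BASE)",),
    "hairpin": ("hl(BASE, BASE, REGION3, BASE, BASE)",),
    "leftB": ("bl(BASE, BASE, REGION30, closed, BASE, BASE)",),
    "rightB": ("br(BASE, BASE, closed, REGION30, BASE, BASE)",),
    "iloop": ("il(BASE, BASE, REGION30, closed, REGION30, BASE, BASE)",),
}

#: NoDangle and OverDangle share one grammar; they differ only in how the
#: evaluation functions drem and ml wire the dangle energy contributions.
NODANGLE = GrammarSpec(
    name="NoDangle",
    axiom="struct",
    productions={
        "struct": (
            "sadd(BASE, struct)",
            "cadd(dangle, struct)",
            "nil(EMPTY)",
        ),
        "dangle": ("drem(LOC, closed, LOC)",),
        **_SHARED_CLOSED,
        "multiloop": ("ml(BASE, BASE, ml_comps, BASE, BASE)",),
        "ml_comps": (
            "sadd(BASE, ml_comps)",
            "cadd(incl(dangle), ml_comps1)",
        ),
        "ml_comps1": (
            "sadd(BASE, ml_comps1)",
            "cadd(incl(dangle), ml_comps1)",
            "incl(dangle)",
            "addss(incl(dangle), REGION)",
        ),
    },
)

OVERDANGLE = GrammarSpec(
    name="OverDangle",
    axiom="struct",
    productions=NODANGLE.productions,
)

MICROSTATE = GrammarSpec(
    name="MicroState",
    axiom="struct",
    productions={
        "struct": (
            "sadd(BASE, struct)",
            "cadd(dangle, struct)",
            "nil(EMPTY)",
        ),
        "dangle": (
            "drem(LOC, closed, LOC)",
            "edl(BASE, closed, LOC)",
            "edr(LOC, closed, BASE)",
            "edlr(BASE, closed, BASE)",
        ),
        **_SHARED_CLOSED,
        "multiloop": (
            "ml(BASE, BASE, ml_comps, BASE, BASE)",
            "mldl(BASE, BASE, BASE, ml_comps, BASE, BASE)",
            "mldr(BASE, BASE, ml_comps, BASE, BASE, BASE)",
            "mldlr(BASE, BASE, BASE, ml_comps, BASE, BASE, BASE)",
        ),
        "ml_comps": (
            "sadd(BASE, ml_comps)",
            "cadd(incl(dangle), ml_comps1)",
        ),
        "ml_comps1": (
            "sadd(BASE, ml_comps1)",
            "cadd(incl(dangle), ml_comps1)",
            "incl(dangle)",
            "addss(incl(dangle), REGION)",
        ),
    },
)

#: MacroState: one derivation per classical structure, with the dangling
#: situation of every helix encoded in the nonterminal structure so the
#: algebra can resolve dangles locally (minimising over the up-to-four
#: microstates of a helix boundary, ambd/ambd'/acomb for shared bases).
MACROSTATE = GrammarSpec(
    name="MacroState",
    axiom="struct",
    productions={
        "struct": ("left_dangle", "trafo(noleft_dangle)", "left_unpaired"),
        "left_unpaired": (
            "sadd(BASE, left_unpaired)",
            "sadd(BASE, left_dangle)",
        ),
        "left_dangle": (
            "ambd(edgl, BASE, noleft_dangle)",
            "cadd'(edgl, {noleft_dangle | nil(LOC)})",
            "cadd(edglr, {left_dangle | left_unpaired})",
            "nil(LOC)",
        ),
        "noleft_dangle": (
            "cadd''(edgr, {left_dangle | left_unpaired})",
            "cadd'''(nodg, {noleft_dangle | nil(LOC)})",
            "ambd'(nodg, BASE, noleft_dangle)",
        ),
        "edgl": ("edl(BASE, closed, LOC)",),
        "edgr": ("edr(LOC, closed, BASE)",),
        "edglr": ("edlr(BASE, closed, BASE)",),
        "nodg": ("drem(LOC, closed, LOC)",),
        **_SHARED_CLOSED,
        "multiloop": (
            "ml(BASE, BASE, mc2, BASE, BASE)",
            "mldl(BASE, BASE, BASE, mc1, BASE, BASE)",
            "mladl(BASE, BASE, BASE, mc2, BASE, BASE)",
            "mldr(BASE, BASE, mc3, BASE, BASE, BASE)",
            "mladr(BASE, BASE, mc2, BASE, BASE, BASE)",
            "mldlr(BASE, BASE, BASE, mc4, BASE, BASE, BASE)",
            "mladlr(BASE, BASE, BASE, mc2, BASE, BASE, BASE)",
            "mldladr(BASE, BASE, BASE, mc1, BASE, BASE, BASE)",
            "mladldr(BASE, BASE, BASE, mc3, BASE, BASE, BASE)",
        ),
        "mc1": (
            "combine(block_dl, mcadd1)",
            "combine(block_dlr, mcadd2)",
            "acomb(block_dl, BASE, mcadd1)",
        ),
        "mc2": (
            "combine(incl(nodg), mcadd1)",
            "combine(incl(edgr), mcadd2)",
            "acomb(incl(nodg), BASE, mcadd1)",
        ),
        "mc3": (
            "combine(incl(nodg), mcadd4)",
            "combine(incl(edgr), mcadd3)",
            "acomb(incl(nodg), BASE, mcadd4)",
        ),
        "mc4": (
            "combine(block_dl, mcadd4)",
            "combine(block_dlr, mcadd3)",
            "acomb(block_dl, BASE, mcadd4)",
        ),
        "mcadd1": (
            "incl(nodg)",
            "combine(incl(nodg), mcadd1)",
            "combine(incl(edgr), mcadd2)",
            "acomb(incl(nodg), BASE, mcadd1)",
        ),
        "mcadd2": (
            "block_dl",
            "combine(block_dl, mcadd1)",
            "combine(block_dlr, mcadd2)",
            "acomb(block_dl, BASE, mcadd1)",
        ),
        "mcadd3": (
            "block_dlr",
            "addss(block_dlr, REGION)",
            "combine(block_dl, mcadd4)",
            "combine(block_dlr, mcadd3)",
            "acomb(block_dl, BASE, mcadd4)",
        ),
        "mcadd4": (
            "incl(edgr)",
            "addss(incl(edgr), REGION)",
            "combine(incl(nodg), mcadd4)",
            "combine(incl(edgr), mcadd3)",
            "acomb(incl(nodg), BASE, mcadd4)",
        ),
        "block_dl": ("ssadd(REGION, edgl)", "incl(edgl)"),
        "block_dlr": ("ssadd(REGION, edglr)", "incl(edglr)"),
    },
)

_SPECS = {
    "NoDangle": NODANGLE,
    "OverDangle": OVERDANGLE,
    "MicroState": MICROSTATE,
    "MacroState": MACROSTATE,
}


def grammar_spec(model: str) -> GrammarSpec:
    if model not in _SPECS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return _SPECS[model]
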