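"""Validated RNA sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import BASES


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over ACGU with an identifier.

    DNA-style ``T`` is silently mapped to ``U``; any other letter is
    rejected with its position.  ``code`` holds the integer encoding
    (A=0, C=1, G=2, U=3) used throughout the numeric core.
    """

    seq: str
    id: str = ""
    code: tuple = field(init=False, repr=False)

    def __post_init__(self):
        cleaned = self.seq.upper().replace("T", "U")
        for pos, ch in enumerate(cleaned, start=1):
            if ch not in BASES:
                raise SequenceError(
                    f"invalid character {ch!r} at position {pos}"
                    + (f" in {self.id}" if self.id else "")
                )
        object.__setattr__(self, "seq", cleaned)
        object.__setattr__(self, "code", tuple(BASES.index(c) for c in cleaned))

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq


def as_sequence(x) -> RnaSequence:
    """Coerce a string into an :class:`RnaSequence` (idempotent)."""
    if isinstance(x, RnaSequence):
        return x
    return RnaSequence(str(x))
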