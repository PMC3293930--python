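"""File input/output: FASTA, dot-bracket files, gold corpora."""

from __future__ import annotations

import io as _io
from typing import List, Tuple

from Bio import SeqIO

from .sequence import RnaSequence
from .structures import SecondaryStructure, parse_dotbracket


def read_fasta(path_or_handle) -> List[RnaSequence]:
    """Read sequences from FASTA (T mapped to U, validation applied)."""
    return [
        RnaSequence(str(rec.seq), id=rec.id)
        for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def read_fasta_like(path_or_handle) -> List[Tuple[RnaSequence, SecondaryStructure]]:
    """Read a gold corpus: records of header, sequence line, structure line."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            text = fh.read()
    else:
        text = path_or_handle.read()
    out = []
    name, seq, db = None, None, None
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    for ln in lines:
        if ln.startswith(">"):
            if name is not None and seq and db:
                out.append((RnaSequence(seq, id=name), parse_dotbracket(db)))
            name, seq, db = ln[1:].split()[0] if len(ln) > 1 else "", None, None
        elif seq is None:
            seq = ln
        else:
            db = ln.split()[0]
    if name is not None and seq and db:
        out.append((RnaSequence(seq, id=name), parse_dotbracket(db)))
    return out


def read_dotbracket_file(path_or_handle) -> List[SecondaryStructure]:
    """One structure per line; lines starting with '>' are ignored."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            text = fh.read()
    else:
        text = path_or_handle.read()
    out = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith(">"):
            continue
        out.append(parse_dotbracket(ln.split()[0]))
    return out
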