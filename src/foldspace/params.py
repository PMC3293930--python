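"""Nearest-neighbor free-energy parameter sets.

All energies are stored as integers in centi-kcal/mol (1 unit = 0.01
kcal/mol), the resolution at which the Turner tables are published.  This
keeps co-optimality ties exact; conversion to float kcal/mol happens only at
API boundaries.

Base encoding: A=0, C=1, G=2, U=3.  Pair-type encoding follows the usual
nearest-neighbor table order::

    CG=1, GC=2, GU=3, UG=4, AU=5, UA=6

with 0 meaning "not a canonical pair".  Tables with a 5-wide base dimension
are indexed ``base + 1`` (index 0 is the wildcard/N column); tables with a
4-wide base dimension are indexed by the base directly.
"""

from __future__ import annotations

import math
import os
import re
import shutil
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

INF = 10_000_000  # forbidden / unavailable table entry, centi-kcal/mol

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)

BASES = "ACGU"
A, C, G, U = 0, 1, 2, 3

#: canonical pair -> pair type code
PAIR_TYPE: Dict[tuple, int] = {
    (C, G): 1,
    (G, C): 2,
    (G, U): 3,
    (U, G): 4,
    (A, U): 5,
    (U, A): 6,
}

#: pair type of the reversed pair, indexed by pair type (0 unused)
REVERSE_TYPE = (0, 2, 1, 4, 3, 6, 5)


def pair_type(b5: int, b3: int) -> int:
    """Pair-type code of (b5, b3), 0 if not canonical."""
    return PAIR_TYPE.get((b5, b3), 0)


def encode(seq: str) -> tuple:
    """Encode an ACGU string as a tuple of base codes."""
    return tuple("ACGU".index(c) for c in seq)


class ParameterError(ValueError):
    """Raised when a parameter set cannot be located or parsed."""


@dataclass
class EnergyParameters:
    """One complete nearest-neighbor parameter set (37 degC free energies).

    Scalars and tables are integer centi-kcal/mol.  ``rt`` is R*T in
    kcal/mol at ``temperature_K``.
    """

    name: str
    stack_table: list  # [7][7]  (pair, inner pair), index ptype-1
    hairpin_length: list  # [31], index = loop size (0..30)
    bulge_length: list  # [31]
    internal_length: list  # [31]
    mismatch_hairpin: list  # [7][5][5]  (ptype-1, 5' mismatch+1, 3' mismatch+1)
    mismatch_internal: list  # [7][5][5]
    mismatch_internal_1n: list  # [7][5][5]
    mismatch_internal_23: list  # [7][5][5]
    dangle5: list  # [7][5]  (ptype-1, base+1)
    dangle3: list  # [7][5]
    int11: list  # [7][7][5][5]
    int21: list  # [7][7][5][5][5]
    int22: list  # [6][6][4][4][4][4]
    tetraloop_bonus: Dict[str, int]  # 6-mer (closing pair + loop) -> energy
    triloop_bonus: Dict[str, int]  # 5-mer
    hexaloop_bonus: Dict[str, int]  # 8-mer
    ninio: int  # asymmetry coefficient per |n1-n2|
    ninio_max: int  # cap on the asymmetry penalty
    terminal_au: int  # non-GC helix end penalty
    lxc: float  # loop length extrapolation coefficient (centi-kcal)
    ml_offset: int  # multiloop closing penalty ("ml_energy")
    ml_branch: int  # penalty per multiloop stem incl. the closing one ("ul_energy")
    ss_unpaired: int  # per unpaired multiloop base ("ss_energy")
    single_base: int  # per single unpaired base ("sbase_energy")
    temperature_K: float = 310.15
    source: str = ""

    @property
    def rt(self) -> float:
        """Gas constant times temperature, kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature_K

    def validate(self) -> None:
        if not (self.rt > 0):
            raise ParameterError("non-positive RT")
        for nm, tab, dims in (
            ("stack", self.stack_table, (7, 7)),
            ("dangle5", self.dangle5, (7, 5)),
            ("dangle3", self.dangle3, (7, 5)),
        ):
            if len(tab) != dims[0] or any(len(row) != dims[1] for row in tab):
                raise ParameterError(f"malformed table: {nm}")
        for nm, tab in (
            ("hairpin", self.hairpin_length),
            ("bulge", self.bulge_length),
            ("internal", self.internal_length),
        ):
            if len(tab) != 31:
                raise ParameterError(f"malformed table: {nm}")


# ---------------------------------------------------------------------------
# ViennaRNA ".par" v2.0 reader

_NUM = re.compile(r"-?\d+(?:\.\d+)?|INF|DEF|NST")


def _tokens(body: str) -> List[str]:
    body = re.sub(r"/\*.*?\*/", " ", body, flags=re.S)
    return _NUM.findall(body)


def _ints(body: str) -> List[int]:
    out = []
    for t in _tokens(body):
        if t in ("INF", "NST", "DEF"):
            out.append(INF)
        else:
            out.append(int(round(float(t))))
    return out


def _reshape(flat: Sequence[int], dims: Sequence[int], name: str) -> list:
    n = 1
    for d in dims:
        n *= d
    if len(flat) != n:
        raise ParameterError(
            f"malformed table {name}: expected {n} entries, found {len(flat)}"
        )

    def build(offset, dims):
        if len(dims) == 1:
            return list(flat[offset : offset + dims[0]])
        step = 1
        for d in dims[1:]:
            step *= d
        return [build(offset + i * step, dims[1:]) for i in range(dims[0])]

    return build(0, list(dims))


def _special_loops(body: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for line in body.splitlines():
        parts = line.split()
        if len(parts) >= 2 and set(parts[0]) <= set("ACGU"):
            out[parts[0]] = int(parts[1])
    return out


def parse_parameter_file(path: str, name: str = "") -> EnergyParameters:
    """Parse a ViennaRNA 2.x parameter file into an :class:`EnergyParameters`."""
    with open(path) as fh:
        text = fh.read()
    if "parameter file v2.0" not in text.splitlines()[0]:
        raise ParameterError(f"{path}: not a v2.0 parameter file")
    sections: Dict[str, str] = {}
    for chunk in re.split(r"^# ", text, flags=re.M)[1:]:
        head, _, body = chunk.partition("\n")
        sections[head.strip()] = body

    def sec(nm: str) -> str:
        if nm not in sections:
            raise ParameterError(f"{path}: missing table {nm}")
        return sections[nm]

    def table(nm: str, dims) -> list:
        return _reshape(_ints(sec(nm)), dims, nm)

    ninio = _ints(sec("NINIO"))
    ml = _ints(sec("ML_params"))
    misc = _tokens(sec("Misc"))
    # Misc: DuplexInit, TerminalAU[, LXC] (each value with its enthalpy);
    # files without an LXC entry use the standard extrapolation coefficient
    terminal_au = int(round(float(misc[2])))
    lxc = float(misc[4]) if len(misc) > 4 else 107.856

    params = EnergyParameters(
        name=name or os.path.basename(path),
        stack_table=table("stack", (7, 7)),
        hairpin_length=table("hairpin", (31,)),
        bulge_length=table("bulge", (31,)),
        internal_length=table("internal", (31,)),
        mismatch_hairpin=table("mismatch_hairpin", (7, 5, 5)),
        mismatch_internal=table("mismatch_internal", (7, 5, 5)),
        mismatch_internal_1n=table("mismatch_internal_1n", (7, 5, 5)),
        mismatch_internal_23=table("mismatch_internal_23", (7, 5, 5)),
        dangle5=table("dangle5", (7, 5)),
        dangle3=table("dangle3", (7, 5)),
        int11=table("int11", (7, 7, 5, 5)),
        int21=table("int21", (7, 7, 5, 5, 5)),
        int22=table("int22", (6, 6, 4, 4, 4, 4)),
        tetraloop_bonus=_special_loops(sec("Tetraloops")),
        triloop_bonus=_special_loops(sections.get("Triloops", "")),
        hexaloop_bonus=_special_loops(sections.get("Hexaloops", "")),
        ninio=ninio[0],
        ninio_max=ninio[2],
        terminal_au=terminal_au,
        lxc=lxc,
        ml_offset=ml[2],
        ml_branch=ml[4],
        ss_unpaired=ml[0],
        single_base=0,
        source=os.path.abspath(path),
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# Bundled set lookup

_SET_FILES = {
    "turner1999": "rna_turner1999.par",
    "turner2004": "rna_turner2004.par",
}

_cache: Dict[str, EnergyParameters] = {}


def _vienna_share_dirs() -> List[str]:
    dirs = []
    env = os.environ.get("FOLDSPACE_PARAM_DIR")
    if env:
        dirs.append(env)
    exe = shutil.which("RNAfold") or shutil.which("RNAeval")
    if exe:
        prefix = os.path.dirname(os.path.dirname(os.path.realpath(exe)))
        dirs.append(os.path.join(prefix, "share", "ViennaRNA"))
    import sys

    dirs.append(os.path.join(sys.prefix, "share", "ViennaRNA"))
    return dirs


def load_parameters(set_name: str = "turner1999") -> EnergyParameters:
    """Load a named nearest-neighbor parameter set.

    ``set_name`` is one of ``"turner1999"`` (default) or ``"turner2004"``,
    or a path to a ViennaRNA v2.0 parameter file.  Named sets are resolved
    against the ViennaRNA data directory of the active environment, so the
    tables are bit-identical to the distribution that RNAfold/RNAeval use.
    """
    if set_name in _cache:
        return _cache[set_name]
    if os.path.isfile(set_name):
        p = parse_parameter_file(set_name)
        _cache[set_name] = p
        return p
    if set_name not in _SET_FILES:
        raise ParameterError(
            f"unknown parameter set {set_name!r}; expected one of "
            f"{sorted(_SET_FILES)} or a parameter-file path"
        )
    fname = _SET_FILES[set_name]
    for d in _vienna_share_dirs():
        path = os.path.join(d, fname)
        if os.path.isfile(path):
            p = parse_parameter_file(path, name=set_name)
            _cache[set_name] = p
            return p
    raise ParameterError(
        f"parameter file {fname} not found; set FOLDSPACE_PARAM_DIR to the "
        "directory containing the ViennaRNA parameter files"
    )
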