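import pytest

from foldspace.params import load_parameters

SHIFT_EXAMPLE_SEQ = "GACCAAAGCCUUUGUCCCACAAAUUGCGAUCGCGUCGCGGAGC"

#: printed level-5 shape probabilities for the sequence above (percent)
SHIFT_EXAMPLE_PROBS = {
    "MacroState": {"[][]": 58.44, "[[][]]": 29.32, "[]": 12.24},
    "MicroState": {"[][]": 32.58, "[[][]]": 63.43, "[]": 3.99},
}

#: the worked 47-nt example structure and its printed shapes
EXAMPLE_STRUCTURE = "((.((((..(((...))).....((.((.....))...)).))))))"
EXAMPLE_SHAPES = {2: "[_[[][_[]_]]]", 5: "[[][]]"}

#: the dangle-variant example: 5 printed variants "and 31 more"
DANGLE_EXAMPLE = "((..((...)).((...)).))"
DANGLE_EXAMPLE_TOTAL = 36


@pytest.fixture(scope="session")
def params():
    return load_parameters("turner1999")
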