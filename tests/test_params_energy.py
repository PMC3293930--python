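"""Parameter loading and the elementary energy functions."""

import math
import subprocess

import pytest

from foldspace import energy as en
from foldspace.params import ParameterError, load_parameters
from foldspace.structures import evaluate_structure_energy, parse_dotbracket


class TestLoadParameters:
    def test_turner1999_scalars(self, params):
        # multiloop penalties of the shared model, centi-kcal/mol
        assert params.ml_offset == 340
        assert params.ml_branch == 40
        assert params.ss_unpaired == 0
        assert params.single_base == 0
        assert params.terminal_au == 50

    def test_rt_at_37C(self, params):
        assert params.temperature_K == pytest.approx(310.15)
        assert params.rt == pytest.approx(0.61633, abs=5e-6)

    def test_unknown_set_rejected(self):
        with pytest.raises(ParameterError):
            load_parameters("nosuchset")

    def test_malformed_file_names_table(self, tmp_path):
        bad = tmp_path / "bad.par"
        bad.write_text("## RNAfold parameter file v2.0\n\n# stack\n1 2 3\n")
        with pytest.raises(ParameterError):
            load_parameters(str(bad))

    def test_turner2004_also_loads(self):
        p = load_parameters("turner2004")
        assert p.ml_offset != 0 and len(p.tetraloop_bonus) > 0


class TestElementaryFunctions:
    def test_stack_is_context_free_lookup(self, params):
        e1 = en.sr_energy("GC", "CG", params)
        e2 = en.sr_energy("GC", "CG", params)
        assert e1 == e2 and isinstance(e1, int)

    def test_stack_rejects_noncanonical(self, params):
        with pytest.raises(en.EnergyError):
            en.sr_energy("AA", "GC", params)

    def test_termau_values(self, params):
        assert en.termau_energy("GC", params) == 0
        assert en.termau_energy("CG", params) == 0
        assert en.termau_energy("AU", params) == params.terminal_au
        assert en.termau_energy("UG", params) == en.termau_energy("GU", params)

    def test_hairpin_minimum_size(self, params):
        with pytest.raises(en.EnergyError):
            en.hairpin_energy("GC", "AA", params)

    def test_hairpin_is_length_plus_context(self, params):
        # size-5 loop: tabulated length penalty plus terminal mismatch
        e = en.hairpin_energy("GC", "AAAAA", params)
        expected = params.hairpin_length[5] + params.mismatch_hairpin[1][1][1]
        assert e == expected

    def test_hairpin_size3_uses_terminal_au(self, params):
        e = en.hairpin_energy("AU", "CCC", params)
        assert e == params.hairpin_length[3] + params.terminal_au

    def test_tetraloop_replaces_hairpin_term(self, params):
        assert en.hairpin_energy("GC", "GGGA", params) == params.tetraloop_bonus[
            "GGGGAC"
        ]

    def test_bulge_bounds(self, params):
        with pytest.raises(en.EnergyError):
            en.bulge_energy("left", "GC", "GC", "", params)
        with pytest.raises(en.EnergyError):
            en.bulge_energy("left", "GC", "GC", "A" * 31, params)

    def test_bulge_one_keeps_stack(self, params):
        e = en.bulge_energy("left", "GC", "GC", "A", params)
        assert e == params.bulge_length[1] + en.sr_energy("GC", "GC", params)

    def test_bulge_sides_share_length_penalty(self, params):
        el = en.bulge_energy("left", "GC", "CG", "AAAA", params)
        er = en.bulge_energy("right", "GC", "CG", "AAAA", params)
        assert el == er  # no terminal-AU asymmetry for GC/CG closings

    def test_internal_requires_both_regions(self, params):
        with pytest.raises(en.EnergyError):
            en.internal_energy("GC", "GC", "", "A", params)

    def test_internal_1x1_uses_special_table(self, params):
        # inner pair seen from the far side: C:G closing, C:G inner reversed
        e = en.internal_energy("CG", "CG", "A", "A", params)
        assert e == params.int11[0][1][1][1]

    def test_multiloop_terms(self, params):
        assert en.multiloop_terms(2, params) == 340 + 3 * 40
        with pytest.raises(en.EnergyError):
            en.multiloop_terms(1, params)

    def test_dangle_requires_base(self, params):
        with pytest.raises(en.EnergyError):
            en.dangle_energy("dl", "GC", None, None, params)

    def test_dli_is_reversed_dr(self, params):
        for b in "ACGU":
            assert en.dangle_energy("dli", "GC", b, None, params) == en.dangle_energy(
                "dr", "CG", None, b, params
            )

    def test_ext_mismatch_is_additive(self, params):
        both = en.dangle_energy("ext_mismatch", "GC", "A", "U", params)
        assert both == en.dangle_energy(
            "dl", "GC", "A", None, params
        ) + en.dangle_energy("dr", "GC", None, "U", params)

    def test_boltzmann_weight(self, params):
        assert en.boltzmann_weight(0.0, params) == 1.0
        assert en.boltzmann_weight(-params.rt * math.log(2), params) == pytest.approx(
            2.0
        )
        assert en.boltzmann_weight(1.0, params) < en.boltzmann_weight(0.5, params)
        with pytest.raises(en.EnergyError):
            en.boltzmann_weight(math.inf, params)


class TestReferenceEvaluator:
    """Full-structure energies against RNAeval (independent implementation
    of the same nearest-neighbor model) for every dangle mode."""

    CASES = [
        ("CGGGGACG", "((....))"),
        ("GGGCGCAAGCCC", "((((....))))"),
        ("AUAAAAU", "((...))"),
        ("GGAGGAAACCCC", "((.((...))))"),
        ("GGAAGGAAACCAAACC", "((..((...))...))"),
        ("GGAAAGGAAACCAAACC", "((...((...))...))"),
        ("GCAGGAAACCAAGGAAACCAAGC", "((.((...))..((...))..))"),
        ("AAGGGAAACCCAAGGGAAACCCAA", "..(((...)))..(((...))).."),
        ("GGGUAAUUUUGACAGGUCACGCAGAGGCGCGCCCUCCUGAAGUGCGUGGACACUC",
         "((((..(((((...(....).))))).(((((.((.....)).)))))...))))"),
    ]

    @pytest.mark.parametrize(
        "dangle,model", [(0, "NoDangle"), (2, "OverDangle"), (1, "MicroState")]
    )
    def test_matches_rnaeval(self, params, dangle, model):
        inp = "\n".join(f"{s}\n{d}" for s, d in self.CASES) + "\n"
        out = subprocess.run(
            ["RNAeval", f"-d{dangle}", "-P", params.source],
            input=inp,
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        ref = [
            float(line.rpartition("(")[2].rstrip(")"))
            for line in out.splitlines()
            if line.strip().endswith(")") and line.split()[0][0] in "()."
        ]
        assert len(ref) == len(self.CASES)
        for (seq, db), expected in zip(self.CASES, ref):
            mine = evaluate_structure_energy(
                seq, parse_dotbracket(db), model, params
            )
            assert mine == pytest.approx(expected, abs=0.005), (seq, db, model)
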