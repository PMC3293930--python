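"""Grammar walkers against the brute-force oracle, plus analysis-level
behavior (co-optimals, suboptimal enumeration, shape distributions)."""

import math

import pytest

import foldspace as fs
from foldspace.engine import count_structures_generic
from foldspace.structures import MicroStructure

MODELS = fs.MODELS


def _corpus():
    seqs = []
    for k, n in enumerate((10, 12, 14, 16, 18)):
        seqs.extend(fs.random_sequences(n, 4, seed=200 + k))
    return seqs


class TestOracleEquivalence:
    @pytest.mark.parametrize("model", MODELS)
    def test_count_mfe_q_match_brute_force(self, params, model):
        for seq in _corpus():
            bf = fs.brute_force_fold(seq, model, params)
            assert fs.count_structures(seq, model) == bf.count
            assert count_structures_generic(seq, model) == bf.count
            res = fs.fold_mfe(seq, model, params)
            assert res.energy == pytest.approx(bf.mfe, abs=1e-9)
            q = fs.partition_function(seq, model, params).q
            assert q == pytest.approx(bf.q, rel=1e-9)

    @pytest.mark.parametrize("model", MODELS)
    def test_shape_masses_match_brute_force(self, params, model):
        for seq in _corpus()[::2]:
            bf = fs.brute_force_fold(seq, model, params)
            for level in (1, 2, 5):
                sd = fs.shape_distribution(seq, model, level, params, cutoff=0)
                ref = bf.shape_masses(level)
                assert set(sd.as_dict()) == set(ref)
                for e in sd.entries:
                    mass, best_e, _ = ref[e.shape]
                    assert e.mass == pytest.approx(mass, rel=1e-9)
                    assert e.shrep_energy == pytest.approx(best_e, abs=1e-9)
                assert sum(e.mass for e in sd.entries) == pytest.approx(
                    sd.q, rel=1e-9
                )

    @pytest.mark.parametrize("model", MODELS)
    def test_all_cooptimals_reported(self, params, model):
        for seq in _corpus()[::2]:
            bf = fs.brute_force_fold(seq, model, params)
            res = fs.fold_mfe(seq, model, params)
            got = {
                (s.base if isinstance(s, MicroStructure) else s).dotbracket
                for s in res.structures
            }
            want = {
                (s.base if isinstance(s, MicroStructure) else s).dotbracket
                for s in bf.mfe_structures
            }
            assert got == want


class TestTrivialInputs:
    @pytest.mark.parametrize("model", MODELS)
    def test_unfoldable_sequence(self, params, model):
        res = fs.fold_mfe("AAAAAAA", model, params)
        assert res.energy == 0.0
        assert [str(s) for s in res.structures] == ["......."]
        assert fs.count_structures("AAAAAAA", model) == 1
        assert fs.partition_function("AAAAAAA", model, params).q == pytest.approx(1.0)

    def test_short_sequence_single_shape(self, params):
        sd = fs.shape_distribution("AAAA", "MacroState", 5, params)
        assert sd.as_dict() == {"_": pytest.approx(1.0)}

    @pytest.mark.parametrize("model", MODELS)
    def test_empty_sequence_rejected(self, params, model):
        with pytest.raises(ValueError):
            fs.fold_mfe("", model, params)


class TestSuboptimals:
    def test_delta_zero_equals_cooptimal_set(self, params):
        seq = fs.random_sequences(16, 1, seed=220)[0]
        subs = fs.enumerate_suboptimals(seq, "NoDangle", 0.0, params=params)
        res = fs.fold_mfe(seq, "NoDangle", params)
        assert {str(s) for s, _ in subs} == {str(s) for s in res.structures}

    @pytest.mark.parametrize("model", MODELS)
    def test_full_enumeration_matches_folding_space(self, params, model):
        for seq in fs.random_sequences(14, 4, seed=221):
            subs = fs.enumerate_suboptimals(seq, model, None, params=params)
            bf = fs.brute_force_fold(seq, model, params)
            assert len(subs) == bf.count  # completeness and unambiguity
            assert len({str(s) for s, _ in subs}) == bf.count  # no duplicates
            energies = [e for _, e in subs]
            assert energies == sorted(energies)

    def test_band_enumeration_is_exact(self, params):
        seq = fs.random_sequences(16, 1, seed=222)[0]
        full = fs.enumerate_suboptimals(seq, "OverDangle", None, params=params)
        mfe = full[0][1]
        band = fs.enumerate_suboptimals(seq, "OverDangle", 1.5, params=params)
        want = [(str(s), e) for s, e in full if e <= mfe + 1.5 + 1e-9]
        assert [(str(s), e) for s, e in band] == want

    def test_overdangle_enumeration_rescored_to_microstate(self, params):
        # the RNAsubopt -d1 protocol: enumerate under OverDangle, then
        # re-evaluate with proper dangles; the ranking may change
        seq = fs.random_sequences(30, 40, seed=9)[0]
        out = fs.enumerate_suboptimals(
            seq, "OverDangle", 3.0, rescore_to="MicroState", params=params
        )
        energies = [e for _, e in out]
        assert energies == sorted(energies)
        for s, e in out[:5]:
            assert fs.evaluate_structure_energy(
                seq, s, "MicroState", params
            ) == pytest.approx(e, abs=1e-9)


class TestModelRelations:
    def test_microstate_counts_sum_variant_products(self, params):
        for seq in fs.random_sequences(16, 6, seed=230):
            total = sum(
                len(fs.enumerate_dangle_variants(s))
                for s in fs.oracle.enumerate_structures(seq)
            )
            assert fs.count_structures(seq, "MicroState") == total

    def test_microstate_mfe_never_above_nodangle(self, params):
        for seq in fs.random_sequences(25, 20, seed=231):
            em = fs.fold_mfe(seq, "MicroState", params).energy
            en_ = fs.fold_mfe(seq, "NoDangle", params).energy
            assert em <= en_ + 1e-9

    def test_microstate_q_at_least_nodangle(self, params):
        for seq in fs.random_sequences(16, 8, seed=232):
            qm = fs.partition_function(seq, "MicroState", params).q
            qn = fs.partition_function(seq, "NoDangle", params).q
            assert qm >= qn - 1e-12
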