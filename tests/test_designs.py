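"""Design-engine tests: growth semantics, compatibility checks and exact
agreement with an independently coded brute-force recursion."""

import pytest

import deldesign as dd
from deldesign.building_blocks import bbs_by_bbt
from deldesign.designs import (
    DesignError,
    apply_connection,
    apply_deprotection,
    check_compatibility,
    finalize,
    grow_all,
    init_edesigns,
    load_designs,
    parse_trace_line,
    replay,
    save_designs,
)
from deldesign.ontology import OntologyError, canonical_bbt
from deldesign.reactions import Reaction, ReactionFGMatrices

from conftest import oracle_designs, trace_key


@pytest.fixture(scope="module")
def onto():
    return dd.default_ontology()


@pytest.fixture(scope="module")
def rxns():
    return dd.default_reactions()


EMPTY = ReactionFGMatrices()


class TestInit:
    def test_one_design_per_headpiece(self, onto):
        designs = init_edesigns([3, 6, 9], onto)
        assert len(designs) == 3
        assert designs[0].live_fgs == (3,)

    def test_duplicates_deduplicated(self, onto):
        assert len(init_edesigns([3, 3, 3], onto)) == 1

    def test_unknown_fg(self, onto):
        with pytest.raises(OntologyError):
            init_edesigns([999], onto)


class TestDeprotection:
    def test_boc_removal(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        d = apply_connection(d, rxns["c_acyl_pri"], canonical_bbt([6, 17]))
        assert d.live_fgs == (17,)
        d2 = apply_deprotection(d, rxns["d_boc"])
        assert d2.live_fgs == (3,)
        assert d.live_fgs == (17,)  # pure: original untouched

    def test_cyanuric_scaffold_adds_triazine(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        d2 = apply_deprotection(d, rxns["d_cyanuric"])
        assert d2.live_fgs == (21,)
        assert rxns["d_cyanuric"].scaffold_atoms == 8  # ring C3N3 + 2 Cl

    def test_missing_fg_errors(self, onto, rxns):
        d = init_edesigns([6], onto)[0]
        with pytest.raises(DesignError, match="fg_not_available"):
            apply_deprotection(d, rxns["d_boc"])


class TestConnection:
    def test_amidation_consumes_both_fgs(self, onto, rxns):
        d = init_edesigns([6], onto)[0]
        d2 = apply_connection(d, rxns["c_amide_pri"], canonical_bbt([3]))
        assert d2.live_fgs == ()  # the amide formed is not a tracked FG
        assert d2.n_cycles_done == 1 and len(d2.nodes) == 1

    def test_snar_creates_new_fg(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        d = apply_deprotection(d, rxns["d_cyanuric"])
        d = apply_connection(d, rxns["c_snar_phenol"], canonical_bbt([9]))
        assert d.live_fgs == (22,)  # monochlorotriazine, still reactive

    def test_bb_spectator_fgs_become_live(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        d = apply_connection(d, rxns["c_acyl_pri"], canonical_bbt([6, 9, 17]))
        assert d.live_fgs == (9, 17)

    def test_incompatible_bb_fg_rejected(self, onto, rxns):
        matrices = ReactionFGMatrices(off_dna={("c_acyl_pri", 7)})
        d = init_edesigns([3], onto)[0]
        with pytest.raises(DesignError, match="incompatible"):
            apply_connection(d, rxns["c_acyl_pri"], canonical_bbt([6, 7]), matrices)


class TestCompatibility:
    def test_empty_matrices_always_ok(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        assert check_compatibility(d, rxns["c_acyl_pri"], canonical_bbt([6]), EMPTY) is None

    def test_live_spectator_blocks_on_dna(self, onto, rxns):
        matrices = ReactionFGMatrices(on_dna={("c_acyl_sec", 9)})
        d = init_edesigns([3], onto)[0]
        # reductive amination with an aldehyde-phenol BB leaves a live
        # phenol spectator next to the new secondary amine
        d = apply_connection(d, rxns["c_red_am"], canonical_bbt([7, 9]))
        assert set(d.live_fgs) == {4, 9}
        violation = check_compatibility(d, rxns["c_acyl_sec"], canonical_bbt([6]), matrices)
        assert violation is not None and "on_dna" in violation

    def test_consumed_fg_is_exempt(self, onto, rxns):
        # the reaction's own input FG never blocks it
        matrices = ReactionFGMatrices(on_dna={("c_acyl_pri", 3)})
        d = init_edesigns([3], onto)[0]
        assert check_compatibility(d, rxns["c_acyl_pri"], canonical_bbt([6]), matrices) is None

    def test_asymmetric_on_off_dna(self, onto, rxns):
        # phenol allowed on the design during triazine amination, blocked
        # when it arrives on the incoming BB
        matrices = ReactionFGMatrices(off_dna={("c_snar_am_pri", 9)})
        d = init_edesigns([3], onto)[0]
        d = apply_deprotection(d, rxns["d_cyanuric"])
        d = apply_connection(d, rxns["c_snar_phenol"], canonical_bbt([9]))
        ok = check_compatibility(d, rxns["c_snar_am_pri"], canonical_bbt([3]), matrices)
        assert ok is None
        bad = check_compatibility(d, rxns["c_snar_am_pri"], canonical_bbt([3, 9]), matrices)
        assert bad is not None and "off_dna" in bad


class TestGrowAll:
    def test_single_cycle_counting(self, onto):
        # 1 headpiece, 1 connecting reaction, k compatible mono BBTs -> k designs
        rxn = Reaction(rxn_id="r", kind="connecting", inputs=(3, 6))
        bbts = [canonical_bbt([6]), canonical_bbt([6, 9]), canonical_bbt([6, 17])]
        out = grow_all(init_edesigns([3], onto), [rxn], bbts, EMPTY, 1)
        assert len(out) == 3

    @pytest.mark.parametrize("n_cycles", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, small_system, small_processed, n_cycles):
        sys_ = small_system
        bbts = sorted(bbs_by_bbt(small_processed))
        got = grow_all(
            init_edesigns(sys_.headpiece_fgs, sys_.ontology),
            list(sys_.reactions), bbts, sys_.matrices, n_cycles,
        )
        expected = oracle_designs(
            sys_.headpiece_fgs[0], list(sys_.reactions), bbts, sys_.matrices, n_cycles
        )
        assert {trace_key(d) for d in got} == expected
        assert len(got) == len(expected)  # no duplicates either

    def test_oracle_with_incompatibilities(self, small_system, small_processed):
        sys_ = small_system
        bbts = sorted(bbs_by_bbt(small_processed))
        matrices = ReactionFGMatrices(
            on_dna={("c_red_am", 17)}, off_dna={("c_acyl_pri", 7)}
        )
        got = grow_all(
            init_edesigns([3], sys_.ontology), list(sys_.reactions), bbts, matrices, 2
        )
        expected = oracle_designs(3, list(sys_.reactions), bbts, matrices, 2)
        assert {trace_key(d) for d in got} == expected

    def test_one_deprotection_per_cycle(self, onto, rxns):
        # a design that would need Fmoc AND Boc removal before connecting
        # in the same cycle is never generated
        bbt_two_prot = canonical_bbt([6, 17, 18])
        reactions = [rxns["c_acyl_pri"], rxns["d_boc"], rxns["d_fmoc"]]
        out = grow_all(init_edesigns([3], onto), reactions, [bbt_two_prot], EMPTY, 2)
        # cycle 2 can remove one protecting group and acylate the revealed
        # amine, but no trace ever contains two deprotections in one cycle
        assert out
        for d in out:
            for t in d.trace:
                assert t.deprotection_id in ("", "d_boc", "d_fmoc")
        live_sets = {d.live_fgs for d in out}
        assert all(len([f for f in fgs if f in (17, 18)]) >= 1 for fgs in live_sets)

    def test_monotone_in_inputs(self, small_system, small_processed):
        sys_ = small_system
        bbts = sorted(bbs_by_bbt(small_processed))
        base = grow_all(
            init_edesigns([3], sys_.ontology),
            [sys_.reactions["c_acyl_pri"], sys_.reactions["d_boc"]],
            bbts, sys_.matrices, 2,
        )
        more_rxn = grow_all(
            init_edesigns([3], sys_.ontology), list(sys_.reactions), bbts,
            sys_.matrices, 2,
        )
        fewer_bbt = grow_all(
            init_edesigns([3], sys_.ontology),
            [sys_.reactions["c_acyl_pri"], sys_.reactions["d_boc"]],
            bbts[:-1], sys_.matrices, 2,
        )
        assert len(more_rxn) >= len(base) >= len(fewer_bbt)
        assert {trace_key(d) for d in base} <= {trace_key(d) for d in more_rxn}

    def test_overflow_guard(self, small_system, small_processed):
        sys_ = small_system
        bbts = sorted(bbs_by_bbt(small_processed))
        from deldesign.designs import DesignSpaceOverflow

        with pytest.raises(DesignSpaceOverflow):
            grow_all(
                init_edesigns([3], sys_.ontology), list(sys_.reactions), bbts,
                sys_.matrices, 2, max_designs=2,
            )


class TestFinalize:
    def test_empty_disallowed_is_identity(self, small_system, small_processed):
        sys_ = small_system
        out = grow_all(
            init_edesigns([3], sys_.ontology), list(sys_.reactions),
            sorted(bbs_by_bbt(small_processed)), sys_.matrices, 2,
        )
        assert finalize(out, []) == out

    def test_disallowed_final_fg_removed(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        d = apply_connection(d, rxns["c_acyl_pri"], canonical_bbt([6, 9, 17]))
        kept = finalize([d], [17])
        assert kept == []

    def test_matches_bruteforce_filter(self, small_system, small_processed):
        sys_ = small_system
        out = grow_all(
            init_edesigns([3], sys_.ontology), list(sys_.reactions),
            sorted(bbs_by_bbt(small_processed)), sys_.matrices, 2,
        )
        survivors = finalize(out, [17])
        assert {trace_key(d) for d in survivors} == {
            trace_key(d) for d in out if 17 not in d.live_fgs
        }


class TestTraceReplay:
    def test_round_trip_all_small_designs(self, small_system, small_processed, tmp_path):
        sys_ = small_system
        out = grow_all(
            init_edesigns([3], sys_.ontology), list(sys_.reactions),
            sorted(bbs_by_bbt(small_processed)), sys_.matrices, 3,
        )
        path = tmp_path / "designs.txt"
        save_designs(out, path)
        loaded = load_designs(path, list(sys_.reactions), sys_.ontology)
        assert loaded == out  # replay reproduces identical state, live FGs included

    def test_parse_inverse(self, onto, rxns):
        d = init_edesigns([3], onto)[0]
        d = apply_deprotection(d, rxns["d_cyanuric"])
        d = apply_connection(
            d, rxns["c_snar_phenol"], canonical_bbt([9]),
            deprotection=("d_cyanuric", 0),
        )
        hp, steps = parse_trace_line(d.trace_line())
        assert replay(hp, steps, list(rxns), onto) == d
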