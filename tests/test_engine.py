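"""Rule-engine behaviour: consensus policy, each rule, and brute-force
truth-table equivalence over all boolean feature combinations."""

import itertools

import pytest

from mispredqc import (
    EngineConfig,
    compute_flag_percentage,
    consensus_topology,
    effective_tm_helices,
    evaluate,
)
from mispredqc.engine import rule4_domain_size_deviation

from conftest import hit, make_record


class TestConsensusTopology:
    def test_single_positive_vote_makes_feature_present(self):
        votes = {
            "signal_peptide": [("SignalP", True, (1, 22)), ("PrediSi", False, None)]
        }
        topo = consensus_topology(votes)
        assert topo.signal_peptide is not None
        assert topo.signal_peptide.end == 22

    def test_unanimous_absence_makes_feature_absent(self):
        votes = {"tm_helix": [("TMHMM", False, None), ("Phobius", False, None)]}
        assert consensus_topology(votes).tm_helices == []

    def test_single_predictor_with_two_helices(self):
        votes = {
            "tm_helix": [
                ("TMHMM", True, (100, 122)),
                ("TMHMM", True, (200, 222)),
            ]
        }
        assert consensus_topology(votes).tm_helices == [(100, 122), (200, 222)]

    def test_span_of_present_feature_is_union_of_supporting_calls(self):
        votes = {
            "signal_peptide": [("SignalP", True, (1, 20)), ("PrediSi", True, (1, 24))]
        }
        assert consensus_topology(votes).signal_peptide.end == 24

    def test_majority_mode_requires_more_yes_than_no(self):
        votes = {
            "signal_peptide": [("SignalP", True, (1, 22)), ("PrediSi", False, None)]
        }
        config = EngineConfig(consensus_mode="majority")
        assert consensus_topology(votes, config).signal_peptide is None

    def test_nterminal_helix_without_sp_becomes_signal_anchor(self):
        votes = {"tm_helix": [("TMHMM", True, (8, 30))]}
        topo = consensus_topology(votes)
        assert topo.signal_anchor == (8, 30)
        assert topo.tm_helices == []

    def test_nterminal_helix_with_sp_stays_a_helix(self):
        votes = {
            "signal_peptide": [("SignalP", True, (1, 22))],
            "tm_helix": [("TMHMM", True, (8, 30))],
        }
        topo = consensus_topology(votes)
        assert topo.signal_anchor is None
        assert topo.tm_helices == [(8, 30)]


class TestEffectiveTmHelices:
    def test_helix_overlapping_signal_peptide_is_reclassified(self):
        record = make_record(sp_end=22, helices=[(5, 25)])
        assert effective_tm_helices(record) == []

    def test_mid_protein_helix_is_retained(self):
        record = make_record(sp_end=22, helices=[(200, 222)])
        assert effective_tm_helices(record) == [(200, 222)]

    def test_cterminal_helix_on_gpi_protein_is_the_gpi_signal(self):
        seq = "M" + "A" * 299  # length 300
        record = make_record(seq=seq, sp_end=22, helices=[(270, 292)], gpi=288)
        assert effective_tm_helices(record) == []

    def test_cterminal_helix_without_gpi_is_retained(self):
        seq = "M" + "A" * 299
        record = make_record(seq=seq, sp_end=22, helices=[(270, 292)])
        assert effective_tm_helices(record) == [(270, 292)]


EXT = hit("PF00051.10", "Kringle", 40, 80)
CYTO = hit("PF00017", "SH2", 140, 78)
NUC = hit("PF00046", "Homeodomain", 240, 57)


class TestIndividualRules:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # rule 1: extracellular domain needs an export signal
            (dict(hits=[EXT]), {1}),
            (dict(hits=[EXT], sp_end=22), set()),
            (dict(hits=[EXT], helices=[(200, 222)]), set()),
            (dict(), set()),
            # rule 2: extra + cyto need a membrane-spanning helix
            (dict(hits=[EXT, CYTO], anchor=(1, 25)), {2}),
            (dict(hits=[EXT, CYTO], sp_end=22, helices=[(200, 222)]), set()),
            (dict(hits=[CYTO]), set()),
            # rule 3 is unconditional, even with a helix
            (dict(hits=[EXT, NUC], sp_end=22), {3}),
            (dict(hits=[EXT, NUC], sp_end=22, helices=[(200, 222)]), {3}),
            (dict(hits=[NUC]), set()),
            # rule 6: SP + cytoplasmic domain need a helix
            (dict(hits=[CYTO], sp_end=22), {6}),
            (dict(hits=[CYTO], sp_end=22, helices=[(300, 322)]), set()),
            (dict(sp_end=22), set()),
            # rules 7-10: GPI logic
            (dict(gpi=390), {7}),
            (dict(gpi=390, sp_end=22), set()),
            (dict(gpi=390, sp_end=22, hits=[CYTO]), {6, 8}),
            (dict(gpi=390, sp_end=22, hits=[NUC]), {9}),
            (dict(gpi=390, sp_end=22, helices=[(200, 222)]), {10}),
            (dict(gpi=390, sp_end=22, helices=[(370, 392)]), set()),
        ],
    )
    def test_rule_outcomes_on_engineered_records(
        self, registries, kwargs, expected, config
    ):
        report = evaluate(make_record(**kwargs), registries, config)
        assert report.rule_ids == expected

    def test_helix_in_cterminal_window_counts_for_rule6(self, registries):
        # {6,11} case above uses a helix inside the GPI window on a
        # non-GPI protein: without GPI it still spans the membrane
        record = make_record(hits=[CYTO], sp_end=22, helices=[(370, 392)])
        report = evaluate(record, registries)
        assert 6 not in report.rule_ids


class TestRule4:
    def test_deviation_beyond_k_sd_is_flagged(self, registries, config):
        # reference 80, sd 6, k 2.5: |64 - 80| = 16 > 15
        record = make_record(hits=[hit("PF00051", "Kringle", 40, 64)], sp_end=22)
        conflict = rule4_domain_size_deviation(record, registries.sizes, config)
        assert conflict is not None and conflict.rule_id == 4

    def test_exact_reference_length_is_clean(self, registries, config):
        record = make_record(hits=[hit("PF00051", "Kringle", 40, 80)], sp_end=22)
        assert rule4_domain_size_deviation(record, registries.sizes, config) is None

    def test_boundary_deviation_is_not_flagged(self, registries, config):
        # |65 - 80| = 15 is exactly k*sd and therefore still normal
        record = make_record(hits=[hit("PF00051", "Kringle", 40, 65)], sp_end=22)
        assert rule4_domain_size_deviation(record, registries.sizes, config) is None

    def test_fractional_bounds_used_without_sd(self, registries, config):
        # PF00040 has no SD on record; reference 49, bounds [0.70, 1.30]
        short = make_record(hits=[hit("PF00040", "fn2", 40, 30)], sp_end=22)
        ok = make_record(hits=[hit("PF00040", "fn2", 40, 45)], sp_end=22)
        assert rule4_domain_size_deviation(short, registries.sizes, config) is not None
        assert rule4_domain_size_deviation(ok, registries.sizes, config) is None

    def test_truncated_domain_flags_the_whole_record(
        self, registries, secreted_two_domain_record
    ):
        report = evaluate(secreted_two_domain_record, registries)
        assert report.rule_ids == {4}
        assert any("WSC" in e for c in report.conflicts for e in c.evidence)


class TestRule5AndSkips:
    def test_segments_on_two_chromosomes_flag_a_chimera(self, registries):
        from mispredqc import SegmentMapping

        maps = [
            SegmentMapping(1, "chr3", "+", 0.99, 0.95, 940.0),
            SegmentMapping(2, "chr7", "+", 0.98, 0.93, 900.0),
        ]
        report = evaluate(make_record(mappings=maps), registries)
        assert report.rule_ids == {5}

    def test_single_chromosome_is_clean(self, registries):
        from mispredqc import SegmentMapping

        maps = [
            SegmentMapping(1, "chr3", "+", 0.99, 0.95, 940.0),
            SegmentMapping(2, "chr3", "-", 0.98, 0.93, 900.0),
        ]
        assert evaluate(make_record(mappings=maps), registries).clean

    def test_no_mappings_skips_rule5_with_notice(self, registries):
        report = evaluate(make_record(), registries)
        assert 5 in {rid for rid, _ in report.skipped}

    def test_missing_predictor_votes_skip_topology_rules(self, registries):
        from mispredqc import ProteinRecord

        record = ProteinRecord(protein_id="P1", sequence="M" + "A" * 99)
        report = evaluate(record, registries)
        skipped = {rid for rid, _ in report.skipped}
        assert {1, 2, 6, 7, 8, 9, 10} <= skipped
        assert report.clean


class TestRule11:
    def test_known_architecture_is_clean(self, registries):
        record = make_record(
            hits=[EXT, hit("PF01822.14", "WSC", 150, 92)], sp_end=22
        )
        assert evaluate(record, registries).clean

    def test_reversed_order_is_a_novel_architecture(self, registries):
        record = make_record(
            hits=[hit("PF01822", "WSC", 40, 92), hit("PF00051", "Kringle", 150, 80)],
            sp_end=22,
        )
        assert evaluate(record, registries).rule_ids == {11}

    def test_repeat_collapse_equates_tandem_copies(self, registries):
        # PF00008,PF00008,PF00084 is registered; a third EGF copy still
        # collapses onto the same key
        record = make_record(
            hits=[
                hit("PF00008", "EGF", 40, 38, copy_index=1),
                hit("PF00008", "EGF", 90, 38, copy_index=2),
                hit("PF00008", "EGF", 140, 38, copy_index=3),
                hit("PF00084", "Sushi", 200, 60),
            ],
            sp_end=22,
        )
        assert evaluate(record, registries).clean

    def test_no_domains_skips_the_rule(self, registries):
        report = evaluate(make_record(sp_end=22), registries)
        assert 11 in {rid for rid, _ in report.skipped}


CORE_RULES = frozenset({1, 2, 3, 6, 7, 8, 9, 10})


def oracle(ext, cyto, nuc, sp, anchor, tm, gpi):
    """Independent restatement of the compartment/topology rules as
    plain boolean logic (the mid-protein helix used in the record
    construction is never reclassified, so effective TM == tm here)."""
    conflicts = set()
    if ext and not (sp or anchor or tm):
        conflicts.add(1)
    if ext and cyto and not tm:
        conflicts.add(2)
    if ext and nuc:
        conflicts.add(3)
    if sp and cyto and not tm:
        conflicts.add(6)
    if gpi and not sp:
        conflicts.add(7)
    if gpi and cyto:
        conflicts.add(8)
    if gpi and nuc:
        conflicts.add(9)
    if gpi and tm:
        conflicts.add(10)
    return conflicts


class TestTruthTableEquivalence:
    def test_engine_matches_brute_force_oracle_on_all_128_states(self, registries):
        config = EngineConfig(enabled_rules=CORE_RULES)
        mismatches = []
        for flags in itertools.product([False, True], repeat=7):
            ext, cyto, nuc, sp, anchor, tm, gpi = flags
            record = make_record(
                hits=[h for h, f in [(EXT, ext), (CYTO, cyto), (NUC, nuc)] if f],
                sp_end=22 if sp else None,
                anchor=(1, 25) if anchor else None,
                helices=[(300, 322)] if tm else [],
                gpi=390 if gpi else None,
            )
            got = evaluate(record, registries, config).rule_ids
            want = oracle(*flags)
            if got != want:
                mismatches.append((flags, sorted(got), sorted(want)))
        assert mismatches == []


class TestEngineProperties:
    def test_adding_an_export_signal_never_creates_rule1(self, registries):
        for kwargs in [dict(hits=[EXT]), dict(hits=[EXT, CYTO])]:
            base = evaluate(make_record(**kwargs), registries).rule_ids
            with_sp = evaluate(make_record(sp_end=22, **kwargs), registries).rule_ids
            assert 1 in base and 1 not in with_sp

    def test_removing_gpi_evidence_clears_rules_7_to_10(self, registries):
        kwargs = dict(sp_end=22, hits=[CYTO, NUC], helices=[(300, 322)])
        with_gpi = evaluate(make_record(gpi=390, **kwargs), registries).rule_ids
        without = evaluate(make_record(**kwargs), registries).rule_ids
        assert with_gpi & {8, 9, 10}
        assert not without & {7, 8, 9, 10}

    def test_evaluation_is_deterministic(self, registries):
        record = make_record(hits=[EXT, CYTO], sp_end=22, gpi=390)
        r1 = evaluate(record, registries)
        r2 = evaluate(record, registries)
        assert r1 == r2

    @pytest.mark.parametrize("disabled", [1, 4, 6, 8, 11])
    def test_disabling_a_rule_removes_exactly_that_rule(
        self, registries, disabled
    ):
        record = make_record(
            hits=[EXT, hit("PF01822", "WSC", 150, 40), CYTO],
            gpi=390,
        )
        full = evaluate(record, registries).rule_ids
        config = EngineConfig(enabled_rules=frozenset(range(1, 12)) - {disabled})
        reduced = evaluate(record, registries, config).rule_ids
        assert reduced == full - {disabled}


class TestFlagPercentage:
    @pytest.mark.parametrize(
        "total, flagged, expected",
        [
            (59000, 2245, 3.81),
            (20215, 762, 3.77),
            (598362, 65786, 10.99),
            (1000, 0, 0.00),
            (1000, 1000, 100.00),
            (800, 1, 0.13),  # 0.125 rounds half-up
        ],
    )
    def test_half_up_rounding_to_two_decimals(self, total, flagged, expected):
        assert compute_flag_percentage(total, flagged) == expected

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            compute_flag_percentage(0, 0)

    def test_flagged_above_total_is_an_error(self):
        with pytest.raises(ValueError):
            compute_flag_percentage(10, 11)
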