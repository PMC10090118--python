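import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stuckenia.genotyping import (
    CHAKASSIENSIS,
    HYBRID_B_MACROCARPA,
    MACROCARPA,
    PECTINATA_A,
    PECTINATA_B,
    UNRESOLVED,
    VAGINATA,
    KeyAnchorError,
    Rule,
    SpeciesCall,
    ambiguity_profile,
    apply_diff_events,
    classify_sample,
    count_motif,
    discordance_report,
    event_inventory,
    extract_diff_events,
    locate_rule,
    partition_groups,
)
from stuckenia.msa import Alignment, pairwise_global, progressive_msa
from stuckenia.seqio import SampleTable, SeqRecord
from stuckenia.synthdata import REF_IDS

DNA = st.text(alphabet="ACGT", min_size=5, max_size=40)


# --------------------------------------------------------------------------
# difference profiling


def test_identical_rows_give_no_events():
    assert extract_diff_events(Alignment(["a", "b"], ["ACGT", "ACGT"])) == []


def test_single_insertion_event():
    (ev,) = extract_diff_events(Alignment(["a", "b"], ["AC-GT", "ACAGT"]))
    assert (ev.kind, ev.column, ev.length) == ("insertion", 3, 1)
    assert ev.states == ("-", "A")


def test_adjacent_substitutions_merge_into_one_run():
    (ev,) = extract_diff_events(Alignment(["a", "b"], ["AACCA", "AAGGA"]))
    assert (ev.kind, ev.column, ev.length, ev.states) == (
        "substitution", 3, 2, ("CC", "GG")
    )


def test_mixed_event_kinds_do_not_merge():
    events = extract_diff_events(Alignment(["a", "b"], ["ACC--T", "ATCGGT"]))
    assert [(e.kind, e.column, e.length) for e in events] == [
        ("substitution", 2, 1),
        ("insertion", 4, 2),
    ]


@given(st.tuples(DNA, DNA))
@settings(max_examples=40)
def test_event_round_trip_reconstructs_second_row(pair):
    a, b = pair
    aln, _ = pairwise_global(
        SeqRecord(id="a", residues=a), SeqRecord(id="b", residues=b)
    )
    events = extract_diff_events(aln)
    assert apply_diff_events(aln, events) == b


@given(st.tuples(DNA, DNA))
@settings(max_examples=40)
def test_event_counts_invariant_under_row_swap(pair):
    a, b = pair
    aln, _ = pairwise_global(
        SeqRecord(id="a", residues=a), SeqRecord(id="b", residues=b)
    )
    swapped = Alignment(["b", "a"], [aln.rows[1], aln.rows[0]])
    fwd = extract_diff_events(aln)
    rev = extract_diff_events(swapped)
    exchange = {"insertion": "deletion", "deletion": "insertion",
                "substitution": "substitution"}
    assert [(exchange[e.kind], e.column, e.length) for e in fwd] == [
        (e.kind, e.column, e.length) for e in rev
    ]


def test_panel_difference_inventory_vaginata_vs_type_a(panel):
    """The defining difference set of the locus: 3 indels (1/1/9 nt) and
    16 one-nt + 2 two-nt substitution runs, re-measured from an alignment."""
    recs = {t: SeqRecord(id=REF_IDS[t], residues=s)
            for t, s in panel.haplotypes.items()}
    aln, _ = pairwise_global(recs[VAGINATA], recs[PECTINATA_A])
    inv = event_inventory(extract_diff_events(aln))
    indels = {ln: n for (k, ln), n in inv.items() if k != "substitution"}
    subs = {ln: n for (k, ln), n in inv.items() if k == "substitution"}
    assert indels == {1: 2, 9: 1}
    assert subs == {1: 16, 2: 2}


# --------------------------------------------------------------------------
# motif counting


@pytest.mark.parametrize(
    "seq,motif,mode,expected",
    [
        ("GCGCGC", "GCGC", "strict", 2),   # overlap counted
        ("AAAA", "GCGC", "strict", 0),
        ("GCSC", "GCGC", "strict", 0),
        ("GCSC", "GCGC", "compatible", 1),  # S = G/C contains G
        ("GC-GC", "GCGC", "strict", 1),     # search runs on ungapped sequence
    ],
)
def test_motif_counting(seq, motif, mode, expected):
    assert count_motif(seq, motif, mode) == expected


@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=4, max_size=60))
@settings(max_examples=40)
def test_strict_count_never_exceeds_compatible_count(seq):
    assert count_motif(seq, "GCGC", "strict") <= count_motif(seq, "GCGC", "compatible")


def test_motif_must_be_unambiguous():
    with pytest.raises(ValueError):
        count_motif("ACGT", "GCNC")


# --------------------------------------------------------------------------
# rule anchoring


def _rule(anchor, offset=1, **kw):
    return Rule(name="r", stage="x", anchor=anchor, offset=offset,
                expected={}, **kw)


def test_locate_rule_on_gap_free_reference():
    ref = "AAACCCGGGTTTACGTACGT"
    aln = Alignment(["ref", "other"], [ref, ref])
    rule = _rule("AAACCCGGGT")  # positions 1..10
    assert locate_rule(aln, rule, "ref") == 11


def test_locate_rule_ignores_gaps_in_other_rows():
    aln = Alignment(["ref", "other"], ["AAACCCGGGTTA", "AAA---GGGTTA"])
    rule = _rule("AAACCCGGGT")
    assert locate_rule(aln, rule, "ref") == 11


def test_locate_rule_follows_reference_gaps():
    # the reference row itself is gapped: the column shifts accordingly
    aln = Alignment(["ref", "other"], ["AA--ACCCGGGTTA", "AAGGACCCGGGTTA"])
    assert locate_rule(aln, _rule("AAACCCGGGT"), "ref") == 13


def test_locate_rule_anchor_errors():
    aln = Alignment(["ref"], ["AAACCCGGGTAAACCCGGGT"])
    with pytest.raises(KeyAnchorError, match="2 times"):
        locate_rule(aln, _rule("AAACCCGGGT"), "ref")
    with pytest.raises(KeyAnchorError, match="absent"):
        locate_rule(aln, _rule("TTTTTTTTTT"), "ref")


def test_key_rules_resolve_to_designated_panel_columns(panel, study_alignment):
    """Generator bookkeeping oracle: each rule lands on the column that
    carries its nominal base-coordinate position in the reference row."""
    from stuckenia.msa import map_position

    key = panel.key
    for rule in key.rules:
        col = locate_rule(study_alignment, rule, key.reference_id)
        assert col == map_position(
            study_alignment, key.reference_id, rule.nominal_position
        )


# --------------------------------------------------------------------------
# classification


@pytest.fixture(scope="module")
def typed_alignment(panel):
    """Panel haplotypes + a hybrid + crafted edge-case samples, aligned."""
    recs = panel.records()
    extra = [SeqRecord(id="hybrid_1", residues=panel.hybrid_sequence())]
    # partial hybrid signal: additivity at the first dinucleotide only
    b = panel.haplotypes[PECTINATA_B]
    d1, d2 = panel.config.dinuc_position
    partial = list(b)
    partial[d1 - 1] = "K"
    extra.append(SeqRecord(id="partial_1", residues="".join(partial)))
    # type-A haplotype with a 2-nt deletion away from any diagnostic site
    a = panel.haplotypes[PECTINATA_A]
    protected = panel.protected_positions(PECTINATA_A)
    pos = next(
        p for p in range(300, 600)
        if not any(q in protected for q in range(p - 2, p + 4))
    )
    extra.append(
        SeqRecord(id="deletion_1", residues=a[: pos - 1] + a[pos + 1:])
    )
    return progressive_msa(recs + extra)


def test_each_pure_haplotype_classifies_as_its_taxon(panel, typed_alignment):
    for taxon, rid in REF_IDS.items():
        call = classify_sample(rid, typed_alignment, panel.key)
        assert call.call == taxon, (rid, call.conflicts)
        assert call.evidence  # non-unresolved calls carry evidence
        assert not call.conflicts


def test_vaginata_call_carries_single_restriction_site_evidence(
    panel, typed_alignment
):
    call = classify_sample(REF_IDS[VAGINATA], typed_alignment, panel.key)
    assert ("motif:GCGC", "1", VAGINATA) in call.evidence


def test_hybrid_called_from_double_additivity(panel, typed_alignment):
    call = classify_sample("hybrid_1", typed_alignment, panel.key)
    assert call.call == HYBRID_B_MACROCARPA
    assert call.ambiguity_fraction > 0


def test_single_position_additivity_is_partial_signal_not_hybrid(
    panel, typed_alignment
):
    call = classify_sample("partial_1", typed_alignment, panel.key)
    assert call.call == UNRESOLVED
    assert any("partial hybrid signal" in c for c in call.conflicts)


def test_gaps_at_non_diagnostic_positions_never_block_a_call(
    panel, typed_alignment
):
    call = classify_sample("deletion_1", typed_alignment, panel.key)
    assert call.call == PECTINATA_A


def test_chakassiensis_separated_only_by_subgroup_position(panel):
    b = panel.haplotypes[PECTINATA_B]
    chak = panel.haplotypes[CHAKASSIENSIS]
    diff = [k for k in range(len(b)) if b[k] != chak[k]]
    assert diff == [panel.config.subgroup_position - 1]


def test_motif_conflict_recorded_never_dropped(panel):
    """A sample with type-B diagnostic states but a destroyed second CfoI
    site must still be called, with the disagreement surfaced."""
    b = list(panel.haplotypes[PECTINATA_B])
    m2 = panel.config.motif_positions[1]
    b[m2 + 1] = "A"  # third base of the second GCGC
    recs = panel.records() + [SeqRecord(id="odd", residues="".join(b))]
    aln = progressive_msa(recs)
    call = classify_sample("odd", aln, panel.key)
    assert call.call == PECTINATA_B
    assert any("GCGC" in c for c in call.conflicts)


# --------------------------------------------------------------------------
# grouping, ambiguity profile, discordance


def _call(sid, taxon):
    return SpeciesCall(sid, taxon, [("r", "G", taxon)], [], 0.0)


def test_partition_groups_definition():
    calls = [
        _call("v", VAGINATA), _call("a", PECTINATA_A), _call("b", PECTINATA_B),
        _call("m", MACROCARPA), _call("c", CHAKASSIENSIS),
        _call("h", HYBRID_B_MACROCARPA),
    ]
    groups, unresolved = partition_groups(calls)
    assert groups == {
        "v": "I", "a": "II", "b": "III-I", "m": "III-I",
        "h": "III-I", "c": "III-II",
    }
    assert unresolved == []


def test_partition_groups_reports_unresolved_separately():
    calls = [SpeciesCall("x", UNRESOLVED, [], ["?"], 0.0)]
    groups, unresolved = partition_groups(calls)
    assert groups == {} and unresolved == ["x"]


def test_ambiguity_profile_examples():
    prof = ambiguity_profile("ACGT")
    assert (prof.fraction, prof.positions, prof.flagged) == (0.0, [], False)
    prof = ambiguity_profile("ACKT")
    assert prof.fraction == 0.25 and prof.positions == [3] and prof.flagged


def test_polymorphic_sample_flagged_at_default_threshold(panel):
    from stuckenia.synthdata import simulate_study

    samples, truth = simulate_study(panel, seed=4)
    flagged = {
        s.id: ambiguity_profile(s.residues).flagged for s in samples
    }
    expected = dict(zip(truth["sample_id"], truth["polymorphic"]))
    # hybrids carry only the two diagnostic ambiguity codes: below threshold
    assert flagged == expected


def test_discordance_report_and_genus_synonyms():
    calls = [
        _call("s1", PECTINATA_B),       # morphology says vaginata
        _call("s2", CHAKASSIENSIS),     # Potamogeton binomial, concordant
        _call("s3", HYBRID_B_MACROCARPA),  # concordant with either parent
        _call("s4", MACROCARPA),        # morphology = call
    ]
    meta = SampleTable(
        df=pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4", "ghost"],
                "morphology_label": [
                    "S. vaginata", "P. chakassiensis",
                    "S. macrocarpa", "Stuckenia macrocarpa",
                ] + ["S. pectinata"],
            }
        )
    )
    report, orphans = discordance_report(calls, meta)
    by_id = report.set_index("sample_id")["concordant"]
    assert bool(by_id["s1"]) is False
    assert bool(by_id["s2"]) is True
    assert bool(by_id["s3"]) is True
    assert bool(by_id["s4"]) is True
    assert orphans == ["ghost"]


def test_morphology_pectinata_concordant_with_both_molecular_types():
    calls = [_call("x", PECTINATA_A), _call("y", PECTINATA_B)]
    meta = SampleTable(
        df=pd.DataFrame(
            {"sample_id": ["x", "y"],
             "morphology_label": ["S. pectinata", "S. pectinata"]}
        )
    )
    report, _ = discordance_report(calls, meta)
    assert report["concordant"].all()
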