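"""Variant calling: alignment, extraction, annotation, cohort registry."""

import numpy as np
import pytest

import mitocohort as mc
from mitocohort import simulate as sim
from mitocohort.calling import (
    CallingError,
    Variant,
    left_align_deletion,
    left_align_insertion,
)


# ---------------------------------------------------------------------------
# alignment


def test_identity_alignment_has_no_differences(ref, fixtures):
    aln = mc.global_align(fixtures["identity_genome"], ref)
    assert aln.n_mismatches == 0 and aln.n_gap_columns == 0
    assert mc.extract_variants(aln, ref) == []


def test_planted_substitution_yields_one_mismatch_column(ref):
    alt = "G" if ref.base(100) != "G" else "A"
    query = sim.apply_variants(
        ref.sequence, [Variant(100, ref.base(100), alt, "substitution")]
    )
    aln = mc.global_align(query, ref)
    assert aln.n_mismatches == 1 and aln.n_gap_columns == 0


def test_planted_deletion_yields_single_gap_run(ref):
    truth = Variant(1000, ref.sequence[999:1001], "", "deletion")
    query = sim.apply_variants(ref.sequence, [truth])
    aln = mc.global_align(query, ref)
    variants = mc.extract_variants(aln, ref)
    assert len(variants) == 1
    v = variants[0]
    assert v.kind == "deletion" and len(v.ref) == 2


def test_empty_or_invalid_query_rejected(ref):
    with pytest.raises(CallingError):
        mc.global_align("", ref)
    with pytest.raises(CallingError, match="non-nucleotide"):
        mc.global_align("ACGTX" * 4000, ref)
    with pytest.raises(CallingError, match="length"):
        mc.global_align("ACGT" * 100, ref)  # fragment without flag


def test_engines_agree_on_fragment_variants(ref):
    rng = np.random.default_rng(33)
    frag = ref.sequence[4000:6500]
    planted = [
        Variant(4500, ref.base(4500), "T" if ref.base(4500) != "T" else "A",
                "substitution"),
        Variant(5200, ref.base(5200), "C" if ref.base(5200) != "C" else "G",
                "substitution"),
    ]
    query = sim.apply_variants(frag, [
        Variant(v.position - 4000, v.ref, v.alt, v.kind) for v in planted
    ])
    for engine in ("needle", "edlib"):
        aln = mc.global_align(query, frag, engine=engine, fragment=True)
        assert aln.n_mismatches == 2


# ---------------------------------------------------------------------------
# extraction and normalization


def test_indel_left_alignment_in_homopolymer(ref):
    # find a >=4-base homopolymer and delete its LAST base: the call
    # must be reported at the run's first position
    seq = ref.sequence
    run_start = next(
        i + 1
        for i in range(2000, 4000)
        if seq[i] == seq[i + 1] == seq[i + 2] == seq[i + 3] != seq[i - 1]
    )
    assert left_align_deletion(seq, run_start + 3, 1) == run_start
    query = sim.apply_variants(
        seq, [Variant(run_start + 3, seq[run_start + 2], "", "deletion")]
    )
    aln = mc.global_align(query, ref)
    variants = mc.extract_variants(aln, ref)
    assert variants == [Variant(run_start, seq[run_start - 1], "", "deletion")]


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, derandomize=True)
@given(
    seq=st.text(alphabet="ACGT", min_size=12, max_size=40),
    pos_frac=st.floats(0.0, 1.0),
    length=st.integers(1, 3),
)
def test_deletion_left_alignment_preserves_result(seq, pos_frac, length):
    """Deleting at the left-aligned coordinate yields the same sequence,
    and no further left shift is possible."""
    pos = 1 + int(pos_frac * (len(seq) - length - 1))
    shifted = left_align_deletion(seq, pos, length)
    assert 1 <= shifted <= pos
    original = seq[: pos - 1] + seq[pos - 1 + length :]
    canonical = seq[: shifted - 1] + seq[shifted - 1 + length :]
    assert original == canonical
    if shifted > 1:  # maximally shifted
        assert seq[shifted - 2] != seq[shifted + length - 2]


@settings(max_examples=200, derandomize=True)
@given(
    seq=st.text(alphabet="ACGT", min_size=12, max_size=40),
    anchor_frac=st.floats(0.0, 1.0),
    inserted=st.text(alphabet="ACGT", min_size=1, max_size=3),
)
def test_insertion_left_alignment_preserves_result(seq, anchor_frac, inserted):
    anchor = int(anchor_frac * len(seq))
    new_anchor, new_bases = left_align_insertion(seq, anchor, inserted)
    assert 0 <= new_anchor <= anchor
    original = seq[:anchor] + inserted + seq[anchor:]
    canonical = seq[:new_anchor] + new_bases + seq[new_anchor:]
    assert original == canonical


def test_insertion_left_alignment_rotates_bases():
    #      123456
    # seq  TTACCA ; inserting CC after position 5 == inserting CC after
    # position 3 (slides through the CC run); the non-sliding case stays put
    assert left_align_insertion("TTACCA", 5, "CC") == (3, "CC")
    assert left_align_insertion("TTACCA", 5, "CA") == (5, "CA")


def test_ambiguous_call_preserved_with_definite_flag_false(ref, fixtures):
    calls = mc.call_sample(fixtures["ambiguity_genome"], ref)
    assert len(calls) == 1
    v, ann = calls[0]
    assert v == Variant(93, "A", "R", "substitution")
    assert not ann.definite and ann.transition is None


def test_rcrs_placeholder_position_not_callable(ref):
    # a query with a real base at the reference N (3107) is not a variant
    query = ref.sequence[:3106] + "C" + ref.sequence[3107:]
    calls = mc.call_sample(query, ref)
    assert calls == []


# ---------------------------------------------------------------------------
# annotation


def test_worked_annotation_examples(ref):
    v, ann = Variant(14308, "T", "C", "substitution"), None
    ann = mc.annotate_variant(v, ref)
    assert [(e.gene, e.synonymy) for e in ann.genes] == [("ND6", "synonymous")]

    ann = mc.annotate_variant(Variant(93, "A", "G", "substitution"), ref)
    assert ann.genes[0].gene == "D-loop"
    assert ann.genes[0].synonymy == "not-protein"
    assert ann.definite and ann.transition is True

    ann = mc.annotate_variant(Variant(1005, "T", "C", "substitution"), ref)
    assert ann.genes[0].gene == "RNR1"


def test_purine_pyrimidine_change_is_transversion(ref):
    pos = next(p for p in range(200, 300) if ref.base(p) == "A")
    ann = mc.annotate_variant(Variant(pos, "A", "C", "substitution"), ref)
    assert ann.transition is False


def test_overlap_position_annotated_in_both_genes(ref):
    base = ref.base(8550)
    alt = "A" if base != "A" else "G"
    ann = mc.annotate_variant(Variant(8550, base, alt, "substitution"), ref)
    assert {e.gene for e in ann.genes} == {"ATP8", "ATP6"}


def test_mismatched_reference_base_rejected(ref):
    wrong = "C" if ref.base(93) != "C" else "G"
    with pytest.raises(CallingError, match="reference base"):
        mc.annotate_variant(Variant(93, wrong, "T", "substitution"), ref)


# ---------------------------------------------------------------------------
# cohort calling


def test_cohort_round_trip_matches_ledger(ref, small_cohort, small_calls):
    for sid, truth in small_cohort.emitted.items():
        called = sorted(v for v, _ in small_calls.per_sample[sid])
        assert called == truth
    # registry carrier counts equal ground-truth carriers
    registry = small_calls.type_registry().set_index("m_notation")
    for col in small_cohort.carriers.columns:
        expected = int(small_cohort.carriers[col].sum())
        planted_amb = sum(
            1
            for evs in small_cohort.emitted.values()
            for v in evs
            if v.m_notation == col
        )
        if expected and planted_amb == expected:
            assert int(registry.loc[col, "carrier_count"]) == expected


def test_called_substitution_ref_matches_reference(ref, small_calls):
    reg = small_calls.type_registry()
    subs = reg[reg["kind"] == "substitution"]
    assert all(
        ref.base(int(row.position)) == row.ref for row in subs.itertuples()
    )


def test_definite_ambiguous_partition_and_ts_tv(small_calls):
    reg = small_calls.type_registry()
    subs = reg[reg["kind"] == "substitution"]
    definite = subs[subs["definite"]]
    ambiguous = subs[~subs["definite"]]
    assert len(definite) + len(ambiguous) == len(subs)
    assert definite["transition"].notna().all()
    assert ambiguous["transition"].isna().all()
    n_ts = int(definite["transition"].astype(bool).sum())
    n_tv = len(definite) - n_ts
    assert n_ts + n_tv == len(definite)


def test_single_identical_record_has_zero_variants(ref):
    calls = mc.call_cohort({"only": ref.sequence}, ref)
    assert calls.per_sample["only"] == []
    assert calls.registry.empty


def test_empty_fasta_rejected(ref, tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(CallingError, match="no FASTA records"):
        mc.call_cohort(p, ref)


def test_duplicate_record_id_fatal(ref, tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(f">a\n{ref.sequence}\n>a\n{ref.sequence}\n")
    with pytest.raises(CallingError, match="duplicate"):
        mc.call_cohort(p, ref)


def test_unmatched_id_skipped_with_warning(ref):
    calls = mc.call_cohort(
        {"known": ref.sequence, "stray": ref.sequence},
        ref,
        metadata_ids=["known"],
    )
    assert list(calls.per_sample) == ["known"]
    assert any("stray" in line for line in calls.log)


def test_vcf_export_readable(ref, small_calls, tmp_path):
    import pysam

    path = tmp_path / "cohort.vcf"
    small_calls.to_vcf(path, ref)
    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
    assert len(records) == len(small_calls.type_registry())
    assert all(rec.chrom == "chrM" for rec in records)
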