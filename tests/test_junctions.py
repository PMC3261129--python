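import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionmut.junctions import (
    AmbiguousBaseError,
    AmpliconPair,
    JunctionError,
    PartialJunction,
    UndeterminedMicrohomologyError,
    UnresolvedJunctionError,
    analyze_rearrangement,
    apply_event,
    classify_substitution,
    enumerate_placements,
    find_event,
    mh_from_partial,
    reverse_complement,
)

from .oracles import (
    deletion_placements,
    insertion_placements,
    rearrangement_anchor_lengths,
)

# ---------------------------------------------------------------------------
# find_event on the published pairs


def test_c30_9_gl2_one_base_deletion_with_mh():
    pair = AmpliconPair("C30-9-gl2", "TGCAGGCTATTCAAAGAGACA", "TGCAGGCTATCAAAGAGACA")
    call = find_event(pair)
    assert call.event_type == "deletion"
    assert call.size == 1
    assert call.mh_length == 1
    # frozen from the brute-force oracle: two valid placements
    assert deletion_placements(pair.wt_seq, pair.mut_seq) == [9, 10]


def test_c30_39_hy1_five_base_deletion():
    pair = AmpliconPair("C30-39-hy1", "CATTGAACAGGAAATCCCTTAGC", "CATTGAACATCCCTTAGC")
    call = find_event(pair)
    assert (call.event_type, call.size, call.mh_length) == ("deletion", 5, 1)


def test_c_55_hy1_deletion_without_mh():
    pair = AmpliconPair("C-55-hy1", "GGCCGGACTGGATATCCGTTGGTC", "GGCCGGACTGATCCGTTGGTC")
    call = find_event(pair)
    assert (call.event_type, call.size, call.mh_length) == ("deletion", 3, 0)


def test_identical_sequences_give_none():
    call = find_event(AmpliconPair("x", "ACGTACGT", "ACGTACGT"))
    assert call.event_type == "none"


def test_lowercase_input_is_uppercased():
    pair = AmpliconPair("x", "acgtacgtacgt", "ACGTACGTACGT")
    assert find_event(pair).event_type == "none"


def test_substitution_call():
    pair = AmpliconPair("x", "AAAACGTTTTCC", "AAAACATTTTCC", chrom="5", anchor_pos=100)
    call = find_event(pair)
    assert call.event_type == "substitution"
    assert call.size == 1
    assert (call.wt_allele, call.mut_allele) == ("G", "A")
    assert call.canonical_start == 5
    assert call.genomic_position == ("5", 105, 105)


def test_complex_two_mismatch_blocks():
    call = find_event(AmpliconPair("x", "AAAACGTTTTCC", "AACACGTTTACC"))
    assert call.event_type == "complex"
    assert call.note


def test_complex_indel_plus_substitution():
    # deletion of 2 plus a distant substitution: not one contiguous event
    wt = "ACGTACGTACGTACGTACGT"
    mut = "ACGTACGTACGTACGAAC"  # drop 2, flip a distant base
    call = find_event(AmpliconPair("x", wt, mut))
    assert call.event_type == "complex"


def test_n_near_event_flagged():
    with pytest.raises(AmbiguousBaseError):
        find_event(AmpliconPair("x", "AAAACGNTTTTCC", "AAAACNTTTTCC"))


def test_n_far_from_event_tolerated():
    wt = "N" + "ACGTACGTAC" * 3 + "GGA" + "ACGTACGTAC" * 3
    mut = "N" + "ACGTACGTAC" * 3 + "GA" + "ACGTACGTAC" * 3
    call = find_event(AmpliconPair("x", wt, mut))
    assert call.event_type == "deletion"


def test_empty_or_invalid_sequences_rejected():
    with pytest.raises(JunctionError):
        AmpliconPair("x", "", "ACGT")
    with pytest.raises(JunctionError):
        AmpliconPair("x", "ACGT", "ACXT")


def test_anchored_deletion_genomic_interval():
    pair = AmpliconPair(
        "C30-39-hy1",
        "CATTGAACAGGAAATCCCTTAGC",
        "CATTGAACATCCCTTAGC",
        chrom="3",
        anchor_pos=2_805_165,
    )
    call = find_event(pair)
    chrom, start, end = call.genomic_position
    assert chrom == "3"
    assert end - start + 1 == 5
    # the published placement Chr.3: 2,805,174-78 lies within the ambiguity interval
    placements = enumerate_placements(pair, call)
    starts = {2_805_165 + p for p in placements}
    assert 2_805_174 in starts


# ---------------------------------------------------------------------------
# placements / oracle agreement


def test_enumerate_c450_100_single_placement():
    pair = AmpliconPair("C(450)-100-gl1", "CATGGATAATTCAGCTCCAGATT", "CATGGATAATTAGCTCCAGATT")
    call = find_event(pair)
    assert enumerate_placements(pair, call) == deletion_placements(pair.wt_seq, pair.mut_seq)
    assert len(enumerate_placements(pair, call)) == 1


def test_homopolymer_deletion_k_placements():
    wt = "GGCC" + "A" * 6 + "TTGG"
    mut = "GGCC" + "A" * 5 + "TTGG"
    pair = AmpliconPair("x", wt, mut)
    call = find_event(pair)
    placements = enumerate_placements(pair, call)
    assert len(placements) == 6
    assert call.mh_length == 5  # ambiguity exceeds the 1 bp event size


def test_enumerate_rejects_substitution_calls():
    pair = AmpliconPair("x", "AAAACGTTTT", "AAAACATTTT")
    call = find_event(pair)
    with pytest.raises(JunctionError):
        enumerate_placements(pair, call)


def test_fixture_pairs_formula_matches_oracle(junction_pairs):
    for pair in junction_pairs:
        call = find_event(pair)
        if call.event_type == "deletion":
            oracle = deletion_placements(pair.wt_seq, pair.mut_seq)
        else:
            oracle = insertion_placements(pair.wt_seq, pair.mut_seq)
        assert call.mh_length == len(oracle) - 1, pair.allele_id
        assert enumerate_placements(pair, call) == oracle, pair.allele_id
        assert call.canonical_start == min(oracle), pair.allele_id


def test_fixture_pairs_reconstruct_and_sizes(junction_pairs):
    for pair in junction_pairs:
        call = find_event(pair)
        assert apply_event(pair.wt_seq, call) == pair.mut_seq, pair.allele_id
        assert call.event_type == {"Del": "deletion", "Ins": "insertion"}[
            _truth(pair.allele_id)["truth_type"]
        ]


def _truth(allele_id):
    import csv
    from importlib.resources import files

    with open(files("ionmut") / "data" / "junction_pairs.tsv") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            if rec["allele_id"] == allele_id:
                return rec
    raise KeyError(allele_id)


def test_reverse_complement_consistency(junction_pairs):
    for pair in junction_pairs:
        call = find_event(pair)
        rc = AmpliconPair(
            pair.allele_id,
            reverse_complement(pair.wt_seq),
            reverse_complement(pair.mut_seq),
        )
        rc_call = find_event(rc)
        assert rc_call.event_type == call.event_type, pair.allele_id
        assert rc_call.size == call.size, pair.allele_id
        assert rc_call.mh_length == call.mh_length, pair.allele_id


def test_calling_is_idempotent(junction_pairs):
    for pair in junction_pairs:
        first = find_event(pair)
        second = find_event(pair)
        assert first == second


@st.composite
def random_deletion_pairs(draw):
    seq = draw(st.text(alphabet="ACGT", min_size=30, max_size=120))
    size = draw(st.integers(min_value=1, max_value=min(10, len(seq) - 20)))
    start = draw(st.integers(min_value=5, max_value=len(seq) - size - 5))
    return seq, seq[:start] + seq[start + size :], size


@settings(max_examples=200, deadline=None)
@given(random_deletion_pairs())
def test_random_deletions_match_oracle(case):
    wt, mut, size = case
    pair = AmpliconPair("prop", wt, mut)
    call = find_event(pair)
    assert call.event_type == "deletion"
    assert call.size == size
    oracle = deletion_placements(wt, mut)
    assert call.mh_length == len(oracle) - 1
    assert call.canonical_start == min(oracle)
    assert apply_event(wt, call) == mut
    # any oracle placement reconstructs the mutant
    for p in oracle:
        assert apply_event(wt, call, start=p) == mut


@settings(max_examples=100, deadline=None)
@given(
    seq=st.text(alphabet="ACGT", min_size=30, max_size=100),
    ins=st.text(alphabet="ACGT", min_size=1, max_size=8),
    offset=st.integers(min_value=5, max_value=10_000),
)
def test_random_insertions_match_oracle(seq, ins, offset):
    start = 5 + offset % max(1, len(seq) - 10)
    mut = seq[:start] + ins + seq[start:]
    pair = AmpliconPair("prop", seq, mut)
    call = find_event(pair)
    assert call.event_type == "insertion"
    assert call.size == len(ins)
    oracle = insertion_placements(seq, mut)
    assert call.mh_length == len(oracle) - 1
    assert enumerate_placements(pair, call) == oracle


# ---------------------------------------------------------------------------
# substitutions


def test_transition_example():
    assert classify_substitution("G", "A") == "transition"


def test_transversion_example():
    assert classify_substitution("A", "T") == "transversion"


def test_all_twelve_ordered_pairs():
    results = [
        classify_substitution(a, b) for a in "ACGT" for b in "ACGT" if a != b
    ]
    assert results.count("transition") == 4
    assert results.count("transversion") == 8


@pytest.mark.parametrize("wt,mut", [("A", "A"), ("N", "A"), ("A", "N"), ("X", "A")])
def test_substitution_input_errors(wt, mut):
    with pytest.raises(JunctionError):
        classify_substitution(wt, mut)


# ---------------------------------------------------------------------------
# partial junctions


def test_mh_from_partial_c162():
    pj = PartialJunction("C-162-gl1", "AGTGGTCTT", "CTTCGC", "CTCCTT", "AGAGTT", 51)
    assert mh_from_partial(pj) == 3


def test_mh_from_partial_c30_273():
    pj = PartialJunction("C30-273-var1", "GGTTTGT", "TCCTT", "GTCTGGT", "GGTGG", 23)
    assert mh_from_partial(pj) == 2


def test_mh_from_partial_all_distinct_flanks():
    pj = PartialJunction("x", "AAAA", "CGCG", "GCGC", "TTTT", 20)
    assert mh_from_partial(pj) == 0


def test_mh_from_partial_undetermined():
    # the printed suffix matches the left flank entirely: true mh is unbounded
    pj = PartialJunction("x", "TTAA", "CCCC", "TTAA", "GGGG", 20)
    with pytest.raises(UndeterminedMicrohomologyError) as err:
        mh_from_partial(pj)
    assert err.value.lower_bound == 4


def test_partial_junction_validation():
    with pytest.raises(JunctionError):
        PartialJunction("x", "", "CC", "GG", "TT", 10)
    with pytest.raises(JunctionError):
        PartialJunction("x", "AA", "CCCCC", "GG", "TT", 3)  # declared < printed


def test_partial_fixture_census(partial_junctions):
    values = {pj.allele_id: mh_from_partial(pj) for pj in partial_junctions}
    assert values == {
        "C-162-gl1": 3,
        "C(450)-135-hy1": 3,
        "C(450)-154-hy1": 0,
        "C30-273-var1": 2,
    }


# ---------------------------------------------------------------------------
# rearrangement junctions


def test_rearrangement_overlap_resolved_by_maximal_anchors():
    donor_left = "AAACCCGGGTTTAC"
    donor_right = "GCAATTTGGGCCCA"
    joined = "AAACCCGGGTTTGGGCCCA"
    # frozen from the split-point oracle: anchors 12 and 10 -> 3 bp overlap
    assert rearrangement_anchor_lengths(joined, donor_left, donor_right) == (12, 10)
    junction = analyze_rearrangement(joined, donor_left, donor_right)
    assert junction.joint_class == "microhomology"
    assert junction.mh_length == 3
    assert junction.filler_seq == ""


def test_rearrangement_blunt(rng):
    from ionmut.simulate import random_amplicon

    donor_left = random_amplicon(60, 0.5, rng)
    donor_right = random_amplicon(60, 0.5, rng)
    e_l, s_r = 30, 25
    dl = donor_left[:e_l]
    dr = donor_right[s_r:]
    if dr[0] == donor_left[e_l]:
        s_r += 1
        dr = donor_right[s_r:]
    joined = dl + dr
    junction = analyze_rearrangement(joined, donor_left, donor_right)
    if junction.joint_class == "blunt":  # chance overlaps can legitimately occur
        assert junction.mh_length == 0
        assert junction.filler_seq == ""


def test_rearrangement_planted_filler_recovered(rng):
    from ionmut.simulate import plant_translocation_junction, random_amplicon

    donor_left = random_amplicon(80, 0.4, rng)
    donor_right = random_amplicon(80, 0.4, rng)
    joined, truth = plant_translocation_junction(
        donor_left, donor_right, "filler", 8, rng
    )
    junction = analyze_rearrangement(joined, *truth.donors)
    assert junction.joint_class == "filler"
    assert junction.filler_seq == truth.planted_filler
    assert len(junction.filler_seq) == 8


def test_rearrangement_unresolved_junction():
    with pytest.raises(UnresolvedJunctionError):
        analyze_rearrangement("ACGTACGTACGTACGTACGT", "T" * 40, "C" * 40)


def test_rearrangement_breakpoint_deletions(rng):
    from ionmut.simulate import plant_translocation_junction, random_amplicon

    donor_left = random_amplicon(100, 0.4, rng)
    donor_right = random_amplicon(100, 0.4, rng)
    joined, truth = plant_translocation_junction(
        donor_left, donor_right, "blunt", 0, rng, breakpoint_deletions=(9, 28)
    )
    junction = analyze_rearrangement(joined, *truth.donors)
    assert junction.joint_class == "blunt"
    assert truth.breakpoint_deletions == (9, 28)
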