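"""Mutation-event calling from near-identical sequence pairs.

Given a wild-type amplicon and the corresponding mutant amplicon differing
by a single contiguous event (one base substitution, one deletion or one
insertion), infer the event, its size, its left-most (canonical) placement
and the placement-ambiguity interval.  For deletions and insertions the
number of alternative placements minus one equals the junction
microhomology length: the short repeat shared by the two ends joined at
the breakpoint.

The module also handles two rearrangement-flavoured inputs:

* partial deletion junctions where only the outer bases of a long deleted
  segment are known (:func:`mh_from_partial`);
* joined reads spanning a translocation breakpoint, classified into
  microhomology / blunt / filler joints (:func:`analyze_rearrangement`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "AmbiguousBaseError",
    "AmpliconPair",
    "JunctionError",
    "MutationCall",
    "PartialJunction",
    "RearrangementJunction",
    "UndeterminedMicrohomologyError",
    "UnresolvedJunctionError",
    "analyze_rearrangement",
    "apply_event",
    "classify_substitution",
    "enumerate_placements",
    "find_event",
    "mh_from_partial",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class JunctionError(ValueError):
    """Base class for junction-calling failures."""


class AmbiguousBaseError(JunctionError):
    """An N base sits inside the event neighbourhood; call needs manual review."""


class UnresolvedJunctionError(JunctionError):
    """A joined read could not be anchored in one or both donor sequences."""


class UndeterminedMicrohomologyError(JunctionError):
    """The printed junction fragments are too short to bound the microhomology.

    ``lower_bound`` carries the number of matching shifts observed before the
    printed fragment ran out, i.e. the true microhomology is >= lower_bound.
    """

    def __init__(self, lower_bound: int, message: str | None = None):
        self.lower_bound = lower_bound
        super().__init__(message or f"microhomology undetermined (>= {lower_bound})")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise JunctionError(f"{label} sequence is empty")
    bad = set(seq) - _ALPHABET
    if bad:
        raise JunctionError(f"{label} sequence contains invalid characters {sorted(bad)}")
    return seq


@dataclass
class AmpliconPair:
    """A wild-type / mutant amplicon pair for one allele.

    Sequences are uppercased on construction; ``chrom``/``anchor_pos`` give
    an optional genomic anchor (1-based position of the first wild-type
    base) used to project calls onto chromosome coordinates.
    """

    allele_id: str
    wt_seq: str
    mut_seq: str
    chrom: Optional[str] = None
    anchor_pos: Optional[int] = None

    def __post_init__(self) -> None:
        self.wt_seq = _validate_seq(self.wt_seq, f"{self.allele_id} wild-type")
        self.mut_seq = _validate_seq(self.mut_seq, f"{self.allele_id} mutant")


@dataclass
class MutationCall:
    """The single inferred event separating a wild-type/mutant pair.

    ``canonical_start`` is the left-most placement, 0-based half-open in
    wild-type coordinates.  ``ambiguity_span`` is the number of alternative
    placements minus one; for indels it equals ``mh_length``, the junction
    microhomology.  ``genomic_position`` is a 1-based inclusive
    ``(chrom, start, end)`` triple when the pair carried an anchor.
    """

    allele_id: str
    event_type: str  # none | substitution | deletion | insertion | complex
    size: Optional[int] = None
    wt_allele: str = ""
    mut_allele: str = ""
    canonical_start: Optional[int] = None
    ambiguity_span: int = 0
    mh_length: int = 0
    genomic_position: Optional[tuple] = None
    note: str = ""


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _check_no_n(pair: AmpliconPair, start: int, size: int, mh: int) -> None:
    w = max(mh, 5)
    lo = max(0, start - w)
    for seq in (pair.wt_seq, pair.mut_seq):
        window = seq[lo : start + size + w]
        if "N" in window:
            raise AmbiguousBaseError(
                f"{pair.allele_id}: N within event neighbourhood; flagged for manual review"
            )


def find_event(pair: AmpliconPair) -> MutationCall:
    """Infer the single mutation event separating ``wt_seq`` and ``mut_seq``.

    Uses the longest common prefix ``P`` and suffix ``S`` of the pair.  For
    a length-preserving pair with exactly one mismatch the event is a
    substitution at ``P``.  For a length change of ``d`` the event is a
    deletion/insertion of size ``d`` with microhomology
    ``mh = P + S - len(shorter)`` and canonical (left-most) start
    ``len(shorter) - S``.  Pairs with more than one mismatch block come
    back as ``event_type="complex"`` with a diagnostic note.
    """
    wt, mut = pair.wt_seq, pair.mut_seq
    if wt == mut:
        return MutationCall(pair.allele_id, "none")

    p = _lcp(wt, mut)
    s = _lcs(wt, mut)

    if len(wt) == len(mut):
        if p + s == len(wt) - 1:
            _check_no_n(pair, p, 1, 0)
            call = MutationCall(
                pair.allele_id,
                "substitution",
                size=1,
                wt_allele=wt[p],
                mut_allele=mut[p],
                canonical_start=p,
            )
            if pair.anchor_pos is not None:
                gpos = pair.anchor_pos + p
                call.genomic_position = (pair.chrom, gpos, gpos)
            return call
        return MutationCall(
            pair.allele_id,
            "complex",
            note=f"equal-length pair with multiple mismatch blocks (P={p}, S={s})",
        )

    longer, shorter = (wt, mut) if len(wt) > len(mut) else (mut, wt)
    d = len(longer) - len(shorter)
    mh = p + s - len(shorter)
    if mh < 0:
        return MutationCall(
            pair.allele_id,
            "complex",
            note=f"length difference {d} with disjoint mismatch blocks (P={p}, S={s})",
        )
    start = len(shorter) - s  # left-most placement
    if len(wt) > len(mut):
        call = MutationCall(
            pair.allele_id,
            "deletion",
            size=d,
            wt_allele=wt[start : start + d],
            mut_allele="",
            canonical_start=start,
            ambiguity_span=mh,
            mh_length=mh,
        )
        if pair.anchor_pos is not None:
            call.genomic_position = (
                pair.chrom,
                pair.anchor_pos + start,
                pair.anchor_pos + start + d - 1,
            )
    else:
        call = MutationCall(
            pair.allele_id,
            "insertion",
            size=d,
            wt_allele="",
            mut_allele=mut[start : start + d],
            canonical_start=start,
            ambiguity_span=mh,
            mh_length=mh,
        )
        if pair.anchor_pos is not None:
            gpos = pair.anchor_pos + start
            call.genomic_position = (pair.chrom, gpos, gpos)
    _check_no_n(pair, start, d, mh)
    assert apply_event(pair.wt_seq, call) == pair.mut_seq, (
        f"{pair.allele_id}: reconstruction failed"
    )
    return call


def apply_event(wt: str, call: MutationCall, start: Optional[int] = None) -> str:
    """Apply ``call`` to ``wt`` at ``start`` (default: canonical placement)."""
    if call.event_type == "none":
        return wt
    if start is None:
        start = call.canonical_start
    if start is None:
        raise JunctionError("call has no placement to apply")
    if call.event_type == "substitution":
        return wt[:start] + call.mut_allele + wt[start + 1 :]
    if call.event_type == "deletion":
        return wt[:start] + wt[start + call.size :]
    if call.event_type == "insertion":
        return wt[:start] + call.mut_allele + wt[start:]
    raise JunctionError(f"cannot apply event of type {call.event_type!r}")


def enumerate_placements(pair: AmpliconPair, call: MutationCall) -> list[int]:
    """All 0-based starts at which applying ``call`` reproduces the mutant.

    Brute-force oracle for placement ambiguity: tries every start position.
    The result is sorted ascending, begins with ``canonical_start``, and has
    length ``mh_length + 1``.
    """
    if call.event_type not in ("deletion", "insertion"):
        raise JunctionError("placements are defined for deletions and insertions only")
    wt, mut, d = pair.wt_seq, pair.mut_seq, call.size
    placements = []
    if call.event_type == "deletion":
        for start in range(len(wt) - d + 1):
            if wt[:start] + wt[start + d :] == mut:
                placements.append(start)
    else:
        for start in range(len(wt) + 1):
            if wt[:start] + mut[start : start + d] + wt[start:] == mut:
                placements.append(start)
    if not placements:
        raise JunctionError(f"{pair.allele_id}: call is inconsistent with the pair")
    return placements


def classify_substitution(wt_base: str, mut_base: str) -> str:
    """Classify a base substitution as ``"transition"`` or ``"transversion"``."""
    wt_base, mut_base = wt_base.upper(), mut_base.upper()
    for b in (wt_base, mut_base):
        if b not in "ACGT":
            raise JunctionError(f"invalid base {b!r}")
    if wt_base == mut_base:
        raise JunctionError("bases are identical; not a substitution")
    same_class = (wt_base in _PURINES) == (mut_base in _PURINES)
    return "transition" if same_class else "transversion"


@dataclass
class PartialJunction:
    """A deletion junction where only the outer deleted bases are printed.

    ``left_flank``/``right_flank`` are retained sequence either side of the
    junction; ``del_prefix``/``del_suffix`` are the first and last printed
    bases of the deleted segment (its middle is elided); ``declared_size``
    is the catalogued deletion length.
    """

    allele_id: str
    left_flank: str
    del_prefix: str
    del_suffix: str
    right_flank: str
    declared_size: int

    def __post_init__(self) -> None:
        for name in ("left_flank", "del_prefix", "del_suffix", "right_flank"):
            value = _validate_seq(getattr(self, name), f"{self.allele_id} {name}")
            setattr(self, name, value)
        if self.declared_size < len(self.del_prefix) or self.declared_size < len(
            self.del_suffix
        ):
            raise JunctionError(
                f"{self.allele_id}: declared size smaller than printed fragments"
            )


def mh_from_partial(pj: PartialJunction) -> int:
    """Junction microhomology of a partially printed deletion.

    The deletion can slide left while the last bases of the deleted segment
    match the last bases of the left flank, and right while its first bases
    match the first bases of the right flank; the microhomology is the total
    number of such shifts, ``L + R``.  If a shift run reaches the end of a
    printed fragment without hitting a mismatch the true value is unbounded
    by the printed data and :class:`UndeterminedMicrohomologyError` is
    raised with the lower bound seen so far.
    """
    left_cap = min(len(pj.del_suffix), len(pj.left_flank))
    l = 0
    while l < left_cap and pj.del_suffix[-(l + 1)] == pj.left_flank[-(l + 1)]:
        l += 1
    left_open = l == left_cap

    right_cap = min(len(pj.del_prefix), len(pj.right_flank))
    r = 0
    while r < right_cap and pj.del_prefix[r] == pj.right_flank[r]:
        r += 1
    right_open = r == right_cap

    if left_open or right_open:
        raise UndeterminedMicrohomologyError(l + r)
    return l + r


@dataclass
class RearrangementJunction:
    """A rejoined breakpoint read classified by its joint structure.

    Exactly one of the three classes holds: ``microhomology`` (the donor
    anchors overlap by ``mh_length`` bases in the joined read), ``blunt``
    (they abut), or ``filler`` (a gap of inserted bases matching neither
    donor).  Breakpoint deletions are bases lost from each donor relative
    to its nominal breakpoint, when those are known.
    """

    junction_id: str
    joined_seq: str
    donor_left: str
    donor_right: str
    joint_class: str  # microhomology | blunt | filler
    mh_length: int = 0
    filler_seq: str = ""
    left_match_len: int = 0
    right_match_len: int = 0
    left_match_pos: int = 0
    right_match_pos: int = 0
    breakpoint_deletion_left: Optional[int] = None
    breakpoint_deletion_right: Optional[int] = None

    def __post_init__(self) -> None:
        flags = [self.joint_class == "microhomology" and self.mh_length > 0,
                 self.joint_class == "filler" and bool(self.filler_seq),
                 self.joint_class == "blunt" and self.mh_length == 0
                 and not self.filler_seq]
        if sum(flags) != 1:
            raise JunctionError(
                f"{self.junction_id}: inconsistent joint class {self.joint_class!r}"
            )


def _max_prefix_match(joined: str, donor: str, min_anchor: int) -> Optional[tuple[int, int]]:
    """Longest prefix of ``joined`` occurring in ``donor`` (leftmost hit)."""
    if len(joined) < min_anchor or donor.find(joined[:min_anchor]) < 0:
        return None
    length = min_anchor
    while length < len(joined) and donor.find(joined[: length + 1]) >= 0:
        length += 1
    return length, donor.find(joined[:length])


def _max_suffix_match(joined: str, donor: str, min_anchor: int) -> Optional[tuple[int, int]]:
    """Longest suffix of ``joined`` occurring in ``donor`` (leftmost hit)."""
    if len(joined) < min_anchor or donor.find(joined[-min_anchor:]) < 0:
        return None
    length = min_anchor
    while length < len(joined) and donor.find(joined[-(length + 1) :]) >= 0:
        length += 1
    return length, donor.find(joined[-length:])


def analyze_rearrangement(
    joined_seq: str,
    donor_left: str,
    donor_right: str,
    nominal_breakpoints: Optional[tuple[int, int]] = None,
    min_anchor: int = 10,
    junction_id: str = "junction",
) -> RearrangementJunction:
    """Classify a joined breakpoint read against its two donor sequences.

    Finds the maximal prefix of ``joined_seq`` present in ``donor_left``
    and the maximal suffix present in ``donor_right`` (each at least
    ``min_anchor`` bases, leftmost occurrence on ties).  Overlapping
    anchors give a microhomology joint, abutting anchors a blunt joint, and
    a remaining gap a filler joint whose sequence matches neither donor.

    ``nominal_breakpoints = (bp_left, bp_right)`` are 0-based cut positions
    in the donors (left donor retains ``donor_left[:bp_left]``, right donor
    retains ``donor_right[bp_right:]``); when given, breakpoint deletions
    are reported as bases lost from each donor relative to its cut.
    """
    joined_seq = _validate_seq(joined_seq, "joined")
    donor_left = _validate_seq(donor_left, "donor_left")
    donor_right = _validate_seq(donor_right, "donor_right")

    left = _max_prefix_match(joined_seq, donor_left, min_anchor)
    right = _max_suffix_match(joined_seq, donor_right, min_anchor)
    if left is None or right is None:
        missing = []
        if left is None:
            missing.append("5' end in donor_left")
        if right is None:
            missing.append("3' end in donor_right")
        raise UnresolvedJunctionError(
            f"{junction_id}: no >= {min_anchor} bp anchor for " + " nor ".join(missing)
        )
    left_len, left_pos = left
    right_len, right_pos = right

    overlap = left_len + right_len - len(joined_seq)
    if overlap > 0:
        joint_class, mh, filler = "microhomology", overlap, ""
    elif overlap == 0:
        joint_class, mh, filler = "blunt", 0, ""
    else:
        joint_class, mh = "filler", 0
        filler = joined_seq[left_len : len(joined_seq) - right_len]

    bdl = bdr = None
    if nominal_breakpoints is not None:
        bp_left, bp_right = nominal_breakpoints
        bdl = bp_left - (left_pos + left_len)
        bdr = right_pos - bp_right

    return RearrangementJunction(
        junction_id=junction_id,
        joined_seq=joined_seq,
        donor_left=donor_left,
        donor_right=donor_right,
        joint_class=joint_class,
        mh_length=mh,
        filler_seq=filler,
        left_match_len=left_len,
        right_match_len=right_len,
        left_match_pos=left_pos,
        right_match_pos=right_pos,
        breakpoint_deletion_left=bdl,
        breakpoint_deletion_right=bdr,
    )
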