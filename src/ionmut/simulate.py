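"""Synthetic sequence pairs, rearrangement junctions and screening cohorts.

Everything downstream of the wet lab is testable against generated data:
amplicon pairs differing by exactly one planted event with controlled
junction microhomology, breakpoint reads with microhomology / blunt /
filler joints and breakpoint deletions, and binomially sampled mutant
counts at per-mil frequencies.

Planted microhomology is engineered by writing a short repeat next to the
deleted segment and then *re-measured* on the finished pair with the
brute-force placement oracle; generation retries (bounded) until the
realized value equals the request, so truth records never rely on the
construction being correct.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .junctions import (
    AmpliconPair,
    JunctionError,
    MutationCall,
    analyze_rearrangement,
    classify_substitution,
    enumerate_placements,
    find_event,
)
from .spectrum import CohortCounts

__all__ = [
    "SimulationError",
    "SpectrumSpec",
    "TruthRecord",
    "generate_dataset",
    "plant_deletion",
    "plant_insertion",
    "plant_substitution",
    "plant_translocation_junction",
    "random_amplicon",
    "simulate_cohort",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_MAX_RETRIES = 100
_EDGE_MARGIN = 10  # planted events stay clear of sequence ends


class SimulationError(ValueError):
    """Raised when a requested synthetic construct is infeasible."""


@dataclass(frozen=True)
class SpectrumSpec:
    """Mixture and size parameters for a synthetic mutation dataset.

    Defaults follow the observed heavy-ion spectrum: mostly substitutions
    and small indels (1-51 bp), a minority of large deletions
    (>= 100 bp) and translocation junctions; junction microhomology 0-3 bp
    for simple deletions and 2-5 bp at translocation joints; filler
    insertions 3-16 bp; breakpoint deletions 9-28 bp.
    """

    p_substitution: float = 0.18
    p_small_del: float = 0.55
    p_small_ins: float = 0.09
    p_large_del: float = 0.09
    p_translocation: float = 0.09
    titv_ratio: float = 1.0 / 3.0
    small_size_range: tuple[int, int] = (1, 51)
    large_size_range: tuple[int, int] = (100, 35_000)
    mh_range: tuple[int, int] = (0, 3)
    junction_mh_range: tuple[int, int] = (2, 5)
    filler_range: tuple[int, int] = (3, 16)
    breakpoint_del_range: tuple[int, int] = (9, 28)
    amplicon_length_range: tuple[int, int] = (400, 900)
    gc: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.p_substitution,
            self.p_small_del,
            self.p_small_ins,
            self.p_large_del,
            self.p_translocation,
        )
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise SimulationError("event probabilities must be non-negative and sum to 1")
        for name in (
            "small_size_range",
            "large_size_range",
            "mh_range",
            "junction_mh_range",
            "filler_range",
            "breakpoint_del_range",
            "amplicon_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SimulationError(f"{name} is empty: {lo} > {hi}")


@dataclass
class TruthRecord:
    """Ground truth for one planted event, with *realized* (re-measured)
    microhomology/ambiguity rather than the requested value."""

    allele_id: str
    event_type: str
    size: Optional[int] = None
    planted_start: Optional[int] = None
    planted_mh: int = 0
    planted_filler: str = ""
    substitution_class: str = ""
    joint_class: str = ""
    breakpoint_deletions: Optional[tuple[int, int]] = None
    donors: Optional[tuple[str, str]] = None


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_amplicon(length: int, gc: float = 0.36, seed=None) -> str:
    """Random amplicon sequence with the given GC fraction.

    Reproducible for a fixed integer seed; a shared
    :class:`numpy.random.Generator` may be passed instead to draw from an
    existing stream.
    """
    if length < 40:
        raise SimulationError(f"amplicon length must be >= 40, got {length}")
    if not 0 < gc < 1:
        raise SimulationError(f"gc must be in (0, 1), got {gc}")
    rng = _as_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def _realized_mh(pair: AmpliconPair, call: MutationCall) -> int:
    return len(enumerate_placements(pair, call)) - 1


def plant_deletion(
    seq: str, size: int, mh: int, seed=None, allele_id: str = "synthetic"
) -> tuple[AmpliconPair, TruthRecord]:
    """Plant one deletion of ``size`` bp whose junction ambiguity is exactly ``mh``.

    A repeat of the first ``mh`` deleted bases is written immediately after
    the deleted segment, flanking bases are forced to break the repeat, and
    the realized ambiguity is verified with the placement oracle; the draw
    is retried (up to 100 times) if chance repeats elsewhere change it.
    """
    rng = _as_rng(seed)
    seq = seq.upper()
    if size < 1:
        raise SimulationError("deletion size must be >= 1")
    if mh < 0:
        raise SimulationError("mh must be >= 0")
    if mh > size:
        raise SimulationError(f"mh ({mh}) cannot exceed deletion size ({size})")
    if len(seq) < size + 2 * (mh + _EDGE_MARGIN):
        raise SimulationError("sequence too short for the requested deletion")

    for _ in range(_MAX_RETRIES):
        wt = list(seq)
        p = int(rng.integers(_EDGE_MARGIN, len(seq) - size - mh - _EDGE_MARGIN + 1))
        # randomize the event neighbourhood, then impose the repeat structure
        for i in range(p - 1, p + size + mh + 1):
            wt[i] = _BASES[rng.integers(4)]
        for j in range(mh):
            wt[p + size + j] = wt[p + j]
        if mh < size:
            wt[p + size + mh] = _other_base(wt[p + mh], rng)  # break rightward
        else:  # mh == size: break after the full repeat copy
            wt[p + size + mh] = _other_base(wt[p + mh], rng)
        wt[p - 1] = _other_base(wt[p + size - 1], rng)  # break leftward
        wt_s = "".join(wt)
        mut_s = wt_s[:p] + wt_s[p + size :]
        pair = AmpliconPair(allele_id, wt_s, mut_s)
        call = find_event(pair)
        if call.event_type == "deletion" and call.size == size:
            realized = _realized_mh(pair, call)
            if realized == mh:
                truth = TruthRecord(allele_id, "deletion", size, p, realized)
                return pair, truth
    raise SimulationError(
        f"could not realize deletion size={size} mh={mh} after {_MAX_RETRIES} tries"
    )


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(3)]


def plant_substitution(
    seq: str, titv_choice: str = "transversion", seed=None, allele_id: str = "synthetic"
) -> tuple[AmpliconPair, TruthRecord]:
    """Plant one base substitution of the requested class."""
    rng = _as_rng(seed)
    seq = seq.upper()
    if titv_choice not in ("transition", "transversion"):
        raise SimulationError(f"unknown substitution class {titv_choice!r}")
    if len(seq) < 2 * _EDGE_MARGIN + 1:
        raise SimulationError("sequence too short")
    p = int(rng.integers(_EDGE_MARGIN, len(seq) - _EDGE_MARGIN))
    wt_base = seq[p]
    if titv_choice == "transition":
        mut_base = _TRANSITION[wt_base]
    else:
        candidates = [
            b for b in _BASES if b != wt_base and classify_substitution(wt_base, b) == "transversion"
        ]
        mut_base = candidates[rng.integers(len(candidates))]
    mut = seq[:p] + mut_base + seq[p + 1 :]
    pair = AmpliconPair(allele_id, seq, mut)
    truth = TruthRecord(
        allele_id, "substitution", 1, p, 0, substitution_class=titv_choice
    )
    return pair, truth


def plant_insertion(
    seq: str, size: int, seed=None, allele_id: str = "synthetic"
) -> tuple[AmpliconPair, TruthRecord]:
    """Plant one insertion of ``size`` random bases; ambiguity is whatever
    the flanking context yields (re-measured into the truth record)."""
    rng = _as_rng(seed)
    seq = seq.upper()
    if size < 1:
        raise SimulationError("insertion size must be >= 1")
    if len(seq) < 2 * _EDGE_MARGIN:
        raise SimulationError("sequence too short")
    p = int(rng.integers(_EDGE_MARGIN, len(seq) - _EDGE_MARGIN + 1))
    ins = "".join(_BASES[rng.integers(4)] for _ in range(size))
    mut = seq[:p] + ins + seq[p:]
    pair = AmpliconPair(allele_id, seq, mut)
    call = find_event(pair)
    if call.event_type != "insertion" or call.size != size:
        raise SimulationError("planted insertion was not recovered as a single event")
    truth = TruthRecord(allele_id, "insertion", size, p, _realized_mh(pair, call))
    return pair, truth


def plant_translocation_junction(
    donor_left: str,
    donor_right: str,
    joint_class: str,
    param: int = 0,
    seed=None,
    breakpoint_deletions: tuple[int, int] = (0, 0),
    junction_id: str = "synthetic-junction",
    min_anchor: int = 10,
) -> tuple[str, TruthRecord]:
    """Construct a joined breakpoint read with a prescribed joint structure.

    ``param`` is the microhomology length (``joint_class="microhomology"``)
    or the filler length (``joint_class="filler"``); ignored for blunt
    joints.  ``breakpoint_deletions`` are bases trimmed from each donor
    relative to its nominal breakpoint.  The donors may be locally edited
    to realize the requested microhomology; the (possibly edited) donors
    are recorded in the truth record, and the construct is verified by
    :func:`~ionmut.junctions.analyze_rearrangement` before being returned.
    """
    rng = _as_rng(seed)
    donor_left = donor_left.upper()
    donor_right = donor_right.upper()
    if joint_class not in ("microhomology", "blunt", "filler"):
        raise SimulationError(f"unknown joint class {joint_class!r}")
    if joint_class == "microhomology" and param < 1:
        raise SimulationError("microhomology joints need param >= 1")
    if joint_class == "filler" and param < 1:
        raise SimulationError("filler joints need param >= 1")
    del_left, del_right = breakpoint_deletions
    if del_left < 0 or del_right < 0:
        raise SimulationError("breakpoint deletions must be non-negative")
    m = param if joint_class == "microhomology" else 0
    need_left = min_anchor + del_left + m + 2
    need_right = min_anchor + del_right + m + 2
    if len(donor_left) < need_left or len(donor_right) < need_right:
        raise SimulationError("donor sequences too short for the requested junction")

    for _ in range(_MAX_RETRIES):
        dl = list(donor_left)
        dr = list(donor_right)
        # cut positions: left donor retains [:e_l], right donor retains [s_r:]
        e_l = int(
            rng.integers(min_anchor + m, len(dl) - del_left) + 0
        )
        bp_left = e_l + del_left
        s_r_min = del_right
        s_r_max = len(dr) - min_anchor - m - 1
        if bp_left > len(dl) or s_r_min > s_r_max:
            continue
        s_r = int(rng.integers(s_r_min, s_r_max + 1))
        bp_right = s_r - del_right

        if joint_class == "microhomology":
            for j in range(m):
                dr[s_r + j] = dl[e_l - m + j]
            if dr[s_r + m] == dl[e_l]:
                dr[s_r + m] = _other_base(dl[e_l], rng)
            if s_r > 0 and dr[s_r - 1] == dl[e_l - m - 1]:
                dr[s_r - 1] = _other_base(dl[e_l - m - 1], rng)
            joined = "".join(dl[:e_l]) + "".join(dr[s_r + m :])
            filler = ""
        elif joint_class == "blunt":
            if dr[s_r] == dl[e_l]:
                dr[s_r] = _other_base(dl[e_l], rng)
            if dr[s_r - 1 if s_r > 0 else 0] == dl[e_l - 1] and s_r > 0:
                dr[s_r - 1] = _other_base(dl[e_l - 1], rng)
            joined = "".join(dl[:e_l]) + "".join(dr[s_r:])
            filler = ""
        else:
            filler = "".join(_BASES[rng.integers(4)] for _ in range(param))
            if filler[0] == dl[e_l]:
                filler = _other_base(dl[e_l], rng) + filler[1:]
            if filler[-1] == dr[s_r - 1 if s_r > 0 else 0] and s_r > 0:
                filler = filler[:-1] + _other_base(dr[s_r - 1], rng)
            joined = "".join(dl[:e_l]) + filler + "".join(dr[s_r:])

        dl_s, dr_s = "".join(dl), "".join(dr)
        try:
            junction = analyze_rearrangement(
                joined,
                dl_s,
                dr_s,
                nominal_breakpoints=(bp_left, bp_right),
                min_anchor=min_anchor,
                junction_id=junction_id,
            )
        except JunctionError:
            continue
        recovered_param = (
            junction.mh_length if joint_class == "microhomology" else len(junction.filler_seq)
        )
        wanted_param = param if joint_class != "blunt" else 0
        if (
            junction.joint_class == joint_class
            and recovered_param == wanted_param
            and junction.breakpoint_deletion_left == del_left
            and junction.breakpoint_deletion_right == del_right
        ):
            truth = TruthRecord(
                junction_id,
                "translocation",
                planted_mh=m,
                planted_filler=filler,
                joint_class=joint_class,
                breakpoint_deletions=(del_left, del_right),
                donors=(dl_s, dr_s),
            )
            return joined, truth
    raise SimulationError(
        f"could not realize {joint_class} junction (param={param}) after {_MAX_RETRIES} tries"
    )


def simulate_cohort(
    n_m2: int, true_freq_permil: float, seed=None, let: float = 30.0, dose: float = 400.0
) -> CohortCounts:
    """Binomially sample a screening cohort at a per-mil mutant frequency."""
    if n_m2 <= 0:
        raise SimulationError("n_m2 must be positive")
    if not 0 <= true_freq_permil <= 1000:
        raise SimulationError("true_freq_permil must be within [0, 1000]")
    rng = _as_rng(seed)
    k = int(rng.binomial(n_m2, true_freq_permil / 1000.0))
    return CohortCounts(let=let, dose=dose, n_m1=0, n_m2=n_m2, n_mutants=k)


_EVENT_KINDS = ("substitution", "small_del", "small_ins", "large_del", "translocation")


def generate_dataset(
    spec: SpectrumSpec,
    n_alleles: int,
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
):
    """Draw ``n_alleles`` synthetic events from ``spec``'s mixture.

    Returns ``(pairs, junctions, truths)`` where ``pairs`` are
    :class:`AmpliconPair` for pair-type events and ``junctions`` are
    ``(joined_seq, truth)`` tuples for translocations.  When ``out_dir`` is
    given, FASTA (``<id>|wt`` / ``<id>|mut`` records), a catalog TSV, a
    junction TSV and a truth TSV are written there (byte-identical for
    identical seeds).
    """
    if n_alleles < 0:
        raise SimulationError("n_alleles must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    used_seed = spec.seed if seed is None else seed

    probs = np.array(
        [
            spec.p_substitution,
            spec.p_small_del,
            spec.p_small_ins,
            spec.p_large_del,
            spec.p_translocation,
        ]
    )
    pairs: list[AmpliconPair] = []
    junctions: list[tuple[str, TruthRecord]] = []
    truths: list[TruthRecord] = []

    for i in range(n_alleles):
        allele_id = f"SYN-{i:05d}"
        kind = _EVENT_KINDS[rng.choice(len(_EVENT_KINDS), p=probs)]
        length = int(rng.integers(*_inc(spec.amplicon_length_range)))
        if kind == "translocation":
            joint_class = ("microhomology", "blunt", "filler")[rng.integers(3)]
            if joint_class == "microhomology":
                param = int(rng.integers(*_inc(spec.junction_mh_range)))
            elif joint_class == "filler":
                param = int(rng.integers(*_inc(spec.filler_range)))
            else:
                param = 0
            bdel = (
                int(rng.integers(*_inc(spec.breakpoint_del_range))),
                int(rng.integers(*_inc(spec.breakpoint_del_range))),
            )
            donor_left = random_amplicon(length, spec.gc, rng)
            donor_right = random_amplicon(length, spec.gc, rng)
            joined, truth = plant_translocation_junction(
                donor_left,
                donor_right,
                joint_class,
                param,
                rng,
                breakpoint_deletions=bdel,
                junction_id=allele_id,
            )
            junctions.append((joined, truth))
        else:
            if kind == "large_del":
                size = int(rng.integers(*_inc(spec.large_size_range)))
                margin = int(rng.integers(200, 401))
                seq = random_amplicon(size + 2 * margin, spec.gc, rng)
                mh = int(rng.integers(*_inc(spec.mh_range)))
                pair, truth = plant_deletion(seq, size, mh, rng, allele_id)
            else:
                seq = random_amplicon(length, spec.gc, rng)
                if kind == "substitution":
                    p_ts = spec.titv_ratio / (1.0 + spec.titv_ratio)
                    choice = "transition" if rng.random() < p_ts else "transversion"
                    pair, truth = plant_substitution(seq, choice, rng, allele_id)
                elif kind == "small_del":
                    size = int(rng.integers(*_inc(spec.small_size_range)))
                    mh = int(rng.integers(0, min(size, spec.mh_range[1]) + 1))
                    pair, truth = plant_deletion(seq, size, mh, rng, allele_id)
                else:
                    size = int(rng.integers(*_inc(spec.small_size_range)))
                    pair, truth = plant_insertion(seq, size, rng, allele_id)
            pairs.append(pair)
        truths.append(truth)

    if out_dir is not None:
        _write_dataset(Path(out_dir), pairs, junctions, truths, used_seed)
    return pairs, junctions, truths


def _inc(rng_pair: tuple[int, int]) -> tuple[int, int]:
    """Half-open bounds for an inclusive integer range."""
    lo, hi = rng_pair
    return lo, hi + 1


def _write_dataset(out_dir, pairs, junctions, truths, seed) -> None:
    from . import io as ionmut_io  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for pair in pairs:
        records.append((f"{pair.allele_id}|wt", pair.wt_seq))
        records.append((f"{pair.allele_id}|mut", pair.mut_seq))
    ionmut_io.write_fasta(records, out_dir / "pairs.fasta")

    with open(out_dir / "catalog.tsv", "w") as fh:
        fh.write("allele_id\ttype\tsize\n")
        code = {
            "substitution": "BS",
            "deletion": "Del",
            "insertion": "Ins",
            "translocation": "RTL",
        }
        for t in truths:
            size = "" if t.size is None else str(t.size)
            fh.write(f"{t.allele_id}\t{code[t.event_type]}\t{size}\n")

    with open(out_dir / "junctions.tsv", "w") as fh:
        fh.write("junction_id\tjoined_seq\tdonor_left\tdonor_right\n")
        for joined, truth in junctions:
            dl, dr = truth.donors
            fh.write(f"{truth.allele_id}\t{joined}\t{dl}\t{dr}\n")

    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write(f"# seed={seed}\n")
        fields = [f.name for f in dataclasses.fields(TruthRecord)]
        fh.write("\t".join(fields) + "\n")
        for t in truths:
            row = []
            for name in fields:
                value = getattr(t, name)
                row.append("" if value is None else str(value))
            fh.write("\t".join(row) + "\n")
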