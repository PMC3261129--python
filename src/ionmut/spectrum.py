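"""Mutation-spectrum classification and screening-frequency statistics.

Calls (or catalogued mutations) are split into *small alterations* — base
substitutions and indels below a size threshold (100 bp by default, strict
inequality) — and *rearrangements* — translocations, complex events and
indels at or above the threshold.  Cohort screening counts yield per-mil
mutation frequencies with exact (Clopper-Pearson) confidence intervals and
pairwise comparisons via conditional-binomial ratio CIs and Fisher's exact
test.  Confidence intervals and tests are methodological additions, not
reproduced values; outputs label them as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .dosimetry import IrradiationCondition
from .junctions import MutationCall, classify_substitution

__all__ = [
    "SMALL_SIZE_THRESHOLD",
    "CohortCounts",
    "DoseResponsePoint",
    "FrequencyEstimate",
    "RatioEstimate",
    "SpectrumError",
    "SpectrumSummary",
    "classify_mutation",
    "clopper_pearson",
    "dose_response_table",
    "interpolate_fluence",
    "mutation_frequency",
    "frequency_ratio",
    "round_half_away",
    "summarize_spectrum",
]

#: Default small/rearrangement size boundary, bp (strict: size < threshold is small).
SMALL_SIZE_THRESHOLD = 100

#: Catalog type codes: base substitution, deletion, insertion, reciprocal
#: translocation, complex rearrangement, no mutation found.
TYPE_CODES = ("BS", "Del", "Ins", "RTL", "CR", "NM")

_EVENT_TO_CODE = {
    "substitution": "BS",
    "deletion": "Del",
    "insertion": "Ins",
    "complex": "CR",
    "none": "NM",
}


class SpectrumError(ValueError):
    """Raised for invalid spectrum/statistics inputs."""


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def classify_mutation(
    mutation,
    size: Optional[int] = None,
    threshold: int = SMALL_SIZE_THRESHOLD,
) -> Optional[str]:
    """Classify one mutation as ``"small"`` or ``"rearrangement"``.

    ``mutation`` is either a :class:`~ionmut.junctions.MutationCall`, an
    object with ``type_code``/``size`` attributes (catalog row), or a bare
    type code string with ``size`` passed separately.  Rows typed ``NM``
    (no mutation found) return ``None`` and are excluded from tallies.
    """
    if isinstance(mutation, MutationCall):
        type_code = _EVENT_TO_CODE[mutation.event_type]
        size = mutation.size
    elif hasattr(mutation, "type_code"):
        type_code = mutation.type_code
        size = mutation.size
    else:
        type_code = mutation

    if type_code not in TYPE_CODES:
        raise SpectrumError(f"unknown mutation type code {type_code!r}")
    if type_code == "NM":
        return None
    if type_code == "BS":
        return "small"
    if type_code in ("RTL", "CR"):
        return "rearrangement"
    # Del / Ins
    if size is None:
        raise SpectrumError(f"{type_code} mutation without a size cannot be classified")
    return "small" if size < threshold else "rearrangement"


@dataclass
class SpectrumSummary:
    """Small/rearrangement and transition/transversion tallies for one group."""

    group_label: str
    n_small: int
    n_rearrangement: int
    n_transition: int = 0
    n_transversion: int = 0
    size_threshold: int = SMALL_SIZE_THRESHOLD

    @property
    def n_total(self) -> int:
        return self.n_small + self.n_rearrangement

    @property
    def pct_small(self) -> float:
        return round_half_away(100.0 * self.n_small / self.n_total, 1)

    @property
    def pct_rearrangement(self) -> float:
        return round_half_away(100.0 * self.n_rearrangement / self.n_total, 1)


def _substitution_bases(row) -> Optional[tuple[str, str]]:
    if isinstance(row, MutationCall):
        if row.event_type == "substitution":
            return row.wt_allele, row.mut_allele
        return None
    change = getattr(row, "change", None)
    if change:
        for sep in (">", "→", "->"):
            if sep in change:
                wt, mut = change.split(sep, 1)
                return wt.strip(), mut.strip()
    return None


def summarize_spectrum(
    mutations: Iterable,
    group_by=lambda row: getattr(row, "let", "all"),
    threshold: int = SMALL_SIZE_THRESHOLD,
) -> list[SpectrumSummary]:
    """Per-group small/rearrangement summary with transition/transversion tallies.

    ``group_by`` maps each mutation to its group label (default: the row's
    ``let`` attribute).  Groups in which every row is unclassifiable (all
    NM) are omitted with a warning.
    """
    groups: dict = {}
    for row in mutations:
        groups.setdefault(group_by(row), []).append(row)

    summaries = []
    for label, rows in groups.items():
        n_small = n_rearr = n_ts = n_tv = 0
        for row in rows:
            cls = classify_mutation(row, threshold=threshold)
            if cls is None:
                continue
            if cls == "small":
                n_small += 1
            else:
                n_rearr += 1
            bases = _substitution_bases(row)
            if bases is not None:
                if classify_substitution(*bases) == "transition":
                    n_ts += 1
                else:
                    n_tv += 1
        if n_small + n_rearr == 0:
            warnings.warn(f"group {label!r} has no classified mutations; omitted")
            continue
        summaries.append(
            SpectrumSummary(str(label), n_small, n_rearr, n_ts, n_tv, threshold)
        )
    return summaries


@dataclass
class CohortCounts:
    """Screening tallies for one irradiation condition.

    ``n_m1``: mutagenized-generation plants (metadata only); ``n_m2``:
    second-generation plants screened (frequency denominator);
    ``n_mutants``: mutants found among them.
    """

    let: float
    dose: float
    n_m1: int
    n_m2: int
    n_mutants: int

    def __post_init__(self) -> None:
        if self.n_m2 <= 0:
            raise SpectrumError("n_m2 must be positive")
        if not 0 <= self.n_mutants <= self.n_m2:
            raise SpectrumError("n_mutants must be within [0, n_m2]")

    @property
    def frequency_raw_permil(self) -> float:
        return 1000.0 * self.n_mutants / self.n_m2

    @property
    def frequency_permil(self) -> float:
        """Point estimate in per mil, rounded half-away-from-zero to 2 decimals."""
        return round_half_away(self.frequency_raw_permil, 2)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion (unrounded)."""
    if not 0 <= k <= n or n <= 0:
        raise SpectrumError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class FrequencyEstimate:
    """Per-mil mutation frequency with an exact binomial CI (an addition,
    not a reproduced value)."""

    permil: float
    ci_low_permil: float
    ci_high_permil: float
    n: int
    k: int
    conf: float = 0.95
    from_paper: bool = False  # CI is a methodological addition


def mutation_frequency(counts: CohortCounts, conf: float = 0.95) -> FrequencyEstimate:
    """Mutation frequency in per mil of screened plants, with exact CI."""
    lo, hi = clopper_pearson(counts.n_mutants, counts.n_m2, conf)
    return FrequencyEstimate(
        permil=counts.frequency_permil,
        ci_low_permil=1000.0 * lo,
        ci_high_permil=1000.0 * hi,
        n=counts.n_m2,
        k=counts.n_mutants,
        conf=conf,
    )


@dataclass
class RatioEstimate:
    """Fold change between two cohort frequencies with conditional exact CI
    and a two-sided Fisher exact p-value (additions, not reproduced values)."""

    ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    fisher_p: float
    one_sided_bound: Optional[float] = None


def frequency_ratio(a: CohortCounts, b: CohortCounts, conf: float = 0.95) -> RatioEstimate:
    """Fold change of cohort ``a``'s frequency over cohort ``b``'s.

    The CI conditions on the total mutant count ``K = k_a + k_b``: under a
    common-rate model ``k_a | K ~ Binomial(K, pi)`` with
    ``pi = n_a r / (n_a r + n_b)`` for frequency ratio ``r``; an exact CI on
    ``pi`` (Clopper-Pearson) maps back to ``r`` via
    ``r = pi / (1 - pi) * n_b / n_a``.  A two-sided Fisher exact p-value on
    the mutant/non-mutant x condition 2x2 table is attached.
    """
    table = [
        [a.n_mutants, a.n_m2 - a.n_mutants],
        [b.n_mutants, b.n_m2 - b.n_mutants],
    ]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])

    k_total = a.n_mutants + b.n_mutants
    if b.n_mutants == 0:
        # Ratio undefined; report a one-sided lower bound on a's rate advantage.
        if k_total == 0:
            return RatioEstimate(float("nan"), None, None, fisher_p, None)
        lo_pi, _ = clopper_pearson(a.n_mutants, k_total, conf)
        bound = None
        if lo_pi < 1.0:
            bound = lo_pi / (1.0 - lo_pi) * b.n_m2 / a.n_m2
        return RatioEstimate(float("inf"), None, None, fisher_p, bound)

    ratio = a.frequency_raw_permil / b.frequency_raw_permil
    lo_pi, hi_pi = clopper_pearson(a.n_mutants, k_total, conf)
    scale = b.n_m2 / a.n_m2
    ci_low = lo_pi / (1.0 - lo_pi) * scale if lo_pi < 1 else float("inf")
    ci_high = hi_pi / (1.0 - hi_pi) * scale if hi_pi < 1 else float("inf")
    return RatioEstimate(ratio, ci_low, ci_high, fisher_p)


@dataclass
class DoseResponsePoint:
    """Observed response at one irradiation condition (descriptive only)."""

    condition: IrradiationCondition
    survival_pct: Optional[float] = None
    albino_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("survival_pct", "albino_pct"):
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 100:
                raise SpectrumError(f"{name} must be within [0, 100], got {value}")

    @property
    def fluence(self) -> float:
        return self.condition.fluence_per_area


def dose_response_table(points: Sequence[DoseResponsePoint]) -> pd.DataFrame:
    """Tidy table of dose-response observations, sorted by LET then fluence."""
    rows = [
        {
            "let_kev_um": p.condition.let,
            "dose_gy": p.condition.dose,
            "fluence_per_area": p.fluence,
            "survival_pct": p.survival_pct,
            "albino_pct": p.albino_pct,
        }
        for p in points
    ]
    df = pd.DataFrame(
        rows,
        columns=["let_kev_um", "dose_gy", "fluence_per_area", "survival_pct", "albino_pct"],
    )
    return df.sort_values(["let_kev_um", "fluence_per_area"], kind="mergesort").reset_index(
        drop=True
    )


def interpolate_fluence(
    points: Sequence[DoseResponsePoint],
    level: float,
    response: str = "survival_pct",
) -> float:
    """Fluence at which the response crosses ``level``, by linear interpolation.

    Points are sorted by fluence internally; the first adjacent pair whose
    response values bracket ``level`` is interpolated.  Queries outside the
    observed response range raise rather than extrapolate.
    """
    usable = [p for p in points if getattr(p, response) is not None]
    if len(usable) < 2:
        raise SpectrumError("need at least two points with the requested response")
    usable.sort(key=lambda p: p.fluence)
    for left, right in zip(usable, usable[1:]):
        y0, y1 = getattr(left, response), getattr(right, response)
        if min(y0, y1) <= level <= max(y0, y1):
            if y1 == y0:
                return left.fluence
            frac = (level - y0) / (y1 - y0)
            return left.fluence + frac * (right.fluence - left.fluence)
    raise SpectrumError(
        f"{response}={level} is outside the observed range; extrapolation refused"
    )
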