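"""Per-chromosome metrics and karyotype-level summaries.

A karyotype is described pair by pair: each homolog pair carries a short-arm
and a long-arm relative length (means over replicate metaphase plates, with
standard errors where available).  From the two arm lengths this module
derives the arm ratio AR = LA/SA and the centromeric index
CI = SA/(SA+LA) x 100, classifies each pair into the Levan morphology
classes (metacentric M, submetacentric SM, subtelocentric ST, telocentric T),
and rolls a whole karyotype up into the standard cytogenetic summary: the
karyotype formula (e.g. ``42M+6SM+4ST+8T``), the fundamental number FN
(total arm count of the diploid complement), and per-class proportions.

Telocentric pairs have no measurable short arm; they are encoded with
``short_arm = 0`` and an infinite arm ratio.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "INFINITE",
    "ChromosomeClass",
    "CLASS_ORDER",
    "ChromosomePair",
    "ChromosomeMetrics",
    "Karyotype",
    "KaryotypeSummary",
    "arm_ratio",
    "centromeric_index",
    "classify",
    "zone_assign",
    "pair_metrics",
    "fundamental_number",
    "format_formula",
    "parse_formula",
    "summarize_karyotype",
    "summary_from_formula",
    "type_proportions",
    "validate_measurements",
]

#: Sentinel arm ratio for telocentric pairs (no short arm).
INFINITE = math.inf


class ChromosomeClass(str, Enum):
    """Levan morphology class of a chromosome, from its arm ratio."""

    M = "M"    # metacentric,    1.0 <= AR < 1.7
    SM = "SM"  # submetacentric, 1.7 <= AR < 3.0
    ST = "ST"  # subtelocentric, 3.0 <= AR < 7.0
    T = "T"    # telocentric,    7.0 <= AR (incl. infinite)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical class order used in formulas, layouts and reports.
CLASS_ORDER: tuple[ChromosomeClass, ...] = (
    ChromosomeClass.M,
    ChromosomeClass.SM,
    ChromosomeClass.ST,
    ChromosomeClass.T,
)

# Lower-inclusive arm-ratio intervals: a pair sitting exactly on a boundary
# belongs to the more asymmetric class (AR = 1.70 is SM, not M).
_CLASS_INTERVALS: tuple[tuple[float, float, ChromosomeClass], ...] = (
    (1.0, 1.7, ChromosomeClass.M),
    (1.7, 3.0, ChromosomeClass.SM),
    (3.0, 7.0, ChromosomeClass.ST),
    (7.0, math.inf, ChromosomeClass.T),
)


def _check_arms(short_arm: float, long_arm: float, pair: object = None) -> None:
    where = f" (pair {pair})" if pair is not None else ""
    if short_arm < 0 or long_arm < 0:
        raise ValueError(f"arm lengths must be nonnegative{where}: "
                         f"SA={short_arm}, LA={long_arm}")
    if long_arm <= 0:
        raise ValueError(f"long arm must be positive{where}: LA={long_arm}")
    if long_arm < short_arm:
        raise ValueError(
            f"arms must be ordered long >= short{where}: "
            f"SA={short_arm} > LA={long_arm}")


def arm_ratio(short_arm: float, long_arm: float, *, pair: object = None) -> float:
    """Arm ratio AR = LA / SA; ``INFINITE`` for a telocentric pair (SA = 0)."""
    _check_arms(short_arm, long_arm, pair)
    if short_arm == 0:
        return INFINITE
    return long_arm / short_arm


def centromeric_index(short_arm: float, long_arm: float, *, pair: object = None) -> float:
    """Centromeric index CI = SA / (SA + LA) x 100; 0 for telocentrics."""
    _check_arms(short_arm, long_arm, pair)
    if short_arm == 0:
        return 0.0
    return short_arm / (short_arm + long_arm) * 100.0


def classify(ar: float) -> ChromosomeClass:
    """Map an arm ratio to its Levan class.

    Intervals are lower-inclusive: [1.0, 1.7) M, [1.7, 3.0) SM,
    [3.0, 7.0) ST, [7.0, inf] T.  An infinite ratio (telocentric) is T.
    """
    if math.isinf(ar):
        return ChromosomeClass.T
    if not ar >= 1.0:
        raise ValueError(f"arm ratio must be >= 1 (arms ordered): got {ar}")
    for lo, hi, cls in _CLASS_INTERVALS:
        if lo <= ar < hi:
            return cls
    return ChromosomeClass.T


def zone_assign(short_arm: float, long_arm: float, *, pair: object = None) -> ChromosomeClass:
    """Levan class of a point in the (SA, LA) plane.

    The class intervals correspond to wedge-shaped zones between lines of
    slope 1, 1.7, 3 and 7 through the origin; this is the geometric view of
    :func:`classify` used for scatter-diagram export, and agrees with it
    exactly.
    """
    return classify(arm_ratio(short_arm, long_arm, pair=pair))


@dataclass(frozen=True)
class ChromosomePair:
    """One homolog pair's arm measurements, in relative-length units.

    ``short_arm = 0`` encodes a telocentric pair.  Standard errors are
    optional: source tables may report them per arm (``short_se``/``long_se``)
    or on the total length and the arm ratio (``total_se``/``ar_se``).
    ``reported_ar``/``reported_type`` hold the values printed in a source
    table, when the pair was transcribed rather than measured here; the
    printed AR is a mean of per-plate ratios and can differ slightly from
    the ratio of the mean arms.
    """

    pair_index: int
    short_arm: float
    long_arm: float
    short_se: Optional[float] = None
    long_se: Optional[float] = None
    total_se: Optional[float] = None
    ar_se: Optional[float] = None
    reported_ar: Optional[float] = None
    reported_type: Optional[ChromosomeClass] = None

    def __post_init__(self) -> None:
        _check_arms(self.short_arm, self.long_arm, self.pair_index)
        for name in ("short_se", "long_se", "total_se", "ar_se"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 (pair {self.pair_index})")
        if self.reported_type is not None and not isinstance(self.reported_type, ChromosomeClass):
            object.__setattr__(self, "reported_type", ChromosomeClass(self.reported_type))

    @property
    def total(self) -> float:
        """Total relative length SA + LA."""
        return self.short_arm + self.long_arm

    @property
    def is_telocentric(self) -> bool:
        return self.short_arm == 0

    @property
    def ar(self) -> float:
        """Arm ratio recomputed from the stored arm lengths."""
        return arm_ratio(self.short_arm, self.long_arm, pair=self.pair_index)

    @property
    def ci(self) -> float:
        return centromeric_index(self.short_arm, self.long_arm, pair=self.pair_index)


@dataclass(frozen=True)
class ChromosomeMetrics:
    """Derived per-pair metrics: total length, AR, CI and Levan class."""

    total: float
    ar: float
    ci: float
    cls: ChromosomeClass


def pair_metrics(pair: ChromosomePair, ar_source: str = "reported") -> ChromosomeMetrics:
    """Compute :class:`ChromosomeMetrics` for one pair.

    ``ar_source='reported'`` uses the printed per-pair AR mean when present
    (falling back to LA/SA); ``'recomputed'`` always uses LA/SA of the stored
    arms.  The printed AR is preferred by default because it averages
    per-plate ratios, which is what determines the published class for
    boundary pairs.
    """
    if ar_source not in ("reported", "recomputed"):
        raise ValueError(f"ar_source must be 'reported' or 'recomputed': {ar_source}")
    if ar_source == "reported" and pair.reported_ar is not None:
        ar = pair.reported_ar
    else:
        ar = pair.ar
    return ChromosomeMetrics(total=pair.total, ar=ar, ci=pair.ci, cls=classify(ar))


@dataclass(frozen=True)
class Karyotype:
    """A species' ordered complement of homolog pairs."""

    species: str
    pairs: tuple[ChromosomePair, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))

    @property
    def n_haploid(self) -> int:
        return len(self.pairs)

    @property
    def two_n(self) -> int:
        return 2 * len(self.pairs)


@dataclass(frozen=True)
class KaryotypeSummary:
    """Class counts (chromosomes, not pairs), formula, FN and 2n."""

    species: str
    counts: Mapping[ChromosomeClass, int]
    formula: str
    fn: int
    two_n: int


def fundamental_number(class_counts: Mapping[ChromosomeClass | str, int]) -> int:
    """Fundamental number (total arm count) of a diploid complement.

    Biarmed classes (M, SM) contribute two arms per chromosome; ST and T
    contribute one.  Counts are chromosome counts and must be even and
    nonnegative.
    """
    counts = {ChromosomeClass(k): int(v) for k, v in class_counts.items()}
    for cls, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count for {cls.value}: {v}")
        if v % 2:
            raise ValueError(f"odd chromosome count for {cls.value}: {v} "
                             "(diploid counts must be even)")
    biarmed = counts.get(ChromosomeClass.M, 0) + counts.get(ChromosomeClass.SM, 0)
    uniarmed = counts.get(ChromosomeClass.ST, 0) + counts.get(ChromosomeClass.T, 0)
    return 2 * biarmed + uniarmed


def format_formula(class_counts: Mapping[ChromosomeClass | str, int]) -> str:
    """Canonical karyotype formula: classes in M, SM, ST, T order, zero
    counts omitted, e.g. ``'42M+6SM+4ST+8T'``."""
    counts = {ChromosomeClass(k): int(v) for k, v in class_counts.items()}
    parts = [f"{counts[c]}{c.value}" for c in CLASS_ORDER if counts.get(c, 0) > 0]
    if not parts:
        raise ValueError("empty karyotype: all class counts are zero")
    return "+".join(parts)


_FORMULA_TERM = re.compile(r"^(\d+)(M|SM|ST|T)$")


def parse_formula(formula: str) -> dict[ChromosomeClass, int]:
    """Parse a karyotype formula string back to per-class chromosome counts."""
    counts: dict[ChromosomeClass, int] = {c: 0 for c in CLASS_ORDER}
    for term in formula.strip().split("+"):
        m = _FORMULA_TERM.match(term.strip())
        if not m:
            raise ValueError(f"malformed formula term: {term!r} in {formula!r}")
        cls = ChromosomeClass(m.group(2))
        if counts[cls]:
            raise ValueError(f"class {cls.value} repeated in {formula!r}")
        counts[cls] = int(m.group(1))
    return counts


def summarize_karyotype(karyotype: Karyotype, ar_source: str = "reported") -> KaryotypeSummary:
    """Summarize a karyotype: per-class chromosome counts, formula and FN."""
    if not karyotype.pairs:
        raise ValueError(f"empty karyotype for {karyotype.species!r}")
    counts: dict[ChromosomeClass, int] = {c: 0 for c in CLASS_ORDER}
    for pair in karyotype.pairs:
        counts[pair_metrics(pair, ar_source).cls] += 2  # two homologs per pair
    return KaryotypeSummary(
        species=karyotype.species,
        counts=counts,
        formula=format_formula(counts),
        fn=fundamental_number(counts),
        two_n=karyotype.two_n,
    )


def summary_from_formula(species: str, formula: str) -> KaryotypeSummary:
    """Build a :class:`KaryotypeSummary` from a published formula string."""
    counts = parse_formula(formula)
    two_n = sum(counts.values())
    return KaryotypeSummary(
        species=species,
        counts=counts,
        formula=format_formula(counts),
        fn=fundamental_number(counts),
        two_n=two_n,
    )


def type_proportions(
    summaries: Sequence[KaryotypeSummary],
    pooled_label: str = "pooled",
) -> dict[str, dict[ChromosomeClass, float]]:
    """Per-class chromosome percentages, per species and pooled.

    The pooled percentage of a class is 100 x (total chromosomes of that
    class across all summaries) / (total chromosomes).  Each row sums to 100
    up to floating-point rounding.
    """
    if not summaries:
        raise ValueError("at least one summary required")
    out: dict[str, dict[ChromosomeClass, float]] = {}
    pooled = {c: 0 for c in CLASS_ORDER}
    pooled_total = 0
    for s in summaries:
        out[s.species] = {c: 100.0 * s.counts.get(c, 0) / s.two_n for c in CLASS_ORDER}
        for c in CLASS_ORDER:
            pooled[c] += s.counts.get(c, 0)
        pooled_total += s.two_n
    out[pooled_label] = {c: 100.0 * pooled[c] / pooled_total for c in CLASS_ORDER}
    return out


# Reported AR is accepted if within max(0.05, 2%) of LA/SA: printed ratios
# are plate means rounded to 2 decimals, so small discrepancies are expected.
_AR_ABS_TOL = 0.05
_AR_REL_TOL = 0.02


def validate_measurements(karyotype: Karyotype) -> list[str]:
    """Audit a transcribed karyotype for internal consistency.

    For pairs with a short arm, flags reported AR values that disagree with
    LA/SA beyond tolerance, and reported types that disagree with the class
    of the reported AR.  Returns a list of human-readable violations
    (empty = clean).  Report-only: never raises on inconsistency.
    """
    violations: list[str] = []
    for pair in karyotype.pairs:
        label = f"{karyotype.species} pair {pair.pair_index}"
        if pair.reported_ar is not None and pair.short_arm > 0 and not math.isinf(pair.reported_ar):
            recomputed = pair.ar
            tol = max(_AR_ABS_TOL, _AR_REL_TOL * pair.reported_ar)
            if abs(recomputed - pair.reported_ar) > tol:
                violations.append(
                    f"{label}: recomputed AR {recomputed:.3f} differs from "
                    f"reported {pair.reported_ar:.3f} by more than {tol:.3f}")
        if pair.reported_type is not None and pair.reported_ar is not None:
            cls = classify(pair.reported_ar)
            if cls is not pair.reported_type:
                violations.append(
                    f"{label}: reported AR {pair.reported_ar} classifies as "
                    f"{cls.value}, but reported type is {pair.reported_type.value}")
    return violations
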