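"""Seeded simulation of karyotype measurement tables.

The generator emulates the structure of a measured karyotype table: a fixed
number of homolog pairs per Levan class, per-pair "true" arm lengths, and
replicate measurements over k metaphase plates with multiplicative noise,
reported as means ± standard errors.  True arm ratios are drawn uniformly
inside each class interval shrunk by a boundary margin, so the class of
every simulated pair is unambiguous ground truth; telocentric pairs get a
zero short arm.  True total lengths follow a geometric decay whose
largest-to-smallest span is a template parameter (observed complements span
roughly 4- to 7.5-fold), rescaled to a target sum.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
given seed reproduces the same table on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import CLASS_ORDER, ChromosomeClass, ChromosomePair, Karyotype

__all__ = ["SyntheticTemplate", "simulate_karyotype", "simulate_taxa"]

# Finite sampling intervals per class; T is sampled as a true telocentric
# (SA = 0), so its interval is unused.
_AR_INTERVALS = {
    ChromosomeClass.M: (1.0, 1.7),
    ChromosomeClass.SM: (1.7, 3.0),
    ChromosomeClass.ST: (3.0, 7.0),
}


@dataclass(frozen=True)
class SyntheticTemplate:
    """Generative description of one species' karyotype table.

    ``class_counts`` gives homolog *pairs* per class (a 2n=60 octopus-like
    complement is 30 pairs).  ``noise_sd`` is the per-plate multiplicative
    measurement noise as a fraction of arm length; ``plates`` is the number
    of metaphase replicates k (at least 7 in careful studies, the default
    here).  ``boundary_margin`` keeps true arm ratios away from class
    boundaries so plate noise rarely flips a class.  ``length_span`` is the
    max/min ratio of the geometric length decay (measured complements span
    about 4x to 7.5x).
    """

    class_counts: Mapping[ChromosomeClass | str, int]
    total_length: float = 100.0
    boundary_margin: float = 0.05
    noise_sd: float = 0.02
    plates: int = 7
    length_span: float = 5.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        counts = {ChromosomeClass(k): int(v) for k, v in self.class_counts.items()}
        object.__setattr__(self, "class_counts", counts)
        if any(v < 0 for v in counts.values()) or sum(counts.values()) == 0:
            raise ValueError("class_counts must be nonnegative with at least one pair")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be >= 0")
        for cls, (lo, hi) in _AR_INTERVALS.items():
            if counts.get(cls, 0) and 2 * self.boundary_margin >= hi - lo:
                raise ValueError(
                    f"boundary_margin {self.boundary_margin} leaves no room in the "
                    f"{cls.value} interval [{lo}, {hi})")
        if self.plates < 1:
            raise ValueError("plates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        if self.length_span < 1:
            raise ValueError("length_span must be >= 1")

    @property
    def n_pairs(self) -> int:
        return sum(self.class_counts.values())


def _true_karyotype(template: SyntheticTemplate, rng: np.random.Generator
                    ) -> list[tuple[ChromosomeClass, float, float]]:
    """Draw true (class, SA, LA) per pair: AR uniform inside the shrunk class
    interval, totals geometrically decaying and scaled to total_length."""
    n = template.n_pairs
    # geometric decay: totals span a length_span-fold range, then rescale
    r = template.length_span ** (-1.0 / max(n - 1, 1))
    totals = r ** np.arange(n)
    totals *= template.total_length / totals.sum()
    classes: list[ChromosomeClass] = []
    for cls in CLASS_ORDER:
        classes.extend([cls] * template.class_counts.get(cls, 0))
    truth = []
    for cls, total in zip(classes, totals):
        if cls is ChromosomeClass.T:
            sa, la = 0.0, total
        else:
            lo, hi = _AR_INTERVALS[cls]
            ar = rng.uniform(lo + template.boundary_margin, hi - template.boundary_margin)
            sa = total / (1.0 + ar)
            la = total - sa
        truth.append((cls, sa, la))
    return truth


def _measure(truth: Sequence[tuple[ChromosomeClass, float, float]],
             template: SyntheticTemplate, rng: np.random.Generator) -> Karyotype:
    """Replicate plate measurements of true arms and report means ± SE."""
    k = template.plates
    noiseless = template.noise_sd == 0
    pairs = []
    for idx, (cls, sa, la) in enumerate(truth, start=1):
        noise = np.zeros((k, 2)) if noiseless else rng.normal(0.0, template.noise_sd, size=(k, 2))
        sa_plates = np.maximum(sa * (1.0 + noise[:, 0]), 0.0)
        la_plates = np.maximum(la * (1.0 + noise[:, 1]), 1e-9)
        sa_mean = float(sa_plates.mean())
        la_mean = float(la_plates.mean())
        if la_mean < sa_mean:  # noise inverted the arms; keep them ordered
            sa_mean, la_mean = la_mean, sa_mean
            sa_plates, la_plates = la_plates, sa_plates
        def se(x: np.ndarray) -> float:
            if noiseless or k == 1:
                return 0.0
            return float(x.std(ddof=1) / math.sqrt(k))
        totals = sa_plates + la_plates
        if sa == 0.0:
            ar_mean: float = math.inf
            ar_se = None
        else:
            ars = la_plates / np.maximum(sa_plates, 1e-12)
            ar_mean = float(ars.mean())
            ar_se = se(ars)
        pairs.append(ChromosomePair(
            pair_index=idx,
            short_arm=round(sa_mean, 6),
            long_arm=round(la_mean, 6),
            short_se=se(sa_plates),
            long_se=se(la_plates),
            total_se=se(totals),
            ar_se=ar_se,
            reported_ar=ar_mean,
            reported_type=cls,
        ))
    return Karyotype(species=template.name, pairs=tuple(pairs))


def simulate_karyotype(template: SyntheticTemplate,
                       rng: Optional[np.random.Generator] = None) -> Karyotype:
    """Simulate one measured karyotype table from a template.

    Fully reproducible: with no explicit generator, a fresh PCG64 stream is
    seeded from ``template.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(template.seed)
    truth = _true_karyotype(template, rng)
    return _measure(truth, template, rng)


def simulate_taxa(templates: Sequence[SyntheticTemplate],
                  replicates_per_template: int = 1,
                  divergence: float = 0.0,
                  seed: Optional[int] = None) -> list[Karyotype]:
    """Simulate related taxa: replicates of each template with divergence.

    Each replicate perturbs the template's true arm lengths multiplicatively
    by ``exp(N(0, divergence))`` per pair before measurement noise is added,
    emulating karyotype divergence among close relatives; ``divergence=0``
    yields identical truths within a template.  Labels encode template
    membership as ``<name>_rep<i>``.
    """
    if len(templates) < 2:
        raise ValueError("need at least two templates")
    if replicates_per_template < 1:
        raise ValueError("replicates_per_template must be >= 1")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed if seed is not None else templates[0].seed)
    out: list[Karyotype] = []
    for template in templates:
        truth = _true_karyotype(template, rng)
        for rep in range(1, replicates_per_template + 1):
            if divergence > 0:
                factors = np.exp(rng.normal(0.0, divergence, size=len(truth)))
                perturbed = [(cls, sa * f, la * f)
                             for (cls, sa, la), f in zip(truth, factors)]
            else:
                perturbed = list(truth)
            labelled = replace(template, name=f"{template.name}_rep{rep}")
            out.append(_measure(perturbed, labelled, rng))
    return out
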