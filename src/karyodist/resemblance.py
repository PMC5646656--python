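"""Resemblance-near coefficients and karyotype evolutionary distance.

Numerical cytotaxonomy compares species through a karyotype parameter
vector — here, the per-pair total relative lengths.  A resemblance-near
coefficient λ in (0, 1] measures the similarity of two such vectors after
rank pairing (both sorted by decreasing length) and, where needed, padding
to a common haploid number.  The karyotype evolutionary distance is
De = −ln λ, so identical karyotypes have λ = 1, De = 0.

The exact λ formula behind published tables of this kind varies between
studies and is often only given in supplementary material; kernels are
therefore pluggable.  The default, ``hamming``, is the classical fuzzy
nearness 1 − mean |a_i − b_i| on max-normalized profiles, which pairs
naturally with the logarithmic distance transform.  Published dual matrices
can also be loaded verbatim (see :mod:`karyodist.io_formats`) so downstream
clustering does not depend on kernel choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import Karyotype

__all__ = [
    "Profile",
    "DualMatrix",
    "KERNELS",
    "build_profile",
    "align_profiles",
    "lambda_hamming",
    "lambda_ratio",
    "lambda_ruzicka",
    "de_from_lambda",
    "lambda_from_de",
    "build_dual_matrix",
    "duality_audit",
    "matrix_stats",
]


@dataclass(frozen=True)
class Profile:
    """A species' haploid length profile: per-pair totals, sorted descending.

    ``mode`` records the normalization applied: ``none`` (raw relative
    lengths), ``max`` (divided by the largest, so values lie in (0, 1]), or
    ``sum`` (divided by the total, so values sum to 1).
    """

    species: str
    values: np.ndarray
    mode: str = "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError(f"profile for {self.species!r} must be a nonempty vector")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError(f"profile for {self.species!r} must be sorted descending")


def build_profile(karyotype: Karyotype, mode: str = "none") -> Profile:
    """Per-pair total lengths (SA + LA), globally sorted descending.

    Source tables order pairs within morphology class, so the profile is
    re-sorted across all classes before rank pairing.
    """
    totals = np.array([p.total for p in karyotype.pairs], dtype=float)
    if totals.size == 0:
        raise ValueError(f"empty karyotype for {karyotype.species!r}")
    if np.any(totals <= 0):
        raise ValueError(f"nonpositive total length in {karyotype.species!r}")
    totals = np.sort(totals)[::-1]
    if mode == "none":
        pass
    elif mode == "max":
        totals = totals / totals[0]
    elif mode == "sum":
        totals = totals / totals.sum()
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return Profile(species=karyotype.species, values=totals, mode=mode)


def align_profiles(a: Profile, b: Profile, pad: str = "zero") -> tuple[np.ndarray, np.ndarray]:
    """Bring two profiles to a common length for rank-paired comparison.

    ``pad='zero'`` right-pads the shorter vector with zeros (a chromosome
    absent from the smaller complement is maximally dissimilar);
    ``pad='truncate'`` cuts both to the shorter length.
    """
    va, vb = a.values, b.values
    if pad == "zero":
        n = max(va.size, vb.size)
        va = np.pad(va, (0, n - va.size))
        vb = np.pad(vb, (0, n - vb.size))
    elif pad == "truncate":
        n = min(va.size, vb.size)
        va, vb = va[:n], vb[:n]
    else:
        raise ValueError(f"unknown pad policy: {pad!r}")
    return va, vb


def _check_aligned(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"profiles are not aligned: lengths {a.size} vs {b.size}")


def lambda_hamming(a: np.ndarray, b: np.ndarray) -> float:
    """Fuzzy-nearness λ = 1 − (1/n) Σ |a_i − b_i| (default kernel).

    Intended for max-normalized profiles, whose entries lie in [0, 1]; the
    result is then guaranteed to lie in [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_aligned(a, b)
    return float(1.0 - np.abs(a - b).mean())


def lambda_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """λ = (1/n) Σ min/max per rank; ranks where both are 0 contribute 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_aligned(a, b)
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    terms = np.where(hi > 0, np.divide(lo, hi, out=np.ones_like(hi), where=hi > 0), 1.0)
    return float(terms.mean())


def lambda_ruzicka(a: np.ndarray, b: np.ndarray) -> float:
    """Ruzicka (weighted Jaccard) λ = Σ min / Σ max."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_aligned(a, b)
    denom = np.maximum(a, b).sum()
    if denom == 0:
        raise ValueError("both profiles are identically zero")
    return float(np.minimum(a, b).sum() / denom)


KERNELS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "hamming": lambda_hamming,
    "ratio": lambda_ratio,
    "ruzicka": lambda_ruzicka,
}

# Normalization each kernel expects before rank pairing.
_KERNEL_MODE = {"hamming": "max", "ratio": "none", "ruzicka": "none"}


def de_from_lambda(lam: float) -> float:
    """Karyotype evolutionary distance De = −ln λ, for λ in (0, 1]."""
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lambda must be in (0, 1]: got {lam}")
    return -math.log(lam)


def lambda_from_de(de: float) -> float:
    """Inverse transform λ = exp(−De), for De >= 0."""
    if de < 0:
        raise ValueError(f"De must be >= 0: got {de}")
    return math.exp(-de)


@dataclass(frozen=True)
class DualMatrix:
    """Paired symmetric matrices over the same taxa: De and λ.

    Mirrors the conventional dual-table layout in which the lower triangle
    holds evolutionary distances and the upper triangle the resemblance-near
    coefficients.  Internally both are stored as full symmetric matrices
    with De diagonal 0 and λ diagonal 1.
    """

    taxa: tuple[str, ...]
    de: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        taxa = tuple(self.taxa)
        object.__setattr__(self, "taxa", taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        de = np.asarray(self.de, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        n = len(taxa)
        for name, m in (("de", de), ("lam", lam)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {n})")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} matrix is not symmetric")
        if not np.allclose(np.diag(de), 0.0):
            raise ValueError("De diagonal must be 0")
        if not np.allclose(np.diag(lam), 1.0):
            raise ValueError("lambda diagonal must be 1")
        if np.any(de < 0):
            raise ValueError("De entries must be >= 0")
        off = ~np.eye(n, dtype=bool)
        if np.any(lam[off] <= 0) or np.any(lam[off] > 1):
            raise ValueError("lambda entries must lie in (0, 1]")
        object.__setattr__(self, "de", de)
        object.__setattr__(self, "lam", lam)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def get_de(self, a: str, b: str) -> float:
        return float(self.de[self.index(a), self.index(b)])

    def get_lam(self, a: str, b: str) -> float:
        return float(self.lam[self.index(a), self.index(b)])

    def pairs(self) -> Iterable[tuple[str, str]]:
        """Unordered off-diagonal taxon pairs, row-major upper triangle."""
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield self.taxa[i], self.taxa[j]


def build_dual_matrix(
    profiles: Sequence[Profile],
    kernel: str = "hamming",
    pad: str = "zero",
) -> DualMatrix:
    """Compute λ for every unordered pair of profiles and De = −ln λ.

    Profiles are re-normalized per the kernel's expected mode (``hamming``
    works on max-normalized values; ``ratio``/``ruzicka`` on raw lengths)
    and aligned per the pad policy before each pairwise evaluation.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    taxa = tuple(p.species for p in profiles)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    fn = KERNELS[kernel]
    mode = _KERNEL_MODE[kernel]
    normed = [_renormalize(p, mode) for p in profiles]
    n = len(profiles)
    lam = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            va, vb = align_profiles(normed[i], normed[j], pad=pad)
            lam[i, j] = lam[j, i] = fn(va, vb)
    with np.errstate(divide="ignore"):
        de = -np.log(lam)
    np.fill_diagonal(de, 0.0)
    return DualMatrix(taxa=taxa, de=de, lam=lam)


def _renormalize(p: Profile, mode: str) -> Profile:
    if p.mode == mode:
        return p
    v = p.values
    if p.mode == "max" and mode == "none":
        raise ValueError("cannot undo max normalization; build profile with mode='none'")
    if mode == "max":
        v = v / v[0]
    elif mode == "sum":
        v = v / v.sum()
    return Profile(species=p.species, values=v, mode=mode)


def duality_audit(
    matrix: DualMatrix, tol: float = 1.6e-3
) -> list[tuple[str, str, float, bool]]:
    """Check the De = −ln λ relation cell by cell.

    Returns ``(taxon_a, taxon_b, residual, flagged)`` for every unordered
    pair, where residual = |De + ln λ| and ``flagged`` marks residuals above
    ``tol``.  Useful for auditing transcribed tables: a flagged pair means
    the printed De and λ are mutually inconsistent (e.g. a typo).
    """
    report = []
    for a, b in matrix.pairs():
        resid = abs(matrix.get_de(a, b) + math.log(matrix.get_lam(a, b)))
        report.append((a, b, resid, resid > tol))
    return report


def matrix_stats(matrix: DualMatrix) -> dict[str, dict[str, object]]:
    """Min / max / mean with arg-pairs over the off-diagonal entries of each
    triangle (De and λ)."""
    out: dict[str, dict[str, object]] = {}
    pairs = list(matrix.pairs())
    if not pairs:
        raise ValueError("need at least two taxa")
    for name, get in (("de", matrix.get_de), ("lam", matrix.get_lam)):
        vals = np.array([get(a, b) for a, b in pairs])
        out[name] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "argmin": pairs[int(vals.argmin())],
            "argmax": pairs[int(vals.argmax())],
        }
    return out
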