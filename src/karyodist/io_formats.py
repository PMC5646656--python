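"""Readers/writers for karyotype tables, dual λ/De matrices, PHYLIP and MEGA
distance formats, plus the packaged reference data.

Three small plain-text tables ship inside the package, transcribed from the
published cytogenetic study of nine cephalopod species that this pipeline
reproduces:

* ``table1.tsv`` — karyotype summaries (2n, FN, formula) of all nine species,
  with their Octopodiformes/Decapodiformes grouping;
* ``table2.csv`` — per-pair arm measurements (30 pairs each) for the three
  octopods karyotyped in that study;
* ``table3.tsv`` — the published dual matrix: evolutionary distance De in
  the lower triangle, resemblance-near coefficient λ in the upper triangle.

All writers are deterministic byte-for-byte given identical input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ChromosomeClass,
    ChromosomePair,
    Karyotype,
    KaryotypeSummary,
    summary_from_formula,
)
from .resemblance import DualMatrix

__all__ = [
    "FixtureSet",
    "read_karyotype_table",
    "write_karyotype_table",
    "read_dual_matrix",
    "write_dual_matrix",
    "read_phylip_dist",
    "write_phylip_dist",
    "write_meg",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_fixtures",
]

PathLike = Union[str, Path]

_SE_COLUMNS = ("short_se", "long_se", "total_se", "ar_se")
_REQUIRED_COLUMNS = ("species", "pair", "short_arm", "long_arm")


def _parse_sa(value: object) -> float:
    """Short-arm cell: '-' or empty means telocentric (SA = 0)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return 0.0
    s = str(value).strip()
    if s in ("", "-"):
        return 0.0
    return float(s)


def _parse_ar(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "-"):
        return None
    if s.lower() in ("inf", "infinite") or s == "∞":
        return math.inf
    return float(s)


def _parse_opt(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return float(s) if s else None


def read_karyotype_table(path: PathLike, sep: Optional[str] = None) -> list[Karyotype]:
    """Read a delimited karyotype measurement table.

    Required columns: ``species, pair, short_arm, long_arm``.  Optional:
    per-arm or total/AR standard errors, ``reported_ar`` (the token ``inf``
    for telocentrics) and ``reported_type``.  A ``-`` or empty short arm
    encodes a telocentric pair.  Delimiter is sniffed from the extension
    unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    karyotypes: list[Karyotype] = []
    seen: set[tuple[str, int]] = set()
    for species, group in df.groupby("species", sort=False):
        pairs = []
        for _, row in group.iterrows():
            idx = int(row["pair"])
            key = (str(species), idx)
            if key in seen:
                raise ValueError(f"{path}: duplicate entry for {species} pair {idx}")
            seen.add(key)
            rtype = row.get("reported_type")
            if isinstance(rtype, str) and rtype.strip():
                rtype = ChromosomeClass(rtype.strip())
            else:
                rtype = None
            try:
                pair = ChromosomePair(
                    pair_index=idx,
                    short_arm=_parse_sa(row["short_arm"]),
                    long_arm=float(row["long_arm"]),
                    short_se=_parse_opt(row.get("short_se")),
                    long_se=_parse_opt(row.get("long_se")),
                    total_se=_parse_opt(row.get("total_se")),
                    ar_se=_parse_opt(row.get("ar_se")),
                    reported_ar=_parse_ar(row.get("reported_ar")),
                    reported_type=rtype,
                )
            except ValueError as e:
                raise ValueError(f"{path}: {species} pair {idx}: {e}") from e
            pairs.append(pair)
        karyotypes.append(Karyotype(species=str(species), pairs=tuple(pairs)))
    return karyotypes


def _fmt_num(x: Optional[float], nd: int = 2) -> str:
    if x is None:
        return ""
    if math.isinf(x):
        return "inf"
    return f"{x:.{nd}f}"


def write_karyotype_table(karyotypes: Sequence[Karyotype], path: PathLike,
                          sep: Optional[str] = None) -> None:
    """Write karyotypes in the same delimited schema ``read_karyotype_table``
    reads; telocentric short arms are written as ``-`` and infinite reported
    AR as ``inf``."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    rows = []
    for kt in karyotypes:
        for p in kt.pairs:
            rows.append({
                "species": kt.species,
                "pair": p.pair_index,
                "short_arm": "-" if p.is_telocentric else f"{p.short_arm:.2f}",
                "long_arm": f"{p.long_arm:.2f}",
                "short_se": _fmt_num(p.short_se),
                "long_se": _fmt_num(p.long_se),
                "total_se": _fmt_num(p.total_se),
                "ar_se": _fmt_num(p.ar_se),
                "reported_ar": _fmt_num(p.reported_ar),
                "reported_type": p.reported_type.value if p.reported_type else "",
            })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_dual_matrix(path: PathLike) -> DualMatrix:
    """Read a dual-table text matrix: row labels, lower triangle De, upper
    triangle λ, blank diagonal.  Column header must repeat the row labels."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    col_taxa = [h.strip() for h in header[1:]]
    rows = [ln.split("\t") for ln in lines[1:]]
    row_taxa = [r[0].strip() for r in rows]
    if row_taxa != col_taxa:
        raise ValueError(f"{path}: row labels {row_taxa} != column labels {col_taxa}")
    n = len(row_taxa)
    de = np.zeros((n, n))
    lam = np.eye(n)
    for i, r in enumerate(rows):
        cells = r[1:]
        for j in range(n):
            cell = cells[j].strip() if j < len(cells) else ""
            if i == j:
                if cell:
                    raise ValueError(f"{path}: diagonal cell ({i},{j}) must be blank")
                continue
            if not cell:
                raise ValueError(f"{path}: missing value at ({row_taxa[i]}, {col_taxa[j]})")
            v = float(cell)
            if j > i:   # upper triangle: lambda
                lam[i, j] = lam[j, i] = v
            else:       # lower triangle: De
                de[i, j] = de[j, i] = v
    # full-precision sidecar overrides the rounded display values
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        de = np.asarray(data["de"], dtype=float)
        lam = np.asarray(data["lam"], dtype=float)
    return DualMatrix(taxa=tuple(row_taxa), de=de, lam=lam)


def write_dual_matrix(matrix: DualMatrix, path: PathLike, decimals: int = 4,
                      sidecar: bool = False) -> None:
    """Write the dual-table layout (lower De / upper λ, 4 decimals by
    default).  With ``sidecar=True`` a full-precision JSON companion is
    written next to the text file so a round trip is lossless."""
    path = Path(path)
    n = matrix.n
    lines = ["\t".join(["species", *matrix.taxa])]
    for i in range(n):
        cells = [matrix.taxa[i]]
        for j in range(n):
            if i == j:
                cells.append("")
            elif j > i:
                cells.append(f"{matrix.lam[i, j]:.{decimals}f}")
            else:
                cells.append(f"{matrix.de[i, j]:.{decimals}f}")
        lines.append("\t".join(cells).rstrip("\t"))
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        payload = {
            "taxa": list(matrix.taxa),
            "de": matrix.de.tolist(),
            "lam": matrix.lam.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(payload, indent=1))


def write_phylip_dist(matrix: Union[DualMatrix, np.ndarray], path: PathLike,
                      shape: str = "square",
                      labels: Optional[Sequence[str]] = None,
                      relaxed: bool = False, decimals: int = 6) -> None:
    """Write a PHYLIP distance matrix (square or lower-triangle).

    In strict mode labels are truncated/padded to the classic 10 characters;
    ``relaxed=True`` keeps long labels, separated by whitespace.  For a
    :class:`DualMatrix` the De triangle is exported.
    """
    if isinstance(matrix, DualMatrix):
        D = matrix.de
        labels = list(matrix.taxa)
    else:
        D = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(D.shape[0])]
    if shape not in ("square", "lower"):
        raise ValueError(f"shape must be 'square' or 'lower': {shape!r}")
    n = D.shape[0]
    lines = [f"{n}"]
    for i in range(n):
        name = labels[i].replace(" ", "_")
        name = name if relaxed else f"{name[:10]:<10}"
        upto = n if shape == "square" else i
        row = " ".join(f"{D[i, j]:.{decimals}f}" for j in range(upto))
        lines.append(f"{name} {row}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_dist(path: PathLike) -> tuple[list[str], np.ndarray]:
    """Read a square or lower-triangle PHYLIP distance matrix (whitespace-
    separated labels)."""
    tokens_by_line = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(tokens_by_line[0][0])
    labels: list[str] = []
    D = np.zeros((n, n))
    for i, toks in enumerate(tokens_by_line[1:1 + n]):
        labels.append(toks[0])
        vals = [float(t) for t in toks[1:]]
        if len(vals) == n:            # square
            D[i, :] = vals
        elif len(vals) == i:          # lower triangle
            D[i, :i] = vals
            D[:i, i] = vals
        else:
            raise ValueError(f"row {labels[-1]}: expected {n} or {i} values, got {len(vals)}")
    return labels, D


def write_meg(matrix: Union[DualMatrix, np.ndarray], path: PathLike,
              title: str = "Karyotype evolutionary distance",
              labels: Optional[Sequence[str]] = None, decimals: int = 4) -> None:
    """Write a MEGA distance-format (.meg) file, lower-left triangle."""
    if isinstance(matrix, DualMatrix):
        D = matrix.de
        labels = list(matrix.taxa)
    else:
        D = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels required for a bare matrix")
    n = D.shape[0]
    if n < 2:
        raise ValueError("MEGA distance export needs at least 2 taxa")
    lines = ["#mega", f"!Title {title};",
             f"!Format DataType=Distance DataFormat=LowerLeft NTaxa={n};", ""]
    for lab in labels:
        lines.append(f"#{lab.replace(' ', '_')}")
    lines.append("")
    for i in range(1, n):
        lines.append(" ".join(f"{D[i, j]:.{decimals}f}" for j in range(i)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference tables


@dataclass(frozen=True)
class Table1Row:
    """One species' published karyotype summary plus its higher-group label."""

    species: str
    group: str
    material: str
    two_n: int
    fn: int
    formula: str
    summary: KaryotypeSummary


def _data_path(name: str) -> Path:
    return Path(str(resources.files("karyodist").joinpath("data", name)))


def load_table1() -> list[Table1Row]:
    """The nine published karyotype summaries (2n, FN, formula, group)."""
    df = pd.read_csv(_data_path("table1.tsv"), sep="\t")
    rows = []
    for _, r in df.iterrows():
        rows.append(Table1Row(
            species=r["species"], group=r["group"], material=r["material"],
            two_n=int(r["two_n"]), fn=int(r["fn"]), formula=r["formula"],
            summary=summary_from_formula(r["species"], r["formula"]),
        ))
    return rows


def load_table2() -> list[Karyotype]:
    """The three measured octopod karyotypes (30 pairs each, means ± SE)."""
    return read_karyotype_table(_data_path("table2.csv"))


def load_table3() -> DualMatrix:
    """The published 9-taxon dual matrix (lower De / upper λ)."""
    return read_dual_matrix(_data_path("table3.tsv"))


@dataclass(frozen=True)
class FixtureSet:
    """All packaged reference data in one object."""

    table1: tuple[Table1Row, ...]
    table2: tuple[Karyotype, ...]
    table3: DualMatrix


def load_fixtures() -> FixtureSet:
    return FixtureSet(
        table1=tuple(load_table1()),
        table2=tuple(load_table2()),
        table3=load_table3(),
    )
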