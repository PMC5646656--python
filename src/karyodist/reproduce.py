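"""Recompute the reference study's published values from the packaged tables.

Every quantity is computed from scratch by the pipeline: per-pair
classification of the measured table, formula/FN summaries, pooled class
proportions over the nine published formulas, dual-matrix statistics, the
De = −ln λ consistency audit, and the UPGMA tree over the published De
matrix.  The expected values are the ones printed in the source study.
"""

from __future__ import annotations

import numpy as np

from .core import ChromosomeClass, summarize_karyotype, type_proportions
from .clustering import branch_length, upgma
from .io_formats import load_fixtures
from .resemblance import duality_audit, matrix_stats

__all__ = ["reference_report"]


def reference_report() -> dict:
    """Run the full fixture-based reproduction and return a check report."""
    fx = load_fixtures()
    checks: dict[str, dict] = {}

    def check(name: str, computed, expected) -> None:
        checks[name] = {"computed": computed, "expected": expected,
                        "pass": computed == expected}

    # karyotype summaries from the measured table
    summaries = {k.species: summarize_karyotype(k) for k in fx.table2}
    published = {row.species: row for row in fx.table1}
    for species, s in summaries.items():
        check(f"formula {species}", s.formula, published[species].formula)
        check(f"fn {species}", s.fn, published[species].fn)
        check(f"2n {species}", s.two_n, published[species].two_n)

    # FN rule against all nine published formulas
    for row in fx.table1:
        check(f"fn from formula {row.species}", row.summary.fn, row.fn)

    # class proportions over the nine published formulas
    props = type_proportions([row.summary for row in fx.table1])
    check("pooled M %", round(props["pooled"][ChromosomeClass.M], 1), 56.9)
    check("S. lycidas M %", round(props["S. lycidas"][ChromosomeClass.M], 1), 71.7)
    check("O. vulgaris T %", round(props["O. vulgaris"][ChromosomeClass.T], 1), 60.0)
    decapods = [row.summary for row in fx.table1 if row.group == "Decapodiformes"]
    dprops = type_proportions(decapods)["pooled"]
    check("Decapodiformes M+SM %",
          round(dprops[ChromosomeClass.M] + dprops[ChromosomeClass.SM], 1), 77.8)
    octopods = [row.summary for row in fx.table1 if row.group == "Octopodiformes"]
    oprops = type_proportions(octopods)["pooled"]
    check("Octopodiformes M+SM %",
          round(oprops[ChromosomeClass.M] + oprops[ChromosomeClass.SM], 1), 65.0)

    # dual-matrix statistics
    stats = matrix_stats(fx.table3)
    check("De min", round(stats["de"]["min"], 4), 0.2013)
    check("De max", round(stats["de"]["max"], 4), 1.3323)
    check("De argmin", sorted(stats["de"]["argmin"]), ["C. chinensis", "O. minor"])
    check("De argmax", sorted(stats["de"]["argmax"]), ["A. fangsiao", "H. bleekeri"])
    check("lambda max", round(stats["lam"]["max"], 4), 0.8184)
    check("lambda min", round(stats["lam"]["min"], 4), 0.2640)

    # De <-> lambda duality audit: three printed pairs are inconsistent
    flagged = sorted((a, b) for a, b, _, bad in duality_audit(fx.table3) if bad)
    check("duality flagged pairs", len(flagged), 3)

    # UPGMA tree on the published De matrix
    dendro = upgma(fx.table3.de, list(fx.table3.taxa))
    om_cc = dendro.find_clade(["O. minor", "C. chinensis"])
    om_cc_af = dendro.find_clade(["O. minor", "C. chinensis", "A. fangsiao"])
    octopoda = dendro.find_clade(
        ["O. minor", "C. chinensis", "A. fangsiao", "O. vulgaris"])
    check("branch above (Om,Cc)", round(branch_length(dendro, om_cc), 4), 0.0249)
    check("branch above (Om,Cc,Af)", round(branch_length(dendro, om_cc_af), 4), 0.1612)
    check("branch octopod clade to root",
          round(branch_length(dendro, octopoda), 4), 0.1418)
    decapoda = dendro.find_clade(
        ["S. lycidas", "S. esculenta", "S. lessoniana", "P. edulis", "H. bleekeri"])
    root_a, root_b = dendro.children(dendro.root)
    check("two maximal clades are the orders",
          sorted([octopoda, decapoda]), sorted([root_a, root_b]))

    return {"checks": checks, "all_pass": all(c["pass"] for c in checks.values())}
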