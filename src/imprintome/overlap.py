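"""Exact contingency-table enrichment and cross-species imprinted-gene overlap.

Two gene sets drawn from a common universe are summarised as a 2x2 table
(a = both, b = A only, c = B only, d = neither).  Enrichment is reported
as the sample cross-product odds ratio a*d / (b*c) with an exact
hypergeometric p-value: two-sided by summation of point masses no larger
than the observed one (the usual exact-test convention), or one-sided
upper tail.  Cross-species comparisons count, in the focal species' gene
namespace, genes with at least one ortholog imprinted in the other
species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # |A & B|
    b: int  # |A - B|
    c: int  # |B - A|
    d: int  # |U - (A | B)|

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OverlapResult:
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    alternative: str  # "two-sided" | "greater"


def contingency_from_sets(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> ContingencyTable:
    """2x2 table of two gene sets against their universe."""
    A, B, U = set(set_a), set(set_b), set(universe)
    stray = (A | B) - U
    if stray:
        shown = sorted(map(str, stray))[:10]
        raise ContractError(
            f"{len(stray)} set element(s) outside the universe, e.g. {shown}"
        )
    a = len(A & B)
    return ContingencyTable(a=a, b=len(A) - a, c=len(B) - a, d=len(U - (A | B)))


def sample_odds_ratio(t: ContingencyTable) -> float:
    """Cross-product ratio a*d/(b*c); inf or 0 on degenerate cells."""
    num, den = t.a * t.d, t.b * t.c
    if den == 0:
        if num == 0:
            return float("nan")
        return float("inf")
    return num / den


def exact_overlap_test(
    table: ContingencyTable,
    alternative: str = "two-sided",
    conditional_mle_or: bool = False,
) -> OverlapResult:
    """Exact enrichment test of a 2x2 table.

    ``alternative="greater"`` gives the upper-tail hypergeometric p (the
    classic over-representation test); the default two-sided p sums all
    hypergeometric point masses not exceeding the observed one.  The odds
    ratio reported is the sample cross-product ratio unless
    ``conditional_mle_or`` requests the conditional MLE.
    """
    if alternative not in ("two-sided", "greater"):
        raise ContractError(f"unknown alternative {alternative!r}")
    t = table
    arr = [[t.a, t.b], [t.c, t.d]]
    if t.n == 0 or (t.a + t.b) == 0 or (t.a + t.c) == 0 or (t.b + t.d) == 0 or (t.c + t.d) == 0:
        p = 1.0  # degenerate margin: only one table is possible
    elif alternative == "greater":
        p = float(stats.hypergeom.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c))
    else:
        p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    p = min(max(p, 0.0), 1.0) or float(np.nextafter(0, 1))  # exact tests give p>0
    if conditional_mle_or:
        odds = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    else:
        odds = sample_odds_ratio(t)
    return OverlapResult(table=t, odds_ratio=odds, p_value=p, alternative=alternative)


def pairwise_species_overlap(
    imprint_lists_by_species: Mapping[str, Iterable[str]],
    ortholog_maps: Mapping[Tuple[str, str], Iterable[Tuple[str, str]]],
) -> dict:
    """Shared-imprinted-gene counts between species connected by ortholog maps.

    For a (focal, other) pair, a focal gene counts as shared when at least
    one of its orthologs in the other species is imprinted there; each
    focal gene counts once per pair regardless of ortholog multiplicity.
    Pairs without an ortholog map are not assessable (NaN), never zero.

    Returns a dict with:
      ``matrix`` — DataFrame, rows = focal species, columns = other species;
      ``shared_with_any`` — per focal species, genes shared with >= 1 species;
      ``mean_pairwise_overlap`` — mean count over assessable ordered pairs.
    """
    species = sorted(imprint_lists_by_species)
    lists = {s: set(v) for s, v in imprint_lists_by_species.items()}

    # normalise map keys so (s1, s2) also serves (s2, s1)
    maps: dict[Tuple[str, str], set[Tuple[str, str]]] = {}
    for (s1, s2), pairs in ortholog_maps.items():
        pairs = set(tuple(p) for p in pairs)
        maps.setdefault((s1, s2), set()).update(pairs)
        maps.setdefault((s2, s1), set()).update((g2, g1) for g1, g2 in pairs)

    matrix = pd.DataFrame(np.nan, index=species, columns=species)
    shared_genes: dict[str, set[str]] = {s: set() for s in species}
    pair_counts = []
    for focal in species:
        for other in species:
            if focal == other:
                continue
            pairs = maps.get((focal, other))
            if pairs is None:
                continue
            shared = {
                g_focal
                for g_focal, g_other in pairs
                if g_focal in lists[focal] and g_other in lists[other]
            }
            matrix.loc[focal, other] = len(shared)
            shared_genes[focal] |= shared
            pair_counts.append(len(shared))
    return {
        "matrix": matrix,
        "shared_with_any": {s: len(g) for s, g in shared_genes.items()},
        "mean_pairwise_overlap": float(np.mean(pair_counts)) if pair_counts else float("nan"),
    }


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene identifiers; blank lines and # comments skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def read_ortholog_map(path) -> list[Tuple[str, str]]:
    """Two-column TSV of (gene_id_species1, gene_id_species2); duplicates dropped."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str).iloc[:, :2]
    df.columns = ["gene1", "gene2"]
    return list(df.drop_duplicates().itertuples(index=False, name=None))
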