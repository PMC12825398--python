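"""Site-level discriminant-allele counts -> per-gene maternal proportions.

The maternal proportion of a gene, theta = M / (M + P), is estimated per
cross direction from reads overlapping informative SNPs.  At a reciprocal
homozygous site every read is directly assignable to a parent.  At a site
where one parent is heterozygous, the tissue is pooled across many seeds:
the heterozygous parent transmits its private allele to half the seeds, so
that allele's expected pooled read frequency is (that parent's expression
share) / 2.  Doubling the private-allele count therefore recovers the
parent's read share; the doubled count is capped at the site total, with a
flag, when sampling noise pushes it past 100%.

Transformed maternal/paternal read equivalents are summed over a gene's
sites before dividing, which weights sites by depth and keeps the gene
totals on the count scale required by the downstream goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .counts import CrossDesign
from .errors import ContractError
from .sites import Genotype, SiteCategory, SiteRecord


@dataclass(frozen=True)
class SiteASE:
    """Maternal/paternal read equivalents for one site in one direction."""

    chrom: str
    pos: int
    direction_id: str
    category: SiteCategory
    m_hat: float
    p_hat: float
    truncated: bool

    @property
    def total(self) -> float:
        return self.m_hat + self.p_hat


@dataclass(frozen=True)
class GeneASE:
    """Aggregated allele-specific expression of one gene in one direction."""

    gene_id: str
    direction_id: str
    M: float
    P: float
    n_sites: int
    status: str  # "ok" | "insufficient"

    @property
    def n_reads(self) -> float:
        return self.M + self.P

    @property
    def theta(self) -> Optional[float]:
        if self.status != "ok":
            return None
        return self.M / (self.M + self.P)


def maternal_allele_index(
    category: SiteCategory, mother_gt: Genotype, father_gt: Genotype
) -> int:
    """Index (0=ref, 1=alt) of the allele whose count is transformed.

    RECIPROCAL_HOM -> the mother's homozygous allele; MOTHER_HET -> the
    mother's private allele; FATHER_HET -> the father's private allele
    (whose doubled count estimates the *paternal* share).
    """
    if mother_gt is None or father_gt is None:
        raise ContractError("both genotypes required")
    if category is SiteCategory.RECIPROCAL_HOM:
        return mother_gt[0]
    if category is SiteCategory.MOTHER_HET:
        return 1 - father_gt[0]  # father homozygous; mother's other allele
    if category is SiteCategory.FATHER_HET:
        return 1 - mother_gt[0]  # mother homozygous; father's other allele
    raise ContractError("uninformative sites carry no discriminant allele")


def site_parental_counts(
    count_ref: int,
    count_alt: int,
    category: SiteCategory,
    mother_gt: Genotype,
    father_gt: Genotype,
    *,
    chrom: str = "",
    pos: int = 0,
    direction_id: str = "",
) -> SiteASE:
    """Transform a site's ref/alt counts into maternal/paternal read
    equivalents under the pooled-transmission model."""
    if category is SiteCategory.UNINFORMATIVE:
        raise ContractError(f"uninformative site {chrom}:{pos} cannot be transformed")
    total = count_ref + count_alt
    if total <= 0:
        raise ContractError(f"site {chrom}:{pos} has zero reads")

    idx = maternal_allele_index(category, mother_gt, father_gt)
    disc = count_alt if idx == 1 else count_ref

    truncated = False
    if category is SiteCategory.RECIPROCAL_HOM:
        m_hat, p_hat = float(disc), float(total - disc)
    elif category is SiteCategory.MOTHER_HET:
        m_hat = float(min(2 * disc, total))
        truncated = 2 * disc > total
        p_hat = total - m_hat
    else:  # FATHER_HET
        p_hat = float(min(2 * disc, total))
        truncated = 2 * disc > total
        m_hat = total - p_hat
    return SiteASE(chrom, pos, direction_id, category, m_hat, p_hat, truncated)


def gene_maternal_proportion(
    site_ases: Sequence[SiteASE], min_reads: int = 10, *, gene_id: str = ""
) -> GeneASE:
    """Sum transformed counts over a gene's informative sites.

    Genes whose pooled read equivalents fall below ``min_reads`` are
    reported with status "insufficient" and carry no theta estimate.
    """
    if not site_ases:
        raise ContractError(f"gene {gene_id}: no informative sites")
    direction = site_ases[0].direction_id
    if any(s.direction_id != direction for s in site_ases):
        raise ContractError(f"gene {gene_id}: mixed directions in one aggregate")
    M = sum(s.m_hat for s in site_ases)
    P = sum(s.p_hat for s in site_ases)
    status = "ok" if M + P >= min_reads else "insufficient"
    return GeneASE(gene_id, direction, M, P, len(site_ases), status)


def build_gene_ase_table(
    sites: Sequence[SiteRecord],
    merged_counts: pd.DataFrame,
    designs: Sequence[CrossDesign],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-gene, per-direction ASE table from filtered, gene-assigned sites.

    Uses sites that pass filters, have a gene, and are informative in the
    direction at hand; sites with zero merged reads in a direction are
    skipped for that direction (no information).  Columns: gene_id,
    direction_id, M, P, theta, n_sites, n_reads, status.
    """
    usable = {
        s.key: s for s in sites if s.pass_filters and s.gene_id and s.both_called
    }
    per_gene: dict[tuple[str, str], list[SiteASE]] = {}
    by_dir = dict(tuple(merged_counts.groupby("direction_id")))
    for design in designs:
        sub = by_dir.get(design.direction_id)
        if sub is None:
            continue
        mother = design.mother_plant_id
        for chrom, pos, cref, calt in zip(
            sub["chrom"], sub["pos"], sub["count_ref"], sub["count_alt"]
        ):
            site = usable.get((chrom, pos))
            if site is None or cref + calt == 0:
                continue
            category = site.category_by_direction[mother]
            if category is SiteCategory.UNINFORMATIVE:
                continue
            mgt, fgt = _role_genotypes(site, design)
            sase = site_parental_counts(
                int(cref), int(calt), category, mgt, fgt,
                chrom=chrom, pos=int(pos), direction_id=design.direction_id,
            )
            per_gene.setdefault((site.gene_id, design.direction_id), []).append(sase)

    rows = []
    for (gene_id, direction_id), ases in sorted(per_gene.items()):
        g = gene_maternal_proportion(ases, min_reads, gene_id=gene_id)
        rows.append(
            {
                "gene_id": gene_id,
                "direction_id": direction_id,
                "M": g.M,
                "P": g.P,
                "theta": g.theta if g.theta is not None else float("nan"),
                "n_sites": g.n_sites,
                "n_reads": g.n_reads,
                "status": g.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "direction_id", "M", "P", "theta",
                 "n_sites", "n_reads", "status"],
    )


def _role_genotypes(site: SiteRecord, design: CrossDesign) -> tuple[Genotype, Genotype]:
    """(mother_gt, father_gt) for the direction, given that
    category_by_direction keys are (plant1_id, plant2_id) in order."""
    keys = list(site.category_by_direction)
    plant1_id = keys[0]
    if design.mother_plant_id == plant1_id:
        return site.gt_plant1, site.gt_plant2
    return site.gt_plant2, site.gt_plant1


def dataset_mean_maternal_proportion(
    gene_ase: pd.DataFrame,
    maternal_plant_id: str,
    designs: Sequence[CrossDesign],
) -> float:
    """Unweighted mean of per-gene theta over the direction(s) in which the
    given plant is the mother."""
    directions = {
        d.direction_id for d in designs if d.mother_plant_id == maternal_plant_id
    }
    sub = gene_ase[
        (gene_ase["direction_id"].isin(directions)) & (gene_ase["status"] == "ok")
    ]
    if sub.empty:
        raise ContractError(
            f"no genes with a reported theta for maternal plant {maternal_plant_id}"
        )
    return float(sub["theta"].mean())
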