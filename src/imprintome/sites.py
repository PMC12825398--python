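"""Parental genotype ingestion, filtering, informative-site classification,
and SNP-to-gene assignment.

A reciprocal cross between two polymorphic diploid plants makes a SNP
informative for parent-of-origin read assignment in two ways:

* both parents homozygous for different alleles (``RECIPROCAL_HOM``) —
  every read is assignable;
* exactly one parent heterozygous (``MOTHER_HET`` / ``FATHER_HET``) —
  the allele private to the heterozygous parent tags that parent's reads,
  at half the parent's transmission frequency in pooled seeds.

Sites where both parents are homozygous for the same allele, or both
heterozygous, carry no discriminant allele (``UNINFORMATIVE``).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, ContractError, ParseError

logger = logging.getLogger(__name__)

#: Unordered diploid genotype over {0 (ref), 1 (alt)}; None when uncalled.
Genotype = Optional[Tuple[int, int]]


class SiteCategory(str, Enum):
    """Informative-site category for one cross direction."""

    RECIPROCAL_HOM = "RECIPROCAL_HOM"
    MOTHER_HET = "MOTHER_HET"
    FATHER_HET = "FATHER_HET"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class FilterConfig:
    """Site-level quality filters applied to parental genotype calls.

    ``min_minor_allele_count`` counts the rarer allele across the four
    parental allele copies; at the default of 2 only sites where both
    alleles are seen twice (reciprocal homozygous or double heterozygous)
    survive.  Set it to 1 to admit sites heterozygous in a single parent,
    e.g. when genotypes come from a trusted source rather than noisy calls.
    """

    min_qual: float = 20.0
    min_depth: int = 5
    min_minor_allele_count: int = 2
    require_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0 or self.min_minor_allele_count < 0:
            raise ConfigurationError("filter thresholds must be non-negative")


@dataclass
class SiteRecord:
    """One biallelic SNP with both parental genotypes.

    ``category_by_direction`` maps the *mother plant id* of a cross
    direction to the site's category in that direction; it is populated
    only when both genotypes are called.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float
    depth: int
    gt_plant1: Genotype
    gt_plant2: Genotype
    gene_id: Optional[str] = None
    pass_filters: bool = False
    category_by_direction: dict = field(default_factory=dict)

    @property
    def key(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def both_called(self) -> bool:
        return self.gt_plant1 is not None and self.gt_plant2 is not None


def _normalize_gt(gt) -> Genotype:
    if gt is None:
        return None
    alleles = tuple(gt)
    if len(alleles) != 2 or any(a is None for a in alleles):
        return None
    return tuple(sorted(int(a) for a in alleles))  # type: ignore[return-value]


def classify_site(mother_gt: Genotype, father_gt: Genotype) -> SiteCategory:
    """Classify a biallelic SNP by which parent carries a discriminant allele.

    The classification is direction-specific: swapping the arguments maps
    MOTHER_HET <-> FATHER_HET and leaves the other categories fixed.
    """
    if mother_gt is None or father_gt is None:
        raise ContractError("classify_site requires both genotypes called")
    m_het = mother_gt[0] != mother_gt[1]
    f_het = father_gt[0] != father_gt[1]
    if m_het and f_het:
        return SiteCategory.UNINFORMATIVE
    if m_het:
        return SiteCategory.MOTHER_HET
    if f_het:
        return SiteCategory.FATHER_HET
    if mother_gt[0] != father_gt[0]:
        return SiteCategory.RECIPROCAL_HOM
    return SiteCategory.UNINFORMATIVE


def site_passes_filters(record: SiteRecord, cfg: FilterConfig) -> bool:
    """True iff the site clears quality, depth, biallelism, genotype
    completeness, and the minor-allele-count floor over the four parental
    allele copies."""
    if not record.both_called:
        return False
    if record.qual is None or record.qual < cfg.min_qual:
        return False
    if record.depth < cfg.min_depth:
        return False
    if cfg.require_biallelic and (
        len(record.ref_allele) != 1
        or len(record.alt_allele) != 1
        or record.ref_allele == record.alt_allele
    ):
        return False
    copies = Counter(record.gt_plant1 + record.gt_plant2)
    minor = min(copies.get(0, 0), copies.get(1, 0))
    return minor >= cfg.min_minor_allele_count


def _categorize(record: SiteRecord, plant1_id: str, plant2_id: str) -> None:
    """Fill category_by_direction keyed by the mother plant of each direction."""
    if not record.both_called:
        return
    record.category_by_direction = {
        plant1_id: classify_site(record.gt_plant1, record.gt_plant2),
        plant2_id: classify_site(record.gt_plant2, record.gt_plant1),
    }


def parse_parental_genotypes(
    vcf_path: str | Path,
    plant1_id: str,
    plant2_id: str,
    filter_config: FilterConfig | None = None,
) -> list[SiteRecord]:
    """Read a two-sample VCF into SiteRecords.

    Multiallelic rows and non-SNP variants are excluded.  Rows with a
    missing genotype in either plant are kept with ``pass_filters=False``
    so attrition can be accounted for; a summary of exclusions is logged.
    """
    import pysam

    cfg = filter_config or FilterConfig()
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read variant file {vcf_path}: {exc}") from exc

    samples = list(vcf.header.samples)
    for plant in (plant1_id, plant2_id):
        if plant not in samples:
            raise ConfigurationError(
                f"sample {plant!r} absent from {vcf_path} (has {samples})"
            )

    records: list[SiteRecord] = []
    n_multiallelic = n_not_snp = n_missing_gt = 0
    for rec in vcf:
        try:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multiallelic += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or set(ref + alt) - set("ACGTacgt"):
                n_not_snp += 1
                continue
            depth = rec.info.get("DP")
            if depth is None:
                depth = sum(
                    rec.samples[s].get("DP") or 0 for s in (plant1_id, plant2_id)
                )
            gt1 = _normalize_gt(rec.samples[plant1_id].get("GT"))
            gt2 = _normalize_gt(rec.samples[plant2_id].get("GT"))
        except (KeyError, ValueError, TypeError) as exc:
            raise ParseError(
                f"malformed record at {rec.chrom}:{rec.pos}: {exc}"
            ) from exc
        site = SiteRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=ref,
            alt_allele=alt,
            qual=rec.qual if rec.qual is not None else 0.0,
            depth=int(depth),
            gt_plant1=gt1,
            gt_plant2=gt2,
        )
        if not site.both_called:
            n_missing_gt += 1
        else:
            _categorize(site, plant1_id, plant2_id)
        site.pass_filters = site_passes_filters(site, cfg)
        records.append(site)
    logger.info(
        "parsed %d SNP sites (%d multiallelic rows excluded, %d non-SNP rows "
        "excluded, %d with missing genotype kept unfiltered)",
        len(records), n_multiallelic, n_not_snp, n_missing_gt,
    )
    return records


# ---------------------------------------------------------------------------
# Gene annotation and site-to-gene assignment
# ---------------------------------------------------------------------------

class GeneAnnotation:
    """Gene intervals per sequence, held as interval trees.

    Coordinates are stored 1-based inclusive, the variant-file convention.
    """

    def __init__(self, genes: Iterable[Tuple[str, str, int, int]]):
        """genes: iterable of (gene_id, chrom, start_1based, end_inclusive)."""
        self._trees: dict[str, IntervalTree] = {}
        self.n_genes = 0
        for gene_id, chrom, start, end in genes:
            if end < start:
                raise ConfigurationError(
                    f"gene {gene_id}: end {end} < start {start}"
                )
            self._trees.setdefault(chrom, IntervalTree())[start : end + 1] = gene_id
            self.n_genes += 1

    @classmethod
    def from_gff3(cls, path: str | Path, feature_type: str = "gene") -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        return cls(
            (feat.id, feat.seqid, feat.start, feat.end)
            for feat in db.features_of_type(feature_type)
        )

    @classmethod
    def from_table(cls, path: str | Path, zero_based_half_open: bool = False) -> "GeneAnnotation":
        """4-column gene table (chrom, start, end, gene_id).

        ``zero_based_half_open=True`` declares BED convention; otherwise the
        table is read as 1-based inclusive.
        """
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "start": int, "end": int, "gene_id": str},
        )
        if zero_based_half_open:
            df["start"] = df["start"] + 1  # end already inclusive under BED
        return cls(df[["gene_id", "chrom", "start", "end"]].itertuples(index=False))

    def sequences(self) -> set[str]:
        return set(self._trees)

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos])


@dataclass
class AssignmentStats:
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_intergenic: int = 0


def assign_sites_to_genes(
    sites: Sequence[SiteRecord], annotation: GeneAnnotation
) -> AssignmentStats:
    """Set ``gene_id`` on every site falling inside exactly one gene.

    Sites overlapping two or more genes are left unassigned (counted as
    ambiguous) to avoid double-counting their reads in two genes' maternal
    proportions; intergenic sites stay unassigned.
    """
    site_chroms = {s.chrom for s in sites}
    if sites and not (site_chroms & annotation.sequences()):
        warnings.warn(
            "annotation sequence names share nothing with variant sequence "
            f"names ({sorted(site_chroms)[:5]} vs "
            f"{sorted(annotation.sequences())[:5]}); zero assignments",
            stacklevel=2,
        )
    stats = AssignmentStats()
    for site in sites:
        hits = annotation.genes_at(site.chrom, site.pos)
        if len(hits) == 1:
            site.gene_id = hits[0]
            stats.n_assigned += 1
        elif len(hits) > 1:
            site.gene_id = None
            stats.n_ambiguous += 1
        else:
            site.gene_id = None
            stats.n_intergenic += 1
    return stats


def sites_to_frame(
    sites: Sequence[SiteRecord], plant1_id: str, plant2_id: str
) -> pd.DataFrame:
    """Tabular view of the site list (one row per SNP)."""

    def fmt_gt(gt: Genotype) -> str:
        return "./." if gt is None else f"{gt[0]}/{gt[1]}"

    rows = []
    for s in sites:
        cats = s.category_by_direction
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref_allele,
                "alt": s.alt_allele,
                "qual": s.qual,
                "depth": s.depth,
                "gt1": fmt_gt(s.gt_plant1),
                "gt2": fmt_gt(s.gt_plant2),
                "pass": s.pass_filters,
                "category_dir1": getattr(cats.get(plant1_id), "value", ""),
                "category_dir2": getattr(cats.get(plant2_id), "value", ""),
                "gene_id": s.gene_id or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "depth", "gt1", "gt2",
                 "pass", "category_dir1", "category_dir2", "gene_id"],
    )
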