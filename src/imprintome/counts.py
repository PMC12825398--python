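"""Per-library allelic read counts at informative sites and replicate merging.

Counts arrive either as a plain table (chrom, pos, library_id, count_ref,
count_alt) or as a VCF whose samples are RNA-seq libraries carrying AD
(allele-depth) fields.  Replicate libraries of one cross direction are
pooled by summation — the tabular analogue of merging replicate alignments
before variant calling — while the per-replicate table is kept for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, ContractError, ParseError
from .sites import SiteRecord

COUNT_COLUMNS = ["chrom", "pos", "library_id", "count_ref", "count_alt"]


@dataclass(frozen=True)
class CrossDesign:
    """One direction of a reciprocal cross and its replicate libraries."""

    direction_id: str
    mother_plant_id: str
    father_plant_id: str
    replicate_library_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mother_plant_id == self.father_plant_id:
            raise ConfigurationError(
                f"direction {self.direction_id}: mother and father are the same plant"
            )
        if len(self.replicate_library_ids) < 1:
            raise ContractError(
                f"direction {self.direction_id}: needs at least one replicate library"
            )


def read_design(path: str | Path) -> list[CrossDesign]:
    """Design TSV: direction_id, mother_plant, father_plant, library_id
    (one row per library)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["direction_id", "mother_plant", "father_plant", "library_id"],
        header=0, dtype=str,
    )
    designs = []
    for (direction, mother, father), grp in df.groupby(
        ["direction_id", "mother_plant", "father_plant"], sort=True
    ):
        designs.append(
            CrossDesign(direction, mother, father, tuple(sorted(grp["library_id"])))
        )
    return designs


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-library allelic count TSV and validate its invariants."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "library_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"count table {path} lacks columns {sorted(missing)}")
    if (df[["count_ref", "count_alt"]] < 0).any().any():
        raise ParseError(f"count table {path} contains negative counts")
    return df[COUNT_COLUMNS].copy()


def extract_allele_depths(
    source: str | Path | pd.DataFrame,
    sites: Sequence[SiteRecord],
    libraries: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-(site, library) ref/alt read counts at the given sites.

    ``source`` is a count table (path or frame) or a VCF whose samples are
    libraries with AD fields.  Sites absent from the source are emitted
    with zero counts for every library so downstream accounting stays
    closed.  A source whose alleles at a site disagree with the SiteRecord
    is an error naming the site.
    """
    if isinstance(source, pd.DataFrame):
        raw = source[COUNT_COLUMNS].copy()
    else:
        path = Path(source)
        if path.suffix in {".vcf", ".bcf", ".gz"}:
            raw = _allele_depths_from_vcf(path, sites)
        else:
            raw = read_count_table(path)

    if libraries is None:
        libraries = sorted(raw["library_id"].unique())
    libraries = list(libraries)

    site_keys = pd.DataFrame(
        [(s.chrom, s.pos) for s in sites], columns=["chrom", "pos"]
    )
    full = site_keys.merge(pd.DataFrame({"library_id": libraries}), how="cross")
    out = full.merge(raw, on=["chrom", "pos", "library_id"], how="left")
    out[["count_ref", "count_alt"]] = (
        out[["count_ref", "count_alt"]].fillna(0).astype(int)
    )
    out["total"] = out["count_ref"] + out["count_alt"]
    return out


def _allele_depths_from_vcf(path: Path, sites: Sequence[SiteRecord]) -> pd.DataFrame:
    import pysam

    wanted = {(s.chrom, s.pos): (s.ref_allele, s.alt_allele) for s in sites}
    vcf = pysam.VariantFile(str(path))
    rows = []
    for rec in vcf:
        key = (rec.chrom, rec.pos)
        if key not in wanted:
            continue
        ref, alt = wanted[key]
        alts = rec.alts or ()
        if rec.ref != ref or len(alts) != 1 or alts[0] != alt:
            raise ParseError(
                f"allele order mismatch at {rec.chrom}:{rec.pos}: "
                f"expected {ref}>{alt}, file has {rec.ref}>{','.join(alts)}"
            )
        for library in rec.samples:
            ad = rec.samples[library].get("AD")
            if ad is None:
                continue
            ad = tuple(0 if x is None else int(x) for x in ad)
            if len(ad) != 2:
                raise ParseError(
                    f"AD field with {len(ad)} values at biallelic site "
                    f"{rec.chrom}:{rec.pos} (library {library})"
                )
            rows.append((rec.chrom, rec.pos, library, ad[0], ad[1]))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def merge_replicate_counts(
    counts: pd.DataFrame, designs: Sequence[CrossDesign]
) -> pd.DataFrame:
    """Sum allelic counts across each direction's replicate libraries.

    Returns one row per (direction_id, chrom, pos).  Every library in the
    count table must belong to exactly one design direction.
    """
    lib_to_dir: dict[str, str] = {}
    for d in designs:
        for lib in d.replicate_library_ids:
            if lib in lib_to_dir:
                raise ConfigurationError(f"library {lib} listed in two directions")
            lib_to_dir[lib] = d.direction_id
    unknown = set(counts["library_id"]) - set(lib_to_dir)
    if unknown:
        raise ConfigurationError(
            f"libraries absent from the cross design: {sorted(unknown)}"
        )
    df = counts.copy()
    df["direction_id"] = df["library_id"].map(lib_to_dir)
    merged = (
        df.groupby(["direction_id", "chrom", "pos"], as_index=False)[
            ["count_ref", "count_alt"]
        ]
        .sum()
        .sort_values(["direction_id", "chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    merged["total"] = merged["count_ref"] + merged["count_alt"]
    return merged
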