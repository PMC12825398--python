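"""Synthetic reciprocal-cross endosperm data with known imprinting truth.

The generator emulates the study design every pipeline stage expects:

* two polymorphic diploid parents ("plant1", "plant2") genotyped at SNPs
  falling inside annotated genes, in the four informative-site
  configurations (reciprocal homozygous, heterozygous in either parent,
  uninformative);
* a reciprocal cross with both role assignments ("1x2" = plant1 mother,
  "2x1" = plant2 mother) and three replicate RNA-seq libraries per
  direction;
* a diploid endosperm: a biparental gene has true maternal proportion
  theta = 0.5; planted MEGs/PEGs carry extreme theta in both directions;
* per-site, per-library sequencing depth from a negative binomial, allelic
  counts from a beta-binomial with intraclass correlation ``rho``
  (``rho=0`` degenerates to binomial);
* optional maternal sporophytic contamination: a fraction ``rho_c`` of
  reads drawn from the maternal parent's own diploid genotype, emulating
  seed-coat/perisperm carry-over into dissected endosperm.

For a site where the mother carries ``ma`` copies of the alt allele and
the father ``fa``, pooled endosperm reads show the alt allele at expected
frequency (1-rho_c) * (theta*ma/2 + (1-theta)*fa/2) + rho_c * ma/2 — in
particular theta/2 for the mother-private allele at a mother-heterozygous
site, which is what the downstream doubling transformation inverts.

All randomness flows from one seeded generator; fixture files embed the
seed in a header comment and are byte-stable given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .counts import CrossDesign
from .errors import ConfigurationError
from .sites import FilterConfig, SiteCategory, SiteRecord, site_passes_filters

GENE_SPACING = 2_000  # bp between gene starts on the synthetic chromosome
GENE_LENGTH = 1_500

PLANT1 = "plant1"
PLANT2 = "plant2"
DIR1 = "1x2"  # plant1 is the mother
DIR2 = "2x1"  # plant2 is the mother


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference scenario used throughout the test
    suite: 1000 genes, 5% planted MEGs at theta 0.95 and 5% PEGs at 0.05
    on a diploid-endosperm null of 0.5, ~5 SNPs per gene, three replicate
    libraries per direction at ~50x per site per library, mild allelic
    overdispersion, no contamination.
    """

    n_genes: int = 1000
    sites_per_gene_mean: float = 5.0
    sites_per_gene_dispersion: float = 10.0  # negative-binomial size
    category_mix: dict = field(
        default_factory=lambda: {
            "RECIPROCAL_HOM": 0.4,
            "MOTHER_HET": 0.2,   # heterozygous in plant1 (the direction-1 mother)
            "FATHER_HET": 0.2,   # heterozygous in plant2
            "UNINFORMATIVE": 0.2,
        }
    )
    frac_meg: float = 0.05
    frac_peg: float = 0.05
    theta_meg: float = 0.95
    theta_peg: float = 0.05
    theta_null: float | None = None  # derived from maternal_dosage_ratio if None
    maternal_dosage_ratio: tuple = (1, 1)  # (maternal, paternal) genome copies
    depth_mean: float = 50.0
    depth_dispersion: float = 10.0  # negative-binomial size
    rho: float = 0.01   # beta-binomial intraclass correlation
    rho_c: float = 0.0  # maternal sporophytic contamination fraction
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_meg + self.frac_peg <= 1:
            raise ConfigurationError("frac_meg + frac_peg must lie in [0, 1]")
        if not all(0 <= v <= 1 for v in self.category_mix.values()):
            raise ConfigurationError("category_mix entries must lie in [0, 1]")
        if abs(sum(self.category_mix.values()) - 1) > 1e-9:
            raise ConfigurationError("category_mix must sum to 1")
        if not (0 <= self.rho < 1 and 0 <= self.rho_c < 1):
            raise ConfigurationError("rho and rho_c must lie in [0, 1)")
        if self.theta_null is None:
            m, p = self.maternal_dosage_ratio
            self.theta_null = m / (m + p)
        if not 0 < self.theta_null < 1:
            raise ConfigurationError("theta_null must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["maternal_dosage_ratio"] = list(d["maternal_dosage_ratio"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "maternal_dosage_ratio" in d:
            d["maternal_dosage_ratio"] = tuple(d["maternal_dosage_ratio"])
        return cls(**d)


def default_designs(cfg: SimConfig) -> list[CrossDesign]:
    """The reciprocal pair of cross directions with their libraries."""
    reps = cfg.n_replicates
    return [
        CrossDesign(DIR1, PLANT1, PLANT2,
                    tuple(f"{DIR1}_rep{i + 1}" for i in range(reps))),
        CrossDesign(DIR2, PLANT2, PLANT1,
                    tuple(f"{DIR2}_rep{i + 1}" for i in range(reps))),
    ]


def simulate_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-gene true maternal proportion and status.

    Exactly round(frac * n_genes) MEGs and PEGs are planted, on a
    rng-shuffled gene order, so the planted counts are deterministic.
    """
    rng = rng or np.random.default_rng(cfg.rng_seed)
    n = cfg.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    order = rng.permutation(n)
    k_meg = round(cfg.frac_meg * n)
    k_peg = round(cfg.frac_peg * n)
    status = np.full(n, "BIPARENTAL", dtype=object)
    theta = np.full(n, cfg.theta_null, dtype=float)
    status[order[:k_meg]] = "MEG"
    theta[order[:k_meg]] = cfg.theta_meg
    status[order[k_meg : k_meg + k_peg]] = "PEG"
    theta[order[k_meg : k_meg + k_peg]] = cfg.theta_peg
    return pd.DataFrame(
        {"gene_id": gene_ids, "true_theta": theta, "true_status": status}
    )


_CATEGORY_ORDER = ["RECIPROCAL_HOM", "MOTHER_HET", "FATHER_HET", "UNINFORMATIVE"]


def simulate_parental_sites(
    cfg: SimConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Genotyped SNPs inside synthetic genes, plus the gene table.

    Returns (sites, gene table with columns gene_id/chrom/start/end).
    Genotypes realise the drawn category; ``MOTHER_HET`` means
    heterozygous in plant1 (the direction-1 mother).  Filter status and
    per-direction categories are filled the same way the parser would.
    """
    n = cfg.n_genes
    size = cfg.sites_per_gene_dispersion
    p_nb = size / (size + cfg.sites_per_gene_mean)
    n_sites = rng.negative_binomial(size, p_nb, n)

    gene_start = 1 + GENE_SPACING * np.arange(n)
    genes = pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "chrom": "chr1",
            "start": gene_start,
            "end": gene_start + GENE_LENGTH - 1,
        }
    )

    probs = [cfg.category_mix[c] for c in _CATEGORY_ORDER]
    bases = np.array(list("ACGT"))
    sites: list[SiteRecord] = []
    fcfg = FilterConfig()
    for g in range(n):
        k = int(n_sites[g])
        if k == 0:
            continue
        offsets = np.sort(rng.choice(GENE_LENGTH, size=min(k, GENE_LENGTH), replace=False))
        cats = rng.choice(len(_CATEGORY_ORDER), size=len(offsets), p=probs)
        for off, ci in zip(offsets, cats):
            cat = _CATEGORY_ORDER[ci]
            flip = bool(rng.integers(2))
            if cat == "RECIPROCAL_HOM":
                gt1, gt2 = ((0, 0), (1, 1)) if flip else ((1, 1), (0, 0))
            elif cat == "MOTHER_HET":
                gt1, gt2 = (0, 1), ((0, 0) if flip else (1, 1))
            elif cat == "FATHER_HET":
                gt1, gt2 = ((0, 0) if flip else (1, 1)), (0, 1)
            else:
                gt1 = gt2 = [(0, 0), (1, 1), (0, 1)][rng.integers(3)]
            ref_i = int(rng.integers(4))
            alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
            site = SiteRecord(
                chrom="chr1",
                pos=int(gene_start[g] + off),
                ref_allele=str(bases[ref_i]),
                alt_allele=str(bases[alt_i]),
                qual=float(rng.integers(30, 100)),
                depth=int(10 + rng.poisson(20)),
                gt_plant1=tuple(gt1),
                gt_plant2=tuple(gt2),
                gene_id=str(truth["gene_id"].iloc[g]),
            )
            site.category_by_direction = {
                PLANT1: SiteCategory(cat),
                PLANT2: SiteCategory(_swap_roles(cat)),
            }
            site.pass_filters = site_passes_filters(site, fcfg)
            sites.append(site)
    return sites, genes


def _swap_roles(cat: str) -> str:
    return {"MOTHER_HET": "FATHER_HET", "FATHER_HET": "MOTHER_HET"}.get(cat, cat)


def expected_alt_frequency(
    theta: float, mother_alt_copies: int, father_alt_copies: int, rho_c: float
) -> float:
    """Expected alt-allele read frequency in pooled endosperm plus
    maternal-sporophyte contamination."""
    endo = theta * mother_alt_copies / 2 + (1 - theta) * father_alt_copies / 2
    return (1 - rho_c) * endo + rho_c * mother_alt_copies / 2


def simulate_count_tables(
    cfg: SimConfig,
    truth: pd.DataFrame,
    sites: Sequence[SiteRecord],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-library allelic count table over all simulated sites.

    Depth per (site, library) ~ NB(depth_mean, depth_dispersion); alt
    count ~ beta-binomial(depth, expected alt frequency, rho).
    """
    theta_by_gene = dict(zip(truth["gene_id"], truth["true_theta"]))
    chroms = np.array([s.chrom for s in sites])
    poss = np.array([s.pos for s in sites])
    theta = np.array([theta_by_gene[s.gene_id] for s in sites])
    alt1 = np.array([sum(s.gt_plant1) for s in sites])  # plant1 alt copies
    alt2 = np.array([sum(s.gt_plant2) for s in sites])

    frames = []
    for direction, mother_alt, father_alt in ((DIR1, alt1, alt2), (DIR2, alt2, alt1)):
        f_alt = (1 - cfg.rho_c) * (
            theta * mother_alt / 2 + (1 - theta) * father_alt / 2
        ) + cfg.rho_c * mother_alt / 2
        for r in range(cfg.n_replicates):
            lib = f"{direction}_rep{r + 1}"
            depth = rng.negative_binomial(
                cfg.depth_dispersion,
                cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean),
                len(sites),
            )
            count_alt = _beta_binomial(depth, f_alt, cfg.rho, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chroms,
                        "pos": poss,
                        "library_id": lib,
                        "count_ref": depth - count_alt,
                        "count_alt": count_alt,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _beta_binomial(
    n: np.ndarray, f: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised beta-binomial draws with intraclass correlation rho."""
    out = np.zeros_like(n)
    interior = (f > 0) & (f < 1)
    if rho == 0:
        out[interior] = rng.binomial(n[interior], f[interior])
    else:
        scale = (1 - rho) / rho
        p = np.empty(interior.sum())
        p = rng.beta(f[interior] * scale, (1 - f[interior]) * scale)
        out[interior] = rng.binomial(n[interior], p)
    out[f >= 1] = n[f >= 1]
    return out


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: truth, sites, gene table, counts, designs."""
    rng = np.random.default_rng(cfg.rng_seed)
    truth = simulate_truth(cfg, rng)
    sites, genes = simulate_parental_sites(cfg, truth, rng)
    counts = simulate_count_tables(cfg, truth, sites, rng)
    return truth, sites, genes, counts, default_designs(cfg)


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def write_fixtures(
    out_dir: str | Path,
    cfg: SimConfig,
    truth: pd.DataFrame,
    sites: Sequence[SiteRecord],
    genes: pd.DataFrame,
    counts: pd.DataFrame,
) -> dict[str, Path]:
    """Write the dataset as plain-text files a real analysis would consume.

    parents.vcf (two samples), genes.gff3, counts.tsv, truth.tsv,
    design.tsv, simconfig.yaml; byte-stable for a given seed, with the
    seed recorded in each file's header.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "parents.vcf",
        "gff3": out / "genes.gff3",
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
        "design": out / "design.tsv",
        "config": out / "simconfig.yaml",
    }
    seed_note = f"simulation seed {cfg.rng_seed}"

    _write_vcf(paths["vcf"], cfg, sites)

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# {seed_note}\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\timprintome-sim\tgene\t{row.start}\t{row.end}"
                f"\t.\t+\t.\tID={row.gene_id}\n"
            )

    for key, df in (("counts", counts), ("truth", truth)):
        with open(paths[key], "w") as fh:
            fh.write(f"# {seed_note}\n")
            df.to_csv(fh, sep="\t", index=False)

    design_rows = [
        (d.direction_id, d.mother_plant_id, d.father_plant_id, lib)
        for d in default_designs(cfg)
        for lib in d.replicate_library_ids
    ]
    with open(paths["design"], "w") as fh:
        fh.write(f"# {seed_note}\n")
        fh.write("direction_id\tmother_plant\tfather_plant\tlibrary_id\n")
        for row in design_rows:
            fh.write("\t".join(row) + "\n")

    cfg.to_yaml(paths["config"])
    return paths


def _write_vcf(path: Path, cfg: SimConfig, sites: Sequence[SiteRecord]) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##imprintome_simulation_seed={cfg.rng_seed}")
    max_pos = max((s.pos for s in sites), default=1)
    header.add_line(f"##contig=<ID=chr1,length={max_pos + GENE_SPACING}>")
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(PLANT1)
    header.add_sample(PLANT2)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            rec = vcf.new_record(
                contig=s.chrom,
                start=s.pos - 1,
                stop=s.pos,
                alleles=(s.ref_allele, s.alt_allele),
                qual=s.qual,
            )
            rec.info["DP"] = s.depth
            rec.samples[PLANT1]["GT"] = s.gt_plant1
            rec.samples[PLANT2]["GT"] = s.gt_plant2
            vcf.write(rec)
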