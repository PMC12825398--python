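"""Imprinting status calls from reciprocal maternal proportions.

In a diploid (1 maternal : 1 paternal) endosperm the null expectation for
a biparentally expressed gene is theta = 0.5; a typical triploid (2m:1p)
endosperm would use 2/3.  Candidate imprinted genes must depart from the
null in BOTH directions of the reciprocal cross — a maternally expressed
gene (MEG) needs theta above the threshold with either plant as mother,
which separates parent-of-origin effects from genotype effects.

Departure from the null is tested per gene with a 1-df chi-squared
goodness-of-fit on maternal/paternal read-equivalent counts pooled across
the two directions, followed by Benjamini-Hochberg FDR adjustment across
genes.  Threshold classes: moderate MEG theta > 0.75, strong MEG > 0.9,
moderate PEG < 0.25, strong PEG < 0.1 (strict inequalities; strong
subsumes moderate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ContractError


class ImprintStatus(str, Enum):
    MEG_STRONG = "MEG_STRONG"
    MEG_MODERATE = "MEG_MODERATE"
    PEG_STRONG = "PEG_STRONG"
    PEG_MODERATE = "PEG_MODERATE"
    BIPARENTAL = "BIPARENTAL"
    UNDETERMINED = "UNDETERMINED"


MEG_STATUSES = (ImprintStatus.MEG_STRONG, ImprintStatus.MEG_MODERATE)
PEG_STATUSES = (ImprintStatus.PEG_STRONG, ImprintStatus.PEG_MODERATE)


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds and significance policy for imprinting calls."""

    meg_moderate: float = 0.75
    meg_strong: float = 0.9
    peg_moderate: float = 0.25
    peg_strong: float = 0.1
    q_cut: float = 0.05
    null_maternal_proportion: float = 0.5  # 2/3 for a 2m:1p triploid endosperm
    require_significance: bool = True

    def __post_init__(self) -> None:
        if not (
            0
            <= self.peg_strong
            < self.peg_moderate
            < self.null_maternal_proportion
            < self.meg_moderate
            < self.meg_strong
            <= 1
        ):
            raise ConfigurationError(
                "thresholds must satisfy 0 <= peg_strong < peg_moderate < null "
                "< meg_moderate < meg_strong <= 1"
            )


@dataclass(frozen=True)
class GeneImprintRecord:
    gene_id: str
    theta_dir1: float
    theta_dir2: float
    M_pooled: float
    P_pooled: float
    chi2: float
    p_value: float
    q_value: float
    status: ImprintStatus


def chi_squared_departure(
    M: float, P: float, null_maternal_proportion: float = 0.5
) -> tuple[float, float]:
    """1-df goodness-of-fit of observed (M, P) against the ploidy null.

    chi2 = (M - n*t0)^2/(n*t0) + (P - n*(1-t0))^2/(n*(1-t0)); p from the
    1-df chi-squared survival function.
    """
    n = M + P
    if n <= 0:
        raise ContractError("chi_squared_departure requires M + P > 0")
    t0 = null_maternal_proportion
    if not 0 < t0 < 1:
        raise ConfigurationError("null maternal proportion must be in (0, 1)")
    em, ep = n * t0, n * (1 - t0)
    chi2 = (M - em) ** 2 / em + (P - ep) ** 2 / ep
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR-adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_gene(
    theta_dir1: Optional[float],
    theta_dir2: Optional[float],
    q_value: Optional[float],
    cfg: CallerConfig,
) -> ImprintStatus:
    """Threshold-based status from the reciprocal theta pair.

    MEG/PEG classes require the threshold to be cleared in BOTH directions
    (strict inequalities); with ``require_significance`` the BH q must also
    be at most ``q_cut``, otherwise the gene is reported biparental.
    """
    if theta_dir1 is None or theta_dir2 is None:
        raise ContractError("call_gene needs theta in both directions")
    t1, t2 = theta_dir1, theta_dir2
    if math.isnan(t1) or math.isnan(t2):
        raise ContractError("call_gene needs theta in both directions")

    if t1 > cfg.meg_strong and t2 > cfg.meg_strong:
        status = ImprintStatus.MEG_STRONG
    elif t1 > cfg.meg_moderate and t2 > cfg.meg_moderate:
        status = ImprintStatus.MEG_MODERATE
    elif t1 < cfg.peg_strong and t2 < cfg.peg_strong:
        status = ImprintStatus.PEG_STRONG
    elif t1 < cfg.peg_moderate and t2 < cfg.peg_moderate:
        status = ImprintStatus.PEG_MODERATE
    else:
        return ImprintStatus.BIPARENTAL

    if cfg.require_significance:
        if q_value is None or math.isnan(q_value) or q_value > cfg.q_cut:
            return ImprintStatus.BIPARENTAL
    return status


def call_imprintome(gene_ase: pd.DataFrame, cfg: CallerConfig | None = None) -> pd.DataFrame:
    """Full imprintome table from the per-gene, per-direction ASE table.

    Genes with an estimable theta in both directions get a pooled 1-df
    chi-squared test and a BH q across all such genes, then a threshold
    call per direction.  Genes estimable in only one direction are
    reported UNDETERMINED and excluded from testing.
    """
    cfg = cfg or CallerConfig()
    directions = sorted(gene_ase["direction_id"].unique())
    if len(directions) != 2:
        raise ContractError(
            f"reciprocal calling needs exactly 2 directions, found {directions}"
        )
    d1, d2 = directions
    ok = gene_ase[gene_ase["status"] == "ok"]
    wide = ok.pivot(index="gene_id", columns="direction_id", values=["theta", "M", "P"])

    rows = []
    testable = []
    for gene_id in wide.index:
        t1 = wide.loc[gene_id, ("theta", d1)] if (("theta", d1) in wide.columns) else np.nan
        t2 = wide.loc[gene_id, ("theta", d2)] if (("theta", d2) in wide.columns) else np.nan
        if np.isnan(t1) or np.isnan(t2):
            rows.append(
                dict(gene_id=gene_id, theta_dir1=t1, theta_dir2=t2,
                     M_pooled=np.nan, P_pooled=np.nan, chi2=np.nan,
                     p=np.nan, q=np.nan, status=ImprintStatus.UNDETERMINED.value)
            )
            continue
        M = float(wide.loc[gene_id, ("M", d1)] + wide.loc[gene_id, ("M", d2)])
        P = float(wide.loc[gene_id, ("P", d1)] + wide.loc[gene_id, ("P", d2)])
        chi2, p = chi_squared_departure(M, P, cfg.null_maternal_proportion)
        testable.append(len(rows))
        rows.append(
            dict(gene_id=gene_id, theta_dir1=float(t1), theta_dir2=float(t2),
                 M_pooled=M, P_pooled=P, chi2=chi2, p=p, q=np.nan, status="")
        )

    df = pd.DataFrame(
        rows,
        columns=["gene_id", "theta_dir1", "theta_dir2", "M_pooled", "P_pooled",
                 "chi2", "p", "q", "status"],
    )
    if testable:
        idx = np.array(testable)
        q = benjamini_hochberg(df.loc[idx, "p"].to_numpy())
        df.loc[idx, "q"] = q
        df.loc[idx, "status"] = [
            call_gene(df.at[i, "theta_dir1"], df.at[i, "theta_dir2"], df.at[i, "q"], cfg).value
            for i in idx
        ]
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def summarize_imprintome(imprintome: pd.DataFrame) -> dict:
    """Class counts plus MEG/PEG totals (strong included in totals)."""
    if imprintome is None or len(imprintome) == 0:
        raise ContractError("summarize_imprintome needs at least one record")
    counts = {s.value: int((imprintome["status"] == s.value).sum()) for s in ImprintStatus}
    meg_total = counts["MEG_STRONG"] + counts["MEG_MODERATE"]
    peg_total = counts["PEG_STRONG"] + counts["PEG_MODERATE"]
    return {
        "counts_by_status": counts,
        "n_meg": meg_total,
        "n_peg": peg_total,
        "n_imprinted": meg_total + peg_total,
        "n_genes": int(len(imprintome)),
        "mean_theta_dir1": float(np.nanmean(imprintome["theta_dir1"]))
        if imprintome["theta_dir1"].notna().any() else float("nan"),
        "mean_theta_dir2": float(np.nanmean(imprintome["theta_dir2"]))
        if imprintome["theta_dir2"].notna().any() else float("nan"),
    }
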