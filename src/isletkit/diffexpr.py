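"""Per-gene knockout-vs-control differential expression.

The count model is beta-binomial: each replicate's count for a gene is
drawn from ``BetaBinomial(n_s, pi, rho_g)`` where ``n_s`` is the sample's
total mapped reads, ``pi`` the gene's transcriptome proportion, and
``rho_g`` a per-gene intra-class correlation capturing between-replicate
(biological) variability beyond sampling noise.  Differential expression is
a likelihood-ratio test of a shared proportion against free per-condition
proportions, referred to chi-square with 1 df; with ``rho = 0`` this is
exactly the two-proportion binomial LRT.

Between-replicate variability is summarized by a single study-level
dispersion: the squared biological coefficient of variation of a gene's
relative abundance across replicates (so ``dispersion = 0.04`` means 20%
replicate-to-replicate variation for every gene).  It maps to the per-gene
beta intra-class correlation as ``rho_g = phi * pi_g / (1 - pi_g)``; a
single shared intra-class correlation would instead imply relative noise
growing without bound as genes get rarer.

Multiplicity is handled with Benjamini-Hochberg; the adjusted value is
reported as the gene's E-value alongside the raw P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._stats import bb_lrt
from .quantify import CountMatrix, fold_change, low_expression_mask, mean_rpkm_by_condition

__all__ = [
    "DispersionEstimate",
    "estimate_dispersion",
    "betabin_test",
    "bh_adjust",
    "de_table",
    "DE_COLUMNS",
]

DE_COLUMNS = [
    "gene",
    "model",
    "fc",
    "log2fc",
    "p",
    "e",
    "mean_rpkm_ko",
    "mean_rpkm_wt",
    "present",
    "tested",
]


@dataclass(frozen=True)
class DispersionEstimate:
    """Study-level overdispersion: squared biological CV of replicate abundance."""

    phi: float
    n_genes_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")


def estimate_dispersion(counts: CountMatrix, min_mean_count: float = 10.0) -> DispersionEstimate:
    """Method-of-moments dispersion from replicate proportion variance.

    For every gene with adequate counts, the excess of the within-condition
    replicate proportion variance over its binomial expectation, relative to
    the squared mean proportion, estimates the squared biological CV.
    Per-gene estimates are pooled with precision weights (a pilot pass
    supplies the weight scale) and truncated to [0, 0.99].

    With a single replicate per condition the dispersion is not identifiable
    and 0 is returned with a warning.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise ValueError("empty count matrix")
    totals = counts.totals.to_numpy(dtype=float)

    rel_list = []  # per-gene relative-excess estimates per condition
    wdf_list = []  # degrees of freedom per condition
    any_replicated = False
    for cond in ("KO", "WT"):
        cols = [counts.counts.columns.get_loc(c) for c in counts.condition_columns(cond)]
        if len(cols) < 2:
            continue
        any_replicated = True
        sub = mat[:, cols]
        n = totals[cols]
        p = sub / n[None, :]
        m = p.mean(axis=1)
        s2 = p.var(axis=1, ddof=1)
        binom = m * (1.0 - m) * np.mean(1.0 / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(m > 0, (s2 - binom) / np.maximum(m, 1e-300) ** 2, np.nan)
        rel_list.append(rel)
        wdf_list.append(len(cols) - 1)

    if not any_replicated:
        warnings.warn(
            "no condition has >= 2 replicates; dispersion is not identifiable, using 0",
            stacklevel=2,
        )
        return DispersionEstimate(phi=0.0, n_genes_used=0)

    rel_arr = np.vstack(rel_list)
    dfs = np.asarray(wdf_list, dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        rel_gene = np.nansum(rel_arr * dfs, axis=0) / dfs.sum()

    mu = mat.mean(axis=1)
    eligible = (mu >= min_mean_count) & np.isfinite(rel_gene)
    n_used = int(eligible.sum())
    if n_used == 0:
        warnings.warn("no gene with adequate counts; dispersion set to 0", stacklevel=2)
        return DispersionEstimate(phi=0.0, n_genes_used=0)

    rel_e = rel_gene[eligible]
    mu_e = mu[eligible]
    pilot = max(float(np.median(rel_e)), 0.0)
    w = (mu_e / (1.0 + pilot * mu_e)) ** 2
    phi = float(np.sum(w * rel_e) / np.sum(w))
    phi = float(np.clip(phi, 0.0, 0.99))
    return DispersionEstimate(phi=phi, n_genes_used=n_used)


def betabin_test(ko_counts, ko_totals, wt_counts, wt_totals, phi: float) -> float:
    """Two-sided beta-binomial LRT p-value for one gene.

    ``phi`` is the beta intra-class correlation in [0, 1); ``phi = 0``
    reduces to the two-proportion binomial LRT.  Replicate counts enter as
    lists aligned with their per-sample totals.
    """
    stat, _, _ = bb_lrt(
        np.asarray(ko_counts, dtype=float)[None, :],
        np.asarray(ko_totals, dtype=float)[None, :],
        np.asarray(wt_counts, dtype=float)[None, :],
        np.asarray(wt_totals, dtype=float)[None, :],
        np.asarray([phi], dtype=float),
    )
    return float(chi2.sf(stat[0], df=1))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, e, _, _ = multipletests(p, method="fdr_bh")
    return e


def de_table(
    counts: CountMatrix,
    model_name: str | None = None,
    *,
    pseudocount: float = 0.5,
    min_rpkm: float = 1.0,
    dispersion: float | None = None,
    fc_source: str = "rpkm",
) -> pd.DataFrame:
    """Full per-model differential-expression table.

    Applies the low-expression filter, estimates the study dispersion
    (unless supplied), runs the beta-binomial LRT on every present,
    expressed gene, computes RPKM-based fold changes, and BH-adjusts the
    p-values into E-values.  Absent genes (all-zero in every replicate, or
    flagged absent upstream) and filtered genes are retained with flags but
    carry no p/E.
    """
    if fc_source not in ("rpkm", "proportions"):
        raise ValueError("fc_source must be 'rpkm' or 'proportions'")
    model_name = model_name or counts.name or "model"
    ko_cols = counts.condition_columns("KO")
    wt_cols = counts.condition_columns("WT")
    if not ko_cols or not wt_cols:
        raise ValueError("both KO and WT samples are required")

    mat = counts.counts
    absent = counts.absent | (mat[ko_cols + wt_cols].sum(axis=1) == 0)
    present = ~absent
    low = low_expression_mask(counts, min_rpkm=min_rpkm)
    tested = present & ~low

    if dispersion is None:
        dispersion = estimate_dispersion(counts).phi
    if not 0.0 <= dispersion < 1.0:
        raise ValueError("dispersion must lie in [0, 1)")

    means = mean_rpkm_by_condition(counts)
    totals = counts.totals

    genes = mat.index
    p = pd.Series(np.nan, index=genes)
    if tested.any():
        ko = mat.loc[tested, ko_cols].to_numpy(dtype=float)
        wt = mat.loc[tested, wt_cols].to_numpy(dtype=float)
        n_ko = np.broadcast_to(totals[ko_cols].to_numpy(dtype=float), ko.shape)
        n_wt = np.broadcast_to(totals[wt_cols].to_numpy(dtype=float), wt.shape)
        pi_pool = (ko.sum(axis=1) + wt.sum(axis=1)) / (n_ko.sum(axis=1) + n_wt.sum(axis=1))
        rho = np.clip(dispersion * pi_pool / np.maximum(1.0 - pi_pool, 1e-12), 0.0, 0.99)
        stat, pi_ko, pi_wt = bb_lrt(ko, n_ko, wt, n_wt, rho)
        p.loc[tested] = chi2.sf(stat, df=1)

    e = pd.Series(np.nan, index=genes)
    if tested.any():
        e.loc[tested] = bh_adjust(p.loc[tested].to_numpy())

    if fc_source == "rpkm":
        fc = pd.Series(
            fold_change(means["KO"].to_numpy(), means["WT"].to_numpy(), pseudocount),
            index=genes,
        )
    else:
        c_ko = mat[ko_cols].sum(axis=1).to_numpy(dtype=float)
        c_wt = mat[wt_cols].sum(axis=1).to_numpy(dtype=float)
        n_ko_t = float(totals[ko_cols].sum())
        n_wt_t = float(totals[wt_cols].sum())
        fc = pd.Series(
            ((c_ko + 0.5) / n_ko_t) / ((c_wt + 0.5) / n_wt_t), index=genes
        )
    fc[absent] = np.nan

    out = pd.DataFrame(
        {
            "gene": genes,
            "model": model_name,
            "fc": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "p": p.to_numpy(),
            "e": e.to_numpy(),
            "mean_rpkm_ko": means["KO"].to_numpy(),
            "mean_rpkm_wt": means["WT"].to_numpy(),
            "present": present.to_numpy(),
            "tested": tested.to_numpy(),
        }
    )
    out.index = pd.RangeIndex(len(out))
    return out
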