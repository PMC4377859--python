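"""Tissue-class annotation, promoter TFBS over-representation, and generic
functional over-representation.

Tissue classification asks, per gene, whether its mean expression across the
tissues of one class (e.g. neuronal, hepatic/intestinal) exceeds its mean
expression everywhere else by a factor; reporting then summarizes what
fraction of a gene list lands in a class.  TFBS enrichment compares a
transcription factor's motif-hit count within the promoters of a submitted
gene list against its genome-wide hit rate with a Poisson upper tail (hit
counts may exceed the number of regions, so a rate model rather than a
drawing-without-replacement model is used), and ranks factors by -log10 P.
Generic over-representation of a list against an annotation term is the
one-sided hypergeometric (Fisher) upper tail, optionally in its conservative
EASE variant (one success removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, poisson

__all__ = [
    "TissueAtlas",
    "PromoterHitTable",
    "classify_tissue",
    "class_fraction",
    "tfbs_enrichment",
    "neglog10_to_p",
    "overrepresentation",
    "round_sig",
]


@dataclass
class TissueAtlas:
    """Genes x tissues expression with a tissue -> class map.

    ``home_class`` is an optional per-gene ground-truth assignment carried
    by synthetic atlases for recovery tests; real atlases leave it None.
    """

    expression: pd.DataFrame
    tissue_class: pd.Series
    home_class: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = self.expression.columns.difference(self.tissue_class.index)
        if len(missing) > 0:
            raise ValueError(f"tissue {missing[0]!r} has no class assignment")
        self.tissue_class = self.tissue_class.reindex(self.expression.columns)
        if self.tissue_class.isna().any():
            raise ValueError("every tissue must belong to exactly one class")
        if self.tissue_class.nunique() < 2:
            raise ValueError("at least 2 tissue classes are required")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression must be non-negative")

    @property
    def classes(self) -> list:
        return sorted(self.tissue_class.unique())


@dataclass
class PromoterHitTable:
    """Per-TF motif hit counts in submitted promoters and genome-wide.

    ``hits`` columns: ``tf``, ``hits_submitted`` (k), ``hits_genome`` (K);
    ``n_submitted`` is the number of submitted promoter regions and
    ``genome_promoters`` the genome-wide region count G.
    """

    hits: pd.DataFrame
    n_submitted: int
    genome_promoters: int

    def __post_init__(self) -> None:
        req = {"tf", "hits_submitted", "hits_genome"}
        if not req.issubset(self.hits.columns):
            raise ValueError(f"hit table needs columns {sorted(req)}")
        if self.genome_promoters <= 0:
            raise ValueError("genome promoter count must be positive")
        if self.n_submitted <= 0 or self.n_submitted > self.genome_promoters:
            raise ValueError("submitted region count must be in (0, genome_promoters]")
        if (self.hits[["hits_submitted", "hits_genome"]].to_numpy() < 0).any():
            raise ValueError("hit counts must be non-negative")


def round_sig(x: float, digits: int = 2) -> float:
    """Round half-up to ``digits`` significant figures (49.09 -> 49, 9.09 -> 9.1)."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    shift = digits - 1 - d.adjusted()
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def classify_tissue(atlas: TissueAtlas, gene, factor: float = 5.0) -> str:
    """Home tissue class of a gene, or ``"none"``.

    A class qualifies when the gene's mean expression over that class's
    tissues is at least ``factor`` times its mean over all other tissues;
    if several qualify the max-ratio class wins.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    if gene not in atlas.expression.index:
        raise KeyError(f"gene {gene!r} not in atlas")
    expr = atlas.expression.loc[gene]
    best, best_ratio = "none", 0.0
    for cls in atlas.classes:
        in_cls = atlas.tissue_class == cls
        inside = float(expr[in_cls.to_numpy()].mean())
        outside = float(expr[~in_cls.to_numpy()].mean())
        ratio = np.inf if outside == 0 and inside > 0 else (inside / outside if outside > 0 else 0.0)
        if ratio >= factor and ratio > best_ratio:
            best, best_ratio = cls, ratio
    return best


def class_fraction(genes, atlas: TissueAtlas, cls: str, factor: float = 5.0):
    """(count, total, percentage) of a gene list classified into ``cls``.

    The percentage is 100*count/total rounded half-up to 2 significant
    figures (27/55 -> 49, 5/55 -> 9.1).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    count = sum(classify_tissue(atlas, g, factor) == cls for g in genes)
    pct = round_sig(100.0 * count / len(genes), 2)
    return count, len(genes), pct


def tfbs_enrichment(table: PromoterHitTable) -> pd.DataFrame:
    """Rank TFs by over-representation of promoter hits in the submitted list.

    Expected submitted hits mu = n_submitted * K / G; p = P(X >= k) with
    X ~ Poisson(mu).  Rows are sorted by -log10 p descending, ties broken
    by k descending then TF name.
    """
    df = table.hits.copy()
    k = df["hits_submitted"].to_numpy(dtype=float)
    K = df["hits_genome"].to_numpy(dtype=float)
    mu = table.n_submitted * K / table.genome_promoters
    zero_rate = (K == 0) & (k > 0)
    if zero_rate.any():
        warnings.warn(
            f"{int(zero_rate.sum())} TF(s) have submitted hits but no genome hits; "
            "using a rate floor of 1e-12",
            stacklevel=2,
        )
        mu = np.where(zero_rate, 1e-12, mu)
    p = np.where(k > 0, poisson.sf(k - 1, np.maximum(mu, 1e-300)), 1.0)
    p = np.clip(p, 1e-300, 1.0)
    out = pd.DataFrame(
        {
            "tf": df["tf"].to_numpy(),
            "hits_submitted": df["hits_submitted"].to_numpy(),
            "hits_genome": df["hits_genome"].to_numpy(),
            "p": p,
            "neglog10_p": -np.log10(p),
        }
    )
    out = out.sort_values(
        by=["neglog10_p", "hits_submitted", "tf"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def neglog10_to_p(x: float) -> float:
    """Convert a -log10 P to the p-value at 2 significant figures."""
    if not np.isfinite(x) or x < 0:
        raise ValueError("-log10 p must be finite and non-negative")
    return round_sig(10.0 ** (-x), 2)


def overrepresentation(k: int, n: int, Kp: int, Np: int, mode: str = "fisher"):
    """One-sided over-representation of a term in a gene list.

    ``k`` of ``n`` list genes carry the term; ``Kp`` of ``Np`` population
    genes do.  Returns ``(p, fold_enrichment, percent_of_list)`` where p is
    the hypergeometric upper tail P(X >= k); ``mode="ease"`` removes one
    success (P(X >= k-1)), DAVID's conservative EASE score.
    """
    if mode not in ("fisher", "ease"):
        raise ValueError("mode must be 'fisher' or 'ease'")
    if not (0 <= k <= n <= Np and k <= Kp <= Np):
        raise ValueError("inconsistent 2x2 margins")
    if n == 0:
        raise ValueError("list is empty")
    kk = k if mode == "fisher" else max(k - 1, 0)
    p = float(hypergeom.sf(kk - 1, Np, Kp, n))
    p = min(max(p, 0.0), 1.0)
    fold = (k / n) / (Kp / Np) if Kp > 0 else np.inf
    percent = 100.0 * k / n
    return p, fold, percent
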