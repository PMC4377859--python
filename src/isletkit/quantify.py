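"""Expression-level quantities: RPKM and condition fold changes.

RPKM (reads per kilobase of transcript per million mapped reads) is the
length- and depth-normalized expression unit used throughout this package:

    RPKM = 1e9 * C / (N * L)

with C the reads mapped to the gene, N the total mapped reads in the sample
and L the transcript length in base pairs.  Fold changes between knockout
and control condition means are computed on RPKM with a small pseudocount so
that genes detected in only one condition keep a bounded log fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "rpkm",
    "rpkm_matrix",
    "fold_change",
    "mean_rpkm_by_condition",
    "low_expression_mask",
]

#: conditions recognised in sample metadata
CONDITIONS = ("KO", "WT")


@dataclass
class CountMatrix:
    """Gene x sample read counts with sample metadata and gene lengths.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows, samples as columns.
    samples
        One row per sample (index matching ``counts.columns``) with columns
        ``model``, ``condition`` (``"KO"``/``"WT"``) and ``replicate``.
    lengths
        Transcript length in bp per gene, indexed like ``counts.index``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series
    name: str = ""
    absent: pd.Series = field(default=None)  # bool per gene; all-zero by design

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("count matrix is empty")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(vals, np.floor(vals)):
            raise ValueError("counts must be integers")
        if list(self.samples.index) != list(self.counts.columns):
            raise ValueError("sample metadata index must match count columns")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing) > 0:
            raise ValueError(f"missing length for gene {missing[0]!r}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths <= 0).any():
            gene = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for gene {gene!r}")
        if self.absent is None:
            self.absent = pd.Series(False, index=self.counts.index)
        else:
            self.absent = self.absent.reindex(self.counts.index).fillna(False).astype(bool)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def totals(self) -> pd.Series:
        """Per-sample total mapped reads (column sums)."""
        return self.counts.sum(axis=0)

    def condition_columns(self, condition: str) -> list:
        return list(self.samples.index[self.samples["condition"] == condition])

    def for_model(self, model: str) -> "CountMatrix":
        cols = list(self.samples.index[self.samples["model"] == model])
        if not cols:
            raise ValueError(f"no samples for model {model!r}")
        return CountMatrix(
            counts=self.counts[cols],
            samples=self.samples.loc[cols],
            lengths=self.lengths,
            name=model,
            absent=self.absent,
        )

    @property
    def models(self) -> list:
        seen: list = []
        for m in self.samples["model"]:
            if m not in seen:
                seen.append(m)
        return seen


def rpkm(C, N, L):
    """Reads per kilobase per million mapped reads: ``1e9 * C / (N * L)``.

    Accepts scalars or arrays (broadcasting); zero iff ``C`` is zero.
    """
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    L = np.asarray(L, dtype=float)
    if (C < 0).any():
        raise ValueError("counts must be non-negative")
    if (N <= 0).any():
        raise ValueError("total mapped reads must be positive")
    if (L <= 0).any():
        raise ValueError("transcript length must be positive")
    out = 1e9 * C / (N * L)
    if out.ndim == 0:
        return float(out)
    return out


def rpkm_matrix(counts: CountMatrix) -> pd.DataFrame:
    """Element-wise RPKM with per-sample totals; preserves ordering."""
    N = counts.totals.to_numpy()[None, :]
    L = counts.lengths.to_numpy()[:, None]
    vals = rpkm(counts.counts.to_numpy(), N, L)
    return pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)


def fold_change(mean_ko, mean_wt, pseudocount: float = 0.5):
    """(mean_ko + eps) / (mean_wt + eps); >1 means up in KO, <1 down.

    The pseudocount (default 0.5 RPKM) bounds fold changes for genes
    detected in only one condition.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ko = np.asarray(mean_ko, dtype=float)
    wt = np.asarray(mean_wt, dtype=float)
    if (ko < 0).any() or (wt < 0).any():
        raise ValueError("condition means must be non-negative")
    if not (np.isfinite(ko).all() and np.isfinite(wt).all()):
        raise ValueError("condition means must be finite")
    out = (ko + pseudocount) / (wt + pseudocount)
    if out.ndim == 0:
        return float(out)
    return out


def mean_rpkm_by_condition(counts: CountMatrix) -> pd.DataFrame:
    """Per-gene mean RPKM per condition (columns ``KO``, ``WT``)."""
    expr = rpkm_matrix(counts)
    out = {}
    for cond in CONDITIONS:
        cols = counts.condition_columns(cond)
        if not cols:
            raise ValueError(f"no samples with condition {cond!r}")
        out[cond] = expr[cols].mean(axis=1)
    return pd.DataFrame(out)


def low_expression_mask(counts: CountMatrix, min_rpkm: float = 1.0) -> pd.Series:
    """True for genes whose mean RPKM is below ``min_rpkm`` in both conditions.

    Such genes are flagged "low-expressed" and by default excluded from
    ranking; fold-change estimates for them are pseudocount-dominated.
    """
    means = mean_rpkm_by_condition(counts)
    return (means["KO"] < min_rpkm) & (means["WT"] < min_rpkm)
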