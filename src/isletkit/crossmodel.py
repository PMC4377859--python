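"""Cross-model concordance: filter an index model's ranked changes by
agreement in further knockout strains.

A gene counts as changed in a model when it is significant (E below the E
threshold or P below the P threshold) with at least the fold-change
threshold in magnitude (>= 1.4-fold up, or <= 1/1.4 down, by default).  A
gene passes the concordance filter when it is changed in the index model
and at least ``min_further_models`` of the other tables show a change in
the same direction under the same criterion.  Genes absent from a model
(no counts) are marked absent there and never count as concordant.

The resulting gene x model table of statuses and signed log2 fold changes
is the input for overlap counting and the heat-map matrix (absent cells
form the gray mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceCriteria",
    "ConcordanceTable",
    "concordance_filter",
    "overlap_counts",
    "heatmap_matrix",
]

STATUSES = ("up", "down", "unchanged", "absent")


@dataclass(frozen=True)
class ConcordanceCriteria:
    """Thresholds of the cross-model filter.

    ``fc_threshold`` is inclusive (>= 1.4-fold); down-regulation means
    FC <= 1/fc_threshold.  ``apply_to_index`` applies the same
    significance-plus-fold rule to the index model itself.
    """

    fc_threshold: float = 1.4
    e_threshold: float = 0.1
    p_threshold: float = 0.05
    min_further_models: int = 1
    apply_to_index: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        for name in ("e_threshold", "p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_further_models < 0:
            raise ValueError("min_further_models must be non-negative")


@dataclass
class ConcordanceTable:
    """Gene x model statuses and signed log2 fold changes.

    ``status`` holds up/down/unchanged/absent per (gene, model); ``log2fc``
    is NaN where absent.  ``index_rank`` ranks genes by the index model's
    log2FC descending (1 = most induced); ``passed`` flags genes meeting
    the concordance criteria.
    """

    status: pd.DataFrame
    log2fc: pd.DataFrame
    index_model: str
    index_rank: pd.Series
    passed: pd.Series
    criteria: ConcordanceCriteria

    def __post_init__(self) -> None:
        if self.status.empty:
            raise ValueError("concordance table is empty")

    @property
    def models(self) -> list:
        return list(self.status.columns)

    @property
    def other_models(self) -> list:
        return [m for m in self.status.columns if m != self.index_model]

    def to_frame(self) -> pd.DataFrame:
        """Flat serializable view: one row per gene."""
        out = pd.DataFrame(index=self.status.index)
        out["index_rank"] = self.index_rank
        out["passed"] = self.passed
        for m in self.models:
            out[f"status:{m}"] = self.status[m]
            out[f"log2fc:{m}"] = self.log2fc[m]
        return out.sort_values("index_rank")


def _status_one(de: pd.DataFrame, criteria: ConcordanceCriteria) -> pd.DataFrame:
    """Per-gene status and log2fc for one DE table."""
    d = de.set_index("gene")
    present = d["present"].astype(bool)
    sig = (d["e"] < criteria.e_threshold) | (d["p"] < criteria.p_threshold)
    sig = sig.fillna(False)
    up = present & sig & (d["fc"] >= criteria.fc_threshold)
    down = present & sig & (d["fc"] <= 1.0 / criteria.fc_threshold)
    status = pd.Series("unchanged", index=d.index)
    status[up] = "up"
    status[down] = "down"
    status[~present] = "absent"
    log2fc = d["log2fc"].where(present, np.nan)
    return pd.DataFrame({"status": status, "log2fc": log2fc})


def concordance_filter(
    index: pd.DataFrame,
    others: list,
    criteria: ConcordanceCriteria = ConcordanceCriteria(),
    display_only: list = (),
) -> ConcordanceTable:
    """Apply the cross-model filter.

    ``others`` are the tables that can corroborate the index model;
    ``display_only`` tables contribute status/log2fc columns but do not
    count toward ``min_further_models``.  Gene universes are outer-joined;
    a gene missing from a table is absent there.
    """
    others = list(others)
    display_only = list(display_only)
    if not others and criteria.min_further_models >= 1:
        raise ValueError("at least one further model is required by the criteria")
    tables = [index] + others + display_only
    names = [t["model"].iloc[0] for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names across DE tables")
    index_model = names[0]

    universe = pd.Index(pd.unique(pd.concat([t["gene"] for t in tables])), name="gene")

    status = pd.DataFrame("absent", index=universe, columns=names)
    log2fc = pd.DataFrame(np.nan, index=universe, columns=names)
    for name, t in zip(names, tables):
        st = _status_one(t, criteria).reindex(universe)
        status[name] = st["status"].fillna("absent")
        log2fc[name] = st["log2fc"]

    idx_status = status[index_model]
    changed = idx_status.isin(["up", "down"])
    if criteria.apply_to_index:
        eligible = changed
    else:
        eligible = status[index_model] != "absent"

    concord = pd.Series(0, index=universe)
    for name in names[1 : 1 + len(others)]:
        concord += (status[name] == idx_status).astype(int) & changed.astype(int)
    passed = eligible & (concord >= criteria.min_further_models)

    rank_metric = log2fc[index_model]
    order = rank_metric.sort_values(ascending=False, kind="mergesort")
    index_rank = pd.Series(np.nan, index=universe)
    index_rank[order.index] = np.arange(1, len(order) + 1)

    return ConcordanceTable(
        status=status,
        log2fc=log2fc,
        index_model=index_model,
        index_rank=index_rank,
        passed=passed,
        criteria=criteria,
    )


def overlap_counts(table: ConcordanceTable, top_k: int):
    """Concordance counts for the top-k most induced index-model genes.

    Returns ``(per_model, per_m)``: per other model, how many of the top-k
    genes are up/down/absent there; and for m = 1..M, how many top-k genes
    are concordant (same status as in the index model) in at least m of the
    M other models.  Absent genes never count as concordant.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ranked = table.index_rank.dropna().sort_values()
    if top_k > len(ranked):
        raise ValueError("top_k exceeds the number of ranked genes")
    top = ranked.index[:top_k]
    others = table.other_models
    idx_status = table.status.loc[top, table.index_model]

    per_model = pd.DataFrame(0, index=others, columns=["up", "down", "absent", "concordant"])
    for m in others:
        st = table.status.loc[top, m]
        per_model.loc[m, "up"] = int((st == "up").sum())
        per_model.loc[m, "down"] = int((st == "down").sum())
        per_model.loc[m, "absent"] = int((st == "absent").sum())
        per_model.loc[m, "concordant"] = int(
            ((st == idx_status) & idx_status.isin(["up", "down"])).sum()
        )

    M = len(others)
    conc_n = pd.Series(0, index=top)
    for m in others:
        st = table.status.loc[top, m]
        conc_n += ((st == idx_status) & idx_status.isin(["up", "down"])).astype(int)
    per_m = pd.Series(
        {m: int((conc_n >= m).sum()) for m in range(1, M + 1)}, name="n_genes"
    )
    per_m.index.name = "concordant_in_at_least"
    return per_model, per_m


def heatmap_matrix(table: ConcordanceTable):
    """Signed log2FC matrix ordered by index rank, plus the absence mask."""
    order = table.index_rank.dropna().sort_values().index
    order = order.append(table.index_rank.index[table.index_rank.isna()])
    matrix = table.log2fc.loc[order]
    mask = table.status.loc[order] == "absent"
    return matrix, mask


def plot_heatmap(table: ConcordanceTable, path, max_genes: int = 60):
    """Render the concordance heat map (red up, blue down, gray absent)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    matrix, mask = heatmap_matrix(table)
    sel = table.passed.reindex(matrix.index).fillna(False)
    matrix = matrix.loc[sel].head(max_genes)
    mask = mask.loc[matrix.index]
    data = np.ma.masked_array(matrix.to_numpy(), mask=mask.to_numpy() | ~np.isfinite(matrix))
    lim = np.nanmax(np.abs(matrix.to_numpy())) if matrix.size else 1.0
    fig, ax = plt.subplots(figsize=(4 + 0.5 * matrix.shape[1], max(3, 0.15 * len(matrix))))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.6")
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 fold change (gray = absent)")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
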