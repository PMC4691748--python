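"""Fraction-purity QC, sample similarity, and cross-sample overlap counting.

Nuclear/cytoplasmic fractionations are accepted only when marker transcripts
show their expected enrichment in the nuclear fraction: by default the
strictly nuclear lncRNA MALAT1 at >=20-fold and the polyadenylated lncRNA
XIST at >=200-fold. Sample relatedness is summarised as a Spearman
correlation heatmap plus an average-linkage dendrogram. Differential-APA
event lists from several cell lines/replicates are intersected to count how
many events recur in exactly k sets with a consistent direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

logger = logging.getLogger("apafrac")

DEFAULT_MARKERS = {"MALAT1": 20.0, "XIST": 200.0}
PSEUDOCOUNT = 0.5


@dataclass
class QcReport:
    """Per-marker nuclear/cytoplasmic fold enrichment against its threshold."""

    fold_enrichment: dict[str, float]
    thresholds: dict[str, float]
    marker_pass: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.marker_pass.values())


def marker_enrichment(expr: pd.DataFrame,
                      markers: Mapping[str, float] | None = None,
                      nuclear_id: str = "nuclear",
                      cyto_id: str = "cytoplasmic") -> QcReport:
    """Fraction-purity QC from a gene x sample expression table.

    Fold enrichment is (nuclear + 0.5) / (cytoplasmic + 0.5); the
    pseudocount keeps folds finite for zero cytoplasmic counts without
    distorting large ones. Every marker must meet its threshold for the
    fractionation to pass.
    """
    markers = dict(DEFAULT_MARKERS if markers is None else markers)
    missing = [g for g in markers if g not in expr.index]
    if missing:
        raise KeyError(f"marker gene(s) missing from expression table: {missing}")
    for col in (nuclear_id, cyto_id):
        if col not in expr.columns:
            raise KeyError(f"sample {col!r} missing from expression table")
    folds, ok = {}, {}
    for gene, thr in markers.items():
        fold = ((expr.loc[gene, nuclear_id] + PSEUDOCOUNT)
                / (expr.loc[gene, cyto_id] + PSEUDOCOUNT))
        folds[gene] = float(fold)
        ok[gene] = bool(fold >= thr)
    return QcReport(fold_enrichment=folds, thresholds=markers, marker_pass=ok)


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.left, labels)
    right = _tree_to_newick(node.right, labels)
    dl = node.dist - node.left.dist   # leaves have dist 0
    dr = node.dist - node.right.dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def sample_similarity(abundance: pd.DataFrame
                      ) -> tuple[pd.DataFrame, str]:
    """Spearman similarity of samples plus an average-linkage dendrogram.

    ``abundance`` is a site x sample table of per-site read abundances over
    a common site set. Sites that are zero in every sample are dropped,
    abundances are log2(x+1)-transformed (Spearman is rank-based; the
    transform only serves downstream plotting of the same matrix), and
    samples are clustered by average linkage on 1 - rho. Returns the
    correlation matrix and a newick string with deterministic leaf order.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need at least two samples")
    kept = abundance.loc[(abundance != 0).any(axis=1)]
    logx = np.log2(kept.to_numpy(dtype=float) + 1.0)
    rho = spearmanr(logx).statistic
    if np.isscalar(rho):  # spearmanr returns a scalar for 2 samples
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=abundance.columns, columns=abundance.columns)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    tree = to_tree(z)
    newick = _tree_to_newick(tree, list(abundance.columns)) + ";"
    return corr, newick


def cross_overlap(event_sets: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Count differential-APA events recurring across sample sets.

    ``event_sets`` maps a set name (cell line / replicate) to a mapping
    gene -> direction call. An event is shared in k sets when the same gene
    carries the same direction in exactly k sets; a gene with conflicting
    directions is counted once, at its largest consistent k (ties broken by
    direction name order), and flagged.

    Returns a frame with one row per gene: direction, k, conflict flag.
    """
    if len(event_sets) < 2:
        raise ValueError("need at least two event sets")
    per_gene: dict[str, dict[str, int]] = {}
    for _set_name, events in sorted(event_sets.items()):
        for gene, direction in events.items():
            per_gene.setdefault(gene, {}).setdefault(direction, 0)
            per_gene[gene][direction] += 1
    rows = []
    for gene in sorted(per_gene):
        dirs = per_gene[gene]
        k = max(dirs.values())
        direction = min(d for d, c in dirs.items() if c == k)
        rows.append(dict(gene_id=gene, direction=direction, k=k,
                         conflict=len(dirs) > 1))
    return pd.DataFrame(rows)


def overlap_profile(events: pd.DataFrame) -> pd.DataFrame:
    """Histogram of `cross_overlap` output: events per (k, direction)."""
    return (events.groupby(["k", "direction"]).size()
            .rename("n_events").reset_index())


def replicate_concordance(set_a: Mapping[str, str],
                          set_b: Mapping[str, str]) -> dict[str, float]:
    """Direction-consistent overlap between two replicate event sets.

    Reports both natural denominators, since either can be meant by an
    "overlap" percentage: the union of events and the smaller set.
    """
    if not set_a or not set_b:
        raise ValueError("empty event set: concordance undefined")
    shared = sum(1 for g, d in set_a.items() if set_b.get(g) == d)
    union = len(set(set_a) | set(set_b))
    smaller = min(len(set_a), len(set_b))
    return {"shared": float(shared),
            "frac_of_union": shared / union,
            "frac_of_smaller": shared / smaller}
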