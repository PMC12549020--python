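"""Single-cell expression integration for matrisome gene sets.

Cells live in an :class:`anndata.AnnData` with raw counts in ``.X`` (sparse),
cluster / life-cycle-phase / cluster-class labels in ``.obs``, and the
library-size-normalized log1p layer in ``.layers["normalized"]``.  On top of
that container: dot-plot summarization (percent detected + scaled average
expression per gene x cluster), expression-bin-matched gene-module scores,
Wilcoxon rank-sum marker detection, and the cnidocyte binning cascade that
sorts genes into not_expressed / ubiquitous / shared / exclusive bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

from .tmt import benjamini_hochberg

__all__ = [
    "ExpressionSummary",
    "BINS",
    "CLUSTER_CLASSES",
    "normalize_counts",
    "split_phases",
    "summarize_dotplot",
    "module_score",
    "find_markers",
    "detect_in_state",
    "bin_cnidocyte_genes",
    "exact_rank_sum_p",
]

PHASES = ("larva", "primary_polyp", "adult")
CLUSTER_CLASSES = ("cnidocyte_specification", "cnidocyte_mature", "non_cnidocyte")
BINS = ("not_expressed", "ubiquitous", "shared",
        "exclusive_specification", "exclusive_mature")
SCALED_CLIP = 2.5


@dataclass
class ExpressionSummary:
    """Dot-plot data matrix: per (gene, cluster) percent detected, average
    expm1 expression, and the per-gene z-scored (clipped) log average."""

    pct_detected: pd.DataFrame  # genes x clusters, in [0, 100]
    avg_exp: pd.DataFrame
    scaled_avg: pd.DataFrame

    @property
    def clusters(self) -> list[str]:
        return list(self.pct_detected.columns)

    def to_frame(self) -> pd.DataFrame:
        long = []
        for name, mat in (("pct_detected", self.pct_detected),
                          ("avg_exp", self.avg_exp),
                          ("scaled_avg", self.scaled_avg)):
            stacked = mat.stack().rename(name)
            long.append(stacked)
        return pd.concat(long, axis=1).rename_axis(["gene", "cluster"]).reset_index()


def _counts(atlas: AnnData) -> sparse.csr_matrix:
    X = atlas.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


def normalize_counts(atlas: AnnData, scale_target: float = 1e4) -> AnnData:
    """Library-size normalization: counts / cell-total * scale_target, log1p.

    Stored in ``.layers["normalized"]``; raw counts stay in ``.X``.  A cell
    with zero total counts is an error.
    """
    X = _counts(atlas)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)[:5]
        raise ValueError(f"cells with zero total counts: rows {bad.tolist()}")
    scaled = sparse.diags(scale_target / totals) @ X
    scaled.data = np.log1p(scaled.data)
    atlas.layers["normalized"] = scaled.tocsr()
    return atlas


def split_phases(atlas: AnnData, phase_key: str = "phase") -> dict[str, AnnData]:
    """Disjoint partition of the atlas by life-cycle phase."""
    phases = atlas.obs[phase_key]
    unknown = set(phases.unique()) - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phase labels: {sorted(unknown)}")
    return {ph: atlas[phases == ph].copy() for ph in PHASES}


def summarize_dotplot(
    atlas: AnnData, genes: Optional[Sequence[str]] = None,
    cluster_key: str = "cluster",
) -> ExpressionSummary:
    """Per gene x cluster: percent of cells detected (raw count > 0), mean
    expm1 of the normalized layer, and the per-gene z-score of
    log1p(avg_exp) across clusters clipped to +-2.5.

    An all-zero gene has undefined z-scores; by convention its scaled average
    is 0 in every cluster (likewise any gene with zero across-cluster
    variance).
    """
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer missing; run normalize_counts first")
    if genes is not None:
        missing = [g for g in genes if g not in atlas.var_names]
        if missing:
            raise KeyError(f"genes absent from atlas: {missing[:5]}")
        atlas = atlas[:, list(genes)]
    clusters = pd.Categorical(atlas.obs[cluster_key])
    raw = _counts(atlas)
    norm = atlas.layers["normalized"].tocsr()
    expm1 = norm.copy()
    expm1.data = np.expm1(expm1.data)
    pct, avg = {}, {}
    for cl in clusters.categories:
        mask = np.asarray(clusters == cl)
        if mask.sum() == 0:
            raise ValueError(f"empty cluster {cl!r}")
        sub_raw = raw[mask]
        pct[str(cl)] = 100.0 * np.asarray(
            (sub_raw > 0).sum(axis=0)).ravel() / mask.sum()
        avg[str(cl)] = np.asarray(expm1[mask].mean(axis=0)).ravel()
    pct_df = pd.DataFrame(pct, index=atlas.var_names)
    avg_df = pd.DataFrame(avg, index=atlas.var_names)
    log_avg = np.log1p(avg_df)
    mu = log_avg.mean(axis=1)
    sd = log_avg.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log_avg.sub(mu, axis=0).div(sd, axis=0)
    z = z.where(sd > 0, 0.0).clip(-SCALED_CLIP, SCALED_CLIP)
    return ExpressionSummary(pct_df, avg_df, z)


def module_score(
    atlas: AnnData, gene_set: Sequence[str], n_bins: int = 24,
    n_ctrl: int = 100, seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched gene-module score per cell.

    Genes are ranked by dataset-average normalized expression and cut into
    ``n_bins`` equal-frequency bins; each gene-set member draws ``n_ctrl``
    control genes uniformly without replacement from its bin (with
    replacement, with a warning, when the bin is too small).  The score is the
    mean normalized expression of the gene set minus that of the pooled
    controls.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    present = [g for g in gene_set if g in atlas.var_names]
    if not present:
        raise KeyError("gene set entirely absent from atlas")
    if "normalized" not in atlas.layers:
        raise ValueError("normalized layer missing; run normalize_counts first")
    norm = atlas.layers["normalized"].tocsr()
    var_names = pd.Index(atlas.var_names)
    avg = np.asarray(norm.mean(axis=0)).ravel()
    order = pd.Series(avg, index=var_names)
    # equal-frequency bins over the whole dataset, ties broken by rank
    ranks = order.rank(method="first")
    bins = np.ceil(ranks / (len(ranks) / n_bins)).clip(1, n_bins).astype(int)
    rng = np.random.default_rng(seed)
    control: list[str] = []
    for gene in present:
        b = bins[gene]
        pool = var_names[(bins == b).to_numpy() & (var_names != gene)]
        if len(pool) >= n_ctrl:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            warnings.warn(
                f"bin {b} has {len(pool)} genes < n_ctrl={n_ctrl}; "
                "sampling with replacement", RuntimeWarning)
            chosen = rng.choice(pool, size=n_ctrl, replace=True)
        control.extend(chosen)
    set_idx = var_names.get_indexer(present)
    ctrl_idx = var_names.get_indexer(control)
    set_mean = np.asarray(norm[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(norm[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=atlas.obs_names, name="score")


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumeration over all rank
    assignments (midranks for ties).  Intended for n <= ~8 per side."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(pooled)
    dev = abs(obs - mu)
    total = math.comb(len(pooled), n1)
    count = 0
    for combo in combinations(range(len(pooled)), n1):
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
            count += 1
    return count / total


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max: int = 8) -> float:
    """Two-sided rank-sum p: exact enumeration for small samples, otherwise
    the tie-corrected normal approximation."""
    if max(len(x), len(y)) <= exact_max:
        return exact_rank_sum_p(x, y)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.pvalue)


def find_markers(
    atlas: AnnData, target_cluster: str, cluster_key: str = "cluster",
    min_pct: float = 0.20, return_p: float = 0.001, logfc_min: float = 0.25,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of one cluster against all other cells.

    Genes are pre-filtered to a detection fraction of at least ``min_pct`` in
    the target or the rest, and a log fold change of mean expm1 expression
    (+1 pseudocount) of at least ``logfc_min``.  Returned genes satisfy
    p <= ``return_p`` on the unadjusted p (BH-adjusted values are reported),
    ranked by p then |logfc|.
    """
    clusters = atlas.obs[cluster_key].astype(str)
    in_target = (clusters == str(target_cluster)).to_numpy()
    if in_target.sum() < 3:
        raise ValueError(f"cluster {target_cluster!r} has fewer than 3 cells")
    raw = _counts(atlas)
    norm = atlas.layers["normalized"].tocsr()
    expm1 = norm.copy()
    expm1.data = np.expm1(expm1.data)

    pct_in = np.asarray((raw[in_target] > 0).sum(axis=0)).ravel() / in_target.sum()
    pct_out = np.asarray((raw[~in_target] > 0).sum(axis=0)).ravel() / (~in_target).sum()
    mean_in = np.asarray(expm1[in_target].mean(axis=0)).ravel()
    mean_out = np.asarray(expm1[~in_target].mean(axis=0)).ravel()
    logfc = np.log((mean_in + 1.0)) - np.log((mean_out + 1.0))
    testable = ((np.maximum(pct_in, pct_out) >= min_pct)
                & (np.abs(logfc) >= logfc_min))
    dense = np.asarray(norm.todense())
    rows = []
    for j in np.flatnonzero(testable):
        x = dense[in_target, j]
        y = dense[~in_target, j]
        if np.all(x == x[0]) and np.all(y == x[0]):
            p = 1.0  # degenerate all-tied expression: retained, p = 1
        else:
            p = _rank_sum_p(x, y)
        rows.append((atlas.var_names[j], logfc[j], pct_in[j], pct_out[j],
                     max(p, np.nextafter(0, 1))))
    table = pd.DataFrame(
        rows, columns=["gene", "logfc", "pct_in", "pct_out", "p"]
    ).set_index("gene")
    if len(table):
        table["p_adjusted"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["p_adjusted"] = []
    table = table[table["p"] <= return_p]
    return table.sort_values(["p", "logfc"], key=lambda s: (
        s if s.name == "p" else -s.abs()))


def detect_in_state(
    summary: ExpressionSummary, gene: str, cluster: str,
    pct_min: float = 5.0, require_above_avg: bool = True,
) -> bool:
    """Detection predicate for one gene in one transcriptomic state: percent
    detected at least ``pct_min`` (inclusive) and, when required, scaled
    average expression above the across-cluster average (scaled_avg > 0)."""
    if cluster not in summary.pct_detected.columns:
        raise KeyError(f"unknown cluster {cluster!r}")
    if gene not in summary.pct_detected.index:
        raise KeyError(f"unknown gene {gene!r}")
    if summary.pct_detected.loc[gene, cluster] < pct_min:
        return False
    if require_above_avg and summary.scaled_avg.loc[gene, cluster] <= 0:
        return False
    return True


def bin_cnidocyte_genes(
    summary: ExpressionSummary,
    cluster_classes: dict[str, str],
    pct_min: float = 5.0,
    nonc_majority: float = 50.0,
    require_above_avg: bool = True,
    exclusive_tiebreak: str = "exclusive_specification",
) -> pd.Series:
    """The cnidocyte binning cascade.

    (1) genes not detected in any cnidocyte state are ``not_expressed``;
    (2) genes also detected in more than ``nonc_majority`` percent of
    non-cnidocyte states are ``ubiquitous``; (3) genes detected in zero
    non-cnidocyte states are exclusive, sub-binned by which cnidocyte class
    detects them (specification / mature; both -> ``exclusive_tiebreak``);
    (4) everything else is ``shared``.  "Absent" uses the same detection
    predicate as presence (symmetric), for robustness to ambient counts.
    """
    unknown = set(cluster_classes.values()) - set(CLUSTER_CLASSES)
    if unknown:
        raise ValueError(f"unknown cluster classes: {sorted(unknown)}")
    missing = set(summary.clusters) - set(cluster_classes)
    if missing:
        raise ValueError(f"clusters without a class label: {sorted(missing)}")
    if exclusive_tiebreak not in ("exclusive_specification", "exclusive_mature"):
        raise ValueError("invalid exclusive_tiebreak")
    spec_clusters = [c for c in summary.clusters
                     if cluster_classes[c] == "cnidocyte_specification"]
    mature_clusters = [c for c in summary.clusters
                       if cluster_classes[c] == "cnidocyte_mature"]
    nonc_clusters = [c for c in summary.clusters
                     if cluster_classes[c] == "non_cnidocyte"]
    if not nonc_clusters:
        raise ValueError("no non-cnidocyte clusters in the atlas")

    assignments = {}
    for gene in summary.pct_detected.index:
        def det(cl):
            return detect_in_state(summary, gene, cl, pct_min, require_above_avg)
        in_spec = any(det(c) for c in spec_clusters)
        in_mature = any(det(c) for c in mature_clusters)
        if not (in_spec or in_mature):
            assignments[gene] = "not_expressed"
            continue
        n_nonc = sum(det(c) for c in nonc_clusters)
        if 100.0 * n_nonc / len(nonc_clusters) > nonc_majority:
            assignments[gene] = "ubiquitous"
        elif n_nonc == 0:
            if in_spec and in_mature:
                assignments[gene] = exclusive_tiebreak
            elif in_spec:
                assignments[gene] = "exclusive_specification"
            else:
                assignments[gene] = "exclusive_mature"
        else:
            assignments[gene] = "shared"
    return pd.Series(assignments, name="bin")
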