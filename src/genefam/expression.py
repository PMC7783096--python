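"""Count normalization, experiment merging, tau specificity, peak-tissue grouping.

The variance-stabilizing transform here is the documented surrogate
``log2(count / size_factor + 1)``: it preserves ranks and flattens the
mean-variance relationship of negative-binomial counts, which is all the
downstream steps rely on.  It is not a reimplementation of the reference
parametric VST.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed on all-positive genes).

    Falls back to total-count ratios (normalized to geometric mean 1) when no
    gene is positive in every sample.  An all-zero matrix is an error.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    if not counts.values.any():
        raise ValueError("all-zero count matrix")
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive):
        geo = np.exp(np.log(positive).mean(axis=1))
        factors = positive.div(geo, axis=0).median(axis=0)
    else:
        totals = counts.sum(axis=0).astype(float)
        factors = totals / np.exp(np.log(totals[totals > 0]).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Stabilized values: log2(count / factor + 1)."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(factors, axis=1) + 1.0)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's gene-median; idempotent."""
    if matrix.shape[0] < 1:
        raise ValueError("matrix needs at least one gene")
    return matrix.sub(matrix.median(axis=0), axis=1)


def merge_experiments(counts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Normalize, stabilize and median-center each experiment, then join.

    Joined on the union of gene ids; genes absent from an experiment are NaN
    (missing, not zero).  Experiments must share at least one gene and sample
    ids must be globally unique.
    """
    if not counts:
        raise ValueError("no experiments to merge")
    frames = []
    gene_sets = [set(df.index) for df in counts.values()]
    if not set.intersection(*gene_sets):
        raise ValueError("experiments share no gene ids")
    for name in counts:
        df = counts[name]
        frames.append(median_center(vst(df, size_factors(df))))
    merged = pd.concat(frames, axis=1, join="outer")
    if merged.columns.duplicated().any():
        raise ValueError("duplicate sample ids across experiments")
    return merged


def tissue_means(matrix: pd.DataFrame, metadata: pd.DataFrame, tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene mean over each tissue's samples (NaN-aware)."""
    meta = metadata.set_index("sample")
    cols = [c for c in matrix.columns if c in meta.index]
    groups = meta.loc[cols, "tissue"]
    means = matrix[cols].T.groupby(groups).mean().T
    if tissues is not None:
        means = means.reindex(columns=[t for t in tissues if t in means.columns])
    return means


def tau(profile: Sequence[float]) -> float:
    """Tissue-specificity index over a per-tissue mean profile.

    tau = sum_i(1 - x_i / max_i x_i) / (N - 1) after clipping negatives to 0
    and dropping missing tissues.  1 = single-tissue, 0 = uniform; NaN when
    the profile is all zero.  Fewer than 2 usable tissues is an error.
    """
    x = np.asarray(profile, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("tau needs at least 2 tissues")
    x = np.clip(x, 0.0, None)
    peak = x.max()
    if peak == 0:
        return float("nan")
    return float((1.0 - x / peak).sum() / (n - 1))


def peak_tissue(profile: Mapping[str, float] | pd.Series, tissue_order: Sequence[str]) -> str:
    """Tissue with the largest mean; ties go to the first tissue in order."""
    series = pd.Series(profile)
    best, best_val = None, -np.inf
    for t in tissue_order:
        if t not in series.index:
            continue
        v = series[t]
        if pd.isna(v):
            continue
        if v > best_val:
            best, best_val = t, v
    if best is None:
        raise ValueError("profile has no finite value")
    return best


def score_genes(
    matrix: pd.DataFrame, metadata: pd.DataFrame, tissue_order: Sequence[str]
) -> pd.DataFrame:
    """Tau, peak tissue and usable tissue count for every gene."""
    means = tissue_means(matrix, metadata, tissue_order)
    rows = []
    for gene in matrix.index:
        profile = means.loc[gene]
        usable = profile.dropna()
        rows.append(
            {
                "gene": gene,
                "tau": tau(profile.values) if len(usable) >= 2 else np.nan,
                "peak_tissue": peak_tissue(profile, tissue_order) if len(usable) else "",
                "n_tissues": len(usable),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "tau", "peak_tissue", "n_tissues"]).set_index("gene")


def heatmap_order(
    matrix: pd.DataFrame,
    peaks: Mapping[str, str] | pd.Series,
    tissue_order: Sequence[str],
) -> list[tuple[str, list[str]]]:
    """Genes grouped by peak tissue, ordered within group by average-linkage
    hierarchical clustering on 1 - Pearson correlation.

    Returns (tissue, ordered gene list) pairs in declared tissue order;
    singleton groups pass through.  Genes are pre-sorted by id so clustering
    ties resolve deterministically.
    """
    peaks = pd.Series(peaks)
    out: list[tuple[str, list[str]]] = []
    for t in tissue_order:
        members = sorted(g for g in matrix.index if peaks.get(g) == t)
        if not members:
            continue
        if len(members) <= 2:
            out.append((t, members))
            continue
        sub = matrix.loc[members]
        corr = sub.T.corr().to_numpy()
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        Z = linkage(squareform(dist, checks=False), method="average")
        order = leaves_list(Z)
        out.append((t, [members[i] for i in order]))
    return out
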