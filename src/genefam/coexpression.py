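"""Guide-gene co-expression networks: mutual information, CLR scores, GraphML."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_BINS = 10
DEFAULT_Z_THRESHOLD = 5.0


def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency discretization into *bins* levels.

    A constant vector maps to a single level (bin 0).  Ties are broken by
    stable sort order so the assignment is deterministic.
    """
    x = np.asarray(x, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.nanmax(x) == np.nanmin(x):
        return np.zeros(x.size, dtype=np.int64)
    ranks = np.empty(x.size, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(x.size)
    return ranks * bins // x.size


def mutual_information(x: Sequence[float], y: Sequence[float], bins: int = DEFAULT_BINS) -> float:
    """Plug-in MI estimate in nats over an equal-frequency 2-D histogram.

    Symmetric and non-negative; zero for any constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < bins:
        raise ValueError("need at least `bins` observations")
    if np.max(x) == np.min(x) or np.max(y) == np.min(y):
        return 0.0
    bx = equal_frequency_bins(x, bins)
    by = equal_frequency_bins(y, bins)
    # canonical argument order makes symmetry exact, not just approximate
    if bx.tobytes() > by.tobytes():
        bx, by = by, bx
    return _mi_from_bins(bx, by, bins)


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    joint = np.bincount(bx * bins + by, minlength=bins * bins).reshape(bins, bins)
    joint = joint / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())


def mi_matrix(series: pd.DataFrame, bins: int = DEFAULT_BINS) -> pd.DataFrame:
    """All-pairs MI over the rows (genes) of a profile series."""
    genes = list(series.index)
    values = series.to_numpy(dtype=float)
    if values.shape[1] < max(bins, 8):
        raise ValueError("profile series needs >= max(bins, 8) positions")
    if np.isnan(values).any():
        raise ValueError("profile series must not contain missing values")
    binned = np.vstack([equal_frequency_bins(row, bins) for row in values])
    constant = values.max(axis=1) == values.min(axis=1)
    n = len(genes)
    mi = np.zeros((n, n))
    for i in range(n):
        if constant[i]:
            continue
        for j in range(i + 1, n):
            if constant[j]:
                continue
            mi[i, j] = mi[j, i] = _mi_from_bins(binned[i], binned[j], bins)
    return pd.DataFrame(mi, index=genes, columns=genes)


def clr_scores(mi: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Context-likelihood-of-relatedness Z matrix from a symmetric MI matrix.

    z_i(j) = max(0, (MI_ij - mu_i) / sigma_i) with row statistics excluding
    the diagonal; clr_ij = sqrt(z_i(j)^2 + z_j(i)^2).  Rows with zero spread
    contribute zero.
    """
    values = mi.to_numpy() if isinstance(mi, pd.DataFrame) else np.asarray(mi, float)
    n = values.shape[0]
    if values.shape != (n, n) or n < 3:
        raise ValueError("MI matrix must be square with >= 3 genes")
    if not np.allclose(values, values.T):
        raise ValueError("MI matrix must be symmetric")
    off = ~np.eye(n, dtype=bool)
    mu = np.array([values[i, off[i]].mean() for i in range(n)])
    sigma = np.array([values[i, off[i]].std() for i in range(n)])
    z = np.zeros((n, n))
    ok = sigma > 0
    z[ok, :] = np.maximum(0.0, (values[ok, :] - mu[ok, None]) / sigma[ok, None])
    np.fill_diagonal(z, 0.0)
    clr = np.sqrt(z**2 + z.T**2)
    if isinstance(mi, pd.DataFrame):
        return pd.DataFrame(clr, index=mi.index, columns=mi.columns)
    return clr


@dataclass(frozen=True)
class CLRNetwork:
    genes: tuple[str, ...]
    guides: tuple[str, ...]
    edges: pd.DataFrame  # source, target, clr, sign, mi, r
    isolated_guides: tuple[str, ...]


def guide_network(
    series: pd.DataFrame,
    guides: Sequence[str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    bins: int = DEFAULT_BINS,
) -> CLRNetwork:
    """First-neighbor network of the guides at the given CLR threshold.

    Edges are undirected and unique, kept when clr >= z_threshold and at
    least one endpoint is a guide; the sign comes from the Pearson
    correlation of the two profiles.  Guides with no surviving edge are
    reported as isolated.
    """
    unknown = sorted(set(guides) - set(series.index))
    if unknown:
        raise ValueError(f"unknown guide ids: {unknown}")
    mi = mi_matrix(series, bins)
    clr = clr_scores(mi)
    corr = np.corrcoef(series.to_numpy(dtype=float))
    genes = list(series.index)
    guide_set = set(guides)
    rows = []
    for i, gi in enumerate(genes):
        for j in range(i + 1, len(genes)):
            gj = genes[j]
            if gi not in guide_set and gj not in guide_set:
                continue
            z = float(clr.iat[i, j])
            if z < z_threshold:
                continue
            r = float(corr[i, j])
            rows.append(
                {
                    "source": gi,
                    "target": gj,
                    "clr": z,
                    "sign": "+" if r >= 0 else "-",
                    "mi": float(mi.iat[i, j]),
                    "r": r,
                }
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "clr", "sign", "mi", "r"])
    touched = set(edges["source"]) | set(edges["target"])
    isolated = tuple(g for g in guides if g not in touched)
    return CLRNetwork(
        genes=tuple(genes),
        guides=tuple(guides),
        edges=edges,
        isolated_guides=isolated,
    )


def to_networkx(net: CLRNetwork) -> nx.Graph:
    G = nx.Graph()
    nodes = set(net.guides)
    nodes |= set(net.edges["source"]) | set(net.edges["target"])
    for node in sorted(nodes):
        G.add_node(node, is_guide=bool(node in net.guides))
    for row in net.edges.itertuples():
        G.add_edge(
            row.source,
            row.target,
            clr=float(row.clr),
            sign=row.sign,
            mi=float(row.mi),
            r=float(row.r),
        )
    return G


def export_graphml(net: CLRNetwork, path) -> None:
    """Write the network as GraphML readable by standard graph tools."""
    try:
        nx.write_graphml(to_networkx(net), str(path))
    except OSError as exc:  # pragma: no cover - io failure path
        raise OSError(f"failed to write GraphML to {path}: {exc}") from exc
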