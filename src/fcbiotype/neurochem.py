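"""Node-abnormality scoring and neurotransmitter-map correlation.

A contrast's signed suprathreshold matrices are summed along the ROI
dimension into per-node degree vectors (counts of abnormally increased
or decreased edges per region). Each degree vector is then spatially
correlated with a battery of parcellated receptor/transporter density
maps; p-values come from the exact t transform and are adjusted by
Benjamini-Hochberg FDR across the whole (contrast x direction x map)
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DimensionError, FormatError
from .maps import MapTable


@dataclass
class NodeAbnormality:
    """Per-ROI counts of suprathreshold increased / decreased edges."""

    contrast: str
    pos_degree: np.ndarray
    neg_degree: np.ndarray


def node_abnormality(threshold_map) -> NodeAbnormality:
    """Row-sum the signed binary matrices into degree vectors.

    The handshake identity holds by construction: the degree vector
    sums to twice the suprathreshold edge count.
    """
    for m in (threshold_map.pos_matrix, threshold_map.neg_matrix):
        if not np.array_equal(m, m.T):
            raise FormatError("threshold matrices must be symmetric")
    return NodeAbnormality(
        contrast=threshold_map.contrast,
        pos_degree=threshold_map.pos_matrix.sum(axis=1).astype(int),
        neg_degree=threshold_map.neg_matrix.sum(axis=1).astype(int),
    )


def map_correlation(
    node_vec, maps: MapTable, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate one node vector with every map.

    Returns a DataFrame with columns map, r, p, flagged. A constant
    node vector (e.g. an empty abnormality map) cannot be correlated:
    every row is flagged and carries NaN, and flagged rows are excluded
    from any downstream FDR family.
    """
    v = np.asarray(node_vec, dtype=float)
    if v.ndim != 1 or v.size != maps.P:
        raise DimensionError(f"node vector length {v.size} != atlas P {maps.P}")
    rows = []
    constant = v.std() == 0
    for name in maps.map_names:
        m = maps.vector(name)
        if constant or m.std() == 0:
            rows.append((name, np.nan, np.nan, True))
            continue
        if method == "spearman":
            r, p = stats.spearmanr(v, m)
        elif method == "pearson":
            r, p = stats.pearsonr(v, m)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((name, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["map", "r", "p", "flagged"])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q(i) = min_{j >= i} (m * p_(j) / j) on the sorted p-values, mapped
    back to the input order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni-adjusted p-values (alternative correction)."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(p * p.size, 1.0)


def neuro_corr_table(
    abnormalities: list[NodeAbnormality],
    maps: MapTable,
    method: str = "pearson",
    correction: str = "bh",
) -> pd.DataFrame:
    """Full correlation table over (contrast, direction, map) cells.

    The FDR family is the entire table (all contrasts and directions in
    one adjustment); flagged degenerate rows are excluded from the
    family and carry NaN q.
    """
    frames = []
    for ab in abnormalities:
        for direction, vec in (("increase", ab.pos_degree), ("decrease", ab.neg_degree)):
            tab = map_correlation(vec, maps, method=method)
            tab.insert(0, "direction", direction)
            tab.insert(0, "contrast", ab.contrast)
            frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    ok = ~table["flagged"]
    q = np.full(len(table), np.nan)
    if ok.any():
        adjust = bh_fdr if correction == "bh" else bonferroni
        if correction not in ("bh", "bonferroni"):
            raise ValueError(f"unknown correction {correction!r}")
        q[ok.to_numpy()] = adjust(table.loc[ok, "p"].to_numpy())
    table["q"] = q
    return table
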