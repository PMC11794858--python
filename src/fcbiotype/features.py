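"""Symptom-correlated edge selection.

Every connectivity edge is correlated with every clinical item within
the patient group; an edge is retained when it is significantly
associated (two-sided p below ``alpha``) with at least ``min_items``
items. No multiplicity correction is applied at this stage — selection
is a screening step, and its stability is assessed downstream by
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DimensionError


@dataclass
class SelectionResult:
    """Edge-item correlation screen and the resulting edge set."""

    r_matrix: np.ndarray        # edges x items
    p_matrix: np.ndarray        # edges x items
    sig_count: np.ndarray       # per edge: items with p < alpha
    selected_edges: np.ndarray  # edge ids with sig_count >= min_items
    per_item_totals: np.ndarray # per item: significant edge count
    alpha: float
    min_items: int
    n_degenerate: int = 0       # zero-variance edge/item pairs (p forced to 1)

    @property
    def n_selected(self) -> int:
        return self.selected_edges.size


def edge_item_correlations(edges, items, method: str = "pearson"):
    """Correlate every edge with every clinical item.

    Parameters
    ----------
    edges : array-like, shape (n_subjects, n_edges)
    items : array-like, shape (n_subjects, n_items)
    method : {"pearson", "spearman"}
        Spearman ranks both sides first, then applies the same t
        transform.

    Returns
    -------
    r, p : ndarray, shape (n_edges, n_items)
        Correlations and two-sided p-values from the exact t transform
        ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    n_degenerate : int
        Count of zero-variance pairs, for which r = 0 and p = 1.
    """
    X = np.asarray(edges, dtype=float)
    Y = np.asarray(items, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise DimensionError(
            f"edges have {X.shape[0]} subjects but items have {Y.shape[0]}"
        )
    n = X.shape[0]
    if n < 4:
        raise DimensionError(f"need at least 4 subjects for the t transform, got {n}")
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
        Y = stats.rankdata(Y, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    bad_x = sx == 0
    bad_y = sy == 0
    sx[bad_x] = 1.0
    sy[bad_y] = 1.0
    r = (Xc / sx).T @ (Yc / sy)
    np.clip(r, -1.0, 1.0, out=r)

    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = bad_x[:, None] | bad_y[None, :]
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        r[degenerate] = 0.0
        p[degenerate] = 1.0
    return r, p, n_degenerate


def select_features(
    r_matrix: np.ndarray,
    p_matrix: np.ndarray,
    alpha: float = 0.005,
    min_items: int = 3,
    n_degenerate: int = 0,
) -> SelectionResult:
    """Threshold the correlation screen into a selected edge set."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    n_items = p_matrix.shape[1]
    if not 1 <= min_items <= n_items:
        raise ValueError(f"min_items must be in 1..{n_items}, got {min_items}")
    sig = p_matrix < alpha
    sig_count = sig.sum(axis=1)
    selected = np.flatnonzero(sig_count >= min_items)
    per_item = sig.sum(axis=0)
    return SelectionResult(
        r_matrix=r_matrix,
        p_matrix=p_matrix,
        sig_count=sig_count,
        selected_edges=selected,
        per_item_totals=per_item,
        alpha=alpha,
        min_items=min_items,
        n_degenerate=n_degenerate,
    )


def screen_and_select(
    edges,
    items,
    alpha: float = 0.005,
    min_items: int = 3,
    method: str = "pearson",
) -> SelectionResult:
    """Convenience wrapper: correlations followed by thresholding."""
    r, p, n_deg = edge_item_correlations(edges, items, method=method)
    return select_features(r, p, alpha=alpha, min_items=min_items, n_degenerate=n_deg)
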