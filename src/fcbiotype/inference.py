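"""Edgewise group contrasts with covariate adjustment and network-block FDR.

Each biotype is contrasted against healthy controls with a per-edge
linear model ``z ~ group + sex + age + education``. Suprathreshold edges
(uncorrected p < 0.005) are binarized by sign, then aggregated into
network-pair blocks whose cluster mass (sum of |t| over suprathreshold
edges) is tested by permutation of group labels and corrected across
blocks by Benjamini-Hochberg FDR. The permutation cluster-mass test is
an explicit, transparent analog of cluster-based parametric multivariate
correction and is labeled as such in reports.

Summary-statistic tests (pooled t, Pearson chi-square, one-way ANOVA
from group means/dispersions) reproduce demographic-table columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas
from .connectome import devectorize
from .errors import DimensionError, FormatError
from .neurochem import bh_fdr


# ---------------------------------------------------------------------
# edgewise GLM
# ---------------------------------------------------------------------

@dataclass
class EdgewiseStats:
    contrast: str
    effect: np.ndarray   # adjusted group mean difference per edge
    t: np.ndarray
    p: np.ndarray
    df: int
    covariates: tuple = ()


def _design_matrix(group: np.ndarray, covars: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(group, dtype=float), group.astype(float)]
    names = ["intercept", "group"]
    if covars is not None and len(covars.columns):
        for c in covars.columns:
            v = covars[c].to_numpy(dtype=float)
            cols.append(v - v.mean())  # centering affects the intercept only
            names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FormatError(f"rank-deficient design; check covariates {names[2:]}")
    return X


def edgewise_glm(
    edges,
    group: np.ndarray,
    covars: pd.DataFrame | None = None,
    contrast: str = "group",
) -> EdgewiseStats:
    """Per-edge linear model; t and two-sided p for the group coefficient.

    ``group`` is a binary indicator (1 = patient group, 0 = controls).
    With no covariates the t equals the pooled two-sample t exactly.
    """
    Y = np.asarray(edges, dtype=float)
    group = np.asarray(group, dtype=float)
    if Y.shape[0] != group.size:
        raise DimensionError(
            f"edges have {Y.shape[0]} rows but group has {group.size} entries"
        )
    if group.min() == group.max():
        raise FormatError("both groups must be nonempty")
    X = _design_matrix(group, covars)
    n, k = X.shape
    df = n - k
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)              # k x E
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
    t = B[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    covnames = tuple(covars.columns) if covars is not None else ()
    return EdgewiseStats(contrast=contrast, effect=B[1], t=t, p=p, df=df, covariates=covnames)


# ---------------------------------------------------------------------
# signed thresholding
# ---------------------------------------------------------------------

@dataclass
class SignedThresholdMap:
    contrast: str
    pos_matrix: np.ndarray   # P x P binary, symmetric, zero diagonal
    neg_matrix: np.ndarray
    alpha_edge: float

    def __post_init__(self) -> None:
        for m in (self.pos_matrix, self.neg_matrix):
            if not np.array_equal(m, m.T):
                raise FormatError("threshold maps must be symmetric")
        if np.any(self.pos_matrix & self.neg_matrix):
            raise FormatError("an edge cannot be both increased and decreased")


def threshold_signed(
    stats_: EdgewiseStats, P: int, alpha_edge: float = 0.005
) -> SignedThresholdMap:
    """Binarize edgewise statistics at the uncorrected edge threshold,
    separately for increases (t > 0) and decreases (t < 0)."""
    pos = ((stats_.p < alpha_edge) & (stats_.t > 0)).astype(np.uint8)
    neg = ((stats_.p < alpha_edge) & (stats_.t < 0)).astype(np.uint8)
    return SignedThresholdMap(
        contrast=stats_.contrast,
        pos_matrix=devectorize(pos, P),
        neg_matrix=devectorize(neg, P),
        alpha_edge=alpha_edge,
    )


# ---------------------------------------------------------------------
# network-pair cluster-mass permutation test with BH-FDR
# ---------------------------------------------------------------------

def _block_ids(atlas: Atlas) -> tuple[np.ndarray, list]:
    """Per-edge block index over unordered network pairs (36 blocks for
    8 networks), plus the block label list."""
    na, nb = atlas.edge_networks()
    pairs = [tuple(sorted(p)) for p in zip(na, nb)]
    labels = sorted(set(pairs))
    lookup = {p: i for i, p in enumerate(labels)}
    return np.array([lookup[p] for p in pairs]), labels


def _block_mass(t, p, block_idx, n_blocks, alpha_edge):
    supra = p < alpha_edge
    mass = np.bincount(block_idx[supra], weights=np.abs(t[supra]), minlength=n_blocks)
    count = np.bincount(block_idx[supra], minlength=n_blocks)
    return mass, count


def network_cluster_fdr(
    edges,
    group: np.ndarray,
    atlas: Atlas,
    covars: pd.DataFrame | None = None,
    alpha_edge: float = 0.005,
    q: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    contrast: str = "group",
) -> pd.DataFrame:
    """Cluster-mass permutation test over network-pair blocks.

    Block statistic: sum of |t| over suprathreshold edges in the block.
    The null re-permutes group labels (covariates fixed), recomputes the
    edgewise model and block masses; the block p-value is
    ``(1 + #{perm >= observed}) / (n_perm + 1)`` and BH-FDR is applied
    across all blocks. Returns one row per network-pair block.
    """
    Y = np.asarray(edges, dtype=float)
    group = np.asarray(group)
    block_idx, labels = _block_ids(atlas)
    n_blocks = len(labels)
    obs = edgewise_glm(Y, group, covars, contrast=contrast)
    mass_obs, count_obs = _block_mass(obs.t, obs.p, block_idx, n_blocks, alpha_edge)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_blocks)
    g = group.astype(float).copy()
    for _ in range(n_perm):
        gp = rng.permutation(g)
        perm = edgewise_glm(Y, gp, covars, contrast=contrast)
        mass_p, _ = _block_mass(perm.t, perm.p, block_idx, n_blocks, alpha_edge)
        exceed += mass_p >= mass_obs
    p_block = (1.0 + exceed) / (n_perm + 1.0)
    q_block = bh_fdr(p_block)
    return pd.DataFrame(
        {
            "contrast": contrast,
            "network_a": [a for a, _ in labels],
            "network_b": [b for _, b in labels],
            "n_suprathreshold": count_obs.astype(int),
            "cluster_mass": mass_obs,
            "p": p_block,
            "q": q_block,
            "significant": (q_block < q) & (count_obs > 0),
        }
    )


# ---------------------------------------------------------------------
# summary-statistic tests (demographic-table columns)
# ---------------------------------------------------------------------

def pooled_t_from_summary(m1, sd1, n1, m2, sd2, n2) -> tuple[float, int]:
    """Pooled-variance two-sample t from group summaries; df = n1+n2-2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def chi2_contingency(table) -> tuple[float, int]:
    """Pearson chi-square without continuity correction; df = (R-1)(C-1)."""
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, int(df)


def anova_from_summary(
    means, dispersions, ns, dispersion_kind: str = "sd"
) -> tuple[float, int, int]:
    """One-way ANOVA F from per-group summaries.

    ``dispersion_kind`` selects whether the dispersion column holds
    standard deviations or standard errors (converted via sd = se*sqrt(n)).
    """
    means = np.asarray(means, dtype=float)
    disp = np.asarray(dispersions, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 groups")
    if dispersion_kind == "se":
        sds = disp * np.sqrt(ns)
    elif dispersion_kind == "sd":
        sds = disp
    else:
        raise ValueError(f"dispersion_kind must be 'sd' or 'se', got {dispersion_kind!r}")
    grand = float(np.sum(ns * means) / ns.sum())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df1 = means.size - 1
    df2 = int(ns.sum()) - means.size
    F = (ssb / df1) / (ssw / df2)
    return float(F), int(df1), int(df2)
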