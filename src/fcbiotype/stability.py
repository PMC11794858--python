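"""Resampling validation: cluster-number stability, NMI, and SVM accuracy.

The harness reruns the whole selection + clustering chain on random 90%
subsamples of the patients, logs the estimated cluster number and labels
per iteration, and quantifies how well the final full-sample partition
is reproduced — against a label-shuffling null — with normalized mutual
information. Classifier reproducibility uses a linear one-vs-one SVM
under repeated stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import screen_and_select
from .simlr import (
    build_kernels,
    cluster,
    estimate_k,
    initial_similarity,
    learn_similarity,
    standardize,
)


# ---------------------------------------------------------------------
# normalized mutual information
# ---------------------------------------------------------------------

def nmi(labels_a, labels_b) -> float:
    """NMI with sqrt normalization: I(A;B) / sqrt(H(A) H(B)).

    Computed from the joint contingency table with natural logarithms.
    Conventions for degenerate partitions: if both are single-class the
    partitions are identical up to relabeling (1.0); if exactly one is
    single-class its entropy is zero and the NMI is defined as 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 subjects")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = a.size
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    # identical up to relabeling <=> one nonzero per row and per column
    if (
        cont.shape[0] == cont.shape[1]
        and np.all((cont > 0).sum(axis=0) == 1)
        and np.all((cont > 0).sum(axis=1) == 1)
    ):
        return 1.0
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    ha = -np.sum(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi)))
    hb = -np.sum(pj * np.log(pj, where=pj > 0, out=np.zeros_like(pj)))
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    outer = pi[:, None] * pj[None, :]
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / outer[nz])))
    val = mi / np.sqrt(ha * hb)
    return float(min(max(val, 0.0), 1.0))


def nmi_null(final_labels, iteration_labels, n_perm: int = 500, seed: int | None = 0):
    """Null NMI distribution: shuffle one labeling, recompute NMI."""
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    other = np.asarray(iteration_labels).copy()
    out = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(other)
        out[i] = nmi(final_labels, other)
    return out


# ---------------------------------------------------------------------
# subsampling loop
# ---------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    subject_idx: np.ndarray
    n_features: int
    estimated_k: int | None
    labels: np.ndarray | None
    skipped: bool = False


@dataclass
class ResampleLog:
    records: list
    n_iter: int
    subsample_frac: float
    seed: int

    def k_counts(self) -> dict:
        counts: dict = {}
        for rec in self.records:
            key = "skipped" if rec.skipped else rec.estimated_k
            counts[key] = counts.get(key, 0) + 1
        return counts

    def modal_k(self) -> tuple[int, int]:
        """(most frequent estimated k, its count) over non-skipped iterations."""
        counts = {k: v for k, v in self.k_counts().items() if k != "skipped"}
        if not counts:
            raise ValueError("all iterations were skipped")
        k = max(sorted(counts), key=lambda x: counts[x])
        return k, counts[k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "n_subjects": [r.subject_idx.size for r in self.records],
                "n_features": [r.n_features for r in self.records],
                "estimated_k": [r.estimated_k for r in self.records],
                "skipped": [r.skipped for r in self.records],
            }
        )


def subsample_loop(
    edges,
    items,
    n_iter: int = 500,
    subsample_frac: float = 0.9,
    alpha: float = 0.005,
    min_items: int = 3,
    k_range=range(2, 9),
    seed: int = 0,
    learn_kwargs: dict | None = None,
) -> ResampleLog:
    """Rerun selection + clustering on random patient subsamples.

    Each iteration draws ``round(frac * N)`` patients without
    replacement, reruns the edge-item screen on that subset, estimates
    the cluster number by eigengap on the initial row-stochastic
    similarity over the selected features, learns the similarity at
    that k and clusters.
    Per-iteration RNG substreams make the log reproducible and
    insensitive to iteration order.
    """
    X = np.asarray(edges, dtype=float)
    Y = np.asarray(items, dtype=float)
    N = X.shape[0]
    size = int(round(subsample_frac * N))
    if not 2 < size <= N:
        raise ValueError(f"subsample size {size} invalid for N={N}")
    learn_kwargs = learn_kwargs or {}
    children = np.random.SeedSequence(seed).spawn(n_iter)
    records = []
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = np.sort(rng.choice(N, size=size, replace=False))
        sel = screen_and_select(X[idx], Y[idx], alpha=alpha, min_items=min_items)
        if sel.n_selected == 0:
            records.append(IterationRecord(it, idx, 0, None, None, skipped=True))
            continue
        Xs = standardize(X[idx][:, sel.selected_edges])
        bank = build_kernels(Xs)
        k_hat = estimate_k(initial_similarity(bank), k_range=k_range)
        learned = learn_similarity(bank, C=k_hat, **learn_kwargs)
        sol = cluster(learned, k=k_hat, seed=int(rng.integers(2**31 - 1)))
        records.append(
            IterationRecord(it, idx, sel.n_selected, k_hat, sol.labels)
        )
    return ResampleLog(records, n_iter=n_iter, subsample_frac=subsample_frac, seed=seed)


def nmi_against_final(final_labels, log: ResampleLog) -> np.ndarray:
    """NMI of the final partition vs each iteration's labels on the
    shared (subsampled) subjects."""
    final_labels = np.asarray(final_labels)
    vals = []
    for rec in log.records:
        if rec.skipped:
            continue
        vals.append(nmi(final_labels[rec.subject_idx], rec.labels))
    return np.asarray(vals)


def nmi_pairwise(log: ResampleLog, max_pairs: int = 1000, seed: int = 0) -> np.ndarray:
    """Alternative stability reading: NMI between random iteration pairs
    on their overlapping subjects."""
    recs = [r for r in log.records if not r.skipped]
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(min(max_pairs, len(recs) * (len(recs) - 1) // 2)):
        i, j = rng.choice(len(recs), size=2, replace=False)
        ri, rj = recs[i], recs[j]
        common, ia, ja = np.intersect1d(ri.subject_idx, rj.subject_idx, return_indices=True)
        if common.size < 2:
            continue
        vals.append(nmi(ri.labels[ia], rj.labels[ja]))
    return np.asarray(vals)


# ---------------------------------------------------------------------
# SVM reproducibility
# ---------------------------------------------------------------------

@dataclass
class SVMReport:
    """Accuracies in percent, averaged over folds and repetitions."""

    train_acc: float
    test_acc: float
    per_class_train: dict = field(default_factory=dict)
    per_class_test: dict = field(default_factory=dict)
    folds: int = 10
    reps: int = 0


def svm_reproducibility(
    X,
    labels,
    folds: int = 10,
    reps: int = 500,
    seed: int = 0,
    C: float = 1.0,
) -> SVMReport:
    """Linear one-vs-one SVM under repeated stratified cross-validation.

    Reports mean train and test accuracy, overall and per class, over
    ``reps`` re-randomized stratified ``folds``-fold splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; "
            "reduce the fold count"
        )
    rng = np.random.default_rng(seed)
    tr_acc, te_acc = [], []
    tr_cls = {c: [] for c in classes}
    te_cls = {c: [] for c in classes}
    for _ in range(reps):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for tr, te in skf.split(X, y):
            clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
            clf.fit(X[tr], y[tr])
            p_tr, p_te = clf.predict(X[tr]), clf.predict(X[te])
            tr_acc.append(np.mean(p_tr == y[tr]))
            te_acc.append(np.mean(p_te == y[te]))
            for c in classes:
                m_tr, m_te = y[tr] == c, y[te] == c
                if m_tr.any():
                    tr_cls[c].append(np.mean(p_tr[m_tr] == c))
                if m_te.any():
                    te_cls[c].append(np.mean(p_te[m_te] == c))
    return SVMReport(
        train_acc=100.0 * float(np.mean(tr_acc)),
        test_acc=100.0 * float(np.mean(te_acc)),
        per_class_train={int(c): 100.0 * float(np.mean(v)) for c, v in tr_cls.items()},
        per_class_test={int(c): 100.0 * float(np.mean(v)) for c, v in te_cls.items()},
        folds=folds,
        reps=reps,
    )
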