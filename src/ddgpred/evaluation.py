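"""Evaluation: Pearson r, RMSE, MAE; the direct/reverse symmetry protocol;
cluster-aware cross-validation folds.

A good stability predictor should assign the reverse mutation the same
magnitude of ddG with the opposite sign.  ``evaluate_symmetric`` makes that
measurable: every direct test pair is mirrored (sequences swapped, target
negated) and the usual metrics are reported for both sides, mirroring the
``r_dir``/``r_rev`` presentation used across the benchmark literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import VariantPair


class ConstantInputWarning(UserWarning):
    """Pearson r is undefined when either vector is constant."""


def metrics(predictions, targets) -> tuple[float, float, float]:
    """Pearson r, RMSE and MAE between two equal-length vectors.

    r is reported as NaN with a :class:`ConstantInputWarning` when either
    side is constant — a silent 0 would corrupt model comparisons.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.size < 2:
        raise ValueError("need at least two points")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    mae = float(np.mean(np.abs(p - t)))
    if np.ptp(p) == 0.0 or np.ptp(t) == 0.0:
        warnings.warn("correlation undefined for constant input",
                      ConstantInputWarning, stacklevel=2)
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, t).statistic)
    return r, rmse, mae


@dataclass
class EvalResult:
    """Paired direct/reverse metrics."""

    r_dir: float
    r_rev: float
    rmse_dir: float
    rmse_rev: float
    mae_dir: float
    mae_rev: float
    n_dir: int
    n_rev: int

    def to_dict(self) -> dict:
        return {"r_dir": self.r_dir, "r_rev": self.r_rev,
                "RMSE_dir": self.rmse_dir, "RMSE_rev": self.rmse_rev,
                "MAE_dir": self.mae_dir, "MAE_rev": self.mae_rev,
                "n_dir": self.n_dir, "n_rev": self.n_rev}


def reverse_set(pairs: list[VariantPair]) -> list[VariantPair]:
    """Mirror a test set: swap sequences, negate targets.  An involution."""
    return [p.reversed() for p in pairs]


def evaluate_symmetric(model, direct_pairs: list[VariantPair]) -> EvalResult:
    """Evaluate a model on a direct test set and its mirrored counterpart."""
    targets_dir = np.array([p.ddg for p in direct_pairs], dtype=float)
    if np.isnan(targets_dir).any():
        raise ValueError("every test pair needs a ddg target")
    reversed_pairs = reverse_set(direct_pairs)
    targets_rev = np.array([p.ddg for p in reversed_pairs], dtype=float)
    pred_dir = np.asarray(model.predict(direct_pairs), dtype=float)
    pred_rev = np.asarray(model.predict(reversed_pairs), dtype=float)
    r_d, rmse_d, mae_d = metrics(pred_dir, targets_dir)
    r_r, rmse_r, mae_r = metrics(pred_rev, targets_rev)
    return EvalResult(r_dir=r_d, r_rev=r_r, rmse_dir=rmse_d, rmse_rev=rmse_r,
                      mae_dir=mae_d, mae_rev=mae_r,
                      n_dir=len(direct_pairs), n_rev=len(reversed_pairs))


class AntisymmetrizedModel:
    """Wrap any model as m'(wt, mt) = (m(wt, mt) - m(mt, wt)) / 2.

    The wrapped model is exactly antisymmetric, so its direct and reverse
    metrics coincide — a useful oracle for the symmetry protocol.
    """

    def __init__(self, base) -> None:
        self.base = base

    def predict(self, pairs) -> np.ndarray:
        pairs = list(pairs)
        fwd = np.asarray(self.base.predict(pairs), dtype=float)
        rev = np.asarray(self.base.predict([p.reversed() for p in pairs]), dtype=float)
        return (fwd - rev) / 2.0


# ---------------------------------------------------------------------------
# Cluster-aware cross-validation


@dataclass
class FoldAssignment:
    """Cluster -> fold mapping; a cluster is never split across folds."""

    k: int
    cluster_of: dict  # sequence name -> cluster index
    fold_of_cluster: dict  # cluster index -> fold index

    def fold_of(self, name: str) -> int:
        return self.fold_of_cluster[self.cluster_of[name]]


def _single_linkage_clusters(names: list[str], edges: set[tuple[str, str]]
                             ) -> dict[str, int]:
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots: dict[str, int] = {}
    out = {}
    for n in names:
        r = find(n)
        out[n] = roots.setdefault(r, len(roots))
    return out


def make_cluster_folds(sequences: dict[str, str], k: int, identity_backend,
                       seed: int = 0, weights: dict | None = None,
                       identity_threshold: float = 30.0,
                       evalue_threshold: float = 0.05) -> FoldAssignment:
    """Assign single-linkage sequence clusters to k folds.

    Two sequences join a cluster when the backend reports identity above the
    threshold with a significant E-value; clusters are then dealt greedily,
    heaviest first, to the currently lightest fold (weight = record count
    when ``weights`` is given, else sequence count).  Deterministic under
    ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    names = sorted(sequences)
    hits = identity_backend.search(sequences, sequences)
    edges = {(h.query, h.target) for h in hits
             if h.query != h.target
             and h.identity > identity_threshold and h.evalue < evalue_threshold}
    cluster_of = _single_linkage_clusters(names, edges)
    n_clusters = len(set(cluster_of.values()))
    if n_clusters < k:
        raise ValueError(f"only {n_clusters} clusters for {k} folds")

    weight_of_cluster: dict[int, float] = {}
    for name, c in cluster_of.items():
        w = weights.get(name, 1.0) if weights else 1.0
        weight_of_cluster[c] = weight_of_cluster.get(c, 0.0) + w

    rng = np.random.default_rng(seed)
    clusters = list(weight_of_cluster)
    rng.shuffle(clusters)
    clusters.sort(key=lambda c: -weight_of_cluster[c])  # stable: shuffle breaks ties

    fold_weight = [0.0] * k
    fold_of_cluster: dict[int, int] = {}
    for c in clusters:
        fold = int(np.argmin(fold_weight))
        fold_of_cluster[c] = fold
        fold_weight[fold] += weight_of_cluster[c]
    return FoldAssignment(k=k, cluster_of=cluster_of, fold_of_cluster=fold_of_cluster)
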