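"""Stability-selected non-negative matrix factorization of RDM ensembles.

Subject RDMs are stacked as a nonnegative matrix ``D`` (subjects x item
pairs, each row the SD-normalized upper-triangle vector) and decomposed as
``D ~ W x H`` with nonnegative mixing weights ``W`` and latent similarity
components ``H`` under the squared Frobenius objective.

Because NMF solutions depend on the random start, the pipeline does not
trust any single fit:

* the rank ``k`` is chosen by *subject generality* — across restarts, the
  largest ``k`` at which every component receives the maximal mixing weight
  of at least ``min_subjects`` subjects;
* the components of many restarts are pooled and clustered agglomeratively
  under the distance ``1 - |Pearson r|``; clusters recurring in a large
  fraction of restarts are kept and averaged into centroids;
* the mixing weights are then refit per subject against the frozen
  centroids by nonnegative least squares.

Components are interpreted by Spearman rank correlation against binary
model RDMs (verb / agent / patient category and friends).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .rdm import RDM, n_pairs, triu_pairs

__all__ = [
    "RDMEnsemble",
    "ComponentSet",
    "ClusterSolution",
    "build_ensemble",
    "nmf_fit",
    "select_k",
    "stability_cluster",
    "refit_mixing",
    "variance_explained",
    "component_model_correlation",
]


@dataclasses.dataclass
class RDMEnsemble:
    """Subjects x pairs data matrix with its item/pair bookkeeping."""

    D: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("ensemble matrix must be 2-D (subjects x pairs)")
        if self.D.shape[1] != n_pairs(len(self.labels)):
            raise ValueError(
                f"{self.D.shape[1]} pair columns do not match "
                f"{len(self.labels)} item labels"
            )
        if np.any(self.D < 0):
            raise ValueError("ensemble entries must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.D.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.D.shape[1]

    def pair_labels(self) -> list[tuple[str, str]]:
        i, j = triu_pairs(len(self.labels))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]


@dataclasses.dataclass
class ComponentSet:
    """One NMF solution: components H (k x pairs), mixing weights W, fit."""

    W: np.ndarray
    H: np.ndarray
    k: int
    fit: float  # residual squared Frobenius norm ||D - WH||_F^2
    converged: bool = True


@dataclasses.dataclass
class ClusterSolution:
    """Pooled components, their cluster assignment and retained centroids."""

    members: np.ndarray  # (n_restarts * k, n_pairs), unit-norm rows
    restart_ids: np.ndarray  # provenance of every pooled component
    assignment: np.ndarray  # cluster id per pooled component
    reliability: dict[int, int]  # cluster id -> distinct restarts contributing
    retained: list[int]  # cluster ids passing the reliability bar
    centroids: np.ndarray  # (n_retained, n_pairs), unit Euclidean norm
    n_restarts: int
    threshold: float


def build_ensemble(rdms: Sequence[RDM], normalize: bool = True) -> RDMEnsemble:
    """Stack subject RDMs into the subjects x pairs matrix.

    Each row is the row-major upper-triangle vector of one subject's RDM,
    divided by its standard deviation (unless ``normalize=False``) so that
    every subject contributes at the same scale.
    """
    if not rdms:
        raise ValueError("need at least one subject RDM")
    labels = rdms[0].labels
    rows = []
    for s, r in enumerate(rdms):
        if r.labels != labels:
            raise ValueError(f"subject {s} has mismatched item labels")
        v = r.utv
        if normalize:
            sdev = float(np.std(v))
            if sdev <= 0:
                raise ValueError(f"subject {s} has a constant RDM (zero SD)")
            v = v / sdev
        rows.append(v)
    return RDMEnsemble(np.vstack(rows), list(labels))


def _as_matrix(D) -> np.ndarray:
    return D.D if isinstance(D, RDMEnsemble) else np.asarray(D, dtype=float)


def nmf_fit(
    D: RDMEnsemble | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ComponentSet:
    """One NMF decomposition from a seeded random start.

    Coordinate descent on the squared Frobenius objective (the objective is
    non-increasing over iterations).  If the solver hits ``max_iter``
    without converging the best iterate is returned and the
    :class:`ComponentSet` is flagged ``converged=False``.
    """
    X = _as_matrix(D)
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k={k} outside 1..min(n_subjects, n_pairs)={min(X.shape)}")
    model = NMF(
        n_components=k,
        init="random",
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        W = model.fit_transform(X)
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = False
    H = model.components_
    fit = float(np.linalg.norm(X - W @ H) ** 2)
    return ComponentSet(W=W, H=H, k=k, fit=fit, converged=converged)


def _restart_seeds(seed: int, n_restarts: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)


def select_k(
    D: RDMEnsemble | np.ndarray,
    k_range: Sequence[int] = range(2, 20),
    n_restarts: int = 20,
    min_subjects: int = 2,
    seed: int = 0,
    return_details: bool = False,
    scan_max_iter: int = 500,
    scan_tol: float = 1e-4,
):
    """Choose the component count by subject generality across restarts.

    For each restart and each candidate ``k``, a component is *general* if
    it receives the maximal mixing weight for at least ``min_subjects``
    subjects.  The restart's best ``k`` is the largest candidate at which
    all ``k`` components are general (1 if none qualifies, i.e. the data
    behave as a single shared pattern).  The final ``k*`` is the rounded
    mean over restarts.

    The scan reads only which component dominates each subject, which
    stabilizes long before the objective converges, so scan fits run at a
    coarser tolerance (``scan_max_iter``, ``scan_tol``) than final fits.
    """
    X = _as_matrix(D)
    seeds = _restart_seeds(seed, n_restarts)
    per_restart = np.ones(n_restarts, dtype=int)
    for r in range(n_restarts):
        best = 1
        for k in k_range:
            if k > min(X.shape):
                break
            comp = nmf_fit(X, k, seed=int(seeds[r]), max_iter=scan_max_iter, tol=scan_tol)
            dominant = np.argmax(comp.W, axis=1)
            counts = np.bincount(dominant, minlength=k)
            if np.all(counts >= min_subjects):
                best = max(best, k)
        per_restart[r] = best
    k_star = int(np.rint(per_restart.mean()))
    if return_details:
        return k_star, per_restart
    return k_star


def stability_cluster(
    D: RDMEnsemble | np.ndarray,
    k: int,
    n_restarts: int = 1000,
    threshold: float = 0.85,
    reliability_fraction: float = 0.72,
    seed: int = 0,
) -> ClusterSolution:
    """Cluster components pooled over many random-restart factorizations.

    All ``n_restarts x k`` component vectors (unit-normalized) are clustered
    agglomeratively (average linkage) under the distance ``1 - |Pearson r|``
    and the dendrogram is cut at ``threshold``.  Clusters whose members span
    at least ``reliability_fraction * n_restarts`` distinct restarts are
    retained; each retained cluster is summarized by the entrywise mean of
    its members, renormalized to unit Euclidean norm.  Centroids are ordered
    by reliability (descending).
    """
    X = _as_matrix(D)
    seeds = _restart_seeds(seed, n_restarts)
    pool = np.empty((n_restarts * k, X.shape[1]))
    restart_ids = np.repeat(np.arange(n_restarts), k)
    for r in range(n_restarts):
        comp = nmf_fit(X, k, seed=int(seeds[r]))
        H = comp.H.copy()
        norms = np.linalg.norm(H, axis=1)
        norms[norms == 0] = 1.0
        pool[r * k : (r + 1) * k] = H / norms[:, None]
    # 1 - |r| distance; rows are unit-norm but Pearson centres them anyway
    corr = np.corrcoef(pool)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(Z, t=threshold, criterion="distance")
    reliability: dict[int, int] = {}
    for cid in np.unique(assignment):
        members = assignment == cid
        reliability[int(cid)] = int(np.unique(restart_ids[members]).size)
    bar = reliability_fraction * n_restarts
    retained = sorted(
        (cid for cid, rel in reliability.items() if rel >= bar),
        key=lambda cid: (-reliability[cid], cid),
    )
    if not retained:
        raise ValueError(
            f"no component cluster recurred in >= {bar:.0f} of {n_restarts} "
            "restarts; consider lowering the threshold or revising k"
        )
    centroids = np.empty((len(retained), X.shape[1]))
    for row, cid in enumerate(retained):
        c = pool[assignment == cid].mean(axis=0)
        nrm = float(np.linalg.norm(c))
        centroids[row] = c / nrm if nrm > 0 else c
    return ClusterSolution(
        members=pool,
        restart_ids=restart_ids,
        assignment=assignment,
        reliability=reliability,
        retained=[int(c) for c in retained],
        centroids=centroids,
        n_restarts=n_restarts,
        threshold=threshold,
    )


def refit_mixing(D: RDMEnsemble | np.ndarray, H_fixed: np.ndarray) -> np.ndarray:
    """Per-subject nonnegative least-squares weights against frozen components.

    Minimizes ``||d_s - w_s H||^2`` with ``w_s >= 0`` for every subject row.
    Subjects whose residual norm stays above 95% of their data norm (no
    explainable variance) are reported in a warning.
    """
    X = _as_matrix(D)
    H = np.asarray(H_fixed, dtype=float)
    if H.ndim != 2 or H.shape[1] != X.shape[1]:
        raise ValueError("H_fixed must be (k, n_pairs) matching the ensemble")
    W = np.zeros((X.shape[0], H.shape[0]))
    unexplained = []
    for s in range(X.shape[0]):
        w, res = nnls(H.T, X[s])
        W[s] = w
        d_norm = float(np.linalg.norm(X[s]))
        if d_norm > 0 and res > 0.95 * d_norm:
            unexplained.append(s)
    if unexplained:
        warnings.warn(
            f"subjects {unexplained} are essentially unexplained by the "
            "fixed components (residual > 95% of data norm)",
            stacklevel=2,
        )
    return W


def variance_explained(
    D: RDMEnsemble | np.ndarray, W: np.ndarray, H: np.ndarray
) -> float:
    """Fraction of squared data norm captured: 1 - ||D - WH||^2 / ||D||^2."""
    X = _as_matrix(D)
    denom = float(np.linalg.norm(X) ** 2)
    if denom == 0:
        raise ValueError("empty or all-zero data matrix")
    resid = float(np.linalg.norm(X - np.asarray(W) @ np.asarray(H)) ** 2)
    return 1.0 - resid / denom


def component_model_correlation(component: np.ndarray, model: RDM) -> float:
    """Spearman rank correlation of a component with a model RDM.

    The model's upper-triangle vector is compared against the component
    (both rank-transformed, ties mid-ranked).  Returns NaN with a warning
    when either input has zero variance.
    """
    comp = np.asarray(component, dtype=float).ravel()
    mvec = model.utv if isinstance(model, RDM) else np.asarray(model, dtype=float).ravel()
    if comp.shape != mvec.shape:
        raise ValueError(
            f"component length {comp.size} does not match model pair count {mvec.size}"
        )
    if np.std(comp) == 0 or np.std(mvec) == 0:
        warnings.warn("zero-variance input; Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho, _p = spearmanr(comp, mvec)
    return float(rho)
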