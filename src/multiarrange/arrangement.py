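"""Adaptive multiple-arrangement engine.

Subjects (here: simulated raters, or recorded trial logs) repeatedly arrange
subsets of items inside a circular arena of radius 1; on-screen distance
expresses dissimilarity.  Each placement of a pair at distance ``dist``
contributes *evidence* ``(dist / sigma)**2`` — the squared signal-to-noise
ratio under an assumed constant placement error ``sigma``.  The *utility* of
further evidence for a pair saturates as ``u(w) = 1 - exp(-w * d)``; with
the default steepness ``d = 10`` utility is essentially saturated once
evidence reaches the termination target of 0.5.

Subset selection first covers unseen pairs, then repeatedly seeds a display
with the minimum-evidence pair and greedily grows it while the expected
utility gain per unit trial cost keeps increasing.  Partial arrangements are
merged into a single RDM by iterative scale-and-average: each trial's
distances are aligned to the evolving global estimate by a least-squares
scale factor, then combined as evidence-weighted means.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .rdm import RDM, n_pairs, pair_index, triu_pairs

__all__ = [
    "TrialArrangement",
    "SessionConfig",
    "SessionState",
    "UnseenPairsError",
    "utility",
    "evidence_increments",
    "select_next_subset",
    "combine_trials",
    "run_session",
    "noun_session_config",
    "sentence_session_config",
]


class UnseenPairsError(ValueError):
    """Raised when an RDM is requested while some pairs were never displayed."""


def utility(w, d: float = 10.0):
    """Saturating utility of evidence, ``u(w) = 1 - exp(-w * d)``.

    Strictly increasing in ``w`` and bounded below 1.  ``u(0) = 0`` and with
    the default steepness ``u(0.5) = 1 - e^{-5} ~= 0.9933``, i.e. a pair at
    the evidence target has next to nothing left to gain.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("evidence must be nonnegative")
    if d <= 0:
        raise ValueError("utility steepness d must be positive")
    out = 1.0 - np.exp(-w * d)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class TrialArrangement:
    """One display: which items were shown and where they were placed.

    Coordinates live in arena units (unit disc, centre at the origin).
    """

    trial_index: int
    item_ids: list[int]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.item_ids = [int(i) for i in self.item_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.item_ids), 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.item_ids)} items"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate items in one display")
        norms = np.linalg.norm(self.coords, axis=1)
        if norms.size and norms.max() > 1.0 + 1e-6:
            raise ValueError("coordinates must lie inside the unit-disc arena")

    def distances(self) -> tuple[np.ndarray, np.ndarray]:
        """Within-display pair distances as (local i, j index pairs, dist)."""
        m = len(self.item_ids)
        i, j = np.triu_indices(m, k=1)
        d = np.linalg.norm(self.coords[i] - self.coords[j], axis=1)
        return np.stack([i, j], axis=1), d


@dataclasses.dataclass
class SessionConfig:
    """Tunables of one arrangement session.

    ``placement_sigma`` is the assumed placement error in arena-radius
    units; it converts on-screen distance into evidence.  ``trial_cost``
    holds (fixed, per-item) cost coefficients standing in for display setup
    and drag-and-drop time.  ``trial_budget`` replaces the wall-clock limit
    of a live session; `None` picks 40 for item sets up to 24 and 120 above.
    """

    d_exponent: float = 10.0
    evidence_target: float = 0.5
    first_trial_size: int | None = None
    min_subset: int = 3
    max_subset: int | None = None
    trial_budget: int | None = None
    placement_sigma: float = 0.3
    trial_cost: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def resolve(self, n_items: int) -> "SessionConfig":
        cfg = dataclasses.replace(self)
        if cfg.first_trial_size is None:
            cfg.first_trial_size = n_items
        if cfg.max_subset is None:
            cfg.max_subset = n_items
        if cfg.trial_budget is None:
            cfg.trial_budget = 40 if n_items <= 24 else 120
        if cfg.d_exponent <= 0:
            raise ValueError("d_exponent must be positive")
        if cfg.placement_sigma <= 0:
            raise ValueError("placement_sigma must be positive")
        if not (3 <= cfg.min_subset <= cfg.max_subset <= n_items):
            raise ValueError(
                f"need 3 <= min_subset <= max_subset <= n_items, got "
                f"{cfg.min_subset}..{cfg.max_subset} for {n_items} items"
            )
        if not (2 <= cfg.first_trial_size <= n_items):
            raise ValueError("first_trial_size out of range")
        return cfg


def noun_session_config(seed: int = 0) -> SessionConfig:
    """Session layout of the 24-noun task: full set first, subsets 3-24."""
    return SessionConfig(first_trial_size=24, max_subset=24, trial_budget=40, seed=seed)


def sentence_session_config(seed: int = 0) -> SessionConfig:
    """Session layout of the 48-sentence task: 10 items first, subsets 3-10."""
    return SessionConfig(first_trial_size=10, max_subset=10, trial_budget=120, seed=seed)


def evidence_increments(
    arr: TrialArrangement, sigma: float, n_items: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair evidence added by one display.

    Returns (global pair indices, increments) where each displayed pair
    (i, j) gains ``(distance_ij / sigma)**2``; coincident items contribute
    zero.  Pairs not displayed are simply absent.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    local, dist = arr.distances()
    ids = np.asarray(arr.item_ids)
    gi = ids[local[:, 0]]
    gj = ids[local[:, 1]]
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    idx = np.array([pair_index(n_items, a, b) for a, b in zip(lo, hi)], dtype=int)
    return idx, (dist / sigma) ** 2


class SessionState:
    """Evolving per-pair evidence, trial log and dissimilarity estimate."""

    def __init__(self, labels: Sequence[str], config: SessionConfig):
        self.labels = [str(x) for x in labels]
        self.config = config.resolve(len(self.labels))
        self.n_items = len(self.labels)
        self.evidence = np.zeros(n_pairs(self.n_items))
        self.trials: list[TrialArrangement] = []
        # cached per-trial (pair indices, distances, increments)
        self._trial_cache: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self._estimate_cache: tuple[int, np.ndarray] | None = None

    def add_trial(self, arr: TrialArrangement) -> None:
        idx, inc = evidence_increments(arr, self.config.placement_sigma, self.n_items)
        _, dist = arr.distances()
        self.evidence[idx] += inc
        self.trials.append(arr)
        self._trial_cache.append((idx, dist, inc))
        self._estimate_cache = None

    @property
    def n_rated_pairs(self) -> int:
        """Pairs with any accumulated evidence (displayed at least once)."""
        return int(np.count_nonzero(self.evidence > 0))

    def min_evidence(self) -> float:
        return float(self.evidence.min()) if self.evidence.size else 0.0

    def terminated(self) -> bool:
        return (
            self.min_evidence() >= self.config.evidence_target
            or len(self.trials) >= self.config.trial_budget
        )

    def estimate_vector(self, max_iter: int = 100) -> np.ndarray:
        """Current combined estimate (NaN for unseen pairs), cached per trial."""
        if self._estimate_cache is not None and self._estimate_cache[0] == len(self.trials):
            return self._estimate_cache[1]
        vec = _combine(self, max_iter=max_iter)
        self._estimate_cache = (len(self.trials), vec)
        return vec


# ---------------------------------------------------------------------------
# combining partial arrangements
# ---------------------------------------------------------------------------


def _combine(state: SessionState, max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Iterative scale-and-average over all logged trials (NaN where unseen).

    Each trial is aligned to the evolving estimate by a least-squares scale
    factor; pairs are then averaged with weights equal to the squared SNR of
    the *aligned* distances, which makes the result invariant to a global
    rescaling of any single trial's coordinates (the alignment absorbs it).
    """
    npair = n_pairs(state.n_items)
    est = np.full(npair, np.nan)
    if not state.trials:
        return est
    sigma = state.config.placement_sigma
    seen = state.evidence > 0
    # initialization: plain average at unit scale
    num = np.zeros(npair)
    den = np.zeros(npair)
    for idx, dist, _inc in state._trial_cache:
        num[idx] += dist
        den[idx] += 1.0
    est[seen] = num[seen] / den[seen]
    for _ in range(max_iter):
        num[:] = 0.0
        den[:] = 0.0
        for idx, dist, _inc in state._trial_cache:
            dd = float(np.dot(dist, dist))
            s = float(np.dot(dist, est[idx]) / dd) if dd > 0 else 1.0
            aligned = s * dist
            w = (aligned / sigma) ** 2
            num[idx] += w * aligned
            den[idx] += w
        new = np.full(npair, np.nan)
        ok = seen & (den > 0)
        new[ok] = num[ok] / den[ok]
        # pairs whose every aligned distance is zero stay at zero dissimilarity
        new[seen & ~ok] = 0.0
        prev_norm = float(np.linalg.norm(est[seen]))
        delta = float(np.linalg.norm(new[seen] - est[seen]))
        est = new
        if prev_norm == 0.0 or delta / prev_norm < tol:
            break
    # the combined RDM is defined only up to scale (every trial contributes
    # relative distances); canonicalize to unit RMS over seen pairs
    rms = float(np.sqrt(np.mean(est[seen] ** 2)))
    if rms > 0:
        est = est / rms
    return est


def combine_trials(state: SessionState, max_iter: int = 100, tol: float = 1e-6) -> RDM:
    """Merge all logged displays into one RDM.

    Every pair must have been displayed at least once; otherwise an
    :class:`UnseenPairsError` lists the missing pairs.
    """
    vec = _combine(state, max_iter=max_iter, tol=tol)
    unseen = np.flatnonzero(~(state.evidence > 0))
    if unseen.size:
        i, j = triu_pairs(state.n_items)
        missing = [(state.labels[i[k]], state.labels[j[k]]) for k in unseen[:20]]
        more = "" if unseen.size <= 20 else f" (+{unseen.size - 20} more)"
        raise UnseenPairsError(f"pairs never displayed: {missing}{more}")
    return RDM.from_utv(state.labels, vec)


# ---------------------------------------------------------------------------
# subset selection
# ---------------------------------------------------------------------------


def _predicted_distances(state: SessionState, subset: list[int]) -> np.ndarray:
    """Predicted on-screen distances for a prospective display.

    The current estimate is rescaled so the subset's largest predicted
    dissimilarity spans the arena diameter (2 radii); pairs without an
    estimate yet get the subset's median predicted distance.
    """
    m = len(subset)
    est = state.estimate_vector(max_iter=15)
    vals = np.empty(m * (m - 1) // 2)
    k = 0
    for a in range(m):
        for b in range(a + 1, m):
            i, j = subset[a], subset[b]
            if i > j:
                i, j = j, i
            vals[k] = est[pair_index(state.n_items, i, j)]
            k += 1
    finite = np.isfinite(vals)
    if finite.any():
        med = float(np.median(vals[finite]))
    else:
        med = 1.0
    vals[~finite] = med if med > 0 else 1.0
    vmax = vals.max() if vals.size else 0.0
    if vmax > 0:
        vals = vals * (2.0 / vmax)
    return vals


def _subset_pair_indices(state: SessionState, subset: list[int]) -> np.ndarray:
    out = []
    for a in range(len(subset)):
        for b in range(a + 1, len(subset)):
            i, j = subset[a], subset[b]
            if i > j:
                i, j = j, i
            out.append(pair_index(state.n_items, i, j))
    return np.asarray(out, dtype=int)


def _efficiency(state: SessionState, subset: list[int]) -> float:
    """Expected summed utility gain of a display divided by its trial cost."""
    cfg = state.config
    d_pred = _predicted_distances(state, subset)
    inc = (d_pred / cfg.placement_sigma) ** 2
    w = state.evidence[_subset_pair_indices(state, subset)]
    gain = float(np.sum(utility(w + inc, cfg.d_exponent) - utility(w, cfg.d_exponent)))
    fixed, per_item = cfg.trial_cost
    return gain / (fixed + per_item * len(subset))


def select_next_subset(state: SessionState) -> list[int]:
    """Choose the items for the next display.

    While any pair is still unseen, items are ranked by how many unseen
    pairs they participate in (ties to the lowest index) so that coverage is
    completed as fast as the display size allows.  Once every pair has some
    evidence, the display is seeded with the globally minimum-evidence pair
    and grown greedily by the single item whose addition most improves
    expected utility gain per unit cost, stopping when no addition improves
    efficiency; size is clamped to [min_subset, max_subset].
    """
    cfg = state.config
    n = state.n_items
    if not state.trials:
        raise ValueError("use run_session (or pick the first display yourself) "
                         "before adaptive selection")
    if np.any(state.evidence == 0):
        i, j = triu_pairs(n)
        unseen = np.zeros((n, n), dtype=bool)
        mask = state.evidence == 0
        unseen[i[mask], j[mask]] = True
        unseen[j[mask], i[mask]] = True
        deg = unseen.sum(axis=1)
        # grow the display so each added item brings the most unseen pairs
        # *with the items already on display* (ties: lowest index)
        subset = [int(np.argmax(deg))]
        in_subset = np.zeros(n, dtype=bool)
        in_subset[subset[0]] = True
        while len(subset) < cfg.max_subset:
            gain = unseen[:, in_subset].sum(axis=1)
            gain[in_subset] = -1
            c = int(np.argmax(gain))
            if gain[c] <= 0 and len(subset) >= cfg.min_subset:
                break
            subset.append(c)
            in_subset[c] = True
        return sorted(subset)

    # seed with the minimum-evidence pair (ties: lowest pair index)
    i, j = triu_pairs(n)
    k0 = int(np.argmin(state.evidence))
    subset = [int(i[k0]), int(j[k0])]
    best_eff = _efficiency(state, subset)
    remaining = [c for c in range(n) if c not in subset]
    while remaining and len(subset) < cfg.max_subset:
        effs = [(_efficiency(state, subset + [c]), -c) for c in remaining]
        eff, negc = max(effs)
        c = -negc
        if eff <= best_eff and len(subset) >= cfg.min_subset:
            break
        subset.append(c)
        remaining.remove(c)
        best_eff = max(best_eff, eff)
    return sorted(subset)


# ---------------------------------------------------------------------------
# session driver
# ---------------------------------------------------------------------------

Rater = Callable[[int, list[str]], np.ndarray]


def run_session(
    rater: Rater,
    labels: Sequence[str],
    config: SessionConfig | None = None,
) -> tuple[RDM, SessionState]:
    """Run one full adaptive session against a rater.

    ``rater`` is called as ``rater(trial_index, subset_labels)`` and must
    return an ``(m, 2)`` coordinate array inside the unit disc (simulated
    raters from :mod:`multiarrange.rater_sim` satisfy this).  The loop
    alternates subset selection, arrangement and evidence update until the
    minimum pair evidence reaches the target or the trial budget is spent.

    Returns the combined RDM (NaN for pairs never displayed, which can only
    happen when the budget runs out first) and the full session state.
    """
    config = (config or SessionConfig()).resolve(len(labels))
    state = SessionState(labels, config)
    rng = np.random.default_rng(config.seed)
    while True:
        t = len(state.trials)
        if t == 0:
            if config.first_trial_size >= state.n_items:
                subset = list(range(state.n_items))
            else:
                subset = sorted(
                    int(x)
                    for x in rng.choice(state.n_items, config.first_trial_size, replace=False)
                )
        else:
            subset = select_next_subset(state)
        sub_labels = [state.labels[k] for k in subset]
        try:
            coords = np.asarray(rater(t, sub_labels), dtype=float)
        except Exception as exc:
            raise RuntimeError(
                f"rater failed on trial {t} with items {sub_labels}"
            ) from exc
        state.add_trial(TrialArrangement(t, subset, coords))
        if state.terminated():
            break
    vec = state.estimate_vector()
    return RDM.from_utv(state.labels, vec), state
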