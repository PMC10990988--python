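"""Synthetic raters: ground-truth mixtures, 2D placements, cohorts.

A simulated subject carries a ground-truth RDM formed as a nonnegative
weighted mixture of binary latent dimension RDMs (verb category, verb
identity, adverb identity, agent category, patient category).  The weights
play the role of attentional bias: the default sampler is verb-dominant,
mirroring cohorts in which most subjects sort sentences by the action
category of the verb while still carrying weak role information.

When asked to arrange a subset, the rater embeds the subset's sub-RDM into
the 2D arena by metric multidimensional scaling, rescales the configuration
to fit the unit disc, and jitters every coordinate with independent
Gaussian placement noise.  This closes the loop: every downstream module
can be exercised without human data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from sklearn.manifold import smacof

from . import stimulus_design as sd
from .arrangement import RDM, SessionConfig, SessionState, run_session
from .rdm import triu_pairs

__all__ = [
    "RaterProfile",
    "CohortConfig",
    "SimulatedRater",
    "SimulatedSubject",
    "DEFAULT_DIMENSIONS",
    "DEFAULT_ALPHA",
    "default_dimensions",
    "ground_truth_rdm",
    "arrange_subset",
    "sample_profiles",
    "simulate_cohort",
    "planted_ensemble_rdms",
]

#: latent dimensions a synthetic subject may attend to, in canonical order
DEFAULT_DIMENSIONS = (
    "verb_category",
    "verb_identity",
    "adverb_identity",
    "agent_category",
    "patient_category",
)

#: Dirichlet concentrations of the default attentional-weight sampler;
#: verb-category dominant, with weak but present role dimensions
DEFAULT_ALPHA = {
    "verb_category": 8.0,
    "verb_identity": 2.0,
    "adverb_identity": 2.0,
    "agent_category": 3.0,
    "patient_category": 3.0,
}


@dataclasses.dataclass
class RaterProfile:
    """A synthetic subject: attentional weights and placement noise.

    ``weights`` maps latent-dimension names to nonnegative attentional
    weights (at least one positive); ``placement_noise`` is the Gaussian
    jitter SD applied to each placed coordinate, in arena-radius units.
    """

    weights: dict[str, float]
    placement_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("profile needs at least one dimension weight")
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("attentional weights must be nonnegative")
        if not np.any(vals > 0):
            raise ValueError("at least one attentional weight must be positive")
        if self.placement_noise < 0:
            raise ValueError("placement noise must be nonnegative")


def default_dimensions(stimuli: sd.StimulusSet) -> dict[str, RDM]:
    """The five standard binary model RDMs for a sentence stimulus set."""
    return {name: sd.build_model_rdm(stimuli, name) for name in DEFAULT_DIMENSIONS}


def ground_truth_rdm(profile: RaterProfile, dims: Mapping[str, RDM]) -> RDM:
    """Weighted mixture of latent dimension RDMs, Sum_k w_k * M_k.

    Linear in the weights, so rescaling all weights rescales the RDM and
    leaves every rank correlation untouched.
    """
    labels = None
    total = None
    for name, w in profile.weights.items():
        if name not in dims:
            raise KeyError(f"profile weights name unknown dimension {name!r}")
        m = dims[name]
        if labels is None:
            labels = m.labels
            total = np.zeros_like(m.values)
        elif m.labels != labels:
            raise ValueError(f"dimension {name!r} has mismatched item labels")
        total = total + w * m.values
    return RDM(list(labels), total)


# ---------------------------------------------------------------------------
# 2D placement
# ---------------------------------------------------------------------------


def _embed_2d(D: np.ndarray, seed: int) -> np.ndarray:
    """Metric 2D embedding: classical MDS start, SMACOF refinement.

    The classical (Torgerson) solution is exact for 2D-embeddable inputs;
    SMACOF then minimizes raw metric stress from that start, which matters
    for inputs that are not exactly embeddable.
    """
    m = D.shape[0]
    if m == 1:
        return np.zeros((1, 2))
    if m == 2:
        return np.array([[-D[0, 1] / 2.0, 0.0], [D[0, 1] / 2.0, 0.0]])
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    top = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[top], 0.0, None)
    init = evecs[:, top] * np.sqrt(lam)[None, :]
    if not np.any(lam > 0):
        return init  # all-zero dissimilarities: stack at the origin
    coords, _stress = smacof(
        D,
        metric=True,
        n_components=2,
        init=init,
        n_init=1,
        max_iter=300,
        eps=1e-10,
        random_state=int(seed) % (2**31),
        normalized_stress=False,
    )
    return coords


def arrange_subset(
    gt: RDM, subset: Sequence[str], sigma: float, seed: int
) -> np.ndarray:
    """Place a subset of items in the arena according to a ground truth.

    The sub-RDM is embedded in 2D, centred, rescaled so the farthest item
    sits on the arena rim, then each coordinate receives independent
    Gaussian jitter of SD ``sigma`` and points outside the disc are pulled
    back to the rim.  Deterministic given ``seed``.
    """
    sub = gt.sub_rdm(subset)
    coords = _embed_2d(sub.values, seed)
    coords = coords - coords.mean(axis=0, keepdims=True)
    maxnorm = float(np.linalg.norm(coords, axis=1).max())
    if maxnorm > 0:
        coords = coords / maxnorm
    if sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, sigma, size=coords.shape)
    norms = np.linalg.norm(coords, axis=1)
    outside = norms > 1.0
    if np.any(outside):
        coords[outside] /= norms[outside, None]
    return coords


class SimulatedRater:
    """Callable rater bound to a profile and a ground-truth RDM.

    Satisfies the ``rater(trial_index, subset_labels) -> coords`` contract
    of :func:`multiarrange.arrangement.run_session`; a fresh deterministic
    placement seed is derived per trial from the profile seed.
    """

    def __init__(self, profile: RaterProfile, dims: Mapping[str, RDM] | None = None,
                 ground_truth: RDM | None = None):
        if (dims is None) == (ground_truth is None):
            raise ValueError("provide exactly one of dims or ground_truth")
        self.profile = profile
        self.ground_truth = (
            ground_truth if ground_truth is not None else ground_truth_rdm(profile, dims)
        )

    def __call__(self, trial_index: int, subset_labels: Sequence[str]) -> np.ndarray:
        seed = int(
            np.random.SeedSequence([self.profile.seed, trial_index]).generate_state(1)[0]
            % (2**31)
        )
        return arrange_subset(
            self.ground_truth, subset_labels, self.profile.placement_noise, seed
        )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CohortConfig:
    """How a synthetic cohort is sampled.

    ``alpha`` gives per-dimension Dirichlet concentrations for the
    attentional weights (the default is verb-dominant); ``verb_bias``
    multiplies the verb-category concentration on top of that, as a single
    dial for bias strength.
    """

    n_subjects: int = 20
    alpha: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ALPHA)
    )
    verb_bias: float = 1.0
    placement_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")

    def concentrations(self) -> tuple[list[str], np.ndarray]:
        names = list(self.alpha)
        a = np.array([self.alpha[k] for k in names], dtype=float)
        if "verb_category" in names:
            a[names.index("verb_category")] *= self.verb_bias
        return names, a


@dataclasses.dataclass
class SimulatedSubject:
    profile: RaterProfile
    rdm: RDM
    state: SessionState | None


def sample_profiles(cfg: CohortConfig) -> list[RaterProfile]:
    """Draw per-subject attentional weights from the cohort's Dirichlet."""
    names, alpha = cfg.concentrations()
    rng = np.random.default_rng(cfg.seed)
    profiles = []
    for s in range(cfg.n_subjects):
        w = rng.dirichlet(alpha)
        seed = int(rng.integers(0, 2**31 - 1))
        profiles.append(
            RaterProfile(dict(zip(names, w)), cfg.placement_noise, seed=seed)
        )
    return profiles


def simulate_cohort(
    stimuli: sd.StimulusSet,
    cfg: CohortConfig,
    session_cfg: SessionConfig | None = None,
    mode: str = "session",
) -> list[SimulatedSubject]:
    """Simulate a cohort of raters on a stimulus set.

    ``mode='session'`` runs the full adaptive multiple-arrangement engine
    for every subject and returns combined RDMs plus session states.
    ``mode='single_arrangement'`` takes each subject's single full-set
    arrangement and returns the resulting on-screen distance matrix; this is
    the fast proxy that deliberately keeps the 2D compression of a lone
    display (no session state is produced).  Reproducible from ``cfg.seed``.
    """
    dims = default_dimensions(stimuli)
    profiles = sample_profiles(cfg)
    out: list[SimulatedSubject] = []
    for s, profile in enumerate(profiles):
        rater = SimulatedRater(profile, dims=dims)
        if mode == "session":
            scfg = dataclasses.replace(
                session_cfg or SessionConfig(), seed=profile.seed
            )
            rdm, state = run_session(rater, stimuli.labels, scfg)
            out.append(SimulatedSubject(profile, rdm, state))
        elif mode == "single_arrangement":
            coords = rater(0, stimuli.labels)
            dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            out.append(SimulatedSubject(profile, RDM(stimuli.labels, dmat), None))
        else:
            raise ValueError(f"unknown cohort mode {mode!r}")
    return out


#: Dirichlet concentrations of the estimated-RDM cohort generator
#: (:func:`mixture_cohort_rdms`), over the five shared dimensions plus one
#: idiosyncratic per-subject dimension.  Calibrated so a simulated cohort
#: reproduces the observed group regime of the sentence task: a group
#: average dominated by verb category (model rho ~ 0.86) while the average
#: *raw* role contrast is statistically indistinguishable from zero —
#: attention is sparse and verb-dominant, and only a small minority of
#: subjects express thematic-role structure.
MIXTURE_COHORT_ALPHA = {
    "verb_category": 1.2,
    "verb_identity": 0.2,
    "adverb_identity": 0.2,
    "agent_category": 0.1,
    "patient_category": 0.1,
    "idiosyncratic": 0.5,
}


def mixture_cohort_rdms(
    dims: Mapping[str, RDM],
    n_subjects: int = 30,
    alpha: Mapping[str, float] | None = None,
    noise_sd_frac: float = 0.75,
    seed: int = 0,
) -> tuple[list[RDM], np.ndarray, list[str]]:
    """Estimated-RDM cohort: sparse attentional mixtures plus noise.

    Emulates the *final* per-subject RDMs of a multiple-arrangement cohort
    (many small subset displays approximate the attended mixture well, so
    the estimate is close to linear in the attended dimensions).  Each
    subject draws sparse Dirichlet weights over the shared dimensions plus
    one private random binary dimension (``idiosyncratic`` — individual
    sorting strategies that do not generalize across subjects), and
    independent Gaussian estimation noise of SD ``noise_sd_frac`` times the
    subject's signal SD is added per pair (clipped at zero).

    Returns (subject RDMs, weight matrix over the named dimensions in
    order, dimension names).  The idiosyncratic weight is the last column.
    """
    names = list(dims)
    alpha = dict(alpha) if alpha is not None else dict(MIXTURE_COHORT_ALPHA)
    idio_a = alpha.pop("idiosyncratic", 0.0)
    avec = np.array([alpha[n] for n in names] + ([idio_a] if idio_a > 0 else []))
    labels = dims[names[0]].labels
    n = len(labels)
    i, j = triu_pairs(n)
    rng = np.random.default_rng(seed)
    rdms: list[RDM] = []
    W = np.zeros((n_subjects, avec.size))
    for s in range(n_subjects):
        w = rng.dirichlet(avec)
        W[s] = w
        gt = sum(wk * dims[nm].values for wk, nm in zip(w, names))
        if idio_a > 0:
            half = rng.permutation(n) < n // 2
            idm = (half[:, None] != half[None, :]).astype(float)
            np.fill_diagonal(idm, 0.0)
            gt = gt + w[-1] * idm
        sd_signal = float(np.std(gt[i, j]))
        noise = np.zeros_like(gt)
        noise[i, j] = rng.normal(0.0, noise_sd_frac * sd_signal, size=i.size)
        noise[j, i] = noise[i, j]
        vals = np.clip(gt + noise, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        rdms.append(RDM(list(labels), vals))
    out_names = names + (["idiosyncratic"] if idio_a > 0 else [])
    return rdms, W, out_names


def random_binary_dimensions(
    labels: Sequence[str], n_dims: int = 5, seed: int = 0
) -> dict[str, RDM]:
    """Independent binary dimension RDMs from random balanced item splits.

    Each dimension assigns half the items to one group and codes pairs 0
    (same group) / 1 (different group).  Independent random splits give
    near-orthogonal model vectors, which makes them the right planted
    ground truth for parameter-recovery studies: recovery failures then
    reflect the pipeline, not structural correlations between dimensions
    (the sentence-design models, by contrast, are correlated by
    construction — verb identity implies verb category, and adverbs nest
    within agent categories).
    """
    labels = [str(x) for x in labels]
    n = len(labels)
    rng = np.random.default_rng(seed)
    dims: dict[str, RDM] = {}
    for d in range(n_dims):
        half = rng.permutation(n) < n // 2
        m = (half[:, None] != half[None, :]).astype(float)
        np.fill_diagonal(m, 0.0)
        dims[f"dim_{d + 1}"] = RDM(list(labels), m)
    return dims


def planted_ensemble_rdms(
    dims: Mapping[str, RDM],
    n_subjects: int = 40,
    dominant_alpha: float = 8.0,
    base_alpha: float = 1.0,
    noise_sd_frac: float = 0.10,
    seed: int = 0,
) -> tuple[list[RDM], np.ndarray, list[str]]:
    """Subject RDMs planted from known dimensions, for recovery studies.

    Subjects are split as evenly as possible across the dimensions; each
    subject's weights come from a Dirichlet whose concentration is
    ``dominant_alpha`` on their assigned dimension and ``base_alpha``
    elsewhere, so every subject is dominated by one planted component.
    Independent Gaussian noise of SD ``noise_sd_frac`` times each subject's
    signal SD is added to the RDM entries (clipped at zero).

    Returns (subject RDMs, true weight matrix, dimension-name order).
    """
    names = list(dims)
    labels = dims[names[0]].labels
    rng = np.random.default_rng(seed)
    i, j = triu_pairs(len(labels))
    rdms: list[RDM] = []
    W = np.zeros((n_subjects, len(names)))
    for s in range(n_subjects):
        dom = s % len(names)
        alpha = np.full(len(names), base_alpha)
        alpha[dom] = dominant_alpha
        w = rng.dirichlet(alpha)
        W[s] = w
        gt = ground_truth_rdm(
            RaterProfile(dict(zip(names, w)), 0.0, seed=0), dims
        ).values.copy()
        sd_signal = float(np.std(gt[i, j]))
        noise = np.zeros_like(gt)
        noise[i, j] = rng.normal(0.0, noise_sd_frac * sd_signal, size=i.size)
        noise[j, i] = noise[i, j]
        vals = np.clip(gt + noise, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        rdms.append(RDM(list(labels), vals))
    return rdms, W, names
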