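"""Group-level summaries, model correlations and the role-controlled contrast.

The centrepiece is the semantic-overlap-controlled thematic-role contrast:
three subsets of sentences are chosen so that a reference subset shares the
semantics of one noun with both comparison subsets, but only one comparison
subset additionally shares the thematic role that noun appeared in.  If
thematic roles shape perceived similarity, cross-subset dissimilarity to the
role-sharing subset must be lower than to the semantics-only subset; the
difference (semantics-only minus semantics+role) is therefore positive under
role sensitivity and exactly zero for any bag-of-words-style (role-blind)
dissimilarity.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr, ttest_1samp

from .arrangement import SessionState
from .rdm import RDM, n_pairs
from .stimulus_design import StimulusSet

__all__ = [
    "ContrastResult",
    "exclude_subjects",
    "group_average_rdm",
    "rdm_model_correlation",
    "within_across_means",
    "role_controlled_contrast",
    "subject_contrast_differences",
    "contrast_test",
    "embedding_rdm",
]


def exclude_subjects(
    sessions: Sequence[SessionState], min_pairs: int = 50
) -> tuple[list[int], pd.DataFrame]:
    """Drop subjects who rated too few item pairs.

    A pair counts as rated once it has any accumulated evidence.  Subjects
    with fewer than ``min_pairs`` rated pairs are excluded (a subject with
    exactly ``min_pairs`` is retained).  Returns the retained subject
    indices and a per-subject report table.
    """
    rows = []
    retained = []
    for s, st in enumerate(sessions):
        n_rated = int(st.n_rated_pairs)
        keep = n_rated >= min_pairs
        rows.append({"subject": s, "n_rated_pairs": n_rated, "retained": keep})
        if keep:
            retained.append(s)
    return retained, pd.DataFrame(rows)


def group_average_rdm(rdms: Sequence[RDM]) -> RDM:
    """SD-normalize each subject's RDM, then average entrywise."""
    if not rdms:
        raise ValueError("need at least one subject RDM")
    labels = rdms[0].labels
    acc = np.zeros_like(rdms[0].values)
    for s, r in enumerate(rdms):
        if r.labels != labels:
            raise ValueError(f"subject {s} has mismatched item labels")
        acc += r.normalized().values
    return RDM(list(labels), acc / len(rdms))


def rdm_model_correlation(rdm: RDM, model: RDM) -> float:
    """Spearman rank correlation between an RDM and a model RDM (utv-wise)."""
    a, b = rdm.utv, model.utv
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance input; Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(a, b)
    return float(rho)


def within_across_means(rdm: RDM, categories: dict[str, str]) -> tuple[float, float]:
    """Mean dissimilarity within vs. across item categories.

    ``categories`` maps item label to category.  Category-driven data show
    a higher across-category mean than within-category mean.
    """
    cats = np.array([categories[lab] for lab in rdm.labels], dtype=object)
    same = cats[:, None] == cats[None, :]
    iu = np.triu_indices(rdm.n, k=1)
    mask = same[iu]
    vals = rdm.values[iu]
    if not mask.any() or mask.all():
        raise ValueError("need both within- and across-category pairs")
    return float(vals[mask].mean()), float(vals[~mask].mean())


# ---------------------------------------------------------------------------
# role-controlled contrast
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ContrastResult:
    """All enumerated subset pairings plus the aggregate contrast test.

    ``difference`` per pairing is mean dissimilarity to the semantics-only
    subset minus mean dissimilarity to the semantics+role subset (positive
    when roles matter); ``t_stat``/``p_value`` give the one-sided test of
    the aggregate difference across pairings.
    """

    pairings: list[dict]
    mean_difference: float
    t_stat: float
    p_value: float
    skipped: list[dict]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairings)


def _values_matrix(values, n_items: int) -> np.ndarray:
    if isinstance(values, RDM):
        if values.n != n_items:
            raise ValueError("values RDM does not match the stimulus count")
        return values.values
    vec = np.asarray(values, dtype=float).ravel()
    if vec.size != n_pairs(n_items):
        raise ValueError(
            f"expected a {n_items}x{n_items} RDM or a {n_pairs(n_items)}-long "
            f"pair vector, got {vec.size} values"
        )
    return squareform(vec)


def _verb_composition(sent_idx: list[int], stimuli: StimulusSet) -> tuple:
    counts = Counter(stimuli.sentences[k].verb.category for k in sent_idx)
    total = sum(counts.values())
    return tuple(sorted((c, n / total) for c, n in counts.items()))


def role_controlled_contrast(values, stimuli: StimulusSet) -> ContrastResult:
    """Thematic-role contrast controlled for semantic overlap.

    For every ordered pair of noun categories (X, Y), X != Y, the reference
    subset holds the sentences with agent category X and patient category Y.
    The *semantics+role* subset (agent Y, patient Y) shares category Y in
    the same (patient) role; the *semantics-only* subset (agent Z not in
    {X, Y}, patient X) shares category X in the opposite role.  A pairing is
    kept only when both comparison subsets exist and have identical
    verb-category proportions, so verb semantics cancel from the contrast;
    otherwise it is skipped and logged.

    ``values`` may be an :class:`RDM` over the sentences or a pair vector
    (e.g. an NMF component row).
    """
    mat = _values_matrix(values, stimuli.n)
    cats = stimuli.noun_categories()
    by_roles: dict[tuple[str, str], list[int]] = {}
    for k, s in enumerate(stimuli.sentences):
        by_roles.setdefault((s.agent.category, s.patient.category), []).append(k)

    pairings, skipped = [], []
    for X, Y in itertools.permutations(cats, 2):
        ref = by_roles.get((X, Y), [])
        role = by_roles.get((Y, Y), [])
        if not ref or not role:
            continue
        for Z in cats:
            if Z in (X, Y):
                continue
            sem = by_roles.get((Z, X), [])
            entry = {"reference": f"{X}->{Y}", "role_subset": f"{Y}->{Y}",
                     "semantics_subset": f"{Z}->{X}"}
            if not sem:
                skipped.append({**entry, "reason": "empty semantics-only subset"})
                continue
            if _verb_composition(role, stimuli) != _verb_composition(sem, stimuli):
                skipped.append({**entry, "reason": "verb-category composition mismatch"})
                continue
            mean_role = float(mat[np.ix_(ref, role)].mean())
            mean_sem = float(mat[np.ix_(ref, sem)].mean())
            pairings.append(
                {
                    **entry,
                    "n_reference": len(ref),
                    "n_role": len(role),
                    "n_semantics": len(sem),
                    "mean_role": mean_role,
                    "mean_semantics_only": mean_sem,
                    "difference": mean_sem - mean_role,
                }
            )
    if not pairings:
        raise ValueError("no valid subset pairings in this stimulus design")
    diffs = np.array([p["difference"] for p in pairings])
    t, p = contrast_test(diffs)
    return ContrastResult(
        pairings=pairings,
        mean_difference=float(diffs.mean()),
        t_stat=t,
        p_value=p,
        skipped=skipped,
    )


def subject_contrast_differences(
    rdms: Sequence[RDM], stimuli: StimulusSet
) -> np.ndarray:
    """Per-subject mean role-contrast difference (one value per subject)."""
    return np.array(
        [role_controlled_contrast(r, stimuli).mean_difference for r in rdms]
    )


def contrast_test(differences: Sequence[float]) -> tuple[float, float]:
    """One-sample, one-sided t-test of mean difference > 0.

    Returns ``(t, p)``; NaN for degenerate input (fewer than two values or
    zero variance), with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2 or np.std(d) == 0:
        warnings.warn(
            "contrast test undefined: need >= 2 differences with nonzero variance",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    res = ttest_1samp(d, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# embedding-derived RDMs
# ---------------------------------------------------------------------------


def embedding_rdm(vectors) -> RDM:
    """Cosine-distance RDM from per-item embedding vectors.

    ``vectors`` is a DataFrame indexed by item label (one row per item) or a
    mapping label -> vector.  Dissimilarity is ``1 - cosine similarity``;
    zero-norm vectors are rejected by item name.
    """
    if isinstance(vectors, pd.DataFrame):
        labels = [str(x) for x in vectors.index]
        X = vectors.to_numpy(dtype=float)
    else:
        labels = [str(k) for k in vectors]
        X = np.array([np.asarray(vectors[k], dtype=float) for k in vectors])
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two equal-length item vectors")
    norms = np.linalg.norm(X, axis=1)
    bad = [labels[k] for k in np.flatnonzero(norms == 0)]
    if bad:
        raise ValueError(f"zero-norm embedding for items: {bad}")
    d = pdist(X, metric="cosine")  # = 1 - cosine similarity
    m = squareform(np.clip(d, 0.0, None))
    return RDM(labels, m)
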