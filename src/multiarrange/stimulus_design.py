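"""Constrained transitive-sentence stimulus design and reference similarity.

The stimulus set consists of simple transitive event descriptions
("<adverb> the <agent> <verb> the <patient>") built from a small vocabulary:
nouns drawn from four professional domains, verbs from two action domains,
and temporal adverbs from two day-groups.  The design balances category
frequencies so that no single word dimension is confounded with another:

1. each noun in agent position is paired once with a same-category and once
   with a different-category patient;
2. each noun appears in both agent and patient position;
3. each noun category appears equally often;
5. each noun category co-occurs equally often with both verb categories;
6. each adverb precedes exactly two of the noun categories, and both verb
   categories equally often.

(The constraint numbering skips 4; the design history simply never had a
fourth constraint, and the gap is kept so the numbers above stay citable.)

Reference similarity between two sentences is scored 0-3 in two ways: a
*bag-of-words* score (shared noun categories regardless of role, plus shared
verb category) and a *relational* score (shared agent category + shared
patient category + shared verb category).  Role reversal is exactly the
case that separates them.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rdm import RDM, n_pairs

__all__ = [
    "VocabularyItem",
    "SentenceStimulus",
    "StimulusSet",
    "ConstraintInfeasibleError",
    "default_vocabulary",
    "generate_stimulus_set",
    "score_pair",
    "reference_rdm",
    "build_model_rdm",
    "check_constraints",
    "MODEL_DIMENSIONS",
]

SAME_DAY = "same_day"
PREVIOUS_DAY = "previous_day"

#: feature extractors for binary model RDMs over sentence stimuli
MODEL_DIMENSIONS = (
    "verb_category",
    "agent_category",
    "patient_category",
    "verb_identity",
    "adverb_identity",
    "adverb_daygroup",
)


class ConstraintInfeasibleError(ValueError):
    """The supplied vocabulary cannot satisfy the design constraints."""


@dataclasses.dataclass(frozen=True)
class VocabularyItem:
    """A word with its part of speech and semantic category.

    For adverbs the ``category`` slot holds the day-group (``same_day`` or
    ``previous_day``); adverb identity is the surface form itself.
    """

    surface: str
    pos: str  # noun | verb | adverb
    category: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("vocabulary item needs a non-empty surface form")
        if self.pos not in ("noun", "verb", "adverb"):
            raise ValueError(f"unknown part of speech {self.pos!r}")
        if not self.category:
            raise ValueError(f"{self.surface!r} needs a category label")


@dataclasses.dataclass(frozen=True)
class SentenceStimulus:
    """One transitive sentence: adverb-first, then verb, agent, patient."""

    id: int
    adverb: VocabularyItem
    verb: VocabularyItem
    agent: VocabularyItem
    patient: VocabularyItem

    def __post_init__(self) -> None:
        if self.agent.pos != "noun" or self.patient.pos != "noun":
            raise ValueError("agent and patient must be nouns")
        if self.verb.pos != "verb":
            raise ValueError("verb slot must hold a verb")
        if self.adverb.pos != "adverb":
            raise ValueError("adverb slot must hold an adverb")

    @property
    def surface(self) -> str:
        """English rendering; scoring never reads this, only category labels."""
        return (
            f"{self.adverb.surface} the {self.agent.surface} "
            f"{self.verb.surface} the {self.patient.surface}."
        )

    @property
    def label(self) -> str:
        return f"s{self.id:02d}"


@dataclasses.dataclass
class StimulusSet:
    """An ordered, constraint-balanced collection of sentence stimuli."""

    sentences: list[SentenceStimulus]
    vocabulary: list[VocabularyItem]

    @property
    def n(self) -> int:
        return len(self.sentences)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sentences]

    @property
    def nouns(self) -> list[VocabularyItem]:
        return [v for v in self.vocabulary if v.pos == "noun"]

    @property
    def verbs(self) -> list[VocabularyItem]:
        return [v for v in self.vocabulary if v.pos == "verb"]

    @property
    def adverbs(self) -> list[VocabularyItem]:
        return [v for v in self.vocabulary if v.pos == "adverb"]

    def noun_categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.nouns:
            seen.setdefault(v.category, None)
        return list(seen)


# ---------------------------------------------------------------------------
# default vocabulary
# ---------------------------------------------------------------------------

_NOUNS = {
    "medicine": ["surgeon", "nurse", "paramedic", "dentist", "pharmacist", "midwife"],
    "manual_labor": ["carpenter", "plumber", "electrician", "mechanic", "welder", "roofer"],
    "sports": ["sprinter", "boxer", "athlete", "swimmer", "goalkeeper", "wrestler"],
    "music": ["guitarist", "drummer", "violinist", "pianist", "cellist", "trumpeter"],
}
_VERBS = {
    "communication": ["comforted", "encouraged", "praised", "complimented", "congratulated", "thanked"],
    "physical": ["beat up", "pushed", "hit", "shoved", "kicked", "tackled"],
}
_ADVERBS = [
    ("Today", SAME_DAY),
    ("This morning", SAME_DAY),
    ("Earlier", SAME_DAY),
    ("In the morning", SAME_DAY),
    ("Yesterday", PREVIOUS_DAY),
    ("Yesterday evening", PREVIOUS_DAY),
]


def default_vocabulary() -> list[VocabularyItem]:
    """The study-scale vocabulary: 24 nouns (4 x 6), 12 verbs (2 x 6), 6 adverbs.

    Nouns name professionals from four domains (medicine, manual labor,
    sports, music); verbs describe positive communicative vs. negative
    physical actions; temporal adverbs fall into two day-groups.
    """
    vocab: list[VocabularyItem] = []
    for cat, words in _NOUNS.items():
        vocab += [VocabularyItem(w, "noun", cat) for w in words]
    for cat, words in _VERBS.items():
        vocab += [VocabularyItem(w, "verb", cat) for w in words]
    vocab += [VocabularyItem(w, "adverb", grp) for w, grp in _ADVERBS]
    return vocab


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _groups(vocab: Iterable[VocabularyItem], pos: str) -> dict[str, list[VocabularyItem]]:
    out: dict[str, list[VocabularyItem]] = {}
    for v in vocab:
        if v.pos == pos:
            out.setdefault(v.category, []).append(v)
    return out


def _feasibility_checks(
    nouns: dict[str, list[VocabularyItem]],
    verbs: dict[str, list[VocabularyItem]],
    adverbs: list[VocabularyItem],
) -> None:
    ncats = list(nouns)
    if len(ncats) < 2:
        raise ConstraintInfeasibleError(
            "constraint (1): need at least two noun categories for "
            "different-category patient pairing"
        )
    sizes = {c: len(nouns[c]) for c in ncats}
    if len(set(sizes.values())) != 1:
        raise ConstraintInfeasibleError(
            f"constraint (3): noun categories must be equally sized, got {sizes}"
        )
    cat_size = sizes[ncats[0]]
    if cat_size < 2:
        raise ConstraintInfeasibleError(
            "constraint (1): need >= 2 nouns per category for same-category pairing"
        )
    if cat_size % 2 != 0:
        raise ConstraintInfeasibleError(
            "constraint (5): nouns per category must be even so each category "
            "splits equally across the two verb categories"
        )
    if len(verbs) != 2:
        raise ConstraintInfeasibleError(
            f"constraint (5): need exactly two verb categories, got {len(verbs)}"
        )
    vsizes = {c: len(v) for c, v in verbs.items()}
    if len(set(vsizes.values())) != 1:
        raise ConstraintInfeasibleError(
            f"constraint (5): verb categories must be equally sized, got {vsizes}"
        )
    n_sent = 2 * cat_size * len(ncats)
    n_verbs = sum(vsizes.values())
    if n_sent % n_verbs != 0:
        raise ConstraintInfeasibleError(
            f"{n_sent} sentences are not divisible over {n_verbs} verbs"
        )
    if not adverbs:
        raise ConstraintInfeasibleError("constraint (6): need at least one adverb")
    if (2 * len(adverbs)) % len(ncats) != 0:
        raise ConstraintInfeasibleError(
            "constraint (6): 2 x n_adverbs must be divisible by the number of "
            "noun categories (each adverb precedes two categories)"
        )
    per_cat_adverbs = 2 * len(adverbs) // len(ncats)
    per_cat_sentences = 2 * cat_size
    if per_cat_sentences % per_cat_adverbs != 0 or (per_cat_sentences // per_cat_adverbs) % 2 != 0:
        raise ConstraintInfeasibleError(
            "constraint (6): sentences per noun category must split evenly over "
            "its adverbs and over both verb categories"
        )


def _derangement(items: list, rng: np.random.Generator, cap: int) -> list:
    """Random permutation without fixed points (so nobody acts on themselves)."""
    idx = np.arange(len(items))
    for _ in range(cap):
        perm = rng.permutation(idx)
        if not np.any(perm == idx):
            return [items[k] for k in perm]
    raise ConstraintInfeasibleError("could not find a same-category derangement")


def generate_stimulus_set(
    vocab: Sequence[VocabularyItem] | None = None,
    seed: int = 0,
    max_retries: int = 10_000,
) -> StimulusSet:
    """Generate a constraint-satisfying transitive sentence set.

    Uses constraint-guided shuffling with rejection (retry cap
    ``max_retries``) rather than exact combinatorial construction; the
    constraints are loose enough that a valid assignment is found within a
    handful of attempts.  Deterministic given ``seed``.

    With the default vocabulary (24 nouns, 12 verbs, 6 adverbs) this yields
    48 sentences in which every noun serves exactly twice as agent and twice
    as patient.

    Raises
    ------
    ConstraintInfeasibleError
        If the vocabulary counts make a constraint unsatisfiable; the
        message names the violated constraint.
    """
    vocab = list(vocab) if vocab is not None else default_vocabulary()
    nouns = _groups(vocab, "noun")
    verbs = _groups(vocab, "verb")
    adverbs = [v for v in vocab if v.pos == "adverb"]
    _feasibility_checks(nouns, verbs, adverbs)

    rng = np.random.default_rng(seed)
    ncats = list(nouns)
    cat_size = len(nouns[ncats[0]])

    # --- noun pairing -------------------------------------------------
    # same-category block: within each category, a derangement gives every
    # noun one same-category patient and one same-category agent partner.
    same_pairs: list[tuple[VocabularyItem, VocabularyItem]] = []
    for cat in ncats:
        agents = list(nouns[cat])
        patients = _derangement(agents, rng, max_retries)
        same_pairs += list(zip(agents, patients))

    # different-category block: agents of category r are dealt patients from
    # other categories according to a balanced category-count table, so each
    # noun is also a different-category patient exactly once.
    diff_pairs = _different_category_pairs(nouns, ncats, cat_size, rng, max_retries)

    # --- verb-category assignment (constraint 5) ----------------------
    vcats = list(verbs)
    same_vcat = _split_half_labels(same_pairs, key=lambda p: p[0].category, labels=vcats, rng=rng)
    diff_vcat = _balanced_diff_verb_labels(diff_pairs, ncats, vcats, cat_size, rng, max_retries)

    records = [
        {"agent": a, "patient": p, "vcat": vc}
        for (a, p), vc in zip(same_pairs, same_vcat)
    ] + [
        {"agent": a, "patient": p, "vcat": vc}
        for (a, p), vc in zip(diff_pairs, diff_vcat)
    ]

    # --- verb identity: each verb used equally often within its category
    uses = 2 * cat_size * len(ncats) // sum(len(v) for v in verbs.values())
    for vc in vcats:
        pool = [v for v in verbs[vc] for _ in range(uses)]
        rng.shuffle(pool)
        for rec in records:
            if rec["vcat"] == vc:
                rec["verb"] = pool.pop()

    # --- adverbs (constraint 6) ---------------------------------------
    _assign_adverbs(records, adverbs, ncats, rng, max_retries)

    # order sentences by (verb category, agent category, patient category)
    # for interpretable figures/matrices; ids follow that order.
    cat_rank = {c: k for k, c in enumerate(ncats)}
    vcat_rank = {c: k for k, c in enumerate(vcats)}
    records.sort(
        key=lambda r: (
            vcat_rank[r["vcat"]],
            cat_rank[r["agent"].category],
            cat_rank[r["patient"].category],
            r["agent"].surface,
        )
    )
    sentences = [
        SentenceStimulus(
            id=k + 1, adverb=r["adverb"], verb=r["verb"], agent=r["agent"], patient=r["patient"]
        )
        for k, r in enumerate(records)
    ]
    stimuli = StimulusSet(sentences, vocab)
    ok, report = check_constraints(stimuli)
    if not ok:  # pragma: no cover - internal consistency guard
        raise RuntimeError(f"generator produced an unbalanced set: {report}")
    return stimuli


def _different_category_pairs(nouns, ncats, cat_size, rng, cap):
    k = len(ncats)
    if cat_size % (k - 1) == 0:
        counts = {(r, c): cat_size // (k - 1) for r in ncats for c in ncats if r != c}
    else:
        counts = _sampled_offdiag_counts(ncats, cat_size, rng, cap)
    # deal agents of each category into patient-category slots, and patients
    # of each category into agent-category slots, then zip within each cell
    agent_deal: dict[tuple[str, str], list] = {}
    patient_deal: dict[tuple[str, str], list] = {}
    for r in ncats:
        pool = list(nouns[r])
        rng.shuffle(pool)
        for c in ncats:
            if c == r:
                continue
            agent_deal[(r, c)] = [pool.pop() for _ in range(counts[(r, c)])]
    for c in ncats:
        pool = list(nouns[c])
        rng.shuffle(pool)
        for r in ncats:
            if r == c:
                continue
            patient_deal[(r, c)] = [pool.pop() for _ in range(counts[(r, c)])]
    pairs = []
    for key in agent_deal:
        pairs += list(zip(agent_deal[key], patient_deal[key]))
    return pairs


def _sampled_offdiag_counts(ncats, cat_size, rng, cap):
    """Zero-diagonal count table with all row and column sums = cat_size."""
    k = len(ncats)
    for _ in range(cap):
        # random permutation-sum construction: cat_size derangements of cats
        table = Counter()
        ok = True
        for _ in range(cat_size):
            idx = np.arange(k)
            for _ in range(cap):
                perm = rng.permutation(idx)
                if not np.any(perm == idx):
                    break
            else:  # pragma: no cover
                ok = False
                break
            for r, c in zip(idx, perm):
                table[(ncats[r], ncats[c])] += 1
        if ok:
            return {(r, c): table[(r, c)] for r in ncats for c in ncats if r != c}
    raise ConstraintInfeasibleError(
        "constraint (1)/(2): could not balance different-category pairing"
    )  # pragma: no cover


def _split_half_labels(pairs, key, labels, rng):
    """Per group under `key`, assign half of the pairs each verb category."""
    out = [None] * len(pairs)
    groups: dict[str, list[int]] = {}
    for k, p in enumerate(pairs):
        groups.setdefault(key(p), []).append(k)
    for idxs in groups.values():
        idxs = list(idxs)
        rng.shuffle(idxs)
        half = len(idxs) // 2
        for k in idxs[:half]:
            out[k] = labels[0]
        for k in idxs[half:]:
            out[k] = labels[1]
    return out


def _balanced_diff_verb_labels(pairs, ncats, vcats, cat_size, rng, cap):
    """Verb categories for the different-category block.

    Each agent category must split half/half (easy to impose directly) and
    the induced patient-category counts must also split half/half; the
    latter is met by rejection over per-row choices.
    """
    half = cat_size // 2
    by_agent: dict[str, list[int]] = {}
    for k, (a, _p) in enumerate(pairs):
        by_agent.setdefault(a.category, []).append(k)
    for _ in range(cap):
        out = [None] * len(pairs)
        for idxs in by_agent.values():
            idxs = list(idxs)
            rng.shuffle(idxs)
            for k in idxs[:half]:
                out[k] = vcats[0]
            for k in idxs[half:]:
                out[k] = vcats[1]
        pat = Counter(
            (pairs[k][1].category, out[k]) for k in range(len(pairs))
        )
        if all(pat[(c, vcats[0])] == half for c in ncats):
            return out
    raise ConstraintInfeasibleError(
        "constraint (5): could not balance verb categories over patient categories"
    )


def _assign_adverbs(records, adverbs, ncats, rng, cap):
    per_cat = 2 * len(adverbs) // len(ncats)
    # bipartite assignment: each adverb covers two agent categories, each
    # category hosts per_cat distinct adverbs
    for _ in range(cap):
        slots = [a for a in adverbs for _ in range(2)]
        rng.shuffle(slots)
        cover = {c: slots[i * per_cat : (i + 1) * per_cat] for i, c in enumerate(ncats)}
        if all(len({a.surface for a in v}) == per_cat for v in cover.values()):
            break
    else:
        raise ConstraintInfeasibleError(
            "constraint (6): could not assign adverbs to category pairs"
        )
    vcats = sorted({r["vcat"] for r in records})
    for cat in ncats:
        cat_adverbs = cover[cat]
        for vc in vcats:
            idxs = [k for k, r in enumerate(records) if r["agent"].category == cat and r["vcat"] == vc]
            rng.shuffle(idxs)
            share = len(idxs) // len(cat_adverbs)
            for i, adv in enumerate(cat_adverbs):
                for k in idxs[i * share : (i + 1) * share]:
                    records[k]["adverb"] = adv


def check_constraints(stimuli: StimulusSet) -> tuple[bool, dict]:
    """Exhaustively tally the design constraints.

    Returns ``(ok, report)`` where the report holds the raw tallies used by
    tests: per-noun agent/patient counts, same/different-category patient
    counts per agent, category frequencies, the noun-category x verb-category
    co-occurrence table, and adverb coverage.
    """
    sents = stimuli.sentences
    agent_counts = Counter(s.agent.surface for s in sents)
    patient_counts = Counter(s.patient.surface for s in sents)
    same_diff = Counter(
        (s.agent.surface, s.agent.category == s.patient.category) for s in sents
    )
    cat_freq = Counter()
    for s in sents:
        cat_freq[s.agent.category] += 1
        cat_freq[s.patient.category] += 1
    cat_by_vcat = Counter()
    for s in sents:
        cat_by_vcat[(s.agent.category, s.verb.category)] += 1
        cat_by_vcat[(s.patient.category, s.verb.category)] += 1
    adverb_cats = {}
    adverb_vcats = Counter()
    for s in sents:
        adverb_cats.setdefault(s.adverb.surface, set()).add(s.agent.category)
        adverb_vcats[(s.adverb.surface, s.verb.category)] += 1

    nouns = [v.surface for v in stimuli.nouns]
    per_role = len(sents) // len(nouns) if nouns else 0
    ok = (
        all(agent_counts[x] == per_role for x in nouns)
        and all(patient_counts[x] == per_role for x in nouns)
        and all(
            same_diff[(x, True)] == same_diff[(x, False)] == per_role // 2 for x in nouns
        )
        and len(set(cat_freq.values())) == 1
        and len(set(cat_by_vcat.values())) == 1
        and all(len(v) == 2 for v in adverb_cats.values())
        and len(set(adverb_vcats.values())) == 1
    )
    report = {
        "agent_counts": dict(agent_counts),
        "patient_counts": dict(patient_counts),
        "same_diff_patients": dict(same_diff),
        "category_frequency": dict(cat_freq),
        "category_by_verb_category": dict(cat_by_vcat),
        "adverb_agent_categories": {k: sorted(v) for k, v in adverb_cats.items()},
        "adverb_by_verb_category": dict(adverb_vcats),
    }
    return ok, report


# ---------------------------------------------------------------------------
# reference similarity and model RDMs
# ---------------------------------------------------------------------------


def score_pair(s1: SentenceStimulus, s2: SentenceStimulus, measure: str) -> int:
    """Reference similarity (0-3) between two sentences.

    ``bow`` counts shared noun semantic categories as an unordered multiset
    plus a shared verb category; ``relational`` credits shared noun
    categories only in matching thematic roles (agent with agent, patient
    with patient) plus the shared verb category.  Two sentences whose nouns
    swap roles therefore score 2 under ``bow`` but 0 under ``relational``
    when the verb categories differ.
    """
    verb = int(s1.verb.category == s2.verb.category)
    if measure == "bow":
        m1 = Counter([s1.agent.category, s1.patient.category])
        m2 = Counter([s2.agent.category, s2.patient.category])
        shared = sum((m1 & m2).values())
        return shared + verb
    if measure == "relational":
        return (
            int(s1.agent.category == s2.agent.category)
            + int(s1.patient.category == s2.patient.category)
            + verb
        )
    raise ValueError(f"unknown measure {measure!r}; use 'bow' or 'relational'")


def reference_rdm(stimuli: StimulusSet, measure: str) -> RDM:
    """Reference dissimilarity RDM: 3 minus the reference similarity score."""
    n = stimuli.n
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = 3 - score_pair(stimuli.sentences[i], stimuli.sentences[j], measure)
        m[i, j] = m[j, i] = d
    return RDM(stimuli.labels, m)


_SENTENCE_FEATURES = {
    "verb_category": lambda s: s.verb.category,
    "agent_category": lambda s: s.agent.category,
    "patient_category": lambda s: s.patient.category,
    "verb_identity": lambda s: s.verb.surface,
    "adverb_identity": lambda s: s.adverb.surface,
    "adverb_daygroup": lambda s: s.adverb.category,
}


def build_model_rdm(stimuli, dimension: str) -> RDM:
    """Binary model RDM: 0 where two items share the named feature, else 1.

    ``stimuli`` is a :class:`StimulusSet` for the sentence dimensions, or a
    sequence of noun :class:`VocabularyItem` for ``noun_category``.
    """
    if dimension == "noun_category":
        if isinstance(stimuli, StimulusSet):
            items = stimuli.nouns
        else:
            items = list(stimuli)
        if not items or any(getattr(v, "pos", None) != "noun" for v in items):
            raise ValueError("noun_category model needs a noun item set")
        labels = [v.surface for v in items]
        feats = [v.category for v in items]
    elif dimension in _SENTENCE_FEATURES:
        if not isinstance(stimuli, StimulusSet):
            raise ValueError(f"{dimension} model needs a StimulusSet")
        labels = stimuli.labels
        f = _SENTENCE_FEATURES[dimension]
        feats = [f(s) for s in stimuli.sentences]
    else:
        raise ValueError(
            f"unknown model dimension {dimension!r}; "
            f"known: {MODEL_DIMENSIONS + ('noun_category',)}"
        )
    arr = np.array(feats, dtype=object)
    m = (arr[:, None] != arr[None, :]).astype(float)
    np.fill_diagonal(m, 0.0)
    return RDM(labels, m)
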