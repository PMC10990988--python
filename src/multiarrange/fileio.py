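"""File formats: RDM CSVs, trial logs, vocabulary/stimulus TSVs, embeddings.

All artifacts are plain text (UTF-8, comma-separated, '.' decimal; JSON
lines for trial logs).  Writers can attach a companion ``<name>.meta.json``
carrying the package version, seed and parameters needed to reproduce the
file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .arrangement import SessionState, TrialArrangement
from .rdm import RDM
from .stimulus_design import SentenceStimulus, StimulusSet, VocabularyItem

__all__ = [
    "read_rdm",
    "write_rdm",
    "read_trial_log",
    "write_trial_log",
    "read_vocabulary",
    "write_vocabulary",
    "read_stimuli",
    "write_stimuli",
    "read_embeddings",
    "write_metadata",
]


def write_metadata(path: str | Path, seed: int | None = None, **params) -> Path:
    """Write the companion ``<path>.meta.json`` for an artifact file."""
    path = Path(path)
    meta = {"version": __version__, "file": path.name, "seed": seed, **params}
    out = path.with_name(path.name + ".meta.json")
    out.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return out


# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------


def write_rdm(rdm: RDM, path: str | Path, seed: int | None = None, **params) -> Path:
    """Square CSV with item labels as header row and index column."""
    path = Path(path)
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, float_format="%.12g")
    write_metadata(path, seed=seed, kind="rdm", **params)
    return path


def read_rdm(path: str | Path) -> RDM:
    """Read an RDM from CSV.

    Accepts either the square layout (header row and index column of item
    labels) or long format with columns ``item_i, item_j, dissimilarity``.
    Symmetry is enforced on read (max asymmetry 1e-9) and NaN entries are
    rejected.
    """
    path = Path(path)
    flat = pd.read_csv(path)
    if {"item_i", "item_j", "dissimilarity"} <= {str(c) for c in flat.columns}:
        return _rdm_from_long(flat, path)
    df = pd.read_csv(path, index_col=0)
    cols = [str(c) for c in df.columns]
    labels = [str(x) for x in df.index]
    if labels != cols:
        raise ValueError(
            f"{path}: square RDM needs matching row/column labels "
            f"(or long format with item_i/item_j/dissimilarity columns)"
        )
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: RDM contains NaN entries")
    try:
        return RDM(labels, values)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def _rdm_from_long(df: pd.DataFrame, path: Path) -> RDM:
    need = {"item_i", "item_j", "dissimilarity"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: long format needs columns {sorted(need)}")
    labels: list[str] = []
    for col in ("item_i", "item_j"):
        for x in df[col].astype(str):
            if x not in labels:
                labels.append(x)
    n = len(labels)
    pos = {lab: k for k, lab in enumerate(labels)}
    m = np.full((n, n), np.nan)
    np.fill_diagonal(m, 0.0)
    for _, row in df.iterrows():
        i, j = pos[str(row["item_i"])], pos[str(row["item_j"])]
        v = float(row["dissimilarity"])
        for a, b in ((i, j), (j, i)):
            if not np.isnan(m[a, b]) and abs(m[a, b] - v) > 1e-9:
                raise ValueError(f"{path}: conflicting entries for pair ({i}, {j})")
            m[a, b] = v
    if np.isnan(m).any():
        raise ValueError(f"{path}: long format does not cover all pairs")
    return RDM(labels, m)


# ---------------------------------------------------------------------------
# trial logs (JSON lines)
# ---------------------------------------------------------------------------


def write_trial_log(
    state: SessionState, path: str | Path, subject: str | int = 0
) -> Path:
    """One record per trial: {subject, trial, items: [labels], x: [...], y: [...]}."""
    path = Path(path)
    with open(path, "w") as fh:
        for arr in state.trials:
            rec = {
                "subject": subject,
                "trial": arr.trial_index,
                "items": [state.labels[k] for k in arr.item_ids],
                "x": [float(v) for v in arr.coords[:, 0]],
                "y": [float(v) for v in arr.coords[:, 1]],
            }
            fh.write(json.dumps(rec) + "\n")
    return path


def read_trial_log(path: str | Path) -> dict[str | int, list[dict]]:
    """Parse a JSON-lines trial log, grouped by subject."""
    path = Path(path)
    out: dict[str | int, list[dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON ({exc})") from None
            for key in ("items", "x", "y"):
                if key not in rec:
                    raise ValueError(f"{path}:{lineno}: missing field {key!r}")
            if not len(rec["items"]) == len(rec["x"]) == len(rec["y"]):
                raise ValueError(f"{path}:{lineno}: items/x/y length mismatch")
            out.setdefault(rec.get("subject", 0), []).append(rec)
    return out


def session_from_records(
    records: Sequence[Mapping], config, labels: Sequence[str] | None = None
) -> SessionState:
    """Rebuild a SessionState from trial-log records (one subject)."""
    if labels is None:
        labels = []
        for rec in records:
            for it in rec["items"]:
                if it not in labels:
                    labels.append(it)
        labels = sorted(labels)
    pos = {lab: k for k, lab in enumerate(labels)}
    state = SessionState(labels, config)
    for t, rec in enumerate(sorted(records, key=lambda r: r.get("trial", 0))):
        ids = [pos[it] for it in rec["items"]]
        coords = np.column_stack([rec["x"], rec["y"]])
        state.add_trial(TrialArrangement(t, ids, coords))
    return state


# ---------------------------------------------------------------------------
# vocabulary and stimuli (TSV)
# ---------------------------------------------------------------------------


def write_vocabulary(vocab: Iterable[VocabularyItem], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{"surface": v.surface, "pos": v.pos, "category": v.category} for v in vocab]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_vocabulary(path: str | Path) -> list[VocabularyItem]:
    df = pd.read_csv(path, sep="\t")
    need = {"surface", "pos", "category"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: vocabulary TSV needs columns {sorted(need)}")
    return [
        VocabularyItem(str(r.surface), str(r.pos), str(r.category))
        for r in df.itertuples()
    ]


def write_stimuli(stimuli: StimulusSet, path: str | Path, seed: int | None = None) -> Path:
    path = Path(path)
    rows = [
        {
            "id": s.id,
            "adverb": s.adverb.surface,
            "verb": s.verb.surface,
            "agent": s.agent.surface,
            "patient": s.patient.surface,
            "verb_cat": s.verb.category,
            "agent_cat": s.agent.category,
            "patient_cat": s.patient.category,
            "surface": s.surface,
        }
        for s in stimuli.sentences
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    write_metadata(path, seed=seed, kind="stimuli", n_sentences=stimuli.n)
    return path


def read_stimuli(path: str | Path, vocabulary: Sequence[VocabularyItem] | None = None) -> StimulusSet:
    """Read a stimulus TSV back into a StimulusSet.

    If ``vocabulary`` is omitted it is reconstructed from the table (adverb
    day-groups then default to a single group unless the surface matches the
    built-in inventory).
    """
    from .stimulus_design import _ADVERBS  # adverb day-group lookup

    df = pd.read_csv(path, sep="\t")
    need = {"id", "adverb", "verb", "agent", "patient", "verb_cat", "agent_cat", "patient_cat"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: stimulus TSV needs columns {sorted(need)}")
    daygroup = dict(_ADVERBS)
    vocab_map: dict[tuple[str, str], VocabularyItem] = {}
    if vocabulary:
        vocab_map = {(v.pos, v.surface): v for v in vocabulary}

    def item(pos: str, surface: str, category: str) -> VocabularyItem:
        key = (pos, surface)
        if key not in vocab_map:
            vocab_map[key] = VocabularyItem(surface, pos, category)
        return vocab_map[key]

    sentences = []
    for r in df.itertuples():
        sentences.append(
            SentenceStimulus(
                id=int(r.id),
                adverb=item("adverb", str(r.adverb), daygroup.get(str(r.adverb), "none")),
                verb=item("verb", str(r.verb), str(r.verb_cat)),
                agent=item("noun", str(r.agent), str(r.agent_cat)),
                patient=item("noun", str(r.patient), str(r.patient_cat)),
            )
        )
    return StimulusSet(sentences, list(vocab_map.values()))


def read_embeddings(path: str | Path) -> pd.DataFrame:
    """Embeddings CSV: first column item id, remaining columns the vector."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an item column plus vector columns")
    df = df.set_index(df.columns[0])
    return df.astype(float)
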