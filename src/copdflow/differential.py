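"""Differential-diagnosis support.

COPD shares its clinical picture with several other respiratory diseases;
this module encodes a seven-disease feature knowledge base (COPD, asthma,
congestive heart failure, bronchiectasis, tuberculosis, obliterative
bronchiolitis, diffuse panbronchiolitis) and ranks alternatives for an
observed presentation.  The output is decision support — "key information
on pathologies with a similar clinical picture" — never an automated
diagnosis.

Scoring is Jaccard similarity over canonical feature keys: explainable,
bounded in [0, 1], and monotone in shared features.  A plug point accepts
any callable ``(features, profile) -> float`` for weighted variants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

EXPECTED_DIAGNOSES = (
    "COPD",
    "asthma",
    "congestive heart failure",
    "bronchiectasis",
    "tuberculosis",
    "obliterative bronchiolitis",
    "diffuse panbronchiolitis",
)


class KnowledgeBaseError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosisProfile:
    name: str
    features: frozenset[str]
    source_text: dict[str, str] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class KnowledgeBase:
    profiles: tuple[DiagnosisProfile, ...]
    vocabulary: frozenset[str]

    def profile(self, name: str) -> DiagnosisProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)


def load_vocabulary(path: str | Path) -> dict[str, str]:
    """Feature vocabulary: canonical key -> human definition."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    vocab = {r["key"]: r["definition"] for r in rows}
    if len(vocab) != len(rows):
        raise KnowledgeBaseError("duplicate keys in vocabulary")
    return vocab


def load_knowledge_base(path: str | Path, vocabulary_path: str | Path) -> KnowledgeBase:
    """Load the diagnosis/feature table, validating against the vocabulary.

    The bundled base must contain exactly the seven expected diagnoses; a
    missing or duplicated diagnosis, or a feature key outside the
    vocabulary, is a validation error naming the offender.
    """
    vocab = load_vocabulary(vocabulary_path)
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise KnowledgeBaseError(f"{path}: empty knowledge base")
    by_dx: dict[str, dict[str, str]] = {}
    for r in rows:
        dx, key = r["diagnosis"], r["feature_key"]
        if key not in vocab:
            raise KnowledgeBaseError(f"unknown feature key {key!r} in diagnosis {dx!r}")
        slot = by_dx.setdefault(dx, {})
        if key in slot:
            raise KnowledgeBaseError(f"duplicate feature {key!r} in diagnosis {dx!r}")
        slot[key] = r.get("source_text", "")
    missing = set(EXPECTED_DIAGNOSES) - set(by_dx)
    if missing:
        raise KnowledgeBaseError(f"knowledge base missing diagnoses: {sorted(missing)}")
    profiles = tuple(
        DiagnosisProfile(name=dx, features=frozenset(by_dx[dx]), source_text=by_dx[dx])
        for dx in by_dx  # file order is the fixed tie-break order
    )
    return KnowledgeBase(profiles=profiles, vocabulary=frozenset(vocab))


def parse_presentation(keys: Iterable[str], kb: KnowledgeBase) -> frozenset[str]:
    """Canonicalize observed feature keys; unknown keys are rejected."""
    keys = frozenset(keys)
    unknown = keys - kb.vocabulary
    if unknown:
        raise KnowledgeBaseError(f"unknown presentation features: {sorted(unknown)}")
    return keys


def jaccard(features: frozenset[str], profile_features: frozenset[str]) -> float:
    union = features | profile_features
    if not union:
        return 0.0
    return len(features & profile_features) / len(union)


@dataclass(frozen=True)
class DifferentialSuggestion:
    diagnosis: str
    score: float
    matched_features: tuple[str, ...]


def suggest_differentials(
    features: Iterable[str],
    kb: KnowledgeBase,
    scorer: Optional[Callable[[frozenset[str], frozenset[str]], float]] = None,
) -> list[DifferentialSuggestion]:
    """Rank all knowledge-base diagnoses against an observed presentation.

    Sorted by score descending; ties broken by the knowledge base's fixed
    diagnosis order.  Matched features are listed per diagnosis so the
    clinician can see *why* a disease scored.
    """
    fs = parse_presentation(features, kb)
    score = scorer or jaccard
    out = [
        DifferentialSuggestion(
            diagnosis=p.name,
            score=score(fs, p.features),
            matched_features=tuple(sorted(fs & p.features)),
        )
        for p in kb.profiles
    ]
    order = {p.name: i for i, p in enumerate(kb.profiles)}
    out.sort(key=lambda s: (-s.score, order[s.diagnosis]))
    return out
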