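"""Random-forest typing of Ab10 haplotypes (cytological types I/II/III).

A forest is trained on the scaled diagnostic-bin tag index of typed
control samples (70/30 stratified split, holdout accuracy reported).
Experimental Ab10-positive samples are typed by tree vote: a call is
made only when at least 65% of trees agree, otherwise the haplotype is
ambiguous — natural Ab10 variation (including recombinants between
types) deliberately falls into the ambiguous class.  The bins the
forest leans on hardest (mean decrease in Gini impurity) feed a PCA for
exploring type variation beyond the three reference types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .io import ControlManifest
from .tag_index import BinIndexMatrix

__all__ = ["TypingResult", "train_typer", "call_types", "gini_pca"]

DEFAULT_VOTE_THRESHOLD = 0.65
AB10_TYPES = ("I", "II", "III")


@dataclass
class TypingResult:
    sample_id: str
    votes: dict[str, float]  # type -> fraction of trees
    call: str  # I / II / III / ambiguous
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD


def _typed_controls(index: BinIndexMatrix, manifest: ControlManifest) -> list[str]:
    t = manifest.table
    ids = t.index[
        (t["sample_class"] == "control")
        & (t["ab10_type"].isin(AB10_TYPES))
    ]
    return [s for s in ids if s in index.sample_ids]


def train_typer(
    index: BinIndexMatrix,
    manifest: ControlManifest,
    train_frac: float = 0.70,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[RandomForestClassifier, float]:
    """Fit the type classifier on a stratified 70% split of typed
    controls; returns (model, holdout accuracy on the remaining 30%).

    Raises if any type would be absent from the training split.
    """
    ids = _typed_controls(index, manifest)
    labels = manifest.table.loc[ids, "ab10_type"]
    counts = labels.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(
            f"need >= 2 typed controls per type to stratify, got {counts.to_dict()}"
        )
    X = index.values[ids].to_numpy(dtype=float).T
    train_ids, test_ids = train_test_split(
        ids, train_size=train_frac, stratify=labels, random_state=seed
    )
    if set(labels[train_ids]) != set(labels):
        raise ValueError("a type is absent from the training split; re-stratify")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    idx = {s: i for i, s in enumerate(ids)}
    model.fit(X[[idx[s] for s in train_ids]], labels[train_ids])
    pred = model.predict(X[[idx[s] for s in test_ids]])
    accuracy = float(np.mean(pred == labels[test_ids].to_numpy()))
    return model, accuracy


def _tree_votes(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for each class (samples x classes)."""
    n = X.shape[0]
    votes = np.zeros((n, len(model.classes_)))
    class_idx = {c: i for i, c in enumerate(model.classes_)}
    for tree in model.estimators_:
        pred = model.classes_[np.argmax(tree.predict_proba(X), axis=1)]
        for i, p in enumerate(pred):
            votes[i, class_idx[p]] += 1
    return votes / len(model.estimators_)


def call_types(
    model: RandomForestClassifier,
    index: BinIndexMatrix,
    sample_ids: list[str] | None = None,
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
) -> list[TypingResult]:
    """Type each sample by tree vote; a call requires the top type to
    reach ``vote_threshold`` of trees (boundary inclusive)."""
    if sample_ids is None:
        sample_ids = index.sample_ids
    X = index.values[list(sample_ids)].to_numpy(dtype=float).T
    votes = _tree_votes(model, X)
    out = []
    for i, s in enumerate(sample_ids):
        v = {str(c): float(votes[i, j]) for j, c in enumerate(model.classes_)}
        top = max(v, key=v.get)
        call = top if v[top] >= vote_threshold else "ambiguous"
        out.append(TypingResult(s, v, call, vote_threshold))
    return out


def gini_pca(
    model: RandomForestClassifier,
    index: BinIndexMatrix,
    top_k: int = 25,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on the top-``top_k`` bins by mean decrease in Gini impurity.

    Returns (per-sample PC scores, variance fraction per PC).
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    top_k = min(top_k, len(index.bins))
    if sample_ids is None:
        sample_ids = index.sample_ids
    importance = model.feature_importances_
    order = np.argsort(importance)[::-1][:top_k]
    X = index.values[list(sample_ids)].to_numpy(dtype=float).T[:, order]
    n_comp = min(X.shape[0], top_k)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    score_df = pd.DataFrame(
        scores,
        index=list(sample_ids),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, pca.explained_variance_ratio_
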