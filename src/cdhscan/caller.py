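"""Control-anchored iterative k-means presence/absence calling.

The caller never trusts a cluster on geometry alone: every k-means
round is anchored by characterized control samples, a cluster is named
positive or negative only when >= 80% of its control members share that
status, and a round in which any control lands in the wrong cluster is
redrawn.  Experimental samples are spiked into control-dominated rounds
in small numbers, inherit their cluster's name, and are assayed
repeatedly (125 rounds by default); only samples whose calls agree 95%
of the time receive a final presence/absence label, all others are
ambiguous.

Two workflow wrappers encode the haplotype-specific logic: the
chromosome-10 pipeline calls Ab10 first and assays only Ab10-negative
samples for K10L2 (the K10L2 signal cannot be told apart from Ab10),
and the B-chromosome pipeline runs a high-copy stage before a low-copy
stage so many-copy samples cannot distort the low-copy clustering.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import BinDefinition, CallTable, ControlManifest
from .tag_index import BinIndexMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterRound",
    "ConsensusState",
    "name_clusters",
    "control_validation",
    "experimental_round",
    "consensus_call",
    "run_cdh_calling",
    "chr10_workflow",
    "b_two_stage_workflow",
    "select_diagnostic_bins",
]

DEFAULT_PURITY = 0.80
DEFAULT_ROUNDS = 125
DEFAULT_CONSENSUS = 0.95
DEFAULT_SPIKE = {"Ab10": 0.25, "K10L2": 0.25, "B": 0.10}
DEFAULT_RETRY_CAP = 50


@dataclass
class ClusterRound:
    """One k=2 clustering round and its control-derived naming."""

    member_ids: list[str]
    assignments: dict[str, int]
    cluster_labels: dict[int, str]  # cluster -> positive / negative / unnamed
    controls_correct: bool
    valid: bool


@dataclass
class ConsensusState:
    """Per-sample tallies of positive/negative calls over rounds."""

    tallies: dict[str, dict[str, int]]
    target_rounds: int = DEFAULT_ROUNDS
    threshold: float = DEFAULT_CONSENSUS

    def record(self, sample_id: str, label: str) -> None:
        self.tallies.setdefault(sample_id, {"positive": 0, "negative": 0})
        self.tallies[sample_id][label] += 1

    def completed(self, sample_id: str) -> int:
        t = self.tallies.get(sample_id, {})
        return sum(t.values())


def _kmeans_assign(X: np.ndarray, seed: int, n_init: int = 10) -> np.ndarray:
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    return km.fit_predict(X)


def name_clusters(
    assignments: Mapping[str, int],
    manifest: ControlManifest,
    cdh: str,
    purity: float = DEFAULT_PURITY,
) -> dict[int, str]:
    """Name each cluster by the status of its control members.

    Purity is computed over controls only (experimental members never
    influence naming).  A cluster is 'positive' or 'negative' only when
    at least ``purity`` of its controls share that status; otherwise it
    stays 'unnamed'.  A cluster with no controls is unnamed.
    """
    status = manifest.status(cdh)
    is_control = manifest.table["sample_class"] == "control"
    labels: dict[int, str] = {}
    for cluster in (0, 1):
        members = [s for s, c in assignments.items() if c == cluster]
        ctrl = [
            s for s in members
            if s in status.index and is_control.get(s, False)
            and status[s] in ("positive", "negative")
        ]
        if not ctrl:
            labels[cluster] = "unnamed"
            continue
        n_pos = sum(status[s] == "positive" for s in ctrl)
        frac_pos = n_pos / len(ctrl)
        if frac_pos >= purity:
            labels[cluster] = "positive"
        elif 1 - frac_pos >= purity:
            labels[cluster] = "negative"
        else:
            labels[cluster] = "unnamed"
    return labels


def _labels_valid(labels: Mapping[int, str]) -> bool:
    """A round is usable only if one cluster is positive and the other negative."""
    return sorted(labels.values()) == ["negative", "positive"]


def _sample_vectors(index: BinIndexMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    return index.values[list(sample_ids)].to_numpy(dtype=float).T


def control_validation(
    index: BinIndexMatrix,
    manifest: ControlManifest,
    cdh: str,
    copy_class: str,
    n_subgroups: int = 3,
    n_reps: int = 100,
    seed: int = 0,
    purity: float = DEFAULT_PURITY,
    min_per_status: int = 2,
) -> pd.Series:
    """Repeatedly cluster random subgroups of controls and score them
    against their known status.

    Positive controls of one copy class are validated together with the
    negative controls (high- and low-copy panels run separately so
    clustering reflects presence/absence, not dosage).  Each repetition
    splits the panel into ``n_subgroups`` random groups, k-means (k=2)
    each, names clusters by control purity, and scores each control
    correct when its cluster is named its true status.  Returns the
    per-control fraction of repetitions scored correct.

    A panel too small to split (fewer than ``n_subgroups *
    min_per_status`` of either status) is clustered as a single group.
    """
    pos = manifest.controls_for(cdh, status="positive", copy_class=copy_class)
    neg = manifest.controls_for(cdh, status="negative")
    panel = [s for s in pos + neg if s in index.sample_ids]
    if len(panel) < 4:
        raise ValueError(f"control panel for {cdh}/{copy_class} too small: {len(panel)}")
    status = manifest.status(cdh)
    n_pos = sum(status[s] == "positive" for s in panel)
    n_neg = len(panel) - n_pos
    groups_possible = min(n_pos, n_neg) >= n_subgroups * min_per_status
    eff_subgroups = n_subgroups if groups_possible else 1
    if not groups_possible:
        logger.info(
            "%s/%s: %d pos / %d neg controls too few for %d subgroups; "
            "clustering as a single group", cdh, copy_class, n_pos, n_neg, n_subgroups
        )

    rng = np.random.default_rng(seed)
    correct = {s: 0 for s in panel}
    for _ in range(n_reps):
        order = list(rng.permutation(panel))
        groups = [list(g) for g in np.array_split(order, eff_subgroups)]
        # merge a subgroup lacking both statuses upward into the next one
        merged: list[list[str]] = []
        for g in groups:
            gp = sum(status[s] == "positive" for s in g)
            gn = len(g) - gp
            if merged and (gp < min_per_status or gn < min_per_status):
                logger.debug("merging undersized subgroup upward")
                merged[-1].extend(g)
            else:
                merged.append(g)
        for g in merged:
            X = _sample_vectors(index, g)
            assign = dict(
                zip(g, _kmeans_assign(X, int(rng.integers(0, 2**31 - 1))))
            )
            labels = name_clusters(assign, manifest, cdh, purity=purity)
            for s in g:
                if labels[assign[s]] == status[s]:
                    correct[s] += 1
    return pd.Series({s: correct[s] / n_reps for s in panel}, name="accuracy")


def experimental_round(
    index: BinIndexMatrix,
    manifest: ControlManifest,
    cdh: str,
    batch: Sequence[str],
    pos_pool: Sequence[str],
    neg_pool: Sequence[str],
    rng: np.random.Generator,
    purity: float = DEFAULT_PURITY,
    retry_cap: int = DEFAULT_RETRY_CAP,
    n_init: int = 10,
) -> ClusterRound | None:
    """One spiked clustering round for a batch of experimental samples.

    Draws roughly equal numbers of positive and negative controls,
    clusters them together with the batch, and names the clusters.  A
    round where naming fails or any control lands in a cluster not
    named its own status is redrawn with fresh controls, up to
    ``retry_cap`` attempts; ``None`` signals an abandoned round.
    """
    status = manifest.status(cdh)
    n_each = min(len(pos_pool), len(neg_pool))
    if n_each < 2:
        raise ValueError(f"need >= 2 controls of each status for {cdh}")
    for _ in range(retry_cap):
        pos = list(rng.choice(pos_pool, size=n_each, replace=False))
        neg = list(rng.choice(neg_pool, size=n_each, replace=False))
        members = pos + neg + list(batch)
        X = _sample_vectors(index, members)
        assign = dict(
            zip(members, _kmeans_assign(X, int(rng.integers(0, 2**31 - 1)), n_init))
        )
        labels = name_clusters(assign, manifest, cdh, purity=purity)
        if not _labels_valid(labels):
            continue
        controls_ok = all(labels[assign[s]] == status[s] for s in pos + neg)
        if controls_ok:
            return ClusterRound(members, assign, labels, True, True)
    logger.warning("%s: round abandoned after %d control redraws", cdh, retry_cap)
    return None


def consensus_call(state: ConsensusState, cdh: str) -> CallTable:
    """Collapse per-round tallies into final calls.

    A sample is called positive/negative when its majority class holds
    at least ``state.threshold`` of recorded rounds; otherwise
    ambiguous.  A sample with zero recorded rounds is ambiguous with
    consensus_fraction 0.
    """
    rows = []
    for sid, tally in state.tallies.items():
        n = tally["positive"] + tally["negative"]
        if n == 0:
            rows.append((sid, cdh, "ambiguous", 0.0, 0))
            continue
        major = "positive" if tally["positive"] >= tally["negative"] else "negative"
        frac = tally[major] / n
        call = major if frac >= state.threshold else "ambiguous"
        rows.append((sid, cdh, call, frac, n))
    table = pd.DataFrame(
        rows, columns=["sample_id", "cdh", "call", "consensus_fraction", "n_rounds"]
    )
    return CallTable(table.sort_values("sample_id").reset_index(drop=True))


def run_cdh_calling(
    index: BinIndexMatrix,
    manifest: ControlManifest,
    cdh: str,
    experimental_ids: Sequence[str],
    seed: int = 0,
    rounds: int = DEFAULT_ROUNDS,
    consensus: float = DEFAULT_CONSENSUS,
    purity: float = DEFAULT_PURITY,
    spike_fraction: float | None = None,
    copy_class: str | None = "low",
    retry_cap: int = DEFAULT_RETRY_CAP,
    n_init: int = 10,
) -> CallTable:
    """Call one CDH on a set of experimental samples.

    Rounds are organized so every experimental sample accrues exactly
    ``rounds`` valid calls; abandoned rounds do not count.  Controls are
    drawn fresh for every batch.
    """
    if spike_fraction is None:
        spike_fraction = DEFAULT_SPIKE.get(cdh, 0.25)
    pos_pool = [
        s for s in manifest.controls_for(cdh, status="positive", copy_class=copy_class)
        if s in index.sample_ids
    ]
    if not pos_pool and copy_class is not None:
        # fall back to any positive controls when the class is unpopulated
        pos_pool = [
            s for s in manifest.controls_for(cdh, status="positive")
            if s in index.sample_ids
        ]
    neg_pool = [
        s for s in manifest.controls_for(cdh, status="negative")
        if s in index.sample_ids
    ]
    experimental_ids = [s for s in experimental_ids if s in index.sample_ids]
    state = ConsensusState(
        {s: {"positive": 0, "negative": 0} for s in experimental_ids},
        target_rounds=rounds,
        threshold=consensus,
    )
    if experimental_ids:
        rng = np.random.default_rng(seed)
        n_controls = 2 * min(len(pos_pool), len(neg_pool))
        batch_size = max(1, int(np.floor(spike_fraction * n_controls)))
        max_passes = rounds * 10  # safety valve; abandoned rounds are rare
        for _ in range(max_passes):
            pending = [s for s in experimental_ids if state.completed(s) < rounds]
            if not pending:
                break
            pending = list(rng.permutation(pending))
            for i in range(0, len(pending), batch_size):
                batch = pending[i : i + batch_size]
                rnd = experimental_round(
                    index, manifest, cdh, batch, pos_pool, neg_pool, rng,
                    purity=purity, retry_cap=retry_cap, n_init=n_init,
                )
                if rnd is None:
                    continue  # batch re-queued on the next pass
                for s in batch:
                    label = rnd.cluster_labels[rnd.assignments[s]]
                    if label in ("positive", "negative"):
                        state.record(s, label)
        else:
            logger.warning("%s: pass cap reached with samples below %d rounds", cdh, rounds)
    return consensus_call(state, cdh)


def chr10_workflow(
    index_ab10: BinIndexMatrix,
    index_k10l2: BinIndexMatrix,
    manifest: ControlManifest,
    experimental_ids: Sequence[str],
    seed: int = 0,
    include_ambiguous_in_k10l2: bool = False,
    **call_kw,
) -> CallTable:
    """Sequential chromosome-10 calling: Ab10 first, then K10L2 on
    Ab10-negative samples only.

    The K10L2 detector responds to Ab10 as well, so Ab10-positive (and,
    by default, Ab10-ambiguous) samples receive K10L2 = 'unknown'.
    """
    ab10_calls = run_cdh_calling(
        index_ab10, manifest, "Ab10", experimental_ids, seed=seed, **call_kw
    )
    eligible = set(ab10_calls.samples_with_call("Ab10", "negative"))
    if include_ambiguous_in_k10l2:
        eligible |= set(ab10_calls.samples_with_call("Ab10", "ambiguous"))
    k10l2_calls = run_cdh_calling(
        index_k10l2, manifest, "K10L2",
        [s for s in experimental_ids if s in eligible],
        seed=seed + 1, **call_kw,
    )
    skipped = [s for s in experimental_ids if s not in eligible]
    extra = pd.DataFrame(
        [(s, "K10L2", "unknown", 0.0, 0) for s in skipped],
        columns=["sample_id", "cdh", "call", "consensus_fraction", "n_rounds"],
    )
    table = pd.concat([ab10_calls.table, k10l2_calls.table, extra], ignore_index=True)
    return CallTable(table.sort_values(["cdh", "sample_id"]).reset_index(drop=True))


def b_two_stage_workflow(
    index_b: BinIndexMatrix,
    manifest: ControlManifest,
    experimental_ids: Sequence[str],
    seed: int = 0,
    **call_kw,
) -> CallTable:
    """Two-stage B chromosome calling.

    Stage 1 uses high-copy controls to pull out high-copy carriers
    (whose extreme dosage would otherwise distort clustering); every
    sample not called positive there is re-assayed against low-copy
    controls.  The final call is positive if either stage is positive,
    otherwise the stage-2 call.
    """
    call_kw.setdefault("spike_fraction", DEFAULT_SPIKE["B"])
    stage1 = run_cdh_calling(
        index_b, manifest, "B", experimental_ids, seed=seed,
        copy_class="high", **call_kw,
    )
    stage1_pos = set(stage1.samples_with_call("B", "positive"))
    remaining = [s for s in experimental_ids if s not in stage1_pos]
    stage2 = run_cdh_calling(
        index_b, manifest, "B", remaining, seed=seed + 1,
        copy_class="low", **call_kw,
    )
    rows = []
    s1 = stage1.table.set_index("sample_id")
    s2 = stage2.table.set_index("sample_id")
    for s in experimental_ids:
        if s in stage1_pos:
            r = s1.loc[s]
        else:
            r = s2.loc[s]
        rows.append((s, "B", r["call"], r["consensus_fraction"], r["n_rounds"]))
    table = pd.DataFrame(
        rows, columns=["sample_id", "cdh", "call", "consensus_fraction", "n_rounds"]
    )
    return CallTable(table.sort_values("sample_id").reset_index(drop=True))


def select_diagnostic_bins(
    index: BinIndexMatrix,
    manifest: ControlManifest,
    cdh: str,
    threshold: float = 0.5,
) -> list[BinDefinition]:
    """Bins whose mean scaled index differs between positive and
    negative controls by at least ``threshold`` — the regions of stark
    carrier/non-carrier contrast the caller operates on."""
    if not index.scaled:
        raise ValueError("diagnostic bin selection expects a scaled matrix")
    pos = [s for s in manifest.controls_for(cdh, "positive") if s in index.sample_ids]
    neg = [s for s in manifest.controls_for(cdh, "negative") if s in index.sample_ids]
    if not pos or not neg:
        raise ValueError(f"need positive and negative controls for {cdh}")
    diff = (
        index.values[pos].mean(axis=1) - index.values[neg].mean(axis=1)
    ).abs()
    return [b for b, d in zip(index.bins, diff) if d >= threshold]
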