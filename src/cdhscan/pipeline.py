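"""End-to-end orchestration: tag index -> calling -> copy number ->
typing, with a single declarative config, one master seed, and a
provenance header on every output file.

A master seed deterministically spawns per-stage sub-seeds
(:func:`stage_seeds`), so a stage can be re-run in isolation and still
reproduce the full run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import numpy as np
import yaml

from . import caller, copy_number as cn, ab10_typing as typing_mod
from .io import (
    ControlManifest,
    read_bins,
    read_manifest,
    read_tag_matrix,
    write_call_table,
)
from .tag_index import compute_tag_index

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "stage_seeds"]

STAGES = ("tagindex", "ab10", "k10l2", "b", "copynumber", "typing", "association")


@dataclass
class RunConfig:
    """Every input path and threshold of the pipeline, with defaults
    matching the published protocol."""

    counts_path: str = ""
    bed_path: str = ""
    manifest_path: str = ""
    bins_path: str = ""          # diagnostic bins (diagnostic_for set)
    sc_bins_path: str = ""       # single-copy core-gene bins
    out_dir: str = "cdhscan_out"

    bin_size: int = 1_000_000
    min_mapq: int = 20
    blank_offset: float = 0.001
    explicit_cutoff: float | None = None
    count_mode: str = "nonzero"

    purity: float = 0.80
    spike_fraction_chr10: float = 0.25
    spike_fraction_b: float = 0.10
    rounds: int = 125
    consensus: float = 0.95
    retry_cap: int = 50
    kmeans_n_init: int = 10
    chr10_copy_class: str = "low"

    rf_train_frac: float = 0.70
    rf_n_trees: int = 500
    vote_threshold: float = 0.65
    gini_top_k: int = 25

    gwas_threshold: float = 5e-8
    alpha: float = 0.01
    collinearity_threshold: float = 0.70
    structure_k: int = 10

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the scientific parameters (the output location is
        excluded so moving a run does not change its provenance)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(STAGES, children)
    }


def _write(df: pd.DataFrame, path: Path, provenance: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(provenance)
        df.to_csv(fh, sep="\t", index=index)


def run_full(config: RunConfig) -> Path:
    """Execute the full detection workflow and write all artifacts.

    Stages: tag index (RPM, blank cutoff, mapq filter, 1 Mb binning,
    scaling) -> sequential Ab10/K10L2 calling -> two-stage B calling ->
    pseudo copy number with zygosity -> random-forest Ab10 typing of
    Ab10-positive samples.  Identical config + seed reproduces every
    output byte-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    prov = f"# cdhscan config={config.digest()} seed={config.seed}\n"
    seeds = stage_seeds(config.seed)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("tagindex")
        tags = read_tag_matrix(config.counts_path, config.bed_path)
        manifest = read_manifest(config.manifest_path)
        bins = read_bins(config.bins_path)
        sc_bins = read_bins(config.sc_bins_path) if config.sc_bins_path else []
        unscaled, scaled = compute_tag_index(
            tags, manifest, list(bins) + list(sc_bins),
            min_mapq=config.min_mapq, blank_offset=config.blank_offset,
            explicit_cutoff=config.explicit_cutoff, count_mode=config.count_mode,
        )
        _write(unscaled.values, out / "tag_index_unscaled.tsv", prov, index=True)
        _write(scaled.values, out / "tag_index_scaled.tsv", prov, index=True)

        experimental = [s for s in manifest.experimental if s in scaled.sample_ids]
        call_kw = dict(
            rounds=config.rounds, consensus=config.consensus, purity=config.purity,
            retry_cap=config.retry_cap, n_init=config.kmeans_n_init,
        )

        stage("chr10")
        cdhs = manifest.cdh_names
        tables = []
        if "Ab10" in cdhs and "K10L2" in cdhs:
            chr10 = caller.chr10_workflow(
                scaled.diagnostic_subset("Ab10"),
                scaled.diagnostic_subset("K10L2"),
                manifest, experimental, seed=seeds["ab10"],
                spike_fraction=config.spike_fraction_chr10,
                copy_class=config.chr10_copy_class, **call_kw,
            )
            tables.append(chr10.table)

        stage("b")
        if "B" in cdhs:
            b_calls = caller.b_two_stage_workflow(
                scaled.diagnostic_subset("B"), manifest, experimental,
                seed=seeds["b"], spike_fraction=config.spike_fraction_b, **call_kw,
            )
            tables.append(b_calls.table)
        calls = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
            columns=["sample_id", "cdh", "call", "consensus_fraction", "n_rounds"]
        )
        _write(calls, out / "calls.tsv", prov)

        stage("copynumber")
        if sc_bins:
            sc_subset = _subset_by_labels(unscaled, [b.label for b in sc_bins])
            cn_frames = []
            for cdh in cdhs:
                diag = unscaled.diagnostic_subset(cdh)
                if not diag.bins:
                    continue
                ests = cn.pseudo_copy_number(diag, sc_subset, cdh)
                if cdh in ("Ab10", "K10L2"):
                    ctrl_ids = set(manifest.controls_for(cdh, status="positive"))
                    ctrl_ests = [e for e in ests if e.sample_id in ctrl_ids]
                    ests = cn.classify_zygosity(ests, ctrl_ests, manifest, cdh)
                    # zygosity is meaningful only for carriers
                    carriers = ctrl_ids | set(
                        calls.loc[
                            (calls["cdh"] == cdh) & (calls["call"] == "positive"),
                            "sample_id",
                        ]
                    )
                    for e in ests:
                        if e.sample_id not in carriers:
                            e.zygosity = "unknown"
                cn_frames.append(cn.estimates_to_frame(ests))
            if cn_frames:
                _write(pd.concat(cn_frames, ignore_index=True),
                       out / "copy_number.tsv", prov)

        stage("typing")
        if "Ab10" in cdhs:
            ab10_scaled = scaled.diagnostic_subset("Ab10")
            typed = typing_mod._typed_controls(ab10_scaled, manifest)
            counts = manifest.table.loc[typed, "ab10_type"].value_counts()
            if len(counts) >= 2 and (counts >= 2).all():
                model, acc = typing_mod.train_typer(
                    ab10_scaled, manifest, train_frac=config.rf_train_frac,
                    seed=seeds["typing"], n_trees=config.rf_n_trees,
                )
                pos = calls.loc[
                    (calls["cdh"] == "Ab10") & (calls["call"] == "positive"),
                    "sample_id",
                ].tolist()
                results = typing_mod.call_types(
                    model, ab10_scaled, pos, vote_threshold=config.vote_threshold
                ) if pos else []
                tdf = pd.DataFrame(
                    [
                        {"sample_id": r.sample_id, "call": r.call,
                         **{f"vote_{k}": v for k, v in sorted(r.votes.items())}}
                        for r in results
                    ]
                )
                _write(tdf if len(tdf) else pd.DataFrame(columns=["sample_id", "call"]),
                       out / "ab10_types.tsv", prov)
                _write(pd.DataFrame({"holdout_accuracy": [acc]}),
                       out / "ab10_typer_holdout.tsv", prov)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    return out


def _subset_by_labels(index, labels):
    from .tag_index import BinIndexMatrix

    keep = [i for i, b in enumerate(index.bins) if b.label in set(labels)]
    return BinIndexMatrix(
        [index.bins[i] for i in keep], index.values.iloc[keep], index.scaled
    )
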