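"""Tag-index computation: RPM normalization, blank-anchored filtering,
1 Mb binning, min/max scaling, and single-copy-gene bin construction.

The tag index of a bin in a sample is ``sqrt(c) + d``: c tags observed
in the bin and d their summed normalized depth.  It blends marker
presence (how many restriction-site tags are seen at all) with coverage
(how deep they are), which is what makes a large extra haplotype stand
out even at GBS coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BinDefinition, ControlManifest, FormatError, TagMatrix, check_bins_disjoint

__all__ = [
    "BinIndexMatrix",
    "rpm_normalize",
    "blank_missingness_cutoff",
    "filter_samples_and_tags",
    "bin_tag_index",
    "minmax_scale",
    "single_copy_gene_bins",
    "compute_tag_index",
]


@dataclass
class BinIndexMatrix:
    """Bins x samples tag-index values."""

    bins: list[BinDefinition]
    values: pd.DataFrame  # index bin label; columns sample ids
    scaled: bool = False

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.values):
            raise ValueError("bin list and value matrix disagree on bin count")
        vals = self.values.to_numpy(dtype=float)
        if vals.size:
            if self.scaled and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("scaled values must lie in [0, 1]")
            if not self.scaled and vals.min() < 0:
                raise ValueError("unscaled values must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def diagnostic_subset(self, cdh: str) -> "BinIndexMatrix":
        keep = [i for i, b in enumerate(self.bins) if b.diagnostic_for == cdh]
        return BinIndexMatrix(
            [self.bins[i] for i in keep], self.values.iloc[keep], self.scaled
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "BinIndexMatrix":
        return BinIndexMatrix(self.bins, self.values[list(sample_ids)], self.scaled)


def rpm_normalize(tags: TagMatrix) -> TagMatrix:
    """Reads-per-million normalization, per sample.

    Each sample's counts are scaled so they sum to 1e6, removing
    library-size differences before any cross-sample comparison.
    """
    totals = tags.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(map(str, zero))}")
    depths = tags.counts / totals * 1e6
    return TagMatrix(tags.locations, depths, normalized=True)


def blank_missingness_cutoff(tags: TagMatrix, manifest: ControlManifest) -> float:
    """Sample-missingness cutoff anchored at the cleanest blank.

    Blanks carry only sequencing background, so any real sample missing
    more tags than a blank is unusable.  Returns min over blanks of the
    per-sample missing fraction, minus 0.001.
    """
    blanks = [b for b in manifest.blanks if b in tags.counts.columns]
    if not blanks:
        raise ValueError(
            "no blank samples present; pass an explicit missingness cutoff instead"
        )
    return float(tags.missingness()[blanks].min()) - 0.001


def filter_samples_and_tags(
    tags: TagMatrix, cutoff: float, min_mapq: int = 20
) -> TagMatrix:
    """Drop samples with missingness above ``cutoff`` and tags with
    mapping quality below ``min_mapq`` (a tag at exactly min_mapq is kept)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    miss = tags.missingness()
    keep_samples = list(miss.index[miss <= cutoff])
    if not keep_samples:
        raise ValueError("missingness cutoff removed every sample")
    keep_tags = list(tags.locations.index[tags.locations["mapq"] >= min_mapq])
    return TagMatrix(
        tags.locations.loc[keep_tags],
        tags.counts.loc[keep_tags, keep_samples],
        tags.normalized,
    )


def _assign_bins(locations: pd.DataFrame, bins: Sequence[BinDefinition]) -> np.ndarray:
    """Index of the bin containing each tag's start, or -1."""
    out = np.full(len(locations), -1, dtype=np.int64)
    chroms = locations["chrom"].to_numpy()
    starts = locations["start"].to_numpy()
    for i, b in enumerate(bins):
        mask = (chroms == b.chrom) & (starts >= b.start) & (starts < b.end)
        out[mask] = i
    return out


def bin_tag_index(
    tags: TagMatrix,
    bins: Sequence[BinDefinition],
    count_mode: str = "nonzero",
) -> BinIndexMatrix:
    """Compute the per-bin tag index sqrt(c) + d.

    ``d`` is the sum over the bin of normalized (RPM) depths; ``c``
    counts tags in the bin — by default only those with nonzero depth in
    that sample (``count_mode="nonzero"``), so an absent haplotype
    contributes neither term; ``count_mode="all"`` counts every tag
    located in the bin regardless of observation.
    """
    if count_mode not in ("nonzero", "all"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    bins = list(bins)
    check_bins_disjoint(bins)
    assignment = _assign_bins(tags.locations, bins)

    depth = tags.counts.to_numpy(dtype=float)
    n_bins, n_samples = len(bins), depth.shape[1]
    d = np.zeros((n_bins, n_samples))
    c = np.zeros((n_bins, n_samples))
    for i in range(n_bins):
        rows = assignment == i
        if not rows.any():
            continue
        sub = depth[rows]
        d[i] = sub.sum(axis=0)
        c[i] = (sub > 0).sum(axis=0) if count_mode == "nonzero" else rows.sum()
    values = pd.DataFrame(
        np.sqrt(c) + d, index=[b.label for b in bins], columns=tags.counts.columns
    )
    # an empty bin is 0, not sqrt(0)+0 ambiguity — identical numerically
    return BinIndexMatrix(bins, values, scaled=False)


def minmax_scale(index: BinIndexMatrix) -> BinIndexMatrix:
    """Scale each bin (row) independently across samples to [0, 1].

    Row-wise scaling preserves the cross-sample carrier/non-carrier
    contrast each bin carries.  A constant row maps to all zeros so
    downstream clustering never sees NaNs.
    """
    if index.scaled:
        raise ValueError("input is already scaled")
    vals = index.values.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.0)
    return BinIndexMatrix(
        index.bins,
        pd.DataFrame(scaled, index=index.values.index, columns=index.values.columns),
        scaled=True,
    )


def single_copy_gene_bins(
    gene_intervals: Sequence[tuple[str, int, int]],
    bin_size: int = 1_000_000,
    label_prefix: str = "sc",
) -> list[BinDefinition]:
    """Bins holding a fixed amount of single-copy gene *sequence*.

    Walks the gene intervals in coordinate order accumulating covered
    gene bases; a bin boundary is emitted every ``bin_size`` of
    cumulative gene sequence, so bins may span large genomic distances.
    A final partial bin is emitted only if at least half full.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in gene_intervals:
        if not s < e:
            raise FormatError(f"gene interval on {chrom} has start >= end")
        by_chrom.setdefault(chrom, []).append((s, e))
    bins: list[BinDefinition] = []
    n = 0
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping gene intervals on {chrom}")
        acc = 0  # gene bases accumulated in the open bin
        bin_start = ivs[0][0]
        pos = ivs[0][0]
        for s, e in ivs:
            pos = s
            while e - pos >= bin_size - acc:
                cut = pos + (bin_size - acc)
                bins.append(
                    BinDefinition(chrom, bin_start, cut, f"{label_prefix}_{n:03d}")
                )
                n += 1
                pos = cut
                acc = 0
                bin_start = cut
            acc += e - pos
            pos = e
        if acc >= bin_size / 2:
            bins.append(BinDefinition(chrom, bin_start, pos, f"{label_prefix}_{n:03d}"))
            n += 1
        # a trailing partial under half a bin of gene sequence is dropped
    return bins


def compute_tag_index(
    tags: TagMatrix,
    manifest: ControlManifest,
    bins: Sequence[BinDefinition],
    min_mapq: int = 20,
    blank_offset: float = 0.001,
    explicit_cutoff: float | None = None,
    count_mode: str = "nonzero",
) -> tuple[BinIndexMatrix, BinIndexMatrix]:
    """End-to-end tag index: RPM -> blank cutoff -> filters -> bin -> scale.

    Returns (unscaled, scaled) matrices over the retained samples.
    Blanks are removed by their own cutoff by construction.
    """
    norm = rpm_normalize(tags)
    if explicit_cutoff is not None:
        cutoff = explicit_cutoff
    else:
        blanks = [b for b in manifest.blanks if b in tags.counts.columns]
        if not blanks:
            raise ValueError("no blanks in dataset; supply explicit_cutoff")
        cutoff = float(tags.missingness()[blanks].min()) - blank_offset
    filtered = filter_samples_and_tags(norm, cutoff, min_mapq=min_mapq)
    unscaled = bin_tag_index(filtered, bins, count_mode=count_mode)
    return unscaled, minmax_scale(unscaled)
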