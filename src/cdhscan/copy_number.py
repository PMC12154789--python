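"""Pseudo copy number: CDH tag index normalized to single-copy genes.

A sample's mean tag index over a haplotype's diagnostic bins, divided
by its mean tag index over single-copy core-gene bins, is a relative
dosage estimate ("pseudo" copy number: the single-copy denominator
makes it comparable across samples but it is not calibrated to absolute
copies).  Both numerator and denominator use the UNSCALED index —
min/max scaling would destroy the ratio's meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ControlManifest
from .tag_index import BinIndexMatrix

__all__ = ["CopyNumberEstimate", "pseudo_copy_number", "classify_zygosity"]


@dataclass
class CopyNumberEstimate:
    sample_id: str
    cdh: str
    cdh_mean_index: float
    single_copy_mean_index: float
    pseudo_copy_number: float
    zygosity: str = "unknown"  # hom / het / unknown


def pseudo_copy_number(
    index: BinIndexMatrix, sc_index: BinIndexMatrix, cdh: str
) -> list[CopyNumberEstimate]:
    """Per-sample ratio of mean CDH tag index to mean single-copy-gene
    tag index.

    Both means are simple averages over bins.  A sample whose
    single-copy mean is zero gets pseudo_copy_number NaN and zygosity
    'unknown' rather than an exception.
    """
    if index.scaled or sc_index.scaled:
        raise ValueError("pseudo copy number requires unscaled matrices")
    samples = index.sample_ids
    if set(samples) != set(sc_index.sample_ids):
        raise ValueError("CDH and single-copy matrices must cover the same samples")
    cdh_mean = index.values.mean(axis=0)
    sc_mean = sc_index.values[samples].mean(axis=0)
    out = []
    for s in samples:
        denom = float(sc_mean[s])
        if denom > 0:
            pcn = float(cdh_mean[s]) / denom
        else:
            pcn = float("nan")
        out.append(
            CopyNumberEstimate(s, cdh, float(cdh_mean[s]), denom, pcn)
        )
    return out


def classify_zygosity(
    estimates: list[CopyNumberEstimate],
    control_estimates: list[CopyNumberEstimate],
    manifest: ControlManifest,
    cdh: str,
) -> list[CopyNumberEstimate]:
    """Split carriers into het/hom at the midpoint of control means.

    The threshold is the midpoint between the mean pseudo copy number
    of known heterozygous (low copy class) and homozygous (high copy
    class) positive controls; a sample at or above it is called hom.
    With either control group missing, zygosity stays 'unknown'.
    """
    het_ids = set(manifest.controls_for(cdh, status="positive", copy_class="low"))
    hom_ids = set(manifest.controls_for(cdh, status="positive", copy_class="high"))
    het = [e.pseudo_copy_number for e in control_estimates
           if e.sample_id in het_ids and np.isfinite(e.pseudo_copy_number)]
    hom = [e.pseudo_copy_number for e in control_estimates
           if e.sample_id in hom_ids and np.isfinite(e.pseudo_copy_number)]
    if not het or not hom:
        return [
            CopyNumberEstimate(e.sample_id, e.cdh, e.cdh_mean_index,
                               e.single_copy_mean_index, e.pseudo_copy_number,
                               "unknown")
            for e in estimates
        ]
    threshold = (float(np.mean(het)) + float(np.mean(hom))) / 2.0
    out = []
    for e in estimates:
        if not np.isfinite(e.pseudo_copy_number):
            z = "unknown"
        else:
            z = "hom" if e.pseudo_copy_number >= threshold else "het"
        out.append(
            CopyNumberEstimate(e.sample_id, e.cdh, e.cdh_mean_index,
                               e.single_copy_mean_index, e.pseudo_copy_number, z)
        )
    return out


def estimates_to_frame(estimates: list[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "cdh": e.cdh,
                "cdh_mean_index": e.cdh_mean_index,
                "single_copy_mean_index": e.single_copy_mean_index,
                "pseudo_copy_number": e.pseudo_copy_number,
                "zygosity": e.zygosity,
            }
            for e in estimates
        ]
    )
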