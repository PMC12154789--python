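"""Synthetic GBS tag datasets and association cohorts.

The generator emulates the statistical structure of a reduced-
representation (GBS) experiment over a genome carrying large drive
haplotypes: negative-binomially overdispersed per-tag read counts with
log-normal library-size variation, dosage-scaled counts inside each
haplotype's diagnostic bins, a small mis-mapping background in
non-carriers, blank (no-DNA) wells with near-total missingness, and a
sample manifest mixing characterized control lines with uncharacterized
experimental samples.

For the association stage it emulates a structured landrace panel:
genotypes from a k-population admixture model (Balding–Nichols allele
frequency divergence), environmental covariates correlated with
admixture, and a binary phenotype from a logistic model over planted
causal effects.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BinDefinition, ControlManifest, TagMatrix, check_bins_disjoint

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_genome",
    "default_cdh_regions",
    "default_single_copy_intervals",
    "simulate_tag_dataset",
    "simulate_association_dataset",
    "simulate_genotype_qc",
]

CHR10_CDHS = ("Ab10", "K10L2")
AB10_TYPES = ("I", "II", "III")


def default_genome() -> list[tuple[str, int]]:
    """Reference layout: a normal-genome chromosome plus one contig per
    drive haplotype (mirroring alignment to haplotype-bearing assemblies)."""
    return [
        ("chr1", 10_000_000),
        ("ab10_hap", 12_000_000),
        ("k10l2_hap", 4_000_000),
        ("B_chrom", 8_000_000),
    ]


def default_cdh_regions() -> dict[str, list[BinDefinition]]:
    """1 Mb diagnostic bins over each haplotype contig."""
    regions: dict[str, list[BinDefinition]] = {}
    spans = {"Ab10": ("ab10_hap", 12), "K10L2": ("k10l2_hap", 4), "B": ("B_chrom", 8)}
    for cdh, (chrom, n_mb) in spans.items():
        regions[cdh] = [
            BinDefinition(chrom, i * 1_000_000, (i + 1) * 1_000_000,
                          f"{chrom}_{i:03d}", diagnostic_for=cdh)
            for i in range(n_mb)
        ]
    return regions


def default_single_copy_intervals() -> list[tuple[str, int, int]]:
    """Single-copy core-gene intervals on the normal genome: 20 genes of
    500 kb each, evenly spaced along chr1 (totals 10 Mb of gene sequence)."""
    return [("chr1", i * 500_000, (i + 1) * 500_000) for i in range(20)]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic GBS experiment.

    Counts for a tag with per-sample mean m are drawn Gamma–Poisson with
    variance m + dispersion * m**2.  A tag inside a diagnostic bin has
    its mean multiplied by ``dosage_effect * copy_number`` in carriers
    and by ``background_rate`` (mis-mapping noise floor) in
    non-carriers.
    """

    n_controls_pos: int = 20            # positive controls per CDH
    n_controls_neg: int = 20            # shared negative controls
    n_experimental: int = 20
    n_blanks: int = 3
    genome: tuple[tuple[str, int], ...] = field(
        default_factory=lambda: tuple(default_genome())
    )
    cdh_regions: Mapping[str, Sequence[BinDefinition]] = field(
        default_factory=default_cdh_regions
    )
    cdhs: tuple[str, ...] = ("Ab10", "K10L2", "B")
    tags_per_mb: int = 30
    baseline_mean: float = 20.0
    dispersion: float = 0.3
    dosage_effect: float = 10.0
    background_rate: float = 0.01
    libsize_sigma: float = 0.3
    missing_rate: float = 0.05
    blank_detect_rate: float = 0.02
    k10l2_cross_reactivity: float = 1.0  # Ab10 signal bleeding into K10L2 bins
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"Ab10": 0.2, "K10L2": 0.15, "B": 0.25}
    )
    b_copy_max: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("missing_rate", self.missing_rate),
            ("blank_detect_rate", self.blank_detect_rate),
            ("background_rate", self.background_rate),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.dosage_effect <= 1.0:
            raise ValueError("dosage_effect must exceed 1")
        chrom_len = dict(self.genome)
        for cdh, bins in self.cdh_regions.items():
            for b in bins:
                if b.chrom not in chrom_len or b.end > chrom_len[b.chrom]:
                    raise ValueError(
                        f"cdh region {b.label!r} for {cdh} lies outside the genome"
                    )
            check_bins_disjoint(list(bins))


@dataclass
class SimTruth:
    """Ground truth per sample: status and copy number per CDH, Ab10 type.

    ``table`` is indexed by sample_id with columns ``status_<cdh>``,
    ``copies_<cdh>`` and ``ab10_type``.  It covers experimental samples
    whose manifest status is hidden ('unknown').
    """

    table: pd.DataFrame

    def copies(self, cdh: str) -> pd.Series:
        return self.table[f"copies_{cdh}"]

    def status(self, cdh: str) -> pd.Series:
        return self.table[f"status_{cdh}"]


def ab10_type_bin_groups(
    ab10_bins: Sequence[BinDefinition],
) -> dict[str, list[int]]:
    """Partition Ab10 diagnostic bins into a shared core plus one
    disjoint signature group per cytological type.

    With n bins: the first n - 3*g are shared (present in every type);
    the remaining 3 groups of g = max(1, n // 6) bins mark types I, II
    and III respectively.  The shared core dominates so presence/absence
    contrast outweighs between-type contrast, as on the real haplotype
    where the types differ in knob appearance, not in most of the span.
    """
    n = len(ab10_bins)
    if n < 4:
        raise ValueError("need >= 4 Ab10 diagnostic bins to encode 3 types")
    g = max(1, n // 6)
    shared = list(range(n - 3 * g))
    groups = {"shared": shared}
    for i, t in enumerate(AB10_TYPES):
        start = n - 3 * g + i * g
        groups[t] = list(range(start, start + g))
    return groups


def _place_tags(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, length in config.genome:
        n = int(round(config.tags_per_mb * length / 1_000_000))
        starts = np.sort(rng.integers(0, length - 64, size=n))
        mapq = np.where(rng.random(n) < 0.1, rng.integers(0, 20, size=n), 60)
        for i, (s, q) in enumerate(zip(starts, mapq)):
            rows.append((f"tag_{chrom}_{i:05d}", chrom, int(s), int(s) + 64, int(q)))
    df = pd.DataFrame(rows, columns=["tag_id", "chrom", "start", "end", "mapq"])
    return df.set_index("tag_id")


def _assign_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the sample roster: per-CDH status/copies, Ab10 type, class."""
    recs: list[dict] = []

    def blank_record(sid: str, sclass: str) -> dict:
        rec = {"sample_id": sid, "sample_class": sclass, "copy_class": "unknown",
               "ab10_type": "unknown", "control_for": ""}
        for cdh in config.cdhs:
            rec[f"status_{cdh}"] = "negative"
            rec[f"copies_{cdh}"] = 0
        return rec

    type_cycle = 0
    for cdh in config.cdhs:
        for i in range(config.n_controls_pos):
            rec = blank_record(f"ctrl_{cdh}_pos_{i:03d}", "control")
            rec["control_for"] = cdh
            rec[f"status_{cdh}"] = "positive"
            high = i % 2 == 0
            rec["copy_class"] = "high" if high else "low"
            if cdh == "B":
                rec[f"copies_{cdh}"] = int(rng.integers(4, 11)) if high else int(
                    rng.integers(1, 3)
                )
            else:
                rec[f"copies_{cdh}"] = 2 if high else 1
            if cdh == "Ab10":
                rec["ab10_type"] = AB10_TYPES[type_cycle % 3]
                type_cycle += 1
            recs.append(rec)
    for i in range(config.n_controls_neg):
        recs.append(blank_record(f"ctrl_neg_{i:03d}", "control"))
    for i in range(config.n_experimental):
        rec = blank_record(f"exp_{i:03d}", "experimental")
        for cdh in config.cdhs:
            if rng.random() < config.prevalence.get(cdh, 0.0):
                rec[f"status_{cdh}"] = "positive"
                if cdh == "B":
                    rec[f"copies_{cdh}"] = int(rng.integers(1, config.b_copy_max + 1))
                else:
                    rec[f"copies_{cdh}"] = int(rng.integers(1, 3))
                if cdh == "Ab10":
                    rec["ab10_type"] = AB10_TYPES[int(rng.integers(0, 3))]
        # K10L2 and Ab10 are alternative chromosome-10 haplotypes: at most one
        if ("Ab10" in config.cdhs and "K10L2" in config.cdhs
                and rec["status_Ab10"] == "positive"):
            rec["status_K10L2"] = "negative"
            rec["copies_K10L2"] = 0
        recs.append(rec)
    for i in range(config.n_blanks):
        recs.append(blank_record(f"blank_{i:02d}", "blank"))
    return pd.DataFrame(recs).set_index("sample_id")


def _mean_matrix(
    config: SimConfig,
    locations: pd.DataFrame,
    truth: pd.DataFrame,
    lib_factors: np.ndarray,
) -> np.ndarray:
    """Expected reads per tag x sample before overdispersion/missingness."""
    n_tags = len(locations)
    samples = truth.index
    factor = np.ones((n_tags, len(samples)), dtype=float)

    starts = locations["start"].to_numpy()
    chroms = locations["chrom"].to_numpy()

    ab10_groups = None
    if "Ab10" in config.cdhs and "Ab10" in config.cdh_regions:
        ab10_groups = ab10_type_bin_groups(list(config.cdh_regions["Ab10"]))

    for cdh in config.cdhs:
        bins = list(config.cdh_regions.get(cdh, []))
        if not bins:
            continue
        copies = truth[f"copies_{cdh}"].to_numpy()
        for bi, b in enumerate(bins):
            in_bin = (chroms == b.chrom) & (starts >= b.start) & (starts < b.end)
            if not in_bin.any():
                continue
            col = np.where(
                copies > 0, config.dosage_effect * copies, config.background_rate
            ).astype(float)
            if cdh == "Ab10" and ab10_groups is not None:
                # type-specific bins carry signal only for the matching type
                for t in AB10_TYPES:
                    if bi in ab10_groups[t]:
                        wrong_type = (truth["ab10_type"].to_numpy() != t) & (copies > 0)
                        col = col.copy()
                        col[wrong_type] = config.background_rate
            if cdh == "K10L2" and "Ab10" in config.cdhs:
                # Ab10 shares sequence with K10L2 diagnostic regions
                ab10_copies = truth["copies_Ab10"].to_numpy()
                cross = (
                    config.dosage_effect * ab10_copies * config.k10l2_cross_reactivity
                )
                col = np.maximum(col, np.where(ab10_copies > 0, cross, 0.0))
            factor[in_bin, :] *= np.where(col > 0, col, config.background_rate)
    return config.baseline_mean * factor * lib_factors[np.newaxis, :]


def simulate_tag_dataset(
    config: SimConfig,
) -> tuple[TagMatrix, ControlManifest, SimTruth]:
    """Draw a complete tag-count dataset with manifest and ground truth.

    Counts are Gamma–Poisson (negative binomial) around a per-tag,
    per-sample mean combining baseline depth, a log-normal library
    factor, and the dosage model described on :class:`SimConfig`.
    Blanks draw from a uniform low-count contaminant model so their
    missingness exceeds every real sample's.
    """
    rng = np.random.default_rng(config.seed)
    locations = _place_tags(config, rng)
    truth = _assign_truth(config, rng)
    samples = truth.index
    n_tags, n_samples = len(locations), len(samples)

    lib_factors = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_samples))
    mean = _mean_matrix(config, locations, truth, lib_factors)

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean * config.dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    dropout = rng.random((n_tags, n_samples)) < config.missing_rate
    counts[dropout] = 0

    is_blank = (truth["sample_class"] == "blank").to_numpy()
    if is_blank.any():
        nb = int(is_blank.sum())
        contam = rng.random((n_tags, nb)) < config.blank_detect_rate
        low = rng.integers(1, 4, size=(n_tags, nb))
        counts[:, is_blank] = np.where(contam, low, 0)

    counts_df = pd.DataFrame(counts, index=locations.index, columns=samples)
    tags = TagMatrix(locations=locations, counts=counts_df)

    manifest_t = truth.copy()
    status_cols = {f"status_{c}": c for c in config.cdhs}
    manifest_t = manifest_t.rename(columns=status_cols)
    # hide truth for experimental samples and blanks
    exp_or_blank = manifest_t["sample_class"].isin(["experimental", "blank"])
    for c in config.cdhs:
        manifest_t.loc[exp_or_blank, c] = "unknown"
    manifest_t.loc[exp_or_blank, "copy_class"] = "unknown"
    manifest_t.loc[exp_or_blank, "ab10_type"] = "unknown"
    # a positive control line is characterized only for its own CDH;
    # negative control lines (control_for empty) are known negative for all
    for c in config.cdhs:
        dedicated_elsewhere = (
            (manifest_t["sample_class"] == "control")
            & (manifest_t["control_for"] != "")
            & (manifest_t["control_for"] != c)
        )
        manifest_t.loc[dedicated_elsewhere, c] = "unknown"
    manifest_t = manifest_t.drop(
        columns=[f"copies_{c}" for c in config.cdhs] + ["control_for"]
    )
    manifest = ControlManifest(
        manifest_t[["sample_class", *config.cdhs, "copy_class", "ab10_type"]]
    )
    return tags, manifest, SimTruth(truth)


# ---------------------------------------------------------------------------
# association cohort
# ---------------------------------------------------------------------------

def simulate_association_dataset(
    n: int,
    n_snps: int,
    k_pops: int,
    causal_spec: Sequence[tuple[str, int, float]] = (),
    seed: int = 0,
    fst: float = 0.1,
    n_env: int = 3,
    env_corr: float = 0.6,
    maf_causal: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Structured genotypes, correlated environment, logistic phenotype.

    Parameters
    ----------
    causal_spec
        Tuples ``("snp", j, odds_ratio)`` or ``("env", i, coefficient)``.
        Causal SNPs are given allele frequency ``maf_causal`` in every
        population (so their effect is not confounded with structure).

    Returns
    -------
    genotypes : DataFrame (samples x SNPs), additive dosage in {0,1,2}
    environment : DataFrame (samples x env variables)
    phenotype : Series of {0,1}
    """
    if k_pops < 1:
        raise ValueError("k_pops must be >= 1")
    causal_snps = [(j, v) for kind, j, v in causal_spec if kind == "snp"]
    causal_env = [(i, v) for kind, i, v in causal_spec if kind == "env"]
    if len(causal_snps) > n_snps:
        raise ValueError("more causal SNPs than n_snps")
    for j, odds in causal_snps:
        if odds <= 0:
            raise ValueError(f"odds-ratio for SNP {j} must be positive, got {odds}")

    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, size=n_snps)
    if k_pops == 1 or fst <= 0:
        pop_freq = np.tile(anc, (k_pops, 1))
    else:
        a = anc * (1 - fst) / fst
        b = (1 - anc) * (1 - fst) / fst
        pop_freq = rng.beta(a, b, size=(k_pops, n_snps))
    for j, _ in causal_snps:
        pop_freq[:, j] = maf_causal

    admix = rng.dirichlet(np.full(k_pops, 0.5), size=n)
    q = admix @ pop_freq  # per-sample allele frequencies
    dosage = rng.binomial(2, q).astype(np.int64)
    geno = pd.DataFrame(
        dosage,
        index=[f"s{i:05d}" for i in range(n)],
        columns=[f"snp{j:05d}" for j in range(n_snps)],
    )

    env_cols = {}
    for i in range(n_env):
        loadings = rng.normal(0.0, 1.0, size=k_pops)
        struct = admix @ loadings
        struct = (struct - struct.mean()) / (struct.std() or 1.0)
        noise = rng.normal(0.0, 1.0, size=n)
        env_cols[f"env{i}"] = env_corr * struct + np.sqrt(1 - env_corr**2) * noise
    env = pd.DataFrame(env_cols, index=geno.index)

    eta = np.zeros(n)
    for j, odds in causal_snps:
        eta += np.log(odds) * dosage[:, j]
    for i, coef in causal_env:
        eta += coef * env.iloc[:, i].to_numpy()
    eta -= eta.mean()  # prevalence ~ 0.5
    prob = 1.0 / (1.0 + np.exp(-eta))
    phen = pd.Series(rng.binomial(1, prob), index=geno.index, name="phenotype")
    return geno, env, phen


def simulate_genotype_qc(
    geno: pd.DataFrame,
    seed: int = 0,
    depth_mean: float = 10.0,
    gq_loc: float = 85.0,
    gq_scale: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-call depth and genotype-quality matrices for a dosage matrix,
    for exercising the hard-filtering stage."""
    rng = np.random.default_rng(seed)
    depth = pd.DataFrame(
        rng.poisson(depth_mean, size=geno.shape), index=geno.index, columns=geno.columns
    )
    gq = pd.DataFrame(
        np.clip(rng.normal(gq_loc, gq_scale, size=geno.shape), 0, 99).astype(int),
        index=geno.index,
        columns=geno.columns,
    )
    return depth, gq
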