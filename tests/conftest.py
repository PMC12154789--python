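import pytest

from cdhscan.pipeline import _subset_by_labels
from cdhscan.simulate import (
    SimConfig,
    default_single_copy_intervals,
    simulate_tag_dataset,
)
from cdhscan.tag_index import compute_tag_index, single_copy_gene_bins


@pytest.fixture(scope="session")
def sim_dataset():
    """A well-separated synthetic cohort: 20 pos + 20 neg controls per
    CDH, 15 experimental samples, 3 blanks, dosage effect 10."""
    config = SimConfig(seed=1, n_experimental=15)
    tags, manifest, truth = simulate_tag_dataset(config)
    return config, tags, manifest, truth


@pytest.fixture(scope="session")
def indexed(sim_dataset):
    """Tag index (unscaled + scaled) over diagnostic and single-copy bins."""
    config, tags, manifest, truth = sim_dataset
    diag = [b for bins in config.cdh_regions.values() for b in bins]
    sc_bins = single_copy_gene_bins(default_single_copy_intervals())
    unscaled, scaled = compute_tag_index(tags, manifest, diag + sc_bins)
    return config, manifest, truth, unscaled, scaled, sc_bins


@pytest.fixture(scope="session")
def sc_subset(indexed):
    _, _, _, unscaled, _, sc_bins = indexed
    return _subset_by_labels(unscaled, [b.label for b in sc_bins])
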