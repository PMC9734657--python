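import numpy as np
import pytest

from scimet.reference import merge_references
from scimet.sim import (
    ExperimentDesign,
    assign_cells,
    glia_like,
    make_genomes,
    neuron_like,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_genomes():
    """One 20 kb chromosome per species; enough cytosines for calling."""
    return make_genomes(1, 20_000, 0.42, seed=11)


@pytest.fixture(scope="session")
def joint_reference(small_genomes):
    return merge_references(small_genomes)


@pytest.fixture(scope="session")
def base_profiles():
    return [neuron_like(), glia_like()]


@pytest.fixture(scope="session")
def clean_run(small_genomes, base_profiles):
    """Noise-free singlet experiment: the exactness workhorse.

    No index/sequencing errors, perfect bisulfite conversion, one event
    per well (no doublets), duplicate_rate 0.5 (mean 1.5 copies).
    """
    design = ExperimentDesign(
        n_cells=30,
        events_per_well=1,
        n_tag_barcodes=12,
        n_pcr_wells=30,
        reads_per_cell=30,
        read_length=60,
        tag_whitelist_min_dist=5,
        duplicate_rate=0.5,
        barcode_error_rate=0.0,
        seq_error_rate=0.0,
        conversion_failure_rate=0.0,
        overconversion_rate=0.0,
        seed=13,
    )
    assignment = assign_cells(design, base_profiles)
    reads = simulate_reads(small_genomes, assignment, base_profiles)
    return assignment, reads


@pytest.fixture(scope="session")
def clean_cell_of_barcode(clean_run):
    """barcode -> cell_id (valid because clean_run has no doublets)."""
    _, reads = clean_run
    tab = reads.truth.cell_table
    assert not tab["is_collision_doublet"].any()
    return dict(zip(tab["barcode"], tab["cell_id"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
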