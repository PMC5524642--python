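import numpy as np
import pytest
from hypothesis import settings

import plateseq as ps

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def barcode_set_96():
    """The study-geometry code: 96 eight-base barcodes at Hamming distance >= 3."""
    bset = ps.design_barcode_set(96, 8, 3, seed=1)
    bset.validate()
    return bset


@pytest.fixture(scope="session")
def toy_tx():
    """Small two-isoform transcriptome used across modules."""
    return ps.simulate_transcriptome(20, 2, (300, 600), seed=3)


@pytest.fixture(scope="session")
def toy_plate():
    """Two drugs plus vehicle, four replicates each (12 wells)."""
    conditions = {
        "drugA": ps.PerturbationSpec({"G0001": 2.0}),
        "drugB": ps.PerturbationSpec({"G0002": -1.0}),
    }
    return ps.design_plate(conditions, vehicle_label="DMSO", replicates=4)


@pytest.fixture(scope="session")
def toy_run(barcode_set_96, toy_tx, toy_plate):
    """Error-free simulated run through counting: (truth, reads, count matrix)."""
    from plateseq.alignio import PseudoAligner, align_reads

    truth = ps.simulate_counts(
        toy_tx, toy_plate, base_mean=40.0, dispersion=0.1, reads_per_well=400, seed=5
    )
    reads = ps.simulate_run(
        truth, toy_tx, barcode_set_96, toy_plate, sub_error_rate=0.0, seed=7
    )
    wells = ps.assign_wells(reads.read1, barcode_set_96)
    aligner = PseudoAligner(toy_tx)
    cm = ps.count_unique(
        align_reads(reads.read2, aligner), wells, toy_tx.tx2gene, toy_tx.spike_ins
    )
    return truth, reads, cm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
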