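"""Synthetic-run simulator: transcriptome, NB counts, reads, ground truth."""

import numpy as np
import pytest

import plateseq as ps
from plateseq import io as pio


class TestTranscriptome:
    def test_counts_and_consistency(self):
        tx = ps.simulate_transcriptome(50, 2, (300, 1000), seed=3)
        assert len(tx.transcripts) == 100
        assert len(tx.genes) == 50
        assert set(tx.transcripts) == set(tx.tx2gene)

    def test_single_gene_single_transcript(self):
        tx = ps.simulate_transcriptome(1, 1, (300, 400), seed=0)
        assert len(tx.transcripts) == 1
        (tid,) = tx.transcripts
        assert tx.tx2gene[tid] == "G0001"

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        for name in ("a.fa", "b.fa"):
            tx = ps.simulate_transcriptome(10, 2, (300, 500), seed=21)
            pio.write_transcriptome(tx, tmp_path / name, tmp_path / (name + ".t2g"))
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_length_below_read_length_is_configuration_error(self):
        with pytest.raises(ValueError, match="read length"):
            ps.simulate_transcriptome(5, 1, (40, 100), seed=0, min_read_len=66)

    def test_spike_ins_flagged_and_mapped(self):
        tx = ps.simulate_transcriptome(5, 1, (300, 400), n_spikeins=2, seed=0)
        assert len(tx.spike_ins) == 2
        for sid in tx.spike_ins:
            assert tx.tx2gene[sid] == sid
        assert len(tx.genes) == 5  # endogenous only


class TestCounts:
    def test_column_sums_equal_reads_per_well(self, toy_tx, toy_plate):
        truth = ps.simulate_counts(toy_tx, toy_plate, 50, 0.1, 777, seed=2)
        assert (truth.realized_counts.sum(axis=0) == 777).all()

    def test_poisson_limit_variance_to_mean(self, toy_tx):
        # zero dispersion: raw draws are Poisson, and with a thinning
        # fraction well below one the realized counts stay near-Poisson
        # (variance/mean ~ 1) across exchangeable replicate wells
        plate = ps.design_plate({}, vehicle_label="DMSO", replicates=12)
        truth = ps.simulate_counts(toy_tx, plate, 100, 0.0, 200, seed=2)
        veh = truth.realized_counts.to_numpy(float)
        ratio = veh.var(axis=1, ddof=1) / veh.mean(axis=1)
        assert 0.5 < np.median(ratio) < 1.5

    def test_null_conditions_are_exchangeable(self, toy_tx):
        plate = ps.design_plate(
            {"drugA": ps.PerturbationSpec()}, vehicle_label="DMSO", replicates=12
        )
        truth = ps.simulate_counts(toy_tx, plate, 100, 0.05, 4000, seed=4)
        cm = truth.realized_counts
        a = cm[plate.condition_samples()["drugA"]].mean(axis=1)
        v = cm[plate.vehicle_wells].mean(axis=1)
        # equal means within Monte-Carlo error: 3 s.e. of the difference
        se = np.sqrt(
            cm[plate.condition_samples()["drugA"]].var(axis=1, ddof=1) / 12
            + cm[plate.vehicle_wells].var(axis=1, ddof=1) / 12
        )
        assert (np.abs(a - v) <= 3 * se + 1e-9).mean() > 0.95

    def test_planted_lfc_ratio_recovered(self, toy_tx):
        plate = ps.design_plate(
            {"drugA": ps.PerturbationSpec({"G0001": 2.0})}, replicates=12
        )
        truth = ps.simulate_counts(toy_tx, plate, 100, 0.05, 5000, seed=6)
        cm = truth.realized_counts
        treated = cm.loc["G0001", plate.condition_samples()["drugA"]]
        vehicle = cm.loc["G0001", plate.vehicle_wells]
        ratio = treated.mean() / vehicle.mean()
        se = ratio * np.sqrt(
            treated.var(ddof=1) / (12 * treated.mean() ** 2)
            + vehicle.var(ddof=1) / (12 * vehicle.mean() ** 2)
        )
        # planting +2 log2 units quadruples the expected count; the realized
        # ratio is slightly damped by renormalization to fixed depth
        assert abs(ratio - 4.0) < 3 * se + 0.4

    def test_expected_counts_fold_change(self, toy_tx, toy_plate):
        truth = ps.simulate_counts(toy_tx, toy_plate, 50, 0.1, 500, seed=0)
        drugA = toy_plate.condition_samples()["drugA"][0]
        veh = toy_plate.vehicle_wells[0]
        assert truth.expected_counts.loc["G0001", drugA] == pytest.approx(
            4 * truth.expected_counts.loc["G0001", veh]
        )


class TestReads:
    def test_error_free_reads_decode_and_match(self, toy_run, barcode_set_96, toy_tx):
        truth, reads, _cm = toy_run
        label_to_index = dict(
            zip(reads.per_read["well_label"], reads.per_read["barcode_index"])
        )
        r1 = dict(reads.read1)
        r2 = dict(reads.read2)
        for row in reads.per_read.itertuples():
            seq1 = r1[row.read_id]
            assert seq1[:8] == barcode_set_96.sequences[row.barcode_index]
            assert seq1[8:] == "T" * 18
            tx_seq = toy_tx.transcripts[row.transcript_id]
            # sense-strand construction: read 2 is an exact forward substring
            assert r2[row.read_id] == tx_seq[row.start : row.start + 66]

    def test_per_read_truth_matches_emitted_ids(self, toy_run):
        _truth, reads, _cm = toy_run
        assert set(reads.per_read["read_id"]) == {rid for rid, _ in reads.read1}
        assert len(reads.read1) == len(reads.read2) == len(reads.per_read)

    def test_reads_within_frag_window_of_3prime_end(self, toy_run, toy_tx):
        _truth, reads, _cm = toy_run
        for row in reads.per_read.itertuples():
            L = len(toy_tx.transcripts[row.transcript_id])
            assert row.start >= max(0, L - 250)
            assert row.start + 66 <= L

    def test_seed_determinism(self, toy_tx, toy_plate, barcode_set_96):
        truth = ps.simulate_counts(toy_tx, toy_plate, 40, 0.1, 200, seed=5)
        a = ps.simulate_run(truth, toy_tx, barcode_set_96, toy_plate, seed=9)
        b = ps.simulate_run(truth, toy_tx, barcode_set_96, toy_plate, seed=9)
        assert a.read1 == b.read1 and a.read2 == b.read2
        assert a.per_read.equals(b.per_read)

    def test_frag_window_shorter_than_read_rejected(self, toy_tx, toy_plate, barcode_set_96):
        truth = ps.simulate_counts(toy_tx, toy_plate, 40, 0.1, 50, seed=5)
        with pytest.raises(ValueError, match="frag_window"):
            ps.simulate_run(
                truth, toy_tx, barcode_set_96, toy_plate, frag_window=50, seed=0
            )

    def test_substitution_errors_appear_at_requested_rate(
        self, toy_tx, toy_plate, barcode_set_96
    ):
        truth = ps.simulate_counts(toy_tx, toy_plate, 40, 0.1, 400, seed=5)
        reads = ps.simulate_run(
            truth, toy_tx, barcode_set_96, toy_plate, sub_error_rate=0.02, seed=11
        )
        label_to_bc = {
            row.well_label: row.barcode_index for row in toy_plate.wells.itertuples()
        }
        r1 = dict(reads.read1)
        mismatches = total = 0
        for row in reads.per_read.itertuples():
            bc = barcode_set_96.sequences[label_to_bc[row.well_label]]
            obs = r1[row.read_id][:8]
            mismatches += sum(a != b for a, b in zip(bc, obs))
            total += 8
        rate = mismatches / total
        se = np.sqrt(0.02 * 0.98 / total)
        assert abs(rate - 0.02) < 4 * se


def test_simulated_regulons_are_valid():
    from plateseq.activity import Regulon

    tx = ps.simulate_transcriptome(100, 1, (300, 400), seed=0)
    regs = ps.simulate_regulons(tx.genes, n_regulons=10, targets_per_regulon=20, seed=0)
    assert len(regs) == 10
    for rid, frame in regs.items():
        reg = Regulon.from_frame(rid, frame)
        assert len(reg) == 20


def test_regulator_perturbation_expands_through_regulon():
    tx = ps.simulate_transcriptome(30, 1, (300, 400), seed=0)
    regs = ps.simulate_regulons(tx.genes, n_regulons=2, targets_per_regulon=5, seed=1)
    rid = sorted(regs)[0]
    spec = ps.PerturbationSpec(regulator_id=rid, magnitude=-1.5)
    lfc = spec.resolve(regs)
    tab = regs[rid]
    for gene, mode in zip(tab["target"], tab["mode"]):
        assert lfc[gene] == pytest.approx(-1.5 * mode)
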