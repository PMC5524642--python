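"""End-to-end pipeline: simulate -> align -> demux/count -> QC -> signatures
-> activity -> noise, with checksum-based stage skipping and a manifest.

Every stage writes plain-text artifacts into the output directory; the
manifest records a hash of each stage's resolved configuration together
with checksums of its outputs, so an unchanged rerun skips all stages and
the same configuration and seed reproduce byte-identical numeric tables.
Progress is logged as line-delimited JSON for machine consumption.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as pio
from .activity import activity_matrix
from .alignio import PseudoAligner, align_reads, write_alignments
from .barcodes import design_barcode_set
from .config import dump_config, load_config, stage_seeds
from .demux import assign_wells, count_unique, iter_fastq
from .noise import duplicate_noise_table, fold_change_distribution, fold_change_quantiles
from .qc import qc_table, saturation_curve
from .signatures import classical_mds, signature, top_differential, vst
from .simulate import (
    PerturbationSpec,
    design_plate,
    simulate_counts,
    simulate_regulons,
    simulate_run,
    simulate_transcriptome,
    write_fastq,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cfg_hash(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class PipelineRun:
    """Stateful single-directory pipeline execution."""

    def __init__(self, cfg: Dict[str, Any], outdir: str) -> None:
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = stage_seeds(cfg["seed"])
        self.manifest_path = self.outdir / "manifest.json"
        self.log_path = self.outdir / "run_log.jsonl"
        self.manifest: Dict[str, Any] = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )

    # -- bookkeeping --------------------------------------------------------

    def _log(self, **event: Any) -> None:
        event["time"] = time.time()
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(event) + "\n")

    def _up_to_date(self, stage: str, stage_cfg: Any, outputs: List[Path]) -> bool:
        entry = self.manifest["stages"].get(stage)
        if entry is None or entry["config"] != _cfg_hash(stage_cfg):
            return False
        for path in outputs:
            if not path.exists() or entry["outputs"].get(path.name) != _sha256(path):
                return False
        return True

    def _record(self, stage: str, stage_cfg: Any, outputs: List[Path]) -> None:
        self.manifest["stages"][stage] = {
            "config": _cfg_hash(stage_cfg),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _paths(self, *names: str) -> List[Path]:
        return [self.outdir / n for n in names]

    # -- stages -------------------------------------------------------------

    def run(self) -> Dict[str, Any]:
        dump_config(self.cfg, self.outdir / "config.resolved.yaml")
        for stage in (
            self.simulate,
            self.align,
            self.count,
            self.qc,
            self.signatures,
            self.activity,
            self.noise,
        ):
            stage()
        return self.manifest

    def simulate(self) -> None:
        cfg = {k: self.cfg[k] for k in ("barcodes", "transcriptome", "plate", "regulons", "counts", "reads")}
        cfg["seed"] = self.seeds["simulate"]
        outs = self._paths(
            "barcodes.tsv", "transcriptome.fasta", "tx2gene.tsv", "layout.csv",
            "regulons.tsv", "truth_counts.tsv", "reads_R1.fastq.gz",
            "reads_R2.fastq.gz", "truth_reads.tsv",
        )
        if self._up_to_date("simulate", cfg, outs):
            self._log(stage="simulate", status="skipped")
            return
        t0 = time.time()
        seed = cfg["seed"]
        bc = self.cfg["barcodes"]
        barcodes = design_barcode_set(
            bc["n"], bc["k"], bc["min_distance"], seed=seed,
            max_homopolymer=bc["max_homopolymer"],
        )
        tc = self.cfg["transcriptome"]
        tx = simulate_transcriptome(
            tc["n_genes"], tc["iso_per_gene"],
            (tc["length_min"], tc["length_max"]),
            n_spikeins=tc["n_spikeins"], seed=seed + 1,
            min_read_len=self.cfg["reads"]["read2_len"],
        )
        pl = self.cfg["plate"]
        regulons = simulate_regulons(
            tx.genes, self.cfg["regulons"]["n_regulons"],
            self.cfg["regulons"]["targets_per_regulon"], seed=seed + 2,
        )
        rng = np.random.default_rng(seed + 3)
        conditions: Dict[str, PerturbationSpec] = {}
        for cond in pl["conditions"]:
            genes = rng.choice(tx.genes, size=pl["planted_genes_per_condition"], replace=False)
            spec = PerturbationSpec(targets={g: pl["planted_lfc"] for g in genes})
            if cond == pl["planted_regulator_condition"] and regulons:
                spec.regulator_id = next(iter(sorted(regulons)))
                spec.magnitude = pl["planted_regulator_magnitude"]
            conditions[cond] = spec
        plate = design_plate(conditions, pl["vehicle"], pl["replicates"])
        ct = self.cfg["counts"]
        truth = simulate_counts(
            tx, plate, ct["base_mean"], ct["dispersion"], ct["reads_per_well"],
            seed=seed + 4, regulons=regulons,
        )
        rd = self.cfg["reads"]
        reads = simulate_run(
            truth, tx, barcodes, plate,
            read1_len=rd["read1_len"], read2_len=rd["read2_len"],
            sub_error_rate=rd["sub_error_rate"], frag_window=rd["frag_window"],
            seed=seed + 5,
        )
        pio.write_barcodes(self.outdir / "barcodes.tsv", barcodes)
        pio.write_transcriptome(tx, self.outdir / "transcriptome.fasta", self.outdir / "tx2gene.tsv")
        pio.write_layout(self.outdir / "layout.csv", plate)
        pio.write_regulons(self.outdir / "regulons.tsv", regulons)
        pio.write_matrix(self.outdir / "truth_counts.tsv", truth.realized_counts)
        write_fastq(reads.read1, self.outdir / "reads_R1.fastq.gz")
        write_fastq(reads.read2, self.outdir / "reads_R2.fastq.gz")
        reads.per_read.to_csv(self.outdir / "truth_reads.tsv", sep="\t", index=False)
        self._record("simulate", cfg, outs)
        self._log(stage="simulate", status="done", seconds=time.time() - t0,
                  n_reads=len(reads.read1))

    def align(self) -> None:
        cfg = {"align": self.cfg["align"]}
        outs = self._paths("alignments.sam")
        if self._up_to_date("align", cfg, outs):
            self._log(stage="align", status="skipped")
            return
        t0 = time.time()
        tx = pio.read_transcriptome(self.outdir / "transcriptome.fasta", self.outdir / "tx2gene.tsv")
        al = self.cfg["align"]
        aligner = PseudoAligner(tx, al["seed_len"], al["match"], al["mismatch"])
        groups = align_reads(iter_fastq(str(self.outdir / "reads_R2.fastq.gz")), aligner)
        write_alignments(str(self.outdir / "alignments.sam"), groups, tx)
        self._record("align", cfg, outs)
        self._log(stage="align", status="done", seconds=time.time() - t0)

    def count(self) -> None:
        cfg = {"demux": self.cfg["demux"]}
        outs = self._paths("counts.tsv", "count_stats.tsv", "spike_counts.tsv", "demux_summary.json")
        if self._up_to_date("count", cfg, outs):
            self._log(stage="count", status="skipped")
            return
        t0 = time.time()
        barcodes = pio.read_barcodes(self.outdir / "barcodes.tsv",
                                     min_distance=self.cfg["barcodes"]["min_distance"])
        tx = pio.read_transcriptome(self.outdir / "transcriptome.fasta", self.outdir / "tx2gene.tsv")
        dm = self.cfg["demux"]
        wells = assign_wells(
            iter_fastq(str(self.outdir / "reads_R1.fastq.gz")), barcodes,
            max_distance=dm["max_distance"], mode=dm["mode"],
        )
        from .alignio import read_alignments
        groups = read_alignments(str(self.outdir / "alignments.sam"), tx.tx2gene)
        cm = count_unique(groups, wells, tx.tx2gene, tx.spike_ins)
        pio.write_count_matrix(cm, self.outdir / "counts.tsv",
                               self.outdir / "count_stats.tsv",
                               self.outdir / "spike_counts.tsv")
        (self.outdir / "demux_summary.json").write_text(json.dumps(wells.summary(), indent=2))
        self._record("count", cfg, outs)
        self._log(stage="count", status="done", seconds=time.time() - t0,
                  **wells.summary())

    def qc(self) -> None:
        cfg = {"qc": self.cfg["qc"], "seed": self.seeds["qc"]}
        outs = self._paths("qc_per_well.tsv", "saturation.tsv")
        if self._up_to_date("qc", cfg, outs):
            self._log(stage="qc", status="skipped")
            return
        t0 = time.time()
        cm = pio.read_count_matrix(self.outdir / "counts.tsv",
                                   self.outdir / "count_stats.tsv",
                                   self.outdir / "spike_counts.tsv")
        q = self.cfg["qc"]
        qc_table(cm, q["min_count"]).to_csv(self.outdir / "qc_per_well.tsv", sep="\t",
                                            index_label="well_label")
        curve = saturation_curve(cm, q["fractions"], q["n_reps"],
                                 seed=self.seeds["qc"], min_count=q["min_count"])
        curve.to_frame().to_csv(self.outdir / "saturation.tsv", sep="\t", index=False)
        self._record("qc", cfg, outs)
        self._log(stage="qc", status="done", seconds=time.time() - t0)

    def signatures(self) -> None:
        cfg = {"signatures": self.cfg["signatures"]}
        outs = self._paths("expression_vst.tsv", "signatures.tsv", "top_genes.txt",
                           "mds_coords.tsv")
        if self._up_to_date("signatures", cfg, outs):
            self._log(stage="signatures", status="skipped")
            return
        t0 = time.time()
        cm = pio.read_count_matrix(self.outdir / "counts.tsv",
                                   self.outdir / "count_stats.tsv",
                                   self.outdir / "spike_counts.tsv")
        plate = pio.read_layout(self.outdir / "layout.csv")
        sg = self.cfg["signatures"]
        expr = vst(cm, pseudocount=sg["pseudocount"])
        sig = signature(expr, plate)
        conditions = plate.condition_samples()
        top = top_differential(sig, conditions, k=sg["top_k"])
        coords = classical_mds(sig.values.loc[top], dims=sg["mds_dims"])
        pio.write_matrix(self.outdir / "expression_vst.tsv", expr.values)
        pio.write_matrix(self.outdir / "signatures.tsv", sig.values)
        (self.outdir / "top_genes.txt").write_text("\n".join(top) + "\n")
        coords.to_csv(self.outdir / "mds_coords.tsv", sep="\t", index_label="well_label")
        self._record("signatures", cfg, outs)
        self._log(stage="signatures", status="done", seconds=time.time() - t0)

    def activity(self) -> None:
        cfg = {"activity": self.cfg["activity"]}
        outs = self._paths("activity_nes.tsv")
        if self._up_to_date("activity", cfg, outs):
            self._log(stage="activity", status="skipped")
            return
        t0 = time.time()
        sig_values = pio.read_matrix(self.outdir / "signatures.tsv")
        regulons = pio.read_regulons(self.outdir / "regulons.tsv")
        act = activity_matrix(sig_values, regulons, min_size=self.cfg["activity"]["min_size"])
        pio.write_matrix(self.outdir / "activity_nes.tsv", act.nes, index_label="regulator")
        self._record("activity", cfg, outs)
        self._log(stage="activity", status="done", seconds=time.time() - t0,
                  method=act.method)

    def noise(self) -> None:
        cfg = {"noise": self.cfg["noise"]}
        outs = self._paths("noise_table.tsv", "fc_quantiles.tsv")
        if self._up_to_date("noise", cfg, outs):
            self._log(stage="noise", status="skipped")
            return
        t0 = time.time()
        cm = pio.read_count_matrix(self.outdir / "counts.tsv",
                                   self.outdir / "count_stats.tsv",
                                   self.outdir / "spike_counts.tsv")
        plate = pio.read_layout(self.outdir / "layout.csv")
        expr = vst(cm, pseudocount=self.cfg["noise"]["pseudocount"])
        linear = expr.linear().clip(lower=0)
        # duplicate pairs: consecutive replicates within each condition
        pairs = []
        for _cond, samples in plate.condition_samples(include_vehicle=True).items():
            for i in range(0, len(samples) - 1, 2):
                pairs.append((samples[i], samples[i + 1]))
        table = duplicate_noise_table(linear, pairs, ddof=self.cfg["noise"]["cv_ddof"])
        table.to_csv(self.outdir / "noise_table.tsv", sep="\t", index_label="gene")
        fc = fold_change_distribution(linear, plate, pseudocount=self.cfg["noise"]["pseudocount"])
        fold_change_quantiles(fc).rename("log2_fc").to_csv(
            self.outdir / "fc_quantiles.tsv", sep="\t", index_label="quantile"
        )
        self._record("noise", cfg, outs)
        self._log(stage="noise", status="done", seconds=time.time() - t0)


def run_pipeline(config_path: Optional[str] = None, outdir: str = "plateseq_run",
                 overrides: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Resolve configuration and execute all stages in dependency order."""
    cfg = load_config(config_path, overrides)
    return PipelineRun(cfg, outdir).run()
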