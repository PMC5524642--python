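"""Readers and writers for the pipeline's plain-text interchange formats.

Conventions, used everywhere: matrices are TSV with genes as rows and well
labels as columns (index header ``gene``); the barcode table is headerless
TSV ``well_label<TAB>sequence``; regulons are TSV with columns
``regulator, target, mode, likelihood``; the plate layout is CSV with
columns ``well_label, barcode_index, condition, is_vehicle``.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .barcodes import BarcodeSet
from .demux import CountMatrix, STAT_COLUMNS
from .simulate import PerturbationSpec, PlateDesign, Transcriptome


# -- barcodes ---------------------------------------------------------------


def write_barcodes(path: str, barcodes: BarcodeSet) -> None:
    pd.DataFrame(
        {"well_label": barcodes.well_labels, "sequence": barcodes.sequences}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_barcodes(path: str, min_distance: int = 3) -> BarcodeSet:
    tab = pd.read_csv(path, sep="\t", header=None, names=["well_label", "sequence"])
    seqs = list(tab["sequence"])
    return BarcodeSet(
        sequences=seqs,
        length_k=len(seqs[0]),
        min_distance=min_distance,
        well_labels=list(tab["well_label"]),
    )


# -- transcriptome ----------------------------------------------------------


def write_transcriptome(tx: Transcriptome, fasta_path: str, tx2gene_path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in sorted(tx.transcripts.items())
    ]
    SeqIO.write(records, fasta_path, "fasta")
    pd.DataFrame(
        {
            "transcript_id": sorted(tx.tx2gene),
            "gene_id": [tx.tx2gene[t] for t in sorted(tx.tx2gene)],
            "spike_in": [t in tx.spike_ins for t in sorted(tx.tx2gene)],
        }
    ).to_csv(tx2gene_path, sep="\t", index=False)


def read_transcriptome(fasta_path: str, tx2gene_path: str) -> Transcriptome:
    transcripts = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
    }
    tab = read_tx2gene(tx2gene_path)
    spikes = frozenset(tab.index[tab.get("spike_in", False) == True])  # noqa: E712
    return Transcriptome(transcripts, dict(tab["gene_id"]), spikes)


def read_tx2gene(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    return tab.set_index("transcript_id")


# -- plate layout -----------------------------------------------------------


def write_layout(path: str, plate: PlateDesign) -> None:
    plate.wells.to_csv(path, index=False)


def read_layout(path: str) -> PlateDesign:
    wells = pd.read_csv(path)
    conditions = {
        c: PerturbationSpec() for c in wells["condition"].unique()
    }
    return PlateDesign(wells, conditions)


# -- regulons ---------------------------------------------------------------


def write_regulons(path: str, regulons: Mapping[str, pd.DataFrame]) -> None:
    rows = []
    for rid, tab in regulons.items():
        frame = tab.copy()
        frame.insert(0, "regulator", rid)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_regulons(path: str) -> Dict[str, pd.DataFrame]:
    tab = pd.read_csv(path, sep="\t")
    return {
        str(rid): grp[["target", "mode", "likelihood"]].reset_index(drop=True)
        for rid, grp in tab.groupby("regulator", sort=True)
    }


# -- matrices ---------------------------------------------------------------


def write_matrix(path: str, matrix: pd.DataFrame, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrix(cm: CountMatrix, counts_path: str, stats_path: str,
                       spike_path: Optional[str] = None) -> None:
    write_matrix(counts_path, cm.counts)
    cm.stats.to_csv(stats_path, sep="\t", index_label="well_label")
    if spike_path is not None:
        write_matrix(spike_path, cm.spike_counts, index_label="spike_in")


def read_count_matrix(counts_path: str, stats_path: Optional[str] = None,
                      spike_path: Optional[str] = None) -> CountMatrix:
    counts = read_matrix(counts_path).astype(int)
    if stats_path is not None:
        stats = pd.read_csv(stats_path, sep="\t", index_col=0)
    else:
        stats = pd.DataFrame(
            0, index=counts.columns, columns=STAT_COLUMNS, dtype=int
        )
        stats["unique_gene"] = counts.sum(axis=0)
        stats["assigned_reads"] = stats["unique_gene"]
    spikes = read_matrix(spike_path).astype(int) if spike_path else None
    return CountMatrix(counts=counts, stats=stats, spike_counts=spikes)
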