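"""Demultiplexing and strand-specific unique-mapping gene counting.

Reads are assigned to wells by error-correcting decoding of the read-1
barcode, then counted per gene per well under the unique-mapping rule: a
read is uniquely mapped when the maximum alignment score among its
correct-strand (sense) alignments is attained only by transcripts of a
single gene. Antisense alignments never veto a sense winner — the library
is 3'-end and strand-specific, so the correct strand is the transcript
sense strand. Multi-gene maximum-score ties are discarded (no EM rescue),
and reads are counted, not deduplicated: the protocol has no UMIs.

Spike-in control transcripts are counted in a separate block and never as
genes; a maximum-score tie spanning a gene and a spike-in is discarded and
logged.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .alignio import SENSE, AlignmentRecord
from .barcodes import BarcodeSet, correct_barcode

logger = logging.getLogger(__name__)

STAT_COLUMNS = [
    "assigned_reads",
    "unique_gene",
    "unique_spikein",
    "multi_gene",
    "gene_spikein_tie",
    "wrong_strand",
    "unmapped",
]


def iter_fastq(path: str) -> Iterator[Tuple[str, str]]:
    """Yield (read_id, sequence) from a (optionally gzipped) FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


@dataclass
class WellAssignmentTable:
    """Read -> well decoding results with exact summary statistics."""

    assignments: Dict[str, Tuple[int, int]]  # read_id -> (well_index, distance)
    total: int
    unassigned: int
    ambiguous: int
    well_labels: List[str]

    @property
    def assigned(self) -> int:
        return len(self.assignments)

    def summary(self) -> Dict[str, int]:
        return {
            "total": self.total,
            "assigned": self.assigned,
            "unassigned": self.unassigned,
            "ambiguous": self.ambiguous,
        }


def assign_wells(
    read1: Iterable[Tuple[str, str]],
    barcodes: BarcodeSet,
    max_distance: int = 1,
    mode: str = "hamming",
    well_labels: Optional[Sequence[str]] = None,
) -> WellAssignmentTable:
    """Decode every read-1 barcode against the designed set.

    ``read1`` is an (id, sequence) stream (see :func:`iter_fastq`).
    Duplicate read ids are a hard error: downstream grouping of alignment
    evidence relies on id uniqueness. Counts satisfy
    ``assigned + unassigned + ambiguous == total`` exactly.
    """
    labels = list(well_labels) if well_labels is not None else list(barcodes.well_labels)
    assignments: Dict[str, Tuple[int, int]] = {}
    total = unassigned = ambiguous = 0
    seen: set = set()
    for rid, seq in read1:
        if rid in seen:
            raise ValueError(f"duplicate read id {rid!r} in read-1 stream")
        seen.add(rid)
        total += 1
        res = correct_barcode(seq, barcodes, max_distance=max_distance, mode=mode)
        if res.status == "assigned":
            assignments[rid] = (res.well_index, res.edit_distance)
        elif res.status == "ambiguous":
            ambiguous += 1
        else:
            unassigned += 1
    return WellAssignmentTable(assignments, total, unassigned, ambiguous, labels)


@dataclass
class CountMatrix:
    """Gene x well counts with per-well provenance statistics.

    ``counts`` holds endogenous genes only; ``spike_counts`` holds the
    spike-in block; ``stats`` has one row per well (columns
    ``STAT_COLUMNS``). Per well, ``unique_gene`` equals the column sum of
    ``counts`` and assigned reads are conserved across the outcome
    categories.
    """

    counts: pd.DataFrame
    stats: pd.DataFrame
    spike_counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.spike_counts is None:
            self.spike_counts = pd.DataFrame(
                np.zeros((0, self.counts.shape[1]), dtype=int),
                columns=self.counts.columns,
            )

    @property
    def wells(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> List[str]:
        return list(self.counts.index)


def count_unique(
    groups: Iterable[Tuple[str, List[AlignmentRecord]]],
    wells: WellAssignmentTable,
    tx2gene: Mapping[str, str],
    spike_ins: frozenset = frozenset(),
    on_unknown: str = "error",
) -> CountMatrix:
    """Apply the unique-mapping counting rule to per-read alignment groups.

    Per read: (1) drop antisense records; (2) take the maximum score among
    the remaining sense records; (3) map the maximum-score transcripts to
    genes; (4) count the read iff they name exactly one gene. Reads
    assigned to a well but never seen in ``groups`` (or seen with no
    alignments) are tallied as unmapped.
    """
    spike_genes = frozenset(tx2gene[t] for t in spike_ins)
    genes = sorted(set(tx2gene.values()) - spike_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    spikes = sorted(spike_genes)
    spike_index = {g: i for i, g in enumerate(spikes)}
    labels = wells.well_labels
    n_wells = len(labels)

    counts = np.zeros((len(genes), n_wells), dtype=np.int64)
    spike_counts = np.zeros((len(spikes), n_wells), dtype=np.int64)
    stats = np.zeros((n_wells, len(STAT_COLUMNS)), dtype=np.int64)
    col = {name: i for i, name in enumerate(STAT_COLUMNS)}

    seen_reads: set = set()
    for rid, records in groups:
        assignment = wells.assignments.get(rid)
        seen_reads.add(rid)
        if assignment is None:
            continue  # unassigned or ambiguous read; not attributable to a well
        w, _dist = assignment
        stats[w, col["assigned_reads"]] += 1
        if not records:
            stats[w, col["unmapped"]] += 1
            continue
        sense = [r for r in records if r.strand == SENSE]
        if not sense:
            stats[w, col["wrong_strand"]] += 1
            continue
        top = max(r.score for r in sense)
        top_genes = set()
        unknown = False
        for r in sense:
            if r.score != top:
                continue
            g = tx2gene.get(r.transcript_id)
            if g is None:
                if on_unknown == "error":
                    raise KeyError(f"transcript {r.transcript_id!r} not in tx2gene")
                logger.warning("unknown transcript %s skipped", r.transcript_id)
                unknown = True
                continue
            top_genes.add(g)
        if not top_genes:
            if unknown:
                stats[w, col["unmapped"]] += 1
            continue
        in_spike = top_genes & spike_genes
        if len(top_genes) > 1:
            if in_spike and top_genes - spike_genes:
                stats[w, col["gene_spikein_tie"]] += 1
            else:
                stats[w, col["multi_gene"]] += 1
            continue
        (gene,) = top_genes
        if gene in spike_index:
            spike_counts[spike_index[gene], w] += 1
            stats[w, col["unique_spikein"]] += 1
        else:
            counts[gene_index[gene], w] += 1
            stats[w, col["unique_gene"]] += 1

    # assigned reads that never produced an alignment group at all
    for rid, (w, _d) in wells.assignments.items():
        if rid not in seen_reads:
            stats[w, col["assigned_reads"]] += 1
            stats[w, col["unmapped"]] += 1

    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=labels),
        stats=pd.DataFrame(stats, index=labels, columns=STAT_COLUMNS),
        spike_counts=pd.DataFrame(spike_counts, index=spikes, columns=labels),
    )


def pool_wells(cm: CountMatrix, groups: Mapping[str, Sequence[str]]) -> CountMatrix:
    """Sum counts column-wise within disjoint groups of wells.

    ``groups`` maps a pooled label to its member wells; members must form a
    partition of a subset of the wells (no overlaps). The gene axis is
    unchanged and statistics are summed alongside.
    """
    members: List[str] = [w for ws in groups.values() for w in ws]
    if len(members) != len(set(members)):
        raise ValueError("well groups overlap; a partition is required")
    unknown = set(members) - set(cm.wells)
    if unknown:
        raise ValueError(f"unknown wells in grouping: {sorted(unknown)}")
    counts = pd.DataFrame(
        {label: cm.counts[list(ws)].sum(axis=1) for label, ws in groups.items()}
    )
    spikes = pd.DataFrame(
        {label: cm.spike_counts[list(ws)].sum(axis=1) for label, ws in groups.items()}
    )
    stats = pd.DataFrame(
        {label: cm.stats.loc[list(ws)].sum(axis=0) for label, ws in groups.items()}
    ).T
    return CountMatrix(counts=counts, stats=stats, spike_counts=spikes)
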