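"""Alignment evidence: SAM/BAM ingestion and a minimal built-in matcher.

The counting rule downstream needs, per read, only the transcript identity,
the strand relative to the transcript, and a score ordering among that
read's alignments — genome coordinates are irrelevant for 3'-end
transcriptome counting. This module normalizes pysam records into that
minimal form and provides :class:`PseudoAligner`, an exact-k-mer-seeded,
ungapped matcher so the pipeline can run self-contained without an external
aligner (it is a test/simulation utility, not a general-purpose aligner).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import pysam

from .simulate import Transcriptome, revcomp

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a read to a transcript.

    ``strand`` is relative to the transcript: a SAM record with the
    reverse-complement flag set is antisense. ``score`` is the aligner's
    alignment score (AS tag) or, failing that, the aligned CIGAR length —
    only its ordering within one read matters.
    """

    read_id: str
    transcript_id: str
    strand: str
    score: int


def _record_score(aln: "pysam.AlignedSegment") -> Optional[int]:
    if aln.has_tag("AS"):
        return int(aln.get_tag("AS"))
    if aln.cigartuples:
        # fallback: aligned length over match-type ops (M, =, X)
        return sum(ln for op, ln in aln.cigartuples if op in (0, 7, 8))
    return None


def read_alignments(
    path: str,
    tx2gene: Optional[Mapping[str, str]] = None,
    on_unknown: str = "error",
) -> Iterator[Tuple[str, List[AlignmentRecord]]]:
    """Stream (read_id, records) groups from a name-grouped SAM/BAM file.

    Secondary/supplementary records join their read's group; unmapped reads
    yield empty groups. Records without a derivable score are dropped with a
    logged count. A transcript name absent from ``tx2gene`` is a hard error
    by default (``on_unknown='drop'`` discards the record with a warning).

    The file must be grouped by read name (all records of a read adjacent);
    a read name reappearing after its group closed raises an error.
    """
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    seen: set = set()
    dropped_unscored = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        current: Optional[str] = None
        group: List[AlignmentRecord] = []
        for aln in fh.fetch(until_eof=True):
            rid = aln.query_name
            if rid != current:
                if current is not None:
                    yield current, group
                    seen.add(current)
                if rid in seen:
                    raise ValueError(
                        f"read {rid!r} reappears after its group closed; input "
                        "must be grouped by read name"
                    )
                current, group = rid, []
            if aln.is_unmapped:
                continue
            ref = aln.reference_name
            if tx2gene is not None and ref not in tx2gene:
                if on_unknown == "error":
                    raise KeyError(f"transcript {ref!r} not present in tx2gene")
                logger.warning("dropping alignment to unknown transcript %s", ref)
                continue
            score = _record_score(aln)
            if score is None:
                dropped_unscored += 1
                continue
            group.append(
                AlignmentRecord(
                    read_id=rid,
                    transcript_id=ref,
                    strand=ANTISENSE if aln.is_reverse else SENSE,
                    score=score,
                )
            )
        if current is not None:
            yield current, group
    if dropped_unscored:
        logger.warning("dropped %d alignment records without a score", dropped_unscored)


def write_alignments(
    path: str,
    groups: Iterable[Tuple[str, List[AlignmentRecord]]],
    tx: Transcriptome,
) -> None:
    """Write alignment groups to SAM/BAM (primary first, rest secondary).

    Sequences/CIGARs are omitted; the score travels in the AS tag, which is
    all :func:`read_alignments` needs to round-trip record content.
    """
    refs = sorted(tx.transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
        "SQ": [{"SN": t, "LN": len(tx.transcripts[t])} for t in refs],
    }
    ref_id = {t: i for i, t in enumerate(refs)}
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rid, records in groups:
            if not records:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rid
                seg.is_unmapped = True
                out.write(seg)
                continue
            for i, rec in enumerate(records):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rid
                seg.reference_id = ref_id[rec.transcript_id]
                seg.reference_start = 0
                seg.mapping_quality = 0
                seg.is_reverse = rec.strand == ANTISENSE
                seg.is_secondary = i > 0
                # a mapped record needs a CIGAR; 1M placeholder, score in AS
                seg.cigarstring = "1M"
                seg.set_tag("AS", int(rec.score))
                out.write(seg)


class PseudoAligner:
    """Exact k-mer seeding on both strands plus ungapped extension.

    Scores are ``matches*match - mismatches*mismatch`` over the read/
    transcript overlap; all distinct (transcript, strand) hits are returned
    with their best score, so ties across isoforms or genes are visible to
    the counting rule. Seeds are taken at the read's start, middle and end.
    """

    def __init__(
        self,
        tx: Transcriptome,
        seed_len: int = 16,
        match: int = 1,
        mismatch: int = 1,
    ) -> None:
        self.tx = tx
        self.seed_len = seed_len
        self.match = match
        self.mismatch = mismatch
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for tid, seq in tx.transcripts.items():
            for pos in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[pos : pos + seed_len], []).append((tid, pos))

    def _extend(self, seq: str, tid: str, start: int) -> Optional[int]:
        t = self.tx.transcripts[tid]
        a, b = max(0, start), min(len(t), start + len(seq))
        if b <= a:
            return None
        read_part = seq[a - start : b - start]
        t_part = t[a:b]
        if read_part == t_part:
            mismatches = 0
        else:
            mismatches = sum(x != y for x, y in zip(read_part, t_part))
        matches = (b - a) - mismatches
        return matches * self.match - mismatches * self.mismatch

    def align(self, read_id: str, read: str) -> List[AlignmentRecord]:
        k = self.seed_len
        if k > len(read):
            raise ValueError("seed_len exceeds read length")
        best: Dict[Tuple[str, str], int] = {}
        offsets = sorted({0, (len(read) - k) // 2, len(read) - k})
        for strand, seq in ((SENSE, read), (ANTISENSE, revcomp(read))):
            seen_diag: set = set()
            for off in offsets:
                kmer = seq[off : off + k]
                for tid, pos in self._index.get(kmer, ()):
                    start = pos - off
                    key = (tid, strand, start)
                    if key in seen_diag:
                        continue
                    seen_diag.add(key)
                    score = self._extend(seq, tid, start)
                    if score is None:
                        continue
                    bkey = (tid, strand)
                    if score > best.get(bkey, -(10**9)):
                        best[bkey] = score
        records = [
            AlignmentRecord(read_id, tid, strand, score)
            for (tid, strand), score in best.items()
        ]
        records.sort(key=lambda r: (-r.score, r.transcript_id, r.strand))
        return records


def pseudo_align(
    read: str,
    tx: Transcriptome,
    seed_len: int = 16,
    match: int = 1,
    mismatch: int = 1,
    read_id: str = "read",
) -> List[AlignmentRecord]:
    """One-shot convenience wrapper around :class:`PseudoAligner`."""
    return PseudoAligner(tx, seed_len, match, mismatch).align(read_id, read)


def align_reads(
    reads: Iterable[Tuple[str, str]],
    aligner: PseudoAligner,
) -> Iterator[Tuple[str, List[AlignmentRecord]]]:
    """Align an (id, sequence) stream, yielding one group per read."""
    for rid, seq in reads:
        yield rid, aligner.align(rid, seq)
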