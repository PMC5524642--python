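"""Synthetic pooled-well 3'-end RNA-Seq runs with full ground truth.

Emulates the structure of a 96-well pooled screen — a toy transcriptome, a
plate layout with drug and vehicle-control conditions, negative-binomial
gene counts with planted log2 fold-change effects, and barcoded paired
FASTQ reads with substitution errors — so the whole pipeline can be
exercised and validated without external sequencing data. Ground truth
(per-read well and transcript of origin, expected and realized counts) is
retained for parameter-recovery and exactness tests.

The generative model mirrors the assumptions of the downstream analysis:
counts are negative binomial (gamma-Poisson) with a common dispersion, the
per-gene mean in a perturbed well is ``base_mean * 2**lfc``, and realized
counts are rescaled to a fixed per-well read total by multinomial thinning
(pooled libraries are sequenced to a roughly constant depth per well).
Read 1 is the well barcode followed by a T-homopolymer fill (the oligo(dT)
tail); read 2 is a sense-strand fragment drawn uniformly from a window at
the transcript 3' end. No UMIs exist in this protocol, so duplicate reads
are legitimate observations.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .barcodes import ALPHABET, BarcodeSet, plate_labels

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


@dataclass
class Transcriptome:
    """A set of transcript sequences with a transcript-to-gene map.

    ``spike_ins`` flags transcript ids that are synthetic spike-in controls;
    their (self-mapping) gene ids are segregated from endogenous genes by
    the counting stage.
    """

    transcripts: Dict[str, str]
    tx2gene: Dict[str, str]
    spike_ins: frozenset = frozenset()

    def __post_init__(self) -> None:
        missing = set(self.transcripts) - set(self.tx2gene)
        if missing:
            raise ValueError(f"transcripts missing from tx2gene: {sorted(missing)[:5]}")
        for tid, seq in self.transcripts.items():
            if not seq or set(seq) - set(ALPHABET):
                raise ValueError(f"transcript {tid} empty or non-ACGT")
        self.spike_ins = frozenset(self.spike_ins)

    @property
    def spike_gene_ids(self) -> frozenset:
        return frozenset(self.tx2gene[t] for t in self.spike_ins)

    @property
    def genes(self) -> List[str]:
        """Sorted endogenous gene ids (spike-in genes excluded)."""
        spikes = self.spike_gene_ids
        return sorted(set(self.tx2gene.values()) - spikes)

    @property
    def all_genes(self) -> List[str]:
        return sorted(set(self.tx2gene.values()))

    def gene_transcripts(self) -> Dict[str, List[str]]:
        by_gene: Dict[str, List[str]] = {}
        for tid in sorted(self.transcripts):
            by_gene.setdefault(self.tx2gene[tid], []).append(tid)
        return by_gene


def simulate_transcriptome(
    n_genes: int,
    iso_per_gene: int = 1,
    length_range: Tuple[int, int] = (300, 1000),
    n_spikeins: int = 0,
    seed: int = 0,
    min_read_len: Optional[int] = None,
) -> Transcriptome:
    """Generate a random transcriptome of ``n_genes * iso_per_gene`` transcripts.

    Gene ids are ``G0001``..; transcript ids ``G0001.T1``..; spike-ins are
    ``SPIKE-01``.. mapping to themselves. Transcript lengths are uniform on
    ``length_range``. Deterministic for a fixed seed.
    """
    if n_genes < 1 or iso_per_gene < 1:
        raise ValueError("n_genes and iso_per_gene must be >= 1")
    lo, hi = length_range
    if min_read_len is not None and lo < min_read_len:
        raise ValueError(
            f"length_range lower bound {lo} is shorter than the read length "
            f"{min_read_len}"
        )
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    transcripts: Dict[str, str] = {}
    tx2gene: Dict[str, str] = {}

    def _random_seq(length: int) -> str:
        return rng.choice(bases, size=length).tobytes().decode()

    width = max(4, len(str(n_genes)))
    for g in range(n_genes):
        gid = f"G{g + 1:0{width}d}"
        for t in range(iso_per_gene):
            tid = f"{gid}.T{t + 1}"
            transcripts[tid] = _random_seq(int(rng.integers(lo, hi + 1)))
            tx2gene[tid] = gid
    spikes = []
    for s in range(n_spikeins):
        sid = f"SPIKE-{s + 1:02d}"
        transcripts[sid] = _random_seq(int(rng.integers(lo, hi + 1)))
        tx2gene[sid] = sid
        spikes.append(sid)
    return Transcriptome(transcripts, tx2gene, frozenset(spikes))


# ---------------------------------------------------------------------------
# plate design
# ---------------------------------------------------------------------------


@dataclass
class PerturbationSpec:
    """Planted per-gene log2 fold changes for one condition.

    ``regulator_id`` optionally names a regulator whose regulon targets
    receive mode-aligned shifts of ``magnitude`` log2 units (a target with
    mode ``m`` gets ``magnitude * m``), emulating a drug that modulates the
    activity of that regulator. Vehicle conditions have an empty target map.
    """

    targets: Dict[str, float] = field(default_factory=dict)
    regulator_id: Optional[str] = None
    magnitude: float = 0.0

    def resolve(self, regulons: Optional[Mapping[str, "pd.DataFrame"]] = None) -> Dict[str, float]:
        """Full gene -> lfc map, expanding the regulator effect if present."""
        lfc = dict(self.targets)
        if self.regulator_id is not None:
            if not regulons or self.regulator_id not in regulons:
                raise ValueError(
                    f"condition references regulator {self.regulator_id!r} but no "
                    "matching regulon was supplied"
                )
            tab = regulons[self.regulator_id]
            for gene, mode in zip(tab["target"], tab["mode"]):
                lfc[gene] = lfc.get(gene, 0.0) + self.magnitude * float(mode)
        return lfc


@dataclass
class PlateDesign:
    """Plate layout: one row per well plus the per-condition perturbations."""

    wells: pd.DataFrame  # columns: well_label, barcode_index, condition, is_vehicle
    conditions: Dict[str, PerturbationSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"well_label", "barcode_index", "condition", "is_vehicle"}
        if not required <= set(self.wells.columns):
            raise ValueError(f"wells table needs columns {sorted(required)}")
        if self.wells["barcode_index"].duplicated().any():
            raise ValueError("barcode_index values must be unique across wells")
        if self.wells["well_label"].duplicated().any():
            raise ValueError("well labels must be unique")

    @property
    def well_labels(self) -> List[str]:
        return list(self.wells["well_label"])

    @property
    def vehicle_wells(self) -> List[str]:
        return list(self.wells.loc[self.wells["is_vehicle"], "well_label"])

    def condition_samples(self, include_vehicle: bool = False) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for cond, grp in self.wells.groupby("condition", sort=True):
            if not include_vehicle and bool(grp["is_vehicle"].iloc[0]):
                continue
            out[str(cond)] = list(grp["well_label"])
        return out


def design_plate(
    conditions: Mapping[str, PerturbationSpec],
    vehicle_label: str = "DMSO",
    replicates: int = 12,
    barcode_labels: Optional[Sequence[str]] = None,
) -> PlateDesign:
    """Lay out ``len(conditions) * replicates`` wells, row-major.

    The default screen geometry is eight conditions (seven perturbagens plus
    a vehicle control) at 12 replicates each on a 96-well plate. The vehicle
    condition must be present and carries an empty perturbation.
    """
    if vehicle_label not in conditions:
        conditions = {**conditions, vehicle_label: PerturbationSpec()}
    if conditions[vehicle_label].targets or conditions[vehicle_label].regulator_id:
        raise ValueError("vehicle condition must have an empty perturbation")
    labels = list(conditions)
    n_wells = len(labels) * replicates
    well_labels = (
        list(barcode_labels) if barcode_labels is not None else plate_labels(n_wells)
    )
    rows = []
    for i in range(n_wells):
        cond = labels[i // replicates]
        rows.append(
            {
                "well_label": well_labels[i],
                "barcode_index": i,
                "condition": cond,
                "is_vehicle": cond == vehicle_label,
            }
        )
    return PlateDesign(pd.DataFrame(rows), dict(conditions))


# ---------------------------------------------------------------------------
# regulons (simulated; real regulons are inputs to the activity module)
# ---------------------------------------------------------------------------


def simulate_regulons(
    genes: Sequence[str],
    n_regulons: int = 50,
    targets_per_regulon: int = 25,
    seed: int = 0,
    activator_fraction: float = 0.75,
) -> Dict[str, pd.DataFrame]:
    """Random regulons: each regulator gets ``targets_per_regulon`` distinct
    target genes with modes +/-1 (``activator_fraction`` positive) and
    likelihood weights uniform on (0.5, 1].

    Regulator ids are ``R001``.. — abstract regulators, deliberately outside
    the gene id space so planted effects act only through targets.
    """
    if targets_per_regulon > len(genes):
        raise ValueError("more targets per regulon than available genes")
    rng = np.random.default_rng(seed)
    genes = np.asarray(genes)
    out: Dict[str, pd.DataFrame] = {}
    for r in range(n_regulons):
        rid = f"R{r + 1:03d}"
        targets = rng.choice(genes, size=targets_per_regulon, replace=False)
        modes = np.where(rng.random(targets_per_regulon) < activator_fraction, 1.0, -1.0)
        likelihood = rng.uniform(0.5, 1.0, size=targets_per_regulon)
        out[rid] = pd.DataFrame(
            {"target": targets, "mode": modes, "likelihood": likelihood}
        )
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Simulator ground truth.

    ``expected_counts`` are the negative-binomial means before thinning;
    ``realized_counts`` are the integer counts actually fragmented into
    reads, whose column sums equal the per-well read totals. ``per_read``
    (filled by :func:`simulate_run`) records the true well and transcript of
    origin for every emitted read.
    """

    expected_counts: pd.DataFrame
    realized_counts: pd.DataFrame
    params: Dict[str, object] = field(default_factory=dict)
    per_read: Optional[pd.DataFrame] = None


def simulate_counts(
    tx: Transcriptome,
    plate: PlateDesign,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    reads_per_well: int = 2000,
    seed: int = 0,
    regulons: Optional[Mapping[str, pd.DataFrame]] = None,
) -> SimTruth:
    """Draw a gene x well count matrix under the negative-binomial model.

    Per-gene mean in a well of condition ``c`` is ``base_mean * 2**lfc(g, c)``
    (``base_mean`` may be a scalar or a per-gene vector). Counts are
    gamma-Poisson with the given dispersion ``alpha`` (variance
    ``mu + alpha*mu^2``; ``alpha -> 0`` is the Poisson limit), then rescaled
    to exactly ``reads_per_well`` per column by multinomial thinning.
    """
    genes = tx.all_genes
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    base = np.broadcast_to(np.asarray(base_mean, dtype=float), (n_genes,)).copy()
    if (base <= 0).any():
        raise ValueError("base_mean must be positive")

    wells = plate.wells
    mu = np.tile(base[:, None], (1, len(wells)))
    lfc_cache: Dict[str, Dict[str, float]] = {}
    for j, (_, row) in enumerate(wells.iterrows()):
        cond = row["condition"]
        if cond not in lfc_cache:
            spec = plate.conditions.get(cond, PerturbationSpec())
            lfc_cache[cond] = spec.resolve(regulons)
        for gene, lfc in lfc_cache[cond].items():
            if not np.isfinite(lfc):
                raise ValueError(f"non-finite log2 fold change for gene {gene}")
            if gene in gene_index:
                mu[gene_index[gene], j] *= 2.0 ** lfc

    rng = np.random.default_rng(seed)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion < 1e-12:
        raw = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        raw = rng.poisson(lam)

    realized = np.zeros_like(raw)
    for j in range(raw.shape[1]):
        total = raw[:, j].sum()
        if total == 0:
            raise ValueError(f"well {wells['well_label'].iloc[j]} drew zero reads")
        realized[:, j] = rng.multinomial(reads_per_well, raw[:, j] / total)

    labels = plate.well_labels
    return SimTruth(
        expected_counts=pd.DataFrame(mu, index=genes, columns=labels),
        realized_counts=pd.DataFrame(realized, index=genes, columns=labels),
        params={
            "base_mean": base_mean,
            "dispersion": dispersion,
            "reads_per_well": reads_per_well,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class SimReads:
    """In-memory paired reads plus the per-read truth table."""

    read1: List[Tuple[str, str]]  # (read_id, sequence)
    read2: List[Tuple[str, str]]
    per_read: pd.DataFrame


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for i in hits:
        arr[i] = lut[arr[i]][rng.integers(3)]
    return arr.tobytes().decode()


def simulate_run(
    truth: SimTruth,
    tx: Transcriptome,
    barcodes: BarcodeSet,
    plate: PlateDesign,
    read1_len: int = 26,
    read2_len: int = 66,
    sub_error_rate: float = 0.0,
    frag_window: int = 250,
    seed: int = 0,
    shuffle: bool = True,
) -> SimReads:
    """Turn realized counts into barcoded paired reads.

    Read 1 is the well barcode followed by a ``T`` homopolymer fill to
    ``read1_len``; read 2 is a sense-strand substring of a transcript of the
    counted gene, starting uniformly within ``frag_window`` bases of the 3'
    end. Substitution errors are applied iid per base at ``sub_error_rate``
    on both reads. Transcripts shorter than ``read2_len`` are skipped with a
    warning; a gene with no usable transcript is an error because its reads
    could not be emitted without breaking count conservation.
    """
    if frag_window < read2_len:
        raise ValueError("frag_window must be >= read2_len")
    if barcodes.length_k > read1_len:
        raise ValueError("read1_len shorter than the barcode length")
    rng = np.random.default_rng(seed)

    by_gene = tx.gene_transcripts()
    eligible: Dict[str, List[str]] = {}
    for gene, tids in by_gene.items():
        keep = [t for t in tids if len(tx.transcripts[t]) >= read2_len]
        for t in tids:
            if len(tx.transcripts[t]) < read2_len:
                logger.warning(
                    "transcript %s (%d bp) shorter than read2_len=%d; skipped",
                    t, len(tx.transcripts[t]), read2_len,
                )
        eligible[gene] = keep

    wells = plate.wells
    label_to_bc = dict(zip(wells["well_label"], wells["barcode_index"]))
    counts = truth.realized_counts
    fill = "T" * (read1_len - barcodes.length_k)

    r1: List[Tuple[str, str]] = []
    r2: List[Tuple[str, str]] = []
    rows = []
    idx = 0
    for well in counts.columns:
        bc_index = int(label_to_bc[well])
        barcode = barcodes.sequences[bc_index]
        col = counts[well]
        for gene in counts.index[col.values > 0]:
            n = int(col[gene])
            tids = eligible.get(gene, [])
            if not tids:
                raise ValueError(
                    f"gene {gene} has counts but no transcript of length >= {read2_len}"
                )
            choice = rng.integers(0, len(tids), size=n)
            for c in choice:
                tid = tids[int(c)]
                seq = tx.transcripts[tid]
                lo = max(0, len(seq) - frag_window)
                hi = len(seq) - read2_len
                start = int(rng.integers(lo, hi + 1))
                read_id = f"sim:{idx:09d}"
                idx += 1
                r1.append((read_id, _apply_errors(barcode + fill, rng, sub_error_rate)))
                r2.append(
                    (read_id, _apply_errors(seq[start : start + read2_len], rng, sub_error_rate))
                )
                rows.append((read_id, well, bc_index, tid, gene, start))

    per_read = pd.DataFrame(
        rows,
        columns=["read_id", "well_label", "barcode_index", "transcript_id", "gene_id", "start"],
    )
    if shuffle and len(r1):
        order = rng.permutation(len(r1))
        r1 = [r1[i] for i in order]
        r2 = [r2[i] for i in order]
        per_read = per_read.iloc[order].reset_index(drop=True)
    return SimReads(read1=r1, read2=r2, per_read=per_read)


def write_fastq(reads: Iterable[Tuple[str, str]], path: str) -> None:
    """Write (id, sequence) pairs as 4-line FASTQ; gzip when path ends in .gz.

    Quality strings are constant 'I' — nothing downstream is
    quality-aware.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
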