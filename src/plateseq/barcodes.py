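"""Error-correcting DNA well barcodes.

Pooled-well 3'-end libraries tag every read with a fixed-length DNA barcode
identifying the well of origin (read 1 carries the barcode at its 5' end).
To tolerate sequencing errors the barcode set is designed as a code with a
guaranteed minimum pairwise Hamming distance ``d``: any set with ``d >= 3``
corrects a single substitution, so decoding accepts observed barcodes at
edit distance up to one from a designed sequence.

Two decoding modes are provided:

* ``hamming`` (default) — fixed-length extraction of the first ``k`` bases,
  substitution-only distance. Substitutions dominate on Illumina platforms.
* ``levenshtein`` — extracts ``k + 1`` bases and allows one indel as well,
  using a prefix (SHW) edit-distance alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

try:  # optional: only required for the Levenshtein decoding mode
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

ALPHABET = "ACGT"

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"


class BarcodeError(ValueError):
    """Base class for barcode design/decoding errors."""


class FeasibilityError(BarcodeError):
    """Requested code parameters exceed what the space can hold."""


class TruncatedReadError(BarcodeError):
    """Observed sequence is shorter than the barcode extraction length."""


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings.

    Symmetric and satisfies the triangle inequality (it is a metric on
    fixed-length strings).
    """
    if len(a) != len(b):
        raise ValueError(
            f"hamming distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def sphere_packing_bound(k: int, min_distance: int) -> int:
    """Hamming (sphere-packing) bound on a quaternary code of length ``k``.

    A code with minimum distance ``d`` has disjoint balls of radius
    ``t = floor((d-1)/2)`` around each codeword, so at most
    ``4^k / V(k, t)`` codewords fit, with ``V`` the ball volume.
    """
    t = (min_distance - 1) // 2
    volume = sum(math.comb(k, i) * 3**i for i in range(t + 1))
    return 4**k // volume


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def plate_labels(n: int) -> list[str]:
    """Row-major multiwell labels A1, A2, ... (8 x 12 for n <= 96, else 16 x 24)."""
    n_rows, n_cols = (8, 12) if n <= 96 else (16, 24)
    if n > n_rows * n_cols:
        return [f"W{i + 1:04d}" for i in range(n)]
    return [
        f"{_PLATE_ROWS[i // n_cols]}{i % n_cols + 1}" for i in range(n)
    ]


@dataclass(frozen=True)
class BarcodeAssignment:
    """Outcome of decoding one observed barcode.

    ``status`` is one of ``assigned``, ``unassigned`` or ``ambiguous``;
    ``well_index``/``edit_distance`` are only present when assigned.
    """

    status: str
    well_index: Optional[int] = None
    edit_distance: Optional[int] = None

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


UNASSIGNED = BarcodeAssignment("unassigned")
AMBIGUOUS = BarcodeAssignment("ambiguous")


@dataclass
class BarcodeSet:
    """An ordered set of fixed-length DNA well barcodes.

    Invariants checked on construction: all sequences have length
    ``length_k``, are unique, and use the A/C/G/T alphabet. The pairwise
    minimum-distance guarantee is verified by :meth:`observed_min_distance`
    (an O(n^2 k) brute-force scan kept separate because it is quadratic).
    """

    sequences: list[str]
    length_k: int
    min_distance: int
    well_labels: Optional[list[str]] = None
    _decode1: Optional[dict] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise BarcodeError("barcode set must contain at least one sequence")
        for s in self.sequences:
            if len(s) != self.length_k:
                raise BarcodeError(
                    f"barcode {s!r} has length {len(s)}, expected {self.length_k}"
                )
            if set(s) - set(ALPHABET):
                raise BarcodeError(f"barcode {s!r} contains non-ACGT characters")
        if len(set(self.sequences)) != len(self.sequences):
            raise BarcodeError("barcode sequences must be unique")
        if self.well_labels is None:
            self.well_labels = plate_labels(len(self.sequences))
        if len(self.well_labels) != len(self.sequences):
            raise BarcodeError("well_labels must parallel sequences")

    def __len__(self) -> int:
        return len(self.sequences)

    def observed_min_distance(self) -> int:
        """Brute-force pairwise minimum Hamming distance (independent check)."""
        return min(
            hamming(a, b) for a, b in itertools.combinations(self.sequences, 2)
        ) if len(self.sequences) > 1 else self.length_k

    def validate(self) -> None:
        """Re-verify the advertised minimum-distance guarantee by brute force."""
        if len(self.sequences) > 1 and self.observed_min_distance() < self.min_distance:
            raise BarcodeError(
                "observed pairwise minimum distance "
                f"{self.observed_min_distance()} < advertised {self.min_distance}"
            )

    # -- fast single-substitution decode table -------------------------------
    def _decode1_table(self) -> dict:
        """Map every barcode and every single-substitution neighbor to
        ``(index, distance)``; collisions map to ``None`` (ambiguous)."""
        if self._decode1 is None:
            table: dict = {}
            for i, seq in enumerate(self.sequences):
                table[seq] = (i, 0)
            for i, seq in enumerate(self.sequences):
                for pos in range(self.length_k):
                    for base in ALPHABET:
                        if base == seq[pos]:
                            continue
                        neighbor = seq[:pos] + base + seq[pos + 1 :]
                        prev = table.get(neighbor, ...)
                        if prev is ...:
                            table[neighbor] = (i, 1)
                        elif prev is not None and prev[1] == 1 and prev[0] != i:
                            table[neighbor] = None  # distance-1 tie -> ambiguous
            object.__setattr__(self, "_decode1", table)
        return self._decode1


def design_barcode_set(
    n: int,
    k: int = 8,
    min_distance: int = 3,
    seed: int = 0,
    max_homopolymer: int = 3,
    max_attempts: Optional[int] = None,
    well_labels: Optional[Sequence[str]] = None,
) -> BarcodeSet:
    """Design ``n`` length-``k`` barcodes with pairwise Hamming distance
    at least ``min_distance``.

    Seeded greedy random accumulation: random k-mers are proposed and kept
    when they pass a homopolymer-run filter (run length <= ``max_homopolymer``,
    for sequencer robustness) and lie at distance >= ``min_distance`` from
    every kept barcode. Deterministic for a fixed seed. The 96-well default
    configuration is ``(n=96, k=8, min_distance=3)``, a single-error-correcting
    code.

    Raises
    ------
    FeasibilityError
        If ``n`` exceeds the sphere-packing bound for ``(k, min_distance)``,
        or the greedy search budget is exhausted.
    """
    if n < 1 or k < 1 or min_distance < 1:
        raise BarcodeError("n, k and min_distance must all be >= 1")
    bound = sphere_packing_bound(k, min_distance)
    if n > bound:
        raise FeasibilityError(
            f"{n} barcodes of length {k} at minimum distance {min_distance} "
            f"exceed the sphere-packing bound of {bound}"
        )
    if max_attempts is None:
        max_attempts = 2000 * n + 20000
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    kept_arr = np.empty((0, k), dtype=np.uint8)
    attempts = 0
    while len(kept) < n:
        if attempts >= max_attempts:
            raise FeasibilityError(
                f"could not place {n} barcodes (k={k}, d={min_distance}) within "
                f"{max_attempts} proposals; sphere-packing bound is {bound}"
            )
        attempts += 1
        codes = rng.integers(0, 4, size=k, dtype=np.uint8)
        seq = "".join(ALPHABET[c] for c in codes)
        if k > max_homopolymer and max_homopolymer_run(seq) > max_homopolymer:
            continue
        if kept_arr.shape[0]:
            dists = (kept_arr != codes).sum(axis=1)
            if int(dists.min()) < min_distance:
                continue
        kept.append(seq)
        kept_arr = np.vstack([kept_arr, codes])
    labels = list(well_labels) if well_labels is not None else None
    return BarcodeSet(kept, length_k=k, min_distance=min_distance, well_labels=labels)


def correct_barcode(
    observed: str,
    barcode_set: BarcodeSet,
    max_distance: int = 1,
    mode: str = "hamming",
) -> BarcodeAssignment:
    """Decode an observed barcode against a designed set.

    The observed string is the start of read 1; the first ``length_k`` bases
    are extracted (``length_k + 1`` in ``levenshtein`` mode, which allows one
    indel via a prefix edit-distance alignment). The nearest barcode within
    ``max_distance`` is returned; a tie at the minimum distance yields an
    ``ambiguous`` assignment and no barcode within range yields
    ``unassigned``. With ``min_distance >= 2*max_distance + 1`` decoding is
    provably unique, so ambiguity cannot occur.
    """
    k = barcode_set.length_k
    if len(observed) < k:
        raise TruncatedReadError(
            f"observed read of length {len(observed)} is shorter than the "
            f"{k}-base barcode"
        )
    if mode == "hamming":
        window = observed[:k]
        if max_distance == 1:
            hit = barcode_set._decode1_table().get(window, ...)
            if hit is ...:
                return UNASSIGNED
            if hit is None:
                return AMBIGUOUS
            return BarcodeAssignment("assigned", hit[0], hit[1])
        dists = [hamming(window, b) for b in barcode_set.sequences]
    elif mode == "levenshtein":
        if edlib is None:  # pragma: no cover
            raise ImportError("levenshtein decoding mode requires the edlib package")
        window = observed[: k + 1]
        dists = [
            edlib.align(b, window, mode="SHW", task="distance")["editDistance"]
            for b in barcode_set.sequences
        ]
    else:
        raise ValueError(f"unknown decoding mode {mode!r}")

    best = min(dists)
    if best > max_distance:
        return UNASSIGNED
    winners = [i for i, d in enumerate(dists) if d == best]
    if len(winners) > 1:
        return AMBIGUOUS
    return BarcodeAssignment("assigned", winners[0], best)
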