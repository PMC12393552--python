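"""Sequences, regions, splits, targets, and the dataset container.

Coordinates are 0-based half-open (BED convention) throughout. Sequences
are stored as small integer codes (A=0, C=1, G=2, T=3, N=4) and one-hot
encoded on demand; targets are dense ``(examples, bins, tracks)`` arrays
of non-negative reals; track metadata travels as a pandas DataFrame.

The dataset container is a versioned ``.npz`` archive holding the code
matrix, the target array, and a JSON header (track table, split label,
window/bin geometry, provenance fingerprint). Round trips are exact.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, EncodingError, PartitionError

logger = logging.getLogger(__name__)

CONTAINER_VERSION = 1

_BASES = "ACGTN"
_CODE = {b: i for i, b in enumerate(_BASES)}
# one-hot rows per code; N maps to the all-zero row
_ONE_HOT = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1], [0, 0, 0, 0]],
    dtype=np.float64,
)


# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0, C=1, G=2, T=3, N=4)."""
    s = sequence.upper()
    codes = np.frombuffer(s.encode("ascii"), dtype=np.uint8) if s else np.empty(0, np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    out = lut[codes]
    bad = np.nonzero(out == 255)[0]
    if bad.size:
        p = int(bad[0])
        raise EncodingError(f"invalid base {s[p]!r} at position {p}")
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in np.asarray(codes, dtype=np.uint8))


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode a DNA string: A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0],
    T=[0,0,0,1], N=[0,0,0,0]. Returns a ``(len, 4)`` matrix."""
    return _ONE_HOT[encode_sequence(sequence)]


def one_hot_decode(encoding: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (all-zero rows decode to N)."""
    enc = np.asarray(encoding)
    if enc.ndim != 2 or enc.shape[1] != 4:
        raise EncodingError(f"expected (L, 4) matrix, got {enc.shape}")
    sums = enc.sum(axis=1)
    if not np.all((sums == 0) | (sums == 1)):
        raise EncodingError("rows must sum to 0 or 1")
    codes = np.where(sums == 0, 4, enc.argmax(axis=1))
    return decode_sequence(codes)


def codes_to_one_hot(codes: np.ndarray) -> np.ndarray:
    return _ONE_HOT[np.asarray(codes, dtype=np.uint8)]


# ---------------------------------------------------------------------------
# regions and splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DataError(f"invalid region {self.chromosome}:{self.start}-{self.end}")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


SPLIT_LABELS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Region -> split-label map with reassignment provenance.

    ``provenance`` values: ``originally_assigned``, ``reassigned_in`` (moved
    into train by the homology rule) or ``reassigned_out`` (moved out of
    train to compensate).
    """

    labels: Dict[Region, str]
    provenance: Dict[Region, str]
    seed: int

    def regions(self, label: Optional[str] = None) -> List[Region]:
        if label is None:
            return list(self.labels)
        return [r for r, l in self.labels.items() if l == label]

    def sizes(self) -> Dict[str, int]:
        out = {l: 0 for l in SPLIT_LABELS}
        for l in self.labels.values():
            out[l] += 1
        return out


def make_regions(chrom_lengths: Mapping[str, int], window: int,
                 stride: int) -> List[Region]:
    """Tile chromosomes into fixed-length windows.

    Regions lie fully inside their chromosome; a chromosome shorter than
    ``window`` contributes none (logged). Ordering is deterministic:
    mapping order, then start coordinate.
    """
    if stride < 1:
        raise DataError("stride must be >= 1")
    if window < 1:
        raise DataError("window must be >= 1")
    regions: List[Region] = []
    for chrom, length in chrom_lengths.items():
        if length < window:
            logger.info("chromosome %s (%d bp) shorter than window %d; skipped",
                        chrom, length, window)
            continue
        for start in range(0, length - window + 1, stride):
            regions.append(Region(chrom, start, start + window))
    return regions


def _largest_remainder(n: int, fractions: Sequence[float]) -> List[int]:
    exact = [f * n for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    # distribute leftovers by descending remainder; ties broken by group order
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def partition_regions(regions: Sequence[Region],
                      fractions: Tuple[float, float, float],
                      seed: int) -> SplitAssignment:
    """Randomly partition regions into train/validation/test.

    Group sizes follow largest-remainder rounding of the requested
    fractions; the assignment is a seeded uniform shuffle.
    """
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise PartitionError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise PartitionError(f"fractions must sum to 1, got {sum(fractions)}")
    n_groups = sum(1 for f in fractions if f > 0)
    if len(regions) < n_groups:
        raise PartitionError(
            f"{len(regions)} regions cannot fill {n_groups} nonempty groups")
    sizes = _largest_remainder(len(regions), fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(regions))
    labels: Dict[Region, str] = {}
    cursor = 0
    for label, size in zip(SPLIT_LABELS, sizes):
        for idx in order[cursor:cursor + size]:
            labels[regions[idx]] = label
        cursor += size
    provenance = {r: "originally_assigned" for r in regions}
    return SplitAssignment(labels=labels, provenance=provenance, seed=seed)


@dataclass
class HomologyTable:
    """Pairs of (internal region, matched external region descriptor)."""

    pairs: List[Tuple[Region, str]]

    @property
    def regions(self) -> List[Region]:
        seen, out = set(), []
        for r, _ in self.pairs:
            if r not in seen:
                seen.add(r)
                out.append(r)
        return out

    @classmethod
    def read_tsv(cls, path) -> "HomologyTable":
        """Read a tab-separated table: chrom, start, end, matched-region."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "match"])
        pairs = [(Region(row.chrom, int(row.start), int(row.end)), str(row.match))
                 for row in df.itertuples()]
        return cls(pairs)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for r, m in self.pairs:
                fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{m}\n")


def homology_reassign(split: SplitAssignment, homology: HomologyTable,
                      seed: int) -> SplitAssignment:
    """Move homologous regions into train; rebalance by moving an equal
    number of non-homologous original-train regions out.

    Every region flagged in the homology table ends up labeled ``train``.
    For each region moved in, one non-homologous region that was originally
    in train is moved out to the label the moved-in region came from
    (seeded uniform choice without replacement). If fewer candidates exist
    than moves required, the shortfall is logged, not fatal.
    """
    universe = set(split.labels)
    homologous = set(homology.regions)
    missing = homologous - universe
    if missing:
        raise DataError(
            f"homology table references {len(missing)} unknown region(s), "
            f"e.g. {next(iter(missing))}")

    labels = dict(split.labels)
    provenance = dict(split.provenance)
    moved_from: List[str] = []
    for r in sorted(homologous):
        if labels[r] != "train":
            moved_from.append(labels[r])
            labels[r] = "train"
            provenance[r] = "reassigned_in"

    k = len(moved_from)
    candidates = sorted(r for r in universe
                        if split.labels[r] == "train" and r not in homologous)
    rng = np.random.default_rng(seed)
    n_out = min(k, len(candidates))
    if n_out < k:
        logger.warning(
            "homology rebalance shortfall: %d regions moved into train but "
            "only %d non-homologous train regions available to move out",
            k, len(candidates))
    chosen = rng.choice(len(candidates), size=n_out, replace=False) if n_out else []
    for idx, dest in zip(sorted(int(i) for i in chosen), moved_from):
        r = candidates[idx]
        labels[r] = dest
        provenance[r] = "reassigned_out"
    return SplitAssignment(labels=labels, provenance=provenance, seed=seed)


def audit_leakage(split: SplitAssignment, homology: HomologyTable) -> int:
    """Number of homologous regions outside the training split (0 = clean)."""
    return sum(1 for r in homology.regions if split.labels.get(r) != "train")


# ---------------------------------------------------------------------------
# coverage binning
# ---------------------------------------------------------------------------

def extract_targets(coverage: np.ndarray, bin_size: int) -> np.ndarray:
    """Sum per-base-pair signal into fixed-width bins.

    Coverage counts are extensive, so the bin statistic is the sum, not
    the mean.
    """
    cov = np.asarray(coverage, dtype=np.float64)
    if cov.ndim != 1:
        raise DataError(f"coverage must be 1-D, got shape {cov.shape}")
    if cov.size % bin_size != 0:
        raise DataError(
            f"region length {cov.size} not divisible by bin_size {bin_size}")
    if np.any(cov < 0):
        raise DataError("coverage contains negative values")
    return cov.reshape(-1, bin_size).sum(axis=1)


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class TrackDataset:
    """Aligned (sequence, target) pairs plus track metadata.

    ``seq_codes``: ``(n, window)`` uint8 base codes.
    ``targets``: ``(n, bins, tracks)`` non-negative reals.
    ``tracks``: DataFrame with at least ``name``, ``assay``, ``species``.
    """

    seq_codes: np.ndarray
    targets: np.ndarray
    tracks: pd.DataFrame
    bin_size: int
    split: str = "train"
    fingerprint: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.seq_codes = np.asarray(self.seq_codes, dtype=np.uint8)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.seq_codes.ndim != 2 or self.targets.ndim != 3:
            raise DataError("seq_codes must be (n, window); targets (n, bins, tracks)")
        if self.seq_codes.shape[0] != self.targets.shape[0]:
            raise DataError("sequence and target example counts differ")
        if np.any(self.targets < 0):
            raise DataError("targets contain negative values")
        if len(self.tracks) != self.targets.shape[2]:
            raise DataError(
                f"track metadata rows ({len(self.tracks)}) != target tracks "
                f"({self.targets.shape[2]})")

    # -- basic views -----------------------------------------------------
    def __len__(self) -> int:
        return self.seq_codes.shape[0]

    @property
    def window(self) -> int:
        return self.seq_codes.shape[1]

    @property
    def bins(self) -> int:
        return self.targets.shape[1]

    @property
    def num_tracks(self) -> int:
        return self.targets.shape[2]

    def one_hot(self, i: int) -> np.ndarray:
        return codes_to_one_hot(self.seq_codes[i])

    def sequence(self, i: int) -> str:
        return decode_sequence(self.seq_codes[i])

    # -- derived datasets ------------------------------------------------
    def select_tracks(self, indices: Sequence[int]) -> "TrackDataset":
        idx = list(indices)
        return TrackDataset(
            seq_codes=self.seq_codes,
            targets=self.targets[:, :, idx],
            tracks=self.tracks.iloc[idx].reset_index(drop=True),
            bin_size=self.bin_size,
            split=self.split,
            fingerprint=self.fingerprint + f"|tracks={idx}",
            extras=dict(self.extras),
        )

    def subsample(self, n: int, seed: int) -> "TrackDataset":
        return subsample_examples(self, n, seed)

    # -- container I/O ---------------------------------------------------
    def save(self, path) -> None:
        header = {
            "version": CONTAINER_VERSION,
            "bin_size": self.bin_size,
            "split": self.split,
            "fingerprint": self.fingerprint,
            "tracks": self.tracks.to_dict(orient="list"),
            "extras": self.extras,
        }
        np.savez_compressed(
            path,
            seq_codes=self.seq_codes,
            targets=self.targets,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "TrackDataset":
        with np.load(path) as z:
            try:
                header = json.loads(bytes(z["header"]).decode())
                seq_codes = z["seq_codes"]
                targets = z["targets"]
            except (KeyError, json.JSONDecodeError) as e:
                raise DataError(f"not a dataset container: {path} ({e})")
        if header.get("version") != CONTAINER_VERSION:
            raise DataError(
                f"container version {header.get('version')} unsupported "
                f"(expected {CONTAINER_VERSION})")
        return cls(
            seq_codes=seq_codes,
            targets=targets,
            tracks=pd.DataFrame(header["tracks"]),
            bin_size=header["bin_size"],
            split=header["split"],
            fingerprint=header["fingerprint"],
            extras=header.get("extras", {}),
        )


def subsample_examples(dataset: TrackDataset, n: int, seed: int) -> TrackDataset:
    """Seeded uniform subsample without replacement, preserving source order.

    Mirrors the balancing step of capping each species' training set at a
    common example count.
    """
    if n > len(dataset):
        raise DataError(f"cannot subsample {n} from {len(dataset)} examples")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(dataset), size=n, replace=False))
    return TrackDataset(
        seq_codes=dataset.seq_codes[idx],
        targets=dataset.targets[idx],
        tracks=dataset.tracks.copy(),
        bin_size=dataset.bin_size,
        split=dataset.split,
        fingerprint=dataset.fingerprint + f"|subsample(n={n},seed={seed})",
        extras=dict(dataset.extras),
    )


# ---------------------------------------------------------------------------
# standard-format I/O (FASTA / BED / bedGraph), gzip tolerated
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_bed(path) -> List[Region]:
    """Read regions from a BED file (first three columns)."""
    regions = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
    return regions


def write_bed(regions: Iterable[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\n")


def read_fasta_regions(fasta_path, regions: Sequence[Region]) -> List[str]:
    """Fetch region sequences from a FASTA file (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), sequence_always_upper=True)
    return [str(fa[r.chromosome][r.start:r.end]) for r in regions]


def write_fasta(names: Sequence[str], sequences: Sequence[str], path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bedgraph_coverage(path, region: Region) -> np.ndarray:
    """Materialize per-bp coverage over ``region`` from a bedGraph file."""
    cov = np.zeros(region.end - region.start, dtype=np.float64)
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom != region.chromosome:
                continue
            lo = max(int(start), region.start) - region.start
            hi = min(int(end), region.end) - region.start
            if lo < hi:
                v = float(value)
                if v < 0:
                    raise DataError(f"negative coverage value {v} in {path}")
                cov[lo:hi] += v
    return cov


def write_bedgraph(path, region: Region, per_bin: np.ndarray,
                   bin_size: int) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(per_bin)):
            s = region.start + i * bin_size
            fh.write(f"{region.chromosome}\t{s}\t{s + bin_size}\t{v:g}\n")
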