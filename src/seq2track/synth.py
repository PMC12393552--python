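"""Synthetic regulatory-grammar data generator.

Generates fixed-length DNA windows whose planted motif content drives
per-bin Poisson rates, emulating the statistical structure of coverage
tracks (ATAC-seq-like counts at fixed bin resolution) at desk scale. The
rate model is additive — baseline plus per-motif weights per overlapping
occurrence plus pairwise long-range interaction terms — with a small
positivity floor, so planted effect sizes map linearly to coverage and
every expected value can be checked by direct enumeration.

Task families share a motif vocabulary across members with a controlled
overlap fraction, emulating a conserved regulatory grammar across
species: the pretraining member supplies many tracks, the fine-tuning
member few, so cross-member transfer has a known, constructed signal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import TrackDataset, encode_sequence
from .errors import DataError

RATE_FLOOR = 1e-3
_ALPHABET = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrammarSpec:
    """A planted regulatory grammar for one task ("species").

    ``motifs`` maps motif names to consensus strings (6-10 bp).
    ``track_weights`` holds one motif->weight map per output track.
    ``interactions`` is a list of ``(motif_a, motif_b, max_distance_bp,
    weight)`` long-range terms: whenever the two motifs co-occur within
    ``max_distance_bp`` (start-to-start), ``weight`` is added to the bin
    containing each partner's start, on every track.
    """

    motifs: Dict[str, str]
    track_weights: Tuple[Dict[str, float], ...]
    window: int
    bin_size: int
    baseline: float = 1.0
    interactions: Tuple[Tuple[str, str, int, float], ...] = ()
    mutation_rate: float = 0.0
    gc: float = 0.5
    mean_plants_per_motif: float = 3.0

    def __post_init__(self):
        if self.baseline <= 0:
            raise DataError("baseline rate must be > 0")
        if self.window % self.bin_size != 0:
            raise DataError("window must be divisible by bin_size")
        if not 0 < self.gc < 1:
            raise DataError("gc must be in (0, 1)")
        for name, consensus in self.motifs.items():
            if not 6 <= len(consensus) <= 10:
                raise DataError(
                    f"motif {name} length {len(consensus)} outside 6-10 bp")
            if set(consensus) - set("ACGT"):
                raise DataError(f"motif {name} has non-ACGT characters")
        for wmap in self.track_weights:
            for m in wmap:
                if m not in self.motifs:
                    raise DataError(f"weight refers to unknown motif {m}")
        for a, b, d, _ in self.interactions:
            if a not in self.motifs or b not in self.motifs:
                raise DataError(f"interaction refers to unknown motif {a}/{b}")
            if d < 1:
                raise DataError("interaction max_distance must be >= 1")

    @property
    def n_tracks(self) -> int:
        return len(self.track_weights)

    @property
    def n_bins(self) -> int:
        return self.window // self.bin_size

    def support(self) -> set:
        """Motifs with nonzero weight on at least one track."""
        return {m for wmap in self.track_weights
                for m, w in wmap.items() if w != 0.0}

    def fingerprint(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TaskFamily:
    """Related tasks sharing a motif vocabulary with controlled overlap."""

    vocabulary: Dict[str, str]
    members: Tuple[GrammarSpec, ...]
    overlap: float
    seed: int

    def measured_overlap(self) -> float:
        """Fraction of the vocabulary with nonzero weight in both of the
        first two members (by construction this equals ``overlap``)."""
        a, b = self.members[0].support(), self.members[1].support()
        return len(a & b) / len(self.vocabulary)


# ---------------------------------------------------------------------------
# sequence sampling and motif scanning
# ---------------------------------------------------------------------------

def sample_sequence(length: int, gc: float, seed: int) -> str:
    """I.i.d. random DNA with the requested GC content."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_ALPHABET, size=length, p=p))


def find_occurrences(sequence: str, motif: str) -> List[int]:
    """All (overlapping) exact-match start positions of ``motif``."""
    hits, start = [], sequence.find(motif)
    while start != -1:
        hits.append(start)
        start = sequence.find(motif, start + 1)
    return hits


def rate_profile(sequence: str, spec: GrammarSpec) -> np.ndarray:
    """Deterministic per-bin Poisson rates implied by a sequence.

    For each bin and track: baseline + sum over motifs of
    weight x (occurrences overlapping the bin) + interaction terms,
    floored at a small positive constant. Returns ``(n_bins, n_tracks)``.
    """
    if len(sequence) != spec.window:
        raise ValueError(
            f"sequence length {len(sequence)} != spec window {spec.window}")
    sequence = sequence.upper()
    b = spec.bin_size
    nb, nt = spec.n_bins, spec.n_tracks
    occ_bins: Dict[str, np.ndarray] = {}
    occ_starts: Dict[str, List[int]] = {}
    for name, consensus in spec.motifs.items():
        starts = find_occurrences(sequence, consensus)
        occ_starts[name] = starts
        counts = np.zeros(nb)
        for p in starts:
            for bin_i in range(p // b, min((p + len(consensus) - 1) // b, nb - 1) + 1):
                counts[bin_i] += 1
        occ_bins[name] = counts

    rates = np.full((nb, nt), spec.baseline, dtype=np.float64)
    for t, wmap in enumerate(spec.track_weights):
        for m, w in wmap.items():
            if w:
                rates[:, t] += w * occ_bins[m]

    for a, bname, maxd, w in spec.interactions:
        if a == bname:
            pairs = itertools.combinations(occ_starts[a], 2)
        else:
            pairs = itertools.product(occ_starts[a], occ_starts[bname])
        for pa, pb in pairs:
            if abs(pa - pb) <= maxd:
                rates[pa // b, :] += w
                rates[pb // b, :] += w

    return np.maximum(rates, RATE_FLOOR)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _plant_motifs(seq: np.ndarray, spec: GrammarSpec,
                  rng: np.random.Generator) -> None:
    """Plant Poisson-many occurrences of each motif at uniform positions,
    with independent per-position mutation of the consensus. In-place on a
    character array; overlapping plants simply overwrite."""
    for consensus in spec.motifs.values():
        k = rng.poisson(spec.mean_plants_per_motif)
        if k == 0:
            continue
        positions = rng.integers(0, spec.window - len(consensus) + 1, size=k)
        for p in positions:
            inst = list(consensus)
            if spec.mutation_rate > 0:
                for i in range(len(inst)):
                    if rng.random() < spec.mutation_rate:
                        inst[i] = str(rng.choice(_ALPHABET))
            seq[p:p + len(inst)] = inst


def make_dataset(spec: GrammarSpec, n_examples: int, seed: int,
                 noise: bool = True, output_bins: Optional[int] = None,
                 split: str = "train", species: str = "synthetic",
                 ) -> TrackDataset:
    """Generate a dataset: planted sequences and (noisy) count targets.

    Each example draws a background sequence, plants motif occurrences,
    computes the deterministic rate profile, and (when ``noise``) samples
    targets as independent Poisson counts with those means; with ``noise``
    off the targets are the exact rates, so a rate-profile oracle scores a
    pooled Pearson correlation of exactly 1 on every informative track.
    ``output_bins`` crops the targets centrally (default: all bins).
    """
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    nb = spec.n_bins
    output_bins = nb if output_bins is None else output_bins
    if output_bins > nb or (nb - output_bins) % 2:
        raise ValueError(
            f"output_bins {output_bins} incompatible with {nb} window bins")
    lo = (nb - output_bins) // 2

    p_bg = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    codes = np.empty((n_examples, spec.window), dtype=np.uint8)
    targets = np.empty((n_examples, output_bins, spec.n_tracks))
    for i in range(n_examples):
        rng = np.random.default_rng([seed, i])
        seq = rng.choice(_ALPHABET, size=spec.window, p=p_bg)
        _plant_motifs(seq, spec, rng)
        s = "".join(seq)
        rates = rate_profile(s, spec)[lo:lo + output_bins]
        targets[i] = rng.poisson(rates) if noise else rates
        codes[i] = encode_sequence(s)

    tracks = pd.DataFrame({
        "name": [f"trk{t:03d}" for t in range(spec.n_tracks)],
        "assay": ["synthetic"] * spec.n_tracks,
        "species": [species] * spec.n_tracks,
    })
    return TrackDataset(
        seq_codes=codes, targets=targets, tracks=tracks,
        bin_size=spec.bin_size, split=split,
        fingerprint=f"{spec.fingerprint()}|seed={seed}|n={n_examples}|noise={noise}",
        extras={"spec_fingerprint": spec.fingerprint(), "noise": noise},
    )


# ---------------------------------------------------------------------------
# task families and transfer pairs
# ---------------------------------------------------------------------------

def _random_motif(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def make_task_family(n_motifs: int, overlap: float, n_tracks_a: int,
                     n_tracks_b: int, window: int, bin_size: int, seed: int,
                     motif_length: int = 8, baseline: float = 1.0,
                     weight_low: float = 3.0, weight_high: float = 8.0,
                     mean_plants_per_motif: float = 3.0) -> TaskFamily:
    """Build a two-member family whose supports share exactly
    ``round(overlap * n_motifs)`` motifs.

    The shared motifs plus one exclusive block each form member A's and
    member B's supports; every track draws positive weights over a random
    subset (at least one motif) of its member's support.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vocab: Dict[str, str] = {}
    while len(vocab) < n_motifs:
        m = _random_motif(rng, motif_length)
        vocab[f"m{len(vocab):02d}"] = m
    names = list(vocab)
    n_shared = round(overlap * n_motifs)
    n_excl = (n_motifs - n_shared) // 2
    shared = names[:n_shared]
    excl_a = names[n_shared:n_shared + n_excl]
    excl_b = names[n_shared + n_excl:n_shared + 2 * n_excl]
    support_a = shared + excl_a if shared + excl_a else names[:1]
    support_b = shared + excl_b if shared + excl_b else names[1:2]

    def weights_for(support: List[str], n_tracks: int) -> Tuple[Dict[str, float], ...]:
        # The leading track weights every support motif (so the member's
        # support is exactly the constructed one); later tracks draw
        # random sub-supports.
        maps = [{m: float(rng.uniform(weight_low, weight_high)) for m in support}]
        for _ in range(1, n_tracks):
            k = int(rng.integers(1, len(support) + 1))
            chosen = rng.choice(len(support), size=k, replace=False)
            maps.append({support[int(i)]: float(rng.uniform(weight_low, weight_high))
                         for i in chosen})
        return tuple(maps)

    common = dict(window=window, bin_size=bin_size, baseline=baseline,
                  mean_plants_per_motif=mean_plants_per_motif)
    member_a = GrammarSpec(motifs=vocab, track_weights=weights_for(support_a, n_tracks_a),
                           **common)
    member_b = GrammarSpec(motifs=vocab, track_weights=weights_for(support_b, n_tracks_b),
                           **common)
    return TaskFamily(vocabulary=vocab, members=(member_a, member_b),
                      overlap=overlap, seed=seed)


def make_transfer_pair(family: TaskFamily, pretrain_tracks: int,
                       finetune_tracks: int, n_pretrain: int, n_finetune: int,
                       seed: int, noise: bool = True,
                       output_bins: Optional[int] = None,
                       ) -> Tuple[TrackDataset, TrackDataset]:
    """Pretraining dataset from member A, fine-tuning dataset from member B.

    Track counts select the leading tracks of each member; sequence seeds
    are disjoint so no sequence is shared between the two datasets. A
    zero-overlap family is allowed as a negative control and flagged in
    the metadata.
    """
    a, b = family.members[0], family.members[1]
    if pretrain_tracks > a.n_tracks or finetune_tracks > b.n_tracks:
        raise ValueError("requested more tracks than the family members define")
    spec_a = dataclasses.replace(a, track_weights=a.track_weights[:pretrain_tracks])
    spec_b = dataclasses.replace(b, track_weights=b.track_weights[:finetune_tracks])
    fam_fp = hashlib.sha1(
        json.dumps(sorted(family.vocabulary.items())).encode()).hexdigest()[:12]
    pre = make_dataset(spec_a, n_pretrain, seed=int(np.random.SeedSequence([seed, 0]).generate_state(1)[0] % 2**31),
                       noise=noise, output_bins=output_bins, species="member_a")
    fin = make_dataset(spec_b, n_finetune, seed=int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % 2**31),
                       noise=noise, output_bins=output_bins, species="member_b")
    for ds in (pre, fin):
        ds.extras["family_fingerprint"] = fam_fp
        ds.extras["overlap"] = family.overlap
        if family.overlap == 0.0:
            ds.extras["negative_control"] = True
    return pre, fin


# ---------------------------------------------------------------------------
# distractor tracks
# ---------------------------------------------------------------------------

DISTRACTOR_MODES = ("permuted", "independent_grammar", "pure_noise")


def make_distractor_tracks(base: TrackDataset, k: int, mode: str,
                           seed: int) -> TrackDataset:
    """Append ``k`` uninformative tracks to a dataset.

    ``permuted``: seeded permutations of real tracks' pooled bin values
    (value multiset preserved, sequence association destroyed).
    ``independent_grammar``: rates from a fresh disjoint-vocabulary
    grammar evaluated on the *same* sequences (chance matches only).
    ``pure_noise``: i.i.d. Poisson at the base's global mean rate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in DISTRACTOR_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {DISTRACTOR_MODES}")
    rng = np.random.default_rng(seed)
    n, nb = len(base), base.bins
    new = np.empty((n, nb, k))

    if mode == "permuted":
        for j in range(k):
            src = j % base.num_tracks
            flat = base.targets[:, :, src].ravel()
            new[:, :, j] = flat[rng.permutation(flat.size)].reshape(n, nb)
    elif mode == "pure_noise":
        lam = float(base.targets.mean())
        new[...] = rng.poisson(lam, size=(n, nb, k))
    else:  # independent_grammar
        motifs = {}
        while len(motifs) < max(2, min(k, 6)):
            motifs[f"d{len(motifs):02d}"] = _random_motif(rng, 8)
        names = list(motifs)
        weights = []
        for _ in range(k):
            kk = int(rng.integers(1, len(names) + 1))
            chosen = rng.choice(len(names), size=kk, replace=False)
            weights.append({names[int(i)]: float(rng.uniform(3.0, 8.0))
                            for i in chosen})
        spec = GrammarSpec(
            motifs=motifs, track_weights=tuple(weights),
            window=base.window, bin_size=base.bin_size,
            baseline=max(RATE_FLOOR * 10, float(base.targets.mean())),
        )
        lo = (spec.n_bins - nb) // 2
        for i in range(n):
            rates = rate_profile(base.sequence(i), spec)[lo:lo + nb]
            new[i] = rng.poisson(rates)

    meta = pd.DataFrame({
        "name": [f"distractor{j:03d}" for j in range(k)],
        "assay": [f"distractor:{mode}"] * k,
        "species": ["distractor"] * k,
    })
    return TrackDataset(
        seq_codes=base.seq_codes,
        targets=np.concatenate([base.targets, new], axis=2),
        tracks=pd.concat([base.tracks, meta], ignore_index=True),
        bin_size=base.bin_size,
        split=base.split,
        fingerprint=base.fingerprint + f"|distractors({mode},k={k},seed={seed})",
        extras=dict(base.extras),
    )
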