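"""Pretrain -> fine-tune machinery and the track-count sweep.

Covers checkpoint save/load (parameters + embedded architecture config),
head replacement, trunk freezing, fine-tuning, the four-variant
architecture ablation, and the generalization/specialization sweep over
the number of jointly trained tracks with post-hoc single-track
fine-tuning.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ArchitectureConfig, TrainingConfig
from .data import TrackDataset
from .errors import CheckpointError, ConfigurationError
from .model import Model, build_model, count_parameters
from .training import TrainingHistory, evaluate, train

CHECKPOINT_VERSION = 1

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "replace_head",
    "set_frozen",
    "finetune",
    "run_ablation",
    "track_sweep",
    "sweep_cell_seed",
]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path, provenance: Optional[dict] = None) -> None:
    """Serialize parameters plus the architecture config that produced them.

    Optimizer state is deliberately excluded: fine-tuning restarts with a
    fresh optimizer rather than resuming.
    """
    header = {
        "version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "provenance": provenance or {},
        "param_names": [p.name for p in model.parameters()],
        "param_groups": [p.group for p in model.parameters()],
    }
    arrays = {f"param:{p.name}": p.value for p in model.parameters()}
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **arrays,
    )


def load_checkpoint(path, expect_num_tracks: Optional[int] = None) -> Model:
    """Rebuild a model from a checkpoint file.

    ``expect_num_tracks`` lets a caller assert the head width it relies
    on; a mismatch raises :class:`CheckpointError` naming both values.
    """
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"no such checkpoint: {path}")
    try:
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            if header.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {header.get('version')} unsupported "
                    f"(this toolkit reads version {CHECKPOINT_VERSION})")
            config = ArchitectureConfig.from_dict(header["config"])
            if (expect_num_tracks is not None
                    and config.num_tracks != expect_num_tracks):
                raise CheckpointError(
                    f"checkpoint head has {config.num_tracks} tracks but "
                    f"caller expects {expect_num_tracks}")
            model = build_model(config, seed=0)
            for p in model.parameters():
                key = f"param:{p.name}"
                if key not in z:
                    raise CheckpointError(f"checkpoint missing parameter {p.name}")
                stored = z[key]
                if stored.shape != p.value.shape:
                    raise CheckpointError(
                        f"parameter {p.name}: stored shape {stored.shape} != "
                        f"built shape {p.value.shape}")
                p.value[...] = stored
    except CheckpointError:
        raise
    except (KeyError, ValueError, OSError, zipfile.BadZipFile,
            json.JSONDecodeError) as e:
        raise CheckpointError(f"corrupted or unreadable checkpoint {path}: {e}")
    return model


def replace_head(model: Model, new_num_tracks: int, seed: int) -> Model:
    """Delete the linear head and install a freshly initialized one that
    outputs ``new_num_tracks`` predictions; trunk weights are untouched."""
    return model.replace_head(new_num_tracks, seed)


def set_frozen(model: Model, freeze_trunk: bool) -> Model:
    """Enable/disable gradient updates for every layer except the head."""
    return model.set_frozen(freeze_trunk)


def finetune(checkpoint, dataset: TrackDataset, cfg: TrainingConfig,
             freeze_trunk: bool = False, head_seed: Optional[int] = None,
             eval_dataset: Optional[TrackDataset] = None,
             eval_tracks: Optional[Sequence[int]] = None,
             ) -> Tuple[Model, TrainingHistory]:
    """Load a pretrained checkpoint, swap the head for the new track set,
    optionally freeze the trunk, and train on ``dataset``.

    ``checkpoint`` may be a path or an already-loaded :class:`Model`.
    """
    model = checkpoint if isinstance(checkpoint, Model) else load_checkpoint(checkpoint)
    if dataset.window != model.config.sequence_length:
        raise ConfigurationError(
            f"dataset window ({dataset.window}) != checkpoint sequence_length "
            f"({model.config.sequence_length})")
    replace_head(model, dataset.num_tracks,
                 seed=head_seed if head_seed is not None else cfg.shuffle_seed)
    set_frozen(model, freeze_trunk)
    try:
        return train(model, dataset, cfg, eval_dataset=eval_dataset,
                     eval_tracks=eval_tracks)
    finally:
        set_frozen(model, False)


# ---------------------------------------------------------------------------
# architecture ablation
# ---------------------------------------------------------------------------

def architecture_variants(base: ArchitectureConfig) -> List[ArchitectureConfig]:
    """The four structural variants of the baseline architecture:
    (0) baseline with both extra layers, (1) no final pointwise layer,
    (2) no attention-block linear layer, (3) neither, (4) neither with the
    attention stack shrunk from 11 to 5 blocks (scaled proportionally when
    the base uses fewer blocks)."""
    reduced_attn = max(1, round(base.num_attention_blocks * 5 / 11))
    full = dataclasses.replace(base, use_final_pointwise=True,
                               use_attention_linear=True)
    return [
        full,
        dataclasses.replace(full, use_final_pointwise=False),
        dataclasses.replace(full, use_attention_linear=False),
        dataclasses.replace(full, use_final_pointwise=False,
                            use_attention_linear=False),
        dataclasses.replace(full, use_final_pointwise=False,
                            use_attention_linear=False,
                            num_attention_blocks=reduced_attn),
    ]


def run_ablation(variants: Sequence[ArchitectureConfig], dataset: TrackDataset,
                 cfg: TrainingConfig, eval_dataset: Optional[TrackDataset] = None,
                 model_seed: int = 0, names: Optional[Sequence[str]] = None,
                 ) -> pd.DataFrame:
    """Train each architecture variant under an identical protocol.

    Paired design: every variant sees the same data order (same
    ``shuffle_seed``), the same initialization seed, and the same
    evaluation set. All variants are validated before any training starts;
    variants with differing ``output_bins`` are rejected as not comparable.
    """
    variants = list(variants)
    if not variants:
        raise ConfigurationError("no variants given")
    bins = {v.output_bins for v in variants}
    if len(bins) != 1:
        raise ConfigurationError(
            f"variants disagree on output_bins {sorted(bins)}; "
            f"results would not be comparable")
    for v in variants:
        v.validate()
        if v.num_tracks != dataset.num_tracks:
            raise ConfigurationError(
                f"variant num_tracks {v.num_tracks} != dataset "
                f"{dataset.num_tracks}")

    rows = []
    for i, v in enumerate(variants):
        model = build_model(v, seed=model_seed)
        model, history = train(model, dataset, cfg, eval_dataset=eval_dataset)
        report = evaluate(model, eval_dataset if eval_dataset is not None else dataset)
        rows.append({
            "variant": names[i] if names else f"variant_{i}",
            "use_final_pointwise": v.use_final_pointwise,
            "use_attention_linear": v.use_attention_linear,
            "num_attention_blocks": v.num_attention_blocks,
            "n_parameters": count_parameters(model),
            "final_pearson": report.average,
            "final_loss": history.records[-1].mean_loss if len(history) else float("nan"),
            "loss_trajectory": [r.mean_loss for r in history.records],
            "dataset_fingerprint": dataset.fingerprint,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# track-count sweep
# ---------------------------------------------------------------------------

def sweep_cell_seed(base_seed: int, count: int, replicate: int) -> int:
    """Stable per-cell seed: adding counts or replicates never perturbs the
    seeds of existing cells."""
    ss = np.random.SeedSequence([base_seed, count, replicate])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def track_sweep(dataset: TrackDataset, track_of_interest: int,
                counts: Sequence[int], replicates: int, cfg: TrainingConfig,
                finetune_lr: float, base_seed: int,
                arch: Optional[ArchitectureConfig] = None,
                eval_dataset: Optional[TrackDataset] = None,
                resample_tracks: bool = True) -> pd.DataFrame:
    """Generalization/specialization sweep over the number of co-trained
    tracks.

    For each (count, replicate): sample ``count`` additional tracks
    (uniform, without replacement, excluding the track of interest), train
    a freshly initialized model on the track of interest plus the sample
    in multi-track mode, evaluate the all-track average and the
    track-of-interest correlation, then fine-tune for another
    ``cfg.epochs`` epochs on the single track of interest at
    ``finetune_lr`` and re-evaluate. Each replicate re-initializes the
    model; ``resample_tracks=False`` holds the track sample fixed across
    replicates of a count.
    """
    if not 0 <= track_of_interest < dataset.num_tracks:
        raise ValueError(f"track_of_interest {track_of_interest} out of range")
    pool = [t for t in range(dataset.num_tracks) if t != track_of_interest]
    for c in counts:
        if not 1 <= c <= len(pool):
            raise ValueError(
                f"count {c} exceeds the {len(pool)} available additional tracks")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if arch is None:
        raise ConfigurationError("an ArchitectureConfig must be supplied")

    rows = []
    for count in counts:
        for rep in range(replicates):
            seed = sweep_cell_seed(base_seed, count, rep)
            track_rng = np.random.default_rng(
                seed if resample_tracks else sweep_cell_seed(base_seed, count, 0))
            extra = sorted(track_rng.choice(pool, size=count, replace=False).tolist())
            chosen = [track_of_interest] + extra
            sub = dataset.select_tracks(chosen)
            sub_eval = eval_dataset.select_tracks(chosen) if eval_dataset is not None else None
            arch_n = dataclasses.replace(arch, num_tracks=len(chosen))
            model = build_model(arch_n, seed=seed)
            cfg_multi = cfg.replace(mode="multi_track", track_index=None,
                                    shuffle_seed=seed)
            model, hist = train(model, sub, cfg_multi, eval_dataset=sub_eval,
                                eval_every=cfg_multi.epochs)
            # the final epoch record holds the evaluation on sub_eval
            avg_before = hist.records[-1].eval_avg_pearson
            toi_before = hist.records[-1].eval_per_track[0]  # track of interest

            cfg_ft = cfg.replace(mode="single_track", track_index=0,
                                 peak_lr=finetune_lr, shuffle_seed=seed + 1)
            model, _ = train(model, sub, cfg_ft, eval_dataset=sub_eval,
                             eval_every=cfg_ft.epochs)
            report_ft = evaluate(model, sub_eval if sub_eval is not None else sub)
            rows.append({
                "additional_track_count": count,
                "replicate": rep,
                "seed": seed,
                "tracks": chosen,
                "avg_pearson_all_tracks": avg_before,
                "pearson_track_of_interest": toi_before,
                "post_finetune_avg_pearson": report_ft.average,
                "post_finetune_track_pearson": report_ft.per_track[0],
                "dataset_fingerprint": sub.fingerprint,
            })
    return pd.DataFrame(rows)
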