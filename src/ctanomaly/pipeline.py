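"""End-to-end experiment orchestration: phantom data → GAN ensemble →
(optional) encoders → threshold sweep on validation → test evaluation.

Every stage is cached under the output directory, keyed by a content hash of
its configuration subtree plus its upstream artifacts, and every artifact is
stamped with that hash and the global seed; re-running with an identical
configuration reuses the caches and reproduces the report byte-for-byte.
Ensemble members use seeds ``seed + {0, 1, 2, ...}``.

The default configuration is the desk-scale study: 32×32 phantoms, a
512-dimensional latent space, three GAN models, hemorrhage-like bright-blob
lesions with radius 8–12% of the image width and intensity offset 0.25–0.40,
and the positive-part residual.  Step counts are scaled to the small images
(the paper-scale counts remain available through the stage configs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .anomaly import AnomalyConfig, close_mask, majority_vote, residual_map, \
    threshold_mask
from .encoder import EncoderLossConfig, EncoderNet, train_encoder
from .evaluation import dice, evaluate_masks
from .gan import GanTrainConfig, Generator, load_model, save_model, train_gan
from .phantom import PhantomSpec, generate_phantom, make_abnormal_dataset
from .restoration import RestorationConfig


@dataclass
class DataConfig:
    n_train: int = 64
    n_validation: int = 12
    n_test: int = 20
    n_normal_stats: int = 8   # lesion-free slices for reconstruction stats
    anomaly_kind: str = "bright_blob"
    radius_frac_range: tuple[float, float] = (0.08, 0.12)
    intensity_delta_range: tuple[float, float] = (0.25, 0.40)


@dataclass
class RunConfig:
    seed: int = 0
    resolution: int = 32
    latent_dim: int = 512
    mode: str = "restore"                 # "restore" or "encoder"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    data: DataConfig = field(default_factory=DataConfig)
    gan: GanTrainConfig = field(default_factory=lambda: GanTrainConfig(
        total_steps=2000, base_channels_g=32, base_channels_d=16))
    encoder: EncoderLossConfig = field(default_factory=lambda:
                                       EncoderLossConfig(steps=600))
    restoration: RestorationConfig = field(default_factory=lambda:
                                           RestorationConfig(steps=200))
    anomaly: AnomalyConfig = field(default_factory=lambda:
                                   AnomalyConfig(residual_kind="positive_part"))
    threshold_grid: tuple[float, float, float] = (0.0, 255.0, 4.0)

    def __post_init__(self):
        # keep the resolution consistent across nested configs
        self.phantom = dataclasses.replace(self.phantom,
                                           resolution=self.resolution,
                                           seed=self.seed)
        self.gan = dataclasses.replace(self.gan, resolution=self.resolution,
                                       latent_dim=self.latent_dim)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("phantom", PhantomSpec), ("data", DataConfig),
                         ("gan", GanTrainConfig),
                         ("encoder", EncoderLossConfig),
                         ("restoration", RestorationConfig),
                         ("anomaly", AnomalyConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                if key == "gan" and "augment" in sub_d and isinstance(
                        sub_d["augment"], dict):
                    from .gan import AugmentConfig
                    aug = {k: tuple(v) if isinstance(v, list) else v
                           for k, v in sub_d["augment"].items()}
                    sub_d["augment"] = AugmentConfig(**aug)
                d[key] = sub(**sub_d)
        for key in ("threshold_grid",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def config_hash(obj) -> str:
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage_dir(root: Path, name: str, key: str) -> Path:
    d = root / f"{name}-{key}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _ensemble_residuals(dataset, models, cfg: RunConfig) -> list[list[np.ndarray]]:
    """Per image, the per-model residual maps (and mean reconstructions)."""
    out = []
    for img in dataset.images:
        per_model = []
        for gen, enc in models:
            from .anomaly import reconstruct
            xhat = reconstruct(img.pixels, gen, enc, mode=cfg.mode,
                               restoration_cfg=cfg.restoration)
            per_model.append((residual_map(img.pixels, xhat,
                                           kind=cfg.anomaly.residual_kind),
                              xhat))
        out.append(per_model)
    return out


def _vote_masks(per_model_residuals, t: float, radius: int) -> np.ndarray:
    member = [close_mask(threshold_mask(r, t), radius)
              for r, _ in per_model_residuals]
    return majority_vote(member)


def run_experiment(config: RunConfig, out_dir: str | Path,
                   use_cache: bool = True) -> dict:
    """Execute the full pipeline; return the evaluation report as a dict.

    Artifacts land under ``out_dir``: trained model checkpoints, the sweep
    table, and ``report.json``.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cfg_d = config.to_dict()

    # -- stage 1: data ---------------------------------------------------
    train_ds = generate_phantom(config.phantom, config.data.n_train, "train")
    val_ds = make_abnormal_dataset(
        config.phantom, config.data.n_validation, "validation",
        kind=config.data.anomaly_kind,
        radius_frac_range=config.data.radius_frac_range,
        intensity_delta_range=config.data.intensity_delta_range)
    test_ds = make_abnormal_dataset(
        config.phantom, config.data.n_test, "test",
        kind=config.data.anomaly_kind,
        radius_frac_range=config.data.radius_frac_range,
        intensity_delta_range=config.data.intensity_delta_range)
    test_normal = generate_phantom(config.phantom,
                                   max(1, config.data.n_normal_stats), "test")

    # -- stage 2/3: model ensemble --------------------------------------
    models: list[tuple[Generator, EncoderNet | None]] = []
    model_key = config_hash({"phantom": cfg_d["phantom"],
                             "data_n": config.data.n_train,
                             "gan": cfg_d["gan"], "seed": config.seed,
                             "mode": config.mode,
                             "encoder": cfg_d["encoder"]})
    mdir = _stage_dir(root, "models", model_key)
    for k in range(config.anomaly.ensemble_size):
        gpath = mdir / f"gen-{k}.npz"
        epath = mdir / f"enc-{k}.npz"
        gan_cfg = dataclasses.replace(config.gan, seed=config.seed + k)
        if use_cache and gpath.exists():
            gen, _ = load_model(gpath)
        else:
            gen, _, _ = train_gan(train_ds, gan_cfg)
            save_model(gpath, gen, seed=gan_cfg.seed, config_hash=model_key)
        enc = None
        if config.mode == "encoder":
            if use_cache and epath.exists():
                enc, _ = load_model(epath)
            else:
                enc_cfg = dataclasses.replace(config.encoder,
                                              seed=config.seed + k)
                enc, _ = train_encoder(train_ds, gen, enc_cfg)
                save_model(epath, enc, seed=enc_cfg.seed,
                           config_hash=model_key)
        models.append((gen, enc))

    # -- stage 4: threshold sweep on validation -------------------------
    radius = config.anomaly.closing_radius_for(config.resolution)
    val_res = _ensemble_residuals(val_ds, models, config)
    t0, t1, dt = config.threshold_grid
    grid = np.arange(t0, t1 + dt / 2, dt)
    sweep = []
    for t in grid:
        dvals = [dice(_vote_masks(pm, t, radius), ref)
                 for pm, ref in zip(val_res, val_ds.masks)]
        sweep.append({"threshold": float(t),
                      "median_dice": float(np.median(dvals)),
                      "mean_dice": float(np.mean(dvals))})
    best = int(np.argmax([row["median_dice"] for row in sweep]))
    t_star = float(grid[best])
    with open(root / "sweep.json", "w") as fh:
        json.dump(sweep, fh, indent=1)

    # -- stage 5: test evaluation ---------------------------------------
    test_res = _ensemble_residuals(test_ds, models, config)
    preds = [_vote_masks(pm, t_star, radius) for pm in test_res]
    mean_res = [np.mean([r for r, _ in pm], axis=0) for pm in test_res]
    abn_pairs = [(img.pixels, np.mean([xh for _, xh in pm], axis=0))
                 for img, pm in zip(test_ds.images, test_res)]
    nor_res = _ensemble_residuals(test_normal, models, config)
    nor_pairs = [(img.pixels, np.mean([xh for _, xh in pm], axis=0))
                 for img, pm in zip(test_normal.images, nor_res)]
    report = evaluate_masks(
        preds, test_ds.masks, t_star, residuals=mean_res,
        pairs=abn_pairs + nor_pairs,
        abnormal=[True] * len(abn_pairs) + [False] * len(nor_pairs))
    out = report.to_dict()
    out["config_hash"] = config_hash(cfg_d)
    out["seed"] = config.seed
    out["mode"] = config.mode
    out["sweep"] = sweep
    with open(root / "report.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out
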