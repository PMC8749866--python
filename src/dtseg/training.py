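"""Two-stage training orchestration: preprocessing, random cropping, the
polynomial learning-rate decay, per-stage loss wiring, checkpointing, and
the ablation grid.

Stage 1 trains the dual-decoder U-Net with loss
``dice(image decoder, label) + L_dist(distance decoder, map)`` (unit
weights), where ``L_dist`` is MAE or MSE against the offline-generated
distance weight map.  Stage 2 freezes stage 1, feeds the channel-concatenated
(segmentation, distance) bridge into U-Net2, and optimizes Dice or Distdice
loss, Distdice weighting the intersection by the frozen stage-1 distance
prediction.  The learning rate decays per epoch as

    alpha(e) = alpha0 * (1 - e / N) ** 0.9

from ``alpha0`` at epoch 0 to exactly 0 at epoch N.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import losses as L
from .distance_maps import make_map
from .metrics import EvalReport, evaluate_pairs
from .networks import (
    NetworkSpec,
    StageOneOutput,
    UNet,
    build_unet1,
    build_unet2,
    stage_bridge,
)
from .nn import Adam, Tensor, no_grad
from .synthetic import PhantomCase
from .volumes import BinaryMask, DistanceWeightMap, IntensityVolume

STAGE1_DISTANCE_LOSSES = ("mae", "mse")
STAGE2_LOSSES = ("dice", "distdice")
MAP_METHODS = ("A", "B", "C", "none")


@dataclass(frozen=True)
class TrainSpec:
    """Training hyperparameters; defaults are the full-scale reference values
    (232x232x32 crop, batch 1, Adam at 1e-4 for 110 epochs)."""

    crop_size: tuple[int, int, int] = (232, 232, 32)
    batch_size: int = 1
    lr0: float = 1e-4
    max_epochs: int = 110
    lr_power: float = 0.9
    seed: int = 0
    stage1_distance_loss: str = "mse"
    stage2_loss: str = "distdice"
    map_method: str = "A"
    map_mode: str = "3d"
    #: append the raw image to the stage-2 input (automatic-context cascade)
    stage2_include_image: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "crop_size", tuple(int(c) for c in self.crop_size))
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.stage1_distance_loss not in STAGE1_DISTANCE_LOSSES:
            raise ValueError(f"stage1_distance_loss must be in {STAGE1_DISTANCE_LOSSES}")
        if self.stage2_loss not in STAGE2_LOSSES:
            raise ValueError(f"stage2_loss must be in {STAGE2_LOSSES}")
        if self.map_method not in MAP_METHODS:
            raise ValueError(f"map_method must be in {MAP_METHODS}")

    def check_against(self, net_spec: NetworkSpec) -> None:
        div = 2**net_spec.levels
        if any(c % div for c in self.crop_size):
            raise ValueError(
                f"crop_size {self.crop_size} must be divisible by {div} "
                f"(network has {net_spec.levels} levels)"
            )


def lr_schedule(e: int, spec: TrainSpec) -> float:
    """Polynomial decay alpha0 * (1 - e/N)**power, defined on 0 <= e <= N."""
    if e < 0 or e > spec.max_epochs:
        raise ValueError(f"epoch {e} outside [0, {spec.max_epochs}]")
    return spec.lr0 * (1.0 - e / spec.max_epochs) ** spec.lr_power


def preprocess(image: IntensityVolume) -> IntensityVolume:
    """Per-volume z-score normalization; a constant volume maps to zeros."""
    x = image.data.astype(np.float64)
    sd = x.std()
    if sd == 0:
        warnings.warn("constant intensity volume; normalized output is all zeros")
        return IntensityVolume(np.zeros_like(x), image.spacing)
    return IntensityVolume((x - x.mean()) / sd, image.spacing)


def _pad_to(arr: np.ndarray, size, constant: float = 0.0) -> np.ndarray:
    pads = []
    for dim, want in zip(arr.shape, size):
        short = max(0, want - dim)
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, constant_values=constant)
    return arr


def random_crop(image, label, dmap, size, rng: np.random.Generator):
    """Crop one uniformly random window, applied identically to all inputs.

    Volumes smaller than the crop are first padded symmetrically with
    background (zeros).
    """
    size = tuple(int(s) for s in size)
    arrays = [np.asarray(image, dtype=np.float64), np.asarray(label)]
    if dmap is not None:
        arrays.append(np.asarray(dmap, dtype=np.float64))
    arrays = [_pad_to(a, size) for a in arrays]
    corner = [int(rng.integers(0, d - s + 1)) for d, s in zip(arrays[0].shape, size)]
    window = tuple(slice(c, c + s) for c, s in zip(corner, size))
    out = [a[window] for a in arrays]
    if dmap is None:
        out.append(None)
    return tuple(out)


@dataclass
class TrainingCase:
    """One preprocessed training record."""

    case_id: str
    image: np.ndarray  # z-scored intensities
    label: np.ndarray  # uint8 {0,1}
    dmap: np.ndarray | None = None
    spacing: tuple[float, float, float] = (0.625, 0.625, 0.625)


def prepare_cases(
    cases: list[PhantomCase], map_method: str = "A", map_mode: str = "3d"
) -> list[TrainingCase]:
    """Normalize phantoms and generate their distance maps offline."""
    out = []
    for i, case in enumerate(cases):
        dmap = None
        if map_method != "none":
            dmap = make_map(case.label, map_method, map_mode).data
        out.append(
            TrainingCase(
                case_id=f"case_{i:03d}",
                image=preprocess(case.image).data,
                label=case.label.data,
                dmap=dmap,
                spacing=case.label.spacing,
            )
        )
    return out


@dataclass
class Checkpoint:
    """Trained weights plus the specs and loss history needed to replay."""

    state: dict[str, np.ndarray]
    net_spec: NetworkSpec
    train_spec: TrainSpec
    history: list[dict] = field(default_factory=list)
    stage: int = 1

    def build(self) -> UNet:
        net = UNet(self.net_spec, seed=0)
        net.load_state_dict(self.state)
        return net

    def save(self, path) -> None:
        meta = json.dumps(
            {
                "net_spec": asdict(self.net_spec),
                "train_spec": asdict(self.train_spec),
                "history": self.history,
                "stage": self.stage,
            }
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"param:{k}": v for k, v in self.state.items()})

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {
                k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")
            }
        return cls(
            state=state,
            net_spec=NetworkSpec(**meta["net_spec"]),
            train_spec=TrainSpec(**meta["train_spec"]),
            history=meta["history"],
            stage=meta["stage"],
        )


def _check_finite(value: float, context: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss ({value}) during {context}; aborting")


def train_stage1(
    cases: list[TrainingCase],
    train_spec: TrainSpec,
    net_spec: NetworkSpec,
    log=None,
) -> Checkpoint:
    """Train the first stage (dual-decoder, or plain U-Net for ablations)."""
    train_spec.check_against(net_spec)
    use_dist = net_spec.with_distance_decoder
    if use_dist:
        missing = [c.case_id for c in cases if c.dmap is None]
        if missing:
            raise ValueError(f"distance maps missing for cases {missing}")
        if train_spec.map_method == "none":
            raise ValueError("map_method='none' but network has a distance decoder")
    dist_loss = L.LOSSES[train_spec.stage1_distance_loss]

    rng = np.random.default_rng(train_spec.seed)
    net = UNet(net_spec, seed=int(rng.integers(2**31)))
    opt = Adam(net.parameters(), lr=train_spec.lr0)
    history = []
    for epoch in range(train_spec.max_epochs):
        opt.lr = lr_schedule(epoch, train_spec)
        seg_losses, map_losses = [], []
        for idx in rng.permutation(len(cases)):
            case = cases[idx]
            img, lbl, dm = random_crop(
                case.image, case.label, case.dmap, train_spec.crop_size, rng
            )
            out = net(Tensor(img[None, None]))
            seg_l = L.dice_loss(out.segmentation, lbl[None, None].astype(np.float64))
            total = seg_l
            if use_dist:
                map_l = dist_loss(out.distance_pred, dm[None, None])
                total = seg_l + map_l
                map_losses.append(map_l.item())
            opt.zero_grad()
            total.backward()
            _check_finite(total.item(), f"stage-1 epoch {epoch}")
            opt.step()
            seg_losses.append(seg_l.item())
        rec = {
            "epoch": epoch,
            "lr": opt.lr,
            "dice_loss": float(np.mean(seg_losses)),
            "distance_loss": float(np.mean(map_losses)) if map_losses else None,
        }
        history.append(rec)
        if log:
            log(rec)
    return Checkpoint(net.state_dict(), net_spec, train_spec, history, stage=1)


def train_stage2(
    cases: list[TrainingCase],
    stage1_ckpt: Checkpoint,
    train_spec: TrainSpec,
    net_spec: NetworkSpec,
    log=None,
) -> Checkpoint:
    """Train the refiner on the frozen first stage's bridged outputs."""
    train_spec.check_against(net_spec)
    if net_spec.with_distance_decoder:
        raise ValueError("stage-2 network must not have a distance decoder")
    stage1 = stage1_ckpt.build()
    bridge_ch = (2 if stage1.spec.with_distance_decoder else 1) + int(
        train_spec.stage2_include_image
    )
    if net_spec.in_channels != bridge_ch:
        raise ValueError(
            f"unet2 in_channels={net_spec.in_channels} but stage-1 bridge has "
            f"{bridge_ch} channels"
        )
    if train_spec.stage2_loss == "distdice" and not stage1.spec.with_distance_decoder:
        raise ValueError("distdice loss needs a stage-1 distance prediction")

    rng = np.random.default_rng(train_spec.seed + 1)
    net2 = UNet(net_spec, seed=int(rng.integers(2**31)))
    opt = Adam(net2.parameters(), lr=train_spec.lr0)
    history = []
    for epoch in range(train_spec.max_epochs):
        opt.lr = lr_schedule(epoch, train_spec)
        step_losses = []
        for idx in rng.permutation(len(cases)):
            case = cases[idx]
            img, lbl, _ = random_crop(
                case.image, case.label, case.dmap, train_spec.crop_size, rng
            )
            x = Tensor(img[None, None])
            with no_grad():  # stage 1 is frozen
                s1 = stage1(x)
                bridge = stage_bridge(
                    s1, x if train_spec.stage2_include_image else None
                ).detach()
            pred = net2(bridge).segmentation
            y = lbl[None, None].astype(np.float64)
            if train_spec.stage2_loss == "distdice":
                loss = L.distdice_loss(pred, y, s1.distance_pred.data)
            else:
                loss = L.dice_loss(pred, y)
            opt.zero_grad()
            loss.backward()
            _check_finite(loss.item(), f"stage-2 epoch {epoch}")
            opt.step()
            step_losses.append(loss.item())
        rec = {"epoch": epoch, "lr": opt.lr, "stage2_loss": float(np.mean(step_losses))}
        history.append(rec)
        if log:
            log(rec)
    return Checkpoint(net2.state_dict(), net_spec, train_spec, history, stage=2)


def predict(
    image: np.ndarray,
    stage1_ckpt: Checkpoint,
    stage2_ckpt: Checkpoint | None = None,
    threshold: float = 0.5,
) -> np.ndarray:
    """Run the (one- or two-stage) pipeline on a full normalized volume."""
    net1 = stage1_ckpt.build()
    with no_grad():
        x = Tensor(image[None, None])
        s1 = net1(x)
        if stage2_ckpt is None:
            prob = s1.segmentation.data[0, 0]
        else:
            net2 = stage2_ckpt.build()
            bridge = stage_bridge(
                s1, x if stage2_ckpt.train_spec.stage2_include_image else None
            )
            prob = net2(bridge).segmentation.data[0, 0]
    return (prob >= threshold).astype(np.uint8)


def evaluate_pipeline(
    cases: list[TrainingCase],
    stage1_ckpt: Checkpoint,
    stage2_ckpt: Checkpoint | None = None,
) -> EvalReport:
    pairs = []
    for case in cases:
        pred = predict(case.image, stage1_ckpt, stage2_ckpt)
        pairs.append(
            (
                case.case_id,
                BinaryMask(pred, case.spacing),
                BinaryMask(case.label, case.spacing),
            )
        )
    return evaluate_pairs(pairs)


@dataclass(frozen=True)
class AblationConfig:
    """One row of the ablation grid."""

    name: str
    two_stage: bool = True
    map_method: str = "A"  # "none" -> plain network without distance decoder
    stage1_distance_loss: str = "mse"
    stage2_loss: str = "dice"


STANDARD_GRID = (
    AblationConfig("one_stage", two_stage=False, map_method="none"),
    AblationConfig("two_stage", two_stage=True, map_method="none"),
    AblationConfig("two_stage_A_mae_dice", map_method="A",
                   stage1_distance_loss="mae", stage2_loss="dice"),
    AblationConfig("two_stage_A_mae_distdice", map_method="A",
                   stage1_distance_loss="mae", stage2_loss="distdice"),
    AblationConfig("two_stage_A_mse_dice", map_method="A",
                   stage1_distance_loss="mse", stage2_loss="dice"),
    AblationConfig("two_stage_A_mse_distdice", map_method="A",
                   stage1_distance_loss="mse", stage2_loss="distdice"),
)


def run_config(
    config: AblationConfig,
    train_cases_raw,
    val_cases_raw,
    train_spec: TrainSpec,
    net_spec: NetworkSpec,
) -> EvalReport:
    """Train one configuration end to end and evaluate on held-out cases."""
    with_dist = config.map_method != "none"
    spec1 = replace(
        net_spec, in_channels=1, with_distance_decoder=with_dist
    )
    tspec = replace(
        train_spec,
        map_method=config.map_method,
        stage1_distance_loss=config.stage1_distance_loss,
        stage2_loss=config.stage2_loss if with_dist else "dice",
    )
    train_cases = prepare_cases(train_cases_raw, config.map_method, tspec.map_mode)
    val_cases = prepare_cases(val_cases_raw, "none")
    ckpt1 = train_stage1(train_cases, tspec, spec1)
    if not config.two_stage:
        return evaluate_pipeline(val_cases, ckpt1)
    spec2 = replace(
        net_spec,
        in_channels=(2 if with_dist else 1) + int(tspec.stage2_include_image),
        with_distance_decoder=False,
    )
    ckpt2 = train_stage2(train_cases, ckpt1, tspec, spec2)
    return evaluate_pipeline(val_cases, ckpt1, ckpt2)


def run_ablation(
    configs,
    train_cases_raw,
    val_cases_raw,
    train_spec: TrainSpec,
    net_spec: NetworkSpec,
    seeds=(0,),
) -> list[dict]:
    """Train every configuration under each seed on identical data; return a
    table of mean Dice (%) / ASSD (mm) per configuration."""
    rows = []
    for config in configs:
        dices, assds = [], []
        for seed in seeds:
            report = run_config(
                config,
                train_cases_raw,
                val_cases_raw,
                replace(train_spec, seed=int(seed)),
                net_spec,
            )
            dices.append(report.mean_dice_percent)
            assds.append(report.mean_assd_mm)
        rows.append(
            {
                "config": config.name,
                "dice_percent": float(np.mean(dices)),
                "assd_mm": float(np.mean(assds)),
                "per_seed_dice": dices,
                "per_seed_assd": assds,
            }
        )
    return rows
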