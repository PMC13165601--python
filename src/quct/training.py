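"""Training loop, transfer learning and the three experiment phases.

Training minimizes the combined focal + Dice loss with Adam, early stopping
on the validation loss (best weights restored).  Transfer learning loads a
pretrained checkpoint and fine-tunes all layers on a small new dataset —
the protocol used to adapt a clean-data model to noisy measurements, to a
square sensor geometry, or to brain-tissue phantoms.

``run_phase`` orchestrates the full generate -> simulate -> train/transfer
-> evaluate pipeline at a configurable scale and writes datasets,
checkpoints and metric reports to disk.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .acoustics import acquire, add_awgn
from .model import SignalToImageNet, build_model, predict
from .objectives import LossConfig, combined_loss, dice_coefficient, evaluate
from .phantoms import labels_to_onehot, make_brain_phantom, make_dataset
from .profiles import Profile, get_profile

__all__ = [
    "TrainConfig", "TrainHistory", "PhaseSpec",
    "train", "transfer_learn", "run_phase", "simulate_pairs",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 8e-5    # grid-searched default for undistorted data
    epochs: int = 100
    batch_size: int = 10
    beta1: float = 0.9
    beta2: float = 0.999
    patience: int = 10             # early stopping on validation loss
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    phase: str = "phase1"
    stop_train_dice: float | None = None   # optional convergence target

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid learning rate, batch size or epoch count")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    epoch_seconds: list = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("train_loss", "val_loss", "train_dice", "val_dice",
                 "epoch_seconds", "best_epoch")}


def _to_arrays(dataset, n_classes):
    """Dataset of (measurement, labels) -> stacked float32/onehot arrays."""
    if not dataset:
        raise ValueError("empty dataset")
    xs, ys = [], []
    for x, y in dataset:
        data = x.data if hasattr(x, "data") else x
        xs.append(np.asarray(data, dtype=np.float32))
        ys.append(np.asarray(y))
    x = np.stack(xs)
    y = np.stack(ys)
    onehot = np.transpose(labels_to_onehot(y, n_classes), (0, 3, 1, 2))
    return x, y, onehot.astype(np.float32)


def _epoch_eval(model, x, y, onehot, loss_cfg, batch_size):
    losses, dices = [], []
    with nn.no_grad():
        for lo in range(0, len(x), batch_size):
            sl = slice(lo, lo + batch_size)
            probs = model(nn.Tensor(x[sl]))
            losses.append(combined_loss(probs, nn.Tensor(onehot[sl]),
                                        loss_cfg).item() * len(x[sl]))
            pred = probs.data.argmax(axis=1)
            for p, g in zip(pred, y[sl]):
                dices.append(dice_coefficient(p, g, onehot.shape[1])[1])
    return float(np.sum(losses) / len(x)), float(np.mean(dices))


def train(model: SignalToImageNet, train_set, val_set, cfg: TrainConfig):
    """Optimize the combined loss; returns (best state dict, history)."""
    C = model.config.n_classes
    x_tr, y_tr, oh_tr = _to_arrays(train_set, C)
    x_va, y_va, oh_va = _to_arrays(val_set, C)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best_state, best_val = model.state_dict(), np.inf
    stale = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(x_tr))
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            model.zero_grad()
            probs = model(nn.Tensor(x_tr[idx]))
            loss = combined_loss(probs, nn.Tensor(oh_tr[idx]), cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch offset {lo}")
            loss.backward()
            opt.step()
        tr_loss, tr_dice = _epoch_eval(model, x_tr, y_tr, oh_tr, cfg.loss,
                                       cfg.batch_size)
        va_loss, va_dice = _epoch_eval(model, x_va, y_va, oh_va, cfg.loss,
                                       cfg.batch_size)
        hist.train_loss.append(tr_loss)
        hist.val_loss.append(va_loss)
        hist.train_dice.append(tr_dice)
        hist.val_dice.append(va_dice)
        hist.epoch_seconds.append(time.time() - t0)
        if va_loss < best_val:
            best_val, best_state = va_loss, model.state_dict()
            hist.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
        if cfg.stop_train_dice is not None and tr_dice >= cfg.stop_train_dice:
            best_state = model.state_dict()
            hist.best_epoch = epoch
            break
    model.load_state_dict(best_state)
    return best_state, hist


def transfer_learn(model: SignalToImageNet, pretrained_state: dict,
                   train_set, val_set, cfg: TrainConfig):
    """Load pretrained weights, fine-tune all layers on the new data.

    ``cfg.epochs == 0`` returns the loaded weights untouched, which is the
    zero-shot evaluation path.
    """
    model.load_state_dict(pretrained_state)
    if cfg.epochs == 0:
        return model.state_dict(), TrainHistory()
    return train(model, train_set, val_set, cfg)


# ---------------------------------------------------------------------------
# phase orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSpec:
    name: str                          # phase1 | phase2 | phase3
    out_dir: str | Path
    profile: str = "tiny"
    variant: str = "original"          # phase-1/2 disc variant
    variants: tuple = ("original", "distorted", "mixed")
    snr_levels: tuple = (20.0, 30.0, 40.0)
    geometry: str = "circle"
    experiment: str = "square"         # phase-3: square | brain
    model_variant: str = "large"
    n_train: int = 8
    n_val: int = 4
    n_test: int = 4
    epochs: int = 30
    transfer_epochs: int = 5
    learning_rate: float = 8e-5
    seed: int = 0
    pretrained: str | Path | None = None

    def __post_init__(self):
        if self.name not in ("phase1", "phase2", "phase3"):
            raise ValueError(f"unknown phase {self.name!r}")


def simulate_pairs(profile: Profile, phantoms, geometry="circle",
                   snr_db=None, noise_seed=0, return_tensors=False):
    """Acquire a measurement for each phantom; returns (tensor, labels) pairs
    (or the full MeasurementTensor objects with ``return_tensors``)."""
    array = profile.sensor_array(geometry)
    pairs, tensors = [], []
    for i, ph in enumerate(phantoms):
        meas = acquire(ph, array, profile.acquisition)
        if snr_db is not None:
            meas = add_awgn(meas, snr_db, noise_seed + i)
        pairs.append((meas.data, ph.labels))
        tensors.append(meas)
    if return_tensors:
        return pairs, tensors
    return pairs


def _make_phantoms(profile: Profile, spec: PhaseSpec, n, seed, brain=False):
    if brain:
        rng = np.random.default_rng(seed)
        return [make_brain_phantom(int(s), profile.brain_spec)
                for s in rng.integers(0, 2 ** 31 - 1, size=n)]
    return make_dataset(spec.variant, n, seed, profile.disc_config)


def _save_checkpoint(state: dict, path: Path):
    np.savez_compressed(path, **state)


def load_checkpoint(path) -> dict:
    with np.load(path) as f:
        return {k: f[k] for k in f.files}


def _train_and_report(profile, spec, model, train_pairs, val_pairs, test_pairs,
                      out_dir, tag, pretrained_state=None):
    cfg = TrainConfig(learning_rate=spec.learning_rate,
                      epochs=(spec.transfer_epochs if pretrained_state is not None
                              else spec.epochs),
                      batch_size=min(10, len(train_pairs)),
                      seed=spec.seed, phase=spec.name)
    if pretrained_state is not None:
        state, hist = transfer_learn(model, pretrained_state, train_pairs,
                                     val_pairs, cfg)
    else:
        state, hist = train(model, train_pairs, val_pairs, cfg)
    scheme = (profile.scheme if model.config.n_classes ==
              profile.scheme.n_classes else None)
    reports = []
    for x, y in test_pairs:
        _, labels, _ = predict(model, x, scheme or profile.scheme)
        if scheme is not None:
            reports.append(evaluate(labels, y, scheme).as_dict())
        else:
            per, mac = dice_coefficient(labels, y, model.config.n_classes)
            reports.append({"dice": mac})
    mean_report = {k: float(np.mean([r[k] for r in reports]))
                   for k in reports[0] if k != "per_class"}
    _save_checkpoint(state, out_dir / f"{tag}_weights.npz")
    (out_dir / f"{tag}_history.json").write_text(json.dumps(hist.as_dict()))
    (out_dir / f"{tag}_report.json").write_text(json.dumps(
        {"mean": mean_report, "per_sample": reports}, default=float))
    return mean_report


def run_phase(spec: PhaseSpec) -> dict:
    """Run one experiment phase at the configured scale.

    Phase 1 trains from scratch on clean disc data; phase 2 transfer-learns
    the phase-1 weights on each variant x SNR setting; phase 3 adapts to a
    square array or to brain phantoms.  Artifacts (weights, histories,
    metric reports) are written under ``spec.out_dir``.
    """
    profile = get_profile(spec.profile)
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}

    def pairs_for(variant, geometry, snr, seed_off, tag, brain=False):
        from .cli_io import DatasetBundle, write_bundle
        sp = replace(spec, variant=variant)
        tr = _make_phantoms(profile, sp, spec.n_train, spec.seed + seed_off, brain)
        va = _make_phantoms(profile, sp, spec.n_val, spec.seed + seed_off + 1, brain)
        te = _make_phantoms(profile, sp, spec.n_test, spec.seed + seed_off + 2, brain)
        pair_sets, tensors = [], []
        for i, p in enumerate((tr, va, te)):
            pairs, meas = simulate_pairs(profile, p, geometry, snr,
                                         noise_seed=spec.seed + seed_off + 3 + i,
                                         return_tensors=True)
            pair_sets.append(pairs)
            tensors.extend(meas)
        n1, n2 = spec.n_train, spec.n_train + spec.n_val
        splits = {"train": list(range(n1)), "val": list(range(n1, n2)),
                  "test": list(range(n2, n2 + spec.n_test))}
        bundle = DatasetBundle(tr + va + te, tensors, splits,
                               provenance={"phase": spec.name, "seed": spec.seed,
                                           "variant": variant,
                                           "geometry": geometry,
                                           "snr_db": snr, "profile": spec.profile})
        write_bundle(bundle, out_dir / f"{tag}_dataset.h5")
        return tuple(pair_sets)

    if spec.name == "phase1":
        model = build_model(profile.model_config(spec.model_variant), spec.seed)
        tr, va, te = pairs_for(spec.variant, spec.geometry, None, 0,
                               f"phase1_{spec.variant}")
        results[spec.variant] = _train_and_report(
            profile, spec, model, tr, va, te, out_dir, f"phase1_{spec.variant}")
    elif spec.name == "phase2":
        if spec.pretrained is None:
            raise ValueError("phase2 needs pretrained phase-1 weights")
        pre = load_checkpoint(spec.pretrained)
        off = 0
        for variant in spec.variants:
            for snr in spec.snr_levels:
                model = build_model(profile.model_config(spec.model_variant),
                                    spec.seed)
                tag = f"phase2_{variant}_snr{int(snr)}"
                tr, va, te = pairs_for(variant, spec.geometry, snr, off, tag)
                results[f"{variant}/snr{int(snr)}"] = _train_and_report(
                    profile, spec, model, tr, va, te, out_dir, tag,
                    pretrained_state=pre)
                off += 10
    else:  # phase3
        if spec.pretrained is None:
            raise ValueError("phase3 needs pretrained phase-1 weights")
        pre = load_checkpoint(spec.pretrained)
        if spec.experiment == "square":
            model = build_model(profile.model_config(spec.model_variant),
                                spec.seed)
            tr, va, te = pairs_for(spec.variant, "square", None, 100,
                                   "phase3_square")
            results["square"] = _train_and_report(
                profile, spec, model, tr, va, te, out_dir, "phase3_square",
                pretrained_state=pre)
        elif spec.experiment == "brain":
            # 8 tissue classes: a fresh output head size; train from scratch
            # at tiny scale unless the checkpoint matches.
            cfgm = profile.model_config(spec.model_variant)
            model = build_model(replace(cfgm, n_classes=8), spec.seed)
            tr, va, te = pairs_for(spec.variant, spec.geometry, None, 200,
                                   "phase3_brain", brain=True)
            try:
                pre_state = pre
                model.load_state_dict(pre_state)
                pretrained = pre_state
            except ValueError:
                pretrained = None
            results["brain"] = _train_and_report(
                profile, spec, model, tr, va, te, out_dir, "phase3_brain",
                pretrained_state=pretrained)
        else:
            raise ValueError(f"unknown phase-3 experiment {spec.experiment!r}")
    (out_dir / f"{spec.name}_summary.json").write_text(
        json.dumps(results, default=float))
    return results
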