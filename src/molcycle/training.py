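"""Losses and the alternating adversarial optimisation loop.

Loss conventions
----------------
* cycle:     E_x ||F(G(x)) - x||_1 + E_y ||G(F(y)) - y||_1
* identity:  E_y ||F(y) - y||_1 + E_x ||G(x) - x||_1
* LSGAN discriminator:  1/2 E[(D(fake))^2] + 1/2 E[(D(real) - 1)^2]
* LSGAN generator:      1/2 E[(D(fake) - 1)^2]
* total generator objective:  adv_G + adv_F + lambda1*cycle + lambda2*identity
  with lambda1 = 0.4, lambda2 = 0.15 by default.

The printed form of the combined objective repeats an adversarial term
where the cycle term belongs; the cycle-consistency reading above is the
one implemented (see README).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np

from . import LATENT_DIM
from . import _engine as eng
from .networks import (
    DiscriminatorParams,
    GeneratorParams,
    discriminator_forward,
    generator_forward,
    init_discriminator,
    init_generator,
    load_params,
    save_params,
)

GenLike = Union[GeneratorParams, Callable[[np.ndarray], np.ndarray]]
DiscLike = Union[DiscriminatorParams, Callable[[np.ndarray], np.ndarray]]


class TrainingDivergence(RuntimeError):
    """Raised when a loss becomes non-finite during training."""

    def __init__(self, epoch: int, batch: int):
        self.epoch = epoch
        self.batch = batch
        super().__init__(f"non-finite loss at epoch {epoch}, batch {batch}")


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 0.4
    lambda2: float = 0.15

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class ModelBundle:
    G: GeneratorParams  # X -> Y
    F: GeneratorParams  # Y -> X
    D_X: DiscriminatorParams
    D_Y: DiscriminatorParams
    weights: LossWeights = field(default_factory=LossWeights)


def init_bundle(seed: int, weights: Optional[LossWeights] = None,
                final_sigmoid: bool = True) -> ModelBundle:
    rng = np.random.default_rng(seed)
    return ModelBundle(
        G=init_generator(rng),
        F=init_generator(rng),
        D_X=init_discriminator(rng, final_sigmoid),
        D_Y=init_discriminator(rng, final_sigmoid),
        weights=weights or LossWeights(),
    )


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    checkpoint_interval: int = 50
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")


@dataclass
class TrainHistory:
    records: List[Dict[str, float]] = field(default_factory=list)

    def column(self, name: str) -> List[float]:
        return [r[name] for r in self.records]

    def save_csv(self, path: str) -> None:
        if not self.records:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("epoch\n")
            return
        cols = list(self.records[0].keys())
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.records)


# ---------------------------------------------------------------------------
# Loss functions (reference implementations over callables or parameters)


def _as_gen_fn(G: GenLike) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(G, GeneratorParams):
        return lambda z: generator_forward(z, G, training=False)
    return G


def _as_disc_fn(D: DiscLike) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(D, DiscriminatorParams):
        return lambda z: np.atleast_1d(discriminator_forward(z, D))
    return D


def _check_batch(batch: np.ndarray, name: str) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2 or batch.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty (n, {LATENT_DIM}) batch")
    return batch


def _mean_l1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.sum(np.abs(a - b), axis=1)))


def cycle_loss(G: GenLike, F: GenLike, batch_x: np.ndarray, batch_y: np.ndarray) -> float:
    """Mean L1 reconstruction error of the two round trips."""
    bx = _check_batch(batch_x, "batch_x")
    by = _check_batch(batch_y, "batch_y")
    g, f = _as_gen_fn(G), _as_gen_fn(F)
    return _mean_l1(f(g(bx)), bx) + _mean_l1(g(f(by)), by)


def identity_loss(G: GenLike, F: GenLike, batch_x: np.ndarray, batch_y: np.ndarray) -> float:
    """Mean L1 distance between each generator's output and its own input."""
    bx = _check_batch(batch_x, "batch_x")
    by = _check_batch(batch_y, "batch_y")
    g, f = _as_gen_fn(G), _as_gen_fn(F)
    return _mean_l1(f(by), by) + _mean_l1(g(bx), bx)


def lsgan_discriminator_loss(D: DiscLike, real_batch: np.ndarray, fake_batch: np.ndarray) -> float:
    real = _check_batch(real_batch, "real_batch")
    fake = _check_batch(fake_batch, "fake_batch")
    d = _as_disc_fn(D)
    return float(0.5 * np.mean(d(fake) ** 2) + 0.5 * np.mean((d(real) - 1.0) ** 2))


def lsgan_generator_loss(D: DiscLike, fake_batch: np.ndarray) -> float:
    fake = _check_batch(fake_batch, "fake_batch")
    d = _as_disc_fn(D)
    return float(0.5 * np.mean((d(fake) - 1.0) ** 2))


def total_generator_loss(
    bundle: ModelBundle, batch_x: np.ndarray, batch_y: np.ndarray
) -> Tuple[float, Dict[str, float]]:
    """Scalar generator objective plus its four components."""
    bx = _check_batch(batch_x, "batch_x")
    by = _check_batch(batch_y, "batch_y")
    g, f = _as_gen_fn(bundle.G), _as_gen_fn(bundle.F)
    components = {
        "adv_G": lsgan_generator_loss(bundle.D_Y, g(bx)),
        "adv_F": lsgan_generator_loss(bundle.D_X, f(by)),
        "cycle": cycle_loss(bundle.G, bundle.F, bx, by),
        "identity": identity_loss(bundle.G, bundle.F, bx, by),
    }
    total = (
        components["adv_G"]
        + components["adv_F"]
        + bundle.weights.lambda1 * components["cycle"]
        + bundle.weights.lambda2 * components["identity"]
    )
    return total, components


# ---------------------------------------------------------------------------
# Training loop


def train(
    bundle: ModelBundle,
    x_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
) -> Tuple[ModelBundle, TrainHistory]:
    """Alternating LSGAN optimisation of the two generator/discriminator pairs.

    One discriminator update and one generator update per batch; batch
    order, which is reshuffled every epoch, derives from ``cfg.seed``.
    The bundle is updated in place and also returned.
    """
    X = _check_batch(x_train, "x_train")
    Y = _check_batch(y_train, "y_train")
    if cfg.epochs == 0:
        return bundle, TrainHistory()
    lam1 = np.float32(bundle.weights.lambda1)
    lam2 = np.float32(bundle.weights.lambda2)

    pG = eng.gen_to_engine(bundle.G)
    pF = eng.gen_to_engine(bundle.F)
    pDX = eng.disc_to_engine(bundle.D_X)
    pDY = eng.disc_to_engine(bundle.D_Y)
    optG = eng.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2)
    optF = eng.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2)
    optDX = eng.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2)
    optDY = eng.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2)

    rng = np.random.default_rng(cfg.seed)
    n = min(len(X), len(Y))
    n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
    history = TrainHistory()
    Xf = X.astype(np.float32)
    Yf = Y.astype(np.float32)

    for epoch in range(cfg.epochs):
        perm_x = rng.permutation(len(Xf))[:n]
        perm_y = rng.permutation(len(Yf))[:n]
        sums: Dict[str, float] = {
            k: 0.0
            for k in ("cycle", "identity", "adv_G", "adv_F", "d_X", "d_Y", "total")
        }
        for b in range(n_batches):
            sl = slice(b * cfg.batch_size, (b + 1) * cfg.batch_size)
            bx = Xf[perm_x[sl]]
            by = Yf[perm_y[sl]]
            nb = bx.shape[0]
            if nb == 0:
                continue

            # ---- forward through the generators (caches reused below);
            # G's two stages share one stacked pass with per-half BN stats
            fake_x, cF1 = eng.gen_forward(pF, by)
            outG, cG = eng.gen_forward(
                pG, np.concatenate([bx, fake_x]), split=nb
            )
            fake_y, rec_y = outG[:nb], outG[nb:]
            rec_x, cF2 = eng.gen_forward(pF, fake_y)

            # ---- discriminator updates (fakes detached, real/fake stacked)
            s_y, cy = eng.disc_forward(pDY, np.concatenate([by, fake_y]))
            s_real_y, s_fake_y = s_y[:nb], s_y[nb:]
            loss_dy = 0.5 * float(np.mean(s_fake_y**2) + np.mean((s_real_y - 1) ** 2))
            g_d, _ = eng.disc_backward(
                pDY, cy, np.concatenate([(s_real_y - 1) / nb, s_fake_y / nb])
            )
            optDY.step(pDY, g_d)

            s_x, cx = eng.disc_forward(pDX, np.concatenate([bx, fake_x]))
            s_real_x, s_fake_x = s_x[:nb], s_x[nb:]
            loss_dx = 0.5 * float(np.mean(s_fake_x**2) + np.mean((s_real_x - 1) ** 2))
            g_d, _ = eng.disc_backward(
                pDX, cx, np.concatenate([(s_real_x - 1) / nb, s_fake_x / nb])
            )
            optDX.step(pDX, g_d)

            # ---- generator update (with the freshly updated discriminators)
            sG, cDY = eng.disc_forward(pDY, fake_y)
            sF, cDX = eng.disc_forward(pDX, fake_x)

            adv_G = 0.5 * float(np.mean((sG - 1) ** 2))
            adv_F = 0.5 * float(np.mean((sF - 1) ** 2))
            cyc = float(
                np.mean(np.sum(np.abs(rec_x - bx), axis=1))
                + np.mean(np.sum(np.abs(rec_y - by), axis=1))
            )
            idt = float(
                np.mean(np.sum(np.abs(fake_x - by), axis=1))
                + np.mean(np.sum(np.abs(fake_y - bx), axis=1))
            )
            total = adv_G + adv_F + float(lam1) * cyc + float(lam2) * idt
            if not np.isfinite(total) or not np.isfinite(loss_dx + loss_dy):
                raise TrainingDivergence(epoch, b)

            # adversarial gradients through the discriminators (D grads unused)
            _, d_fake_y = eng.disc_backward(pDY, cDY, (sG - 1) / nb)
            _, d_fake_x = eng.disc_backward(pDX, cDX, (sF - 1) / nb)

            # cycle gradients through the second-stage generators
            d_rec_x = lam1 * np.sign(rec_x - bx, dtype=np.float32) / nb
            d_rec_y = lam1 * np.sign(rec_y - by, dtype=np.float32) / nb
            gF2, d_fy_cyc = eng.gen_backward(pF, cF2, d_rec_x)

            # identity gradients act directly on the first-stage outputs;
            # G's stacked backward handles both stages at once
            d_fy = d_fake_y + d_fy_cyc + lam2 * np.sign(fake_y - bx, dtype=np.float32) / nb
            gG, d_big = eng.gen_backward(pG, cG, np.concatenate([d_fy, d_rec_y]))
            d_fx_cyc = d_big[nb:]
            d_fx = d_fake_x + d_fx_cyc + lam2 * np.sign(fake_x - by, dtype=np.float32) / nb
            gF1, _ = eng.gen_backward(pF, cF1, d_fx)

            optG.step(pG, gG)
            optF.step(pF, {k: gF1[k] + gF2[k] for k in gF1})

            sums["cycle"] += cyc
            sums["identity"] += idt
            sums["adv_G"] += adv_G
            sums["adv_F"] += adv_F
            sums["d_X"] += loss_dx
            sums["d_Y"] += loss_dy
            sums["total"] += total

        record = {"epoch": float(epoch + 1)}
        record.update({k: v / n_batches for k, v in sums.items()})
        history.records.append(record)

        if (
            cfg.out_dir
            and cfg.checkpoint_interval > 0
            and (epoch + 1) % cfg.checkpoint_interval == 0
        ):
            _sync_bundle(bundle, pG, pF, pDX, pDY)
            save_checkpoint(bundle, os.path.join(cfg.out_dir, f"checkpoint_{epoch + 1:05d}"),
                            seed=cfg.seed)

    _sync_bundle(bundle, pG, pF, pDX, pDY)
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        history.save_csv(os.path.join(cfg.out_dir, "history.csv"))
    return bundle, history


def _sync_bundle(bundle, pG, pF, pDX, pDY) -> None:
    eng.engine_to_gen(pG, bundle.G)
    eng.engine_to_gen(pF, bundle.F)
    eng.engine_to_disc(pDX, bundle.D_X)
    eng.engine_to_disc(pDY, bundle.D_Y)


def save_checkpoint(bundle: ModelBundle, directory: str, seed: Optional[int] = None) -> None:
    save_params(
        directory,
        {"G": bundle.G, "F": bundle.F, "D_X": bundle.D_X, "D_Y": bundle.D_Y},
        seed=seed,
    )


def load_checkpoint(directory: str, weights: Optional[LossWeights] = None) -> ModelBundle:
    bundle = init_bundle(seed=0, weights=weights)
    load_params(
        directory,
        {"G": bundle.G, "F": bundle.F, "D_X": bundle.D_X, "D_Y": bundle.D_Y},
    )
    return bundle
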