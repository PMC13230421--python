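"""Training protocol for the mask-guided, fidelity-constrained translator.

Per iteration both generators are updated first (adversarial + weighted cycle
+ identity terms), then both discriminators, each group with its own Adam
instance (beta1=0.5, beta2=0.999).  The learning rate is held at ``base_lr``
for the first ``decay_start_epoch`` epochs and then decays linearly to exactly
zero at the final epoch.  Validation is the mean per-slice MSE of CT->ADC
translations on the [0, 255] scale, recorded once per epoch; the best model is
the epoch with the lowest validation MSE after a burn-in period (default: the
20th epoch), ties resolved to the earliest epoch.

Everything is seeded: weight init, data order and any sampling are pure
functions of ``TrainConfig.seed``, so two runs with the same config produce
bit-identical loss curves on one machine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import losses as L
from .features import build_extractor
from .masking import default_dilation_radius, extract_brain_mask
from .networks import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
)
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainState",
    "lr_schedule",
    "train",
    "select_best_model",
    "ablation_presets",
    "smoke_train_config",
    "save_checkpoint",
    "load_checkpoint",
    "translate_slices",
]

CHECKPOINT_FORMAT_VERSION = 1

_MASK_MODES = ("concat", "multiply", "none")
_LOSS_MODES = ("fidelity", "l1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    base_lr: float = 2e-4
    decay_start_epoch: int = 50
    seed: int = 0
    mask_mode: str = "concat"
    loss_mode: str = "fidelity"
    image_size: int = 256
    base_width: int = 64
    n_residual_blocks: int = 9
    disc_base_width: int = 64
    disc_layers: int = 3
    lambda_cyc: float = 10.0
    lambda_id: float = 5.0
    adversarial_objective: str = "least_squares"
    two_step_cycle: bool = False
    use_image_buffer: bool = False
    dilation_radius: int | None = None
    fx_backend: str = "fixed_random"
    fx_layer_tag: str = "conv3"
    select_min_epoch: int = 20
    arm_name: str = "full"

    def __post_init__(self):
        if not (0 < self.decay_start_epoch < self.epochs):
            raise ValueError("need 0 < decay_start_epoch < epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.mask_mode not in _MASK_MODES:
            raise ValueError(f"mask_mode must be one of {_MASK_MODES}")
        if self.loss_mode not in _LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {_LOSS_MODES}")

    @property
    def generator_in_channels(self) -> int:
        return 2 if self.mask_mode == "concat" else 1

    @property
    def effective_dilation_radius(self) -> int:
        if self.dilation_radius is not None:
            return self.dilation_radius
        return default_dilation_radius(self.image_size)


@dataclass
class TrainState:
    config: TrainConfig
    epoch: int = 0
    iteration: int = 0
    train_loss_epochs: list[dict] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    untrained_val_mse: float = float("nan")
    checkpoint_paths: dict[int, str] = field(default_factory=dict)
    iteration_log: list[dict] = field(default_factory=list)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant ``base_lr`` then linear decay to zero at the last epoch."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [1, {cfg.epochs}]")
    if epoch <= cfg.decay_start_epoch:
        return cfg.base_lr
    return cfg.base_lr * (cfg.epochs - epoch) / (cfg.epochs - cfg.decay_start_epoch)


def select_best_model(state: TrainState, min_epoch: int | None = None) -> int:
    """1-based epoch with the lowest validation MSE among epochs > min_epoch."""
    min_epoch = state.config.select_min_epoch if min_epoch is None else min_epoch
    curve = np.asarray(state.val_mse, dtype=float)
    if len(curve) <= min_epoch:
        raise ValueError(
            f"need more than {min_epoch} recorded epochs, have {len(curve)}"
        )
    rel = int(np.argmin(curve[min_epoch:]))  # argmin -> earliest tie
    return min_epoch + rel + 1


def ablation_presets(base: TrainConfig | None = None) -> list[TrainConfig]:
    """The five experiment arms: plain CycleGAN baseline, hard-filter mask,
    soft-guide mask, fidelity loss alone, and the full method.  All arms share
    the seed and schedule of ``base`` so the comparison is controlled."""
    base = base or TrainConfig()
    arms = [
        ("cyclegan_baseline", "none", "l1"),
        ("mask_multiply", "multiply", "l1"),
        ("mask_concat", "concat", "l1"),
        ("fidelity_loss", "none", "fidelity"),
        ("full_method", "concat", "fidelity"),
    ]
    return [replace(base, arm_name=n, mask_mode=m, loss_mode=lm)
            for n, m, lm in arms]


def smoke_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Desk-scale configuration: 64x64 phantoms, narrow networks, 3 residual
    blocks, 5 epochs, batch size 1 (the cycle-translation reference convention
    for small datasets), standard learning rate."""
    defaults = dict(
        epochs=5, batch_size=1, decay_start_epoch=3, image_size=64,
        base_width=8, n_residual_blocks=3, disc_base_width=16, disc_layers=2,
        seed=seed,
    )
    defaults.update(overrides)
    if "epochs" in overrides and "decay_start_epoch" not in overrides:
        defaults["decay_start_epoch"] = max(1, overrides["epochs"] // 2)
    return TrainConfig(**defaults)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _prepare(slices, cfg: TrainConfig):
    """Stack slices into model-scale arrays and compute brain masks (from the
    CT side; co-registration lets the pair share one mask)."""
    if not slices:
        raise ValueError("empty slice list")
    r = cfg.effective_dilation_radius
    cts, adcs, masks = [], [], []
    for s in slices:
        ct01 = np.asarray(s.ct, dtype=float)
        adc01 = np.asarray(s.adc, dtype=float)
        masks.append(extract_brain_mask(ct01, dilation_radius=r).mask)
        cts.append(2.0 * ct01 - 1.0)
        adcs.append(2.0 * adc01 - 1.0)
    f32 = np.float32
    return (np.stack(cts)[:, None].astype(f32),
            np.stack(adcs)[:, None].astype(f32),
            np.stack(masks)[:, None].astype(f32))


def _gen_input(x, m, mask_mode):
    if mask_mode == "concat":
        return np.concatenate([x, m], axis=1)
    if mask_mode == "multiply":
        return x * m
    return x


def _image_grad_from_input(d_in, m, mask_mode):
    """Map a gradient w.r.t. a generator *input* back onto the image."""
    if mask_mode == "concat":
        return d_in[:, :1]
    if mask_mode == "multiply":
        return d_in * m
    return d_in


class _ImagePool:
    """History buffer of generated images for discriminator updates."""

    def __init__(self, rng, size=50):
        self.rng, self.size, self.items = rng, size, []

    def query(self, batch):
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.items) < self.size:
                self.items.append(img)
                out.append(img)
            elif self.rng.uniform() > 0.5:
                i = int(self.rng.integers(self.size))
                out.append(self.items[i])
                self.items[i] = img
            else:
                out.append(img)
        return np.stack(out)


# ---------------------------------------------------------------------------
# loss gradients (value + gradient w.r.t. the generated image)
# ---------------------------------------------------------------------------

def _adv_gen_grad(scores, objective):
    if objective == "least_squares":
        value = float(np.mean((scores - 1.0) ** 2))
        grad = 2.0 * (scores - 1.0) / scores.size
    else:
        sig = 1.0 / (1.0 + np.exp(-scores))
        value = float(np.mean(np.logaddexp(0.0, scores) - scores))
        grad = (sig - 1.0) / scores.size
    return value, grad


def _adv_disc_grads(s_real, s_fake, objective):
    if objective == "least_squares":
        value = 0.5 * (float(np.mean((s_real - 1.0) ** 2))
                       + float(np.mean(s_fake ** 2)))
        g_real = (s_real - 1.0) / s_real.size
        g_fake = s_fake / s_fake.size
    else:
        sig_r = 1.0 / (1.0 + np.exp(-s_real))
        sig_f = 1.0 / (1.0 + np.exp(-s_fake))
        value = 0.5 * (float(np.mean(np.logaddexp(0.0, s_real) - s_real))
                       + float(np.mean(np.logaddexp(0.0, s_fake))))
        g_real = 0.5 * (sig_r - 1.0) / s_real.size
        g_fake = 0.5 * sig_f / s_fake.size
    return value, g_real, g_fake


def _recon_value_grad(out, target, cfg, fx):
    """Cycle/identity residual term: value and gradient w.r.t. ``out``."""
    if cfg.loss_mode == "fidelity":
        feat_out, cache = fx.forward(out)
        feat_tgt = fx.extract(target)
        diff = feat_out - feat_tgt
        value = float(np.mean(diff ** 2))
        dfeat = 2.0 * diff / diff.size
        return value, fx.backward_input(cache, dfeat)
    diff = out - target
    value = float(np.mean(np.abs(diff)))
    return value, np.sign(diff) / diff.size


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _build_models(cfg: TrainConfig, seed_seq: np.random.SeedSequence):
    keys = {k: np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(i,))) for i, k in enumerate(
            ("g_mri", "g_ct", "d_mri", "d_ct"))}
    gcfg = GeneratorConfig(in_channels=cfg.generator_in_channels,
                           base_width=cfg.base_width,
                           n_residual_blocks=cfg.n_residual_blocks,
                           image_size=cfg.image_size)
    dcfg = DiscriminatorConfig(in_channels=1, base_width=cfg.disc_base_width,
                               n_layers=cfg.disc_layers)
    return {
        "G_MRI": build_generator(gcfg, keys["g_mri"]),
        "G_CT": build_generator(gcfg, keys["g_ct"]),
        "D_MRI": build_discriminator(dcfg, keys["d_mri"]),
        "D_CT": build_discriminator(dcfg, keys["d_ct"]),
    }


def _validation_mse(g_mri, ct, adc, mask, cfg, batch=8):
    """Mean per-slice MSE of CT->ADC translations on the [0, 255] scale."""
    vals = []
    for i in range(0, len(ct), batch):
        xin = _gen_input(ct[i:i + batch], mask[i:i + batch], cfg.mask_mode)
        fake = g_mri(xin)
        a = (fake + 1.0) * 127.5
        b = (adc[i:i + batch] + 1.0) * 127.5
        vals.extend(np.mean((a - b) ** 2, axis=(1, 2, 3)))
    return float(np.mean(vals))


def train(cfg: TrainConfig, train_slices, val_slices, out_dir=None,
          checkpoint_every: int | None = 1, fx=None) -> TrainState:
    """Run the full adversarial training protocol; returns the state with
    per-epoch training-loss means, the validation-MSE curve and checkpoints
    (written when ``out_dir`` is given)."""
    tr_ct, tr_adc, tr_mask = _prepare(train_slices, cfg)
    va_ct, va_adc, va_mask = _prepare(val_slices, cfg)
    train_pids = {s.patient_id for s in train_slices}
    val_pids = {s.patient_id for s in val_slices}
    if train_pids & val_pids:
        raise ValueError(f"patient overlap between splits: {train_pids & val_pids}")

    models = _build_models(cfg, np.random.SeedSequence(cfg.seed))
    g_mri, g_ct = models["G_MRI"], models["G_CT"]
    d_mri, d_ct = models["D_MRI"], models["D_CT"]
    if fx is None:
        fx = build_extractor(cfg.fx_backend, cfg.fx_layer_tag, seed=cfg.seed)
    weights = L.LossWeights(cfg.lambda_cyc, cfg.lambda_id)
    opt_g = Adam([g_mri.net, g_ct.net])
    opt_d = Adam([d_mri.net, d_ct.net])
    order_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(4,)))
    pool_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(5,)))
    pools = (_ImagePool(pool_rng) if cfg.use_image_buffer else None,
             _ImagePool(pool_rng) if cfg.use_image_buffer else None)

    state = TrainState(config=cfg)
    state.untrained_val_mse = _validation_mse(g_mri, va_ct, va_adc, va_mask, cfg)
    fingerprint_before = fx.weights_fingerprint

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    n = len(tr_ct)
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_schedule(epoch, cfg)
        order = order_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            rec = _train_step(cfg, weights, fx, g_mri, g_ct, d_mri, d_ct,
                              opt_g, opt_d, tr_ct[idx], tr_adc[idx],
                              tr_mask[idx], lr, pools)
            state.iteration += 1
            rec.update(epoch=epoch, iteration=state.iteration, lr=lr)
            epoch_losses.append(rec)
            state.iteration_log.append(rec)
        means = {k: float(np.mean([r[k] for r in epoch_losses]))
                 for k in ("adv", "cyc", "id", "total", "d_loss")}
        means["epoch"] = epoch
        state.train_loss_epochs.append(means)
        state.val_mse.append(
            _validation_mse(g_mri, va_ct, va_adc, va_mask, cfg))
        state.epoch = epoch
        if out_dir is not None and checkpoint_every and epoch % checkpoint_every == 0:
            path = out_dir / f"epoch_{epoch:03d}.npz"
            save_checkpoint(path, models, (opt_g, opt_d), epoch, cfg,
                            state.val_mse, state.untrained_val_mse)
            state.checkpoint_paths[epoch] = str(path)

    assert fx.weights_fingerprint == fx._fingerprint() == fingerprint_before
    if out_dir is not None:
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for rec in state.iteration_log:
                fh.write(json.dumps(rec) + "\n")
        (out_dir / "curves.json").write_text(json.dumps({
            "val_mse": state.val_mse,
            "untrained_val_mse": state.untrained_val_mse,
            "train_loss_epochs": state.train_loss_epochs,
        }, indent=1))
        try:
            best = select_best_model(state)
            best_path = out_dir / "best.ckpt.npz"
            best_src = state.checkpoint_paths.get(best)
            if best_src:
                best_path.write_bytes(Path(best_src).read_bytes())
        except ValueError:
            pass  # shorter runs than the burn-in period keep all checkpoints
    return state


def _train_step(cfg, weights, fx, g_mri, g_ct, d_mri, d_ct, opt_g, opt_d,
                ct, adc, mask, lr, pools):
    obj = cfg.adversarial_objective
    in_ct = _gen_input(ct, mask, cfg.mask_mode)
    in_adc = _gen_input(adc, mask, cfg.mask_mode)

    # ---- generator update ------------------------------------------------
    opt_g.zero_grad()
    fake_adc, c_gm1 = g_mri.forward(in_ct)
    fake_ct, c_gc1 = g_ct.forward(in_adc)
    idt_ct, c_gc2 = g_ct.forward(in_ct)     # G_CT applied to a CT image
    idt_adc, c_gm2 = g_mri.forward(in_adc)  # G_MRI applied to an ADC image

    s_fa, c_dm = d_mri.forward(fake_adc)
    adv_mri, ds_fa = _adv_gen_grad(s_fa, obj)
    g_fa_adv = d_mri.backward(c_dm, ds_fa)  # D grads cleared before D update
    s_fc, c_dc = d_ct.forward(fake_ct)
    adv_ct, ds_fc = _adv_gen_grad(s_fc, obj)
    g_fc_adv = d_ct.backward(c_dc, ds_fc)

    if cfg.two_step_cycle and weights.lambda_cyc > 0:
        # close the loop through the second generator
        rec_ct, c_rc = g_ct.forward(_gen_input(fake_adc, mask, cfg.mask_mode))
        rec_adc, c_ra = g_mri.forward(_gen_input(fake_ct, mask, cfg.mask_mode))
        cyc_a, g_rc = _recon_value_grad(rec_ct, ct, cfg, fx)
        cyc_b, g_ra = _recon_value_grad(rec_adc, adc, cfg, fx)
        d_in_rc = g_ct.backward(c_rc, weights.lambda_cyc * g_rc)
        d_in_ra = g_mri.backward(c_ra, weights.lambda_cyc * g_ra)
        g_fa_cyc = _image_grad_from_input(d_in_rc, mask, cfg.mask_mode)
        g_fa_cyc = g_fa_cyc / weights.lambda_cyc
        g_fc_cyc = _image_grad_from_input(d_in_ra, mask, cfg.mask_mode)
        g_fc_cyc = g_fc_cyc / weights.lambda_cyc
        cyc_mri, cyc_ct_v = cyc_a, cyc_b
    elif cfg.two_step_cycle:
        cyc_mri = cyc_ct_v = 0.0
        g_fa_cyc = g_fc_cyc = 0.0
    else:
        cyc_mri, g_fa_cyc = _recon_value_grad(fake_adc, adc, cfg, fx)
        cyc_ct_v, g_fc_cyc = _recon_value_grad(fake_ct, ct, cfg, fx)
    id_ct_v, g_ic = _recon_value_grad(idt_ct, ct, cfg, fx)
    id_adc_v, g_ia = _recon_value_grad(idt_adc, adc, cfg, fx)

    g_mri.backward(c_gm1, g_fa_adv + weights.lambda_cyc * g_fa_cyc)
    g_ct.backward(c_gc1, g_fc_adv + weights.lambda_cyc * g_fc_cyc)
    g_ct.backward(c_gc2, weights.lambda_id * g_ic)
    g_mri.backward(c_gm2, weights.lambda_id * g_ia)
    opt_g.step(lr)

    # ---- discriminator update -------------------------------------------
    opt_d.zero_grad()
    fa = pools[0].query(fake_adc) if pools[0] is not None else fake_adc
    fc = pools[1].query(fake_ct) if pools[1] is not None else fake_ct
    d_loss = 0.0
    for disc, real, fake in ((d_mri, adc, fa), (d_ct, ct, fc)):
        s_r, c_r = disc.forward(real)
        s_f, c_f = disc.forward(fake)
        val, g_r, g_f = _adv_disc_grads(s_r, s_f, obj)
        disc.backward(c_r, g_r)
        disc.backward(c_f, g_f)
        d_loss += val
    opt_d.step(lr)

    adv = adv_mri + adv_ct
    cyc = cyc_mri + cyc_ct_v
    idt = id_ct_v + id_adc_v
    return {
        "adv": adv, "cyc": cyc, "id": idt,
        "total": L.total_loss(adv, cyc, idt, weights), "d_loss": d_loss,
        "adv_mri": adv_mri, "adv_ct": adv_ct,
        "cyc_ct_to_mri": cyc_mri, "cyc_mri_to_ct": cyc_ct_v,
        "id_ct": id_ct_v, "id_mri": id_adc_v,
    }


# ---------------------------------------------------------------------------
# checkpoints and inference
# ---------------------------------------------------------------------------

def save_checkpoint(path, models, optimizers, epoch, cfg, val_mse,
                    untrained_val_mse):
    arrays = {}
    for mname, model in models.items():
        for k, p in model.state_items():
            arrays[f"param::{mname}::{k}"] = p
    for oname, opt in zip(("opt_g", "opt_d"), optimizers):
        for k, v in opt.state_dict().items():
            arrays[f"optim::{oname}::{k}"] = np.asarray(v)
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "epoch": int(epoch),
            "config": asdict(cfg), "val_mse": list(map(float, val_mse)),
            "untrained_val_mse": float(untrained_val_mse)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Rebuild the four networks (and metadata) from a checkpoint file."""
    with np.load(path) as data:
        arrays = dict(data.items())
    meta = json.loads(bytes(arrays.pop("meta_json")).decode())
    if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
    cfg = TrainConfig(**meta["config"])
    models = _build_models(cfg, np.random.SeedSequence(cfg.seed))
    for mname, model in models.items():
        for name, layer in model.named_layers():
            for k in layer.params:
                key = f"param::{mname}::{name}{k}"
                layer.params[k] = arrays[key].astype(float)
    return {"models": models, "config": cfg, "epoch": meta["epoch"],
            "val_mse": meta["val_mse"],
            "untrained_val_mse": meta["untrained_val_mse"]}


def translate_slices(g_mri, slices, cfg: TrainConfig, batch: int = 8):
    """CT->ADC inference; returns [0, 1]-scale translated arrays per slice."""
    ct, _, mask = _prepare(slices, cfg)
    out = []
    for i in range(0, len(ct), batch):
        xin = _gen_input(ct[i:i + batch], mask[i:i + batch], cfg.mask_mode)
        fake = g_mri(xin)
        out.extend((fake[:, 0] + 1.0) / 2.0)
    return [np.asarray(a) for a in out]
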