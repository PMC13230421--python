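"""Training objective: adversarial, fidelity-constrained cycle and identity
losses, and the weighted total.

Notation: ``G_MRI`` maps CT -> synthetic ADC, ``G_CT`` maps ADC -> synthetic
CT; ``phi`` is the frozen feature extractor.  The fidelity loss between two
images is the per-element mean of the squared L2 distance between their
feature representations; dividing by the feature count keeps the loss
magnitude (and the default weights) independent of the extractor size.

The cycle term is implemented, as the method defines it in its supervised
setting, as the fidelity between each one-step translation and the paired
registered target, summed over both directions:

    L_cyc = E[ L_fid(G_MRI(x_CT), x_MRI) ] + E[ L_fid(G_CT(x_MRI), x_CT) ]

A true two-step cycle (compare G_CT(G_MRI(x_CT)) with x_CT) is available via
``mode='two_step'`` for comparison with the unpaired formulation.  The
identity term feeds each generator its own output-domain image:

    L_id = E[ L_fid(G_CT(x_CT), x_CT) ] + E[ L_fid(G_MRI(x_MRI), x_MRI) ]

Total: L = L_adv + lambda1 * L_cyc + lambda2 * L_id.  The expectation E is
realised as the batch mean of per-image means.  The adversarial term uses the
least-squares objective by default (cross-entropy selectable); the printed
log-form equations of the source method are reproduced by ``'cross_entropy'``
up to their typographical inconsistencies, and least-squares is the lineage
reference objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "LossBundle",
    "adversarial_loss",
    "fidelity_loss",
    "cycle_loss",
    "identity_loss",
    "total_loss",
    "l1_cycle_identity_losses",
]


@dataclass(frozen=True)
class LossWeights:
    lambda_cyc: float = 10.0
    lambda_id: float = 5.0

    def __post_init__(self):
        if self.lambda_cyc < 0 or self.lambda_id < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossBundle:
    """Per-batch loss values; ``directions`` holds the per-direction terms."""

    adv: float
    cyc: float
    id: float
    total: float
    directions: dict[str, float]


def adversarial_loss(d_real_scores, d_fake_scores, role: str,
                     objective: str = "least_squares") -> float:
    """GAN objective term for one discriminator's score grids.

    ``role='generator'``: how far fake scores are from the real label.
    ``role='discriminator'``: mean of the real-side and fake-side terms.
    """
    d_real = np.asarray(d_real_scores, dtype=float)
    d_fake = np.asarray(d_fake_scores, dtype=float)
    if role not in ("generator", "discriminator"):
        raise ValueError("role must be 'generator' or 'discriminator'")
    if objective not in ("least_squares", "cross_entropy"):
        raise ValueError(f"unknown adversarial objective {objective!r}")
    if role == "discriminator" and d_real.shape != d_fake.shape:
        raise ValueError(
            f"score shape mismatch: {d_real.shape} vs {d_fake.shape}"
        )
    if objective == "least_squares":
        if role == "generator":
            return float(np.mean((d_fake - 1.0) ** 2))
        return float(0.5 * (np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2)))
    # cross-entropy on raw scores through a numerically stable sigmoid:
    # BCE(s, t) = log(1 + exp(s)) - t*s
    def _bce(scores, target):
        s = np.asarray(scores, dtype=float)
        return float(np.mean(np.logaddexp(0.0, s) - target * s))
    if role == "generator":
        return _bce(d_fake, 1.0)
    return 0.5 * (_bce(d_real, 1.0) + _bce(d_fake, 0.0))


def _per_image_mean_sq(diff: np.ndarray) -> float:
    """Batch mean of per-image mean squared residuals."""
    d = np.asarray(diff, dtype=float)
    if d.ndim <= 2:
        return float(np.mean(d * d))
    return float(np.mean(d.reshape(d.shape[0], -1) ** 2))


def _per_image_mean_abs(diff: np.ndarray) -> float:
    d = np.asarray(diff, dtype=float)
    return float(np.mean(np.abs(d)))


def fidelity_loss(a: np.ndarray, b: np.ndarray, fx) -> float:
    """Mean squared distance between phi(a) and phi(b); symmetric, zero iff
    the feature representations coincide."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _per_image_mean_sq(fx.extract(a) - fx.extract(b))


def _pairs_to_batches(batch):
    """Accept a list of PairedSlice-likes or a (ct, adc) array tuple; return
    model-scale (N,1,H,W) arrays."""
    if isinstance(batch, tuple) and len(batch) == 2:
        ct, adc = (np.asarray(x, dtype=float) for x in batch)
    else:
        try:
            ct = np.stack([np.asarray(s.ct, dtype=float) for s in batch])
            adc = np.stack([np.asarray(s.adc, dtype=float) for s in batch])
        except AttributeError as exc:
            raise ValueError(
                "cycle/identity losses need a paired batch (PairedSlice list "
                "or (ct, adc) arrays)"
            ) from exc
        ct, adc = 2.0 * ct - 1.0, 2.0 * adc - 1.0  # [0,1] -> model scale
    if ct.ndim == 3:
        ct, adc = ct[:, None], adc[:, None]
    if ct.shape != adc.shape:
        raise ValueError("unpaired batch: ct and adc shapes differ")
    return ct, adc


def cycle_loss(batch, g_mri, g_ct, fx, mode: str = "paired") -> float:
    """Fidelity-constrained cycle term (batch mean, both directions).

    ``mode='paired'`` (default) compares each one-step translation with its
    registered target; ``mode='two_step'`` closes the loop through both
    generators and compares with the source image.
    """
    if mode not in ("paired", "two_step"):
        raise ValueError(f"unknown cycle mode {mode!r}")
    ct, adc = _pairs_to_batches(batch)
    fake_adc = g_mri(ct)
    fake_ct = g_ct(adc)
    if mode == "paired":
        return (fidelity_loss(fake_adc, adc, fx)
                + fidelity_loss(fake_ct, ct, fx))
    rec_ct = g_ct(fake_adc)
    rec_adc = g_mri(fake_ct)
    return (fidelity_loss(rec_ct, ct, fx) + fidelity_loss(rec_adc, adc, fx))


def identity_loss(batch, g_mri, g_ct, fx) -> float:
    """Fidelity-constrained identity term: each generator applied to the
    modality it is expected to reproduce unchanged."""
    ct, adc = _pairs_to_batches(batch)
    return (fidelity_loss(g_ct(ct), ct, fx)
            + fidelity_loss(g_mri(adc), adc, fx))


def l1_cycle_identity_losses(batch, g_mri, g_ct) -> tuple[float, float]:
    """Pixel-space L1 cycle/identity terms (traditional ablation arm)."""
    ct, adc = _pairs_to_batches(batch)
    cyc = (_per_image_mean_abs(g_mri(ct) - adc)
           + _per_image_mean_abs(g_ct(adc) - ct))
    idt = (_per_image_mean_abs(g_ct(ct) - ct)
           + _per_image_mean_abs(g_mri(adc) - adc))
    return cyc, idt


def total_loss(adv: float, cyc: float, idt: float,
               weights: LossWeights = LossWeights()) -> float:
    """L = L_adv + lambda1 * L_cyc + lambda2 * L_id."""
    return float(adv + weights.lambda_cyc * cyc + weights.lambda_id * idt)


def make_bundle(adv, cyc, idt, weights: LossWeights,
                directions: dict[str, float] | None = None) -> LossBundle:
    return LossBundle(adv=float(adv), cyc=float(cyc), id=float(idt),
                      total=total_loss(adv, cyc, idt, weights),
                      directions=directions or {})
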