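"""Synthetic paired CT / ADC brain phantoms.

Generates per-patient stacks of co-registered, skull-stripped 2-D slice pairs
with the structure the translation model assumes: an elliptical brain on an
exactly-zero background, several internal tissue compartments whose CT and
ADC intensities are distinct monotone functions of tissue class, and optional
ischaemic lesions that are subtle on CT but markedly hypointense on ADC (the
diffusion-restriction signature of acute stroke).

The dataset is a pure function of :class:`PhantomSpec`: identical spec and
seed give bit-identical arrays.  Intensities are stored in [0, 1]; mapping to
the model's [-1, 1] domain happens at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "PairedSlice",
    "generate_patient",
    "generate_dataset",
    "generate_split",
    "write_dataset",
]

# Tissue intensity conventions (normalised units). CT: CSF darker than
# parenchyma, cortical rim brightest; levels keep the histogram cleanly
# bimodal (zero background vs tissue) so Otsu recovers the whole brain.
# ADC: CSF bright (free diffusion), rim darkest.
_CT_LEVELS = {"ventricle": 0.40, "interior": 0.60, "rim": 0.80}
_ADC_LEVELS = {"ventricle": 0.90, "interior": 0.55, "rim": 0.40}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic paired-slice dataset."""

    image_size: int = 64
    n_patients: int = 60
    slices_per_patient: int = 25
    lesion_probability: float = 0.3
    ct_noise_sd: float = 0.02
    adc_noise_sd: float = 0.03
    lesion_ct_shift: float = -0.03
    lesion_adc_shift: float = -0.35
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.slices_per_patient < 1:
            raise ValueError("slices_per_patient must be >= 1")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ValueError("lesion_probability must lie in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.adc_noise_sd < 0:
            raise ValueError("adc_noise_sd must be >= 0")


@dataclass
class PairedSlice:
    """One co-registered CT/ADC slice pair ([0, 1] intensities, zero background)."""

    ct: np.ndarray
    adc: np.ndarray
    patient_id: str
    slice_index: int
    lesion_mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = field(default=None, repr=False)


def _ellipse(size, cy, cx, ry, rx, theta=0.0):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    y, x = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_patient(spec: PhantomSpec, patient_index: int) -> list[PairedSlice]:
    """Generate all slices for one patient.

    Slices share the patient's anatomy parameters with small per-slice jitter
    (a cheap stand-in for moving through a 3-D head along the axial axis).
    """
    if not isinstance(spec, PhantomSpec):
        raise TypeError("spec must be a PhantomSpec")
    if not 0 <= patient_index < spec.n_patients:
        raise ValueError(
            f"patient_index {patient_index} out of range for n_patients={spec.n_patients}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(patient_index,))
    )
    n = spec.image_size
    # patient-level anatomy
    cy = n / 2 + rng.uniform(-0.03, 0.03) * n
    cx = n / 2 + rng.uniform(-0.03, 0.03) * n
    ry = rng.uniform(0.36, 0.42) * n
    rx = rng.uniform(0.30, 0.36) * n
    vent_scale = rng.uniform(0.18, 0.26)
    rim_frac = rng.uniform(0.10, 0.16)
    slices = []
    for s_idx in range(spec.slices_per_patient):
        jy = ry * (1 + rng.uniform(-0.05, 0.05))
        jx = rx * (1 + rng.uniform(-0.05, 0.05))
        brain = _ellipse(n, cy, cx, jy, jx)
        vent = _ellipse(n, cy, cx, vent_scale * jy, vent_scale * jx,
                        theta=rng.uniform(-0.3, 0.3))
        inner = _ellipse(n, cy, cx, (1 - rim_frac) * jy, (1 - rim_frac) * jx)
        rim = brain & ~inner
        interior = inner & ~vent
        ct = np.zeros((n, n))
        adc = np.zeros((n, n))
        for name, region in (("ventricle", vent & brain), ("interior", interior),
                             ("rim", rim)):
            ct[region] = _CT_LEVELS[name]
            adc[region] = _ADC_LEVELS[name]
        lesion_mask = None
        if rng.uniform() < spec.lesion_probability:
            lesion_mask = _draw_lesion(rng, n, brain, interior)
            if lesion_mask is not None:
                ct[lesion_mask] += spec.lesion_ct_shift
                adc[lesion_mask] += spec.lesion_adc_shift
        ct[brain] += rng.normal(0.0, spec.ct_noise_sd, size=int(brain.sum()))
        adc[brain] += rng.normal(0.0, spec.adc_noise_sd, size=int(brain.sum()))
        # keep brain strictly positive so the zero background stays unambiguous
        ct[brain] = np.clip(ct[brain], 0.05, 1.0)
        adc[brain] = np.clip(adc[brain], 0.02, 1.0)
        slices.append(PairedSlice(
            ct=ct, adc=adc, patient_id=f"P{patient_index:03d}", slice_index=s_idx,
            lesion_mask=lesion_mask, brain_mask=brain,
        ))
    return slices


def _draw_lesion(rng, n, brain, interior):
    """Random elliptical lesion, area 1-5% of the brain, fully inside it."""
    brain_area = brain.sum()
    ys, xs = np.nonzero(interior)
    if len(ys) == 0:
        return None
    for _ in range(20):
        i = rng.integers(len(ys))
        cy, cx = ys[i], xs[i]
        target = rng.uniform(0.01, 0.05) * brain_area
        r = np.sqrt(target / np.pi)
        ry = r * rng.uniform(0.7, 1.4)
        rx = target / np.pi / ry
        lesion = _ellipse(n, cy, cx, ry, rx, theta=rng.uniform(0, np.pi))
        if lesion.sum() > 0 and (lesion & ~brain).sum() == 0:
            return lesion
    return None


def generate_dataset(spec: PhantomSpec) -> list[PairedSlice]:
    """All patients' slices, patient-major order."""
    out = []
    for p in range(spec.n_patients):
        out.extend(generate_patient(spec, p))
    return out


def generate_split(spec: PhantomSpec, n_train: int, n_val: int, n_test: int):
    """Patient-level random split into train/val/test slice lists.

    Membership is a deterministic function of ``spec.seed``; no patient
    contributes slices to more than one split.
    """
    if n_train + n_val + n_test != spec.n_patients:
        raise ValueError(
            f"split counts {n_train}+{n_val}+{n_test} != n_patients={spec.n_patients}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(987654,))
    )
    order = rng.permutation(spec.n_patients)
    groups = (order[:n_train], order[n_train:n_train + n_val],
              order[n_train + n_val:])
    out = []
    for g in groups:
        sl = []
        for p in sorted(int(i) for i in g):
            sl.extend(generate_patient(spec, p))
        out.append(sl)
    return tuple(out)


def write_dataset(slices: list[PairedSlice], directory, fmt: str = "nifti") -> dict:
    """Write slices to disk as per-patient NIfTI volumes or per-slice PNGs.

    Returns a manifest mapping each slice to its files; the manifest is also
    written as ``manifest.json`` in ``directory``.
    """
    import imageio.v3 as iio
    import nibabel as nib

    if fmt not in ("nifti", "png"):
        raise ValueError(f"unknown format: {fmt!r} (expected 'nifti' or 'png')")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    if fmt == "nifti":
        by_patient: dict[str, list[PairedSlice]] = {}
        for s in slices:
            by_patient.setdefault(s.patient_id, []).append(s)
        for pid, group in by_patient.items():
            group = sorted(group, key=lambda s: s.slice_index)
            for modality in ("ct", "adc"):
                vol = np.stack([getattr(s, modality) for s in group], axis=-1)
                path = directory / f"{pid}_{modality}.nii.gz"
                nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), path)
            for s in group:
                entries.append({
                    "patient_id": pid, "slice_index": s.slice_index,
                    "ct_path": f"{pid}_ct.nii.gz", "adc_path": f"{pid}_adc.nii.gz",
                })
    else:
        for s in slices:
            paths = {}
            for modality in ("ct", "adc"):
                arr = np.clip(getattr(s, modality), 0, 1)
                img = np.round(arr * 255).astype(np.uint8)
                name = f"{s.patient_id}_{s.slice_index:03d}_{modality}.png"
                iio.imwrite(directory / name, img)
                paths[f"{modality}_path"] = name
            entries.append({"patient_id": s.patient_id,
                            "slice_index": s.slice_index, **paths})
    manifest = {"format": fmt, "slices": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
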