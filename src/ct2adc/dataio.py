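"""Readers, writers, normalisation and run configuration.

Datasets live on disk as per-patient NIfTI volumes (axial slices along the
last axis) or per-slice 8-bit grayscale PNGs, indexed by a JSON manifest.
Intensities are min-max normalised per volume to [0, 1]; the affine map to
the model's [-1, 1] domain happens in the training/inference code.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import yaml

from .phantom import PairedSlice, PhantomSpec
from .training import TrainConfig

__all__ = ["load_slices", "load_paired_dataset", "RunConfig",
           "load_run_config", "save_run_config"]

CONFIG_VERSION = 1


def _minmax01(vol: np.ndarray) -> np.ndarray:
    vol = np.asarray(vol, dtype=float)
    lo, hi = vol.min(), vol.max()
    if hi == lo:
        return np.zeros_like(vol)
    return (vol - lo) / (hi - lo)


def load_slices(path, modality: str | None = None):
    """Load one modality's slices from a dataset directory.

    Returns ``{patient_id: [2-D arrays]}`` with per-volume min-max
    normalisation to [0, 1].  ``modality`` is 'ct' or 'adc'.
    """
    if modality not in ("ct", "adc"):
        raise ValueError("modality must be 'ct' or 'adc'")
    return _load_modality(Path(path), modality)


def _load_modality(directory: Path, modality: str):
    import nibabel as nib

    manifest = _read_manifest(directory)
    out: dict[str, list[np.ndarray]] = {}
    if manifest["format"] == "nifti":
        seen = set()
        for e in manifest["slices"]:
            pid = e["patient_id"]
            if pid in seen:
                continue
            seen.add(pid)
            vol = np.asarray(
                nib.load(directory / e[f"{modality}_path"]).get_fdata())
            vol = _minmax01(vol)
            out[pid] = [vol[:, :, i] for i in range(vol.shape[-1])]
    else:
        import imageio.v3 as iio

        per_patient: dict[str, list] = {}
        for e in manifest["slices"]:
            per_patient.setdefault(e["patient_id"], []).append(e)
        for pid, entries in per_patient.items():
            entries = sorted(entries, key=lambda e: e["slice_index"])
            arrs = [np.asarray(iio.imread(directory / e[f"{modality}_path"]),
                               dtype=float) for e in entries]
            vol = np.stack(arrs, axis=-1)
            vol = _minmax01(vol)
            out[pid] = [vol[:, :, i] for i in range(vol.shape[-1])]
    return out


def _read_manifest(directory: Path) -> dict:
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    return json.loads(mpath.read_text())


def load_paired_dataset(path) -> list[PairedSlice]:
    """Load paired CT/ADC slices from a written dataset directory.

    Raises a pairing error naming the patient when the two modalities have
    different slice counts.
    """
    directory = Path(path)
    ct = _load_modality(directory, "ct")
    adc = _load_modality(directory, "adc")
    slices = []
    for pid in sorted(ct):
        if pid not in adc:
            raise ValueError(f"patient {pid}: CT volume present but no ADC")
        if len(ct[pid]) != len(adc[pid]):
            raise ValueError(
                f"patient {pid}: {len(ct[pid])} CT slices but "
                f"{len(adc[pid])} ADC slices"
            )
        for i, (c, a) in enumerate(zip(ct[pid], adc[pid])):
            slices.append(PairedSlice(ct=c, adc=a, patient_id=pid,
                                      slice_index=i))
    return slices


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class RunConfig:
    """Composed configuration: training settings, phantom spec, data paths
    and evaluation options.  Unknown keys are rejected; round-trips through
    YAML unchanged."""

    def __init__(self, train: TrainConfig | None = None,
                 phantom: PhantomSpec | None = None,
                 data_dir: str | None = None, out_dir: str | None = None,
                 split: tuple[int, int, int] | None = None,
                 n_boot: int = 10000, version: int = CONFIG_VERSION):
        if version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {version}")
        self.train = train or TrainConfig()
        self.phantom = phantom or PhantomSpec()
        self.data_dir = data_dir
        self.out_dir = out_dir
        self.split = tuple(split) if split is not None else None
        self.n_boot = n_boot
        self.version = CONFIG_VERSION

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "train": asdict(self.train),
            "phantom": asdict(self.phantom),
            "data_dir": self.data_dir,
            "out_dir": self.out_dir,
            "split": list(self.split) if self.split else None,
            "n_boot": self.n_boot,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"version", "train", "phantom", "data_dir", "out_dir",
                 "split", "n_boot"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        train_d = d.get("train") or {}
        bad = set(train_d) - {f.name for f in fields(TrainConfig)}
        if bad:
            raise ValueError(f"unknown train config keys: {sorted(bad)}")
        phantom_d = d.get("phantom") or {}
        bad = set(phantom_d) - {f.name for f in fields(PhantomSpec)}
        if bad:
            raise ValueError(f"unknown phantom config keys: {sorted(bad)}")
        return cls(train=TrainConfig(**train_d), phantom=PhantomSpec(**phantom_d),
                   data_dir=d.get("data_dir"), out_dir=d.get("out_dir"),
                   split=d.get("split"), n_boot=d.get("n_boot", 10000),
                   version=d.get("version", CONFIG_VERSION))


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
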