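"""NIfTI / CSV / YAML input-output and run configuration.

Voxel indices are 0-based internally; the NIfTI affine governs world
coordinates.  Masks must live on the same grid as the images they index
— a grid mismatch is an error, never silently resampled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dce_kinetics import AIFModel, DEFAULT_R1_RELAXIVITY
from .phantom import CohortSpec, SequenceSpec

#: in-plane 0.273 mm, slice 1.5 mm — the protocol's DCE resolution
DEFAULT_VOXEL_SIZE = (0.273, 0.273, 1.5)


def default_affine(voxel_size=DEFAULT_VOXEL_SIZE) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None,
               units: str | None = None) -> None:
    if affine is None:
        affine = default_affine()
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    if units:
        img.header["descrip"] = units.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def check_same_grid(shape_a, shape_b, context: str = "") -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"grid mismatch {context}: "
                         f"{tuple(shape_a)} vs {tuple(shape_b)}")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, YAML round-trippable."""

    seed: int = 0
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    aif: dict = field(default_factory=dict)       # overrides of AIFModel
    r1_relaxivity: float = DEFAULT_R1_RELAXIVITY
    noise_sigma: float = 0.0
    phantom_shape: tuple = (32, 32, 4)
    tumour_radius: float = 6.0
    fix_vp: float | None = None
    qc_rss_percentile: float = 100.0
    cohorts: tuple = (1, 2)
    n_per_group: int = 5

    def make_aif(self):
        from .phantom import default_aif
        return default_aif(self.sequence, **self.aif)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sequence"] = asdict(self.sequence)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sequence" in d and isinstance(d["sequence"], dict):
            seq = dict(d["sequence"])
            for key in ("t1map_trs", "b_values"):
                if key in seq:
                    seq[key] = tuple(seq[key])
            d["sequence"] = SequenceSpec(**seq)
        for key in ("phantom_shape", "cohorts"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        canon = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _listify(obj):
    """Tuples -> lists so YAML/JSON round-trips compare equal."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    return obj


def load_aif_yaml(path) -> AIFModel:
    return AIFModel(**yaml.safe_load(Path(path).read_text()))


def write_provenance(path, config: RunConfig) -> None:
    from . import __version__
    payload = dict(config_sha256=config.digest(), seed=config.seed,
                   software="dcequant", version=__version__,
                   config=_listify(config.to_dict()))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
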