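"""Voxelwise pipeline: 4D volumes -> parameter maps -> ROI values.

Each masked voxel's 80-odd per-volume signals are powder-averaged into
shells and fitted independently with the gamma model; unmasked or failed
voxels carry NaN. Spatial metadata (affine) passes through unchanged, no
reorientation is performed, and voxel indices are 0-based.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .encoding import EncodingScheme
from .gamma import FitConfig, GammaDiffusionModel
from .powder import PowderShells

__all__ = [
    "VolumeSet",
    "ParameterMaps",
    "fit_volume",
    "extract_roi",
    "default_mask",
    "TISSUE_CLASSES",
]

#: Closed set of tissue-class labels used in group statistics.
TISSUE_CLASSES = ("G3+3", "G3+4", "G4+3", "PZ", "TZ")

MAP_NAMES = ("s0", "md", "mk_i", "mk_a")
MAP_UNITS = {"s0": "signal", "md": "um^2/ms", "mk_i": "1", "mk_a": "1"}


@dataclass
class VolumeSet:
    """4D signal array (x, y, z, volume) with affine, aligned to a scheme."""

    data: np.ndarray
    affine: np.ndarray
    scheme: EncodingScheme

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("signal array must be 4D (x, y, z, volume)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must equal the scheme "
                f"entry count ({len(self.scheme)})"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        voxdim = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        if np.any(voxdim <= 0):
            raise ValueError("voxel dimensions must be positive")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @classmethod
    def from_nifti(cls, path, scheme: EncodingScheme) -> "VolumeSet":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine, scheme)


@dataclass
class ParameterMaps:
    """Voxelwise gamma-fit output: one 3D map per parameter plus diagnostics.

    Non-fitted voxels hold NaN; ``converged`` is 1 where the solver reported
    convergence, 0 where it did not, NaN outside the mask.
    """

    maps: dict
    affine: np.ndarray
    converged: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def spatial_shape(self) -> tuple:
        return self.maps["md"].shape

    def write(self, outdir) -> None:
        """One NIfTI per parameter plus a shared sidecar JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in MAP_NAMES:
            nib.save(nib.Nifti1Image(self.maps[name].astype(np.float64), self.affine), outdir / f"{name}.nii")
        nib.save(nib.Nifti1Image(self.converged.astype(np.float64), self.affine), outdir / "converged.nii")
        cfg = asdict(self.config)
        cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
        sidecar = {
            "software": "dividemri",
            "version": __version__,
            "units": MAP_UNITS,
            "missing_value": "NaN",
            "config": cfg,
            "config_hash": cfg_hash,
        }
        (outdir / "maps.json").write_text(json.dumps(sidecar, indent=2, default=str))

    @classmethod
    def read(cls, indir) -> "ParameterMaps":
        indir = Path(indir)
        maps = {}
        affine = None
        for name in MAP_NAMES:
            img = nib.load(str(indir / f"{name}.nii"))
            maps[name] = np.asanyarray(img.dataobj)
            affine = img.affine
        conv = np.asanyarray(nib.load(str(indir / "converged.nii")).dataobj)
        return cls(maps=maps, affine=affine, converged=conv)


def default_mask(volumes: VolumeSet, rel_threshold: float = 0.02) -> np.ndarray:
    """Foreground mask: mean lowest-b-shell signal above a relative floor.

    Voxels below ``rel_threshold`` times the volume maximum of that mean are
    skipped — at low signal-to-noise the fit produces spuriously high
    kurtosis, so near-empty voxels are not worth fitting.
    """
    shells = volumes.scheme.shells()
    bmin = min(b for b, _, _ in shells)
    idx = sorted({i for b, _, ix in shells if b == bmin for i in ix})
    low = volumes.data[..., idx].mean(axis=3)
    return low > rel_threshold * low.max()


def fit_volume(
    volumes: VolumeSet,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> ParameterMaps:
    """Powder-average and gamma-fit every masked voxel independently."""
    config = config or FitConfig()
    shape = volumes.spatial_shape
    if mask is None:
        mask = default_mask(volumes)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} must match spatial grid {shape}")

    # shell structure is identical across voxels: precompute index lists
    shell_rows = volumes.scheme.shells()
    b = np.array([r[0] for r in shell_rows])
    bd = np.array([r[1] for r in shell_rows])
    idx_lists = [np.array(r[2]) for r in shell_rows]
    n_dirs = np.array([len(ix) for ix in idx_lists])

    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    converged = np.full(shape, np.nan)
    for vox in np.argwhere(mask):
        vox = tuple(vox)
        sig = volumes.data[vox]
        means = np.array([sig[ix].mean() for ix in idx_lists])
        sds = np.array(
            [sig[ix].std(ddof=1) if len(ix) > 1 else 0.0 for ix in idx_lists]
        )
        shells = PowderShells.from_arrays(b, bd, means, n_dirs, sds)
        res = GammaDiffusionModel(shells).fit(config)
        for name in MAP_NAMES:
            maps[name][vox] = res.params[name]
        converged[vox] = float(res.converged)
    return ParameterMaps(maps=maps, affine=volumes.affine.copy(), converged=converged, config=config)


def extract_roi(
    maps: ParameterMaps,
    labels: np.ndarray,
    label_map: dict,
    statistic: str = "median",
) -> pd.DataFrame:
    """Per-ROI summary of each parameter map.

    Parameters
    ----------
    labels : 3D int array
        ROI id per voxel on the map grid (0 = outside every ROI).
    label_map : dict
        ROI id -> tissue class (one of ``TISSUE_CLASSES``). Every nonzero id
        present in ``labels`` must be mapped.
    statistic : "median" or "mean"
        Reduction over the ROI's fitted (non-NaN) voxels. The median is the
        default to match the group-level median tests.

    Returns a tidy table ``roi_id, class, parameter, value, n_voxels``; ROIs
    with no fitted voxels are kept with NaN value and n_voxels = 0.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.spatial_shape:
        raise ValueError("label volume must be on the map grid")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    ids = [int(i) for i in np.unique(labels) if i != 0]
    missing = [i for i in ids if i not in label_map]
    if missing:
        raise KeyError(f"label ids missing from label_map: {missing}")
    for i, cls in label_map.items():
        if cls not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {cls!r} for ROI {i}")
    reduce = np.nanmedian if statistic == "median" else np.nanmean
    param_of = {"md": "MD", "mk_i": "MK_I", "mk_a": "MK_A"}
    rows = []
    for roi in ids:
        m = labels == roi
        for key, pname in param_of.items():
            vals = maps[key][m]
            n = int(np.isfinite(vals).sum())
            value = float(reduce(vals)) if n else float("nan")
            rows.append((roi, label_map[roi], pname, value, n))
    return pd.DataFrame(rows, columns=["roi_id", "class", "parameter", "value", "n_voxels"])
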