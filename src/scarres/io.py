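"""Cohort persistence: HDF5 (primary) and NIfTI (interoperability).

HDF5 layout: one group per volume (``volume_000`` ...), one subgroup per
slice with datasets ``image_real``, ``image_imag`` (float32) and
``gt_myo``/``gt_scar``/``remote_roi`` (uint8); file attributes carry the
pixel spacing, the seed and a YAML dump of the generating config.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import yaml

from .phantom import PhantomCohort, PhantomConfig, PhantomSlice

__all__ = ["save_cohort", "load_cohort", "export_nifti"]


def save_cohort(cohort: PhantomCohort, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["pixel_mm"] = cohort.config.pixel_mm
        f.attrs["seed"] = cohort.config.seed
        f.attrs["config_yaml"] = yaml.safe_dump(
            dataclasses.asdict(cohort.config)
        )
        for s in cohort.slices:
            g = f.require_group(f"volume_{s.volume_id:03d}")
            sg = g.create_group(f"slice_{s.slice_id:03d}")
            sg.create_dataset("image_real", data=s.image.real.astype(np.float32))
            sg.create_dataset("image_imag", data=s.image.imag.astype(np.float32))
            sg.create_dataset("gt_myo", data=s.gt_myo.astype(np.uint8))
            sg.create_dataset("gt_scar", data=s.gt_scar.astype(np.uint8))
            sg.create_dataset("remote_roi", data=s.remote_roi.astype(np.uint8))
            sg.attrs["effective_dx_mm"] = s.effective_dx_mm


def load_cohort(path) -> PhantomCohort:
    path = Path(path)
    with h5py.File(path, "r") as f:
        cfg_dict = yaml.safe_load(f.attrs["config_yaml"])
        for key in ("slices_per_volume", "wall_ratio_range"):
            if isinstance(cfg_dict.get(key), list):
                cfg_dict[key] = tuple(cfg_dict[key])
        config = PhantomConfig(**cfg_dict)
        slices = []
        for vname in sorted(f.keys()):
            vid = int(vname.split("_")[1])
            for sname in sorted(f[vname].keys()):
                sg = f[vname][sname]
                sid = int(sname.split("_")[1])
                image = sg["image_real"][...].astype(float) + 1j * sg[
                    "image_imag"
                ][...].astype(float)
                slices.append(
                    PhantomSlice(
                        image=image,
                        gt_myo=sg["gt_myo"][...].astype(bool),
                        gt_scar=sg["gt_scar"][...].astype(bool),
                        remote_roi=sg["remote_roi"][...].astype(bool),
                        pixel_mm=float(f.attrs["pixel_mm"]),
                        volume_id=vid,
                        slice_id=sid,
                        effective_dx_mm=float(sg.attrs["effective_dx_mm"]),
                    )
                )
    return PhantomCohort(slices=tuple(slices), config=config)


def export_nifti(cohort: PhantomCohort, outdir) -> list[Path]:
    """Write per-volume magnitude image + multi-label mask NIfTI pairs.

    Labels: 0 background, 1 healthy myocardium, 2 scar; the remote ROI
    is exported as label 3 overlayed on healthy myocardium.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    px = cohort.config.pixel_mm
    affine = np.diag([px, px, 1.0, 1.0])
    for vid in cohort.volume_ids():
        vol = cohort.by_volume(vid)
        mag = np.stack([np.abs(s.image) for s in vol], axis=-1)
        lab = np.zeros(mag.shape, dtype=np.uint8)
        for k, s in enumerate(vol):
            lab[..., k][s.gt_myo] = 1
            lab[..., k][s.gt_scar] = 2
            lab[..., k][s.remote_roi & ~s.gt_scar] = 3
        img_path = outdir / f"volume_{vid:03d}_mag.nii"
        lab_path = outdir / f"volume_{vid:03d}_labels.nii"
        nib.save(nib.Nifti1Image(mag.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(lab, affine), lab_path)
        written += [img_path, lab_path]
    return written
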