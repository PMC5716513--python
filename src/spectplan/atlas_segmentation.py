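"""Atlas-based CT organ segmentation by label propagation.

A template CT of a representative patient with expert-delineated structures
(the atlas) is deformably registered to a new subject CT; the resulting
displacement field then warps each binary structure onto the subject grid,
producing an automated segmentation.  The subject is registered as the fixed
image, so the field directly pulls atlas labels onto the subject grid without
field inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .demons import (DemonsParams, DisplacementField, register_deformable,
                     warp_mask_fractional)
from .imaging_core import LabelMask, Volume
from .preprocessing import anisotropic_diffusion, histogram_match


@dataclass
class Atlas:
    """Template CT plus its named binary structure masks."""

    ct: Volume
    structures: dict

    def __post_init__(self):
        if not self.structures:
            raise ValueError("atlas has no structures")
        for name, mask in self.structures.items():
            if not isinstance(mask, LabelMask):
                raise TypeError(f"structure {name!r} is not a LabelMask")
            if not mask.same_grid(self.ct):
                raise ValueError(f"structure {name!r} is not on the atlas CT grid")
        names = list(self.structures)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.array_equal(self.structures[a].data,
                                  self.structures[b].data):
                    raise ValueError(f"structures {a!r} and {b!r} are identical")


@dataclass
class SegmentationResult:
    masks: dict
    displacement: DisplacementField
    log: pd.DataFrame
    preprocessing: dict = field(default_factory=dict)


def segment_with_atlas(atlas: Atlas, subject_ct: Volume,
                       params: DemonsParams | None = None,
                       diffusion: dict | None = None,
                       matching: dict | None = None) -> SegmentationResult:
    """Segment a subject CT by propagating atlas structures.

    Pipeline: Perona–Malik diffusion of both CTs, histogram matching of the
    atlas onto the subject, diffeomorphic demons registration with the
    subject fixed, then per-structure mask warping.  Where independently
    warped structures overlap, the voxel is assigned to the structure with
    the largest interpolated pre-threshold value (ties go to the structure
    listed first).  An empty output mask raises a warning — the structure was
    lost by the registration — but does not abort.
    """
    params = params or DemonsParams()
    diffusion = dict(diffusion or {})
    matching = dict(matching or {})
    diff_on = diffusion.pop("enabled", True)
    match_on = matching.pop("enabled", True)

    subj = anisotropic_diffusion(subject_ct, **diffusion) if diff_on \
        else subject_ct
    atl = anisotropic_diffusion(atlas.ct, **diffusion) if diff_on else atlas.ct
    if match_on:
        atl = histogram_match(atl, subj, **matching)

    fld, log = register_deformable(fixed=subj, moving=atl, params=params)

    names = list(atlas.structures)
    fractional = np.stack(
        [warp_mask_fractional(atlas.structures[n], fld).data for n in names])
    binary = fractional >= 0.5
    multi = binary.sum(axis=0) > 1
    if np.any(multi):
        winner = np.argmax(fractional, axis=0)  # stable: first wins ties
        for i in range(len(names)):
            binary[i][multi & (winner != i)] = False
    masks = {}
    for i, name in enumerate(names):
        m = LabelMask(binary[i].astype(np.uint8), subject_ct.spacing,
                      subject_ct.origin)
        if m.count() == 0:
            warnings.warn(f"structure {name!r} was lost during propagation "
                          "(empty warped mask)", stacklevel=2)
        masks[name] = m
    return SegmentationResult(masks, fld, log,
                              {"diffusion": diff_on, "histogram_match": match_on})


# ---------------------------------------------------------------------------
# Atlas package on disk: directory with atlas_ct.nii.gz, structures/<name>.nii.gz
# and an atlas.yaml manifest listing the structure names in order.

def save_atlas(atlas: Atlas, directory) -> Path:
    directory = Path(directory)
    (directory / "structures").mkdir(parents=True, exist_ok=True)
    io.write_volume(atlas.ct, directory / "atlas_ct.nii.gz")
    for name, mask in atlas.structures.items():
        io.write_mask(mask, directory / "structures" / f"{name}.nii.gz")
    manifest = {"structures": list(atlas.structures)}
    (directory / "atlas.yaml").write_text(yaml.safe_dump(manifest))
    return directory


def load_atlas(directory) -> Atlas:
    directory = Path(directory)
    manifest_path = directory / "atlas.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no atlas.yaml manifest in {directory}")
    manifest = yaml.safe_load(manifest_path.read_text())
    ct = io.read_volume(directory / "atlas_ct.nii.gz")
    structures = {}
    for name in manifest["structures"]:
        structures[name] = io.read_mask(directory / "structures" / f"{name}.nii.gz")
    return Atlas(ct, structures)
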