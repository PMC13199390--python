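"""Region-level reduction of voxel abnormality maps.

Each subject's sparse lesion z-map is reduced to one median abnormality per
(marker, region) over the extended parcellation, plus a log-transformed
regional lesion volume. Regions with fewer than 5 lesion voxels are imputed
as 0 (no lesion-related abnormality) and flagged. Markers whose lesion effect
is negative (FA, ICVF, OD) are sign-inverted so that larger values always
mean worse pathophysiology. With the canonical 7-marker panel and 3 regions
this yields 24 features per subject (8 measures x 3 regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import LABEL_WMH, NEGATIVE_MARKERS

MIN_REGION_VOXELS = 5


@dataclass
class ROIFeatureMatrix:
    """Subjects x (region x measure) feature table.

    Columns are region-major, measure-minor: for each region, the marker
    medians (inverted markers already sign-flipped) followed by the log
    regional WMH volume. ``imputed`` flags entries set to 0 by the
    minimum-voxel rule.
    """

    data: pd.DataFrame  # index: subject id
    imputed: pd.DataFrame  # bool, same shape
    markers: tuple
    regions: tuple
    inverted_markers: tuple = NEGATIVE_MARKERS

    @property
    def measures(self) -> tuple:
        return tuple(self.markers) + ("logvol",)

    def region_columns(self, region: int, include_volume: bool = False):
        cols = [f"{m}_region{region}" for m in self.markers]
        if include_volume:
            cols.append(f"logvol_region{region}")
        return cols

    def region_block(self, region: int) -> pd.DataFrame:
        """Marker medians of one region (staging input; volume excluded)."""
        return self.data[self.region_columns(region)]

    def volume_columns(self):
        return [f"logvol_region{r}" for r in self.regions]


def extract_roi_features(
    abnormality_map,
    label_volume: np.ndarray,
    parcellation,
    voxel_volume: float = 1.0,
    markers=None,
) -> tuple[pd.Series, pd.Series]:
    """One subject's (region x measure) feature row plus imputation flags.

    Median abnormality per marker within the subject's WMH voxels of each
    region; regions with < 5 WMH voxels have all marker medians imputed as 0.
    Regional volume = voxel count x voxel volume, log(x + 1)-transformed so
    lesion-free subjects are defined. FA/ICVF/OD medians are sign-inverted.
    """
    labels = parcellation.labels if hasattr(parcellation, "labels") else np.asarray(parcellation)
    if labels.shape != label_volume.shape:
        raise ValueError("parcellation grid does not match subject label volume")
    markers = tuple(markers or abnormality_map.markers)
    regions = tuple(int(r) for r in np.unique(labels) if r > 0)
    region_of_voxel = labels.ravel()
    am_regions = region_of_voxel[abnormality_map.flat_indices]
    wmh_flat = label_volume.ravel() == LABEL_WMH

    values, flags = {}, {}
    for r in regions:
        n_vox = int(np.sum(wmh_flat & (region_of_voxel == r)))
        impute = n_vox < MIN_REGION_VOXELS
        rows = am_regions == r
        for j, m in enumerate(markers):
            col = f"{m}_region{r}"
            if impute or not rows.any():
                values[col] = 0.0
                flags[col] = True
            else:
                med = float(np.median(abnormality_map.z[rows, j]))
                values[col] = -med if m in NEGATIVE_MARKERS else med
                flags[col] = False
        vcol = f"logvol_region{r}"
        values[vcol] = float(np.log(n_vox * voxel_volume + 1.0))
        flags[vcol] = False
    name = abnormality_map.subject_id
    return pd.Series(values, name=name), pd.Series(flags, name=name)


def assemble_feature_matrix(
    abnormality_maps,
    label_volumes,
    parcellation,
    voxel_volume: float = 1.0,
    markers=None,
) -> ROIFeatureMatrix:
    """Stack per-subject feature rows into the cohort feature matrix."""
    if len(abnormality_maps) != len(label_volumes):
        missing = {am.subject_id for am in abnormality_maps}
        raise ValueError(f"abnormality maps and label volumes misaligned: {sorted(missing)[:5]}...")
    markers = tuple(markers or abnormality_maps[0].markers)
    labels = parcellation.labels if hasattr(parcellation, "labels") else np.asarray(parcellation)
    regions = tuple(int(r) for r in np.unique(labels) if r > 0)
    rows, frows = [], []
    for am, sv in zip(abnormality_maps, label_volumes):
        lab = sv.label_volume if hasattr(sv, "label_volume") else sv
        v, f = extract_roi_features(am, lab, parcellation, voxel_volume, markers)
        rows.append(v)
        frows.append(f)
    data = pd.DataFrame(rows)
    data.index.name = "id"
    # enforce region-major, measure-minor column order
    cols = [f"{m}_region{r}" for r in regions for m in list(markers) + ["logvol"]]
    data = data[cols]
    imputed = pd.DataFrame(frows)[cols]
    return ROIFeatureMatrix(data=data, imputed=imputed, markers=markers, regions=regions)
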