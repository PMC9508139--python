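"""Plasma metabolome preprocessing: plate normalization, imputation, coding.

Raw inputs are mass-spectrometry peak areas measured on instrument plates
(nominally 144 samples each).  Processing follows three steps:

1. per metabolite and plate, detected peak areas are divided by the plate
   median of detected values (removes plate-level instrument drift);
2. metabolites with fewer than ``min_measured`` detected measurements are
   dropped; undetected entries of retained non-drug metabolites are imputed
   with the metabolite's global minimum observed normalized value;
3. non-drug metabolites are ln(1+x) transformed; drug metabolites are coded
   binary (1 = detected, 0 = not detected).

Metabolites unmeasured in a delivery batch stay missing (NaN) for those
samples; downstream analyses take complete cases per pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["name", "class", "subclass", "is_drug", "batches_measured"]


@dataclass
class RawMetabolitePlates:
    """Raw peak-area data and detection flags per sample and metabolite.

    ``areas``: samples x metabolites positive peak areas (NaN where
    undetected or unmeasured); ``detected``: boolean frame of the same shape;
    ``measured``: boolean frame, False where a sample's delivery batch did not
    measure the metabolite; ``plate``: per-sample instrument-plate label;
    ``annotations``: per-metabolite frame with ``ANNOTATION_COLUMNS``.
    """

    areas: pd.DataFrame
    detected: pd.DataFrame
    plate: pd.Series
    annotations: pd.DataFrame
    measured: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.measured is None:
            self.measured = pd.DataFrame(
                True, index=self.areas.index, columns=self.areas.columns
            )
        det = self.detected.to_numpy()
        if np.any(~np.isfinite(self.areas.to_numpy()[det])):
            raise ValueError("detected entries must carry a finite peak area")
        if np.any(self.areas.to_numpy()[det] <= 0):
            raise ValueError("detected peak areas must be positive")


def normalize_plates(raw: RawMetabolitePlates) -> RawMetabolitePlates:
    """Divide detected peak areas by their plate median, per metabolite.

    The median is taken over detected values only (undetected entries carry no
    peak area).  A metabolite with zero detected values on a plate where it
    was measured is left undetected there with a warning.
    """
    values = raw.areas.copy()
    det = raw.detected
    for plate_id, idx in raw.areas.groupby(raw.plate).groups.items():
        block = values.loc[idx]
        block_det = det.loc[idx]
        med = block.where(block_det).median(axis=0)
        missing = med.isna() & raw.measured.loc[idx].any(axis=0)
        if missing.any():
            warnings.warn(
                f"plate {plate_id}: {int(missing.sum())} metabolites have no "
                "detected values; left undetected"
            )
        values.loc[idx] = block.div(med, axis=1)
    values = values.where(det)
    return RawMetabolitePlates(
        areas=values,
        detected=det.copy(),
        plate=raw.plate.copy(),
        annotations=raw.annotations.copy(),
        measured=raw.measured.copy(),
    )


@dataclass
class MetaboliteMatrix:
    """Analysis-ready metabolite matrix.

    ``values``: samples x metabolites; ln(1+normalized) for non-drug columns,
    {0, 1} for drug columns, NaN where unmeasured.  ``normalized`` retains the
    pre-log normalized scale (imputed, used for derived ratio outcomes).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    normalized: pd.DataFrame
    retained: list[str] = field(default_factory=list)

    @property
    def drug_columns(self) -> list[str]:
        flags = self.annotations["is_drug"].astype(bool)
        return [m for m in self.values.columns if flags.get(m, False)]


def impute_and_code(
    normalized: RawMetabolitePlates, min_measured: int = 100
) -> MetaboliteMatrix:
    """Measurement-count filter, minimum-value imputation and final coding."""
    if min_measured > len(normalized.areas):
        raise ValueError("min_measured exceeds the number of samples")
    det_counts = normalized.detected.sum(axis=0)
    retained = det_counts[det_counts >= min_measured].index.tolist()
    logger.info(
        "measurement filter kept %d / %d metabolites",
        len(retained), normalized.areas.shape[1],
    )
    ann = normalized.annotations.loc[retained]
    is_drug = ann["is_drug"].astype(bool)

    values = pd.DataFrame(index=normalized.areas.index, columns=retained, dtype=float)
    norm_scale = pd.DataFrame(index=normalized.areas.index, columns=retained, dtype=float)
    for m in retained:
        measured = normalized.measured[m]
        if is_drug[m]:
            v = normalized.detected[m].astype(float).where(measured)
            values[m] = v
            norm_scale[m] = v
            continue
        col = normalized.areas[m].copy()
        fill = col.min()  # global minimum observed normalized value
        col = col.fillna(fill).where(measured)
        norm_scale[m] = col
        values[m] = np.log1p(col)
    return MetaboliteMatrix(
        values=values, annotations=ann, normalized=norm_scale, retained=retained
    )


def process_metabolites(
    raw: RawMetabolitePlates, min_measured: int = 100
) -> MetaboliteMatrix:
    """Full preprocessing chain: normalize, filter, impute, code."""
    return impute_and_code(normalize_plates(raw), min_measured=min_measured)
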