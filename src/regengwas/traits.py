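"""Trait extraction from semantic segmentation masks.

Each mask labels every pixel as background, unregenerated stem, callus or
shoot. The two per-timepoint traits are the proportion of total plant area
(stem + callus + shoot; background excluded) occupied by callus ("callus
area") and by shoot ("shoot area"). A mask with no plant pixels yields an
explicit missing value, never zero, so that downstream zero-inflation
handling is not biased by imaging failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_CLASS_MAP


@dataclass
class SegmentationMask:
    """2-D integer label grid with a class map over the four tissue classes."""

    labels: np.ndarray
    class_map: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D grid")
        known = set(self.class_map)
        present = set(np.unique(self.labels).tolist())
        if not present <= known:
            raise ValueError(f"unknown mask labels: {sorted(present - known)}")

    def _code(self, name: str) -> int:
        for code, cls in self.class_map.items():
            if cls == name:
                return code
        raise KeyError(f"class {name!r} absent from class_map")


def mask_class_proportions(mask: SegmentationMask):
    """(callus_area, shoot_area) as fractions of plant pixels.

    Plant pixels are stem + callus + shoot. Returns (nan, nan) when the mask
    contains no plant pixel (missing observation, not zero regeneration).
    """
    lab = mask.labels
    n_stem = int(np.count_nonzero(lab == mask._code("stem")))
    n_callus = int(np.count_nonzero(lab == mask._code("callus")))
    n_shoot = int(np.count_nonzero(lab == mask._code("shoot")))
    n_plant = n_stem + n_callus + n_shoot
    if n_plant == 0:
        return (float("nan"), float("nan"))
    return (n_callus / n_plant, n_shoot / n_plant)


def traits_from_masks(masks, meta: pd.DataFrame) -> pd.DataFrame:
    """Build a replicate-level trait table from masks plus metadata rows.

    ``meta`` must align row-for-row with ``masks`` and provide genotype_id,
    replicate and timepoint (extra columns such as diameter/phase pass
    through).
    """
    if len(masks) != len(meta):
        raise ValueError("masks and metadata rows must align")
    props = [mask_class_proportions(m) for m in masks]
    out = meta.reset_index(drop=True).copy()
    out["callus_area"] = [p[0] for p in props]
    out["shoot_area"] = [p[1] for p in props]
    return out


TRAIT_COLUMNS = ("callus_area", "shoot_area")


def merge_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype trait table: mean over replicates within genotype x timepoint.

    With two replicates the arithmetic mean is taken; a single (or single
    non-missing) replicate passes through unchanged; the merged value is
    missing only when every replicate is missing. Idempotent on already
    merged tables. Covariates (diameter, phase) take their first non-missing
    value within the group.
    """
    need = {"genotype_id", "timepoint"}
    if not need <= set(table.columns):
        raise ValueError(f"trait table must carry columns {sorted(need)}")
    traits = [c for c in TRAIT_COLUMNS if c in table.columns]
    extras = [c for c in table.columns
              if c not in traits and c not in ("genotype_id", "replicate", "timepoint")]
    agg = {c: "mean" for c in traits}
    agg.update({c: "first" for c in extras})
    merged = (table.groupby(["genotype_id", "timepoint"], sort=True)
              .agg(agg).reset_index())
    merged.insert(1, "replicate", 0)  # 0 marks a replicate-merged row
    return merged[["genotype_id", "replicate", "timepoint"] + traits + extras]
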