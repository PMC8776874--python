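"""Channel normalization, ROI combination, and strided voxel sampling.

Four co-registered channels per subject — CE-T1WI, FLAIR, MTRasym(3.0 ppm)
and ADC — are z-score normalized per subject within the brain mask (so
scanner and protocol scale differences cancel), the three mutually exclusive
tumor ROIs are combined into one tumor mask, and the clustering feature
matrix is drawn from every stride-aligned voxel (default every 4x4x4 = 64
voxels) of the whole-brain mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed channel order used everywhere in the package.
CHANNEL_NAMES = ("ce_t1wi", "flair", "mtr_asym", "adc")
N_CHANNELS = len(CHANNEL_NAMES)
ADC_CHANNEL = CHANNEL_NAMES.index("adc")

IDH_MUTANT = "mutant"
IDH_WILDTYPE = "wildtype"


@dataclass
class SubjectStack:
    """One subject's four co-registered channel volumes, masks, and status.

    channels is a ``(4, x, y, z)`` array in :data:`CHANNEL_NAMES` order.
    ADC values are ingested as-is (any consistent unit) because z-scoring
    cancels the unit; ``metadata`` may record the source unit.
    """

    subject_id: str
    channels: np.ndarray
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    idh_status: Optional[str] = None
    age: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        if self.channels.ndim != 4 or self.channels.shape[0] != N_CHANNELS:
            raise ValueError(
                f"channels must have shape (4, x, y, z), got {self.channels.shape}"
            )
        shape = self.channels.shape[1:]
        if self.brain_mask.shape != shape or self.tumor_mask.shape != shape:
            raise ValueError("masks must match the channel spatial shape")
        outside = self.tumor_mask & ~self.brain_mask
        if outside.any():
            raise ValueError(
                f"tumor mask has {int(outside.sum())} voxels outside the brain mask"
            )
        if self.idh_status is not None and self.idh_status not in (IDH_MUTANT, IDH_WILDTYPE):
            raise ValueError(f"unknown IDH status {self.idh_status!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]


@dataclass
class FeatureMatrix:
    """Sampled voxel features: ``X`` is (n_rows, 4); provenance maps each
    row back to (subject_id, i, j, k)."""

    X: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_CHANNELS:
            raise ValueError("X must be (n_rows, 4)")
        if len(self.provenance) != len(self.X):
            raise ValueError("provenance length must match X")

    def __len__(self) -> int:
        return len(self.X)


def zscore_channel(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score one channel within a mask (population sd); NaN outside.

    Raises on fewer than 2 masked voxels, zero variance, or NaN values
    inside the mask.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    vals = volume[mask]
    if vals.size < 2:
        raise ValueError(f"mask has {vals.size} voxels; need >= 2 to z-score")
    n_bad = int(np.sum(~np.isfinite(vals)))
    if n_bad:
        raise ValueError(f"{n_bad} non-finite voxels inside the mask")
    sd = vals.std()  # population sd (ddof=0)
    if sd == 0:
        raise ValueError("channel is constant within the mask (zero variance)")
    out = np.full(volume.shape, np.nan)
    out[mask] = (vals - vals.mean()) / sd
    return out


def normalize_stack(stack: SubjectStack) -> SubjectStack:
    """Z-score every channel of a stack within its brain mask.

    Voxels with an undefined channel value (e.g. MTRasym masked out by the
    CEST stage) are excluded from the normalization statistics and remain
    NaN, so they are skipped by sampling and label assignment downstream.
    """
    channels = np.empty_like(stack.channels)
    for c in range(N_CHANNELS):
        finite = stack.brain_mask & np.isfinite(stack.channels[c])
        dropped = int(stack.brain_mask.sum() - finite.sum())
        if dropped:
            logger.info("subject %s channel %s: %d undefined voxels excluded "
                        "from normalization", stack.subject_id, CHANNEL_NAMES[c], dropped)
        channels[c] = zscore_channel(stack.channels[c], finite)
    return SubjectStack(
        subject_id=stack.subject_id,
        channels=channels,
        brain_mask=stack.brain_mask,
        tumor_mask=stack.tumor_mask,
        idh_status=stack.idh_status,
        age=stack.age,
        metadata={**stack.metadata, "normalized": True},
    )


def combine_tumor_rois(
    enhancing: np.ndarray, necrosis: np.ndarray, nonenhancing: np.ndarray
) -> np.ndarray:
    """Union of the three mutually exclusive tumor ROIs.

    The three components (contrast-enhancing tumor, central necrosis,
    non-enhancing T2/FLAIR-hyperintense tumor) must be pairwise disjoint;
    any overlap is an error naming the offending pair.
    """
    rois = {
        "enhancing": np.asarray(enhancing, dtype=bool),
        "necrosis": np.asarray(necrosis, dtype=bool),
        "nonenhancing": np.asarray(nonenhancing, dtype=bool),
    }
    shapes = {m.shape for m in rois.values()}
    if len(shapes) != 1:
        raise ValueError("ROI masks must share one shape")
    names = list(rois)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            overlap = rois[names[a]] & rois[names[b]]
            if overlap.any():
                raise ValueError(
                    f"ROIs {names[a]} and {names[b]} overlap in "
                    f"{int(overlap.sum())} voxels"
                )
    union = rois["enhancing"] | rois["necrosis"] | rois["nonenhancing"]
    if not union.any():
        logger.warning("combine_tumor_rois: all three ROIs are empty")
    return union


def sample_features(stacks: Sequence[SubjectStack], stride: int = 4) -> FeatureMatrix:
    """Strided voxel sampling of normalized channels within the brain mask.

    Takes the voxel at every stride-aligned grid position (phase anchored at
    array index (0, 0, 0)) where the brain mask is true and all four
    channels are finite, stacking rows across subjects.  stride=4 samples
    one voxel per 4x4x4 = 64-voxel cell.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = []
    prov = []
    for stack in stacks:
        sub = stack.channels[:, ::stride, ::stride, ::stride]
        submask = stack.brain_mask[::stride, ::stride, ::stride]
        finite = np.isfinite(sub).all(axis=0)
        n_skipped = int((submask & ~finite).sum())
        if n_skipped:
            logger.info("subject %s: %d sampled positions skipped (non-finite "
                        "channel)", stack.subject_id, n_skipped)
        keep = submask & finite
        ii, jj, kk = np.nonzero(keep)
        rows.append(sub[:, ii, jj, kk].T)
        prov.append(pd.DataFrame({
            "subject_id": stack.subject_id,
            "i": ii * stride, "j": jj * stride, "k": kk * stride,
        }))
    X = np.concatenate(rows, axis=0) if rows else np.empty((0, N_CHANNELS))
    if len(X) == 0:
        raise ValueError("no voxels sampled (empty masks or all-NaN channels)")
    return FeatureMatrix(X, pd.concat(prov, ignore_index=True))
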