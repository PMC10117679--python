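"""Thickness maps, A-scan quality control, eye mirroring and ROI blocks.

Layer thickness is the axial distance between consecutive segmented
boundaries, converted to um; total retinal thickness (TRT) spans the
vitreous-RNFL to the RPE-choroid interface, so it equals the sum of the
eight layer thicknesses by construction.

Three quality criteria guard every A-scan before averaging:

1. *contrast* — the intensity step across each boundary (Michelson-style,
   over short axial windows) must exceed a minimum; corrupted or
   low-contrast A-scans have no reliable boundary signal;
2. *consistency* — a boundary that disagrees with all four neighbouring
   A-scans by more than a jump threshold is a segmentation glitch;
3. *distribution* — per-layer thicknesses are screened against the volume's
   own robust statistics (median/MAD z-score), catching gross outliers
   without being dragged by them.

Failing any criterion excludes the A-scan. The en-face map is then cropped
by one pixel per side (512 -> 510) and split into 3 x 3 non-overlapping
blocks B1..B9, temporal->nasal and superior->inferior; a block whose
excluded fraction exceeds 10% is discarded entirely. Left-eye (OS) maps are
mirrored first so the left half of every map is temporal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import AxialScale, VolumeMeta, OCTVolume
from .reference import ALL_NAMES
from .segmentation import BoundarySet

__all__ = [
    "ThicknessMap",
    "QCParams",
    "QCReport",
    "BlockSummary",
    "BLOCK_IDS",
    "compute_thickness",
    "qc_ascan",
    "apply_qc",
    "mirror_if_left",
    "crop_and_block",
]

BLOCK_IDS = tuple(f"B{i}" for i in range(1, 10))


@dataclass
class ThicknessMap:
    """Per-layer (8) + TRT thickness in um over the en-face grid.

    ``values``: (9, H, W), ordered as :data:`muroct.reference.ALL_NAMES`
    (TRT last); invalid A-scans hold NaN. ``valid``: (H, W) bool.
    """

    values: np.ndarray
    valid: np.ndarray
    meta: VolumeMeta = field(default_factory=VolumeMeta)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 3 or v.shape[0] != len(ALL_NAMES):
            raise ValueError(f"values must be (9, H, W), got {v.shape}")
        mask = np.asarray(self.valid, bool)
        if mask.shape != v.shape[1:]:
            raise ValueError("valid mask shape mismatch")
        v = v.copy()
        v[:, ~mask] = np.nan
        if mask.any() and np.nanmin(v[:8][:, mask]) < 0:
            raise ValueError("valid layer thicknesses must be >= 0")
        self.values = v
        self.valid = mask

    def layer(self, name: str) -> np.ndarray:
        return self.values[ALL_NAMES.index(name)]


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the three A-scan quality criteria."""

    contrast_window: int = 3  # samples per side of the boundary
    min_contrast: float = 0.05  # Michelson-style contrast floor
    max_jump: int = 15  # samples; neighbour-consistency threshold
    z_cap: float = 4.0  # robust z-score cap for thickness outliers
    # resolution floor of the robust scale, in axial samples: boundaries sit
    # at integer samples, so near-flat layers quantise to one dominant value
    # and MAD collapses to 0; deviations within a few quantisation steps are
    # sub-resolution and must never count as outliers
    mad_floor_samples: float = 1.0
    block_exclusion_fraction: float = 0.10  # strict '>' excludes the block

    def __post_init__(self) -> None:
        if self.contrast_window < 1:
            raise ValueError("contrast_window must be >= 1")
        if min(self.min_contrast, self.max_jump, self.z_cap) <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if self.mad_floor_samples < 0:
            raise ValueError("mad_floor_samples must be >= 0")
        if not 0.0 < self.block_exclusion_fraction < 1.0:
            raise ValueError("block_exclusion_fraction must lie in (0, 1)")


@dataclass
class QCReport:
    """Per-A-scan pass/fail of each criterion; True means the A-scan passed."""

    contrast_pass: np.ndarray
    consistency_pass: np.ndarray
    distribution_pass: np.ndarray
    params: QCParams

    @property
    def ascan_pass(self) -> np.ndarray:
        return self.contrast_pass & self.consistency_pass & self.distribution_pass


@dataclass
class BlockSummary:
    """Mean/SD per layer over one ROI block (or the whole cropped area)."""

    block_id: str  # 'B1'..'B9' or 'whole'
    mean_um: np.ndarray  # (9,) per ALL_NAMES, NaN if block excluded/empty
    sd_um: np.ndarray  # (9,)
    n: int  # retained A-scans
    excluded_fraction: float
    retained: bool
    meta: VolumeMeta = field(default_factory=VolumeMeta)


def compute_thickness(
    boundaries: BoundarySet,
    scale: AxialScale,
    meta: VolumeMeta | None = None,
) -> ThicknessMap:
    """Boundary surfaces -> um thickness map.

    Layer k = (b_{k+1} - b_k) * microns_per_sample; TRT = (b_8 - b_0) *
    microns_per_sample. A-scans with crossing boundaries are marked invalid
    rather than producing negative thickness.
    """
    b = boundaries.boundaries
    mps = scale.microns_per_sample
    diffs = np.diff(b, axis=0)
    valid = boundaries.valid & ~np.any(diffs < 0, axis=0)
    values = np.concatenate([diffs * mps, (b[-1] - b[0])[None] * mps], axis=0)
    return ThicknessMap(values, valid, meta or VolumeMeta())


def _boundary_contrast(
    volume: np.ndarray, boundaries: np.ndarray, w: int
) -> np.ndarray:
    """(9, H, W) Michelson-style contrast across each boundary.

    Windows of at most ``w`` samples on either side are clipped to the extent
    of the adjoining layer, so the comparison is always between the two
    structures that actually meet at the boundary (a fixed window would leak
    into third layers wherever a layer is thinner than ``w`` samples).
    """
    h, wd, n = volume.shape
    eps = 1e-9
    nb = boundaries.shape[0]
    out = np.empty(boundaries.shape)
    vol = volume.astype(np.float64)
    offs = np.arange(w)
    b_int = np.rint(boundaries).astype(int)
    for k in range(nb):
        b = np.clip(b_int[k], w, n - w)
        # extent of the layer above/below, clipped to [1, w]
        ext_above = np.clip(b - (b_int[k - 1] if k > 0 else 0), 1, w)
        ext_below = np.clip((b_int[k + 1] if k < nb - 1 else n) - b, 1, w)
        above_win = np.take_along_axis(vol, b[..., None] - 1 - offs, axis=2)
        below_win = np.take_along_axis(vol, b[..., None] + offs, axis=2)
        mask_a = offs < ext_above[..., None]
        mask_b = offs < ext_below[..., None]
        above = (above_win * mask_a).sum(axis=2) / mask_a.sum(axis=2)
        below = (below_win * mask_b).sum(axis=2) / mask_b.sum(axis=2)
        out[k] = np.abs(below - above) / (below + above + eps)
    return out


def _neighbor_min_jump(b: np.ndarray) -> np.ndarray:
    """Per A-scan, min over the 4 neighbours of |boundary difference|.

    A real displacement disagrees with *all* neighbours; its neighbours still
    agree with the rest of theirs, so only the displaced A-scan is flagged.
    """
    h, w = b.shape
    best = np.full((h, w), np.inf)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        d = np.full((h, w), np.inf)
        rs = slice(max(dr, 0), h + min(dr, 0))
        rd = slice(max(-dr, 0), h + min(-dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        cd = slice(max(-dc, 0), w + min(-dc, 0))
        d[rd, cd] = np.abs(b[rd, cd] - b[rs, cs])
        best = np.minimum(best, d)
    return best


def qc_ascan(
    volume: OCTVolume,
    boundaries: BoundarySet,
    thickness: ThicknessMap,
    params: QCParams = QCParams(),
) -> QCReport:
    """Evaluate the three quality criteria for every A-scan."""
    if not thickness.valid.any():
        raise ValueError("no valid A-scans to quality-check")
    b = boundaries.boundaries
    contrast = _boundary_contrast(volume.intensities, b, params.contrast_window)
    contrast_pass = np.all(contrast >= params.min_contrast, axis=0)

    jump_fail = np.zeros(b.shape[1:], bool)
    for k in range(b.shape[0]):
        jump_fail |= _neighbor_min_jump(b[k]) > params.max_jump
    consistency_pass = ~jump_fail

    dist_fail = np.zeros(b.shape[1:], bool)
    floor_um = params.mad_floor_samples * volume.scale.microns_per_sample
    for k in range(8):
        t = thickness.values[k]
        med = np.nanmedian(t)
        mad = np.nanmedian(np.abs(t - med))
        denom = max(1.4826 * mad, floor_um, 1e-12)
        z = np.abs(t - med) / denom
        dist_fail |= np.nan_to_num(z, nan=0.0) > params.z_cap
    distribution_pass = ~dist_fail

    return QCReport(contrast_pass, consistency_pass, distribution_pass, params)


def apply_qc(thickness: ThicknessMap, report: QCReport) -> ThicknessMap:
    """New map whose validity excludes every A-scan that failed a criterion."""
    return ThicknessMap(
        thickness.values, thickness.valid & report.ascan_pass, thickness.meta
    )


def mirror_if_left(tmap: ThicknessMap) -> ThicknessMap:
    """Mirror left-eye maps so the left half of every map is temporal.

    OD maps are returned unchanged (a copy); applying the function twice to
    an OS map is the identity.
    """
    if tmap.meta.eye not in ("OS", "OD"):
        raise ValueError("missing or invalid eye metadata")
    if tmap.meta.eye == "OD":
        return ThicknessMap(tmap.values.copy(), tmap.valid.copy(), tmap.meta)
    return ThicknessMap(
        tmap.values[:, :, ::-1].copy(), tmap.valid[:, ::-1].copy(), tmap.meta
    )


def _summarize(values: np.ndarray, valid: np.ndarray, block_id: str,
               meta: VolumeMeta, threshold: float) -> BlockSummary:
    n = int(valid.sum())
    excl = 1.0 - n / valid.size
    retained = excl <= threshold  # strict '>' excludes
    if retained and n > 0:
        sub = values[:, valid]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1) if n > 1 else np.zeros(len(ALL_NAMES))
    else:
        mean = np.full(len(ALL_NAMES), np.nan)
        sd = np.full(len(ALL_NAMES), np.nan)
    return BlockSummary(block_id, mean, sd, n if retained else 0, excl, retained, meta)


def crop_and_block(
    tmap: ThicknessMap, params: QCParams = QCParams()
) -> tuple[list[BlockSummary], BlockSummary]:
    """Central 1-pixel crop, then 3 x 3 blocks B1..B9 plus the whole area.

    For the standard 512 x 512 grid this is the 510 x 510 crop with 170 x 170
    blocks. Any grid whose trimmed dimensions divide by 3 is accepted. B1 is
    the top-left (superior-temporal) block, B9 bottom-right; block means use
    retained A-scans only, and a block is discarded entirely when its
    excluded fraction is strictly above the threshold. The whole-area summary
    averages all retained A-scans of the crop, regardless of block fate.
    """
    h, w = tmap.valid.shape
    if (h - 2) % 3 or (w - 2) % 3:
        raise ValueError(
            f"grid {h}x{w} does not split into 3x3 blocks after the 1-pixel trim"
        )
    vals = tmap.values[:, 1:-1, 1:-1]
    valid = tmap.valid[1:-1, 1:-1]
    bh, bw = (h - 2) // 3, (w - 2) // 3
    blocks: list[BlockSummary] = []
    for i in range(3):
        for j in range(3):
            rs = slice(i * bh, (i + 1) * bh)
            cs = slice(j * bw, (j + 1) * bw)
            blocks.append(
                _summarize(
                    vals[:, rs, cs], valid[rs, cs], BLOCK_IDS[i * 3 + j],
                    tmap.meta, params.block_exclusion_fraction,
                )
            )
    whole = _summarize(vals, valid, "whole", tmap.meta, 1.0)
    return blocks, whole
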