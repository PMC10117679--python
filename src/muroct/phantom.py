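"""Synthetic layered-retina OCT phantoms with known ground truth.

The phantom emulates what the scanner sees over the imaged region (a square
patch horizontally aligned with and directly above the optic disc): eight
stacked layers whose thickness follows the published age trajectory of its
group, a superior->inferior gradient toward the disc, a temporal->nasal
asymmetry, a persistent per-animal random effect, multiplicative speckle,
and optional corrupted A-scans for QC testing. Every generated volume comes
with exact boundary surfaces, so downstream stages can be validated without
animal data.

Geometry conventions: en-face row = B-scan index (row 0 superior), en-face
column = A-scan index. Right-eye (OD) volumes have temporal at column 0;
left-eye (OS) volumes are rendered with temporal on the RIGHT, so that the
left-eye mirroring rule of the thickness stage is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import AxialScale, OCTVolume, VolumeMeta
from .reference import (
    AGES_MONTHS,
    LAYER_NAMES,
    N_LAYERS,
    NORMATIVE_MEAN_UM,
    NORMATIVE_SD_UM,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CorruptionSpec",
    "PhantomRecord",
    "thickness_field",
    "generate_phantom",
    "corrupt",
    "simulate_cohort",
]

# Mean reflectivity per class: vitreous, the 8 layers (inner to outer), sub-RPE.
# Plexiform/fiber layers and photoreceptor segments are bright, nuclear layers
# dark, RPE brightest — the usual alternating OCT banding. Values are spaced
# so every interface has Michelson contrast >= 0.15, as in healthy scans.
DEFAULT_REFLECTIVITY = np.array(
    [0.04, 0.85, 0.50, 0.20, 0.55, 0.14, 0.38, 0.62, 0.95, 0.12]
)

# Superior->inferior gradient amplitude per layer (um). Inner retinal layers
# thicken toward the optic disc (inferior edge of the imaged patch); OPL, the
# photoreceptor segments and the RPE thicken away from it.
DEFAULT_GRADIENT_UM = np.array([1.5, 3.5, 2.0, -0.5, 3.0, -0.4, -0.3, -0.8])

# Temporal->nasal asymmetry amplitude per layer (um); temporal side thicker
# for the inner layers, near-symmetric outer layers.
DEFAULT_ASYMMETRY_UM = np.array([0.6, 1.2, 0.8, 0.1, 1.0, 0.1, 0.1, 0.1])


@dataclass(frozen=True)
class CorruptionSpec:
    """Which fraction of A-scans to corrupt and how."""

    fraction: float = 0.0
    mode: Literal["low-contrast", "dropout"] = "low-contrast"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("corruption fraction must be in [0, 1)")
        if self.mode not in ("low-contrast", "dropout"):
            raise ValueError(f"unknown corruption mode {self.mode!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic retina.

    ``mean_um[k, j]`` is the thickness of layer k at age ``ages[j]``; ages in
    between are interpolated linearly. The grid mean of every generated
    thickness field equals the age-interpolated mean (gradient and asymmetry
    are centered), so cohort averages are calibrated to the published
    normative table the defaults are taken from.
    """

    ages: tuple[float, ...] = AGES_MONTHS
    mean_um: np.ndarray = field(
        default_factory=lambda: NORMATIVE_MEAN_UM["WT"].copy()
    )
    gradient_um: np.ndarray = field(default_factory=lambda: DEFAULT_GRADIENT_UM.copy())
    asymmetry_um: np.ndarray = field(
        default_factory=lambda: DEFAULT_ASYMMETRY_UM.copy()
    )
    reflectivity: np.ndarray = field(
        default_factory=lambda: DEFAULT_REFLECTIVITY.copy()
    )
    animal_sd_um: np.ndarray = field(
        default_factory=lambda: NORMATIVE_SD_UM["WT"].mean(axis=1)
    )
    speckle_sigma: float = 0.2
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    top_margin_um: float = 120.0
    # Tilt of the retina inside the scan window (um across the grid, per
    # axis). It shifts all boundaries of an A-scan together, so thickness
    # fields are unaffected; it only makes the axial placement vary the way a
    # real acquisition does.
    tilt_um: tuple[float, float] = (30.0, 12.0)
    contrast_margin: float = 0.08

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_um", np.asarray(self.mean_um, float))
        object.__setattr__(self, "gradient_um", np.asarray(self.gradient_um, float))
        object.__setattr__(self, "asymmetry_um", np.asarray(self.asymmetry_um, float))
        object.__setattr__(self, "reflectivity", np.asarray(self.reflectivity, float))
        object.__setattr__(self, "animal_sd_um", np.asarray(self.animal_sd_um, float))
        if self.mean_um.shape != (N_LAYERS, len(self.ages)):
            raise ValueError(
                f"mean_um must be {(N_LAYERS, len(self.ages))}, got {self.mean_um.shape}"
            )
        if np.any(self.mean_um <= 0):
            raise ValueError("all base thicknesses must be positive")
        if self.reflectivity.shape != (N_LAYERS + 2,):
            raise ValueError("reflectivity needs vitreous + 8 layers + sub-RPE values")
        if np.any(self.reflectivity <= 0) or np.any(self.reflectivity > 1):
            raise ValueError("reflectivities must lie in (0, 1]")
        gaps = np.abs(np.diff(self.reflectivity))
        if np.any(gaps < self.contrast_margin):
            raise ValueError(
                "adjacent structures must differ in reflectivity by at least "
                f"{self.contrast_margin}; got minimum gap {gaps.min():.3f}"
            )
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")

    @classmethod
    def for_group(cls, group: str, **overrides) -> "PhantomSpec":
        """Spec calibrated to a published group ('WT' or '3xTg-AD')."""
        return cls(
            mean_um=NORMATIVE_MEAN_UM[group].copy(),
            animal_sd_um=NORMATIVE_SD_UM[group].mean(axis=1),
            **overrides,
        )

    def base_um(self, age_months: float) -> np.ndarray:
        """Per-layer mean thickness (um) at an age, linear between time points."""
        return np.array(
            [np.interp(age_months, self.ages, self.mean_um[k]) for k in range(N_LAYERS)]
        )

    def with_trt_offset(self, offset_um: float) -> "PhantomSpec":
        """Shift total retinal thickness by ``offset_um``, spread over layers
        in proportion to their mean thickness."""
        weights = self.mean_um / self.mean_um.sum(axis=0, keepdims=True)
        return replace(self, mean_um=self.mean_um + offset_um * weights)


@dataclass
class GroundTruth:
    """Exact boundary surfaces of a phantom: 9 surfaces over the en-face grid,
    in (fractional) axial sample units, strictly increasing along each A-scan."""

    boundaries: np.ndarray  # (9, n_bscans, n_ascans)
    scale: AxialScale

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b.ndim != 3 or b.shape[0] != N_LAYERS + 1:
            raise ValueError(f"boundaries must be (9, H, W), got {b.shape}")
        if np.any(np.diff(b, axis=0) <= 0):
            raise ValueError("boundaries must be strictly increasing per A-scan")
        self.boundaries = b

    @property
    def layer_thickness_um(self) -> np.ndarray:
        """(8, H, W) per-layer thickness in um."""
        return np.diff(self.boundaries, axis=0) * self.scale.microns_per_sample

    @property
    def trt_um(self) -> np.ndarray:
        """(H, W) total retinal thickness in um."""
        return (self.boundaries[-1] - self.boundaries[0]) * self.scale.microns_per_sample


@dataclass
class PhantomRecord:
    """One simulated acquisition: volume (optional), truth and metadata."""

    truth: GroundTruth
    meta: VolumeMeta
    volume: OCTVolume | None = None


def thickness_field(
    spec: PhantomSpec,
    layer: int,
    age_months: float,
    row,
    col,
    animal_effect_um: float = 0.0,
    grid_shape: tuple[int, int] = (512, 512),
) -> np.ndarray | float:
    """Noise-free thickness (um) of one layer at en-face position(s).

    ``layer`` is 1-based (1..8). The field is the age-interpolated mean plus a
    centered superior->inferior gradient and a centered temporal->nasal
    asymmetry plus the per-animal effect, floored at 1 um; its grid average is
    exactly the age-interpolated mean when the effect is zero.
    """
    if not 1 <= layer <= N_LAYERS:
        raise ValueError(f"layer must be in 1..{N_LAYERS}, got {layer}")
    k = layer - 1
    rows, cols = grid_shape
    r = np.asarray(row, float)
    c = np.asarray(col, float)
    base = float(np.interp(age_months, spec.ages, spec.mean_um[k]))
    val = (
        base
        + spec.gradient_um[k] * (r / (rows - 1) - 0.5)
        + spec.asymmetry_um[k] * (0.5 - c / (cols - 1))
        + animal_effect_um
    )
    return np.maximum(val, 1.0)


def _thickness_fields(
    spec: PhantomSpec,
    age_months: float,
    grid_shape: tuple[int, int],
    animal_effect_um: np.ndarray,
    eye: str,
) -> np.ndarray:
    """(8, H, W) noise-free thickness fields; OS has temporal on the right."""
    rows, cols = grid_shape
    r = np.arange(rows, dtype=float)[:, None]
    c = np.arange(cols, dtype=float)[None, :]
    if eye == "OS":
        c = (cols - 1) - c
    fields = np.empty((N_LAYERS, rows, cols))
    for k in range(N_LAYERS):
        fields[k] = thickness_field(
            spec, k + 1, age_months, r, c, float(animal_effect_um[k]), grid_shape
        )
    return fields


def _render(
    boundaries: np.ndarray,
    reflectivity: np.ndarray,
    n_samples: int,
    speckle_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a uint16 volume from boundary surfaces.

    Sample s of an A-scan belongs to class k iff b_k <= s < b_{k+1} (class 0
    above b_0, class 9 at/below b_8); intensity is the class reflectivity
    times unit-mean gamma speckle.
    """
    _, n_b, n_a = boundaries.shape
    s = np.arange(n_samples)
    out = np.empty((n_b, n_a, n_samples), np.uint16)
    shape_k = 1.0 / speckle_sigma**2 if speckle_sigma > 0 else None
    for i in range(n_b):
        # class index = number of boundaries <= s
        cls = (s[None, :] >= np.ceil(boundaries[:, i, :, None])).sum(axis=0)
        signal = reflectivity[cls]
        if shape_k is not None:
            signal = signal * rng.gamma(shape_k, 1.0 / shape_k, size=signal.shape)
        out[i] = np.clip(signal * 50000.0, 0, 65535).astype(np.uint16)
    return out


def generate_phantom(
    spec: PhantomSpec,
    meta: VolumeMeta,
    seed: int | np.random.SeedSequence,
    shape: tuple[int, int, int] = (512, 512, 1024),
    depth_mm: float = 1.4,
    animal_effect_um: np.ndarray | None = None,
    render: bool = True,
) -> tuple[OCTVolume | None, GroundTruth]:
    """Generate one phantom volume plus its exact ground truth.

    Deterministic given the seed. ``render=False`` skips the intensity volume
    (the truth alone suffices for thickness/normative/statistics testing).
    """
    n_b, n_a, n_s = shape
    scale = AxialScale(depth_mm, n_s)
    rng = np.random.default_rng(seed)
    if animal_effect_um is None:
        animal_effect_um = np.zeros(N_LAYERS)
    fields = _thickness_fields(
        spec, meta.age_months, (n_b, n_a), animal_effect_um, meta.eye
    )
    mps = scale.microns_per_sample
    r = np.arange(n_b, dtype=float)[:, None] / max(n_b - 1, 1)
    c = np.arange(n_a, dtype=float)[None, :] / max(n_a - 1, 1)
    b0 = (
        spec.top_margin_um
        + spec.tilt_um[0] * (r - 0.5)
        + spec.tilt_um[1] * (c - 0.5)
    ) / mps
    cum = np.cumsum(fields, axis=0) / mps
    boundaries = np.concatenate([b0[None], b0[None] + cum], axis=0)
    if boundaries[-1].max() >= n_s - 1:
        raise ValueError(
            "retina exceeds imaging depth: deepest boundary at sample "
            f"{boundaries[-1].max():.1f} of {n_s}"
        )
    truth = GroundTruth(boundaries, scale)
    if not render:
        return None, truth
    data = _render(boundaries, spec.reflectivity, n_s, spec.speckle_sigma, rng)
    return OCTVolume(data, meta=meta, scale=scale), truth


def corrupt(
    volume: OCTVolume,
    corruption: CorruptionSpec,
    seed: int | np.random.SeedSequence,
    region: np.ndarray | None = None,
) -> tuple[OCTVolume, np.ndarray]:
    """Corrupt a random fraction of A-scans; returns (volume, (m, 2) coords).

    'low-contrast' flattens the A-scan to its own mean (zero boundary
    contrast); 'dropout' zeroes it. ``region`` restricts the candidate
    A-scans to an (H, W) boolean mask. The input volume is not modified.
    """
    if corruption.fraction == 0.0:
        return volume, np.empty((0, 2), int)
    rng = np.random.default_rng(seed)
    h, w = volume.n_bscans, volume.n_ascans
    if region is None:
        candidates = np.stack(
            np.unravel_index(np.arange(h * w), (h, w)), axis=1
        )
    else:
        candidates = np.argwhere(region)
    m = int(round(corruption.fraction * len(candidates)))
    picked = candidates[rng.choice(len(candidates), size=m, replace=False)]
    data = volume.intensities.copy()
    r, c = picked[:, 0], picked[:, 1]
    if corruption.mode == "low-contrast":
        means = data[r, c, :].mean(axis=1)
        data[r, c, :] = means[:, None].astype(data.dtype)
    else:
        data[r, c, :] = 0
    out = OCTVolume(data, meta=volume.meta, scale=volume.scale)
    return out, picked


def simulate_cohort(
    specs: dict[str, PhantomSpec],
    ages: Sequence[float],
    n_animals: int,
    seed: int,
    shape: tuple[int, int, int] = (512, 512, 1024),
    render: bool = False,
    eyes: Iterable[str] = ("OS", "OD"),
) -> list[PhantomRecord]:
    """Simulate a longitudinal cohort: per group, ``n_animals`` mice, both
    eyes, every age; the per-(animal, layer) Gaussian effect persists across
    ages and eyes, producing repeated-measures structure.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    ages = list(ages)
    if not ages:
        raise ValueError("age list must not be empty")
    root = np.random.SeedSequence(seed)
    records: list[PhantomRecord] = []
    for g_idx, group in enumerate(sorted(specs)):
        spec = specs[group]
        eff_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(g_idx,))
        )
        for a_idx in range(n_animals):
            animal_id = f"{group}-{a_idx:03d}"
            effect = eff_rng.normal(0.0, spec.animal_sd_um)
            for age in ages:
                for eye in eyes:
                    meta = VolumeMeta(
                        eye=eye, age_months=age, group=group, animal_id=animal_id
                    )
                    child = np.random.SeedSequence(
                        entropy=root.entropy,
                        spawn_key=(g_idx, a_idx, int(age * 4),
                                   0 if eye == "OS" else 1),
                    )
                    vol, truth = generate_phantom(
                        spec, meta, child, shape=shape,
                        animal_effect_um=effect, render=render,
                    )
                    records.append(PhantomRecord(truth=truth, meta=meta, volume=vol))
    return records
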