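"""Volume I/O for murine OCT data.

An OCT acquisition is a stack of B-scans (cross-sectional images); each B-scan
is a set of A-scans (axial reflectivity profiles). Volumes are stored as
non-compressed grayscale TIFF — either one multipage file or one file per
B-scan — with a JSON/YAML sidecar carrying the eye, age, group and animal id
(TIFF tags are dialect-prone, so metadata never lives in the image file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
import yaml

__all__ = ["AxialScale", "VolumeMeta", "OCTVolume", "read_volume", "write_volume"]

#: Default acquisition geometry: 512 B-scans x 512 A-scans x 1024 samples.
DEFAULT_SHAPE = (512, 512, 1024)


@dataclass(frozen=True)
class AxialScale:
    """Axial sampling of the scanner: ``depth_mm`` imaged over ``n_samples``.

    The default (1.4 mm over 1024 samples) gives 1.3672 um per sample.
    """

    depth_mm: float = 1.4
    n_samples: int = 1024

    def __post_init__(self) -> None:
        if self.depth_mm <= 0 or self.n_samples <= 0:
            raise ValueError("depth_mm and n_samples must be positive")

    @property
    def microns_per_sample(self) -> float:
        return 1000.0 * self.depth_mm / self.n_samples

    def with_samples(self, n_samples: int) -> "AxialScale":
        """Same physical depth resampled to ``n_samples`` (reduced volumes)."""
        return AxialScale(self.depth_mm, n_samples)


@dataclass
class VolumeMeta:
    """Acquisition metadata: which animal, eye, age and experimental group."""

    eye: Literal["OS", "OD"] = "OD"
    age_months: int = 1
    group: str = "WT"
    animal_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.eye not in ("OS", "OD"):
            raise ValueError(f"eye must be 'OS' or 'OD', got {self.eye!r}")

    def to_dict(self) -> dict:
        return {
            "eye": self.eye,
            "age_months": int(self.age_months),
            "group": self.group,
            "animal_id": self.animal_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMeta":
        return cls(
            eye=d["eye"],
            age_months=int(d["age_months"]),
            group=str(d["group"]),
            animal_id=str(d["animal_id"]),
        )


@dataclass
class OCTVolume:
    """A 3-D reflectivity volume indexed [b_scan, a_scan, axial sample]."""

    intensities: np.ndarray
    meta: VolumeMeta = field(default_factory=VolumeMeta)
    scale: AxialScale = field(default_factory=AxialScale)

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 3:
            raise ValueError(f"intensities must be 3-D, got shape {a.shape}")
        if any(s < 1 for s in a.shape):
            raise ValueError(f"empty volume dimensions: {a.shape}")
        if np.issubdtype(a.dtype, np.floating):
            if not np.all(np.isfinite(a)):
                raise ValueError("intensities must be finite")
            if a.size and a.min() < 0:
                raise ValueError("intensities must be non-negative")
        self.intensities = a
        if self.scale.n_samples != a.shape[2]:
            self.scale = self.scale.with_samples(a.shape[2])

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]


def _read_meta(path: Path) -> VolumeMeta:
    if path.is_dir():
        candidates = [path / n for n in ("meta.json", "meta.yaml", "meta.yml")]
    else:
        candidates = [
            path.parent / (path.stem + suffix)
            for suffix in ("_meta.json", "_meta.yaml", "_meta.yml")
        ]
    for c in candidates:
        if c.is_file():
            text = c.read_text()
            d = json.loads(text) if c.suffix == ".json" else yaml.safe_load(text)
            return VolumeMeta.from_dict(d)
    return VolumeMeta()


def read_volume(path: str | Path, scale: AxialScale | None = None) -> OCTVolume:
    """Read a volume from a directory of TIFFs or a single (multipage) TIFF.

    B-scan order is the lexicographic order of the filenames (for a directory)
    or page order (for a multipage file). Integer data round-trip bit-exact.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"no TIFF files in {path}")
        pages: list[np.ndarray] = []
        for f in files:
            img = tifffile.imread(f)
            pages.append(img[None] if img.ndim == 2 else img)
        shapes = {p.shape[1:] for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"mixed B-scan shapes in {path}: {sorted(shapes)}")
        data = np.concatenate(pages, axis=0)
    else:
        if not path.is_file():
            raise FileNotFoundError(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected grayscale pages, got shape {data.shape}")
    meta = _read_meta(path)
    vol = OCTVolume(data, meta=meta)
    if scale is not None:
        vol.scale = scale.with_samples(vol.n_samples)
    return vol


def write_volume(volume: OCTVolume, path: str | Path, multipage: bool = True) -> Path:
    """Write a volume as non-compressed TIFF plus a JSON metadata sidecar.

    ``multipage=True`` writes one file; otherwise one zero-padded file per
    B-scan into ``path`` treated as a directory.
    """
    path = Path(path)
    if multipage:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, volume.intensities, compression=None)
        sidecar = path.parent / (path.stem + "_meta.json")
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(volume.n_bscans)))
        for i in range(volume.n_bscans):
            tifffile.imwrite(
                path / f"bscan_{i:0{width}d}.tif",
                volume.intensities[i],
                compression=None,
            )
        sidecar = path / "meta.json"
    sidecar.write_text(json.dumps(volume.meta.to_dict(), indent=2) + "\n")
    return path
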