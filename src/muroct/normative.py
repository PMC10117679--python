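"""Normative database, kernel densities, longitudinal maps and deviation scores.

The normative database stratifies block-level thickness by group x age x eye
x layer x region (the nine ROI blocks plus the whole imaged area). Each entry
keeps the mean, SD and N *across volumes* (never across A-scans) and retains
the raw per-volume values, so kernel-density summaries and nonparametric
percentile scoring remain available.

A subject's scan is scored against its matched entry: the Gaussian two-sided
tail probability of its z-score (the observed thickness distributions are
overwhelmingly normal), with an optional rank-based percentile mode. Blocks
whose probability falls below the chosen level are flagged as outside the
normal range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ALL_NAMES
from .thickness import BlockSummary

__all__ = [
    "NormativeDatabase",
    "KDEstimate",
    "build_normative",
    "kde",
    "normalize_longitudinal",
    "abnormality",
]

_KEY = ["group", "age_months", "eye", "layer", "region"]


@dataclass
class KDEstimate:
    """Gaussian-kernel density plus empirical quartiles of the raw values."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    median: float
    q1: float
    q3: float

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class NormativeDatabase:
    """Entries (mean/sd/n per stratum) plus the raw per-volume values."""

    entries: pd.DataFrame  # columns _KEY + mean_um, sd_um, n
    raw: pd.DataFrame  # columns _KEY + animal_id, value_um
    metadata: dict

    def entry(self, group, age_months, eye, layer, region) -> pd.Series | None:
        m = self.entries
        sel = m[
            (m.group == group)
            & (m.age_months == age_months)
            & (m.eye == eye)
            & (m.layer == layer)
            & (m.region == region)
        ]
        return None if sel.empty else sel.iloc[0]

    def raw_values(self, group, age_months, eye, layer, region) -> np.ndarray:
        m = self.raw
        sel = m[
            (m.group == group)
            & (m.age_months == age_months)
            & (m.eye == eye)
            & (m.layer == layer)
            & (m.region == region)
        ]
        return sel.value_um.to_numpy()

    def kde_for(self, group, age_months, eye, layer, region,
                bandwidth="auto") -> KDEstimate:
        return kde(self.raw_values(group, age_months, eye, layer, region), bandwidth)

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.entries.to_csv(csv_path, index=False, float_format="%.6f")
        meta_path = csv_path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(self.metadata, indent=2, default=str) + "\n")


def build_normative(
    summaries: Iterable[BlockSummary],
    pool_eyes: bool = False,
    metadata: dict | None = None,
) -> NormativeDatabase:
    """Aggregate per-volume block summaries into a normative database.

    One entry per (group, age, eye, layer, region); mean/SD are computed
    across volumes. ``pool_eyes=True`` merges OS and OD into a single 'both'
    stratum (the published overall tables pool both eyes). Cells with fewer
    than 2 volumes are kept but flagged by their n; empty cells simply do not
    appear (a warning is emitted if every input was excluded).
    """
    rows = []
    for s in summaries:
        if not s.retained or s.n == 0:
            continue
        eye = "both" if pool_eyes else s.meta.eye
        for li, layer in enumerate(ALL_NAMES):
            if np.isnan(s.mean_um[li]):
                continue
            rows.append(
                {
                    "group": s.meta.group,
                    "age_months": s.meta.age_months,
                    "eye": eye,
                    "layer": layer,
                    "region": s.block_id,
                    "animal_id": s.meta.animal_id,
                    "value_um": float(s.mean_um[li]),
                }
            )
    raw = pd.DataFrame(rows, columns=_KEY + ["animal_id", "value_um"])
    if raw.empty:
        warnings.warn("no retained block summaries; normative database is empty",
                      stacklevel=2)
        entries = pd.DataFrame(columns=_KEY + ["mean_um", "sd_um", "n"])
    else:
        g = raw.groupby(_KEY, sort=True)["value_um"]
        entries = g.agg(mean_um="mean", sd_um=lambda v: v.std(ddof=1), n="count")
        entries = entries.reset_index()
        entries["sd_um"] = entries["sd_um"].fillna(0.0)
    meta = {"pool_eyes": pool_eyes}
    meta.update(metadata or {})
    return NormativeDatabase(entries, raw, meta)


def kde(values, bandwidth="auto", n_grid: int = 512) -> KDEstimate:
    """Gaussian-kernel density estimate of a set of thickness values.

    'auto' bandwidth is Silverman's rule (via scipy); a numeric bandwidth is
    the absolute kernel SD in the data units. Quartiles are computed from the
    empirical values, never from the density. Zero-variance input degenerates
    to a narrow spike with a minimum bandwidth.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 finite values for a density estimate")
    med, q1, q3 = (float(np.percentile(v, p)) for p in (50, 25, 75))
    sd = v.std(ddof=1)
    if bandwidth == "auto":
        if sd == 0:
            h = max(1e-6, 1e-3 * max(abs(v[0]), 1.0))
        else:
            h = float(stats.gaussian_kde(v, bw_method="silverman").factor * sd)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(v.min() - 4 * h, v.max() + 4 * h, n_grid)
    if sd == 0:
        density = stats.norm.pdf(grid, loc=v[0], scale=h)
    else:
        k = stats.gaussian_kde(v, bw_method=h / sd)
        density = k(grid)
    return KDEstimate(grid, density, h, med, q1, q3)


def normalize_longitudinal(block_means: np.ndarray) -> np.ndarray:
    """Min-max normalise per-layer block means across all (block, age) cells.

    ``block_means``: (n_layers, n_blocks, n_ages) (NaN allowed for missing
    cells). Each layer is mapped to [0, 1] over its own cells; a constant
    layer maps to 0.5 everywhere by convention.
    """
    x = np.asarray(block_means, float)
    if x.ndim != 3:
        raise ValueError("expected (n_layers, n_blocks, n_ages)")
    out = np.empty_like(x)
    for k in range(x.shape[0]):
        cells = x[k]
        finite = cells[np.isfinite(cells)]
        if finite.size < 2:
            raise ValueError(f"layer {k}: need >= 2 values to normalise")
        lo, hi = finite.min(), finite.max()
        out[k] = 0.5 if hi == lo else (cells - lo) / (hi - lo)
    return out


def longitudinal_block_table(
    db: NormativeDatabase, group: str, eye: str, layers=None, regions=None,
    ages=None,
) -> tuple[np.ndarray, list[str], list[str], list]:
    """Assemble the (layer, block, age) mean-thickness array behind the
    normalized longitudinal maps. Returns (array, layers, regions, ages)."""
    e = db.entries
    e = e[(e.group == group) & (e.eye == eye) & (e.region != "whole")]
    layers = list(layers or ALL_NAMES)
    regions = list(regions or sorted(e.region.unique()))
    ages = list(ages or sorted(e.age_months.unique()))
    arr = np.full((len(layers), len(regions), len(ages)), np.nan)
    for _, row in e.iterrows():
        try:
            i = layers.index(row.layer)
            j = regions.index(row.region)
            k = ages.index(row.age_months)
        except ValueError:
            continue
        arr[i, j, k] = row.mean_um
    return arr, layers, regions, ages


def abnormality(
    subject: Iterable[BlockSummary] | Mapping[tuple[str, str], float],
    db: NormativeDatabase,
    group: str,
    age_months,
    eye: str,
    alpha: float = 0.05,
    mode: str = "gaussian",
) -> pd.DataFrame:
    """Score a subject's blocks against the matched normative entries.

    Returns one row per (layer, region) with the z-score, the two-sided tail
    probability that a normal retina shows a value at least this far from the
    normative mean, and a flag at level ``alpha``. Blocks without a usable
    matched entry (missing, n < 2 or zero SD) are reported not-evaluable and
    never flagged. ``mode='percentile'`` uses the rank of the value among the
    raw normative values instead of the Gaussian tail.
    """
    if mode not in ("gaussian", "percentile"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(subject, Mapping):
        items = list(subject.items())
    else:
        items = []
        for s in subject:
            for li, layer in enumerate(ALL_NAMES):
                if not np.isnan(s.mean_um[li]):
                    items.append(((layer, s.block_id), float(s.mean_um[li])))
    rows = []
    for (layer, region), value in items:
        entry = db.entry(group, age_months, eye, layer, region)
        row = {
            "layer": layer, "region": region, "value_um": value,
            "z": np.nan, "p": np.nan, "flag": False, "evaluable": False,
        }
        if entry is not None and entry.n >= 2 and entry.sd_um > 0:
            z = (value - entry.mean_um) / entry.sd_um
            row["z"] = z
            if mode == "gaussian":
                p = 2.0 * stats.norm.sf(abs(z))
            else:
                vals = db.raw_values(group, age_months, eye, layer, region)
                rank = (vals <= value).sum()
                lo = rank / (len(vals) + 1)
                p = 2.0 * min(lo, 1.0 - lo)
            p = min(max(p, np.finfo(float).tiny), 1.0)
            row["p"] = p
            row["flag"] = bool(p < alpha)
            row["evaluable"] = True
        rows.append(row)
    return pd.DataFrame(rows)
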