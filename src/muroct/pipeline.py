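"""End-to-end orchestration: phantoms -> segmentation -> thickness/QC ->
normative database -> statistics, with deterministic tabular outputs.

Given fixed seeds the four outputs are byte-identical across runs:

* ``thickness_blocks.csv`` — per-volume block and whole-area summaries;
* ``group_means.csv`` — group x age mean (SD) per layer + TRT, eyes pooled,
  the same layout as a published longitudinal thickness table;
* ``normative.csv`` (+ ``normative.meta.json``) — the normative database;
* ``stats_report.csv`` and ``pairwise_<group>_<eye>_TRT.csv`` — the group
  comparisons per age/layer and the longitudinal pairwise age matrices.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import AxialScale
from .normative import build_normative
from .phantom import PhantomSpec, simulate_cohort
from .reference import ALL_NAMES
from .segmentation import boundaries_from_classmap, oracle_classmap
from .stats import complete_cases, compare_groups, rm_anova_oneway, rm_anova_twoway, tukey_kramer
from .thickness import apply_qc, compute_thickness, crop_and_block, mirror_if_left, qc_ascan
from .unet import UNet, segment

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the offending volume."""


def _float(x) -> str:
    return "" if x is None or not np.isfinite(x) else f"{x:.6f}"


def summaries_from_frame(long_df: pd.DataFrame):
    """Rebuild BlockSummary objects from a thickness_blocks.csv frame."""
    from .io import VolumeMeta
    from .thickness import BlockSummary

    out = []
    keys = ["group", "animal_id", "eye", "age_months", "region"]
    for key, sub in long_df.groupby(keys, sort=True):
        group, animal, eye, age, region = key
        sub = sub.set_index("layer")
        mean = np.array([sub.loc[l, "mean_um"] for l in ALL_NAMES])
        sd = np.array([sub.loc[l, "sd_um"] for l in ALL_NAMES])
        row = sub.iloc[0]
        out.append(
            BlockSummary(
                block_id=region,
                mean_um=mean,
                sd_um=sd,
                n=int(row.n),
                excluded_fraction=float(row.excluded_fraction),
                retained=bool(row.retained),
                meta=VolumeMeta(eye=eye, age_months=age, group=group,
                                animal_id=str(animal)),
            )
        )
    return out


def _process_volume(rec, config: PipelineConfig, model: UNet | None):
    if config.segmentation.mode == "oracle":
        cm = oracle_classmap(rec.truth, rec.volume.n_samples)
    else:
        cm = segment(model, rec.volume)
    bs = boundaries_from_classmap(cm)
    tm = compute_thickness(bs, rec.volume.scale, rec.meta)
    report = qc_ascan(rec.volume, bs, tm, config.qc)
    tm = apply_qc(tm, report)
    tm = mirror_if_left(tm)
    blocks, whole = crop_and_block(tm, config.qc)
    return blocks + [whole]


def run_pipeline(config: PipelineConfig, model: UNet | None = None) -> dict[str, Path]:
    """Run the full pipeline; returns the paths of the emitted files.

    Any stage failure is logged with the volume id and re-raised as
    :class:`PipelineError` (the CLI converts that into a nonzero exit).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort
    specs = {
        g: PhantomSpec.for_group(g, speckle_sigma=cohort.speckle_sigma)
        for g in cohort.groups
    }
    if config.segmentation.mode == "network":
        if model is None:
            if config.segmentation.checkpoint is None:
                raise PipelineError("network mode needs a model or checkpoint")
            model = UNet.load(config.segmentation.checkpoint)
    records = simulate_cohort(
        specs, cohort.ages, cohort.n_animals, config.seed,
        shape=cohort.shape, render=True,
    )

    summaries = []
    for rec in records:
        vol_id = f"{rec.meta.animal_id}/{rec.meta.eye}/{rec.meta.age_months}mo"
        try:
            summaries.extend(_process_volume(rec, config, model))
        except Exception as exc:
            logger.error("pipeline stage failed for volume %s: %s", vol_id, exc)
            raise PipelineError(f"volume {vol_id}: {exc}") from exc

    paths: dict[str, Path] = {}

    # (a) per-volume block summaries, long format
    rows = []
    for s in summaries:
        for li, layer in enumerate(ALL_NAMES):
            rows.append(
                {
                    "group": s.meta.group,
                    "animal_id": s.meta.animal_id,
                    "eye": s.meta.eye,
                    "age_months": s.meta.age_months,
                    "region": s.block_id,
                    "layer": layer,
                    "mean_um": s.mean_um[li],
                    "sd_um": s.sd_um[li],
                    "n": s.n,
                    "excluded_fraction": s.excluded_fraction,
                    "retained": s.retained,
                }
            )
    long_df = pd.DataFrame(rows).sort_values(
        ["group", "animal_id", "eye", "age_months", "region", "layer"],
        kind="mergesort",
    )
    paths["thickness_blocks"] = out / "thickness_blocks.csv"
    long_df.to_csv(paths["thickness_blocks"], index=False, float_format="%.6f")

    # (b) group x age mean (SD) table over the whole area, eyes pooled
    whole = long_df[(long_df.region == "whole") & long_df.retained]
    tbl_rows = []
    for group in cohort.groups:
        for age in cohort.ages:
            sel = whole[(whole.group == group) & (whole.age_months == age)]
            row = {"group": group, "age_months": age}
            for layer in ALL_NAMES:
                v = sel[sel.layer == layer].mean_um
                row[layer] = (
                    f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if len(v) > 1 else ""
                )
            tbl_rows.append(row)
    paths["group_means"] = out / "group_means.csv"
    pd.DataFrame(tbl_rows).to_csv(paths["group_means"], index=False)

    # (c) normative database (eyes kept separate)
    db = build_normative(
        summaries,
        metadata={
            "seed": config.seed,
            "qc": config.qc.__dict__,
            "normalization": "per-layer min-max across blocks x ages",
        },
    )
    paths["normative"] = out / "normative.csv"
    db.save(paths["normative"])

    # (d) statistics report
    paths["stats_report"] = stats_report_from_frame(long_df, config, paths)
    return paths


def stats_report_from_frame(
    long_df: pd.DataFrame, config: PipelineConfig, paths: dict | None = None
) -> Path:
    """Group comparisons + longitudinal tests from per-volume block summaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = paths if paths is not None else {}
    groups = sorted(long_df.group.unique(),
                    key=list(long_df.group).index)  # preserve first-seen order
    ages = sorted(long_df.age_months.unique())
    whole = long_df[(long_df.region == "whole") & long_df.retained]

    stats_rows = []
    if len(groups) >= 2:
        g0, g1 = groups[0], groups[1]
        for age in ages:
            for eye in ("OS", "OD"):
                sel = whole[(whole.age_months == age) & (whole.eye == eye)]
                for layer in ALL_NAMES:
                    a = sel[(sel.group == g0) & (sel.layer == layer)].mean_um.to_numpy()
                    b = sel[(sel.group == g1) & (sel.layer == layer)].mean_um.to_numpy()
                    m = 1 if layer == "TRT" else config.stats.bonferroni_m
                    res = compare_groups(a, b, m_comparisons=m, seed=config.seed)
                    stats_rows.append(
                        {
                            "analysis": f"{g0}-vs-{g1}",
                            "eye": eye,
                            "age_months": age,
                            "layer": layer,
                            "method": res.method,
                            "statistic": _float(res.statistic),
                            "p": _float(res.p),
                            "p_adj": _float(res.p_adj),
                            "stars": res.stars,
                        }
                    )

    # longitudinal TRT per group and eye: RANOVA/Friedman + pairwise ages
    for group in groups:
        for eye in ("OS", "OD"):
            sel = whole[(whole.group == group) & (whole.eye == eye) & (whole.layer == "TRT")]
            rec_df = sel.rename(
                columns={"animal_id": "subject", "age_months": "time", "mean_um": "value"}
            )[["subject", "time", "value"]]
            if rec_df.empty:
                continue
            table, dropped = complete_cases(rec_df, times=ages)
            if table.n_subjects < 3 or table.n_times < 2:
                continue
            res = rm_anova_oneway(table, config.stats.normality_alpha, seed=config.seed)
            stats_rows.append(
                {
                    "analysis": "longitudinal-TRT",
                    "eye": eye,
                    "age_months": "",
                    "layer": f"{group}",
                    "method": res.method,
                    "statistic": _float(res.statistic),
                    "p": _float(res.p),
                    "p_adj": "",
                    "stars": res.stars,
                }
            )
            pm = tukey_kramer(table)
            p_path = out / f"pairwise_{group.replace('/', '-')}_{eye}_TRT.csv"
            pm.p.to_csv(p_path, float_format="%.6f")
            paths[f"pairwise_{group}_{eye}"] = p_path

    # two-way (group x time) TRT per eye
    if len(groups) >= 2 and len(ages) >= 2:
        for eye in ("OS", "OD"):
            tables = {}
            for group in groups[:2]:
                sel = whole[
                    (whole.group == group) & (whole.eye == eye) & (whole.layer == "TRT")
                ]
                rec_df = sel.rename(
                    columns={"animal_id": "subject", "age_months": "time", "mean_um": "value"}
                )[["subject", "time", "value"]]
                if rec_df.empty:
                    break
                tables[group], _ = complete_cases(rec_df, times=ages)
            if len(tables) == 2 and all(t.n_subjects >= 3 for t in tables.values()):
                res2 = rm_anova_twoway(tables)
                for effect, res in res2.items():
                    stats_rows.append(
                        {
                            "analysis": "two-way-RANOVA-TRT",
                            "eye": eye,
                            "age_months": "",
                            "layer": effect,
                            "method": res.method,
                            "statistic": _float(res.statistic),
                            "p": _float(res.p),
                            "p_adj": "",
                            "stars": res.stars,
                        }
                    )

    report = out / "stats_report.csv"
    pd.DataFrame(stats_rows).to_csv(report, index=False)
    return report
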