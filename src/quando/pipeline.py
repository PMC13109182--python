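"""Batch orchestration: per-image, per-cell preprocessing, density and ICCS,
with CSV emission and group summaries.

Per image the steps are: segment nuclei on the raw DNA channel (count
masks are built before intensity files; a flag flips this), rolling-ball
background subtraction on both channels, damage mask at the per-experiment
threshold, then per nucleus: area, focus count, normalized-DNA density and
the ICCS colocalization fractions. Everything is deterministic for a fixed
config, and per-cell failures are recorded, never fatal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as qio
from .density import NO_FOCI, dna_density, normalize_dna
from .iccs import IccsParams, per_cell_iccs
from .preprocess import count_foci, damage_mask, rolling_ball_subtract, segment_nuclei
from .types import ChannelImage, CountMask

logger = logging.getLogger("quando")

RESULT_COLUMNS = [
    "image_id", "cell_id", "area_px", "n_foci", "roi_area_px", "dna_density",
    "f1", "f2", "w_cross_px", "w_auto1_px", "w_auto2_px",
    "G0_cross", "G0_auto1", "G0_auto2", "valid", "reason",
]


@dataclass
class RunConfig:
    """All tunables of a batch run; round-trips losslessly through YAML."""

    rolling_radius_px: int = 10
    foci_threshold: float = 50.0
    min_area_px: int = 5000
    max_area_px: int | None = None
    min_solidity: float | None = None
    exclude_border: bool = True
    segment_on_subtracted: bool = False
    min_focus_px: int = 4
    max_lag: int = 32
    min_overlap: int = 100
    range_factor: float = 3.0
    range_tol_px: float = 0.5
    max_fit_iter: int = 10
    width_bounds_px: tuple[float, float] = (0.5, 30.0)
    f_limit: float = 1.2
    max_percentile: float | None = None
    channel_order: tuple[str, str] = ("damage", "dna")
    pixel_size_nm: float = 45.0
    out_dir: str | None = None
    save_masks: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rolling_radius_px < 1:
            raise ValueError("rolling_radius_px must be >= 1")
        if self.min_area_px < 0 or self.min_focus_px < 0:
            raise ValueError("area thresholds must be >= 0")
        if self.max_lag < 3:
            raise ValueError("max_lag must be >= 3")
        self.width_bounds_px = tuple(self.width_bounds_px)  # type: ignore[assignment]
        self.channel_order = tuple(self.channel_order)  # type: ignore[assignment]

    def iccs_params(self) -> IccsParams:
        return IccsParams(
            max_lag=self.max_lag,
            min_overlap=self.min_overlap,
            range_factor=self.range_factor,
            range_tol_px=self.range_tol_px,
            max_fit_iter=self.max_fit_iter,
            width_bounds_px=self.width_bounds_px,
            f_limit=self.f_limit,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["width_bounds_px"] = list(self.width_bounds_px)
        data["channel_order"] = list(self.channel_order)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def analyze_pair(
    ch_damage: ChannelImage,
    ch_dna: ChannelImage,
    config: RunConfig | None = None,
    image_id: str = "image",
) -> pd.DataFrame:
    """Run the full per-cell analysis on one channel pair.

    Returns one row per segmented nucleus (columns ``RESULT_COLUMNS``);
    an empty table when no nuclei survive segmentation.
    """
    config = config or RunConfig()
    if ch_damage.shape != ch_dna.shape:
        raise ValueError("channel shapes differ")

    dna_sub = rolling_ball_subtract(ch_dna, config.rolling_radius_px)
    dmg_sub = rolling_ball_subtract(ch_damage, config.rolling_radius_px)
    seg_source = dna_sub if config.segment_on_subtracted else ch_dna
    nuclei = segment_nuclei(
        seg_source,
        min_area_px=config.min_area_px,
        exclude_border=config.exclude_border,
        max_area_px=config.max_area_px,
        min_solidity=config.min_solidity,
    )
    if nuclei.n_objects == 0:
        logger.warning("%s: no nuclei survived segmentation", image_id)
        return pd.DataFrame(columns=RESULT_COLUMNS)

    dmask = damage_mask(dmg_sub, config.foci_threshold)
    coloc = per_cell_iccs(dmg_sub, dna_sub, nuclei, config.iccs_params())

    rows = []
    for (label, region), cres in zip(nuclei.iter_regions(), coloc):
        area = int(region.sum())
        n_foci = count_foci(dmask, region, config.min_focus_px)
        try:
            norm = normalize_dna(
                dna_sub, region, nucleus_label=label, max_percentile=config.max_percentile
            )
            dres = dna_density(norm, region, dmask)
            density_val, roi_area, density_reason = dres.dna_density, dres.roi_area_px, dres.reason
        except ValueError as exc:
            density_val, roi_area, density_reason = math.nan, 0, str(exc)

        reasons = [r for r in (density_reason, cres.reason) if r]
        valid = cres.valid and not math.isnan(density_val)
        rows.append(
            dict(
                image_id=image_id,
                cell_id=label,
                area_px=area,
                n_foci=n_foci,
                roi_area_px=roi_area,
                dna_density=density_val,
                f1=cres.f1,
                f2=cres.f2,
                w_cross_px=_fit_attr(cres.fit_cross, "width_w_px"),
                w_auto1_px=_fit_attr(cres.fit_auto1, "width_w_px"),
                w_auto2_px=_fit_attr(cres.fit_auto2, "width_w_px"),
                G0_cross=_fit_attr(cres.fit_cross, "amplitude_g0"),
                G0_auto1=_fit_attr(cres.fit_auto1, "amplitude_g0"),
                G0_auto2=_fit_attr(cres.fit_auto2, "amplitude_g0"),
                valid=valid,
                reason="; ".join(reasons),
            )
        )
        logger.info(
            "%s cell %d: area=%d foci=%d density=%.3f f1=%.3f valid=%s %s",
            image_id, label, area, n_foci, density_val,
            cres.f1 if cres.f1 == cres.f1 else float("nan"), valid,
            ("(" + "; ".join(reasons) + ")") if reasons else "",
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_quando(
    config: RunConfig,
    inputs: Sequence[tuple[str | Path, str | Path | None]],
    image_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the batch over TIFF inputs and write CSVs.

    ``inputs`` is a sequence of ``(path1, path2)`` pairs (``path2`` None for
    a single 2-channel TIFF). Unreadable or mismatched images become error
    records; the batch continues. Writes ``results.csv`` and
    ``summary.csv`` under ``config.out_dir`` when set.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    ids = list(image_ids) if image_ids is not None else [
        Path(str(p1)).stem for p1, _ in inputs
    ]
    if len(ids) != len(inputs):
        raise ValueError("image_ids must match inputs")

    tables = []
    errors = []
    for image_id, (p1, p2) in zip(ids, inputs):
        try:
            ch_damage, ch_dna = qio.read_channel_pair(
                p1, p2, channel_order=config.channel_order,
                pixel_size_nm=config.pixel_size_nm,
            )
            table = analyze_pair(ch_damage, ch_dna, config, image_id=image_id)
            tables.append(table)
            if config.save_masks and config.out_dir:
                _save_masks(ch_damage, ch_dna, config, image_id)
        except Exception as exc:
            logger.error("%s: %s", image_id, exc)
            errors.append(dict(image_id=image_id, error=str(exc)))
    results = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    summary = summarize(results, "image_id") if len(results) else pd.DataFrame()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results_csv(results, out / "results.csv")
        write_results_csv(summary, out / "summary.csv")
        if errors:
            write_results_csv(pd.DataFrame(errors), out / "errors.csv")
    return results, summary


def summarize(results: pd.DataFrame, group_by: str) -> pd.DataFrame:
    """Per-group mean ± sd of density and f1 over valid cells, with an
    exclusion tally by reason."""
    if len(results) == 0:
        raise ValueError("results table is empty")
    if group_by not in results.columns:
        raise ValueError(f"unknown grouping key {group_by!r}")
    rows = []
    for key, grp in results.groupby(group_by, sort=True):
        valid = grp[grp["valid"] == True]  # noqa: E712 - CSV round-trips as object
        excluded = grp[grp["valid"] != True]  # noqa: E712
        rows.append(
            dict(
                group=key,
                n_cells=len(valid),
                dna_density_mean=float(valid["dna_density"].mean()) if len(valid) else math.nan,
                dna_density_sd=float(valid["dna_density"].std(ddof=1)) if len(valid) > 1 else math.nan,
                f1_mean=float(valid["f1"].mean()) if len(valid) else math.nan,
                f1_sd=float(valid["f1"].std(ddof=1)) if len(valid) > 1 else math.nan,
                n_foci_mean=float(grp["n_foci"].mean()),
                n_excluded=len(excluded),
                exclusion_reasons="; ".join(
                    sorted({str(r) for r in excluded["reason"] if isinstance(r, str) and r})
                ),
            )
        )
    return pd.DataFrame(rows)


def write_results_csv(table: pd.DataFrame, path: str | Path) -> None:
    """UTF-8 CSV with header row and NA for undefined values (deterministic)."""
    table.to_csv(path, index=False, na_rep="NA", encoding="utf-8", lineterminator="\n")


def _fit_attr(fit, attr: str) -> float:
    if fit is None:
        return math.nan
    return float(getattr(fit, attr))


def _save_masks(ch_damage: ChannelImage, ch_dna: ChannelImage, config: RunConfig, image_id: str) -> None:
    out = Path(config.out_dir)  # type: ignore[arg-type]
    out.mkdir(parents=True, exist_ok=True)
    seg_source = (
        rolling_ball_subtract(ch_dna, config.rolling_radius_px)
        if config.segment_on_subtracted else ch_dna
    )
    nuclei = segment_nuclei(
        seg_source, min_area_px=config.min_area_px, exclude_border=config.exclude_border,
        max_area_px=config.max_area_px, min_solidity=config.min_solidity,
    )
    dmg_sub = rolling_ball_subtract(ch_damage, config.rolling_radius_px)
    qio.write_count_mask(out / f"{image_id}_count_mask.tif", nuclei)
    qio.write_binary_mask(out / f"{image_id}_damage_mask.tif", damage_mask(dmg_sub, config.foci_threshold))
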