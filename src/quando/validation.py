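"""Single-cell simulate-and-analyze batches for validation studies.

Drives the full analysis path (simulate -> segment -> background subtract ->
damage mask -> density -> ICCS) over many independent synthetic nuclei and
collects per-cell numbers, so validation experiments (independence null,
heterochromatin-targeted placement, p_het sweeps) are one call.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .density import dna_density, normalize_dna
from .iccs import IccsParams, per_cell_iccs
from .preprocess import count_foci, damage_mask, rolling_ball_subtract, segment_nuclei
from .synthetic import SceneParams, simulate_nucleus


def simulate_and_analyze(
    n_cells: int,
    scene: SceneParams | None = None,
    base_seed: int = 0,
    foci_threshold: float = 100.0,
    rolling_radius_px: int = 10,
    min_focus_px: int = 4,
    min_area_px: int = 2000,
    iccs_params: IccsParams | None = None,
    identical_channels: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_cells`` independent nuclei (seeds ``base_seed + i``) and
    run the per-cell analysis on each.

    With ``identical_channels`` the background-subtracted DNA channel is used
    as both ICCS inputs (the perfect-colocalization limit).

    Returns a table with one row per simulated cell: ``seed, segmented,
    f1, f2, valid, reason, dna_density, roi_area_px, n_foci, p_het``.
    """
    scene = scene or SceneParams()
    iccs_params = iccs_params or IccsParams()
    rows = []
    for i in range(n_cells):
        params = replace(scene, seed=base_seed + i)
        ch1, ch2, truth = simulate_nucleus(params)
        nuclei = segment_nuclei(ch2, min_area_px=min_area_px)
        row = dict(
            seed=params.seed, segmented=nuclei.n_objects, p_het=params.p_het,
            f1=np.nan, f2=np.nan, valid=False, reason="",
            dna_density=np.nan, roi_area_px=0, n_foci=0,
        )
        if nuclei.n_objects != 1:
            row["reason"] = f"segmentation found {nuclei.n_objects} objects"
            rows.append(row)
            continue
        sub1 = rolling_ball_subtract(ch1, rolling_radius_px)
        sub2 = rolling_ball_subtract(ch2, rolling_radius_px)
        iccs_ch1 = sub2.with_pixels(sub2.pixels.copy()) if identical_channels else sub1
        res = per_cell_iccs(iccs_ch1, sub2, nuclei, iccs_params)[0]
        row.update(f1=res.f1, f2=res.f2, valid=res.valid, reason=res.reason)

        region = nuclei.region(1)
        dmask = damage_mask(sub1, foci_threshold)
        dres = dna_density(normalize_dna(sub2, region), region, dmask)
        row.update(
            dna_density=dres.dna_density,
            roi_area_px=dres.roi_area_px,
            n_foci=count_foci(dmask, region, min_focus_px),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def mean_valid_f1(table: pd.DataFrame) -> float:
    """Mean f1 over QC-valid cells."""
    valid = table[table["valid"]]
    return float(valid["f1"].mean()) if len(valid) else float("nan")


def mean_defined_density(table: pd.DataFrame) -> float:
    """Mean DNA density over cells with a nonempty damage ROI."""
    defined = table[table["roi_area_px"] > 0]
    return float(defined["dna_density"].mean()) if len(defined) else float("nan")
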