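"""Monte-Carlo calibration of the end-to-end pipeline.

Two study-level operating characteristics:

* power: a known per-zone vessel-density effect (expressed in units of the
  generator's nominal between-eye SD) is injected into one group's phantom
  eyes; the full raster pipeline (rasterize -> zones -> skeleton -> metrics ->
  gated statistics) is run and the fraction of replicates flagging the
  injected cell is reported;
* type-I error: the gated statistics protocol is run on null cohorts drawn
  from the generator's between-eye sampling model (normal per-eye densities,
  identical across groups) and the overall false-flag rate over all metric
  cells is reported.  The type-I simulation works at the metric-table level:
  the protocol under calibration is identical, and this permits hundreds of
  replicates where full rasterization would permit only a handful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantoms import CohortSpec, generate_cohort
from .pipeline import PipelineConfig, cohort_metrics
from .stats import StatsConfig, compare_metric_across_groups

#: parafoveal per-class density and its nominal between-eye SD (defaults of
#: :class:`vesselmetrics.phantoms.CohortSpec`: 0.18 per zone split over two
#: classes, 8% relative eye effect)
NOMINAL_CLASS_VD = 0.09
NOMINAL_BETWEEN_EYE_SD = 0.08 * NOMINAL_CLASS_VD


def estimate_power_injected_vd(
    seed: int,
    n_reps: int = 10,
    eyes_per_group: int = 10,
    effect_sds: float = 3.0,
    zone: str = "para_I",
    vessel_class: str = "vein",
    image_px: int = 152,
) -> dict:
    """Detection rate of an injected per-zone VD deficit, full pipeline.

    The effect is ``effect_sds`` times the nominal between-eye SD, removed
    from one group's target density in one zone/class cell.
    """
    offset = -effect_sds * NOMINAL_BETWEEN_EYE_SD
    hits = 0
    config = PipelineConfig()
    for rep in range(n_reps):
        spec = CohortSpec(
            eyes_per_group=eyes_per_group,
            image_shape=(image_px, image_px),
            pixel_pitch_mm=3.0 / image_px,
            vessel_width_mm=(0.04, 0.07),
            density_offsets={"NPDR": {(zone, vessel_class): offset}},
            seed=(seed * 1009 + rep) % (2**31),
        )
        cohort = generate_cohort(spec)
        table, _ = cohort_metrics(cohort, config)
        results = compare_metric_across_groups(
            table, cohort.manifest[["eye_id", "group"]], config.stats, metrics=["VD"]
        )
        cell = results[
            (results.zone == zone) & (results.vessel_class == vessel_class)
        ]
        if bool(cell["significant"].iloc[0]):
            hits += 1
    return {"power": hits / n_reps, "n_reps": n_reps, "eyes_per_group": eyes_per_group}


def _null_metric_table(rng: np.random.Generator, eyes_per_group: int) -> pd.DataFrame:
    rows = []
    for g in ("control", "NDR", "NPDR"):
        for e in range(eyes_per_group):
            for zone in ("fovea", "para_S", "para_I", "para_N", "para_T"):
                mu = NOMINAL_CLASS_VD if zone != "fovea" else 0.03
                for cls in ("artery", "vein"):
                    rows.append(
                        {
                            "eye_id": f"{g}{e}",
                            "zone": zone,
                            "vessel_class": cls,
                            "group": g,
                            "VD": rng.normal(mu, 0.08 * mu),
                        }
                    )
    return pd.DataFrame(rows)


def estimate_protocol_type_i(
    seed: int,
    n_sims: int = 500,
    eyes_per_group: int = 10,
    config: StatsConfig | None = None,
) -> dict:
    """False-positive rate of the full gated protocol on null cohorts."""
    rng = np.random.default_rng(seed)
    flagged = tested = 0
    for _ in range(n_sims):
        table = _null_metric_table(rng, eyes_per_group)
        out = compare_metric_across_groups(
            table, dict(zip(table.eye_id, table.group)), config
        )
        flagged += int(out["significant"].sum())
        tested += int(out["p"].notna().sum())
    return {"type_i_error": flagged / tested, "n_sims": n_sims, "n_cells": tested}
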