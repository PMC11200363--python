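"""Outcome metrics: area-weighted averages, stent effect, comparison reports.

Three scalar metrics summarize each scenario, all area-weighted averages
over element (edge) measures:

* ``Pavg`` (Pa): fluid pressure on the vessel wall over the dehiscence
  (SSWD) patch, at the moment of maximum velocity of the last cycle;
* ``Davg`` (um): displacement magnitude of the wall over the SSWD patch at
  the same moment;
* ``SPLavg`` (dB): sound pressure level along the tympanum at the acoustic
  analysis frequency.

The stent effect is reported as the pre - post difference for each metric
(positive = improvement) and as a percent reduction relative to the
preoperative value.  A bundled six-patient reference cohort (pre/post
values reported from a clinical imaging study) exercises the difference
arithmetic end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

REPORT_COLUMNS = ["scenario", "phase", "Pavg_Pa", "Davg_um", "SPLavg_dB",
                  "dPavg_Pa", "dDavg_um", "dSPL_dB", "pct_Pavg"]


def area_weighted_average(values, areas) -> float:
    """sum(value_i area_i) / sum(area_i)."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if values.shape != areas.shape or values.size == 0:
        raise ValueError("values and areas must be equal-length and non-empty")
    if np.any(areas < 0) or areas.sum() <= 0:
        raise ValueError("element measures must be positive overall")
    return float(np.sum(values * areas) / np.sum(areas))


def pre_post_difference(pre: float, post: float) -> float:
    """Stent effect: preoperative minus postoperative value.

    One convention for all three metrics; positive means the metric
    decreased after stenting.
    """
    if not (np.isfinite(pre) and np.isfinite(post)):
        raise ValueError("pre and post must be finite")
    return pre - post


def percent_reduction(pre: float, post: float) -> float:
    """100 x (pre - post) / pre."""
    if pre == 0:
        raise ValueError("percent reduction undefined for pre = 0")
    return 100.0 * (pre - post) / pre


@dataclass
class MetricsRecord:
    """Metrics of one scenario run."""

    scenario: str
    phase: str               # "pre" or "post"
    Pavg: float              # Pa
    Davg: float              # um
    SPLavg: float            # dB
    reynolds_max: float = float("nan")
    analysis_frequency: float = float("nan")   # Hz
    first_mode_frequency: float = float("nan")  # Hz
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def build_comparison_report(pairs: dict[str, tuple[MetricsRecord, MetricsRecord]]
                            ) -> pd.DataFrame:
    """Assemble a pre/post comparison table.

    ``pairs`` maps scenario name -> (pre record, post record).  The result
    has one row per record; difference columns are attached to the 'pre'
    rows (pre - post for all three metrics).
    """
    rows = []
    for name, (pre, post) in pairs.items():
        if pre.phase == post.phase:
            raise ValueError(f"scenario {name!r}: need one pre and one post record")
        if pre.phase != "pre":
            pre, post = post, pre
        rows.append({
            "scenario": name, "phase": "pre",
            "Pavg_Pa": pre.Pavg, "Davg_um": pre.Davg, "SPLavg_dB": pre.SPLavg,
            "dPavg_Pa": pre_post_difference(pre.Pavg, post.Pavg),
            "dDavg_um": pre_post_difference(pre.Davg, post.Davg),
            "dSPL_dB": pre_post_difference(pre.SPLavg, post.SPLavg),
            "pct_Pavg": percent_reduction(pre.Pavg, post.Pavg),
        })
        rows.append({
            "scenario": name, "phase": "post",
            "Pavg_Pa": post.Pavg, "Davg_um": post.Davg, "SPLavg_dB": post.SPLavg,
            "dPavg_Pa": np.nan, "dDavg_um": np.nan, "dSPL_dB": np.nan,
            "pct_Pavg": np.nan,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def save_report(df: pd.DataFrame, basepath: str | Path) -> None:
    """Serialize a comparison report as CSV and JSON side by side."""
    base = Path(basepath)
    df.to_csv(base.with_suffix(".csv"), index=False)
    base.with_suffix(".json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=1, allow_nan=True))


def load_report(basepath: str | Path) -> pd.DataFrame:
    base = Path(basepath)
    if base.with_suffix(".csv").exists():
        return pd.read_csv(base.with_suffix(".csv"))
    recs = json.loads(base.with_suffix(".json").read_text())
    return pd.DataFrame(recs, columns=REPORT_COLUMNS)


# -- reference cohort -------------------------------------------------------

#: Pre/post metric values of a six-patient clinical cohort (patients 1-3:
#: middle-segment stenosis; 4-6: middle segment with proximal involvement),
#: as reported in the literature.  Columns: Pavg (Pa), Davg (um), SPLavg (dB).
REFERENCE_COHORT = pd.DataFrame(
    [
        (1, "group1", 161.34, 164.67, 5.02, 5.06, 69.63, 69.93),
        (2, "group1", 155.72, 157.62, 8.99, 9.08, 78.89, 79.90),
        (3, "group1", 108.32, 103.64, 4.39, 4.15, 62.42, 62.74),
        (4, "group2", 600.71, 404.02, 16.83, 12.03, 67.35, 58.08),
        (5, "group2", 469.67, 419.27, 60.78, 53.61, 96.05, 84.80),
        (6, "group2", 341.92, 231.48, 11.56, 7.29, 59.72, 41.32),
    ],
    columns=["patient", "group", "Pavg_pre", "Pavg_post", "Davg_pre",
             "Davg_post", "SPL_pre", "SPL_post"],
)

#: the difference cells printed alongside the cohort (pre - post)
REFERENCE_DIFFERENCES = pd.DataFrame(
    [
        (1, -3.33, -0.04, -0.30),
        (2, -1.90, -0.09, -1.02),
        (3, 4.68, 0.24, -0.32),
        (4, 196.69, 4.80, 9.27),
        (5, 50.39, 7.17, 11.25),
        (6, 110.44, 4.27, 18.40),
    ],
    columns=["patient", "dPavg", "dDavg", "dSPL"],
)


def cohort_differences() -> pd.DataFrame:
    """Recompute every difference cell of the reference cohort."""
    rows = []
    for _, r in REFERENCE_COHORT.iterrows():
        rows.append({
            "patient": int(r["patient"]),
            "dPavg": pre_post_difference(r["Pavg_pre"], r["Pavg_post"]),
            "dDavg": pre_post_difference(r["Davg_pre"], r["Davg_post"]),
            "dSPL": pre_post_difference(r["SPL_pre"], r["SPL_post"]),
        })
    return pd.DataFrame(rows)


def cohort_percent_reductions() -> pd.DataFrame:
    """Percent Pavg reduction per cohort patient."""
    out = []
    for _, r in REFERENCE_COHORT.iterrows():
        out.append({"patient": int(r["patient"]),
                    "pct_Pavg": percent_reduction(r["Pavg_pre"], r["Pavg_post"])})
    return pd.DataFrame(out)
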