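"""The packaged clinical dataset and its reproduction.

Fourteen two-time-point observations of truncated-CSF3R clone frequencies in
severe-congenital-neutropenia patients, collated from three published
longitudinal sequencing studies, ship with the package (``data/table1.csv``)
together with the odds and selection-coefficient values printed in the original
tabulation.  :func:`reproduce_table1` recomputes those columns from the printed
``(y0, y1, dt_years, lambda)`` inputs and flags every row whose printed value is
not recovered at printed precision — the printed frequencies are rounded
readings of source figures, so some rows cannot match the original spreadsheet
exactly, and they are reported side by side rather than silently altered.

:func:`fig3_summary` summarizes the estimates against the observation interval
(the scatter shows a negative association, plausibly an ascertainment effect:
faster progression is re-sequenced sooner) and by disease phase (MDS vs AML).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import TwoPointObservation, estimate_s_given_u
from .moran import InvalidParameterError

__all__ = [
    "PatientRecord",
    "load_table1",
    "table1_dataframe",
    "record_to_observation",
    "reproduce_table1",
    "printed_scatter",
    "fig3_summary",
]

PHASES = ("MDS", "AML", "unclassified")


@dataclass(frozen=True)
class PatientRecord:
    """One row of the packaged dataset, values exactly as printed."""

    identifier: int
    reference: str
    figure: str
    case_label: str
    phase: str
    y0: float
    y1: float
    dt_years: float
    lam: float
    printed_odds0: float
    printed_odds1: float
    printed_s_hat: float
    mutation: str


def table1_dataframe() -> pd.DataFrame:
    """The packaged dataset as a DataFrame, columns as printed."""
    with resources.files("moranselect.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_table1() -> list[PatientRecord]:
    """All 14 patient records, verbatim."""
    df = table1_dataframe()
    records = [
        PatientRecord(
            identifier=int(r["identifier"]),
            reference=str(r["reference"]),
            figure=str(r["figure"]),
            case_label=str(r["case_label"]),
            phase=str(r["phase"]),
            y0=float(r["y0"]),
            y1=float(r["y1"]),
            dt_years=float(r["dt_years"]),
            lam=float(r["lambda"]),
            printed_odds0=float(r["printed_odds0"]),
            printed_odds1=float(r["printed_odds1"]),
            printed_s_hat=float(r["printed_s_hat"]),
            mutation=str(r["mutation"]),
        )
        for _, r in df.iterrows()
    ]
    assert len(records) == 14
    return records


def record_to_observation(rec: PatientRecord) -> TwoPointObservation:
    return TwoPointObservation(
        y0=rec.y0,
        y1=rec.y1,
        dt_years=rec.dt_years,
        lam=rec.lam,
        case_id=rec.case_label,
        phase=rec.phase,
        mutation=rec.mutation,
        source=rec.reference,
    )


def reproduce_table1(u: float = 0.0, lam: float | None = None) -> pd.DataFrame:
    """Recompute odds and s_hat for every record and compare to printed values.

    Rounding follows the table's printing: odds to 2 decimals, s_hat to 3.
    ``match_*`` columns are True where the rounded recomputation equals the
    printed value; mismatching rows are flagged, never altered.  ``lam``
    optionally overrides the division rate of every record (the printed values
    assume 24/year, so overriding it will unmatch the s_hat column).
    """
    rows = []
    for rec in load_table1():
        obs = record_to_observation(rec)
        if lam is not None:
            obs = TwoPointObservation(
                y0=obs.y0, y1=obs.y1, dt_years=obs.dt_years, lam=lam,
                case_id=obs.case_id, phase=obs.phase, mutation=obs.mutation,
                source=obs.source,
            )
        res = estimate_s_given_u(obs, u)
        s_r = round(res.s_hat, 3)
        o0_r = round(res.odds0, 2)
        o1_r = round(res.odds1, 2)
        rows.append(
            {
                "identifier": rec.identifier,
                "case_label": rec.case_label,
                "phase": rec.phase,
                "y0": rec.y0,
                "y1": rec.y1,
                "dt_years": rec.dt_years,
                "lambda": obs.lam,
                "computed_odds0": o0_r,
                "printed_odds0": rec.printed_odds0,
                "computed_odds1": o1_r,
                "printed_odds1": rec.printed_odds1,
                "computed_s_hat": s_r,
                "printed_s_hat": rec.printed_s_hat,
                "s_hat_unrounded": res.s_hat,
                "match_odds0": o0_r == rec.printed_odds0,
                "match_odds1": o1_r == rec.printed_odds1,
                "match_s_hat": s_r == rec.printed_s_hat,
            }
        )
    return pd.DataFrame(rows)


def printed_scatter() -> pd.DataFrame:
    """(identifier, s_hat, dt_years, phase) using the printed estimates."""
    recs = load_table1()
    return pd.DataFrame(
        {
            "identifier": [r.identifier for r in recs],
            "s_hat": [r.printed_s_hat for r in recs],
            "dt_years": [r.dt_years for r in recs],
            "phase": [r.phase for r in recs],
        }
    )


def fig3_summary(scatter: pd.DataFrame | None = None) -> dict:
    """Association of the estimates with the observation interval, plus phase means.

    Pearson and Spearman correlations of (s_hat, dt_years) are reported both on
    all records and excluding negative estimates (a shrinking clone is outside
    the growth model the estimator assumes).  Raises on fewer than 3 records or
    on degenerate (zero-variance) inputs.
    """
    if scatter is None:
        scatter = printed_scatter()
    if len(scatter) < 3:
        raise InvalidParameterError("need at least 3 records for an association")
    s = scatter["s_hat"].to_numpy(dtype=float)
    dt = scatter["dt_years"].to_numpy(dtype=float)
    if np.ptp(s) == 0.0 or np.ptp(dt) == 0.0:
        raise InvalidParameterError("correlation undefined on constant input")

    def _corrs(sv, dtv):
        return {
            "pearson_r": float(stats.pearsonr(sv, dtv).statistic),
            "spearman_rho": float(stats.spearmanr(sv, dtv).statistic),
            "n": int(len(sv)),
        }

    positive = s > 0
    out = {
        "all": _corrs(s, dt),
        "excluding_negative": (
            _corrs(s[positive], dt[positive]) if positive.sum() >= 3 else None
        ),
        "phase_mean_s_hat": {
            ph: float(scatter.loc[scatter["phase"] == ph, "s_hat"].mean())
            for ph in PHASES
            if (scatter["phase"] == ph).any()
        },
        "scatter": scatter[["identifier", "s_hat", "dt_years", "phase"]].copy(),
    }
    return out
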