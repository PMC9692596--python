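"""Reference per-lysosome pixel counts and their reproduction.

The package ships the published per-lysosome measurements (total pixels and
foreground "red" pixels for 8 lysosome/microvesicle images, with the
percentages and particle estimates printed alongside them) as a small CSV
fixture. :func:`reproduce` re-derives the percentage and particle-count
columns from the pixel counts alone, using the reporting convention of a
6 px/particle footprint with round-half-up, and flags the rows whose
printed estimates do not follow from their printed pixel counts (rows 1, 6,
7 and 8 do not; rows 2-5 and the averages reproduce exactly).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quantification import (
    QuantRecord,
    QuantSummary,
    estimate_particles,
    summarize,
)
from ._rounding import round_half_up_decimals

#: Conventional per-particle area, in pixels at the reduced (3.88 nm/px)
#: resolution, used for the published estimates.
REFERENCE_FOOTPRINT_PX = 6.0


def printed_rows() -> pd.DataFrame:
    """The published table: image, total_px, red_px, printed_pct, printed_est."""
    with resources.files("spioquant.data").joinpath("table1.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def printed_average_uptake() -> int:
    """Mean of the eight published per-lysosome estimates, truncated.

    The published average (78 particles per lysosome) is the truncated
    arithmetic mean of the printed estimate column — including the rows
    whose estimates do not follow from their own printed pixel counts — so
    it is derived here from that column, not from re-estimation.
    """
    est = printed_rows()["printed_est"]
    return int(est.sum() / len(est))  # truncation toward zero


def reproduce(
    footprint_px: float = REFERENCE_FOOTPRINT_PX,
) -> tuple[QuantSummary, pd.DataFrame]:
    """Recompute percentages and estimates from the printed pixel counts.

    Returns the recomputed summary and a comparison frame with columns
    ``recomputed_pct``, ``recomputed_est``, ``printed_pct``, ``printed_est``
    and ``est_matches`` (whether the printed estimate equals the recomputed
    one).
    """
    rows = printed_rows()
    records = []
    for row in rows.itertuples(index=False):
        records.append(
            QuantRecord(
                roi_name=f"lysosome{int(row.image)}",
                total_px=int(row.total_px),
                red_px=int(row.red_px),
                red_pct=round_half_up_decimals(
                    100.0 * row.red_px / row.total_px, 2
                ),
                est_particles=estimate_particles(int(row.red_px), footprint_px),
            )
        )
    summary = summarize(records)
    comparison = pd.DataFrame(
        {
            "image": rows["image"],
            "total_px": rows["total_px"],
            "red_px": rows["red_px"],
            "recomputed_pct": [r.red_pct for r in records],
            "printed_pct": rows["printed_pct"],
            "recomputed_est": [r.est_particles for r in records],
            "printed_est": rows["printed_est"],
        }
    )
    comparison["est_matches"] = (
        comparison["recomputed_est"] == comparison["printed_est"]
    )
    return summary, comparison
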