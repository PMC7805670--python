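"""Reference bookkeeping tables for the mode-specific classification scheme.

These are the published per-class training-example counts of the
able-bodied bilateral benchmark (10 subjects, both legs combined) and the
decision counts of the powered-prosthesis case study.  They are bundled so
structural bookkeeping — row totals as sums of per-class counts, the
steady-state/transitional split of decisions — can be checked against the
implementation's own accounting.
"""

from __future__ import annotations

import pandas as pd

from .suite import MODES

#: training examples per mode-specific classifier cell (event_incoming ->
#: counts per true outgoing mode) with the published row totals.
TRAINING_EXAMPLE_COUNTS: dict[str, dict[str, int]] = {
    "HC_LW": {"LW": 4523, "RA": 240, "RD": 240, "SA": 239, "SD": 248, "total": 5490},
    "TO_LW": {"LW": 4637, "RA": 245, "RD": 246, "SA": 253, "SD": 243, "total": 5624},
    "HC_RA": {"LW": 243, "RA": 1408, "total": 1651},
    "TO_RA": {"LW": 252, "RA": 1416, "total": 1668},
    "HC_RD": {"LW": 239, "RD": 1757, "total": 1996},
    "TO_RD": {"LW": 245, "RD": 1762, "total": 2007},
    "HC_SA": {"LW": 238, "SA": 489, "total": 727},
    "TO_SA": {"LW": 245, "SA": 472, "total": 717},
    "HC_SD": {"LW": 248, "SD": 475, "total": 723},
    "TO_SD": {"LW": 242, "SD": 478, "total": 720},
}

#: decision counts of the powered-prosthesis case study
PROSTHESIS_DECISION_COUNTS: dict[str, int] = {
    "steady_state": 3027,
    "transitional": 400,
    "total": 3427,
}


def training_counts_table() -> pd.DataFrame:
    """Reference training-example counts as a DataFrame (NaN = illegal)."""
    rows = {
        cell: {m: counts.get(m, float("nan")) for m in MODES}
        | {"total": counts["total"]}
        for cell, counts in TRAINING_EXAMPLE_COUNTS.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def recomputed_row_totals() -> pd.Series:
    """Row totals recomputed as the sum of the per-class counts."""
    return pd.Series(
        {
            cell: sum(v for k, v in counts.items() if k != "total")
            for cell, counts in TRAINING_EXAMPLE_COUNTS.items()
        }
    )


def published_row_totals() -> pd.Series:
    return pd.Series({c: v["total"] for c, v in TRAINING_EXAMPLE_COUNTS.items()})


def recomputed_decision_total() -> int:
    """Prosthesis decision total recomputed from its split counts."""
    c = PROSTHESIS_DECISION_COUNTS
    return c["steady_state"] + c["transitional"]
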