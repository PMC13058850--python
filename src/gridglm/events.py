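"""BIDS-style events TSV reading and writing.

Tables are tab-separated with a header row; ``onset`` and ``duration`` are in
seconds, ``direction`` in degrees (allocentric movement direction for
translations, signed turn magnitude for rotations).  Missing values are
written as ``n/a``.  Unknown columns are preserved untouched on read.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ["onset", "duration", "trial_type"]


class EventTableError(ValueError):
    """Malformed events table."""


def write_events(trajectory_or_table, path) -> None:
    """Write an events table (or a Trajectory) as a BIDS-style TSV."""
    table = getattr(trajectory_or_table, "events", trajectory_or_table)
    table.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    """Read and validate a BIDS-style events TSV.

    Raises :class:`EventTableError` naming the offending row for missing
    mandatory columns, translations without a direction, or non-monotone
    onsets.
    """
    table = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise EventTableError(f"missing mandatory column(s): {missing}")
    onsets = table["onset"].to_numpy()
    for i in range(1, len(onsets)):
        if onsets[i] < onsets[i - 1]:
            raise EventTableError(f"onsets not monotone at row {i}")
    if "direction" not in table.columns:
        if (table["trial_type"] == "translation").any():
            row = int(table.index[table["trial_type"] == "translation"][0])
            raise EventTableError(
                f"translation event at row {row} has no 'direction' column"
            )
    else:
        bad = table.index[
            (table["trial_type"] == "translation") & table["direction"].isna()
        ]
        if len(bad):
            raise EventTableError(f"translation event at row {int(bad[0])} lacks a direction")
    return table
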