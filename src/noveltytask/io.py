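"""Tab-separated events I/O (BIDS-events-like).

Events tables are written as UTF-8 TSV with a header row and ``n/a`` for
missing values; the write/read round trip is lossless for every column.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_events", "write_events", "EventsFormatError"]

NA_REP = "n/a"

# canonical column order; extra columns are appended after these
_CANONICAL = [
    "onset",
    "duration",
    "trial_index",
    "stim_left",
    "stim_middle",
    "stim_right",
    "pres_left",
    "pres_middle",
    "pres_right",
    "chosen",
    "feedback",
    "ev_chosen",
    "rpe",
    "explore",
]

_INT_COLS = {
    "trial_index",
    "stim_left",
    "stim_middle",
    "stim_right",
    "pres_left",
    "pres_middle",
    "pres_right",
    "chosen",
}


class EventsFormatError(ValueError):
    """Malformed events file."""


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an events table as TSV (UTF-8, header row, n/a for missing)."""
    cols = [c for c in _CANONICAL if c in events.columns]
    cols += [c for c in events.columns if c not in cols]
    out = events[cols].copy()

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return NA_REP
        if isinstance(x, (bool, np.bool_)):
            return "true" if x else "false"
        if isinstance(x, (float, np.floating)):
            return repr(float(x))
        return str(x)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in out.iterrows():
            fh.write("\t".join(fmt(v) for v in row) + "\n")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events`.

    A row with the wrong number of fields raises
    :class:`EventsFormatError` naming the 1-based line number.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise EventsFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_cols = len(header)
    for i, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != n_cols:
            raise EventsFormatError(
                f"{path}: line {i} has {len(line.split(chr(9)))} fields, expected {n_cols}"
            )
    df = pd.read_csv(
        _io.StringIO("\n".join(lines)),
        sep="\t",
        na_values=[NA_REP],
        keep_default_na=False,
    )
    if "explore" in df.columns and df["explore"].notna().all():
        df["explore"] = df["explore"].map(
            {"true": True, "false": False, True: True, False: False}
        ).astype(bool)
    for col in df.columns:
        if col in _INT_COLS and df[col].notna().all():
            df[col] = df[col].astype(int)
    return df
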