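"""Reading and writing the delimited frequency-table format.

One row per condition with columns ``condition, lineup_size, cp_culprit,
cp_filler, cp_reject, ca_suspect, ca_filler, ca_reject`` (an optional
``ca_reconstructed`` flag marks culprit-absent tables whose suspect/filler
split was reconstructed from a pooled false-identification count).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .trees import LineupCounts

__all__ = [
    "COUNT_COLUMNS",
    "counts_from_dataframe",
    "counts_to_dataframe",
    "read_counts_csv",
    "write_counts_csv",
]

COUNT_COLUMNS = (
    "condition",
    "lineup_size",
    "cp_culprit",
    "cp_filler",
    "cp_reject",
    "ca_suspect",
    "ca_filler",
    "ca_reject",
)


def counts_from_dataframe(frame: pd.DataFrame) -> list[LineupCounts]:
    for col in COUNT_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"data table is missing required column {col!r}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            LineupCounts(
                condition_id=str(row["condition"]),
                lineup_size=int(row["lineup_size"]),
                cp_culprit=int(row["cp_culprit"]),
                cp_filler=int(row["cp_filler"]),
                cp_reject=int(row["cp_reject"]),
                ca_suspect=int(row["ca_suspect"]),
                ca_filler=int(row["ca_filler"]),
                ca_reject=int(row["ca_reject"]),
                ca_reconstructed=bool(row.get("ca_reconstructed", False)),
            )
        )
    return out


def counts_to_dataframe(data: Sequence[LineupCounts]) -> pd.DataFrame:
    rows = []
    for d in data:
        rows.append(
            {
                "condition": d.condition_id,
                "lineup_size": d.lineup_size,
                "cp_culprit": d.cp_culprit,
                "cp_filler": d.cp_filler,
                "cp_reject": d.cp_reject,
                "ca_suspect": d.ca_suspect,
                "ca_filler": d.ca_filler,
                "ca_reject": d.ca_reject,
                "ca_reconstructed": d.ca_reconstructed,
            }
        )
    return pd.DataFrame(rows)


def read_counts_csv(path) -> list[LineupCounts]:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # surface file/parse problems with the path
        raise ValueError(f"could not read count table {path!r}: {exc}") from exc
    return counts_from_dataframe(frame)


def write_counts_csv(data: Sequence[LineupCounts], path) -> None:
    counts_to_dataframe(data).to_csv(path, index=False)
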