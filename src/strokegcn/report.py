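"""Report bundle writers: summary tables, confusion matrices, run logs."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .training import ConfusionMatrix, RunSummary

__all__ = ["write_run_summary", "write_confusion", "append_run_log"]


def write_run_summary(summary: RunSummary, path) -> pd.DataFrame:
    """Write the Mean/Max/Min/SD table (percent scale) as CSV."""
    table = summary.table()
    table.to_csv(path, index_label="metric", float_format="%.2f")
    return table


def write_confusion(cm: ConfusionMatrix, path_counts, path_percent=None) -> None:
    """Write a confusion matrix as counts and optionally row-percentages."""
    idx = [f"true_{c}" for c in cm.class_names]
    cols = [f"pred_{c}" for c in cm.class_names]
    pd.DataFrame(cm.counts, index=idx, columns=cols).to_csv(path_counts)
    if path_percent is not None:
        pd.DataFrame(cm.as_percent(), index=idx, columns=cols).to_csv(
            path_percent, float_format="%.2f")


def append_run_log(path, record: dict) -> None:
    """Append one JSON line with seeds, config and results."""
    record = {"timestamp": datetime.now(timezone.utc).isoformat(), **record}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
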