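"""Participant exclusion, RT trimming, and behavioural summaries.

The trial table is a tidy pandas DataFrame with one row per trial and columns
``participant``, ``task``, ``condition`` (congruent | incongruent | neutral),
``rt_ms``, ``correct`` (0/1), plus an optional ``block`` label for designs
with speed/accuracy instruction blocks.

Cleaning follows the standard two-step convention for conflict-task data:

* participants below 60% overall accuracy in any single task are excluded
  from all tasks (decided on untrimmed data, strict inequality, so exactly
  60% is retained);
* within each participant x task x condition cell, RTs below 100 ms are
  removed first, then RTs strictly greater than median + 3 * MAD of the
  remaining RTs, where MAD is the raw (unscaled) median absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "BehavioralSummary",
    "exclude_participants",
    "trim_rts",
    "behavioral_summary",
]

REQUIRED_COLUMNS = ("participant", "task", "condition", "rt_ms", "correct")
_CELL = ["participant", "task", "condition"]


@dataclass
class BehavioralSummary:
    """Per participant x task costs and RT quantiles.

    ``costs`` has one row per participant x task with per-condition accuracy
    and mean correct RT plus ``rt_cost`` (ms, incongruent - congruent mean
    correct RT) and ``error_cost`` (incongruent - congruent error rate).
    ``quantiles`` is long-format: one row per participant x task x condition
    x correctness x probability.
    """

    costs: pd.DataFrame
    quantiles: pd.DataFrame


def _check_table(table: pd.DataFrame) -> None:
    if len(table) == 0:
        raise ValueError("trial table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")


def exclude_participants(
    table: pd.DataFrame, threshold: float = 0.60
) -> tuple[pd.DataFrame, list]:
    """Drop participants whose overall accuracy in any task falls below
    ``threshold``; returns the filtered table and the excluded IDs.

    Accuracy is pooled over all conditions and blocks of a task, and the
    exclusion applies to the participant's data in every task.
    """
    _check_table(table)
    acc = table.groupby(["participant", "task"], sort=False)["correct"].mean()
    bad = acc[acc < threshold].index.get_level_values("participant").unique()
    excluded = sorted(bad.tolist())
    return table[~table["participant"].isin(excluded)].copy(), excluded


def trim_rts(
    table: pd.DataFrame,
    *,
    fast_cutoff_ms: float = 100.0,
    mad_multiplier: float = 3.0,
    mad_scale: float = 1.0,
    stats_after_fast_trim: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove implausibly fast and slow RTs per participant x task x condition.

    RTs below ``fast_cutoff_ms`` are dropped, then RTs strictly greater than
    median + ``mad_multiplier`` * MAD of the cell.  ``mad_scale`` = 1.4826
    applies the normal-consistency scaling to the MAD (off by default);
    ``stats_after_fast_trim`` controls whether the median/MAD are computed
    after removing the fast trials (default) or on the raw cell.

    Returns the trimmed table and a per-cell report with counts removed by
    each rule and a flag for cells left empty.
    """
    _check_table(table)
    kept_parts: list[pd.DataFrame] = []
    report_rows = []
    for key, cell in table.groupby(_CELL, sort=False):
        rt = cell["rt_ms"].to_numpy(dtype=float)
        fast = rt < fast_cutoff_ms
        basis = rt[~fast] if stats_after_fast_trim else rt
        if basis.size:
            med = float(np.median(basis))
            mad = mad_scale * float(np.median(np.abs(basis - med)))
            cutoff = med + mad_multiplier * mad
        else:
            cutoff = np.inf
        slow = ~fast & (rt > cutoff)
        keep = ~(fast | slow)
        kept_parts.append(cell[keep])
        report_rows.append(
            dict(
                zip(_CELL, key),
                n_total=rt.size,
                n_fast_removed=int(fast.sum()),
                n_slow_removed=int(slow.sum()),
                n_retained=int(keep.sum()),
                slow_cutoff_ms=cutoff,
                empty_after_trim=bool(keep.sum() == 0),
            )
        )
    trimmed = pd.concat(kept_parts).sort_index() if kept_parts else table.iloc[0:0]
    return trimmed.copy(), pd.DataFrame(report_rows)


def behavioral_summary(
    table: pd.DataFrame,
    quantile_probs=(0.1, 0.3, 0.5, 0.7, 0.9),
) -> BehavioralSummary:
    """Per participant x task accuracy, mean correct RTs, costs, and quantiles.

    RT costs use correct trials only; error cost is the difference in error
    rates.  Groups missing the congruent or incongruent condition get NaN
    costs and ``complete=False``.  Neutral trials contribute their own
    accuracy/RT columns but never enter the costs.
    """
    _check_table(table)
    probs = np.asarray(quantile_probs, dtype=float)
    cost_rows = []
    quant_rows = []
    for (pid, task), grp in table.groupby(["participant", "task"], sort=False):
        row: dict = {"participant": pid, "task": task}
        for cond, sub in grp.groupby("condition", sort=False):
            correct = sub["correct"].astype(bool)
            row[f"accuracy_{cond}"] = float(correct.mean())
            crt = sub.loc[correct, "rt_ms"]
            row[f"mean_rt_{cond}"] = float(crt.mean()) if len(crt) else np.nan
            for is_correct, label in ((True, "correct"), (False, "error")):
                rts = sub.loc[correct == is_correct, "rt_ms"].to_numpy()
                if rts.size:
                    qs = np.quantile(rts, probs)
                    quant_rows.extend(
                        {
                            "participant": pid,
                            "task": task,
                            "condition": cond,
                            "correctness": label,
                            "prob": p,
                            "rt_ms": q,
                        }
                        for p, q in zip(probs, qs)
                    )
        complete = "accuracy_congruent" in row and "accuracy_incongruent" in row
        row["complete"] = complete
        if complete:
            row["rt_cost"] = row["mean_rt_incongruent"] - row["mean_rt_congruent"]
            row["error_cost"] = (1 - row["accuracy_incongruent"]) - (
                1 - row["accuracy_congruent"]
            )
        else:
            row["rt_cost"] = np.nan
            row["error_cost"] = np.nan
        cost_rows.append(row)
    return BehavioralSummary(
        costs=pd.DataFrame(cost_rows), quantiles=pd.DataFrame(quant_rows)
    )
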