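"""Epoch features: FHR transition counts and per-label dwell totals.

Records are cut into fixed epochs anchored at delivery: epoch ``k`` spans
``[(k+1)*epoch_seconds, k*epoch_seconds)`` in time-before-delivery, so
``k = 0`` ends at delivery and indices grow backwards in time. A trailing
partial epoch at the record start is dropped. An epoch is *valid* when at
least ``min_valid`` (default 80%) of its span is interpretable.

Each valid epoch carries 11 features: six ordered FHR transition counts
(BAS<->ACC, BAS<->DEC, ACC<->DEC, both directions) and five dwell totals
in seconds (BAS, ACC, DEC on FHR; CON, RIN on UP). A transition is counted
for a chronologically consecutive pair of FHR events with different labels
whose inter-event gap is at most ``gap_tolerance`` (default 60 s), and is
assigned to the epoch containing the later event's start instant; boundary
instants belong to the closer-to-delivery epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import FHR, UP, EventInterval, LaborRecord

EPOCH_SECONDS = 1200.0
MIN_VALID_FRACTION = 0.8
GAP_TOLERANCE_S = 60.0

TRANSITION_PAIRS = (
    ("BAS", "ACC"),
    ("ACC", "BAS"),
    ("BAS", "DEC"),
    ("DEC", "BAS"),
    ("ACC", "DEC"),
    ("DEC", "ACC"),
)
DWELL_LABELS = ("BAS", "ACC", "DEC", "CON", "RIN")

TRANSITION_NAMES = tuple(f"t_{a.lower()}_{b.lower()}" for a, b in TRANSITION_PAIRS)
DWELL_NAMES = tuple(f"d_{lab.lower()}" for lab in DWELL_LABELS)
FEATURE_NAMES = TRANSITION_NAMES + DWELL_NAMES  # the 11-dimensional epoch vector

FEATURE_TABLE_COLUMNS = (
    "subject_id",
    "group",
    "epoch_index",
    "valid",
    "valid_fraction",
    *FEATURE_NAMES,
)

_PAIR_INDEX = {pair: i for i, pair in enumerate(TRANSITION_PAIRS)}
_DWELL_INDEX = {lab: i for i, lab in enumerate(DWELL_LABELS)}


@dataclass
class FeaturizeConfig:
    epoch_seconds: float = EPOCH_SECONDS
    min_valid: float = MIN_VALID_FRACTION
    gap_tolerance: float = GAP_TOLERANCE_S


def epoch_of_instant(t: float, epoch_seconds: float = EPOCH_SECONDS) -> int:
    """Epoch index containing instant ``t`` (seconds before delivery).

    Boundary instants belong to the later (closer-to-delivery) epoch:
    ``t = epoch_seconds`` is the earliest instant of epoch 0.
    """
    if t <= 0:
        return 0
    return max(int(math.ceil(t / epoch_seconds)) - 1, 0)


def epoch_grid(
    record: LaborRecord, epoch_seconds: float = EPOCH_SECONDS
) -> list[tuple[int, float]]:
    """(epoch_index, valid_fraction) for every complete epoch in the record.

    valid_fraction is the interpretable share of the epoch: 1 minus the
    overlap of the record's uninterpretable segments with the epoch window,
    divided by the epoch length.
    """
    n_epochs = int(record.duration // epoch_seconds)
    invalid_overlap = np.zeros(n_epochs)
    for start, end in record.invalid_intervals:
        _accumulate_overlap(invalid_overlap, start, end, n_epochs, epoch_seconds)
    return [(k, 1.0 - invalid_overlap[k] / epoch_seconds) for k in range(n_epochs)]


def _accumulate_overlap(
    acc: np.ndarray, start: float, end: float, n_epochs: int, epoch_seconds: float
) -> None:
    """Add the overlap of interval (start, end) with each epoch to ``acc``."""
    k_lo = max(int(end // epoch_seconds), 0)
    k_hi = min(int(math.ceil(start / epoch_seconds)), n_epochs)
    for k in range(k_lo, k_hi):
        ov = min(start, (k + 1) * epoch_seconds) - max(end, k * epoch_seconds)
        if ov > 0:
            acc[k] += ov


def count_transitions(
    fhr_events: list[EventInterval],
    n_epochs: int,
    gap_tolerance: float = GAP_TOLERANCE_S,
    epoch_seconds: float = EPOCH_SECONDS,
) -> np.ndarray:
    """Per-epoch counts of the six ordered FHR label transitions.

    Returns an ``(n_epochs, 6)`` integer array ordered as
    :data:`TRANSITION_PAIRS`. Pairs separated by a gap longer than
    ``gap_tolerance`` and pairs with equal labels (possible across a gap)
    are not counted.
    """
    counts = np.zeros((n_epochs, len(TRANSITION_PAIRS)), dtype=int)
    for earlier, later in zip(fhr_events, fhr_events[1:]):
        gap = earlier.end - later.start
        if gap > gap_tolerance or earlier.label == later.label:
            continue
        k = epoch_of_instant(later.start, epoch_seconds)
        if k < n_epochs:
            counts[k, _PAIR_INDEX[(earlier.label, later.label)]] += 1
    return counts


def dwell_times(
    events: list[EventInterval],
    n_epochs: int,
    epoch_seconds: float = EPOCH_SECONDS,
) -> np.ndarray:
    """Per-epoch dwell totals (seconds) for the five event labels.

    Returns an ``(n_epochs, 5)`` array ordered as :data:`DWELL_LABELS`;
    each entry is the length of the intersection of that label's intervals
    with the epoch window.
    """
    totals = np.zeros((n_epochs, len(DWELL_LABELS)))
    for ev in events:
        col = _DWELL_INDEX[ev.label]
        k_lo = max(int(ev.end // epoch_seconds), 0)
        k_hi = min(int(math.ceil(ev.start / epoch_seconds)), n_epochs)
        for k in range(k_lo, k_hi):
            ov = min(ev.start, (k + 1) * epoch_seconds) - max(ev.end, k * epoch_seconds)
            if ov > 0:
                totals[k, col] += ov
    return totals


def featurize_record(
    record: LaborRecord, config: FeaturizeConfig | None = None
) -> pd.DataFrame:
    """One row per complete epoch; invalid epochs are kept as placeholders.

    Rows whose ``valid_fraction`` falls below the validity threshold have
    ``valid = False`` and NaN features — they stay on the grid because the
    downstream alert-aggregation rule needs to know which slots are missing.
    """
    cfg = config or FeaturizeConfig()
    grid = epoch_grid(record, cfg.epoch_seconds)
    n_epochs = len(grid)
    trans = count_transitions(
        record.channel_events(FHR), n_epochs, cfg.gap_tolerance, cfg.epoch_seconds
    )
    dwells = dwell_times(
        record.channel_events(FHR) + record.channel_events(UP), n_epochs, cfg.epoch_seconds
    )
    rows = []
    for k, valid_fraction in grid:
        valid = valid_fraction >= cfg.min_valid
        feats = np.concatenate([trans[k], dwells[k]]).astype(float)
        if not valid:
            feats[:] = np.nan
        rows.append(
            {
                "subject_id": record.subject_id,
                "group": record.group,
                "epoch_index": k,
                "valid": valid,
                "valid_fraction": valid_fraction,
                **dict(zip(FEATURE_NAMES, feats)),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def featurize_cohort(
    records: list[LaborRecord], config: FeaturizeConfig | None = None
) -> pd.DataFrame:
    """Feature table for a whole cohort (concatenated per-record tables)."""
    frames = [featurize_record(rec, config) for rec in records]
    if not frames:
        return pd.DataFrame(columns=FEATURE_TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(FEATURE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table
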