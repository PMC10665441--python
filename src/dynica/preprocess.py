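"""Raw fluorescence -> log2 fold-change matrices.

The processing chain is fixed, in this order:

1. background correction: (raw - background) / background,
2. running median filter (kernel 11 on the 10-min grid, zero-padded edges),
3. promoterless-control normalization: (signal - control) / control, where the
   control is the mean of the processed promoterless strains,
4. windowed log2 fold change against the window's reference point (window start
   for the induction phase, window end for recovery), at points spaced 40 min.

The result is a promoters x (metal, timepoint) matrix: 6 metals x 6 induction
points gives 36 columns; the recovery variant has 6 x 20 columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .design import ExperimentDesign

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ("promoter_id", "time_min", "fluorescence", "background")

#: relative scale of the additive offset applied to rows with non-positive
#: normalized values before taking the log (see build_fold_change_matrix)
EPSILON_FRACTION = 1e-3


def background_correct(
    raw: np.ndarray, background: np.ndarray, promoter_id: str | None = None
) -> np.ndarray:
    """Amplification of the signal over the local background.

    value(t) = (raw(t) - background(t)) / background(t).
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError("raw and background series differ in length")
    bad = np.where(background <= 0)[0]
    if bad.size:
        who = f" for promoter {promoter_id!r}" if promoter_id else ""
        raise ValueError(
            f"non-positive background{who} at sample index {int(bad[0])}"
        )
    return (raw - background) / background


def median_filter_series(values: np.ndarray, kernel_size: int = 11) -> np.ndarray:
    """Running median with zero-padded edges; length preserved."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    values = np.asarray(values, dtype=float)
    if kernel_size == 1:
        return values.copy()
    return medfilt(values, kernel_size=kernel_size)


def control_normalize(
    series: pd.Series, control_mean: pd.Series
) -> pd.Series:
    """Normalize a processed series by the processed promoterless mean.

    value(t) = (s(t) - c(t)) / c(t), on the intersection of the time grids.
    """
    shared = series.index.intersection(control_mean.index)
    if len(shared) == 0:
        raise ValueError("series and control share no time points")
    c = control_mean.loc[shared].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise ValueError("control mean is non-positive on the shared grid")
    s = series.loc[shared].to_numpy(dtype=float)
    return pd.Series((s - c) / c, index=shared)


def _pivot_long(series_long: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = set(SERIES_COLUMNS) - set(series_long.columns)
    if missing:
        raise ValueError(f"long-format series is missing columns {sorted(missing)}")
    df = series_long.copy()
    df["time_min"] = df["time_min"].astype(float).round(6)
    raw = df.pivot(index="time_min", columns="promoter_id", values="fluorescence")
    bg = df.pivot(index="time_min", columns="promoter_id", values="background")
    return raw.sort_index(), bg.sort_index()


def process_series_frame(
    series_long: pd.DataFrame, kernel_size: int = 11
) -> pd.DataFrame:
    """Background-correct and median-filter every promoter series.

    Returns a wide frame: rows = time_min, columns = promoter ids.
    """
    raw, bg = _pivot_long(series_long)
    out = {}
    for pid in raw.columns:
        corrected = background_correct(
            raw[pid].to_numpy(), bg[pid].to_numpy(), promoter_id=str(pid)
        )
        out[pid] = median_filter_series(corrected, kernel_size=kernel_size)
    return pd.DataFrame(out, index=raw.index)


def control_mean_series(
    control_long: pd.DataFrame, kernel_size: int = 11
) -> pd.Series:
    """Processed promoterless strains averaged into one reference series."""
    processed = process_series_frame(control_long, kernel_size=kernel_size)
    return processed.mean(axis=1)


def normalize_frame(
    processed: pd.DataFrame, control_mean: pd.Series
) -> pd.DataFrame:
    shared = processed.index.intersection(control_mean.index)
    if len(shared) == 0:
        raise ValueError("series and control share no time points")
    c = control_mean.loc[shared]
    if np.any(c.to_numpy() <= 0):
        raise ValueError("control mean is non-positive on the shared grid")
    return processed.loc[shared].sub(c, axis=0).div(c, axis=0)


def build_fold_change_matrix(
    normalized: pd.DataFrame,
    design: ExperimentDesign,
    phase: str = "induction",
) -> pd.DataFrame:
    """Windowed log2 fold changes for every promoter.

    Parameters
    ----------
    normalized
        Wide frame of control-normalized values (rows = time_min, columns =
        promoter ids).
    phase
        ``"induction"``: reference = window start, points at start + j*40,
        j = 1..6.  ``"recovery"``: reference = window end, points at
        end + j*40, j = 1..20.

    Entries are log2(value(t_j) / value(t_ref)).  Rows with non-positive
    values at required points receive a small additive offset (1e-3 times the
    global median of positive normalized values) on numerator and denominator;
    rows that remain non-positive are dropped with a logged warning.
    """
    n_points = design.n_points(phase)
    grid = pd.Index(np.round(normalized.index.to_numpy(dtype=float), 6))
    frame = normalized.set_axis(grid, axis=0)

    # gather required times per metal: reference first, then the n selected
    needed: list[tuple[str, float, np.ndarray]] = []
    for metal in design.metals:
        if phase == "induction":
            ref = design.induction_reference(metal)
            times = design.induction_times(metal)
        else:
            ref = design.recovery_reference(metal)
            times = design.recovery_times(metal)
        for j, t in enumerate(times, start=1):
            if round(float(t), 6) not in frame.index:
                raise ValueError(
                    f"time point {t} min (metal {metal!r}, j={j}) "
                    "is not on the series grid"
                )
        if round(float(ref), 6) not in frame.index:
            raise ValueError(
                f"reference time {ref} min (metal {metal!r}) "
                "is not on the series grid"
            )
        needed.append((metal, ref, times))

    positive = frame.to_numpy()
    positive = positive[np.isfinite(positive) & (positive > 0)]
    eps = EPSILON_FRACTION * (np.median(positive) if positive.size else 1.0)

    columns = design.condition_columns(phase)
    rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for pid in frame.columns:
        col = frame[pid]
        vals = []
        ok = True
        for metal, ref, times in needed:
            v_ref = float(col.loc[round(float(ref), 6)])
            v_sel = np.array(
                [float(col.loc[round(float(t), 6)]) for t in times], dtype=float
            )
            pts = np.concatenate([[v_ref], v_sel])
            if not np.all(np.isfinite(pts)):
                ok = False
                break
            if np.any(pts <= 0):
                pts = pts + eps  # offset guard for signal below control
                if np.any(pts <= 0):
                    ok = False
                    break
            vals.append(np.log2(pts[1:] / pts[0]))
        if ok:
            rows[pid] = np.concatenate(vals)
        else:
            dropped.append(str(pid))
    if dropped:
        logger.warning(
            "dropped %d promoter rows with non-finite or non-positive values: %s%s",
            len(dropped),
            ", ".join(dropped[:10]),
            "..." if len(dropped) > 10 else "",
        )
    X = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    X.index.name = "promoter_id"
    return X


def preprocess(
    series_long: pd.DataFrame,
    control_long: pd.DataFrame,
    design: ExperimentDesign,
    phase: str = "induction",
    kernel_size: int = 11,
) -> pd.DataFrame:
    """Full chain: background correction -> median filter -> control
    normalization -> windowed log2 fold-change matrix."""
    processed = process_series_frame(series_long, kernel_size=kernel_size)
    control = control_mean_series(control_long, kernel_size=kernel_size)
    normalized = normalize_frame(processed, control)
    return build_fold_change_matrix(normalized, design, phase=phase)
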