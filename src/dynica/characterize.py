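"""From robust components to annotated iModulons.

Membership comes from an iterative D'Agostino K-squared procedure: promoters
with the largest absolute weight are removed one at a time until the
remaining weight distribution looks normal (K^2 below a fixed cutoff of 800);
the removed, positively weighted promoters are the members.  Each iModulon is
then assigned the heavy metal whose induction window carries the highest
aggregate activity, classified by the temporal shape of its activity within
that window (center of mass and highest peak), and flagged for discard when a
single promoter dominates its weight vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .ica import IcaDecomposition

SHAPE_FAST = "Fast"
SHAPE_INTERMEDIATE = "Intermediate"
SHAPE_STEADY = "Steady"
SHAPE_OTHER = "Other"


@dataclass(frozen=True)
class ThresholdConfig:
    """Membership thresholding parameters (K^2 cutoff fixed at 800; only
    positively weighted promoters count as members)."""

    k2_cutoff: float = 800.0
    positive_only: bool = True

    def __post_init__(self) -> None:
        if self.k2_cutoff <= 0:
            raise ValueError("k2_cutoff must be positive")


@dataclass
class IModulon:
    """One component's weights, membership and temporal annotation."""

    id: str
    weights: pd.Series
    threshold: float
    members: set
    primary_metal: str
    shape: str
    cm: float | None
    hp: int | None
    discarded: bool = False
    discard_reason: str = ""


# ---------------------------------------------------------------------------
# D'Agostino K-squared


def _skew_z(values: np.ndarray) -> float:
    # D'Agostino (1970) transformed sample-skewness statistic
    n = values.size
    m = values.mean()
    d = values - m
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    b1 = m3 / m2**1.5
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (
        3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3)
        / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    return delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))


def _kurt_z(values: np.ndarray) -> float:
    # Anscombe & Glynn (1983) transformed sample-kurtosis statistic
    n = values.size
    m = values.mean()
    d = values - m
    m2 = np.mean(d**2)
    m4 = np.mean(d**4)
    b2 = m4 / m2**2
    e = 3.0 * (n - 1) / (n + 1)
    var = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    x = (b2 - e) / math.sqrt(var)
    sqrtbeta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrtbeta1 * (
        2.0 / sqrtbeta1 + math.sqrt(1.0 + 4.0 / sqrtbeta1**2)
    )
    term = (1.0 - 2.0 / a) / (1.0 + x * math.sqrt(2.0 / (a - 4.0)))
    term = math.copysign(abs(term) ** (1.0 / 3.0), term)
    return (1.0 - 2.0 / (9.0 * a) - term) / math.sqrt(2.0 / (9.0 * a))


def dagostino_k2(values) -> float:
    """Omnibus normality statistic K^2 = Z_skew^2 + Z_kurt^2.

    Large values indicate a heavy-tailed or outlier-bearing distribution.
    Requires at least 20 finite values (the small-sample transforms are
    unstable below that); constant input has undefined moments and raises.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 20:
        raise ValueError(f"need at least 20 finite values, got {arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("constant input: K^2 moments are undefined")
    return _skew_z(arr) ** 2 + _kurt_z(arr) ** 2


# ---------------------------------------------------------------------------
# membership threshold


def compute_threshold(
    weights: pd.Series, cfg: ThresholdConfig | None = None
) -> tuple[float, set]:
    """Iterative K^2 outlier removal on one weight column.

    Promoters are removed in order of descending |weight|, recomputing K^2 on
    the remainder, until the statistic falls below the cutoff.  The membership
    boundary is the |weight| of the last promoter removed (+inf, with empty
    membership, when the column is already near-normal); members are the
    removed promoters with positive weight when ``positive_only`` is set.
    """
    cfg = cfg or ThresholdConfig()
    w = pd.Series(weights).astype(float)
    order = w.abs().sort_values(ascending=False, kind="stable").index
    values = w.loc[order].to_numpy()

    if dagostino_k2(values) < cfg.k2_cutoff:
        return math.inf, set()
    n_removed = 0
    while True:
        n_removed += 1
        remaining = values[n_removed:]
        if remaining.size < 20:
            raise ValueError(
                "degenerate component: fewer than 20 weights remain before "
                "K^2 drops below the cutoff"
            )
        if dagostino_k2(remaining) < cfg.k2_cutoff:
            break
    threshold = float(abs(values[n_removed - 1]))
    removed = order[:n_removed]
    if cfg.positive_only:
        members = {p for p in removed if w.loc[p] > 0}
    else:
        members = set(removed)
    return threshold, members


def flag_single_promoter(
    weights: pd.Series, members: set, share: float = 0.7
) -> bool:
    """True when one promoter dominates: a singleton member set, or the
    largest squared weight exceeds ``share`` of the column's total."""
    if len(members) == 1:
        return True
    w = np.asarray(weights, dtype=float)
    total = float(np.sum(w**2))
    if total == 0:
        return False
    return float(np.max(w**2)) / total > share


# ---------------------------------------------------------------------------
# primary metal and temporal shape


def assign_primary_metal(a_row, design: ExperimentDesign,
                         phase: str = "induction") -> str:
    """Metal whose window carries the highest aggregate activity; ties go to
    the earlier metal in the design order."""
    a = np.asarray(a_row, dtype=float)
    n = design.n_points(phase)
    if a.size != len(design.metals) * n:
        raise ValueError("activity row length does not match the design")
    sums = a.reshape(len(design.metals), n).sum(axis=1)
    return design.metals[int(np.argmax(sums))]


def classify_shape(a_window) -> tuple[float | None, int, str]:
    """Center of mass, highest peak and activation label for a 6-point window.

    Negative activities are clipped to zero for the center-of-mass weighting
    (CM locates activation mass; repression should not shift it):
    cm = sum(i * w_i) / sum(w_i) with 1-based positions, hp = 1-based argmax
    (earliest on ties).  Labels, most specific first:
    Fast (cm <= 4, hp <= 3), Intermediate (cm <= 4, hp <= 4),
    Steady (cm <= 5, hp >= 4), otherwise Other.
    """
    a = np.asarray(a_window, dtype=float)
    if a.size != 6:
        raise ValueError("shape classification expects a 6-point window")
    if not np.all(np.isfinite(a)):
        raise ValueError("activity window contains non-finite values")
    hp = int(np.argmax(a)) + 1
    w = np.clip(a, 0.0, None)
    total = float(w.sum())
    if total == 0:
        return None, hp, SHAPE_OTHER
    cm = float(np.clip(np.sum(np.arange(1, 7) * w) / total, 1.0, 6.0))
    if cm <= 4 and hp <= 3:
        return cm, hp, SHAPE_FAST
    if cm <= 4 and hp <= 4:
        return cm, hp, SHAPE_INTERMEDIATE
    if cm <= 5 and hp >= 4:
        return cm, hp, SHAPE_STEADY
    return cm, hp, SHAPE_OTHER


def window_profile(a_row, design: ExperimentDesign, metal: str,
                   phase: str = "induction") -> np.ndarray:
    a = np.asarray(a_row, dtype=float)
    n = design.n_points(phase)
    i = design.metals.index(metal)
    return a[i * n : (i + 1) * n]


def _cm_hp(profile: np.ndarray) -> tuple[float | None, int]:
    hp = int(np.argmax(profile)) + 1
    w = np.clip(profile, 0.0, None)
    total = float(w.sum())
    if total == 0:
        return None, hp
    cm = float(np.clip(
        np.sum(np.arange(1, profile.size + 1) * w) / total, 1.0, profile.size
    ))
    return cm, hp


# ---------------------------------------------------------------------------
# assembling iModulons


def characterize(
    decomposition: IcaDecomposition,
    design: ExperimentDesign,
    threshold_cfg: ThresholdConfig | None = None,
    share: float = 0.7,
    phase: str = "induction",
) -> list[IModulon]:
    """Annotate every robust component: membership threshold, discard flag,
    primary metal and temporal shape.

    Recovery-phase profiles (20 points) receive cm/hp but no activation label
    (the printed shape rules are specific to the 6-point induction window);
    they are reported as Other.
    """
    threshold_cfg = threshold_cfg or ThresholdConfig()
    out: list[IModulon] = []
    for comp in decomposition.M.columns:
        weights = decomposition.M[comp]
        a_row = decomposition.A.loc[comp].to_numpy(dtype=float)
        threshold, members = compute_threshold(weights, threshold_cfg)
        metal = assign_primary_metal(a_row, design, phase=phase)
        profile = window_profile(a_row, design, metal, phase=phase)
        if phase == "induction" and profile.size == 6:
            cm, hp, label = classify_shape(profile)
        else:
            cm, hp = _cm_hp(profile)
            label = SHAPE_OTHER
        discarded = flag_single_promoter(weights, members, share=share)
        reason = "single high-coefficient promoter" if discarded else ""
        out.append(
            IModulon(
                id=str(comp),
                weights=weights,
                threshold=threshold,
                members=members,
                primary_metal=metal,
                shape=label,
                cm=cm,
                hp=hp,
                discarded=discarded,
                discard_reason=reason,
            )
        )
    return out


def summary_table(imodulons: list[IModulon]) -> pd.DataFrame:
    rows = []
    for im in imodulons:
        rows.append(
            {
                "imodulon_id": im.id,
                "n_members": len(im.members),
                "threshold": im.threshold,
                "discarded": im.discarded,
                "reason": im.discard_reason,
                "primary_metal": im.primary_metal,
                "cm": np.nan if im.cm is None else im.cm,
                "hp": im.hp,
                "shape": im.shape,
            }
        )
    return pd.DataFrame(rows)


def membership_table(imodulons: list[IModulon]) -> pd.DataFrame:
    rows = []
    for im in imodulons:
        for pid in sorted(im.members):
            rows.append(
                {
                    "imodulon_id": im.id,
                    "promoter_id": pid,
                    "weight": float(im.weights.loc[pid]),
                }
            )
    return pd.DataFrame(rows, columns=["imodulon_id", "promoter_id", "weight"])


# ---------------------------------------------------------------------------
# functional category shift


CATEGORIES = ("stress/damage", "transcription/translation/synthesis", "other")


def summarize_category_shift(
    induction_members: set,
    recovery_members: set,
    annotation_table: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Counts and fractions of member promoters per functional category in
    the induction versus recovery phase.

    The annotation table maps promoter id -> category (stress/damage,
    transcription/translation/synthesis, other); unannotated members count as
    "other".  Fractions are NaN for an empty member set.
    """
    if isinstance(annotation_table, pd.DataFrame):
        mapping = dict(
            zip(annotation_table["promoter_id"], annotation_table["category"])
        )
    else:
        mapping = dict(annotation_table)
    rows = []
    for phase, members in (
        ("induction", set(induction_members)),
        ("recovery", set(recovery_members)),
    ):
        counts = dict.fromkeys(CATEGORIES, 0)
        for pid in members:
            cat = mapping.get(pid, "other")
            if cat not in counts:
                cat = "other"
            counts[cat] += 1
        total = sum(counts.values())
        for cat in CATEGORIES:
            rows.append(
                {
                    "phase": phase,
                    "category": cat,
                    "count": counts[cat],
                    "fraction": counts[cat] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)
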