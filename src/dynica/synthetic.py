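"""Synthetic Dynomics-like data with planted iModulon structure.

The generator plants k sparse promoter-weight vectors (columns of ``M_true``)
and k temporal activity profiles (rows of ``A_true``), one per heavy-metal
induction window, and emits either the resulting log2 fold-change matrix
``X = M_true @ A_true + noise`` directly, or a full raw fluorescence time
series whose preprocessing round-trips back to the planted fold changes.

Activity profiles follow the five activation shapes observed in promoter
libraries under heavy-metal stress: fast (immediate peak, geometric decay),
intermediate (mid-window peak), steady (linear ramp), partial_steady (ramp
with late repression) and late (silent first half, then ramp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import RAW_SPACING_MIN, DEFAULT_METALS, ExperimentDesign

SHAPE_LABELS = ("fast", "intermediate", "steady", "partial_steady", "late")

#: recovery activity decays linearly to zero over this many recovery samples
RECOVERY_DECAY_STEPS = 12

#: default planted assignment: one component per metal, all five shapes used
DEFAULT_SHAPES = (
    "fast",
    "late",
    "steady",
    "steady",
    "intermediate",
    "partial_steady",
)


def make_shape_template(shape_label: str, n_timepoints: int) -> np.ndarray:
    """One activation shape over an induction window, max-normalized to 1.

    steady          linear ramp 1/n .. 1
    fast            peak at the first point, geometric decay with ratio 0.5
    intermediate    unimodal peak at position ceil(n/2)+1, linear flanks
    partial_steady  linear ramp that drops to 0.1 at the final point
    late            zeros over the first half, then a linear ramp
    """
    if n_timepoints < 3:
        raise ValueError("shape templates need at least 3 time points")
    n = n_timepoints
    if shape_label == "steady":
        return np.arange(1, n + 1) / n
    if shape_label == "fast":
        return 0.5 ** np.arange(n)
    if shape_label == "intermediate":
        p = int(np.ceil(n / 2)) + 1  # 1-based peak position
        i = np.arange(1, n + 1, dtype=float)
        left = i / p
        right = (n + 1 - i) / (n + 1 - p)
        return np.where(i <= p, left, right)
    if shape_label == "partial_steady":
        ramp = np.arange(1, n, dtype=float) / (n - 1)
        return np.concatenate([ramp, [0.1]])
    if shape_label == "late":
        half = n // 2
        m = n - half
        ramp = np.arange(1, m + 1, dtype=float) / m
        return np.concatenate([np.zeros(half), ramp])
    raise ValueError(f"unknown shape label {shape_label!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the synthetic study.

    Defaults emulate the Dynomics heavy-metal screen: ~1805 promoters, six
    4-h induction windows sampled every 10 min, six 40-min-spaced induction
    points per window, sparse heavy-tailed member weights.
    """

    n_promoters: int = 1805
    metals: tuple[str, ...] = DEFAULT_METALS
    n_components: int = 6
    #: component index -> (metal, shape label); every component lives in
    #: exactly one metal window
    shape_assignment: dict[int, tuple[str, str]] = field(default_factory=dict)
    weight_sparsity: float = 0.01
    weight_scale: float = 1.0
    #: probability that a member weight is negative; 0 plants all-positive
    #: memberships (activation modules), 0.5 plants sign-balanced sources
    #: whose column means vanish, making the planted sources uncorrelated
    weight_sign_frac: float = 0.0
    #: allow a promoter to belong to several components (off by default)
    allow_overlap: bool = False
    background_level: float = 100.0
    baseline_level: float = 500.0
    control_level: float = 50.0
    #: additive noise on each component's log2 activity time course (the
    #: pathway activity itself fluctuates; shared by all promoters that
    #: report the component)
    noise_sd: float = 0.05
    #: per-promoter, per-sample measurement noise on the log2 signal
    measurement_sd: float = 0.02
    spike_prob: float = 0.01
    n_control_strains: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components > self.n_promoters:
            raise ValueError("more components than promoters")
        if not 0 < self.weight_sparsity <= 1:
            raise ValueError("weight_sparsity must be in (0, 1]")
        if not 0 <= self.weight_sign_frac <= 1:
            raise ValueError("weight_sign_frac must be in [0, 1]")
        for name in ("weight_scale", "background_level", "baseline_level",
                     "control_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_level <= self.control_level:
            raise ValueError("baseline_level must exceed control_level")
        if not self.shape_assignment:
            assignment = {}
            for k in range(self.n_components):
                metal = self.metals[k % len(self.metals)]
                shape = DEFAULT_SHAPES[k % len(DEFAULT_SHAPES)]
                assignment[k] = (metal, shape)
            object.__setattr__(self, "shape_assignment", assignment)
        if set(self.shape_assignment) != set(range(self.n_components)):
            raise ValueError("shape_assignment must cover components 0..k-1")
        for k, (metal, shape) in self.shape_assignment.items():
            if metal not in self.metals:
                raise ValueError(f"component {k} assigned to unknown metal {metal!r}")
            if shape not in SHAPE_LABELS:
                raise ValueError(f"unknown shape label {shape!r}")


@dataclass
class SyntheticTruth:
    """Planted weights, activities and memberships for recovery testing."""

    M_true: pd.DataFrame  # promoters x k_true
    A_true: pd.DataFrame  # k_true x induction conditions
    member_sets: dict[str, set]  # component id -> member promoter ids
    shape_labels: dict[str, str]
    metal_assignment: dict[str, str]
    config: SyntheticConfig


def _promoter_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"p{i:0{width}d}" for i in range(n)]


def generate_truth(
    config: SyntheticConfig, design: ExperimentDesign | None = None
) -> SyntheticTruth:
    """Draw the planted M_true / A_true pair for a configuration.

    Member supports are disjoint across components (a promoter reports one
    module); member weights are weight_scale * (1 + small jitter), off-member
    weights are small Gaussians N(0, (weight_scale/20)^2) so the bulk of each
    column is realistically near-normal.
    """
    if design is None:
        design = ExperimentDesign(metals=config.metals)
    rng = np.random.default_rng(config.seed)
    n, k = config.n_promoters, config.n_components
    pids = _promoter_ids(n)
    comp_ids = [f"c{j}" for j in range(k)]

    scale = config.weight_scale
    off_sd = scale / 20.0
    # off-member bulk, clipped so no off-member ever crosses the scale/2 line
    M = rng.normal(0.0, off_sd, size=(n, k)) if k else np.zeros((n, 0))
    if k:
        M = np.clip(M, -scale / 4, scale / 4)

    member_sets: dict[str, set] = {}
    available = np.arange(n)
    for j in range(k):
        size = int(rng.binomial(n, config.weight_sparsity))
        size = max(1, min(size, available.size))
        pick = rng.choice(available, size=size, replace=False)
        jitter = np.clip(rng.normal(0.0, 0.05, size=pick.size), -0.4, 0.4)
        signs = np.where(
            rng.random(pick.size) < config.weight_sign_frac, -1.0, 1.0
        )
        M[pick, j] = signs * scale * (1.0 + jitter)
        member_sets[comp_ids[j]] = {pids[i] for i in pick}
        if not config.allow_overlap:
            available = np.setdiff1d(available, pick)

    columns = design.condition_columns("induction")
    A = np.zeros((k, len(columns)))
    shape_labels: dict[str, str] = {}
    metal_assignment: dict[str, str] = {}
    npts = design.n_induction_points
    for j in range(k):
        metal, shape = config.shape_assignment[j]
        template = make_shape_template(shape, npts)
        start = design.metals.index(metal) * npts
        A[j, start : start + npts] = template
        shape_labels[comp_ids[j]] = shape
        metal_assignment[comp_ids[j]] = metal

    return SyntheticTruth(
        M_true=pd.DataFrame(M, index=pids, columns=comp_ids),
        A_true=pd.DataFrame(A, index=comp_ids, columns=columns),
        member_sets=member_sets,
        shape_labels=shape_labels,
        metal_assignment=metal_assignment,
        config=config,
    )


def generate_fold_change(
    truth: SyntheticTruth, noise_sd: float | None = None, seed: int | None = None
) -> pd.DataFrame:
    """X = M_true @ A_true + N(0, noise_sd^2) with (metal, timepoint) columns."""
    if noise_sd is None:
        noise_sd = truth.config.noise_sd
    if seed is None:
        seed = truth.config.seed + 1
    X = truth.M_true.to_numpy() @ truth.A_true.to_numpy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return pd.DataFrame(
        X, index=truth.M_true.index.copy(), columns=truth.A_true.columns.copy()
    )


def _recovery_decay(a_end: float, n_recovery: int) -> np.ndarray:
    s = np.arange(1, n_recovery + 1, dtype=float)
    return a_end * np.maximum(0.0, 1.0 - s / RECOVERY_DECAY_STEPS)


def planted_recovery_fold_change(
    truth: SyntheticTruth, design: ExperimentDesign | None = None
) -> pd.DataFrame:
    """Planted recovery-phase matrix: log2 fold change relative to each
    window's end, under the generator's linear post-induction decay."""
    if design is None:
        design = ExperimentDesign(metals=truth.config.metals)
    columns = design.condition_columns("recovery")
    npts = design.n_recovery_points
    X = np.zeros((len(truth.M_true.index), len(columns)))
    for j, comp in enumerate(truth.A_true.index):
        metal = truth.metal_assignment[comp]
        a_end = float(
            truth.A_true.loc[comp, f"{metal}:{design.n_induction_points}"]
        )
        rec = _recovery_decay(a_end, npts) - a_end
        start = design.metals.index(metal) * npts
        X[:, start : start + npts] += np.outer(
            truth.M_true.iloc[:, j].to_numpy(), rec
        )
    return pd.DataFrame(X, index=truth.M_true.index.copy(), columns=columns)


# ---------------------------------------------------------------------------
# raw fluorescence synthesis


def _component_activity_grid(
    template: np.ndarray,
    design: ExperimentDesign,
    metal: str,
    grid: np.ndarray,
    knot_noise: np.ndarray | None = None,
) -> np.ndarray:
    """Planted activity on the full 10-min grid for one component.

    Knots sit at the window reference (activity 0), the induction samples
    (template values) and the recovery samples (linear decay back to 0).
    Between 40-min knots the 10-min grid is filled with a staircase
    (v_a, v_a, v_b); at a strict local maximum the plateau is widened over the
    left gap.  This infill makes the kernel-11 running median exactly equal to
    the knot value at every sampled point, so preprocessing inverts the
    generator without bias (see docs/methods.md).
    """
    start, end = design.window(metal)
    knot_t = np.concatenate(
        [[start], design.induction_times(metal), design.recovery_times(metal)]
    )
    a_end = template[-1]
    knot_v = np.concatenate(
        [[0.0], template, _recovery_decay(a_end, design.n_recovery_points)]
    )
    if knot_noise is not None:
        # activity fluctuations live on the 40-min knot grid: the realized
        # curve is a noisy staircase, so the median filter still acts
        # identically on every promoter reporting this component; silent
        # knots (activity exactly 0, incl. the window reference) stay quiet
        knot_v = knot_v + np.where(knot_v != 0, knot_noise, 0.0)

    g = np.zeros(grid.size)
    t0 = grid[0]
    step = RAW_SPACING_MIN
    idx = np.round((knot_t - t0) / step).astype(int)
    if np.any(idx < 0) or np.any(idx >= grid.size):
        raise ValueError("design sampling grid does not cover the windows")
    g[idx] = knot_v
    # staircase infill between consecutive knots (4 grid steps apart)
    for (ia, va), (ib, vb) in zip(zip(idx[:-1], knot_v[:-1]),
                                  zip(idx[1:], knot_v[1:])):
        g[ia + 1] = va
        g[ia + 2] = va
        g[ia + 3] = vb
    # widen the plateau left of strict local maxima
    for j in range(1, knot_v.size - 1):
        if knot_v[j] > knot_v[j - 1] and knot_v[j] > knot_v[j + 1]:
            g[idx[j] - 3] = knot_v[j]
            g[idx[j] - 2] = knot_v[j]
    return g


def generate_raw_fluorescence(
    truth: SyntheticTruth,
    design: ExperimentDesign | None = None,
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format raw series plus a promoterless-control series.

    Each promoter's expression follows its planted log2 fold-change curve
    f_p(t): the control-normalized processed signal equals
    (rho - 1) * 2^(f_p(t)) with rho = baseline_level / control_level, so the
    preprocessing chain recovers the planted fold changes at the sampled time
    points (exactly when noise_sd = 0 and spike_prob = 0, within ~3*noise_sd
    otherwise).  Additive impulse artifacts are injected with probability
    spike_prob per sample to exercise the median filter.

    Returns ``(series, control)`` long-format frames with columns
    promoter_id, time_min, fluorescence, background.
    """
    if config is None:
        config = truth.config
    if design is None:
        design = ExperimentDesign(metals=config.metals)
    if design.sampling_spacing_min % RAW_SPACING_MIN != 0:
        raise ValueError("sampling spacing must be a multiple of the 10-min grid")
    rng = np.random.default_rng(config.seed + 2)
    grid = design.raw_grid()
    n, k = config.n_promoters, config.n_components
    pids = list(truth.M_true.index)

    n_knots = 1 + design.n_induction_points + design.n_recovery_points
    G = np.zeros((k, grid.size))
    for j, comp in enumerate(truth.A_true.index):
        metal = truth.metal_assignment[comp]
        npts = design.n_induction_points
        start = design.metals.index(metal) * npts
        template = truth.A_true.iloc[j, start : start + npts].to_numpy(dtype=float)
        noise = (
            rng.normal(0.0, config.noise_sd, size=n_knots)
            if config.noise_sd > 0
            else None
        )
        G[j] = _component_activity_grid(template, design, metal, grid, noise)

    F = truth.M_true.to_numpy() @ G  # log2 fold-change curves per promoter
    if config.measurement_sd > 0:
        F = F + rng.normal(0.0, config.measurement_sd, size=F.shape)

    rho = config.baseline_level / config.control_level
    expression = ((rho - 1.0) * np.exp2(F) + 1.0) / rho
    raw = config.background_level + config.baseline_level * expression
    if config.spike_prob > 0:
        spikes = rng.random(raw.shape) < config.spike_prob
        raw = raw + spikes * (5.0 * config.baseline_level)

    bg = np.full(grid.size, config.background_level)
    series = pd.DataFrame(
        {
            "promoter_id": np.repeat(pids, grid.size),
            "time_min": np.tile(grid, n),
            "fluorescence": raw.ravel(),
            "background": np.tile(bg, n),
        }
    )

    n_ctrl = config.n_control_strains
    ctrl_expr = np.ones((n_ctrl, grid.size))
    if config.measurement_sd > 0:
        ctrl_expr = np.exp2(rng.normal(0.0, config.measurement_sd,
                                       size=ctrl_expr.shape))
    ctrl_raw = config.background_level + config.control_level * ctrl_expr
    control = pd.DataFrame(
        {
            "promoter_id": np.repeat(
                [f"control_{i}" for i in range(n_ctrl)], grid.size
            ),
            "time_min": np.tile(grid, n_ctrl),
            "fluorescence": ctrl_raw.ravel(),
            "background": np.tile(bg, n_ctrl),
        }
    )
    return series, control
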