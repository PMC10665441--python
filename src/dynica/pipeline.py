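"""End-to-end orchestration: data -> fold changes -> robust ICA -> iModulons.

Every intermediate artifact is written to the output directory (the analysis
is meant to be iterated on processed matrices, so each stage can be rerun in
isolation from its written inputs): the fold-change matrix ``X_<phase>.tsv``,
the component matrices ``M.tsv`` and ``A.tsv``, the per-iModulon summary and
membership tables, and a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .characterize import (
    ThresholdConfig,
    characterize,
    membership_table,
    summarize_category_shift,
    summary_table,
)
from .design import ExperimentDesign
from .ica import IcaConfig, robust_ica, select_dimension
from .preprocess import preprocess
from .synthetic import SyntheticConfig, generate_raw_fluorescence, generate_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and where the inputs live.

    Exactly one input source applies, checked in this order: a prebuilt
    fold-change matrix (``matrix_path``), raw series files (``series_path`` +
    ``control_path``), or a synthetic configuration (``synthetic``).
    """

    out_dir: str | Path = "dynica_out"
    phase: str = "induction"
    design: ExperimentDesign | None = None
    design_path: str | Path | None = None
    matrix_path: str | Path | None = None
    series_path: str | Path | None = None
    control_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    annotations_path: str | Path | None = None
    ica: IcaConfig = field(default_factory=IcaConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    share: float = 0.7
    kernel_size: int = 11
    seed: int = 0
    log_level: str = "INFO"

    def resolve_design(self) -> ExperimentDesign:
        if self.design is not None:
            return self.design
        if self.design_path is not None:
            return ExperimentDesign.from_yaml(self.design_path)
        if self.synthetic is not None:
            return ExperimentDesign(metals=self.synthetic.metals)
        return ExperimentDesign()


@dataclass
class RunReport:
    """Everything needed to reproduce a run: config echo, seed, digests,
    matrix shape, selected and retained dimensions, per-iModulon summary."""

    version: str
    seed: int
    phase: str
    input_digests: dict
    matrix_shape: tuple[int, int]
    k_selected: int
    k_robust: int
    n_discarded: int
    imodulons: list[dict]
    config_echo: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def validate_inputs(
    series_path, control_path=None
) -> list[str]:
    """Diagnostics on long-format inputs; never mutates anything.

    Reports duplicate (promoter, time) records, non-finite values (naming
    promoter and time), irregular time grids, and promoters whose grid is not
    covered by the control grid.
    """
    diagnostics: list[str] = []
    series = io.read_series(series_path)
    frames = {"series": series}
    if control_path is not None:
        frames["control"] = io.read_series(control_path)
    for name, df in frames.items():
        dup = df.duplicated(subset=["promoter_id", "time_min"])
        for _, row in df[dup].iterrows():
            diagnostics.append(
                f"{name}: duplicate record for promoter "
                f"{row['promoter_id']!r} at t={row['time_min']}"
            )
        for col in ("fluorescence", "background"):
            bad = df[~np.isfinite(df[col].astype(float))]
            for _, row in bad.iterrows():
                diagnostics.append(
                    f"{name}: non-finite {col} for promoter "
                    f"{row['promoter_id']!r} at t={row['time_min']}"
                )
        for pid, grp in df.groupby("promoter_id"):
            t = np.unique(grp["time_min"].to_numpy(dtype=float))
            dt = np.diff(t)
            if dt.size and not np.allclose(dt, dt[0]):
                diagnostics.append(
                    f"{name}: irregular time grid for promoter {pid!r}"
                )
    if control_path is not None:
        ctrl_times = set(frames["control"]["time_min"].astype(float).round(6))
        for pid, grp in series.groupby("promoter_id"):
            missing = set(grp["time_min"].astype(float).round(6)) - ctrl_times
            if missing:
                diagnostics.append(
                    f"series: promoter {pid!r} has {len(missing)} time points "
                    "absent from the control grid"
                )
    return diagnostics


def _load_matrix(config: PipelineConfig, design: ExperimentDesign):
    digests = {}
    if config.matrix_path is not None:
        digests["matrix"] = io.file_digest(config.matrix_path)
        return io.read_matrix(config.matrix_path), digests, None
    if config.series_path is not None:
        if config.control_path is None:
            raise ValueError("raw series input requires a control file")
        digests["series"] = io.file_digest(config.series_path)
        digests["control"] = io.file_digest(config.control_path)
        series = io.read_series(config.series_path)
        control = io.read_series(config.control_path)
        X = preprocess(
            series, control, design, phase=config.phase,
            kernel_size=config.kernel_size,
        )
        return X, digests, None
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        truth = generate_truth(syn, design)
        series, control = generate_raw_fluorescence(truth, design, syn)
        X = preprocess(
            series, control, design, phase=config.phase,
            kernel_size=config.kernel_size,
        )
        digests["synthetic_seed"] = str(config.seed)
        return X, digests, truth
    raise ValueError("no input source: set matrix_path, series_path or synthetic")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, writing every intermediate artifact.

    Idempotent for a fixed config and seed: rerunning writes byte-identical
    matrices and summaries.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.resolve_design()
    design.to_yaml(out / "design.yaml")
    design_text = (out / "design.yaml").read_text()
    (out / "design.yaml").write_text(
        f"# version={__version__}\n# seed={config.seed}\n{design_text}"
    )

    ica_cfg = dataclasses.replace(config.ica, base_seed=config.seed)

    X, digests, _truth = _load_matrix(config, design)
    if X.shape[0] == 0:
        raise RuntimeError("stage preprocess: no promoter rows survived")
    meta = {"seed": config.seed, "inputs": ";".join(
        f"{k}:{v}" for k, v in digests.items()) or "none"}
    io.write_matrix(X, out / f"X_{config.phase}.tsv", meta)
    logger.info("fold-change matrix: %d promoters x %d conditions", *X.shape)

    try:
        k_selected = select_dimension(X, ica_cfg.variance_fraction)
    except ValueError as err:
        raise RuntimeError(f"stage select_dimension: {err}") from err
    decomposition = robust_ica(X, ica_cfg)
    io.write_matrix(decomposition.M, out / "M.tsv", meta)
    io.write_matrix(decomposition.A, out / "A.tsv", meta)
    logger.info(
        "robust ICA: k_selected=%d, k_robust=%d",
        k_selected, decomposition.k_robust,
    )

    imodulons = characterize(
        decomposition, design, config.threshold,
        share=config.share, phase=config.phase,
    )
    summary = summary_table(imodulons)
    io.write_table(summary, out / "imodulons.tsv", meta)
    io.write_table(membership_table(imodulons), out / "membership.tsv", meta)
    for im in imodulons:
        if im.discarded:
            logger.info("iModulon %s discarded: %s", im.id, im.discard_reason)

    report = RunReport(
        version=__version__,
        seed=config.seed,
        phase=config.phase,
        input_digests=digests,
        matrix_shape=tuple(X.shape),
        k_selected=k_selected,
        k_robust=decomposition.k_robust,
        n_discarded=int(summary["discarded"].sum()) if len(summary) else 0,
        imodulons=summary.to_dict(orient="records"),
        config_echo={
            "phase": config.phase,
            "kernel_size": config.kernel_size,
            "share": config.share,
            "ica": dataclasses.asdict(ica_cfg),
            "threshold": dataclasses.asdict(config.threshold),
        },
    )
    report.write(out / "report.json")
    _write_text_summary(report, out / "report.txt")
    return report


def _write_text_summary(report: RunReport, path) -> None:
    lines = [
        f"dynica {report.version} run (seed={report.seed}, phase={report.phase})",
        f"matrix: {report.matrix_shape[0]} promoters x "
        f"{report.matrix_shape[1]} conditions",
        f"k selected by PCA: {report.k_selected}",
        f"robust components: {report.k_robust} "
        f"({report.n_discarded} discarded)",
        "",
    ]
    for rec in report.imodulons:
        lines.append(
            f"  {rec['imodulon_id']}: metal={rec['primary_metal']} "
            f"shape={rec['shape']} members={rec['n_members']} "
            f"cm={rec['cm']:.3g} hp={rec['hp']}"
            + ("  [discarded]" if rec["discarded"] else "")
        )
    Path(path).write_text("\n".join(lines) + "\n")


def category_shift_from_runs(
    induction_dir, recovery_dir, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Fig-style functional-category shift between the two phases, computed
    from the membership tables written by two pipeline runs."""
    ind = io.read_table(Path(induction_dir) / "membership.tsv")
    rec = io.read_table(Path(recovery_dir) / "membership.tsv")
    ind_sum = io.read_table(Path(induction_dir) / "imodulons.tsv")
    rec_sum = io.read_table(Path(recovery_dir) / "imodulons.tsv")
    keep_ind = set(ind_sum.loc[~ind_sum["discarded"], "imodulon_id"])
    keep_rec = set(rec_sum.loc[~rec_sum["discarded"], "imodulon_id"])
    ind_members = set(ind.loc[ind["imodulon_id"].isin(keep_ind), "promoter_id"])
    rec_members = set(rec.loc[rec["imodulon_id"].isin(keep_rec), "promoter_id"])
    return summarize_category_shift(ind_members, rec_members, annotations)
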