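"""End-to-end pipeline: read -> harmonize -> select -> power curves -> plot.

Driven by a :class:`RunConfig` (YAML on disk, see the CLI). Every run writes
a JSON report with input/retained/selected counts, thresholds, seed and
package versions so results can be audited and reproduced. On any stage
failure the partial artifacts of the run are removed and a
:class:`PipelineError` naming the stage is raised.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .harmonize import OrientationMode, harmonize_table
from .ld_select import (
    LDReference,
    clump,
    ld_from_genotypes,
    read_ld_matrix,
    stepwise_select,
)
from .model import SumstatsTable
from .plotting import (
    TrumpetPlotSpec,
    build_plot_data,
    render_interactive,
    render_static,
)
from .power import PowerCurveSpec, build_power_curves
from .sumstats_io import read_sumstats

import pandas as pd

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    sumstats: str = ""
    out_dir: str = "trumpet_out"
    ld: Optional[str] = None
    ld_kind: str = "auto"  # auto | matrix | genotypes
    n: int = 0
    trait_model: str = "quantitative"
    trait_name: str = ""
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    dialect: Union[str, dict] = "auto"
    # selection
    method: str = "clump"  # clump | stepwise | none
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    window_kb: float = 100.0
    maf_min: float = 0.01
    # power + plot
    mode: str = "minor_allele_signed"
    alpha: float = 5e-8
    power_levels: Sequence[float] = (0.5, 0.7, 0.9)
    f_min: float = 1e-5
    min_effect_display: float = 0.0
    min_effect_display_html: float = 0.05
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_ld(path: str, kind: str = "auto") -> LDReference:
    """Load an LD reference from a TSV correlation matrix or genotype table.

    ``auto`` treats a square table whose row index equals its header as a
    correlation matrix, anything else as individuals x variants dosages.
    """
    if kind == "matrix":
        return read_ld_matrix(path)
    if kind == "genotypes":
        G = pd.read_csv(path, sep="\t")
        return ld_from_genotypes(G)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == df.shape[1] and list(map(str, df.index)) == [
        str(c) for c in df.columns
    ]:
        return read_ld_matrix(path)
    return ld_from_genotypes(pd.read_csv(path, sep="\t"))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report dict.

    Artifacts written to ``config.out_dir``: ``selected.tsv`` (independent
    significant variants), ``power_curves.tsv``, ``trumpet.svg``,
    ``trumpet.html`` and ``report.json``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: list[str] = []

    def _path(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        artifacts.append(p)
        return p

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    try:
        # ---- read
        stage = "read"
        if not config.sumstats:
            raise PipelineError(stage, "no sumstats path configured")
        table = read_sumstats(
            config.sumstats,
            dialect=config.dialect,
            trait_name=config.trait_name,
            study_n=config.n or None,
            trait_model=config.trait_model,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
        )
        lr = table.load_report
        report["counts"] = {
            "input_rows": lr.n_input,
            "retained": lr.n_loaded,
            "rejected": lr.n_rejected,
        }

        # ---- harmonize
        stage = "harmonize"
        mode = OrientationMode(config.mode)
        table = harmonize_table(table, mode)

        # ---- select
        stage = "select"
        if config.method not in ("clump", "stepwise", "none"):
            raise PipelineError(stage, f"unknown method {config.method!r}")
        window_bp = int(config.window_kb * 1000)
        if config.method == "none":
            selected_table = table
            report["selection"] = {"method": "none", "n_selected": len(table)}
        else:
            if not config.ld:
                raise PipelineError(
                    stage, f"method {config.method!r} needs an ld reference path"
                )
            ld = load_ld(config.ld, config.ld_kind)
            if config.method == "clump":
                result = clump(
                    table, ld,
                    p_threshold=config.p_threshold,
                    r2_threshold=config.r2_threshold,
                    window_bp=window_bp,
                    maf_min=config.maf_min,
                )
            else:
                result = stepwise_select(
                    table, ld,
                    p_threshold=config.p_threshold,
                    window_bp=window_bp,
                    maf_min=config.maf_min,
                )
            sel_frame = result.to_frame(table)
            sel_frame.to_csv(_path("selected.tsv"), sep="\t", index=False)
            keep = set(result.lead_ids)
            selected_table = table.with_records(
                [r for r in table.records if r.variant_id in keep]
            )
            report["selection"] = {
                "method": result.method,
                "n_candidates": result.n_candidates,
                "n_selected": len(result.lead_ids),
            }
            if not result.lead_ids:
                raise PipelineError(stage, "no variants selected; nothing to plot")

        # ---- power curves
        stage = "power"
        power_spec = PowerCurveSpec(
            n=config.n or table.study_n,
            alpha=config.alpha,
            trait_model=config.trait_model,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            power_levels=tuple(config.power_levels),
            f_min=config.f_min,
            f_max=0.5 if mode is OrientationMode.MINOR_ALLELE_SIGNED else 1 - config.f_min,
        )
        curves = build_power_curves(power_spec)
        curve_rows = []
        for c in curves:
            for f, b in zip(c.freqs, c.beta_min):
                curve_rows.append({"level": c.level, "freq": f, "beta_min": b})
        pd.DataFrame(curve_rows).to_csv(
            _path("power_curves.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )

        # ---- plot
        stage = "plot"
        plot_spec = TrumpetPlotSpec(
            orientation=mode,
            f_min=config.f_min,
            min_effect_display=config.min_effect_display,
            power=power_spec,
        )
        data = build_plot_data(selected_table, plot_spec)
        render_static(data, _path("trumpet.svg"))
        html_spec = TrumpetPlotSpec(
            orientation=mode,
            f_min=config.f_min,
            min_effect_display=config.min_effect_display_html,
            power=power_spec,
        )
        html_data = build_plot_data(selected_table, html_spec)
        render_interactive(html_data, _path("trumpet.html"))
        report["plot"] = {
            "points_static": int(len(data.points)),
            "points_interactive": int(len(html_data.points)),
            "dropped_static": data.n_dropped,
            "dropped_interactive": html_data.n_dropped,
            "clipped": data.n_clipped,
        }

        # ---- report
        report_path = os.path.join(config.out_dir, "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["artifacts"] = artifacts + [report_path]
        return report
    except PipelineError:
        _cleanup(artifacts)
        raise
    except Exception as exc:
        _cleanup(artifacts)
        raise PipelineError(stage, str(exc)) from exc


def _cleanup(paths: list[str]) -> None:
    for p in paths:
        if os.path.exists(p):
            try:
                os.remove(p)
            except OSError:  # pragma: no cover
                pass
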