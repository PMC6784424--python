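"""End-to-end orchestration: generate streams, simulate candidates, rank.

Three stages mirror how a laboratory would run the optimisation:

1. ``generate_streams`` — synthesise (or later: load) one result stream
   per analyte;
2. ``simulate_analytes`` — for every candidate procedure, compute the MA
   series and control limits on the unbiased stream, run the bias grid and
   write runs/summaries/series CSVs;
3. ``rank_analytes`` — rebuild validation charts from the summaries, apply
   the optimisation criteria and write per-analyte rankings and plots.

Every output file starts with ``# key=value`` comment lines carrying the
configuration hash and seed, and each stage writes a machine-readable
``manifest_<stage>.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import AnalyteConfig, PipelineConfig, config_hash
from .evaluate import (
    ValidationChartData,
    build_validation_chart,
    OptimizationCriteria,
    rank_candidates,
)
from .ma import MAConfig, compute_ma_series, derive_control_limits
from .plots import plot_bias_detection_curves, plot_validation_chart
from .evaluate import build_bias_detection_curve
from .simulate import BiasGrid, DetectionSummary, simulate_bias_grid
from .streams import ResultStream, generate_stream

logger = logging.getLogger("pbrtqc")

__all__ = [
    "generate_streams",
    "simulate_analytes",
    "rank_analytes",
    "stream_path",
]

_SEED_MOD = 2**31


def _meta(config: PipelineConfig, **extra) -> dict:
    return {"config_hash": config_hash(config), "seed": config.seed, **extra}


def _write_csv(frame: pd.DataFrame, path: Path, meta: dict) -> None:
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, files: list[str]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "files": sorted(files),
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def stream_path(out_dir: Path, analyte: str) -> Path:
    return Path(out_dir) / f"stream_{analyte}.csv"


def generate_streams(config: PipelineConfig, out_dir: Path) -> dict[str, Path]:
    """Write one stream CSV per analyte; per-analyte seeds derive from the base seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for i, analyte in enumerate(config.analytes):
        path = stream_path(out_dir, analyte.name)
        if analyte.stream_file is not None:
            logger.info("%s: using existing stream file %s", analyte.name, analyte.stream_file)
            paths[analyte.name] = Path(analyte.stream_file)
            continue
        seed = (config.seed + i) % _SEED_MOD
        stream = generate_stream(analyte.profile, config.n_days, seed)
        stream.meta["config_hash"] = config_hash(config)
        stream.to_csv(path)
        logger.info("%s: generated %d results (seed %d) -> %s",
                    analyte.name, len(stream), seed, path)
        paths[analyte.name] = path
    _write_manifest(out_dir, "generate", config, [p.name for p in paths.values()])
    return paths


def _load_stream(analyte: AnalyteConfig, streams_dir: Path) -> ResultStream:
    if analyte.stream_file is not None:
        return ResultStream.from_csv(analyte.stream_file, analyte=analyte.name)
    path = stream_path(streams_dir, analyte.name)
    if not path.exists():
        raise FileNotFoundError(
            f"no stream for analyte {analyte.name!r} at {path}; run generate first"
        )
    return ResultStream.from_csv(path, analyte=analyte.name)


def simulate_candidate(
    stream: ResultStream,
    ma_config: MAConfig,
    grid: BiasGrid,
    block: int,
):
    """MA series, control limits and full bias grid for one candidate."""
    series = compute_ma_series(stream, ma_config)
    limits = derive_control_limits(series)
    summaries, runs = simulate_bias_grid(
        stream, ma_config, limits, grid, block=block, return_runs=True
    )
    return series, limits, summaries, runs


def _summary_frame(analyte: str, config_id: str, summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte": analyte,
            "config_id": config_id,
            "bias_percent": [s.bias_percent for s in summaries],
            "median_n": [s.median_n for s in summaries],
            "min_n": [s.min_n for s in summaries],
            "max_n": [s.max_n for s in summaries],
            "n_runs": [s.n_runs for s in summaries],
            "n_detected": [s.n_detected for s in summaries],
        }
    )


def _runs_frame(analyte: str, config_id: str, runs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte": analyte,
            "config_id": config_id,
            "bias_percent": [r.bias_percent for r in runs],
            "injection_index": [r.injection_index for r in runs],
            "n_to_detection": [r.n_to_detection for r in runs],
            "n_accepted_to_detection": [r.n_accepted_to_detection for r in runs],
            "censored": [r.censored for r in runs],
        }
    )


def simulate_analytes(
    config: PipelineConfig,
    streams_dir: Path,
    out_dir: Path,
    write_series: bool = True,
) -> dict[str, Path]:
    """Run every candidate for every analyte; resumable per candidate.

    If a summary CSV already holds rows for a candidate, that candidate is
    skipped, so an interrupted run picks up where it stopped.
    """
    streams_dir, out_dir = Path(streams_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    summary_paths: dict[str, Path] = {}
    for analyte in config.analytes:
        stream = _load_stream(analyte, streams_dir)
        if len(stream) == 0:
            raise ValueError(f"stream for {analyte.name!r} is empty")
        grid = BiasGrid.default(analyte.tea_percent)
        candidates = analyte.resolved_candidates()

        summary_path = out_dir / f"summary_{analyte.name}.csv"
        runs_path = out_dir / f"runs_{analyte.name}.csv"
        limits_path = out_dir / f"limits_{analyte.name}.csv"
        done: set[str] = set()
        summary_frames, runs_frames, limit_rows = [], [], []
        if summary_path.exists():
            prior = read_csv(summary_path)
            done = set(prior["config_id"].unique())
            summary_frames.append(prior)
            if runs_path.exists():
                runs_frames.append(read_csv(runs_path))
            if limits_path.exists():
                limit_rows = read_csv(limits_path).to_dict("records")

        for ma_config in candidates:
            cid = ma_config.key
            if cid in done:
                logger.info("%s/%s: summary exists, skipping", analyte.name, cid)
                continue
            series, limits, summaries, runs = simulate_candidate(
                stream, ma_config, grid, config.block
            )
            summary_frames.append(_summary_frame(analyte.name, cid, summaries))
            runs_frames.append(_runs_frame(analyte.name, cid, runs))
            limit_rows.append(
                {"analyte": analyte.name, "config_id": cid,
                 "lower": limits.lower, "upper": limits.upper}
            )
            if write_series:
                series_path = out_dir / f"series_{analyte.name}_{cid}.csv"
                _write_csv(
                    series.to_frame(stream.timestamps, limits),
                    series_path,
                    _meta(config, analyte=analyte.name, config_id=cid),
                )
                written.append(series_path.name)
            logger.info("%s/%s: limits (%.6g, %.6g), %d runs",
                        analyte.name, cid, limits.lower, limits.upper, len(runs))

        meta = _meta(config, analyte=analyte.name)
        _write_csv(pd.concat(summary_frames, ignore_index=True), summary_path, meta)
        _write_csv(pd.concat(runs_frames, ignore_index=True), runs_path, meta)
        _write_csv(pd.DataFrame(limit_rows), limits_path, meta)
        written += [summary_path.name, runs_path.name, limits_path.name]
        summary_paths[analyte.name] = summary_path
    _write_manifest(out_dir, "simulate", config, written)
    return summary_paths


def _charts_from_summary(frame: pd.DataFrame) -> list[ValidationChartData]:
    charts = []
    for cid, group in frame.groupby("config_id", sort=True):
        summaries = [
            DetectionSummary(
                bias_percent=float(row.bias_percent),
                median_n=None if pd.isna(row.median_n) else float(row.median_n),
                min_n=None if pd.isna(row.min_n) else int(row.min_n),
                max_n=None if pd.isna(row.max_n) else int(row.max_n),
                n_runs=int(row.n_runs),
                n_detected=int(row.n_detected),
            )
            for row in group.itertuples()
        ]
        charts.append(build_validation_chart(summaries, str(cid)))
    return charts


def rank_analytes(
    config: PipelineConfig,
    summaries_dir: Path,
    out_dir: Path,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Rank every analyte's candidates and write ranking CSVs and plots."""
    summaries_dir, out_dir = Path(summaries_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    ranking_paths: dict[str, Path] = {}
    for analyte in config.analytes:
        summary_path = summaries_dir / f"summary_{analyte.name}.csv"
        if not summary_path.exists():
            raise FileNotFoundError(
                f"no summaries for {analyte.name!r} at {summary_path}; run simulate first"
            )
        frame = read_csv(summary_path)
        charts = _charts_from_summary(frame)
        if not charts:
            raise ValueError(f"summary file for {analyte.name!r} holds no candidates")
        daily = analyte.resolved_daily_volume()
        criteria = OptimizationCriteria(
            tea_percent=analyte.tea_percent, daily_volume=daily
        )
        configs = {c.key: c for c in analyte.resolved_candidates()}
        ranking = rank_candidates(charts, criteria, configs)
        rank_frame = pd.DataFrame(
            {
                "rank": [r.rank for r in ranking],
                "config_id": [r.config_id for r in ranking],
                "feasible": [r.feasible for r in ranking],
                "reason": ["; ".join(r.report.reasons) or "ok" for r in ranking],
                "median_plus_tea": [r.median_at_plus_tea for r in ranking],
                "median_minus_tea": [r.median_at_minus_tea for r in ranking],
            }
        )
        rank_path = out_dir / f"ranking_{analyte.name}.csv"
        _write_csv(rank_frame, rank_path, _meta(config, analyte=analyte.name))
        written.append(rank_path.name)
        ranking_paths[analyte.name] = rank_path

        if make_plots:
            curves = [
                build_bias_detection_curve(
                    [s for s in _chart_summaries(frame, chart.config_id)], chart.config_id
                )
                for chart in charts
            ]
            fig = plot_bias_detection_curves(
                curves, title=f"{analyte.name}: candidate bias detection curves",
                window=config.block,
            )
            curve_png = out_dir / f"curves_{analyte.name}.png"
            fig.savefig(curve_png, dpi=120)
            best = next((c for c in charts if c.config_id == ranking[0].config_id), None)
            chart_png = out_dir / f"validation_{analyte.name}.png"
            if best is not None:
                fig2 = plot_validation_chart(
                    best, daily_volume=daily,
                    title=f"{analyte.name}: {best.config_id} (rank 1)",
                )
                fig2.savefig(chart_png, dpi=120)
                written.append(chart_png.name)
            written.append(curve_png.name)
            import matplotlib.pyplot as plt

            plt.close("all")
    _write_manifest(out_dir, "rank", config, written)
    return ranking_paths


def _chart_summaries(frame: pd.DataFrame, config_id: str):
    group = frame[frame["config_id"] == config_id]
    return [
        DetectionSummary(
            bias_percent=float(row.bias_percent),
            median_n=None if pd.isna(row.median_n) else float(row.median_n),
            min_n=None if pd.isna(row.min_n) else int(row.min_n),
            max_n=None if pd.isna(row.max_n) else int(row.max_n),
            n_runs=int(row.n_runs),
            n_detected=int(row.n_detected),
        )
        for row in group.itertuples()
    ]
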