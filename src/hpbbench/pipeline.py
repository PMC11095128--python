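"""End-to-end pipeline: registry -> indicators -> benchmarks -> power/funnel.

One invocation produces a result directory with the registry (when
simulated), indicator summaries, the benchmark table, the
detectable-difference grid, minimum-volume requirements, the volume
adequacy report, funnel curves with outlier calls, and a run manifest.
Reruns with an identical configuration and seed are byte-identical apart
from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .definitions import Indicator, Procedure
from .funnel import FunnelMethod, classify, funnel_limits
from .indicators import NATIONAL, benchmark_table, los_thresholds, summarize
from .io import dump_sim_config, validate_registry, write_rates, write_registry
from .power import (
    DEFAULT_POOLING_YEARS,
    DEFAULT_VOLUMES,
    PowerSpec,
    threshold_table,
    volume_requirement_table,
)
from .registry import SimConfig, simulate_registry

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    inputs: dict
    outputs: list[str]
    version: str
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _config_hash(config: SimConfig) -> str:
    blob = json.dumps(
        {
            "label": config.label,
            "seed": config.seed,
            "years": list(config.years),
            "hospitals": [
                {
                    "hospital_id": h.hospital_id,
                    "procedures": {
                        p.value: dataclasses.asdict(params)
                        for p, params in sorted(h.procedures.items(), key=lambda kv: kv[0].value)
                    },
                }
                for h in config.hospitals
            ],
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    window: tuple[int, int] | None = None,
    volumes: tuple[int, ...] = DEFAULT_VOLUMES,
    pooling_years: tuple[int, ...] = DEFAULT_POOLING_YEARS,
    level: float = 0.95,
    method: FunnelMethod = FunnelMethod.EXACT,
    spec: PowerSpec = PowerSpec(),
) -> Path:
    """Run the full analysis on a simulated registry and write all outputs.

    ``window`` defaults to the last two registry years (the benchmark
    window).  Procedure groups without records are flagged absent in the
    outputs rather than failing the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    registry = simulate_registry(config)
    logger.info("simulated %d records from %d hospitals", len(registry), len(config.hospitals))
    write_registry(registry, out / "registry.csv")
    dump_sim_config(config, out / "scenario.yaml")

    report = validate_registry(registry)
    if not report.ok:
        raise ValueError(f"simulated registry failed validation: {report.violations[:5]}")

    if window is None:
        window = (config.years[1] - 1, config.years[1])
    benchmarks = benchmark_table(registry, window)
    write_rates(benchmarks, out / "benchmarks.csv")
    n_empty = int(benchmarks["empty"].sum())
    if n_empty:
        logger.warning("%d benchmark strata have no eligible records", n_empty)

    thresholds = los_thresholds(registry, window)
    summary_rows = []
    for procedure in Procedure:
        if not (registry["procedure"] == procedure.value).any():
            logger.warning("no records for %s; downstream outputs flagged absent", procedure.value)
            continue
        for indicator in Indicator:
            for s in summarize(registry, window, indicator, procedure, thresholds):
                summary_rows.append(
                    {
                        "hospital_id": s.hospital_id,
                        "procedure": s.procedure.value,
                        "indicator": s.indicator.value,
                        "window_start": s.window[0],
                        "window_end": s.window[1],
                        "numerator": s.numerator,
                        "denominator": s.denominator,
                        "rate": float(f"{s.rate:.6g}") if s.denominator else float("nan"),
                    }
                )
    pd.DataFrame(summary_rows).to_csv(out / "indicator_summaries.csv", index=False)

    present = benchmarks[~benchmarks["empty"]]
    grid = threshold_table(present, volumes, spec)
    grid.to_csv(out / "threshold_grid.csv", index=False)
    vols = volume_requirement_table(present, years=pooling_years, spec=spec)
    vols.to_csv(out / "volume_requirements.csv", index=False)

    # adequacy: observed per-hospital annual volumes vs the 5-point scenario
    adequacy_rows = []
    req5 = vols[(vols["scenario"] == "5pt") & ~vols["infeasible"]]
    counts = registry.groupby(["procedure", "hospital_id", "year"]).size()
    for row in req5.itertuples(index=False):
        if row.procedure in counts.index.get_level_values(0):
            proc_counts = counts.loc[row.procedure]
        else:
            proc_counts = pd.Series(dtype=int)
        met = 0
        hospitals = proc_counts.index.get_level_values(0).unique() if len(proc_counts) else []
        for hid in hospitals:
            pooled = int(proc_counts.loc[hid].sort_index().iloc[-row.years:].sum())
            met += pooled >= row.n_total
        adequacy_rows.append(
            {
                "procedure": row.procedure,
                "indicator": row.indicator,
                "scenario": row.scenario,
                "years": row.years,
                "n_hospitals": len(hospitals),
                "n_meeting": met,
                "proportion_meeting": met / len(hospitals) if len(hospitals) else float("nan"),
            }
        )
    pd.DataFrame(adequacy_rows).to_csv(out / "adequacy.csv", index=False)

    # funnel curves and outlier calls per (procedure, indicator)
    curve_rows, call_rows = [], []
    volume_grid = sorted({*volumes, *range(10, 201, 10)})
    for row in present.itertuples(index=False):
        procedure, indicator = Procedure(row.procedure), Indicator(row.indicator)
        curve = funnel_limits(row.p0, volume_grid, level, method)
        for c in curve.table.itertuples(index=False):
            curve_rows.append(
                {
                    "procedure": procedure.value,
                    "indicator": indicator.value,
                    "p0": row.p0,
                    "volume": c.volume,
                    "lower": c.lower,
                    "upper": c.upper,
                    "method": method.value,
                    "level": level,
                }
            )
        summaries = [
            s
            for s in summarize(registry, window, indicator, procedure, thresholds)
            if s.hospital_id != NATIONAL
        ]
        for call in classify(summaries, curve):
            call_rows.append(
                {
                    "hospital_id": call.hospital_id,
                    "procedure": call.procedure.value,
                    "indicator": call.indicator.value,
                    "observed_rate": float(f"{call.observed_rate:.6g}"),
                    "volume": call.volume,
                    "status": call.status.value,
                    "lower": float(f"{call.lower:.6g}"),
                    "upper": float(f"{call.upper:.6g}"),
                }
            )
    pd.DataFrame(curve_rows).to_csv(out / "funnel_curves.csv", index=False)
    pd.DataFrame(call_rows).to_csv(out / "outlier_calls.csv", index=False)

    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    RunManifest(
        command="pipeline",
        config_hash=_config_hash(config),
        seed=config.seed,
        inputs={"label": config.label, "years": list(config.years), "window": list(window)},
        outputs=outputs,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    ).write(out / "manifest.json")
    return out
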