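"""End-to-end pipeline: simulate -> fit -> summarize -> ROC, with
deterministic file I/O.

Curves travel as plain CSV (UTF-8, comma, '.' decimal) with columns
``lesion_id, group, subtype, time_s, si`` and seven rows per lesion.
A run emits the curve table, a per-lesion fit table, a group-summary
table (CSV and Markdown), per-marker ROC tables and a JSON manifest
(config, seed, package versions) sufficient to reproduce the bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitOptions, FitResult, fit_cohort
from .model import KineticCurve
from .stats import summarize_cohort
from .synthetic import CohortSpec, LesionRecord, simulate_cohort, table2_cohort_spec

__all__ = ["RunConfig", "read_curves", "write_curves", "run_analysis"]

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["lesion_id", "group", "subtype", "time_s", "si"]
_FLOAT_FMT = "%.17g"  # repr-round-trip safe


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "full"  # simulate | fit | analyze | full
    output_dir: str | Path = "dce_run"
    seed: int = 0
    cohort_spec: CohortSpec | None = None
    input_curves: str | Path | None = None
    fit_options: FitOptions = field(default_factory=FitOptions)
    markers: Sequence[str] = ("a", "b", "c", "d", "initial_rate", "delayed_rate")
    grouping: tuple | None = None  # default: the two most frequent groups
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "cohort_spec" in raw and isinstance(raw["cohort_spec"], dict):
            raw["cohort_spec"] = CohortSpec.from_dict(raw["cohort_spec"])
        if "fit_options" in raw and isinstance(raw["fit_options"], dict):
            raw["fit_options"] = FitOptions(**raw["fit_options"])
        if "grouping" in raw and raw["grouping"] is not None:
            raw["grouping"] = tuple(raw["grouping"])
        if "markers" in raw:
            raw["markers"] = tuple(raw["markers"])
        return cls(**raw)


def write_curves(records: Sequence[LesionRecord], path: str | Path) -> None:
    """Write lesion curves as canonical CSV (deterministic bytes)."""
    rows = []
    for rec in records:
        for t, s in zip(rec.curve.times, rec.curve.si):
            rows.append((rec.lesion_id, rec.group, rec.subtype, t, s))
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curves(path: str | Path) -> list:
    """Read and validate lesion curves written by :func:`write_curves`.

    Rows are grouped by ``lesion_id`` (times sorted on load); each
    lesion must have exactly 7 phases, exactly one pre-contrast time,
    and strictly positive signal.  Violations raise a validation error
    naming the lesion.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve file {path} missing columns: {sorted(missing)}")
    records = []
    for lesion_id, sub in df.groupby("lesion_id", sort=False):
        sub = sub.sort_values("time_s")
        if len(sub) != 7:
            raise ValueError(
                f"lesion {lesion_id!r}: expected 7 phases, got {len(sub)} "
                f"(rows {sub.index.min() + 2}..{sub.index.max() + 2})"
            )
        groups = sub["group"].unique()
        subtypes = sub["subtype"].unique()
        if len(groups) != 1 or len(subtypes) != 1:
            raise ValueError(f"lesion {lesion_id!r}: inconsistent group/subtype labels")
        try:
            curve = KineticCurve(
                times=tuple(sub["time_s"]), si=tuple(sub["si"]), normalized=False
            )
        except ValueError as exc:
            raise ValueError(f"lesion {lesion_id!r}: {exc}") from exc
        records.append(LesionRecord(
            lesion_id=str(lesion_id), group=str(groups[0]),
            subtype=str(subtypes[0]), curve=curve,
        ))
    return records


def _fits_frame(records: Sequence[LesionRecord], fits: Sequence[FitResult]) -> pd.DataFrame:
    rows = []
    for rec, fit in zip(records, fits):
        rows.append({
            "lesion_id": rec.lesion_id, "group": rec.group, "subtype": rec.subtype,
            "a": fit.params.a, "b": fit.params.b, "c": fit.params.c,
            "d": fit.params.d, "si0": fit.params.si0,
            "residual_norm": fit.residual_norm, "r_squared": fit.r_squared,
            "converged": fit.converged, "condition_flag": fit.condition_flag,
        })
    return pd.DataFrame(rows)


def _roc_frame(records, fits, marker: str, grouping: tuple) -> pd.DataFrame:
    from .stats import DEFAULT_MARKER_DIRECTIONS, roc_points
    from .stats import _marker_values  # shared extraction logic

    fitted = [r.with_fit(f) for r, f in zip(records, fits)]
    recs = [r for r in fitted if r.group in grouping]
    vals = np.array([_marker_values(r, marker) for r in recs])
    labels = np.array([r.group for r in recs])
    roc = roc_points(vals, labels, grouping[0],
                     DEFAULT_MARKER_DIRECTIONS.get(marker, "larger"))
    return pd.DataFrame({
        "threshold": roc.thresholds,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
    })


def _pick_grouping(records: Sequence[LesionRecord]) -> tuple:
    counts = pd.Series([r.group for r in records]).value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"need two groups for analysis; found only {list(counts.index)}"
        )
    return tuple(counts.index[:2])


def run_analysis(config: RunConfig) -> dict:
    """Execute the configured pipeline stages.

    Returns a dict of output paths plus the in-memory summary frame.
    Identical configs (including seed) produce byte-identical tables.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"output_dir": out}

    if config.mode not in ("simulate", "fit", "analyze", "full"):
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- inputs -----------------------------------------------------------
    if config.mode in ("simulate", "full") or (
        config.input_curves is None and config.mode in ("fit", "analyze")
    ):
        spec = config.cohort_spec or table2_cohort_spec(seed=config.seed)
        if config.cohort_spec is None:
            spec = spec.replace(seed=config.seed)
        records = simulate_cohort(spec)
        curves_path = out / "curves.csv"
        write_curves(records, curves_path)
        bundle["curves"] = curves_path
    else:
        records = read_curves(config.input_curves)
        bundle["curves"] = Path(config.input_curves)
    logger.info("pipeline: %d lesions loaded", len(records))

    manifest = {
        "package": "dcekinetics",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "mode": config.mode,
        "seed": config.seed,
        "markers": list(config.markers),
        "cohort_spec": (config.cohort_spec.to_dict() if config.cohort_spec
                        else ("table2-default" if config.input_curves is None
                              else None)),
        "input_curves": (str(config.input_curves) if config.input_curves else None),
        "fit_options": {
            "fix_si0": config.fit_options.fix_si0,
            "multistart": config.fit_options.multistart,
            "normalize": config.fit_options.normalize,
            "steepness": config.fit_options.steepness,
            "tolerance": config.fit_options.tolerance,
        },
    }

    if config.mode != "simulate":
        # --- fit ----------------------------------------------------------
        fits = fit_cohort(records, config.fit_options)
        fits_path = out / "fits.csv"
        _fits_frame(records, fits).to_csv(fits_path, index=False,
                                          float_format=_FLOAT_FMT)
        bundle["fits"] = fits_path

        if config.mode in ("analyze", "full"):
            # --- summarize + ROC -----------------------------------------
            grouping = config.grouping or _pick_grouping(records)
            fitted = [r.with_fit(f) for r, f in zip(records, fits)]
            summary = summarize_cohort(fitted, grouping, config.markers)
            summary_path = out / "summary.csv"
            summary.to_csv(summary_path, index=False, float_format=_FLOAT_FMT)
            (out / "summary.md").write_text(summary.to_markdown(index=False) + "\n")
            bundle["summary"] = summary_path
            bundle["summary_frame"] = summary
            for marker in config.markers:
                roc_path = out / f"roc_{marker}.csv"
                _roc_frame(records, fits, marker, grouping).to_csv(
                    roc_path, index=False, float_format=_FLOAT_FMT)
                bundle[f"roc_{marker}"] = roc_path
            manifest["grouping"] = list(grouping)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["manifest"] = manifest_path
    return bundle
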