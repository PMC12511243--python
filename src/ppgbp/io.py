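"""CSV/YAML input-output.

All artifacts are plain text: one CSV per recording (t_seconds, ppg), a
population manifest, the segment-level feature table, per-selector
ranking tables, grid-result tables and the agreement summary.  Every
file written by an experiment starts with a ``#`` comment header that
embeds the configuration hash, so any output can be traced back to the
exact configuration that produced it; readers skip those lines.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import EvalResult, grid_frame
from .population import PopulationConfig, PPGRecording
from .selection import SelectionResult

__all__ = [
    "config_hash",
    "load_config",
    "dump_config",
    "write_recording",
    "read_recording",
    "write_manifest",
    "read_manifest",
    "read_population_dir",
    "write_table",
    "read_table",
    "write_selection",
    "write_grid_results",
    "write_agreement",
]

MANIFEST_COLUMNS = ["subject_id", "fs", "duration", "sbp_ref", "dbp_ref", "category"]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def population_config_from_dict(cfg: dict) -> PopulationConfig:
    """Build a PopulationConfig from the ``population`` section of a config."""
    fields = {
        k: cfg[k]
        for k in (
            "n_subjects", "category_fractions", "sbp_range", "dbp_range",
            "seed", "fs", "duration", "noise_sd", "baseline_drift_amp",
            "jitter_sd",
        )
        if k in cfg
    }
    for tup in ("category_fractions", "sbp_range", "dbp_range"):
        if tup in fields:
            fields[tup] = tuple(fields[tup])
    return PopulationConfig(**fields)


def _write_csv(df: pd.DataFrame, path: str | Path, header_hash: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if header_hash is not None:
        buf.write(f"# config={header_hash}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_recording(
    recording: PPGRecording, path: str | Path, header_hash: str | None = None
) -> None:
    """One recording as a two-column CSV (t_seconds, ppg)."""
    t = np.arange(len(recording.samples)) / recording.fs
    _write_csv(
        pd.DataFrame({"t_seconds": t, "ppg": recording.samples}), path, header_hash
    )


def read_recording(path: str | Path, manifest_row: pd.Series) -> PPGRecording:
    """Rebuild a recording from its CSV and its manifest row.

    The same layout serves as the adapter contract for real data: provide
    per-recording CSVs and a manifest with subject_id, fs, duration,
    sbp_ref, dbp_ref and category columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = _read_csv(path)
    return PPGRecording(
        subject_id=str(manifest_row["subject_id"]),
        samples=df["ppg"].to_numpy(dtype=float),
        fs=float(manifest_row["fs"]),
        duration=float(manifest_row["duration"]),
        sbp_ref=float(manifest_row["sbp_ref"]),
        dbp_ref=float(manifest_row["dbp_ref"]),
        category=str(manifest_row["category"]),
    )


def write_manifest(
    recordings: list[PPGRecording], path: str | Path, header_hash: str | None = None
) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "fs": r.fs,
            "duration": r.duration,
            "sbp_ref": r.sbp_ref,
            "dbp_ref": r.dbp_ref,
            "category": r.category,
        }
        for r in recordings
    ]
    _write_csv(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), path, header_hash)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def read_population_dir(directory: str | Path) -> list[PPGRecording]:
    """Read a manifest.csv plus per-subject <subject_id>.csv recordings."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    return [
        read_recording(directory / f"{row['subject_id']}.csv", row)
        for _, row in manifest.iterrows()
    ]


def write_table(
    table: pd.DataFrame, path: str | Path, header_hash: str | None = None
) -> None:
    _write_csv(table, path, header_hash)


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path)


def write_selection(
    result: SelectionResult, path: str | Path, header_hash: str | None = None
) -> None:
    """Ranked CSV (rank, feature, score) for one (method, target)."""
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(result.ranking) + 1),
            "feature": list(result.ranking),
            "score": [result.scores[f] for f in result.ranking],
        }
    )
    _write_csv(df, path, header_hash)


def write_grid_results(
    results: list[EvalResult], out_dir: str | Path, header_hash: str | None = None
) -> None:
    """One CSV per selector (model, target, RMSE, r2, MSE, MAE) plus an
    agreement summary across all cells."""
    out_dir = Path(out_dir)
    df = grid_frame(results)
    for sel, sub in df.groupby("selector", observed=True):
        cols = ["model", "target", "rmse", "r2", "mse", "mae", "n", "error"]
        _write_csv(sub[cols], out_dir / f"grid_{sel}.csv", header_hash)


def write_agreement(
    results: list[EvalResult], path: str | Path, header_hash: str | None = None
) -> None:
    """Bland-Altman summary rows for the best (min MAE) cell per target."""
    from .evaluation import best_models

    best = best_models(results)
    rows = []
    for r in best.itertuples(index=False):
        match = next(
            x for x in results
            if x.error is None and x.selector == r.selector
            and x.spec.variant == r.model and x.target == r.target
        )
        a = match.agreement
        rows.append(
            {
                "target": r.target, "selector": r.selector, "model": r.model,
                "bias": a.bias, "loa_low": a.loa_low, "loa_high": a.loa_high,
                "ci_low": a.ci_low, "ci_high": a.ci_high, "n": a.n,
            }
        )
    _write_csv(pd.DataFrame(rows), path, header_hash)
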