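"""Pipeline orchestration: manifest -> features -> descriptives -> model.

Each stage writes plain-file products stamped with a configuration hash, so
stages are independently runnable and a rerun with identical inputs and
configuration is byte-identical.  A per-file cache keyed by (audio bytes,
config hash) avoids recomputing the modulation spectrum on model-only
reruns.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import load_audio, preprocess
from .config import AnalysisConfig, config_hash
from .contour import articulation_space_area
from .errors import ComparabilityWarning, FitError
from .hlm import assemble_dataset, descriptives, fit_hlm

__all__ = ["run_pipeline", "compute_features", "write_model_report"]

MANIFEST_COLUMNS = [
    "participant_id",
    "pair_id",
    "gender",
    "country",
    "age",
    "cr",
    "aq",
    "wav_path",
]


def _cache_key(wav_path: Path, cfg_hash: str) -> str:
    h = hashlib.sha256()
    h.update(wav_path.read_bytes())
    h.update(cfg_hash.encode())
    return h.hexdigest()[:24]


def compute_features(
    manifest: pd.DataFrame,
    config: AnalysisConfig,
    base_dir: Path | None = None,
    cache_dir: Path | None = None,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-participant articulation-space features.

    Unreadable files are logged and skipped (the skip count is returned);
    the run only fails if *no* file can be processed.
    """
    log = log if log is not None else []
    cfg_hash = config_hash(config)
    rows = []
    n_skipped = 0
    grid = None
    for rec in manifest.itertuples(index=False):
        wav_path = Path(rec.wav_path)
        if base_dir is not None and not wav_path.is_absolute():
            wav_path = base_dir / wav_path
        cached = None
        if cache_dir is not None and wav_path.exists():
            cache_file = Path(cache_dir) / f"{_cache_key(wav_path, cfg_hash)}.json"
            if cache_file.exists():
                cached = json.loads(cache_file.read_text())
        try:
            if cached is None:
                sig = preprocess(load_audio(wav_path, config.preprocess), config.preprocess)
                area, diag = articulation_space_area(sig, config)
                cached = {
                    "area_px": area,
                    "articulation_time_s": diag["articulation_time_s"],
                    "n_segments": diag["n_segments"],
                    "fraction_achieved": diag["fraction_achieved"],
                    "tm_step_hz": diag["tm_step_hz"],
                    "sm_step_cyc_per_khz": diag["sm_step_cyc_per_khz"],
                }
                if cache_dir is not None:
                    Path(cache_dir).mkdir(parents=True, exist_ok=True)
                    cache_file.write_text(json.dumps(cached))
        except Exception as exc:
            n_skipped += 1
            log.append(f"SKIP {rec.participant_id}: {wav_path} -> {exc}")
            continue
        step = (cached["tm_step_hz"], cached["sm_step_cyc_per_khz"])
        if grid is None:
            grid = step
        elif not np.allclose(step, grid):
            warnings.warn(
                f"{rec.participant_id}: modulation grid {step} differs from "
                f"{grid}; pixel areas are not comparable across recordings",
                ComparabilityWarning,
            )
        rows.append(
            {
                "participant_id": rec.participant_id,
                "pair_id": rec.pair_id,
                "area_px": cached["area_px"],
                "articulation_time_s": cached["articulation_time_s"],
                "fraction": config.contour.fraction,
                "tm_lo": config.contour.tm_lo,
                "tm_hi": config.contour.tm_hi,
                "n_segments": cached["n_segments"],
                "config_hash": cfg_hash,
            }
        )
    if not rows:
        raise FitError("no audio file could be processed")
    features = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
    return features, n_skipped


def write_model_report(result, out_csv: Path, out_txt: Path) -> None:
    """Fixed-effects table as CSV plus an aligned human-readable rendering."""
    fe = result.fixed_effects
    fe.to_csv(out_csv, index=False, float_format="%.6g")
    lines = [
        "Hierarchical linear model: articulation space (pixels)",
        f"Method: {result.fit_meta['method']}  coding: {result.fit_meta['coding']}  "
        f"n_obs: {result.n_obs}  n_pairs: {result.n_pairs}",
        f"Random-intercept variance (pair): {result.var_pair:.3f}   "
        f"Residual variance: {result.var_resid:.3f}",
        "",
        f"{'Name':<14}{'Effect':<14}{'Estimate':>10}{'SE':>9}{'Lower':>10}"
        f"{'Upper':>10}{'df':>8}{'t':>8}{'p':>8}",
    ]
    for row in fe.itertuples(index=False):
        lines.append(
            f"{row.name:<14}{row.effect:<14}{row.estimate:>10.3f}{row.se:>9.3f}"
            f"{row.ci_lo:>10.3f}{row.ci_hi:>10.3f}{row.df:>8.1f}{row.t:>8.3f}{row.p:>8.4f}"
        )
    out_txt.write_text("\n".join(lines) + "\n")


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    make_plots: bool = False,
) -> dict:
    """Run manifest -> features -> descriptives -> mixed model.

    Returns a summary dict with output paths and skip counts.  The model is
    fitted only when at least three complete pairs survive feature
    extraction.
    """
    config = config or AnalysisConfig()
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    if len(manifest) == 0:
        raise ValueError(f"empty manifest: {manifest_path}")
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest lacks columns: {sorted(missing_cols)}")

    log: list[str] = []
    cfg_hash = config_hash(config)
    log.append(f"config_hash {cfg_hash}")
    features, n_skipped = compute_features(
        manifest,
        config,
        base_dir=manifest_path.parent,
        cache_dir=out_dir / "cache",
        log=log,
    )
    features_csv = out_dir / "features.csv"
    features.to_csv(features_csv, index=False, float_format="%.10g")
    config.save(out_dir / "run_config.yaml")

    summary: dict = {
        "features_csv": str(features_csv),
        "n_features": len(features),
        "n_skipped": n_skipped,
        "config_hash": cfg_hash,
    }

    # keep only pairs with both members' features for the dyadic stages
    ok_ids = set(features["participant_id"])
    man_ok = manifest[manifest["participant_id"].isin(ok_ids)]
    pair_sizes = man_ok.groupby("pair_id")["participant_id"].count()
    whole_pairs = pair_sizes[pair_sizes == 2].index
    man_ok = man_ok[man_ok["pair_id"].isin(whole_pairs)]
    log.append(f"complete pairs: {len(whole_pairs)}")

    if len(whole_pairs) >= 3:
        records = assemble_dataset(features, man_ok)
        records["duration"] = records["articulation_time_s"]
        desc = descriptives(records)
        desc_csv = out_dir / "descriptives.csv"
        desc.to_csv(desc_csv, index=False, float_format="%.6g")
        summary["descriptives_csv"] = str(desc_csv)
        try:
            result = fit_hlm(records, config.model)
        except FitError as exc:
            log.append(f"model fit failed: {exc}")
            summary["model"] = None
        else:
            write_model_report(result, out_dir / "model_report.csv", out_dir / "model_report.txt")
            summary["model"] = str(out_dir / "model_report.csv")
            if make_plots:
                from .plots import plot_scatter_fit

                for cov in ("cr", "aq"):
                    plot_scatter_fit(records, cov, result, out_dir / f"area_vs_{cov}.png")
    else:
        log.append("fewer than 3 complete pairs; model stage skipped")
        summary["model"] = None

    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return summary
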