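"""End-to-end orchestration: manifests in, tidy CSV/JSON results out.

``run_pipeline`` processes one shoulder; ``analyze_cohort`` maps it over a
directory of generated shoulders and stacks the results.  Outputs:

* ``samples.csv``   - per-frame kinematics (x, y, WSS, abduction),
* ``metrics.csv``   - per-shoulder looseness metrics + tear classification,
* ``normalized.csv``- head-centre trajectories in percent-of-glenoid units,
* ``registrations.json`` - per-frame rigid transforms and ICP diagnostics,
* ``run.log``       - fit residuals and iteration counts per stage.

Given identical inputs and configuration the outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import StudyManifest, load_manifest
from .kinematics import (
    SequenceAnalysis,
    analyze_sequence,
    classify_tear,
    normalize_to_glenoid_percent,
)
from .stats import repeatability_spread
from .synthetic import SyntheticProfile, default_profiles, generate_sequence

__all__ = ["run_pipeline", "analyze_cohort", "repeatability_trial", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "icp_max_iter": 100,
    "icp_tol": 1e-4,
    "trim_fraction": 0.0,
    "wss_tear_threshold_mm": 4.0,
}

FLOAT_FMT = "%.6f"

log = logging.getLogger("glenokin")


def _analysis_tables(manifest_like, analysis: SequenceAnalysis, threshold: float):
    sid = manifest_like.shoulder_id
    group = getattr(manifest_like, "group", "NA")
    samples = pd.DataFrame(
        [
            {
                "shoulder_id": sid,
                "group": group,
                "frame_index": s.frame_index,
                "time_s": s.time_s,
                "x_mm": s.x_mm,
                "y_mm": s.y_mm,
                "wss_mm": s.wss_mm,
                "abduction_deg": s.abduction_deg,
            }
            for s in analysis.samples
        ]
    )
    metrics = pd.DataFrame(
        [
            {"shoulder_id": sid, "group": group}
            | analysis.metrics.as_dict()
            | {"classification": classify_tear(analysis.metrics, threshold)}
        ]
    )
    norm_rows = []
    for s in analysis.samples:
        x_pct, y_pct = normalize_to_glenoid_percent(s.x_mm, s.y_mm, analysis.glenoid_cs)
        norm_rows.append(
            {
                "shoulder_id": sid,
                "group": group,
                "frame_index": s.frame_index,
                "x_pct": x_pct,
                "y_pct": y_pct,
            }
        )
    return samples, metrics, pd.DataFrame(norm_rows)


def _registration_records(analysis: SequenceAnalysis) -> dict:
    return {
        str(idx): {
            "transform": rep.transform.to_dict(),
            "rms_before_mm": rep.rms_before,
            "rms_after_mm": rep.rms_after,
            "iterations": rep.iterations,
            "converged": rep.converged,
        }
        for idx, rep in analysis.registrations.items()
    }


def run_pipeline(manifest: StudyManifest | str | Path, out_dir, config: dict | None = None) -> Path:
    """Analyze one shoulder described by a manifest; write all outputs.

    ``config`` overrides :data:`DEFAULT_CONFIG` keys.  Returns the output
    directory.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = load_manifest(manifest)
    cfg = DEFAULT_CONFIG | (config or {}) | manifest.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        frames = manifest.load_frames()
        log.info("loaded %d frames for %s", len(frames), manifest.shoulder_id)
        analysis = analyze_sequence(
            frames,
            reference_index=manifest.reference_index,
            superior_hint=manifest.superior_hint,
            anterior_hint=manifest.anterior_hint,
            icp_max_iter=int(cfg["icp_max_iter"]),
            icp_tol=float(cfg["icp_tol"]),
            trim_fraction=float(cfg["trim_fraction"]),
        )
        cs = analysis.glenoid_cs
        log.info(
            "glenoid ellipse: semi-axes %.3f/%.3f mm, rim rms %.4f mm",
            cs.semi_major,
            cs.semi_minor,
            cs.rms_residual,
        )
        for idx, rep in analysis.registrations.items():
            log.info(
                "frame %d: icp rms %.4f -> %.4f mm in %d iterations (converged=%s)",
                idx,
                rep.rms_before,
                rep.rms_after,
                rep.iterations,
                rep.converged,
            )
        samples, metrics, norm = _analysis_tables(
            manifest, analysis, float(cfg["wss_tear_threshold_mm"])
        )
        samples.to_csv(out / "samples.csv", index=False, float_format=FLOAT_FMT)
        metrics.to_csv(out / "metrics.csv", index=False, float_format=FLOAT_FMT)
        norm.to_csv(out / "normalized.csv", index=False, float_format=FLOAT_FMT)
        (out / "registrations.json").write_text(
            json.dumps(_registration_records(analysis), indent=2, sort_keys=True)
        )
    except Exception:
        log.exception("pipeline failed for %s", manifest.shoulder_id)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def analyze_cohort(cohort_dir, out_dir, config: dict | None = None) -> Path:
    """Run the pipeline over every ``manifest.json`` below ``cohort_dir``
    and stack results into cohort-level CSVs in ``out_dir``."""
    cohort_dir = Path(cohort_dir)
    manifests = sorted(cohort_dir.glob("*/manifest.json"))
    if not manifests:
        raise FileNotFoundError(f"no */manifest.json under {cohort_dir}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_samples, all_metrics, all_norm = [], [], []
    for mpath in manifests:
        sub = run_pipeline(mpath, out / mpath.parent.name, config=config)
        all_samples.append(pd.read_csv(sub / "samples.csv"))
        all_metrics.append(pd.read_csv(sub / "metrics.csv"))
        all_norm.append(pd.read_csv(sub / "normalized.csv"))
    pd.concat(all_samples, ignore_index=True).to_csv(
        out / "samples.csv", index=False, float_format=FLOAT_FMT
    )
    pd.concat(all_metrics, ignore_index=True).to_csv(
        out / "metrics.csv", index=False, float_format=FLOAT_FMT
    )
    pd.concat(all_norm, ignore_index=True).to_csv(
        out / "normalized.csv", index=False, float_format=FLOAT_FMT
    )
    return out


def repeatability_trial(
    profile: SyntheticProfile | None = None,
    frame_index: int = 4,
    n_repeats: int = 6,
    noise_sd_mm: float = 0.3,
    seed: int = 0,
):
    """Emulate the intra-observer repeatability protocol.

    One intermediate frame of one (by default normal) synthetic shoulder is
    "reconstructed" ``n_repeats`` times - fresh segmentation noise each time
    - and each reconstruction is registered to the (once-reconstructed)
    reference and measured.  Returns ``(samples, spreads)`` where spreads
    are the per-quantity max - min over the repeats.
    """
    from .kinematics import _measure_frame, apply_transform  # internal reuse
    from .registration import register_rigid
    from .synthetic import _noisy

    if profile is None:
        profile = default_profiles()["N"]
    profile = replace(profile, noise_sd_mm=0.0, seed=seed)
    frames, truth = generate_sequence(profile)
    rng = np.random.default_rng(seed)

    ref = frames[0]
    ref_noisy = {name: _noisy(obj, rng, noise_sd_mm) for name, obj in ref.regions.items()}
    from .kinematics import LabelledFrame
    from .geometry import fit_glenoid_cs

    ref_frame = LabelledFrame(0, ref.time_s, ref_noisy, side=ref.side)
    cs = fit_glenoid_cs(
        ref_frame.points("glenoid_contour"),
        truth.superior_hint,
        truth.anterior_hint,
        side=ref.side,
    )
    target = frames[frame_index]
    ref_scap = ref_frame.points("scapula")
    samples = []
    for _ in range(n_repeats):
        noisy_regions = {
            name: _noisy(obj, rng, noise_sd_mm) for name, obj in target.regions.items()
        }
        noisy = LabelledFrame(
            target.frame_index, target.time_s, noisy_regions, side=target.side
        )
        report = register_rigid(noisy.points("scapula"), ref_scap)
        registered = apply_transform(noisy, report.transform)
        samples.append(_measure_frame(registered, cs))
    return samples, repeatability_spread(samples)
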