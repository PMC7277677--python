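"""Shared file I/O: TIFF stacks, CSV tables, JSON sidecars, run manifests.

Conventions: movies are multi-page grayscale TIFF (8- or 16-bit on disk,
float in memory); traces, metrics, force curves and rheology sweeps are
RFC-4180 CSV with a fixed header row; ground truth and summaries are JSON.
Force-curve CSVs carry a one-line JSON header block (prefixed ``#``) with
the probe constants.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from calmech.detect import NeuronSignal
from calmech.mechanics import ForceCurve, RheologySweep
from calmech.metrics import RecordingSummary
from calmech.simulate import GroundTruth, MovieStack

__all__ = [
    "read_stack", "write_stack",
    "write_ground_truth", "read_ground_truth",
    "write_force_curve", "read_force_curve",
    "read_rheology_sweep", "write_rheology_sweep",
    "write_roi_table", "write_metrics_table", "write_summary_json",
    "write_run_manifest",
]


def read_stack(path: str | Path, frame_rate: float = 30.0) -> MovieStack:
    """Read a multi-page grayscale TIFF as a MovieStack."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a T x H x W grayscale stack, got {data.shape}")
    if data.dtype.kind not in "ui" or data.dtype.itemsize > 2:
        if data.dtype.kind != "f":
            raise ValueError(f"unsupported TIFF dtype {data.dtype}")
    return MovieStack(data=data.astype(float), frame_rate=frame_rate)


def write_stack(stack: MovieStack, path: str | Path) -> None:
    """Write a stack as 16-bit multi-page TIFF (values clipped to range)."""
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    """2-column CSV (displacement_m, force_N) with a JSON probe header."""
    header = {
        "sphere_radius_m": curve.sphere_radius,
        "spring_constant_n_per_m": curve.spring_constant,
        "poisson_ratio": curve.poisson_ratio,
        "sensitivity_m_per_v": curve.sensitivity,
        "is_indentation": curve.is_indentation,
    }
    force = curve.force_values()
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("displacement_m,force_N\n")
        for z, f in zip(curve.displacement, force):
            fh.write(f"{float(z)!r},{float(f)!r}\n")


def read_force_curve(path: str | Path) -> ForceCurve:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("force-curve CSV must start with a JSON header line")
        header = json.loads(first.lstrip("# "))
        table = pd.read_csv(fh)
    return ForceCurve(
        displacement=table["displacement_m"].to_numpy(),
        force=table["force_N"].to_numpy(),
        sphere_radius=header["sphere_radius_m"],
        spring_constant=header["spring_constant_n_per_m"],
        poisson_ratio=header["poisson_ratio"],
        sensitivity=header.get("sensitivity_m_per_v"),
        is_indentation=bool(header.get("is_indentation", False)),
    )


def write_rheology_sweep(sweep: RheologySweep, path: str | Path) -> None:
    df = pd.DataFrame({
        "frequency_hz": sweep.frequency,
        "g_prime_pa": sweep.storage_modulus,
    })
    if sweep.loss_modulus is not None:
        df["g_doubleprime_pa"] = sweep.loss_modulus
    df.to_csv(path, index=False)


def read_rheology_sweep(path: str | Path) -> RheologySweep:
    df = pd.read_csv(path)
    return RheologySweep(
        frequency=df["frequency_hz"].to_numpy(),
        storage_modulus=df["g_prime_pa"].to_numpy(),
        loss_modulus=df["g_doubleprime_pa"].to_numpy()
        if "g_doubleprime_pa" in df else None,
    )


def write_roi_table(signals: list[NeuronSignal], out_dir: str | Path) -> None:
    """ROI summary CSV plus one trace CSV per ROI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(signals):
        rows.append({
            "roi_id": i, "n_pixels": s.n_pixels,
            "row0": s.bbox[0], "col0": s.bbox[1],
            "row1": s.bbox[2], "col1": s.bbox[3],
        })
        pd.DataFrame({
            "time_s": np.arange(len(s.trace)) / s.frame_rate,
            "intensity": s.trace,
        }).to_csv(out / f"trace_{i:04d}.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "rois.csv", index=False)


def write_metrics_table(signals: list[NeuronSignal], path: str | Path) -> None:
    rows = []
    for i, s in enumerate(signals):
        events = s.events or []
        flagged = sum(e.tau_flag for e in events)
        rows.append({
            "neuron_id": i,
            "n_events": len(events),
            "frequency_hz": s.frequency,
            "mean_dff_pct": s.mean_amplitude,
            "tau_s": s.tau if s.tau is not None else "",
            "tau_flag": flagged,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(summary: RecordingSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "frequencies_hz": summary.frequencies,
        "mean_amplitudes_pct": summary.mean_amplitudes,
        "taus_s": summary.taus,
        "synchronized_pair": summary.synchronized_pair,
        "synchronized_triple": summary.synchronized_triple,
        "n_synchronized_pairs": summary.n_synchronized_pairs,
    }, indent=1))


def write_run_manifest(path: str | Path, config: dict,
                       seed: int | None = None) -> None:
    """Log config, seed and library versions for reproducibility."""
    import scipy

    manifest = {
        "config": config,
        "seed": seed,
        "python": sys.version,
        "platform": platform.platform(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "tifffile": tifffile.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
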