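"""Readers and writers for the standard neuroimaging formats the toolkit
touches: per-echo NIfTI series with BIDS-style JSON sidecars (EchoTime in
seconds), BIDS event TSVs, physio/motion TSVs with a sampling-rate header
line, parameter-map NIfTIs and machine-readable JSON reports.

All writers are deterministic: re-running with an identical configuration
produces byte-identical files (timestamps live only in the human log).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .combine import CombinedSeries, EchoWeightMap
from .fitting import MultiEchoSeries, T2StarResults
from .nuisance import RespiratoryTrace

__all__ = [
    "read_multiecho",
    "write_phantom",
    "write_parameter_maps",
    "write_weight_map",
    "write_combined",
    "read_events",
    "write_events",
    "read_physio",
    "write_physio",
    "read_motion",
    "write_motion",
    "write_report",
    "config_hash",
    "save_nifti",
]

_DEFAULT_AFFINE = np.diag([2.4, 2.4, 2.4, 1.0])


def save_nifti(data: np.ndarray, path, affine: Optional[np.ndarray] = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                          _DEFAULT_AFFINE if affine is None else affine)
    nib.save(img, str(path))
    return path


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".json")
    return image_path.with_suffix(".json")


def read_multiecho(paths: Sequence, te_ms: Optional[Sequence[float]] = None,
                   tr_s: Optional[float] = None) -> MultiEchoSeries:
    """Load per-echo NIfTI files into a :class:`MultiEchoSeries`.

    Echo times come from each file's JSON sidecar (BIDS ``EchoTime``, in
    seconds, converted to ms) when present, from ``te_ms`` otherwise; when
    both exist they must agree within 1e-3 ms.  Echoes are sorted ascending
    by TE regardless of the argument order.  All files must share shape and
    affine (within 1e-4).
    """
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise ValueError("need at least two echo images")
    if te_ms is not None and len(te_ms) != len(paths):
        raise ValueError(f"{len(paths)} files but {len(te_ms)} echo times")

    imgs = [nib.load(str(p)) for p in paths]
    shape0, aff0 = imgs[0].shape, imgs[0].affine
    for p, img in zip(paths[1:], imgs[1:]):
        if img.shape != shape0:
            raise ValueError(f"shape mismatch: {p} has {img.shape}, expected {shape0}")
        if not np.allclose(img.affine, aff0, atol=1e-4):
            raise ValueError(f"affine mismatch in {p}")

    tes = []
    for i, p in enumerate(paths):
        sidecar = _sidecar_path(p)
        te_side = None
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "EchoTime" in meta:
                te_side = float(meta["EchoTime"]) * 1000.0  # s -> ms
        te_arg = float(te_ms[i]) if te_ms is not None else None
        if te_side is not None and te_arg is not None:
            if abs(te_side - te_arg) > 1e-3:
                raise ValueError(
                    f"echo time conflict for {p}: sidecar {te_side} ms vs argument {te_arg} ms"
                )
        te = te_side if te_side is not None else te_arg
        if te is None:
            raise ValueError(f"no echo time for {p} (no sidecar, none supplied)")
        tes.append(te)

    order = np.argsort(tes)
    data = np.stack([np.asarray(imgs[i].dataobj, dtype=float) for i in order])
    if data.ndim == 4:
        data = data[..., np.newaxis]
    te_sorted = np.asarray(tes)[order]

    if tr_s is None:
        zooms = imgs[0].header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return MultiEchoSeries(data=data, echo_times=te_sorted, tr_s=tr_s, affine=aff0)


# ----------------------------------------------------------------------
# tabular sidecars
# ----------------------------------------------------------------------

def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False,
                  columns=["onset", "duration", "trial_type"], float_format="%.6f")
    return path


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"events file missing column {col!r}")
    return df


def write_physio(trace: RespiratoryTrace, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={trace.fs_hz:.6f}\n")
        fh.write("respiratory\n")
        for v in trace.samples:
            fh.write(f"{v:.8f}\n")
    return path


def read_physio(path) -> RespiratoryTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#") or "fs_hz=" not in header:
        raise ValueError("physio TSV must begin with a '# fs_hz=<rate>' header line")
    fs_hz = float(header.split("fs_hz=")[1])
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    return RespiratoryTrace(samples=df.iloc[:, 0].to_numpy(), fs_hz=fs_hz)


_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion(params: np.ndarray, tr_s: float, path) -> Path:
    path = Path(path)
    params = np.asarray(params, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# tr_s={tr_s:.6f}\n")
        fh.write("\t".join(_MOTION_COLS) + "\n")
        for row in params:
            fh.write("\t".join(f"{v:.8f}" for v in row) + "\n")
    return path


def read_motion(path) -> tuple:
    """Returns (params (n_volumes, 6), tr_s)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#") or "tr_s=" not in header:
        raise ValueError("motion TSV must begin with a '# tr_s=<TR>' header line")
    tr_s = float(header.split("tr_s=")[1])
    df = pd.read_csv(path, sep="\t", skiprows=1)
    if df.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 parameter columns")
    return df.to_numpy(dtype=float), tr_s


# ----------------------------------------------------------------------
# dataset / result writers
# ----------------------------------------------------------------------

def write_phantom(phantom, out_dir) -> dict:
    """Write a generated phantom as a BIDS-flavoured dataset.

    Per-echo NIfTIs with EchoTime sidecars (seconds), events TSV, physio
    and motion TSVs, ground-truth maps and a JSON ground-truth summary.
    Returns a manifest of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = phantom.series
    affine = series.affine if series.affine is not None else _DEFAULT_AFFINE
    manifest = {"echoes": []}
    for e in range(series.n_echoes):
        img_path = out / f"echo-{e + 1}_bold.nii.gz"
        save_nifti(series.data[e], img_path, affine)
        sidecar = _sidecar_path(img_path)
        sidecar.write_text(json.dumps(
            {"EchoTime": float(series.echo_times[e]) / 1000.0,
             "RepetitionTime": float(series.tr_s)}, indent=2, sort_keys=True))
        manifest["echoes"].append(str(img_path))
    manifest["events"] = str(write_events(phantom.events, out / "events.tsv"))
    manifest["physio"] = str(write_physio(
        RespiratoryTrace(phantom.resp_samples, phantom.resp_fs_hz), out / "physio.tsv"))
    manifest["motion"] = str(write_motion(phantom.motion_params, series.tr_s,
                                          out / "motion.tsv"))
    truth = phantom.truth
    save_nifti(truth.s0_map, out / "truth_s0.nii.gz", affine)
    save_nifti(np.nan_to_num(truth.t2star_map), out / "truth_t2star.nii.gz", affine)
    save_nifti(truth.tissue_mask.astype(float), out / "truth_tissue_mask.nii.gz", affine)
    save_nifti(truth.activation_mask.astype(float), out / "truth_activation_mask.nii.gz",
               affine)
    truth_meta = {
        "x0": truth.x0,
        "seed": int(phantom.spec.seed),
        "echo_times_ms": [float(t) for t in series.echo_times],
        "tr_s": float(series.tr_s),
        "n_volumes": int(series.n_volumes),
        "rois": {label: int(m.sum()) for label, m in truth.roi_masks.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth_meta, indent=2, sort_keys=True))
    manifest["truth"] = str(out / "truth.json")
    return manifest


def write_parameter_maps(results: T2StarResults, out_dir) -> dict:
    """T2*/S0/x0 maps, failed mask, and a JSON fit report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = results.affine if results.affine is not None else _DEFAULT_AFFINE
    paths = {
        "t2star": save_nifti(np.nan_to_num(results.t2star_map), out / "t2star.nii.gz", affine),
        "s0": save_nifti(np.nan_to_num(results.s0_map), out / "s0.nii.gz", affine),
        "x0": save_nifti(np.nan_to_num(results.x0_map), out / "x0.nii.gz", affine),
        "failed_mask": save_nifti(results.failed_mask.astype(float),
                                  out / "failed_mask.nii.gz", affine),
    }
    report = {
        "method": results.method,
        "echo_times_ms": [float(t) for t in results.echo_times],
        "n_obs_per_voxel": int(results.n_obs_per_voxel),
        "n_voxels_fitted": results.n_fitted,
        "n_voxels_failed": results.n_failed,
        "t2star_bounds_ms": [1.0, 500.0],
        "objective_tolerance": 1e-12,
    }
    (out / "fit_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    paths["report"] = out / "fit_report.json"
    return {k: str(v) for k, v in paths.items()}


def write_weight_map(wmap: EchoWeightMap, path, affine=None) -> Path:
    return save_nifti(wmap.weights, path, affine)


def write_combined(combined: CombinedSeries, path) -> Path:
    return save_nifti(combined.data, path, combined.affine)


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (order-independent)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(results: dict, out_dir, config: Optional[dict] = None,
                 name: str = "report.json") -> Path:
    """Machine-readable JSON report plus a human log line.

    The JSON carries the results, configuration and its hash, and library
    versions — but no timestamp, so identical runs produce byte-identical
    reports.  Timestamps go to ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "results": results,
        "config": config or {},
        "config_hash": config_hash(config or {}),
        "versions": {"numpy": np.__version__, "nibabel": nib.__version__},
    }
    path = out / name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    with open(out / "run.log", "a") as fh:
        fh.write(f"{datetime.datetime.now().isoformat()} wrote {name}\n")
    return path
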