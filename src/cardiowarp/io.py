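"""File formats, run configuration, and the demo pipeline.

NIfTI for cine volumes (single 4D file or one 3D file per frame, plus a
JSON sidecar carrying frame times and ED/ES indices), Gmsh MSH / legacy
VTK for meshes and fields, CSV for strain curves and statistics tables,
YAML for configuration, JSON for peaks and provenance.  World
coordinates are mm, right-handed; voxel indices are 0-based and map to
world through the image affine; frames are 0-based with explicit ED/ES
indices.  Strain is dimensionless internally and percent at I/O.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mesh import write_msh, write_vtk
from .phantom import PhantomSpec, spec_from_dict, spec_to_dict
from .strain import StrainCurves, peak_systolic
from .warping import ImageSeries, WarpConfig

logger = logging.getLogger("cardiowarp")


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# NIfTI image series
# ---------------------------------------------------------------------------

def save_image_series(series: ImageSeries, path, split_frames: bool = False) -> list:
    """Write an ImageSeries as 4D NIfTI (default) or per-frame 3D NIfTI.

    A JSON sidecar ``<stem>.json`` records frame times, ED/ES indices
    and the normalization record.  Returns the written paths.
    """
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if split_frames:
        for t in range(series.n_frames):
            p = path.with_name(f"{path.stem}_frame{t:03d}.nii")
            nib.save(nib.Nifti1Image(series.frames[t], series.affine), p)
            written.append(p)
    else:
        data = np.moveaxis(series.frames, 0, -1)  # (nx,ny,nz,T)
        nib.save(nib.Nifti1Image(data, series.affine), path)
        written.append(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_times": list(map(float, series.frame_times)),
                "es_index": int(series.es_index),
                "ed_index": int(series.ed_index),
                "normalization": series.normalization,
                "n_frames": series.n_frames,
            },
            indent=2,
        )
    )
    written.append(sidecar)
    return written


def load_image_series(path) -> ImageSeries:
    """Read a 4D NIfTI (or the first of a per-frame set) plus its sidecar."""
    import nibabel as nib

    path = Path(path)
    if "_frame" in path.stem:
        sidecar = path.with_name(path.stem.split("_frame")[0] + ".json")
    else:
        sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise IOError_(f"missing sidecar {sidecar} (frame times / ED / ES)")
    meta = json.loads(sidecar.read_text())
    if "_frame" in path.stem:
        stem = path.stem.split("_frame")[0]
        frames = []
        for t in range(meta["n_frames"]):
            p = path.with_name(f"{stem}_frame{t:03d}.nii")
            img = nib.load(str(p))
            frames.append(np.asarray(img.dataobj, dtype=float))
        data = np.stack(frames, axis=0)
        affine = img.affine
    else:
        img = nib.load(str(path))
        data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        affine = img.affine
    return ImageSeries(
        frames=data,
        affine=affine,
        frame_times=np.asarray(meta["frame_times"], float),
        es_index=int(meta["es_index"]),
        ed_index=int(meta["ed_index"]),
        normalization=meta.get("normalization"),
    )


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def save_yaml(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, PhantomSpec):
        payload = {"phantom": spec_to_dict(obj)}
    elif isinstance(obj, WarpConfig):
        payload = {"warp": dataclasses.asdict(obj)}
    else:
        payload = obj
    path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_phantom_spec(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    return spec_from_dict(d["phantom"] if "phantom" in d else d)


def load_warp_config(path) -> WarpConfig:
    d = yaml.safe_load(Path(path).read_text())
    return WarpConfig(**(d["warp"] if "warp" in d else d))


# ---------------------------------------------------------------------------
# Curves / peaks
# ---------------------------------------------------------------------------

def save_curves(curves: StrainCurves, path) -> None:
    """Strain-time curves to CSV (region, component, frame, time_s, strain_percent)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curves.to_dataframe().to_csv(path, index=False, float_format="%.8g")


def load_curves(path, es_index: int, ed_index: int) -> StrainCurves:
    return StrainCurves.from_dataframe(pd.read_csv(path), es_index, ed_index)


def save_peaks(peaks: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(peaks, indent=2))


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def provenance_record(config_payload: dict, seed: int | None) -> dict:
    blob = yaml.safe_dump(config_payload, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "cardiowarp_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }


# ---------------------------------------------------------------------------
# Demo pipeline
# ---------------------------------------------------------------------------

def run_demo(
    outdir,
    seed: int = 0,
    phantom_overrides: dict | None = None,
    warp_overrides: dict | None = None,
    write_outputs: bool = True,
) -> dict:
    """Full pipeline on the default phantom: generate, track, score.

    Builds the phantom at ``seed``, renders the cine series, registers
    the ES mesh through the cycle, extracts regional strain curves and
    peaks, and reports recovered-vs-oracle peak strains.  All outputs
    (images, meshes, curves, peaks, provenance) land in ``outdir``.
    """
    from .directions import build_directions
    from .phantom import (
        es_configuration,
        ground_truth_strains,
        make_phantom_mesh,
        render_image_series,
    )
    from .strain import compute_strain_curves
    from .warping import normalize_series, track_cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(phantom_overrides or {})
    overrides["seed"] = int(seed)
    spec = PhantomSpec(**overrides)
    wkw = dict(warp_overrides or {})
    wkw.setdefault("mapse", spec.mapse)
    config = WarpConfig(**wkw)

    logger.info("rendering phantom image series (%d frames)", spec.n_frames)
    raw = render_image_series(spec)
    series = normalize_series(
        raw.frames, raw.affine, raw.frame_times, raw.es_index, raw.ed_index
    )
    logger.info("meshing phantom")
    mesh_ed = make_phantom_mesh(spec)
    mesh = es_configuration(spec, mesh_ed)
    dirs = build_directions(mesh)
    oracle = ground_truth_strains(spec, mesh_ed=mesh_ed, directions=dirs)
    logger.info("tracking %d frames from ES", series.n_frames)
    sol = track_cycle(mesh, series, config)
    curves = compute_strain_curves(
        sol.F, dirs, mesh, series.frame_times, series.es_index, series.ed_index,
        volume_weighted=config.volume_weighted_regions,
    )
    peaks = peak_systolic(curves, window=config.peak_window)
    oracle_peaks = peak_systolic(oracle, window=config.peak_window)

    report = {
        "recovered_peaks_percent": peaks,
        "oracle_peaks_percent": oracle_peaks,
        "max_abs_error_percent": max(
            abs(peaks[r][c] - oracle_peaks[r][c])
            for r in peaks
            for c in peaks[r]
        ),
        "provenance": provenance_record(
            {"phantom": spec_to_dict(spec), "warp": dataclasses.asdict(config)},
            seed,
        ),
    }
    if write_outputs:
        save_image_series(series, outdir / "cine.nii")
        write_msh(mesh, outdir / "mesh_es.msh")
        write_vtk(
            mesh,
            outdir / "mesh_es.vtk",
            cell_data={"e_c": dirs.e_c, "e_l": dirs.e_l, "e_r": dirs.e_r},
        )
        save_yaml(
            {"phantom": spec_to_dict(spec), "warp": dataclasses.asdict(config)},
            outdir / "config.yaml",
        )
        save_curves(curves, outdir / "strain_curves.csv")
        save_curves(oracle, outdir / "oracle_curves.csv")
        save_peaks(report, outdir / "peaks_report.json")
    result = dict(report)
    result.update(
        curves=curves, oracle=oracle, solution=sol, mesh=mesh, directions=dirs,
        spec=spec, series=series,
    )
    return result
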