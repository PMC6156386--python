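"""ED-referenced Green-Lagrange strains from tracked deformation gradients.

Tracking runs with the end-systolic geometry as its origin, but strain
is conventionally reported against end-diastole.  The reference is
switched by the relative deformation F_rel = F F_ED^{-1}, giving

    E = 1/2 (F_rel^T F_rel - I),

which is exactly zero at ED for every cell, insensitive to rigid
motions, and reduces in 1D to dL/L + (dL/L)^2 / 2.  Normal components
along the rule-based triads are eps_ii = e_i . E e_i for
i in {C, L, R}; region curves are elementwise averages over the LV
free wall, septum and RV free wall, and peak systolic values are the
extrema over the ED->ES arc (minimum for the shortening components
eps_CC and eps_LL, maximum for the thickening component eps_RR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .directions import DirectionField
from .mesh import BivMesh, Region

COMPONENTS = ("CC", "LL", "RR")
REGION_ORDER = (Region.LV_FREE, Region.SEPTUM, Region.RV_FREE)


class StrainError(ValueError):
    pass


def remap_reference(F: np.ndarray, F_ed: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain with ED as the reference configuration.

    ``F`` and ``F_ed`` are deformation gradients w.r.t. the tracking
    (ES) configuration; the relative gradient F F_ED^{-1} re-references
    the strain to ED.  Works on stacked (..., 3, 3) arrays.
    """
    F = np.asarray(F, float)
    F_ed = np.asarray(F_ed, float)
    det = np.linalg.det(F_ed)
    if np.any(np.abs(det) < 1e-12):
        raise StrainError("F_ED is singular; cannot re-reference")
    if np.any(det < 0) or np.any(np.linalg.det(F) < 0):
        raise StrainError("deformation gradients must have positive determinant")
    F_rel = F @ np.linalg.inv(F_ed)
    Ft = np.swapaxes(F_rel, -1, -2)
    return 0.5 * (Ft @ F_rel - np.eye(3))


def project_strain(E: np.ndarray, triad) -> np.ndarray:
    """Normal components (eps_CC, eps_LL, eps_RR) of E along a triad.

    ``triad`` is a :class:`DirectionField` (or (e_c, e_l, e_r) arrays);
    E may be (..., m, 3, 3) stacked over frames.
    """
    if isinstance(triad, DirectionField):
        vecs = (triad.e_c, triad.e_l, triad.e_r)
    else:
        vecs = triad
    comps = [np.einsum("mi,...mij,mj->...m", e, E, e) for e in vecs]
    return np.stack(comps, axis=-1)  # (..., m, 3)


@dataclass
class StrainCurves:
    """Region x component x frame strain-time curves (dimensionless).

    ``values[r, c, t]`` follows REGION_ORDER x COMPONENTS x frames;
    strains are stored dimensionless and reported in percent at I/O.
    """

    values: np.ndarray
    frame_times: np.ndarray
    es_index: int
    ed_index: int

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[2])

    def curve(self, region: Region, component: str) -> np.ndarray:
        return self.values[REGION_ORDER.index(Region(region)), COMPONENTS.index(component)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ri, region in enumerate(REGION_ORDER):
            for ci, comp in enumerate(COMPONENTS):
                for t in range(self.n_frames):
                    rows.append(
                        {
                            "region": region.name,
                            "component": comp,
                            "frame": t,
                            "time_s": float(self.frame_times[t]),
                            "strain_percent": 100.0 * self.values[ri, ci, t],
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, es_index: int, ed_index: int):
        T = df["frame"].max() + 1
        vals = np.zeros((len(REGION_ORDER), len(COMPONENTS), T))
        times = np.zeros(T)
        for _, row in df.iterrows():
            ri = [r.name for r in REGION_ORDER].index(row["region"])
            ci = COMPONENTS.index(row["component"])
            vals[ri, ci, int(row["frame"])] = row["strain_percent"] / 100.0
            times[int(row["frame"])] = row["time_s"]
        return cls(vals, times, es_index, ed_index)


def region_average(
    cell_strains: np.ndarray,
    mesh: BivMesh,
    frame_times: np.ndarray,
    es_index: int,
    ed_index: int,
    volume_weighted: bool = False,
) -> StrainCurves:
    """Average per-cell strain components over the three regions.

    ``cell_strains`` is (T, m, 3) in COMPONENTS order.  The default is
    the unweighted mean over elements; ``volume_weighted`` switches to
    a cell-volume weighting.
    """
    if mesh.region_labels is None:
        raise StrainError("mesh has no region labels; run partition_regions first")
    cs = np.asarray(cell_strains, float)
    T = cs.shape[0]
    vals = np.zeros((len(REGION_ORDER), len(COMPONENTS), T))
    w = mesh.cell_volumes() if volume_weighted else np.ones(mesh.n_cells)
    for ri, region in enumerate(REGION_ORDER):
        sel = mesh.region_labels == int(region)
        if not np.any(sel):
            raise StrainError(f"region {region.name} is empty")
        wr = w[sel] / w[sel].sum()
        vals[ri] = np.einsum("tmc,m->ct", cs[:, sel, :], wr)
    return StrainCurves(
        values=vals,
        frame_times=np.asarray(frame_times, float),
        es_index=int(es_index),
        ed_index=int(ed_index),
    )


def compute_strain_curves(
    F_frames: np.ndarray,
    directions: DirectionField,
    mesh: BivMesh,
    frame_times: np.ndarray,
    es_index: int,
    ed_index: int,
    volume_weighted: bool = False,
) -> StrainCurves:
    """Full post-processing path: remap to ED, project, region-average.

    ``F_frames`` is (T, m, 3, 3) deformation gradients w.r.t. the
    tracking configuration (any fixed configuration works — the ED
    entry supplies the re-referencing).
    """
    F_frames = np.asarray(F_frames, float)
    E = remap_reference(F_frames, F_frames[ed_index])
    cs = project_strain(E, directions)
    return region_average(
        cs, mesh, frame_times, es_index, ed_index, volume_weighted
    )


def _systole_arc(curves: StrainCurves) -> np.ndarray:
    T = curves.n_frames
    k = (curves.es_index - curves.ed_index) % T
    return (curves.ed_index + np.arange(k + 1)) % T


def peak_systolic(curves: StrainCurves, window: str = "systole") -> dict:
    """Peak systolic strain per region/component, in percent, sign kept.

    Shortening components (eps_CC, eps_LL) take their minimum (most
    negative) value, the thickening component (eps_RR) its maximum.
    ``window`` is the ED->ES arc by default; "cycle" searches all
    frames (atrial-kick effects can shift extrema slightly).
    """
    if window == "systole":
        idx = _systole_arc(curves)
    elif window == "cycle":
        idx = np.arange(curves.n_frames)
    else:
        raise StrainError(f"unknown peak window {window!r}")
    peaks: dict[str, dict[str, float]] = {}
    for ri, region in enumerate(REGION_ORDER):
        peaks[region.name] = {}
        for ci, comp in enumerate(COMPONENTS):
            c = curves.values[ri, ci, idx]
            v = c.max() if comp == "RR" else c.min()
            peaks[region.name][comp] = float(100.0 * v)
    return peaks
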