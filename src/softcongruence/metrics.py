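"""Surface-congruence statistics per aesthetic unit.

For each region the report carries:

* ``IO%`` — percentage of evaluated vertices whose unsigned distance is
  within the tolerance tau (default ±2 mm, the conventional bound for a
  clinically correct prediction); comparison inclusive (|d| <= tau).
* ``MTL`` — the signed arithmetic mean of the distance map (mm).  Note
  the field's customary label reads "mean absolute", yet the quantity
  is reported with negative values in practice; it is the signed mean.
* ``RMS`` — root-mean-square of the signed distances (mm).
* ``SD`` — sample standard deviation (n-1 denominator, mm).
* ``min``/``max`` — extremes of the signed distances, and ``n``.

IO% counts vertices, unweighted; an area-weighted variant (per-vertex
barycentric area weights) is available behind a flag for sensitivity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMap, EmptyRegionError
from .mesh_io import TriangleMesh
from .regions import REGION_NAMES, RegionMasks, restrict

DEFAULT_TAU = 2.0

REPORT_COLUMNS = ("n", "io_pct", "mtl", "rms", "sd", "min", "max")


def congruence_percent(values: np.ndarray, tau: float = DEFAULT_TAU) -> float:
    """IO%: 100 * |{v : |v| <= tau}| / n."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    if len(values) == 0:
        raise EmptyRegionError("IO% undefined on an empty region")
    if not tau > 0:
        raise ValueError("tau must be positive")
    return 100.0 * float(np.count_nonzero(np.abs(values) <= tau)) / len(values)


def weighted_congruence_percent(
    values: np.ndarray, weights: np.ndarray, tau: float = DEFAULT_TAU
) -> float:
    """Area-weighted IO%: 100 * sum(w within tau) / sum(w)."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    weights = np.asarray(weights, dtype=np.float64).reshape(-1)
    if len(values) == 0:
        raise EmptyRegionError("IO% undefined on an empty region")
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("weights must have positive total")
    return 100.0 * float(weights[np.abs(values) <= tau].sum()) / total


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle."""
    areas = mesh.face_areas()
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], areas / 3.0)
    return out


@dataclass
class SummaryStats:
    mtl: float
    rms: float
    sd: float
    min: float
    max: float
    n: int


def summary_stats(values: np.ndarray) -> SummaryStats:
    """Signed mean (MTL), RMS, sample SD and extremes of a distance sample."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    n = len(values)
    if n == 0:
        raise EmptyRegionError("summary statistics undefined on an empty region")
    mtl = float(values.mean())
    rms = float(np.sqrt(np.mean(values**2)))
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    return SummaryStats(mtl, rms, sd, float(values.min()), float(values.max()), n)


@dataclass
class CongruenceReport:
    """One case's per-region congruence table.

    ``table`` is indexed by region name with columns
    ``n, io_pct, mtl, rms, sd, min, max``; empty regions carry n = 0 and
    NaN statistics (missing, not zero).
    """

    table: pd.DataFrame
    tau: float = DEFAULT_TAU
    area_weighted: bool = False
    notes: dict = field(default_factory=dict)

    def row(self, region: str) -> pd.Series:
        return self.table.loc[region]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "region", out.index)
        out.to_csv(path, index=False, float_format="%.10g")

    def to_long(self, patient_id: str) -> pd.DataFrame:
        """Long format (patient, region, metric, value) for cohort stacking."""
        rows = []
        for region, r in self.table.iterrows():
            for metric in REPORT_COLUMNS:
                rows.append((patient_id, region, metric, r[metric]))
        return pd.DataFrame(rows, columns=["patient", "region", "metric", "value"])


def case_report(
    dmap: DistanceMap,
    masks: RegionMasks,
    tau: float = DEFAULT_TAU,
    area_weighted: bool = False,
) -> CongruenceReport:
    """Per-region congruence table for one simulation/scan pair."""
    if dmap.mesh.n_vertices != masks.n_vertices:
        raise ValueError("region masks are not hosted on the distance map's mesh")
    weights = vertex_areas(dmap.mesh) if area_weighted else None
    rows = {}
    any_nonempty = False
    for region in REGION_NAMES:
        idx = masks[region]
        vals = restrict(dmap, idx)
        if len(vals) == 0:
            rows[region] = dict(
                n=0, io_pct=np.nan, mtl=np.nan, rms=np.nan, sd=np.nan,
                min=np.nan, max=np.nan,
            )
            continue
        any_nonempty = True
        s = summary_stats(vals)
        if area_weighted:
            keep = dmap.valid[idx]
            io = weighted_congruence_percent(vals, weights[idx[keep]], tau)
        else:
            io = congruence_percent(vals, tau)
        rows[region] = dict(
            n=s.n, io_pct=io, mtl=s.mtl, rms=s.rms, sd=s.sd, min=s.min, max=s.max
        )
    if not any_nonempty:
        raise EmptyRegionError("every region is empty")
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(REGION_NAMES)]
    table.index.name = "region"
    return CongruenceReport(table=table, tau=tau, area_weighted=area_weighted)
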