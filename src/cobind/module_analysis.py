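"""Interpretive layers on top of a fitted module-TF matrix.

Participation and "main driver" calls standardize the matrix along
factors (columns) or modules (rows) and threshold the z-score at 1.
Region-level module usage requires at least ``min_sites`` assigned sites
and a within-region z-score above 1.  Modules driven by similar factor
sets are grouped by average-linkage clustering at Pearson-correlation
distance 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .topic_model import ModuleTFMatrix

__all__ = [
    "zscore",
    "call_participation",
    "call_main_drivers",
    "module_labels",
    "region_module_matrix",
    "call_module_usage",
    "multi_module_census",
    "group_modules",
    "ModuleGroups",
    "pca_modules",
    "PCAResult",
]

MAX_LABEL_DRIVERS = 8


def _as_array(m) -> np.ndarray:
    if isinstance(m, ModuleTFMatrix):
        return np.asarray(m.counts, dtype=float)
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float)
    return np.asarray(m, dtype=float)


def zscore(matrix, axis: int = 0) -> np.ndarray:
    """Standardize each vector along ``axis`` (sample sd, ddof=1).

    axis=0 standardizes each column across rows; axis=1 each row across
    columns.  Constant vectors map to all zeros rather than NaN.
    """
    x = _as_array(matrix)
    if x.size == 0:
        raise ValueError("empty matrix")
    mean = x.mean(axis=axis, keepdims=True)
    n = x.shape[axis]
    if n < 2:
        return np.zeros_like(x)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return np.where(sd > 0, z, 0.0)


def call_participation(mtm: ModuleTFMatrix, z_cut: float = 1.0) -> np.ndarray:
    """Boolean (module, factor) matrix: factor participates in module.

    Each factor's site counts are standardized across modules (down the
    columns); a pair is called when its z-score exceeds ``z_cut``.
    """
    return zscore(mtm, axis=0) > z_cut


def call_main_drivers(mtm: ModuleTFMatrix, z_cut: float = 1.0) -> list[list[str]]:
    """Per-module driver lists: factors whose within-module (row) z-score
    exceeds ``z_cut``, ranked by descending z."""
    z = zscore(mtm, axis=1)
    factors = np.asarray(mtm.factors, dtype=object)
    drivers: list[list[str]] = []
    for k in range(z.shape[0]):
        idx = np.flatnonzero(z[k] > z_cut)
        # ties broken by factor name so ordering is column-order invariant
        order = sorted(idx, key=lambda j: (-z[k, j], factors[j]))
        drivers.append([factors[j] for j in order])
    return drivers


def module_labels(mtm: ModuleTFMatrix, z_cut: float = 1.0) -> list[str]:
    """Human-readable labels: concatenated top drivers, or ``module_k``."""
    labels = []
    for k, drv in enumerate(call_main_drivers(mtm, z_cut=z_cut)):
        mid = mtm.module_ids[k] if mtm.module_ids else k
        labels.append("+".join(drv[:MAX_LABEL_DRIVERS]) if drv else f"module_{mid}")
    return labels


def region_module_matrix(assignments: pd.DataFrame, n_modules: int | None = None) -> pd.DataFrame:
    """Summarize the assignment table into a region x module count matrix.

    Row order follows first appearance of each region in the table.
    """
    required = {"region_id", "module"}
    if not required <= set(assignments.columns):
        raise ValueError(f"assignment table must have columns {sorted(required)}")
    K = int(n_modules if n_modules is not None else assignments["module"].max() + 1)
    region_ids = assignments["region_id"].drop_duplicates().to_numpy()
    row_of = {r: i for i, r in enumerate(region_ids)}
    counts = np.zeros((len(region_ids), K), dtype=np.int64)
    rows = assignments["region_id"].map(row_of).to_numpy()
    np.add.at(counts, (rows, assignments["module"].to_numpy()), 1)
    return pd.DataFrame(counts, index=region_ids, columns=list(range(K)))


def call_module_usage(
    rmm: pd.DataFrame,
    min_sites: int = 3,
    z_cut: float = 1.0,
    usage_z_axis: str = "region",
) -> pd.DataFrame:
    """Boolean usage calls: a region uses a module when it has at least
    ``min_sites`` sites assigned to it AND the z-score of that count
    exceeds ``z_cut``.

    ``usage_z_axis='region'`` (default) standardizes each region's counts
    across the K modules; ``'module'`` standardizes each module's counts
    across regions.
    """
    counts = rmm.to_numpy(dtype=float)
    if usage_z_axis == "region":
        z = zscore(counts, axis=1)
    elif usage_z_axis == "module":
        z = zscore(counts, axis=0)
    else:
        raise ValueError("usage_z_axis must be 'region' or 'module'")
    used = (counts >= min_sites) & (z > z_cut)
    return pd.DataFrame(used, index=rmm.index, columns=rmm.columns)


def multi_module_census(usage: pd.DataFrame) -> dict[int, int]:
    """Histogram of modules-used-per-region over all regions."""
    per_region = usage.to_numpy(dtype=bool).sum(axis=1)
    values, counts = np.unique(per_region, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


@dataclass
class ModuleGroups:
    group_of: dict[int, int]  # module id -> group id (1-based)
    linkage: np.ndarray | None

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))


def _correlation_distance_condensed(rows: np.ndarray) -> np.ndarray:
    n = rows.shape[0]
    d = []
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = rows[i], rows[j]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                r = 1.0 if (si == 0 and sj == 0) else 0.0
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            d.append(1.0 - r)
    return np.asarray(d)


def group_modules(mtm: ModuleTFMatrix, cutoff: float = 0.5) -> ModuleGroups:
    """Average-linkage clustering of module rows at Pearson-correlation
    distance, cut at ``cutoff``."""
    rows = _as_array(mtm)
    ids = mtm.module_ids if isinstance(mtm, ModuleTFMatrix) else list(range(rows.shape[0]))
    if rows.shape[0] < 2:
        return ModuleGroups(group_of={ids[0]: 1} if rows.shape[0] else {}, linkage=None)
    dist = _correlation_distance_condensed(rows)
    Z = average(dist)
    flat = fcluster(Z, t=cutoff, criterion="distance")
    return ModuleGroups(group_of={mid: int(g) for mid, g in zip(ids, flat)}, linkage=Z)


@dataclass
class PCAResult:
    components: np.ndarray  # (n_comp, V) orthonormal axes in factor space
    module_scores: np.ndarray  # (K, n_comp) projections of the modules
    explained_variance_ratio: np.ndarray


def pca_modules(mtm: ModuleTFMatrix) -> PCAResult:
    """PCA of the module-TF matrix with modules as observations.

    Factor columns are mean-centered, not scaled.  All components up to
    the matrix rank are returned, so variance fractions sum to 1.
    """
    x = _as_array(mtm)
    if x.size == 0:
        raise ValueError("empty matrix")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has zero variance")
    keep = var > total * 1e-12
    return PCAResult(
        components=vt[keep],
        module_scores=(u[:, keep] * s[keep]),
        explained_variance_ratio=var[keep] / total,
    )
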