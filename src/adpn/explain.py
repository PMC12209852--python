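"""Saliency-based network derivation: class-activation maps, regional
expression scores, group-specific region selection, and composite scores.

The chain is: a trained classifier yields, per scan, a gradient-weighted
class-activation map (non-negative, upsampled to scan resolution); averaging
the map within each atlas region gives that region's *local expression score*;
regions whose scores separate two groups at Bonferroni-corrected significance
form the group-specific network; the mean local score over the network's
regions, z-scored against the training-control distribution, is the scan's
composite network expression score.

No per-map rescaling is applied anywhere in this chain: maps enter regional
averaging and z-scoring in their native gradient units, so scores are
comparable across scans of one trained model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import zoom

from .classify import TrainedClassifier
from .volumes import Atlas, Volume, roi_means

__all__ = [
    "ExplainMap",
    "RegionSelection",
    "gradcam",
    "gradcam_batch",
    "local_expression_scores",
    "ensemble_expression",
    "select_regions",
    "composite_score",
    "group_mean_map",
]


@dataclass
class ExplainMap:
    """A rectified class-activation map at scan resolution."""

    data: np.ndarray
    scan_id: str
    target_class: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("explainable map must be 3D")
        if self.data.size and self.data.min() < 0:
            raise ValueError("explainable map must be non-negative")


def _trilinear_resize(arr: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    factors = [o / s for o, s in zip(out_shape, arr.shape)]
    out = zoom(arr, factors, order=1, mode="nearest", grid_mode=True)
    if out.shape != tuple(out_shape):  # guard against rounding in non-integer ratios
        out = out[tuple(slice(0, s) for s in out_shape)]
        pad = [(0, t - s) for t, s in zip(out_shape, out.shape)]
        if any(p[1] for p in pad):
            out = np.pad(out, pad, mode="edge")
    return out


def gradcam(clf: TrainedClassifier, volume: Volume | np.ndarray, target_class: int,
            scan_id: str = "", output_shape: tuple[int, int, int] | None = None) -> ExplainMap:
    """Gradient-weighted class-activation map for one scan.

    Per-channel weights are the spatial means of the gradient of the
    ``target_class`` logit with respect to the final convolutional layer's
    activations; the map is the rectified (negative values zeroed)
    channel-weighted sum of those activations, trilinearly upsampled to the
    scan grid.  The target class is fixed by the caller (conventionally the
    disease class for every scan) so maps are comparable across groups.
    """
    if clf.model.final_conv_index is None:
        raise ValueError("model exposes no convolutional layer for class-activation mapping")
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, float)
    x = clf.prepare([volume])
    acts, grad = clf.model.final_conv_activations_and_grad(x, target_class)
    weights = grad.mean(axis=(2, 3, 4))           # (1, C)
    coarse = np.maximum(np.einsum("nc,ncdhw->ndhw", weights, acts)[0], 0.0)
    target = output_shape or data.shape
    return ExplainMap(_trilinear_resize(coarse, tuple(target)), scan_id, target_class)


def gradcam_batch(clf: TrainedClassifier, volumes: list, target_class: int,
                  scan_ids: list[str], output_shape: tuple[int, int, int],
                  batch_size: int = 16) -> list[ExplainMap]:
    """Class-activation maps for many scans, batched.

    Per-sample gradients at the final convolutional layer never mix across a
    batch (every layer's backward is sample-diagonal), so one batched
    forward/backward yields each scan's map exactly as :func:`gradcam` would.
    """
    maps: list[ExplainMap] = []
    for start in range(0, len(volumes), batch_size):
        chunk = volumes[start:start + batch_size]
        x = clf.prepare(chunk)
        acts, grad = clf.model.final_conv_activations_and_grad(x, target_class)
        weights = grad.mean(axis=(2, 3, 4))
        coarse = np.maximum(np.einsum("nc,ncdhw->ndhw", weights, acts), 0.0)
        for j in range(len(chunk)):
            maps.append(ExplainMap(_trilinear_resize(coarse[j], tuple(output_shape)),
                                   scan_ids[start + j], target_class))
    return maps


def local_expression_scores(maps: list[ExplainMap], atlas: Atlas) -> pd.DataFrame:
    """Scans x regions table of local expression scores (regional means of
    each scan's explainable map, in atlas region order)."""
    rows, ids = [], []
    for m in maps:
        if m.data.shape != atlas.shape:
            raise ValueError(f"map shape {m.data.shape} != atlas shape {atlas.shape}")
        rows.append(roi_means(m.data, atlas).to_numpy())
        ids.append(m.scan_id)
    return pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="scan_id"),
                        columns=pd.Index(atlas.region_ids, name="region_id"))


def ensemble_expression(classifiers: list[TrainedClassifier], volumes: dict,
                        scan_ids: list[str], atlas: Atlas,
                        target_class: int = 1) -> pd.DataFrame:
    """Mean expression table over an ensemble of trained classifiers.

    Each classifier contributes one scans x regions table of local expression
    scores from its own class-activation maps; the entrywise mean is returned.
    Attribution from a single compact network depends on which sufficient
    subset of informative regions its random init latched onto; the ensemble
    mean is the stable estimate used for region selection.
    """
    if not classifiers:
        raise ValueError("need at least one classifier")
    tables = []
    vols = [volumes[s] for s in scan_ids]
    for clf in classifiers:
        maps = gradcam_batch(clf, vols, target_class, list(scan_ids), atlas.shape)
        tables.append(local_expression_scores(maps, atlas))
    out = tables[0]
    for t in tables[1:]:
        out = out + t
    return out / len(tables)


@dataclass
class RegionSelection:
    """Regions separating a group pair at Bonferroni-corrected significance,
    with the direction constraint (the named group's mean must be greater)."""

    comparison: tuple[str, str]
    direction_group: str
    alpha: float
    table: pd.DataFrame = field(repr=False)   # region_id, means, t, p_raw, p_corrected, selected
    selected_region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        sel = self.table.loc[self.table["selected"], "region_id"]
        self.selected_region_ids = [int(r) for r in sel]


def select_regions(expression: pd.DataFrame, groups: pd.Series,
                   group_pair: tuple[str, str], direction: str | None = None,
                   alpha: float = 0.05, equal_var: bool = False) -> RegionSelection:
    """Per-region two-sample t-test between the two groups' expression scores
    with Bonferroni correction over the number of regions tested.

    A region is selected iff its corrected two-sided p is below ``alpha`` AND
    the ``direction`` group's mean is the greater one.  The Welch (unequal
    variance) statistic is the default; ``equal_var=True`` gives the pooled
    form.  Regions with zero variance in both groups get p = 1 with a warning.
    """
    a_name, b_name = group_pair
    direction = direction or a_name
    if direction not in group_pair:
        raise ValueError("direction must be one of the compared groups")
    groups = pd.Series(np.asarray(groups), index=expression.index)
    xa = expression.loc[groups == a_name].to_numpy(float)
    xb = expression.loc[groups == b_name].to_numpy(float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("both groups need >= 2 scans")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var, axis=0)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} region(s) with zero within-group variance; p set to 1")
        p = np.where(degenerate, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)

    n_regions = expression.shape[1]
    p_corr = np.minimum(p * n_regions, 1.0)
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    dir_ok = mean_a > mean_b if direction == a_name else mean_b > mean_a
    selected = (p_corr < alpha) & dir_ok
    table = pd.DataFrame({
        "region_id": expression.columns.to_numpy(int),
        f"mean_{a_name}": mean_a, f"mean_{b_name}": mean_b,
        "t": t, "p_raw": p, "p_corrected": p_corr, "selected": selected,
    })
    return RegionSelection(comparison=group_pair, direction_group=direction,
                           alpha=alpha, table=table)


def composite_score(expression: pd.DataFrame, selected_region_ids: list[int],
                    reference_scan_ids: list[str]) -> tuple[pd.DataFrame, dict]:
    """Composite network expression score per scan.

    raw = mean of local scores over the selected regions; z = (raw - m) / s
    with m, s the mean/SD of the raw scores of the reference scans (training
    controls).  Returns the per-scan table and the reference statistics needed
    to score future scans reproducibly.
    """
    if len(selected_region_ids) == 0:
        raise ValueError("empty region selection: no composite score defined")
    missing = set(selected_region_ids) - set(int(c) for c in expression.columns)
    if missing:
        raise ValueError(f"selected regions absent from expression table: {sorted(missing)}")
    raw = expression[list(selected_region_ids)].mean(axis=1)
    ref = raw.loc[list(reference_scan_ids)]
    if len(ref) < 2:
        raise ValueError("need >= 2 reference scans")
    m, s = float(ref.mean()), float(ref.std(ddof=1))
    if s <= 0:
        raise ValueError("reference scores have zero variance")
    out = pd.DataFrame({"raw": raw, "z": (raw - m) / s})
    out.index.name = "scan_id"
    return out, {"reference_mean": m, "reference_sd": s,
                 "region_ids": [int(r) for r in selected_region_ids]}


def group_mean_map(maps: list[ExplainMap], scan_id: str = "group_mean") -> ExplainMap:
    """Voxelwise arithmetic mean of explainable maps (for group display)."""
    if not maps:
        raise ValueError("need at least one map")
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have differing shapes: {shapes}")
    mean = np.mean([m.data for m in maps], axis=0)
    return ExplainMap(mean, scan_id, maps[0].target_class)
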