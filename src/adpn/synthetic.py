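"""Synthetic multi-group volumetric PET-like cohort with known ground truth.

The generator emulates the data regime of a metabolic-network psychosis study:
three groups sharing one parcellated anatomy —

* ``HEC``   healthy elderly controls,
* ``AD+P``  Alzheimer's disease with psychosis,
* ``AD-P``  Alzheimer's disease without psychosis,

with group-specific regional hypometabolism (disease regions reduced in both
AD groups, psychosis regions additionally reduced in AD+P), designated
inter-regional covariance differences, within-subject longitudinal
progression at 0/6/12/24 months, and clinical scores (CDRSB up, MMSE down)
coupled linearly to a per-subject latent disease burden.

Every downstream stage of the pipeline is testable against the returned
:class:`GroundTruth`.  Two sampling paths share one region-level model:
:func:`generate_cohort` paints voxel volumes (noise + smoothing included),
while :func:`simulate_roi_cohort` returns the region-level draws directly for
statistics-heavy analyses where voxels add nothing but runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import Atlas, Volume, smooth_gaussian, write_atlas, write_volume

__all__ = [
    "GROUPS",
    "RegionSpec",
    "EdgeEffect",
    "SimConfig",
    "GroundTruth",
    "build_atlas",
    "build_region_specs",
    "assign_ground_truth",
    "simulate_scan",
    "generate_cohort",
    "simulate_roi_cohort",
]

GROUP_HEC = "HEC"
GROUP_ADP = "AD+P"
GROUP_ADNP = "AD-P"
GROUPS = (GROUP_HEC, GROUP_ADP, GROUP_ADNP)

#: groups carrying the disease effect
AD_GROUPS = (GROUP_ADP, GROUP_ADNP)


@dataclass(frozen=True)
class RegionSpec:
    """Per-region generative parameters (a synthetic stand-in for an
    anatomical parcellation's region list)."""

    region_id: int
    name: str
    is_disease: bool = False
    is_psychosis: bool = False
    is_reference: bool = False
    base_mean: float = 1.0
    base_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ValueError("region_id must be a positive integer")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be > 0")


@dataclass(frozen=True)
class EdgeEffect:
    """Target between-subject correlation for one region pair in one group."""

    node_a: int
    node_b: int
    group: str
    target_r: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("edge endpoints must differ")
        if abs(self.target_r) > 0.95:
            raise ValueError("|target_r| must be <= 0.95 to keep covariance positive definite")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the cohort design the pipeline is meant to exercise:
    174 controls, 88 psychotic AD subjects and 174 non-psychotic AD subjects;
    follow-up imaging at 6/12 months for 26 and at 24 months for 29 AD+P
    subjects plus 59 controls at all four timepoints; 8 mm smoothing on a
    half-resolution common-space grid (4 mm voxels).
    """

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_regions: int = 95
    n_reference: int = 2
    n_subjects: dict = field(default_factory=lambda: {GROUP_HEC: 174, GROUP_ADP: 88, GROUP_ADNP: 174})
    timepoints: tuple[int, ...] = (0, 6, 12, 24)
    # longitudinal design: how many subjects of each group carry follow-ups
    n_longitudinal: dict = field(default_factory=lambda: {GROUP_ADP: {6: 26, 12: 26, 24: 29},
                                                          GROUP_HEC: {6: 59, 12: 59, 24: 59}})
    n_disease_regions: int = 20
    n_psychosis_regions: int = 10
    effect_size_disease: float = 1.0
    effect_size_psychosis: float = 1.5
    progression_per_month: float = -0.5 * 0.05 / 12.0  # -0.5 region-SD per year
    burden_mean: float = 1.0
    burden_sd: float = 0.3
    burden_floor: float = 0.3
    base_sd: float = 0.05
    reference_sd: float = 0.01
    cdrsb_intercept: float = 0.5
    cdrsb_slope: float = 4.5
    cdrsb_noise_sd: float = 4.5 * 0.3 * np.sqrt(3.0)  # true corr(burden, CDRSB) = 0.5
    mmse_intercept: float = 29.0
    mmse_slope: float = -6.0
    mmse_noise_sd: float = 6.0 * 0.3 * np.sqrt(3.0)   # true corr(burden, MMSE) = -0.5
    voxel_noise_sd: float = 0.01
    background_level: float = 0.6
    smoothing_fwhm_mm: float = 8.0
    altered_edges: list[EdgeEffect] | None = None  # None -> default pattern
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(n <= 0 for n in self.n_subjects.values()):
            raise ValueError("subject counts must be positive")
        tps = tuple(self.timepoints)
        if tps[0] != 0 or list(tps) != sorted(tps):
            raise ValueError("timepoints must be ascending and start at 0")
        if self.effect_size_disease < 0 or self.effect_size_psychosis < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.n_disease_regions + self.n_psychosis_regions + self.n_reference > self.n_regions:
            raise ValueError("disease + psychosis + reference regions exceed n_regions")


@dataclass
class GroundTruth:
    """What the generator embedded, for downstream validation."""

    disease_region_ids: list[int]
    psychosis_region_ids: list[int]
    altered_edges: list[EdgeEffect]
    burdens: dict  # subject_id -> latent burden

    def to_json(self, path: str | Path) -> None:
        payload = {
            "disease_region_ids": [int(i) for i in self.disease_region_ids],
            "psychosis_region_ids": [int(i) for i in self.psychosis_region_ids],
            "altered_edges": [asdict(e) for e in self.altered_edges],
            "burdens": {k: float(v) for k, v in self.burdens.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            disease_region_ids=list(d["disease_region_ids"]),
            psychosis_region_ids=list(d["psychosis_region_ids"]),
            altered_edges=[EdgeEffect(**e) for e in d["altered_edges"]],
            burdens=dict(d["burdens"]),
        )


# ---------------------------------------------------------------------------
# Atlas construction


def build_atlas(grid_shape: tuple[int, int, int], n_regions: int, seed: int,
                voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
                n_reference: int = 2) -> Atlas:
    """Parcellate an ellipsoidal mask into contiguous regions by seeded
    Voronoi growth (nearest-seed assignment under the Euclidean metric, two
    Lloyd relaxation sweeps to even out cell sizes).

    Voronoi cells of point seeds are convex, so their digitizations restricted
    to the convex ellipsoid mask stay spatially contiguous.  The ``n_reference``
    regions whose centroids sit lowest along the third axis are flagged as the
    intensity-normalization reference (the stand-in for cerebellum).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(int(s) for s in grid_shape)
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) * 0.45
    idx = np.indices(shape)
    mask = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3)) <= 1.0
    n_vox = int(mask.sum())
    if n_vox < n_regions * 27:
        raise ValueError(
            f"grid {shape} too small: {n_vox} mask voxels < {n_regions * 27} "
            f"needed for {n_regions} regions of >= 27 voxels")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
    coords = np.argwhere(mask)
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]

    def assign(seed_pts: np.ndarray) -> np.ndarray:
        marker = np.zeros(shape, dtype=np.int32)
        marker[tuple(seed_pts.T)] = np.arange(1, n_regions + 1)
        _, (ix, iy, iz) = ndimage.distance_transform_edt(marker == 0, return_indices=True)
        lab = marker[ix, iy, iz]
        lab[~mask] = 0
        return lab

    labels = assign(seeds)
    for _ in range(2):  # Lloyd relaxation for more even cells
        cents = np.array(ndimage.center_of_mass(mask, labels, index=np.arange(1, n_regions + 1)))
        cents = np.rint(cents).astype(int)
        cents = np.clip(cents, 0, np.array(shape) - 1)
        # snap any centroid that fell outside the mask back to the nearest mask voxel
        for k in range(n_regions):
            if not mask[tuple(cents[k])]:
                d = np.abs(coords - cents[k]).sum(axis=1)
                cents[k] = coords[np.argmin(d)]
        # deduplicate collisions deterministically
        seen: dict[tuple[int, int, int], int] = {}
        for k in range(n_regions):
            key = tuple(int(c) for c in cents[k])
            while key in seen:
                alt = coords[rng.integers(len(coords))]
                key = tuple(int(c) for c in alt)
            seen[key] = k
            cents[k] = key
        labels = assign(cents)

    sizes = np.bincount(labels.ravel(), minlength=n_regions + 1)[1:]
    if sizes.min() == 0:
        raise RuntimeError("empty region after relaxation (should not happen)")

    order = np.array(ndimage.center_of_mass(mask, labels, index=np.arange(1, n_regions + 1)))
    lowest = np.argsort(order[:, 2])[:n_reference]  # inferior regions -> reference
    is_ref = np.zeros(n_regions, dtype=bool)
    is_ref[lowest] = True
    regions = pd.DataFrame({
        "region_id": np.arange(1, n_regions + 1),
        "name": [f"Reference_{i+1:02d}" if is_ref[i] else f"Region_{i+1:03d}" for i in range(n_regions)],
        "abbreviation": [f"REF{i+1}" if is_ref[i] else f"R{i+1}" for i in range(n_regions)],
        "is_reference": is_ref,
    })
    return Atlas(labels=labels, regions=regions,
                 reference_ids=frozenset(int(i + 1) for i in lowest),
                 voxel_size_mm=tuple(float(v) for v in voxel_size_mm))


def build_region_specs(atlas: Atlas, config: SimConfig, ground_truth: "GroundTruth") -> list[RegionSpec]:
    """Per-region generative parameters: base means vary mildly across regions
    (seeded), reference regions get a small variance (the rationale for using
    them as the normalization denominator)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
    disease = set(ground_truth.disease_region_ids)
    psych = set(ground_truth.psychosis_region_ids)
    specs = []
    for rid, name, is_ref in zip(atlas.regions["region_id"], atlas.regions["name"],
                                 atlas.regions["is_reference"]):
        rid = int(rid)
        specs.append(RegionSpec(
            region_id=rid, name=str(name),
            is_disease=rid in disease, is_psychosis=rid in psych,
            is_reference=bool(is_ref),
            base_mean=float(1.0 + 0.1 * rng.uniform(-1, 1)),
            base_sd=config.reference_sd if is_ref else config.base_sd,
        ))
    return specs


def _default_edges(disease_ids: list[int], psychosis_ids: list[int]) -> list[EdgeEffect]:
    """Default covariance ground truth: four node-disjoint edges among
    psychosis regions with higher correlation in AD+P than AD-P (enhanced,
    delta 0.4), and four among disease regions present in controls but absent
    in both AD groups (lost)."""
    edges: list[EdgeEffect] = []
    p = psychosis_ids
    for k in range(min(4, len(p) // 2)):
        a, b = p[2 * k], p[2 * k + 1]
        edges += [EdgeEffect(a, b, GROUP_HEC, 0.3),
                  EdgeEffect(a, b, GROUP_ADNP, 0.3),
                  EdgeEffect(a, b, GROUP_ADP, 0.7)]
    d = disease_ids
    for k in range(min(4, len(d) // 2)):
        a, b = d[2 * k], d[2 * k + 1]
        edges += [EdgeEffect(a, b, GROUP_HEC, 0.6),
                  EdgeEffect(a, b, GROUP_ADNP, 0.0),
                  EdgeEffect(a, b, GROUP_ADP, 0.0)]
    return edges


def assign_ground_truth(atlas: Atlas, config: SimConfig) -> GroundTruth:
    """Draw the affected-region sets and the altered-edge list (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E0]))
    candidates = [int(r) for r in atlas.region_ids if int(r) not in atlas.reference_ids]
    picked = rng.choice(candidates, size=config.n_disease_regions + config.n_psychosis_regions,
                        replace=False)
    disease = sorted(int(i) for i in picked[: config.n_disease_regions])
    psych = sorted(int(i) for i in picked[config.n_disease_regions:])
    edges = config.altered_edges if config.altered_edges is not None else _default_edges(disease, psych)
    return GroundTruth(disease_region_ids=disease, psychosis_region_ids=psych,
                       altered_edges=list(edges), burdens={})


# ---------------------------------------------------------------------------
# Region-level generative model


def _effect_sd_units(spec: RegionSpec, config: SimConfig, group: str) -> float:
    """Total standardized hypometabolic effect for a region in a group."""
    if group == GROUP_HEC:
        return 0.0
    e = 0.0
    if spec.is_disease:
        e += config.effect_size_disease
    if spec.is_psychosis and group == GROUP_ADP:
        e += config.effect_size_psychosis
    return e


def _edge_loadings(specs: list[RegionSpec], config: SimConfig,
                   edges: list[EdgeEffect], group: str) -> list[tuple[int, int, float, float]]:
    """Latent-factor loadings realizing each edge's target correlation.

    With x_i = mu_i - e_i*sd_i*b + sd_i*(lam_i*f_e + resid), b ~ N(mu_b, s_b),
    the between-subject correlation of a node-disjoint edge (i, j) is
    (lam_i*lam_j + g_i*g_j) / sqrt((1+g_i^2)(1+g_j^2)) with g = e*s_b.  The
    loadings are solved so the *total* correlation equals target_r, i.e. the
    shared-burden contribution in the AD groups is compensated analytically.
    """
    by_id = {s.region_id: s for s in specs}
    out = []
    for e in edges:
        if e.group != group:
            continue
        gi = _effect_sd_units(by_id[e.node_a], config, group) * config.burden_sd
        gj = _effect_sd_units(by_id[e.node_b], config, group) * config.burden_sd
        prod = e.target_r * np.sqrt((1 + gi ** 2) * (1 + gj ** 2)) - gi * gj
        lam = np.sqrt(abs(prod))
        if lam > 1.0:
            raise ValueError(f"edge ({e.node_a},{e.node_b}) target {e.target_r} infeasible in {group}")
        out.append((e.node_a, e.node_b, lam, float(np.sign(prod)) if prod != 0 else 0.0))
    return out


def _check_node_budget(loadings, specs) -> None:
    budget: dict[int, float] = {}
    for a, b, lam, _ in loadings:
        budget[a] = budget.get(a, 0.0) + lam ** 2
        budget[b] = budget.get(b, 0.0) + lam ** 2
    over = {k: v for k, v in budget.items() if v > 1.0}
    if over:
        raise ValueError(f"edge loadings exceed unit variance budget at nodes {over}")


def draw_burden(config: SimConfig, group: str, rng: np.random.Generator) -> float:
    """Per-subject latent disease burden: 0 for controls, truncated normal for
    AD subjects (a diagnosed case carries at least ``burden_floor`` pathology)."""
    if group == GROUP_HEC:
        return 0.0
    return float(max(config.burden_floor, rng.normal(config.burden_mean, config.burden_sd)))


def sample_region_values(specs: list[RegionSpec], config: SimConfig, ground_truth: GroundTruth,
                         group: str, burden: float, months: float,
                         rng: np.random.Generator) -> np.ndarray:
    """One scan's region-mean vector (ordered as ``specs``)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    loadings = _edge_loadings(specs, config, ground_truth.altered_edges, group)
    _check_node_budget(loadings, specs)
    lam2 = {s.region_id: 0.0 for s in specs}
    shared = {s.region_id: 0.0 for s in specs}
    for a, b, lam, sign in loadings:
        f = rng.normal()
        shared[a] += lam * f
        shared[b] += (sign if sign != 0 else 1.0) * lam * f
        lam2[a] += lam ** 2
        lam2[b] += lam ** 2

    vals = np.empty(len(specs))
    affected_progression = set(ground_truth.disease_region_ids)
    if group == GROUP_ADP:
        affected_progression |= set(ground_truth.psychosis_region_ids)
    for k, s in enumerate(specs):
        e = _effect_sd_units(s, config, group)
        resid = np.sqrt(max(0.0, 1.0 - lam2[s.region_id]))
        v = s.base_mean - e * s.base_sd * burden \
            + s.base_sd * (shared[s.region_id] + resid * rng.normal())
        if group in AD_GROUPS and s.region_id in affected_progression:
            v += config.progression_per_month * months
        vals[k] = v
    return vals


def _clinical_scores(config: SimConfig, group: str, burden: float,
                     rng: np.random.Generator) -> tuple[float, float]:
    if group == GROUP_HEC:
        cdrsb = abs(rng.normal(0.0, 0.12))
        mmse = float(np.clip(rng.normal(28.9, 1.3), 0, 30))
    else:
        cdrsb = float(np.clip(config.cdrsb_intercept + config.cdrsb_slope * burden
                              + rng.normal(0.0, config.cdrsb_noise_sd), 0, 18))
        mmse = float(np.clip(config.mmse_intercept + config.mmse_slope * burden
                             + rng.normal(0.0, config.mmse_noise_sd), 0, 30))
    return cdrsb, mmse


# ---------------------------------------------------------------------------
# Scan and cohort synthesis


def simulate_scan(atlas: Atlas, specs: list[RegionSpec], ground_truth: GroundTruth,
                  config: SimConfig, group: str, months: float, burden: float,
                  rng: np.random.Generator) -> Volume:
    """Paint one scan: region means -> voxels, plus independent voxel noise,
    then Gaussian smoothing at ``smoothing_fwhm_mm``.  Smoothing happens after
    effect injection, so regional effects bleed across parcel boundaries the
    way preprocessed PET does."""
    vals = sample_region_values(specs, config, ground_truth, group, burden, months, rng)
    lut = np.full(int(atlas.region_ids.max()) + 1, config.background_level)
    lut[atlas.region_ids] = vals
    data = lut[atlas.labels]
    data = data + rng.normal(0.0, config.voxel_noise_sd, size=data.shape)
    vol = Volume(np.clip(data, 1e-3, None), atlas.voxel_size_mm, space_tag="synthetic-common")
    return smooth_gaussian(vol, config.smoothing_fwhm_mm)


def _scan_plan(config: SimConfig) -> list[tuple[str, int, int]]:
    """(group, subject_index, months) for every scan in the cohort."""
    plan = []
    for group in GROUPS:
        n = config.n_subjects.get(group, 0)
        longit = config.n_longitudinal.get(group, {})
        for s in range(n):
            plan.append((group, s, 0))
            for t in config.timepoints[1:]:
                if s < longit.get(t, 0):
                    plan.append((group, s, int(t)))
    return plan


def _subject_rng(config: SimConfig, group: str, subj: int) -> np.random.Generator:
    gi = GROUPS.index(group)
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + gi, subj]))


def _scan_rng(config: SimConfig, group: str, subj: int, months: int) -> np.random.Generator:
    gi = GROUPS.index(group)
    return np.random.default_rng(np.random.SeedSequence([config.seed, 2000 + gi, subj, months]))


def _build_manifest(config: SimConfig, ground_truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for group, s, months in _scan_plan(config):
        sid = f"{group}_{s:04d}"
        rows.append({"subject_id": sid, "group": group, "months": months,
                     "scan_id": f"{sid}_m{months:02d}"})
    manifest = pd.DataFrame(rows)
    # burden and clinical scores are per subject (baseline assessment),
    # replicated onto every scan row; per-subject substreams keep them stable
    # under changes of cohort size
    clin = {}
    for sid in manifest["subject_id"].unique():
        group, s = sid.rsplit("_", 1)
        srng = _subject_rng(config, group, int(s))
        burden = draw_burden(config, group, srng)
        cdrsb, mmse = _clinical_scores(config, group, burden, srng)
        clin[sid] = (burden, cdrsb, mmse)
        ground_truth.burdens[sid] = burden
    manifest["cdrsb"] = [clin[s][1] for s in manifest["subject_id"]]
    manifest["mmse"] = [clin[s][2] for s in manifest["subject_id"]]
    return manifest


def simulate_roi_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth, Atlas, list[RegionSpec]]:
    """Region-level fast path: the same generative model as the voxel path but
    without painting/smoothing voxels.

    Returns ``(roi_values, manifest, ground_truth, atlas, specs)`` where
    ``roi_values`` is scans x regions indexed by scan_id.
    """
    atlas = build_atlas(config.grid_shape, config.n_regions, config.seed,
                        config.voxel_size_mm, config.n_reference)
    gt = assign_ground_truth(atlas, config)
    specs = build_region_specs(atlas, config, gt)
    manifest = _build_manifest(config, gt)
    rows = np.empty((len(manifest), len(specs)))
    for i, rec in enumerate(manifest.itertuples()):
        group, s = rec.subject_id.rsplit("_", 1)
        rng = _scan_rng(config, group, int(s), int(rec.months))
        rows[i] = sample_region_values(specs, config, gt, group,
                                       gt.burdens[rec.subject_id], rec.months, rng)
    roi = pd.DataFrame(rows, index=pd.Index(manifest["scan_id"], name="scan_id"),
                       columns=pd.Index(atlas.region_ids, name="region_id"))
    return roi, manifest, gt, atlas, specs


def generate_cohort(config: SimConfig, out_dir: str | Path | None = None,
                    ) -> tuple[pd.DataFrame, GroundTruth, Atlas, dict]:
    """Generate the full voxel cohort.

    If ``out_dir`` is given, writes ``scans/<scan_id>.nii.gz``, the atlas
    (``atlas.nii.gz`` + ``regions.csv``), ``manifest.csv`` (with a ``path``
    column) and ``ground_truth.json`` there, and returns an empty volume dict;
    otherwise returns volumes in memory keyed by scan_id.
    """
    atlas = build_atlas(config.grid_shape, config.n_regions, config.seed,
                        config.voxel_size_mm, config.n_reference)
    gt = assign_ground_truth(atlas, config)
    specs = build_region_specs(atlas, config, gt)
    manifest = _build_manifest(config, gt)

    volumes: dict[str, Volume] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            (out_dir / "scans").mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths = []
    for rec in manifest.itertuples():
        group, s = rec.subject_id.rsplit("_", 1)
        rng = _scan_rng(config, group, int(s), int(rec.months))
        vol = simulate_scan(atlas, specs, gt, config, group, rec.months,
                            gt.burdens[rec.subject_id], rng)
        if out_dir is not None:
            p = out_dir / "scans" / f"{rec.scan_id}.nii.gz"
            write_volume(vol, p)
            paths.append(f"scans/{rec.scan_id}.nii.gz")  # relative to out_dir
        else:
            volumes[rec.scan_id] = vol
            paths.append("")
    manifest = manifest.assign(path=paths)

    if out_dir is not None:
        write_atlas(atlas, out_dir / "atlas.nii.gz", out_dir / "regions.csv")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        gt.to_json(out_dir / "ground_truth.json")
    return manifest, gt, atlas, volumes
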