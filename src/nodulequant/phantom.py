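"""Synthetic CT phantoms of subsolid lung nodules, with known ground truth.

Clinical CT studies of early lung adenocarcinoma are not publicly deposited,
so every downstream stage here (segmentation, histogram quantification,
threshold derivation, cohort statistics) is exercised on digital phantoms
whose composition is known exactly.

A phantom nodule is an ellipsoid (sphere by default) embedded in aerated lung
background. Its voxels are partitioned into a ground-glass (GGO) shell and a
single central solid focus — the geometry of a lepidic-predominant tumor with
a central area of invasion. Per-voxel HU are drawn i.i.d. from Gaussian noise
models per component (defaults match the whole-class appearance statistics:
pGGO -553.38 +/- 101.1 HU, solid -104.24 +/- 93.05 HU), clamped to
[-1024, 100] HU, and finally smoothed with an isotropic Gaussian to emulate
the partial-volume effect. Optional air pockets (vacuole < 5 mm, cyst/cavity
>= 5 mm) are set to -1000 HU; an optional bright vessel cylinder touching the
nodule exercises the segmentation-editing contract.

Cohort-level simulation draws per-tumor covariate records (size, contour,
necrosis, vacuole/cyst, location, GGOc/Sc proportions, SUV_max, lepidic
percentage) group-wise for invasive vs non-invasive adenocarcinoma, with
defaults reproducing the published cohort margins (283 invasive / 92
non-invasive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ctnumber import CTVolume, NoduleMask, HU_MIN

__all__ = [
    "NoduleSpec",
    "GroundTruth",
    "CohortConfig",
    "TumorRecord",
    "simulate_nodule",
    "classify_appearance",
    "assign_histology",
    "simulate_cohort",
    "simulate_appearance_cohort",
    "cohort_to_frame",
    "APPEARANCE_HU",
    "COHORT_MARGIN_DEFAULTS",
]

#: Whole-class mean +/- SD of tumor mean CT value per visual appearance class
#: (HU). Used as generator defaults and by :func:`simulate_appearance_cohort`.
APPEARANCE_HU: dict[str, tuple[float, float]] = {
    "pGGO": (-553.38, 101.1),
    "PSN": (-364.87, 129.61),
    "SN": (-104.24, 93.05),
}

_HU_CLAMP = (-1024.0, 100.0)  # soft-tissue phantoms never exceed +100 HU


@dataclass(frozen=True)
class NoduleSpec:
    """Parameters of one synthetic nodule.

    ``lepidic_fraction`` is the fraction of nodule volume assigned to the GGO
    component; the remainder forms a single central solid focus.
    ``invasive_focus_mm`` is the largest invasive-focus diameter used for the
    histologic label; if None it defaults to the physical diameter of the
    solid focus. The study population is cT1 (diameter <= 3 cm).
    """

    diameter_cm: float = 1.5
    lepidic_fraction: float = 0.5
    invasive_focus_mm: float | None = None
    n_vacuoles: int = 0
    n_cysts: int = 0
    vessel: bool = False
    voxel_mm: float = 1.0
    hu_ggo_mean: float = APPEARANCE_HU["pGGO"][0]
    hu_ggo_sd: float = APPEARANCE_HU["pGGO"][1]
    hu_solid_mean: float = APPEARANCE_HU["SN"][0]
    hu_solid_sd: float = APPEARANCE_HU["SN"][1]
    hu_lung_mean: float = -870.0
    hu_lung_sd: float = 50.0
    blur_sigma_mm: float = 0.5
    margin_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lepidic_fraction <= 1.0:
            raise ValueError(
                f"lepidic_fraction must be in [0, 1], got {self.lepidic_fraction}"
            )
        if not 0.0 < self.diameter_cm <= 3.0:
            raise ValueError(
                f"diameter_cm must be in (0, 3] (cT1 nodules), got {self.diameter_cm}"
            )
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        for name in ("hu_ggo_sd", "hu_solid_sd", "hu_lung_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.invasive_focus_mm is not None and self.invasive_focus_mm < 0:
            raise ValueError("invasive_focus_mm must be >= 0")
        if self.n_vacuoles < 0 or self.n_cysts < 0:
            raise ValueError("air pocket counts must be >= 0")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact composition of a generated nodule.

    ``solid_voxel_fraction`` counts tissue voxels drawn from the solid HU
    distribution over all tissue (GGO + solid) voxels, before partial-volume
    blur; ``lepidic_pct`` is its complement on the pathologist's 5% recording
    grid, so ``lepidic_pct/100 + solid_voxel_fraction = 1`` to within the grid
    resolution (2.5 points).
    """

    lepidic_pct: float
    solid_voxel_fraction: float
    appearance: str
    invasive: bool
    histologic_group: str
    n_ggo_voxels: int = 0
    n_solid_voxels: int = 0
    n_air_voxels: int = 0


def classify_appearance(
    solid_voxel_fraction: float,
    pggo_max: float = 0.05,
    sn_min: float = 0.95,
) -> str:
    """Map a solid-volume fraction to the visual appearance class.

    Pure classes absorb trace components below visual detectability: pGGO for
    fractions below ``pggo_max``, SN above ``sn_min``, part-solid (PSN)
    otherwise. The band edges are a convention, not a published mapping, and
    are configurable.
    """
    if not 0.0 <= solid_voxel_fraction <= 1.0:
        raise ValueError(
            f"solid fraction must be in [0, 1], got {solid_voxel_fraction}"
        )
    if solid_voxel_fraction < pggo_max:
        return "pGGO"
    if solid_voxel_fraction > sn_min:
        return "SN"
    return "PSN"


def assign_histology(lepidic_pct: float, invasive_focus_mm: float) -> tuple[str, bool]:
    """Histologic group from the invasive-focus size.

    AIS has no invasive focus; MIA has a focus of at most 5 mm; anything
    larger is invasive adenocarcinoma. AIS and MIA together form the
    non-invasive group. Returns ``(group, invasive_flag)``.
    """
    if not 0.0 <= lepidic_pct <= 100.0:
        raise ValueError(f"lepidic_pct must be in [0, 100], got {lepidic_pct}")
    if invasive_focus_mm < 0:
        raise ValueError(f"invasive focus size must be >= 0, got {invasive_focus_mm}")
    if invasive_focus_mm == 0:
        return "AIS", False
    if invasive_focus_mm <= 5.0:
        return "MIA", False
    return "invasive", True


def _round_to_grid(value: float, grid: float = 5.0) -> float:
    return float(np.round(value / grid) * grid)


def simulate_nodule(spec: NoduleSpec) -> tuple[CTVolume, NoduleMask, GroundTruth]:
    """Generate one phantom volume, its true nodule mask, and ground truth.

    The mask is the pre-blur nodule support (including carved air pockets);
    the solid focus is placed centrally by ranking nodule voxels by distance
    from the center and labelling the nearest ``round(n * (1 - lepidic))``
    voxels solid, which pins the composition to within one voxel. Identical
    specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    r_mm = spec.diameter_cm * 10.0 / 2.0
    half_extent = r_mm + spec.margin_mm
    n = int(np.ceil(2 * half_extent / spec.voxel_mm))
    if n < 3:
        raise ValueError("volume extent too small for the requested nodule")
    shape = (n, n, n)
    center = (n - 1) / 2.0

    coords = np.arange(n) - center
    dx, dy, dz = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)
    dist_mm = np.sqrt(dx**2 + dy**2 + dz**2) * spec.voxel_mm
    nodule = dist_mm <= r_mm
    n_total = int(nodule.sum())
    if n_total == 0:
        raise ValueError("nodule smaller than one voxel at this spacing")

    # component labels: 0 lung, 1 GGO, 2 solid, 3 air pocket
    labels = np.zeros(shape, dtype=np.uint8)
    labels[nodule] = 1
    n_solid = int(np.round(n_total * (1.0 - spec.lepidic_fraction)))
    if n_solid > 0:
        flat_idx = np.flatnonzero(nodule.ravel())
        order = np.argsort(dist_mm.ravel()[flat_idx], kind="stable")
        solid_idx = flat_idx[order[:n_solid]]
        labels.ravel()[solid_idx] = 2

    solid_radius_mm = (n_solid / n_total) ** (1.0 / 3.0) * r_mm

    _carve_air_pockets(labels, rng, nodule, dist_mm, r_mm, spec)

    n_ggo = int((labels == 1).sum())
    n_sol = int((labels == 2).sum())
    n_air = int((labels == 3).sum())
    tissue = n_ggo + n_sol
    solid_fraction = n_sol / tissue if tissue else 0.0

    hu = np.empty(shape, dtype=np.float64)
    hu[labels == 0] = rng.normal(spec.hu_lung_mean, spec.hu_lung_sd, int((labels == 0).sum()))
    hu[labels == 1] = rng.normal(spec.hu_ggo_mean, spec.hu_ggo_sd, n_ggo)
    hu[labels == 2] = rng.normal(spec.hu_solid_mean, spec.hu_solid_sd, n_sol)
    np.clip(hu, *_HU_CLAMP, out=hu)
    hu[labels == 3] = -1000.0

    if spec.vessel:
        _add_vessel(hu, rng, dx, dy, r_mm, spec.voxel_mm)

    if spec.blur_sigma_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma_mm / spec.voxel_mm)

    voxels = np.clip(np.rint(hu), HU_MIN, 3071).astype(np.int16)
    volume = CTVolume(voxels=voxels, spacing_mm=(spec.voxel_mm,) * 3)
    mask = NoduleMask(support=nodule, connectivity=3)

    lepidic_pct = _round_to_grid((1.0 - solid_fraction) * 100.0)
    focus_mm = (
        spec.invasive_focus_mm
        if spec.invasive_focus_mm is not None
        else 2.0 * solid_radius_mm
    )
    group, invasive = assign_histology(lepidic_pct, focus_mm)
    truth = GroundTruth(
        lepidic_pct=lepidic_pct,
        solid_voxel_fraction=solid_fraction,
        appearance=classify_appearance(solid_fraction),
        invasive=invasive,
        histologic_group=group,
        n_ggo_voxels=n_ggo,
        n_solid_voxels=n_sol,
        n_air_voxels=n_air,
    )
    return volume, mask, truth


def _carve_air_pockets(
    labels: np.ndarray,
    rng: np.random.Generator,
    nodule: np.ndarray,
    dist_mm: np.ndarray,
    r_mm: float,
    spec: NoduleSpec,
) -> None:
    """Set spherical air pockets (label 3) inside the nodule."""
    pockets: list[float] = []
    for _ in range(spec.n_vacuoles):
        pockets.append(float(rng.uniform(1.0, 4.9)))  # vacuole sign: < 5 mm
    for _ in range(spec.n_cysts):
        hi = max(5.0, min(9.0, 1.8 * r_mm))
        pockets.append(float(rng.uniform(5.0, hi)))  # cyst/cavity: >= 5 mm
    if not pockets:
        return
    interior = nodule & (dist_mm <= max(r_mm * 0.6, r_mm - max(pockets) / 2.0))
    centers = np.argwhere(interior if interior.any() else nodule)
    shape = labels.shape
    for diam in pockets:
        c = centers[rng.integers(len(centers))]
        rad_vox = diam / 2.0 / spec.voxel_mm
        lo = np.maximum(np.floor(c - rad_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c + rad_vox).astype(int) + 1, shape)
        sub = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = sum((g - ci) ** 2 for g, ci in zip(sub, c))
        region = (d2 <= rad_vox**2) & nodule[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][region] = 3


def _add_vessel(
    hu: np.ndarray,
    rng: np.random.Generator,
    dx: np.ndarray,
    dy: np.ndarray,
    r_mm: float,
    voxel_mm: float,
) -> None:
    """Bright cylinder (mean +50 HU) along z, tangent to the nodule surface."""
    vessel_radius_mm = 1.5
    offset_vox = (r_mm + vessel_radius_mm) / voxel_mm
    in_cyl = (dx - offset_vox) ** 2 + dy**2 <= (vessel_radius_mm / voxel_mm) ** 2
    in_cyl = np.broadcast_to(in_cyl, hu.shape)
    hu[in_cyl] = rng.normal(50.0, 20.0, int(in_cyl.sum()))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorRecord:
    """One tumor's covariates for the invasiveness analysis."""

    tumor_id: int
    group: str  # "invasive" | "non-invasive"
    invasive: int
    size_cm: float
    location: str  # "centre" | "periphery"
    contour: str  # "smooth" | "lobular" | "spiculated"
    necrosis: int
    vacuole_cyst: str  # "none" | "vacuole" | "cyst"
    mean_hu: float
    ggoc_pct: float
    sc_pct: float
    suv_max: float | None
    lepidic_pct: float
    appearance: str


#: Published cohort margins: per-group continuous (mean, sd, lo, hi) and
#: categorical probabilities, invasive n=283 vs non-invasive n=92.
COHORT_MARGIN_DEFAULTS: dict[str, dict] = {
    "invasive": {
        "n": 283,
        "continuous": {
            "size_cm": (2.04, 0.55, 0.1, 3.0),
            "ggoc_pct": (14.0, 17.0, 0.0, 100.0),
            "sc_pct": (56.0, 30.0, 0.0, 100.0),
            "suv_max": (3.75, 2.85, 0.0, 40.0),
        },
        "categorical": {
            "location": {"centre": 50 / 283, "periphery": 233 / 283},
            "contour": {"smooth": 36 / 283, "lobular": 143 / 283, "spiculated": 104 / 283},
            "necrosis": {1: 33 / 283, 0: 250 / 283},
            "vacuole_cyst": {"none": 172 / 283, "vacuole": 89 / 283, "cyst": 22 / 283},
        },
    },
    "non-invasive": {
        "n": 92,
        "continuous": {
            "size_cm": (1.55, 0.51, 0.1, 3.0),
            "ggoc_pct": (44.0, 29.0, 0.0, 100.0),
            "sc_pct": (14.0, 21.0, 0.0, 100.0),
            "suv_max": (1.54, 2.41, 0.0, 40.0),
        },
        "categorical": {
            "location": {"centre": 14 / 92, "periphery": 78 / 92},
            "contour": {"smooth": 40 / 92, "lobular": 42 / 92, "spiculated": 10 / 92},
            "necrosis": {1: 1 / 92, 0: 91 / 92},
            "vacuole_cyst": {"none": 77 / 92, "vacuole": 12 / 92, "cyst": 3 / 92},
        },
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Group-wise generative model for a tumor cohort.

    ``groups`` maps group name to ``{"n": int, "continuous": {var: (mean, sd,
    lo, hi)}, "categorical": {var: {level: prob}}}``. Continuous covariates are
    drawn from truncated normals on the stated support; categoricals from the
    stated probabilities. Defaults reproduce the published cohort margins.
    ``suv_coverage`` is the fraction of tumors with a PET/CT study (others get
    a missing SUV_max).
    """

    groups: Mapping[str, dict] = field(default_factory=lambda: COHORT_MARGIN_DEFAULTS)
    suv_coverage: float = 147 / 375
    lepidic_noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, g in self.groups.items():
            if g["n"] < 2:
                raise ValueError(f"group {name!r} needs n >= 2, got {g['n']}")
            for var, (mean, sd, lo, hi) in g["continuous"].items():
                if sd < 0:
                    raise ValueError(f"{name}/{var}: sd must be >= 0")
                if not lo < hi:
                    raise ValueError(f"{name}/{var}: need lo < hi")
            for var, probs in g["categorical"].items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{name}/{var}: category probabilities sum to {total}, not 1"
                    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: CohortConfig | None = None) -> list[TumorRecord]:
    """Draw a cohort of tumor records group-wise from the configured model.

    The tumor mean CT value is drawn from the appearance-class HU model after
    the appearance is derived from the drawn Sc proportion; the ground-truth
    lepidic percentage is generated as the (noisy, 5%-grid) complement of the
    Sc proportion, which couples it negatively to Sc and positively to GGOc as
    observed histopathologically. Same config and seed give identical records.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    records: list[TumorRecord] = []
    tumor_id = 0
    for group_name, g in config.groups.items():
        n = int(g["n"])
        cont = {
            var: _truncated_normal(rng, *params, size=n)
            for var, params in g["continuous"].items()
        }
        cat = {}
        for var, probs in g["categorical"].items():
            # exact composition: level counts by largest remainder, assignment
            # by seeded permutation — reproduces published contingency margins
            levels = list(probs)
            p = np.array([probs[k] for k in levels], dtype=float)
            base = np.floor(p * n).astype(int)
            short = n - base.sum()
            order = np.argsort(-(p * n - base), kind="stable")
            base[order[:short]] += 1
            pool = np.repeat(np.arange(len(levels)), base)
            cat[var] = [levels[i] for i in rng.permutation(pool)]
        has_suv = rng.random(n) < config.suv_coverage
        lep_noise = rng.normal(0.0, config.lepidic_noise_sd, n)
        for i in range(n):
            sc = float(cont["sc_pct"][i])
            ggoc = float(cont["ggoc_pct"][i])
            appearance = classify_appearance(min(sc / 100.0, 1.0))
            mu, sd = APPEARANCE_HU[appearance]
            mean_hu = float(np.clip(rng.normal(mu, sd), -1000.0, 100.0))
            # lepidic tracks the GGO component: average of GGOc and (100 - Sc)
            # plus pathologist noise, recorded on the 5% grid
            lep_base = (ggoc + (100.0 - sc)) / 2.0
            lepidic = _round_to_grid(float(np.clip(lep_base + lep_noise[i], 0.0, 100.0)))
            records.append(
                TumorRecord(
                    tumor_id=tumor_id,
                    group=group_name,
                    invasive=int(group_name == "invasive"),
                    size_cm=float(cont["size_cm"][i]),
                    location=cat["location"][i],
                    contour=cat["contour"][i],
                    necrosis=int(cat["necrosis"][i]),
                    vacuole_cyst=cat["vacuole_cyst"][i],
                    mean_hu=mean_hu,
                    ggoc_pct=float(cont["ggoc_pct"][i]),
                    sc_pct=sc,
                    suv_max=float(cont["suv_max"][i]) if has_suv[i] else None,
                    lepidic_pct=lepidic,
                    appearance=appearance,
                )
            )
            tumor_id += 1
    return records


def cohort_to_frame(records: Sequence[TumorRecord]) -> pd.DataFrame:
    """Cohort records as a DataFrame (the CSV schema used throughout)."""
    return pd.DataFrame([r.__dict__ for r in records])


def simulate_appearance_cohort(
    n_pggo: int = 58,
    n_psn: int = 159,
    n_sn: int = 158,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tumor mean CT values labeled by visual appearance class.

    This is the input to component-threshold derivation: each tumor
    contributes its mean HU drawn from the whole-class appearance model.
    Default class sizes match the published cohort (58 / 159 / 158).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n in (("pGGO", n_pggo), ("PSN", n_psn), ("SN", n_sn)):
        mu, sd = APPEARANCE_HU[cls]
        hu = np.clip(rng.normal(mu, sd, n), -1000.0, 100.0)
        rows.extend({"appearance": cls, "mean_hu": float(v)} for v in hu)
    return pd.DataFrame(rows)
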