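"""Synthetic head-and-neck phantoms and a parametric ground-truth dose engine.

Real treatment-planning cohorts are private, so every downstream stage is
exercised on generated cases: an elliptical body containing a PTV with an
interior boost volume at two prescription levels (60.06 / 69.96 Gy in 33
fractions), 21 organs at risk placed at varying distances from the target,
and a dose field that plateaus inside the targets and decays monotonically
with distance-to-PTV outside them, with organ-specific sparing and
near-zero dose outside the treated field.

The dose engine is deliberately simple: outside the targets the dose is an
exponential function of the distance-to-PTV map multiplied by an
organ-sparing factor.  Distance is therefore *sufficient* information for
dose by construction, which turns the comparison between a predictor that
sees the distance channel and one that does not into a controlled
experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import DoseMap, ROISet, VolumeGrid, load_roiset, load_volume, save_roiset, save_volume

__all__ = [
    "OARDescriptor",
    "PhantomSpec",
    "DoseEngineParams",
    "PhantomCase",
    "CohortRanges",
    "generate_phantom",
    "simulate_dose",
    "make_cohort",
    "save_case",
    "load_case",
    "DEFAULT_OARS",
    "DEFAULT_SPARING",
]

PTV_PRESCRIPTION_GY = 60.06
BOOST_PRESCRIPTION_GY = 69.96
N_FRACTIONS = 33


@dataclass(frozen=True)
class OARDescriptor:
    """One organ-at-risk primitive.

    ``kind`` is ``"ellipsoid"`` or ``"cylinder"`` (axis along z); ``center``
    and ``size`` are in mm relative to the volume center (size = semiaxes
    for ellipsoids, (rx, ry, half-length) for cylinders).  A planning
    organ-at-risk volume (PRV) is expressed as ``prv_of`` = base organ name
    plus ``margin_mm``; its mask is the base organ expanded isotropically.
    """

    name: str
    kind: str = "ellipsoid"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size: tuple[float, float, float] = (10.0, 10.0, 10.0)
    prv_of: str | None = None
    margin_mm: float = 0.0


# 21 organs at risk of a nasopharyngeal plan: paired lenses, optic nerves,
# parotids, mandibles, TMJs and temporal lobes; midline chiasm, pituitary,
# larynx, thyroid, trachea; brain stem and spinal cord with their PRVs
# (3 mm and 5 mm safety expansions respectively).
DEFAULT_OARS: tuple[OARDescriptor, ...] = (
    OARDescriptor("BrainStem", "ellipsoid", (0, -45, 6), (9, 9, 15)),
    OARDescriptor("BrainStem_PRV", prv_of="BrainStem", margin_mm=3.0),
    OARDescriptor("SpinalCord", "cylinder", (0, -70, 0), (5, 5, 200)),
    OARDescriptor("SpinalCord_PRV", prv_of="SpinalCord", margin_mm=5.0),
    OARDescriptor("Larynx", "ellipsoid", (0, 40, -12), (12, 12, 8)),
    OARDescriptor("Lens_L", "ellipsoid", (-28, 85, 6), (5, 5, 5)),
    OARDescriptor("Lens_R", "ellipsoid", (28, 85, 6), (5, 5, 5)),
    OARDescriptor("Mandible_L", "ellipsoid", (-45, 50, -8), (12, 18, 10)),
    OARDescriptor("Mandible_R", "ellipsoid", (45, 50, -8), (12, 18, 10)),
    OARDescriptor("OpticChiasm", "ellipsoid", (0, 58, 6), (8, 5, 4)),
    OARDescriptor("OpticNerve_L", "ellipsoid", (-14, 72, 6), (4, 10, 4)),
    OARDescriptor("OpticNerve_R", "ellipsoid", (14, 72, 6), (4, 10, 4)),
    OARDescriptor("Parotid_L", "ellipsoid", (-75, -10, 0), (15, 20, 14)),
    OARDescriptor("Parotid_R", "ellipsoid", (75, -10, 0), (15, 20, 14)),
    OARDescriptor("Pituitary", "ellipsoid", (0, 48, 10), (5, 5, 4)),
    OARDescriptor("TMJ_L", "ellipsoid", (-60, 10, 2), (6, 6, 6)),
    OARDescriptor("TMJ_R", "ellipsoid", (60, 10, 2), (6, 6, 6)),
    OARDescriptor("TemporalLobe_L", "ellipsoid", (-55, 15, 12), (18, 22, 9)),
    OARDescriptor("TemporalLobe_R", "ellipsoid", (55, 15, 12), (18, 22, 9)),
    OARDescriptor("ThyroidGland", "ellipsoid", (0, 35, -18), (18, 10, 5)),
    OARDescriptor("Trachea", "cylinder", (0, 28, -16), (7, 7, 40)),
)

# Multiplicative sparing applied to the falloff dose inside each organ;
# serially irradiated structures (cord, brain stem, optics) are pushed
# hardest, glands moderately.  Values are fractions in (0, 1].
DEFAULT_SPARING: dict[str, float] = {
    "SpinalCord": 0.35,
    "SpinalCord_PRV": 0.45,
    "BrainStem": 0.50,
    "BrainStem_PRV": 0.60,
    "OpticChiasm": 0.70,
    "OpticNerve_L": 0.65,
    "OpticNerve_R": 0.65,
    "Lens_L": 0.30,
    "Lens_R": 0.30,
    "Pituitary": 0.80,
    "Parotid_L": 0.60,
    "Parotid_R": 0.60,
    "Larynx": 0.70,
    "ThyroidGland": 0.75,
    "Trachea": 0.70,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic case.

    Lengths are mm; centers are relative to the volume center.  Default
    grid is a desk-scale 64x64x16 at (4, 4, 3) mm spacing, anisotropic like
    clinical CT (3 mm slices).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (4.0, 4.0, 3.0)
    body_semiaxes: tuple[float, float, float] = (115.0, 120.0, 400.0)
    ptv_center: tuple[float, float, float] = (0.0, 20.0, 0.0)
    ptv_semiaxes: tuple[float, float, float] = (45.0, 50.0, 9.0)
    boost_center: tuple[float, float, float] = (0.0, 20.0, 0.0)
    boost_semiaxes: tuple[float, float, float] = (20.0, 22.0, 5.0)
    oar_descriptors: tuple[OARDescriptor, ...] = DEFAULT_OARS
    field_margin_mm: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 8 per axis, got {self.grid_shape}")
        for name in ("body_semiaxes", "ptv_semiaxes", "boost_semiaxes"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        # boost ellipsoid strictly inside PTV ellipsoid: the point of the
        # boost surface deepest along each semiaxis must satisfy the PTV
        # inequality with room to spare.
        c = np.asarray(self.boost_center) - np.asarray(self.ptv_center)
        q = (np.abs(c) + np.asarray(self.boost_semiaxes)) / np.asarray(self.ptv_semiaxes)
        if np.any(q >= 1.0):
            raise ValueError("boost volume is not strictly inside the PTV")


@dataclass(frozen=True)
class DoseEngineParams:
    """Parameters of the parametric dose engine.

    ``falloff_tau`` is the exponential decay length (mm) of dose versus
    distance-to-PTV in normal tissue; ``oar_sparing`` multiplies the
    falloff dose inside each named organ (strongest factor wins where
    organs overlap); ``out_of_field_level`` scales the whole falloff
    outside the treated field.  ``noise_sd`` is additive Gaussian noise in
    Gy, clipped so dose stays non-negative.
    """

    prescription_ptv: float = PTV_PRESCRIPTION_GY
    prescription_boost: float = BOOST_PRESCRIPTION_GY
    falloff_tau: float = 25.0
    oar_sparing: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPARING))
    out_of_field_level: float = 0.02
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not (self.prescription_boost >= self.prescription_ptv > 0):
            raise ValueError("prescriptions must satisfy boost >= PTV > 0")
        if self.falloff_tau <= 0:
            raise ValueError("falloff_tau must be positive")
        for name, m in self.oar_sparing.items():
            if not (0 < m <= 1):
                raise ValueError(f"sparing multiplier for {name} must be in (0, 1], got {m}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomCase:
    """One synthetic patient: CT, ROI set, optional ground-truth dose."""

    ct: VolumeGrid
    rois: ROISet
    dose_gt: DoseMap | None
    prescriptions: dict[str, float]
    n_fractions: int = N_FRACTIONS
    seed: int = 0

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.ct.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.shape


def _voxel_coords(shape, spacing):
    """Physical voxel-center coordinates, origin at the volume center."""
    axes = [
        (np.arange(n) + 0.5) * s - n * s / 2.0
        for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(coords, center, semiaxes):
    xx, yy, zz = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def _cylinder(coords, center, size):
    xx, yy, zz = coords
    cx, cy, cz = center
    rx, ry, hl = size
    radial = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    return radial & (np.abs(zz - cz) <= hl)


def _expand(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Isotropic physical expansion via the Euclidean distance transform."""
    if not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return d <= margin_mm


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize one case (CT + ROI set); the dose is added separately.

    Deterministic for a given spec (the CT texture noise is drawn from
    ``spec.seed``).  Raises if the boost is not strictly inside the PTV or
    if the rasterized PTV escapes the body.
    """
    spec.validate()
    shape, spacing = spec.grid_shape, spec.spacing
    coords = _voxel_coords(shape, spacing)
    rng = np.random.default_rng(spec.seed)

    body = _ellipsoid(coords, (0.0, 0.0, 0.0), spec.body_semiaxes)
    if not body.any():
        raise ValueError("grid too small to contain the body volume")
    ptv = _ellipsoid(coords, spec.ptv_center, spec.ptv_semiaxes)
    boost = _ellipsoid(coords, spec.boost_center, spec.boost_semiaxes)
    if not ptv.any() or not boost.any():
        raise ValueError("grid too coarse: a target rasterized to zero voxels")
    if np.any(ptv & ~body):
        raise ValueError("PTV is not contained in the body volume")
    if np.any(boost & ~ptv):
        raise ValueError("boost mask escapes the PTV after rasterization")

    masks: dict[str, np.ndarray] = {"Body": body, "PTV": ptv, "Boost": boost}
    oar_names: list[str] = []
    for d in spec.oar_descriptors:
        if d.prv_of is not None:
            if d.prv_of not in masks:
                raise ValueError(f"PRV {d.name} references unknown base organ {d.prv_of}")
            m = _expand(masks[d.prv_of], d.margin_mm, spacing)
        elif d.kind == "ellipsoid":
            m = _ellipsoid(coords, d.center, d.size)
        elif d.kind == "cylinder":
            m = _cylinder(coords, d.center, d.size)
        else:
            raise ValueError(f"unknown OAR primitive kind {d.kind!r}")
        masks[d.name] = m & body  # organs clipped to the body
        oar_names.append(d.name)

    # treated field: slices within field_margin_mm of the target extent
    zz = coords[2].ravel()
    target_z = zz[np.any(ptv, axis=(0, 1))]
    in_field_z = (zz >= target_z.min() - spec.field_margin_mm) & (
        zz <= target_z.max() + spec.field_margin_mm
    )
    in_field = np.broadcast_to(in_field_z[None, None, :], shape).copy()

    # schematic CT: air outside the body, soft tissue inside, a bone-like
    # shell near the body surface (skull/vertebral analogue)
    xx, yy, zzg = coords
    r2 = (
        (xx / spec.body_semiaxes[0]) ** 2
        + (yy / spec.body_semiaxes[1]) ** 2
        + (zzg / spec.body_semiaxes[2]) ** 2
    )
    r2 = np.broadcast_to(r2, shape)
    ct = np.full(shape, -1000.0)
    ct[body] = 40.0
    shell = body & (r2 >= 0.70)
    ct[shell] = 700.0
    ct = ct + rng.normal(0.0, 20.0, size=shape) * body

    rois = ROISet(
        masks=masks,
        targets=["PTV", "Boost"],
        oars=oar_names,
        body="Body",
        in_field=in_field,
        prescriptions_gy={"PTV": PTV_PRESCRIPTION_GY, "Boost": BOOST_PRESCRIPTION_GY},
        n_fractions=N_FRACTIONS,
        spacing=spacing,
    )
    return PhantomCase(
        ct=VolumeGrid(ct, spacing),
        rois=rois,
        dose_gt=None,
        prescriptions=dict(rois.prescriptions_gy),
        seed=spec.seed,
    )


def simulate_dose(
    case: PhantomCase,
    params: DoseEngineParams,
    dptv: VolumeGrid,
    seed: int | None = None,
) -> DoseMap:
    """Parametric ground-truth dose on the case grid.

    Before noise: boost voxels receive the boost prescription, remaining
    PTV voxels the PTV prescription; in-field normal tissue follows
    ``Rx_ptv * exp(-DPTV / tau)`` times the organ sparing factor (the
    smallest factor wins where organs overlap); out-of-field voxels get
    the same falloff scaled by ``out_of_field_level``; voxels outside the
    body get zero.  Gaussian noise of ``noise_sd`` Gy is then added inside
    the body and the result clipped at 0.
    """
    params.validate()
    case.ct.require_same_grid(dptv, "distance map")
    rois = case.rois
    body = rois.body_mask
    ptv = rois.masks["PTV"]
    boost = rois.masks["Boost"]

    sparing = np.ones(case.shape)
    for name, mult in params.oar_sparing.items():
        if name in rois.masks:
            m = rois.masks[name]
            sparing[m] = np.minimum(sparing[m], mult)

    falloff = params.prescription_ptv * np.exp(-dptv.values / params.falloff_tau) * sparing
    dose = np.zeros(case.shape)
    nt = body & ~ptv
    dose[nt & rois.in_field] = falloff[nt & rois.in_field]
    oof = nt & ~rois.in_field
    dose[oof] = params.out_of_field_level * falloff[oof]
    dose[ptv] = params.prescription_ptv
    dose[boost] = params.prescription_boost

    if params.noise_sd > 0:
        if seed is None:
            seed = (case.seed + 1) % (2**31)
        rng = np.random.default_rng(seed)
        dose = dose + rng.normal(0.0, params.noise_sd, size=case.shape) * body
    return DoseMap(np.clip(dose, 0.0, None), case.spacing)


@dataclass(frozen=True)
class CohortRanges:
    """Uniform jitter ranges (mm or unitless scale) applied per case."""

    ptv_center_mm: tuple[float, float] = (-8.0, 8.0)
    ptv_center_z_mm: tuple[float, float] = (-3.0, 3.0)
    ptv_scale: tuple[float, float] = (0.85, 1.15)
    boost_scale: tuple[float, float] = (0.85, 1.15)
    body_scale: tuple[float, float] = (0.92, 1.08)
    oar_center_mm: tuple[float, float] = (-5.0, 5.0)

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name} is empty: ({lo}, {hi})")


def make_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    ranges: CohortRanges | None = None,
    dose_params: DoseEngineParams | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` distinct cases with ground-truth dose attached.

    Per-case seeds and geometric jitter are all derived from the master
    seed, so identical arguments reproduce the cohort exactly.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base = base_spec if base_spec is not None else PhantomSpec()
    ranges = ranges if ranges is not None else CohortRanges()
    ranges.validate()
    dose_params = dose_params if dose_params is not None else DoseEngineParams()
    # imported here: features depends only on grids, so no cycle in practice,
    # but keeping phantom importable without features at module load time
    from .features import compute_dptv

    master = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        case_seed = int(master.integers(2**31))
        jit = np.random.default_rng(case_seed)

        def u(lo_hi, size=None):
            return jit.uniform(*lo_hi, size=size)

        dc = np.array([u(ranges.ptv_center_mm), u(ranges.ptv_center_mm), u(ranges.ptv_center_z_mm)])
        ptv_scale = u(ranges.ptv_scale)
        boost_scale = min(u(ranges.boost_scale), ptv_scale)
        spec = replace(
            base,
            seed=case_seed,
            body_semiaxes=tuple(np.asarray(base.body_semiaxes) * u(ranges.body_scale)),
            ptv_center=tuple(np.asarray(base.ptv_center) + dc),
            ptv_semiaxes=tuple(np.asarray(base.ptv_semiaxes) * ptv_scale),
            boost_center=tuple(np.asarray(base.boost_center) + dc),
            boost_semiaxes=tuple(np.asarray(base.boost_semiaxes) * boost_scale),
            oar_descriptors=tuple(
                d
                if d.prv_of is not None
                else replace(d, center=tuple(np.asarray(d.center) + u(ranges.oar_center_mm, 3)))
                for d in base.oar_descriptors
            ),
        )
        case = generate_phantom(spec)
        dptv = compute_dptv(case.rois.masks["PTV"], case.rois.body_mask, case.spacing)
        case.dose_gt = simulate_dose(case, dose_params, dptv)
        cases.append(case)
    return cases


def save_case(case: PhantomCase, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(case.ct, directory / "ct.nii.gz")
    if case.dose_gt is not None:
        save_volume(case.dose_gt, directory / "dose.nii.gz")
    save_roiset(case.rois, directory / "rois")
    meta = {
        "spacing": list(case.spacing),
        "prescriptions_gy": case.prescriptions,
        "n_fractions": case.n_fractions,
        "seed": case.seed,
    }
    (directory / "case.json").write_text(json.dumps(meta, indent=2))


def load_case(directory: str | Path) -> PhantomCase:
    directory = Path(directory)
    meta = json.loads((directory / "case.json").read_text())
    ct = load_volume(directory / "ct.nii.gz")
    dose_path = directory / "dose.nii.gz"
    dose = load_volume(dose_path) if dose_path.exists() else None
    rois = load_roiset(directory / "rois")
    return PhantomCase(
        ct=ct,
        rois=rois,
        dose_gt=dose,
        prescriptions={k: float(v) for k, v in meta["prescriptions_gy"].items()},
        n_fractions=int(meta["n_fractions"]),
        seed=int(meta["seed"]),
    )
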