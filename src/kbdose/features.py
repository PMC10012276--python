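"""Network input features: distance-to-PTV maps, structure maps, channel stacks.

The distance map (DPTV) assigns every normal-tissue voxel its minimum 3D
Euclidean distance in mm to the PTV, computed with physical voxel spacing so
anisotropic grids (3 mm slices vs 1 mm in-plane) are handled correctly.  PTV
voxels and voxels outside the body are both coded 0 — an intentionally
ambiguous convention that the structure-map channel disambiguates.

The structure map is a single integer-labelled volume: targets carry large,
widely spaced codes and organs at risk small ones, so a voxel inside both an
organ and a target can be coded as the *sum* of the two labels without
ambiguity.  Out-of-field voxels get their own code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import ROISet, VolumeGrid

__all__ = [
    "DPTVMap",
    "LabelTable",
    "StructureMap",
    "InputStack",
    "compute_dptv",
    "build_label_table",
    "encode_structures",
    "decode_roi",
    "assemble_inputs",
    "DEFAULT_DPTV_CAP_MM",
    "DEFAULT_CT_WINDOW",
]

DEFAULT_DPTV_CAP_MM = 150.0
DEFAULT_CT_WINDOW = (-1000.0, 1000.0)

BODY_CODE = 1
OUT_OF_FIELD_CODE = 2
OAR_CODE_START = 3
TARGET_CODE_STEP = 100


# The distance map is a plain VolumeGrid whose values are mm.
DPTVMap = VolumeGrid


def compute_dptv(
    ptv_mask: np.ndarray,
    body_mask: np.ndarray,
    spacing: tuple[float, float, float],
) -> DPTVMap:
    """Minimum Euclidean distance (mm) from each body voxel to the PTV.

    Distances are between voxel centers, computed in full 3D with the
    physical spacing.  PTV voxels and voxels outside the body map to 0.

    Raises ``ValueError`` for an empty PTV, mask shape mismatch, a PTV not
    contained in the body, or non-positive spacing.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if ptv_mask.shape != body_mask.shape:
        raise ValueError(f"mask shape mismatch: {ptv_mask.shape} vs {body_mask.shape}")
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    if np.any(ptv_mask & ~body_mask):
        raise ValueError("PTV mask is not contained in the body mask")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing}")

    d = ndimage.distance_transform_edt(~ptv_mask, sampling=spacing)
    d[~body_mask] = 0.0
    return DPTVMap(d, spacing)


@dataclass(frozen=True)
class LabelTable:
    """Integer codes for the structure map.

    Targets take multiples of ``TARGET_CODE_STEP`` and organs small
    consecutive codes, so every organ+target sum is distinct from every
    single code and from every other sum.  Validated on construction.
    """

    codes: dict[str, int]
    targets: tuple[str, ...]
    oars: tuple[str, ...]
    body_code: int = BODY_CODE
    out_of_field_code: int = OUT_OF_FIELD_CODE

    def __post_init__(self) -> None:
        singles = [self.body_code, self.out_of_field_code] + [self.codes[n] for n in self.targets + self.oars]
        if len(set(singles)) != len(singles):
            raise ValueError("label codes are not unique")
        sums = [self.codes[t] + self.codes[o] for t in self.targets for o in self.oars]
        all_codes = singles + sums
        if len(set(all_codes)) != len(all_codes):
            raise ValueError("an organ+target sum collides with another code")

    @property
    def max_code(self) -> int:
        top_t = max(self.codes[t] for t in self.targets)
        top_o = max((self.codes[o] for o in self.oars), default=0)
        return top_t + top_o


def build_label_table(rois: ROISet) -> LabelTable:
    if len(rois.oars) > TARGET_CODE_STEP - OAR_CODE_START:
        raise ValueError("too many organs for the spaced target codes")
    codes: dict[str, int] = {}
    for i, name in enumerate(rois.oars):
        codes[name] = OAR_CODE_START + i
    for i, name in enumerate(rois.targets):
        codes[name] = TARGET_CODE_STEP * (i + 1)
    return LabelTable(codes=codes, targets=tuple(rois.targets), oars=tuple(rois.oars))


@dataclass
class StructureMap:
    labels: VolumeGrid
    table: LabelTable


def encode_structures(rois: ROISet, table: LabelTable | None = None) -> StructureMap:
    """Paint the single integer-labelled structure volume.

    Precedence: among nested targets the highest-prescription (innermost)
    target wins; among overlapping organs the first in ``rois.oars`` wins
    (base organs are listed before their PRV expansions).  A voxel inside
    both an organ and a target is coded with the sum of the two labels.
    Voxels in the body but in no ROI get the body code; voxels outside the
    treated field get the out-of-field code; in-field voxels outside the
    body are left 0.
    """
    if table is None:
        table = build_label_table(rois)
    shape = rois.shape
    tcode = np.zeros(shape, dtype=np.int32)
    for name in rois.targets:  # increasing prescription order: later overrides
        tcode[rois.masks[name]] = table.codes[name]
    ocode = np.zeros(shape, dtype=np.int32)
    for name in rois.oars:
        m = rois.masks[name] & (ocode == 0)
        ocode[m] = table.codes[name]

    labels = np.zeros(shape, dtype=np.int32)
    body = rois.body_mask
    labels[body] = table.body_code
    labels[ocode > 0] = ocode[ocode > 0]
    overlap = tcode > 0
    labels[overlap] = tcode[overlap] + ocode[overlap]
    labels[~rois.in_field] = table.out_of_field_code
    return StructureMap(VolumeGrid(labels, rois.spacing), table)


def decode_roi(smap: StructureMap, name: str) -> np.ndarray:
    """Recover an ROI mask from the structure map (up to precedence losses)."""
    table = smap.table
    code = table.codes[name]
    lab = smap.labels.values
    if name in table.targets:
        hits = lab == code
        for o in table.oars:
            hits |= lab == code + table.codes[o]
        return hits
    hits = lab == code
    for t in table.targets:
        hits |= lab == code + table.codes[t]
    return hits


@dataclass
class InputStack:
    """Per-slice channel stack for the network.

    ``channels`` has shape (n_slices, C, H, W) with the fixed channel order
    (CT, structure map, DPTV); the distance channel is present only in COM
    mode, so C = 2 for ANAT and 3 for COM.  All channels are normalized to
    [0, 1]; the normalization constants are kept in ``meta`` so dose
    predictions can be mapped back to Gy.
    """

    channels: np.ndarray
    mode: str
    meta: dict

    @property
    def n_slices(self) -> int:
        return self.channels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    def __iter__(self):
        return iter(self.channels)


def assemble_inputs(
    case,
    mode: str,
    dptv: DPTVMap | None = None,
    ct_window: tuple[float, float] = DEFAULT_CT_WINDOW,
    dptv_cap_mm: float = DEFAULT_DPTV_CAP_MM,
    table: LabelTable | None = None,
) -> InputStack:
    """Assemble the axial-slice input stack for one case.

    ANAT mode stacks (CT, structure map); COM mode adds the DPTV channel.
    CT is linearly windowed to [0, 1]; structure codes are divided by the
    largest valid code; DPTV is divided by ``dptv_cap_mm`` and clipped to
    [0, 1].
    """
    mode = mode.upper()
    if mode not in ("ANAT", "COM"):
        raise ValueError(f"unknown input mode {mode!r}; expected 'ANAT' or 'COM'")
    rois = case.rois
    lo, hi = ct_window
    ct = np.clip((case.ct.values - lo) / (hi - lo), 0.0, 1.0)
    smap = encode_structures(rois, table)
    struct = smap.labels.values / float(smap.table.max_code)
    planes = [ct, struct]
    if mode == "COM":
        if dptv is None:
            dptv = compute_dptv(rois.masks[rois.targets[0]], rois.body_mask, rois.spacing)
        case.ct.require_same_grid(dptv, "distance map")
        planes.append(np.clip(dptv.values / dptv_cap_mm, 0.0, 1.0))
    # (nx, ny, nz) -> (nz, C, nx, ny): axial slices are the 2D unit
    vol = np.stack(planes, axis=0).astype(np.float32)
    channels = np.ascontiguousarray(np.moveaxis(vol, 3, 0))
    meta = {
        "ct_window": tuple(ct_window),
        "dptv_cap_mm": float(dptv_cap_mm),
        "max_label_code": smap.table.max_code,
    }
    return InputStack(channels=channels, mode=mode, meta=meta)


def save_label_table(table: LabelTable, path: str | Path) -> None:
    payload = {
        "codes": table.codes,
        "targets": list(table.targets),
        "oars": list(table.oars),
        "body_code": table.body_code,
        "out_of_field_code": table.out_of_field_code,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_label_table(path: str | Path) -> LabelTable:
    payload = json.loads(Path(path).read_text())
    return LabelTable(
        codes={k: int(v) for k, v in payload["codes"].items()},
        targets=tuple(payload["targets"]),
        oars=tuple(payload["oars"]),
        body_code=int(payload["body_code"]),
        out_of_field_code=int(payload["out_of_field_code"]),
    )
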