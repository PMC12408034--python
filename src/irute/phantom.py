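"""Synthetic 2D digital head phantom for IR-UTE myelin imaging experiments.

The phantom is a procedurally generated label map with six tissue classes
(CSF, long-T2 gray matter GM_L, long-T2 white matter WM_L, myelin, skull
bone, subcutaneous fat) arranged as concentric anatomically ordered shells,
plus two CSF "ventricles" and a configurable number of demyelinated lesion
discs inside the white matter.  Myelin co-exists with long-T2 white-matter
water: a pixel labeled ``Myelin`` contains both the myelin proton pool and
the WM_L water pool, so the WM_L support is the union of the ``WM_L`` and
``Myelin`` labels.

Conventions: 0-based pixel indices, image center at pixel ``(N//2, N//2)``,
row axis = superior-inferior (SI).  Label maps are categorical and are only
ever resampled with nearest-neighbor interpolation; continuous maps derived
from them (e.g. the proton-density map) are interpolated linearly.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical label assignment for the six tissue classes (0 = background)
LABELS = {
    "Background": 0,
    "CSF": 1,
    "GM_L": 2,
    "WM_L": 3,
    "Myelin": 4,
    "Skull": 5,
    "Fat": 6,
}


@dataclass(frozen=True)
class TissueParams:
    """MR parameters of one tissue class.

    ``inversion_response`` describes the effect of the long adiabatic
    inversion pulse: long-T2 species are inverted (Mz -> -Mz) while
    sub-millisecond-T2* species (myelin, cortical bone) cannot follow the
    sweep and are driven to saturation (Mz -> 0).
    """

    label: int
    name: str
    pd: float        # relative proton density, dimensionless, >= 0
    t1_ms: float     # longitudinal relaxation time [ms]
    t2s_ms: float    # apparent transverse relaxation time T2* [ms]
    inversion_response: str  # "invert" | "saturate"

    def __post_init__(self) -> None:
        if self.pd < 0:
            raise ValueError(f"pd must be >= 0, got {self.pd}")
        if self.t1_ms <= 0 or self.t2s_ms <= 0:
            raise ValueError("t1_ms and t2s_ms must be > 0")
        if self.inversion_response not in ("invert", "saturate"):
            raise ValueError(
                f"inversion_response must be 'invert' or 'saturate', "
                f"got {self.inversion_response!r}"
            )


# Default tissue table.  PD/T1/T2* are representative 3 T brain values;
# WM_L T1 = 1000 ms fixes the long-T2 white-matter null at TI = 379.9 ms
# for TR = 1000 ms.  Myelin protons: very low density, T2* ~ 0.3 ms,
# short T1, saturated (not inverted) by the adiabatic pulse.  Cortical
# bone likewise has sub-millisecond T2* and saturates.
DEFAULT_TISSUES: tuple[TissueParams, ...] = (
    TissueParams(0, "Background", 0.0, 1.0, 1.0, "invert"),
    TissueParams(1, "CSF", 1.0, 4000.0, 2000.0, "invert"),
    TissueParams(2, "GM_L", 0.80, 1400.0, 60.0, "invert"),
    TissueParams(3, "WM_L", 0.65, 1000.0, 50.0, "invert"),
    TissueParams(4, "Myelin", 0.10, 300.0, 0.3, "saturate"),
    TissueParams(5, "Skull", 0.25, 250.0, 0.4, "saturate"),
    TissueParams(6, "Fat", 0.90, 380.0, 30.0, "invert"),
)


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotation about the image center, then translation.

    ``dx_mm`` translates along columns, ``dy_mm`` along rows (SI axis),
    ``theta_deg`` rotates counter-clockwise about the image center.
    """

    dx_mm: float = 0.0
    dy_mm: float = 0.0
    theta_deg: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.dx_mm == 0.0 and self.dy_mm == 0.0 and self.theta_deg == 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx_mm, self.dy_mm, self.theta_deg)


@dataclass
class PhantomModel:
    """Tissue label map plus per-tissue MR parameters and pixel geometry.

    ``lesion_specs`` records demyelinated lesion discs as
    ``((row, col), radius)`` in pixels of the *original* (untransformed)
    frame; inside each disc the myelin pool is removed (label Myelin ->
    WM_L) while the long-T2 white-matter water is unchanged.
    """

    label_map: np.ndarray
    tissues: tuple[TissueParams, ...] = DEFAULT_TISSUES
    pixel_mm: float = 1.0
    fov_mm: float = 220.0
    lesion_specs: tuple[tuple[tuple[int, int], int], ...] = field(default_factory=tuple)
    #: optional per-tissue partial-volume fraction maps (float in [0, 1]);
    #: where present they override the binary label support, e.g. for
    #: anti-aliased analytic test objects.  The default generator emits
    #: none (one tissue combination per pixel).
    pv_maps: dict | None = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        present = set(np.unique(self.label_map).tolist())
        known = {t.label for t in self.tissues}
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no TissueParams entry")

    # -- lookups ---------------------------------------------------------
    @property
    def matrix_size(self) -> int:
        return int(self.label_map.shape[0])

    def tissue(self, name: str) -> TissueParams:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def support_labels(self, name: str) -> set[int]:
        """Label values whose pixels contain tissue ``name``.

        WM_L water fills both the ``WM_L`` and ``Myelin`` labels (myelin
        co-exists with long-T2 white matter water).
        """
        t = self.tissue(name)
        labels = {t.label}
        if name == "WM_L":
            myelin = [u.label for u in self.tissues if u.name == "Myelin"]
            labels.update(myelin)
        return labels

    def support(self, name: str) -> np.ndarray:
        """Boolean mask of pixels containing tissue ``name``."""
        mask = np.zeros(self.label_map.shape, dtype=bool)
        for lab in self.support_labels(name):
            mask |= self.label_map == lab
        return mask

    def tissue_map(self, name: str) -> np.ndarray:
        """Tissue occupancy as a float map: the partial-volume fraction map
        if one was supplied, otherwise the binary label support."""
        if self.pv_maps and name in self.pv_maps:
            return np.asarray(self.pv_maps[name], dtype=float)
        return self.support(name).astype(float)

    def pd_map(self) -> np.ndarray:
        """Total proton-density map (co-located pools add)."""
        pdm = np.zeros(self.label_map.shape, dtype=float)
        for t in self.tissues:
            if t.pd > 0 and t.label != 0:
                pdm += t.pd * self.tissue_map(t.name)
        return pdm

    def imaged_tissues(self) -> list[TissueParams]:
        """Tissues with signal (pd > 0) that are present in the label map."""
        out = []
        for t in self.tissues:
            if t.pd > 0 and self.tissue_map(t.name).any():
                out.append(t)
        return out


def _ellipse_rho(n: int, center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    return np.sqrt(
        ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2
    )


def build_default_phantom(
    matrix_size: int,
    n_lesions: int = 4,
    seed: int = 1,
    fov_mm: float = 220.0,
    tissues: tuple[TissueParams, ...] = DEFAULT_TISSUES,
) -> PhantomModel:
    """Generate the concentric-shell head phantom.

    From the outside in: subcutaneous fat ring, skull, CSF ring, a gray
    matter ribbon, and a white-matter interior carrying myelin, plus two
    CSF ventricles and ``n_lesions`` non-overlapping demyelinated lesion
    discs fully inside the myelinated white matter.  Deterministic for a
    fixed ``seed``.
    """
    n = int(matrix_size)
    if n < 32:
        raise ValueError(f"matrix_size {n} too small to host all tissue shells (need >= 32)")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")

    c = n // 2
    # head slightly taller (SI) than wide, with margin to the FOV edge
    semi = (0.44 * n, 0.40 * n)
    rho = _ellipse_rho(n, (c, c), semi)

    lab = np.zeros((n, n), dtype=np.int16)
    lab[rho <= 1.00] = LABELS["Fat"]
    lab[rho <= 0.92] = LABELS["Skull"]
    lab[rho <= 0.84] = LABELS["CSF"]
    lab[rho <= 0.76] = LABELS["GM_L"]
    lab[rho <= 0.60] = LABELS["Myelin"]   # WM interior, myelin co-located

    # lateral ventricles (CSF) slightly superior to center, left/right
    for sgn in (-1.0, 1.0):
        vc = (c - 0.06 * n, c + sgn * 0.10 * n)
        vrho = _ellipse_rho(n, vc, (0.10 * n, 0.045 * n))
        inside_wm = (vrho <= 1.0) & (lab == LABELS["Myelin"])
        lab[inside_wm] = LABELS["CSF"]

    for name in ("CSF", "GM_L", "Myelin", "Skull", "Fat"):
        if not (lab == LABELS[name]).any():
            raise ValueError(f"matrix_size {n} too small: shell {name} is empty")

    # demyelinated lesions: discs where Myelin -> WM_L (myelin pd zeroed,
    # long-T2 white matter unchanged)
    rng = np.random.default_rng(seed)
    radius = max(2, round(0.025 * n))
    rr, cc = np.mgrid[0:n, 0:n]
    specs: list[tuple[tuple[int, int], int]] = []
    tries = 0
    while len(specs) < n_lesions:
        tries += 1
        if tries > 20000:
            raise ValueError(
                f"could not place {n_lesions} non-overlapping lesions of radius "
                f"{radius} px inside the white matter at matrix_size {n}"
            )
        r0 = int(rng.integers(0, n))
        c0 = int(rng.integers(0, n))
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        if not np.all(lab[disc] == LABELS["Myelin"]):
            continue
        if any((r0 - p[0]) ** 2 + (c0 - p[1]) ** 2 <= (2 * radius + 2) ** 2 for p, _ in specs):
            continue
        specs.append(((r0, c0), radius))
        lab[disc] = LABELS["WM_L"]

    return PhantomModel(
        label_map=lab,
        tissues=tissues,
        pixel_mm=fov_mm / n,
        fov_mm=fov_mm,
        lesion_specs=tuple(specs),
    )


def _affine_inputs(
    t: RigidTransform, shape: tuple[int, int], pixel_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset for ``scipy.ndimage.affine_transform`` implementing
    ``g(x) = f(R_{-theta} (x - c - d) + c)``: rotation by ``theta`` about the
    image center followed by translation ``d`` (in pixels)."""
    th = math.radians(t.theta_deg)
    # rotation of (row, col) coordinates by -theta
    rot = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    c = np.array([shape[0] // 2, shape[1] // 2], dtype=float)
    d = np.array([t.dy_mm / pixel_mm, t.dx_mm / pixel_mm])
    offset = c - rot @ (c + d)
    return rot, offset


def apply_rigid_transform(phantom: PhantomModel, t: RigidTransform) -> PhantomModel:
    """Resample the label map under a rigid transform (nearest-neighbor).

    The tissue table is unchanged.  If the transform pushes head tissue out
    of the FOV a warning is logged (not fatal).  ``lesion_specs`` keep
    referring to the original frame.
    """
    if t.is_identity:
        return phantom
    rot, offset = _affine_inputs(t, phantom.label_map.shape, phantom.pixel_mm)
    new = ndimage.affine_transform(
        phantom.label_map, rot, offset=offset, order=0, mode="constant", cval=0
    )
    if np.count_nonzero(new) < np.count_nonzero(phantom.label_map):
        logger.warning(
            "rigid transform %s clipped head support at the FOV edge "
            "(%d -> %d nonzero pixels)",
            t, np.count_nonzero(phantom.label_map), np.count_nonzero(new),
        )
    return replace(phantom, label_map=new)


def transform_continuous(
    img: np.ndarray, t: RigidTransform, pixel_mm: float
) -> np.ndarray:
    """Rigidly transform a continuous-valued map (linear interpolation)."""
    if t.is_identity:
        return img.copy()
    rot, offset = _affine_inputs(t, img.shape, pixel_mm)
    return ndimage.affine_transform(img, rot, offset=offset, order=1, mode="constant", cval=0.0)


# -- NIfTI / JSON round-trip ---------------------------------------------

def save_phantom(phantom: PhantomModel, nii_path: str, json_path: str | None = None) -> None:
    """Write the label map as NIfTI plus a JSON sidecar (tissue table, lesions)."""
    aff = np.diag([phantom.pixel_mm, phantom.pixel_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(phantom.label_map.astype(np.int16), aff), nii_path)
    if json_path is None:
        json_path = str(nii_path).rsplit(".nii", 1)[0] + ".json"
    meta = {
        "pixel_mm": phantom.pixel_mm,
        "fov_mm": phantom.fov_mm,
        "lesion_specs": [[list(p), r] for p, r in phantom.lesion_specs],
        "tissues": [
            {
                "label": t.label, "name": t.name, "pd": t.pd,
                "t1_ms": t.t1_ms, "t2s_ms": t.t2s_ms,
                "inversion_response": t.inversion_response,
            }
            for t in phantom.tissues
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_phantom(nii_path: str, json_path: str | None = None) -> PhantomModel:
    img = nib.load(nii_path)
    lab = np.asarray(img.dataobj).astype(np.int16)
    if lab.ndim == 3 and lab.shape[2] == 1:
        lab = lab[:, :, 0]
    if json_path is None:
        json_path = str(nii_path).rsplit(".nii", 1)[0] + ".json"
    with open(json_path) as fh:
        meta = json.load(fh)
    tissues = tuple(TissueParams(**t) for t in meta["tissues"])
    lesions = tuple((tuple(p), int(r)) for p, r in meta["lesion_specs"])
    return PhantomModel(
        label_map=lab,
        tissues=tissues,
        pixel_mm=float(meta["pixel_mm"]),
        fov_mm=float(meta["fov_mm"]),
        lesion_specs=lesions,
    )


def remove_myelin(phantom: PhantomModel) -> PhantomModel:
    """Return a copy with the myelin pool removed everywhere (Myelin -> WM_L).

    Long-T2 white-matter water is untouched; this is the fully demyelinated
    control used to verify the echo-subtraction contrast mechanism.
    """
    lab = phantom.label_map.copy()
    lab[lab == LABELS["Myelin"]] = LABELS["WM_L"]
    return replace(phantom, label_map=lab)
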