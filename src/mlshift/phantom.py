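"""Synthetic axial head-CT phantoms with exact midline-shift ground truth.

Each phantom is a deliberately schematic head: an elliptical skull at bone
HU around brain parenchyma, a falx line on the midline, a pair of lateral
ventricles flanking a septum-pellucidum segment, and optionally a
hemorrhage-like lesion and metal-streak artifacts. The septum (with its
ventricles) is displaced laterally from the midline by a per-slice shift
that peaks, at the mid-ventricle slice, at exactly the requested midline
shift — so every generated scan carries landmark annotations whose
geometric MLS reproduces the requested value to float precision, and the
whole measurement pipeline can be exercised without clinical data.

The phantoms make no claim of anatomical realism: the lesion classes are
rendered as simple density templates (parenchymal blob, subdural crescent,
epidural lens, intraventricular blob, thin parafalcine layer) whose only
job is to stratify the dataset split and perturb the image the way a mass
lesion perturbs the windows.

Dataset assembly splits by patient, never by scan, with an 8:1:1
train/validation/test ratio applied within each lesion class by
largest-remainder rounding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .geometry import KeypointSet, aggregate_scan, compute_mls_slice
from .io import AnnotationRecord, CTVolume

__all__ = [
    "HU",
    "LESION_TYPES",
    "PhantomSpec",
    "LabeledScan",
    "generate_phantom",
    "simulate_metal_streaks",
    "build_dataset",
    "parse_mls_distribution",
]


class HU:
    """Nominal tissue densities used by the renderer (Hounsfield units)."""

    AIR = -1000.0
    BRAIN = 30.0
    CSF = 8.0
    FALX = 60.0
    SEPTUM = 38.0
    BLOOD = 70.0
    CHRONIC_BLOOD = 18.0
    BONE = 1000.0


#: The six hemorrhage classes used to stratify the dataset split.
LESION_TYPES = ("ICH", "IVH", "SAH", "acute_SDH", "chronic_SDH", "EDH")


@dataclass
class PhantomSpec:
    """Parameters generating one synthetic scan with known ground truth."""

    patient_id: str
    scan_id: str
    image_size: int = 256
    spacing: tuple[float, float, float] = (5.0, 0.9, 0.9)  # (slice, row, col) mm
    n_slices: int = 14
    skull_axes: tuple[float, float] = (80.0, 100.0)  # (x, y) outer semi-axes, px
    true_mls_mm: float = 0.0
    shift_profile: str = "raised_cosine"
    lesion: Optional[tuple[tuple[float, float], float, float]] = None  # ((x,y), r, HU)
    lesion_type_label: str = "ICH"
    artifacts: Optional[tuple[int, float]] = None  # (n_streaks, amplitude HU)
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_mls_mm < 0:
            raise ValueError("true_mls_mm must be non-negative")
        if min(self.skull_axes) <= 0:
            raise ValueError("skull axes must be positive")
        if self.lesion_type_label not in LESION_TYPES and self.lesion_type_label != "none":
            raise ValueError(
                f"unknown lesion type {self.lesion_type_label!r}; "
                f"expected one of {list(LESION_TYPES)} or 'none'"
            )


@dataclass
class LabeledScan:
    """A generated scan with its ground truth (volume optional, see below).

    ``volume`` is ``None`` when the scan was generated geometry-only
    (``render_voxels=False``); annotations and true MLS are always present.
    """

    volume: Optional[CTVolume]
    annotations: list[AnnotationRecord]
    true_mls_mm: float
    lesion_type_label: str
    patient_id: str = ""
    scan_id: str = ""
    spec: Optional[PhantomSpec] = None


# skull shell thickness and ventricle geometry, px at the 256 default grid
_SKULL_THICKNESS = 8.0
_SEPTUM_HALF_LEN = 16.0
_VENTRICLE_HALF_WIDTH = 9.0
_VENTRICLE_HALF_LEN = 22.0


def _slice_scale(i: int, n: int) -> float:
    """Mild spherical tapering of the skull cross-section along z."""
    zc = (n - 1) / 2.0
    zr = n * 0.85
    return max(0.6, math.sqrt(max(0.0, 1.0 - ((i - zc) / zr) ** 2)))


def _ventricle_window(n_slices: int) -> tuple[int, int, int]:
    """(first, peak, last) slice indices of the ventricle-level band."""
    peak = n_slices // 2
    half = max(2, n_slices // 4)
    return max(0, peak - half), peak, min(n_slices - 1, peak + half)


def shift_profile_values(spec: PhantomSpec) -> dict[int, float]:
    """Per-slice shift scaling in [0, 1], peaking at exactly 1.

    A truncated raised cosine over the ventricle-level slices: the peak slice
    carries the full ``true_mls_mm``, neighbours fall off smoothly, and
    slices outside the band carry no septum (hence no annotation).
    """
    lo, peak, hi = _ventricle_window(spec.n_slices)
    half = max(peak - lo, hi - peak, 1)
    if spec.shift_profile == "raised_cosine":
        return {
            i: math.cos(0.5 * math.pi * (i - peak) / (half + 1)) ** 2
            for i in range(lo, hi + 1)
        }
    if spec.shift_profile == "flat":
        return {i: 1.0 for i in range(lo, hi + 1)}
    raise ValueError(f"unknown shift profile {spec.shift_profile!r}")


def ground_truth_keypoints(spec: PhantomSpec) -> list[AnnotationRecord]:
    """Exact landmark annotations for every slice where the septum is drawn."""
    size = spec.image_size
    cx = cy = (size - 1) / 2.0
    col_mm = spec.spacing[2]
    a_out, b_out = spec.skull_axes
    t = _SKULL_THICKNESS * size / 256.0
    sep_half = _SEPTUM_HALF_LEN * size / 256.0
    vent_w = _VENTRICLE_HALF_WIDTH * size / 256.0
    profile = shift_profile_values(spec)
    records = []
    for i, frac in sorted(profile.items()):
        s = _slice_scale(i, spec.n_slices)
        a_in, b_in = (a_out - t) * s, (b_out - t) * s
        shift_px = spec.true_mls_mm * frac / col_mm
        # septum (with ventricles) must stay inside the inner skull
        margin_x = shift_px + vent_w + 2.0
        margin_y = sep_half
        if (margin_x / a_in) ** 2 + (margin_y / b_in) ** 2 >= 1.0:
            raise ValueError(
                f"true_mls_mm={spec.true_mls_mm} pushes the septum outside the "
                f"skull (slice {i}, inner semi-axes {a_in:.1f}x{b_in:.1f} px)"
            )
        kp = KeypointSet(
            falx_anterior=(cx, cy - b_in),
            falx_posterior=(cx, cy + b_in),
            septum_anterior=(cx + shift_px, cy - sep_half),
            septum_posterior=(cx + shift_px, cy + sep_half),
        )
        records.append(
            AnnotationRecord(
                scan_id=spec.scan_id, slice_index=i, keypoints=kp, annotator="ground_truth"
            )
        )
    return records


def _ellipse_mask(xx, yy, cx, cy, a, b):
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _render_lesion(img, xx, yy, spec, cx, cy, a_in, b_in, s):
    """Paint the lesion template for this slice in place."""
    if spec.lesion is not None:
        (lx, ly), r, hu = spec.lesion
        img[_ellipse_mask(xx, yy, lx, ly, r, r)] = hu
        return
    label = spec.lesion_type_label
    if label == "none":
        return
    if label == "ICH":
        img[_ellipse_mask(xx, yy, cx - 0.45 * a_in, cy, 0.22 * a_in, 0.28 * b_in)] = HU.BLOOD
    elif label == "IVH":
        img[_ellipse_mask(xx, yy, cx - 0.18 * a_in, cy + 0.05 * b_in,
                          0.10 * a_in, 0.16 * b_in)] = HU.BLOOD
    elif label == "SAH":
        band = np.abs(xx - cx) <= 2.5
        inside = _ellipse_mask(xx, yy, cx, cy, a_in, 0.85 * b_in)
        img[band & inside] = 0.5 * (HU.BLOOD + HU.BRAIN)
    elif label in ("acute_SDH", "chronic_SDH"):
        hu = HU.BLOOD if label == "acute_SDH" else HU.CHRONIC_BLOOD
        outer = _ellipse_mask(xx, yy, cx, cy, a_in, b_in)
        inner = _ellipse_mask(xx, yy, cx, cy, a_in - 10.0 * s, b_in - 10.0 * s)
        img[outer & ~inner & (xx < cx - 0.3 * a_in)] = hu
    elif label == "EDH":
        img[_ellipse_mask(xx, yy, cx - a_in, cy, 0.35 * a_in, 0.45 * b_in)
            & _ellipse_mask(xx, yy, cx, cy, a_in, b_in)] = HU.BLOOD


def generate_phantom(spec: PhantomSpec, render_voxels: bool = True) -> LabeledScan:
    """Generate one labelled synthetic scan; deterministic under ``spec.seed``.

    With ``render_voxels=False`` only the ground-truth annotations are built
    (useful for large cohort-level Monte-Carlo experiments that never look
    at pixels).
    """
    annotations = ground_truth_keypoints(spec)
    per_slice = [
        (r.slice_index, compute_mls_slice(r.keypoints, spec.spacing[1:]))
        for r in annotations
    ]
    true_from_geometry = aggregate_scan(per_slice, spec.scan_id).scan_mls_mm

    volume = None
    if render_voxels:
        volume = _render_volume(spec)
        for r in annotations:
            r.validate_against(volume)
    scan = LabeledScan(
        volume=volume,
        annotations=annotations,
        true_mls_mm=spec.true_mls_mm,
        lesion_type_label=spec.lesion_type_label,
        patient_id=spec.patient_id,
        scan_id=spec.scan_id,
        spec=spec,
    )
    # internal consistency: the emitted annotations reproduce the requested MLS
    assert abs(true_from_geometry - spec.true_mls_mm) < 0.1
    return scan


def _render_volume(spec: PhantomSpec) -> CTVolume:
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    cx = cy = (size - 1) / 2.0
    a_out, b_out = spec.skull_axes
    t = _SKULL_THICKNESS * size / 256.0
    sep_half = _SEPTUM_HALF_LEN * size / 256.0
    vent_w = _VENTRICLE_HALF_WIDTH * size / 256.0
    vent_l = _VENTRICLE_HALF_LEN * size / 256.0
    col_mm = spec.spacing[2]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    profile = shift_profile_values(spec)
    lo, peak, hi = _ventricle_window(spec.n_slices)

    voxels = np.full((spec.n_slices, size, size), HU.AIR)
    for i in range(spec.n_slices):
        s = _slice_scale(i, spec.n_slices)
        a_o, b_o = a_out * s, b_out * s
        a_in, b_in = (a_out - t) * s, (b_out - t) * s
        img = voxels[i]
        skull = _ellipse_mask(xx, yy, cx, cy, a_o, b_o)
        brain = _ellipse_mask(xx, yy, cx, cy, a_in, b_in)
        img[skull] = HU.BONE
        img[brain] = HU.BRAIN

        if lo <= i <= hi:
            _render_lesion(img, xx, yy, spec, cx, cy, a_in, b_in, s)

        # falx: thin dense line along the midline inside the brain
        falx = (np.abs(xx - cx) <= 0.8) & brain
        img[falx] = HU.FALX

        if i in profile:
            shift_px = spec.true_mls_mm * profile[i] / col_mm
            sx = cx + shift_px
            for side in (-1.0, 1.0):
                vent = _ellipse_mask(
                    xx, yy, sx + side * (vent_w + 1.5), cy, vent_w, vent_l
                )
                img[vent & brain] = HU.CSF
            septum = (np.abs(xx - sx) <= 1.2) & (np.abs(yy - cy) <= sep_half)
            img[septum & brain] = HU.SEPTUM

        if spec.noise_sigma > 0:
            img[brain] += rng.normal(0.0, spec.noise_sigma, int(brain.sum()))

        if spec.artifacts is not None:
            n_streaks, amplitude = spec.artifacts
            voxels[i] = simulate_metal_streaks(img, n_streaks, amplitude, rng)

    return CTVolume(
        voxels=voxels,
        spacing=spec.spacing,
        scan_id=spec.scan_id,
        patient_id=spec.patient_id,
    )


def simulate_metal_streaks(
    slice_hu: np.ndarray,
    n_streaks: int,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add alternating-sign linear streaks through a random interior point.

    A simplified stand-in for sinogram-domain metal-artifact simulation:
    ``n_streaks`` straight lines at random orientations pass through one
    random point in the central region of the slice, alternating between
    +amplitude and -amplitude HU. Zero streaks or zero amplitude is the
    identity. Deterministic for a fixed generator state.
    """
    if amplitude < 0:
        raise ValueError("streak amplitude must be non-negative")
    if n_streaks == 0 or amplitude == 0:
        return slice_hu
    h, w = slice_hu.shape
    out = np.array(slice_hu, dtype=np.float64, copy=True)
    # random point in the central third (inside the skull for any sane spec)
    px = rng.uniform(w * 0.4, w * 0.6)
    py = rng.uniform(h * 0.4, h * 0.6)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for k in range(n_streaks):
        theta = rng.uniform(0.0, math.pi)
        dist = np.abs((xx - px) * math.sin(theta) - (yy - py) * math.cos(theta))
        out[dist <= 1.0] += amplitude * (1.0 if k % 2 == 0 else -1.0)
    return out


def parse_mls_distribution(dist) -> Callable[[np.random.Generator], float]:
    """Turn a distribution description into a sampler.

    Accepts a callable ``rng -> mm``, or a string: ``"uniform:a,b"``,
    ``"normal:mu,sd"`` (truncated at 0) or ``"constant:v"``.
    """
    if callable(dist):
        return dist
    name, _, args = str(dist).partition(":")
    vals = [float(v) for v in args.split(",")] if args else []
    if name == "uniform" and len(vals) == 2:
        return lambda rng: float(rng.uniform(vals[0], vals[1]))
    if name == "normal" and len(vals) == 2:
        return lambda rng: float(max(0.0, rng.normal(vals[0], vals[1])))
    if name == "constant" and len(vals) == 1:
        return lambda rng: vals[0]
    raise ValueError(f"cannot parse MLS distribution {dist!r}")


def _largest_remainder_split(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda j: (raw[j] - counts[j], -j), reverse=True)
    for j in order[:rem]:
        counts[j] += 1
    return counts


def build_dataset(
    n_patients: int,
    mls_distribution="uniform:0,15",
    type_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    scans_per_patient: int = 1,
    render_voxels: bool = True,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    **phantom_kwargs,
) -> dict[str, list[LabeledScan]]:
    """Generate a patient-disjoint stratified train/valid/test phantom cohort.

    Patients are assigned a lesion class according to ``type_mix`` (uniform
    over the six hemorrhage classes by default) and, within each class, split
    into train/validation/test at ``ratios`` (default 8:1:1) by
    largest-remainder rounding. All scans of a patient land in the same
    partition. A class with fewer than 3 patients is assigned entirely to
    train, with a warning. Deterministic under ``seed``.
    """
    if n_patients < 10:
        raise ValueError("need at least 10 patients for an 8:1:1 split")
    rng = np.random.default_rng(seed)
    sampler = parse_mls_distribution(mls_distribution)
    if type_mix is None:
        type_mix = {t: 1.0 / len(LESION_TYPES) for t in LESION_TYPES}
    labels = list(type_mix)
    fracs = np.array([type_mix[t] for t in labels], dtype=float)
    fracs = fracs / fracs.sum()
    type_counts = _largest_remainder_split(n_patients, fracs)

    patient_types: list[str] = []
    for label, cnt in zip(labels, type_counts):
        patient_types += [label] * cnt
    patient_types = [patient_types[j] for j in rng.permutation(n_patients)]

    partitions: dict[str, list[LabeledScan]] = {"train": [], "valid": [], "test": []}
    part_names = ("train", "valid", "test")
    by_type: dict[str, list[int]] = {}
    for pid, label in enumerate(patient_types):
        by_type.setdefault(label, []).append(pid)

    assignment: dict[int, str] = {}
    for label in labels:
        pids = by_type.get(label, [])
        if not pids:
            continue
        if len(pids) < 3:
            warnings.warn(
                f"lesion type {label!r} has only {len(pids)} patient(s); "
                "assigning all to train"
            )
            for pid in pids:
                assignment[pid] = "train"
            continue
        counts = _largest_remainder_split(len(pids), ratios)
        shuffled = [pids[j] for j in rng.permutation(len(pids))]
        k = 0
        for part, cnt in zip(part_names, counts):
            for pid in shuffled[k : k + cnt]:
                assignment[pid] = part
            k += cnt

    for pid, label in enumerate(patient_types):
        part = assignment[pid]
        for s in range(scans_per_patient):
            spec = PhantomSpec(
                patient_id=f"P{pid:04d}",
                scan_id=f"P{pid:04d}_S{s}",
                true_mls_mm=sampler(rng),
                lesion_type_label=label,
                seed=int(rng.integers(2**31)),
                **phantom_kwargs,
            )
            partitions[part].append(generate_phantom(spec, render_voxels=render_voxels))
    return partitions
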