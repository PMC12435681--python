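"""Class-conditional synthetic IHC and H&E patch generator.

HER2 scoring of immunohistochemistry (IHC) patches follows three visual
factors: the fraction of positive tumour cells, the intensity of the brown
DAB membrane stain, and the completeness of each cell's membrane ring.
The generator encodes exactly these factors: patches show blue hematoxylin
nuclei on a pale background, and a score-dependent fraction of cells carry
brown elliptical ring arcs of score-dependent intensity and arc fraction.
The union of ring pixels is returned as a ground-truth mask for
localization scoring.  H&E patches show purple nuclei and pink cytoplasm;
their class signal is deliberately subtler (nucleus density and size scale
with score, no brown channel), emulating the fact that HER2 status is not
directly visible in routine H&E stains.

Each synthetic patient owns one HER2 score and one style offset (small hue
rotation and brightness shift applied to every patch), which creates the
patient-identity signal that separates random from subject-wise splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import ellipse

__all__ = [
    "ClassProfile", "DEFAULT_PROFILES", "PatientStyle", "SplitResult",
    "generate_patch", "generate_cohort", "load_cohort",
    "split_random", "split_subjectwise",
]

SCORES = ("0", "1+", "2+", "3+")


@dataclass(frozen=True)
class ClassProfile:
    her2_score: str
    positive_cell_fraction: float
    membrane_intensity: float
    membrane_completeness: float

    def __post_init__(self):
        for v in (self.positive_cell_fraction, self.membrane_intensity,
                  self.membrane_completeness):
            if not 0 <= v <= 1:
                raise ValueError("profile factors must be in [0, 1]")


# Qualitative encoding of the clinical scoring factors: fraction of positive
# cells, stain intensity, membrane completeness, all non-decreasing in score.
DEFAULT_PROFILES = {
    "0": ClassProfile("0", 0.02, 0.05, 0.10),
    "1+": ClassProfile("1+", 0.30, 0.30, 0.40),
    "2+": ClassProfile("2+", 0.50, 0.50, 0.90),
    "3+": ClassProfile("3+", 0.70, 0.90, 1.00),
}

_BACKGROUND_IHC = np.array([0.93, 0.91, 0.94])
_NUCLEUS_IHC = np.array([0.32, 0.34, 0.64])
_DAB_BROWN = np.array([0.42, 0.24, 0.09])
_BACKGROUND_HE = np.array([0.95, 0.90, 0.93])
_NUCLEUS_HE = np.array([0.45, 0.27, 0.58])
_CYTOPLASM_HE = np.array([0.91, 0.65, 0.76])


@dataclass(frozen=True)
class PatientStyle:
    hue_shift: float = 0.0
    brightness: float = 0.0

    @classmethod
    def sample(cls, rng, hue_range: float = 0.05,
               brightness_range: float = 0.08) -> "PatientStyle":
        return cls(hue_shift=float(rng.uniform(-hue_range, hue_range)),
                   brightness=float(rng.uniform(-brightness_range, brightness_range)))


def _place_cells(size, n_target, r_lo, r_hi, rng, max_tries=400):
    """Rejection-sample non-overlapping ellipse centres/radii."""
    cells = []
    tries = 0
    while len(cells) < n_target and tries < max_tries:
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        margin = 1.6 * r
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (1.45 * (r + rr)) ** 2
               for y, x, rr, _ in cells):
            cells.append((cy, cx, r, rng.uniform(0.75, 1.3)))
    return cells


def _ring_arc(cy, cx, r_in, r_out, aspect, completeness, phase, shape):
    """Pixel coordinates of an elliptical ring arc."""
    oy, ox = ellipse(cy, cx, r_out, r_out * aspect, shape=shape)
    iy, ix = ellipse(cy, cx, r_in, r_in * aspect, shape=shape)
    ring = np.zeros(shape, dtype=bool)
    ring[oy, ox] = True
    ring[iy, ix] = False
    ys, xs = np.nonzero(ring)
    if completeness < 1.0:
        ang = (np.arctan2(ys - cy, (xs - cx) / aspect) - phase) % (2 * np.pi)
        keep = ang <= 2 * np.pi * completeness
        ys, xs = ys[keep], xs[keep]
    return ys, xs


def generate_patch(profile: ClassProfile, stain: str, size: int,
                   patient_style: PatientStyle, rng):
    """One synthetic patch.  Returns ``(image, mask)`` with image an
    (size, size, 3) float RGB array in [0, 1] and mask the boolean union of
    membrane-ring pixels (all-False for H&E)."""
    stain = stain.upper().replace("&", "")
    if stain not in ("IHC", "HE"):
        raise ValueError(f"unknown stain {stain!r}; use 'IHC' or 'HE'")
    if size < 64:
        raise ValueError("patch size must be at least 64 pixels")

    score_idx = SCORES.index(profile.her2_score)
    shape = (size, size)
    bg = _BACKGROUND_IHC if stain == "IHC" else _BACKGROUND_HE
    img = bg[None, None, :] + rng.normal(0, 0.015, (size, size, 3))
    mask = np.zeros(shape, dtype=bool)

    density = 1.0 if stain == "IHC" else 1.0 + 0.25 * score_idx
    n_cells = max(int(10 * density * (size / 128.0) ** 2), 3)
    r_scale = 1.0 if stain == "IHC" else 1.0 + 0.08 * score_idx
    r_lo, r_hi = 0.045 * size * r_scale, 0.07 * size * r_scale
    cells = _place_cells(size, n_cells, r_lo, r_hi, rng)
    if not cells:
        raise ValueError(f"patch size {size} too small to place a cell")

    for cy, cx, r, aspect in cells:
        if stain == "HE":
            yy, xx = ellipse(cy, cx, 1.8 * r, 1.8 * r * aspect, shape=shape)
            img[yy, xx] = 0.65 * img[yy, xx] + 0.35 * _CYTOPLASM_HE
        nucleus = _NUCLEUS_IHC if stain == "IHC" else _NUCLEUS_HE
        jitter = rng.normal(0, 0.03, 3)
        yy, xx = ellipse(cy, cx, r, r * aspect, shape=shape)
        img[yy, xx] = np.clip(nucleus + jitter, 0, 1)
        if stain == "IHC" and rng.random() < profile.positive_cell_fraction:
            intensity = np.clip(
                profile.membrane_intensity * rng.uniform(0.85, 1.15), 0, 1)
            completeness = np.clip(
                profile.membrane_completeness * rng.uniform(0.9, 1.1), 0, 1)
            ys, xs = _ring_arc(cy, cx, 1.05 * r, 1.45 * r, aspect,
                               completeness, rng.uniform(0, 2 * np.pi), shape)
            img[ys, xs] = (1 - intensity) * img[ys, xs] + intensity * _DAB_BROWN
            mask[ys, xs] = True

    img = np.clip(img, 0, 1)
    if patient_style.hue_shift or patient_style.brightness:
        hsv = rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + patient_style.hue_shift) % 1.0
        hsv[..., 2] = np.clip(hsv[..., 2] + patient_style.brightness, 0, 1)
        img = hsv2rgb(hsv)
    return img.astype(np.float32), mask


def _patients_per_class(n_patients: int, class_mix: dict) -> list[str]:
    total = sum(class_mix.values())
    if total <= 0 or any(v < 0 for v in class_mix.values()):
        raise ValueError("class_mix proportions must be non-negative with a positive sum")
    if n_patients < len(class_mix):
        raise ValueError("need at least one patient per class in class_mix")
    quotas = {s: n_patients * v / total for s, v in class_mix.items()}
    counts = {s: max(int(np.floor(q)), 1) for s, q in quotas.items()}
    while sum(counts.values()) > n_patients:
        s = max(counts, key=lambda s: counts[s] - quotas[s])
        if counts[s] == 1:
            raise ValueError("class_mix incompatible with the patient count")
        counts[s] -= 1
    rema = sorted(class_mix, key=lambda s: quotas[s] - counts[s], reverse=True)
    i = 0
    while sum(counts.values()) < n_patients:
        counts[rema[i % len(rema)]] += 1
        i += 1
    out = []
    for s in class_mix:
        out.extend([s] * counts[s])
    return out


def generate_cohort(n_patients: int, patches_per_patient: int, stain: str,
                    class_mix: dict | None = None, seed: int = 0,
                    size: int = 128, out_dir=None,
                    profiles: dict | None = None,
                    style_hue_range: float = 0.05,
                    style_brightness_range: float = 0.08):
    """A cohort of synthetic patients, each with one HER2 score and one
    style offset shared by all their patches.

    Returns ``(manifest, images, masks)``: a DataFrame with columns
    (path, patient_id, stain, her2_score, mask_path, style_seed), an
    (N, size, size, 3) float32 image array and an (N, size, size) boolean
    mask array, in manifest order.  When ``out_dir`` is given, PNG images,
    single-channel PNG masks and ``manifest.csv`` are also written.
    """
    profiles = profiles or DEFAULT_PROFILES
    class_mix = class_mix or {s: 1.0 for s in SCORES}
    rng = np.random.default_rng(seed)
    scores = _patients_per_class(n_patients, class_mix)

    records, images, masks = [], [], []
    for p_idx, score in enumerate(scores):
        patient = f"P{p_idx:03d}"
        style = PatientStyle.sample(rng, style_hue_range, style_brightness_range)
        style_seed = int(rng.integers(0, 2**31 - 1))
        for k in range(patches_per_patient):
            img, mask = generate_patch(profiles[score], stain, size, style, rng)
            images.append(img)
            masks.append(mask)
            records.append({
                "path": f"{patient}_{k:02d}.png",
                "patient_id": patient,
                "stain": stain.upper().replace("&", ""),
                "her2_score": score,
                "mask_path": f"{patient}_{k:02d}_mask.png" if stain.upper().startswith("I") else "",
                "style_seed": style_seed,
            })
    manifest = pd.DataFrame(records)
    images = np.stack(images)
    masks = np.stack(masks)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, img, mask in zip(records, images, masks):
            iio.imwrite(out_dir / rec["path"], (img * 255).astype(np.uint8))
            if rec["mask_path"]:
                iio.imwrite(out_dir / rec["mask_path"],
                            (mask * 255).astype(np.uint8))
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, images, masks


def load_cohort(manifest_path):
    """Read a cohort written by :func:`generate_cohort` back from disk."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    root = manifest_path.parent
    images = np.stack([
        np.asarray(iio.imread(root / p), dtype=np.float32) / 255.0
        for p in manifest["path"]
    ])
    masks = np.stack([
        (np.asarray(iio.imread(root / p)) > 127) if p else
        np.zeros(images.shape[1:3], dtype=bool)
        for p in manifest["mask_path"]
    ])
    return manifest, images, masks


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    mode: str

    def tag(self, manifest: pd.DataFrame) -> pd.DataFrame:
        out = manifest.copy()
        out["split"] = "train"
        out.loc[out.index[self.test_idx], "split"] = "test"
        return out


def _check_fraction(test_fraction):
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")


def split_random(manifest: pd.DataFrame, test_fraction: float,
                 seed: int = 0) -> SplitResult:
    """Patch-level split, stratified by HER2 score; patients may contribute
    to both sides (the leakage-prone protocol)."""
    from sklearn.model_selection import train_test_split

    _check_fraction(test_fraction)
    idx = np.arange(len(manifest))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=manifest["her2_score"])
    return SplitResult(np.sort(train_idx), np.sort(test_idx), "random")


def split_subjectwise(manifest: pd.DataFrame, test_fraction: float,
                      seed: int = 0) -> SplitResult:
    """Patient-level split: whole patients go to train or test,
    class-stratified over patients with largest-remainder rounding so the
    test set holds ``round(test_fraction * n_patients)`` patients."""
    _check_fraction(test_fraction)
    rng = np.random.default_rng(seed)
    by_patient = manifest.groupby("patient_id")["her2_score"].first()
    classes = sorted(by_patient.unique())
    n_total = len(by_patient)
    n_test_total = int(round(test_fraction * n_total))
    if n_test_total < len(classes):
        raise ValueError(
            f"test_fraction {test_fraction} yields {n_test_total} test patients, "
            f"fewer than the {len(classes)} classes to stratify over")
    quotas, floors = {}, {}
    for c in classes:
        pats = by_patient[by_patient == c]
        if len(pats) < 2:
            raise ValueError(f"class {c!r} has {len(pats)} patient(s); "
                             "need at least 2 for a subject-wise split")
        quotas[c] = test_fraction * len(pats)
        floors[c] = min(max(int(np.floor(quotas[c])), 1), len(pats) - 1)
    while sum(floors.values()) < n_test_total:
        cand = [c for c in classes
                if floors[c] < len(by_patient[by_patient == c]) - 1]
        c = max(cand, key=lambda c: quotas[c] - floors[c])
        floors[c] += 1
    while sum(floors.values()) > n_test_total:
        c = max(classes, key=lambda c: floors[c] - quotas[c])
        if floors[c] <= 1:
            raise ValueError("cannot satisfy the test fraction with at least "
                             "one test patient per class")
        floors[c] -= 1
    test_patients = set()
    for c in classes:
        pats = list(by_patient[by_patient == c].index)
        test_patients.update(rng.choice(pats, size=floors[c], replace=False))
    is_test = manifest["patient_id"].isin(test_patients).to_numpy()
    return SplitResult(np.nonzero(~is_test)[0], np.nonzero(is_test)[0],
                       "subject_wise")
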