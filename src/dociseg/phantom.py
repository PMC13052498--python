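"""Seeded generator of synthetic multichannel-autofluorescence cohorts.

The phantom emulates the statistical structure the analysis pipeline assumes:
per-specimen H×W×C voxel stacks whose pixels draw from class-dependent
spectral signatures, an irregular contiguous tissue region on a dark
background, tumor-dominant lesions (one main blob plus satellites, as in
resected nodule sections), patient grouping, and class-aware split assignment
with no (patient, class) leakage across splits.

Class signatures are Gaussian bumps in channel-index space over a common
baseline: normal centered at C/4, follicular at C/2, papillary at 3C/4, with
bump amplitude equal to ``signature_separation``.  The "atypical"
(anaplastic-like) class is a per-pixel random mixture of the follicular and
papillary signatures with elevated within-slide variance.  This is a
statistical stand-in, not a model of autofluorescence-decay physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label

from .voxelio import (
    BinaryMask,
    VoxelStack,
    assign_splits,
    read_mask_tiff,
    read_metadata,
    read_stack_tiff,
    write_mask_tiff,
    write_metadata,
    write_stack_tiff,
)

CLASSES = ("normal", "follicular", "papillary", "atypical")
TUMOR_CLASSES = ("follicular", "papillary", "atypical")


@dataclass
class PhantomConfig:
    """Cohort-level generation parameters.

    ``class_mix`` gives proportions over the four diagnostic classes;
    ``signature_separation`` is the spectral distance (bump amplitude) between
    class mean signatures, ``noise_sd`` the per-channel i.i.d. noise level and
    ``tumor_fraction_range`` the fraction of tissue occupied by tumor.
    """

    n_patients: int = 16
    slides_per_patient: int = 1
    height: int = 64
    width: int = 64
    n_channels: int = 8
    class_mix: dict = field(
        default_factory=lambda: {
            "normal": 0.4, "follicular": 0.3, "papillary": 0.3, "atypical": 0.0,
        }
    )
    signature_separation: float = 4.0
    noise_sd: float = 0.5
    tumor_fraction_range: tuple[float, float] = (0.45, 0.75)
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_patients < 1 or self.slides_per_patient < 1:
            raise ValueError("n_patients and slides_per_patient must be >= 1")
        mix = {c: float(self.class_mix.get(c, 0.0)) for c in CLASSES}
        extra = set(self.class_mix) - set(CLASSES)
        if extra:
            raise ValueError(f"unknown classes in class_mix: {sorted(extra)}")
        if any(v < 0 for v in mix.values()) or not np.isclose(sum(mix.values()), 1.0):
            raise ValueError("class_mix proportions must be nonnegative and sum to 1")
        self.class_mix = mix
        lo, hi = self.tumor_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("tumor_fraction_range must lie inside (0, 1)")
        if self.signature_separation < 0 or self.noise_sd < 0:
            raise ValueError("signature_separation and noise_sd must be >= 0")


@dataclass
class PhantomSpecimen:
    specimen_id: str
    patient_id: str
    true_class: str
    voxels: VoxelStack
    tissue_mask: BinaryMask
    tumor_mask: BinaryMask
    split: str = ""

    def __post_init__(self):
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if np.any(self.tumor_mask.data & ~self.tissue_mask.data.astype(bool)):
            raise ValueError("tumor_mask must be a subset of tissue_mask")
        has_tumor = bool(self.tumor_mask.data.any())
        if has_tumor == (self.true_class == "normal"):
            raise ValueError("tumor_mask must be empty iff true_class is 'normal'")
        if np.any(self.voxels.data < 0):
            raise ValueError("voxels must be nonnegative")


_BASELINE = 1.0
_BACKGROUND = 0.1


def _signature_centers(n_channels: int) -> dict[str, float]:
    c = n_channels
    return {"normal": c / 4.0, "follicular": c / 2.0, "papillary": 3.0 * c / 4.0}


def class_mean_signature(config: PhantomConfig, cls: str) -> np.ndarray:
    """Generative mean spectrum of a class (atypical = equal F/P mixture mean)."""
    c = config.n_channels
    ch = np.arange(c, dtype=float)
    width = max(c / 12.0, 0.6)
    centers = _signature_centers(c)

    def bump(center):
        return _BASELINE + config.signature_separation * np.exp(
            -((ch - center) ** 2) / (2.0 * width**2)
        )

    if cls == "atypical":
        return 0.5 * (bump(centers["follicular"]) + bump(centers["papillary"]))
    if cls not in centers:
        raise ValueError(f"unknown class {cls!r}")
    return bump(centers[cls])


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _make_tissue_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
    ry = h * rng.uniform(0.40, 0.48)
    rx = w * rng.uniform(0.40, 0.48)
    r = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    perturb = 0.15 * _smooth_field(rng, h, w, sigma=max(h, w) / 8.0)
    return (r < 1.0 + perturb).astype(np.uint8)


def _make_tumor_mask(
    rng: np.random.Generator, tissue: np.ndarray, frac: float
) -> np.ndarray:
    """Threshold a low-pass random field inside tissue to get 1-3 blobs."""
    h, w = tissue.shape
    g = _smooth_field(rng, h, w, sigma=max(h, w) / 6.0)
    vals = g[tissue.astype(bool)]
    thr = np.quantile(vals, 1.0 - frac)
    cand = (g >= thr) & tissue.astype(bool)
    lab, n = cc_label(cand, return_num=True, connectivity=1)
    if n == 0:  # degenerate tiny tissue; seed a single pixel blob
        idx = np.argwhere(tissue)[0]
        out = np.zeros_like(tissue)
        out[idx[0], idx[1]] = 1
        return out
    sizes = np.bincount(lab.ravel())[1:]
    keep = np.argsort(-sizes)[:3] + 1
    return np.isin(lab, keep).astype(np.uint8)


def _generate_specimen(
    config: PhantomConfig, index: int, specimen_id: str, patient_id: str, cls: str
) -> PhantomSpecimen:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    h, w, c = config.height, config.width, config.n_channels
    tissue = _make_tissue_mask(rng, h, w)
    if cls == "normal":
        tumor = np.zeros((h, w), dtype=np.uint8)
    else:
        frac = rng.uniform(*config.tumor_fraction_range)
        tumor = _make_tumor_mask(rng, tissue, frac)

    vox = np.full((h, w, c), _BACKGROUND)
    normal_sig = class_mean_signature(config, "normal")
    tis = tissue.astype(bool)
    vox[tis] = normal_sig
    tum = tumor.astype(bool)
    if cls == "atypical":
        # per-pixel random follicular/papillary mixture, extra heterogeneity
        sig_f = class_mean_signature(config, "follicular")
        sig_p = class_mean_signature(config, "papillary")
        lam = rng.uniform(0.2, 0.8, size=int(tum.sum()))[:, None]
        vox[tum] = lam * sig_f + (1 - lam) * sig_p
        noise_scale = np.where(tum[..., None], 1.8, 1.0)
    elif cls != "normal":
        vox[tum] = class_mean_signature(config, cls)
        noise_scale = 1.0
    else:
        noise_scale = 1.0
    vox = vox + rng.standard_normal((h, w, c)) * config.noise_sd * noise_scale
    vox = np.clip(vox, 0.0, None)

    stack = VoxelStack(
        vox, [f"DOCI-{i + 1}" for i in range(c)], specimen_id=specimen_id
    )
    return PhantomSpecimen(
        specimen_id=specimen_id,
        patient_id=patient_id,
        true_class=cls,
        voxels=stack,
        tissue_mask=BinaryMask(tissue, role="tissue"),
        tumor_mask=BinaryMask(tumor, role="tumor"),
    )


def _patient_classes(config: PhantomConfig) -> list[str]:
    """Deterministic largest-remainder allocation of classes to patients."""
    n = config.n_patients
    props = np.array([config.class_mix[c] for c in CLASSES])
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    classes = [c for c, k in zip(CLASSES, counts) for _ in range(k)]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10**6]))
    rng.shuffle(classes)
    return classes


def generate_cohort(config: PhantomConfig) -> list[PhantomSpecimen]:
    """Generate a seeded synthetic cohort with class-aware split assignment.

    Deterministic given ``config.seed``; each specimen uses its own RNG stream
    derived from (seed, specimen index).  Raises if any represented class has
    too few patients to populate the requested splits.
    """
    classes = _patient_classes(config)
    n_splits = int(np.count_nonzero(np.asarray(config.split_fractions) > 0))
    counts = pd.Series(classes).value_counts()
    for cls, k in counts.items():
        if k < n_splits:
            raise ValueError(
                f"class {cls!r} has {k} patient(s) but {n_splits} splits are "
                "requested; increase n_patients or adjust class_mix"
            )
    specimens: list[PhantomSpecimen] = []
    index = 0
    for p, cls in enumerate(classes):
        patient_id = f"P{p:03d}"
        for s in range(config.slides_per_patient):
            sid = f"S{index:04d}"
            specimens.append(
                _generate_specimen(config, index, sid, patient_id, cls)
            )
            index += 1
    meta = cohort_metadata(specimens)
    splits = assign_splits(meta, config.split_fractions, seed=config.seed)
    for spec, sp in zip(specimens, splits):
        spec.split = sp
    return specimens


def cohort_metadata(specimens: list[PhantomSpecimen]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in specimens],
            "patient_id": [s.patient_id for s in specimens],
            "class": [s.true_class for s in specimens],
            "split": [s.split for s in specimens],
        }
    )


def write_cohort(out_dir: str | Path, specimens: list[PhantomSpecimen]) -> None:
    """Write a cohort to disk: per-specimen TIFFs plus a metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in specimens:
        write_stack_tiff(out / f"{s.specimen_id}_voxels.tiff", s.voxels)
        write_mask_tiff(out / f"{s.specimen_id}_tissue.tiff", s.tissue_mask)
        write_mask_tiff(out / f"{s.specimen_id}_tumor.tiff", s.tumor_mask)
    write_metadata(out / "metadata.csv", cohort_metadata(specimens))


def read_cohort(in_dir: str | Path) -> list[PhantomSpecimen]:
    src = Path(in_dir)
    meta = read_metadata(src / "metadata.csv")
    specimens = []
    for _, row in meta.iterrows():
        sid = row["specimen_id"]
        specimens.append(
            PhantomSpecimen(
                specimen_id=sid,
                patient_id=row["patient_id"],
                true_class=row["class"],
                voxels=read_stack_tiff(src / f"{sid}_voxels.tiff", specimen_id=sid),
                tissue_mask=read_mask_tiff(src / f"{sid}_tissue.tiff", role="tissue"),
                tumor_mask=read_mask_tiff(src / f"{sid}_tumor.tiff", role="tumor"),
                split=row["split"],
            )
        )
    return specimens
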