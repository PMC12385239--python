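"""Seeded synthetic blood-smear image generator with ground-truth nucleus masks.

Real peripheral-blood-smear benchmarks (the four-class ALL-subtype set and
the binary blast-vs-normal C-NMC set) are external downloads; this module
emulates their structure so the full pipeline — balancing, training,
cross-validation and explanation-quality scoring — is exercisable offline.
Each image is a single leukocyte: a pale cytoplasm ellipse over a smear
background, with a stained nucleus disc whose size, chromatin speckle and
hue depend on the class.  The nucleus mask is returned exactly as drawn,
which is what makes attribution-localization metrics (IoU against the
nucleus) well defined.

Class morphology follows classic cytology cues: blast-like classes get a
larger nucleus (higher nucleus-to-cytoplasm ratio) and coarser chromatin.
The per-class parameter values are free choices of this package, not
estimates of the real datasets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image

__all__ = [
    "CellParams", "MorphologyDistribution", "DatasetSpec",
    "render_cell", "generate_dataset",
    "all_style_spec", "cnmc_style_spec", "desk_spec",
]


@dataclass(frozen=True)
class CellParams:
    """Morphology of one rendered cell.

    nucleus_radius_frac : nucleus radius as a fraction of the image side,
        in [0, 0.5); 0 renders no nucleus (empty mask).
    chromatin_granularity : amplitude of the speckle noise inside the
        nucleus (0 = perfectly smooth chromatin).
    nc_ratio : nucleus-to-cytoplasm area ratio proxy in (0, 1]; sets the
        cytoplasm ellipse area to nucleus_area / nc_ratio.
    stain_hue : base hue of the nuclear stain in [0, 1] (HSV wheel).
    background_level : smear background brightness in [0, 1].
    """

    nucleus_radius_frac: float = 0.2
    chromatin_granularity: float = 0.05
    nc_ratio: float = 0.5
    stain_hue: float = 0.7
    background_level: float = 0.9

    def validate(self) -> None:
        if not 0.0 <= self.nucleus_radius_frac < 0.5:
            raise ValueError(
                f"nucleus_radius_frac must be in [0, 0.5), got {self.nucleus_radius_frac}")
        if self.chromatin_granularity < 0:
            raise ValueError(
                f"chromatin_granularity must be >= 0, got {self.chromatin_granularity}")
        if not 0.0 < self.nc_ratio <= 1.0:
            raise ValueError(f"nc_ratio must be in (0, 1], got {self.nc_ratio}")
        if not 0.0 <= self.stain_hue <= 1.0:
            raise ValueError(f"stain_hue must be in [0, 1], got {self.stain_hue}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError(
                f"background_level must be in [0, 1], got {self.background_level}")


@dataclass(frozen=True)
class MorphologyDistribution:
    """Mean cell parameters for a class plus a relative jitter per field."""

    mean: CellParams
    rel_spread: float = 0.08   # multiplicative jitter on radius/granularity/ratio

    def sample(self, rng: np.random.Generator) -> CellParams:
        m = self.mean

        def jitter(v: float, lo: float, hi: float) -> float:
            return float(np.clip(v * (1.0 + self.rel_spread * rng.standard_normal()),
                                 lo, hi))

        p = CellParams(
            nucleus_radius_frac=jitter(m.nucleus_radius_frac, 0.0, 0.499),
            chromatin_granularity=jitter(m.chromatin_granularity, 0.0, 1.0),
            nc_ratio=jitter(m.nc_ratio, 1e-3, 1.0),
            stain_hue=float(np.clip(m.stain_hue + 0.02 * rng.standard_normal(), 0, 1)),
            background_level=float(np.clip(
                m.background_level + 0.03 * rng.standard_normal(), 0, 1)),
        )
        p.validate()
        return p


@dataclass
class DatasetSpec:
    """Recipe for a synthetic dataset: classes, counts, morphology, seed."""

    class_names: list[str]
    counts: dict[str, int]
    image_side: int = 64
    class_morphology: dict[str, MorphologyDistribution] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")
        for c in self.class_names:
            if self.counts.get(c, 0) < 1:
                raise ValueError(f"count for class {c!r} must be >= 1")
        if self.image_side < 16:
            raise ValueError("image_side must be >= 16")


def _disc_mask(side: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def render_cell(params: CellParams, side: int, seed: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell image and its exact nucleus mask.

    Returns ``(image, mask)`` with image shape (side, side, 3) in [0, 1] and a
    boolean mask of the nucleus pixels.  Deterministic in (params, side, seed).
    """
    params.validate()
    if side < 16:
        raise ValueError("side must be >= 16")
    rng = np.random.default_rng(seed)

    # smear background: pale pink with mild low-frequency texture
    base = np.array(hsv_to_rgb([0.95, 0.08, params.background_level]))
    img = np.broadcast_to(base, (side, side, 3)).copy()
    img += 0.02 * rng.standard_normal((side, side, 1))

    r_nuc = params.nucleus_radius_frac * side
    margin = max(2.0, 0.05 * side)
    centre_jitter = 0.05 * side
    lim = side / 2 - r_nuc - margin
    jit = min(centre_jitter, max(lim, 0.0))
    cy = side / 2 + rng.uniform(-jit, jit)
    cx = side / 2 + rng.uniform(-jit, jit)

    # cytoplasm ellipse: area = nucleus area / nc_ratio (capped to the frame)
    if r_nuc > 0:
        r_cyt = min(r_nuc / np.sqrt(params.nc_ratio), side / 2 - 1)
    else:
        r_cyt = 0.3 * side
    ecc = rng.uniform(0.8, 1.25)
    yy, xx = np.mgrid[0:side, 0:side]
    cyt = ((yy - cy) / (r_cyt * ecc)) ** 2 + ((xx - cx) / (r_cyt / ecc)) ** 2 <= 1.0
    cyt_col = np.array(hsv_to_rgb([params.stain_hue, 0.15, 0.85]))
    img[cyt] = 0.25 * img[cyt] + 0.75 * cyt_col

    # nucleus disc with chromatin speckle
    if r_nuc > 0:
        mask = _disc_mask(side, cy, cx, r_nuc)
    else:
        mask = np.zeros((side, side), dtype=bool)
    if mask.any():
        nuc_col = np.array(hsv_to_rgb([params.stain_hue, 0.75, 0.45]))
        img[mask] = nuc_col
        speckle = params.chromatin_granularity * rng.standard_normal((side, side))
        for ch, w in zip(range(3), (0.6, 0.4, 1.0)):   # stain-dependent speckle
            img[..., ch][mask] += w * speckle[mask]

    return np.clip(img, 0.0, 1.0), mask


# -- preset morphologies ------------------------------------------------------

def _dist(radius, granularity, nc, hue) -> MorphologyDistribution:
    return MorphologyDistribution(CellParams(
        nucleus_radius_frac=radius, chromatin_granularity=granularity,
        nc_ratio=nc, stain_hue=hue))


#: Four maturation-stage classes in the style of the ALL-subtype benchmark.
#: Benign cells: small smooth nucleus, low N:C ratio; progressively more
#: blast-like classes get larger nuclei and coarser chromatin.
ALL_STYLE_MORPHOLOGY: dict[str, MorphologyDistribution] = {
    "Benign": _dist(0.12, 0.02, 0.30, 0.78),
    "Early": _dist(0.20, 0.05, 0.50, 0.72),
    "Pre": _dist(0.28, 0.08, 0.65, 0.66),
    "Pro": _dist(0.36, 0.12, 0.80, 0.60),
}

#: Binary blast-vs-normal classes in the style of C-NMC.
CNMC_STYLE_MORPHOLOGY: dict[str, MorphologyDistribution] = {
    "hem": _dist(0.14, 0.02, 0.35, 0.76),
    "all": _dist(0.32, 0.10, 0.75, 0.62),
}

#: Class counts of the real four-class ALL-subtype dataset (3256 images).
ALL_STYLE_COUNTS = {"Benign": 504, "Early": 985, "Pre": 963, "Pro": 804}
#: Class counts of the real binary C-NMC dataset.
CNMC_STYLE_COUNTS = {"hem": 3389, "all": 7272}


def all_style_spec(image_side: int = 64, seed: int = 0,
                   counts: dict[str, int] | None = None) -> DatasetSpec:
    counts = dict(counts or ALL_STYLE_COUNTS)
    return DatasetSpec(class_names=list(ALL_STYLE_MORPHOLOGY), counts=counts,
                       image_side=image_side,
                       class_morphology=dict(ALL_STYLE_MORPHOLOGY), seed=seed)


def cnmc_style_spec(image_side: int = 64, seed: int = 0,
                    counts: dict[str, int] | None = None) -> DatasetSpec:
    counts = dict(counts or CNMC_STYLE_COUNTS)
    return DatasetSpec(class_names=list(CNMC_STYLE_MORPHOLOGY), counts=counts,
                       image_side=image_side,
                       class_morphology=dict(CNMC_STYLE_MORPHOLOGY), seed=seed)


def desk_spec(per_class: int = 200, image_side: int = 64, seed: int = 0) -> DatasetSpec:
    """Desk-scale four-class set (default 200 images/class at 64 px)."""
    return all_style_spec(image_side=image_side, seed=seed,
                          counts={c: per_class for c in ALL_STYLE_MORPHOLOGY})


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray((np.clip(arr, 0, 1) * 255).round().astype(np.uint8)).save(path)


def generate_dataset(spec: DatasetSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the dataset to disk and return its manifest.

    Layout: ``<out_dir>/<class>/<class>_<idx>.png`` with nucleus masks under
    ``<out_dir>/masks/``.  Manifest columns: path, label, is_synthetic,
    mask_path.  One RNG stream per image keyed by (seed, class index, image
    index), so generation order cannot change pixel content.
    """
    spec.validate()
    out_dir = Path(out_dir)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cname in enumerate(spec.class_names):
        cdir = out_dir / cname
        cdir.mkdir(parents=True, exist_ok=True)
        morph = spec.class_morphology.get(
            cname, MorphologyDistribution(CellParams()))
        for idx in range(spec.counts[cname]):
            rng = np.random.default_rng((spec.seed, ci, idx))
            params = morph.sample(rng)
            pix_seed = int(rng.integers(0, 2 ** 31))
            img, mask = render_cell(params, spec.image_side, pix_seed)
            img_path = cdir / f"{cname}_{idx}.png"
            mask_path = out_dir / "masks" / f"{cname}_{idx}_mask.png"
            _save_png(img, img_path)
            _save_png(mask.astype(float), mask_path)
            rows.append({"path": str(img_path), "label": cname,
                         "is_synthetic": False, "mask_path": str(mask_path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def manifest_hash(manifest: pd.DataFrame) -> str:
    """Stable content hash of a manifest (paths relativized columnwise)."""
    payload = manifest.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
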