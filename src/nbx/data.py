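"""Manifest I/O, class-aware augmentation balancing, resizing, label encoding.

The unit of dataset handling is the *manifest*: a DataFrame with columns
``path, label, is_synthetic, mask_path`` (augment-parameter columns are
appended for synthesized rows).  Class imbalance is removed by oversampling
every minority class with randomized augmentations (rotation up to ±30°,
zoom up to ±20%, horizontal flip, brightness 80–120%) until it matches the
majority class — e.g. a 504/963/804/985 four-class set gains 481/22/181/0
synthetic images for a balanced total of 3940, and a 3389/7272 binary set
gains 3883 for a total of 14544.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from sklearn.preprocessing import LabelEncoder

__all__ = [
    "MANIFEST_COLUMNS", "AugmentPlan", "AugmentParams",
    "load_manifest", "save_manifest", "class_counts",
    "plan_balance", "augment_image", "apply_balance",
    "load_image", "encode_labels",
]

MANIFEST_COLUMNS = ["path", "label", "is_synthetic", "mask_path"]


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    if "is_synthetic" in df.columns:
        df["is_synthetic"] = df["is_synthetic"].astype(str).str.lower().isin(
            ["true", "1"])
    else:
        df["is_synthetic"] = False
    if "mask_path" not in df.columns:
        df["mask_path"] = ""
    missing = [c for c in ("path", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if df["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    return df


def save_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def class_counts(manifest: pd.DataFrame) -> dict[str, int]:
    return manifest["label"].value_counts().to_dict()


@dataclass(frozen=True)
class AugmentPlan:
    """How many synthetic images each class needs to reach the majority count."""

    target_count: int
    per_class_deficit: dict[str, int]

    @property
    def total_added(self) -> int:
        return int(sum(self.per_class_deficit.values()))


def plan_balance(counts: dict[str, int]) -> AugmentPlan:
    """Oversampling plan: every class is raised to the majority-class count."""
    if not counts:
        raise ValueError("class count map is empty")
    for c, n in counts.items():
        if n < 1:
            raise ValueError(f"class {c!r} has count {n}; counts must be >= 1")
    target = max(counts.values())
    deficits = {c: target - n for c, n in counts.items()}
    return AugmentPlan(target_count=target, per_class_deficit=deficits)


@dataclass(frozen=True)
class AugmentParams:
    """One randomized augmentation draw.

    Ranges follow the balancing protocol: rotation ±30°, zoom ±20%,
    optional horizontal flip, multiplicative brightness 0.8–1.2.
    """

    rotation_deg: float = 0.0
    zoom_frac: float = 0.0
    hflip: bool = False
    brightness_factor: float = 1.0

    def validate(self) -> None:
        if not -30.0 <= self.rotation_deg <= 30.0:
            raise ValueError(f"rotation_deg out of [-30, 30]: {self.rotation_deg}")
        if not -0.2 <= self.zoom_frac <= 0.2:
            raise ValueError(f"zoom_frac out of [-0.2, 0.2]: {self.zoom_frac}")
        if not 0.8 <= self.brightness_factor <= 1.2:
            raise ValueError(
                f"brightness_factor out of [0.8, 1.2]: {self.brightness_factor}")

    @staticmethod
    def sample(rng: np.random.Generator) -> "AugmentParams":
        return AugmentParams(
            rotation_deg=float(rng.uniform(-30, 30)),
            zoom_frac=float(rng.uniform(-0.2, 0.2)),
            hflip=bool(rng.integers(0, 2)),
            brightness_factor=float(rng.uniform(0.8, 1.2)),
        )


def augment_image(image: np.ndarray, p: AugmentParams) -> np.ndarray:
    """Apply one augmentation draw to an (H, W, 3) image in [0, 1].

    Rotation and zoom are about the image centre with reflect padding (no
    black corners for the model to shortcut on); brightness is
    multiplicative; output is clipped back to [0, 1].  Identity parameters
    return the image unchanged.
    """
    p.validate()
    out = np.asarray(image, dtype=np.float64)
    if p.hflip:
        out = out[:, ::-1, :]
    if p.rotation_deg != 0.0:
        out = ndimage.rotate(out, p.rotation_deg, axes=(0, 1), reshape=False,
                             order=1, mode="reflect")
    if p.zoom_frac != 0.0:
        h, w = out.shape[:2]
        scale = 1.0 / (1.0 + p.zoom_frac)      # zoom in for positive fractions
        matrix = np.diag([scale, scale, 1.0])
        offset = [(1 - scale) * (h - 1) / 2, (1 - scale) * (w - 1) / 2, 0.0]
        out = ndimage.affine_transform(out, matrix, offset=offset, order=1,
                                       mode="reflect")
    if p.brightness_factor != 1.0:
        out = out * p.brightness_factor
    return np.clip(out, 0.0, 1.0)


def apply_balance(manifest: pd.DataFrame, plan: AugmentPlan, seed: int,
                  out_dir: str | Path, materialize: bool = True) -> pd.DataFrame:
    """Oversample minority classes per ``plan`` and return the balanced manifest.

    Source images within a class are picked round-robin over a seeded
    shuffle, so every original is used before any repeats.  Each synthetic
    row records its source path and the freshly sampled augment parameters;
    with ``materialize=False`` only the manifest is produced (count-level
    plan mode), otherwise augmented pixels are written under
    ``<out_dir>/<class>/``.
    """
    counts = class_counts(manifest)
    for c, deficit in plan.per_class_deficit.items():
        if c not in counts:
            raise ValueError(f"plan class {c!r} absent from manifest")
        if counts[c] + deficit != plan.target_count:
            raise ValueError(
                f"plan inconsistent for class {c!r}: "
                f"{counts[c]} + {deficit} != {plan.target_count}")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    new_rows = []
    for cname in sorted(plan.per_class_deficit):
        deficit = plan.per_class_deficit[cname]
        if deficit == 0:
            continue
        src = manifest[manifest["label"] == cname].reset_index(drop=True)
        order = rng.permutation(len(src))
        cdir = out_dir / cname
        if materialize:
            cdir.mkdir(parents=True, exist_ok=True)
        for j in range(deficit):
            row = src.iloc[order[j % len(src)]]
            params = AugmentParams.sample(rng)
            new_path = cdir / f"{cname}_aug_{j}.png"
            if materialize:
                img = np.asarray(Image.open(row["path"]).convert("RGB"),
                                 dtype=np.float64) / 255.0
                aug = augment_image(img, params)
                Image.fromarray((aug * 255).round().astype(np.uint8)).save(new_path)
            new_rows.append({
                "path": str(new_path), "label": cname, "is_synthetic": True,
                "mask_path": "", "source_path": row["path"],
                "rotation_deg": params.rotation_deg,
                "zoom_frac": params.zoom_frac, "hflip": params.hflip,
                "brightness_factor": params.brightness_factor,
            })
    if not new_rows:
        return manifest.copy()
    balanced = pd.concat([manifest, pd.DataFrame(new_rows)], ignore_index=True)
    balanced["is_synthetic"] = balanced["is_synthetic"].astype(bool)
    return balanced


def load_image(path: str | Path, side: int = 128) -> np.ndarray:
    """Load an RGB image as a (3, side, side) float array in [0, 1].

    Resizing is bilinear; an already-(side, side) image passes through
    without resampling.
    """
    try:
        img = Image.open(path).convert("RGB")
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if img.size != (side, side):
        img = img.resize((side, side), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float64) / 255.0
    return arr.transpose(2, 0, 1)


def encode_labels(labels, encoder: LabelEncoder | None = None
                  ) -> tuple[np.ndarray, LabelEncoder]:
    """Integer-encode labels in sorted-lexicographic vocabulary order.

    Pass a fitted ``encoder`` to reuse a vocabulary; unseen labels raise.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to encode")
    if encoder is None:
        encoder = LabelEncoder()
        codes = encoder.fit_transform(labels)
    else:
        codes = encoder.transform(labels)
    return np.asarray(codes, dtype=np.int64), encoder
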