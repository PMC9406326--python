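"""Synthetic two-class image datasets and the published fold-metric fixtures.

Two generators emulate the statistical structure of the study data without
any downloads:

* **Lesion-like images** — dermoscopy-style RGB images: a textured skin
  background with one central darker region. Normal (label 0) regions are
  near-elliptical with a smooth boundary and uniform tone; abnormal
  (label 1) regions add boundary irregularity (radial noise), a centroid
  offset (asymmetry) and a multi-tone interior, each scaled by the
  profile's ``separability``. At separability 0 the two class-generating
  distributions are identical.
* **Scalogram-like images** — time-frequency images of heart sounds: pairs
  of low-frequency Gaussian energy blobs (the S1/S2 heart sounds) repeating
  with a beat period; abnormal images add a band of mid-frequency energy
  between the blob pairs (a systolic murmur) with amplitude proportional to
  ``separability``. All content sits in the lower part of the frequency
  axis, mimicking recordings low-pass filtered below ~195 Hz.

Images are 8-bit (values 0..255) and are treated as floating point
downstream. Generation is bit-reproducible given the profile seed.

The module also ships the per-fold metric tables transcribed from the
source study's results (10 folds x 5 metrics for each dataset/structure
pair); summary rows are recomputed from the fold values, never stored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .exceptions import InvalidProfileError
from .training_eval import FoldMetricTable

__all__ = [
    "DatasetProfile",
    "DatasetManifest",
    "generate_lesion_dataset",
    "generate_scalogram_dataset",
    "load_paper_fold_table",
    "lesion_heterogeneity_score",
    "murmur_band_energy",
    "ISIC_LIKE",
    "PH2_LIKE",
    "PASCAL_LIKE",
]

_FIXTURE_PACKAGE = "cvfair.data.fold_tables"
_DATASET_IDS = ("ISIC2017", "PH2", "PASCAL")
_STRUCTURE_IDS = ("complex", "real")

# murmur band extent as fractions of the frequency (row) axis; rows grow
# downward so low frequencies live near the bottom of the image
_MURMUR_ROWS = (0.45, 0.60)
_S1S2_ROWS = (0.70, 0.92)


@dataclass(frozen=True)
class DatasetProfile:
    """Generation recipe for one synthetic two-class dataset."""

    name: str
    n_normal: int
    n_abnormal: int
    image_size: int = 224
    separability: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise InvalidProfileError("class counts must be non-negative")
        if self.image_size < 8:
            raise InvalidProfileError("image_size must be >= 8")
        if not 0.0 <= self.separability <= 1.0:
            raise InvalidProfileError("separability must lie in [0, 1]")


#: Profiles with the class-imbalance ratios of the three study datasets.
ISIC_LIKE = DatasetProfile("isic-like", 1621, 374, 224, 0.8, seed=1)
PH2_LIKE = DatasetProfile("ph2-like", 160, 40, 224, 0.8, seed=1)
PASCAL_LIKE = DatasetProfile("pascal-like", 320, 141, 224, 0.8, seed=1)


@dataclass
class DatasetManifest:
    """Ordered (image, label) records plus the generating profile."""

    records: list
    profile: DatasetProfile

    def __post_init__(self):
        labels = self.labels
        n0, n1 = int(np.sum(labels == 0)), int(np.sum(labels == 1))
        if (n0, n1) != (self.profile.n_normal, self.profile.n_abnormal):
            raise InvalidProfileError(
                f"label counts ({n0}, {n1}) do not match profile "
                f"({self.profile.n_normal}, {self.profile.n_abnormal})"
            )

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.records], dtype=int)

    @property
    def images(self) -> list:
        return [img for img, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def write(self, out_dir) -> Path:
        """Write PNG images, a ``path,label`` CSV manifest and a YAML sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, label) in enumerate(self.records):
            fname = f"{self.profile.name}_{i:05d}.png"
            Image.fromarray(np.asarray(img, dtype=np.uint8)).save(out / fname)
            rows.append((fname, label))
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "label"])
            w.writerows(rows)
        with open(out / "profile.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.profile), fh, sort_keys=False)
        return out


def _interleave(images0, images1):
    """Deterministic record order: all normals then all abnormals."""
    return [(im, 0) for im in images0] + [(im, 1) for im in images1]


def _low_freq_field(rng, size, cells=4, amplitude=1.0):
    """Smooth background field: bilinear upsampling of a coarse random grid."""
    coarse = rng.normal(0.0, 1.0, size=(cells, cells))
    xs = np.linspace(0, cells - 1, size)
    i0 = np.clip(xs.astype(int), 0, cells - 2)
    frac = xs - i0
    rows = coarse[i0] * (1 - frac)[:, None] + coarse[i0 + 1] * frac[:, None]
    vals = rows[:, i0] * (1 - frac)[None, :] + rows[:, i0 + 1] * frac[None, :]
    return amplitude * vals


def _lesion_image(rng: np.random.Generator, size: int, separability: float,
                  abnormal: bool) -> np.ndarray:
    s = float(separability) if abnormal else 0.0
    base = np.array([196.0, 156.0, 140.0])  # skin-like RGB tone
    field = _low_freq_field(rng, size, cells=4, amplitude=10.0)
    img = base[None, None, :] + field[:, :, None]
    img += rng.normal(0.0, 5.0, size=(size, size, 3))

    # lesion geometry: smooth base boundary shared by both classes,
    # irregularity and centroid offset scaled by separability for abnormals
    cx = size / 2 + s * rng.uniform(-0.08, 0.08) * size
    cy = size / 2 + s * rng.uniform(-0.08, 0.08) * size
    r0 = rng.uniform(0.24, 0.30) * size
    phase = rng.uniform(0, 2 * np.pi)
    ecc = rng.uniform(0.0, 0.10)
    k = np.arange(2, 7)
    amp = s * rng.normal(0.0, 0.06, size=k.size)
    phi = rng.uniform(0, 2 * np.pi, size=k.size)

    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(yy - cy, xx - cx)
    boundary = r0 * (1 + ecc * np.cos(2 * (theta - phase))
                     + (amp[None, None, :] * np.cos(k[None, None, :] * theta[:, :, None]
                                                    + phi[None, None, :])).sum(axis=2))
    mask = rr <= boundary

    depth = rng.uniform(0.75, 1.0)
    lesion_tone = depth * np.array([88.0, 102.0, 110.0])
    img[mask] -= lesion_tone

    # multi-tone interior for abnormals: a few blotches inside the lesion
    n_blobs = 3
    for _ in range(n_blobs):
        bx = cx + rng.uniform(-0.4, 0.4) * r0
        by = cy + rng.uniform(-0.4, 0.4) * r0
        sig = rng.uniform(0.15, 0.3) * r0
        blob_amp = s * rng.uniform(25.0, 45.0) * rng.choice([-1.0, 1.0])
        blob = blob_amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2))
        img += np.where(mask, blob, 0.0)[:, :, None]

    return np.clip(img, 0, 255).astype(np.uint8)


def _scalogram_image(rng: np.random.Generator, size: int, separability: float,
                     abnormal: bool) -> np.ndarray:
    s = float(separability) if abnormal else 0.0
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]

    period = rng.uniform(0.22, 0.30) * size
    phase = rng.uniform(0.0, period)
    sys_frac = rng.uniform(0.32, 0.38)  # S2 delay after S1, as fraction of beat
    r_lo, r_hi = (_S1S2_ROWS[0] * size, _S1S2_ROWS[1] * size)
    f_center = rng.uniform(r_lo, r_hi)
    sig_t = 0.020 * size
    sig_f = 0.06 * size

    t = phase
    while t < size + period:
        for offset, amp_rng in ((0.0, (0.8, 1.0)), (sys_frac * period, (0.6, 0.85))):
            a = rng.uniform(*amp_rng)
            img += a * np.exp(-((xx - (t + offset)) ** 2) / (2 * sig_t**2)
                              - ((yy - f_center) ** 2) / (2 * sig_f**2))
        # murmur: mid-frequency energy filling the S1->S2 interval
        if s > 0:
            m_amp = s * rng.uniform(0.5, 0.8)
            m_lo, m_hi = _MURMUR_ROWS[0] * size, _MURMUR_ROWS[1] * size
            in_band = (yy >= m_lo) & (yy <= m_hi)
            t_mid = t + 0.5 * sys_frac * period
            t_sig = 0.22 * sys_frac * period
            img += m_amp * in_band * np.exp(-((xx - t_mid) ** 2) / (2 * t_sig**2))
        t += period

    img += rng.normal(0.0, 0.05, size=(size, size))
    img = np.clip(img, 0.0, 1.6) * (255.0 / 1.6)
    return np.repeat(img.astype(np.uint8)[:, :, None], 3, axis=2)


def _generate(profile: DatasetProfile, renderer) -> DatasetManifest:
    ss = np.random.SeedSequence([profile.seed, profile.image_size])
    children = ss.spawn(profile.n_normal + profile.n_abnormal)
    images0 = [renderer(np.random.default_rng(children[i]), profile.image_size,
                        profile.separability, False)
               for i in range(profile.n_normal)]
    images1 = [renderer(np.random.default_rng(children[profile.n_normal + i]),
                        profile.image_size, profile.separability, True)
               for i in range(profile.n_abnormal)]
    return DatasetManifest(_interleave(images0, images1), profile)


def generate_lesion_dataset(profile: DatasetProfile) -> DatasetManifest:
    """Dermoscopy-like two-class dataset per the profile (see module docs)."""
    return _generate(profile, _lesion_image)


def generate_scalogram_dataset(profile: DatasetProfile) -> DatasetManifest:
    """Heart-sound-scalogram-like two-class dataset per the profile."""
    return _generate(profile, _scalogram_image)


# -- scalar class discriminants (used by the monotone-separability checks) --


def lesion_heterogeneity_score(img) -> float:
    """Tone heterogeneity of the lesion interior.

    Standard deviation of pixel intensity inside the central disk of radius
    ``0.18 * size`` (well inside the lesion); abnormal lesions' multi-tone
    interiors raise it in proportion to the generating separability.
    """
    px = np.asarray(img, dtype=float).mean(axis=2)
    size = px.shape[0]
    yy, xx = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    disk = np.hypot(yy - size / 2, xx - size / 2) <= 0.18 * size
    return float(px[disk].std())


def murmur_band_energy(img) -> float:
    """Mean intensity in the murmur (mid-frequency) row band."""
    px = np.asarray(img, dtype=float)
    if px.ndim == 3:
        px = px.mean(axis=2)
    size = px.shape[0]
    lo, hi = int(_MURMUR_ROWS[0] * size), int(_MURMUR_ROWS[1] * size)
    return float(px[lo:hi, :].mean())


# -- published fold tables ---------------------------------------------------


def load_paper_fold_table(dataset_id: str, structure_id: str) -> FoldMetricTable:
    """The 10 published fold rows for one dataset/structure pair.

    ``dataset_id`` in {ISIC2017, PH2, PASCAL}; ``structure_id`` in
    {complex, real}. Fold values are returned exactly as printed in the
    source study; summary rows are always recomputed (the printed summary
    rows are inconsistent for some tables).
    """
    ds, st = str(dataset_id), str(structure_id).lower()
    ds_key = {d.lower(): d for d in _DATASET_IDS}.get(ds.lower())
    if ds_key is None or st not in _STRUCTURE_IDS:
        raise KeyError(f"unknown fold table ({dataset_id!r}, {structure_id!r})")
    fname = f"{ds_key.lower()}_{st}.csv"
    ref = resources.files(_FIXTURE_PACKAGE).joinpath(fname)
    with resources.as_file(ref) as path:
        return FoldMetricTable.from_csv(path, dataset_id=ds_key, structure_id=st)
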