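"""Seeded generator of synthetic multi-finger tremor recordings and their
grayscale image encodings.

The generator emulates the capacitive-sensor output format: a recording is
a 10 (fingers) x 640 (samples) matrix, 5 s at 128 Hz, encoded as an 8-bit
grayscale image 640 px wide by 10 px high (one row per finger, one column
per sample), with a severity label in {Healthy, Mild, Moderate, Severe}.
Per subject a tremor frequency is drawn uniformly from the clinical 4-12 Hz
band; each finger carries a phase-jittered sinusoid plus a weaker second
harmonic, scaled by a class-dependent amplitude, on top of a slow baseline
drift and white sensor noise.  Healthy subjects have zero tremor amplitude
(noise and drift only).

Datasets mirror the cohort structure of the sensor study: roughly five
recordings per subject (193 images from 40 participants), with the
train/validation/test split drawn at the *image* level, so held-out images
are new recordings of subjects that also appear in training.  Each
recording of a subject keeps the subject's tremor frequency and severity
but re-draws phases, drift and noise.

This is a synthetic stand-in chosen so the four classes are separable but
overlapping; it makes no claim about real tremor physiology.  All outputs
are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "SubjectProfile",
    "draw_subject",
    "dataset_profiles",
    "extra_recordings",
    "SignalParams",
    "TremorRecording",
    "TremorImage",
    "LabeledDataset",
    "simulate_recording",
    "encode_image",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

CLASS_NAMES = ("Healthy", "Mild", "Moderate", "Severe")


@dataclass(frozen=True)
class SignalParams:
    """Signal-model parameters (normalised signal units unless noted).

    fs               sampling rate, Hz
    duration         recording length, s
    n_fingers        sensor rows per subject
    f0_range         per-subject tremor frequency band, Hz
    class_amplitudes fundamental amplitude per class, strictly increasing
    harmonic2        relative weight of the second harmonic
    phase_jitter     std-dev of per-finger phase offsets, rad
    drift_amp        amplitude of the slow (0.2 Hz) baseline drift
    noise_sigma      white-noise std-dev
    clip_range       symmetric amplitude bound of the 8-bit encoder
    images_per_subject  recordings per synthetic participant (the cohort's
                     193 images over 40 participants give about five)
    recording_jitter std-dev (rad) of the per-recording global phase offset
                     around the subject's stable finger-phase profile
    """

    fs: float = 128.0
    duration: float = 5.0
    n_fingers: int = 10
    f0_range: tuple[float, float] = (4.0, 12.0)
    class_amplitudes: tuple[float, ...] = (0.0, 0.15, 0.40, 0.80)
    harmonic2: float = 0.25
    phase_jitter: float = 0.6
    drift_amp: float = 0.02
    noise_sigma: float = 0.05
    clip_range: float = 1.0
    images_per_subject: int = 5
    recording_jitter: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not (lo >= 4.0 - 1e-9 and hi <= 12.0 + 1e-9 and lo < hi):
            raise ValueError("f0_range must lie within the 4-12 Hz tremor band")
        amps = self.class_amplitudes
        if len(amps) != 4 or any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("class_amplitudes must be 4 strictly increasing values")
        if self.images_per_subject < 1:
            raise ValueError("images_per_subject must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @classmethod
    def well_separated(cls) -> "SignalParams":
        """A high-contrast setting (larger amplitude gaps, less noise) used
        by the end-to-end recovery tests; the default is deliberately more
        overlapping."""
        return cls(class_amplitudes=(0.0, 0.3, 0.6, 0.95), noise_sigma=0.03,
                   drift_amp=0.01)


@dataclass(frozen=True)
class SubjectProfile:
    """Stable per-subject tremor characteristics: pinned frequency and the
    finger-phase pattern (hand-specific propagation of the tremor)."""

    label: int
    f0: float
    finger_phases: tuple[float, ...]
    harmonic_phases: tuple[float, ...]


def draw_subject(cls: int, params: SignalParams | None = None, seed: int = 0,
                 f0: float | None = None) -> SubjectProfile:
    params = params or SignalParams()
    if cls not in range(len(CLASS_NAMES)):
        raise ValueError(f"class label must be in 0..3, got {cls}")
    rng = np.random.default_rng(seed)
    if f0 is None:
        f0 = float(rng.uniform(*params.f0_range))
    base = rng.uniform(0.0, 2.0 * np.pi)
    phases = tuple(base + rng.normal(0.0, params.phase_jitter)
                   for _ in range(params.n_fingers))
    phases2 = tuple(rng.uniform(0.0, 2.0 * np.pi) for _ in range(params.n_fingers))
    return SubjectProfile(label=cls, f0=f0, finger_phases=phases,
                          harmonic_phases=phases2)


@dataclass
class TremorRecording:
    """Real-valued 10 x 640 sensor matrix plus its severity label."""

    signal: np.ndarray
    label: int
    seed: int
    params: SignalParams


@dataclass
class TremorImage:
    """8-bit grayscale encoding (values 0-255) of a recording."""

    pixels: np.ndarray
    label: int
    seed: int = 0
    subject: int = -1
    f0: float = float("nan")

    @property
    def normalized(self) -> np.ndarray:
        return self.pixels.astype(float) / 255.0


@dataclass
class LabeledDataset:
    images: list[TremorImage]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    params: SignalParams
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.images)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(set(all_idx.tolist())) != n or len(all_idx) != n:
            raise ValueError("splits must be disjoint and exhaustive")

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images], dtype=int)

    def arrays(self, split: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with X the normalised image stack (N, 10, 640) in [0, 1]."""
        idx = {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx,
               None: np.arange(len(self.images))}[split]
        x = np.stack([self.images[i].normalized for i in idx])
        y = self.labels[idx]
        return x, y


def simulate_recording(cls: int, params: SignalParams | None = None, seed: int = 0,
                       f0: float | None = None,
                       profile: SubjectProfile | None = None) -> TremorRecording:
    """Simulate one 10-finger recording for severity class ``cls``.

    Without a ``profile`` a fresh subject is drawn (its tremor frequency
    from the band unless ``f0`` pins it).  With a ``profile`` the recording
    re-uses the subject's frequency and finger-phase pattern and re-draws
    only the per-recording variation: a small global phase offset
    (``recording_jitter``), baseline drift and sensor noise.
    """
    params = params or SignalParams()
    if cls not in range(len(CLASS_NAMES)):
        raise ValueError(f"class label must be in 0..3, got {cls}")
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = draw_subject(cls, params, seed=int(rng.integers(0, 2**31 - 1)), f0=f0)
    elif profile.label != cls:
        raise ValueError("profile label does not match the requested class")
    n = params.n_samples
    t = np.arange(n) / params.fs
    f0 = profile.f0
    amp = params.class_amplitudes[cls]
    # a recording-level time offset shifts the fundamental by dphi and the
    # second harmonic by 2*dphi
    dphi = rng.normal(0.0, params.recording_jitter)
    sig = np.empty((params.n_fingers, n))
    for f in range(params.n_fingers):
        phi = profile.finger_phases[f] + dphi
        phi2 = profile.harmonic_phases[f] + 2.0 * dphi
        tremor = np.sin(2.0 * np.pi * f0 * t + phi) \
            + params.harmonic2 * np.sin(4.0 * np.pi * f0 * t + phi2)
        drift = params.drift_amp * np.sin(2.0 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
        noise = params.noise_sigma * rng.standard_normal(n)
        sig[f] = amp * tremor + drift + noise
    return TremorRecording(signal=sig, label=cls, seed=seed, params=params)


def encode_image(rec: TremorRecording, clip_range: float | None = None) -> TremorImage:
    """8-bit encoding: pixel = round(255 * clip(0.5 + s / (2 c), 0, 1)).

    Zero signal maps to mid-gray 128; +/- clip_range maps to 255 / 0.
    """
    c = rec.params.clip_range if clip_range is None else float(clip_range)
    if c <= 0.0:
        raise ValueError("clip_range must be positive")
    scaled = np.clip(0.5 + rec.signal / (2.0 * c), 0.0, 1.0)
    pixels = np.rint(255.0 * scaled).astype(np.uint8)
    return TremorImage(pixels=pixels, label=rec.label, seed=rec.seed)


def _split_sizes(n: int) -> tuple[int, int, int]:
    if n == 193:
        return 153, 17, 23  # the sensor study's printed split
    n_val = int(np.floor(0.1 * n))
    n_test = int(np.floor(0.1 * n))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(n: int = 193, class_proportions: tuple[float, ...] | None = None,
                     params: SignalParams | None = None, seed: int = 0) -> LabeledDataset:
    """Generate ``n`` labelled images with near-balanced classes and a
    stratified 80/10/10 train/val/test split (153/17/23 when n = 193)."""
    from sklearn.model_selection import train_test_split

    params = params or SignalParams()
    if n < 8:
        raise ValueError("need at least 8 images for a 3-way split")
    props = class_proportions or (0.25, 0.25, 0.25, 0.25)
    props = np.asarray(props, dtype=float)
    if props.size != 4 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class_proportions must be 4 non-negative values summing to 1")

    # largest-remainder apportionment of n among the 4 classes
    raw = props * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[order[i % 4]] += 1

    labels = np.repeat(np.arange(4), counts)
    rng = np.random.default_rng(seed)
    images = []
    subject_id = 0
    for c in range(4):
        n_c = int(counts[c])
        if n_c == 0:
            continue
        n_subj = max(1, -(-n_c // params.images_per_subject))
        per = [n_c // n_subj + (1 if i < n_c % n_subj else 0) for i in range(n_subj)]
        for m in per:
            prof = draw_subject(c, params, seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(m):
                img_seed = int(rng.integers(0, 2**31 - 1))
                rec = simulate_recording(c, params, seed=img_seed, profile=prof)
                im = encode_image(rec)
                im.subject = subject_id
                im.f0 = prof.f0
                images.append(im)
            subject_id += 1

    n_train, n_val, n_test = _split_sizes(n)
    idx = np.arange(n)
    strat = labels if (counts.min() >= 2 and n_test >= 4) else None
    rest, test_idx = train_test_split(idx, test_size=n_test, random_state=seed,
                                      stratify=strat)
    strat_rest = labels[rest] if (strat is not None and n_val >= 4) else None
    train_idx, val_idx = train_test_split(rest, test_size=n_val, random_state=seed + 1,
                                          stratify=strat_rest)
    return LabeledDataset(images=images, train_idx=np.sort(train_idx),
                          val_idx=np.sort(val_idx), test_idx=np.sort(test_idx),
                          params=params, seed=seed)


def dataset_profiles(ds: LabeledDataset) -> dict[int, SubjectProfile]:
    """Re-derive each subject's profile from the dataset's generation seed
    (profiles are a pure function of (params, seed))."""
    counts = np.bincount(ds.labels, minlength=4)
    params = ds.params
    rng = np.random.default_rng(ds.seed)
    profiles = {}
    subject_id = 0
    for c in range(4):
        n_c = int(counts[c])
        if n_c == 0:
            continue
        n_subj = max(1, -(-n_c // params.images_per_subject))
        per = [n_c // n_subj + (1 if i < n_c % n_subj else 0) for i in range(n_subj)]
        for m in per:
            profiles[subject_id] = draw_subject(c, params,
                                                seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(m):
                rng.integers(0, 2**31 - 1)  # consume the recording seeds
            subject_id += 1
    return profiles


def extra_recordings(ds: LabeledDataset, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fresh recordings of the dataset's own subjects (new phase offset,
    drift and noise around each subject's stable profile): an out-of-sample
    evaluation set from the same cohort.  Returns (X, y) with X the
    normalised image stack."""
    profiles = dataset_profiles(ds)
    keys = sorted(profiles)
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i in range(n):
        prof = profiles[keys[i % len(keys)]]
        img_seed = int(rng.integers(0, 2**31 - 1))
        rec = simulate_recording(prof.label, ds.params, seed=img_seed, profile=prof)
        xs.append(encode_image(rec).normalized)
        ys.append(prof.label)
    return np.stack(xs), np.array(ys, dtype=int)


def write_dataset(ds: LabeledDataset, directory: str) -> str:
    """One grayscale PNG per image plus manifest.csv and params.json;
    returns the manifest path."""
    from PIL import Image

    os.makedirs(directory, exist_ok=True)
    split_of = {}
    for name, idx in (("train", ds.train_idx), ("val", ds.val_idx), ("test", ds.test_idx)):
        for i in idx:
            split_of[int(i)] = name
    rows = []
    for i, im in enumerate(ds.images):
        fname = f"image_{i:04d}.png"
        Image.fromarray(im.pixels, mode="L").save(os.path.join(directory, fname))
        rows.append({"filename": fname, "label": im.label, "split": split_of[i],
                     "seed": im.seed, "subject": im.subject, "f0": im.f0})
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(os.path.join(directory, "params.json"), "w") as fh:
        payload = dataclasses.asdict(ds.params)
        payload["dataset_seed"] = ds.seed
        json.dump(payload, fh, indent=2, sort_keys=True)
    return manifest


def read_dataset(directory: str) -> LabeledDataset:
    """Inverse of :func:`write_dataset`; errors name any missing file."""
    from PIL import Image

    manifest = os.path.join(directory, "manifest.csv")
    if not os.path.exists(manifest):
        raise FileNotFoundError(f"missing manifest: {manifest}")
    params_path = os.path.join(directory, "params.json")
    if not os.path.exists(params_path):
        raise FileNotFoundError(f"missing params file: {params_path}")
    with open(params_path) as fh:
        payload = json.load(fh)
    dataset_seed = payload.pop("dataset_seed", 0)
    payload["f0_range"] = tuple(payload["f0_range"])
    payload["class_amplitudes"] = tuple(payload["class_amplitudes"])
    params = SignalParams(**payload)

    table = pd.read_csv(manifest)
    images, splits = [], {"train": [], "val": [], "test": []}
    for i, row in table.iterrows():
        path = os.path.join(directory, row["filename"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing image file: {path}")
        pixels = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
        images.append(TremorImage(pixels=pixels, label=int(row["label"]),
                                  seed=int(row["seed"]),
                                  subject=int(row.get("subject", -1)),
                                  f0=float(row.get("f0", float("nan")))))
        splits[row["split"]].append(i)
    return LabeledDataset(images=images,
                          train_idx=np.array(splits["train"], dtype=int),
                          val_idx=np.array(splits["val"], dtype=int),
                          test_idx=np.array(splits["test"], dtype=int),
                          params=params, seed=int(dataset_seed))
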