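"""Synthetic scenes and simulated observers for pipeline testing.

The study conditions being emulated: aerial frames containing tens of birds,
each annotated redundantly by 10-15 observers who occasionally miss targets,
jitter box placement by a few pixels, confuse similar classes, and draw
spurious boxes over background clutter.  A ground-truth scene fixes target
boxes and classes; an observer profile fixes the error rates; every draw is
reproducible from explicit seeds, with per-observer seeds derived by stable
hashing so adding an observer never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotation_model import Annotation, BoundingBox, ImageMeta

DEFAULT_MIN_SEPARATION = 60.0  # 4x the default clustering radius of 15 px


@dataclass
class GroundTruthScene:
    meta: ImageMeta
    targets: list[tuple[BoundingBox, str]]
    image: np.ndarray | None = None

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class ObserverProfile:
    """Error model of one simulated annotator.

    detection_prob may be a single probability or a per-class mapping;
    center jitter is isotropic Gaussian (sigma px), size jitter
    multiplicative lognormal (sigma_size on the log scale); the confusion
    matrix maps each true class to a distribution over reported labels;
    spurious boxes arrive Poisson(false_positive_rate) per image with
    uniform positions and labels drawn from ``spurious_labels`` (uniform
    over the confusion classes when unset).
    """

    observer_id: str
    detection_prob: float | Mapping[str, float] = 0.9
    jitter_sigma: float = 3.0
    size_sigma: float = 0.1
    confusion: Mapping[str, Mapping[str, float]] | None = None
    false_positive_rate: float = 0.5
    spurious_labels: Mapping[str, float] | None = None

    def p_detect(self, cls: str) -> float:
        if isinstance(self.detection_prob, Mapping):
            return float(self.detection_prob[cls])
        return float(self.detection_prob)


def uniform_confusion(
    classes: Sequence[str], off_diagonal: float
) -> dict[str, dict[str, float]]:
    """Row-stochastic confusion matrix with total off-diagonal mass shared evenly."""
    classes = list(classes)
    if not 0 <= off_diagonal < 1:
        raise ValueError("off_diagonal must be in [0, 1)")
    out: dict[str, dict[str, float]] = {}
    for c in classes:
        if len(classes) == 1:
            out[c] = {c: 1.0}
            continue
        share = off_diagonal / (len(classes) - 1)
        out[c] = {d: (1.0 - off_diagonal if d == c else share) for d in classes}
    return out


def observer_seed(master_seed: int, observer_id: str) -> int:
    """Stable per-observer seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{observer_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_scene(
    n_targets: int,
    class_mix: Mapping[str, float],
    meta: ImageMeta,
    seed: int,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    size_mean: float = 40.0,
    size_sigma: float = 0.2,
    max_attempts: int = 10_000,
) -> GroundTruthScene:
    """Place targets by rejection sampling with a minimum center separation.

    Box sizes are lognormal around ``size_mean`` pixels (log-sd
    ``size_sigma``), roughly a duck-sized bird at sub-centimeter aerial
    resolution.  Classes are drawn i.i.d. from ``class_mix``.
    """
    probs = np.array(list(class_mix.values()), dtype=float)
    if n_targets > 0 and not np.isclose(probs.sum(), 1.0):
        raise ValueError("class mix proportions must sum to 1")
    classes = list(class_mix)
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    targets: list[tuple[BoundingBox, str]] = []
    for _ in range(n_targets):
        for attempt in range(max_attempts):
            w = float(np.exp(rng.normal(np.log(size_mean), size_sigma)))
            h = float(np.exp(rng.normal(np.log(size_mean), size_sigma)))
            cx = rng.uniform(w / 2, meta.width - w / 2)
            cy = rng.uniform(h / 2, meta.height - h / 2)
            if all(
                (cx - ox) ** 2 + (cy - oy) ** 2 >= min_separation**2
                for ox, oy in centers
            ):
                break
        else:
            raise RuntimeError(
                f"could not place {n_targets} targets at separation "
                f"{min_separation}; reduce n_targets or enlarge the image"
            )
        centers.append((cx, cy))
        cls = classes[int(rng.choice(len(classes), p=probs))]
        targets.append((BoundingBox(cx - w / 2, cy - h / 2, w, h), cls))
    return GroundTruthScene(meta=meta, targets=targets)


def simulate_observer(
    scene: GroundTruthScene, profile: ObserverProfile, seed: int
) -> list[Annotation]:
    """One observer's annotation pass over a scene.

    Each target is detected independently; detected boxes get Gaussian
    center jitter and lognormal size jitter and a label drawn from the
    confusion row of the true class; spurious boxes are appended last.
    With perfect detection, zero jitter, identity confusion and zero
    false-positive rate the output reproduces the ground truth exactly.
    """
    rng = np.random.default_rng(seed)
    meta = scene.meta
    out: list[Annotation] = []
    for box, cls in scene.targets:
        if rng.random() >= profile.p_detect(cls):
            continue
        cx, cy = box.center
        cx += rng.normal(0.0, profile.jitter_sigma) if profile.jitter_sigma else 0.0
        cy += rng.normal(0.0, profile.jitter_sigma) if profile.jitter_sigma else 0.0
        w = box.w * (np.exp(rng.normal(0.0, profile.size_sigma)) if profile.size_sigma else 1.0)
        h = box.h * (np.exp(rng.normal(0.0, profile.size_sigma)) if profile.size_sigma else 1.0)
        label = cls
        if profile.confusion is not None:
            row = profile.confusion[cls]
            labels = list(row)
            label = labels[int(rng.choice(len(labels), p=np.array(list(row.values()))))]
        jittered = _clipped_box(cx, cy, w, h, meta)
        out.append(Annotation(profile.observer_id, meta.image_id, jittered, label))
    n_fp = int(rng.poisson(profile.false_positive_rate)) if profile.false_positive_rate else 0
    fp_labels = profile.spurious_labels
    if fp_labels is None and profile.confusion is not None:
        fp_labels = {c: 1.0 / len(profile.confusion) for c in profile.confusion}
    for _ in range(n_fp):
        w = float(np.exp(rng.normal(np.log(30.0), 0.3)))
        h = float(np.exp(rng.normal(np.log(30.0), 0.3)))
        cx = rng.uniform(0, meta.width)
        cy = rng.uniform(0, meta.height)
        if fp_labels:
            keys = list(fp_labels)
            p = np.array(list(fp_labels.values()), dtype=float)
            label = keys[int(rng.choice(len(keys), p=p / p.sum()))]
        else:
            label = scene.targets[0][1] if scene.targets else "other"
        out.append(Annotation(profile.observer_id, meta.image_id,
                              _clipped_box(cx, cy, w, h, meta), label))
    return out


def _clipped_box(cx: float, cy: float, w: float, h: float, meta: ImageMeta) -> BoundingBox:
    x = min(max(cx - w / 2, 0.0), meta.width - 1.0)
    y = min(max(cy - h / 2, 0.0), meta.height - 1.0)
    w = min(w, meta.width - x)
    h = min(h, meta.height - y)
    return BoundingBox(x, y, max(w, 1.0), max(h, 1.0))


def generate_crowd(
    scene: GroundTruthScene,
    profiles: Sequence[ObserverProfile],
    master_seed: int,
) -> list[Annotation]:
    """Independent annotation passes by every observer, concatenated."""
    if not profiles:
        raise ValueError("need at least one observer profile")
    out: list[Annotation] = []
    for profile in profiles:
        out.extend(
            simulate_observer(scene, profile, observer_seed(master_seed, profile.observer_id))
        )
    return out


def default_crowd_profiles(
    n_observers: int,
    classes: Sequence[str],
    detection_prob: float = 0.9,
    jitter_sigma: float = 3.0,
    size_sigma: float = 0.1,
    confusion_off_diagonal: float = 0.1,
    false_positive_rate: float = 0.5,
) -> list[ObserverProfile]:
    """A homogeneous crowd at the default error regime."""
    confusion = uniform_confusion(classes, confusion_off_diagonal)
    return [
        ObserverProfile(
            observer_id=f"obs{str(i + 1).zfill(2)}",
            detection_prob=detection_prob,
            jitter_sigma=jitter_sigma,
            size_sigma=size_sigma,
            confusion=confusion,
            false_positive_rate=false_positive_rate,
        )
        for i in range(n_observers)
    ]


@dataclass
class TextureParams:
    """Stationary Gaussian texture: mean intensity, sd, correlation length (px)."""

    mean: float = 120.0
    sd: float = 20.0
    correlation_length: float = 3.0


def render_textured_image(
    scene: GroundTruthScene,
    target_textures: Mapping[str, TextureParams],
    background_texture: TextureParams,
    seed: int,
) -> np.ndarray:
    """Grayscale pixel matrix: textured background with per-class target patches.

    Textures are correlated Gaussian fields (white noise smoothed at the
    stated correlation length, rescaled to the stated sd).  Statistical
    stand-ins only; no attempt at photorealism.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.meta.height, scene.meta.width
    image = _texture_field(rng, (h, w), background_texture)
    for box, cls in scene.targets:
        params = target_textures[cls]
        y1, x1 = int(box.y), int(box.x)
        y2, x2 = min(int(round(box.y2)), h), min(int(round(box.x2)), w)
        if y2 <= y1 or x2 <= x1:
            continue
        image[y1:y2, x1:x2] = _texture_field(rng, (y2 - y1, x2 - x1), params)
    return np.clip(image, 0, 255).astype(np.uint8)


def _texture_field(
    rng: np.random.Generator, shape: tuple[int, int], params: TextureParams
) -> np.ndarray:
    if params.sd == 0:
        return np.full(shape, params.mean, dtype=float)
    noise = rng.normal(0.0, 1.0, shape)
    smooth = gaussian_filter(noise, params.correlation_length)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * params.sd
    return params.mean + smooth
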