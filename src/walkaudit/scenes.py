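"""Procedural rendering of labeled synthetic streetscape scenes.

Real audits classify street-level photographs; this module renders small
synthetic stand-ins with exactly known labels so classifiers and every
downstream aggregation stage can be tested end to end.  Each of the eight
primitive features is drawn as a geometric archetype with bounded
position/scale/hue jitter, in a canonical image region:

* horizontal bands (top to bottom): sky, background ground, optional
  sidewalk strip, optional vegetated buffer strip, road;
* zebra crosswalk: striped white band across the mid road;
* line crosswalk: a parallel pair of transverse lines on the upper road;
* curb cut: a ramp wedge at the sidewalk/road boundary;
* walk signal: a signal box with an orange symbol on a pole;
* bike symbol: a pale teal bicycle glyph painted on the road;
* streetlight: a pole topped by a bright luminaire in the sky region.

Distractors (confusers that must never flip a label): dark shadow stripes
on the road that mimic zebra markings, a parked "real" bike off the road,
and a bare pole without a luminaire.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from walkaudit.features import PRIMITIVE_FEATURES, StreetFeature

IMAGE_SIZE = 256  # square scenes; small enough for CPU training

DISTRACTOR_TAGS = ("shadow-stripes", "parked-bike", "pole-without-light")

# Vertical layout anchors (fractions of image height, before jitter).
_SKY_BOTTOM = 0.38
_ROAD_TOP = 0.66

# Base glyph colors (R, G, B); jittered within +/- _HUE_JITTER per channel.
_COLORS = {
    "sky": (140, 185, 225),
    "ground": (150, 125, 95),
    "road": (52, 52, 55),
    "sidewalk": (200, 198, 195),
    "buffer": (70, 150, 60),
    "curb_cut": (235, 200, 40),
    "zebra": (250, 250, 250),
    "line": (180, 195, 255),
    "walk_signal_box": (25, 25, 28),
    "walk_signal_glyph": (255, 120, 20),
    "bike_symbol": (170, 250, 200),
    "streetlight_pole": (60, 55, 50),
    "streetlight_lamp": (255, 230, 90),
    "shadow": (30, 30, 33),
    "parked_bike": (170, 40, 40),
}
_HUE_JITTER = 12
# the two road markings are separated by a blue-channel offset; keep their
# jitter small enough that the offset survives photometric adjustment
_TIGHT_JITTER = {"zebra", "line"}


class SceneValidationError(ValueError):
    """Raised when a SceneSpec violates its invariants."""


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one streetscape scene.

    ``feature_flags`` must cover exactly the eight primitive features; a
    sidewalk buffer requires a sidewalk (the buffer is the strip rendered
    between road and sidewalk).  ``distractors`` are confusers that leave
    labels unchanged.  ``brightness``/``contrast`` are photometric scalars
    applied after drawing.  ``layout_seed`` controls the geometry jitter.
    """

    feature_flags: dict[StreetFeature, bool]
    distractors: frozenset[str] = frozenset()
    brightness: float = 1.0
    contrast: float = 1.0
    layout_seed: int = 0

    def __post_init__(self) -> None:
        expected = set(PRIMITIVE_FEATURES)
        got = set(self.feature_flags)
        if got != expected:
            missing = {f.value for f in expected - got}
            extra = {getattr(f, "value", f) for f in got - expected}
            raise SceneValidationError(
                f"feature_flags must cover exactly the 8 primitive features; missing={sorted(missing)} extra={sorted(extra)}"
            )
        if self.feature_flags[StreetFeature.SIDEWALK_BUFFER] and not self.feature_flags[StreetFeature.SIDEWALK]:
            raise SceneValidationError("sidewalk_buffer=True requires sidewalk=True")
        unknown = set(self.distractors) - set(DISTRACTOR_TAGS)
        if unknown:
            raise SceneValidationError(f"unknown distractor tags: {sorted(unknown)}")


@dataclasses.dataclass(frozen=True)
class LabeledImage:
    """A rendered scene with its ground-truth labels."""

    image: np.ndarray  # (H, W, 3) uint8
    labels: dict[StreetFeature, bool]
    scene_id: str


def _jitter_color(rng: np.random.Generator, name: str) -> tuple[int, int, int]:
    base = _COLORS[name]
    amp = 8 if name in _TIGHT_JITTER else _HUE_JITTER
    j = rng.integers(-amp, amp + 1, size=3)
    return tuple(int(np.clip(c + d, 0, 255)) for c, d in zip(base, j))


def _draw_bike(draw: ImageDraw.ImageDraw, cx: int, cy: int, r: int, color: tuple[int, int, int], width: int) -> None:
    """Two wheels plus a frame triangle — the bicycle archetype."""
    draw.ellipse([cx - 2 * r, cy - r, cx, cy + r], outline=color, width=width)
    draw.ellipse([cx, cy - r, cx + 2 * r, cy + r], outline=color, width=width)
    draw.line([cx - r, cy, cx, cy - r, cx + r, cy], fill=color, width=width)
    draw.line([cx, cy - r, cx - r // 2, cy - 2 * r + r // 2], fill=color, width=width)


def render_scene(spec: SceneSpec, seed: int, scene_id: str = "scene") -> LabeledImage:
    """Render ``spec`` deterministically for a fixed ``(spec, seed)`` pair.

    Labels echo ``spec.feature_flags`` exactly; distractors and photometric
    adjustments never change them.
    """
    # stream id 1 = rendering; keeps layout jitter statistically
    # independent of the flag draws (stream 0) for the same (seed, index)
    rng = np.random.default_rng([int(seed) % (2**31), int(spec.layout_seed) % (2**31), 1])
    S = IMAGE_SIZE
    flags = spec.feature_flags

    img = Image.new("RGB", (S, S), _jitter_color(rng, "sky"))
    draw = ImageDraw.Draw(img)

    sky_bottom = int(S * (_SKY_BOTTOM + rng.uniform(-0.03, 0.03)))
    road_top = int(S * (_ROAD_TOP + rng.uniform(-0.03, 0.03)))

    # ground between sky and road
    draw.rectangle([0, sky_bottom, S, S], fill=_jitter_color(rng, "ground"))
    draw.rectangle([0, road_top, S, S], fill=_jitter_color(rng, "road"))

    # sidewalk and buffer strips stack upward from the road edge
    strip_top = road_top
    if flags[StreetFeature.SIDEWALK_BUFFER]:
        h = int(S * rng.uniform(0.045, 0.06))
        draw.rectangle([0, strip_top - h, S, strip_top], fill=_jitter_color(rng, "buffer"))
        strip_top -= h
    if flags[StreetFeature.SIDEWALK]:
        h = int(S * rng.uniform(0.06, 0.085))
        draw.rectangle([0, strip_top - h, S, strip_top], fill=_jitter_color(rng, "sidewalk"))
        strip_top -= h

    if flags[StreetFeature.CURB_CUT]:
        # ramp wedge with tactile-yellow surface at the road boundary
        cx = int(S * rng.uniform(0.25, 0.75))
        w = int(S * rng.uniform(0.10, 0.16))
        color = _jitter_color(rng, "curb_cut")
        draw.polygon([(cx - w, road_top - 2), (cx + w, road_top - 2), (cx, road_top + w)], fill=color)

    if flags[StreetFeature.ZEBRA_CROSSWALK]:
        band_top = int(road_top + S * rng.uniform(0.12, 0.16))
        band_h = int(S * rng.uniform(0.09, 0.12))
        stripe_w = int(S * rng.uniform(0.035, 0.05))
        color = _jitter_color(rng, "zebra")
        x = int(rng.uniform(0, stripe_w))
        while x < S:
            draw.rectangle([x, band_top, x + stripe_w, band_top + band_h], fill=color)
            x += 2 * stripe_w

    if flags[StreetFeature.LINE_CROSSWALK]:
        # parallel transverse pair on the upper road
        y0 = int(road_top + S * rng.uniform(0.02, 0.05))
        gap = int(S * rng.uniform(0.045, 0.07))
        color = _jitter_color(rng, "line")
        lw = max(2, int(S * 0.014))
        draw.rectangle([0, y0, S, y0 + lw], fill=color)
        draw.rectangle([0, y0 + gap, S, y0 + gap + lw], fill=color)

    if flags[StreetFeature.BIKE_SYMBOL]:
        cx = int(S * rng.uniform(0.3, 0.7))
        cy = int(road_top + S * rng.uniform(0.22, 0.28))
        r = int(S * rng.uniform(0.035, 0.05))
        _draw_bike(draw, cx, cy, r, _jitter_color(rng, "bike_symbol"), width=3)

    pole_slots = [0.12, 0.85]
    rng.shuffle(pole_slots)
    if flags[StreetFeature.WALK_SIGNAL]:
        px = int(S * (pole_slots[0] + rng.uniform(-0.03, 0.03)))
        box_top = int(S * rng.uniform(0.16, 0.24))
        box_h = int(S * rng.uniform(0.08, 0.11))
        draw.line([px, box_top + box_h, px, road_top], fill=_jitter_color(rng, "streetlight_pole"), width=3)
        draw.rectangle([px - box_h // 2, box_top, px + box_h // 2, box_top + box_h], fill=_jitter_color(rng, "walk_signal_box"))
        draw.rectangle(
            [px - box_h // 4, box_top + box_h // 4, px + box_h // 4, box_top + 3 * box_h // 4],
            fill=_jitter_color(rng, "walk_signal_glyph"),
        )

    if flags[StreetFeature.STREETLIGHT]:
        px = int(S * (pole_slots[1] + rng.uniform(-0.03, 0.03)))
        lamp_y = int(S * rng.uniform(0.08, 0.16))
        r = int(S * rng.uniform(0.028, 0.04))
        draw.line([px, lamp_y, px, road_top], fill=_jitter_color(rng, "streetlight_pole"), width=3)
        draw.ellipse([px - r, lamp_y - r, px + r, lamp_y + r], fill=_jitter_color(rng, "streetlight_lamp"))

    # ---- distractors: stripe-like, bike-like, pole-like confusers ----
    if "shadow-stripes" in spec.distractors:
        band_top = int(road_top + S * rng.uniform(0.12, 0.16))
        band_h = int(S * rng.uniform(0.09, 0.12))
        stripe_w = int(S * rng.uniform(0.035, 0.05))
        color = _jitter_color(rng, "shadow")
        x = int(rng.uniform(0, stripe_w))
        while x < S:
            draw.rectangle([x, band_top, x + stripe_w, band_top + band_h], fill=color)
            x += 2 * stripe_w
    if "parked-bike" in spec.distractors:
        cx = int(S * rng.uniform(0.2, 0.8))
        cy = int((sky_bottom + road_top) // 2 + rng.uniform(-4, 4))
        _draw_bike(draw, cx, cy, int(S * rng.uniform(0.03, 0.045)), _jitter_color(rng, "parked_bike"), width=3)
    if "pole-without-light" in spec.distractors:
        px = int(S * rng.uniform(0.3, 0.7))
        draw.line([px, int(S * rng.uniform(0.1, 0.18)), px, road_top], fill=_jitter_color(rng, "streetlight_pole"), width=3)

    arr = np.asarray(img, dtype=np.float32)
    # photometrics: brightness scale then contrast stretch about the mean
    arr = arr * float(spec.brightness)
    arr = (arr - arr.mean()) * float(spec.contrast) + arr.mean()
    arr = arr + rng.normal(0.0, 1.5, size=arr.shape)  # mild sensor noise
    arr = np.clip(arr, 0, 255).astype(np.uint8)

    labels = {f: bool(flags[f]) for f in PRIMITIVE_FEATURES}
    return LabeledImage(image=arr, labels=labels, scene_id=scene_id)


def _draw_spec(
    rng: np.random.Generator,
    prevalence: dict[StreetFeature, float],
    distractor_rate: float,
    layout_seed: int,
) -> SceneSpec:
    """One scene's random draws, in the documented consumption order.

    Order: one uniform per primitive feature (canonical order), one uniform
    per distractor tag, then brightness and contrast.  The sidewalk-buffer
    flag is the conjunction of its own draw with the sidewalk flag.
    """
    flags: dict[StreetFeature, bool] = {}
    for f in PRIMITIVE_FEATURES:
        flags[f] = bool(rng.uniform() < prevalence.get(f, 0.0))
    flags[StreetFeature.SIDEWALK_BUFFER] = flags[StreetFeature.SIDEWALK_BUFFER] and flags[StreetFeature.SIDEWALK]
    distractors = frozenset(tag for tag in DISTRACTOR_TAGS if rng.uniform() < distractor_rate)
    brightness = float(rng.uniform(0.92, 1.08))
    contrast = float(rng.uniform(0.92, 1.08))
    return SceneSpec(
        feature_flags=flags,
        distractors=distractors,
        brightness=brightness,
        contrast=contrast,
        layout_seed=layout_seed,
    )


class SceneDataset:
    """A generated scene collection: manifest plus in-memory images."""

    def __init__(self, manifest: pd.DataFrame, images: dict[str, LabeledImage], seed: int):
        self.manifest = manifest
        self.images = images
        self.seed = seed

    def loader(self):
        """Return a callable mapping scene_id -> uint8 image array."""

        def _load(scene_id: str) -> np.ndarray:
            return self.images[scene_id].image

        return _load

    def write(self, out_dir: str | Path) -> Path:
        """Write PNGs and the manifest CSV; returns the manifest path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, li in self.images.items():
            Image.fromarray(li.image).save(out / f"{sid}.png")
        path = out / "manifest.csv"
        self.manifest.to_csv(path, index=False)
        return path


def generate_scene_dataset(
    n: int,
    prevalence: dict[StreetFeature, float],
    distractor_rate: float = 0.0,
    seed: int = 0,
    forced_distractors: frozenset[str] | None = None,
    render: bool = True,
) -> SceneDataset:
    """Generate ``n`` labeled scenes with independent per-feature flags.

    Each scene consumes its own RNG stream derived from ``(seed, index)``,
    so the draw sequence is reproducible independent of generation order.
    ``forced_distractors`` adds the given confuser tags to every scene (used
    to build hard-example pools).  With ``render=False`` only the manifest
    is produced (labels are defined by the draws, not the rendering).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for f, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {f} outside [0, 1]: {p}")
    if not 0.0 <= distractor_rate <= 1.0:
        raise ValueError(f"distractor_rate outside [0, 1]: {distractor_rate}")

    rows = []
    images: dict[str, LabeledImage] = {}
    for i in range(n):
        # stream id 0 = scene-spec draws (flags, distractors, photometrics)
        rng = np.random.default_rng([int(seed) % (2**31), i, 0])
        spec = _draw_spec(rng, prevalence, distractor_rate, layout_seed=i)
        if forced_distractors:
            spec = dataclasses.replace(spec, distractors=spec.distractors | forced_distractors)
        sid = f"scene_{seed}_{i:05d}"
        if render:
            li = render_scene(spec, seed=seed, scene_id=sid)
            images[sid] = li
        row = {"scene_id": sid, "path": f"{sid}.png"}
        row.update({f.value: int(spec.feature_flags[f]) for f in PRIMITIVE_FEATURES})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return SceneDataset(manifest=manifest, images=images, seed=seed)


# ---------------------------------------------------------------------------
# Pixel-statistic oracle: proves the learning task is well-posed.
# ---------------------------------------------------------------------------

def pixel_oracle(image: np.ndarray, feature: StreetFeature) -> bool:
    """Classify a clean scene by counting glyph-colored pixels in the
    feature's canonical region.

    The predicates are channel-relation tests (hue-dominance and grayness),
    which survive the bounded photometric jitter.  Exists to certify that
    the learning task is well-posed, not as a production classifier.
    """
    S = image.shape[0]
    a = image.astype(np.int32)
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    mn = a.min(axis=-1)
    spread = a.max(axis=-1) - mn

    def region(mask: np.ndarray, y0: float, y1: float) -> int:
        return int(mask[int(y0 * S) : int(y1 * S)].sum())

    if feature == StreetFeature.SIDEWALK:
        light_gray = (mn > 150) & (spread < 30)
        return region(light_gray, 0.40, 0.72) > 0.02 * 0.32 * S * S
    if feature == StreetFeature.SIDEWALK_BUFFER:
        green = (g - r > 40) & (g - b > 50)
        return region(green, 0.40, 0.72) > 0.01 * 0.32 * S * S
    if feature == StreetFeature.CURB_CUT:
        yellow = (r > 180) & (g > 150) & (b < 120) & (r - b > 100)
        return region(yellow, 0.55, 0.88) > 60
    if feature == StreetFeature.ZEBRA_CROSSWALK:
        white = (mn > 190) & (np.abs(b - r) < 30)
        return region(white, 0.73, 1.0) > 800
    if feature == StreetFeature.LINE_CROSSWALK:
        pale_blue = (b - g > 25) & (mn > 150)
        return region(pale_blue, 0.60, 1.0) > 150
    if feature == StreetFeature.WALK_SIGNAL:
        orange = (r > 180) & (r - g > 80) & (r - b > 150)
        return region(orange, 0.0, 0.45) > 30
    if feature == StreetFeature.BIKE_SYMBOL:
        teal = (g > 170) & (g - r > 40) & (g - b > 20)
        return region(teal, 0.72, 1.0) > 40
    if feature == StreetFeature.STREETLIGHT:
        lamp = (r > 200) & (g > 170) & (b < 160) & (r - b > 80)
        return region(lamp, 0.0, 0.30) > 30
    raise ValueError(f"no oracle for composite feature {feature}")
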