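"""Rasterize kinematogram scenes into frames, PNG sequences and GIFs.

Shapes are drawn with Pillow without anti-aliasing by default, so identical
scene specs and seeds produce bit-identical rasters.  Triangles are isosceles
(height = object size, base = 0.6 x height) centered on their centroid with
the apex pointing along the orientation; squares rotate with orientation;
circles are orientation-invariant.  Sprite stimuli are rotated about the
center of their bounding box, or — when a mirror axis is configured —
reflected across that axis instead of rotated, which suits objects with two
natural orientation axes.  The "bird" and "leaf" stimuli ship as small
procedurally generated placeholder sprites (synthetic stand-ins, not the
original artwork).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .core import (
    ApertureShape,
    LayerOrder,
    LayerSpec,
    MirrorAxis,
    Region,
    SceneSpec,
    StimulusType,
)
from .errors import InvalidParameterError, MissingAssetError

__all__ = [
    "Drawable",
    "shape_geometry",
    "select_keyframe",
    "rasterize_frame",
    "write_frames",
    "resolve_sprite",
    "builtin_sprite",
    "builtin_background",
]


def select_keyframe(elapsed: float, n_keyframes: int, keyframe_time: float) -> int:
    """Sprite keyframe index at ``elapsed`` seconds: floor(t / keyframe_time)
    cycling modulo the keyframe count."""
    if n_keyframes < 1 or keyframe_time <= 0:
        raise InvalidParameterError("need n_keyframes >= 1 and keyframe_time > 0")
    return int(elapsed // keyframe_time) % n_keyframes


@dataclass
class Drawable:
    """Resolved geometry for one object: polygon vertices (canvas offsets
    from the object position), an ellipse bounding box, or a transformed
    sprite raster."""

    kind: str  # "polygon" | "ellipse" | "sprite"
    vertices: Optional[list[tuple[float, float]]] = None
    bbox: Optional[tuple[float, float, float, float]] = None
    sprite: Optional[Image.Image] = None


def _rotate_local(points: list[tuple[float, float]], theta_deg: float) -> list[tuple[float, float]]:
    """Rotate math-coordinate (y up) local points by theta and map to canvas
    offsets (y down)."""
    c, s = math.cos(math.radians(theta_deg)), math.sin(math.radians(theta_deg))
    return [(u * c - v * s, -(u * s + v * c)) for u, v in points]


def shape_geometry(
    kind: StimulusType,
    size: float,
    orientation: float,
    mirror: MirrorAxis = MirrorAxis.none,
    sprite: Optional[Image.Image] = None,
) -> Drawable:
    """Geometry of one object of the given stimulus type and size (pixels)."""
    if size <= 0:
        raise InvalidParameterError("size must be positive")
    kind = StimulusType(kind)
    if kind is StimulusType.triangle:
        h = size
        local = [(2 * h / 3, 0.0), (-h / 3, 0.3 * h), (-h / 3, -0.3 * h)]
        return Drawable(kind="polygon", vertices=_rotate_local(local, orientation))
    if kind is StimulusType.circle:
        r = size / 2.0
        return Drawable(kind="ellipse", bbox=(-r, -r, r, r))
    if kind is StimulusType.square:
        half = size / 2.0
        local = [(half, half), (-half, half), (-half, -half), (half, -half)]
        return Drawable(kind="polygon", vertices=_rotate_local(local, orientation))
    if kind in (StimulusType.bird, StimulusType.image):
        if sprite is None:
            sprite = builtin_sprite("bird")[0] if kind is StimulusType.bird else None
        if sprite is None:
            raise MissingAssetError("image stimulus requires a sprite")
        scale = size / sprite.width
        img = sprite.resize(
            (max(1, round(sprite.width * scale)), max(1, round(sprite.height * scale))),
            Image.NEAREST,
        )
        mirror = MirrorAxis(mirror)
        dx, dy_screen = math.cos(math.radians(orientation)), -math.sin(math.radians(orientation))
        if mirror is MirrorAxis.none:
            img = img.rotate(orientation, expand=True, resample=Image.NEAREST)
        elif mirror is MirrorAxis.y_axis:
            # reflect across the vertical axis when pointing left, never rotate
            if dx < 0:
                img = img.transpose(Image.FLIP_LEFT_RIGHT)
        else:  # x_axis: reflect across the horizontal axis when pointing down
            if dy_screen > 0:
                img = img.transpose(Image.FLIP_TOP_BOTTOM)
        return Drawable(kind="sprite", sprite=img)
    raise InvalidParameterError(f"unknown stimulus type {kind!r}")


# ---------------------------------------------------------------------------
# built-in procedural assets


def builtin_sprite(name: str) -> list[Image.Image]:
    """Procedural placeholder sprites ('bird': 2 keyframes, 'leaf': 1).

    Synthetic artwork generated in code; pointing rightward at orientation 0.
    """
    if name == "bird":
        frames = []
        for wing_up in (True, False):
            img = Image.new("RGBA", (32, 32), (0, 0, 0, 0))
            d = ImageDraw.Draw(img)
            d.polygon([(4, 16), (24, 12), (28, 16), (24, 20)], fill=(60, 60, 70, 255))
            wing = [(12, 14), (18, 4 if wing_up else 28), (20, 14)]
            d.polygon(wing, fill=(90, 90, 100, 255))
            frames.append(img)
        return frames
    if name == "leaf":
        img = Image.new("RGBA", (48, 24), (0, 0, 0, 0))
        d = ImageDraw.Draw(img)
        d.ellipse([6, 4, 42, 20], fill=(60, 140, 50, 255))
        d.line([(0, 12), (10, 12)], fill=(100, 70, 30, 255), width=2)
        d.line([(10, 12), (42, 12)], fill=(40, 100, 35, 255), width=1)
        return [img]
    raise MissingAssetError(f"no builtin sprite named {name!r}")


def builtin_background(name: str, width: int, height: int) -> Image.Image:
    """Procedural background images ('nature': green-to-brown gradient with
    deterministic speckle).  Synthetic stand-in for a photographic scene."""
    if name != "nature":
        raise MissingAssetError(f"no builtin background named {name!r}")
    rng = np.random.default_rng(20220503)  # fixed: backgrounds are assets, not stimuli
    rows = np.linspace(0, 1, height)[:, None]
    top = np.array([110, 160, 120], dtype=float)
    bottom = np.array([90, 70, 40], dtype=float)
    grad = (1 - rows) * top + rows * bottom
    img = np.repeat(grad[:, None, :], width, axis=1)
    speckle = rng.normal(0, 12, size=(height, width, 1))
    img = np.clip(img + speckle, 0, 255).astype(np.uint8)
    return Image.fromarray(img, "RGB")


def resolve_sprite(ref: str) -> list[Image.Image]:
    """Resolve a sprite reference to keyframe images.

    ``builtin:<name>`` uses the procedural sprites; anything else is opened
    as a PNG path.  Unresolvable references raise :class:`MissingAssetError`.
    """
    if ref.startswith("builtin:"):
        return builtin_sprite(ref.split(":", 1)[1])
    path = Path(ref)
    if not path.exists():
        raise MissingAssetError(f"sprite not found: {ref}")
    return [Image.open(path).convert("RGBA")]


def _resolve_background(ref: str, width: int, height: int) -> Image.Image:
    if ref.startswith("builtin:"):
        return builtin_background(ref.split(":", 1)[1], width, height)
    path = Path(ref)
    if not path.exists():
        raise MissingAssetError(f"background image not found: {ref}")
    return Image.open(path).convert("RGB").resize((width, height), Image.BILINEAR)


# ---------------------------------------------------------------------------
# frame rasterization


def _aperture_mask(region: Region, width: int, height: int) -> Image.Image:
    mask = Image.new("L", (width, height), 0)
    d = ImageDraw.Draw(mask)
    box = [region.x0, region.y0, region.x1, region.y1]
    if region.shape is ApertureShape.elliptic:
        d.ellipse(box, fill=255)
    else:
        d.rectangle(box, fill=255)
    return mask


def _layer_sprites(layer: LayerSpec) -> Optional[list[Image.Image]]:
    if layer.stimulus_type is StimulusType.image:
        if not layer.stimulus_images:
            raise MissingAssetError("stimulus_type image needs stimulus_images")
        frames: list[Image.Image] = []
        for ref in layer.stimulus_images:
            frames.extend(resolve_sprite(ref))
        return frames
    if layer.stimulus_type is StimulusType.bird:
        return builtin_sprite("bird")
    return None


def rasterize_frame(
    scene: SceneSpec,
    states: Sequence,
    clock=None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw one frame: background, then each (aperture, layer) in order, each
    object composited at its position with its alpha and clipped to its
    aperture region.  Returns an (H, W, 3) uint8 array."""
    if len(states) != len(scene.apertures):
        raise InvalidParameterError("one LayerState per scene layer required")
    w, h = scene.canvas_width, scene.canvas_height
    if scene.background_image is not None:
        base = _resolve_background(scene.background_image, w, h).convert("RGBA")
    else:
        base = Image.new("RGBA", (w, h), tuple(scene.background_color) + (255,))

    order = list(range(len(states)))
    if scene.layer_order is LayerOrder.randomized:
        if rng is None:
            raise InvalidParameterError("randomized layer order needs an rng")
        rng.shuffle(order)

    for idx in order:
        aperture, layer = scene.apertures[idx]
        st = states[idx]
        region = aperture.region(w, h)
        overlay = Image.new("RGBA", (w, h), (0, 0, 0, 0))
        draw = ImageDraw.Draw(overlay)
        sprites = _layer_sprites(layer)
        from .core import to_pixels  # local to avoid import noise at top

        size_px = to_pixels(layer.oob_size, region, layer.units)
        for i in range(st.n):
            alpha = float(st.alpha[i])
            if alpha <= 0:
                continue
            sprite = None
            if sprites is not None:
                sprite = sprites[int(st.keyframe_index[i]) % len(sprites)]
            g = shape_geometry(
                layer.stimulus_type,
                size_px,
                float(st.orientation[i]),
                layer.stimulus_mirror,
                sprite=sprite,
            )
            color = tuple(int(c) for c in st.colors[i]) + (int(round(alpha * 255)),)
            x, y = float(st.x[i]), float(st.y[i])
            if g.kind == "polygon":
                draw.polygon([(x + ox, y + oy) for ox, oy in g.vertices], fill=color)
            elif g.kind == "ellipse":
                x0, y0, x1, y1 = g.bbox
                draw.ellipse([x + x0, y + y0, x + x1, y + y1], fill=color)
            else:
                spr = g.sprite
                if alpha < 1:
                    spr = spr.copy()
                    a = spr.getchannel("A").point(lambda v: int(v * alpha))
                    spr.putalpha(a)
                overlay.alpha_composite(
                    spr, (round(x - spr.width / 2), round(y - spr.height / 2))
                )
        mask = _aperture_mask(region, w, h)
        clipped = Image.composite(overlay, Image.new("RGBA", (w, h), (0, 0, 0, 0)), mask)
        base = Image.alpha_composite(base, clipped)

    return np.asarray(base.convert("RGB"))


def write_frames(
    rasters: Sequence[np.ndarray], path, fmt: str = "png_sequence", fps: float = 60.0
) -> list[Path]:
    """Write frames as a zero-padded PNG sequence into a directory, or as a
    single animated GIF with frame delay 1000/fps ms."""
    if len(rasters) == 0:
        raise InvalidParameterError("need at least one raster")
    path = Path(path)
    if fmt == "png_sequence":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(len(rasters))))
        files = []
        for i, raster in enumerate(rasters):
            f = path / f"frame_{i:0{width}d}.png"
            Image.fromarray(raster, "RGB").save(f)
            files.append(f)
        return files
    if fmt == "animated_gif":
        frames = [Image.fromarray(r, "RGB") for r in rasters]
        frames[0].save(
            path,
            save_all=True,
            append_images=frames[1:],
            duration=1000.0 / fps,
            loop=0,
        )
        return [path]
    raise InvalidParameterError(f"unknown frame format {fmt!r}")
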