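"""Procedural glossy-surface stimulus generator.

Generates undulating surfaces lit by a square area source, with exact
per-pixel intrinsic components (diffuse shading, specular, texture) so the
ground-truth specular map is known by construction.  Rendering happens in
heightfield parameter space with a fixed oblique view direction; the image
is composed as ``clip(shading * texture + specular, 0, 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

# Highlight floor: one display-quantization step.  A pixel "contains a
# highlight" iff its ground-truth specular value exceeds this.
EPS_SPECULAR = 1.0 / 255.0

#: The 15 per-scene conditions: 1 plain + 12 textures + 2 false-highlight.
TEXTURE_KINDS = ("voronoi", "marble", "checker")
CONDITIONS = (
    ("plain",)
    + tuple(f"{kind}{s}" for kind in TEXTURE_KINDS for s in range(4))
    + ("false_highlight_1", "false_highlight_2")
)

# Calibrated renderer defaults (frozen; see calibration test).
DEFAULT_N_WAVES = 24
DEFAULT_RMS_SLOPE = 0.35
DEFAULT_SPECULAR_EXPONENT = 4000.0
DEFAULT_SPECULAR_GAIN = 60.0
DEFAULT_LIGHT_SAMPLES = 7
DEFAULT_SHADING_QUANTILE = 0.95
CAMERA_DISTANCE = 2.0
VIEW_ELEVATION_DEG = 45.0


class ConfigurationError(ValueError):
    """Raised for invalid scene or generator configuration."""


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters fully determining one rendered scene (sans texture)."""

    scene_id: int
    scale_level: int
    seed: int
    image_size: int = 256
    light_center: tuple[float, float] = (0.5, 0.5)
    light_height: float = 6.0
    light_half_width: float = 0.55
    view_elevation: float = VIEW_ELEVATION_DEG

    def __post_init__(self) -> None:
        if self.scale_level not in (0, 1, 2, 3):
            raise ConfigurationError(f"scale_level must be 0-3, got {self.scale_level}")
        if self.image_size % 64 != 0:
            raise ConfigurationError(
                f"image_size must be divisible by 64, got {self.image_size}"
            )


def view_direction() -> np.ndarray:
    """Unit vector from the surface toward the camera (45 deg elevation)."""
    e = np.deg2rad(VIEW_ELEVATION_DEG)
    return np.array([0.0, -np.cos(e), np.sin(e)])


def camera_position() -> np.ndarray:
    return np.array([0.5, 0.5, 0.0]) + CAMERA_DISTANCE * view_direction()


def camera_vertical_distance() -> float:
    return CAMERA_DISTANCE * np.sin(np.deg2rad(VIEW_ELEVATION_DEG))


def sample_scene(scene_id: int, scale_level: int, seed: int, size: int = 256) -> SceneSpec:
    """Draw the random light geometry for one scene.

    The light is a square source parallel to the surface at 3.8-4.8 times
    the camera's vertical distance.  Its center is placed so the direction
    from the surface center to the light deviates from the flat-surface
    mirror direction by a random angle, putting highlights on wave flanks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, scene_id, 7]))
    height = float(rng.uniform(3.8, 4.8)) * camera_vertical_distance()
    # mirror of the view ray about the flat-surface normal (0, 0, 1)
    mirror = np.array([0.0, np.cos(np.deg2rad(VIEW_ELEVATION_DEG)),
                       np.sin(np.deg2rad(VIEW_ELEVATION_DEG))])
    # deviation angle of the light direction from the mirror direction
    psi = float(rng.uniform(np.deg2rad(8.0), np.deg2rad(38.0)))
    azim = float(rng.uniform(0.0, 2.0 * np.pi))
    # build an orthonormal frame around the mirror direction
    a = np.array([1.0, 0.0, 0.0])
    b = np.cross(mirror, a)
    b /= np.linalg.norm(b)
    d = np.cos(psi) * mirror + np.sin(psi) * (np.cos(azim) * a + np.sin(azim) * b)
    if d[2] < 0.2:  # keep the light above the surface
        d = np.cos(psi) * mirror + np.sin(psi) * (np.cos(azim) * a - np.sin(azim) * b)
        if d[2] < 0.2:
            d = mirror
    t = height / d[2]
    center = (0.5 + t * d[0], 0.5 + t * d[1])
    half_width = float(rng.uniform(0.2, 0.35))
    # per-scene geometry seed so scenes sharing a catalog seed still get
    # distinct heightfields
    scene_seed = int(np.random.SeedSequence([seed, scene_id]).generate_state(1)[0]
                     % (2 ** 31))
    return SceneSpec(
        scene_id=scene_id,
        scale_level=scale_level,
        seed=scene_seed,
        image_size=size,
        light_center=center,
        light_height=height,
        light_half_width=half_width,
    )


# ---------------------------------------------------------------------------
# Heightfield synthesis
# ---------------------------------------------------------------------------

@dataclass
class HeightField:
    heights: np.ndarray         # (size, size)
    normals: np.ndarray         # (size, size, 3), unit length
    curvature: np.ndarray       # (size, size), discrete Laplacian of heights


def wave_parameters(scale_level: int, seed: int, n_waves: int = DEFAULT_N_WAVES):
    """Seeded directional-sinusoid parameters for one heightfield.

    Returns (frequencies, orientations, phases, amplitudes).  The dominant
    spatial frequency doubles per scale_level step; amplitudes fall off as
    1/f so slope magnitude is roughly scale-invariant.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    f_dom = 2.0 * (2.0 ** scale_level)          # cycles per unit (image width)
    freqs = f_dom * 2.0 ** rng.uniform(-0.8, 0.8, size=n_waves)
    thetas = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    amps = 1.0 / freqs
    return freqs, thetas, phases, amps


def evaluate_waves(x, y, freqs, thetas, phases, amps):
    """Direct evaluation of the wave sum at coordinates (x, y) in [0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    h = np.zeros(np.broadcast(x, y).shape, dtype=np.float64)
    for f, th, ph, a in zip(freqs, thetas, phases, amps):
        h += a * np.sin(2.0 * np.pi * f * (x * np.cos(th) + y * np.sin(th)) + ph)
    return h


def pixel_grid(size: int):
    """Pixel-center coordinates in surface-plane units (row-major, 0-based)."""
    coords = (np.arange(size) + 0.5) / size
    x = coords[np.newaxis, :]   # columns -> x
    y = coords[:, np.newaxis]   # rows    -> y
    return np.broadcast_to(x, (size, size)), np.broadcast_to(y, (size, size))


def make_heightfield(
    scale_level: int,
    seed: int,
    size: int,
    n_waves: int = DEFAULT_N_WAVES,
    rms_slope: float = DEFAULT_RMS_SLOPE,
    amplitude: float = 1.0,
) -> HeightField:
    """Sum of seeded directional sinusoids, normals from central differences."""
    if size < 64 or size % 64 != 0:
        raise ConfigurationError(f"size must be >= 64 and divisible by 64, got {size}")
    freqs, thetas, phases, amps = wave_parameters(scale_level, seed, n_waves)
    x, y = pixel_grid(size)
    h = evaluate_waves(x, y, freqs, thetas, phases, amps)

    spacing = 1.0 / size
    gy, gx = np.gradient(h, spacing)
    rms = float(np.sqrt(np.mean(gx ** 2 + gy ** 2)))
    scale = amplitude * (rms_slope / rms if rms > 0 else 0.0)
    h = h * scale
    gy, gx = np.gradient(h, spacing)

    normals = np.empty((size, size, 3))
    normals[..., 0] = -gx
    normals[..., 1] = -gy
    normals[..., 2] = 1.0
    normals /= np.linalg.norm(normals, axis=-1, keepdims=True)

    lap = (np.roll(h, 1, 0) + np.roll(h, -1, 0) + np.roll(h, 1, 1)
           + np.roll(h, -1, 1) - 4.0 * h) / spacing ** 2
    return HeightField(heights=h, normals=normals, curvature=lap)


# ---------------------------------------------------------------------------
# Shading
# ---------------------------------------------------------------------------

@dataclass
class RenderComponents:
    """Per-pixel intrinsic components and geometry buffers for one scene."""

    shading: np.ndarray         # diffuse component, [0, 1]
    specular: np.ndarray        # ground-truth specular map, [0, 1], direct only
    depth: np.ndarray           # distance to camera per pixel
    buffers: dict = field(default_factory=dict)


def shade_components(
    hf: HeightField,
    scene: SceneSpec,
    n_light_samples: int = DEFAULT_LIGHT_SAMPLES,
    specular_exponent: float = DEFAULT_SPECULAR_EXPONENT,
    specular_gain: float = DEFAULT_SPECULAR_GAIN,
    shading_norm_quantile: float = DEFAULT_SHADING_QUANTILE,
) -> RenderComponents:
    """Area-light Lambert diffuse + Blinn-Phong specular lobe.

    The square source is sampled on a J x J grid; diffuse terms carry
    inverse-square distance attenuation and are normalized per scene by a
    high quantile then clipped to [0, 1], so every scene has a small
    saturated bright-shading region whose texture markings are confusable
    with highlights.  The specular sum is scaled by a fixed calibrated
    gain so the brightest highlights across a calibration set approach 1.
    """
    n = hf.normals
    norms = np.linalg.norm(n, axis=-1)
    if np.any(norms < 1e-9):
        idx = np.argwhere(norms < 1e-9)[0]
        raise FloatingPointError(
            f"degenerate normal at pixel ({int(idx[0])}, {int(idx[1])})")
    size = hf.heights.shape[0]
    x, y = pixel_grid(size)
    p = np.stack([x, y, hf.heights], axis=-1)

    v = view_direction()
    J = n_light_samples
    cx, cy = scene.light_center
    w = scene.light_half_width
    offsets = (np.arange(J) + 0.5) / J * 2.0 * w - w
    weight = 1.0 / (J * J)

    diffuse = np.zeros((size, size))
    specular = np.zeros((size, size))
    for ox in offsets:
        for oy in offsets:
            s = np.array([cx + ox, cy + oy, scene.light_height])
            l = s - p
            dist2 = np.sum(l * l, axis=-1)
            l /= np.sqrt(dist2)[..., None]
            ndotl = np.maximum(0.0, np.sum(n * l, axis=-1))
            diffuse += weight * ndotl / dist2
            hvec = l + v
            hvec /= np.linalg.norm(hvec, axis=-1, keepdims=True)
            ndoth = np.maximum(0.0, np.sum(n * hvec, axis=-1))
            specular += weight * ndoth ** specular_exponent

    dnorm = np.quantile(diffuse, shading_norm_quantile)
    if dnorm > 0:
        diffuse = np.clip(diffuse / dnorm, 0.0, 1.0)
    specular = np.clip(specular_gain * specular, 0.0, 1.0)

    cam = camera_position()
    to_cam = cam - p
    cam_dist = np.linalg.norm(to_cam, axis=-1)
    to_cam_u = to_cam / cam_dist[..., None]
    light_c = np.array([cx, cy, scene.light_height])
    to_light = light_c - p
    light_dist = np.linalg.norm(to_light, axis=-1)
    to_light_u = to_light / light_dist[..., None]
    buffers = {
        "camera_distance": cam_dist,
        "angle_to_camera": np.arccos(np.clip(np.sum(n * to_cam_u, -1), -1, 1)),
        "light_distance": light_dist,
        "angle_to_light": np.arccos(np.clip(np.sum(n * to_light_u, -1), -1, 1)),
        "normal_x": n[..., 0].copy(),
        "normal_y": n[..., 1].copy(),
        "normal_z": n[..., 2].copy(),
        "curvature": hf.curvature.copy(),
    }
    return RenderComponents(
        shading=diffuse, specular=specular, depth=cam_dist, buffers=buffers
    )


# ---------------------------------------------------------------------------
# Textures
# ---------------------------------------------------------------------------

def _rescale_texture(tex: np.ndarray, t_max: float) -> np.ndarray:
    lo, hi = float(tex.min()), float(tex.max())
    if hi - lo < 1e-12:
        return np.full_like(tex, t_max)
    return 0.1 + (tex - lo) / (hi - lo) * (t_max - 0.1)


def voronoi_sites(tex_scale: int, seed: int) -> np.ndarray:
    """Seeded feature-point set in [0, 1)^2; feature size doubles per step."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, tex_scale, 13]))
    n_sites = max(4, (2 ** (4 - tex_scale)) ** 2)
    return rng.uniform(0.0, 1.0, size=(n_sites, 2))


def make_texture(kind: str, tex_scale: int, seed: int, size: int,
                 t_max: float = 1.0) -> np.ndarray:
    """Procedural texture map in [0.1, t_max]."""
    if tex_scale not in (0, 1, 2, 3):
        raise ConfigurationError(f"tex_scale must be 0-3, got {tex_scale}")
    x, y = pixel_grid(size)
    if kind == "voronoi":
        sites = voronoi_sites(tex_scale, seed)
        pts = np.stack([x.ravel(), y.ravel()], axis=1)
        dist, _ = cKDTree(sites).query(pts)
        tex = dist.reshape(size, size)
    elif kind == "marble":
        rng = np.random.default_rng(np.random.SeedSequence([seed, tex_scale, 17]))
        f = 8.0 / (2.0 ** tex_scale)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        coord = x * np.cos(theta) + y * np.sin(theta)
        turb = np.zeros_like(coord)
        for k in range(4):
            fk = f * (1.5 ** k)
            th = rng.uniform(0.0, 2.0 * np.pi)
            ph = rng.uniform(0.0, 2.0 * np.pi)
            turb += (0.5 ** k) * np.sin(
                2 * np.pi * fk * (x * np.cos(th) + y * np.sin(th)) + ph)
        tex = np.sin(2.0 * np.pi * f * coord + 1.5 * turb)
    elif kind == "checker":
        n_cells = max(2, 2 ** (4 - tex_scale))
        cx_i = np.floor(x * n_cells).astype(int)
        cy_i = np.floor(y * n_cells).astype(int)
        tex = ((cx_i + cy_i) % 2).astype(float)
    else:
        raise ConfigurationError(f"unknown texture kind: {kind!r}")
    return _rescale_texture(tex, t_max)


def make_false_highlight_texture(donor_specular: np.ndarray, gain: float = 4.0,
                                 t_max: float = 1.0) -> np.ndarray:
    """Texture built from another scene's specular map (monotone in donor)."""
    tex = 1.0 + gain * donor_specular
    if float(tex.max()) - float(tex.min()) < 1e-12:
        return tex
    # keep a bright floor so non-highlight regions stay visible texture
    lo, hi = float(tex.min()), float(tex.max())
    return 0.35 + (tex - lo) / (hi - lo) * (t_max - 0.35)


# ---------------------------------------------------------------------------
# Composition and records
# ---------------------------------------------------------------------------

@dataclass
class StimulusRecord:
    image: np.ndarray
    components: RenderComponents
    texture_map: np.ndarray
    condition: str
    scene: SceneSpec

    @property
    def texture_family(self) -> str:
        c = self.condition
        if c == "plain":
            return "plain"
        if c.startswith("false_highlight"):
            return "false_highlight"
        return c.rstrip("0123")

    @property
    def texture_scale(self) -> int | None:
        c = self.condition
        if c[-1].isdigit() and not c.startswith("false"):
            return int(c[-1])
        return None


def compose(components: RenderComponents, texture: np.ndarray,
            condition: str, scene: SceneSpec) -> StimulusRecord:
    if texture.shape != components.shading.shape:
        raise ValueError(
            f"shape mismatch: texture {texture.shape} vs components "
            f"{components.shading.shape}")
    image = np.clip(components.shading * texture + components.specular, 0.0, 1.0)
    return StimulusRecord(
        image=image.astype(np.float32),
        components=components,
        texture_map=texture,
        condition=condition,
        scene=scene,
    )


def render_scene(spec: SceneSpec) -> tuple[HeightField, RenderComponents]:
    hf = make_heightfield(spec.scale_level, spec.seed, spec.image_size)
    return hf, shade_components(hf, spec)


def rotate_specular(record: StimulusRecord, angle: int) -> StimulusRecord:
    """Recompose a plain stimulus with its specular map rotated about center.

    Rotation is counter-clockwise in image coordinates; only multiples of
    90 degrees are valid.  The stored ground truth is the rotated map.
    """
    if record.condition != "plain":
        raise ValueError("rotate_specular requires an untextured (plain) record")
    if angle % 90 != 0:
        raise ValueError(f"angle must be a multiple of 90, got {angle}")
    k = (angle // 90) % 4
    if k == 0:
        return record
    rotated = np.rot90(record.components.specular, k=k).copy()
    comps = replace(record.components, specular=rotated)
    return compose(comps, record.texture_map, "plain", record.scene)


def specular_pixel_fraction(specular: np.ndarray,
                            eps: float = EPS_SPECULAR) -> float:
    return float(np.mean(specular > eps))


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass
class Catalog:
    records: list
    n_scenes: int
    size: int
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def split_validation(self, n_validation: int, seed: int = 0):
        """Withhold a validation subset balanced over scale and condition."""
        rng = np.random.default_rng(seed)
        cells: dict = {}
        for i, r in enumerate(self.records):
            cells.setdefault((r.scene.scale_level, r.condition), []).append(i)
        for idxs in cells.values():
            rng.shuffle(idxs)
        val: list[int] = []
        depth = 0
        while len(val) < n_validation:
            added = False
            for key in sorted(cells):
                idxs = cells[key]
                if depth < len(idxs) and len(val) < n_validation:
                    val.append(idxs[depth])
                    added = True
            if not added:
                break
            depth += 1
        val_set = set(val)
        train = [i for i in range(len(self.records)) if i not in val_set]
        return train, sorted(val_set)

    def manifest(self) -> list[dict]:
        out = []
        for r in self.records:
            out.append({
                "scene_id": r.scene.scene_id,
                "condition": r.condition,
                "seed": r.scene.seed,
                "scale_level": r.scene.scale_level,
                "image_size": r.scene.image_size,
                "light_center": list(r.scene.light_center),
                "light_height": r.scene.light_height,
                "light_half_width": r.scene.light_half_width,
            })
        return out

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.manifest():
                fh.write(json.dumps(row) + "\n")


def scene_conditions(include_false_highlights: bool = True) -> tuple[str, ...]:
    if include_false_highlights:
        return CONDITIONS
    return CONDITIONS[:13]


def build_catalog(
    n_scenes: int,
    size: int = 128,
    seed: int = 0,
    include_false_highlights: bool = True,
    render: bool = True,
) -> Catalog:
    """Render (or enumerate) the full condition grid for ``n_scenes`` scenes.

    Scale levels are balanced by assigning ``scale_level = scene % 4``;
    false-highlight donors come from the previous scene (cyclically), so at
    least two scenes are required when false highlights are enabled.
    """
    if n_scenes < 1:
        raise ConfigurationError("n_scenes must be >= 1")
    if include_false_highlights and n_scenes < 2:
        raise ConfigurationError(
            "false-highlight conditions need a donor from a different scene; "
            "use n_scenes >= 2 or disable them")
    conds = scene_conditions(include_false_highlights)
    specs = [
        sample_scene(i, i % 4, seed, size)
        for i in range(n_scenes)
    ]
    records: list[StimulusRecord] = []
    if not render:
        empty = RenderComponents(
            shading=np.zeros((0, 0)), specular=np.zeros((0, 0)),
            depth=np.zeros((0, 0)))
        for spec in specs:
            for cond in conds:
                records.append(StimulusRecord(
                    image=None, components=empty, texture_map=None,
                    condition=cond, scene=spec))
        return Catalog(records=records, n_scenes=n_scenes, size=size, seed=seed)

    rendered = [render_scene(spec) for spec in specs]
    ones = np.ones((size, size))
    for i, (spec, (hf, comps)) in enumerate(zip(specs, rendered)):
        tex_seed = seed * 100003 + spec.scene_id
        for cond in conds:
            if cond == "plain":
                tex = ones
            elif cond.startswith("false_highlight"):
                which = int(cond[-1])
                donor_idx = (i - which) % n_scenes
                if donor_idx == i:
                    donor_idx = (i + 1) % n_scenes
                donor = rendered[donor_idx][1].specular
                tex = make_false_highlight_texture(donor)
            else:
                kind = cond.rstrip("0123")
                tex = make_texture(kind, int(cond[-1]), tex_seed, size)
            records.append(compose(comps, tex, cond, spec))
    return Catalog(records=records, n_scenes=n_scenes, size=size, seed=seed)
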