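"""Synthetic en-face SHG crypt-field scenes with ground truth.

In second-harmonic-generation images of colonic mucosa the collagen
network between crypts is bright while crypt lumens are dark, so a scene
is modelled as a bright background with dark, roughly elliptical lumens
punched out of it.  Three phenotype presets mirror the qualitative
morphology of the study cohorts:

``normal``
    uniform, near-circular crypts on a fairly regular field;
``tumor_adjacent``
    heterogeneous sizes (both abnormally large and abnormally small
    crypts), oblong shapes and serrated boundaries;
``tumor``
    collagen signal but no discernible crypt structures (zero crypts).

Every scene carries its ground truth (per-crypt geometry plus an integer
label mask), so downstream segmentation and morphometry are testable
without any real acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .images import DEFAULT_BIT_DEPTH, DEFAULT_PITCH_UM, GrayImage

_BOUNDARY_VERTICES = 96  # polygon resolution used for placement and rasterization


class InfeasibleDensityError(ValueError):
    """Requested crypt packing cannot fit in the field."""


class OverlapError(ValueError):
    """Two crypt polygons rasterize onto the same pixel."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic crypt-field scene.

    Lengths are micrometres; intensities are detector counts in the
    14-bit range.  ``lumen_radius_um`` and ``aspect_ratio`` are
    (mean, SD) pairs sampled per crypt; ``serration`` is an
    (amplitude_um, lobe_count) boundary perturbation
    ``r(theta) = r0 + A * sin(k * theta + phase)``.
    """

    field_size_px: int = 512
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    crypt_count: int = 40
    lumen_radius_um: tuple[float, float] = (16.0, 2.0)
    aspect_ratio: tuple[float, float] = (1.15, 0.08)
    serration: tuple[float, int] = (0.0, 0)
    min_edge_spacing_um: float = 8.0
    background_intensity: int = 9000
    lumen_intensity: int = 2500
    noise_sigma: float = 325.0
    bit_depth: int = DEFAULT_BIT_DEPTH
    phenotype: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        max_val = 2**self.bit_depth - 1
        if not (0 <= self.lumen_intensity < self.background_intensity <= max_val):
            raise ValueError(
                "need 0 <= lumen_intensity < background_intensity <= "
                f"{max_val}; got {self.lumen_intensity}, {self.background_intensity}"
            )
        if self.lumen_radius_um[0] <= 0:
            raise ValueError("mean lumen radius must be positive")
        if self.aspect_ratio[0] < 1:
            raise ValueError("mean aspect ratio must be >= 1")
        if self.serration[0] < 0:
            raise ValueError("serration amplitude must be >= 0")
        if self.min_edge_spacing_um < 0:
            raise ValueError("min_edge_spacing_um must be >= 0")
        if self.phenotype not in ("normal", "tumor_adjacent", "tumor"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.phenotype == "tumor" and self.crypt_count != 0:
            raise ValueError("tumor phenotype has no discernible crypts; crypt_count must be 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def field_size_um(self) -> float:
        return self.field_size_px * self.pixel_pitch_um


#: Phenotype presets.  Intensity and geometry defaults emulate the
#: qualitative cohort descriptions; the tumor preset has no crypts.
PHENOTYPE_PRESETS: dict[str, dict] = {
    "normal": dict(
        crypt_count=40,
        lumen_radius_um=(16.0, 2.0),
        aspect_ratio=(1.15, 0.08),
        serration=(0.0, 0),
        min_edge_spacing_um=8.0,
    ),
    "tumor_adjacent": dict(
        crypt_count=25,
        lumen_radius_um=(18.0, 8.0),
        aspect_ratio=(1.8, 0.4),
        serration=(3.0, 9),
        min_edge_spacing_um=6.0,
    ),
    "tumor": dict(
        crypt_count=0,
        lumen_radius_um=(16.0, 2.0),
        aspect_ratio=(1.0, 0.0),
        serration=(0.0, 0),
        min_edge_spacing_um=0.0,
    ),
}


def preset(phenotype: str, seed: int = 0, **overrides) -> SceneParams:
    """Build :class:`SceneParams` for a phenotype preset, with overrides."""
    if phenotype not in PHENOTYPE_PRESETS:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    kw = dict(PHENOTYPE_PRESETS[phenotype])
    kw.update(overrides)
    return SceneParams(phenotype=phenotype, seed=seed, **kw)


@dataclass(frozen=True)
class CryptGeometry:
    """One crypt lumen: a serrated ellipse in micrometre coordinates."""

    center_um: tuple[float, float]  # (x, y)
    a_um: float  # semi-major axis
    b_um: float  # semi-minor axis
    orientation_rad: float
    serration_amplitude_um: float = 0.0
    serration_lobes: int = 0
    serration_phase_rad: float = 0.0

    def boundary_polygon(self, n_vertices: int = _BOUNDARY_VERTICES) -> np.ndarray:
        """Boundary vertices as an (n, 2) array of (x, y) in um."""
        theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        a = self.a_um
        b = self.b_um
        if self.serration_lobes > 0 and self.serration_amplitude_um > 0:
            mod = self.serration_amplitude_um * np.sin(
                self.serration_lobes * theta + self.serration_phase_rad
            )
            a = a + mod
            b = b + mod
        x_loc = a * np.cos(theta)
        y_loc = b * np.sin(theta)
        c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
        x = self.center_um[0] + c * x_loc - s * y_loc
        y = self.center_um[1] + s * x_loc + c * y_loc
        return np.column_stack([x, y])

    @property
    def area_um2(self) -> float:
        """Exact polygon area (shoelace on the boundary polygon)."""
        return Polygon(self.boundary_polygon()).area


@dataclass
class CryptLayout(Sequence):
    """Placed crypt geometries plus a placement-shortfall flag."""

    crypts: list[CryptGeometry]
    requested: int
    shortfall: int = 0

    def __len__(self) -> int:
        return len(self.crypts)

    def __getitem__(self, i):
        return self.crypts[i]

    def __iter__(self) -> Iterator[CryptGeometry]:
        return iter(self.crypts)


@dataclass
class GroundTruth:
    """Per-scene ground truth: geometries and a matching label mask."""

    crypts: list[CryptGeometry]
    label_mask: np.ndarray

    def __post_init__(self) -> None:
        n_labels = len(np.setdiff1d(np.unique(self.label_mask), [0]))
        if n_labels != len(self.crypts):
            raise ValueError(
                f"label mask has {n_labels} crypts but geometry list has "
                f"{len(self.crypts)}"
            )

    @property
    def centroids_px(self) -> np.ndarray:
        """Ground-truth centroids as (n, 2) array of (x, y) pixels."""
        if not self.crypts:
            return np.empty((0, 2))
        return np.array([c.center_um for c in self.crypts])  # um == px * pitch

    def centroids_in_px(self, pitch_um: float) -> np.ndarray:
        if not self.crypts:
            return np.empty((0, 2))
        return np.array([c.center_um for c in self.crypts]) / pitch_um


@dataclass
class SyntheticScene:
    """A rendered scene: image + ground truth + generating parameters."""

    image: GrayImage
    truth: GroundTruth
    params: SceneParams
    shortfall: int = 0


def _layout_rng(params: SceneParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, 0]))


def _noise_rng(params: SceneParams, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, 1, stream]))


def sample_crypt_layout(
    params: SceneParams, max_tries_per_crypt: int = 200
) -> CryptLayout:
    """Place crypt geometries by rejection sampling.

    Crypts are sampled one at a time (radius, aspect, orientation,
    serration phase, centre) and accepted when the boundary polygon lies
    inside the field with a one-pixel margin and keeps at least
    ``min_edge_spacing_um`` edge-to-edge distance to every previously
    accepted crypt.  After ``max_tries_per_crypt`` consecutive rejections
    the crypt is dropped and the shortfall recorded.

    Raises
    ------
    InfeasibleDensityError
        If the expected packing area (count x pi x (effective radius +
        half spacing)^2) exceeds the field area, before any sampling.
    """
    if params.crypt_count == 0:
        return CryptLayout([], requested=0)

    r_mean = params.lumen_radius_um[0]
    asp_mean = max(params.aspect_ratio[0], 1.0)
    r_eff = r_mean * np.sqrt(asp_mean) + params.serration[0] + params.min_edge_spacing_um / 2
    expected_area = params.crypt_count * np.pi * r_eff**2
    field_area = params.field_size_um**2
    if expected_area > field_area:
        raise InfeasibleDensityError(
            f"expected packing area {expected_area:.0f} um^2 exceeds field "
            f"area {field_area:.0f} um^2 for {params.crypt_count} crypts"
        )

    rng = _layout_rng(params)
    amp, lobes = params.serration
    # keep polygons >= 1 px away from the field edge so rasterized crypts
    # never touch the border (border objects are excluded downstream);
    # pixel centers live at 0..(n-1) * pitch, so stay within [1, n-2] px
    margin = params.pixel_pitch_um
    lo = margin
    hi = params.field_size_um - 2 * margin

    accepted: list[CryptGeometry] = []
    accepted_polys: list[Polygon] = []
    shortfall = 0
    for _ in range(params.crypt_count):
        placed = False
        for _try in range(max_tries_per_crypt):
            r = rng.normal(*params.lumen_radius_um)
            if r < 3.0:  # truncate: sub-3 um lumens are not crypts
                continue
            asp = max(rng.normal(*params.aspect_ratio), 1.0)
            a = r * np.sqrt(asp)
            b = r / np.sqrt(asp)
            geom = CryptGeometry(
                center_um=(rng.uniform(lo, hi), rng.uniform(lo, hi)),
                a_um=a,
                b_um=b,
                orientation_rad=rng.uniform(0, np.pi),
                serration_amplitude_um=amp,
                serration_lobes=lobes,
                serration_phase_rad=rng.uniform(0, 2 * np.pi) if lobes else 0.0,
            )
            if amp >= b:  # serration must not invert the boundary
                continue
            verts = geom.boundary_polygon()
            if verts.min() < lo or verts.max() > hi:
                continue
            poly = Polygon(verts)
            if all(
                poly.distance(other) >= params.min_edge_spacing_um
                for other in accepted_polys
            ):
                accepted.append(geom)
                accepted_polys.append(poly)
                placed = True
                break
        if not placed:
            shortfall += 1
    return CryptLayout(accepted, requested=params.crypt_count, shortfall=shortfall)


def render_scene(
    layout: CryptLayout | Sequence[CryptGeometry],
    params: SceneParams,
    noise_stream: int = 0,
    metadata: dict | None = None,
) -> SyntheticScene:
    """Rasterize a layout into a 14-bit image plus label mask.

    Pixels inside a lumen polygon are drawn at ``lumen_intensity``, the
    collagen background at ``background_intensity``; Gaussian noise of SD
    ``noise_sigma`` is added and the result rounded and clipped to the
    14-bit range.  Labels are assigned in layout order (1..K).
    """
    n = params.field_size_px
    pitch = params.pixel_pitch_um
    label_mask = np.zeros((n, n), dtype=np.int32)
    crypts = list(layout)
    for i, geom in enumerate(crypts, start=1):
        verts = geom.boundary_polygon()
        rows = verts[:, 1] / pitch  # y -> row
        cols = verts[:, 0] / pitch  # x -> col
        rr, cc = draw_polygon(rows, cols, shape=(n, n))
        if np.any(label_mask[rr, cc] != 0):
            raise OverlapError(f"crypt {i} rasterizes onto an already-labelled pixel")
        label_mask[rr, cc] = i

    img = np.full((n, n), float(params.background_intensity))
    img[label_mask > 0] = float(params.lumen_intensity)
    if params.noise_sigma > 0:
        img = img + _noise_rng(params, noise_stream).normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 2**params.bit_depth - 1).astype(np.uint16)

    shortfall = layout.shortfall if isinstance(layout, CryptLayout) else 0
    meta = dict(metadata or {})
    meta.setdefault("phenotype", params.phenotype)
    return SyntheticScene(
        image=GrayImage(
            img,
            bit_depth=params.bit_depth,
            pixel_pitch_um=pitch,
            metadata=meta,
        ),
        truth=GroundTruth(crypts=crypts, label_mask=label_mask),
        params=params,
        shortfall=shortfall,
    )


def generate_scene(params: SceneParams, metadata: dict | None = None) -> SyntheticScene:
    """Sample a layout and render it in one step."""
    return render_scene(sample_crypt_layout(params), params, metadata=metadata)


def generate_depth_stack(
    params: SceneParams,
    depths_um: Sequence[float],
    drift: dict[float, float] | None = None,
    metadata: dict | None = None,
) -> list[SyntheticScene]:
    """Generate one scene per acquisition depth with persistent crypts.

    The layout is sampled once so crypt identities (centroids) persist
    across the stack, emulating stacks acquired at consecutive depths of
    the same field.  ``drift`` optionally maps depth to a multiplicative
    radius scale; the default (no drift) repeats the identical layout at
    every depth.  Noise is drawn independently per depth.
    """
    depths = list(depths_um)
    if not depths:
        raise ValueError("depth list must be non-empty")
    if sorted(depths) != depths:
        raise ValueError("depths must be sorted ascending")
    base = sample_crypt_layout(params)
    scenes = []
    for k, depth in enumerate(depths):
        scale = 1.0 if drift is None else float(drift.get(depth, 1.0))
        if scale == 1.0:
            layout = base
        else:
            layout = CryptLayout(
                [
                    replace(g, a_um=g.a_um * scale, b_um=g.b_um * scale)
                    for g in base
                ],
                requested=base.requested,
                shortfall=base.shortfall,
            )
        meta = dict(metadata or {})
        meta["depth_um"] = depth
        scenes.append(render_scene(layout, params, noise_stream=k, metadata=meta))
    return scenes
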