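"""Synthetic TMA cores and patient cohorts with planted ground truth.

Images emulate the acquisition layout of the real study: ~1-mm circular
cores imaged as tiled 500x400 um fields of view over three staining rounds,
each round contributing a nuclei channel, a protein channel, and one glycan
channel (round 1: TRA before sialidase, round 2: CA19-9, round 3: sTRA).
Planted regions of dual or exclusive glycan expression are recorded as
boolean truth masks so recovery can be scored exactly.

Cohorts carry a planted outcome rule: short-TTP patients are drawn from a
mixture of a low-dual component and a high-everything component, long-TTP
patients from a high-dual / low-singles component.  The generating
densities are known, so a Monte-Carlo estimate of the Bayes accuracy of the
generator is available for benchmarking panel searches.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.stats import norm
from skimage import draw

__all__ = [
    "RegionSpec",
    "SceneSpec",
    "RenderedCore",
    "FovTile",
    "CohortSpec",
    "CoreEntry",
    "ROUND_CHANNELS",
    "GLYCAN_CHANNEL_BY_ROUND",
    "generate_scene",
    "render_fov_tiles",
    "generate_cohort",
    "bayes_accuracy",
    "write_dataset",
    "load_manifest",
    "make_category_scene",
    "SceneSpecError",
]

#: channel names rendered for each staining round
ROUND_CHANNELS: dict[int, tuple[str, str, str]] = {
    1: ("nuclei", "protein", "tra"),
    2: ("nuclei", "protein", "ca199"),
    3: ("nuclei", "protein", "stra"),
}

#: which round's glycan channel feeds each of the two quantified glycans
GLYCAN_CHANNEL_BY_ROUND = {2: "ca199", 3: "stra"}

MARKER_CLASSES = ("dual", "ca199_only", "stra_only", "none")

#: the five quantified marker types
MARKERS = ("ca199", "stra", "ca199_only", "stra_only", "dual")


class SceneSpecError(ValueError):
    """Raised when a scene specification violates its invariants."""


@dataclass(frozen=True)
class RegionSpec:
    """One planted expression region inside the core disk.

    ``shape`` is ``"disk"`` (``center_um`` + ``radius_um``) or ``"polygon"``
    (``vertices_um`` as an (k, 2) array of row/col coordinates in um).
    ``mean_intensity`` is added on top of the tissue background in the
    matching glycan channel(s); ``texture_sd`` is per-pixel Gaussian jitter.
    """

    marker_class: str
    shape: str = "disk"
    center_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 100.0
    vertices_um: tuple[tuple[float, float], ...] | None = None
    mean_intensity: float = 2000.0
    texture_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise SceneSpecError(f"unknown marker_class {self.marker_class!r}")
        if self.shape not in ("disk", "polygon"):
            raise SceneSpecError(f"unknown shape {self.shape!r}")
        if self.mean_intensity < 0 or self.texture_sd < 0:
            raise SceneSpecError("intensities must be nonnegative")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered core."""

    core_diameter_um: float = 1000.0
    pixel_size_um: float = 1.0
    fov_width_um: float = 500.0
    fov_height_um: float = 400.0
    regions: tuple[RegionSpec, ...] = ()
    background_mean: float = 500.0
    background_sd: float = 50.0
    nuclei_density: float = 5e-4  # nuclei per um^2
    nuclei_intensity: float = 1500.0
    nuclei_radius_um: float = 3.0
    protein_intensity: float = 800.0
    tra_round1_scale: float = 0.6  # round-1 TRA signal relative to sTRA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise SceneSpecError("core diameter and pixel size must be positive")
        if self.fov_width_um <= 0 or self.fov_height_um <= 0:
            raise SceneSpecError("FOV dimensions must be positive")
        if self.background_mean < 0 or self.background_sd < 0:
            raise SceneSpecError("background intensities must be nonnegative")

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = int(math.ceil(self.core_diameter_um / self.pixel_size_um))
        return (n, n)

    @property
    def fov_shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.fov_height_um / self.pixel_size_um)),
            int(round(self.fov_width_um / self.pixel_size_um)),
        )


@dataclass
class FovTile:
    """One field-of-view crop of a rendered core."""

    tile_id: int
    y0: int
    x0: int
    images: dict[tuple[int, str], np.ndarray]
    truth: dict[str, np.ndarray]
    tissue: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue.shape


@dataclass
class RenderedCore:
    """All channel images of one core plus ground truth."""

    spec: SceneSpec
    images: dict[tuple[int, str], np.ndarray]  # (round, channel) -> uint16
    truth: dict[str, np.ndarray]  # marker_class -> bool mask
    tissue: np.ndarray  # bool mask of the core disk
    tile_bounds: list[tuple[int, int, int, int]]  # (y0, y1, x0, x1)

    @property
    def truth_ca199(self) -> np.ndarray:
        return self.truth["dual"] | self.truth["ca199_only"]

    @property
    def truth_stra(self) -> np.ndarray:
        return self.truth["dual"] | self.truth["stra_only"]

    @property
    def n_tiles(self) -> int:
        return len(self.tile_bounds)


def _region_mask(region: RegionSpec, spec: SceneSpec) -> np.ndarray:
    shape = spec.grid_shape
    mask = np.zeros(shape, dtype=bool)
    px = spec.pixel_size_um
    if region.shape == "disk":
        rr, cc = draw.disk(
            (region.center_um[0] / px, region.center_um[1] / px),
            region.radius_um / px,
            shape=shape,
        )
    else:
        if region.vertices_um is None:
            raise SceneSpecError("polygon region requires vertices_um")
        verts = np.asarray(region.vertices_um, dtype=float) / px
        rr, cc = draw.polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def _tile_bounds(shape: tuple[int, int], tile_shape: tuple[int, int]) -> list[tuple[int, int, int, int]]:
    h, w = shape
    th, tw = tile_shape
    bounds = []
    for y0 in range(0, h, th):
        for x0 in range(0, w, tw):
            bounds.append((y0, min(y0 + th, h), x0, min(x0 + tw, w)))
    return bounds


def generate_scene(spec: SceneSpec) -> RenderedCore:
    """Render one core from its specification.

    Deterministic for a fixed ``spec.seed``.  Pixels of a planted region
    have expected intensity ``background_mean + mean_intensity`` in the
    matching glycan channel, so regions with ``mean_intensity >= 5 *
    background_sd`` are detectable by construction.  Regions of different
    marker classes must not overlap.
    """

    shape = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    radius_px = spec.core_diameter_um / spec.pixel_size_um / 2.0
    tissue = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2

    truth = {cls: np.zeros(shape, dtype=bool) for cls in MARKER_CLASSES}
    claimed = np.full(shape, -1, dtype=np.int8)
    for region in spec.regions:
        mask = _region_mask(region, spec)
        if not mask[tissue].sum() == mask.sum():
            raise SceneSpecError("region extends outside the core disk")
        cls_idx = MARKER_CLASSES.index(region.marker_class)
        conflict = mask & (claimed >= 0) & (claimed != cls_idx)
        if conflict.any():
            raise SceneSpecError("overlapping regions of different marker classes")
        claimed[mask] = cls_idx
        truth[region.marker_class] |= mask

    images: dict[tuple[int, str], np.ndarray] = {}

    def finish(img: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    def background() -> np.ndarray:
        img = np.zeros(shape, dtype=float)
        img[tissue] = spec.background_mean + rng.normal(0.0, spec.background_sd, int(tissue.sum()))
        return img

    def add_regions(img: np.ndarray, classes: Sequence[str], scale: float = 1.0) -> None:
        for region in spec.regions:
            if region.marker_class not in classes:
                continue
            mask = _region_mask(region, spec)
            img[mask] += scale * region.mean_intensity + rng.normal(
                0.0, region.texture_sd, int(mask.sum())
            )

    # nuclei positions shared across rounds (same physical section)
    area_um2 = math.pi * (spec.core_diameter_um / 2.0) ** 2
    n_nuclei = rng.poisson(spec.nuclei_density * area_um2)
    nuc_mask = np.zeros(shape, dtype=bool)
    if n_nuclei:
        theta = rng.uniform(0, 2 * math.pi, n_nuclei)
        r = radius_px * np.sqrt(rng.uniform(0, 1, n_nuclei))
        for cy, cx in zip(center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)):
            rr, cc = draw.disk((cy, cx), spec.nuclei_radius_um / spec.pixel_size_um, shape=shape)
            nuc_mask[rr, cc] = True
    nuc_mask &= tissue

    for rnd, channels in ROUND_CHANNELS.items():
        for channel in channels:
            img = background()
            if channel == "nuclei":
                img[nuc_mask] += spec.nuclei_intensity
            elif channel == "protein":
                # epithelial stain: lifts every planted region regardless of class
                img[claimed >= 0] += spec.protein_intensity
            elif channel == "ca199":
                add_regions(img, ("dual", "ca199_only"))
            elif channel == "stra":
                add_regions(img, ("dual", "stra_only"))
            elif channel == "tra":
                add_regions(img, ("dual", "stra_only"), scale=spec.tra_round1_scale)
            images[(rnd, channel)] = finish(img)

    tile_shape = spec.fov_shape_px
    bounds = _tile_bounds(shape, tile_shape)
    return RenderedCore(spec=spec, images=images, truth=truth, tissue=tissue, tile_bounds=bounds)


def render_fov_tiles(core: RenderedCore) -> list[FovTile]:
    """Split a rendered core into its field-of-view tiles.

    The tiles partition the core bounding box; concatenating them back in
    row-major order reproduces every channel image bit-exactly.
    """

    tiles = []
    for tid, (y0, y1, x0, x1) in enumerate(core.tile_bounds):
        sl = (slice(y0, y1), slice(x0, x1))
        tiles.append(
            FovTile(
                tile_id=tid,
                y0=y0,
                x0=x0,
                images={key: img[sl] for key, img in core.images.items()},
                truth={cls: m[sl] for cls, m in core.truth.items()},
                tissue=core.tissue[sl],
            )
        )
    return tiles


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

_DEFAULT_COMPONENTS: dict[str, dict[str, tuple[float, float]]] = {
    # short-TTP component A: low dual, moderate exclusive markers
    "short_low_dual": {"ca199_only": (18.0, 5.0), "stra_only": (15.0, 5.0), "dual": (4.0, 2.5)},
    # short-TTP component B: high everything
    "short_high_all": {"ca199_only": (40.0, 5.0), "stra_only": (38.0, 5.0), "dual": (35.0, 5.0)},
    # long TTP: high dual, low exclusive markers
    "long": {"ca199_only": (8.0, 4.0), "stra_only": (7.0, 4.0), "dual": (35.0, 5.0)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic patient cohort.

    ``components`` maps the three generating components to per-marker
    (location, scale) pairs on the 0-100 percent scale.  Short-TTP patients
    come from a mixture of ``short_low_dual`` (weight
    ``short_component_weight``) and ``short_high_all``; long-TTP patients
    from ``long``.  TTP is exponential per class, truncated to the matching
    side of ``ttp_cutoff_months`` so that with no censoring the planted
    class and the observed dichotomized class coincide exactly.
    """

    n_patients: int = 45
    prop_short_ttp: float = 2.0 / 3.0
    components: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _DEFAULT_COMPONENTS
    )
    short_component_weight: float = 0.5
    ttp_scale_short: float = 10.0
    ttp_scale_long: float = 30.0
    ttp_cutoff_months: float = 24.0
    censoring_rate: float = 0.0
    paired_adjacent_effect: float | None = 0.25
    adjacent_jitter_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_short_ttp <= 1.0:
            raise ValueError("prop_short_ttp must be in [0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.ttp_scale_short <= 0 or self.ttp_scale_long <= 0 or self.ttp_cutoff_months <= 0:
            raise ValueError("time scales must be positive")
        for comp in ("short_low_dual", "short_high_all", "long"):
            if comp not in self.components:
                raise ValueError(f"missing component {comp!r}")


def _draw_markers(
    rng: np.random.Generator, params: Mapping[str, tuple[float, float]], size: int
) -> dict[str, np.ndarray]:
    dual = np.clip(rng.normal(*params["dual"], size), 0.0, 100.0)
    out = {"dual": dual}
    for m in ("ca199_only", "stra_only"):
        v = np.clip(rng.normal(*params[m], size), 0.0, None)
        out[m] = np.minimum(v, 100.0 - dual)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with planted marker/outcome structure.

    Exactly ``round(n * prop_short_ttp)`` patients are planted short.  With
    ``censoring_rate == 0`` every event flag is 1 and ``class_label`` equals
    the planted class; with censoring, censor times are drawn uniformly
    below the latent progression time and ``class_label`` is re-derived
    from the observed record (so early-censored patients become
    ``indeterminate``).
    """

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_short = int(round(n * spec.prop_short_ttp))
    planted = np.array(["short"] * n_short + ["long"] * (n - n_short))
    rng.shuffle(planted)
    is_short = planted == "short"

    component = np.where(
        is_short,
        np.where(rng.random(n) < spec.short_component_weight, "short_low_dual", "short_high_all"),
        "long",
    )

    markers = {m: np.zeros(n) for m in ("ca199_only", "stra_only", "dual")}
    for comp in ("short_low_dual", "short_high_all", "long"):
        sel = component == comp
        if sel.any():
            drawn = _draw_markers(rng, spec.components[comp], int(sel.sum()))
            for m in markers:
                markers[m][sel] = drawn[m]

    # truncated-exponential TTP on the matching side of the cutoff
    cutoff = spec.ttp_cutoff_months
    u = rng.uniform(size=n)
    f_cut = 1.0 - math.exp(-cutoff / spec.ttp_scale_short)
    ttp = np.where(
        is_short,
        -spec.ttp_scale_short * np.log1p(-u * f_cut),
        cutoff + rng.exponential(spec.ttp_scale_long, n),
    )
    event = np.ones(n, dtype=int)
    if spec.censoring_rate > 0:
        censored = rng.random(n) < spec.censoring_rate
        ttp = np.where(censored, rng.uniform(0, ttp), ttp)
        event[censored] = 0
    ttp = np.maximum(ttp, 1e-6)

    label = np.where(
        ttp >= cutoff, "long", np.where(event == 1, "short", "indeterminate")
    )

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "ca199_only": markers["ca199_only"],
            "stra_only": markers["stra_only"],
            "dual": markers["dual"],
            "ttp_months": ttp,
            "event": event,
            "class_label": label,
            "planted_class": planted,
            "planted_component": component,
        }
    )
    table["ca199"] = table["ca199_only"] + table["dual"]
    table["stra"] = table["stra_only"] + table["dual"]

    if spec.paired_adjacent_effect is not None:
        factor = spec.paired_adjacent_effect * np.exp(
            rng.normal(0.0, spec.adjacent_jitter_sd, (n, 3))
        )
        table["adj_ca199_only"] = np.minimum(table["ca199_only"] * factor[:, 0], 100.0)
        table["adj_stra_only"] = np.minimum(table["stra_only"] * factor[:, 1], 100.0)
        table["adj_dual"] = np.minimum(table["dual"] * factor[:, 2], 100.0)
        table["adj_ca199"] = table["adj_ca199_only"] + table["adj_dual"]
        table["adj_stra"] = table["adj_stra_only"] + table["adj_dual"]

    cols = ["patient_id", *MARKERS, "ttp_months", "event", "class_label"]
    cols += [c for c in table.columns if c.startswith("adj_")]
    cols += ["planted_class", "planted_component"]
    return table[cols]


def bayes_accuracy(spec: CohortSpec, n_mc: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the Bayes accuracy of the cohort generator.

    Draws ``n_mc`` patients, evaluates the exact class-posterior under the
    generating mixture (ignoring the negligible boundary clipping), and
    returns the accuracy of the optimal predictor.
    """

    big = dataclasses.replace(spec, n_patients=n_mc, seed=seed, censoring_rate=0.0)
    table = generate_cohort(big)
    x = table[["ca199_only", "stra_only", "dual"]].to_numpy()

    def comp_logpdf(comp: str) -> np.ndarray:
        params = spec.components[comp]
        out = np.zeros(len(table))
        for j, m in enumerate(("ca199_only", "stra_only", "dual")):
            loc, scale = params[m]
            out += norm.logpdf(x[:, j], loc, scale)
        return out

    w = spec.short_component_weight
    log_short = np.logaddexp(
        math.log(w) + comp_logpdf("short_low_dual"),
        math.log(1 - w) + comp_logpdf("short_high_all"),
    ) + math.log(spec.prop_short_ttp)
    log_long = comp_logpdf("long") + math.log(1.0 - spec.prop_short_ttp)
    pred = np.where(log_short > log_long, "short", "long")
    return float(np.mean(pred == table["planted_class"].to_numpy()))


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------


@dataclass
class CoreEntry:
    """A rendered core with its manifest metadata."""

    core_id: str
    core: RenderedCore
    patient_id: str = ""
    tissue_type: str = "tumor"
    planted_category: str = ""


def make_category_scene(category: str, seed: int = 0, **overrides) -> SceneSpec:
    """Scene spec whose planted regions realize one core expression category.

    ``category`` is one of ``both``, ``ca199_only_core``, ``stra_only_core``,
    ``neither``.  Region sizes are chosen so each planted marker covers well
    over 1% of the tissue, the core-level presence threshold.
    """

    d = overrides.pop("core_diameter_um", 1000.0)
    c = d / 2.0
    r = d * 0.12
    regions: list[RegionSpec] = []
    if category == "both":
        regions = [
            RegionSpec("dual", center_um=(c - d * 0.18, c), radius_um=r),
            RegionSpec("ca199_only", center_um=(c + d * 0.18, c - d * 0.18), radius_um=r),
            RegionSpec("stra_only", center_um=(c + d * 0.18, c + d * 0.18), radius_um=r),
        ]
    elif category == "ca199_only_core":
        regions = [RegionSpec("ca199_only", center_um=(c, c), radius_um=r * 1.5)]
    elif category == "stra_only_core":
        regions = [RegionSpec("stra_only", center_um=(c, c), radius_um=r * 1.5)]
    elif category != "neither":
        raise ValueError(f"unknown category {category!r}")
    return SceneSpec(core_diameter_um=d, regions=tuple(regions), seed=seed, **overrides)


def write_dataset(
    entries: Sequence[CoreEntry],
    cohort: pd.DataFrame | None,
    outdir: str | Path,
    overwrite: bool = False,
    params: Mapping | None = None,
) -> pd.DataFrame:
    """Write cores as per-tile single-channel 16-bit TIFFs plus CSV metadata.

    Produces ``images/`` (one TIFF per channel per round per tile),
    ``truth/`` (8-bit truth masks per marker class and the tissue mask),
    ``manifest.csv`` linking patients to cores to tile files, ``cohort.csv``
    (when a cohort is given) and a ``params.json`` sidecar.  Refuses to
    clobber an existing manifest unless ``overwrite`` is set.
    """

    outdir = Path(outdir)
    manifest_path = outdir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    rows = []
    for entry in entries:
        tiles = render_fov_tiles(entry.core)
        for tile in tiles:
            for (rnd, channel), img in tile.images.items():
                fname = f"{entry.core_id}_r{rnd}_{channel}_tile{tile.tile_id}.tif"
                tifffile.imwrite(outdir / "images" / fname, img)
                rows.append(
                    {
                        "core_id": entry.core_id,
                        "patient_id": entry.patient_id,
                        "tissue_type": entry.tissue_type,
                        "planted_category": entry.planted_category,
                        "round": rnd,
                        "channel": channel,
                        "tile_id": tile.tile_id,
                        "y0": tile.y0,
                        "x0": tile.x0,
                        "path": f"images/{fname}",
                    }
                )
        for cls, mask in entry.core.truth.items():
            tifffile.imwrite(
                outdir / "truth" / f"{entry.core_id}_{cls}.tif",
                (mask.astype(np.uint8) * 255),
            )
        tifffile.imwrite(
            outdir / "truth" / f"{entry.core_id}_tissue.tif",
            entry.core.tissue.astype(np.uint8) * 255,
        )

    manifest = pd.DataFrame(
        rows,
        columns=[
            "core_id",
            "patient_id",
            "tissue_type",
            "planted_category",
            "round",
            "channel",
            "tile_id",
            "y0",
            "x0",
            "path",
        ],
    )
    manifest.to_csv(manifest_path, index=False)
    if cohort is not None:
        cohort.to_csv(outdir / "cohort.csv", index=False)
    sidecar = {"generator": "glycotma.synthetic_data", "params": dict(params or {})}
    (outdir / "params.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return manifest


def load_manifest(dataset_dir: str | Path) -> pd.DataFrame:
    """Read a dataset manifest written by :func:`write_dataset`."""

    dataset_dir = Path(dataset_dir)
    manifest = pd.read_csv(dataset_dir / "manifest.csv", keep_default_na=False)
    missing = [
        p for p in manifest["path"].unique() if not (dataset_dir / p).exists()
    ]
    if missing:
        raise FileNotFoundError(
            "manifest references missing tile files: " + ", ".join(sorted(missing))
        )
    return manifest
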