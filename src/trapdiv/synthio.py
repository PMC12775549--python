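"""Synthetic study generator: design, land cover, counts, boxes, detections.

Generates every input the analysis pipeline consumes, with known parameters,
so downstream stages have recoverable truth.  The default configuration
emulates a reservoir-archipelago sticky-trap survey: 236 traps split across
17 forest islands (72 traps), open-water matrix transects at quasi-log
distances of 10-4000 m from focal islands (119 traps), and 3 continuous
mainland forest sites (45 traps); each 20 x 15 cm trap is photographed on
both sides (A/B).

Counts follow a log-linear abundance model with opposite-signed forest
effects for the two lifecycle groups (terrestrial slope +1.36, aquatic slope
-0.93 on the log scale per unit forest cover), negative-binomial dispersion,
and lognormal bounding-box areas with taxon-specific forest effects on size.
Per-fold noisy detections carry separated true-positive / false-positive
confidence distributions (Beta(8,2) vs Beta(2,8) by default) so threshold
calibration has a recoverable optimum.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxes import Box
from .detect import Detection, GroundTruth
from .landcov import ClassRaster

__all__ = [
    "DesignConfig",
    "CommunityEffects",
    "DetectionErrorModel",
    "generate_design",
    "generate_raster",
    "raster_for_design",
    "generate_counts",
    "generate_truth_boxes",
    "generate_detections",
    "study_config",
    "default_effects",
    "default_error_model",
    "TRAP_AREA_CM2",
    "IMAGE_SIZE",
]

# two-sided trapping area of one 20 cm x 15 cm double-sided trap
TRAP_AREA_CM2 = 2 * 20 * 15
# full-resolution trap photograph size in pixels
IMAGE_SIZE = (4608, 3465)


@dataclass
class DesignConfig:
    """Sampling-design parameters.

    Island trap layout is given explicitly per island (transect count and
    traps per transect) because island-size rules map to trap counts, not
    polygon geometry.  Matrix transects radiate from focal islands with traps
    at the quasi-log ``matrix_distances``; a transect of m traps uses the
    first m distances.
    """

    n_islands: int = 17
    island_transects: tuple[int, ...] = (2,) + (1,) * 16
    island_trap_counts: tuple[int, ...] = (5,) * 8 + (3,) * 9
    matrix_distances: tuple[float, ...] = (10, 30, 80, 200, 500, 1000, 2000, 4000)
    matrix_transect_sizes: tuple[int, ...] = (8,) * 14 + (7,)
    n_continuous_sites: int = 3
    transects_per_continuous_site: int = 3
    traps_per_forest_transect: int = 5
    trap_spacing: float = 100.0
    island_spacing: float = 9500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_islands <= 0 and (self.matrix_transect_sizes or self.n_continuous_sites):
            pass
        if self.n_islands < 0 or self.n_continuous_sites < 0:
            raise ValueError("counts must be non-negative")
        if len(self.island_transects) != self.n_islands:
            raise ValueError("island_transects must have one entry per island")
        if len(self.island_trap_counts) != self.n_islands:
            raise ValueError("island_trap_counts must have one entry per island")
        if any(t <= 0 for t in self.island_transects):
            raise ValueError("island transect counts must be positive")
        if any(t <= 0 for t in self.island_trap_counts):
            raise ValueError("island trap counts must be positive")
        d = np.asarray(self.matrix_distances, dtype=float)
        if (d <= 0).any() or (np.diff(d) <= 0).any():
            raise ValueError("matrix distances must be strictly positive and increasing")
        if any(not 0 < m <= len(self.matrix_distances) for m in self.matrix_transect_sizes):
            raise ValueError("matrix transect sizes must be in 1..len(matrix_distances)")
        if self.trap_spacing <= 0:
            raise ValueError("trap spacing must be positive")
        if self.transects_per_continuous_site < 0 or self.traps_per_forest_transect <= 0:
            raise ValueError("continuous-site configuration must be positive")


def study_config() -> DesignConfig:
    """The default 236-trap archipelago design (72 island + 119 matrix + 45
    continuous traps)."""
    return DesignConfig()


def generate_design(config: DesignConfig) -> pd.DataFrame:
    """Lay out the trap table: trap_id, x, y (projected meters), stratum.

    Islands sit on a line at y = 0 with forest transects running inland (+y,
    one trap every ``trap_spacing``); matrix transects run into open water
    (-y) with traps at the quasi-log distances; continuous forest sites sit in
    a mainland band to the north.  Deterministic: the same config always
    yields byte-identical tables.
    """
    config.validate()
    rows: list[tuple[str, float, float, str]] = []
    for i in range(config.n_islands):
        cx = i * config.island_spacing
        for t in range(config.island_transects[i]):
            x = cx + t * 400.0  # parallel transects on large islands
            for j in range(config.island_trap_counts[i]):
                rows.append(
                    (f"I{i + 1:02d}T{t + 1}P{j + 1}", x, j * config.trap_spacing, "island")
                )
    n_isl = max(config.n_islands, 1)
    for m, size in enumerate(config.matrix_transect_sizes):
        focal = m % n_isl
        lane = m // n_isl
        x = focal * config.island_spacing + 150.0 + 60.0 * lane
        for j in range(size):
            rows.append(
                (f"M{m + 1:02d}P{j + 1}", x, -float(config.matrix_distances[j]), "matrix")
            )
    y_mainland = 8000.0
    for s in range(config.n_continuous_sites):
        sx = s * 6000.0
        for t in range(config.transects_per_continuous_site):
            x = sx + t * 500.0
            for j in range(config.traps_per_forest_transect):
                rows.append(
                    (
                        f"C{s + 1}T{t + 1}P{j + 1}",
                        x,
                        y_mainland + j * config.trap_spacing,
                        "continuous",
                    )
                )
    df = pd.DataFrame(rows, columns=["trap_id", "x", "y", "stratum"])
    if df["trap_id"].duplicated().any():
        raise AssertionError("duplicate trap ids generated")
    if df.duplicated(subset=["x", "y"]).any():
        raise AssertionError("duplicate trap coordinates generated")
    return df


def generate_raster(
    extent: float | tuple[float, float],
    pixel_size: float = 30.0,
    field=1.0,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ClassRaster:
    """Generate an integer class raster (1 = forest, 0 = non-forest).

    ``field`` is either a constant forest probability or a callable
    ``p(x, y) -> [0, 1]`` evaluated at pixel centers; each pixel is forest
    with that probability (deterministic where p is 0 or 1).  ``extent`` is
    (width, height) in meters and must be a positive multiple of
    ``pixel_size``; ``origin`` is the lower-left corner.
    """
    if np.isscalar(extent):
        extent = (float(extent), float(extent))
    w, h = float(extent[0]), float(extent[1])
    for v in (w, h):
        if v <= 0 or abs(v / pixel_size - round(v / pixel_size)) > 1e-9:
            raise ValueError(f"extent {v} is not a positive multiple of pixel size {pixel_size}")
    n_cols, n_rows = int(round(w / pixel_size)), int(round(h / pixel_size))
    x0, y_ll = origin
    y_ul = y_ll + h
    xs = x0 + (np.arange(n_cols) + 0.5) * pixel_size
    ys = y_ul - (np.arange(n_rows) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    if callable(field):
        p = np.clip(np.asarray(field(gx, gy), dtype=float), 0.0, 1.0)
    else:
        p = np.full((n_rows, n_cols), float(field))
    rng = np.random.default_rng(seed)
    grid = np.where(
        p >= 1.0, 1, np.where(p <= 0.0, 0, (rng.random(p.shape) < p).astype(int))
    )
    return ClassRaster(grid=grid.astype(int), origin=(x0, y_ul), pixel_size=pixel_size)


def raster_for_design(
    traps: pd.DataFrame,
    pixel_size: float = 30.0,
    forest_radius: float = 250.0,
    ramp: float = 200.0,
    margin: float = 300.0,
    seed: int = 0,
) -> ClassRaster:
    """Land-cover raster consistent with a trap layout.

    Forest probability ramps from 1 within ``forest_radius`` of any
    forest-stratum (island or continuous) trap down to 0 beyond
    ``forest_radius + ramp``, emulating forest patches in an open-water
    matrix; traps far along matrix transects therefore see zero cover while
    near-island matrix traps see partial cover in their buffers.
    """
    forest_pts = traps.loc[traps["stratum"] != "matrix", ["x", "y"]].to_numpy(float)
    if forest_pts.shape[0] == 0:
        raise ValueError("design has no forest-stratum traps to anchor the raster")
    xmin = np.floor((traps["x"].min() - margin) / pixel_size) * pixel_size
    ymin = np.floor((traps["y"].min() - margin) / pixel_size) * pixel_size
    xmax = np.ceil((traps["x"].max() + margin) / pixel_size) * pixel_size
    ymax = np.ceil((traps["y"].max() + margin) / pixel_size) * pixel_size

    def field(gx, gy):
        # distance to the nearest forest trap, chunked over pixels
        d2 = np.full(gx.shape, np.inf)
        for px, py in forest_pts:
            d2 = np.minimum(d2, (gx - px) ** 2 + (gy - py) ** 2)
        d = np.sqrt(d2)
        return np.clip(1.0 - (d - forest_radius) / ramp, 0.0, 1.0)

    return generate_raster(
        (xmax - xmin, ymax - ymin), pixel_size, field, seed=seed, origin=(xmin, ymin)
    )


@dataclass
class CommunityEffects:
    """Generative community model: log-linear abundance and lognormal size.

    Counts for taxon t at a trap with forest cover f are negative binomial
    with ``log mean = intercept_t + slope(lifecycle_t) * f + site effect`` and
    dispersion ``alpha_t`` (variance mu + alpha mu^2; Poisson when alpha = 0).
    The site effect is a taxon-specific normal deviate shared by all traps of
    one sampling site (island, matrix transect or continuous transect) with
    standard deviation ``site_sd_t``: aquatic insects emerge from discrete
    breeding habitats and are therefore strongly clumped among sites, while
    terrestrial taxa are close to uniform — this is what drives the higher
    compositional turnover of aquatic assemblages.  Bounding-box areas (px^2)
    are lognormal with
    ``log area ~ N(size_mu_t + size_forest_slope_t * f, size_sigma_t^2)``.
    """

    taxa: tuple[tuple[str, str], ...]
    intercepts: dict[str, float]
    forest_slopes: dict[str, float]
    overdispersion: dict[str, float]
    size_mu: dict[str, float]
    size_sigma: dict[str, float]
    size_forest_slope: dict[str, float]
    site_sd: dict[str, float] = field(default_factory=dict)
    # optional per-taxon forest slopes; taxa not listed fall back to their
    # lifecycle slope.  Real taxa respond with very different strengths, and
    # this heterogeneity is what turns the community over along the gradient.
    taxon_slopes: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name, lc in self.taxa:
            if lc not in ("terrestrial", "aquatic"):
                raise ValueError(f"lifecycle {lc!r} for {name!r} not allowed")
            if self.overdispersion.get(name, 0.0) < 0:
                raise ValueError(f"negative overdispersion for {name!r}")

    @property
    def lifecycles(self) -> dict[str, str]:
        return dict(self.taxa)


def default_effects() -> CommunityEffects:
    """Default seven-taxon community with opposite-signed lifecycle slopes.

    Intercepts (log abundance at forest cover 0) are set so the realized
    taxon mix is mosquito-dominated with the aquatic groups thriving in open
    water and terrestrial groups in forest, at roughly 60-100 individuals per
    trap overall.
    """
    taxa = (
        ("Nematocera", "aquatic"),
        ("Ephemeroptera", "aquatic"),
        ("Trichoptera", "aquatic"),
        ("Brachycera", "terrestrial"),
        ("Coleoptera", "terrestrial"),
        ("Hemiptera", "terrestrial"),
        ("Hymenoptera", "terrestrial"),
    )
    intercepts = {
        "Nematocera": float(np.log(80.0)),
        "Ephemeroptera": float(np.log(14.0)),
        "Trichoptera": float(np.log(2.5)),
        "Brachycera": float(np.log(3.0)),
        "Coleoptera": float(np.log(2.2)),
        "Hemiptera": float(np.log(4.5)),
        "Hymenoptera": float(np.log(1.2)),
    }
    slopes = {"terrestrial": 1.36, "aquatic": -0.93}
    overdisp = {name: 0.4 for name, _ in taxa}
    size_mu = {
        "Nematocera": float(np.log(1200.0)),
        "Ephemeroptera": float(np.log(2500.0)),
        "Trichoptera": float(np.log(2000.0)),
        "Brachycera": float(np.log(1800.0)),
        "Coleoptera": float(np.log(5000.0)),
        "Hemiptera": float(np.log(7000.0)),
        "Hymenoptera": float(np.log(4000.0)),
    }
    size_sigma = {name: 0.5 for name, _ in taxa}
    size_slope = {
        "Nematocera": 0.0,
        "Ephemeroptera": -0.3,
        "Trichoptera": 0.0,
        "Brachycera": -0.3,
        "Coleoptera": -0.3,
        "Hemiptera": 0.0,
        "Hymenoptera": -0.3,
    }
    # aquatic taxa clump strongly among sites (discrete breeding habitats);
    # terrestrial taxa are near-uniform
    life = dict(taxa)
    site_sd = {name: (0.5 if life[name] == "aquatic" else 0.15) for name, _ in taxa}
    # heterogeneous per-taxon response strengths (lifecycle signs preserved):
    # the dominant aquatic taxon carries the lifecycle-level slope while the
    # minor aquatic taxa respond much more strongly / weakly, turning aquatic
    # composition over along the gradient
    taxon_slopes = {
        "Nematocera": -0.93,
        "Ephemeroptera": -2.0,
        "Trichoptera": -0.15,
        "Brachycera": 1.2,
        "Coleoptera": 1.36,
        "Hemiptera": 1.6,
        "Hymenoptera": 1.36,
    }
    return CommunityEffects(
        taxa, intercepts, slopes, overdisp, size_mu, size_sigma, size_slope,
        site_sd, taxon_slopes,
    )


def generate_counts(
    traps: pd.DataFrame,
    forest: pd.Series,
    effects: CommunityEffects,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the trap x taxon count matrix from the community model.

    ``forest`` is per-trap forest cover in [0, 1] indexed by trap_id.  Counts
    are negative binomial (gamma-mixed Poisson) with the log-linear mean;
    reproducible under the seed.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    trap_ids = traps["trap_id"].tolist()
    f = forest.loc[trap_ids].to_numpy(float)
    if np.isnan(f).any() or (f < 0).any() or (f > 1).any():
        raise ValueError("every trap needs forest cover in [0, 1]")
    # sampling site = transect prefix of the trap id (traps of one transect
    # share the same breeding-habitat neighbourhood)
    sites = pd.Index([t.rsplit("P", 1)[0] for t in trap_ids])
    site_levels = sites.unique()
    data = {}
    for name, lifecycle in effects.taxa:
        sd = effects.site_sd.get(name, 0.0)
        eps_by_site = dict(zip(site_levels, rng.normal(0.0, sd, len(site_levels)))) \
            if sd > 0 else {}
        eps = np.array([eps_by_site.get(s, 0.0) for s in sites])
        slope = effects.taxon_slopes.get(name, effects.forest_slopes[lifecycle])
        mu = np.exp(effects.intercepts[name] + slope * f + eps)
        alpha = effects.overdispersion.get(name, 0.0)
        if alpha == 0.0:
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
            counts = rng.poisson(lam)
        data[name] = counts
    return pd.DataFrame(data, index=pd.Index(trap_ids, name="trap_id"))


def generate_truth_boxes(
    counts: pd.DataFrame,
    forest: pd.Series,
    effects: CommunityEffects,
    seed: int = 0,
    image_size: tuple[int, int] = IMAGE_SIZE,
) -> tuple[list[GroundTruth], list[str]]:
    """Place ground-truth boxes on two image sides per trap.

    Each individual in the count matrix lands on side A or B with equal
    probability; its bounding-box area is lognormal with the taxon's
    size model at the trap's forest cover, with a mild lognormal aspect
    ratio.  Returns the truth boxes and the full list of image ids
    (``<trap>_A``, ``<trap>_B`` — present even when empty, so false
    positives can be generated on insect-free images).
    """
    rng = np.random.default_rng(seed)
    w_img, h_img = image_size
    truths: list[GroundTruth] = []
    image_ids: list[str] = []
    tid = 0
    for trap_id, row in counts.iterrows():
        f = float(forest.loc[trap_id])
        for side in ("A", "B"):
            image_ids.append(f"{trap_id}_{side}")
        for taxon, n in row.items():
            if n == 0:
                continue
            sides = rng.random(int(n)) < 0.5
            log_area = rng.normal(
                effects.size_mu[taxon] + effects.size_forest_slope[taxon] * f,
                effects.size_sigma[taxon],
                int(n),
            )
            aspect = np.exp(rng.normal(0.0, 0.2, int(n)))
            for k in range(int(n)):
                area = float(np.exp(log_area[k]))
                bw = max(4.0, min(float(np.sqrt(area * aspect[k])), w_img / 4))
                bh = max(4.0, min(float(np.sqrt(area / aspect[k])), h_img / 4))
                x = rng.uniform(0, w_img - bw)
                y = rng.uniform(0, h_img - bh)
                side = "A" if sides[k] else "B"
                truths.append(
                    GroundTruth(f"{trap_id}_{side}", side, taxon, Box(x, y, bw, bh), tid)
                )
                tid += 1
    return truths, image_ids


@dataclass
class DetectionErrorModel:
    """Stochastic detection-error model for one ensemble fold.

    ``miss_rate`` is the per-class probability a truth box yields no
    detection in a fold; ``fp_rate`` the expected spurious boxes per image per
    fold; confidences are Beta-distributed with the true-positive
    distribution stochastically dominating the false-positive one by default;
    ``box_jitter`` is the pixel SD applied to truth boxes (jittered boxes are
    clipped to the image, never dropped).
    """

    miss_rate: float | dict[str, float] = 0.25
    fp_rate: float = 0.5
    tp_confidence: tuple[float, float] = (8.0, 2.0)
    fp_confidence: tuple[float, float] = (2.0, 8.0)
    box_jitter: float = 3.0

    def validate(self) -> None:
        rates = self.miss_rate.values() if isinstance(self.miss_rate, dict) else [self.miss_rate]
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"miss rate {r} outside [0, 1]")
        if self.fp_rate < 0 or self.box_jitter < 0:
            raise ValueError("fp_rate and box_jitter must be non-negative")

    def class_miss(self, cls: str) -> float:
        if isinstance(self.miss_rate, dict):
            return self.miss_rate.get(cls, 0.25)
        return self.miss_rate


def default_error_model() -> DetectionErrorModel:
    return DetectionErrorModel()


def _beta_conf(rng: np.random.Generator, params: tuple[float, float], n: int) -> np.ndarray:
    # keep confidences strictly inside (0, 1)
    return np.clip(rng.beta(params[0], params[1], n), 1e-6, 1 - 1e-6)


def generate_detections(
    truths: list[GroundTruth],
    image_ids: list[str],
    error_model: DetectionErrorModel,
    n_folds: int = 5,
    seed: int = 0,
    image_size: tuple[int, int] = IMAGE_SIZE,
    classes: list[str] | None = None,
) -> tuple[list[Detection], list[tuple[str, int]]]:
    """Simulate per-fold noisy detections from truth boxes.

    Each truth box appears in each fold with probability 1 - miss_rate (class
    specific), with Gaussian positional jitter and a true-positive-Beta
    confidence; false positives arrive Poisson(fp_rate) per image per fold
    with false-positive-Beta confidences and random boxes/classes.  Returns
    the detections plus a parallel provenance list ``("TP", truth_id)`` /
    ``("FP", -1)`` so calibration tests have an oracle.
    """
    error_model.validate()
    rng = np.random.default_rng(seed)
    w_img, h_img = image_size
    if classes is None:
        classes = sorted({t.class_label for t in truths}) or ["unknown"]
    detections: list[Detection] = []
    provenance: list[tuple[str, int]] = []
    for fold in range(1, n_folds + 1):
        for t in truths:
            if rng.random() < error_model.class_miss(t.class_label):
                continue
            jitter = error_model.box_jitter
            if jitter > 0:
                dx, dy = rng.normal(0, jitter, 2)
                # clamp the origin so a jittered box stays inside the image
                # (clipped, never dropped)
                x_new = min(max(t.box.x_min + dx, 0.0), w_img - t.box.width)
                y_new = min(max(t.box.y_min + dy, 0.0), h_img - t.box.height)
                box = Box(x_new, y_new, t.box.width, t.box.height).clip(w_img, h_img)
            else:
                box = t.box
            conf = float(_beta_conf(rng, error_model.tp_confidence, 1)[0])
            detections.append(Detection(t.image_id, t.side, fold, t.class_label, box, conf))
            provenance.append(("TP", t.truth_id))
        for image_id in image_ids:
            side = image_id.rsplit("_", 1)[-1]
            n_fp = rng.poisson(error_model.fp_rate)
            for _ in range(int(n_fp)):
                bw = float(np.exp(rng.normal(np.log(40.0), 0.4)))
                bh = float(np.exp(rng.normal(np.log(40.0), 0.4)))
                x = rng.uniform(0, w_img - bw)
                y = rng.uniform(0, h_img - bh)
                cls = classes[int(rng.integers(len(classes)))]
                conf = float(_beta_conf(rng, error_model.fp_confidence, 1)[0])
                detections.append(Detection(image_id, side, fold, cls, Box(x, y, bw, bh), conf))
                provenance.append(("FP", -1))
    return detections, provenance
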