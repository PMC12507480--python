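"""Lamellar thickness from en-face OCT images.

Pipeline: central 400x400 crop -> per-pixel feature stack -> 2-class
Random Forest (bright vs dark band) -> boundary tracing from operator seed
points through the class-probability transition -> perpendicular distance
between adjacent boundaries, converted to micrometres.

The feature stack comprises: the original image; detail-preserving
anisotropic diffusion (DPAD) at 1000 and 5000 iterations; z-scored median
filters (5x5, 15x15, 31x31, 100x3, 3x100); z-scored Haralick textures
(angular second moment, entropy, sum of squares) of the DPAD image in a
7x7 window and of the original in a 7x21 window, with vertical
co-occurrence offsets of 1 and 2 rows; and the z-scored speckle index
(local SD / local mean) in 5x5, 11x11, 101x3 and 3x101 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .types import LamellaeParams  # noqa: F401  (re-exported for convenience)

__all__ = [
    "OCTImage",
    "FeatureStack",
    "ThicknessResult",
    "BoundaryRejected",
    "crop_central",
    "write_oct_image",
    "read_oct_image",
    "write_boundaries_json",
    "read_boundaries_json",
    "dpad",
    "haralick_planes",
    "speckle_index",
    "compute_features",
    "train_classifier",
    "save_classifier",
    "load_classifier",
    "LamellaeClassifier",
    "trace_boundaries",
    "measure_layers",
    "measure_thickness",
    "seeds_from_truth",
]

DEFAULT_PIXEL_SIZE_UM = 10.23


@dataclass
class OCTImage:
    """A single-channel en-face OCT slice."""

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D single channel")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


def write_oct_image(image: OCTImage, path) -> None:
    """Write as 16-bit grayscale TIFF, scaling the intensity range to full."""
    import tifffile

    data = image.data
    hi = float(np.max(data))
    scaled = (data / hi * 65535.0 if hi > 0 else data).astype(np.uint16)
    tifffile.imwrite(path, scaled, metadata={"pixel_size_um": image.pixel_size_um})


def read_oct_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> OCTImage:
    import tifffile

    return OCTImage(
        tifffile.imread(path).astype(np.float32), pixel_size_um=pixel_size_um
    )


def write_boundaries_json(boundaries: list[np.ndarray], path) -> None:
    """Ground-truth or traced borders as JSON polylines (row per column)."""
    import json
    from pathlib import Path

    Path(path).write_text(
        json.dumps([np.asarray(b, dtype=float).tolist() for b in boundaries])
    )


def read_boundaries_json(path) -> list[np.ndarray]:
    import json
    from pathlib import Path

    return [np.asarray(b, dtype=float) for b in json.loads(Path(path).read_text())]


def crop_central(image: OCTImage, size_px: int = 400) -> OCTImage:
    """Centered ``size_px`` square crop; odd margins resolve top-left."""
    h, w = image.data.shape
    if h < size_px or w < size_px:
        raise ValueError(f"image {h}x{w} smaller than requested {size_px} crop")
    r0 = (h - size_px) // 2
    c0 = (w - size_px) // 2
    return OCTImage(
        data=image.data[r0 : r0 + size_px, c0 : c0 + size_px],
        pixel_size_um=image.pixel_size_um,
        meta=dict(image.meta, crop=(r0, c0, size_px)),
    )


# ---------------------------------------------------------------------------
# DPAD speckle filtering


@njit(cache=True)
def _dpad_run(img, n_iter, dt, q0_stride):  # pragma: no cover - numba kernel
    h, w = img.shape
    cur = img.copy()
    nxt = np.empty_like(cur)
    rs = np.empty((h, w), np.float32)
    rs2 = np.empty((h, w), np.float32)
    q2 = np.empty((h, w), np.float32)
    c = np.empty((h, w), np.float32)
    for _ in range(n_iter):
        # separable 3x3 sums with replicated edges
        for i in range(h):
            for j in range(w):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < w - 1 else w - 1
                v = cur[i, jm] + cur[i, j] + cur[i, jp]
                v2 = (
                    cur[i, jm] * cur[i, jm]
                    + cur[i, j] * cur[i, j]
                    + cur[i, jp] * cur[i, jp]
                )
                rs[i, j] = v
                rs2[i, j] = v2
        for i in range(h):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < h - 1 else h - 1
            for j in range(w):
                s = rs[im, j] + rs[i, j] + rs[ip, j]
                s2 = rs2[im, j] + rs2[i, j] + rs2[ip, j]
                m = s / 9.0
                var = s2 / 9.0 - m * m
                if var < 0.0:
                    var = 0.0
                q2[i, j] = var / (m * m + 1e-12)
        # speckle (homogeneous-region) coefficient of variation: a robust
        # median over a strided subsample stands in for the mode estimator
        sub = q2[::q0_stride, ::q0_stride].copy().ravel()
        q02 = np.median(sub)
        if q02 < 1e-9:
            q02 = 1e-9
        for i in range(h):
            for j in range(w):
                q2ij = q2[i, j]
                if q2ij < 1e-12:
                    q2ij = 1e-12
                cc = (q02 * (1.0 + q2ij)) / (q2ij * (1.0 + q02))
                if cc > 1.0:
                    cc = 1.0
                c[i, j] = cc
        for i in range(h):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < h - 1 else h - 1
            for j in range(w):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < w - 1 else w - 1
                div = (
                    0.5 * (c[ip, j] + c[i, j]) * (cur[ip, j] - cur[i, j])
                    + 0.5 * (c[im, j] + c[i, j]) * (cur[im, j] - cur[i, j])
                    + 0.5 * (c[i, jp] + c[i, j]) * (cur[i, jp] - cur[i, j])
                    + 0.5 * (c[i, jm] + c[i, j]) * (cur[i, jm] - cur[i, j])
                )
                nxt[i, j] = cur[i, j] + dt * div
        cur, nxt = nxt, cur
    return cur


def dpad(
    image: np.ndarray,
    iterations: tuple[int, ...] = (1000, 5000),
    dt: float = 0.2,
    q0_stride: int = 3,
) -> list[np.ndarray]:
    """Detail-preserving anisotropic diffusion snapshots.

    The diffusivity is the Kuan-weight form ``c = q0^2 (1+q^2) / (q^2
    (1+q0^2))`` clipped to [0, 1], where ``q^2`` is the local (3x3)
    squared coefficient of variation and ``q0^2`` its image-wide median —
    the homogeneous-speckle estimate.  Snapshots are returned at each
    requested iteration count (ascending), computed in one pass.
    """
    its = sorted(iterations)
    img = np.ascontiguousarray(image, dtype=np.float32)
    out = []
    done = 0
    cur = img
    for n in its:
        cur = _dpad_run(cur, n - done, np.float32(dt), q0_stride)
        done = n
        out.append(cur.copy())
    return out


# ---------------------------------------------------------------------------
# Texture features


def _zscore(plane: np.ndarray) -> np.ndarray:
    m = float(np.mean(plane))
    s = float(np.std(plane))
    if s < 1e-12:
        return np.zeros_like(plane, dtype=np.float32)  # constant-plane convention
    return ((plane - m) / s).astype(np.float32)


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = float(np.min(img)), float(np.max(img))
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.int32)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def haralick_planes(
    img: np.ndarray,
    window: tuple[int, int],
    offset_rows: int,
    levels: int = 32,
) -> dict[str, np.ndarray]:
    """Windowed Haralick ASM, entropy and sum-of-squares.

    The co-occurrence pairs are (pixel, pixel ``offset_rows`` below); local
    pair histograms are accumulated with box filters so the cost is one
    uniform filter per observed grey-level pair.  Sum of squares is the
    GLCM marginal variance, i.e. the windowed variance of the quantized
    image.
    """
    q = _quantize(img, levels)
    d = offset_rows
    a = q[:-d, :]
    b = q[d:, :]
    codes = a * levels + b
    h, w = codes.shape
    win = (min(window[0], h), min(window[1], w))
    asm = np.zeros((h, w), dtype=np.float32)
    ent = np.zeros((h, w), dtype=np.float32)
    for code in np.unique(codes):
        ind = (codes == code).astype(np.float32)
        p = ndimage.uniform_filter(ind, size=win, mode="reflect")
        asm += p * p
        lp = np.log2(np.where(p > 0, p, 1.0))
        ent -= (p * lp).astype(np.float32)
    af = a.astype(np.float32)
    m1 = ndimage.uniform_filter(af, size=win, mode="reflect")
    m2 = ndimage.uniform_filter(af * af, size=win, mode="reflect")
    ssq = np.maximum(m2 - m1 * m1, 0.0).astype(np.float32)
    pad = ((0, d), (0, 0))
    return {
        "asm": np.pad(asm, pad, mode="edge"),
        "entropy": np.pad(ent, pad, mode="edge"),
        "ssq": np.pad(ssq, pad, mode="edge"),
    }


def speckle_index(img: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Local coefficient of variation (SD / mean)."""
    f = img.astype(np.float32)
    m1 = ndimage.uniform_filter(f, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(f * f, size=window, mode="reflect")
    sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    return sd / (np.abs(m1) + 1e-12)


@dataclass
class FeatureStack:
    """Named, ordered per-pixel feature planes (float32, image-shaped)."""

    names: list[str]
    planes: np.ndarray  # (n_features, H, W)

    def as_matrix(self) -> np.ndarray:
        f, h, w = self.planes.shape
        return self.planes.reshape(f, h * w).T

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


MEDIAN_WINDOWS = ((5, 5), (15, 15), (31, 31), (100, 3), (3, 100))
SPECKLE_WINDOWS = ((5, 5), (11, 11), (101, 3), (3, 101))


def compute_features(
    image: OCTImage,
    dpad_iterations: tuple[int, int] = (1000, 5000),
    glcm_levels: int = 32,
) -> FeatureStack:
    """The full deterministic per-pixel feature stack (21 planes)."""
    img = image.data.astype(np.float32)
    names: list[str] = []
    planes: list[np.ndarray] = []

    names.append("original")
    planes.append(img)

    dpad_imgs = dpad(img, iterations=dpad_iterations)
    for n_it, d_img in zip(sorted(dpad_iterations), dpad_imgs):
        names.append(f"dpad{n_it}")
        planes.append(d_img)

    for wnd in MEDIAN_WINDOWS:
        med = ndimage.median_filter(img, size=wnd, mode="reflect")
        names.append(f"median{wnd[0]}x{wnd[1]}_z")
        planes.append(_zscore(med))

    # Haralick of the DPAD-filtered image (7x7 window, vertical offset 1)
    for feat, plane in haralick_planes(
        dpad_imgs[0], (7, 7), offset_rows=1, levels=glcm_levels
    ).items():
        names.append(f"haralick_dpad_7x7_d1_{feat}_z")
        planes.append(_zscore(plane))
    # Haralick of the original (7x21 window, vertical offsets 1 and 2)
    for d in (1, 2):
        for feat, plane in haralick_planes(
            img, (7, 21), offset_rows=d, levels=glcm_levels
        ).items():
            names.append(f"haralick_orig_7x21_d{d}_{feat}_z")
            planes.append(_zscore(plane))

    for wnd in SPECKLE_WINDOWS:
        names.append(f"speckle{wnd[0]}x{wnd[1]}_z")
        planes.append(_zscore(speckle_index(img, wnd)))

    return FeatureStack(names=names, planes=np.stack(planes).astype(np.float32))


# ---------------------------------------------------------------------------
# Random-Forest pixel classification


@dataclass
class LamellaeClassifier:
    """A fitted bright/dark pixel classifier."""

    forest: RandomForestClassifier
    feature_names: list[str]

    def predict_proba_image(self, stack: FeatureStack) -> np.ndarray:
        """Per-pixel probability of the *bright* class."""
        if stack.names != self.feature_names:
            raise ValueError("feature stack does not match training features")
        h, w = stack.shape
        proba = self.forest.predict_proba(stack.as_matrix())
        bright_col = list(self.forest.classes_).index(1)
        return proba[:, bright_col].reshape(h, w)


def train_classifier(
    stacks: list[FeatureStack],
    bright_masks: list[np.ndarray],
    n_trees: int = 100,
    max_features: int = 5,
    seed: int = 0,
    max_pixels_per_image: int = 8000,
) -> LamellaeClassifier:
    """Fit a 2-class Random Forest (100 trees, 5 candidate features/split).

    Training pixels are subsampled uniformly per image (seeded).  Labels
    must contain both classes.
    """
    if not stacks:
        raise ValueError("need at least one labelled image")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for stack, mask in zip(stacks, bright_masks):
        x = stack.as_matrix()
        y = np.asarray(mask, dtype=np.int32).ravel()
        if y.size != x.shape[0]:
            raise ValueError("label mask shape does not match feature stack")
        if max_pixels_per_image and y.size > max_pixels_per_image:
            idx = rng.choice(y.size, size=max_pixels_per_image, replace=False)
            x, y = x[idx], y[idx]
        xs.append(x)
        ys.append(y)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    if np.unique(y_all).size < 2:
        raise ValueError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(x_all, y_all)
    return LamellaeClassifier(forest=forest, feature_names=list(stacks[0].names))


def save_classifier(clf: LamellaeClassifier, path) -> None:
    """Persist a fitted classifier (joblib) with a format-version tag."""
    import joblib

    joblib.dump(
        {"format_version": 1, "feature_names": clf.feature_names, "forest": clf.forest},
        path,
    )


def load_classifier(path) -> LamellaeClassifier:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognised classifier file version")
    return LamellaeClassifier(
        forest=payload["forest"], feature_names=list(payload["feature_names"])
    )


# ---------------------------------------------------------------------------
# Boundary tracing and thickness measurement


class BoundaryRejected(ValueError):
    """No class transition near the seed polyline for too many columns."""


def seeds_from_truth(
    boundary_rows: np.ndarray,
    n_seeds: int = 15,
    jitter_px: float = 3.0,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Emulated operator initialisation: evenly spaced, vertically jittered
    markers along a known border.  Returns an ``(n_seeds, 2)`` array of
    (column, row)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = boundary_rows.size
    cols = np.linspace(0, w - 1, n_seeds)
    rows = np.interp(cols, np.arange(w), boundary_rows)
    rows = rows + rng.normal(0.0, jitter_px, size=rows.shape)
    return np.column_stack([cols, rows])


def _transition_rows(p_col: np.ndarray) -> np.ndarray:
    """Subpixel rows where P(bright) crosses 0.5 in one column."""
    g = p_col - 0.5
    s = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
    if s.size == 0:
        return np.empty(0)
    frac = -g[s] / (g[s + 1] - g[s])
    return s + frac


def trace_boundaries(
    prob_bright: np.ndarray,
    seeds_per_border: list[np.ndarray],
    capture_radius_px: float = 10.0,
    max_missing_frac: float = 0.05,
    smooth_sigma: float = 1.0,
) -> list[np.ndarray]:
    """Snap each seeded border onto the nearest class transition.

    For every column the border row is the subpixel zero crossing of
    ``P(bright) - 0.5`` closest to the interpolated seed polyline, within
    ``capture_radius_px``.  Columns with no transition in range are filled
    by interpolation, but a border missing more than ``max_missing_frac``
    of its columns is rejected.
    """
    p = ndimage.gaussian_filter(
        prob_bright.astype(np.float32), sigma=(smooth_sigma, smooth_sigma)
    )
    h, w = p.shape
    cols = np.arange(w)
    borders: list[np.ndarray] = []
    for k, seeds in enumerate(seeds_per_border):
        seeds = np.asarray(seeds, dtype=float)
        order = np.argsort(seeds[:, 0])
        sx, sy = seeds[order, 0], seeds[order, 1]
        guide = np.interp(cols, sx, sy)
        rows = np.full(w, np.nan)
        for x in cols:
            cands = _transition_rows(p[:, x])
            if cands.size == 0:
                continue
            dist = np.abs(cands - guide[x])
            j = int(np.argmin(dist))
            if dist[j] <= capture_radius_px:
                rows[x] = cands[j]
        missing = np.isnan(rows)
        if missing.mean() > max_missing_frac:
            raise BoundaryRejected(
                f"border {k}: no transition within {capture_radius_px} px of the "
                f"seed line for {missing.mean():.1%} of columns"
            )
        if missing.any():
            rows[missing] = np.interp(cols[missing], cols[~missing], rows[~missing])
        borders.append(rows)
    return borders


@dataclass
class ThicknessResult:
    """Perpendicular thickness statistics for one image."""

    per_layer_mean_um: np.ndarray
    mean_um: float
    layer_count: int
    distances_um: np.ndarray
    coverage: float  # fraction of nodes whose normal hit the partner border


def _perpendicular_distances(
    upper: np.ndarray,
    lower: np.ndarray,
    node_step: int,
    tangent_sigma: float = 3.0,
) -> tuple[np.ndarray, int]:
    """March along the local normal of the upper border to the lower one."""
    w = upper.size
    up_s = ndimage.gaussian_filter1d(upper, tangent_sigma, mode="nearest")
    slope = np.gradient(up_s)
    xs = np.arange(0, w, node_step)
    gaps = lower - upper
    t_max = float(np.max(gaps)) * 2.0 + 4.0
    dists, misses = [], 0
    col = np.arange(w)
    for x0 in xs:
        s = slope[x0]
        norm = np.hypot(s, 1.0)
        nx, ny = -s / norm, 1.0 / norm  # normal pointing to increasing row
        ts = np.arange(0.0, t_max, 0.25)
        px = x0 + nx * ts
        py = upper[x0] + ny * ts
        inside = (px >= 0) & (px <= w - 1)
        if not inside.any():
            misses += 1
            continue
        px, py, ts = px[inside], py[inside], ts[inside]
        g = py - np.interp(px, col, lower)
        sign_change = np.flatnonzero((g[:-1] < 0) & (g[1:] >= 0))
        if sign_change.size == 0:
            misses += 1
            continue
        j = sign_change[0]
        frac = -g[j] / (g[j + 1] - g[j]) if g[j + 1] != g[j] else 0.0
        dists.append(ts[j] + frac * (ts[j + 1] - ts[j]))
    return np.asarray(dists), misses


def measure_layers(
    borders: list[np.ndarray | None],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    node_step: int = 4,
) -> ThicknessResult:
    """Thickness over layers whose *both* borders were traced.

    ``borders`` is the vertically ordered border list with ``None`` marking
    borders that failed tracing; only adjacent present pairs form included
    layers (a layer needs two labelled borders).
    """
    pairs = [
        (borders[i], borders[i + 1])
        for i in range(len(borders) - 1)
        if borders[i] is not None and borders[i + 1] is not None
    ]
    if not pairs:
        raise ValueError("no layer has both borders traced")
    per_layer, all_d = [], []
    total_nodes = total_miss = 0
    for up, lo in pairs:
        if np.any(np.asarray(lo) <= np.asarray(up)):
            raise ValueError("boundaries cross; cannot measure thickness")
        d, misses = _perpendicular_distances(
            np.asarray(up, dtype=float), np.asarray(lo, dtype=float), node_step
        )
        total_nodes += d.size + misses
        total_miss += misses
        if d.size == 0:
            continue
        per_layer.append(float(np.mean(d)) * pixel_size_um)
        all_d.append(d * pixel_size_um)
    if not all_d:
        raise ValueError("no perpendicular measurement landed on a partner border")
    distances = np.concatenate(all_d)
    return ThicknessResult(
        per_layer_mean_um=np.asarray(per_layer),
        mean_um=float(np.mean(distances)),
        layer_count=len(per_layer),
        distances_um=distances,
        coverage=1.0 - total_miss / max(total_nodes, 1),
    )


def measure_thickness(
    boundaries: list[np.ndarray],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    node_step: int = 4,
) -> ThicknessResult:
    """Mean lamellar thickness from vertically ordered, non-crossing borders.

    At nodes along each upper border the distance is measured along the
    local normal to the next border down; the overall mean is the
    unweighted mean over all node measurements of all layers.
    """
    if len(boundaries) < 2:
        raise ValueError("need at least two boundaries spanning the image")
    order = np.argsort([float(np.mean(b)) for b in boundaries])
    bs = [np.asarray(boundaries[i], dtype=float) for i in order]
    for up, lo in zip(bs[:-1], bs[1:]):
        if np.any(lo <= up):
            raise ValueError("boundaries cross; cannot measure thickness")
    per_layer, all_d = [], []
    total_nodes = 0
    total_miss = 0
    for up, lo in zip(bs[:-1], bs[1:]):
        d, misses = _perpendicular_distances(up, lo, node_step)
        total_nodes += d.size + misses
        total_miss += misses
        if d.size == 0:
            raise ValueError("no perpendicular measurement landed on the partner")
        per_layer.append(float(np.mean(d)) * pixel_size_um)
        all_d.append(d * pixel_size_um)
    distances = np.concatenate(all_d)
    return ThicknessResult(
        per_layer_mean_um=np.asarray(per_layer),
        mean_um=float(np.mean(distances)),
        layer_count=len(per_layer),
        distances_um=distances,
        coverage=1.0 - total_miss / max(total_nodes, 1),
    )
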