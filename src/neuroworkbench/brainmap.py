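"""Brain-shape averaging, stiffness/synapse map fusion and association tests.

Per embryo: a manually annotated brain outline, an AFM grid of elastic
moduli, and an FM1-43 fluorescence image.  Outlines are resampled to 150
equally spaced points and affinely normalised via an ellipse fit; a mean
contour is computed; dynamic time warping matches each outline to the mean,
and a linear radial-basis-function warp built on the matched points carries
AFM coordinates and pixel coordinates into the common shape space.  Fused
maps are per-grid-node medians across the cohort.  Association between
stiffness and fluorescence is quantified by Pearson correlation and by a
2x2 contingency table (60th-percentile split) with an odds ratio, a
two-sided Fisher exact p-value, and conditional probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree
from skimage.measure import EllipseModel, points_in_poly, profile_line

__all__ = [
    "BrainSample",
    "AffineNormalisation",
    "FusedMaps",
    "ContingencyTable",
    "bin_image",
    "resample_contour",
    "ellipse_align",
    "orient_clockwise",
    "mean_contour",
    "dtw_correspond",
    "rbf_warp",
    "fuse_maps",
    "circle_average",
    "fisher_exact_p",
    "odds_ratio",
    "associate",
    "line_profile_ratio",
]


@dataclass
class BrainSample:
    """One embryo: closed outline (x, y), AFM points, FM1-43 image."""

    outline: np.ndarray  # (n, 2) x, y
    afm_points: np.ndarray  # (m, 3) x, y, modulus_pa
    fm_image: np.ndarray  # 2-D
    fm_pixel: float = 1.0  # image units per pixel

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        self.afm_points = np.asarray(self.afm_points, dtype=float)
        self.fm_image = np.asarray(self.fm_image, dtype=float)


@dataclass
class AffineNormalisation:
    """Ellipse-based affine transform into the unit-circle frame."""

    centre: np.ndarray
    matrix: np.ndarray  # 2x2: rotate major axis to +x, scale axes to 1

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.centre) @ self.matrix.T


@dataclass
class ContingencyTable:
    """2x2 counts of (stiff/soft x high/low) with derived statistics."""

    n_stiff_high: int
    n_stiff_low: int
    n_soft_high: int
    n_soft_low: int

    @property
    def total(self) -> int:
        return self.n_stiff_high + self.n_stiff_low + self.n_soft_high + self.n_soft_low

    @property
    def odds_ratio(self) -> float | None:
        """O = (stiff/soft odds among high) / (stiff/soft odds among low).

        None (undefined) when a denominator of the chain is zero.
        """
        if min(self.n_soft_high, self.n_soft_low, self.n_stiff_low) == 0:
            return None
        return (self.n_stiff_high / self.n_soft_high) / (
            self.n_stiff_low / self.n_soft_low
        )

    @property
    def fisher_p(self) -> float:
        return fisher_exact_p(
            self.n_stiff_high, self.n_stiff_low, self.n_soft_high, self.n_soft_low
        )

    def conditional_probs(self) -> pd.DataFrame:
        """P(AFM class | FM class): columns sum to 1."""
        counts = pd.DataFrame(
            [[self.n_stiff_high, self.n_stiff_low], [self.n_soft_high, self.n_soft_low]],
            index=["stiff", "soft"],
            columns=["high", "low"],
        )
        return counts / counts.sum(axis=0)


# ---------------------------------------------------------------------------
# image and contour preprocessing


def bin_image(image: np.ndarray, block: int = 15) -> np.ndarray:
    """Average over block x block pixel tiles, then normalise to the maximum.

    Trailing rows/columns that do not fill a tile are dropped.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    img = np.asarray(image, dtype=float)
    h, w = (img.shape[0] // block) * block, (img.shape[1] // block) * block
    if h == 0 or w == 0:
        raise ValueError("image smaller than one block")
    binned = img[:h, :w].reshape(h // block, block, w // block, block).mean(axis=(1, 3))
    peak = binned.max()
    return binned / peak if peak > 0 else binned


def resample_contour(outline: np.ndarray, n: int = 150) -> np.ndarray:
    """Resample a closed contour to n points equally spaced in arc length."""
    if n < 3:
        raise ValueError("need at least 3 points")
    pts = np.asarray(outline, dtype=float)
    if len(pts) < 3:
        raise ValueError("outline needs at least 3 vertices")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[0]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate outline of zero length")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def ellipse_align(contour: np.ndarray) -> tuple[np.ndarray, AffineNormalisation]:
    """Normalise a contour by its least-squares ellipse fit.

    The fitted centre moves to the origin, the major axis rotates onto +x,
    and both half-axes scale to 1, so every brain maps near the unit circle.
    """
    pts = np.asarray(contour, dtype=float)
    model = EllipseModel()
    if not model.estimate(pts) or not np.isfinite(model.params).all():
        raise ValueError("ellipse fit failed (degenerate contour?)")
    xc, yc, a, b, theta = model.params
    if a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse axes")
    if b > a:  # ensure a is the major half-axis
        a, b = b, a
        theta += np.pi / 2.0
    # the fitted orientation is ambiguous up to 180 degrees; wrap the applied
    # rotation into (-90, 90] so consistently mounted samples are never
    # flipped head-to-tail relative to each other
    theta = (theta + np.pi / 2.0) % np.pi - np.pi / 2.0
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, -s], [s, c]])
    scale = np.diag([1.0 / a, 1.0 / b])
    tf = AffineNormalisation(centre=np.array([xc, yc]), matrix=scale @ rot)
    return tf.apply(pts), tf


def _signed_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def orient_clockwise(contour: np.ndarray) -> np.ndarray:
    """Enforce clockwise orientation in image coordinates (y downward).

    With y increasing downward, clockwise on screen corresponds to positive
    shoelace area in the raw (x, y) values.
    """
    return contour if _signed_area(contour) > 0 else contour[::-1].copy()


def _shift_to_start(contour: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Circularly shift so that the point nearest ``reference`` comes first."""
    d = np.hypot(*(contour - reference).T)
    return np.roll(contour, -int(np.argmin(d)), axis=0)


def mean_contour(
    contours: list[np.ndarray], reference: np.ndarray | None = None
) -> np.ndarray:
    """Pointwise mean of aligned contours.

    Each contour is oriented clockwise and circularly shifted so all start at
    the point nearest a common reference (default: (1, 0), the major-axis
    vertex of the normalised frame), then x and y are averaged positionwise.
    """
    if not contours:
        raise ValueError("need at least one contour")
    n = len(contours[0])
    if any(len(c) != n for c in contours):
        raise ValueError("contours must have equal length")
    ref = np.array([1.0, 0.0]) if reference is None else np.asarray(reference, float)
    prepared = [_shift_to_start(orient_clockwise(c), ref) for c in contours]
    return np.mean(prepared, axis=0)


# ---------------------------------------------------------------------------
# correspondence and warping


def dtw_correspond(
    contour: np.ndarray, mean: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise correspondence contour -> mean via dynamic time warping.

    Standard DTW over the two point sequences with Euclidean cost (the
    cyclic start is handled by the prior circular shift).  Where several
    contour points map to one mean point their coordinates are averaged, so
    the result is one control-point pair per mean point:
    returns (matched_source_points, mean_points), both (m, 2).
    """
    a = np.asarray(contour, dtype=float)
    b = np.asarray(mean, dtype=float)
    n, m = len(a), len(b)
    cost = np.hypot(
        a[:, 0][:, None] - b[:, 0][None, :], a[:, 1][:, None] - b[:, 1][None, :]
    )
    big = np.inf
    acc = np.full((n + 1, m + 1), big)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        ci = cost[i - 1]
        prev = acc[i - 1]
        cur = acc[i]
        for j in range(1, m + 1):
            cur[j] = ci[j - 1] + min(prev[j], prev[j - 1], cur[j - 1])
    # backtrack
    i, j = n, m
    path = []
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        moves = ((acc[i - 1, j - 1], i - 1, j - 1), (acc[i - 1, j], i - 1, j), (acc[i, j - 1], i, j - 1))
        _, i, j = min(moves)
    path.reverse()
    src = np.zeros((m, 2))
    cnt = np.zeros(m)
    for pi, pj in path:
        src[pj] += a[pi]
        cnt[pj] += 1
    covered = cnt > 0
    src[covered] /= cnt[covered, None]
    src, dst = src[covered], b[covered]
    # one contour point can also map to several mean points; collapse those
    # too, otherwise duplicated control sources make the RBF system singular
    _, inv = np.unique(np.round(src, 9), axis=0, return_inverse=True)
    k = inv.max() + 1
    src_u = np.zeros((k, 2))
    dst_u = np.zeros((k, 2))
    for g in range(k):
        sel = inv == g
        src_u[g] = src[sel].mean(axis=0)
        dst_u[g] = dst[sel].mean(axis=0)
    return src_u, dst_u


def rbf_warp(
    control_src: np.ndarray, control_dst: np.ndarray, coords: np.ndarray
) -> np.ndarray:
    """Warp coordinates with a linear-kernel RBF built on control points.

    phi(r) = r plus a degree-1 polynomial term: exact at the control points
    and reproducing affine maps exactly.
    """
    interp = RBFInterpolator(
        np.asarray(control_src, float),
        np.asarray(control_dst, float),
        kernel="linear",
        degree=1,
    )
    coords = np.asarray(coords, dtype=float)
    return interp(coords.reshape(-1, 2)).reshape(coords.shape)


# ---------------------------------------------------------------------------
# cohort fusion


@dataclass
class FusedMaps:
    """Cohort-averaged shape, stiffness grid and fluorescence grid."""

    mean_contour: np.ndarray  # (150, 2)
    stiff_nodes: np.ndarray  # (k, 2) grid nodes inside the mean contour
    stiff_values: np.ndarray  # per-node median modulus
    fm_nodes: np.ndarray  # (l, 2)
    fm_values: np.ndarray  # per-node median intensity
    circle_radii: np.ndarray = field(default_factory=lambda: np.empty(0))

    def paired_nodes(self) -> pd.DataFrame:
        """Stiffness and circle-averaged FM intensity at each AFM grid node.

        FM values are averaged within non-overlapping circles centred on the
        AFM nodes; each radius is half the distance to the nearest other
        node, which maximises coverage under the non-overlap constraint.
        Returns columns x, y, stiffness, fm, radius for nodes where both
        maps have coverage.
        """
        radii = _half_nn_distance(self.stiff_nodes)
        vals = circle_average(self.fm_nodes, self.fm_values, self.stiff_nodes, radii)
        ok = np.isfinite(vals) & np.isfinite(self.stiff_values)
        return pd.DataFrame(
            {
                "x": self.stiff_nodes[ok, 0],
                "y": self.stiff_nodes[ok, 1],
                "stiffness": self.stiff_values[ok],
                "fm": vals[ok],
                "radius": radii[ok],
            }
        )


def _half_nn_distance(nodes: np.ndarray) -> np.ndarray:
    d = np.hypot(
        nodes[:, 0][:, None] - nodes[:, 0][None, :],
        nodes[:, 1][:, None] - nodes[:, 1][None, :],
    )
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) / 2.0


def circle_average(
    points: np.ndarray, values: np.ndarray, nodes: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Mean of ``values`` at ``points`` within each node's circle (nan if empty)."""
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    out = np.full(len(nodes), np.nan)
    for k, (node, r) in enumerate(zip(np.asarray(nodes, float), radii)):
        sel = np.hypot(points[:, 0] - node[0], points[:, 1] - node[1]) <= r
        sel &= np.isfinite(values)
        if sel.any():
            out[k] = values[sel].mean()
    return out


def _grid_inside(contour: np.ndarray, spacing: float, margin: float = 0.0) -> np.ndarray:
    xmin, ymin = contour.min(axis=0)
    xmax, ymax = contour.max(axis=0)
    xs = np.arange(xmin, xmax + spacing / 2, spacing)
    ys = np.arange(ymin, ymax + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    inside = points_in_poly(nodes, contour)
    return nodes[inside]


def fuse_maps(samples: list[BrainSample], n_points: int = 150, block: int = 15) -> FusedMaps:
    """Register a cohort into the mean shape and fuse its maps.

    Steps: resample outlines, affine-normalise via ellipse fits (the same
    transform is applied to AFM and pixel coordinates), average the aligned
    contours, DTW-match each contour to the mean, RBF-warp coordinates into
    mean-shape space, interpolate each sample onto common grids (AFM-pitch
    grid for stiffness, binned-pixel-pitch grid for FM) and take per-node
    medians across the cohort.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    aligned_outlines, tfs = [], []
    for s in samples:
        contour = resample_contour(s.outline, n_points)
        aligned, tf = ellipse_align(contour)
        aligned_outlines.append(aligned)
        tfs.append(tf)
    mean = mean_contour(aligned_outlines)

    warped_afm, warped_px = [], []
    nn_spacing, px_spacing = [], []
    for s, contour, tf in zip(samples, aligned_outlines, tfs):
        prepared = _shift_to_start(orient_clockwise(contour), np.array([1.0, 0.0]))
        src, dst = dtw_correspond(prepared, mean)
        afm_xy = tf.apply(s.afm_points[:, :2])
        afm_warp = rbf_warp(src, dst, afm_xy)
        warped_afm.append(np.column_stack([afm_warp, s.afm_points[:, 2]]))
        nn_spacing.append(np.median(_half_nn_distance(afm_warp) * 2.0))

        binned = bin_image(s.fm_image, block=block)
        h, w = binned.shape
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        px_xy = np.column_stack(
            [(cols.ravel() + 0.5) * block * s.fm_pixel, (rows.ravel() + 0.5) * block * s.fm_pixel]
        )
        px_aligned = tf.apply(px_xy)
        px_warp = rbf_warp(src, dst, px_aligned)
        warped_px.append(np.column_stack([px_warp, binned.ravel()]))
        px_spacing.append(np.median(_half_nn_distance(px_warp[:: max(1, len(px_warp) // 400)]) * 2.0))

    stiff_nodes = _grid_inside(mean, float(np.median(nn_spacing)))
    fm_nodes = _grid_inside(mean, float(np.median(px_spacing)))


    def fused(node_xy: np.ndarray, clouds: list[np.ndarray], reach: float) -> np.ndarray:
        # nearest-measurement regridding: each node takes the value of the
        # closest warped data point of each sample (or no value if none lies
        # within ``reach``), and the cohort median is taken per node.  This
        # keeps one measurement cluster per node instead of blending
        # neighbouring clusters into spatially correlated estimates.
        stack = []
        for cloud in clouds:
            tree = cKDTree(cloud[:, :2])
            dist, idx = tree.query(node_xy)
            vals = np.where(dist <= reach, cloud[idx, 2], np.nan)
            stack.append(vals)
        with np.errstate(all="ignore"):
            return np.nanmedian(np.asarray(stack), axis=0)

    stiff_pitch = float(np.median(nn_spacing))
    fm_pitch = float(np.median(px_spacing))
    stiff_values = fused(stiff_nodes, warped_afm, reach=0.75 * stiff_pitch)
    fm_values = fused(fm_nodes, warped_px, reach=1.5 * fm_pitch)
    return FusedMaps(
        mean_contour=mean,
        stiff_nodes=stiff_nodes,
        stiff_values=stiff_values,
        fm_nodes=fm_nodes,
        fm_values=fm_values,
        circle_radii=_half_nn_distance(stiff_nodes),
    )


# ---------------------------------------------------------------------------
# association statistics


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Point-probability method: sum the hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (within a 1e-9 relative tolerance for ties).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()))


def odds_ratio(table: ContingencyTable) -> float | None:
    return table.odds_ratio


def associate(
    stiffness: np.ndarray, fm: np.ndarray, percentile: float = 60.0
) -> tuple[float, ContingencyTable]:
    """Pearson r plus 60th-percentile contingency statistics.

    A point is "stiff"/"high" if its value strictly exceeds the given
    percentile (linear-interpolation definition) of its own distribution.
    """
    stiffness = np.asarray(stiffness, dtype=float)
    fm = np.asarray(fm, dtype=float)
    ok = np.isfinite(stiffness) & np.isfinite(fm)
    stiffness, fm = stiffness[ok], fm[ok]
    if len(stiffness) < 3:
        raise ValueError("need at least 3 paired points")
    r = float(stats.pearsonr(stiffness, fm)[0])
    stiff = stiffness > np.percentile(stiffness, percentile)
    high = fm > np.percentile(fm, percentile)
    table = ContingencyTable(
        n_stiff_high=int((stiff & high).sum()),
        n_stiff_low=int((stiff & ~high).sum()),
        n_soft_high=int((~stiff & high).sum()),
        n_soft_low=int((~stiff & ~high).sum()),
    )
    return r, table


def line_profile_ratio(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 100,
) -> tuple[np.ndarray, float]:
    """Max/mean ratio of the intensity profile along a wide stripe.

    The profile is the across-width mean at each along-stripe position of a
    ``width_px``-wide stripe from ``start`` to ``end`` (row, col coords).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    profile = profile_line(
        img, start, end, linewidth=width_px, reduce_func=np.mean, mode="reflect"
    )
    mean = float(profile.mean())
    if mean <= 0:
        raise ValueError("stripe has non-positive mean intensity")
    return profile, float(profile.max() / mean)
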