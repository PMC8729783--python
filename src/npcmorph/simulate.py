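"""Synthetic SMLM data: random hard-disc NPC fields, labelling, rendering.

The null model of NPC organization is complete spatial randomness constrained
by steric exclusion: pore centers are uniform on a flat nuclear-envelope patch
subject to a minimum pairwise distance of one pore diameter.  On top of the
geometry the generator emulates DNA-PAINT imaging of a tagged nucleoporin:
each pore carries a fixed number of protein copies on its ring, each copy is
labelled independently (Bernoulli), each labelled copy produces a Poisson
number of localizations, and each localization is displaced by isotropic
Gaussian noise of the stated localization precision.

All lengths are in nm unless the name says pixels; 1 pixel = 10 nm throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

PIXEL_NM = 10.0

#: columns of the native localization-table dialect
LOC_COLUMNS = [
    "x_nm",
    "y_nm",
    "frame",
    "photons",
    "background",
    "precision_nm",
    "psf_sigma_nm",
    "loglik",
    "channel",
]


class PlacementError(RuntimeError):
    """Raised when the requested pore coverage cannot be realised."""


def _child_seed(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stage RNG derived from a master seed and a key."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class PoreField:
    """Ground-truth NPC centers on a rectangular membrane patch.

    Centers are float pixel coordinates (x right, y down, origin at the
    top-left pixel corner).  Non-overlap (pairwise center distance >= one
    pore diameter) and a one-radius border margin are guaranteed by the
    placement routines.
    """

    region_width_px: int
    region_height_px: int
    pore_radius_px: float
    centers: np.ndarray  # (n, 2) float64, columns x, y in pixels
    target_coverage: float
    achieved_coverage: float
    seed: int

    @property
    def n_pores(self) -> int:
        return len(self.centers)

    @property
    def area_px2(self) -> float:
        return float(self.region_width_px * self.region_height_px)

    def coverage_from_centers(self) -> float:
        """Recompute the disc-area fraction from the stored centers."""
        return self.n_pores * np.pi * self.pore_radius_px**2 / self.area_px2

    def min_pair_distance(self) -> float:
        """Brute-force minimum pairwise center distance (inf for n < 2)."""
        if self.n_pores < 2:
            return np.inf
        d = np.linalg.norm(self.centers[:, None, :] - self.centers[None, :, :], axis=-1)
        return float(d[np.triu_indices(self.n_pores, k=1)].min())

    def to_json(self) -> str:
        return json.dumps(
            {
                "region_width_px": self.region_width_px,
                "region_height_px": self.region_height_px,
                "pore_radius_px": self.pore_radius_px,
                "target_coverage": self.target_coverage,
                "achieved_coverage": self.achieved_coverage,
                "seed": self.seed,
                "centers_px": self.centers.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PoreField":
        d = json.loads(text)
        return cls(
            region_width_px=d["region_width_px"],
            region_height_px=d["region_height_px"],
            pore_radius_px=d["pore_radius_px"],
            centers=np.asarray(d["centers_px"], dtype=float).reshape(-1, 2),
            target_coverage=d["target_coverage"],
            achieved_coverage=d["achieved_coverage"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class LabelledPoreField:
    """Labelled binding sites on the rings of a :class:`PoreField`.

    ``sites`` are nm coordinates of the copies retained by Bernoulli
    labelling; ``pore_index`` maps each site back to its pore.
    """

    parent: PoreField
    efficiency: float
    copies_per_pore: int
    sites: np.ndarray  # (m, 2) float64, nm
    pore_index: np.ndarray  # (m,) int


@dataclass(frozen=True)
class RenderedImage:
    """Super-resolved image grid (float counts), 10 nm/px by default."""

    pixels: np.ndarray
    pixel_nm: float = PIXEL_NM
    origin_nm: tuple[float, float] = (0.0, 0.0)
    n_out_of_bounds: int = 0
    smoothed: bool = False


def _greedy_nonconflicting(cand: np.ndarray, min_dist: float) -> np.ndarray:
    """Keep a maximal prefix-greedy subset of candidates with pairwise
    distance >= min_dist (approximates sequential dart throwing)."""
    if len(cand) < 2:
        return cand
    pairs = cKDTree(cand).query_pairs(min_dist, output_type="ndarray")
    if len(pairs) == 0:
        return cand
    rejected = np.zeros(len(cand), dtype=bool)
    # process pairs ordered by the earlier index: keep first arrival
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    for i, j in pairs[order]:
        if not rejected[i]:
            rejected[j] = True
    return cand[~rejected]


def _rsa_place(
    rng: np.random.Generator,
    n_target: int,
    width: float,
    height: float,
    radius: float,
    max_attempts: int,
    region_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Random sequential adsorption (dart throwing) of hard discs.

    Candidates are drawn in vectorised batches; within a batch a greedy
    first-come pass resolves conflicts, which reproduces the statistics of
    one-at-a-time dart throwing.  ``region_mask`` (bool, [y, x] in pixels)
    optionally restricts where centers may fall.
    """
    accepted = np.empty((0, 2))
    lo = np.array([radius, radius])
    hi = np.array([width - radius, height - radius])
    if np.any(hi <= lo):
        raise PlacementError("region too small for the pore radius")
    attempts = 0
    while len(accepted) < n_target and attempts < max_attempts:
        m = int(min(max(4 * (n_target - len(accepted)), 1024), max_attempts - attempts))
        attempts += m
        cand = rng.uniform(lo, hi, size=(m, 2))
        if region_mask is not None:
            ix = np.clip(cand[:, 0].astype(int), 0, region_mask.shape[1] - 1)
            iy = np.clip(cand[:, 1].astype(int), 0, region_mask.shape[0] - 1)
            cand = cand[region_mask[iy, ix]]
        if len(accepted) and len(cand):
            d, _ = cKDTree(accepted).query(cand, k=1)
            cand = cand[d >= 2 * radius]
        if len(cand):
            cand = _greedy_nonconflicting(cand, 2 * radius)
            take = min(len(cand), n_target - len(accepted))
            accepted = np.vstack([accepted, cand[:take]])
    return accepted


def _lattice_place(
    rng: np.random.Generator,
    n_target: int,
    width: float,
    height: float,
    radius: float,
) -> np.ndarray:
    """Jittered triangular lattice at the requested density.

    Dart throwing jams near 55% disc coverage; for denser fields the centers
    are laid on a triangular lattice whose spacing realises the target
    density, jittered uniformly by less than half the surplus spacing so the
    hard-core constraint is preserved by construction, then thinned at random
    to the exact count.
    """
    # spacing from the density on the margin-reduced patch, progressively
    # densified until the clipped lattice holds enough centers
    inner_area = (width - 2 * radius) * (height - 2 * radius)
    phi = n_target * np.pi * radius**2 / inner_area
    s0 = np.sqrt(2 * np.pi * radius**2 / (np.sqrt(3) * phi))
    for shrink in (1.0, 0.98, 0.96, 0.94, 0.92, 0.90):
        s = shrink * s0
        if s <= 2 * radius:
            break
        dy = s * np.sqrt(3) / 2
        ys = np.arange(radius, height - radius + 1e-9, dy)
        pts = []
        for i, y in enumerate(ys):
            x0 = radius + (s / 2 if i % 2 else 0.0)
            xs = np.arange(x0, width - radius + 1e-9, s)
            pts.append(np.column_stack([xs, np.full_like(xs, y)]))
        pts = np.vstack(pts)
        if len(pts) < n_target:
            continue
        # per-axis uniform jitter: diagonal displacement reaches j*sqrt(2),
        # so j <= (s - 2r) / (2 sqrt(2)) keeps every pair >= 2r apart
        jitter = (s - 2 * radius) / (2 * np.sqrt(2)) * 0.98
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], radius, width - radius)
        pts[:, 1] = np.clip(pts[:, 1], radius, height - radius)
        keep = rng.choice(len(pts), size=n_target, replace=False)
        return pts[keep]
    raise PlacementError(
        f"jittered lattice cannot place {n_target} non-overlapping pores "
        f"(local coverage {phi:.3f})"
    )


def place_pores(
    width_px: int,
    height_px: int,
    target_coverage: float,
    pore_radius_px: float = 5.0,
    seed: int = 0,
    *,
    tolerance: float = 0.005,
    max_attempts: int = 1_000_000,
) -> PoreField:
    """Place non-overlapping pores uniformly at random on the patch.

    The pore count is the one whose total disc area best matches
    ``target_coverage``.  Placement is dart-throwing rejection sampling; if
    the requested density is beyond the dart-throwing jamming limit the
    jittered-lattice fallback is used so the full 3-60% coverage range is
    reachable.

    Raises
    ------
    PlacementError
        If the achieved coverage differs from the target by more than
        ``tolerance`` (absolute), naming both values.
    """
    if not 0.0 <= target_coverage <= 0.60:
        raise ValueError(f"target_coverage {target_coverage} outside [0, 0.60]")
    area = width_px * height_px
    disc_area = np.pi * pore_radius_px**2
    n_target = int(round(target_coverage * area / disc_area))
    rng = _child_seed(seed, 0)
    if n_target == 0:
        centers = np.empty((0, 2))
    else:
        centers = _rsa_place(
            rng, n_target, width_px, height_px, pore_radius_px, max_attempts
        )
        if len(centers) < n_target:
            centers = _lattice_place(
                _child_seed(seed, 1), n_target, width_px, height_px, pore_radius_px
            )
    achieved = len(centers) * disc_area / area
    if abs(achieved - target_coverage) > tolerance:
        raise PlacementError(
            f"achieved coverage {achieved:.4f} vs target {target_coverage:.4f} "
            f"(tolerance {tolerance})"
        )
    return PoreField(
        region_width_px=width_px,
        region_height_px=height_px,
        pore_radius_px=pore_radius_px,
        centers=centers,
        target_coverage=target_coverage,
        achieved_coverage=achieved,
        seed=seed,
    )


def place_pores_clustered(
    width_px: int,
    height_px: int,
    target_coverage: float,
    pore_radius_px: float = 5.0,
    seed: int = 0,
    *,
    ribbon_fraction: float = 0.30,
    ribbon_width_px: float = 40.0,
    max_attempts: int = 1_000_000,
) -> PoreField:
    """Place non-overlapping pores restricted to random ribbon strips.

    Emulates the clustered phenotype in which NPCs form inter-linked chains
    separated by pore-free areas: randomly oriented straight strips are
    accumulated until they occupy ``ribbon_fraction`` of the patch, and pores
    are dart-thrown only inside them.  The global coverage matches
    ``target_coverage``; local density inside the ribbons is accordingly
    higher, so the target must keep the local coverage below the hard-disc
    jamming limit (~0.5).
    """
    local = target_coverage / ribbon_fraction
    if local > 0.45:
        raise PlacementError(
            f"local ribbon coverage {local:.2f} too dense for dart throwing"
        )
    rng = _child_seed(seed, 2)
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    mask = np.zeros((height_px, width_px), dtype=bool)
    diag = np.hypot(width_px, height_px)
    while mask.mean() < ribbon_fraction:
        theta = rng.uniform(0, np.pi)
        cx, cy = rng.uniform(0, width_px), rng.uniform(0, height_px)
        # signed distance to the line through (cx, cy) with direction theta
        d = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        mask |= np.abs(d) <= ribbon_width_px / 2
        if diag <= 0:  # pragma: no cover - defensive
            break
    area = width_px * height_px
    disc_area = np.pi * pore_radius_px**2
    n_target = int(round(target_coverage * area / disc_area))
    centers = _rsa_place(
        rng, n_target, width_px, height_px, pore_radius_px, max_attempts, region_mask=mask
    )
    if len(centers) < n_target:
        raise PlacementError(
            f"placed {len(centers)} of {n_target} pores inside ribbons"
        )
    achieved = len(centers) * disc_area / area
    return PoreField(
        region_width_px=width_px,
        region_height_px=height_px,
        pore_radius_px=pore_radius_px,
        centers=centers,
        target_coverage=target_coverage,
        achieved_coverage=achieved,
        seed=seed,
    )


def apply_labelling(
    pores: PoreField,
    efficiency: float,
    copies_per_pore: int = 32,
    seed: int | None = None,
    *,
    per_pore: bool = False,
) -> LabelledPoreField:
    """Label protein copies on each pore ring with independent probability.

    ``copies_per_pore`` binding sites are spaced at equal angles on the ring
    of each pore (radius = pore radius), with an independent uniform phase
    per pore.  Each site is retained with probability ``efficiency``.  With
    ``per_pore=True`` whole pores are retained or dropped instead (all-or-
    nothing labelling); the per-copy default is the physically faithful mode.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency {efficiency} outside [0, 1]")
    rng = _child_seed(pores.seed if seed is None else seed, 3)
    n = pores.n_pores
    if n == 0:
        return LabelledPoreField(
            parent=pores,
            efficiency=efficiency,
            copies_per_pore=copies_per_pore,
            sites=np.empty((0, 2)),
            pore_index=np.empty(0, dtype=int),
        )
    phases = rng.uniform(0, 2 * np.pi, size=n)
    angles = phases[:, None] + 2 * np.pi * np.arange(copies_per_pore)[None, :] / copies_per_pore
    r_nm = pores.pore_radius_px * PIXEL_NM
    cx = pores.centers[:, 0][:, None] * PIXEL_NM + r_nm * np.cos(angles)
    cy = pores.centers[:, 1][:, None] * PIXEL_NM + r_nm * np.sin(angles)
    if per_pore:
        keep = np.repeat(rng.random(n) < efficiency, copies_per_pore).reshape(n, -1)
    else:
        keep = rng.random((n, copies_per_pore)) < efficiency
    pore_idx = np.broadcast_to(np.arange(n)[:, None], keep.shape)
    sites = np.column_stack([cx[keep], cy[keep]])
    return LabelledPoreField(
        parent=pores,
        efficiency=efficiency,
        copies_per_pore=copies_per_pore,
        sites=sites,
        pore_index=pore_idx[keep].copy(),
    )


def draw_localization_coords(
    labelled: LabelledPoreField,
    mean_blinks_per_site: float = 10.0,
    precision_nm: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Blink coordinates only: the fast path used by the simulation grid.

    Same statistical model and random stream as
    :func:`render_localizations`, without the fit-quality metadata columns.
    """
    if mean_blinks_per_site <= 0:
        raise ValueError("mean_blinks_per_site must be > 0")
    if precision_nm < 0:
        raise ValueError("precision_nm must be >= 0")
    rng = _child_seed(seed, 4)
    if len(labelled.sites) == 0:
        return np.empty((0, 2))
    counts = rng.poisson(mean_blinks_per_site, size=len(labelled.sites))
    pts = np.repeat(labelled.sites, counts, axis=0)
    if precision_nm > 0:
        pts = pts + rng.normal(0.0, precision_nm, size=pts.shape)
    return pts


def render_localizations(
    labelled: LabelledPoreField,
    mean_blinks_per_site: float = 10.0,
    precision_nm: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw DNA-PAINT localizations from labelled sites.

    Each site blinks Poisson(``mean_blinks_per_site``) times; every blink is
    localized with isotropic Gaussian error of ``precision_nm`` (the 8-14 nm
    regime of typical line-scanning DNA-PAINT data).  Photon counts, PSF
    widths and log-likelihoods are filled with plausible values so the table
    exercises the same fit-quality filters as real data.
    """
    pts = draw_localization_coords(labelled, mean_blinks_per_site, precision_nm, seed)
    if len(pts) == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
    rng = _child_seed(seed, 4, 1)
    k = len(pts)
    return pd.DataFrame(
        {
            "x_nm": pts[:, 0],
            "y_nm": pts[:, 1],
            "frame": rng.integers(0, 50_000, size=k),
            "photons": rng.gamma(4.0, 300.0, size=k),
            "background": rng.gamma(4.0, 2.5, size=k),
            "precision_nm": np.full(k, float(precision_nm)),
            "psf_sigma_nm": rng.normal(100.0, 8.0, size=k),
            "loglik": rng.normal(-250.0, 30.0, size=k),
            "channel": np.zeros(k, dtype=int),
        }
    )


def render_image(
    locs,
    width_px: int,
    height_px: int,
    pixel_nm: float = PIXEL_NM,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    smooth_sigma_px: float | None = None,
) -> RenderedImage:
    """Render localizations (a table or an (n, 2) nm array) to a 2D histogram.

    Floor binning: a localization at coordinate c lands in pixel
    ``floor((c - origin) / pixel_nm)``; pixels are half-open.  Out-of-bounds
    localizations are dropped and counted.  With ``smooth_sigma_px`` set the
    histogram is Gaussian-smoothed (flagged in the result); in plain
    histogram mode the pixel sum equals the in-bounds localization count.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be > 0")
    if isinstance(locs, pd.DataFrame):
        xy = locs[["x_nm", "y_nm"]].to_numpy(dtype=float) if len(locs) else np.empty((0, 2))
    else:
        xy = np.asarray(locs, dtype=float).reshape(-1, 2)
    img = np.zeros((height_px, width_px), dtype=float)
    n_oob = 0
    if len(xy):
        ix = np.floor((xy[:, 0] - origin_nm[0]) / pixel_nm).astype(int)
        iy = np.floor((xy[:, 1] - origin_nm[1]) / pixel_nm).astype(int)
        ok = (ix >= 0) & (ix < width_px) & (iy >= 0) & (iy < height_px)
        n_oob = int((~ok).sum())
        np.add.at(img, (iy[ok], ix[ok]), 1.0)
    smoothed = False
    if smooth_sigma_px is not None and smooth_sigma_px > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma_px, mode="constant")
        smoothed = True
    return RenderedImage(
        pixels=img,
        pixel_nm=pixel_nm,
        origin_nm=origin_nm,
        n_out_of_bounds=n_oob,
        smoothed=smoothed,
    )


def render_ideal_image(
    pores: PoreField, amplitude: float = 100.0, pixel_nm: float = PIXEL_NM
) -> RenderedImage:
    """Render the ground-truth field as ideal filled discs (no noise).

    The noise-free counterpart of the localization pipeline: every pore is a
    uniform disc of its nominal radius.  Useful for calibrating and testing
    the morphological chain in isolation from labelling statistics.
    """
    h, w = pores.region_height_px, pores.region_width_px
    img = np.zeros((h, w), dtype=float)
    if pores.n_pores:
        yy, xx = np.mgrid[0:h, 0:w]
        for cx, cy in pores.centers:
            sel = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= pores.pore_radius_px**2
            img[sel] = amplitude
    return RenderedImage(pixels=img, pixel_nm=pixel_nm)


def make_filament_fixture(
    p0_nm: tuple[float, float],
    p1_nm: tuple[float, float],
    sigma_nm: float,
    n_locs: int,
    second_line_offset_nm: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Localizations scattered around one line segment (or two parallel ones).

    Points are uniform along the segment and displaced perpendicular to it by
    Gaussian(``sigma_nm``) noise — the fixture for profile-width fitting.
    With ``second_line_offset_nm`` set, localizations are split evenly
    between the segment and a parallel copy shifted by that offset along the
    segment normal (the double-membrane scenario).
    """
    if n_locs <= 0:
        raise ValueError("n_locs must be > 0")
    if sigma_nm < 0:
        raise ValueError("sigma_nm must be >= 0")
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        raise ValueError("degenerate line: endpoints coincide")
    u = (p1 - p0) / length
    n_hat = np.array([-u[1], u[0]])
    rng = _child_seed(seed, 5)
    t = rng.uniform(0.0, 1.0, size=n_locs)
    d = rng.normal(0.0, sigma_nm, size=n_locs) if sigma_nm > 0 else np.zeros(n_locs)
    if second_line_offset_nm is not None:
        which = np.arange(n_locs) % 2  # even split between the two lines
        d = d + which * second_line_offset_nm
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :] + d[:, None] * n_hat[None, :]
    k = len(pts)
    return pd.DataFrame(
        {
            "x_nm": pts[:, 0],
            "y_nm": pts[:, 1],
            "frame": np.arange(k),
            "photons": np.full(k, 1000.0),
            "background": np.full(k, 10.0),
            "precision_nm": np.full(k, max(sigma_nm, 1.0)),
            "psf_sigma_nm": np.full(k, 100.0),
            "loglik": np.full(k, -250.0),
            "channel": np.zeros(k, dtype=int),
        }
    )
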