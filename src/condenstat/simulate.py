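"""Synthetic fluorescence microscopy with exact ground truth.

The generator embodies a minimal mechanistic picture of interface-mediated
aggregate coarsening:

* a two-channel cell ("p62" scaffold channel, "polyQ" aggregate channel)
  with Gaussian-background cytoplasm;
* solid aggregates with a broad lognormal size distribution, rendered as
  filled disks whose integrated intensity is exactly proportional to their
  true area;
* liquid-like condensates that nucleate in the scaffold channel at the
  start of each blue-light interval, grow while the light is on, and
  dissolve exponentially when it switches off;
* interfacial adsorption: an aggregate whose centre lies within
  ``capture_dist_um`` of a condensate rim is repositioned onto the nearest
  rim point (instantaneous; no transport law is modelled);
* coalescence on dissolution: when a condensate dissolves, all aggregates
  on its rim merge into a single aggregate whose area (and hence integrated
  intensity) is the sum of the merged areas, placed at their
  intensity-weighted centroid.

Signal is therefore conserved by construction — repositioning and merging
never create or destroy aggregate intensity — which downstream bulk-
intensity analysis can verify.  A Gaussian point-spread blur and additive
Gaussian detector noise are applied last, per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datamodel import CellROI, ImageStack

#: pixel size at which the 16-pixel minimum object filter corresponds to
#: a physical area of 0.116 um^2 (and, with 0.25 um sections, 64 voxels to
#: 0.116 um^3).
DEFAULT_PIXEL_SIZE_UM = 0.0851


class GenerationError(RuntimeError):
    """Requested scene could not be generated."""


@dataclass
class SimParams:
    """Scene and dynamics parameters for :func:`simulate_cell`.

    Defaults describe one cycling experiment frame-for-interval: condensation
    intervals during which condensates nucleate and grow, separated by dark
    gaps long enough for full dissolution.  Sizes are in micrometres,
    intensities in arbitrary detector units.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = 0.25
    frame_interval_s: float = 30.0
    # cytoplasmic background
    bg_mean: float = 200.0
    bg_sd: float = 20.0
    # elliptical cell mask, semi-axes as fractions of the image half-size
    cell_axes_frac: tuple[float, float] = (0.86, 0.78)
    # aggregates: lognormal areas (natural-log parameters, um^2)
    n_aggregates: int = 60
    agg_area_logmean_um2: float = math.log(0.18)
    agg_area_logsd: float = 0.6
    # chosen so the per-pixel aggregate amplitude (~100 units above the
    # cytoplasm) is twice the default threshold margin (2.5 x bg_sd = 50):
    # the mean+2.5SD threshold then crosses a blurred object edge at its
    # half-maximum, making detected areas unbiased estimates of true areas
    aggregate_intensity_per_um2: float = 1.4e4
    # condensates
    n_condensates: int = 4
    condensate_r0_um: float = 0.4
    condensate_growth_um_per_frame: float = 0.15
    condensate_dissolution_tau_frames: float = 1.0
    condensate_intensity: float = 1200.0
    # interface adsorption / coalescence
    capture_dist_um: float = 2.5
    # interfacial recruitment is size-selective and capacity-limited: only
    # small aggregates adsorb, and one rim holds a bounded number of them
    capture_max_area_um2: float = 1.5
    max_rim_occupancy: int | None = 6
    merge_on_dissolution: bool = True
    # small aggregates released without coalescing redisperse by diffusion
    # during the dark interval; rms displacement of that relaxation
    detach_jitter_um: float = 1.2
    # optics
    psf_sigma_um: float = 0.10
    # light schedule: half-open frame intervals; None -> 3 cycles + final round
    light_schedule: list[tuple[int, int]] | None = None
    n_frames: int | None = None
    # optional photobleach events: (frame, (y_um, x_um), radius_um, depth)
    frap_events: list[tuple[int, tuple[float, float], float, float]] = field(default_factory=list)
    frap_immobile_fraction: float = 0.5
    frap_rate_per_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bg_sd < 0:
            raise ValueError("bg_sd must be >= 0")
        if self.capture_dist_um < 0:
            raise ValueError("capture_dist_um must be >= 0")
        for name in (
            "pixel_size_um",
            "z_step_um",
            "aggregate_intensity_per_um2",
            "condensate_r0_um",
            "condensate_growth_um_per_frame",
            "condensate_dissolution_tau_frames",
            "psf_sigma_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.light_schedule is None:
            # three condensation/dissolution cycles plus one final condensation
            on, off = 6, 4
            sched = []
            t = 1
            for _ in range(3):
                sched.append((t, t + on))
                t += on + off
            sched.append((t, t + on))
            self.light_schedule = sched
            if self.n_frames is None:
                self.n_frames = t + on + 1
        elif self.n_frames is None:
            self.n_frames = max(b for _, b in self.light_schedule) + 1


@dataclass
class GroundTruth:
    """Exact per-frame scene description emitted alongside the rendered stack.

    ``objects`` has one row per object per frame (aggregates and
    condensates); ``merge_events`` records the coalescence lineage;
    ``total_aggregate_intensity`` is the true integrated aggregate signal
    per frame, conserved by construction.
    """

    objects: pd.DataFrame
    merge_events: pd.DataFrame
    total_aggregate_intensity: np.ndarray

    def aggregates_at(self, frame: int) -> pd.DataFrame:
        df = self.objects
        return df[(df["frame"] == frame) & (df["type"] == "aggregate")]

    def condensates_at(self, frame: int) -> pd.DataFrame:
        df = self.objects
        return df[(df["frame"] == frame) & (df["type"] == "condensate")]

    def mean_small_aggregate_area(self, frame: int, cutoff_um2: float = 5.0) -> float:
        areas = self.aggregates_at(frame)["area_um2"].to_numpy()
        small = areas[areas < cutoff_um2]
        return float(np.mean(small)) if small.size else float("nan")


# ---------------------------------------------------------------------------
# internal scene state


class _Aggregate:
    __slots__ = ("oid", "y", "x", "area", "attached", "angle")

    def __init__(self, oid: int, y: float, x: float, area: float):
        self.oid = oid
        self.y = y
        self.x = x
        self.area = area
        self.attached: int | None = None
        self.angle: float | None = None

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)


class _Condensate:
    __slots__ = ("oid", "y", "x", "radius", "r_at_off", "frames_off", "alive")

    def __init__(self, oid: int, y: float, x: float, radius: float):
        self.oid = oid
        self.y = y
        self.x = x
        self.radius = radius
        self.r_at_off = radius
        self.frames_off = 0
        self.alive = True


def _ellipse_mask(shape: tuple[int, int], axes_frac: tuple[float, float]) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = axes_frac[0] * ny / 2.0, axes_frac[1] * nx / 2.0
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _draw_disk(canvas: np.ndarray, y_um: float, x_um: float, radius_um: float,
               total_intensity: float, pixel_size_um: float) -> None:
    """Add a filled disk carrying exactly ``total_intensity`` integrated signal.

    The disk is rasterized on pixel centres; the per-pixel amplitude is then
    scaled so the rendered integral matches the true integrated intensity
    regardless of rasterization error.
    """
    ny, nx = canvas.shape
    cy, cx = y_um / pixel_size_um, x_um / pixel_size_um
    r_px = max(radius_um / pixel_size_um, 0.6)  # never rasterize to nothing
    y0, y1 = max(0, int(cy - r_px) - 1), min(ny, int(cy + r_px) + 2)
    x0, x1 = max(0, int(cx - r_px) - 1), min(nx, int(cx + r_px) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    n = int(inside.sum())
    if n == 0:
        return
    canvas[y0:y1, x0:x1][inside] += total_intensity / n


def _sample_positions(rng: np.random.Generator, mask: np.ndarray, n: int,
                      pixel_size_um: float, margin_um: float) -> list[tuple[float, float]]:
    """Rejection-sample n positions inside the mask eroded by ``margin_um``."""
    ny, nx = mask.shape
    margin_px = margin_um / pixel_size_um
    if 2 * margin_px >= min(ny, nx):
        raise GenerationError(
            f"image of {ny}x{nx} px cannot hold objects with a "
            f"{margin_um:.2f} um placement margin"
        )
    out: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(out) == n:
            break
        y = rng.uniform(margin_px, ny - margin_px)
        x = rng.uniform(margin_px, nx - margin_px)
        iy, ix = int(round(y)), int(round(x))
        # crude erosion check: the pixel and its margin-neighbourhood corners
        ok = True
        for dy, dx in ((0, 0), (margin_px, 0), (-margin_px, 0), (0, margin_px), (0, -margin_px)):
            jy, jx = int(round(y + dy)), int(round(x + dx))
            if not (0 <= jy < ny and 0 <= jx < nx and mask[jy, jx]):
                ok = False
                break
        if ok and mask[iy, ix]:
            out.append((y * pixel_size_um, x * pixel_size_um))
    if len(out) < n:
        raise GenerationError(f"could only place {len(out)} of {n} objects in cell mask")
    return out


def simulate_cell(params: SimParams) -> tuple[ImageStack, CellROI, GroundTruth]:
    """Render one synthetic cell time-lapse with exact ground truth.

    Returns the stack (channels ``["p62", "polyQ"]``), the true cell mask,
    and the :class:`GroundTruth` scene description.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    px = params.pixel_size_um
    mask = _ellipse_mask(params.image_shape, params.cell_axes_frac)
    n_frames = int(params.n_frames)
    schedule = [(int(a), int(b)) for a, b in params.light_schedule]
    on_starts = {a for a, _ in schedule}

    def light_on(t: int) -> bool:
        return any(a <= t < b for a, b in schedule)

    # --- initial aggregates; keep 1 um clear of the mask edge so the PSF
    # blur does not carry signal outside the ROI, and place without overlap
    margin_um = 1.0
    areas = rng.lognormal(params.agg_area_logmean_um2, params.agg_area_logsd,
                          size=params.n_aggregates)
    aggregates: list[_Aggregate] = []
    for i, area in enumerate(areas):
        r_new = math.sqrt(area / math.pi)
        placed = False
        for _ in range(500):
            (y, x), = _sample_positions(rng, mask, 1, px, margin_um)
            if all(math.hypot(y - a.y, x - a.x) > r_new + a.radius + 0.1
                   for a in aggregates):
                aggregates.append(_Aggregate(i + 1, y, x, float(area)))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place {params.n_aggregates} non-overlapping "
                f"aggregates in the cell mask ({len(aggregates)} achieved)"
            )
    next_oid = params.n_aggregates + 1
    condensates: list[_Condensate] = []
    next_cid = 1

    obj_rows: list[dict] = []
    merge_rows: list[dict] = []
    total_intensity = np.zeros(n_frames)
    data = np.zeros((n_frames, 1, 2, ny, nx), dtype=float)
    psf_sigma_px = params.psf_sigma_um / px
    frap_by_frame: dict[int, list] = {}
    for ev in params.frap_events:
        frap_by_frame.setdefault(int(ev[0]), []).append(ev)
    active_bleaches: list[tuple[int, tuple[float, float], float, float]] = []

    half_um = ((ny - 1) / 2.0 * px, (nx - 1) / 2.0 * px)

    for t in range(n_frames):
        on = light_on(t)
        # --- condensate dynamics
        if t in on_starts:
            pos = _sample_positions(rng, mask, params.n_condensates, px,
                                    margin_um + 2.5)
            for (y, x) in pos:
                condensates.append(_Condensate(next_cid + 10000, y, x, params.condensate_r0_um))
                next_cid += 1
        for c in condensates:
            if not c.alive:
                continue
            if on:
                c.radius += params.condensate_growth_um_per_frame if t not in on_starts else 0.0
                c.r_at_off = c.radius
                c.frames_off = 0
            else:
                c.frames_off += 1
                c.radius = c.r_at_off * math.exp(-c.frames_off / params.condensate_dissolution_tau_frames)
                if c.radius < 0.25 * params.condensate_r0_um:
                    # dissolution: coalesce everything on this rim
                    members = [a for a in aggregates if a.attached == c.oid]
                    if params.merge_on_dissolution and len(members) >= 2:
                        tot = sum(a.area for a in members)
                        ym = sum(a.y * a.area for a in members) / tot
                        xm = sum(a.x * a.area for a in members) / tot
                        child = _Aggregate(next_oid, ym, xm, tot)
                        next_oid += 1
                        merge_rows.append({
                            "frame": t,
                            "condensate_id": c.oid,
                            "parent_ids": ";".join(str(a.oid) for a in members),
                            "child_id": child.oid,
                            "area_um2": tot,
                        })
                        aggregates = [a for a in aggregates if a.attached != c.oid]
                        aggregates.append(child)
                    else:
                        for a in members:
                            a.attached = None
                            a.angle = None
                            if params.detach_jitter_um > 0:
                                others = [o for o in aggregates if o is not a]
                                for _ in range(100):
                                    dy, dx = rng.normal(0.0, params.detach_jitter_um, 2)
                                    yn, xn = a.y + dy, a.x + dx
                                    iy = int(round(yn / px))
                                    ix = int(round(xn / px))
                                    my = int(round(margin_um / px))
                                    if not (my <= iy < ny - my and my <= ix < nx - my
                                            and mask[iy, ix]):
                                        continue
                                    # solid particles do not interpenetrate
                                    if all(math.hypot(yn - o.y, xn - o.x)
                                           > a.radius + o.radius + 0.1
                                           for o in others):
                                        a.y, a.x = yn, xn
                                        break
                    c.alive = False
        condensates = [c for c in condensates if c.alive]

        # --- interfacial adsorption (skipped on the nucleation frame so the
        # first frame of each condensation cycle shows the coarsened state
        # inherited from the previous dissolution)
        if on and t not in on_starts and params.capture_dist_um > 0:
            for c in condensates:
                occupied = sum(1 for a in aggregates if a.attached == c.oid)
                for a in aggregates:
                    if a.attached == c.oid:
                        # follow the moving rim at a fixed angle
                        a.y = c.y + c.radius * math.sin(a.angle)
                        a.x = c.x + c.radius * math.cos(a.angle)
                    elif a.attached is None:
                        if params.max_rim_occupancy is not None and occupied >= params.max_rim_occupancy:
                            continue
                        if a.area >= params.capture_max_area_um2:
                            continue
                        d = math.hypot(a.y - c.y, a.x - c.x)
                        if abs(d - c.radius) <= params.capture_dist_um:
                            ang = math.atan2(a.y - c.y, a.x - c.x) if d > 1e-9 else rng.uniform(0, 2 * math.pi)
                            a.attached = c.oid
                            a.angle = ang
                            a.y = c.y + c.radius * math.sin(ang)
                            a.x = c.x + c.radius * math.cos(ang)
                            occupied += 1

        # --- bookkeeping
        for a in aggregates:
            obj_rows.append({
                "frame": t, "object_id": a.oid, "type": "aggregate",
                "y_um": a.y, "x_um": a.x, "area_um2": a.area,
                "radius_um": a.radius,
                "attached_to": a.attached if a.attached is not None else -1,
            })
        for c in condensates:
            obj_rows.append({
                "frame": t, "object_id": c.oid, "type": "condensate",
                "y_um": c.y, "x_um": c.x, "area_um2": math.pi * c.radius**2,
                "radius_um": c.radius, "attached_to": -1,
            })
        total_intensity[t] = params.aggregate_intensity_per_um2 * sum(a.area for a in aggregates)

        # --- render: sharp shapes, then PSF blur, then background + noise
        polyq = np.zeros((ny, nx))
        p62 = np.zeros((ny, nx))
        for a in aggregates:
            _draw_disk(polyq, a.y, a.x, a.radius,
                       params.aggregate_intensity_per_um2 * a.area, px)
        for c in condensates:
            area_px = math.pi * (c.radius / px) ** 2
            _draw_disk(p62, c.y, c.x, c.radius,
                       params.condensate_intensity * area_px, px)
        polyq = gaussian_filter(polyq, psf_sigma_px, mode="reflect")
        p62 = gaussian_filter(p62, psf_sigma_px, mode="reflect")

        # photobleach scars recover with single-exponential kinetics
        active_bleaches.extend(frap_by_frame.get(t, []))
        for (t0, (by, bx), br, depth) in active_bleaches:
            dt = (t - t0) * params.frame_interval_s
            rec = depth * (1 - params.frap_immobile_fraction) * (1 - math.exp(-params.frap_rate_per_s * dt))
            factor = (1 - depth) + rec
            yy, xx = np.mgrid[0:ny, 0:nx]
            reg = ((yy * px - by) ** 2 + (xx * px - bx) ** 2) <= br**2
            p62[reg] *= factor

        for canvas, ci in ((p62, 0), (polyq, 1)):
            canvas += params.bg_mean
            if params.bg_sd > 0:
                canvas += rng.normal(0.0, params.bg_sd, size=canvas.shape)
                np.clip(canvas, 0.0, None, out=canvas)
            data[t, 0, ci] = canvas

    stack = ImageStack(
        data=data,
        pixel_size_um=px,
        channel_names=["p62", "polyQ"],
        frame_interval_s=params.frame_interval_s,
        z_step_um=None,
        light_schedule=schedule,
    )
    roi = CellROI(cell_id=f"sim{params.seed}", mask=mask, provenance="synthetic_truth")
    truth = GroundTruth(
        objects=pd.DataFrame(obj_rows),
        merge_events=pd.DataFrame(
            merge_rows, columns=["frame", "condensate_id", "parent_ids", "child_id", "area_um2"]
        ),
        total_aggregate_intensity=total_intensity,
    )
    return stack, roi, truth


# ---------------------------------------------------------------------------
# FRAP trace generator (closed form)


def simulate_frap_trace(
    f_immobile: float,
    k: float,
    bleach_depth: float,
    t: np.ndarray,
    noise_sd: float = 0.0,
    n_prebleach: int = 3,
    seed: int | None = None,
):
    """Normalized single-exponential FRAP recovery trace.

    Pre-bleach samples sit at 1; from the bleach instant the trace follows

        F(t) = (1 - d) + d * (1 - f_immobile) * (1 - exp(-k t)),

    where ``d`` is the bleach depth, so an entirely immobile pool
    (``f_immobile = 1``) stays flat at ``1 - d`` and a fully mobile pool
    recovers to 1.  Gaussian noise of SD ``noise_sd`` is added throughout.
    """
    from .frap import FRAPTrace  # local import to avoid a cycle

    if not 0 <= f_immobile <= 1:
        raise ValueError("f_immobile must be in [0, 1]")
    if k < 0:
        raise ValueError("k must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    t_pre = t[0] - dt * np.arange(n_prebleach, 0, -1)
    time = np.concatenate([t_pre, t])
    post = (1 - bleach_depth) + bleach_depth * (1 - f_immobile) * (1 - np.exp(-k * (t - t[0])))
    intensity = np.concatenate([np.ones(n_prebleach), post])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return FRAPTrace(time_s=time, intensity=intensity, bleach_index=n_prebleach)


# ---------------------------------------------------------------------------
# optogenetic titration (phase-diagram ground truth)


def simulate_titration(
    n_cells: int,
    c_core_range: tuple[float, float] = (0.02, 5.0),
    valence_range: tuple[float, float] = (0.2, 50.0),
    K: float = 1.0,
    label_noise: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample cells across an intracellular phase diagram.

    Cells are drawn log-uniformly in (core concentration C, valence V); the
    true binodal is the hyperbola ``V * C = K``: a cell condenses iff
    ``V * C > K``.  ``label_noise`` optionally flips each label with the
    given probability (misclassified cells near the boundary).

    Returns a DataFrame with columns ``cell_id, c_core_uM, valence,
    condensed`` where ``condensed`` is the true label.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if K <= 0:
        raise ValueError("K must be > 0")
    if min(c_core_range) <= 0 or min(valence_range) <= 0:
        raise ValueError("concentration and valence ranges must be positive")
    rng = np.random.default_rng(seed)
    c = np.exp(rng.uniform(np.log(c_core_range[0]), np.log(c_core_range[1]), n_cells))
    v = np.exp(rng.uniform(np.log(valence_range[0]), np.log(valence_range[1]), n_cells))
    condensed = v * c > K
    if label_noise > 0:
        flip = rng.random(n_cells) < label_noise
        condensed = condensed ^ flip
    return pd.DataFrame({
        "cell_id": [f"cell{i:04d}" for i in range(n_cells)],
        "c_core_uM": c,
        "valence": v,
        "condensed": condensed,
    })


def render_contact_pair(
    agg_radius_um: float,
    overlap: float,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = (96, 96),
    bg_mean: float = 100.0,
    noise_sd: float = 3.0,
    amplitude: float = 400.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One aggregate/scaffold object pair in physical contact.

    Renders an aggregate disk in channel B and a scaffold blob of the same
    radius in channel A, displaced so that ``overlap = 1`` is concentric
    (co-labelled, near-perfect correlation) and ``overlap = 0`` is merely
    touching (interfacial contact, weak correlation).  Returns
    ``(img_a, img_b, mask_a, mask_b)``; masks are the true disks.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    ny, nx = shape
    cy, cx = (ny / 2) * pixel_size_um, (nx / 2) * pixel_size_um
    offset = (1.0 - overlap) * 2.0 * agg_radius_um
    rng = np.random.default_rng(seed)
    img_a = np.zeros(shape)
    img_b = np.zeros(shape)
    area_px = math.pi * (agg_radius_um / pixel_size_um) ** 2
    _draw_disk(img_b, cy, cx, agg_radius_um, amplitude * area_px, pixel_size_um)
    _draw_disk(img_a, cy, cx + offset, agg_radius_um, amplitude * area_px, pixel_size_um)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr_b = np.hypot(yy * pixel_size_um - cy, xx * pixel_size_um - cx)
    rr_a = np.hypot(yy * pixel_size_um - cy, xx * pixel_size_um - (cx + offset))
    mask_b = rr_b <= agg_radius_um
    mask_a = rr_a <= agg_radius_um
    sigma_px = 0.10 / pixel_size_um
    img_a = gaussian_filter(img_a, sigma_px, mode="reflect") + bg_mean
    img_b = gaussian_filter(img_b, sigma_px, mode="reflect") + bg_mean
    if noise_sd > 0:
        img_a = np.clip(img_a + rng.normal(0, noise_sd, shape), 0, None)
        img_b = np.clip(img_b + rng.normal(0, noise_sd, shape), 0, None)
    return img_a, img_b, mask_a, mask_b


def render_activation_response(
    condensed: bool,
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    bg_mean: float = 200.0,
    bg_sd: float = 5.0,
    n_droplets: int = 4,
    droplet_radius_um: float = 0.8,
    droplet_intensity: float = 800.0,
    irregular: bool = False,
    seed: int | None = None,
) -> tuple[ImageStack, CellROI]:
    """Minimal pre/post light-activation stack for condensation classifiers.

    Frame 0 is uniform cytoplasm; frames 1-2 either develop bright circular
    droplets (``condensed=True``), recruit signal onto ragged plus-shaped
    aggregates (``irregular=True``), or stay uniform.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    mask = _ellipse_mask(shape, (0.9, 0.9))
    # fixed droplet sites, kept well separated so each stays a distinct
    # circular object after blur
    min_sep = 5.0 * droplet_radius_um
    sites: list[tuple[float, float]] = []
    for _attempt in range(50):
        sites = []
        for _ in range(500):
            if len(sites) == n_droplets:
                break
            (y, x), = _sample_positions(rng, mask, 1, pixel_size_um, 1.5)
            if all(math.hypot(y - sy, x - sx) >= min_sep for sy, sx in sites):
                sites.append((y, x))
        if len(sites) == n_droplets:
            break
    if len(sites) < n_droplets:
        raise GenerationError(f"could not place {n_droplets} separated droplets")
    data = np.zeros((3, 1, 1, ny, nx))
    for t in range(3):
        frame = np.zeros((ny, nx))
        if t >= 1 and condensed:
            for (y, x) in sites:
                if irregular:
                    # thin ragged cross: low circularity by construction
                    cy, cx = int(y / pixel_size_um), int(x / pixel_size_um)
                    r = int(droplet_radius_um / pixel_size_um) * 3
                    frame[cy - 1:cy + 2, max(0, cx - r):cx + r] += droplet_intensity
                    frame[max(0, cy - r):cy + r, cx - 1:cx + 2] += droplet_intensity
                else:
                    area_px = math.pi * (droplet_radius_um / pixel_size_um) ** 2
                    _draw_disk(frame, y, x, droplet_radius_um,
                               droplet_intensity * area_px, pixel_size_um)
        frame = gaussian_filter(frame, 0.12 / pixel_size_um, mode="reflect")
        frame += bg_mean
        if bg_sd > 0:
            frame += rng.normal(0, bg_sd, frame.shape)
            np.clip(frame, 0, None, out=frame)
        data[t, 0, 0] = frame
    stack = ImageStack(data=data, pixel_size_um=pixel_size_um,
                       channel_names=["p62"], frame_interval_s=30.0,
                       light_schedule=[(1, 3)])
    roi = CellROI("phase-cell", mask, provenance="synthetic_truth")
    return stack, roi
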