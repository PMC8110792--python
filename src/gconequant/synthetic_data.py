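"""Seeded synthetic data with ground truth for every assay in the pipeline.

Each generator is a pure function of its parameter object (including the
seed): the same parameters always produce identical output, and ground
truth is emitted alongside rendered data so downstream recovery is
assertable.

The generators emulate:

* neurosphere scenes on alternating-stripe substrata, where neurites grow
  as persistent random walks whose steps onto a cue lane are accepted with
  probability exp(-beta) — a one-parameter monotone repulsion (beta = 0:
  indifferent; large beta: near-total avoidance);
* spread vs. collapsed growth-cone morphologies with known labels;
* leading-edge extension tracks sampled at fixed intervals with optional
  retraction events;
* donor/acceptor image pairs around an acceptor photobleach with a known
  true FRET efficiency;
* immunolabel intensity fields with group-dependent means over background.

Rendering uses a plain Gaussian blur as the point-spread stand-in; there is
no attempt at photorealistic optics, and neurosphere interiors are not
drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .fret_glisa import FRETPair
from .growthcone_morph import CollapseCall
from .kinetics import TimeLapseTrack
from .stripe_guidance import NeuriteTrace, SphereGeometry, StripePattern


# --------------------------------------------------------------------------
# Parameter objects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Neurosphere scene on a striped substratum.

    ``avoidance_beta`` scales cue repulsion: a proposed step entering a cue
    lane is accepted with probability exp(-beta).
    """

    sphere_radius: float = 150.0     # µm (spheres are a few hundred µm across)
    n_neurites: int = 200
    step_length: float = 5.0         # µm per growth step
    turn_sd: float = 0.25            # radians, per-step heading jitter
    avoidance_beta: float = 0.0      # >= 0, dimensionless
    max_length: float = 400.0        # µm, trace truncation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sphere_radius:
            raise ValueError("sphere_radius must be positive")
        if self.n_neurites < 0:
            raise ValueError("n_neurites must be nonnegative")
        if self.avoidance_beta < 0:
            raise ValueError("avoidance_beta must be nonnegative")
        if self.step_length <= 0 or self.max_length <= 0:
            raise ValueError("step_length and max_length must be positive")


@dataclass(frozen=True)
class GrowthConeParams:
    """Spread or collapsed growth-cone morphology.

    Spread cones get a filled veil disc with Poisson-many Gamma-length
    filopodia radiating from the rim; collapsed cones get a thin shaft with
    at most two short filopodia and essentially no veil.
    """

    state: str = "spread"                # {"spread", "collapsed"}
    veil_radius: float = 8.0             # µm
    filopodia_count_mean: float = 8.0    # Poisson mean (spread state)
    filopodia_length_shape: float = 4.0  # Gamma shape
    filopodia_length_scale: float = 3.75  # Gamma scale, µm (mean 15 µm)
    noise_sd: float = 0.05               # intensity units (signal peak = 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in ("spread", "collapsed"):
            raise ValueError("state must be 'spread' or 'collapsed'")
        if self.veil_radius < 0 or self.noise_sd < 0:
            raise ValueError("veil_radius and noise_sd must be nonnegative")


@dataclass(frozen=True)
class TrackParams:
    """Leading-edge track advancing at a constant true rate."""

    true_rate: float = 12.0          # µm/hr
    frame_interval: float = 5.0      # minutes
    n_frames: int = 13               # one hour of imaging by default
    position_noise_sd: float = 0.5   # µm
    retraction_prob: float = 0.0     # per-frame probability
    retraction_magnitude: float = 0.0  # µm subtracted on a retraction event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0 <= self.retraction_prob <= 1:
            raise ValueError("retraction_prob must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")


@dataclass(frozen=True)
class FretParams:
    """Acceptor-photobleaching pair with known true efficiency."""

    true_efficiency: float = 0.15    # dimensionless, in [0, 1)
    donor_base: float = 1e4          # unquenched donor photon counts per pixel
    bleach_fraction: float = 1.0     # fraction of acceptor removed in the ROI
    background_counts: float = 500.0  # counts per pixel outside/under the cell
    noise_model: str = "poisson"     # {"poisson", "none"}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_efficiency < 1:
            raise ValueError("true_efficiency must lie in [0, 1)")
        if not 0 < self.bleach_fraction <= 1:
            raise ValueError("bleach_fraction must lie in (0, 1]")
        if self.noise_model not in ("poisson", "none"):
            raise ValueError("noise_model must be 'poisson' or 'none'")


# --------------------------------------------------------------------------
# Stripe patterns
# --------------------------------------------------------------------------

def generate_stripe_pattern(
    stripe_width: float,
    image_size: tuple[int, int],
    scale: float,
    orientation: str = "vertical",
) -> StripePattern:
    """Alternating equal-width cue / laminin lanes on a pixel grid.

    Lane boundaries are half-open so every pixel carries exactly one label;
    pixel labels are taken at pixel centers. ``vertical`` lanes run along y
    (label varies with x); ``horizontal`` is the transpose.
    """
    if stripe_width <= 0 or scale <= 0:
        raise ValueError("stripe_width and scale must be positive")
    h, w = image_size
    if orientation == "vertical":
        centers = (np.arange(w) + 0.5) * scale
        lanes = np.floor(centers / stripe_width).astype(int)
        row = lanes % 2 == 0
        mask = np.broadcast_to(row, (h, w)).copy()
        o = np.array([0.0, 1.0])
    elif orientation == "horizontal":
        centers = (np.arange(h) + 0.5) * scale
        lanes = np.floor(centers / stripe_width).astype(int)
        col = lanes % 2 == 0
        mask = np.broadcast_to(col[:, None], (h, w)).copy()
        o = np.array([1.0, 0.0])
    else:
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    return StripePattern(cue_mask=mask, orientation=o, scale=scale,
                         stripe_width=stripe_width)


# --------------------------------------------------------------------------
# Neurite traces
# --------------------------------------------------------------------------

def simulate_neurite_traces(
    scene: SceneParams,
    stripes: StripePattern,
    sphere: SphereGeometry | None = None,
    max_retries: int = 10,
) -> list[NeuriteTrace]:
    """Grow neurites from the sphere rim as cue-avoiding persistent walks.

    Each trace starts at a uniform rim angle heading radially outward and
    advances in fixed-length steps with Gaussian heading jitter. A proposed
    step that would enter a cue lane (current point off cue, endpoint on
    cue) is accepted with probability exp(-beta); otherwise the heading is
    redrawn (up to ``max_retries`` times), after which the step is taken
    parallel to the stripes in the direction closest to the current heading.
    Penalizing the entering transition rather than mere presence on cue
    means a neurite that happens to sprout on a cue lane can still leave it
    instead of being herded along it forever. Traces are truncated at
    ``max_length`` or at the canvas edge. The acceptance draw is made on
    every proposal, so with beta = 0 the vertex stream is identical for any
    stripe map under the same seed.
    """
    rng = np.random.default_rng(scene.seed)
    if sphere is None:
        w_um, h_um = stripes.extent_um
        sphere = SphereGeometry(center=(w_um / 2.0, h_um / 2.0),
                                radius=scene.sphere_radius)
    w_um, h_um = stripes.extent_um
    accept_cue = math.exp(-scene.avoidance_beta)
    n_steps = int(scene.max_length / scene.step_length)
    ox, oy = float(stripes.orientation[0]), float(stripes.orientation[1])
    L = scene.step_length
    traces: list[NeuriteTrace] = []

    for i in range(scene.n_neurites):
        a0 = rng.uniform(0.0, 2.0 * math.pi)
        x = sphere.center[0] + sphere.radius * math.cos(a0)
        y = sphere.center[1] + sphere.radius * math.sin(a0)
        heading = a0
        verts = [(x, y)]
        on_cue = stripes.is_cue(x, y)
        for _ in range(n_steps):
            accepted = False
            for _ in range(max_retries):
                h2 = heading + rng.normal(0.0, scene.turn_sd)
                px = x + L * math.cos(h2)
                py = y + L * math.sin(h2)
                u = rng.random()
                entering_cue = stripes.is_cue(px, py) and not on_cue
                if (not entering_cue) or u < accept_cue:
                    heading = h2
                    accepted = True
                    break
            if not accepted:
                # bounded retries exhausted: step parallel to the stripes
                sign = 1.0 if (math.cos(heading) * ox + math.sin(heading) * oy) >= 0 else -1.0
                px = x + L * sign * ox
                py = y + L * sign * oy
                heading = math.atan2(sign * oy, sign * ox)
            if not (0.0 <= px < w_um and 0.0 <= py < h_um):
                break
            x, y = px, py
            on_cue = stripes.is_cue(x, y)
            verts.append((x, y))
        if len(verts) >= 2:
            traces.append(NeuriteTrace(trace_id=i, vertices=np.array(verts)))
    return traces


@dataclass
class SceneBundle:
    """A simulated stripe-assay scene with its full ground truth."""

    params: SceneParams
    sphere: SphereGeometry
    stripes: StripePattern
    traces: list[NeuriteTrace]


def simulate_scene(
    scene: SceneParams,
    stripe_width: float = 50.0,
    scale: float = 1.0,
    orientation: str = "vertical",
    margin_um: float = 20.0,
) -> SceneBundle:
    """Convenience wrapper: build a pattern sized to the scene and grow traces."""
    side_um = 2.0 * (scene.sphere_radius + scene.max_length + margin_um)
    side_px = int(math.ceil(side_um / scale))
    stripes = generate_stripe_pattern(stripe_width, (side_px, side_px), scale,
                                      orientation)
    w_um, h_um = stripes.extent_um
    sphere = SphereGeometry(center=(w_um / 2.0, h_um / 2.0),
                            radius=scene.sphere_radius)
    traces = simulate_neurite_traces(scene, stripes, sphere)
    return SceneBundle(params=scene, sphere=sphere, stripes=stripes, traces=traces)


# --------------------------------------------------------------------------
# Scene rendering
# --------------------------------------------------------------------------

def rasterize_traces(
    traces: list[NeuriteTrace],
    shape: tuple[int, int],
    scale: float,
) -> np.ndarray:
    """Binary raster of trace polylines at 1-px linewidth (clipped to canvas)."""
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    clipped = False
    for tr in traces:
        v = tr.vertices
        cols = np.clip(np.round(v[:, 0] / scale - 0.5).astype(int), 0, w - 1)
        rows = np.clip(np.round(v[:, 1] / scale - 0.5).astype(int), 0, h - 1)
        in_canvas = (v[:, 0] >= 0) & (v[:, 0] < w * scale) & \
                    (v[:, 1] >= 0) & (v[:, 1] < h * scale)
        if not in_canvas.all():
            clipped = True
        for (r0, c0), (r1, c1) in zip(zip(rows[:-1], cols[:-1]),
                                      zip(rows[1:], cols[1:])):
            rr, cc = draw_line(r0, c0, r1, c1)
            out[rr, cc] = True
    if clipped:
        import warnings

        warnings.warn("traces extend outside the canvas: clipped", stacklevel=2)
    return out


@dataclass
class RenderedScene:
    factin: np.ndarray        # F-actin channel, float
    stripe_channel: np.ndarray  # cue marker channel, float
    trace_raster: np.ndarray  # ground-truth binary raster of the traces
    scale: float


def render_scene(
    traces: list[NeuriteTrace],
    stripes: StripePattern,
    sphere: SphereGeometry,
    psf_sigma: float = 0.5,      # µm, Gaussian point-spread stand-in
    background: float = 0.0,     # intensity offset
    noise_sd: float = 0.0,       # Gaussian noise SD
    amplitude: float = 1.0,
    seed: int = 0,
) -> RenderedScene:
    """Render a two-channel fluorescence image of a scene.

    The F-actin channel is the blurred trace raster plus background and
    Gaussian noise; the stripe channel encodes the cue lanes (same blur and
    noise treatment is deliberately not applied so the pattern's cue
    fraction is preserved exactly). The ground-truth raster is retained.
    """
    rng = np.random.default_rng(seed)
    raster = rasterize_traces(traces, stripes.shape, stripes.scale)
    factin = raster.astype(float) * amplitude
    if psf_sigma > 0:
        factin = gaussian_filter(factin, sigma=psf_sigma / stripes.scale)
    factin = factin + background
    if noise_sd > 0:
        factin = factin + rng.normal(0.0, noise_sd, size=factin.shape)
    stripe_channel = stripes.cue_mask.astype(float) * amplitude
    return RenderedScene(factin=factin, stripe_channel=stripe_channel,
                         trace_raster=raster, scale=stripes.scale)


# --------------------------------------------------------------------------
# Growth cones
# --------------------------------------------------------------------------

@dataclass
class GrowthConeImage:
    """Rendered growth cone plus its generative ground truth."""

    image: np.ndarray
    scale: float
    truth: CollapseCall
    state: str
    filopodia_lengths_um: list[float]
    mask_truth: np.ndarray  # noiseless binary raster of the morphology


def simulate_growth_cone(
    params: GrowthConeParams,
    shape: tuple[int, int] = (256, 256),
    scale: float = 0.25,          # µm per pixel (64 µm field)
    psf_sigma_um: float = 0.4,
    background: float = 0.1,
) -> GrowthConeImage:
    """Render one spread or collapsed growth cone with ground truth.

    Spread: filled veil disc of the configured radius at the field center,
    an axon shaft running to the left border, and Poisson-many filopodia of
    Gamma-distributed length radiating from the rim as 1-px lines.
    Collapsed: shaft only plus 0-2 short (< 8 µm) filopodia at the tip.
    The binary raster is blurred, offset by the background, and Gaussian
    noise is added; the same seed gives a byte-identical image.
    """
    rng = np.random.default_rng(params.seed)
    h, w = shape
    canvas = np.zeros((h, w), dtype=bool)
    cy, cx = h // 2, w // 2

    def draw_segment(r0, c0, r1, c1, width_px=1):
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = True
        if width_px > 1:
            for dr in range(-(width_px // 2), width_px // 2 + 1):
                rr2 = rr[ok] + dr
                ok2 = (rr2 >= 0) & (rr2 < h)
                canvas[rr2[ok2], cc[ok][ok2]] = True

    filopodia_lengths: list[float] = []
    if params.state == "spread":
        r_px = max(1, int(round(params.veil_radius / scale)))
        rr, cc = draw_disk((cy, cx), r_px, shape=shape)
        canvas[rr, cc] = True
        # shaft to the left border, 2 px wide (~0.5 µm)
        draw_segment(cy, 0, cy, cx - r_px + 1, width_px=2)
        n_filo = int(rng.poisson(params.filopodia_count_mean))
        for _ in range(n_filo):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            length = float(rng.gamma(params.filopodia_length_shape,
                                     params.filopodia_length_scale))
            length = float(np.clip(length, 2.0, 25.0))
            filopodia_lengths.append(length)
            b_r = cy + r_px * math.sin(ang)
            b_c = cx + r_px * math.cos(ang)
            t_r = cy + (r_px + length / scale) * math.sin(ang)
            t_c = cx + (r_px + length / scale) * math.cos(ang)
            draw_segment(b_r, b_c, t_r, t_c)
        truth = CollapseCall(
            collapsed=False,
            veil_area_um2=math.pi * params.veil_radius**2,
            n_filopodia=n_filo,
            max_filopodium_length_um=max(filopodia_lengths, default=0.0),
        )
    else:
        # collapsed: thin shaft from the left border to a tip at the center
        draw_segment(cy, 0, cy, cx, width_px=2)
        n_filo = int(min(2, rng.poisson(0.8)))
        for _ in range(n_filo):
            ang = rng.uniform(-math.pi / 2, math.pi / 2)  # forward fan
            length = float(np.clip(rng.gamma(2.0, 1.5), 1.5, 8.0))
            filopodia_lengths.append(length)
            t_r = cy + (length / scale) * math.sin(ang)
            t_c = cx + (length / scale) * math.cos(ang)
            draw_segment(cy, cx, t_r, t_c)
        truth = CollapseCall(
            collapsed=True,
            veil_area_um2=0.0,
            n_filopodia=n_filo,
            max_filopodium_length_um=max(filopodia_lengths, default=0.0),
        )

    img = canvas.astype(float)
    if psf_sigma_um > 0:
        img = gaussian_filter(img, sigma=psf_sigma_um / scale)
        peak = img.max()
        if peak > 0:
            img = img / peak
    img = img + background
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return GrowthConeImage(
        image=img,
        scale=scale,
        truth=truth,
        state=params.state,
        filopodia_lengths_um=filopodia_lengths,
        mask_truth=canvas,
    )


# --------------------------------------------------------------------------
# Time-lapse tracks
# --------------------------------------------------------------------------

@dataclass
class TrackTruth:
    true_rate: float
    true_positions: np.ndarray
    retraction_frames: np.ndarray


def simulate_timelapse_track(
    params: TrackParams,
    track_id: int | str = 0,
    treatment_time_min: float | None = None,
) -> tuple[TimeLapseTrack, TrackTruth]:
    """Leading-edge positions advancing at ``true_rate`` with optional retractions.

    The true position advances ``true_rate * frame_interval / 60`` µm per
    frame, minus ``retraction_magnitude`` on frames where a retraction event
    fires; the observed positions add Gaussian measurement noise.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    t = params.frame_interval * np.arange(n)
    step = params.true_rate * params.frame_interval / 60.0
    true_pos = np.empty(n)
    true_pos[0] = 0.0
    retract = np.zeros(n, dtype=bool)
    for i in range(1, n):
        d = step
        if params.retraction_prob > 0 and rng.random() < params.retraction_prob:
            d -= params.retraction_magnitude
            retract[i] = True
        true_pos[i] = true_pos[i - 1] + d
    if params.position_noise_sd > 0:
        obs = true_pos + rng.normal(0.0, params.position_noise_sd, size=n)
    else:
        obs = true_pos.copy()
    track = TimeLapseTrack(track_id=track_id, t_min=t, positions=obs,
                           treatment_time_min=treatment_time_min)
    truth = TrackTruth(true_rate=params.true_rate, true_positions=true_pos,
                       retraction_frames=np.flatnonzero(retract))
    return track, truth


# --------------------------------------------------------------------------
# FRET pairs
# --------------------------------------------------------------------------

def simulate_fret_pair(
    params: FretParams,
    shape: tuple[int, int] = (64, 64),
    roi_radius_px: int = 12,
    scale: float = 0.2,
) -> tuple[FRETPair, float]:
    """Donor/acceptor pre/post-bleach pair with known true efficiency.

    The cell occupies a disc ROI at the field center. Donor counts are
    quenched by the true efficiency before the bleach,
    ``donor_base * (1 - E)``, and dequenched in proportion to the bleached
    acceptor fraction afterwards, ``donor_base * (1 - E * (1 - f))``, so
    with a full bleach the donor-dequenching estimator returns E exactly.
    The acceptor channel loses fraction f inside the ROI. A flat background
    sits under everything; Poisson noise is applied per pixel unless the
    noise model is "none". Returns the pair and the true efficiency.
    """
    h, w = shape
    roi = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((h // 2, w // 2), roi_radius_px, shape=shape)
    roi[rr, cc] = True

    E = params.true_efficiency
    f = params.bleach_fraction
    b = params.background_counts
    S = params.donor_base

    donor_pre = np.full(shape, b, dtype=float)
    donor_pre[roi] = b + S * (1.0 - E)
    donor_post = np.full(shape, b, dtype=float)
    donor_post[roi] = b + S * (1.0 - E * (1.0 - f))
    acceptor_pre = np.full(shape, b, dtype=float)
    acceptor_pre[roi] = b + S
    acceptor_post = np.full(shape, b, dtype=float)
    acceptor_post[roi] = b + S * (1.0 - f)

    if params.noise_model == "poisson":
        rng = np.random.default_rng(params.seed)
        donor_pre = rng.poisson(donor_pre).astype(float)
        donor_post = rng.poisson(donor_post).astype(float)
        acceptor_pre = rng.poisson(acceptor_pre).astype(float)
        acceptor_post = rng.poisson(acceptor_post).astype(float)

    pair = FRETPair(
        donor_pre=donor_pre,
        donor_post=donor_post,
        acceptor_pre=acceptor_pre,
        acceptor_post=acceptor_post,
        bleach_roi=roi,
        scale=scale,
    )
    return pair, E


# --------------------------------------------------------------------------
# Immunolabel intensity fields
# --------------------------------------------------------------------------

def simulate_intensity_field(
    signal_level: float,
    background: float = 20.0,
    noise_sd_fraction: float = 0.1,
    shape: tuple[int, int] = (128, 128),
    roi_radius_px: int = 30,
    scale: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Immunolabel field: a disc ROI at ``background + signal_level`` over
    background, with Gaussian noise of SD ``noise_sd_fraction * signal_level``.

    Returns (label_image, roi_mask); pair with ``measure_roi_intensity`` to
    emulate genotype-dependent fluorescence differences.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    roi = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((h // 2, w // 2), roi_radius_px, shape=shape)
    roi[rr, cc] = True
    img = np.full(shape, background, dtype=float)
    img[roi] += signal_level
    if noise_sd_fraction > 0:
        img = img + rng.normal(0.0, noise_sd_fraction * signal_level, size=shape)
    return img, roi
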