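"""Ground-truth-annotated synthetic inputs emulating two-colour condensate data.

Rendered micrographs contain round (monophasic) discs and Janus/biphasic
doublets with analytically exact partition coefficients and contact angles,
followed by Gaussian blur, additive Gaussian noise and optional Poisson shot
noise — the features the measurement pipeline must be robust to.  Composition
grids and temperature-ramp melting stacks (sigmoidal condensate dissolution
with optional heating/cooling hysteresis) are generated with the study's
default sampling conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters

from .errors import CapacityError, CompositionInfeasibleError
from .geometry import Line, make_doublet_geometry
from .image import TwoChannelImage
from .stoichiometry import (
    DEFAULT_THRESHOLD,
    MixtureComposition,
    classify_phase,
    order_parameter,
)

#: Default nanostar-fraction levels of the composition grid (symmetric emulation
#: of the study's five levels, which are not individually documented).
DEFAULT_FA_LEVELS = (0.25, 0.375, 0.5, 0.625, 0.75)

#: Default F_ab increment (the experimental 5% pipetting steps).
DEFAULT_FAB_STEP = 0.05


@dataclass(frozen=True)
class SyntheticDropletSpec:
    """One droplet to rasterise: geometry plus per-domain channel intensities.

    ``intensity_A``/``intensity_B`` are (value in A-rich domain, value in
    B-rich domain) for the respective channel, all in [0, 1]; the implied
    ground-truth partition coefficients are rho_A = intensity_A[1] /
    intensity_A[0] and rho_B = intensity_B[0] / intensity_B[1].  A disc uses
    the A-rich values for both channels.
    """

    geometry: str  # "disc" | "doublet"
    center: tuple[float, float]  # (x, y) pixel coordinates
    radius_px: float
    theta_A: float | None = None
    theta_B: float | None = None
    intensity_A: tuple[float, float] = (1.0, 0.2)
    intensity_B: tuple[float, float] = (0.2, 1.0)
    rotation: float = 0.0

    def __post_init__(self):
        if self.geometry not in ("disc", "doublet"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        for pair in (self.intensity_A, self.intensity_B):
            if not all(0.0 <= v <= 1.0 for v in pair):
                raise ValueError("intensities must lie in [0, 1]")
        if self.geometry == "doublet":
            if self.theta_A is None or self.theta_B is None:
                raise ValueError("doublet requires target contact angles")
            make_doublet_geometry(self.theta_A, self.theta_B, self.radius_px)  # validates

    @classmethod
    def disc(cls, center, radius_px, i_a=1.0, i_b=1.0):
        return cls("disc", tuple(center), radius_px,
                   intensity_A=(i_a, i_a), intensity_B=(i_b, i_b))

    @classmethod
    def doublet(cls, center, radius_px, theta_a, theta_b,
                rho_a=0.2, rho_b=0.2, peak=1.0, rotation=0.0):
        """Doublet with prescribed partition coefficients (enriched level ``peak``)."""
        return cls(
            "doublet", tuple(center), radius_px, theta_a, theta_b,
            intensity_A=(peak, peak * rho_a),
            intensity_B=(peak * rho_b, peak),
            rotation=rotation,
        )

    @property
    def true_rho_A(self) -> float:
        if self.geometry == "disc":
            return 1.0
        return self.intensity_A[1] / self.intensity_A[0]

    @property
    def true_rho_B(self) -> float:
        if self.geometry == "disc":
            return 1.0
        return self.intensity_B[0] / self.intensity_B[1]

    def bounding_radius(self) -> float:
        if self.geometry == "disc":
            return self.radius_px
        geom = make_doublet_geometry(self.theta_A, self.theta_B, self.radius_px)
        return abs(geom.circle_A.cx) + geom.circle_A.r


@dataclass
class DropletTruth:
    spec: SyntheticDropletSpec
    mask: np.ndarray
    mask_Arich: np.ndarray
    mask_Brich: np.ndarray
    rho_A: float
    rho_B: float
    theta_A: float | None
    theta_B: float | None


@dataclass
class SyntheticGroundTruth:
    droplets: list[DropletTruth] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _doublet_masks(spec: SyntheticDropletSpec, shape: tuple[int, int]):
    """Boolean A-domain / B-domain masks of a doublet on the canvas."""
    geom = make_doublet_geometry(spec.theta_A, spec.theta_B, spec.radius_px)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dx = xx - spec.center[0]
    dy = yy - spec.center[1]
    c, s = math.cos(-spec.rotation), math.sin(-spec.rotation)
    xr = c * dx - s * dy
    yr = s * dx + c * dy
    in_a_cap = (xr - geom.circle_A.cx) ** 2 + yr**2 <= geom.circle_A.r**2
    in_b_cap = (xr - geom.circle_B.cx) ** 2 + yr**2 <= geom.circle_B.r**2
    iface = geom.interface
    if isinstance(iface, Line):
        a_side = xr <= 0.0
    else:
        inside = (xr - iface.cx) ** 2 + yr**2 <= iface.r**2
        # phase A is on the same side of the arc as the far point of cap A
        far_a_inside = (geom.circle_A.cx - geom.circle_A.r - iface.cx) ** 2 <= iface.r**2
        a_side = inside if far_a_inside else ~inside
    mask_a = in_a_cap & a_side
    mask_b = in_b_cap & ~a_side
    return mask_a, mask_b


def _disc_mask(spec: SyntheticDropletSpec, shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return (xx - spec.center[0]) ** 2 + (yy - spec.center[1]) ** 2 <= spec.radius_px**2


def render_image(
    specs: list[SyntheticDropletSpec],
    canvas_shape: tuple[int, int] = (256, 256),
    *,
    background: float = 0.02,
    blur_sigma_px: float = 1.0,
    noise_frac: float = 0.05,
    poisson_photons: float | None = None,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> tuple[TwoChannelImage, SyntheticGroundTruth]:
    """Rasterise droplets, apply blur then noise; return image plus ground truth.

    Droplets must fit on the canvas without mutual overlap (checked on
    bounding circles).  Reproducible bit-for-bit from specs + seed.
    """
    for i, sp in enumerate(specs):
        br = sp.bounding_radius()
        x, y = sp.center
        if not (br <= x <= canvas_shape[1] - br and br <= y <= canvas_shape[0] - br):
            raise ValueError(f"droplet {i} does not fit on the canvas")
        for sq in specs[:i]:
            dist = math.hypot(x - sq.center[0], y - sq.center[1])
            if dist < br + sq.bounding_radius():
                raise ValueError(f"droplets overlap near {sp.center} / {sq.center}")

    cha = np.full(canvas_shape, background, dtype=float)
    chb = np.full(canvas_shape, background, dtype=float)
    truth = SyntheticGroundTruth(params={
        "background": background, "blur_sigma_px": blur_sigma_px,
        "noise_frac": noise_frac, "poisson_photons": poisson_photons, "seed": seed,
    })
    for sp in specs:
        if sp.geometry == "disc":
            mask = _disc_mask(sp, canvas_shape)
            mask_a, mask_b = mask, np.zeros_like(mask)
            cha[mask] = sp.intensity_A[0]
            chb[mask] = sp.intensity_B[0]
        else:
            mask_a, mask_b = _doublet_masks(sp, canvas_shape)
            mask = mask_a | mask_b
            cha[mask_a] = sp.intensity_A[0]
            cha[mask_b] = sp.intensity_A[1]
            chb[mask_a] = sp.intensity_B[0]
            chb[mask_b] = sp.intensity_B[1]
        truth.droplets.append(
            DropletTruth(sp, mask, mask_a, mask_b, sp.true_rho_A, sp.true_rho_B,
                         sp.theta_A, sp.theta_B)
        )

    rng = np.random.default_rng(seed)
    out = []
    for ch in (cha, chb):
        if blur_sigma_px > 0:
            ch = filters.gaussian(ch, sigma=blur_sigma_px, preserve_range=True)
        if poisson_photons:
            ch = rng.poisson(np.clip(ch, 0, None) * poisson_photons) / poisson_photons
        if noise_frac > 0:
            ch = ch + rng.normal(0.0, noise_frac, ch.shape)
        out.append(np.clip(ch, 0.0, None))
    img = TwoChannelImage(out[0], out[1], pixel_size=pixel_size,
                          metadata={"synthetic": True, "seed": seed})
    return img, truth


def random_droplet_field(
    n: int,
    canvas_shape: tuple[int, int],
    rng: np.random.Generator,
    *,
    radius_px: float = 24.0,
    theta_a: float = 2.35619,
    theta_b: float = 2.35619,
    rho_a: float = 0.2,
    rho_b: float = 0.2,
    biphasic: bool = True,
    max_tries: int = 2000,
) -> list[SyntheticDropletSpec]:
    """Place ``n`` non-overlapping droplets at random positions.

    Raises :class:`CapacityError` when placement fails after bounded retries.
    """
    specs: list[SyntheticDropletSpec] = []
    proto = (
        SyntheticDropletSpec.doublet((0, 0), radius_px, theta_a, theta_b, rho_a, rho_b)
        if biphasic
        else SyntheticDropletSpec.disc((0, 0), radius_px)
    )
    br = proto.bounding_radius() + 2
    tries = 0
    while len(specs) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(f"placed {len(specs)}/{n} droplets in {max_tries} tries")
        x = rng.uniform(br, canvas_shape[1] - br)
        y = rng.uniform(br, canvas_shape[0] - br)
        if any(math.hypot(x - s.center[0], y - s.center[1]) < 2 * br for s in specs):
            continue
        rot = rng.uniform(0, 2 * np.pi) if biphasic else 0.0
        specs.append(
            SyntheticDropletSpec.doublet((x, y), radius_px, theta_a, theta_b,
                                         rho_a, rho_b, rotation=rot)
            if biphasic
            else SyntheticDropletSpec.disc((x, y), radius_px)
        )
    return specs


# ---------------------------------------------------------------------------
# Composition grids
# ---------------------------------------------------------------------------


def composition_grid(
    fa_list=DEFAULT_FA_LEVELS,
    fab_step: float = DEFAULT_FAB_STEP,
    fab_max: float = 1.0,
    ns_total: float = 0.5,
    linker_total: float = 1.0,
) -> list[MixtureComposition]:
    """Feasible Cartesian grid of compositions (infeasible points dropped)."""
    n_steps = int(round(fab_max / fab_step))
    fab_values = np.linspace(0.0, n_steps * fab_step, n_steps + 1)
    comps = []
    for fa in fa_list:
        for fab in fab_values:
            try:
                comps.append(
                    MixtureComposition(float(fa), float(round(fab, 12)),
                                       ns_total, linker_total)
                )
            except CompositionInfeasibleError:
                continue
    return comps


def composition_table(
    comps: list[MixtureComposition], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Annotate compositions with fractions, order parameter and phase class."""
    rows = []
    for c in comps:
        op = order_parameter(c.F_A, c.F_ab)
        rows.append({
            "F_A": c.F_A, "F_B": c.F_B, "F_ab": c.F_ab,
            "F_aa": c.F_aa, "F_bb": c.F_bb,
            "f_alpha_ab": op.f_alpha_ab, "f_beta_ab": op.f_beta_ab,
            "order_param": op.order_param,
            "phase_class": classify_phase(op.order_param, threshold),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Melting stacks
# ---------------------------------------------------------------------------


def melt_stack(
    tm_true: float,
    *,
    t_min: float = 30.0,
    t_max: float = 60.0,
    t_step: float = 0.5,
    hysteresis: float = 0.0,
    direction: str = "heating",
    transition_width: float = 0.4,
    specs: list[SyntheticDropletSpec] | None = None,
    canvas_shape: tuple[int, int] = (128, 128),
    background: float = 0.02,
    blur_sigma_px: float = 1.0,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> tuple[list[TwoChannelImage], np.ndarray, SyntheticGroundTruth]:
    """Temperature-indexed image stack of condensates dissolving at ``tm_true``.

    Total fluorophore is conserved: each frame interpolates between the
    condensed image and a uniform image with the same per-channel mean.  The
    condensed contrast is zero above the transition and grows steadily below
    it (a softplus ramp of width ``transition_width`` centred at
    ``tm_true + hysteresis/2`` on heating, ``- hysteresis/2`` on cooling), so
    the coefficient-of-variation trace shows a single kink at the transition.
    Temperatures are ascending on heating ramps, descending on cooling.
    """
    if direction not in ("heating", "cooling"):
        raise ValueError("direction must be 'heating' or 'cooling'")
    temps = np.arange(t_min, t_max + t_step / 2, t_step)
    if direction == "cooling":
        temps = temps[::-1]
    if specs is None:
        rng = np.random.default_rng(seed)
        specs = random_droplet_field(4, canvas_shape, rng, radius_px=14.0, biphasic=False)
    center = tm_true + (hysteresis / 2.0 if direction == "heating" else -hysteresis / 2.0)
    base, truth = render_image(
        specs, canvas_shape, background=background, blur_sigma_px=blur_sigma_px,
        noise_frac=0.0, seed=seed,
    )
    chans = [base.channel_A, base.channel_B]
    means = [float(ch.mean()) for ch in chans]
    scale = max(center - float(temps.min()), transition_width)
    frames = []
    for i, t in enumerate(temps):
        # softplus ramp: ~0 above the transition, ~linear growth below it
        c = transition_width * math.log1p(math.exp((center - t) / transition_width)) / scale
        c = min(c, 1.0)
        rng_f = np.random.default_rng(seed + 1000 + i)
        out = []
        for ch, mu in zip(chans, means):
            fr = c * ch + (1.0 - c) * mu
            if noise_frac > 0:
                fr = fr + rng_f.normal(0.0, noise_frac, fr.shape)
            out.append(np.clip(fr, 0.0, None))
        img = TwoChannelImage(out[0], out[1], metadata={"temperature": float(t)})
        frames.append(img)
    truth.params.update(
        tm_true=tm_true, hysteresis=hysteresis, direction=direction,
        transition_center=center, transition_width=transition_width,
    )
    return frames, temps, truth
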