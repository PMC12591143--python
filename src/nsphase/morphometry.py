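"""Condensate morphometry: segmentation, partitioning, contact angles, melting traces.

The pipeline mirrors a standard confocal-image analysis of two-colour
condensates.  Background is removed by an Otsu threshold on the smoothed
channel sum, condensates are 8-connected components, and each condensate is
split into A-rich/B-rich domains by comparing quantile-normalised channels
(with a contrast criterion: nearly-mixed droplets, whose apparent domains are
noise speckle, are classified monophasic).  Partition coefficients (rho) are
depleted-over-enriched mean intensities on eroded domain masks.  Contact
angles are measured per A-B interface: circles are fitted to the
solvent-facing contour arcs near each triple junction and to the interfacial
arc, and the wedge angles between the tangents give theta_A and theta_B
(averaged over the interface's two junctions).  Interfacial-tension ratios
follow from the Neumann force balance at the triple junction:

    gamma_A / gamma_AB = -sin(theta_B) / sin(theta_A + theta_B)
    gamma_B / gamma_AB = -sin(theta_A) / sin(theta_A + theta_B)
    gamma_AB = 2 gamma_0 cos(theta / 2),   theta = 2*pi - theta_A - theta_B,

the last relation under the symmetric-tension assumption gamma_A = gamma_B
= gamma_0.  Melting traces are per-frame coefficient-of-variation statistics
whose two-segment piecewise-linear breakpoint locates the transition
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import filters, measure, morphology

from .errors import SingularConfigurationError, UnfittableError
from .geometry import (
    Circle,
    CircleFit,
    Line,
    circle_intersections,
    fit_circle_taubin,
    fit_line_pca,
    measure_contact_angles,
    wedge_angle,
)
from .image import TwoChannelImage

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable knobs of the segmentation/measurement pipeline (pixel units)."""

    smooth_sigma: float = 2.0          # Gaussian smoothing before Otsu background removal
    min_area: int = 64                 # smallest condensate kept, px
    domain_smooth_sigma: float = 1.0   # smoothing before A/B domain comparison
    norm_quantile: float = 0.95        # per-condensate channel normalisation quantile
    min_domain_frac: float = 0.02      # domains below this area fraction are discarded
    domain_contrast: float = 0.15      # min normalised intensity separation of domains
    erode_px: int = 2                  # erosion of domain masks before intensity sampling
    min_arc_px: int = 8                # smallest contour arc accepted for a circle fit
    line_radius_factor: float = 25.0   # interface radius above factor*droplet radius -> line
    junction_arc_factor: float = 2.0   # solvent-arc window = factor * component radius


def _erode(mask: np.ndarray, px: int = 1) -> np.ndarray:
    if px <= 0:
        return mask
    return morphology.erosion(mask, morphology.disk(px))


def _dilate(mask: np.ndarray, px: int = 1) -> np.ndarray:
    return morphology.dilation(mask, morphology.disk(px))


@dataclass
class InterfaceRecord:
    """One A-B interface: contact angles, tensions and circle fits."""

    theta_A: float
    theta_B: float
    theta: float
    cos_half_theta: float
    gammaA_over_gammaAB: float
    gammaB_over_gammaAB: float
    fit_A: CircleFit | None = None
    fit_B: CircleFit | None = None
    fit_interface: CircleFit | None = None
    interface_is_line: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class CondensateRecord:
    """One segmented condensate: masks, domain split and partition coefficients."""

    label: int
    mask: np.ndarray
    mask_Arich: np.ndarray
    mask_Brich: np.ndarray
    rho_A: float
    rho_B: float
    raw_rho_A: float
    raw_rho_B: float
    n_domains: int
    interfaces: list[InterfaceRecord] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def is_biphasic(self) -> bool:
        return self.n_domains >= 2

    @property
    def interface(self) -> InterfaceRecord | None:
        """The first (or only) measured interface, if any."""
        return self.interfaces[0] if self.interfaces else None

    @property
    def area(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_condensates(img: TwoChannelImage, cfg: MorphometryConfig | None = None) -> np.ndarray:
    """Label condensates: Otsu threshold on the smoothed channel sum, 8-connectivity.

    Returns an integer label image; an empty/constant image yields zero labels.
    """
    cfg = cfg or MorphometryConfig()
    total = img.channel_A + img.channel_B
    smoothed = filters.gaussian(total, sigma=cfg.smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) <= 0:
        return np.zeros(img.shape, dtype=int)
    thr = filters.threshold_otsu(smoothed)
    labels = measure.label(smoothed > thr, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= cfg.min_area)
    keep = keep[keep > 0]
    relabel = np.zeros(areas.size, dtype=int)
    relabel[keep] = np.arange(1, keep.size + 1)
    return relabel[labels]


def split_domains(
    mask: np.ndarray, img: TwoChannelImage, cfg: MorphometryConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assign condensate pixels to A-rich / B-rich domains.

    Channels are lightly smoothed and normalised by their within-condensate
    upper quantile (robust to unequal dye brightness); a pixel is A-rich where
    normalised A exceeds normalised B.  The split is demoted to monophasic
    (one empty mask) when either candidate domain falls below the
    ``min_domain_frac`` area fraction or when the normalised-intensity
    separation between the domains is below ``domain_contrast`` — the
    apparent domains of a nearly-mixed droplet are noise speckle, and small
    or nearly-mixed domains are genuinely unresolvable.
    """
    cfg = cfg or MorphometryConfig()
    if not mask.any():
        raise ValueError("empty condensate mask")
    cha = filters.gaussian(img.channel_A, sigma=cfg.domain_smooth_sigma, preserve_range=True)
    chb = filters.gaussian(img.channel_B, sigma=cfg.domain_smooth_sigma, preserve_range=True)
    qa = np.quantile(cha[mask], cfg.norm_quantile)
    qb = np.quantile(chb[mask], cfg.norm_quantile)
    na = cha / qa if qa > 0 else cha
    nb = chb / qb if qb > 0 else chb
    arich = mask & (na > nb)
    brich = mask & ~arich
    monophasic = False
    min_px = cfg.min_domain_frac * mask.sum()
    if arich.sum() < min_px or brich.sum() < min_px:
        monophasic = True
    else:
        diff = na - nb
        sep_a = float(diff[arich].mean())
        sep_b = float(-diff[brich].mean())
        if min(sep_a, sep_b) < cfg.domain_contrast:
            monophasic = True
    if monophasic:
        # attribute the whole condensate to the brighter channel
        if float(na[mask].mean()) >= float(nb[mask].mean()):
            return mask.copy(), np.zeros_like(mask)
        return np.zeros_like(mask), mask.copy()
    return arich, brich


def partition_coefficients(
    img: TwoChannelImage,
    mask_arich: np.ndarray,
    mask_brich: np.ndarray,
    cfg: MorphometryConfig | None = None,
) -> tuple[float, float, float, float, list[str]]:
    """(rho_A, rho_B, raw_rho_A, raw_rho_B, flags) for one condensate.

    rho_A = mean A intensity over the eroded B-rich mask divided by mean A
    intensity over the eroded A-rich mask (and symmetrically for B).  A
    monophasic condensate (either domain empty) returns (1, 1).  Raw ratios
    above 1 are capped at 1 for reporting.
    """
    cfg = cfg or MorphometryConfig()
    flags: list[str] = []
    if not mask_arich.any() or not mask_brich.any():
        return 1.0, 1.0, 1.0, 1.0, flags

    def sample(m):
        er = _erode(m, cfg.erode_px)
        return er if er.any() else m  # fall back to uneroded for tiny domains

    ea, eb = sample(mask_arich), sample(mask_brich)
    a_in_a = float(img.channel_A[ea].mean())
    a_in_b = float(img.channel_A[eb].mean())
    b_in_b = float(img.channel_B[eb].mean())
    b_in_a = float(img.channel_B[ea].mean())
    if a_in_a <= 0 or b_in_b <= 0:
        flags.append("undefined-ratio")
        return np.nan, np.nan, np.nan, np.nan, flags
    raw_a = a_in_b / a_in_a
    raw_b = b_in_a / b_in_b
    return min(raw_a, 1.0), min(raw_b, 1.0), raw_a, raw_b, flags


# ---------------------------------------------------------------------------
# Interface geometry
# ---------------------------------------------------------------------------


@dataclass
class InterfaceCircleFits:
    fit_A: CircleFit
    fit_B: CircleFit
    interface: CircleFit | tuple[Line, float]
    is_line: bool


def _coords(mask: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    return np.column_stack([cc.astype(float), rr.astype(float)])  # (x, y)


def _fit_interface_arc(pts: np.ndarray, r_cap: float):
    """Circle fit to interface pixels, demoted to a line beyond the radius cap."""
    try:
        fit = fit_circle_taubin(pts)
        if fit.circle.r <= r_cap:
            return fit, False
    except UnfittableError:
        pass
    line, res = fit_line_pca(pts)
    return (line, res), True


def fit_interface_circles(
    mask: np.ndarray,
    mask_arich: np.ndarray,
    mask_brich: np.ndarray,
    cfg: MorphometryConfig | None = None,
) -> InterfaceCircleFits:
    """Fit circles to the two solvent-facing arcs and the A-B interface arc.

    Intended for simple two-domain condensates: the solvent-facing arc of each
    domain is its share of the condensate boundary, the interface arc the
    pixel band where the domains touch.  An interface whose fitted radius
    exceeds ``line_radius_factor`` times the equivalent droplet radius is
    reported as a straight line.  Raises :class:`UnfittableError` when any
    arc has too few pixels.
    """
    cfg = cfg or MorphometryConfig()
    if not (mask_arich.any() and mask_brich.any()):
        raise UnfittableError("both domains required for interface fitting")
    boundary = mask & ~_erode(mask)
    arc_a = boundary & mask_arich
    arc_b = boundary & mask_brich
    interface_px = (mask_arich & _dilate(mask_brich)) | (mask_brich & _dilate(mask_arich))
    if min(arc_a.sum(), arc_b.sum(), interface_px.sum()) < cfg.min_arc_px:
        raise UnfittableError("insufficient arc pixels")
    fit_a = fit_circle_taubin(_coords(arc_a))
    fit_b = fit_circle_taubin(_coords(arc_b))
    r_eq = np.sqrt(mask.sum() / np.pi)
    fit_i, is_line = _fit_interface_arc(
        _coords(interface_px), cfg.line_radius_factor * r_eq
    )
    return InterfaceCircleFits(fit_a, fit_b, fit_i, is_line)


def contact_angles(
    fits: InterfaceCircleFits, ref_a: np.ndarray, ref_b: np.ndarray
) -> tuple[float, float]:
    """Contact angles (radians) from fitted circles, averaged over both triple points.

    ``ref_a``/``ref_b`` are interior reference points of the two phases
    (domain centroids in pipeline use).
    """
    interface = fits.interface[0] if fits.is_line else fits.interface.circle
    return measure_contact_angles(
        fits.fit_A.circle, fits.fit_B.circle, interface, ref_a, ref_b
    )


def neumann_ratios(theta_a: float, theta_b: float) -> tuple[float, float]:
    """Interfacial-tension ratios from the Neumann force balance."""
    s = np.sin(theta_a + theta_b)
    if abs(s) < 1e-9:
        raise SingularConfigurationError("theta_A + theta_B is a multiple of pi")
    return float(-np.sin(theta_b) / s), float(-np.sin(theta_a) / s)


def gamma_ab_reduced(theta_a: float, theta_b: float) -> float:
    """cos(theta/2) = gamma_AB / (2 gamma_0), theta = 2*pi - theta_A - theta_B."""
    theta = TWO_PI - theta_a - theta_b
    return float(np.cos(theta / 2.0))


def _interface_record(
    theta_a: float, theta_b: float, fits: InterfaceCircleFits | None = None
) -> InterfaceRecord:
    theta = TWO_PI - theta_a - theta_b
    flags: list[str] = []
    try:
        ga, gb = neumann_ratios(theta_a, theta_b)
    except SingularConfigurationError:
        ga = gb = np.nan
        flags.append("singular-configuration")
    return InterfaceRecord(
        theta_A=theta_a,
        theta_B=theta_b,
        theta=theta,
        cos_half_theta=gamma_ab_reduced(theta_a, theta_b),
        gammaA_over_gammaAB=ga,
        gammaB_over_gammaAB=gb,
        fit_A=fits.fit_A if fits else None,
        fit_B=fits.fit_B if fits else None,
        fit_interface=None if (fits is None or fits.is_line) else fits.interface,
        interface_is_line=bool(fits.is_line) if fits else False,
        flags=flags,
    )


def _centroid(mask: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    return np.array([cc.mean(), rr.mean()])


def _tangent_at(shape: Circle | Line, p: np.ndarray, toward: np.ndarray) -> np.ndarray:
    if isinstance(shape, Line):
        t = shape.direction / np.linalg.norm(shape.direction)
    else:
        radial = p - shape.center
        radial = radial / np.linalg.norm(radial)
        t = np.array([-radial[1], radial[0]])
    if np.dot(t, toward - p) < 0:
        t = -t
    return t


def _tangent_along_arc(circle: Circle, p: np.ndarray, arc_pts: np.ndarray) -> np.ndarray:
    """Unit tangent of ``circle`` at endpoint ``p``, oriented into the arc.

    The sign is chosen from the signed angular offsets of the arc pixels
    around the circle centre (their median tells which way the arc runs),
    which stays correct however far the arc wraps around the circle.
    """
    radial = p - circle.center
    radial = radial / np.linalg.norm(radial)
    phi_p = np.arctan2(radial[1], radial[0])
    phis = np.arctan2(arc_pts[:, 1] - circle.cy, arc_pts[:, 0] - circle.cx)
    d = np.angle(np.exp(1j * (phis - phi_p)))
    sign = 1.0 if np.median(d) >= 0 else -1.0
    return sign * np.array([-radial[1], radial[0]])


def _subpixel_points(field: np.ndarray, level: float) -> np.ndarray:
    """Marching-squares iso-contour points of ``field`` as (x, y) coordinates."""
    segs = measure.find_contours(field, level)
    if not segs:
        return np.empty((0, 2))
    pts = np.vstack(segs)
    return np.column_stack([pts[:, 1], pts[:, 0]])  # (row, col) -> (x, y)


def _near_mask(pts: np.ndarray, mask: np.ndarray, tol_px: float = 1.5) -> np.ndarray:
    """Subset of points within ``tol_px`` of any True pixel of ``mask``."""
    if not len(pts) or not mask.any():
        return np.empty((0, 2))
    from scipy.spatial import cKDTree

    tree = cKDTree(_coords(mask))
    d, _ = tree.query(pts, k=1)
    return pts[d <= tol_px]


def _measure_interface(
    comp_a: np.ndarray,
    comp_b: np.ndarray,
    boundary: np.ndarray,
    r_eq: float,
    cfg: MorphometryConfig,
    solvent_pts: dict[str, np.ndarray] | None = None,
    interface_pts: np.ndarray | None = None,
) -> InterfaceRecord | None:
    """Junction-local contact-angle measurement for one adjacent domain pair.

    Circles are fitted to the interfacial pixel band and, per triple junction,
    to each domain's solvent-facing contour within a window around the
    junction; the triple point is the intersection of the two solvent circles
    nearest the junction.  Works for simple doublets and for segments of
    branched/striped condensates alike.  Returns None when the pair shares no
    sufficient interface; raises UnfittableError for defective geometry.
    """
    band = (comp_a & _dilate(comp_b)) | (comp_b & _dilate(comp_a))
    if band.sum() < cfg.min_arc_px:
        return None
    pts_i = _coords(band)
    if interface_pts is not None and len(interface_pts):
        sub = _near_mask(interface_pts, band)
        if len(sub) >= cfg.min_arc_px:
            pts_i = sub
    fit_i, is_line = _fit_interface_arc(pts_i, cfg.line_radius_factor * r_eq)
    iface_shape = fit_i[0] if is_line else fit_i.circle
    band_centroid = _centroid(band)

    # triple-junction clusters: interface pixels near the solvent boundary
    near = band & _dilate(boundary, 2)
    jlab = measure.label(near, connectivity=2)
    if jlab.max() < 2:
        raise UnfittableError("interface does not reach the condensate boundary twice")
    sizes = np.bincount(jlab.ravel())[1:]
    top2 = np.argsort(sizes)[-2:] + 1
    junctions = [_centroid(jlab == j) for j in top2]

    cen_a, cen_b = _centroid(comp_a), _centroid(comp_b)
    # solvent-facing contour pieces per domain (a stripe has disjoint wall arcs)
    arc_pieces = {}
    for key, comp in (("A", comp_a), ("B", comp_b)):
        lab = measure.label(boundary & comp, connectivity=2)
        if lab.max() == 0:
            raise UnfittableError(f"domain {key} has no solvent-facing contour")
        arc_pieces[key] = [_coords(lab == i) for i in range(1, lab.max() + 1)]
    radii = {
        "A": np.sqrt(comp_a.sum() / np.pi),
        "B": np.sqrt(comp_b.sum() / np.pi),
    }
    th_a, th_b = [], []
    fits_first: dict[str, CircleFit] = {}
    sels: dict[str, np.ndarray] = {}
    for pj in junctions:
        local_fits = {}
        for key in ("A", "B"):
            # the contour piece running through this junction, windowed around it
            dists = [np.hypot(pc[:, 0] - pj[0], pc[:, 1] - pj[1]) for pc in arc_pieces[key]]
            nearest = int(np.argmin([d.min() for d in dists]))
            w = max(cfg.junction_arc_factor * radii[key], 6.0)
            sel = arc_pieces[key][nearest][dists[nearest] <= w]
            if len(sel) < cfg.min_arc_px:
                raise UnfittableError(f"too few solvent-arc pixels near junction ({key})")
            if solvent_pts is not None and len(solvent_pts.get(key, ())):
                # refine to the sub-pixel contour tracking this pixel arc
                from scipy.spatial import cKDTree

                cand = solvent_pts[key]
                d_sub, _ = cKDTree(sel).query(cand, k=1)
                sub = cand[d_sub <= 1.5]
                if len(sub) >= cfg.min_arc_px:
                    sel = sub
            local_fits[key] = fit_circle_taubin(sel)
            sels[key] = sel
            fits_first.setdefault(key, local_fits[key])
        pts_x = circle_intersections(local_fits["A"].circle, local_fits["B"].circle)
        if not pts_x:
            raise UnfittableError("local solvent circles do not intersect")
        p = min(pts_x, key=lambda q: np.hypot(q[0] - pj[0], q[1] - pj[1]))
        t_i = _tangent_at(iface_shape, p, band_centroid)
        for key, cen, acc in (("A", cen_a, th_a), ("B", cen_b, th_b)):
            t_s = _tangent_along_arc(local_fits[key].circle, p, sels[key])
            ref = cen - p
            if np.linalg.norm(ref) < 1e-9:
                raise UnfittableError("degenerate phase reference point")
            acc.append(wedge_angle(t_s, t_i, ref / np.linalg.norm(ref)))

    fits = InterfaceCircleFits(fits_first["A"], fits_first["B"], fit_i, is_line)
    rec = _interface_record(float(np.mean(th_a)), float(np.mean(th_b)), fits)
    # measurement-quality flags: the two junction estimates of an angle must
    # agree, and the contour circle fits must actually track the contours
    spread = max(np.ptp(th_a), np.ptp(th_b)) if len(th_a) > 1 else 0.0
    if spread > np.radians(25.0):
        rec.flags.append("junction-disagreement")
    rms_vals = [fits_first["A"].rms_residual, fits_first["B"].rms_residual]
    rms_vals.append(fit_i[1] if is_line else fit_i.rms_residual)
    if max(rms_vals) > 1.5:
        rec.flags.append("poor-contour-fit")
    return rec


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _domain_components(mask_domain: np.ndarray, min_px: float) -> list[np.ndarray]:
    lab = measure.label(mask_domain, connectivity=2)
    return [
        lab == i
        for i in range(1, lab.max() + 1)
        if (lab == i).sum() >= min_px
    ]


def analyze_image(
    img: TwoChannelImage, cfg: MorphometryConfig | None = None
) -> list[CondensateRecord]:
    """Full per-image pipeline: segment, split domains, measure rho and angles.

    Every adjacent A-domain/B-domain pair inside a condensate yields an
    interface measurement where the junction geometry is fittable; complex
    topologies that defeat the circle fits are flagged, not errors.
    """
    cfg = cfg or MorphometryConfig()
    labels = segment_condensates(img, cfg)
    # sub-pixel solvent-facing contour of the whole image (marching squares at
    # the same Otsu level used for segmentation)
    total = filters.gaussian(img.channel_A + img.channel_B, sigma=cfg.smooth_sigma,
                             preserve_range=True)
    solvent_pts = (
        _subpixel_points(total, filters.threshold_otsu(total))
        if np.ptp(total) > 0 and labels.max() > 0
        else np.empty((0, 2))
    )
    cha = filters.gaussian(img.channel_A, sigma=cfg.domain_smooth_sigma, preserve_range=True)
    chb = filters.gaussian(img.channel_B, sigma=cfg.domain_smooth_sigma, preserve_range=True)
    records: list[CondensateRecord] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        arich, brich = split_domains(mask, img, cfg)
        rho_a, rho_b, raw_a, raw_b, flags = partition_coefficients(img, arich, brich, cfg)
        min_px = cfg.min_domain_frac * mask.sum()
        comps_a = _domain_components(arich, min_px)
        comps_b = _domain_components(brich, min_px)
        biphasic = bool(comps_a) and bool(comps_b)
        n_domains = (len(comps_a) + len(comps_b)) if biphasic else 1
        rec = CondensateRecord(
            label=lab,
            mask=mask,
            mask_Arich=arich,
            mask_Brich=brich,
            rho_A=rho_a,
            rho_B=rho_b,
            raw_rho_A=raw_a,
            raw_rho_B=raw_b,
            n_domains=n_domains,
            flags=flags,
        )
        if biphasic:
            boundary = mask & ~_erode(mask)
            r_eq = np.sqrt(mask.sum() / np.pi)
            # sub-pixel A-B interface: zero contour of the normalised channel
            # difference inside the condensate
            qa = np.quantile(cha[mask], cfg.norm_quantile)
            qb = np.quantile(chb[mask], cfg.norm_quantile)
            diff = cha / (qa if qa > 0 else 1.0) - chb / (qb if qb > 0 else 1.0)
            interface_pts = _subpixel_points(np.where(mask, diff, np.nan), 0.0)
            # assign sub-pixel solvent points to the domain owning the nearest pixel
            sol_by_domain = {"A": np.empty((0, 2)), "B": np.empty((0, 2))}
            near_b = _near_mask(solvent_pts, boundary)
            if len(near_b):
                from scipy.spatial import cKDTree

                d_a, _ = cKDTree(_coords(arich)).query(near_b, k=1)
                d_b, _ = cKDTree(_coords(brich)).query(near_b, k=1)
                sol_by_domain = {"A": near_b[d_a < d_b], "B": near_b[d_b <= d_a]}
            for ca in comps_a:
                for cb in comps_b:
                    try:
                        ir = _measure_interface(
                            ca, cb, boundary, r_eq, cfg,
                            solvent_pts=sol_by_domain, interface_pts=interface_pts,
                        )
                    except UnfittableError as exc:
                        rec.flags.append(f"unfittable: {exc}")
                        continue
                    if ir is not None:
                        rec.interfaces.append(ir)
        records.append(rec)
    return records


def analyze_image_periodic(
    img: TwoChannelImage, cfg: MorphometryConfig | None = None
) -> list[CondensateRecord]:
    """Analyze a periodic field (e.g. a simulation snapshot).

    The image is tiled 2x2 so every condensate that straddles the periodic
    boundary is measured whole; each structure is kept once (centroid inside
    the central window) and structures still cut at the tiled border — larger
    than half the domain — are dropped.
    """
    n0, n1 = img.shape
    tiled = TwoChannelImage(
        np.tile(img.channel_A, (2, 2)), np.tile(img.channel_B, (2, 2)),
        pixel_size=img.pixel_size,
    )
    out = []
    for r in analyze_image(tiled, cfg):
        rr, cc = np.nonzero(r.mask)
        if not (n0 / 2 <= rr.mean() < 3 * n0 / 2 and n1 / 2 <= cc.mean() < 3 * n1 / 2):
            continue
        if rr.min() == 0 or cc.min() == 0 or rr.max() == 2 * n0 - 1 or cc.max() == 2 * n1 - 1:
            continue
        out.append(r)
    return out


def records_to_dataframe(
    records: list[CondensateRecord], composition: str | float = ""
) -> pd.DataFrame:
    """Flatten condensate records into one row per condensate.

    Angle columns report the condensate's median over its measured
    interfaces (a simple doublet has exactly one).
    """
    rows = []
    for r in records:
        row = {
            "composition": composition,
            "label": r.label,
            "area_px": r.area,
            "n_domains": r.n_domains,
            "n_interfaces": len(r.interfaces),
            "rho_A": r.rho_A,
            "rho_B": r.rho_B,
            "raw_rho_A": r.raw_rho_A,
            "raw_rho_B": r.raw_rho_B,
            "flags": ";".join(r.flags),
        }
        if r.interfaces:
            row.update(
                theta_A=float(np.median([i.theta_A for i in r.interfaces])),
                theta_B=float(np.median([i.theta_B for i in r.interfaces])),
                cos_half_theta=float(np.median([i.cos_half_theta for i in r.interfaces])),
                gammaA_over_gammaAB=float(np.median([i.gammaA_over_gammaAB for i in r.interfaces])),
                gammaB_over_gammaAB=float(np.median([i.gammaB_over_gammaAB for i in r.interfaces])),
            )
        rows.append(row)
    cols = [
        "composition", "label", "area_px", "n_domains", "n_interfaces",
        "rho_A", "rho_B", "raw_rho_A", "raw_rho_B", "theta_A", "theta_B",
        "cos_half_theta", "gammaA_over_gammaAB", "gammaB_over_gammaAB", "flags",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def population_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-composition medians, IQRs and counts of the morphometric observables."""
    if df.empty:
        raise ValueError("no records to summarise")
    metrics = [
        "rho_A", "rho_B", "theta_A", "theta_B", "cos_half_theta",
        "gammaA_over_gammaAB", "gammaB_over_gammaAB",
    ]
    out = []
    for comp, grp in df.groupby("composition", sort=False):
        row: dict = {"composition": comp, "n_condensates": len(grp)}
        for mcol in metrics:
            vals = grp[mcol].dropna() if mcol in grp else pd.Series(dtype=float)
            row[f"{mcol}_median"] = vals.median() if len(vals) else np.nan
            row[f"{mcol}_iqr"] = (
                vals.quantile(0.75) - vals.quantile(0.25) if len(vals) else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Melting traces
# ---------------------------------------------------------------------------


@dataclass
class MeltTrace:
    """Per-frame coefficient-of-variation statistics along a temperature ramp."""

    temperatures: np.ndarray
    cv_A: np.ndarray
    cv_B: np.ndarray
    direction: str = "heating"


@dataclass(frozen=True)
class TmResult:
    tm: float
    residual: float
    no_transition: bool = False


def cv_trace(
    frames: list[TwoChannelImage], temperatures, direction: str = "heating"
) -> MeltTrace:
    """sigma/mean of the pixel values per frame and channel (nan where mean = 0)."""
    temps = np.asarray(temperatures, dtype=float)
    if len(frames) != len(temps):
        raise ValueError("one temperature per frame required")
    shape = frames[0].shape
    cva, cvb = [], []
    for fr in frames:
        if fr.shape != shape:
            raise ValueError("stack frames must share a shape")
        for ch, acc in ((fr.channel_A, cva), (fr.channel_B, cvb)):
            m = ch.mean()
            acc.append(ch.std() / m if m > 0 else np.nan)
    return MeltTrace(temps, np.array(cva), np.array(cvb), direction)


def _two_segment_sse(b: float, t: np.ndarray, y: np.ndarray):
    x = np.column_stack([np.ones_like(t), t - b, np.maximum(t - b, 0.0)])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), coef


def _detect_tm_single(t: np.ndarray, y: np.ndarray) -> TmResult:
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 8:
        raise ValueError("need at least 8 temperature points")
    order = np.argsort(t)
    t, y = t[order], y[order]
    # single-line baseline
    x1 = np.column_stack([np.ones_like(t), t])
    c1, _, _, _ = np.linalg.lstsq(x1, y, rcond=None)
    sse1 = float(np.sum((y - x1 @ c1) ** 2))
    # scan interior breakpoints on the observed grid, then refine continuously
    candidates = t[2:-2]
    sses = [_two_segment_sse(b, t, y)[0] for b in candidates]
    i = int(np.argmin(sses))
    lo = candidates[max(i - 1, 0)]
    hi = candidates[min(i + 1, len(candidates) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda b: _two_segment_sse(b, t, y)[0], bounds=(lo, hi), method="bounded"
        )
        best_b, best_sse = float(res.x), float(res.fun)
    else:
        best_b, best_sse = float(candidates[i]), sses[i]
    scale = float(np.var(y) * len(y))
    rms = np.sqrt(best_sse / len(y))
    if scale <= 0 or sse1 <= 1e-12 * max(scale, 1.0) or (sse1 - best_sse) / sse1 < 0.25:
        return TmResult(np.nan, rms, no_transition=True)
    # a genuine transition also needs a marked slope change at the breakpoint
    _, coef = _two_segment_sse(best_b, t, y)
    m1, m2 = coef[1], coef[1] + coef[2]
    if abs(m2 - m1) < 0.5 * max(abs(m1), abs(m2), 1e-12):
        return TmResult(np.nan, rms, no_transition=True)
    return TmResult(best_b, rms, no_transition=False)


def detect_Tm(trace: MeltTrace) -> dict[str, TmResult]:
    """Transition temperature per channel from the piecewise-linear breakpoint.

    A two-segment continuous fit is scanned over the observed temperatures and
    refined; traces with no meaningful slope change (the two-segment fit barely
    improves on a single line) are flagged ``no_transition``.
    """
    return {
        "A": _detect_tm_single(trace.temperatures, trace.cv_A),
        "B": _detect_tm_single(trace.temperatures, trace.cv_B),
    }
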