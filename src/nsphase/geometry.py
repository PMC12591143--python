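"""Circle geometry shared by the morphometry pipeline and the droplet generator.

A biphasic ("Janus") droplet is modelled as two circular caps — the A-rich and
B-rich phases — bounded by solvent-facing circles of equal radius and joined
along a circular-arc (or straight) interface through the two triple points.
Contact angles are wedge angles at a triple point between the oriented tangent
of a phase's solvent-facing circle and the oriented tangent of the A-B
interface, measured inside the dense phase.

The module provides a Taubin-style algebraic circle fit, circle-circle
intersection, the analytic doublet construction for target contact angles, and
the tangent-wedge angle measurement used both on analytic geometry and on
circles fitted to segmented contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, UnfittableError

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])


@dataclass(frozen=True)
class Line:
    """Infinite-radius interface: point + unit direction."""

    px: float
    py: float
    dx: float
    dy: float

    @property
    def point(self) -> np.ndarray:
        return np.array([self.px, self.py])

    @property
    def direction(self) -> np.ndarray:
        return np.array([self.dx, self.dy])


@dataclass(frozen=True)
class CircleFit:
    circle: Circle
    rms_residual: float
    n_points: int


def fit_circle_taubin(points: np.ndarray) -> CircleFit:
    """Taubin algebraic least-squares circle through an (n, 2) point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise UnfittableError("need at least 3 planar points for a circle fit")
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    z = x * x + y * y
    zm, xm2, ym2 = z.mean(), (x * x).mean(), (y * y).mean()
    zx, zy, xy = (z * x).mean(), (z * y).mean(), (x * y).mean()
    zz = (z * z).mean()
    # Taubin constraint: minimise algebraic distance normalised by gradient norm
    m = np.array([[zz - zm * zm, zx, zy], [zx, xm2, xy], [zy, xy, ym2]])
    c = np.array([[4.0 * zm, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    try:
        w, v = np.linalg.eig(np.linalg.solve(c, m))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise UnfittableError("degenerate point configuration") from exc
    w = np.real(w)
    v = np.real(v)
    # smallest non-negative eigenvalue (zero for exact data)
    order = np.argsort(np.where(w < -1e-9, np.inf, w))
    a, b, cc = v[:, order[0]]
    if abs(a) < 1e-14:
        raise UnfittableError("points are collinear (infinite radius)")
    # a(x^2+y^2) + b x + c y + d = 0 with d fixed by passing through centroid frame
    d = -(a * zm + b * 0.0 + cc * 0.0)  # means of x, y are zero in centred frame
    ux = -b / (2.0 * a)
    uy = -cc / (2.0 * a)
    r2 = ux * ux + uy * uy - d / a
    if r2 <= 0:
        raise UnfittableError("imaginary circle radius")
    r = float(np.sqrt(r2))
    cx = float(ux + pts[:, 0].mean())
    cy = float(uy + pts[:, 1].mean())
    res = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
    return CircleFit(Circle(cx, cy, r), float(np.sqrt((res**2).mean())), pts.shape[0])


def fit_line_pca(points: np.ndarray) -> tuple[Line, float]:
    """Total-least-squares line through a point set (principal axis)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise UnfittableError("need at least 2 points for a line fit")
    mean = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - mean, full_matrices=False)
    direction = vt[0] / np.linalg.norm(vt[0])
    resid = (pts - mean) @ vt[1] if vt.shape[0] > 1 else np.zeros(pts.shape[0])
    line = Line(float(mean[0]), float(mean[1]), float(direction[0]), float(direction[1]))
    return line, float(np.sqrt((resid**2).mean()))


def circle_intersections(c1: Circle, c2: Circle) -> list[np.ndarray]:
    """Intersection points of two circles (0, 1 or 2 points)."""
    p1, p2 = c1.center, c2.center
    d = float(np.linalg.norm(p2 - p1))
    if d == 0:
        return []
    if d > c1.r + c2.r or d < abs(c1.r - c2.r):
        return []
    a = (c1.r**2 - c2.r**2 + d * d) / (2.0 * d)
    h2 = c1.r**2 - a * a
    h = np.sqrt(max(h2, 0.0))
    mid = p1 + a * (p2 - p1) / d
    if h < 1e-12:
        return [mid]
    perp = np.array([-(p2 - p1)[1], (p2 - p1)[0]]) / d
    return [mid + h * perp, mid - h * perp]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction")
    return v / n


def _tangent_into_arc(circle: Circle, p: np.ndarray, arc_ref: np.ndarray) -> np.ndarray:
    """Unit tangent of ``circle`` at point ``p``, oriented toward ``arc_ref``.

    ``arc_ref`` is any point on (or near) the arc away from ``p``; the tangent
    pointing into the arc has positive component toward it.
    """
    radial = _unit(p - circle.center)
    t = np.array([-radial[1], radial[0]])
    if np.dot(t, arc_ref - p) < 0:
        t = -t
    return t


def wedge_angle(t1: np.ndarray, t2: np.ndarray, ref_dir: np.ndarray) -> float:
    """Angle of the wedge between directions t1 and t2 that contains ref_dir."""
    a1 = np.arctan2(t1[1], t1[0])
    a2 = np.arctan2(t2[1], t2[0])
    am = np.arctan2(ref_dir[1], ref_dir[0])
    span = (a1 - a2) % TWO_PI
    inside = (am - a2) % TWO_PI
    return float(span if inside <= span else TWO_PI - span)


@dataclass(frozen=True)
class DoubletGeometry:
    """Analytic two-cap droplet in a canonical frame.

    The interface chord is the segment between the two triple points
    ``(0, +h)`` and ``(0, -h)``; phase A occupies x < interface, B the other
    side.  ``interface`` is a Circle (centre on the A side when the arc bulges
    toward B and vice versa) or a Line when the target angles are symmetric.
    """

    circle_A: Circle
    circle_B: Circle
    interface: Circle | Line
    triple_points: tuple[tuple[float, float], tuple[float, float]]
    theta_A: float
    theta_B: float

    @property
    def half_chord(self) -> float:
        return abs(self.triple_points[0][1])


#: Interface arcs flatter than this tangent-chord angle are rendered straight.
_PSI_STRAIGHT = 1e-9


def make_doublet_geometry(theta_a: float, theta_b: float, radius: float) -> DoubletGeometry:
    """Construct a doublet whose contact angles equal the targets exactly.

    Both solvent-facing caps share the outer radius ``radius``.  Requires
    ``0 < theta_A, theta_B < pi`` and ``theta_A + theta_B > pi`` (the flat
    limit ``theta_A + theta_B = pi`` is approached but not included; pass a
    sum slightly above pi for a near-straight interface).

    Geometry: with tangent-chord angle tau = (theta_A + theta_B)/2 for both
    caps, the half-chord is h = R sin(tau) and the cap centres sit at
    x = +-h/tan(tau).  The interface tangent-chord angle is
    psi = (theta_A - theta_B)/2; for psi != 0 the interface is an arc of
    radius h/|sin(psi)| whose centre of curvature lies inside the
    higher-angle phase, i.e. the interface bulges into the lower-angle phase
    (the higher-angle phase has the larger surface tension and hence the
    higher Laplace pressure).
    """
    if not (0 < theta_a < np.pi and 0 < theta_b < np.pi):
        raise GeometryError("each contact angle must lie in (0, pi)")
    if not (np.pi < theta_a + theta_b < TWO_PI):
        raise GeometryError("theta_A + theta_B must lie in (pi, 2*pi)")
    if radius <= 0:
        raise GeometryError("radius must be positive")
    tau = 0.5 * (theta_a + theta_b)
    h = radius * np.sin(tau)
    x_a = h / np.tan(tau)  # negative for tau in (pi/2, pi)
    circle_a = Circle(float(x_a), 0.0, float(radius))
    circle_b = Circle(float(-x_a), 0.0, float(radius))
    psi = 0.5 * (theta_a - theta_b)
    interface: Circle | Line
    if abs(psi) < _PSI_STRAIGHT:
        interface = Line(0.0, 0.0, 0.0, 1.0)
    else:
        r_i = h / abs(np.sin(psi))
        x_i = -h / np.tan(psi)  # centre on A side for psi > 0
        interface = Circle(float(x_i), 0.0, float(r_i))
    return DoubletGeometry(
        circle_a,
        circle_b,
        interface,
        ((0.0, float(h)), (0.0, float(-h))),
        float(theta_a),
        float(theta_b),
    )


def _interface_tangent(interface: Circle | Line, p: np.ndarray, chord_mid: np.ndarray) -> np.ndarray:
    if isinstance(interface, Line):
        t = _unit(interface.direction)
        if np.dot(t, chord_mid - p) < 0:
            t = -t
        return t
    # arc midpoint lies on the far side of the chord midpoint from the centre
    arc_mid = interface.center + interface.r * _unit(chord_mid - interface.center)
    return _tangent_into_arc(interface, p, arc_mid)


def measure_contact_angles(
    circle_a: Circle,
    circle_b: Circle,
    interface: Circle | Line,
    ref_a: np.ndarray,
    ref_b: np.ndarray,
) -> tuple[float, float]:
    """Contact angles from three circles, averaged over both triple points.

    ``ref_a``/``ref_b`` are interior reference points of the two phases (e.g.
    domain centroids) used to pick the wedge on the correct side.  Raises
    :class:`UnfittableError` when the solvent-facing circles do not intersect.
    """
    pts = circle_intersections(circle_a, circle_b)
    if len(pts) < 2:
        raise UnfittableError("solvent-facing circles do not define two triple points")
    chord_mid = 0.5 * (pts[0] + pts[1])
    ref_a = np.asarray(ref_a, dtype=float)
    ref_b = np.asarray(ref_b, dtype=float)
    # solvent-arc reference points: cap far points away from the other cap
    far_a = circle_a.center + circle_a.r * _unit(circle_a.center - circle_b.center)
    far_b = circle_b.center + circle_b.r * _unit(circle_b.center - circle_a.center)
    th_a, th_b = [], []
    for p in pts:
        t_i = _interface_tangent(interface, p, chord_mid)
        t_a = _tangent_into_arc(circle_a, p, far_a)
        t_b = _tangent_into_arc(circle_b, p, far_b)
        th_a.append(wedge_angle(t_a, t_i, _unit(ref_a - p)))
        th_b.append(wedge_angle(t_b, t_i, _unit(ref_b - p)))
    return float(np.mean(th_a)), float(np.mean(th_b))


def doublet_reference_points(geom: DoubletGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Interior reference points of the A and B phases of an analytic doublet."""
    chord_mid = np.zeros(2)
    far_a = geom.circle_A.center + geom.circle_A.r * np.array([-1.0, 0.0])
    far_b = geom.circle_B.center + geom.circle_B.r * np.array([1.0, 0.0])
    return 0.5 * (far_a + chord_mid), 0.5 * (far_b + chord_mid)
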