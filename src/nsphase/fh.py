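"""Ternary Flory-Huggins free energy evolved by Cahn-Hilliard dynamics.

The mixture is described by two conserved volume-fraction fields phi_A and
phi_B on a periodic 2-D lattice (the solvent fraction is 1 - phi_A - phi_B).
The local free-energy density is

    f = phi_A ln phi_A + phi_B ln phi_B + phi_S ln phi_S
        + chi_AB phi_A phi_B + chi_AA phi_A phi_S + chi_BB phi_B phi_S,

with phi_S = 1 - phi_A - phi_B, supplemented by square-gradient energy
(lambda^2 chi_ii / 2) |grad phi_i|^2 that sets the interface width.  The
gradient stiffness is taken positive: a negative square-gradient coefficient
would make the initial-value problem ill-posed at high wavenumber, whereas a
positive one yields the smooth interfaces the model is meant to produce.
Cross-gradient terms between the two dense phases are omitted.

Dynamics are the conserved gradient flow  d phi_i / dt = M lap(mu_i)  with
mu_i = df/dphi_i - lambda^2 chi_ii lap(phi_i), integrated by a first-order
semi-implicit Fourier-spectral scheme: the biharmonic stiffness plus a
constant-coefficient convex splitting of the local term are treated
implicitly, the remaining nonlinearity explicitly.  The k = 0 mode is never
touched, so the spatial means of both fields are conserved to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, SimulationUnstableError
from .image import TwoChannelImage

#: Clipping floor keeping the logarithms finite during evaluation.
CLIP_EPS = 1e-6

#: Steps between non-finiteness checks inside the integration loop.
_CHECK_EVERY = 200


@dataclass(frozen=True)
class FHParams:
    """Interaction, discretisation and initialisation parameters.

    chi_AA, chi_BB penalise nanostar-solvent contacts of each species (their
    magnitude controls condensation); chi_AB penalises A-B contacts and drives
    internal de-mixing.  lam is the interface-width parameter (grid units),
    mobility the common Cahn-Hilliard mobility.  phi_A0/phi_B0 are the mean
    packing fractions; the initial condition is that mean plus i.i.d. Gaussian
    noise of amplitude noise_amp (mean-subtracted, seeded).
    """

    chi_AA: float = 4.0
    chi_BB: float = 4.0
    chi_AB: float = 2.0
    lam: float = 2.0
    mobility: float = 1.0
    grid_n: int = 128
    dx: float = 1.0
    dt: float = 0.1
    phi_A0: float = 0.23
    phi_B0: float = 0.23
    noise_amp: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (self.phi_A0 > 0 and self.phi_B0 > 0 and self.phi_A0 + self.phi_B0 < 1):
            raise DomainError("initial means must satisfy 0 < phi_A0, phi_B0, phi_A0+phi_B0 < 1")
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.grid_n < 32:
            raise DomainError("grid_n must be >= 32")
        if self.dx <= 0 or self.mobility <= 0:
            raise DomainError("dx and mobility must be positive")


@dataclass
class FieldState:
    """Volume-fraction fields on the periodic lattice plus accumulated time."""

    phi_A: np.ndarray
    phi_B: np.ndarray
    time: float = 0.0
    steps: int = 0
    params: FHParams | None = field(default=None, repr=False)


def initial_state(p: FHParams) -> FieldState:
    """Uniform means plus seeded, mean-subtracted Gaussian noise."""
    rng = np.random.default_rng(p.seed)
    shape = (p.grid_n, p.grid_n)
    phi_a = np.full(shape, p.phi_A0)
    phi_b = np.full(shape, p.phi_B0)
    if p.noise_amp > 0:
        na = rng.normal(0.0, p.noise_amp, shape)
        nb = rng.normal(0.0, p.noise_amp, shape)
        phi_a += na - na.mean()
        phi_b += nb - nb.mean()
    return FieldState(phi_a, phi_b, time=0.0, steps=0, params=p)


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------


def _xlogx(x: np.ndarray) -> np.ndarray:
    # 0 log 0 -> 0 limit
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def free_energy_density(phi_a, phi_b, p: FHParams):
    """Local (gradient-free) free-energy density; scalars or arrays."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    phi_s = 1.0 - phi_a - phi_b
    if (phi_a < 0).any() or (phi_b < 0).any() or (phi_s < -1e-12).any():
        raise DomainError("volume fractions must lie inside the composition simplex")
    phi_s = np.clip(phi_s, 0.0, None)
    f = (
        _xlogx(phi_a)
        + _xlogx(phi_b)
        + _xlogx(phi_s)
        + p.chi_AB * phi_a * phi_b
        + p.chi_AA * phi_a * phi_s
        + p.chi_BB * phi_b * phi_s
    )
    return f if f.ndim else float(f)


def _wavenumbers(n: int, dx: float):
    kx = 2.0 * np.pi * np.fft.fftfreq(n, d=dx)
    ky = 2.0 * np.pi * np.fft.rfftfreq(n, d=dx)
    k2 = kx[:, None] ** 2 + ky[None, :] ** 2
    return k2


def _clip_simplex(phi_a: np.ndarray, phi_b: np.ndarray):
    """Clipped copies used when evaluating logarithms; the state is untouched."""
    pa = np.clip(phi_a, CLIP_EPS, 1.0 - CLIP_EPS)
    pb = np.clip(phi_b, CLIP_EPS, 1.0 - CLIP_EPS)
    s = pa + pb
    over = s > 1.0 - CLIP_EPS
    if over.any():
        scale = (1.0 - CLIP_EPS) / s[over]
        pa = pa.copy()
        pb = pb.copy()
        pa[over] *= scale
        pb[over] *= scale
    return pa, pb


def _dfdphi(pa: np.ndarray, pb: np.ndarray, p: FHParams):
    """Partial derivatives of the local density wrt phi_A and phi_B."""
    log_s = np.log(1.0 - pa - pb)
    g_a = np.log(pa) - log_s + p.chi_AB * pb + p.chi_AA * (1.0 - 2.0 * pa - pb) - p.chi_BB * pb
    g_b = np.log(pb) - log_s + p.chi_AB * pa + p.chi_BB * (1.0 - pa - 2.0 * pb) - p.chi_AA * pa
    return g_a, g_b


def _spectral_lap(phi: np.ndarray, k2: np.ndarray) -> np.ndarray:
    return np.fft.irfft2(-k2 * np.fft.rfft2(phi), s=phi.shape)


def _grad_energy(phi: np.ndarray, kappa: float, n: int, dx: float) -> float:
    """(kappa/2) * sum |grad phi|^2, evaluated spectrally (Parseval).

    Uses the same k^2 symbol as the Laplacian in :func:`chemical_potentials`,
    so the discrete functional derivative of the energy matches mu exactly.
    """
    k2 = _wavenumbers(n, dx)
    ft = np.fft.rfft2(phi)
    w = np.full(ft.shape, 2.0)  # rfft stores half the spectrum
    w[:, 0] = 1.0
    if n % 2 == 0:
        w[:, -1] = 1.0
    return 0.5 * kappa * float((w * k2 * np.abs(ft) ** 2).sum()) / n**2


def total_free_energy(s: FieldState, p: FHParams) -> float:
    """Grid total of local density plus square-gradient energy, times cell area."""
    pa, pb = _clip_simplex(s.phi_A, s.phi_B)
    local = float(free_energy_density(pa, pb, p).sum())
    grad = _grad_energy(s.phi_A, p.lam**2 * p.chi_AA, p.grid_n, p.dx) + _grad_energy(
        s.phi_B, p.lam**2 * p.chi_BB, p.grid_n, p.dx
    )
    return (local + grad) * p.dx**2


def chemical_potentials(s: FieldState, p: FHParams):
    """mu_i = df/dphi_i - lambda^2 chi_ii lap(phi_i), spectral Laplacian."""
    pa, pb = _clip_simplex(s.phi_A, s.phi_B)
    g_a, g_b = _dfdphi(pa, pb, p)
    k2 = _wavenumbers(p.grid_n, p.dx)
    mu_a = g_a - p.lam**2 * p.chi_AA * _spectral_lap(s.phi_A, k2)
    mu_b = g_b - p.lam**2 * p.chi_BB * _spectral_lap(s.phi_B, k2)
    return mu_a, mu_b


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------


def step(s: FieldState, p: FHParams, n_steps: int) -> FieldState:
    """Advance the conserved dynamics by ``n_steps`` semi-implicit updates.

    Raises :class:`SimulationUnstableError` (reporting the global step index)
    if any field value becomes non-finite.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    n, dx, dt, m = p.grid_n, p.dx, p.dt, p.mobility
    k2 = _wavenumbers(n, dx)
    k4 = k2 * k2
    kap_a = p.lam**2 * p.chi_AA
    kap_b = p.lam**2 * p.chi_BB
    # Convex-splitting stabilisation of the explicit local term.  The floor
    # approximates sup f'' over binodal compositions at chi ~ 4, where the
    # solvent fraction in the dense phase reaches ~0.03 (1/phi_S ~ 33).
    a_stab = max(2.0 * max(p.chi_AA, p.chi_BB, p.chi_AB, 1.0), 33.0)
    den_a = 1.0 + dt * m * (a_stab * k2 + kap_a * k4)
    den_b = 1.0 + dt * m * (a_stab * k2 + kap_b * k4)

    fa = np.fft.rfft2(s.phi_A)
    fb = np.fft.rfft2(s.phi_B)
    shape = s.phi_A.shape
    for i in range(n_steps):
        phi_a = np.fft.irfft2(fa, s=shape)
        phi_b = np.fft.irfft2(fb, s=shape)
        if i % _CHECK_EVERY == 0 and not (
            np.isfinite(phi_a).all() and np.isfinite(phi_b).all()
        ):
            raise SimulationUnstableError(s.steps + i)
        pa, pb = _clip_simplex(phi_a, phi_b)
        g_a, g_b = _dfdphi(pa, pb, p)
        fa = (fa - dt * m * k2 * (np.fft.rfft2(g_a) - a_stab * fa)) / den_a
        fb = (fb - dt * m * k2 * (np.fft.rfft2(g_b) - a_stab * fb)) / den_b

    phi_a = np.fft.irfft2(fa, s=shape)
    phi_b = np.fft.irfft2(fb, s=shape)
    if not (np.isfinite(phi_a).all() and np.isfinite(phi_b).all()):
        raise SimulationUnstableError(s.steps + n_steps)
    return FieldState(
        phi_a, phi_b, time=s.time + n_steps * dt, steps=s.steps + n_steps, params=p
    )


#: Default total step count of a production run; checkpoints are geometric.
DEFAULT_TOTAL_STEPS = 60000


def default_snapshot_steps(total: int = DEFAULT_TOTAL_STEPS, n_snapshots: int = 5):
    """Five geometrically spaced checkpoints; the last one is analysed."""
    return [max(1, round(total * 2.0 ** (k - n_snapshots + 1))) for k in range(n_snapshots)]


def run(p: FHParams, snapshot_steps: Sequence[int] | None = None) -> list[FieldState]:
    """Integrate from the seeded initial condition, returning checkpoint states.

    ``snapshot_steps`` are increasing cumulative step counts; the trajectory
    is deterministic given ``p.seed``.
    """
    if snapshot_steps is None:
        snapshot_steps = default_snapshot_steps()
    snapshot_steps = list(snapshot_steps)
    if any(b <= a for a, b in zip(snapshot_steps, snapshot_steps[1:])):
        raise ValueError("snapshot_steps must be strictly increasing")
    state = initial_state(p)
    out = []
    prev = 0
    for target in snapshot_steps:
        state = step(state, p, target - prev)
        prev = target
        out.append(state)
    return out


def mass_error(s: FieldState, p: FHParams) -> tuple[float, float]:
    """Deviation of the spatial means from their initial values."""
    return (
        abs(float(s.phi_A.mean()) - p.phi_A0),
        abs(float(s.phi_B.mean()) - p.phi_B0),
    )


def render_snapshot(s: FieldState) -> TwoChannelImage:
    """Render fields as a two-channel image, each channel min-max rescaled to [0, 1]."""
    p = s.params
    meta: dict = {"time": s.time, "steps": s.steps}
    chans = []
    for phi in (s.phi_A, s.phi_B):
        lo, hi = float(phi.min()), float(phi.max())
        if hi - lo <= 0:
            chans.append(np.zeros_like(phi))
            meta["degenerate_rescale"] = True
        else:
            chans.append((phi - lo) / (hi - lo))
    return TwoChannelImage(
        chans[0], chans[1], pixel_size=(p.dx if p is not None else 1.0), metadata=meta
    )
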