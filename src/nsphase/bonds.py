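"""Combinatorial bond counting for stoichiometrically matched mixtures.

With N nanostars of each species (N_A = N_B = N) and a matched linker pool
N_L = 4N, the number of distinct nanostar-nanostar bonds each linker class can
mediate is a pure function of the cross-linker fraction F_ab:

    D_AA = D_BB = 4 N^2 (1 - F_ab)^2,      D_AB = 4 N^2 F_ab^2,
    D_tot = 8 N^2 (F_ab^2 / 2 + (1 - F_ab)^2).

D_tot is maximal at F_ab = 0 (value 8 N^2) and minimal at F_ab = 2/3; the
same non-monotonic shape is followed by the measured condensate melting
temperature, which motivates using the min-max-normalised curve as a
qualitative T_m trend proxy.  The symmetric quadratic decomposition into
(D_AA, D_BB, D_AB) is the unique one consistent with the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BondCount", "d_tot", "d_components", "argmin_dtot", "tm_trend_proxy"]


@dataclass(frozen=True)
class BondCount:
    """Pairwise bond counts for one composition."""

    N: int
    F_ab: float
    d_AA: float
    d_BB: float
    d_AB: float

    @property
    def d_tot(self) -> float:
        return self.d_AA + self.d_BB + self.d_AB


def _check(f_ab, n: int) -> None:
    if np.any(np.asarray(f_ab) < 0) or np.any(np.asarray(f_ab) > 1):
        raise ValueError("F_ab must lie in [0, 1]")
    if n < 1:
        raise ValueError("N must be a positive count")


def d_tot(f_ab, n: int = 1):
    """Total possible nanostar-nanostar bond count, 8 N^2 (F_ab^2/2 + (1-F_ab)^2)."""
    _check(f_ab, n)
    f = np.asarray(f_ab, dtype=float)
    out = 8.0 * n * n * (f**2 / 2.0 + (1.0 - f) ** 2)
    return out if out.ndim else float(out)


def d_components(f_ab: float, n: int = 1) -> BondCount:
    """Decomposition of the bond count into A-A, B-B and A-B contributions."""
    _check(f_ab, n)
    same = 4.0 * n * n * (1.0 - f_ab) ** 2
    cross = 4.0 * n * n * f_ab**2
    return BondCount(N=n, F_ab=f_ab, d_AA=same, d_BB=same, d_AB=cross)


def argmin_dtot() -> float:
    """Minimiser of D_tot over F_ab in [0, 1].

    Closed form: d/dF [F^2/2 + (1-F)^2] = 3F - 2 = 0, i.e. F_ab = 2/3 (the
    boundary values F_ab = 0 and 1 are local maxima, the global maximum being
    at 0).
    """
    return 2.0 / 3.0


def tm_trend_proxy(f_ab_grid, n: int = 1) -> np.ndarray:
    """Min-max normalised D_tot curve for qualitative comparison with T_m trends."""
    vals = d_tot(np.asarray(f_ab_grid, dtype=float), n)
    vals = np.atleast_1d(vals)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros_like(vals)
    return (vals - lo) / (hi - lo)
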