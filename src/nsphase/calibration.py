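"""Linear-fit calibration between the simulation and experimental axes.

The reduced A-B interfacial tension cos(theta/2) falls linearly both with the
simulation's chi_AB and with the mixture's order parameter.  Equating the two
straight lines defines the affine change of variables

    order_param = (chi_AB - c0) / c1,

which is the mapping used to predict morphology for a composition: order
parameter -> chi_AB -> Cahn-Hilliard simulation -> rendered snapshot ->
morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import fh, morphometry, stoichiometry
from .errors import DegenerateMappingError
from .stoichiometry import MixtureComposition


@dataclass(frozen=True)
class LinearFit:
    """A fitted straight line y = slope*x + intercept."""

    slope: float
    intercept: float
    constrained: bool = False
    residual: float = 0.0
    n: int = 0

    @property
    def zero_crossing(self) -> float:
        if self.slope == 0:
            raise DegenerateMappingError("zero slope has no zero crossing")
        return -self.intercept / self.slope

    def __call__(self, x):
        return self.slope * np.asarray(x) + self.intercept


@dataclass(frozen=True)
class ChiMapping:
    """chi_AB <-> order-parameter mapping constants of order = (chi - c0)/c1."""

    c0: float = stoichiometry.DEFAULT_C0
    c1: float = stoichiometry.DEFAULT_C1

    def __post_init__(self):
        if self.c1 == 0:
            raise DegenerateMappingError("c1 must be nonzero")

    def chi(self, order_param: float) -> float:
        return stoichiometry.chi_from_order(order_param, self.c0, self.c1)

    def order(self, chi_ab: float) -> float:
        return stoichiometry.order_from_chi(chi_ab, self.c0, self.c1)


def fit_line(x, y, constraint: tuple[float, float] | None = None) -> LinearFit:
    """Least-squares line, optionally forced exactly through ``constraint``.

    Unconstrained fits need >= 2 points with spread in x; constrained fits
    need >= 1 point distinct in x from the constraint point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if constraint is None:
        if len(x) < 2 or np.ptp(x) == 0:
            raise DegenerateMappingError("need >= 2 points with distinct x values")
        slope, intercept = np.polyfit(x, y, 1)
        constrained = False
    else:
        x0, y0 = constraint
        dx = x - x0
        denom = float(np.sum(dx * dx))
        if len(x) < 1 or denom == 0:
            raise DegenerateMappingError("constrained fit needs a point away from the anchor")
        slope = float(np.sum(dx * (y - y0)) / denom)
        intercept = y0 - slope * x0
        constrained = True
    resid = y - (slope * x + intercept)
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        constrained=constrained,
        residual=float(np.sqrt(np.mean(resid**2))),
        n=len(x),
    )


def calibrate_mapping(sim_fit: LinearFit, exp_fit: LinearFit) -> ChiMapping:
    """Solve for (c0, c1) mapping the experimental line onto the simulated line.

    With the simulation axis fit ``cos = a_s*chi + b_s`` and the experimental
    axis fit ``cos = a_e*order + b_e``, substituting order = (chi - c0)/c1
    and matching slope and intercept gives c1 = a_e/a_s and
    c0 = (b_e - b_s)/a_s, which maps zero crossings onto each other.
    """
    if sim_fit.slope == 0 or exp_fit.slope == 0:
        raise DegenerateMappingError("both fits must have nonzero slope")
    c1 = exp_fit.slope / sim_fit.slope
    c0 = (exp_fit.intercept - sim_fit.intercept) / sim_fit.slope
    return ChiMapping(c0=float(c0), c1=float(c1))


# ---------------------------------------------------------------------------
# Simulation-axis sweep and end-to-end prediction
# ---------------------------------------------------------------------------


def sweep_morphometry(
    chi_ab_values,
    params: fh.FHParams | None = None,
    cfg: morphometry.MorphometryConfig | None = None,
    snapshot_steps=None,
    seed: int | None = None,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Run the simulator across chi_AB values and measure the final snapshots.

    Each chi_AB is simulated ``n_replicates`` times with distinct seeds;
    contact angles are pooled at the interface level across replicates (the
    per-snapshot condensate count is small after coarsening, so replicates
    stabilise the medians).  Returns one row per chi_AB with median
    cos(theta/2), median partition coefficients and counts, computed by the
    same morphometry pipeline used for synthetic micrographs.
    """
    params = params or fh.FHParams()
    cfg = cfg or morphometry.MorphometryConfig()
    base_seed = params.seed if seed is None else seed
    rows = []
    per_interface: dict[float, list[float]] = {}
    for i, chi in enumerate(chi_ab_values):
        cos_vals: list[float] = []
        rho_a: list[float] = []
        rho_b: list[float] = []
        n_cond = n_biph = 0
        for rep in range(n_replicates):
            p = replace(
                params, chi_AB=float(chi), seed=base_seed + i + 1000 * rep
            )
            final = fh.run(p, snapshot_steps)[-1]
            img = fh.render_snapshot(final)
            records = morphometry.analyze_image_periodic(img, cfg)
            df = morphometry.records_to_dataframe(records, chi)
            n_cond += len(df)
            n_biph += int((df["n_domains"] >= 2).sum())
            cos_vals += [
                i_.cos_half_theta for r in records for i_ in r.interfaces
                if np.isfinite(i_.cos_half_theta) and not i_.flags
            ]
            rho_a += list(df["rho_A"].dropna())
            rho_b += list(df["rho_B"].dropna())
        rows.append({
            "chi_AB": float(chi),
            "n_condensates": n_cond,
            "n_biphasic": n_biph,
            "n_interfaces": len(cos_vals),
            "cos_half_theta_median": float(np.median(cos_vals)) if cos_vals else np.nan,
            "rho_A_median": float(np.median(rho_a)) if rho_a else np.nan,
            "rho_B_median": float(np.median(rho_b)) if rho_b else np.nan,
        })
        per_interface[float(chi)] = cos_vals
    out = pd.DataFrame(rows)
    out.attrs["cos_half_theta_values"] = per_interface
    out.attrs["chi_cap"] = float(min(params.chi_AA, params.chi_BB))
    return out


def fit_sim_axis(sweep: pd.DataFrame) -> LinearFit:
    """Line through cos(theta/2) vs chi_AB over the biphasic range.

    When the sweep carries per-interface measurements (attrs set by
    :func:`sweep_morphometry`) a Theil-Sen line through all of them is used:
    near the mixing threshold the domains are weakly segregated and single
    interfaces can report wild angles, which a median-of-pairwise-slopes
    estimator tolerates.  The fit is restricted to chi_AB strictly below
    min(chi_AA, chi_BB): at and beyond that point A-B contact is no cheaper
    than solvent contact, condensates de-mix into tangent or separate
    droplets (the zero-cross-linker regime) and the Janus doublet geometry
    the calibration relies on degenerates.  Otherwise an ordinary
    least-squares line through the per-chi_AB medians is fitted.
    """
    values = sweep.attrs.get("cos_half_theta_values")
    if values:
        cap = sweep.attrs.get("chi_cap", np.inf)
        values = {chi: v for chi, v in values.items() if v and chi < cap}
        x = np.concatenate([[chi] * len(v) for chi, v in values.items()]) if values else np.array([])
        y = np.concatenate(list(values.values())) if values else np.array([])
        if len(x) >= 3 and np.ptp(x) > 0:
            from scipy.stats import theilslopes

            slope, intercept, _, _ = theilslopes(y, x)
            resid = y - (slope * x + intercept)
            return LinearFit(
                slope=float(slope),
                intercept=float(intercept),
                residual=float(np.sqrt(np.mean(resid**2))),
                n=len(x),
            )
    ok = sweep.dropna(subset=["cos_half_theta_median"])
    ok = ok[ok["n_biphasic"] > 0]
    return fit_line(ok["chi_AB"].to_numpy(), ok["cos_half_theta_median"].to_numpy())


@dataclass
class MorphologyPrediction:
    composition: MixtureComposition
    order_param: float
    chi_AB: float
    phase_class: str
    cos_half_theta: float
    rho_A: float
    rho_B: float
    n_condensates: int
    n_biphasic: int


def predict_morphology(
    comp: MixtureComposition,
    mapping: ChiMapping | None = None,
    params: fh.FHParams | None = None,
    cfg: morphometry.MorphometryConfig | None = None,
    snapshot_steps=None,
    threshold: float = stoichiometry.DEFAULT_THRESHOLD,
) -> MorphologyPrediction:
    """Composition -> order parameter -> chi_AB -> simulate -> measure.

    Fully deterministic given the simulation seed in ``params``.
    """
    mapping = mapping or ChiMapping()
    params = params or fh.FHParams()
    cfg = cfg or morphometry.MorphometryConfig()
    op = stoichiometry.order_parameter(comp.F_A, comp.F_ab)
    chi = mapping.chi(op.order_param)
    p = replace(params, chi_AB=chi)
    final = fh.run(p, snapshot_steps)[-1]
    img = fh.render_snapshot(final)
    df = morphometry.records_to_dataframe(morphometry.analyze_image(img, cfg))
    biph = df[df["n_domains"] >= 2]
    return MorphologyPrediction(
        composition=comp,
        order_param=op.order_param,
        chi_AB=chi,
        phase_class=stoichiometry.classify_phase(op.order_param, threshold),
        cos_half_theta=float(biph["cos_half_theta"].median()) if len(biph) else np.nan,
        rho_A=float(df["rho_A"].median()) if len(df) else np.nan,
        rho_B=float(df["rho_B"].median()) if len(df) else np.nan,
        n_condensates=len(df),
        n_biphasic=len(biph),
    )
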