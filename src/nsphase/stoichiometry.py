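"""Composition calculus for binary nanostar + three-linker mixtures.

The mixture contains two four-armed DNA nanostars (A, B) and three divalent
linkers (aa, bb, ab).  Sticky-end neutrality — every sticky end on a nanostar
is matched by one complementary end on a linker,

    4[A] = 2[aa] + [ab],        4[B] = 2[bb] + [ab],

reduces the five concentrations to two free parameters: the nanostar fraction
``F_A = [A]/[NS]`` and the cross-linker fraction ``F_ab = [ab]/[linker]``.
From these the module derives the remaining fractions, the per-family
sticky-end fractions carried by ab linkers,

    f_ab_alpha = [ab] / (4[A]),      f_ab_beta = [ab] / (4[B]),

whose sum is the empirical order parameter governing the monophasic/biphasic
transition (boundary at ~0.5), and the linear mapping between that order
parameter and the effective Flory-Huggins cross-interaction chi_AB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    CompositionInfeasibleError,
    DegenerateMappingError,
    UndefinedOrderParameterError,
)

#: Default mapping constants between chi_AB and the order parameter:
#: order = (chi_AB - C0) / C1.  Obtained by equating linear fits of
#: cos(theta/2) on the simulation (chi_AB) and experimental (order
#: parameter) axes; the calibration module can re-derive them.
DEFAULT_C0 = 4.1
DEFAULT_C1 = -3.4

#: Empirical order-parameter value at the monophasic/biphasic boundary.
DEFAULT_THRESHOLD = 0.5


def _check_feasible(f_a: float, f_ab: float) -> None:
    if not (0.0 <= f_a <= 1.0):
        raise CompositionInfeasibleError(f"F_A={f_a} outside [0, 1]")
    if not (0.0 <= f_ab <= 1.0):
        raise CompositionInfeasibleError(f"F_ab={f_ab} outside [0, 1]")
    if f_ab > 2.0 * f_a:
        raise CompositionInfeasibleError(
            f"F_ab={f_ab} > 2*F_A={2 * f_a}: F_aa would be negative"
        )
    if f_ab > 2.0 * (1.0 - f_a):
        raise CompositionInfeasibleError(
            f"F_ab={f_ab} > 2*(1-F_A)={2 * (1 - f_a)}: F_bb would be negative"
        )


@dataclass(frozen=True)
class MixtureComposition:
    """A feasible five-species composition under sticky-end neutrality.

    Parameters
    ----------
    F_A : molar fraction of nanostar A among nanostars, in [0, 1].
    F_ab : molar fraction of the ab cross-linker among linkers, in [0, 1],
        bounded by ``F_ab <= 2*F_A`` and ``F_ab <= 2*(1-F_A)``.
    ns_total : total nanostar concentration [A]+[B], uM.
    linker_total : total linker concentration [aa]+[bb]+[ab], uM.  Neutrality
        requires ``linker_total = 2 * ns_total``.
    """

    F_A: float
    F_ab: float
    ns_total: float = 0.5
    linker_total: float = 1.0

    def __post_init__(self):
        _check_feasible(self.F_A, self.F_ab)
        if self.ns_total <= 0 or self.linker_total <= 0:
            raise CompositionInfeasibleError("concentrations must be positive")

    @property
    def F_B(self) -> float:
        return 1.0 - self.F_A

    @property
    def F_aa(self) -> float:
        return self.F_A - self.F_ab / 2.0

    @property
    def F_bb(self) -> float:
        return (1.0 - self.F_A) - self.F_ab / 2.0


@dataclass(frozen=True)
class ComponentConcentrations:
    """Absolute concentrations (uM) of the five species."""

    conc_A: float
    conc_B: float
    conc_aa: float
    conc_bb: float
    conc_ab: float

    def neutrality_residuals(self) -> tuple[float, float]:
        """Residuals of the two sticky-end neutrality constraints (should be ~0)."""
        r_alpha = 4.0 * self.conc_A - (2.0 * self.conc_aa + self.conc_ab)
        r_beta = 4.0 * self.conc_B - (2.0 * self.conc_bb + self.conc_ab)
        return r_alpha, r_beta

    @property
    def linker_total(self) -> float:
        return self.conc_aa + self.conc_bb + self.conc_ab

    @property
    def ns_total(self) -> float:
        return self.conc_A + self.conc_B


@dataclass(frozen=True)
class OrderParameterValue:
    """Sticky-end fractions carried by ab linkers and their sum."""

    f_alpha_ab: float
    f_beta_ab: float
    order_param: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "order_param", self.f_alpha_ab + self.f_beta_ab)


def component_fractions(f_a: float, f_ab: float) -> dict[str, float]:
    """Remaining molar fractions given F_A and F_ab.

    Returns ``{"F_B", "F_aa", "F_bb"}`` with F_B = 1 - F_A,
    F_aa = F_A - F_ab/2, F_bb = (1 - F_A) - F_ab/2.
    """
    _check_feasible(f_a, f_ab)
    return {
        "F_B": 1.0 - f_a,
        "F_aa": f_a - f_ab / 2.0,
        "F_bb": (1.0 - f_a) - f_ab / 2.0,
    }


def concentrations(comp: MixtureComposition) -> ComponentConcentrations:
    """Absolute species concentrations for a composition.

    Nanostar fractions scale ``ns_total``; linker fractions scale
    ``linker_total``.  The sticky-end neutrality identities hold exactly
    whenever ``linker_total = 2 * ns_total`` (the default), and are verified
    internally in that case.
    """
    fr = component_fractions(comp.F_A, comp.F_ab)
    out = ComponentConcentrations(
        conc_A=comp.F_A * comp.ns_total,
        conc_B=fr["F_B"] * comp.ns_total,
        conc_aa=fr["F_aa"] * comp.linker_total,
        conc_bb=fr["F_bb"] * comp.linker_total,
        conc_ab=comp.F_ab * comp.linker_total,
    )
    if abs(comp.linker_total - 2.0 * comp.ns_total) < 1e-12:
        r_alpha, r_beta = out.neutrality_residuals()
        assert abs(r_alpha) < 1e-9 and abs(r_beta) < 1e-9
    return out


def order_parameter(f_a: float, f_ab: float) -> OrderParameterValue:
    """Sticky-end fractions on ab linkers and the mixing order parameter.

    Under neutrality, ``f_alpha_ab = F_ab / (2 F_A)`` and
    ``f_beta_ab = F_ab / (2 (1 - F_A))``.  Undefined when a nanostar species
    is absent (F_A in {0, 1}) while ab linkers are present.
    """
    _check_feasible(f_a, f_ab)
    if f_ab == 0.0:
        return OrderParameterValue(0.0, 0.0)
    if f_a in (0.0, 1.0):
        raise UndefinedOrderParameterError(
            f"F_A={f_a} with F_ab={f_ab} > 0: a sticky-end family is absent"
        )
    return OrderParameterValue(
        f_alpha_ab=f_ab / (2.0 * f_a),
        f_beta_ab=f_ab / (2.0 * (1.0 - f_a)),
    )


def classify_phase(order_param: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Classify a mixture as ``"monophasic"`` or ``"biphasic"``.

    Biphasic iff ``order_param < threshold``; the boundary value itself is
    assigned to the monophasic side (deterministic closed/open convention).
    """
    if order_param < 0:
        raise ValueError("order parameter must be non-negative")
    return "biphasic" if order_param < threshold else "monophasic"


def chi_from_order(
    order_param: float, c0: float = DEFAULT_C0, c1: float = DEFAULT_C1
) -> float:
    """Map an order parameter onto the effective chi_AB: chi = c0 + c1*order."""
    return c0 + c1 * order_param


def order_from_chi(
    chi_ab: float, c0: float = DEFAULT_C0, c1: float = DEFAULT_C1
) -> float:
    """Inverse mapping: order = (chi_AB - c0) / c1."""
    if c1 == 0:
        raise DegenerateMappingError("c1 = 0: chi does not determine the order parameter")
    return (chi_ab - c0) / c1
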