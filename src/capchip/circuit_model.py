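"""Closed-form equivalent-circuit capacitances of the interdigitated electrode.

The sensing electrode pair of the chip is a coplanar interdigitated electrode
(IDE) on the top metal of a CMOS process, covered by a thin native Al2O3 film.
Its terminal capacitance decomposes into

* a substrate parasitic ``C_sub`` (area + perimeter process coefficients),
* a direct sidewall coupling ``C_dir`` between facing finger walls,
* a fringe path through the oxide ``C_fringe`` and through the sample medium
  ``C_sens``; the oxide fringe is ``eps_SiO2`` times the air fringe by symmetry,
* and, once cells are deposited, per-electrode passivation/cell stacks whose
  weight is the *confluence* (fraction of metal area covered by cells).

All capacitances are expressed in femtofarad, lengths in micrometre, so the
vacuum permittivity is ``EPS0 = 8.854e-3 fF/µm`` and the printed anchors of the
design (8.4 fF/µm² areal passivation capacitance, ~59 pF full-area plate,
~109 fF dry baseline) come out at convenient magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EPS0",
    "InvalidParameterError",
    "ElectrodeGeometry",
    "MaterialStack",
    "CapacitanceBreakdown",
    "CellDeposit",
    "WetInterface",
    "substrate_capacitance",
    "direct_capacitance",
    "fringe_capacitance",
    "offset_capacitance",
    "parallel_plate_areal",
    "sensing_capacitance",
    "dry_equivalent",
    "cell_layer_capacitance",
    "series_combination",
    "cell_equivalent",
    "capacitance_breakdown",
    "calibrate_d_eff_air",
]

#: vacuum permittivity in fF/µm (8.8541878128e-12 F/m)
EPS0 = 8.8541878128e-3


class InvalidParameterError(ValueError):
    """A geometry/material parameter violates its physical domain."""


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Interdigitated-electrode layout.

    Defaults describe the fabricated sensor: five fingers of 12 µm width and
    12 µm gap forming a 228 µm × 108 µm active window.  ``area`` is the metal
    area entering the plate formulas (7056 µm² for the implemented IDE, which
    differs from width × length of the active window; both are kept as
    explicit fields because the two prints are inconsistent).  ``pitch`` is
    read as the inter-finger gap.
    """

    n_fingers: int = 5
    finger_width: float = 12.0  # µm
    gap: float = 12.0  # µm, electrode pitch d
    finger_length: float = 228.0  # µm
    thickness: float = 0.9  # µm, metal thickness W_th
    area: float = 7056.0  # µm², metal area A
    perimeter: float | None = None  # µm, metal perimeter P
    coinciding_perimeter: float | None = None  # µm, facing-wall length

    def __post_init__(self) -> None:
        if self.n_fingers < 1:
            raise InvalidParameterError("n_fingers must be >= 1")
        for name in ("finger_width", "gap", "finger_length", "thickness", "area"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.perimeter is None:
            object.__setattr__(
                self,
                "perimeter",
                2.0 * self.n_fingers * (self.finger_length + self.finger_width),
            )
        if self.coinciding_perimeter is None:
            # each of the n-1 adjacent finger pairs faces over one finger length
            object.__setattr__(
                self,
                "coinciding_perimeter",
                (self.n_fingers - 1) * self.finger_length,
            )
        if self.perimeter <= 0 or self.coinciding_perimeter < 0:
            raise InvalidParameterError("perimeter values must be positive")

    @property
    def span(self) -> float:
        """Lateral extent of the finger array (µm)."""
        return self.n_fingers * self.finger_width + (self.n_fingers - 1) * self.gap


# default effective air fringe distance: analytic calibration so that the dry
# equivalent equals the printed 109 fF experimental baseline (see
# calibrate_d_eff_air); kept as an explicit config number, not recomputed.
_D_EFF_AIR_DEFAULT = 2.8686  # µm


@dataclass(frozen=True)
class MaterialStack:
    """Permittivities, layer thicknesses and process coefficients.

    ``alpha1``/``alpha2`` (substrate capacitance per area / per perimeter) are
    proprietary process numbers and default to zero, folding the substrate
    parasitic into the calibratable offset.  ``eps_cell`` and ``d_eff_cell``
    are never printed for oral-cell remnants; the defaults are plausible for a
    moist cell layer and carry no fidelity claim.
    """

    eps0: float = EPS0  # fF/µm
    eps_SiO2: float = 3.9
    eps_PL: float = 9.5  # native Al2O3 passivation
    eps_air: float = 1.0
    eps_cell: float = 20.0  # moist cell remnants (assumption)
    eps_water: float = 80.0
    d_PL: float = 0.010  # µm (10 nm native film)
    d_eff_air: float = _D_EFF_AIR_DEFAULT  # µm, effective fringe path in air
    d_eff_cell: float = 5.0  # µm, average deposited-cell thickness (assumption)
    alpha1: float = 0.0  # fF/µm², substrate capacitance per area
    alpha2: float = 0.0  # fF/µm, substrate capacitance per perimeter

    def __post_init__(self) -> None:
        for name in ("eps_SiO2", "eps_PL", "eps_air", "eps_cell", "eps_water"):
            if getattr(self, name) < 1.0:
                raise InvalidParameterError(f"{name} must be >= 1")
        for name in ("eps0", "d_PL", "d_eff_air", "d_eff_cell"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise InvalidParameterError("alpha coefficients must be >= 0")


@dataclass(frozen=True)
class CapacitanceBreakdown:
    """All lumped capacitances of the model, in fF."""

    C_sub: float
    C_dir: float
    C_fringe: float
    C_off: float
    C_sens: float
    C_T1: float
    C_T2: float
    C_air: float
    C_equivalent: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not math.isclose(
            self.C_off, self.C_sub + self.C_dir + self.C_fringe, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise InvalidParameterError("C_off must equal C_sub + C_dir + C_fringe")


@dataclass(frozen=True)
class CellDeposit:
    """Cell coverage state of the two electrode plates."""

    conf1: float = 0.0  # confluence of plate 1, A_covered / A
    conf2: float = 0.0
    eps_cell: float | None = None  # overrides MaterialStack when given
    d_eff_cell: float | None = None

    def __post_init__(self) -> None:
        for c in (self.conf1, self.conf2):
            if not 0.0 <= c <= 1.0:
                raise InvalidParameterError("confluence must lie in [0, 1]")


@dataclass(frozen=True)
class WetInterface:
    """Electrode–electrolyte interface while bulk liquid is present.

    The solution resistance and double-layer capacitance are not fitted to
    values (none are printed); the ``saturated`` flag is what the readout
    simulator consumes: bulk liquid drives the output to its rail.
    """

    R_sol: float = 0.0  # ohm, solution resistive path
    C_dl: float = 0.0  # fF, double-layer capacitance
    saturated: bool = True


def substrate_capacitance(geom: ElectrodeGeometry, stack: MaterialStack) -> float:
    """Substrate parasitic ``alpha1*A + alpha2*P`` in fF."""
    if stack.alpha1 < 0 or stack.alpha2 < 0:
        raise InvalidParameterError("alpha coefficients must be >= 0")
    return stack.alpha1 * geom.area + stack.alpha2 * geom.perimeter


def direct_capacitance(geom: ElectrodeGeometry, stack: MaterialStack) -> float:
    """Sidewall coupling between facing finger walls through the oxide, fF."""
    if geom.gap <= 0:
        raise InvalidParameterError("gap must be > 0")
    return (
        stack.eps0
        * stack.eps_SiO2
        * geom.coinciding_perimeter
        * geom.thickness
        / geom.gap
    )


def fringe_capacitance(c_sens: float, stack: MaterialStack) -> float:
    """Oxide-side fringe capacitance: ``eps_SiO2`` times the air fringe, fF."""
    if c_sens < 0:
        raise InvalidParameterError("c_sens must be >= 0")
    return stack.eps_SiO2 * c_sens


def offset_capacitance(c_sub: float, c_dir: float, c_fringe: float) -> float:
    """Offset capacitance C_off = C_sub + C_dir + C_fringe, fF."""
    if min(c_sub, c_dir, c_fringe) < 0:
        raise InvalidParameterError("capacitance parts must be >= 0")
    return c_sub + c_dir + c_fringe


def parallel_plate_areal(eps_r: float, d: float, eps0: float = EPS0) -> float:
    """Areal parallel-plate capacitance ``eps0*eps_r/d`` in fF/µm²."""
    if d <= 0:
        raise InvalidParameterError("d must be > 0")
    if eps_r < 1:
        raise InvalidParameterError("eps_r must be >= 1")
    return eps0 * eps_r / d


def _stack_areal(eps_mid: float, d_mid: float, stack: MaterialStack) -> float:
    """Areal capacitance of a passivation/medium/passivation vertical stack.

    Series combination (per unit area) of the two 10 nm passivation films and
    the medium filling the effective fringe distance between the plates.
    """
    denom = stack.eps_PL * d_mid + eps_mid * 2.0 * stack.d_PL
    if denom <= 0:
        raise InvalidParameterError("degenerate stack: zero denominator")
    return stack.eps0 * stack.eps_PL * eps_mid / denom


def sensing_capacitance(geom: ElectrodeGeometry, stack: MaterialStack) -> float:
    """Air-path sensing capacitance C_sens in fF (the dry fringe term)."""
    return geom.area * _stack_areal(stack.eps_air, stack.d_eff_air, stack)


def dry_equivalent(
    geom: ElectrodeGeometry, stack: MaterialStack, c_off: float | None = None
) -> float:
    """Total equivalent capacitance without sample, fF.

    Sensing term through passivation + air plus the offset; when ``c_off`` is
    not supplied it is computed from the same geometry and stack.
    """
    c_sens = sensing_capacitance(geom, stack)
    if c_off is None:
        c_off = offset_capacitance(
            substrate_capacitance(geom, stack),
            direct_capacitance(geom, stack),
            fringe_capacitance(c_sens, stack),
        )
    if c_off < 0:
        raise InvalidParameterError("c_off must be >= 0")
    return c_sens + c_off


def cell_layer_capacitance(
    deposit_conf: float, geom: ElectrodeGeometry, stack: MaterialStack,
    eps_cell: float | None = None, d_eff_cell: float | None = None,
) -> float:
    """Per-electrode interface capacitance C_Tn for coverage ``deposit_conf``, fF.

    C_Tn = eps0*A*( eps_PL*eps_cell*conf/(eps_PL*d_eff_cell + eps_cell*d_PL)
                    + eps_PL*(1-conf)/d_PL )

    Note: as a lumped sum of a covered series stack and the bare passivation
    plate, this quantity *decreases* with coverage (the bare-plate term
    eps_PL/d_PL dominates any covered term for positive cell thickness); the
    monotone rise of the measured equivalent lives in :func:`cell_equivalent`.
    """
    if not 0.0 <= deposit_conf <= 1.0:
        raise InvalidParameterError("confluence must lie in [0, 1]")
    e_c = stack.eps_cell if eps_cell is None else eps_cell
    d_c = stack.d_eff_cell if d_eff_cell is None else d_eff_cell
    if d_c <= 0:
        raise InvalidParameterError("d_eff_cell must be > 0")
    covered = stack.eps_PL * e_c / (stack.eps_PL * d_c + e_c * stack.d_PL)
    bare = stack.eps_PL / stack.d_PL
    return stack.eps0 * geom.area * (covered * deposit_conf + bare * (1.0 - deposit_conf))


def series_combination(caps: list[float] | tuple[float, ...]) -> float:
    """Series combination ``1 / sum(1/C_i)`` in fF."""
    if len(caps) == 0:
        raise InvalidParameterError("series combination needs at least one capacitor")
    total = 0.0
    for c in caps:
        if c <= 0:
            raise InvalidParameterError("series combination requires all C > 0")
        if math.isinf(c):
            continue  # an infinite capacitor is a short: contributes nothing
        total += 1.0 / c
    if total == 0.0:
        return math.inf
    return 1.0 / total


def cell_equivalent(
    deposit: CellDeposit, geom: ElectrodeGeometry, stack: MaterialStack
) -> float:
    """Total equivalent capacitance with deposited cells, fF.

    The through-sample path is an area-weighted parallel mixture, per
    electrode, of the covered stack (passivation / cell layer / passivation)
    and the uncovered stack (passivation / air / passivation):

        C_path = eps0*A * mean_n[ conf_n * s_cell + (1 - conf_n) * s_air ]

    with ``s_cell``/``s_air`` the areal series-stack capacitances.  At zero
    confluence this reduces exactly to the dry sensing term, and because a
    moist cell layer is a far better dielectric path than air it rises
    strictly with coverage — the behaviour the chip measures.  The lumped
    C_Tn of :func:`cell_layer_capacitance` is reported for reference in
    :func:`capacitance_breakdown` but is not series-chained here: chaining the
    bare-plate-dominated C_Tn with a fixed air term is monotone the wrong way
    for every physical parameter choice.
    """
    e_c = stack.eps_cell if deposit.eps_cell is None else deposit.eps_cell
    d_c = stack.d_eff_cell if deposit.d_eff_cell is None else deposit.d_eff_cell
    if d_c <= 0:
        raise InvalidParameterError("d_eff_cell must be > 0")
    s_air = _stack_areal(stack.eps_air, stack.d_eff_air, stack)
    s_cell = _stack_areal(e_c, d_c, stack)
    mix = 0.5 * (
        deposit.conf1 * s_cell + (1.0 - deposit.conf1) * s_air
        + deposit.conf2 * s_cell + (1.0 - deposit.conf2) * s_air
    )
    c_path = geom.area * mix
    c_sens = sensing_capacitance(geom, stack)
    c_off = offset_capacitance(
        substrate_capacitance(geom, stack),
        direct_capacitance(geom, stack),
        fringe_capacitance(c_sens, stack),
    )
    return c_off + c_path


def capacitance_breakdown(
    geom: ElectrodeGeometry,
    stack: MaterialStack,
    deposit: CellDeposit | None = None,
) -> CapacitanceBreakdown:
    """Full lumped breakdown for a (possibly cell-covered) electrode pair."""
    if deposit is None:
        deposit = CellDeposit()
    c_sub = substrate_capacitance(geom, stack)
    c_dir = direct_capacitance(geom, stack)
    c_sens = sensing_capacitance(geom, stack)
    c_fringe = fringe_capacitance(c_sens, stack)
    c_off = offset_capacitance(c_sub, c_dir, c_fringe)
    c_air = parallel_plate_areal(stack.eps_air, stack.d_eff_air, stack.eps0) * geom.area
    c_t1 = cell_layer_capacitance(deposit.conf1, geom, stack, deposit.eps_cell, deposit.d_eff_cell)
    c_t2 = cell_layer_capacitance(deposit.conf2, geom, stack, deposit.eps_cell, deposit.d_eff_cell)
    c_eq = cell_equivalent(deposit, geom, stack)
    return CapacitanceBreakdown(
        C_sub=c_sub, C_dir=c_dir, C_fringe=c_fringe, C_off=c_off, C_sens=c_sens,
        C_T1=c_t1, C_T2=c_t2, C_air=c_air, C_equivalent=c_eq,
    )


def calibrate_d_eff_air(
    geom: ElectrodeGeometry, stack: MaterialStack, target_fF: float = 109.0
) -> float:
    """Solve for the effective air fringe distance giving a dry baseline.

    The dry equivalent is ``(1 + eps_SiO2) * C_sens + C_sub + C_dir`` with
    C_sens the passivation/air/passivation stack over the metal area; this
    inverts that relation analytically for ``d_eff_air``.  Default target is
    the printed experimental dry baseline of the chip (≈109 fF).
    """
    c_sub = substrate_capacitance(geom, stack)
    c_dir = direct_capacitance(geom, stack)
    c_sens_needed = (target_fF - c_sub - c_dir) / (1.0 + stack.eps_SiO2)
    if c_sens_needed <= 0:
        raise InvalidParameterError("target baseline below the offset floor")
    # c_sens = eps0*eps_PL*eps_air*A / (eps_PL*d + eps_air*2*d_PL)
    num = stack.eps0 * stack.eps_PL * stack.eps_air * geom.area
    d = (num / c_sens_needed - stack.eps_air * 2.0 * stack.d_PL) / stack.eps_PL
    if d <= 0:
        raise InvalidParameterError("no positive fringe distance reaches the target")
    return d
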