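"""Closed-form induced-charge electrokinetic (ICEK) model for cavity-decorated
uncharged nanopores.

The system is a cylindrical pore of radius ``R`` through an insulating membrane
of thickness ``L``, coaxially surrounded by an annular cavity of width ``w``
and depth ``d = L − h`` separated from the lumen by a solid wall of thickness
``s``.  An applied transmembrane voltage ΔV charges the "lateral capacitor"
formed by the cavity and the lumen across the wall: counter-ions pile up in the
cavity and a mirror induced Debye layer (IDL) of net charge

    q_N = −C_s · ΔV

forms inside the lumen, with a purely geometric lateral capacitance ``C_s``.
Because both the IDL sign and the driving field flip together with ΔV, the
resulting ionic selectivity is odd in ΔV with quadratic magnitude, and the
electroosmotic flow (EOF) is even in ΔV — a unidirectional flow pointing
toward the cavity opening for either polarity.

Sign conventions
----------------
The z axis points from the biased reservoir (held at ΔV, which may be
negative) to the grounded one, so the driving field is E_z = ΔV/L.  A positive
velocity means flow from the biased toward the grounded reservoir.  With the
cavity opening facing the biased reservoir (the default), the induced EOF is
negative for both polarities; ``cavity_side`` mirrors the geometry and flips
every odd quantity coherently.

Validity
--------
The thin-Debye-layer closure (plug EOF, planar-layer charge ∝ ζ_w/λ_D) holds
for λ_D ≪ R.  ``eof_flow`` warns once λ_D/R exceeds 0.2 and refuses to
evaluate in the Debye-overlap regime λ_D ≥ R.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .units import (
    EPS0,
    KB,
    molar_to_per_A3,
    surface_charge_to_internal,
    viscosity_to_internal,
)

__all__ = [
    "CavitySide",
    "ElectrolyteSpec",
    "PoreGeometry",
    "SurfaceChargeSpec",
    "DriveCondition",
    "ICEKPrediction",
    "DebyeOverlapError",
    "ThinLayerWarning",
    "debye_length",
    "lateral_capacitance",
    "induced_charge",
    "mean_charge_density",
    "selectivity",
    "eof_flow",
    "fixed_charge_velocity",
    "threshold_voltage",
    "far_field_velocity",
    "predict",
    "sweep",
]


class DebyeOverlapError(ValueError):
    """Raised when λ_D ≥ R: the thin-layer EOF closure is meaningless."""


class ThinLayerWarning(UserWarning):
    """Emitted when λ_D/R > 0.2: predictions are extrapolations."""


class CavitySide(str, enum.Enum):
    """Which reservoir the annular cavity opens toward."""

    FACING_BIASED_RESERVOIR = "facing_biased_reservoir"
    FACING_GROUNDED_RESERVOIR = "facing_grounded_reservoir"

    @property
    def sign(self) -> int:
        """+1 when the cavity faces the biased reservoir, −1 otherwise."""
        return 1 if self is CavitySide.FACING_BIASED_RESERVOIR else -1


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Bulk properties of a symmetric ν:ν electrolyte.

    Parameters
    ----------
    c0 : float
        Bulk salt concentration, mol/L.
    valence : int
        Charge number ν of the (symmetric) ions, ≥ 1.
    epsilon_L : float
        Relative permittivity of the liquid.
    eta : float
        Dynamic viscosity, mPa·s.
    mu : float
        Ion electrophoretic mobility, Å²/(V·ns); assumed equal for both
        species.
    T : float
        Temperature, K.
    """

    c0: float
    valence: int = 1
    epsilon_L: float = 78.4
    eta: float = 0.89
    mu: float = 4.4e3
    T: float = 298.0

    def __post_init__(self) -> None:
        _require_positive(
            c0=self.c0, epsilon_L=self.epsilon_L, eta=self.eta, mu=self.mu, T=self.T
        )
        if not isinstance(self.valence, int) or self.valence < 1:
            raise ValueError(f"valence must be an integer >= 1, got {self.valence!r}")


@dataclass(frozen=True)
class PoreGeometry:
    """Cavity-decorated cylindrical pore. All lengths in Å.

    ``R``: pore radius; ``L``: membrane thickness; ``s``: solid wall between
    lumen and cavity; ``w``: cavity width; ``h``: residual solid below the
    cavity, so the cavity depth is ``d = L − h``; ``epsilon_S``: relative
    permittivity of the solid.
    """

    R: float
    L: float
    s: float
    w: float
    h: float
    epsilon_S: float = 1.0
    cavity_side: CavitySide = CavitySide.FACING_BIASED_RESERVOIR

    def __post_init__(self) -> None:
        _require_positive(R=self.R, L=self.L, s=self.s, w=self.w, epsilon_S=self.epsilon_S)
        if not 0 <= self.h <= self.L:
            raise ValueError(f"h must satisfy 0 <= h <= L, got h={self.h}, L={self.L}")
        object.__setattr__(self, "cavity_side", CavitySide(self.cavity_side))

    @property
    def d(self) -> float:
        """Cavity depth L − h, Å."""
        return self.L - self.h


@dataclass(frozen=True)
class SurfaceChargeSpec:
    """Fixed (intrinsic) wall surface charge density σ_w, mC/m².

    σ_w may be produced by any user-parameterised σ_w(pH) model via
    :meth:`from_ph_model`; no literature fit coefficients are baked in.
    """

    sigma_w: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.sigma_w):
            raise ValueError(f"sigma_w must be finite, got {self.sigma_w!r}")

    @classmethod
    def from_ph_model(
        cls, model: Callable[[float], float], ph: float
    ) -> "SurfaceChargeSpec":
        """Evaluate a user-supplied σ_w(pH) functional form (mC/m²) at ``ph``."""
        return cls(sigma_w=float(model(ph)))

    @property
    def sigma_w_internal(self) -> float:
        """σ_w in e/Å²."""
        return surface_charge_to_internal(self.sigma_w)


@dataclass(frozen=True)
class DriveCondition:
    """Applied transmembrane voltage ΔV (V, signed).

    ΔV > 0 means the reservoir the cavity opening faces under the default
    orientation (point A) is at +ΔV with the opposite reservoir grounded.
    """

    delta_V: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_V):
            raise ValueError(f"delta_V must be finite, got {self.delta_V!r}")


@dataclass(frozen=True)
class ICEKPrediction:
    """Model outputs for one (geometry, electrolyte, drive[, σ_w]) point.

    Units: C_s e/V; q_N e; rho_el_mean e/Å³; zeta_w V; delta_J 1/(Å²·ns);
    Q_eo Å³/ns; v_eo and v_eo_FC Å/ns; delta_V_star V.
    """

    C_s: float
    q_N: float
    rho_el_mean: float
    zeta_w: float
    delta_J: float
    Q_eo: float
    v_eo: float
    v_eo_FC: float | None = None
    delta_V_star: float | None = None


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def debye_length(electrolyte: ElectrolyteSpec) -> float:
    """Debye screening length λ_D of a symmetric ν:ν electrolyte, in Å.

    λ_D = sqrt(ε0 εL k_B T / (2 ν² e² n0)) with n0 the bulk number density of
    each species.  Scales as c0^(−1/2) and (εL·T)^(1/2).
    """
    n0 = molar_to_per_A3(electrolyte.c0)  # Å⁻³
    # internal units: e = 1, so ν²e²n0 → ν²n0 [e²/Å³]; EPS0·KB·T [e²/(Å·eV)·eV]
    lam2 = EPS0 * electrolyte.epsilon_L * KB * electrolyte.T / (
        2.0 * electrolyte.valence**2 * n0
    )
    return math.sqrt(lam2)


def lateral_capacitance(geom: PoreGeometry) -> float:
    """Lateral (cavity–lumen) capacitance C_s, in e/V.

    Quasi-1D model: the dead-end cavity is isopotential with the reservoir it
    opens toward, while the lumen potential drops linearly between the
    reservoirs.  Integrating the annular wall capacitance per unit length,
    c' = 2π ε0 εS / ln(1 + s/R), against the local cavity–lumen potential
    difference over the cavity depth d gives

        C_s = π ε0 εS d² / (L · ln(1 + s/R)).

    C_s vanishes with the cavity depth (d → 0) and decreases with the wall
    thickness s.  See :func:`icekpore.quasi1d.lateral_capacitance_fd` for the
    finite-difference cross-check of the d²/2L averaging factor.
    """
    d = geom.d
    if d < 0:
        raise ValueError("cavity depth d = L - h must be >= 0")
    return math.pi * EPS0 * geom.epsilon_S * d * d / (
        geom.L * math.log1p(geom.s / geom.R)
    )


def induced_charge(geom: PoreGeometry, drive: DriveCondition) -> float:
    """Net induced charge q_N in the pore lumen, in e.

    q_N = −C_s · ΔV for a cavity facing the biased reservoir: a positive bias
    pulls cations into the cavity and mirrors an anionic IDL into the lumen.
    Antisymmetric in ΔV; mirrored geometries flip the sign.
    """
    return -geom.cavity_side.sign * lateral_capacitance(geom) * drive.delta_V


def mean_charge_density(geom: PoreGeometry, drive: DriveCondition) -> float:
    """Volume-averaged net charge density ⟨ρ_el⟩ = q_N/(πR²L), in e/Å³."""
    return induced_charge(geom, drive) / (math.pi * geom.R**2 * geom.L)


def selectivity(
    geom: PoreGeometry, electrolyte: ElectrolyteSpec, drive: DriveCondition
) -> float:
    """Ionic selectivity ΔJ = μ⟨ρ_el⟩|E_z|/(νe): cation minus anion flux
    magnitude per unit pore cross-section, in 1/(Å²·ns).

    Electrophoretic fluxes are μ c_± E, so the flux imbalance is set by the
    IDL net density.  ΔJ is odd in ΔV with |ΔJ| ∝ ΔV² (the IDL and the driving
    field each contribute one power), positive when the pore is
    cation-selective (q_N > 0).  The convective (EOF) contribution to ion
    transport is deliberately not included.
    """
    e_mag = abs(drive.delta_V) / geom.L  # |E_z|, V/Å
    rho = mean_charge_density(geom, drive)
    return electrolyte.mu * rho * e_mag / electrolyte.valence


def _check_thin_layer(geom: PoreGeometry, electrolyte: ElectrolyteSpec) -> float:
    lam = debye_length(electrolyte)
    if lam >= geom.R:
        raise DebyeOverlapError(
            f"Debye overlap: lambda_D = {lam:.3g} A >= R = {geom.R:.3g} A; "
            "the thin-layer EOF model does not apply"
        )
    if lam / geom.R > 0.2:
        warnings.warn(
            f"lambda_D/R = {lam / geom.R:.2f} > 0.2: thin-Debye-layer EOF "
            "prediction is an extrapolation",
            ThinLayerWarning,
            stacklevel=3,
        )
    return lam


def eof_flow(
    geom: PoreGeometry, electrolyte: ElectrolyteSpec, drive: DriveCondition
) -> tuple[float, float]:
    """Induced-charge electroosmotic flow: (Q_eo Å³/ns, v_eo Å/ns).

    The thin-layer closure equates q_N with the planar-layer relation
    q_N = 2πRL·ε0 εL ζ_w/λ_D, giving the induced wall potential
    ζ_w = q_N λ_D/(2πRL ε0 εL), and the Helmholtz–Smoluchowski plug velocity
    then yields the parabolic law

        v_eo = q_N λ_D ΔV / (2πR L² η) = −σ_c C_s λ_D ΔV² / (2πR L² η),

    even in ΔV and always directed toward the cavity opening (σ_c = +1 when
    the cavity faces the biased reservoir, hence v_eo ≤ 0 there).
    Q_eo = πR²·v_eo.
    """
    lam = _check_thin_layer(geom, electrolyte)
    eta = viscosity_to_internal(electrolyte.eta)
    q_n = induced_charge(geom, drive)
    v_eo = q_n * lam * drive.delta_V / (2.0 * math.pi * geom.R * geom.L**2 * eta)
    return math.pi * geom.R**2 * v_eo, v_eo


def fixed_charge_velocity(
    geom: PoreGeometry,
    electrolyte: ElectrolyteSpec,
    drive: DriveCondition,
    charge: SurfaceChargeSpec,
) -> float:
    """Classical fixed-charge EO velocity v_eo,FC = −σ_w λ_D ΔV/(η L), Å/ns.

    This is the same plug-flow closure with the wall potential set by the
    intrinsic surface charge, ζ_w = σ_w λ_D/(ε0 εL): linear (odd) in ΔV and
    linear in σ_w.  A positive σ_w gives a counter-ion (negative) screening
    cloud, so the fluid moves against the field for ΔV > 0.
    """
    lam = debye_length(electrolyte)
    eta = viscosity_to_internal(electrolyte.eta)
    sigma = charge.sigma_w_internal  # e/Å²
    return -sigma * lam * drive.delta_V / (eta * geom.L)


def threshold_voltage(
    geom: PoreGeometry, electrolyte: ElectrolyteSpec, charge: SurfaceChargeSpec
) -> float:
    """Threshold voltage ΔV* (V) above which the induced-charge EOF dominates.

    Equating |v_eo,FC| (linear in ΔV) with |v_eo| (quadratic) gives

        ΔV* = 2πRL|σ_w| / C_s,

    independent of λ_D and εL, monotone in |σ_w|.  σ_w = 0 returns 0 (the
    induced mechanism dominates at any voltage); a cavity-less pore
    (C_s = 0) returns +inf.
    """
    sigma = abs(charge.sigma_w_internal)
    if sigma == 0.0:
        return 0.0
    c_s = lateral_capacitance(geom)
    if c_s == 0.0:
        return math.inf
    return 2.0 * math.pi * geom.R * geom.L * sigma / c_s


def far_field_velocity(v_eo: float, R: float, r: float) -> float:
    """Fluid speed at distance ``r`` from the pore mouth: v_eo·(R/r)².

    The pore acts as a point-like volume source, so the velocity magnitude
    decays as the inverse square of the distance; v(R) = v_eo.  Any
    consistent unit pair works (v in the unit of v_eo, r and R alike).
    """
    _require_positive(R=R)
    if r < R:
        raise ValueError(f"far field requires r >= R, got r={r}, R={R}")
    return v_eo * (R / r) ** 2


# ---------------------------------------------------------------------------
# assembled prediction and sweeps
# ---------------------------------------------------------------------------

def predict(
    geom: PoreGeometry,
    electrolyte: ElectrolyteSpec,
    drive: DriveCondition,
    charge: SurfaceChargeSpec | None = None,
) -> ICEKPrediction:
    """Evaluate the full model at one parameter point."""
    c_s = lateral_capacitance(geom)
    q_n = induced_charge(geom, drive)
    rho = mean_charge_density(geom, drive)
    lam = debye_length(electrolyte)
    zeta = q_n * lam / (2.0 * math.pi * geom.R * geom.L * EPS0 * electrolyte.epsilon_L)
    d_j = selectivity(geom, electrolyte, drive)
    q_eo, v_eo = eof_flow(geom, electrolyte, drive)
    v_fc = None
    dv_star = None
    if charge is not None:
        v_fc = fixed_charge_velocity(geom, electrolyte, drive, charge)
        dv_star = threshold_voltage(geom, electrolyte, charge)
    return ICEKPrediction(
        C_s=c_s,
        q_N=q_n,
        rho_el_mean=rho,
        zeta_w=zeta,
        delta_J=d_j,
        Q_eo=q_eo,
        v_eo=v_eo,
        v_eo_FC=v_fc,
        delta_V_star=dv_star,
    )


_GEOM_COLS = ("R", "L", "s", "w", "h", "d", "epsilon_S", "cavity_side")
_PRED_COLS = (
    "C_s",
    "q_N",
    "rho_el_mean",
    "zeta_w",
    "delta_J",
    "Q_eo",
    "v_eo",
    "v_eo_FC",
    "delta_V_star",
)


def sweep(
    geometries: Sequence[PoreGeometry] | PoreGeometry,
    electrolyte: ElectrolyteSpec,
    voltages: Iterable[float],
    charge: SurfaceChargeSpec | None = None,
) -> pd.DataFrame:
    """Evaluate the model over a geometry × voltage grid.

    Returns one row per (geometry, ΔV) pair, in the given order (geometry
    outer, voltage inner), carrying the inputs alongside every
    :class:`ICEKPrediction` field — the raw material for trend curves such as
    |v_eo| vs L or ΔV* vs σ_w maps.
    """
    if isinstance(geometries, PoreGeometry):
        geometries = [geometries]
    geometries = list(geometries)
    voltages = [float(v) for v in voltages]
    if not geometries or not voltages:
        raise ValueError("sweep requires at least one geometry and one voltage")
    rows = []
    for geom in geometries:
        for dv in voltages:
            pred = predict(geom, electrolyte, DriveCondition(dv), charge)
            row: dict[str, object] = {
                "R": geom.R,
                "L": geom.L,
                "s": geom.s,
                "w": geom.w,
                "h": geom.h,
                "d": geom.d,
                "epsilon_S": geom.epsilon_S,
                "cavity_side": geom.cavity_side.value,
                "c0": electrolyte.c0,
                "valence": electrolyte.valence,
                "epsilon_L": electrolyte.epsilon_L,
                "eta": electrolyte.eta,
                "mu": electrolyte.mu,
                "T": electrolyte.T,
                "lambda_D": debye_length(electrolyte),
                "sigma_w": charge.sigma_w if charge is not None else None,
                "delta_V": dv,
            }
            for name in _PRED_COLS:
                row[name] = getattr(pred, name)
            rows.append(row)
    return pd.DataFrame(rows)
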