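"""Wisconsin-type bioenergetics model for juvenile walleye pollock.

Daily specific growth is computed as a mass balance: realized consumption
(a fraction ``eta`` of the temperature- and weight-specific maximum
consumption) minus egestion, excretion, specific dynamic action, and
respiration, with consumed prey biomass converted into predator biomass
through the ratio of predator to prey energy density (``rho``).

All rates are specific rates (g per g of fish per day); weights are wet
weights; energy densities are kJ per g wet weight on the public surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BioenParams",
    "BioenInput",
    "GrowthResult",
    "temp_scaling",
    "cmax",
    "respiration",
    "growth",
    "solve_eta",
    "solve_eta_stations",
    "growth_surface",
]


@dataclass(frozen=True)
class BioenParams:
    """Parameter set of the juvenile pollock bioenergetics model.

    Defaults are the published values for age-0 walleye pollock:
    allometric consumption (alpha_c, beta_c) with a dome-shaped thermal
    response (q_c, t_co, t_cm), allometric respiration (a_r, b_r) with its
    own thermal dome (q_r, t_ro, t_rm), proportional waste terms, an
    active-metabolism multiplier, and the oxycalorific coefficient
    converting respired oxygen to energy.
    """

    alpha_c: float = 0.119     # intercept of the allometric function for C
    beta_c: float = -0.46      # slope of the allometric function for C
    q_c: float = 2.6           # temperature-dependent coefficient for C
    t_co: float = 10.0         # optimum temperature for consumption (degC)
    t_cm: float = 15.0         # maximum temperature for consumption (degC)
    a_r: float = 0.0075        # intercept of the allometric function for R
    b_r: float = -0.251        # slope of the allometric function for R
    q_r: float = 2.6           # temperature-dependent coefficient for R
    t_ro: float = 13.0         # optimum temperature for respiration (degC)
    t_rm: float = 18.0         # maximum temperature for respiration (degC)
    d_s: float = 0.125         # proportion of assimilated energy lost to SDA
    a_m: float = 2.0           # multiplier for active metabolism
    f_a: float = 0.15          # egestion, proportion of consumed energy
    u_a: float = 0.11          # excretion, proportion of assimilated energy
    o2cal: float = 13560.0     # J per g O2 respired
    eta: float = 1.0           # relative foraging rate (realized C / Cmax)

    def __post_init__(self) -> None:
        if not self.t_co < self.t_cm:
            raise ValueError("t_co must be below t_cm")
        if not self.t_ro < self.t_rm:
            raise ValueError("t_ro must be below t_rm")
        for name in ("d_s", "f_a", "u_a", "eta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def with_eta(self, eta: float) -> "BioenParams":
        return replace(self, eta=eta)


@dataclass(frozen=True)
class BioenInput:
    """Station-level inputs to a single simulation day.

    weight_g
        fish wet weight W at the start of the day (g).
    temp_c
        mean temperature of the upper 30 m at the station (degC).
    prey_ed
        biomass-weighted mean energy density of available prey (kJ/g wet).
    fish_ed
        annual mean fish energy density (kJ/g wet).
    """

    weight_g: float
    temp_c: float
    prey_ed: float
    fish_ed: float
    station_id: str = ""

    def __post_init__(self) -> None:
        if self.weight_g <= 0:
            raise ValueError("weight_g must be positive")
        if self.prey_ed <= 0 or self.fish_ed <= 0:
            raise ValueError("energy densities must be positive")

    @property
    def rho(self) -> float:
        """Predator:prey energy-density ratio used to convert prey mass."""
        return self.fish_ed / self.prey_ed


@dataclass
class GrowthResult:
    """Daily growth with the full energy-budget diagnostics.

    Mass-specific rates are g prey (or g O2 for respiration) per g fish
    per day; energy rates are kJ per g fish per day.
    """

    station_id: str
    growth: float                    # G, g g^-1 d^-1
    cmax: float                      # maximum consumption, g g^-1 d^-1
    consumption: float               # realized C = eta * Cmax
    egestion: float                  # F = F_a * C
    excretion: float                 # U = U_a * (C - F)
    sda: float                       # SDA = D_s * (C - F)
    respiration: float               # R, g O2 g^-1 d^-1
    consumption_energy: float = 0.0  # C * prey_ed
    respiration_energy: float = 0.0  # R * o2cal / 1000
    model: str = "bioenergetics"


def temp_scaling(temp_c: float, q: float, t_opt: float, t_max: float) -> float:
    """Dome-shaped thermal response, 1 at ``t_opt`` and 0 at/above ``t_max``.

    The classic Wisconsin form: with V = (t_max - T)/(t_max - t_opt),
    Z = ln(Q)(t_max - t_opt), Y = ln(Q)(t_max - t_opt + 2) and
    X = (Z^2/400)(1 + sqrt(1 + 40/Y))^2, the factor is V^X * exp(X(1 - V)).
    """
    if not t_opt < t_max:
        raise ValueError("t_opt must be below t_max")
    if temp_c >= t_max:
        return 0.0
    v = (t_max - temp_c) / (t_max - t_opt)
    z = math.log(q) * (t_max - t_opt)
    y = math.log(q) * (t_max - t_opt + 2.0)
    x = (z * z / 400.0) * (1.0 + math.sqrt(1.0 + 40.0 / y)) ** 2
    return v**x * math.exp(x * (1.0 - v))


def cmax(weight_g: float, temp_c: float, params: BioenParams | None = None) -> float:
    """Maximum specific daily consumption (g prey per g fish per day)."""
    p = params or BioenParams()
    if weight_g <= 0:
        raise ValueError("weight_g must be positive")
    return p.alpha_c * weight_g**p.beta_c * temp_scaling(temp_c, p.q_c, p.t_co, p.t_cm)


def respiration(
    weight_g: float,
    temp_c: float,
    params: BioenParams | None = None,
    *,
    active_multiplier: float | None = None,
) -> float:
    """Specific respiration (g O2 per g fish per day), incl. activity multiplier."""
    p = params or BioenParams()
    if weight_g <= 0:
        raise ValueError("weight_g must be positive")
    a_m = p.a_m if active_multiplier is None else active_multiplier
    return a_m * p.a_r * weight_g**p.b_r * temp_scaling(temp_c, p.q_r, p.t_ro, p.t_rm)


def growth(inp: BioenInput, params: BioenParams | None = None) -> GrowthResult:
    """Daily mass-balance growth G (g g^-1 d^-1) for one station day.

    C = eta * Cmax; egestion F = F_a * C; excretion U and SDA are taken
    from assimilated consumption (C - F); respiration is converted to a
    prey-mass-equivalent loss through the oxycalorific coefficient and
    the fish energy density, and the net prey-mass surplus is converted
    into fish mass by dividing by rho = fish_ed / prey_ed.
    """
    p = params or BioenParams()
    c_max = cmax(inp.weight_g, inp.temp_c, p)
    c = p.eta * c_max
    f = p.f_a * c
    assimilated = c - f
    u = p.u_a * assimilated
    sda = p.d_s * assimilated
    r = respiration(inp.weight_g, inp.temp_c, p)
    resp_energy = r * p.o2cal / 1000.0  # kJ g^-1 d^-1
    g = (c - f - u - sda) / inp.rho - resp_energy / inp.fish_ed
    return GrowthResult(
        station_id=inp.station_id,
        growth=g,
        cmax=c_max,
        consumption=c,
        egestion=f,
        excretion=u,
        sda=sda,
        respiration=r,
        consumption_energy=c * inp.prey_ed,
        respiration_energy=resp_energy,
    )


def solve_eta(
    inp: BioenInput,
    params: BioenParams | None = None,
    target_growth: float = 0.0,
) -> float | None:
    """Relative foraging rate at which growth equals ``target_growth``.

    Returns the root eta* in [0, 1], or ``None`` when the target is not
    bracketed by growth at eta=0 and eta=1 (e.g. stations where even
    maximum consumption cannot offset metabolic losses).
    """
    p = params or BioenParams()

    def g_of_eta(eta: float) -> float:
        return growth(inp, p.with_eta(eta)).growth - target_growth

    g0, g1 = g_of_eta(0.0), g_of_eta(1.0)
    if g0 == 0.0:
        return 0.0
    if g1 == 0.0:
        return 1.0
    if g0 * g1 > 0:
        return None
    return float(brentq(g_of_eta, 0.0, 1.0, xtol=1e-12))


def solve_eta_stations(
    inputs: list[BioenInput],
    params: BioenParams | None = None,
) -> float:
    """Foraging rate at which exactly half the stations sustain positive growth.

    Computed as the median of per-station break-even rates eta*; stations
    where growth is negative even at eta=1 contribute +inf (no feasible
    rate), so they push the median upward.
    """
    if not inputs:
        raise ValueError("at least one station input is required")
    etas = []
    for inp in inputs:
        e = solve_eta(inp, params)
        etas.append(math.inf if e is None else e)
    return float(np.median(etas))


def growth_surface(
    temps: np.ndarray,
    prey_eds: np.ndarray,
    weight_g: float = 2.5,
    fish_ed: float = 5.29,
    params: BioenParams | None = None,
) -> np.ndarray:
    """Growth evaluated on a temperature x prey-ED grid at eta from params.

    Returns an array of shape (len(temps), len(prey_eds)); cells at or
    above the maximum consumption temperature are NaN because maximum
    consumption is zero there and growth is not estimable.
    """
    p = params or BioenParams()
    temps = np.asarray(temps, dtype=float)
    prey_eds = np.asarray(prey_eds, dtype=float)
    out = np.full((temps.size, prey_eds.size), np.nan)
    for i, t in enumerate(temps):
        if t >= p.t_cm:
            continue
        for j, ed in enumerate(prey_eds):
            inp = BioenInput(weight_g=weight_g, temp_c=float(t), prey_ed=float(ed), fish_ed=fish_ed)
            out[i, j] = growth(inp, p).growth
    return out
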