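"""Sensitivity analyses and bioenergetics-vs-IBM comparison.

Covers +-1 pooled-SD perturbations of the bioenergetics inputs (fish
weight, temperature, prey and fish energy density), Monte Carlo variation
of fish weight and energy density at a representative station, the IBM
alternate scenarios (2.0 g starting weight, uniform vertical prey
distributions), and the spatial model comparison: per-station growth
differences, regime percent reductions, and the relative foraging rate
needed for positive growth at half of all stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioen import BioenInput, BioenParams, growth, solve_eta_stations
from . import survey

__all__ = [
    "SensitivitySummary",
    "ComparisonResult",
    "pooled_sd",
    "station_inputs",
    "base_growth_table",
    "perturb_and_summarize",
    "monte_carlo_station",
    "ibm_scenarios",
    "compare_models",
]

# Perturbable inputs: constant-across-station scalars vs station fields
SCALAR_PARAMS = ("W", "fishED")
STATION_PARAMS = ("T", "preyED")


@dataclass
class SensitivitySummary:
    """One summary row in the shape of the published sensitivity tables."""

    parameter: str
    direction: str               # "base", "+1SD", "-1SD", or a scenario tag
    sd: float                    # pooled SD applied (0 for base/scenarios)
    min: float
    mean: float
    max: float
    deltas: pd.Series | None = None   # per-station field (base carries values)


@dataclass
class ComparisonResult:
    differences: pd.Series       # per-station bioenergetics - IBM growth
    mean_bioen: float
    mean_ibm: float
    percent_reduction: float     # 100 * (1 - mean_ibm / mean_bioen)
    eta_half: float              # foraging rate for positive growth at half of stations
    reduction_implied_by_eta: float  # 100 * (1 - eta_half)


def pooled_sd(values: np.ndarray, regimes: np.ndarray) -> float:
    """SD of station values pooled across regimes after removing regime means.

    Residuals are each station's value minus its regime mean; the SD uses
    n - (number of regimes) degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    regimes = np.asarray(regimes)
    labels = np.unique(regimes)
    if values.size <= labels.size:
        raise ValueError("need more values than regimes")
    resid = values.copy()
    for lab in labels:
        m = regimes == lab
        resid[m] -= values[m].mean()
    return float(np.sqrt((resid**2).sum() / (values.size - labels.size)))


def station_inputs(
    bundle,
    weight_g: float = 2.5,
    fish_ed: float | None = None,
    taxa: list[str] | None = None,
) -> list[BioenInput]:
    """Bioenergetics inputs for every station of a bundle with prey biomass.

    Builds the upper-30-m temperature and biomass-weighted prey ED per
    station; stations with zero main-prey biomass are excluded.
    """
    from .synth import modeling_taxa

    taxa = taxa if taxa is not None else modeling_taxa(bundle.regime)
    if fish_ed is None:
        fish_ed = survey.fish_energy_summary_table(bundle.fish_obs)[0]
    summary, _ = survey.prep_temperature(bundle.temperature_profiles, bundle.stations)
    temps = summary.set_index("station_id")["upper30_mean_C"]
    eds = bundle.prey_traits.set_index("taxon")["ed_kj_g"].loc[taxa]
    inputs = []
    for sid in temps.index:
        fld = bundle.prey_field
        fld = fld[fld["station_id"] == sid].set_index("taxon")
        biom = fld["biomass_g_per_m3"].reindex(taxa).fillna(0.0)
        if biom.sum() <= 0:
            continue
        pe = survey.station_prey_energy(biom.to_dict(), eds.to_dict(), station_id=sid)
        inputs.append(BioenInput(
            weight_g=weight_g, temp_c=float(temps[sid]),
            prey_ed=pe.prey_ed, fish_ed=fish_ed, station_id=sid,
        ))
    return inputs


def base_growth_table(
    inputs: list[BioenInput], params: BioenParams | None = None
) -> pd.Series:
    """Per-station maximum growth potential (eta from params, default 1)."""
    vals = {inp.station_id: growth(inp, params).growth for inp in inputs}
    return pd.Series(vals, name="growth")


def _perturbed_input(inp: BioenInput, parameter: str, delta: float) -> BioenInput | None:
    if parameter == "W":
        return BioenInput(inp.weight_g + delta, inp.temp_c, inp.prey_ed,
                          inp.fish_ed, inp.station_id)
    if parameter == "T":
        return BioenInput(inp.weight_g, inp.temp_c + delta, inp.prey_ed,
                          inp.fish_ed, inp.station_id)
    if parameter == "preyED":
        return BioenInput(inp.weight_g, inp.temp_c, inp.prey_ed + delta,
                          inp.fish_ed, inp.station_id)
    if parameter == "fishED":
        return BioenInput(inp.weight_g, inp.temp_c, inp.prey_ed,
                          inp.fish_ed + delta, inp.station_id)
    raise ValueError(f"unknown parameter {parameter!r}")


def perturb_and_summarize(
    inputs: list[BioenInput],
    parameter: str,
    sd: float,
    sign: int,
    params: BioenParams | None = None,
) -> SensitivitySummary:
    """Growth deltas after shifting one input by +-1 SD at every station.

    The relative foraging rate stays at its base value (1 by default) so
    the comparison is among maximum-growth scenarios. Stations where the
    perturbed temperature reaches the maximum consumption temperature are
    non-estimable (delta NaN); the summary statistics skip them.
    """
    p = params or BioenParams()
    base = base_growth_table(inputs, p)
    delta = sign * sd
    out = {}
    for inp in inputs:
        pert = _perturbed_input(inp, parameter, delta)
        if parameter == "T" and pert.temp_c >= p.t_cm:
            out[inp.station_id] = math.nan
            continue
        out[inp.station_id] = growth(pert, p).growth - base[inp.station_id]
    deltas = pd.Series(out)
    valid = deltas.dropna()
    return SensitivitySummary(
        parameter=parameter,
        direction=f"{'+' if sign > 0 else '-'}1SD",
        sd=sd,
        min=float(valid.min()),
        mean=float(valid.mean()),
        max=float(valid.max()),
        deltas=deltas,
    )


def monte_carlo_station(
    inp: BioenInput,
    vary: str,
    sd: float,
    n: int = 1000,
    seed: int = 0,
    params: BioenParams | None = None,
) -> dict[str, float]:
    """Monte Carlo growth distribution varying one input at one station.

    ``vary`` is "W" or "fishED"; n draws come from a normal with the
    base value as mean and the supplied SD, truncated below at 1% of the
    mean to keep weights and energy densities physical.
    """
    if vary not in SCALAR_PARAMS:
        raise ValueError(f"vary must be one of {SCALAR_PARAMS}")
    rng = np.random.default_rng(seed)
    base_val = inp.weight_g if vary == "W" else inp.fish_ed
    draws = rng.normal(base_val, sd, n)
    draws = np.maximum(draws, 0.01 * base_val)
    g = np.empty(n)
    for i, v in enumerate(draws):
        g[i] = growth(_perturbed_input(inp, vary, v - base_val), params).growth
    return {
        "min": float(g.min()), "max": float(g.max()),
        "mean": float(g.mean()), "sd": float(g.std(ddof=1)),
        "n": float(n),
    }


def ibm_scenarios(
    base: pd.DataFrame, scenario: pd.DataFrame, tag: str
) -> list[SensitivitySummary]:
    """Growth and depth deltas of an IBM scenario run against the base run.

    Both frames come from ``ibm.simulate_bundle`` with identical seeds.
    Negative depth deltas mean a shallower distribution. Returns one
    summary row for growth and one for depth.
    """
    b = base.set_index("station_id")
    s = scenario.set_index("station_id")
    common = b.index.intersection(s.index)
    if len(common) == 0:
        raise ValueError("no common stations between base and scenario")
    out = []
    for fld in ("growth", "mean_depth"):
        d = (s.loc[common, fld] - b.loc[common, fld]).rename(f"delta_{fld}")
        out.append(SensitivitySummary(
            parameter=fld, direction=tag, sd=0.0,
            min=float(d.min()), mean=float(d.mean()), max=float(d.max()),
            deltas=d,
        ))
    return out


def compare_models(
    bioen_growth: pd.Series,
    ibm_growth: pd.Series,
    inputs: list[BioenInput] | None = None,
    params: BioenParams | None = None,
) -> ComparisonResult:
    """Spatial comparison of maximum growth potential against IBM growth.

    Computes the per-station difference field (bioenergetics - IBM), the
    regime-mean percent reduction 100*(1 - mean_IBM / mean_bioen), and —
    when station inputs are supplied — the relative foraging rate at
    which half of all stations sustain positive growth, with the
    reduction it implies (100*(1 - eta)).
    """
    if set(bioen_growth.index) != set(ibm_growth.index):
        raise ValueError("station sets of the two models do not match")
    ibm_growth = ibm_growth.reindex(bioen_growth.index)
    diff = bioen_growth - ibm_growth
    mb, mi = float(bioen_growth.mean()), float(ibm_growth.mean())
    reduction = 100.0 * (1.0 - mi / mb) if mb > 0 else math.nan
    eta_half = math.nan
    if inputs is not None:
        eta_half = solve_eta_stations(inputs, params)
    implied = 100.0 * (1.0 - eta_half) if math.isfinite(eta_half) else math.nan
    return ComparisonResult(
        differences=diff, mean_bioen=mb, mean_ibm=mi,
        percent_reduction=reduction, eta_half=eta_half,
        reduction_implied_by_eta=implied,
    )
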