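"""Survey data preparation: CPUE, diets, prey energy, vertical profiles, temperature.

Implements the computations that turn station-level shelf-survey tables
into model-ready inputs: trawl catch per unit effort, CPUE-weighted diet
composition and the main-prey selection rule, the energy-density vs
percent-lipid regression for copepods, biomass-weighted station prey
energy density, MOCNESS-style vertical-profile construction, and
temperature-profile handling (upper-30-m means, 1-m bins, interpolation,
nearest-station fill-in).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FishObservation",
    "EDRegression",
    "StationPreyEnergy",
    "compute_cpue",
    "cpue_table",
    "weighted_diet_composition",
    "select_main_prey",
    "fit_ed_lipid_regression",
    "predict_ed_from_lipid",
    "station_prey_energy",
    "mean_individual_biomass",
    "build_vertical_profiles",
    "upper_layer_mean",
    "prep_temperature",
    "fish_energy_summary",
]

DEFAULT_TRAWL_SPREAD_M = 50.0  # horizontal trawl spread h; results scale as 1/h


@dataclass(frozen=True)
class FishObservation:
    """One trawl haul with its catch and the processed-fish measurements."""

    station_id: str
    n_caught: int
    trawl_distance_m: float
    trawl_spread_m: float = DEFAULT_TRAWL_SPREAD_M
    tow_type: str = "surface"
    weights_g: tuple[float, ...] = ()
    lengths_mm: tuple[float, ...] = ()
    fish_ed: tuple[float, ...] = ()  # kJ/g wet, processed individuals


@dataclass(frozen=True)
class EDRegression:
    """OLS fit of copepod energy density (kJ/g) on percent lipid."""

    intercept: float
    slope: float
    r_squared: float
    resid_sd: float


@dataclass(frozen=True)
class StationPreyEnergy:
    station_id: str
    prey_ed: float                      # biomass-weighted mean, kJ/g wet
    biomass_shares: dict[str, float]    # per-taxon share of total biomass


def compute_cpue(obs: FishObservation) -> float:
    """Catch per unit effort (fish per m^2) for a surface tow.

    CPUE = n / (d * h) with trawl distance d and horizontal spread h.
    Midwater tows target acoustic sign and are excluded (returns NaN with
    a warning) rather than entering the station density field.
    """
    if obs.tow_type != "surface":
        warnings.warn(
            f"station {obs.station_id}: {obs.tow_type} tow excluded from CPUE",
            stacklevel=2,
        )
        return math.nan
    if obs.trawl_distance_m <= 0 or obs.trawl_spread_m <= 0:
        raise ValueError("trawl distance and spread must be positive")
    if obs.n_caught < 0:
        raise ValueError("catch count must be nonnegative")
    return obs.n_caught / (obs.trawl_distance_m * obs.trawl_spread_m)


def cpue_table(observations: list[FishObservation]) -> pd.DataFrame:
    """CPUE per station for all surface tows, as a tidy table."""
    rows = []
    for obs in observations:
        if obs.tow_type != "surface":
            continue
        rows.append({"station_id": obs.station_id, "cpue": compute_cpue(obs)})
    return pd.DataFrame(rows, columns=["station_id", "cpue"])


def weighted_diet_composition(
    diets: pd.DataFrame, cpue: pd.DataFrame
) -> pd.Series:
    """CPUE-weighted mean percent-volume diet composition across stations.

    ``diets`` has columns (station_id, taxon, percent_volume); ``cpue``
    has (station_id, cpue). Station contributions are weighted by the
    local juvenile pollock CPUE. If every weight is zero the unweighted
    mean is returned with a warning.
    """
    merged = diets.merge(cpue, on="station_id", how="left")
    if merged["cpue"].isna().any():
        missing = merged.loc[merged["cpue"].isna(), "station_id"].unique()
        raise ValueError(f"stations without CPUE: {sorted(missing)}")
    stations = merged["station_id"].unique()
    w = merged.drop_duplicates("station_id").set_index("station_id")["cpue"]
    if w.sum() == 0:
        warnings.warn("all CPUE weights zero; using unweighted mean", stacklevel=2)
        w = pd.Series(1.0, index=w.index)
    wide = merged.pivot_table(
        index="station_id", columns="taxon", values="percent_volume",
        aggfunc="sum", fill_value=0.0,
    ).reindex(stations, fill_value=0.0)
    weights = w.reindex(wide.index)
    mean = wide.mul(weights, axis=0).sum(axis=0) / weights.sum()
    return mean.sort_values(ascending=False)


def select_main_prey(mean_diet: pd.Series, *,
                     cumulative_target: float = 90.0,
                     individual_min: float = 2.0) -> pd.DataFrame:
    """Select the main prey taxa from a mean diet composition.

    Taxa are ranked by descending individual percent volume (ties broken
    alphabetically). Every taxon contributing at least ``individual_min``
    percent is retained, and ranking continues below that floor until the
    running total reaches ``cumulative_target`` percent. Returns a table
    with columns (taxon, individual_pct, cumulative_pct); the cumulative
    column is the full-precision running sum rounded to one decimal, with
    the first row blank (NaN) as is conventional for these diet tables.
    """
    if mean_diet.empty:
        return pd.DataFrame(columns=["taxon", "individual_pct", "cumulative_pct"])
    if (mean_diet < 0).any():
        raise ValueError("diet percentages must be nonnegative")
    ordered = mean_diet.iloc[np.lexsort((mean_diet.index, -mean_diet.values))]
    rows: list[tuple[str, float, float]] = []
    cum = 0.0
    for taxon, pct in ordered.items():
        if cum >= cumulative_target and pct < individual_min:
            break
        cum += float(pct)
        rows.append((str(taxon), float(pct), round(cum, 1)))
    out = pd.DataFrame(rows, columns=["taxon", "individual_pct", "cumulative_pct"])
    if not out.empty:
        out.loc[0, "cumulative_pct"] = np.nan
    return out


def fit_ed_lipid_regression(samples: list[tuple[float, float]]) -> EDRegression:
    """OLS of energy density (kJ/g) on percent lipid over copepod samples."""
    if len(samples) < 3:
        raise ValueError("need at least 3 (percent lipid, ED) samples")
    lipid = np.array([s[0] for s in samples], dtype=float)
    ed = np.array([s[1] for s in samples], dtype=float)
    if np.ptp(lipid) == 0:
        raise ValueError("percent lipid has zero variance")
    model = sm.OLS(ed, sm.add_constant(lipid)).fit()
    resid_sd = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    return EDRegression(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        r_squared=float(model.rsquared),
        resid_sd=resid_sd,
    )


def predict_ed_from_lipid(percent_lipid: float, reg: EDRegression) -> float:
    """Predicted energy density at a given percent lipid: alpha + beta * L."""
    if percent_lipid < 0:
        raise ValueError("percent lipid must be nonnegative")
    return reg.intercept + reg.slope * percent_lipid


def station_prey_energy(
    prey_biomass: dict[str, float],
    taxon_ed: dict[str, float],
    station_id: str = "",
) -> StationPreyEnergy:
    """Biomass-weighted mean prey energy density at one station.

    Each taxon's biomass share of the station total is multiplied by its
    energy density and summed. Taxa with zero biomass drop out; a station
    with no prey biomass is flagged by raising ValueError so it can be
    excluded from growth maps.
    """
    present = {t: b for t, b in prey_biomass.items() if b > 0}
    if not present:
        raise ValueError(f"station {station_id}: zero total prey biomass")
    missing = set(present) - set(taxon_ed)
    if missing:
        raise KeyError(f"no energy density for taxa: {sorted(missing)}")
    total = sum(present.values())
    shares = {t: b / total for t, b in present.items()}
    ed = sum(shares[t] * taxon_ed[t] for t in present)
    return StationPreyEnergy(station_id=station_id, prey_ed=ed, biomass_shares=shares)


def mean_individual_biomass(subsample_weights_g: list[float], count: int) -> float:
    """Mean individual biomass: summed subsample mass over specimens counted."""
    if count <= 0:
        raise ValueError("subsample count must be positive")
    return float(sum(subsample_weights_g)) / count


def build_vertical_profiles(
    tows: pd.DataFrame,
    column_depth_m: int = 100,
    fallback: dict[str, str] | None = None,
    genus_average: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Day/night vertical distribution profiles from depth-stratified tows.

    ``tows`` has columns (tow_id, taxon, period, depth_top_m, depth_bottom_m,
    abundance) giving per-stratum abundances (# m^-3). Within each tow,
    abundance is assumed uniform inside each sampled stratum and spread
    into 1-m bins; bins are averaged across tows of the same period and
    normalized to fractions summing to 1.

    ``fallback`` maps (taxon) -> donor taxon whose profile substitutes for
    a period with no tows; ``genus_average`` maps a rarely caught taxon to
    a taxon-name prefix over which profiles are averaged. A taxon/period
    with no data at all falls back to a uniform profile with a warning.

    Returns a tidy frame (taxon, period, depth_bin_top_m, fraction).
    """
    fallback = fallback or {}
    genus_average = genus_average or {}
    nbins = int(column_depth_m)
    taxa = sorted(tows["taxon"].unique())

    def raw_profile(sub: pd.DataFrame) -> np.ndarray | None:
        """Mean 1-m abundance profile across this period's tows, or None."""
        if sub.empty:
            return None
        per_tow = []
        for _, tow in sub.groupby("tow_id"):
            bins = np.zeros(nbins)
            for _, row in tow.iterrows():
                top = int(row["depth_top_m"])
                bot = min(int(row["depth_bottom_m"]), nbins)
                if bot > top:
                    bins[top:bot] += row["abundance"]
            per_tow.append(bins)
        return np.mean(per_tow, axis=0)

    profiles: dict[tuple[str, str], np.ndarray | None] = {}
    for taxon in taxa:
        for period in ("day", "night"):
            sub = tows[(tows["taxon"] == taxon) & (tows["period"] == period)]
            profiles[(taxon, period)] = raw_profile(sub)

    # genus averages built from raw (pre-normalization) profiles
    for taxon, prefix in genus_average.items():
        members = [t for t in taxa if t.startswith(prefix)]
        for period in ("day", "night"):
            stacks = [profiles[(t, period)] for t in members
                      if profiles.get((t, period)) is not None]
            if stacks:
                profiles[(taxon, period)] = np.mean(stacks, axis=0)

    rows = []
    for taxon in taxa:
        for period in ("day", "night"):
            prof = profiles[(taxon, period)]
            if prof is None and taxon in fallback:
                prof = profiles.get((fallback[taxon], period))
            if prof is None or prof.sum() == 0:
                warnings.warn(
                    f"{taxon}/{period}: no stratified data, using uniform profile",
                    stacklevel=2,
                )
                prof = np.ones(nbins)
            frac = prof / prof.sum()
            for z in range(nbins):
                rows.append((taxon, period, z, frac[z]))
    return pd.DataFrame(rows, columns=["taxon", "period", "depth_bin_top_m", "fraction"])


def upper_layer_mean(profile: pd.DataFrame, depth_m: float = 30.0) -> float:
    """Mean temperature over the upper ``depth_m`` of a 1-m binned profile."""
    upper = profile[profile["depth_m"] < depth_m]
    if upper.empty:
        raise ValueError("profile has no bins above the cutoff depth")
    return float(upper["temp_C"].mean())


def _haversine_km(lon1, lat1, lon2, lat2) -> float:
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def prep_temperature(
    temps: pd.DataFrame,
    stations: pd.DataFrame,
    max_depth_m: int = 100,
    depth_similarity: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model-ready temperatures: upper-30-m means and 1-m bin vectors.

    ``temps`` has columns (station_id, depth_m, temp_C); ``stations`` has
    (station_id, lon, lat, bottom_depth). Gaps within a profile are
    linearly interpolated over depth. A station with no profile at all is
    filled from the nearest station (great-circle distance) whose bottom
    depth differs by no more than ``depth_similarity`` (fractional); if no
    donor qualifies the station is dropped with a warning.

    Returns (summary, bins): summary has (station_id, upper30_mean_C);
    bins has (station_id, depth_m, temp_C) on 1-m bins truncated at
    min(bottom depth, ``max_depth_m``).
    """
    st = stations.set_index("station_id")
    have = set(temps["station_id"].unique())
    summary_rows, bin_frames = [], []
    for sid in st.index:
        bottom = float(st.loc[sid, "bottom_depth"])
        zmax = int(min(bottom, max_depth_m))
        donor = sid
        if sid not in have:
            cands = []
            for other in have:
                if other not in st.index:
                    continue
                ob = float(st.loc[other, "bottom_depth"])
                if abs(ob - bottom) <= depth_similarity * bottom:
                    d = _haversine_km(
                        st.loc[sid, "lon"], st.loc[sid, "lat"],
                        st.loc[other, "lon"], st.loc[other, "lat"],
                    )
                    cands.append((d, other))
            if not cands:
                warnings.warn(
                    f"station {sid}: no temperature profile and no donor; excluded",
                    stacklevel=2,
                )
                continue
            donor = min(cands)[1]
        prof = temps[temps["station_id"] == donor].sort_values("depth_m")
        z = np.arange(zmax, dtype=float)
        t = np.interp(z, prof["depth_m"].to_numpy(float), prof["temp_C"].to_numpy(float))
        frame = pd.DataFrame({"station_id": sid, "depth_m": z.astype(int), "temp_C": t})
        bin_frames.append(frame)
        summary_rows.append({"station_id": sid, "upper30_mean_C": upper_layer_mean(frame)})
    summary = pd.DataFrame(summary_rows, columns=["station_id", "upper30_mean_C"])
    bins = (
        pd.concat(bin_frames, ignore_index=True)
        if bin_frames
        else pd.DataFrame(columns=["station_id", "depth_m", "temp_C"])
    )
    return summary, bins


def fish_energy_summary_table(fish_obs: pd.DataFrame) -> tuple[float, dict[str, float]]:
    """Regime-mean fish ED from an aggregated trawl table.

    Expects columns (station_id, tow_type, n_caught, trawl_distance_m,
    trawl_spread_m, n_processed, mean_fish_ed_kj_g, mean_weight_g).
    Station mean EDs are weighted by CPUE times fish processed.
    """
    sub = fish_obs[(fish_obs["tow_type"] == "surface") & (fish_obs["n_processed"] > 0)]
    sub = sub.dropna(subset=["mean_fish_ed_kj_g"])
    if sub.empty:
        raise ValueError("no processed fish in any surface tow")
    cpue = sub["n_caught"] / (sub["trawl_distance_m"] * sub["trawl_spread_m"])
    wts = cpue * sub["n_processed"]
    if wts.sum() == 0:
        raise ValueError("no processed fish with positive CPUE")
    vbar = float((wts * sub["mean_fish_ed_kj_g"]).sum() / wts.sum())
    stats = {
        "mean_weight_g": float((wts * sub["mean_weight_g"]).sum() / wts.sum()),
        "n_stations": float(len(sub)),
    }
    return vbar, stats


def fish_energy_summary(
    observations: list[FishObservation],
) -> tuple[float, dict[str, float]]:
    """Regime-mean fish energy density and weight statistics.

    Station mean fish EDs are weighted by CPUE times the number of fish
    processed at the station. Returns (mean fish ED in kJ/g, stats dict
    with mean/sd of individual weights).
    """
    num = den = 0.0
    weights: list[float] = []
    for obs in observations:
        weights.extend(obs.weights_g)
        if not obs.fish_ed or obs.tow_type != "surface":
            continue
        w = compute_cpue(obs) * len(obs.fish_ed)
        num += w * float(np.mean(obs.fish_ed))
        den += w
    if den == 0:
        raise ValueError("no processed fish with positive CPUE")
    stats = {
        "mean_weight_g": float(np.mean(weights)) if weights else math.nan,
        "sd_weight_g": float(np.std(weights, ddof=1)) if len(weights) > 1 else math.nan,
        "n_fish": float(len(weights)),
    }
    return num / den, stats
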