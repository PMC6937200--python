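"""Synthetic pelagic-survey generator with a truth manifest.

The generator emulates the structure of a summer ecosystem trawl survey:
stations scattered over five sub-areas around Iceland across several years,
each with position, date-time, 0-50 m mean temperature and salinity, bottom
depth, zooplankton dry-weight biomass and total catch; roughly ten stomachs
per station; per-stomach prey compositions drawn from a Dirichlet
distribution around an area (x year) base composition over the ten analysis
prey groups; empty stomachs at a configurable Bernoulli rate; and a known
covariate model for log stomach (content) weight so that every downstream
statistic has a recomputable expected value.

Counts are derived from weights through a mean individual prey mass per
group (a copepod weighs a fraction of a milligram, a prey fish several
grams), which makes numerical and gravimetric composition diverge in the
realistic way: copepods dominate counts far more than weight.

One seed governs everything; each station draws from its own child stream
keyed by (seed, year, area, station index), so a dataset is byte-identical
across runs and stable under station reordering.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .data_model import (
    AREAS,
    PREY_GROUPS,
    PreyItem,
    StationRecord,
    StomachRecord,
    write_station_table,
    write_stomach_table,
)
from .errors import ConfigurationError, ValidationError

#: Default base compositions per area (weight fractions over PREY_GROUPS).
#: Illustrative, not fitted: copepod-dominated everywhere, euphausiids
#: elevated in the east/south-east, large crustaceans in the north.
DEFAULT_BASE_COMPOSITION: dict[str, tuple[float, ...]] = {
    "N": (0.02, 0.55, 0.06, 0.08, 0.17, 0.02, 0.04, 0.02, 0.02, 0.02),
    "E": (0.02, 0.50, 0.07, 0.22, 0.05, 0.03, 0.05, 0.02, 0.02, 0.02),
    "SE": (0.02, 0.52, 0.08, 0.20, 0.05, 0.03, 0.04, 0.02, 0.02, 0.02),
    "SW": (0.03, 0.65, 0.08, 0.08, 0.04, 0.02, 0.04, 0.02, 0.02, 0.02),
    "W": (0.03, 0.63, 0.09, 0.09, 0.04, 0.02, 0.04, 0.02, 0.02, 0.02),
}

#: Mild year-to-year multiplier on the large-crustacean share (renormalized),
#: giving the composition a real year signal by default.
DEFAULT_YEAR_EFFECT: dict[int, float] = {2011: 1.6, 2012: 1.2, 2013: 0.7, 2014: 0.5}

#: Mean individual wet mass (g) per prey group, used to convert weights to counts.
MEAN_INDIVIDUAL_MASS: dict[str, float] = {
    "molluscs": 0.01,
    "copepods": 0.0003,
    "amphipods": 0.02,
    "euphausiids": 0.05,
    "large_crustaceans": 0.3,
    "small_crustaceans": 0.005,
    "fish": 5.0,
    "appendicularians": 0.001,
    "chaetognaths": 0.01,
    "ova": 0.0002,
}

REPRESENTATIVE_TAXON: dict[str, str] = {
    "molluscs": "Limacina helicina",
    "copepods": "Calanus finmarchicus",
    "amphipods": "Themisto abyssorum",
    "euphausiids": "Thysanoessa inermis",
    "large_crustaceans": "Decapoda megalopa",
    "small_crustaceans": "Evadne spp.",
    "fish": "Ammodytes spp.",
    "appendicularians": "Oikopleura spp.",
    "chaetognaths": "Sagitta spp.",
    "ova": "Actinopteri ova",
}

# Sampling boxes (lon_lo, lon_hi, lat_lo, lat_hi) inset inside the default
# area rectangles so generated stations always classify into their area.
_AREA_BOXES = {
    "N": (-27.0, -8.0, 66.3, 69.0),
    "E": (-14.5, -8.0, 62.5, 65.7),
    "SE": (-18.7, -15.3, 62.3, 63.7),
    "SW": (-24.7, -19.3, 62.3, 63.7),
    "W": (-28.0, -20.0, 64.3, 65.7),
}

# Mean 0-50 m temperature by area (deg C): Atlantic water south/west, colder
# mixed water north/east.
_AREA_SST = {"N": 7.5, "E": 8.0, "SE": 10.0, "SW": 11.0, "W": 9.5}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic survey."""

    seed: int = 0
    years: tuple[int, ...] = (2011, 2012, 2013, 2014)
    areas: tuple[str, ...] = AREAS
    n_stations: int = 3  # per area x year
    stomachs_per_station: int = 10
    vacuity: float = 0.083  # Bernoulli probability of an empty stomach
    concentration: float = 50.0  # Dirichlet concentration around the base
    base_composition: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COMPOSITION)
    )
    year_effect_large_crustaceans: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_YEAR_EFFECT)
    )
    # stomach content weight (g): lognormal baseline modulated by covariates
    content_mu: float = math.log(2.0)
    content_sigma: float = 0.0  # extra lognormal spread beyond sigma_e
    # covariate model for log content weight
    sst_effect_kind: str = "sine"  # sine | quadratic | none
    sst_effect_amplitude: float = 0.25
    zoopl_effect: float = 0.0  # slope on standardized log zooplankton biomass
    period4_offset: float = -0.065
    sigma_e: float = 0.3
    # environment
    sst_spread: float = 1.5
    sss_range: tuple[float, float] = (33.0, 35.5)
    depth_range: tuple[float, float] = (80.0, 1500.0)
    zoopl_mu: float = math.log(80.0)
    zoopl_sigma: float = 0.6
    catch_mu: float = math.log(1500.0)
    catch_sigma: float = 0.8
    count_jitter_sigma: float = 0.2
    # prey items below this share of the content weight go unrecorded, giving
    # the realistic spread of frequency-of-occurrence across groups
    detection_threshold: float = 0.01
    include_tissue: bool = False  # add organ tissue weight to stomach_weight

    def __post_init__(self) -> None:
        if not 0 <= self.vacuity < 1:
            raise ValidationError(f"vacuity must be in [0, 1), got {self.vacuity}")
        if self.concentration <= 0 or self.sigma_e < 0:
            raise ValidationError("scale parameters must be positive")
        for area, vec in self.base_composition.items():
            v = np.asarray(vec, dtype=float)
            if len(v) != len(PREY_GROUPS) or (v < 0).any():
                raise ValidationError(f"bad composition vector for area {area}")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"composition for area {area} sums to {v.sum()}, not 1"
                )

    def base_for(self, area: str, year: int) -> np.ndarray:
        vec = np.asarray(self.base_composition[area], dtype=float).copy()
        mult = self.year_effect_large_crustaceans.get(year, 1.0)
        i = PREY_GROUPS.index("large_crustaceans")
        vec[i] *= mult
        return vec / vec.sum()

    def sst_effect(self, sst: float) -> float:
        if self.sst_effect_kind == "none" or self.sst_effect_amplitude == 0:
            return 0.0
        if self.sst_effect_kind == "sine":
            # half-sine hump over the realistic 6-13 deg C range
            return self.sst_effect_amplitude * math.sin(
                math.pi * (sst - 6.0) / 7.0
            )
        if self.sst_effect_kind == "quadratic":
            return -self.sst_effect_amplitude * ((sst - 9.5) / 3.5) ** 2
        raise ConfigurationError(f"unknown sst_effect_kind {self.sst_effect_kind!r}")


@dataclass
class TruthManifest:
    """Everything needed to recompute expected values of downstream statistics."""

    config: dict
    station_truth: dict[str, dict]  # per station: area, year, base composition, sst
    covariate_model: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "station_truth": self.station_truth,
                "covariate_model": self.covariate_model,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SurveyDataset:
    stomachs: list[StomachRecord]
    stations: list[StationRecord]
    manifest: TruthManifest

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "stomachs": out / "stomachs.csv",
            "stations": out / "stations.csv",
            "truth": out / "truth.json",
        }
        write_stomach_table(self.stomachs, paths["stomachs"])
        write_station_table(self.stations, paths["stations"])
        paths["truth"].write_text(self.manifest.to_json(), encoding="utf-8")
        return paths


def _config_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["base_composition"] = {k: list(v) for k, v in d["base_composition"].items()}
    d["year_effect_large_crustaceans"] = {
        str(k): v for k, v in d["year_effect_large_crustaceans"].items()
    }
    return d


def generate(config: GeneratorConfig) -> SurveyDataset:
    """Generate one survey: stomach records, station records and the truth."""
    zoopl_mean_log = config.zoopl_mu  # standardization reference for the effect
    stations: list[StationRecord] = []
    stomachs: list[StomachRecord] = []
    station_truth: dict[str, dict] = {}

    for year in config.years:
        for a_idx, area in enumerate(config.areas):
            for k in range(config.n_stations):
                rng = np.random.default_rng([config.seed, year, a_idx, k])
                sid = f"S{year}-{area}-{k + 1:02d}"
                lon_lo, lon_hi, lat_lo, lat_hi = _AREA_BOXES[area]
                lon = float(rng.uniform(lon_lo, lon_hi))
                lat = float(rng.uniform(lat_lo, lat_hi))
                day = int(rng.integers(0, 45))  # July 1 + up to ~6 weeks
                hour = int(rng.integers(0, 24))
                minute = int(rng.integers(0, 60))
                dt = datetime(year, 7, 1) + timedelta(
                    days=day, hours=hour, minutes=minute
                )
                sst = float(
                    rng.uniform(-config.sst_spread, config.sst_spread)
                    + _AREA_SST[area]
                )
                sss = float(rng.uniform(*config.sss_range))
                depth = float(rng.uniform(*config.depth_range))
                zoopl = float(rng.lognormal(config.zoopl_mu, config.zoopl_sigma))
                catch = float(rng.lognormal(config.catch_mu, config.catch_sigma))
                station = StationRecord(
                    station_id=sid,
                    longitude=round(lon, 4),
                    latitude=round(lat, 4),
                    datetime=dt,
                    year=year,
                    week_number=dt.isocalendar().week,
                    bottom_depth=round(depth, 1),
                    sst_0_50=round(sst, 3),
                    sss_0_50=round(sss, 3),
                    zooplankton_biomass=round(zoopl, 3),
                    total_catch=round(catch, 1),
                ).with_derived_labels()
                stations.append(station)
                base = config.base_for(area, year)
                station_truth[sid] = {
                    "area": area,
                    "year": year,
                    "base_composition": [float(x) for x in base],
                    "sst": station.sst_0_50,
                    "expected_log_content": _truth_mean(
                        config, station, zoopl_mean_log
                    ),
                }
                stomachs.extend(
                    _station_stomachs(config, rng, station, base, zoopl_mean_log)
                )

    manifest = TruthManifest(
        config=_config_dict(config),
        station_truth=station_truth,
        covariate_model={
            "response": "log(stomach content weight, g)",
            "intercept": config.content_mu,
            "sst_effect_kind": config.sst_effect_kind,
            "sst_effect_amplitude": config.sst_effect_amplitude,
            "zoopl_effect": config.zoopl_effect,
            "period4_offset": config.period4_offset,
            "sigma_e": config.sigma_e,
        },
    )
    return SurveyDataset(stomachs=stomachs, stations=stations, manifest=manifest)


def _truth_mean(config, station: StationRecord, zoopl_mean_log: float) -> float:
    mu = config.content_mu + config.sst_effect(station.sst_0_50)
    if config.zoopl_effect:
        mu += config.zoopl_effect * (
            (math.log(station.zooplankton_biomass) - zoopl_mean_log)
            / max(config.zoopl_sigma, 1e-12)
        )
    if station.time_period == "P4":
        mu += config.period4_offset
    return mu


def _station_stomachs(config, rng, station, base, zoopl_mean_log):
    out = []
    mu = _truth_mean(config, station, zoopl_mean_log)
    for j in range(config.stomachs_per_station):
        fid = f"{station.station_id}-F{j + 1:02d}"
        length = float(np.clip(np.round(rng.normal(36.0, 3.5)), 26, 47))
        k_cond = rng.normal(0.85, 0.05)
        body_w = round(float(max(k_cond, 0.6) * length**3 / 100.0), 1)
        tissue = 0.012 * body_w
        empty = bool(rng.random() < config.vacuity)
        items: list[PreyItem] = []
        if empty:
            content = 0.0
        else:
            noise = rng.normal(0.0, config.sigma_e) + (
                rng.normal(0.0, config.content_sigma) if config.content_sigma else 0.0
            )
            content = float(math.exp(mu + noise))
            shares = rng.dirichlet(config.concentration * base)
            for g_idx, group in enumerate(PREY_GROUPS):
                if shares[g_idx] < config.detection_threshold:
                    continue  # unrecorded trace item
                w = content * float(shares[g_idx])
                if w < 1e-6:
                    continue
                mass = MEAN_INDIVIDUAL_MASS[group] * float(
                    math.exp(rng.normal(0.0, config.count_jitter_sigma))
                )
                items.append(
                    PreyItem(
                        taxon_name=REPRESENTATIVE_TAXON[group],
                        prey_group=group,
                        count=round(w / mass, 3),
                        weight=round(w, 6),
                    )
                )
        stomach_w = content + (tissue if config.include_tissue else 0.0)
        if empty and not config.include_tissue:
            stomach_w = 0.0
        out.append(
            StomachRecord(
                fish_id=fid,
                station_id=station.station_id,
                length=length,
                body_weight=body_w,
                stomach_weight=round(stomach_w, 6),
                items=tuple(items),
            )
        )
    return out


def make_null_dataset(config: GeneratorConfig, factor: str) -> SurveyDataset:
    """Generate a dataset in which the named factor truly has no effect.

    ``factor`` is one of area, year, length_group, sst, zooplankton,
    time_period.  Compositions (or covariate effects) are equalized across
    that factor's levels; everything else follows the configuration.
    """
    cfg = dataclasses.replace(config)
    if factor == "area":
        mean_vec = np.mean(
            [np.asarray(v, float) for v in cfg.base_composition.values()], axis=0
        )
        mean_vec = mean_vec / mean_vec.sum()
        cfg.base_composition = {a: tuple(mean_vec) for a in cfg.base_composition}
    elif factor == "year":
        cfg.year_effect_large_crustaceans = {}
    elif factor == "length_group":
        pass  # compositions never depend on predator length in this generator
    elif factor == "sst":
        cfg.sst_effect_amplitude = 0.0
    elif factor == "zooplankton":
        cfg.zoopl_effect = 0.0
    elif factor == "time_period":
        cfg.period4_offset = 0.0
    else:
        raise ConfigurationError(
            f"unknown factor {factor!r}; expected area, year, length_group, "
            "sst, zooplankton or time_period"
        )
    return generate(cfg)


def recovery_report(
    dataset: SurveyDataset,
    manifest: TruthManifest | None = None,
    *,
    fit_covariate_model: bool = False,
) -> "pd.DataFrame":
    """Compare estimated quantities against the generator's truth.

    Rows: realized vacuity vs configured rate; per-area gravimetric
    composition of the dominant groups vs the Dirichlet-mean truth; and
    optionally the time-period-4 coefficient of the covariate model.
    Absolute errors are reported alongside.
    """
    import pandas as pd

    from .data_model import build_diet_matrix
    from .diet_indices import composition, vacuity_index

    manifest = manifest or dataset.manifest
    if {s.station_id for s in dataset.stations} != set(manifest.station_truth):
        raise ValidationError("manifest does not describe this dataset's stations")
    cfg = manifest.config
    rows = []

    n_empty = sum(1 for s in dataset.stomachs if s.is_empty)
    vi = vacuity_index(n_empty, len(dataset.stomachs))
    rows.append(
        {
            "quantity": "vacuity_index_percent",
            "stratum": "all",
            "estimate": vi,
            "truth": 100.0 * cfg["vacuity"],
            "abs_error": abs(vi - 100.0 * cfg["vacuity"]),
        }
    )

    matrix = build_diet_matrix(dataset.stomachs, dataset.stations)
    for area in sorted({v["area"] for v in manifest.station_truth.values()}):
        sub = matrix.subset(matrix.labels["area"] == area)
        est = composition(sub, "weight")
        # truth: station-weighted mean of per-station base compositions
        bases = [
            np.asarray(v["base_composition"], float)
            for v in manifest.station_truth.values()
            if v["area"] == area
        ]
        truth_vec = 100.0 * np.mean(bases, axis=0)
        for g_idx, group in enumerate(PREY_GROUPS):
            if truth_vec[g_idx] < 1.0:
                continue  # report only non-trivial groups
            rows.append(
                {
                    "quantity": f"percent_W[{group}]",
                    "stratum": area,
                    "estimate": float(est[group]),
                    "truth": float(truth_vec[g_idx]),
                    "abs_error": abs(float(est[group]) - float(truth_vec[g_idx])),
                }
            )

    if fit_covariate_model:
        from .stomach_weight_model import ModelSpec, prepare_model_frame, fit_additive_model

        tab = prepare_model_frame(dataset.stomachs, dataset.stations)
        smooths = []
        if cfg["sst_effect_amplitude"]:
            smooths.append("sst_0_50")
        if cfg["zoopl_effect"]:
            smooths.append("zooplankton_biomass")
        spec = ModelSpec(smooth_terms=tuple(smooths), factor_terms=("time_period",))
        fit = fit_additive_model(spec, tab)
        par = fit.parametric_table().set_index("term")
        est = float(par.loc["time_period[P4]", "estimate"])
        rows.append(
            {
                "quantity": "period4_offset",
                "stratum": "all",
                "estimate": est,
                "truth": cfg["period4_offset"],
                "abs_error": abs(est - cfg["period4_offset"]),
            }
        )
    return pd.DataFrame(rows)
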