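"""Additive modelling of log stomach weight and AIC-based model selection.

The response is the log of the recorded stomach weight (the organ weighed
with its content, as collected at sea).  Candidate terms are the station and
fish covariates of the survey: smooth effects of zooplankton biomass, a
joint longitude-latitude surface, bottom depth, 0-50 m salinity and
temperature, log total catch and Fulton's condition factor, plus the
categorical time-period, distance-to-shore, week and year factors.  All
candidates share the Gaussian family with identity link and REML smoothing
selection; they are ranked by AIC, Akaike weight
``w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)``, and the 95% confidence set
(the smallest weight-ordered subset with cumulative weight >= 0.95).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .gam import GamFit, SmoothTerm, TensorSmooth, fit_gaussian_gam

#: Admissible smooth terms; "lonlat" is the single joint geographic surface.
SMOOTH_POOL = (
    "zooplankton_biomass",
    "lonlat",
    "bottom_depth",
    "sss_0_50",
    "sst_0_50",
    "log_total_catch",
    "fulton_k",
)

FACTOR_POOL = ("time_period", "distance_to_shore_class", "week", "year")

RESPONSE = "log_stomach_weight"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a set of smooth terms and a set of factors.

    The response is fixed (log stomach weight, Gaussian, identity link); the
    spline basis dimension is k per 1-D term and k2 per margin of the
    geographic surface.
    """

    smooth_terms: tuple[str, ...] = ()
    factor_terms: tuple[str, ...] = ()
    k: int = 10
    k2: int = 5

    def __post_init__(self) -> None:
        bad = set(self.smooth_terms) - set(SMOOTH_POOL)
        if bad:
            raise ConfigurationError(f"unknown smooth term(s): {sorted(bad)}")
        bad = set(self.factor_terms) - set(FACTOR_POOL)
        if bad:
            raise ConfigurationError(f"unknown factor term(s): {sorted(bad)}")

    def formula(self) -> str:
        parts = []
        for t in self.smooth_terms:
            parts.append("s(longitude,latitude)" if t == "lonlat" else f"s({t})")
        parts.extend(self.factor_terms)
        rhs = " + ".join(parts) if parts else "1"
        return f"{RESPONSE} ~ {rhs}"

    def build_smooths(self) -> list:
        out = []
        for t in self.smooth_terms:
            if t == "lonlat":
                out.append(TensorSmooth("longitude", "latitude", k=self.k2))
            else:
                out.append(SmoothTerm(t, k=self.k))
        return out


def check_collinearity(data: pd.DataFrame, variables: list[str], threshold: float = 0.95) -> pd.DataFrame:
    """Report absolute pairwise correlations above the threshold.

    Run before modelling; strongly collinear covariates make individual
    smooth effects unidentifiable even when the penalized fit is computable.
    """
    num = data[variables].select_dtypes("number")
    corr = num.corr().abs()
    rows = []
    for a, b in itertools.combinations(corr.columns, 2):
        if corr.loc[a, b] >= threshold:
            rows.append({"var_a": a, "var_b": b, "abs_correlation": corr.loc[a, b]})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "abs_correlation"])


def fit_additive_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    assume_filtered: bool = False,
    log_lambda: dict[str, float] | None = None,
) -> GamFit:
    """Fit one candidate model to the filtered modelling table.

    Refuses unfiltered data: the modelling protocol removes fish under 25 cm
    and stations with fewer than ten stomachs before any fit (see
    ``data_model.apply_model_filters``).  Tables produced by
    ``prepare_model_frame`` carry the filter marker automatically; pass
    ``assume_filtered=True`` only for data known to be pre-filtered.
    """
    if not assume_filtered and not data.attrs.get("model_filters_applied", False):
        raise ValidationError(
            "data has not passed the modelling filters; run "
            "data_model.apply_model_filters / prepare_model_frame first, or pass "
            "assume_filtered=True for externally filtered tables"
        )
    missing = [c for c in (RESPONSE,) if c not in data.columns]
    if missing:
        raise ConfigurationError(f"missing column(s): {missing}")
    # factors must be strings for stable reference-level ordering
    work = data.copy()
    for f in spec.factor_terms:
        work[f] = work[f].astype(str)
    return fit_gaussian_gam(
        work[RESPONSE],
        work,
        smooths=spec.build_smooths(),
        factors=list(spec.factor_terms),
        log_lambda=log_lambda,
    )


def prepare_model_frame(stomachs, stations, **filter_kwargs) -> pd.DataFrame:
    """Filter records and join covariates into the modelling table."""
    from .data_model import apply_model_filters, modelling_table

    kept, kept_st, report = apply_model_filters(stomachs, stations, **filter_kwargs)
    tab = modelling_table(kept, kept_st)
    tab.attrs["model_filters_applied"] = True
    tab.attrs["filter_report"] = report
    return tab


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def akaike_table(
    aics=None, deltas=None, labels=None, level: float = 0.95
) -> pd.DataFrame:
    """Rank candidates by AIC: delta AIC, Akaike weights, 95% confidence set.

    Provide either raw AICs or a delta-AIC column directly (reported
    selection tables often print only deltas; weights depend on nothing
    else).  Weights are ``exp(-delta/2)`` normalized to sum to one.
    """
    if (aics is None) == (deltas is None):
        raise ValidationError("provide exactly one of aics or deltas")
    if aics is not None:
        arr = np.asarray(list(aics), dtype=float)
        if arr.size == 0:
            raise ValidationError("empty candidate list")
        deltas = arr - arr.min()
    else:
        deltas = np.asarray(list(deltas), dtype=float)
        if deltas.size == 0:
            raise ValidationError("empty candidate list")
        deltas = deltas - deltas.min()  # tolerate unanchored deltas
        arr = None
    rel = np.exp(-deltas / 2.0)
    w = rel / rel.sum()
    tab = pd.DataFrame(
        {
            "model": labels if labels is not None else list(range(len(deltas))),
            "AIC": arr if arr is not None else np.nan,
            "delta_AIC": deltas,
            "weight": w,
        }
    )
    tab["in_confidence_set"] = confidence_set(w, level=level)
    return tab


def confidence_set(weights, level: float = 0.95) -> np.ndarray:
    """Flags for the smallest weight-ordered subset with cumulative weight >= level."""
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        raise ValidationError("empty weight list")
    if not 0 < level <= 1:
        raise ValidationError(f"level must be in (0, 1], got {level}")
    order = np.argsort(-w, kind="stable")
    csum = np.cumsum(w[order])
    cutoff = int(np.searchsorted(csum, level - 1e-12)) + 1
    flags = np.zeros(w.size, dtype=bool)
    flags[order[:cutoff]] = True
    return flags


@dataclass
class ModelRanking:
    """Exhaustively enumerated candidates with their AIC ranking."""

    table: pd.DataFrame  # formula, AIC, delta_AIC, weight, dev_expl, r2_adj, edf, flag
    specs: list[ModelSpec]
    fits: list[GamFit] | None = None

    @property
    def best(self) -> ModelSpec:
        return self.specs[int(self.table["delta_AIC"].idxmin())]


def candidate_search(
    data: pd.DataFrame,
    smooth_pool: tuple[str, ...] = (),
    factor_pool: tuple[str, ...] = (),
    *,
    always_factors: tuple[str, ...] = (),
    max_candidates: int = 256,
    level: float = 0.95,
    keep_fits: bool = False,
    assume_filtered: bool = False,
    k: int = 10,
    k2: int = 5,
) -> ModelRanking:
    """Fit every subset of the term pool and rank by AIC.

    The joint geographic surface counts as a single term ("lonlat").  The
    intercept-only model is always included.  Enumeration order (and hence
    row order at equal AIC) is reproducible: subsets are generated in
    increasing size, pools in the order given.
    """
    terms = [("s", t) for t in smooth_pool] + [("f", t) for t in factor_pool]
    n_cand = 2 ** len(terms)
    if n_cand > max_candidates:
        raise ConfigurationError(
            f"{n_cand} candidate models exceed the cap of {max_candidates}; "
            "reduce the term pool or raise max_candidates"
        )
    specs, rows, fits = [], [], []
    for size in range(len(terms) + 1):
        for combo in itertools.combinations(terms, size):
            sm = tuple(t for kind, t in combo if kind == "s")
            fc = tuple(t for kind, t in combo if kind == "f") + tuple(always_factors)
            spec = ModelSpec(smooth_terms=sm, factor_terms=fc, k=k, k2=k2)
            fit = fit_additive_model(spec, data, assume_filtered=assume_filtered)
            specs.append(spec)
            fits.append(fit)
            rows.append(
                {
                    "formula": spec.formula(),
                    "AIC": fit.aic,
                    "dev_expl": fit.deviance_explained,
                    "r2_adj": fit.r2_adj,
                    "edf": fit.edf_total,
                }
            )
    tab = pd.DataFrame(rows)
    tab["delta_AIC"] = tab["AIC"] - tab["AIC"].min()
    rel = np.exp(-tab["delta_AIC"] / 2.0)
    tab["weight"] = rel / rel.sum()
    tab["in_confidence_set"] = confidence_set(tab["weight"].to_numpy(), level=level)
    return ModelRanking(table=tab, specs=specs, fits=fits if keep_fits else None)
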