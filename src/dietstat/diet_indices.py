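"""Diet composition and feeding-strategy indices.

Implements the standard stomach-content summary statistics for a set of
stomachs pooled over some stratum (year, area, length group, or everything):

* vacuity index ``Vi`` — percent of stomachs that are empty;
* numerical and gravimetric composition ``%N`` / ``%W`` — share of total prey
  count / wet weight contributed by each prey group over all stomachs;
* frequency of occurrence ``FOi`` — percent of stomachs containing group *i*;
* prey-specific abundance ``PWi`` / ``PNi`` — share of group *i* by weight /
  count computed only over the stomachs that contain it;
* the prey-specific index of relative importance
  ``PSIRI = FOi * (PWi + PNi) / 2`` (all terms in percent, so the product is
  divided by 100), which sums to 100 over exhaustive, mutually exclusive
  groups;
* the Amundsen feeding-strategy coordinates ``(FOi, Pi)``, where ``Pi`` is
  the weight-based prey-specific abundance (identical to ``PWi``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DietMatrix
from .errors import NoDataError, ValidationError

QUADRANTS = (
    "dominant",
    "specialised",
    "rare/generalised",
    "high-FO/generalised",
)


def vacuity_index(n_empty: int, n_total: int) -> float:
    """Vi = 100 * Es / Ts: the percentage of empty stomachs."""
    if n_total <= 0:
        raise ValidationError("vacuity index undefined for zero stomachs")
    if not 0 <= n_empty <= n_total:
        raise ValidationError(
            f"empty count {n_empty} outside [0, {n_total}]"
        )
    return 100.0 * n_empty / n_total


def composition(matrix: DietMatrix, basis: str = "weight") -> pd.Series:
    """Percent composition over all stomachs: %W (basis='weight') or %N ('count').

    Group total divided by the grand total, times 100.  Excluded groups are
    never in the matrix, hence never in the denominator.
    """
    if basis not in ("weight", "count"):
        raise ValidationError(f"basis must be 'weight' or 'count', got {basis!r}")
    data = matrix.weight if basis == "weight" else matrix.count
    totals = data.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise NoDataError("all stomachs empty: percent composition undefined")
    return 100.0 * totals / grand


def frequency_of_occurrence(
    matrix: DietMatrix, *, include_empty: bool = True
) -> pd.Series:
    """FOi = percent of stomachs in which group *i* is present.

    By default the denominator is all stomachs, empty ones included (vacuity
    is reported separately); set ``include_empty=False`` to restrict the
    denominator to stomachs containing food.
    """
    present = (matrix.weight > 0) | (matrix.count > 0)
    if include_empty:
        denom = matrix.n_stomachs
    else:
        denom = int(present.any(axis=1).sum())
    if denom == 0:
        raise NoDataError("no stomachs in frequency-of-occurrence denominator")
    return 100.0 * present.sum(axis=0) / denom


def prey_specific_ratios(matrix: DietMatrix, method: str = "mean") -> pd.DataFrame:
    """PWi and PNi: abundance of group *i* within the stomachs that contain it.

    Two conventions exist and differ on heterogeneous stomachs:

    * ``method="mean"`` (default): the mean over stomachs containing *i* of
      the per-stomach proportion ``w_is / W_s``.  This is the canonical
      prey-specific abundance of the PSIRI index, and the form under which
      PSIRI sums to 100 over exhaustive, mutually exclusive groups.
    * ``method="pooled"``: the ratio of sums, summed weight of *i* divided by
      the summed total content of the stomachs containing *i* (a
      fullness-weighted mean of the same proportions).

    Groups never observed get NaN (absent, not zero).
    """
    if method not in ("mean", "pooled"):
        raise ValidationError(f"method must be 'mean' or 'pooled', got {method!r}")
    present = (matrix.weight > 0) | (matrix.count > 0)
    w_tot = matrix.weight.sum(axis=1)
    c_tot = matrix.count.sum(axis=1)
    out = {}
    for g in matrix.weight.columns:
        mask = present[g]
        if not mask.any():
            out[g] = (math.nan, math.nan)
            continue
        if method == "pooled":
            pw = 100.0 * matrix.weight.loc[mask, g].sum() / w_tot[mask].sum()
            denom_c = c_tot[mask].sum()
            pn = (
                100.0 * matrix.count.loc[mask, g].sum() / denom_c
                if denom_c > 0
                else math.nan
            )
        else:
            mw = mask & (w_tot > 0)
            mc = mask & (c_tot > 0)
            pw = (
                100.0 * (matrix.weight.loc[mw, g] / w_tot[mw]).mean()
                if mw.any()
                else math.nan
            )
            pn = (
                100.0 * (matrix.count.loc[mc, g] / c_tot[mc]).mean()
                if mc.any()
                else math.nan
            )
        out[g] = (pw, pn)
    return pd.DataFrame(out, index=["PW", "PN"]).T


def psiri(fo: float, pw: float, pn: float) -> float:
    """PSIRI = FO * (PW + PN) / 2, all in percent (product rescaled by 1/100)."""
    for name, v in (("FO", fo), ("PW", pw), ("PN", pn)):
        if not 0 <= v <= 100:
            raise ValidationError(f"{name} = {v} outside [0, 100]")
    return fo * (pw + pn) / 2.0 / 100.0


def prey_specific_abundance(matrix: DietMatrix, method: str = "mean") -> pd.Series:
    """Weight-based prey-specific abundance Pi (identical to PWi by definition)."""
    return prey_specific_ratios(matrix, method=method)["PW"]


@dataclass(frozen=True)
class StrategyPoint:
    """One prey group's position in the feeding-strategy diagram."""

    prey_group: str
    fo: float  # frequency of occurrence, %
    pi: float  # weight-based prey-specific abundance, %
    quadrant: str


def _quadrant(fo: float, pi: float) -> str:
    # Half-open convention: the 50% midlines belong to the upper/right side.
    high_fo = fo >= 50.0
    high_pi = pi >= 50.0
    if high_fo and high_pi:
        return "dominant"
    if high_pi:
        return "specialised"
    if high_fo:
        return "high-FO/generalised"
    return "rare/generalised"


def amundsen_plot(matrix: DietMatrix, method: str = "mean") -> list[StrategyPoint]:
    """Feeding-strategy coordinates (FOi, Pi) for every observed prey group.

    Quadrants relative to the 50/50 midlines: upper-right = dominant prey of
    a specialised population; upper-left = prey specialised on by a subset of
    individuals (between-phenotype niche component); lower regions = rare or
    generalist feeding (within-phenotype component).
    """
    fo = frequency_of_occurrence(matrix)
    pi = prey_specific_abundance(matrix, method=method)
    points = []
    for g in matrix.weight.columns:
        if math.isnan(pi[g]):
            continue  # never observed
        points.append(
            StrategyPoint(
                prey_group=g, fo=float(fo[g]), pi=float(pi[g]),
                quadrant=_quadrant(float(fo[g]), float(pi[g])),
            )
        )
    if not points:
        raise NoDataError("no prey group observed in any stomach")
    return points


def plot_amundsen(points: list[StrategyPoint], path=None):
    """Render the feeding-strategy scatter; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for p in points:
        ax.scatter(p.fo, p.pi, color="tab:blue")
        ax.annotate(p.prey_group, (p.fo, p.pi), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    ax.axhline(50, color="grey", lw=0.8, ls="--")
    ax.axvline(50, color="grey", lw=0.8, ls="--")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Frequency of occurrence FOi (%)")
    ax.set_ylabel("Prey-specific abundance Pi (%)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def index_table(matrix: DietMatrix, method: str = "mean") -> pd.DataFrame:
    """Full index table: one row per observed prey group.

    Columns: percent_N, percent_W, FO, PW, PN, PSIRI, n_stomachs_with_group;
    attrs carry n_stomachs_total and the vacuity index.  All indices are
    computed on the same stomach set, so the identity
    ``PSIRI = FO * (PW + PN) / 200`` holds row-wise to machine precision.
    """
    pn_pw = prey_specific_ratios(matrix, method=method)
    fo = frequency_of_occurrence(matrix)
    pct_n = composition(matrix, "count")
    pct_w = composition(matrix, "weight")
    present = ((matrix.weight > 0) | (matrix.count > 0)).sum(axis=0)

    tab = pd.DataFrame(
        {
            "percent_N": pct_n,
            "percent_W": pct_w,
            "FO": fo,
            "PW": pn_pw["PW"],
            "PN": pn_pw["PN"],
        }
    )
    tab = tab[~tab["PW"].isna()].copy()  # only observed groups, as reported
    tab["PSIRI"] = np.array(
        [psiri(r.FO, r.PW, r.PN) for r in tab.itertuples()]
    )
    tab["n_stomachs_with_group"] = present[tab.index]
    n_empty = int((matrix.weight.sum(axis=1) + matrix.count.sum(axis=1) == 0).sum())
    tab.attrs["n_stomachs_total"] = matrix.n_stomachs
    tab.attrs["vacuity_index"] = vacuity_index(n_empty, matrix.n_stomachs)
    return tab
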