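"""End-to-end orchestration: simulate/ingest -> filter -> indices -> strategy
-> clustering -> PERMANOVA -> stomach-weight model ranking.

Every run writes its configuration, a manifest (package version, seed, input
hashes) and one CSV/JSON artefact per analysis stage into the output
directory, so each table in the rendered report is reproducible from the
directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import (
    apply_model_filters,
    build_diet_matrix,
    read_station_table,
    read_stomach_table,
)
from .community_stats import (
    bray_curtis,
    fourth_root,
    permanova_pairwise,
    permanova_twoway,
    pool_matrix,
    to_newick,
    upgma,
)
from .diet_indices import amundsen_plot, index_table
from .errors import ConfigurationError, DietstatError
from .stomach_weight_model import candidate_search, prepare_model_frame
from .synthetic_data import GeneratorConfig, generate

log = logging.getLogger("dietstat")

ANALYSES = ("indices", "strategy", "cluster", "permanova", "gam")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    stomach_csv: str | None = None
    station_csv: str | None = None
    simulate: dict | None = None  # GeneratorConfig fields
    analyses: tuple[str, ...] = ANALYSES
    apply_filters: bool = True
    n_perm: int = 999
    seed: int | None = None
    alpha: float = 0.05
    gam_smooth_pool: tuple[str, ...] = ("sst_0_50", "zooplankton_biomass")
    gam_factor_pool: tuple[str, ...] = ("time_period",)

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ConfigurationError(f"unknown analyses: {sorted(unknown)}")
        needs_seed = self.simulate is not None or "permanova" in self.analyses
        if needs_seed and self.seed is None:
            raise ConfigurationError(
                "a seed is mandatory when simulating data or running "
                "permutation tests"
            )
        if self.simulate is None and (self.stomach_csv is None or self.station_csv is None):
            raise ConfigurationError(
                "provide stomach_csv and station_csv, or a simulate block"
            )


def significance_band(p: float, alpha: float = 0.05) -> str:
    """Conventional reporting bands for a raw p-value."""
    if pd.isna(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < alpha:
        return f"<{alpha:g}"
    if p <= 0.1:
        return "<=0.1"
    return ">0.1"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Any stage failure aborts with the stage name; artefacts already written
    are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str),
        encoding="utf-8",
    )
    stage = "input"
    try:
        if config.simulate is not None:
            gen_cfg = GeneratorConfig(
                **{**config.simulate, "seed": config.simulate.get("seed", config.seed)}
            )
            dataset = generate(gen_cfg)
            paths = dataset.write(out / "simulated")
            stomach_csv, station_csv = paths["stomachs"], paths["stations"]
        else:
            stomach_csv = Path(config.stomach_csv)
            station_csv = Path(config.station_csv)
        stomachs = read_stomach_table(stomach_csv)
        stations = read_station_table(station_csv)
        log.info("input: %d stomachs, %d stations", len(stomachs), len(stations))

        if config.apply_filters:
            stage = "filter"
            stomachs_f, stations_f, report = apply_model_filters(stomachs, stations)
            (out / "filter_report.json").write_text(report.to_json(), encoding="utf-8")
            log.info(
                "filters: %d -> %d stomachs (%d small fish, %d at sparse stations)",
                report.n_fish_in,
                report.n_fish_out,
                report.n_fish_removed_small,
                report.n_fish_removed_with_station,
            )
        else:
            stomachs_f, stations_f = stomachs, stations

        stage = "diet matrix"
        matrix = build_diet_matrix(stomachs_f, stations_f)

        if "indices" in config.analyses:
            stage = "indices"
            tab = index_table(matrix)
            tab.round(1).to_csv(out / "index_table.csv")
            (out / "vacuity.json").write_text(
                json.dumps(
                    {
                        "vacuity_index_percent": tab.attrs["vacuity_index"],
                        "n_stomachs": tab.attrs["n_stomachs_total"],
                    },
                    indent=2,
                ),
                encoding="utf-8",
            )

        if "strategy" in config.analyses:
            stage = "strategy"
            points = amundsen_plot(matrix)
            pd.DataFrame(
                [
                    {"prey_group": p.prey_group, "FO": p.fo, "Pi": p.pi,
                     "quadrant": p.quadrant}
                    for p in points
                ]
            ).round(2).to_csv(out / "strategy_points.csv", index=False)

        if "cluster" in config.analyses:
            stage = "cluster"
            pooled = pool_matrix(matrix, "area")
            D = bray_curtis(fourth_root(pooled))
            tree = upgma(D)
            (out / "dendrogram.nwk").write_text(to_newick(tree), encoding="utf-8")
            pd.DataFrame(
                {
                    "merge": range(1, len(tree.merges) + 1),
                    "height": tree.merges[:, 2],
                    "similarity_percent": tree.similarity_percent(),
                }
            ).to_csv(out / "cluster_similarity.csv", index=False)

        if "permanova" in config.analyses:
            stage = "permanova"
            D = bray_curtis(fourth_root(matrix.weight))
            res = permanova_twoway(
                D,
                matrix.labels["area"].to_numpy(),
                matrix.labels["year"].to_numpy(),
                n_perm=config.n_perm,
                seed=config.seed,
                names=("Area", "Year"),
            )
            (out / "permanova_twoway.json").write_text(res.to_json(), encoding="utf-8")
            tab = res.table.copy()
            tab["band"] = [significance_band(p, config.alpha) for p in tab["p"]]
            tab.to_csv(out / "permanova_twoway.csv", index=False)
            pw = permanova_pairwise(
                D,
                matrix.labels["area"].to_numpy(),
                n_perm=config.n_perm,
                seed=config.seed,
            )
            pw["band"] = [significance_band(p, config.alpha) for p in pw["p"]]
            pw.to_csv(out / "permanova_pairwise_area.csv", index=False)

        if "gam" in config.analyses:
            stage = "gam"
            tab = prepare_model_frame(stomachs, stations)
            ranking = candidate_search(
                tab,
                smooth_pool=config.gam_smooth_pool,
                factor_pool=config.gam_factor_pool,
                keep_fits=True,
            )
            ranking.table.to_csv(out / "model_ranking.csv", index=False)
            best_i = int(ranking.table["delta_AIC"].idxmin())
            best_fit = ranking.fits[best_i]
            best_fit.parametric_table().to_csv(
                out / "best_model_parametric.csv", index=False
            )
            best_fit.smooth_table().to_csv(out / "best_model_smooths.csv", index=False)
            for sm in best_fit.smooths:
                if len(sm.variables) == 1:
                    best_fit.smooth_curve(sm.label).to_csv(
                        out / f"best_model_curve_{sm.variables[0]}.csv", index=False
                    )

        stage = "manifest"
        manifest = {
            "dietstat_version": __version__,
            "seed": config.seed,
            "analyses": list(config.analyses),
            "n_permutations": config.n_perm,
            "inputs": {
                "stomachs": {"path": str(stomach_csv), "sha256": _sha256(Path(stomach_csv))},
                "stations": {"path": str(station_csv), "sha256": _sha256(Path(station_csv))},
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
    except DietstatError as exc:
        raise DietstatError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def render_reports(out_dir) -> str:
    """Assemble the human-readable summary from pipeline artefacts.

    Sections missing their upstream file are marked "not run".  Regeneration
    is idempotent: the text depends only on files in the directory.
    """
    out = Path(out_dir)
    lines = ["# Diet analysis summary", ""]

    def section(title: str, filename: str, render) -> None:
        lines.append(f"## {title}")
        path = out / filename
        if not path.exists():
            lines.append("(not run)")
        else:
            render(path)
        lines.append("")

    def _indices(path):
        tab = pd.read_csv(path, index_col=0)
        lines.append(tab.to_string())
        vac = out / "vacuity.json"
        if vac.exists():
            meta = json.loads(vac.read_text())
            lines.append(
                f"vacuity index: {meta['vacuity_index_percent']:.1f}% of "
                f"{meta['n_stomachs']} stomachs empty"
            )

    def _strategy(path):
        lines.append(pd.read_csv(path).to_string(index=False))

    def _cluster(path):
        lines.append(pd.read_csv(path).to_string(index=False))
        nwk = out / "dendrogram.nwk"
        if nwk.exists():
            lines.append(f"newick: {nwk.read_text().strip()}")

    def _permanova(path):
        lines.append(pd.read_csv(path).to_string(index=False))
        pw = out / "permanova_pairwise_area.csv"
        if pw.exists():
            lines.append("pairwise (areas):")
            lines.append(pd.read_csv(pw).to_string(index=False))

    def _gam(path):
        lines.append(pd.read_csv(path).to_string(index=False))

    section("Diet index table", "index_table.csv", _indices)
    section("Feeding strategy", "strategy_points.csv", _strategy)
    section("Area clustering", "cluster_similarity.csv", _cluster)
    section("PERMANOVA", "permanova_twoway.csv", _permanova)
    section("Stomach-weight model ranking", "model_ranking.csv", _gam)

    text = "\n".join(lines)
    (out / "summary.txt").write_text(text, encoding="utf-8")
    return text
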