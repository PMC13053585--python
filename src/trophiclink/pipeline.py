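"""End-to-end orchestration: simulate -> indices -> grid -> three tiers -> report.

Every stage reads and writes plain CSV in a fixed dialect (comma-separated,
UTF-8, '.' decimal, header row, empty field = missing) so runs are
resumable from cached artifacts and byte-reproducible for a given config
and seed.  A manifest records per-stage row counts, timing and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, gpedm, gridding, indices, panelfe, report, synthgrid
from .errors import ConfigError, TrophicLinkError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    scales_m: tuple = (100_000, 50_000, 10_000)
    pairings: tuple = (("insectivore", "insects"),)
    sim: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)   # min_run, max_zero_frac, span
    edm: dict = field(default_factory=dict)           # n_starts, prior_scale, E, tau
    panel: dict = field(default_factory=dict)         # max_zero_frac, standardize_insect

    def validate(self, diet: pd.DataFrame) -> None:
        scales = list(self.scales_m)
        if scales != sorted(scales, reverse=True):
            raise ConfigError("scales_m must be descending")
        for a, b in zip(scales, scales[1:]):
            if a % b != 0:
                raise ConfigError(f"scales_m: {b} does not divide {a}")
        known = set(map(tuple, diet[["insectivore", "insect_group"]].itertuples(index=False, name=None)))
        for p in self.pairings:
            if tuple(p) not in known:
                raise ConfigError(f"pairing {tuple(p)} not present in diet matrix")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scales_m" in raw:
            raw["scales_m"] = tuple(raw["scales_m"])
        if "pairings" in raw:
            raw["pairings"] = tuple(tuple(p) for p in raw["pairings"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scales_m": list(self.scales_m),
            "pairings": [list(p) for p in self.pairings],
            "sim": self.sim, "association": self.association,
            "edm": self.edm, "panel": self.panel,
        }


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


class Manifest:
    def __init__(self, cfg: RunConfig):
        self.data = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "package_version": _version(),
            "stages": {},
            "warnings": [],
        }

    def record(self, stage: str, seconds: float, rows: dict) -> None:
        self.data["stages"][stage] = {"wall_seconds": round(seconds, 3), "rows": rows}
        logger.info("stage %s: %.2fs, rows=%s", stage, seconds, rows)

    def warn(self, msg: str) -> None:
        self.data["warnings"].append(msg)
        logger.warning(msg)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2))


def _version() -> str:
    from . import __version__

    return __version__


def run_pipeline(cfg: RunConfig, outdir, resume: bool = False) -> Path:
    """Execute all stages and write artifacts into ``outdir``.

    With ``resume=True`` stages whose output CSVs already exist are skipped
    and their cached artifacts reused.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    diet = synthgrid.default_diet_matrix()
    cfg.validate(diet)
    manifest = Manifest(cfg)

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    paths = {n: out / f"{n}.csv" for n in ("visits", "species_index", "weather", "site_index")}
    if resume and all(p.exists() for p in paths.values()):
        visits = pd.read_csv(paths["visits"])
        species = pd.read_csv(paths["species_index"])
        weather = pd.read_csv(paths["weather"])
    else:
        sim_cfg = synthgrid.SimConfig(**{"seed": cfg.seed, **cfg.sim})
        truth, visits, species, weather = synthgrid.simulate(sim_cfg)
        truth.to_json(out / "truth.json")
        _write_csv(visits, paths["visits"])
        _write_csv(species, paths["species_index"])
        _write_csv(weather, paths["weather"])
        _write_csv(diet, out / "diet_matrix.csv")
    manifest.record("simulate", time.perf_counter() - t0,
                    {"visits": len(visits), "species_index": len(species), "weather": len(weather)})

    # --- indices --------------------------------------------------------
    t0 = time.perf_counter()
    bird = indices.bird_site_index(visits, include_flyover=False, taxon="insectivore")
    insect = indices.order_index(species)
    site_index = pd.concat([bird, insect], ignore_index=True)
    _write_csv(site_index, paths["site_index"])
    manifest.record("indices", time.perf_counter() - t0, {"site_index": len(site_index)})

    # --- grid + tiers per scale ----------------------------------------
    assoc_rows, edm_tables, link_rows, trend_rows, panel_rows, cell_frames = [], [], [], [], [], []
    assoc_cfg = {"min_run": 10, "max_zero_frac": 0.5, "span": 0.75, **cfg.association}
    panel_cfg = {"max_zero_frac": 0.5, "standardize_insect": True, **cfg.panel}
    edm_cfg = dict(cfg.edm)
    gp_config = gpedm.GPConfig(
        n_starts=edm_cfg.pop("n_starts", 5),
        prior_scale=edm_cfg.pop("prior_scale", 1.0),
        seed=cfg.seed,
    )

    for scale in cfg.scales_m:
        t0 = time.perf_counter()
        cells = gridding.aggregate_to_cells(site_index, scale)
        cell_frames.append(cells)
        for pairing in cfg.pairings:
            pairing = tuple(pairing)
            paired = gridding.pair_series(
                cells[cells["taxon"] == pairing[0]],
                cells[cells["taxon"] == pairing[1]],
                weather, pairing,
            )
            if paired.empty:
                manifest.warn(f"no paired data for {pairing} at {scale}")
                continue
            label = f"{pairing[0]}|{pairing[1]}"

            # tier 1: association
            slopes_by_taxon = {}
            for taxon, col in ((pairing[0], "insectivore_value"), (pairing[1], "insect_value")):
                series = paired.rename(columns={col: "value"})[["scale_m", "ix", "iy", "year", "value"]]
                runs = []
                for (s, ix, iy), g in series.groupby(["scale_m", "ix", "iy"]):
                    run = association.longest_run(
                        g["year"], g["value"], assoc_cfg["min_run"], assoc_cfg["max_zero_frac"]
                    )
                    if run is not None:
                        runs.append(pd.DataFrame({"scale_m": s, "ix": ix, "iy": iy,
                                                  "year": run[0], "value": run[1]}))
                if runs:
                    slopes = association.cell_slopes(pd.concat(runs), method="shrunk")
                    slopes_by_taxon[taxon] = slopes
                    trend_rows.append((taxon, scale, report.classify_overall_trend(slopes)))
                else:
                    trend_rows.append((taxon, scale, "no_change"))
            decomps = association.decompose_paired_panel(
                paired, assoc_cfg["min_run"], assoc_cfg["max_zero_frac"], assoc_cfg["span"]
            )
            try:
                agree = association.sign_agreement(
                    slopes_by_taxon[pairing[0]], slopes_by_taxon[pairing[1]]
                ) if len(slopes_by_taxon) == 2 else None
            except TrophicLinkError as exc:
                manifest.warn(f"sign agreement unavailable for {label}@{scale}: {exc}")
                agree = None
            try:
                rcs = association.remainder_correlations(decomps)
            except TrophicLinkError as exc:
                manifest.warn(f"remainder correlations unavailable for {label}@{scale}: {exc}")
                rcs = None
            assoc_rows.append((
                label, scale,
                agree.n_cells if agree else 0, agree.k_agree if agree else 0,
                agree.p_value if agree else np.nan,
                rcs.mean if rcs else np.nan,
                rcs.ci_low if rcs else np.nan, rcs.ci_high if rcs else np.nan,
            ))

            # tier 2: GP-EDM 10-model suite
            try:
                comp = gpedm.comparison_suite(paired, pairing, scale, gp_config, **edm_cfg)
                edm_tables.append(comp.table)
            except TrophicLinkError as exc:
                manifest.warn(f"EDM unavailable for {label}@{scale}: {exc}")

            # tier 3: panel fixed effects
            try:
                panel = panelfe.build_panel(paired, panel_cfg["max_zero_frac"])
                fits, summary = panelfe.run_spec_grid(
                    panel, scale, standardize_insect=panel_cfg["standardize_insect"]
                )
                summary.insert(0, "pairing", label)
                link_rows.append(summary)
                for sid, f in fits.items():
                    for term in f.coef.index:
                        panel_rows.append((label, scale, sid, term, f.coef[term], f.se[term],
                                           f.tstat[term], f.pvalue[term], f.n_obs, f.n_clusters))
            except TrophicLinkError as exc:
                manifest.warn(f"panel tier unavailable for {label}@{scale}: {exc}")
        manifest.record(f"scale_{scale}", time.perf_counter() - t0, {"cells": len(cells)})

    _write_csv(pd.concat(cell_frames, ignore_index=True), out / "cell_series.csv")
    assoc_df = pd.DataFrame(
        assoc_rows, columns=["pairing", "scale_m", "n_cells", "k_agree", "p",
                             "mean_r", "ci_low", "ci_high"],
    )
    _write_csv(assoc_df, out / "association_results.csv")
    edm_df = pd.concat(edm_tables, ignore_index=True) if edm_tables else pd.DataFrame()
    if not edm_df.empty:
        _write_csv(edm_df, out / "edm_results.csv")
    links_df = pd.concat(link_rows, ignore_index=True) if link_rows else pd.DataFrame(
        columns=["pairing", "scale_m", "term", "n_significant", "direction"]
    )
    _write_csv(links_df, out / "link_summary.csv")
    panel_df = pd.DataFrame(
        panel_rows, columns=["pairing", "scale_m", "spec", "term", "coefficient",
                             "se", "t", "p", "n_obs", "n_clusters"],
    )
    _write_csv(panel_df, out / "panel_results.csv")
    trends_df = pd.DataFrame(trend_rows, columns=["taxon", "scale_m", "trend"]).drop_duplicates()
    _write_csv(trends_df, out / "trend_summary.csv")

    text, payload = report.build_report(trends_df, assoc_df, edm_df, links_df)
    (out / "report.md").write_text(text)
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))
    manifest.write(out / "manifest.json")
    return out
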