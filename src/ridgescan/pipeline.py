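"""End-to-end orchestration: simulate -> pyramid -> terrain -> structure ->
autocorrelation -> association scan -> habitat comparison -> report.

Configuration is a single YAML/dict; one global seed fans out deterministically
to per-stage seeds, and each run writes a provenance file (config + seed +
stage checksums).  Stages are resumable: a stage is skipped when its outputs
exist and the stored config hash matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Any

import numpy as np
import pandas as pd

from . import autocorr as autocorr_mod
from . import gea, habitat, structure, synth, terrain
from .grid_io import Grid, read_grid, read_samples, write_grid, write_samples
from .pyramid import ResolutionLadder, build_pyramid

__all__ = ["default_config", "run_pipeline", "make_report"]

FLOAT_FMT = "%.10g"


def default_config() -> dict[str, Any]:
    """Desk-scale defaults; the study-scale values (1,000 c-means runs,
    10,000 greedy repeats, 9,999 permutations) are noted per key."""
    return {
        "seed": 0,
        "out_dir": "ridgescan_out",
        "scenario": dataclasses.asdict(synth.ScenarioConfig()),
        "dem": None, "samples": None, "genotypes": None,
        "ladder": {"base_cell_size": 0.5, "factors": [1, 2, 4, 8, 16]},
        "terrain": {"variables": list(terrain.TERRAIN_VARIABLES)},
        "structure": {"k_max": 20, "runs": 50, "greedy_repeats": 200, "m": 1.02,
                      "maf_min": 0.05},          # study scale: 1000 / 10000
        "autocorr": {"classes": 20, "perms": 999},  # study scale: 9999
        "scan": {"alpha": 0.05, "standardize": True},
        "write_rasters": False,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = default_config()
    if path:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _cfg_hash(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(int(seed))
    names = ["simulate", "structure", "autocorr", "scan"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


class _Provenance:
    def __init__(self, out_dir: str, cfg: dict):
        self.path = os.path.join(out_dir, "provenance.json")
        self.cfg = cfg
        self.state: dict[str, str] = {}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.state = json.load(fh).get("stages", {})

    def fresh(self, stage: str, outputs: list[str]) -> bool:
        """True if the stage must (re)run."""
        h = _cfg_hash({"stage": stage, "cfg": self.cfg})
        if self.state.get(stage) != h:
            return True
        return not all(os.path.exists(p) for p in outputs)

    def mark(self, stage: str) -> None:
        import scipy

        from . import __version__

        self.state[stage] = _cfg_hash({"stage": stage, "cfg": self.cfg})
        versions = {"ridgescan": __version__, "numpy": np.__version__,
                    "scipy": scipy.__version__, "pandas": pd.__version__}
        with open(self.path, "w") as fh:
            json.dump({"config": self.cfg, "versions": versions,
                       "stages": self.state}, fh, indent=1, default=str)


def run_pipeline(cfg: dict, progress=print) -> dict[str, Any]:
    """Execute every stage; returns the in-memory bundle of results.

    Any stage failure raises with the stage name; partial outputs of earlier
    stages remain valid and are reused on rerun.
    """
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    prov = _Provenance(out_dir, cfg)
    bundle: dict[str, Any] = {"out_dir": out_dir}

    def path(name: str) -> str:
        return os.path.join(out_dir, name)

    # -- inputs: simulate or load ------------------------------------------
    scenario = None
    if cfg.get("dem"):
        dem = read_grid(cfg["dem"])
        samples = read_samples(cfg["samples"])
        gm = pd.read_csv(cfg["genotypes"], index_col=0)
    else:
        sc = dict(cfg["scenario"])
        sc["seed"] = seeds["simulate"]
        links = sc.pop("adaptive_links", None)
        if links is not None:
            links = tuple(synth.AdaptiveLink(**l) if isinstance(l, dict) else l
                          for l in links)
        scenario = synth.ScenarioConfig(**{**sc, "adaptive_links": links})
        sim_outputs = [path(p) for p in ("dem.asc", "samples.csv",
                                         "genotypes.csv", "truth.json")]
        if prov.fresh("simulate", sim_outputs):
            progress("[simulate] generating landscape and genotypes")
            dem = synth.make_ridge_dem(scenario)
            samples = synth.make_sampling(scenario, dem)
            pyr = build_pyramid(dem, _ladder(cfg))
            tcfg = _terrain_cfg(cfg, scenario)
            stack = terrain.compute_stack(pyr, tcfg)
            gm, truth = synth.simulate_genotypes(scenario, dem, samples, stack)
            write_grid(dem, path("dem.asc"))
            write_samples(samples, path("samples.csv"))
            gm.to_csv(path("genotypes.csv"))
            truth.to_json(path("truth.json"))
            prov.mark("simulate")
            bundle["pyramid"], bundle["stack"] = pyr, stack
        dem = read_grid(path("dem.asc"))
        samples = read_samples(path("samples.csv"))
        gm = pd.read_csv(path("genotypes.csv"), index_col=0)
    bundle.update(dem=dem, samples=samples, genotypes=gm)

    # -- pyramid + terrain --------------------------------------------------
    if "pyramid" not in bundle:
        progress("[terrain] building pyramid and attribute stack")
        bundle["pyramid"] = build_pyramid(dem, _ladder(cfg))
        bundle["stack"] = terrain.compute_stack(bundle["pyramid"],
                                                _terrain_cfg(cfg, scenario))
    env = terrain.extract_stack(bundle["stack"], samples)
    env.to_csv(path("env_by_sample.csv"), index=False, float_format=FLOAT_FMT)
    if cfg.get("write_rasters"):
        rdir = path("stack")
        os.makedirs(rdir, exist_ok=True)
        for (var, res), grid in bundle["stack"].items():
            write_grid(grid, os.path.join(rdir, f"{var}_{res:g}m.asc"))
    bundle["env"] = env

    # -- structure ----------------------------------------------------------
    progress("[structure] clustering")
    scfg = cfg["structure"]
    sres = structure.run_structure(
        gm, k_range=range(2, scfg["k_max"] + 1), n_runs=scfg["runs"],
        greedy_repeats=scfg["greedy_repeats"], m=scfg["m"],
        seed=seeds["structure"], maf_min=scfg["maf_min"])
    sres.to_frame().to_csv(path("membership.csv"), index=False,
                           float_format=FLOAT_FMT)
    pd.DataFrame({"K": list(sres.calinski), "calinski": list(sres.calinski.values())}
                 ).to_csv(path("calinski.csv"), index=False, float_format=FLOAT_FMT)
    bundle["structure"] = sres

    # -- autocorrelation ----------------------------------------------------
    progress("[autocorr] correlogram")
    acfg = cfg["autocorr"]
    gm_qc = structure.qc_filter(gm, scfg["maf_min"])
    corr = autocorr_mod.correlogram(gm_qc, samples, n_classes=acfg["classes"],
                                    n_perm=acfg["perms"], seed=seeds["autocorr"])
    corr.to_frame().to_csv(path("correlogram.tsv"), sep="\t", index=False,
                           float_format=FLOAT_FMT)
    bundle["correlogram"] = corr

    # -- association scan ---------------------------------------------------
    progress("[scan] gene-environment associations")
    gcfg = cfg["scan"]
    scan_df = gea.scan(gm_qc, env, samples, bundle["pyramid"],
                       membership=sres.membership,
                       cfg=gea.ScanConfig(alpha=gcfg["alpha"],
                                          standardize=gcfg["standardize"]))
    scan_df.to_csv(path("scan.tsv"), sep="\t", index=False, float_format=FLOAT_FMT)
    bundle["scan"] = scan_df

    # -- habitat comparison -------------------------------------------------
    progress("[habitat] group comparison")
    hab = habitat.habitat_table(env, samples, sres.assignment,
                                alpha=gcfg["alpha"])
    hab.to_csv(path("habitat.tsv"), sep="\t", index=False, float_format=FLOAT_FMT)
    hab.attrs["summary"].to_csv(path("habitat_summary.tsv"), sep="\t", index=False,
                                float_format=FLOAT_FMT)
    bundle["habitat"] = hab
    prov.mark("pipeline")
    return bundle


def _ladder(cfg: dict) -> ResolutionLadder:
    lad = cfg["ladder"]
    return ResolutionLadder(base_cell_size=lad["base_cell_size"],
                            factors=tuple(lad["factors"]))


def _terrain_cfg(cfg: dict, scenario) -> terrain.TerrainConfig:
    t = dict(cfg.get("terrain", {}))
    t["variables"] = tuple(t.get("variables", terrain.TERRAIN_VARIABLES))
    return terrain.TerrainConfig(**t)


# ---------------------------------------------------------------------------
# Report

def make_report(bundle: dict[str, Any], top_n: int = 10) -> str:
    """Render plots and a markdown summary into ``<out_dir>/report``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = bundle["out_dir"]
    rdir = os.path.join(out_dir, "report")
    os.makedirs(rdir, exist_ok=True)
    lines = ["# ridgescan run summary", ""]

    sres = bundle["structure"]
    samples = bundle["samples"]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(samples["x"], sres.membership, s=8,
               c=sres.membership, cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xlabel("position along ridge (m)")
    ax.set_ylabel("membership to pop. A")
    fig.tight_layout()
    fig.savefig(os.path.join(rdir, "membership_ridge.png"), dpi=120)
    plt.close(fig)
    counts = pd.Series(sres.assignment).value_counts()
    lines += [f"## Population structure",
              f"K = {sres.K}; mean pairwise similarity G = {sres.similarity:.3f}",
              f"assignments: {counts.to_dict()}", ""]

    corr = bundle["correlogram"]
    cdf = corr.to_frame()
    fig, ax = plt.subplots(figsize=(6, 3))
    colors = np.where(cdf["significant"], "black", "white")
    ax.scatter(cdf["d_upper"], cdf["mean_r"], c=colors, edgecolors="black")
    ax.axhline(0, lw=0.5)
    ax.set_xlabel("distance class upper bound (m)")
    ax.set_ylabel("mean r")
    ax.set_title(f"correlogram (alpha = 0.05/{corr.n_classes})")
    fig.tight_layout()
    fig.savefig(os.path.join(rdir, "correlogram.png"), dpi=120)
    plt.close(fig)

    scan_df = bundle["scan"]
    thr = scan_df.attrs["bonferroni_threshold"]
    top = scan_df.dropna(subset=["p"]).sort_values("p").head(top_n)
    lines += ["## Top associations",
              f"{scan_df.attrs['n_tests']} models; Bonferroni threshold "
              f"{thr:.3g}", "",
              top[["locus", "variable", "resolution", "p", "beta0", "beta1",
                   "aic_null", "aic_full"]].to_markdown(index=False), ""]
    sig_pairs = (scan_df[scan_df["significant"]]
                 .drop_duplicates(subset=["locus", "variable"]))
    for _, row in sig_pairs.iterrows():
        if pd.isna(row["resolution"]):
            continue
        prof = gea.resolution_profile(scan_df, row["locus"], row["variable"])
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(prof["resolution"], prof["neglog10_p"], "o-")
        ax.axhline(-np.log10(thr), color="red", ls="--", lw=1)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("resolution (m)")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{row['locus']} ~ {row['variable']}")
        fig.tight_layout()
        fig.savefig(os.path.join(rdir,
                    f"profile_{row['locus']}_{row['variable']}.png"), dpi=120)
        plt.close(fig)

    hab = bundle["habitat"]
    lines += ["## Habitat comparison (best resolution per variable)", "",
              hab.attrs["summary"].to_markdown(index=False), ""]
    report_path = os.path.join(rdir, "summary.md")
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines))
    return report_path
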