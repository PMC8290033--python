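"""End-to-end pipeline orchestration.

``run_pipeline`` drives simulate -> preprocess -> connectivity ->
brain-network features -> feature assembly -> model grid from one nested
configuration dictionary (YAML-friendly), writes every stage's outputs as
plain-text artefacts and records a manifest (config, seed, per-file
checksums, library versions) that fully determines the run: re-executing
with the same config and seed reproduces all outputs bit-identically.

Stages can be run selectively; a later stage reloads its inputs from the
output directory when the earlier stage was skipped, so e.g. the model
grid can be rerun on precomputed feature tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .brain_network import eeg_feature_vector
from .connectivity import connectivity_matrix
from .eeg_preprocess import DEFAULT_BANDS, preprocess_recording
from .feature_assembly import INPUT_SETS, assemble, cohort_statistics
from .ml_framework import FrameworkSpec, run_framework
from .synthdata import (
    BloodSimParams,
    EEGSimParams,
    MicrobiotaSimParams,
    make_cohort,
    simulate_blood,
    simulate_eeg,
    simulate_microbiota,
)

__all__ = ["DEFAULT_CONFIG", "smoke_config", "validate_config", "run_pipeline"]

log = logging.getLogger("multibiodx")

ALL_STAGES = ("simulate", "preprocess", "connectivity", "brainnet", "assemble", "framework")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "cohort": {"n_sz": 49, "n_hc": 50},
    "eeg": {"n_channels": 16, "fs": 1000.0, "duration": 180.0},
    "preprocess": {"epoch_length": 2.0, "amp_threshold": 100.0},
    "connectivity": {"edge_trim": 0.05},
    "brainnet": {"cost_min": 0.34, "cost_max": 0.73, "cost_step": 0.01, "n_null": 100},
    "microbiota": {},
    "blood": {},
    "framework": {
        "input_sets": list(INPUT_SETS),
        "fs_methods": ["None", "PCA", "RFE", "ANOVA"],
        "classifiers": ["SVM", "RF", "LDA", "LR", "KNN"],
        "cv_schemes": ["10fold", "5fold", "3fold", "LOO"],
        "holdout_ratio": 3.0,
        "params": {},
        "with_cv": True,
    },
    "io": {"write_raw_eeg": False},
}


def smoke_config() -> dict:
    """A minutes-scale configuration exercising every stage end to end."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["cohort"] = {"n_sz": 6, "n_hc": 6}
    cfg["eeg"].update(duration=10.0)
    cfg["brainnet"].update(n_null=8)
    cfg["microbiota"] = {"n_taxa": 20, "n_core": 12}
    cfg["framework"].update(
        fs_methods=["None", "ANOVA"],
        cv_schemes=["3fold"],
        params={"rf_n_estimators": 100},
    )
    return cfg


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(overrides: dict | None = None) -> dict:
    return _merge(DEFAULT_CONFIG, overrides or {})


def validate_config(cfg: dict) -> list[str]:
    """Range and consistency checks; returns a list of human-readable issues."""
    issues: list[str] = []
    bn = cfg.get("brainnet", {})
    cmin, cmax = bn.get("cost_min", 0.34), bn.get("cost_max", 0.73)
    if not (0 < cmin <= 1 and 0 < cmax <= 1):
        issues.append(f"cost grid outside (0, 1]: [{cmin}, {cmax}]")
    if cmin >= cmax:
        issues.append("cost_min must be below cost_max")
    if bn.get("cost_step", 0.01) <= 0:
        issues.append("cost_step must be positive")
    fs = cfg.get("eeg", {}).get("fs", 1000.0)
    top_edge = max(hi for _, hi in DEFAULT_BANDS.values())
    if fs <= 2 * top_edge:
        issues.append(f"fs={fs} does not exceed twice the highest band edge ({top_edge} Hz)")
    fw = cfg.get("framework", {})
    if fw.get("holdout_ratio", 3.0) <= 1:
        issues.append("holdout_ratio must exceed 1")
    if "Blood" in fw.get("input_sets", []):
        banned = {"PCA", "RFE"} & set(fw.get("fs_methods", []))
        if banned and fw.get("input_sets") == ["Blood"]:
            issues.append(f"Blood input set cannot use {sorted(banned)} feature selection")
    pp = cfg.get("preprocess", {})
    if pp.get("epoch_length", 2.0) <= 0:
        issues.append("epoch_length must be positive")
    if cfg.get("eeg", {}).get("duration", 180.0) < pp.get("epoch_length", 2.0):
        issues.append("EEG duration shorter than one epoch")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cost_grid(bn: dict) -> np.ndarray:
    n = int(round((bn["cost_max"] - bn["cost_min"]) / bn["cost_step"])) + 1
    return np.round(bn["cost_min"] + bn["cost_step"] * np.arange(n), 6)


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages and return the run manifest."""
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg.get("stages", ALL_STAGES))
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "versions": _versions()}
    written: dict[str, Path] = {}

    cohort = recordings = band_epochs = plvs = None
    eeg_features = taxa = blood = None

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "files": {str(p.relative_to(out)): _sha256(p) for p in paths},
        }

    if "simulate" in stages:
        t0 = time.time()
        cohort = make_cohort(seed=seed, **cfg["cohort"])
        taxa = simulate_microbiota(cohort, MicrobiotaSimParams(**cfg["microbiota"]), seed)
        blood = simulate_blood(cohort, BloodSimParams(), seed)
        eeg_params = EEGSimParams(**cfg["eeg"])
        recordings = simulate_eeg(cohort, eeg_params, seed)
        paths = [
            mio.write_cohort(cohort, out / "cohort.csv"),
            mio.write_table(taxa, out / "taxa.tsv"),
            mio.write_table(blood, out / "blood.tsv"),
        ]
        stats_path = out / "cohort_stats.csv"
        cohort_statistics(cohort).to_csv(stats_path, index=False)
        paths.append(stats_path)
        if cfg["io"].get("write_raw_eeg"):
            eeg_dir = out / "eeg"
            eeg_dir.mkdir(exist_ok=True)
            for sid, rec in recordings.items():
                paths.append(mio.write_eeg(rec, eeg_dir / f"{sid}.csv"))
        record("simulate", paths)
        log.info("simulate: %d subjects in %.1fs", len(cohort), time.time() - t0)

    if "preprocess" in stages:
        t0 = time.time()
        if recordings is None:
            eeg_dir = out / "eeg"
            recordings = {p.stem: mio.read_eeg(p) for p in sorted(eeg_dir.glob("*.csv"))}
        band_epochs = {
            sid: preprocess_recording(rec, **cfg["preprocess"])
            for sid, rec in recordings.items()
        }
        ep_dir = out / "epochs"
        ep_dir.mkdir(exist_ok=True)
        paths = [mio.write_epochs(bands, ep_dir / f"{sid}.npz")
                 for sid, bands in band_epochs.items()]
        record("preprocess", paths)
        log.info("preprocess: %.1fs", time.time() - t0)

    if "connectivity" in stages:
        t0 = time.time()
        if band_epochs is None:
            ep_dir = out / "epochs"
            band_epochs = {p.stem: mio.read_epochs(p) for p in sorted(ep_dir.glob("*.npz"))}
        plvs = {
            sid: {b: connectivity_matrix(es, **cfg["connectivity"])
                  for b, es in bands.items()}
            for sid, bands in band_epochs.items()
        }
        plv_dir = out / "plv"
        plv_dir.mkdir(exist_ok=True)
        paths = []
        for sid, bands in plvs.items():
            for b, m in bands.items():
                paths.append(mio.write_plv(m, plv_dir / f"{sid}_{b}.csv"))
        record("connectivity", paths)
        log.info("connectivity: %.1fs", time.time() - t0)

    if "brainnet" in stages:
        t0 = time.time()
        if plvs is None:
            plv_dir = out / "plv"
            plvs = {}
            for p in sorted(plv_dir.glob("*.csv")):
                sid, band = p.stem.rsplit("_", 1)
                plvs.setdefault(sid, {})[band] = mio.read_plv(p, band_label=band)
        costs = _cost_grid(cfg["brainnet"])
        n_null = int(cfg["brainnet"]["n_null"])
        rows = {
            sid: eeg_feature_vector(bands, costs=costs, n_null=n_null, seed=seed)
            for sid, bands in plvs.items()
        }
        eeg_features = pd.DataFrame(rows).T.sort_index()
        eeg_features.index.name = "subject_id"
        path = out / "eeg_features.csv"
        eeg_features.to_csv(path)
        record("brainnet", [path])
        log.info("brainnet: %.1fs", time.time() - t0)

    tables = None
    if "assemble" in stages:
        if cohort is None:
            cohort = mio.read_cohort(out / "cohort.csv")
        if taxa is None:
            taxa = mio.read_table(out / "taxa.tsv")
        if blood is None:
            blood = mio.read_table(out / "blood.tsv")
        if eeg_features is None:
            eeg_features = pd.read_csv(out / "eeg_features.csv", index_col="subject_id")
        groups = cohort["group"]
        # align subject order across modalities
        taxa = taxa.loc[cohort.index]
        blood = blood.loc[cohort.index]
        eeg_features = eeg_features.loc[cohort.index]
        tables = {
            mode: assemble(taxa, blood, eeg_features, groups, mode=mode)
            for mode in cfg["framework"]["input_sets"]
        }
        paths = [
            mio.write_feature_table(ft, out / f"features_{mode.lower()}.csv")
            for mode, ft in tables.items()
        ]
        record("assemble", [p for p in paths] + [p.with_suffix(p.suffix + ".json") for p in paths])

    if "framework" in stages:
        t0 = time.time()
        if tables is None:
            tables = {
                mode: mio.read_feature_table(out / f"features_{mode.lower()}.csv")
                for mode in cfg["framework"]["input_sets"]
            }
        fw = cfg["framework"]
        spec = FrameworkSpec(
            input_sets=tuple(fw["input_sets"]),
            fs_methods=tuple(fw["fs_methods"]),
            classifiers=tuple(fw["classifiers"]),
            cv_schemes=tuple(fw["cv_schemes"]),
            holdout_ratio=fw["holdout_ratio"],
            seed=seed,
            params=dict(fw.get("params", {})),
        )
        results = run_framework(tables, spec, with_cv=fw.get("with_cv", True))
        path = out / "results.csv"
        results.to_csv(path, index=False)
        record("framework", [path])
        log.info("framework: %d models in %.1fs", len(results), time.time() - t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _versions() -> dict[str, str]:
    import sklearn
    import scipy

    from . import __version__

    return {
        "multibiodx": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
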