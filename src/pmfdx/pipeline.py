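"""End-to-end orchestration: simulate -> detect -> fingerprint -> qc ->
explore -> train -> panel -> trends -> stats, with a hash manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records a SHA-256 per written artifact so reruns with the same config and
seed can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import hier_cluster_samples, pca, plsda
from .fingerprint import build_feature_axis, build_fingerprints, detect_peaks
from .io import read_metadata, read_spectrum, write_fingerprints_csv, write_metadata, write_spectrum_csv
from .model import HyperGrid, SplitSpec, evaluate_roc, stratified_split, tune_and_fit
from .panel import evaluate_panel_external, rank_key_features, search_panel
from .qc import qc_summary
from .stats import kendall_network, pilot_power_curve
from .synthetic import CohortSpec, external_cohort_spec, generate_cohort, generate_replicate_series
from .trends import cluster_trends, compute_trend_profiles

log = logging.getLogger("pmfdx")

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    output_dir: str = "pmfdx_run"
    seed: int = 0
    # input mode: either simulate a cohort or point at spectra + metadata
    simulate: bool = True
    spectra_dir: str | None = None
    metadata_path: str | None = None
    write_spectra: bool = False
    # synthetic cohort
    n_per_grade: dict = field(default_factory=lambda: {1: 35, 2: 30, 3: 35, 4: 25})
    n_points: int = 120_000
    n_background_peaks: int = 260
    replicate_noise_cv: float = 0.12
    n_replicates: int = 20
    external_cohort: bool = True
    external_n_per_grade: dict = field(default_factory=lambda: {1: 44, 2: 36, 3: 25, 4: 18})
    # peak detection / axis
    half_window_points: int = 10
    snr_min: float = 6.0
    tolerance_da: float = 0.1
    min_detection_frac: float = 0.5
    max_features: int = 200
    normalization: str = "tic"
    qc_max_features: int = 265
    # optional stages
    run_qc: bool = True
    run_explore: bool = True
    # modeling
    discovery_frac: float = 0.7
    penalties: tuple = ("l1", "l2")
    strength_grid: tuple = tuple(np.logspace(-3, 3, 13))
    n_folds: int = 5
    # panel search
    max_rank: int = 30
    t_test_alpha: float = 0.05
    max_size: int = 6
    combination_budget: int = 2_000_000
    # trends / stats
    trend_k: int = 5
    trend_restarts: int = 50
    power_fdr: float = 0.15
    power_top_k: int = 25
    power_n_grid: tuple = (5, 10, 15, 20, 25, 30, 40, 50)
    correlation_alpha: float = 0.1

    def validate(self) -> None:
        if not 0 < self.discovery_frac < 1:
            raise ConfigError("discovery_frac must be in (0, 1)")
        if self.normalization not in ("tic", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if not self.simulate:
            if not self.spectra_dir or not self.metadata_path:
                raise ConfigError("spectra_dir and metadata_path are required when simulate is false")
            if not Path(self.metadata_path).exists():
                raise ConfigError(f"metadata file not found: {self.metadata_path}")
            if not Path(self.spectra_dir).is_dir():
                raise ConfigError(f"spectra directory not found: {self.spectra_dir}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for f in ("penalties", "strength_grid", "power_n_grid"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        for f in ("n_per_grade", "external_n_per_grade"):
            setattr(cfg, f, {int(k): int(v) for k, v in getattr(cfg, f).items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for f in ("penalties", "power_n_grid"):
            d[f] = list(d[f])
        d["strength_grid"] = [float(s) for s in d["strength_grid"]]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_per_grade=dict(self.n_per_grade),
            n_points=self.n_points,
            n_background_peaks=self.n_background_peaks,
            replicate_noise_cv=self.replicate_noise_cv,
            seed=self.seed,
        )

    def hyper_grid(self) -> HyperGrid:
        return HyperGrid(
            penalties=tuple(self.penalties),
            strength_grid=tuple(float(s) for s in self.strength_grid),
            n_folds=self.n_folds,
            fold_seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, name: str):
        self.name = name
        self.t0 = 0.0

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise StageError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %-12s done in %.2fs", self.name, time.perf_counter() - self.t0)


def _detect_all(spectra, cfg: RunConfig):
    return [detect_peaks(s, cfg.half_window_points, cfg.snr_min) for s in spectra]


def _fingerprint(peaklists, cfg: RunConfig, max_features=None):
    axis = build_feature_axis(
        peaklists, cfg.tolerance_da, cfg.min_detection_frac,
        max_features if max_features is not None else cfg.max_features,
    )
    return axis, build_fingerprints(peaklists, axis, cfg.normalization)


def _task(name, fp, metadata, positive_mask_fn, cfg, out, artifacts):
    """One diagnostic task: split, tune, ROC, panel, correlations."""
    md = metadata[metadata["sample_id"].map(positive_mask_fn("include"))].reset_index(drop=True)
    labels = {r.sample_id: positive_mask_fn("label")(r) for r in md.itertuples()}
    disc_ids, val_ids = stratified_split(md, SplitSpec(cfg.discovery_frac, "mmd_grade", cfg.seed))
    disc = fp.subset_samples(disc_ids)
    val = fp.subset_samples(val_ids)
    y_disc = np.array([labels[s] for s in disc_ids])
    y_val = np.array([labels[s] for s in val_ids])

    model = tune_and_fit(disc, y_disc, cfg.hyper_grid())
    roc_disc = evaluate_roc(model, disc, y_disc)
    roc_val = evaluate_roc(model, val, y_val, threshold=roc_disc.threshold)

    key = rank_key_features(model, disc, y_disc, cfg.max_rank, cfg.t_test_alpha)
    panel_grid = HyperGrid(penalties=(model.penalty,), strength_grid=(model.strength,),
                           n_folds=cfg.n_folds, fold_seed=cfg.seed)
    panel = search_panel(
        key, disc, y_disc, max_size=min(cfg.max_size, len(key)), cv=panel_grid,
        budget=cfg.combination_budget, validation_matrix=val, validation_labels=y_val,
    )
    network = kendall_network(fp.subset_samples([*disc_ids, *val_ids]),
                              feature_mz=panel.features, alpha=cfg.correlation_alpha)

    model.to_json(out / f"{name}_model.json")
    roc_disc.to_json(out / f"{name}_roc_discovery.json")
    roc_val.to_json(out / f"{name}_roc_validation.json")
    panel.to_json(out / f"{name}_panel.json")
    network.to_json(out / f"{name}_kendall.json")
    artifacts += [out / f"{name}_{x}.json" for x in
                  ("model", "roc_discovery", "roc_validation", "panel", "kendall")]
    return {
        "discovery_ids": disc_ids, "validation_ids": val_ids,
        "model": model, "roc_discovery": roc_disc, "roc_validation": roc_val,
        "key_features": key, "panel": panel, "network": network,
        "labels": labels,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the in-memory report (artifacts on disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list = []
    report: dict = {"version": __version__, "seed": config.seed}

    with _Stage("simulate"):
        if config.simulate:
            spec = config.cohort_spec()
            spectra, metadata = generate_cohort(spec)
            write_metadata(metadata, out / "metadata.csv")
            artifacts.append(out / "metadata.csv")
            if config.write_spectra:
                sdir = out / "spectra"
                sdir.mkdir(exist_ok=True)
                for s in spectra:
                    write_spectrum_csv(s, sdir / f"{s.sample_id}.csv")
        else:
            spec = None
            metadata = read_metadata(config.metadata_path)
            sdir = Path(config.spectra_dir)
            spectra = []
            for sid in metadata["sample_id"]:
                for ext in (".csv", ".mzML", ".mzml"):
                    p = sdir / f"{sid}{ext}"
                    if p.exists():
                        spectra.append(read_spectrum(p, sample_id=str(sid)))
                        break
                else:
                    raise FileNotFoundError(f"no spectrum file for sample {sid} in {sdir}")

    with _Stage("detect"):
        peaklists = _detect_all(spectra, config)
        peaks_df = pd.concat(
            [pd.DataFrame({"sample_id": p.sample_id, "centroid_mz": p.centroid_mz,
                           "apex_intensity": p.apex_intensity}) for p in peaklists],
            ignore_index=True,
        )
        peaks_df.to_csv(out / "peaks.csv", index=False)
        artifacts.append(out / "peaks.csv")

    with _Stage("fingerprint"):
        axis, fp = _fingerprint(peaklists, config)
        write_fingerprints_csv(fp, out / "fingerprints.csv")
        artifacts.append(out / "fingerprints.csv")
        report["n_features"] = fp.n_features
        report["n_samples"] = fp.n_samples

    if config.run_qc and spec is not None:
        with _Stage("qc"):
            reps = generate_replicate_series(spec, config.n_replicates)
            rep_peaks = _detect_all(reps, config)
            rep_axis, rep_fp = _fingerprint(rep_peaks, config, max_features=config.qc_max_features)
            qc = qc_summary(rep_fp, thresholds=(0.15, 0.30))
            qc.to_json(out / "qc.json")
            artifacts.append(out / "qc.json")
            report["qc"] = qc

    if config.run_explore:
        with _Stage("explore"):
            pm = metadata.set_index("sample_id")["pm_label"]
            ncomp = min(2, fp.n_samples - 1, fp.n_features)
            ord_pca = pca(fp, n_components=ncomp, scale="none")
            ord_pls = plsda(fp, pm.loc[fp.sample_ids].to_numpy(), n_components=ncomp)
            clusters = hier_cluster_samples(fp, "ward", k=2)
            scores = ord_pca.scores.join(ord_pls.scores)
            scores["pm_label"] = pm.loc[fp.sample_ids].to_numpy()
            scores["hier_cluster"] = [clusters[s] for s in fp.sample_ids]
            scores.to_csv(out / "explore_scores.csv")
            artifacts.append(out / "explore_scores.csv")
            report["explore"] = {"pca": ord_pca, "plsda": ord_pls, "clusters": clusters}

    md_idx = metadata.set_index("sample_id")
    with _Stage("train+panel"):
        def pm_task(which):
            if which == "include":
                return lambda sid: True
            return lambda row: int(md_idx.loc[row.sample_id, "pm_label"])

        def severity_task(which):
            if which == "include":
                return lambda sid: md_idx.loc[sid, "group3"] in ("MMD 2-3", "MMD 4")
            return lambda row: int(md_idx.loc[row.sample_id, "group3"] == "MMD 4")

        report["pm_task"] = _task("pm", fp, metadata, pm_task, config, out, artifacts)
        report["severity_task"] = _task("severity", fp, metadata, severity_task, config, out, artifacts)

    if config.external_cohort and spec is not None:
        with _Stage("external"):
            ext_spec = external_cohort_spec(spec)
            ext_spec = CohortSpec(**{**asdict_spec(ext_spec), "n_per_grade": dict(config.external_n_per_grade)})
            ext_spectra, ext_md = generate_cohort(ext_spec)
            ext_peaks = _detect_all(ext_spectra, config)
            ext_fp = build_fingerprints(ext_peaks, axis, config.normalization)
            ext_pm = ext_md.set_index("sample_id")["pm_label"]
            roc_ext = evaluate_panel_external(report["pm_task"]["panel"], ext_fp,
                                              ext_pm.loc[ext_fp.sample_ids].to_numpy())
            roc_ext.to_json(out / "pm_panel_external_roc.json")
            artifacts.append(out / "pm_panel_external_roc.json")
            report["pm_external"] = roc_ext
            ext_grp = ext_md.set_index("sample_id")["group3"]
            sev_ids = [s for s in ext_fp.sample_ids if ext_grp.loc[s] in ("MMD 2-3", "MMD 4")]
            sev_fp = ext_fp.subset_samples(sev_ids)
            sev_y = np.array([int(ext_grp.loc[s] == "MMD 4") for s in sev_ids])
            roc_ext_sev = evaluate_panel_external(report["severity_task"]["panel"], sev_fp, sev_y)
            roc_ext_sev.to_json(out / "severity_panel_external_roc.json")
            artifacts.append(out / "severity_panel_external_roc.json")
            report["severity_external"] = roc_ext_sev

    with _Stage("trends"):
        group3 = md_idx["group3"].to_dict()
        profiles = compute_trend_profiles(fp, group3)
        clusters = cluster_trends(profiles, k=config.trend_k, seed=config.seed,
                                  n_restarts=config.trend_restarts)
        pd.DataFrame(
            {"feature_mz": [f"{m:.4f}" for m in clusters.assignments],
             "cluster": list(clusters.assignments.values())}
        ).to_csv(out / "trend_assignments.csv", index=False)
        with open(out / "trend_centroids.json", "w", encoding="utf-8") as fh:
            json.dump({"centroids": np.round(clusters.centroids, 12).tolist(),
                       "inertia": round(clusters.inertia, 9)}, fh, indent=1)
        artifacts += [out / "trend_assignments.csv", out / "trend_centroids.json"]
        report["trends"] = clusters

    with _Stage("stats"):
        pm = md_idx["pm_label"]
        hm_ids = [s for s in fp.sample_ids if pm.loc[s] == 0][:5]
        pm_ids = [s for s in fp.sample_ids if pm.loc[s] == 1][:5]
        pilot = fp.subset_samples(hm_ids + pm_ids)
        y_pilot = np.array([0] * len(hm_ids) + [1] * len(pm_ids))
        curve = pilot_power_curve(pilot, y_pilot, config.power_n_grid,
                                  fdr=config.power_fdr, top_k=config.power_top_k)
        curve.to_json(out / "power_curve.json")
        artifacts.append(out / "power_curve.json")
        report["power_curve"] = curve

    with _Stage("manifest"):
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts), key=lambda p: p.name)},
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        report["manifest"] = manifest
    return report


def asdict_spec(spec: CohortSpec) -> dict:
    d = {f: getattr(spec, f) for f in CohortSpec.__dataclass_fields__}
    return d
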