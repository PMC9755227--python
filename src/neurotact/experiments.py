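"""Scripted end-to-end experiments on simulated scans.

Four protocols, each deterministic given its seeds and emitting a
machine-readable report:

* ``run_innervation_sweep`` -- texture classification from SA-I-only and
  RA-I-only features as the mean receptive-field size is swept
  (1.3, 4.3, 7.2, 10.5, 12.5 innervated taxels per afferent), six textures
  at the fastest scan speed.
* ``run_fusion_experiment`` -- modality-ablation table over tactile and
  proprioceptive feature subsets on the full texture x speed grid.
* ``run_displacement_experiment`` -- accuracy as a function of explored
  surface length (feature windows covering the first X mm of each scan).
* ``rate_vs_speed_table`` -- mean firing rate per afferent class at the
  slowest and fastest speeds.

Because the underlying data are synthetic, the experiments assert ordering
and shape claims (fusion benefit, interior optimum, saturation with
displacement) rather than absolute accuracy values.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .encoding import IzhikevichParams
from .features_classify import (
    EncodedTrial,
    MODALITY_GROUPS,
    ablate_modalities,
    build_feature_matrix,
    crossval_classify,
    encode_trial,
)
from .innervation import build_innervation
from .spindle import SpindleConfig
from .synth_rig import ScanConfig, TextureSpec, default_texture_library, make_dataset

__all__ = [
    "ExperimentReport",
    "encode_dataset",
    "run_innervation_sweep",
    "run_fusion_experiment",
    "run_displacement_experiment",
    "rate_vs_speed_table",
    "DEFAULT_SWEEP_TARGETS",
    "DEFAULT_DISPLACEMENTS_MM",
    "FUSION_SUBSETS",
]

DEFAULT_SWEEP_TARGETS = (1.3, 4.3, 7.2, 10.5, 12.5)
DEFAULT_DISPLACEMENTS_MM = (5.0, 10.0, 20.0, 30.0, 40.0)
FUSION_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("SA-I",), ("RA-I",), ("RA-II",), ("MS-Prim",), ("MS-Sec",),
    ("SA-I", "RA-I"), ("SA-I", "RA-I", "RA-II"), tuple(MODALITY_GROUPS),
)


@dataclass
class ExperimentReport:
    """Result table plus the config snapshot needed to reproduce it."""

    experiment_id: str
    config: dict
    table: list[dict]
    seeds: list[int]
    runtime_s: float = 0.0
    figures: list[str] = field(default_factory=list)

    def rows(self, **match) -> list[dict]:
        return [r for r in self.table
                if all(r.get(k) == v for k, v in match.items())]

    def to_json(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "config": self.config,
            "seeds": self.seeds,
            "runtime_s": self.runtime_s,
            "table": self.table,
            "figures": self.figures,
        }


def encode_dataset(specs: list[TextureSpec], speeds: list[float],
                   repetitions: int, seed: int,
                   target_mean: float = 7.2,
                   displacement_mm: float = 40.0,
                   indentation: float = 0.4,
                   spindle_cfg: SpindleConfig | None = None,
                   ) -> list[EncodedTrial]:
    """Simulate and encode a full factorial dataset with one innervation map.

    The innervation map is drawn once per dataset (fixed wiring across
    trials, as on a physical sensor) from ``seed``; per-trial simulator
    seeds derive from the same master seed.
    """
    imap = build_innervation(target_mean=target_mean, seed=seed)
    cfg = ScanConfig(speed=speeds[0], displacement=displacement_mm,
                     indentation=indentation)
    recordings = make_dataset(specs, speeds, repetitions, cfg,
                              master_seed=seed)
    params = IzhikevichParams()
    return [encode_trial(rec, imap, params=params, spindle_cfg=spindle_cfg)
            for rec in recordings]


def run_innervation_sweep(targets=DEFAULT_SWEEP_TARGETS,
                          n_textures: int = 6, speed: float = 90.0,
                          repetitions: int = 10,
                          seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                          knn_k: int = 1, folds: int = 5,
                          ) -> ExperimentReport:
    """Sweep the mean receptive-field size at the fastest scan speed.

    For each target density and seed, classifies ``n_textures`` textures
    from SA-I-only and RA-I-only spike-rate features with KNN.
    """
    if len(targets) < 2:
        raise ValueError("need at least two sweep targets")
    t0 = time.perf_counter()
    specs = default_texture_library()[:n_textures]
    table = []
    for seed in seeds:
        for target in targets:
            trials = encode_dataset(specs, [speed], repetitions, seed,
                                    target_mean=target)
            fm = build_feature_matrix(trials)
            for group in ("SA-I", "RA-I"):
                res = crossval_classify(fm, target="texture", clf="knn",
                                        folds=folds, seed=seed,
                                        groups=[group], k=knn_k)
                table.append({
                    "target_mean": target, "features": group, "seed": seed,
                    "accuracy": res.mean_accuracy,
                })
    config = {"targets": list(targets), "n_textures": n_textures,
              "speed": speed, "repetitions": repetitions, "knn_k": knn_k,
              "folds": folds}
    report = ExperimentReport("innervation_sweep", config, table,
                              list(seeds), time.perf_counter() - t0)
    return report


def _mean_over_seeds(table: list[dict], key: str, **match) -> float:
    vals = [r[key] for r in table
            if all(r.get(k) == v for k, v in match.items())]
    return float(np.mean(vals))


def run_fusion_experiment(n_textures: int = 10,
                          speeds: tuple[float, ...] = (40, 50, 60, 70, 80, 90),
                          repetitions: int = 10,
                          seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                          classifiers: tuple[str, ...] = ("rf", "knn"),
                          n_estimators: int = 1000, knn_k: int = 1,
                          folds: int = 5,
                          target: str = "texture") -> ExperimentReport:
    """Modality-ablation table on the full texture x speed x repetition grid.

    Reports paired-fold CV accuracy for every subset in
    :data:`FUSION_SUBSETS` and both classifiers; the headline comparison is
    all-modality fusion versus the SA-I + RA-I tactile pair.
    """
    t0 = time.perf_counter()
    specs = default_texture_library()[:n_textures]
    table = []
    for seed in seeds:
        trials = encode_dataset(specs, list(speeds), repetitions, seed)
        fm = build_feature_matrix(trials)
        for clf in classifiers:
            kwargs = ({"n_estimators": n_estimators} if clf == "rf"
                      else {"k": knn_k})
            results = ablate_modalities(
                fm, [list(s) for s in FUSION_SUBSETS], target=target,
                clf=clf, folds=folds, seed=seed, **kwargs)
            for key, res in results.items():
                table.append({
                    "subset": key, "clf": clf, "seed": seed,
                    "accuracy": res.mean_accuracy,
                    "fold_accuracies": res.fold_accuracies,
                })
    config = {"n_textures": n_textures, "speeds": list(speeds),
              "repetitions": repetitions, "classifiers": list(classifiers),
              "n_estimators": n_estimators, "knn_k": knn_k, "folds": folds,
              "target": target}
    return ExperimentReport("fusion", config, table, list(seeds),
                            time.perf_counter() - t0)


def run_displacement_experiment(
        displacements=DEFAULT_DISPLACEMENTS_MM,
        n_textures: int = 10,
        speeds: tuple[float, ...] = (40, 50, 60, 70, 80, 90),
        repetitions: int = 10,
        seeds: tuple[int, ...] = (0, 1, 2),
        clf: str = "rf", n_estimators: int = 1000, folds: int = 5,
        ) -> ExperimentReport:
    """Classification accuracy versus explored surface length.

    Features are recomputed on windows covering only the first X mm of
    each scan; the report flags the smallest X within 2 accuracy points of
    the best.
    """
    t0 = time.perf_counter()
    specs = default_texture_library()[:n_textures]
    max_disp = max(displacements)
    table = []
    for seed in seeds:
        trials = encode_dataset(specs, list(speeds), repetitions, seed,
                                displacement_mm=max_disp)
        for disp in displacements:
            fm = build_feature_matrix(trials, window_mm=disp)
            kwargs = {"n_estimators": n_estimators} if clf == "rf" else {}
            res = crossval_classify(fm, target="texture", clf=clf,
                                    folds=folds, seed=seed, **kwargs)
            table.append({"displacement_mm": disp, "seed": seed,
                          "accuracy": res.mean_accuracy})
    means = {d: _mean_over_seeds(table, "accuracy", displacement_mm=d)
             for d in displacements}
    best = max(means.values())
    sufficient = min(d for d, acc in means.items() if acc >= best - 0.02)
    config = {"displacements": list(displacements), "n_textures": n_textures,
              "speeds": list(speeds), "repetitions": repetitions,
              "clf": clf, "folds": folds,
              "sufficient_displacement_mm": sufficient}
    return ExperimentReport("displacement", config, table, list(seeds),
                            time.perf_counter() - t0)


def rate_vs_speed_table(texture_ids: tuple[int, ...] = (1, 6, 9),
                        speeds: tuple[float, float] = (40.0, 90.0),
                        repetitions: int = 3, seed: int = 0,
                        ) -> ExperimentReport:
    """Mean firing rate per afferent class at the slowest vs fastest speed."""
    t0 = time.perf_counter()
    lib = {s.texture_id: s for s in default_texture_library()}
    specs = [lib[t] for t in texture_ids]
    trials = encode_dataset(specs, list(speeds), repetitions, seed)
    fm = build_feature_matrix(trials)
    table = []
    for tex in texture_ids:
        row_entries = {}
        for speed in speeds:
            sel = np.array([m["texture_id"] == tex and m["speed"] == speed
                            for m in fm.meta])
            for group in MODALITY_GROUPS:
                cols = fm.columns_of([group])
                rate = float(np.mean(fm.X[np.ix_(sel, cols)]))
                row_entries[(group, speed)] = rate
                table.append({"texture_id": tex, "class": group,
                              "speed": speed, "mean_rate": rate})
        for group in MODALITY_GROUPS:
            slow = row_entries[(group, speeds[0])]
            fast = row_entries[(group, speeds[1])]
            table.append({"texture_id": tex, "class": group,
                          "speed": "ratio",
                          "mean_rate": fast / slow if slow > 0 else np.inf})
    config = {"texture_ids": list(texture_ids), "speeds": list(speeds),
              "repetitions": repetitions}
    return ExperimentReport("rate_vs_speed", config, table, [seed],
                            time.perf_counter() - t0)
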