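"""End-to-end orchestration of the recurrence-prediction experiments.

A run executes preprocessing -> pool2 feature extraction -> dynamic
selection -> OSF -> linear-SVM evaluation for one experiment preset, on
either a synthetic cohort or a manifest of image files, and writes a
machine-readable summary plus all intermediate artifacts (OSF table,
per-fold sets, selection traces, per-patient scores, log).

Presets mirror the three fine-tuning evaluations and the two timepoint
configurations: DSF (per-fold dynamically selected features), OSF (the
fixed optimal subset) and OSF+clinical, each for T1-only or T1-T2.
T1-only presets restrict the feature space to the pre-treatment block
(indices < 43264) before selection.

One root seed drives every stochastic stage through named substreams;
identical config + seed reproduces byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._rng import STREAM_COHORT, STREAM_SELECTION, derive_int_seed
from .classify_eval import ClinicalBlock, SvmConfig, loo_evaluate
from .cnn_features import (
    FEATURES_PER_ROI,
    SeededAlexNetBackend,
    extract_patient_matrix,
    locate_feature,
)
from .errors import ConfigurationError
from .preprocessing import preprocess_roi
from .stability_selection import (
    FeatureIndexSet,
    SelectionConfig,
    compute_osf,
    dynamic_selection,
)
from .synthetic_data import (
    CohortConfig,
    SyntheticPatient,
    cohort_labels,
    config_to_dict,
    generate_cohort,
    read_cohort,
)

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

#: preset -> (feature source mode, clinical flag, T1-only flag)
PRESETS: dict[str, tuple[str, bool, bool]] = {
    "DSF_T1": ("dynamic", False, True),
    "DSF_T1T2": ("dynamic", False, False),
    "OSF_T1": ("fixed", False, True),
    "OSF_T1T2": ("fixed", False, False),
    "OSF_clin_T1": ("fixed", True, True),
    "OSF_clin_T1T2": ("fixed", True, False),
}


@dataclass
class RunConfig:
    preset: str = "OSF_T1T2"
    cohort: CohortConfig | None = None
    manifest: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    backend_seed: int = 0
    out_dir: str = "runs/latest"
    seed: int = 0

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )
        if (self.cohort is None) == (self.manifest is None):
            raise ConfigurationError(
                "exactly one data source (cohort config or manifest) is required"
            )


def _load_patients(config: RunConfig) -> list[SyntheticPatient]:
    if config.manifest is not None:
        return read_cohort(config.manifest)
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=derive_int_seed(config.seed, STREAM_COHORT)
    )
    return generate_cohort(cohort_cfg)


def compute_feature_matrix(
    patients: list[SyntheticPatient], backend
) -> np.ndarray:
    """Preprocess both timepoints of every patient and extract descriptors."""
    rois_t1, rois_t2 = [], []
    for p in patients:
        rois_t1.append(
            preprocess_roi(p.slice_t1, p.mask_t1, p.ld_pixels, p.patient_id, "T1")
        )
        rois_t2.append(
            preprocess_roi(p.slice_t2, p.mask_t2, p.ld_pixels, p.patient_id, "T2")
        )
    return extract_patient_matrix(rois_t1, rois_t2, backend)


def _osf_rows(osf: FeatureIndexSet) -> list[dict]:
    rows = []
    for idx in osf.indices:
        tp = "T1" if idx < FEATURES_PER_ROI else "T2"
        loc = locate_feature(idx % FEATURES_PER_ROI, tp)
        rows.append(
            {
                "flat_index": idx,
                "timepoint": tp,
                "channel": loc.channel,
                "row": loc.row,
                "col": loc.col,
            }
        )
    return rows


def run(config: RunConfig) -> dict:
    """Execute one experiment preset; returns the summary dictionary.

    Artifacts written to ``config.out_dir``: summary.json, osf.csv,
    fold_sets.json, traces.jsonl, scores.csv, run.log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("stablerec")
    root.addHandler(handler)
    t_start = time.perf_counter()
    try:
        mode, with_clinical, t1_only = PRESETS[config.preset]

        stage_t = time.perf_counter()
        patients = _load_patients(config)
        labels = cohort_labels(patients)
        ids = [p.patient_id for p in patients]
        logger.info("loaded %d patients in %.1fs", len(patients), time.perf_counter() - stage_t)

        stage_t = time.perf_counter()
        backend = SeededAlexNetBackend(seed=config.backend_seed)
        features = compute_feature_matrix(patients, backend)
        logger.info("extracted features %s in %.1fs", features.shape, time.perf_counter() - stage_t)

        if t1_only:
            features_sel = features[:, :FEATURES_PER_ROI]
        else:
            features_sel = features

        stage_t = time.perf_counter()
        sel_cfg = dataclasses.replace(
            config.selection, seed=derive_int_seed(config.seed, STREAM_SELECTION)
        )
        fold_sets, traces = dynamic_selection(features_sel, labels, sel_cfg, ids)
        osf = compute_osf(fold_sets)
        logger.info(
            "selection done in %.1fs; |OSF| = %d %s",
            time.perf_counter() - stage_t,
            len(osf),
            osf.timepoint_counts(),
        )

        clinical = (
            [ClinicalBlock(p.age, p.er, p.pgr, p.her2) for p in patients]
            if with_clinical
            else None
        )
        source = fold_sets if mode == "dynamic" else osf
        report = loo_evaluate(
            features_sel, labels, ids, source, clinical, config.svm
        )

        summary = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "package_version": __version__,
            "preset": config.preset,
            "seed": config.seed,
            "backend_id": backend.backend_id,
            "config": {
                "cohort": config_to_dict(config.cohort) if config.cohort else None,
                "manifest": config.manifest,
                "selection": dataclasses.asdict(config.selection),
                "svm": dataclasses.asdict(config.svm),
            },
            "n_patients": len(patients),
            "n_non_rfsi": int(labels.sum()),
            "osf_size": len(osf),
            "osf_timepoint_counts": osf.timepoint_counts(),
            "osf_indices": list(osf.indices),
            "fold_set_sizes": {pid: len(s) for pid, s in fold_sets.items()},
            "metrics": report.summary_dict(),
        }

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        import csv as _csv

        with open(out / "osf.csv", "w", newline="") as fh:
            writer = _csv.DictWriter(
                fh, fieldnames=["flat_index", "timepoint", "channel", "row", "col"]
            )
            writer.writeheader()
            writer.writerows(_osf_rows(osf))
        with open(out / "fold_sets.json", "w") as fh:
            json.dump(
                {pid: list(s.indices) for pid, s in fold_sets.items()},
                fh,
                sort_keys=True,
            )
        with open(out / "traces.jsonl", "w") as fh:
            for tr in traces:
                for rec in tr.iterations:
                    fh.write(
                        json.dumps(
                            {
                                "fold_id": tr.fold_id,
                                "iteration": rec.iteration,
                                "subset_set_sizes": [len(s) for s in rec.subset_sets],
                                "union": list(rec.union),
                                "cumulative": list(rec.cumulative),
                                "discarded": rec.discarded,
                            },
                            sort_keys=True,
                        )
                        + "\n"
                    )
        with open(out / "scores.csv", "w", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["patient_id", "label", "score", "prediction"])
            for pid, lab, sc, pr in zip(
                report.patient_ids, report.labels, report.scores, report.predictions
            ):
                writer.writerow([pid, lab, repr(sc), pr])
        logger.info("run complete in %.1fs", time.perf_counter() - t_start)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
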