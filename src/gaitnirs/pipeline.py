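"""End-to-end reproducible runs: preprocess -> features -> selection -> GA/SVM.

A run reads a cohort directory, computes slope-feature matrices for all
trials, and — for each classification dimension (step length, walking
speed) — selects features on the training subjects, searches feature
subsets with the adaptive GA under leave-one-subject-out SVM fitness,
and finally scores the held-out test subjects.  All outputs are JSON
with sorted keys and no timestamps, so identical configurations produce
byte-identical reports; a provenance block (config hash, seed, package
version) makes any run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .bands import LEVEL, MODE, N_AVG, N_BANDS, WAVELET, compute_feature_matrix
from .classify import (
    GAParams,
    build_instances,
    ga_select,
    loso_fitness,
    train_and_test,
)
from .core import PRE_WINDOW, Recording, StageError, ValidationError
from .preprocess import SE_LENGTH
from .selection import ALPHA, FREQ_THRESHOLD, SelectionResult, select_features
from .states import DIMENSIONS

log = logging.getLogger("gaitnirs")


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from JSON."""

    cohort_dir: str
    output_dir: str
    training_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    window: int = PRE_WINDOW
    se_length: int = SE_LENGTH
    level: int = LEVEL
    n_bands: int = N_BANDS
    wavelet: str = WAVELET
    boundary_mode: str = MODE
    n_avg: int = N_AVG
    freq_threshold: float = FREQ_THRESHOLD
    alpha: float = ALPHA
    key_count_rule: str = "mode"
    ga: GAParams = field(default_factory=GAParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.training_subjects = tuple(self.training_subjects)
        self.test_subjects = tuple(self.test_subjects)
        if isinstance(self.ga, dict):
            self.ga = GAParams(**self.ga)
        overlap = set(self.training_subjects) & set(self.test_subjects)
        if overlap:
            raise ValidationError(f"training/test subjects overlap: {sorted(overlap)}")
        if not self.training_subjects:
            raise ValidationError("no training subjects")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def compute_all_features(
    recordings: Sequence[Recording], config: PipelineConfig
) -> dict[tuple[str, str, str], np.ndarray]:
    """Slope matrices for every trial, keyed (subject, state, kind)."""
    featmats = {}
    for rec in recordings:
        fm = compute_feature_matrix(
            rec,
            window=config.window,
            se_length=config.se_length,
            level=config.level,
            n_bands=config.n_bands,
            wavelet=config.wavelet,
            mode=config.boundary_mode,
            n_avg=config.n_avg,
        )
        featmats[(rec.subject_id, rec.state.label, rec.signal_kind)] = fm.values
    return featmats


def classify_dimension(
    featmats: Mapping[tuple[str, str, str], np.ndarray],
    config: PipelineConfig,
    dimension: str,
    selection: SelectionResult,
) -> dict:
    """GA subset search plus final train/test for one dimension."""
    specs = selection.specs
    report: dict = {
        "dimension": dimension,
        "candidate_features": [s.to_dict() for s in specs],
    }
    X_tr, y_tr, groups = build_instances(
        featmats, config.training_subjects, specs, dimension
    )
    if specs:
        ga = GAParams(**{**asdict(config.ga), "seed": config.seed})
        result = ga_select(
            len(specs), lambda m: loso_fitness(X_tr, y_tr, groups, m), ga
        )
        chosen = [s for s, keep in zip(specs, result.best_mask) if keep]
        report["ga"] = {
            "best_fitness": result.best_fitness,
            "n_evaluations": result.n_evaluations,
            "trace": result.trace.tolist(),
        }
    else:
        chosen = []
        report["ga"] = {"best_fitness": None, "n_evaluations": 0, "trace": []}
    report["selected_features"] = [s.to_dict() for s in chosen]
    X_tr_sel, y_tr, _ = build_instances(
        featmats, config.training_subjects, chosen, dimension
    )
    X_te, y_te, _ = build_instances(featmats, config.test_subjects, chosen, dimension)
    report["test"] = train_and_test(X_tr_sel, y_tr, X_te, y_te, dimension)
    return report


def run_pipeline(
    config: PipelineConfig, recordings: Sequence[Recording] | None = None
) -> dict:
    """Execute the full pipeline and write reports to the output dir.

    Returns the combined report dict; per-dimension JSON reports plus a
    run-level ``report.json`` are written under ``config.output_dir``.
    Any stage failure is re-raised as a :class:`StageError` tagged with
    the stage name.
    """
    from .io import read_cohort  # local import to avoid cycles

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if recordings is None:
        log.info("stage: read cohort (%s)", config.cohort_dir)
        recordings = _stage("read_cohort", read_cohort, config.cohort_dir)

    present = {r.subject_id for r in recordings}
    missing = (set(config.training_subjects) | set(config.test_subjects)) - present
    if missing:
        raise ValidationError(f"subjects not in cohort: {sorted(missing)}")

    log.info("stage: preprocessing and wavelet-packet slope features")
    featmats = _stage("band_features", compute_all_features, recordings, config)

    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "seed": config.seed,
            "version": __version__,
        },
        "dimensions": {},
    }
    for dimension in DIMENSIONS:
        log.info("stage: feature selection (%s)", dimension)
        selection = _stage(
            "feature_selection",
            select_features,
            featmats,
            config.training_subjects,
            dimension,
            threshold=config.freq_threshold,
            alpha=config.alpha,
            key_count_rule=config.key_count_rule,
        )
        log.info("stage: GA/SVM classification (%s)", dimension)
        dim_report = _stage(
            "classify", classify_dimension, featmats, config, dimension, selection
        )
        dim_report["selection"] = {
            "n_candidates": len(selection.candidate_specs),
            "pvalues": selection.pvalues,
            "class_means": selection.class_means,
        }
        report["dimensions"][dimension] = dim_report
        with open(out / f"report_{dimension}.json", "w") as fh:
            json.dump(dim_report, fh, indent=1, sort_keys=True)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ValidationError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(name, str(exc)) from exc
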