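"""End-to-end orchestration: filter -> reject -> baseline -> component
extraction -> per-band DSP fit/transform -> fusion -> selection -> CV.

Evaluation modes
----------------
``fit_scope="fold"`` (default)
    Honest reporting: the DSP models (and, with ``selection="forward"``,
    the feature ordering and forward selection) are refit inside each
    training fold; test folds only pass through frozen transforms.
``fit_scope="all"``
    Paper-style: models (and selection) fit on the full trial set,
    cross-validation only on the classifier. Optimistically biased.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_model import DEFAULT_BANDS, EpochSet
from .dsp import dsp_classic, dsp_improved, scatter_matrices, transform, vectorize
from .io import read_epochs
from .preprocess import (
    DEFAULT_COMPONENT_TABLE,
    bandpass_filter,
    baseline_correct,
    component_windows,
    extract_combine,
    reject_artifacts,
)
from .selection import (
    CvConfig,
    MetricsReport,
    confusion_metrics,
    fuse_bands,
    knn_predict,
    repeated_cv,
    sequential_select,
)
from . import simulate as sim

logger = logging.getLogger("dspline")

REPORT_SCHEMA = "dspline-report-1"
FUSION = "fusion"


@dataclass
class RunConfig:
    """One self-contained, serializable description of a pipeline run."""

    manifest: str | None = None            # canonical epochs on disk, or ...
    preset: str | None = None              # ... a synthetic preset name
    tasks: list = field(default_factory=lambda: [
        ("Ug", "Tg"), ("Ug", "Sc"), ("Tg", "Sc"),
    ])
    bands: list = field(default_factory=lambda: [
        "delta", "theta", "alpha", "beta", "whole", FUSION,
    ])
    backend: str = "improved"
    filter_order: int = 4
    threshold_uv: float = 75.0
    reg_gamma: float = 1e-3
    half_width: int = 2
    component_table: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_TABLE))
    k_neighbors: int = 3
    n_folds: int = 5
    n_repeats: int = 10
    fit_scope: str = "fold"                # fold | all
    selection: str = "forward"             # forward | none
    inner_repeats: int = 1
    n_components: int = 2                  # classic backend only
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = [list(t) for t in self.tasks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tasks" in d:
            d["tasks"] = [tuple(t) for t in d["tasks"]]
        if "component_table" in d:
            d["component_table"] = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in d["component_table"].items()
            }
        return cls(**d)


def _load_input(config: RunConfig) -> EpochSet:
    if config.manifest:
        path = Path(config.manifest)
        if not path.exists():
            raise FileNotFoundError(f"input manifest not found: {path}")
        return read_epochs(path)
    if config.preset:
        preset = {"paper": sim.paper_preset, "small": sim.small_preset}
        if config.preset not in preset:
            raise ValueError(f"unknown preset {config.preset!r}")
        epochs, _ = sim.generate(preset[config.preset](seed=config.seed))
        return epochs
    raise ValueError("RunConfig needs either a manifest or a preset")


def fit_transform_band(train: EpochSet, backend: str, reg_gamma: float,
                       n_components: int = 2, test: EpochSet | None = None):
    """Fit a DSP model on ``train`` and project train (and ``test``).

    Returns ``(train_features, test_features_or_None)``. The improved
    backend never materializes the D x D scatter above the dense limit.
    """
    v_train = vectorize(train)
    materialize = backend == "classic" or v_train.n_features <= 2000
    s = scatter_matrices(v_train, reg_gamma=reg_gamma, materialize=materialize)
    if backend == "improved":
        model = dsp_improved(s)
    elif backend == "classic":
        model = dsp_classic(s, m=min(n_components, v_train.n_features))
    else:
        raise ValueError(f"unknown backend {backend!r}")
    train_feats = transform(model, v_train)
    test_feats = transform(model, vectorize(test)) if test is not None else None
    return train_feats, test_feats


def _band_order(bands) -> list:
    return [b for b in bands if b != FUSION]


def evaluate_task_nested(extracted: dict, bands: list, config: RunConfig,
                         cfg: CvConfig) -> dict:
    """Per-fold refit evaluation of one label pair over all bands at once.

    ``extracted`` maps band name to the pair-subset, component-extracted
    EpochSet; all bands must carry the same trials in the same order so
    folds (and the fusion table) stay aligned. Returns band -> report.
    """
    member_bands = _band_order(bands)
    labels = extracted[member_bands[0]].labels
    y = np.asarray(labels, dtype=object)
    classes = np.unique(y)
    binary = len(classes) == 2
    positive = cfg.positive_class
    if binary and positive is None:
        positive = labels[0]
    n = len(labels)
    select = config.selection == "forward"

    acc: dict = {b: [] for b in bands}
    conf = {b: {"tp": 0, "fn": 0, "tn": 0, "fp": 0} for b in bands}
    sel_counts: dict = {b: [] for b in bands}
    for rep in range(cfg.n_repeats):
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                              random_state=cfg.seed + rep)
        correct = {b: 0 for b in bands}
        for train_idx, test_idx in skf.split(np.zeros(n), y):
            train_tbl, test_tbl = {}, {}
            for b in member_bands:
                es = extracted[b]
                train_tbl[b], test_tbl[b] = fit_transform_band(
                    es.subset(train_idx), config.backend, config.reg_gamma,
                    config.n_components, test=es.subset(test_idx),
                )
            if FUSION in bands:
                train_tbl[FUSION] = fuse_bands(
                    [train_tbl[b] for b in member_bands])
                test_tbl[FUSION] = fuse_bands(
                    [test_tbl[b] for b in member_bands])
            truth = [labels[i] for i in test_idx]
            for b in bands:
                tr, te = train_tbl[b], test_tbl[b]
                if select:
                    inner = CvConfig(
                        k_neighbors=cfg.k_neighbors, n_folds=cfg.n_folds,
                        n_repeats=config.inner_repeats,
                        seed=cfg.seed + 1000 * (rep + 1),
                        positive_class=positive,
                    )
                    cols, _ = sequential_select(tr, inner)
                    sel_counts[b].append(len(cols))
                    tr, te = tr.select_columns(cols), te.select_columns(cols)
                pred = knn_predict(tr, te, cfg.k_neighbors)
                correct[b] += sum(p == t for p, t in zip(pred, truth))
                if binary:
                    for t, p in zip(truth, pred):
                        if t == positive:
                            conf[b]["tp" if p == positive else "fn"] += 1
                        else:
                            conf[b]["tn" if p != positive else "fp"] += 1
        for b in bands:
            acc[b].append(100.0 * correct[b] / n)

    reports = {}
    for b in bands:
        sens = spec = None
        if binary:
            m = confusion_metrics(conf[b])
            sens, spec = m["sensitivity"], m["specificity"]
        reports[b] = MetricsReport(
            acc_mean=float(np.mean(acc[b])),
            acc_sd=float(np.std(acc[b], ddof=1)) if len(acc[b]) > 1 else 0.0,
            sensitivity=sens, specificity=spec,
            repeat_accuracies=list(acc[b]), confusion=conf[b],
            n_features=train_tbl[b].n_features,
            positive_class=positive if binary else None,
            selected_count=(int(round(float(np.mean(sel_counts[b]))))
                            if sel_counts[b] else None),
        )
    return reports


def evaluate_task_pooled(extracted: dict, bands: list, config: RunConfig,
                         cfg: CvConfig) -> dict:
    """Paper-style evaluation: models (and, for ``whole`` mode, feature
    selection) are fit on the full trial set before cross-validation."""
    member_bands = _band_order(bands)
    tables = {}
    for b in member_bands:
        tables[b], _ = fit_transform_band(
            extracted[b], config.backend, config.reg_gamma,
            config.n_components)
    if FUSION in bands:
        tables[FUSION] = fuse_bands([tables[b] for b in member_bands])
    reports = {}
    for b in bands:
        if config.selection == "forward":
            _, rep = sequential_select(tables[b], cfg)
        else:
            rep = repeated_cv(tables[b], cfg)
        reports[b] = rep
    return reports


def preprocess_bands(epochs: EpochSet, config: RunConfig):
    """Broadband filter + baseline + artifact rejection, then per-band
    filtered copies of the surviving trials.

    Rejection is decided once on the broadband signal so every band (and
    the fusion table) carries the identical trial set.
    """
    whole = DEFAULT_BANDS["whole"]
    base = bandpass_filter(epochs, whole, order=config.filter_order)
    base = baseline_correct(base)
    base, report = reject_artifacts(base, config.threshold_uv)
    logger.info("artifact rejection: kept %d/%d trials (per class: %s)",
                len(report.kept_ids), epochs.n_trials,
                report.surviving_per_class)
    surviving_raw = epochs.subset(report.kept_ids)

    band_sets = {}
    for name in _band_order(config.bands):
        if name == "whole":
            band_sets[name] = base
        else:
            band = DEFAULT_BANDS[name]
            filtered = bandpass_filter(surviving_raw, band,
                                       order=config.filter_order)
            band_sets[name] = baseline_correct(filtered)
    return band_sets, report


def run_pipeline(config: RunConfig, report_path) -> Path:
    """Execute the full chain and write a deterministic JSON report.

    Any stage failure aborts with the stage name; a partial report file
    is removed.
    """
    report_path = Path(report_path)
    stage = "load"
    try:
        if not _band_order(config.bands):
            raise ValueError("bands must include at least one frequency band")
        epochs = _load_input(config)
        logger.info("loaded %d trials (%d channels x %d samples)",
                    epochs.n_trials, epochs.n_channels, epochs.n_samples)

        stage = "preprocess"
        band_sets, rejection = preprocess_bands(epochs, config)

        stage = "extract"
        windows = component_windows(
            epochs.sampling_rate, epochs.onset_index,
            half_width=config.half_width, table=config.component_table,
            n_samples=epochs.n_samples,
        )
        extracted = {name: extract_combine(es, windows)
                     for name, es in band_sets.items()}

        stage = "evaluate"
        results: dict = {}
        any_band = next(iter(extracted.values()))
        for task in config.tasks:
            a, b = task
            task_key = f"{a}-vs-{b}"
            pair_idx = [i for i, lab in enumerate(any_band.labels)
                        if lab in (a, b)]
            if not pair_idx:
                raise ValueError(f"task {task_key}: no trials with these labels")
            pair_sets = {name: es.subset(pair_idx)
                         for name, es in extracted.items()}
            cfg = CvConfig(
                k_neighbors=config.k_neighbors, n_folds=config.n_folds,
                n_repeats=config.n_repeats, seed=config.seed,
                positive_class=a,
            )
            if config.selection not in ("forward", "none"):
                raise ValueError(
                    f"unknown selection mode {config.selection!r}")
            if config.fit_scope == "fold":
                reports = evaluate_task_nested(
                    pair_sets, config.bands, config, cfg)
            elif config.fit_scope == "all":
                reports = evaluate_task_pooled(
                    pair_sets, config.bands, config, cfg)
            else:
                raise ValueError(f"unknown fit scope {config.fit_scope!r}")
            results[task_key] = {name: rep.as_dict()
                                 for name, rep in reports.items()}
            for name, rep in reports.items():
                logger.info("%s / %s: ACC %.2f%% (SD %.2f)", task_key, name,
                            rep.acc_mean, rep.acc_sd)

        stage = "report"
        body = {
            "schema": REPORT_SCHEMA,
            "config": config.to_dict(),
            "rejection": {
                "removed_ids": rejection.removed_ids,
                "surviving_per_class": rejection.surviving_per_class,
            },
            "windows": {
                "combined_length": windows.combined_length,
                "windows": [list(w) for w in windows.windows],
            },
            "results": results,
        }
        report_path.parent.mkdir(parents=True, exist_ok=True)
        report_path.write_text(json.dumps(body, indent=2, sort_keys=True))
        return report_path
    except Exception as exc:
        if report_path.exists():
            report_path.unlink()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
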