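"""Self-contained property benchmarks used by the acceptance suite.

Each function recomputes one quantity from scratch by running the
package's public machinery on freshly generated synthetic inputs; no
stored results, no tuning toward expected values.
"""

from __future__ import annotations

import time

import numpy as np
import scipy.linalg

from .data_model import DEFAULT_BANDS
from .dsp import (
    VectorizedTrials,
    dsp_classic,
    dsp_improved,
    ridge_solve_lowrank,
    scatter_matrices,
    vectorize,
)
from .pipeline import RunConfig, evaluate_task_nested, preprocess_bands
from .preprocess import component_windows, extract_combine, reject_artifacts
from .selection import CvConfig, FeatureTable, confusion_metrics, repeated_cv
from . import simulate as sim


def _random_vectorized(rng, n_classes, dim, n_range=(4, 12), spread=1.0):
    vecs, labels = [], []
    for j in range(n_classes):
        nj = int(rng.integers(*n_range))
        mean = rng.normal(scale=spread, size=dim)
        vecs.append(mean + rng.normal(size=(nj, dim)))
        labels += [f"C{j}"] * nj
    return VectorizedTrials(vectors=np.vstack(vecs), labels=labels,
                            dims=(1, dim))


def scatter_identity_max_rel_err(n_instances=100, seed=0):
    """max over random instances of ||S_W + S_B - total|| / ||total||."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        dim = int(rng.integers(2, 21))
        k = int(rng.integers(2, 5))
        v = _random_vectorized(rng, k, dim)
        s = scatter_matrices(v, reg_gamma=1e-3, materialize=True)
        grand = v.vectors.mean(axis=0)
        total = (v.vectors - grand).T @ (v.vectors - grand)
        err = (np.linalg.norm(s.s_w + s.s_b - total)
               / max(np.linalg.norm(total), 1e-300))
        worst = max(worst, err)
    return worst


def zero_sum_identity_max(n_instances=100, seed=0):
    """max over random instances of ||sum_j n_j (M_j - M)|| (exact zero)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        dim = int(rng.integers(2, 21))
        k = int(rng.integers(2, 5))
        v = _random_vectorized(rng, k, dim, spread=10.0)
        s = scatter_matrices(v, reg_gamma=1e-3, materialize=False)
        scale = max(np.abs(s.class_means).max(), 1.0)
        worst = max(worst,
                    np.abs(s.class_offsets().sum(axis=0)).max() / scale)
    return worst


def oracle_equivalence_min_cos(n_instances=50, seed=0, gamma=1e-3):
    """min |cos| between the improved direction and the classic backend's
    leading generalized eigenvector on random two-class instances."""
    rng = np.random.default_rng(seed)
    worst = 1.0
    for _ in range(n_instances):
        dim = int(rng.integers(3, 51))
        v = _random_vectorized(rng, 2, dim, n_range=(dim + 2, dim + 10))
        s = scatter_matrices(v, reg_gamma=gamma, materialize=True)
        improved = dsp_improved(s)
        classic = dsp_classic(s, m=1)
        cos = abs(improved.W1[:, 0] @ classic.W1[:, 0])
        worst = min(worst, cos)
    return worst


def lowrank_solve_rel_err(dim=500, n=60, seed=0):
    """Matrix-free vs dense ridge solve at a dimension both can handle."""
    rng = np.random.default_rng(seed)
    v = _random_vectorized(rng, 2, dim, n_range=(n // 2, n // 2 + 1))
    s = scatter_matrices(v, reg_gamma=1e-3, materialize=True)
    b = s.class_offsets().T
    dense = np.linalg.solve(s.s_w + s.ridge * np.eye(dim), b)
    lowrank = ridge_solve_lowrank(s.centered, s.ridge, b)
    return float(np.linalg.norm(lowrank - dense) / np.linalg.norm(dense))


def lowrank_large_instance(n_channels=60, t_prime=182, n=60, seed=0):
    """Fit at D = n_channels * t_prime without materializing D x D.

    Returns ``(D, wall_seconds)``; raises if the lazy path would need the
    dense matrices.
    """
    rng = np.random.default_rng(seed)
    dim = n_channels * t_prime
    vecs = rng.normal(size=(n, dim))
    vecs[: n // 2] += 0.5
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    v = VectorizedTrials(vectors=vecs, labels=labels,
                         dims=(n_channels, t_prime))
    start = time.perf_counter()
    s = scatter_matrices(v, reg_gamma=1e-3, materialize=False)
    assert s.s_w is None and s.s_b is None
    model = dsp_improved(s, method="lowrank")
    elapsed = time.perf_counter() - start
    assert model.W1.shape == (dim, 2)
    return dim, elapsed


def recovery_cosines(n_seeds=20, seed=0):
    """|cos| between fitted improved direction and the analytic one."""
    out = []
    for s_off in range(n_seeds):
        cfg = sim.recovery_preset(seed=seed + s_off)
        epochs, truth = sim.generate(cfg)
        ex = extract_combine(epochs, sim.default_windows(cfg))
        v = vectorize(ex)
        model = dsp_improved(scatter_matrices(v, reg_gamma=1e-3))
        out.append(abs(model.W1[:, 0]
                       @ truth.pair_directions[("Ug", "Sc")]))
    return out


def _pair_subset(extracted, pair):
    labels = extracted.labels
    idx = [i for i, lab in enumerate(labels) if lab in pair]
    return extracted.subset(idx)


def _nested_acc(pair_set, seed, n_repeats=2):
    rc = RunConfig(selection="none")
    cv = CvConfig(n_repeats=n_repeats, seed=seed)
    reports = evaluate_task_nested({"whole": pair_set}, ["whole"], rc, cv)
    return reports["whole"].acc_mean


def classification_sanity(n_seeds=20, seed=0):
    """Full-pipeline accuracy on the separable preset and on a label
    permutation of the same data. Returns ``(accs, null_accs)``."""
    accs, nulls = [], []
    config = RunConfig(bands=["whole"], selection="none")
    for s_off in range(n_seeds):
        cfg = sim.small_preset(seed=seed + s_off)
        epochs, _ = sim.generate(cfg)
        band_sets, _ = preprocess_bands(epochs, config)
        windows = component_windows(
            epochs.sampling_rate, epochs.onset_index,
            n_samples=epochs.n_samples)
        ex = extract_combine(band_sets["whole"], windows)
        pair = _pair_subset(ex, ("Ug", "Sc"))
        accs.append(_nested_acc(pair, seed + s_off))
        rng = np.random.default_rng(seed + s_off)
        perm = pair.subset(range(pair.n_trials))
        perm.labels = list(rng.permutation(pair.labels))
        nulls.append(_nested_acc(perm, seed + s_off))
    return accs, nulls


def component_arithmetic():
    """Default window sample counts at 500 Hz, onset sample 100."""
    w = component_windows(500.0, 100)
    by_name = {n: (a, b) for n, a, b in w.windows}
    return {
        "lengths": {n: b - a for n, (a, b) in by_name.items()},
        "combined_length": w.combined_length,
        "n70_span": by_name["N70"],
    }


def artifact_rejection_exact(n_trials=300, rate=0.1, seed=0):
    """Planted artifacts vs rejected set; boundary inclusivity check.

    Returns ``(removed_matches_truth, n_removed, boundary_retained)``.
    """
    cfg = sim.small_preset(seed=seed, trials_per_class=n_trials // 3,
                           artifact_rate=rate)
    epochs, truth = sim.generate(cfg)
    _, report = reject_artifacts(epochs, 75.0)
    matches = report.removed_ids == truth.artifact_ids

    boundary = np.zeros((2, 10))
    boundary[0, 3] = 75.0
    boundary[1, 7] = -75.0
    from .data_model import EpochSet
    bset = EpochSet(trials=[boundary], labels=["x"],
                    channel_names=["a", "b"], sampling_rate=500.0)
    surv, _ = reject_artifacts(bset, 75.0)
    return matches, len(report.removed_ids), surv.n_trials == 1


def cv_protocol_checks(seed=0):
    """Determinism of repeated CV + confusion-ratio arithmetic."""
    rng = np.random.default_rng(seed)
    feats = FeatureTable(
        matrix=rng.normal(size=(40, 3)), labels=["A", "B"] * 20,
        feature_provenance=[("whole", j) for j in range(3)],
    )
    r1 = repeated_cv(feats, CvConfig(seed=seed))
    r2 = repeated_cv(feats, CvConfig(seed=seed))
    deterministic = (r1.repeat_accuracies == r2.repeat_accuracies
                     and r1.confusion == r2.confusion)
    m = confusion_metrics({"tp": 8, "fn": 2, "tn": 7, "fp": 3})
    return deterministic, m


def fusion_dominance(n_seeds=20, seed=0, n_repeats=2):
    """Per-seed (fused - best single band) accuracy margins."""
    bands = ["delta", "theta", "alpha", "beta", "whole", "fusion"]
    config = RunConfig(bands=bands, selection="none")
    margins = []
    for s_off in range(n_seeds):
        cfg = sim.multiband_preset(seed=seed + s_off)
        epochs, _ = sim.generate(cfg)
        band_sets, _ = preprocess_bands(epochs, config)
        windows = component_windows(
            epochs.sampling_rate, epochs.onset_index,
            table=cfg.latency_table, n_samples=epochs.n_samples)
        extracted = {b: extract_combine(es, windows)
                     for b, es in band_sets.items()}
        cv = CvConfig(n_repeats=n_repeats, seed=seed + s_off)
        reports = evaluate_task_nested(extracted, bands, config, cv)
        single = max(reports[b].acc_mean for b in bands if b != "fusion")
        margins.append(reports["fusion"].acc_mean - single)
    return margins
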