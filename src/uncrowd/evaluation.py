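"""Test protocol for (un)crowding, iteration sweeps and statistics.

Accuracy is the fraction of trials on which the vernier decoder picks the
true offset direction out of (left, right, no-vernier); picking
"no-vernier" while a vernier is present counts as an error. Uncrowding
scores are percent-correct differences against the matched
central-flanker-alone baseline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .heads_losses import VERNIER_LABELS
from .stimuli import (AugmentationConfig, StimulusConfig, TestCondition,
                      augment, compose_test_stimulus, render_vernier)
from .training import TrainedModel

DEFAULT_N_TRIALS = 1000


@dataclass
class ConditionResult:
    condition: str
    percent_correct: float
    n_trials: int
    network_id: int = 0
    routing_iterations: int | None = None


@dataclass
class UncrowdingScore:
    configuration: str
    delta: float        # percent_correct(config) - percent_correct(baseline)


@dataclass
class LineFit:
    slope: float
    intercept: float


# ----------------------------------------------------------------- inference
def predict_vernier_directions(model: TrainedModel, images: np.ndarray,
                               iterations: int | None = None) -> np.ndarray:
    """Predicted class index per image over (left, right, none)."""
    out = model.net.forward(images, iterations=iterations)
    if model.is_capsnet:
        scores = model.heads.decode_vernier(
            out, vernier_index=model.classes.index("vernier"))
    else:
        scores = model.heads.decode_vernier(out)
    return np.argmax(scores.data, axis=-1)


def _condition_trials(condition: TestCondition, cfg: StimulusConfig,
                      n_trials: int, rng: np.random.Generator,
                      aug: AugmentationConfig) -> tuple[np.ndarray, np.ndarray]:
    images, labels = [], []
    for _ in range(n_trials):
        direction = ("left", "right")[int(rng.integers(0, 2))]
        vern = render_vernier(direction, cfg)
        frame = compose_test_stimulus(vern, condition, cfg, rng)
        frame = augment(frame, aug, rng)
        images.append(frame.image)
        labels.append(VERNIER_LABELS.index(direction))
    return np.stack(images), np.array(labels)


def accuracy_on_condition(model: TrainedModel, condition: TestCondition,
                          n_trials: int = DEFAULT_N_TRIALS,
                          iterations: int | None = None,
                          rng: np.random.Generator | None = None,
                          aug: AugmentationConfig | None = None,
                          batch_size: int = 100) -> ConditionResult:
    """Percent correct left/right discrimination on one test condition."""
    if not model.trained:
        raise ValueError("model must be trained before evaluation")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng or np.random.default_rng()
    aug = aug or AugmentationConfig()
    images, labels = _condition_trials(condition, model.stimulus, n_trials,
                                       rng, aug)
    correct = 0
    for lo in range(0, n_trials, batch_size):
        batch = images[lo:lo + batch_size]
        preds = predict_vernier_directions(model, batch, iterations=iterations)
        correct += int((preds == labels[lo:lo + batch_size]).sum())
    return ConditionResult(condition.name, 100.0 * correct / n_trials,
                           n_trials, routing_iterations=iterations)


def uncrowding_score(model: TrainedModel, configuration: TestCondition,
                     baseline: TestCondition, n_trials: int = DEFAULT_N_TRIALS,
                     iterations: int | None = None,
                     rng: np.random.Generator | None = None) -> UncrowdingScore:
    """Delta percent correct: full configuration minus central flanker alone."""
    if configuration.baseline_name is not None and \
            baseline.name != configuration.baseline_name:
        raise ValueError(
            f"baseline {baseline.name!r} does not match the configuration's "
            f"required baseline {configuration.baseline_name!r}")
    rng = rng or np.random.default_rng()
    full = accuracy_on_condition(model, configuration, n_trials, iterations, rng)
    base = accuracy_on_condition(model, baseline, n_trials, iterations, rng)
    return UncrowdingScore(configuration.name,
                           full.percent_correct - base.percent_correct)


def iteration_sweep(model: TrainedModel, conditions: list[TestCondition],
                    iteration_range: range = range(1, 9),
                    n_trials: int = DEFAULT_N_TRIALS,
                    rng: np.random.Generator | None = None,
                    aug: AugmentationConfig | None = None) -> dict:
    """Error rate (100 - %correct) per routing iteration per condition."""
    if not model.is_capsnet:
        raise ValueError(
            "iteration sweeps are only supported for capsule networks")
    rng = rng or np.random.default_rng()
    out = {c.name: {} for c in conditions}
    for condition in conditions:
        for its in iteration_range:
            res = accuracy_on_condition(model, condition, n_trials,
                                        iterations=its, rng=rng, aug=aug)
            out[condition.name][its] = 100.0 - res.percent_correct
    return out


def top_reconstructions(model: TrainedModel, image: np.ndarray,
                        k: int = 3,
                        iterations: int | None = None) -> list[dict]:
    """Single-capsule reconstructions of the k most active secondaries."""
    if not model.is_capsnet:
        raise ValueError("per-capsule reconstructions require a capsule model")
    n_types = len(model.classes)
    if k > n_types:
        raise ValueError(f"k={k} exceeds the {n_types} capsule types")
    secondary = model.net.forward(image[None], iterations=iterations)
    norms = secondary.norms.data[0]
    order = np.argsort(-norms)[:k]
    results = []
    for idx in order:
        mask = np.zeros((1, n_types))
        mask[0, idx] = 1.0
        rec = model.heads.reconstruct(secondary, mask=mask)
        results.append({"capsule": model.classes[idx], "norm": float(norms[idx]),
                        "reconstruction": rec.data[0]})
    return results


# ---------------------------------------------------------------- statistics
def fit_line(x, y) -> LineFit:
    """Ordinary least squares for y = a x + b."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least 2 distinct x values")
    a, b = np.polyfit(x, y, 1)
    return LineFit(float(a), float(b))


def compare_slopes(slopes_a, slopes_b) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-subject / per-network slopes."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 slopes per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def one_sample_test(values, reference: float) -> tuple[float, float]:
    """Two-sided one-sample t-test against a reference value."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.var(v) == 0:
        if np.allclose(v.mean(), reference):
            return 0.0, 1.0
        raise ValueError("zero variance in the sample")
    t, p = stats.ttest_1samp(v, reference)
    return float(t), float(p)


# ------------------------------------------------------------------- tables
def results_to_csv(rows: list[dict], path: str | Path) -> None:
    """Tidy CSV: network, arch, condition, iterations, n_trials, %correct, delta."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["network", "arch", "condition", "iterations", "n_trials",
            "percent_correct", "delta"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in cols})
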