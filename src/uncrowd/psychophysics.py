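"""Adaptive staircase (PEST) and cumulative-Gaussian threshold estimation.

Stimulus geometry is expressed in arcmin of visual angle. The staircase
targets 75% correct, starting at 16.66' and never exceeding 33.3'; runs
are split into blocks of 80 trials (160 per condition). Thresholds come
from a maximum-likelihood cumulative-Gaussian (probit) fit; human
observers are replaced by simulated 2AFC observers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .evaluation import LineFit, compare_slopes, fit_line, one_sample_test


@dataclass
class GeometrySpec:
    """Human-experiment stimulus geometry (arcmin unless noted)."""

    vernier_line_length: float = 40.0
    vernier_gap: float = 4.0
    eccentricity_deg: float = 5.0
    fixation_cross: float = 6.0
    flanker_line_length: float = 84.0
    flanker_distance: float = 40.0
    cuboid_width: float = 58.0
    oblique_angle_deg: float = 135.0
    oblique_length: float = 23.33
    viewing_distance_cm: float = 75.0

    def __post_init__(self):
        for name in ("vernier_line_length", "vernier_gap", "flanker_line_length",
                     "flanker_distance", "cuboid_width", "oblique_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @staticmethod
    def arcmin_to_deg(arcmin: float) -> float:
        return arcmin / 60.0


@dataclass
class StaircaseConfig:
    target_proportion: float = 0.75
    start_offset: float = 16.66
    max_offset: float = 33.3          # twice the starting value
    min_offset: float = 0.1
    block_length: int = 80
    n_blocks: int = 2
    initial_step: float = 8.0
    min_step: float = 0.25
    max_step: float = 8.0
    wald_limit: float = 1.0           # PEST deviation limit W

    @property
    def total_trials(self) -> int:
        return self.block_length * self.n_blocks


@dataclass
class TrialRecord:
    offset: float                 # arcmin, magnitude
    direction: str                # 'left' | 'right'
    response: str                 # 'left' | 'right' | 'omitted'
    correct: bool


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    threshold: float              # offset at the target proportion correct
    guess_rate: float
    log_likelihood: float


# ----------------------------------------------------------------- observers
def make_simulated_observer(true_threshold: float, spread: float,
                            lapse_rate: float = 0.0):
    """2AFC observer: p(correct) = 0.5 + (0.5 - lapse) * Phi((x - shift)/spread).

    ``shift`` is chosen so that accuracy is exactly 0.75 at
    ``true_threshold``. Returns a callable offset -> probability correct.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if not 0 <= lapse_rate <= 0.1:
        raise ValueError("lapse rate must lie in [0, 0.1]")
    amp = 0.5 - lapse_rate
    shift = true_threshold - spread * stats.norm.ppf(0.25 / amp)

    def observer(offset: float) -> float:
        return 0.5 + amp * stats.norm.cdf((offset - shift) / spread)

    observer.true_threshold = true_threshold
    observer.spread = spread
    observer.lapse_rate = lapse_rate
    return observer


# ------------------------------------------------------------------ staircase
def _pest_block(observer, config: StaircaseConfig,
                rng: np.random.Generator) -> list[TrialRecord]:
    """One PEST block: Wald rule for level changes, standard step-size rules."""
    level = config.start_offset
    step = config.initial_step
    trials: list[TrialRecord] = []
    n_at_level = 0
    c_at_level = 0
    last_direction = 0           # -1 down (harder), +1 up (easier)
    same_direction_steps = 0
    doubled_before_reversal = False
    p_target = config.target_proportion
    for _ in range(config.block_length):
        direction = ("left", "right")[int(rng.integers(0, 2))]
        p = observer(level)
        correct = bool(rng.random() < p)
        response = direction if correct else \
            ("right" if direction == "left" else "left")
        trials.append(TrialRecord(level, direction, response, correct))
        n_at_level += 1
        c_at_level += int(correct)
        expected = p_target * n_at_level
        move = 0
        if c_at_level - expected >= config.wald_limit:
            move = -1            # performing above target: make it harder
        elif expected - c_at_level >= config.wald_limit:
            move = +1            # below target: make it easier
        if move == 0:
            continue
        if last_direction != 0 and move != last_direction:
            # reversal: halve the step
            doubled_before_reversal = same_direction_steps >= 3
            step = max(step / 2.0, config.min_step)
            same_direction_steps = 1
        else:
            same_direction_steps += 1
            if same_direction_steps == 3 and not doubled_before_reversal:
                step = min(step * 2.0, config.max_step)
            elif same_direction_steps > 3:
                step = min(step * 2.0, config.max_step)
        last_direction = move
        level = level + move * step
        level = float(np.clip(level, config.min_offset, config.max_offset))
        n_at_level = 0
        c_at_level = 0
    return trials


def run_pest(observer, config: StaircaseConfig | None = None,
             rng: np.random.Generator | None = None) -> list[TrialRecord]:
    """Full PEST run (n_blocks blocks); offsets never exceed the cap."""
    config = config or StaircaseConfig()
    rng = rng or np.random.default_rng()
    probe = [observer(x) for x in (1.0, 10.0, 30.0)]
    if any(b < a - 1e-9 for a, b in zip(probe, probe[1:])):
        import warnings
        warnings.warn("observer response function is not monotone; "
                      "the psychometric fit may fail")
    trials: list[TrialRecord] = []
    for _ in range(config.n_blocks):
        trials.extend(_pest_block(observer, config, rng))
    return trials


# ---------------------------------------------------------------------- fits
def fit_psychometric(trials: list[TrialRecord],
                     guess_rate: float = 0.5,
                     target_proportion: float = 0.75) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of correctness vs offset.

    With guess_rate = 0.5 (2AFC floor): p(x) = 0.5 + 0.5 Phi((x-mu)/sigma)
    and the 75% threshold equals mu. With guess_rate = 0 (plain probit):
    threshold = mu + z(0.75) sigma.
    """
    x = np.array([t.offset for t in trials], dtype=float)
    y = np.array([t.correct for t in trials], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("trials must span at least 2 offset levels")
    if y.all() or not y.any():
        raise ValueError("degenerate data: all responses correct or incorrect "
                         "(perfect separation, no maximum-likelihood fit)")
    g = guess_rate

    def nll(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        p = g + (1 - g) * stats.norm.cdf((x - mu) / sigma)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

    # probit-style starting point from a linearized fit
    mu0 = float(np.average(x, weights=np.ones_like(x)))
    best = None
    for s0 in (0.5, 2.0, 8.0):
        res = optimize.minimize(nll, [mu0, np.log(s0)], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = float(best.x[0]), float(np.exp(best.x[1]))
    z = stats.norm.ppf((target_proportion - g) / (1 - g))
    threshold = mu + sigma * z
    return PsychometricFit(mu, sigma, float(threshold), g, float(-best.fun))


def estimate_threshold(observer, config: StaircaseConfig | None = None,
                       rng: np.random.Generator | None = None,
                       guess_rate: float = 0.5) -> tuple[float, list[TrialRecord]]:
    """Staircase + fit in one call; returns (threshold, trials)."""
    trials = run_pest(observer, config, rng)
    fit = fit_psychometric(trials, guess_rate=guess_rate)
    return fit.threshold, trials


# --------------------------------------------------------------- group study
def duration_series_analysis(thresholds_by_subject: dict) -> dict:
    """Per-subject line fits of threshold vs duration plus the slope set.

    ``thresholds_by_subject``: {subject: {duration_ms: threshold_arcmin}}.
    Returns {'fits': {subject: LineFit}, 'slopes': np.ndarray}.
    """
    fits = {}
    for subject, series in thresholds_by_subject.items():
        if len(series) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 durations")
        durations = sorted(series)
        fits[subject] = fit_line(durations, [series[d] for d in durations])
    slopes = np.array([f.slope for f in fits.values()])
    return {"fits": fits, "slopes": slopes}


def compare_conditions(thresholds_a: dict, thresholds_b: dict) -> dict:
    """Slope comparison between two conditions (two-sample t-test)."""
    slopes_a = duration_series_analysis(thresholds_a)["slopes"]
    slopes_b = duration_series_analysis(thresholds_b)["slopes"]
    t, p = compare_slopes(slopes_a, slopes_b)
    return {"t": t, "p": p, "slopes_a": slopes_a, "slopes_b": slopes_b}


def crowding_check(condition_thresholds, vernier_alone_threshold: float) -> dict:
    """One-sample t-test of condition thresholds against the vernier-alone one."""
    t, p = one_sample_test(condition_thresholds, vernier_alone_threshold)
    return {"t": t, "p": p}
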