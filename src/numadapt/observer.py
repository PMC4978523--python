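"""Generative observer model and experiment simulators.

The observer perceives a numerosity ``n`` as ``g · n · (1 + w·ε)`` with
``ε ~ N(0, 1)``: a multiplicative adaptation gain ``g`` (keyed to the
adaptation level and to whether the test appeared on the adapted screen
side) times scalar Weber-like noise with coefficient of variation ``w``.
Responses are rounded to integers and floored at ``min_response``.

Two experiments are simulated from this model:

* magnitude estimation — numerosities 6–14, two adaptation levels, test on
  the adapted (congruent) or opposite (incongruent) screen side;
* two-alternative forced choice — two dot clouds with numerosities in 5–20
  differing by at most 5; the probability of judging the right (adapted)
  side more numerous follows a cumulative Gaussian in the normalized
  difference ``x = (n_R − n_L) / ((n_R + n_L)/2)``.

Adaptation is keyed to SCREEN SIDE (external coordinates), not to the
tapping hand: the crossed-hand condition is simulated by moving the adapted
side.  One RNG stream is derived per subject from the master seed, so
adding subjects never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import InvalidParameterError

__all__ = [
    "ObserverParams",
    "ExperimentDesign",
    "perceive_numerosity",
    "simulate_estimation_experiment",
    "simulate_forced_choice_experiment",
    "ESTIMATION_COLUMNS",
    "FORCED_CHOICE_COLUMNS",
]

ESTIMATION_COLUMNS = [
    "subject_id", "condition_label", "adaptation", "test_side",
    "congruent", "n_true", "response",
]
FORCED_CHOICE_COLUMNS = [
    "subject_id", "adaptation", "n_right", "n_left", "x", "choice_right_more",
]

CONDITION_LABELS = (
    "sequential", "simultaneous", "visual_tactile", "tactile_only",
    "visual_only", "rh_right", "lh_left", "rh_left",
)


@dataclass(frozen=True)
class ObserverParams:
    """Gains per (adaptation level, congruency) and Weber fraction.

    ``gain`` maps ``(adaptation, congruency)`` with adaptation in
    {"fast", "slow", "none"} and congruency in {"congruent", "incongruent"}
    to a multiplicative factor.  Unlisted keys default to 1 (no bias);
    the "none" level is pinned to 1.
    """

    gain: dict = field(default_factory=dict)
    weber_fraction: float = 0.15
    min_response: int = 1

    def __post_init__(self):
        if self.weber_fraction < 0:
            raise InvalidParameterError("weber_fraction must be >= 0")
        if self.min_response < 0:
            raise InvalidParameterError("min_response must be >= 0")
        for (level, cong), g in self.gain.items():
            if g <= 0:
                raise InvalidParameterError(f"gain for {(level, cong)} must be > 0")
            if level == "none" and g != 1.0:
                raise InvalidParameterError("gain for adaptation 'none' must be 1")

    @classmethod
    def from_gains(
        cls,
        g_fast: float = 1.0,
        g_slow: float = 1.0,
        g_fast_incongruent: float = 1.0,
        g_slow_incongruent: float = 1.0,
        weber_fraction: float = 0.15,
        min_response: int = 1,
    ) -> "ObserverParams":
        """Build params from the four fast/slow × congruent/incongruent gains."""
        gain = {
            ("fast", "congruent"): g_fast,
            ("slow", "congruent"): g_slow,
            ("fast", "incongruent"): g_fast_incongruent,
            ("slow", "incongruent"): g_slow_incongruent,
        }
        return cls(gain=gain, weber_fraction=weber_fraction, min_response=min_response)

    def gain_for(self, adaptation: str, congruent: bool) -> float:
        if adaptation == "none":
            return 1.0
        key = (adaptation, "congruent" if congruent else "incongruent")
        return self.gain.get(key, 1.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of a simulated session."""

    subjects: int = 6
    trials_per_cell: int = 15
    numerosities: tuple = tuple(range(6, 15))
    adaptation_levels: tuple = ("fast", "slow")
    sides_tested: tuple = ("left", "right")
    adapted_side: str = "right"
    condition_label: str = "sequential"
    seed: int = 0

    def __post_init__(self):
        if self.subjects < 1 or self.trials_per_cell < 1:
            raise InvalidParameterError("subjects and trials_per_cell must be >= 1")
        nums = tuple(self.numerosities)
        if sorted(set(nums)) != list(nums):
            raise InvalidParameterError("numerosities must be sorted and unique")
        if self.adapted_side not in ("left", "right"):
            raise InvalidParameterError("adapted_side must be 'left' or 'right'")

    @property
    def n_trials(self) -> int:
        return (
            self.subjects * self.trials_per_cell * len(self.numerosities)
            * len(self.adaptation_levels) * len(self.sides_tested)
        )


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _perceive_vec(
    params: ObserverParams, n_true: np.ndarray, gains: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    eps = rng.standard_normal(n_true.shape)
    raw = gains * n_true * (1.0 + params.weber_fraction * eps)
    resp = np.floor(raw + 0.5).astype(int)  # round half up
    return np.maximum(resp, params.min_response)


def perceive_numerosity(
    params: ObserverParams,
    n_true: int,
    adaptation: str = "none",
    congruent: bool = True,
    rng_seed=None,
) -> int:
    """Draw one integer estimation response from the observer model."""
    if n_true < 1:
        raise InvalidParameterError("n_true must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    g = params.gain_for(adaptation, congruent)
    return int(_perceive_vec(params, np.asarray([float(n_true)]), np.asarray([g]), rng)[0])


def simulate_estimation_experiment(
    design: ExperimentDesign, params: ObserverParams
) -> "pd.DataFrame":
    """Simulate a full magnitude-estimation session.

    Returns one row per trial with columns ``ESTIMATION_COLUMNS``.  Cells
    (subject × adaptation × side × numerosity) are fully balanced with
    ``trials_per_cell`` trials each; row order is shuffled within subject.
    """
    import pandas as pd

    rngs = _subject_rngs(design.seed, design.subjects)
    nums = np.asarray(design.numerosities, dtype=int)
    frames = []
    for s_idx, rng in enumerate(rngs):
        grid = [
            (adapt, side, n)
            for adapt in design.adaptation_levels
            for side in design.sides_tested
            for n in nums
        ]
        rows = np.repeat(np.arange(len(grid)), design.trials_per_cell)
        rng.shuffle(rows)
        adapt = np.array([grid[i][0] for i in rows])
        side = np.array([grid[i][1] for i in rows])
        n_true = np.array([grid[i][2] for i in rows], dtype=int)
        congruent = side == design.adapted_side
        gains = np.array(
            [params.gain_for(a, c) for a, c in zip(adapt, congruent)]
        )
        response = _perceive_vec(params, n_true.astype(float), gains, rng)
        frames.append(pd.DataFrame({
            "subject_id": f"s{s_idx}",
            "condition_label": design.condition_label,
            "adaptation": adapt,
            "test_side": side,
            "congruent": congruent,
            "n_true": n_true,
            "response": response,
        }))
    return pd.concat(frames, ignore_index=True)[ESTIMATION_COLUMNS]


def simulate_forced_choice_experiment(
    design: ExperimentDesign,
    psychometric: dict,
    n_min: int = 5,
    n_max: int = 20,
    max_delta: int = 5,
) -> "pd.DataFrame":
    """Simulate a 2AFC numerosity-comparison session.

    ``psychometric`` maps adaptation level to ``(mu, sigma)`` of the
    cumulative-Gaussian choice law on the normalized-difference axis.  The
    right-side numerosity is uniform on ``[n_min, n_max]``; the left differs
    by a uniform offset in ``±max_delta`` clamped back into range.
    ``design.trials_per_cell`` counts trials per adaptation level.
    Equal numerosities give x = 0 and hence a fair-coin choice.
    """
    import pandas as pd

    for level, (mu, sigma) in psychometric.items():
        if sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0 for level {level!r}")
    rngs = _subject_rngs(design.seed, design.subjects)
    frames = []
    for s_idx, rng in enumerate(rngs):
        for level, (mu, sigma) in psychometric.items():
            m = design.trials_per_cell
            n_right = rng.integers(n_min, n_max + 1, size=m)
            delta = rng.integers(-max_delta, max_delta + 1, size=m)
            n_left = np.clip(n_right + delta, n_min, n_max)
            x = (n_right - n_left) / ((n_right + n_left) / 2.0)
            p_right = norm.cdf((x - mu) / sigma)
            choice = rng.uniform(size=m) < p_right
            frames.append(pd.DataFrame({
                "subject_id": f"s{s_idx}",
                "adaptation": level,
                "n_right": n_right,
                "n_left": n_left,
                "x": x,
                "choice_right_more": choice,
            }))
    return pd.concat(frames, ignore_index=True)[FORCED_CHOICE_COLUMNS]
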