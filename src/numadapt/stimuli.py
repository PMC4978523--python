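"""Stimulus and motor-bout generators.

Three kinds of event are produced, mirroring the structure of a
tapping-adaptation numerosity experiment:

* :class:`TappingBout` — a 6-s bout of finger taps at a fast (~5–6 Hz) or
  slow (~0.7–1.3 Hz) rate; the adapting action.
* :class:`FlashTrain` — a sequential numerosity stimulus: ``n`` brief white
  disks jittered inside a 2-s window with a minimum inter-stimulus interval.
* :class:`DotCloud` — a simultaneous numerosity stimulus: non-overlapping
  half-white/half-black dots inside a circular region.

All generators are deterministic given ``rng`` / ``rng_seed`` and validate
their geometry on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FeasibilityError, InvalidParameterError, PackingError

__all__ = [
    "TappingBout",
    "FlashTrain",
    "DotCloud",
    "generate_tapping_bout",
    "generate_flash_train",
    "generate_dot_cloud",
]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


@dataclass(frozen=True)
class TappingBout:
    """One adaptation bout: ordered tap times within ``[0, duration_s]``."""

    condition: str
    duration_s: float
    tap_times_s: tuple[float, ...]
    subject_id: str = "s0"
    hand: str = "right"
    side: str = "right"  # screen side, external coordinates

    def __post_init__(self):
        t = np.asarray(self.tap_times_s, dtype=float)
        if t.size and (t.min() < 0 or t.max() > self.duration_s):
            raise InvalidParameterError("tap times must lie in [0, duration]")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("tap times must be strictly increasing")

    @property
    def n_taps(self) -> int:
        return len(self.tap_times_s)

    @property
    def rate_hz(self) -> float:
        return self.n_taps / self.duration_s


@dataclass(frozen=True)
class FlashTrain:
    """A sequence of flashes; onsets in ms relative to window start."""

    n_events: int
    onsets_ms: tuple[float, ...]
    flash_ms: float = 40.0
    window_ms: float = 2000.0
    disk_diam_deg: float = 7.0

    def __post_init__(self):
        if self.n_events != len(self.onsets_ms):
            raise InvalidParameterError("n_events must equal len(onsets_ms)")

    def isis_ms(self) -> np.ndarray:
        """Gaps between one flash's offset and the next flash's onset."""
        on = np.asarray(self.onsets_ms)
        return on[1:] - (on[:-1] + self.flash_ms)


@dataclass(frozen=True)
class DotCloud:
    """Non-overlapping dots in a circular region; centers in deg re cloud center."""

    n_dots: int
    centers_deg: tuple[tuple[float, float], ...]
    colors: tuple[str, ...]
    dot_diam_deg: float = 0.3
    region_diam_deg: float = 7.0
    eccentricity_deg: float = 7.0  # signed horizontal offset of the cloud center

    def __post_init__(self):
        if self.n_dots != len(self.centers_deg) or self.n_dots != len(self.colors):
            raise InvalidParameterError("centers and colors must match n_dots")

    def min_pairwise_distance(self) -> float:
        c = np.asarray(self.centers_deg)
        if len(c) < 2:
            return math.inf
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        return float(d[np.triu_indices(len(c), k=1)].min())


def generate_tapping_bout(
    condition: str,
    duration_s: float = 6.0,
    rate_mean_hz: float | None = None,
    rate_sd_hz: float = 0.0,
    rng_seed=None,
    jitter_frac: float = 0.2,
    subject_id: str = "s0",
    hand: str = "right",
    side: str = "right",
) -> TappingBout:
    """Simulate one tapping bout.

    The subject's rate is drawn from Normal(rate_mean, rate_sd) truncated to
    positive values; taps are evenly spaced at that rate with ±``jitter_frac``
    uniform jitter per interval, so the tap count is ``round(rate × duration)``.
    Defaults for the rate follow the fast (5.5 Hz) and slow (1.1 Hz)
    conditions when ``rate_mean_hz`` is omitted.
    """
    if condition not in ("fast", "slow"):
        raise InvalidParameterError(f"condition must be 'fast' or 'slow', got {condition!r}")
    if rate_mean_hz is None:
        rate_mean_hz = 5.5 if condition == "fast" else 1.1
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    if rate_mean_hz <= 0:
        raise InvalidParameterError("rate_mean_hz must be positive")
    if rate_sd_hz < 0:
        raise InvalidParameterError("rate_sd_hz must be non-negative")

    rng = _as_rng(rng_seed)
    rate = rate_mean_hz
    if rate_sd_hz > 0:
        rate = 0.0
        while rate <= 0:
            rate = rng.normal(rate_mean_hz, rate_sd_hz)
    n_taps = int(np.floor(rate * duration_s + 0.5))  # round half up
    if n_taps == 0:
        return TappingBout(condition, duration_s, (), subject_id, hand, side)
    interval = duration_s / n_taps
    base = (np.arange(n_taps) + 0.5) * interval
    # jitter < interval/2 keeps the sequence strictly increasing and in range
    jitter = rng.uniform(-jitter_frac, jitter_frac, size=n_taps) * interval
    times = np.clip(base + jitter, 0.0, duration_s)
    return TappingBout(condition, duration_s, tuple(times.tolist()), subject_id, hand, side)


def generate_flash_train(
    n_events: int,
    window_ms: float = 2000.0,
    flash_ms: float = 40.0,
    min_isi_ms: float = 40.0,
    rng_seed=None,
    disk_diam_deg: float = 7.0,
) -> FlashTrain:
    """Sample flash onsets uniformly under the minimum-ISI constraint.

    Feasibility requires ``n·flash + (n−1)·min_isi ≤ window``.  Onsets are
    drawn uniformly over the constrained region via the spacing transform:
    lay down the minimum occupancy, then distribute the slack with sorted
    uniform draws.  This is the same distribution as accept/reject of
    uniform onsets, but succeeds even at tight packings.
    """
    if n_events < 1:
        raise InvalidParameterError("n_events must be >= 1")
    occupancy = n_events * flash_ms + (n_events - 1) * min_isi_ms
    if occupancy > window_ms:
        raise FeasibilityError(
            f"cannot place {n_events} flashes of {flash_ms} ms with "
            f"min ISI {min_isi_ms} ms in {window_ms} ms "
            f"(minimum occupancy {occupancy} ms)"
        )
    rng = _as_rng(rng_seed)
    slack = window_ms - occupancy
    u = np.sort(rng.uniform(0.0, slack, size=n_events))
    onsets = np.arange(n_events) * (flash_ms + min_isi_ms) + u
    return FlashTrain(
        n_events=n_events,
        onsets_ms=tuple(onsets.tolist()),
        flash_ms=flash_ms,
        window_ms=window_ms,
        disk_diam_deg=disk_diam_deg,
    )


def generate_dot_cloud(
    n_dots: int,
    region_diam_deg: float = 7.0,
    dot_diam_deg: float = 0.3,
    rng_seed=None,
    eccentricity_deg: float = 7.0,
    max_iter: int = 10_000,
) -> DotCloud:
    """Dart-throwing placement of non-overlapping dots in a circular region.

    Colors are split half white / half black; an odd count gives the extra
    dot to white.  A packing-density pre-check rejects hopeless requests
    before sampling; otherwise placement retries up to ``max_iter`` times
    per cloud and raises :class:`PackingError` on failure.
    """
    if n_dots < 1:
        raise InvalidParameterError("n_dots must be >= 1")
    if dot_diam_deg <= 0 or region_diam_deg <= 0:
        raise InvalidParameterError("diameters must be positive")
    r_region = region_diam_deg / 2.0
    r_dot = dot_diam_deg / 2.0
    if r_dot > r_region:
        raise FeasibilityError("dot larger than region")
    # disks of radius r_dot cannot exceed ~90% hexagonal packing of the region
    density = n_dots * r_dot**2 / r_region**2
    if density > 0.9:
        raise PackingError(
            f"{n_dots} dots of {dot_diam_deg} deg cannot pack a "
            f"{region_diam_deg} deg region (density {density:.2f})"
        )
    rng = _as_rng(rng_seed)
    r_max = r_region - r_dot  # keeps dots fully inside the region
    centers: list[tuple[float, float]] = []
    pts = np.empty((0, 2))
    attempts = 0
    while len(centers) < n_dots:
        if attempts >= max_iter:
            raise PackingError(
                f"failed to place {n_dots} dots after {max_iter} attempts"
            )
        attempts += 1
        theta = rng.uniform(0, 2 * math.pi)
        rad = r_max * math.sqrt(rng.uniform())
        p = (rad * math.cos(theta), rad * math.sin(theta))
        if len(centers) and np.min(np.linalg.norm(pts - p, axis=1)) < dot_diam_deg:
            continue
        centers.append(p)
        pts = np.vstack([pts, p])
    n_white = (n_dots + 1) // 2  # odd count: extra dot is white
    colors = ("white",) * n_white + ("black",) * (n_dots - n_white)
    return DotCloud(
        n_dots=n_dots,
        centers_deg=tuple(centers),
        colors=colors,
        dot_diam_deg=dot_diam_deg,
        region_diam_deg=region_diam_deg,
        eccentricity_deg=eccentricity_deg,
    )
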