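"""Stimulus generation for the delayed match-to-numerosity task.

Sequential samples are sequences of centered single dots separated by pauses.
In the standard protocol the item and pause durations are drawn randomly anew
for every trial under two constraints: the whole sample period must add up to
2625 ms and no single item or pause may be shorter than 300 ms.  Two temporal
controls remove co-varying cues: the *equal variance* control fixes all
durations within a numerosity (total still 2625 ms, so single-interval
duration decreases with numerosity), and the *equal item duration* control
fixes every interval across numerosities (so total sample duration grows with
numerosity).

Simultaneous samples are dot arrays on a 30 mm gray background circle with
dot diameters between 2 and 4 mm.  The standard protocol randomizes dot size
and position; the area/density control equalizes total dot area and mean
pairwise center distance across numerosities.

A session is a balanced, shuffled crossing of numerosity (1-4) x format
(sequential/simultaneous) x protocol (standard/control) x match/non-match.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

#: Total sequential sample-period duration (items + pauses), ms.
SAMPLE_TOTAL_MS = 2625.0
#: Minimum duration of any single item or pause, ms.
MIN_INTERVAL_MS = 300.0
#: Memory delay duration, ms.
DELAY_MS = 1000.0
#: Pre-sample (empty background circle) duration, ms.
PRESAMPLE_MS = 500.0
#: Simultaneous sample (dot array) duration, ms.
SIM_SAMPLE_MS = 800.0
#: Test display duration; a second test follows 800 ms after the first.
TEST_MS = 800.0
#: Gray background circle diameter, mm.
BACKGROUND_DIAMETER_MM = 30.0
#: Dot radius range, mm (2-4 mm diameters).
DOT_RADIUS_RANGE_MM = (1.0, 2.0)
#: Numerosities used in the task.
NUMEROSITIES = (1, 2, 3, 4)
#: Extra pre-sample jitter applied to sequential-standard numerosity-1
#: trials so that sample onset alone does not predict the numerosity.
PRESAMPLE_JITTER_MAX_MS = 500.0


class Format(str, enum.Enum):
    """Presentation format of the sample numerosity."""

    SEQ = "seq"
    SIM = "sim"


class Protocol(str, enum.Enum):
    STANDARD = "standard"
    CONTROL = "control"


class SeqCondition(str, enum.Enum):
    """Timing condition of a sequential sample."""

    STANDARD = "standard"
    EQUAL_VARIANCE = "equal_variance"
    EQUAL_ITEM = "equal_item"


class DotCondition(str, enum.Enum):
    """Spatial condition of a simultaneous dot display."""

    STANDARD = "standard"
    AREA_DENSITY_CONTROL = "area_density_control"


class Choice(str, enum.Enum):
    """When the subject released the light barrier."""

    RESPOND_AT_TEST1 = "test1"
    RESPOND_AT_TEST2 = "test2"


class StimulusError(ValueError):
    """Raised for infeasible stimulus requests."""


def _check_numerosity(n: int) -> int:
    if n not in NUMEROSITIES:
        raise StimulusError(f"numerosity must be in {NUMEROSITIES}, got {n!r}")
    return int(n)


@dataclass
class SequentialTiming:
    """Realized item/pause durations of one sequential sample.

    The sample consists of ``numerosity`` items, each followed by a pause;
    the final pause abuts the delay period.
    """

    numerosity: int
    item_durations_ms: np.ndarray
    pause_durations_ms: np.ndarray
    condition: SeqCondition

    @property
    def total_ms(self) -> float:
        return float(np.sum(self.item_durations_ms) + np.sum(self.pause_durations_ms))

    def interleaved(self) -> np.ndarray:
        """Durations in presentation order: item1, pause1, item2, pause2, ..."""
        out = np.empty(2 * self.numerosity)
        out[0::2] = self.item_durations_ms
        out[1::2] = self.pause_durations_ms
        return out

    def item_onsets(self, sample_on_ms: float = 0.0) -> np.ndarray:
        """Item onset times relative to ``sample_on_ms``."""
        inter = self.interleaved()
        starts = np.concatenate([[0.0], np.cumsum(inter)[:-1]])
        return sample_on_ms + starts[0::2]

    def item_offsets(self, sample_on_ms: float = 0.0) -> np.ndarray:
        return self.item_onsets(sample_on_ms) + self.item_durations_ms

    def validate(self) -> None:
        n = _check_numerosity(self.numerosity)
        if len(self.item_durations_ms) != n or len(self.pause_durations_ms) != n:
            raise StimulusError("timing length does not match numerosity")
        if np.min(self.interleaved()) < MIN_INTERVAL_MS - 1e-9:
            raise StimulusError("interval below 300 ms floor")
        if self.condition in (SeqCondition.STANDARD, SeqCondition.EQUAL_VARIANCE):
            if abs(self.total_ms - SAMPLE_TOTAL_MS) > 1.0:
                raise StimulusError("total sample duration must be 2625 ms")

    def to_dict(self) -> dict:
        return {
            "numerosity": int(self.numerosity),
            "item_durations_ms": [float(x) for x in self.item_durations_ms],
            "pause_durations_ms": [float(x) for x in self.pause_durations_ms],
            "condition": self.condition.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequentialTiming":
        return cls(
            numerosity=int(d["numerosity"]),
            item_durations_ms=np.asarray(d["item_durations_ms"], dtype=float),
            pause_durations_ms=np.asarray(d["pause_durations_ms"], dtype=float),
            condition=SeqCondition(d["condition"]),
        )


@dataclass
class DotDisplay:
    """One simultaneous dot array.

    Positions are in mm relative to the center of the background circle.
    """

    numerosity: int
    centers_mm: np.ndarray  # (n, 2)
    radii_mm: np.ndarray  # (n,)
    condition: DotCondition

    @property
    def total_area_mm2(self) -> float:
        return float(np.sum(np.pi * self.radii_mm**2))

    def mean_pairwise_distance_mm(self) -> float:
        """Mean center-to-center distance over all dot pairs (nan if < 2 dots)."""
        if self.numerosity < 2:
            return float("nan")
        d = self.centers_mm[:, None, :] - self.centers_mm[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        iu = np.triu_indices(self.numerosity, k=1)
        return float(dist[iu].mean())

    def validate(self) -> None:
        n = _check_numerosity(self.numerosity)
        if self.centers_mm.shape != (n, 2) or self.radii_mm.shape != (n,):
            raise StimulusError("display geometry does not match numerosity")
        lo, hi = DOT_RADIUS_RANGE_MM
        if np.any(self.radii_mm < lo - 1e-9) or np.any(self.radii_mm > hi + 1e-9):
            raise StimulusError("dot radius outside 1-2 mm")
        r_bg = BACKGROUND_DIAMETER_MM / 2.0
        rho = np.sqrt((self.centers_mm**2).sum(-1))
        if np.any(rho + self.radii_mm > r_bg + 1e-9):
            raise StimulusError("dot extends beyond the background circle")
        if n >= 2:
            d = self.centers_mm[:, None, :] - self.centers_mm[None, :, :]
            dist = np.sqrt((d**2).sum(-1))
            sums = self.radii_mm[:, None] + self.radii_mm[None, :]
            iu = np.triu_indices(n, k=1)
            if np.any(dist[iu] <= sums[iu]):
                raise StimulusError("overlapping dots")

    def to_dict(self) -> dict:
        return {
            "numerosity": int(self.numerosity),
            "centers_mm": [[float(x), float(y)] for x, y in self.centers_mm],
            "radii_mm": [float(r) for r in self.radii_mm],
            "condition": self.condition.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DotDisplay":
        return cls(
            numerosity=int(d["numerosity"]),
            centers_mm=np.asarray(d["centers_mm"], dtype=float).reshape(-1, 2),
            radii_mm=np.asarray(d["radii_mm"], dtype=float),
            condition=DotCondition(d["condition"]),
        )


@dataclass
class TrialRecord:
    """One behavioral trial with its epoch boundaries (ms from trial start)."""

    trial_id: int
    sample_numerosity: int
    test1_numerosity: int
    format: Format
    protocol: Protocol
    is_match: bool
    pre_sample_on: float
    sample_on: float
    sample_off: float
    delay_on: float
    delay_off: float
    test1_on: float
    test2_on: float | None
    trial_end: float
    seq_condition: SeqCondition | None = None
    presample_jitter_ms: float = 0.0
    choice: Choice | None = None
    correct: bool | None = None
    estimated_numerosity: int | None = None

    def validate(self) -> None:
        assert abs((self.delay_off - self.delay_on) - DELAY_MS) < 1e-6
        assert abs((self.sample_on - self.pre_sample_on) - PRESAMPLE_MS - self.presample_jitter_ms) < 1e-6
        if self.format is Format.SIM:
            assert abs((self.sample_off - self.sample_on) - SIM_SAMPLE_MS) < 1e-6
        assert self.is_match == (self.test1_numerosity == self.sample_numerosity)
        if not self.is_match:
            assert self.test2_on is not None
            assert abs((self.test2_on - self.test1_on) - TEST_MS) < 1e-6


# ---------------------------------------------------------------------------
# Sequential timing generators
# ---------------------------------------------------------------------------


def gen_sequential_standard(numerosity: int, rng: np.random.Generator) -> SequentialTiming:
    """Draw random item/pause durations summing to 2625 ms with a 300 ms floor.

    The 2n intervals are sampled uniformly on the constrained simplex: every
    interval gets the 300 ms floor and the excess (2625 - 600*n ms) is split
    by a flat Dirichlet partition.
    """
    n = _check_numerosity(numerosity)
    k = 2 * n
    excess = SAMPLE_TOTAL_MS - MIN_INTERVAL_MS * k
    weights = rng.dirichlet(np.ones(k))
    d = MIN_INTERVAL_MS + excess * weights
    d[-1] = SAMPLE_TOTAL_MS - d[:-1].sum()  # exact total despite float rounding
    t = SequentialTiming(n, d[0::2].copy(), d[1::2].copy(), SeqCondition.STANDARD)
    t.validate()
    return t


def gen_sequential_equal_variance(numerosity: int) -> SequentialTiming:
    """Equal-variance control: all 2n intervals equal, total 2625 ms."""
    n = _check_numerosity(numerosity)
    d = np.full(2 * n, SAMPLE_TOTAL_MS / (2 * n))
    t = SequentialTiming(n, d[0::2].copy(), d[1::2].copy(), SeqCondition.EQUAL_VARIANCE)
    t.validate()
    return t


def gen_sequential_equal_item(numerosity: int, item_ms: float = MIN_INTERVAL_MS) -> SequentialTiming:
    """Equal-item-duration control: every interval is ``item_ms``; the total
    sample duration 2n*item_ms therefore grows with numerosity."""
    n = _check_numerosity(numerosity)
    if item_ms < MIN_INTERVAL_MS:
        raise StimulusError(f"item_ms must be >= {MIN_INTERVAL_MS}, got {item_ms}")
    d = np.full(2 * n, float(item_ms))
    t = SequentialTiming(n, d[0::2].copy(), d[1::2].copy(), SeqCondition.EQUAL_ITEM)
    t.validate()
    return t


def make_sequential_timing(
    numerosity: int,
    condition: SeqCondition,
    rng: np.random.Generator,
    equal_item_ms: float = MIN_INTERVAL_MS,
) -> SequentialTiming:
    if condition is SeqCondition.STANDARD:
        return gen_sequential_standard(numerosity, rng)
    if condition is SeqCondition.EQUAL_VARIANCE:
        return gen_sequential_equal_variance(numerosity)
    return gen_sequential_equal_item(numerosity, equal_item_ms)


# ---------------------------------------------------------------------------
# Dot display generators
# ---------------------------------------------------------------------------


def _place_dots(
    radii: np.ndarray, rng: np.random.Generator, max_attempts: int = 200
) -> np.ndarray | None:
    """Rejection-sample non-overlapping centers inside the background circle."""
    r_bg = BACKGROUND_DIAMETER_MM / 2.0
    n = len(radii)
    for _ in range(max_attempts):
        centers = np.empty((n, 2))
        ok = True
        for i in range(n):
            placed = False
            for _ in range(100):
                rho = (r_bg - radii[i]) * math.sqrt(rng.random())
                theta = rng.uniform(0.0, 2.0 * math.pi)
                c = np.array([rho * math.cos(theta), rho * math.sin(theta)])
                if i == 0 or np.all(
                    np.sqrt(((centers[:i] - c) ** 2).sum(-1)) > radii[:i] + radii[i]
                ):
                    centers[i] = c
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return centers
    return None


def gen_dot_display_standard(numerosity: int, rng: np.random.Generator) -> DotDisplay:
    """Random non-overlapping dots of random size at random locations."""
    n = _check_numerosity(numerosity)
    lo, hi = DOT_RADIUS_RANGE_MM
    for _ in range(20):
        radii = rng.uniform(lo, hi, size=n)
        centers = _place_dots(radii, rng)
        if centers is not None:
            disp = DotDisplay(n, centers, radii, DotCondition.STANDARD)
            disp.validate()
            return disp
    raise StimulusError("failed to place dots without overlap")  # pragma: no cover


def gen_dot_display_control(
    rng: np.random.Generator,
    target_area_mm2: float = 4.0 * math.pi,
    target_mean_distance_mm: float = 7.0,
    area_tol: float = 0.02,
    density_tol: float = 0.05,
) -> dict[int, DotDisplay]:
    """Area/density-equalized displays, one per numerosity 1-4.

    Total dot area is solved analytically (per-dot area = target/n); for two
    or more dots the centers are iteratively rescaled about their centroid so
    that the mean pairwise center distance matches the target.

    Note the radius bound [1, 2] mm forces the target area into the narrow
    band [4*pi*1^2, 1*pi*2^2] mm^2; the default (four pi) is the unique value
    feasible for all numerosities with equal-size dots per display.
    """
    displays: dict[int, DotDisplay] = {}
    lo, hi = DOT_RADIUS_RANGE_MM
    for n in NUMEROSITIES:
        r = math.sqrt(target_area_mm2 / (n * math.pi))
        if r < lo - 1e-9 or r > hi + 1e-9:
            raise StimulusError(
                f"target area {target_area_mm2:.2f} mm^2 infeasible for n={n}: "
                f"per-dot radius {r:.2f} outside [{lo}, {hi}] mm"
            )
        radii = np.full(n, r)
        if n == 1:
            centers = _place_dots(radii, rng)
            disp = DotDisplay(n, centers, radii, DotCondition.AREA_DENSITY_CONTROL)
            disp.validate()
            displays[n] = disp
            continue
        disp = None
        for _ in range(500):
            centers = _place_dots(radii, rng)
            if centers is None:
                continue
            centroid = centers.mean(axis=0)
            cand = DotDisplay(n, centers, radii, DotCondition.AREA_DENSITY_CONTROL)
            m = cand.mean_pairwise_distance_mm()
            scaled = centroid + (centers - centroid) * (target_mean_distance_mm / m)
            cand = DotDisplay(n, scaled, radii, DotCondition.AREA_DENSITY_CONTROL)
            try:
                cand.validate()
            except StimulusError:
                continue
            if abs(cand.mean_pairwise_distance_mm() - target_mean_distance_mm) <= (
                density_tol * target_mean_distance_mm
            ):
                disp = cand
                break
        if disp is None:  # pragma: no cover - practically unreachable at n<=4
            raise StimulusError(f"could not equalize density for n={n}")
        displays[n] = disp

    areas = np.array([displays[n].total_area_mm2 for n in NUMEROSITIES])
    if np.max(np.abs(areas - areas.mean())) > area_tol * areas.mean():  # pragma: no cover
        raise StimulusError("area equalization failed")
    return displays


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------


@dataclass
class Session:
    """A generated session: trials plus their per-trial stimulus realizations."""

    trials: list[TrialRecord]
    timings: dict[int, SequentialTiming] = field(default_factory=dict)
    displays: dict[int, DotDisplay] = field(default_factory=dict)


def gen_session(
    trials_per_condition: int,
    rng: np.random.Generator,
    seq_control: SeqCondition = SeqCondition.EQUAL_VARIANCE,
    equal_item_ms: float = MIN_INTERVAL_MS,
    n_displays: int = 12,
    presample_jitter: bool = True,
) -> Session:
    """Generate a balanced, shuffled session.

    Every cell of numerosity x format x protocol x match receives exactly
    ``trials_per_condition`` trials.  ``seq_control`` selects which temporal
    control is used for sequential control trials in this session (the two
    controls alternate between sessions).  Twelve dot displays per numerosity
    are generated fresh for the session and sampled per trial.

    Choices and correctness are left unset; a behavioral model (see
    :mod:`numcrow.synthdata`) fills them in.
    """
    if trials_per_condition < 1:
        raise StimulusError("trials_per_condition must be >= 1")
    if seq_control is SeqCondition.STANDARD:
        raise StimulusError("seq_control must be one of the two control conditions")

    std_displays = {
        n: [gen_dot_display_standard(n, rng) for _ in range(n_displays)] for n in NUMEROSITIES
    }
    ctl_sets = [gen_dot_display_control(rng) for _ in range(n_displays)]

    cells = list(
        itertools.product(NUMEROSITIES, (Format.SEQ, Format.SIM), (Protocol.STANDARD, Protocol.CONTROL), (True, False))
    )
    order = [cell for cell in cells for _ in range(trials_per_condition)]
    order = [order[i] for i in rng.permutation(len(order))]

    session = Session(trials=[])
    for trial_id, (num, fmt, proto, is_match) in enumerate(order):
        if is_match:
            test1 = num
        else:
            others = [m for m in NUMEROSITIES if m != num]
            test1 = int(others[rng.integers(len(others))])

        jitter = 0.0
        timing = None
        display = None
        if fmt is Format.SEQ:
            cond = SeqCondition.STANDARD if proto is Protocol.STANDARD else seq_control
            timing = make_sequential_timing(num, cond, rng, equal_item_ms)
            if presample_jitter and cond is SeqCondition.STANDARD and num == 1:
                jitter = float(rng.uniform(0.0, PRESAMPLE_JITTER_MAX_MS))
            sample_dur = timing.total_ms
        else:
            cond = None
            if proto is Protocol.STANDARD:
                display = std_displays[num][rng.integers(n_displays)]
            else:
                display = ctl_sets[rng.integers(n_displays)][num]
            sample_dur = SIM_SAMPLE_MS

        sample_on = PRESAMPLE_MS + jitter
        sample_off = sample_on + sample_dur
        delay_on = sample_off
        delay_off = delay_on + DELAY_MS
        test1_on = delay_off
        test2_on = None if is_match else test1_on + TEST_MS
        trial_end = (test2_on if test2_on is not None else test1_on) + TEST_MS

        rec = TrialRecord(
            trial_id=trial_id,
            sample_numerosity=num,
            test1_numerosity=test1,
            format=fmt,
            protocol=proto,
            is_match=is_match,
            pre_sample_on=0.0,
            sample_on=sample_on,
            sample_off=sample_off,
            delay_on=delay_on,
            delay_off=delay_off,
            test1_on=test1_on,
            test2_on=test2_on,
            trial_end=trial_end,
            seq_condition=cond,
            presample_jitter_ms=jitter,
        )
        rec.validate()
        session.trials.append(rec)
        if timing is not None:
            session.timings[trial_id] = timing
        if display is not None:
            session.displays[trial_id] = display
    return session


def trials_to_frame(trials: list[TrialRecord]):
    """Flatten trial records into a pandas DataFrame (one row per trial)."""
    import pandas as pd

    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "sample_numerosity": t.sample_numerosity,
                "test1_numerosity": t.test1_numerosity,
                "format": t.format.value,
                "protocol": t.protocol.value,
                "seq_condition": t.seq_condition.value if t.seq_condition else "",
                "is_match": t.is_match,
                "presample_jitter_ms": t.presample_jitter_ms,
                "pre_sample_on": t.pre_sample_on,
                "sample_on": t.sample_on,
                "sample_off": t.sample_off,
                "delay_on": t.delay_on,
                "delay_off": t.delay_off,
                "test1_on": t.test1_on,
                "test2_on": np.nan if t.test2_on is None else t.test2_on,
                "trial_end": t.trial_end,
                "choice": t.choice.value if t.choice else "",
                "correct": t.correct,
                "estimated_numerosity": (
                    np.nan if t.estimated_numerosity is None else t.estimated_numerosity
                ),
            }
        )
    return pd.DataFrame(rows)
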