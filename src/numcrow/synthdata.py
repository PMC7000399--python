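"""Synthetic behaving subject and spiking neurons for the numerosity task.

The simulator provides ground truth for parameter-recovery tests of every
analysis stage.  It emulates the population structure the analyses probe:

* ``SEQ_SAMPLE`` neurons are numerosity tuned only while sequential items are
  on screen;
* ``SIM_SAMPLE`` neurons are tuned only during simultaneous dot arrays;
* ``DELAY_NUM`` neurons are tuned to numerosity during the memory delay
  irrespective of format, but their early-delay activity also carries a
  format signal that decays as a numerosity ramp takes over (complementary
  logistics crossing mid-delay);
* ``FORMAT_ONLY`` neurons carry only the decaying delay format signal;
* ``NONSEL`` neurons fire at baseline throughout.

Tuning is a Gaussian on the log2 numerosity axis, which produces the
behavioral and neuronal numerical size effect (tuning widens on the linear
scale as the preferred numerosity grows).  Behavior follows a noisy internal
log-magnitude estimate (Weber-scaled confusion): the subject reads out the
numerosity nearest its estimate and responds "match" when that readout equals
the test numerosity.  On error trials the neurons are driven by the
behaviorally estimated numerosity rather than the true sample, coupling
neuronal and behavioral errors.

Spikes are emitted by an inhomogeneous Poisson process with a
piecewise-constant rate profile.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from numcrow import stimgen
from numcrow.stimgen import (
    Choice,
    Format,
    NUMEROSITIES,
    SeqCondition,
    Session,
    TrialRecord,
    gen_session,
    trials_to_frame,
)

_LOG2_LEVELS = np.log2(np.asarray(NUMEROSITIES, dtype=float))


class Population(str, enum.Enum):
    SEQ_SAMPLE = "seq_sample"
    SIM_SAMPLE = "sim_sample"
    DELAY_NUM = "delay_num"
    FORMAT_ONLY = "format_only"
    NONSEL = "nonsel"


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated neuron."""

    neuron_id: int
    population: Population
    preferred_numerosity: int | None
    baseline_rate: float  # Hz
    gain: float  # Hz, peak tuned modulation
    tuning_width_sigma: float  # on the log2 numerosity axis
    format_signal_amp: float  # Hz, early-delay format component
    latency_ms: float  # stimulus-driven response latency

    def __post_init__(self) -> None:
        if self.baseline_rate < 0.5:
            raise ValueError("included neurons must fire at >= 0.5 Hz baseline")
        if self.gain < 0 or self.tuning_width_sigma <= 0:
            raise ValueError("gain must be >= 0 and sigma > 0")


@dataclass
class BehaviorParams:
    """Weber-scaled internal noise plus lapses."""

    weber_w: float = 0.35  # SD of the internal estimate on the log2 axis
    lapse_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.weber_w <= 0:
            raise ValueError("weber_w must be > 0")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must be in [0, 0.5)")


@dataclass
class SimConfig:
    """Population sizes and simulator parameters.

    The default population counts mirror the recorded sample the analyses
    were designed around: 376 neurons in total, of which 64 are tuned to
    sequential samples, 45 to simultaneous samples and 37 carry the
    format-independent delay code.
    """

    n_seq_sample: int = 64
    n_sim_sample: int = 45
    n_delay_num: int = 37
    n_format_only: int = 20
    n_nonsel: int = 210
    trials_per_condition: int = 8
    seq_control: SeqCondition = SeqCondition.EQUAL_VARIANCE
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    gain_range_hz: tuple[float, float] = (8.0, 12.0)
    baseline_log_mean: float = math.log(4.0)  # lognormal location, ~4 Hz median
    baseline_log_sigma: float = 0.6
    tuning_sigma_range: tuple[float, float] = (0.35, 0.55)
    format_amp_range_hz: tuple[float, float] = (6.0, 10.0)
    latency_ms: float = 100.0
    crossover_ms: float = 500.0  # delay format->numerosity handover midpoint
    crossover_steepness_ms: float = 50.0
    rate_step_ms: float = 20.0  # discretization of the smooth delay profile
    overdispersion: float = 0.0  # optional trial-wise gamma rate multiplier; off by default
    #: couple neural tuning to the behavioral estimate on error trials; when
    #: False, errors are purely behavioral and the spikes stay clean
    error_corruption: bool = True

    @property
    def n_neurons(self) -> int:
        return (
            self.n_seq_sample
            + self.n_sim_sample
            + self.n_delay_num
            + self.n_format_only
            + self.n_nonsel
        )

    def validate(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.n_neurons < 1:
            raise ValueError("at least one neuron required")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seq_control"] = self.seq_control.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "seq_control" in d:
            d["seq_control"] = SeqCondition(d["seq_control"])
        if "behavior" in d and isinstance(d["behavior"], dict):
            d["behavior"] = BehaviorParams(**d["behavior"])
        for key in ("gain_range_hz", "tuning_sigma_range", "format_amp_range_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Tuning and behavior
# ---------------------------------------------------------------------------


def tuning_value(preferred: int, n: int, sigma: float) -> float:
    """Gaussian tuning on the log2 numerosity axis, 1 at the preferred value.

    Constant width in log space yields wider linear-scale tuning for larger
    preferred numerosities (the numerical size effect).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = math.log2(n) - math.log2(preferred)
    return math.exp(-(d**2) / (2.0 * sigma**2))


def simulate_choice(
    sample: int,
    test1: int,
    is_match: bool,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[Choice, bool, int]:
    """Simulate one match/non-match decision.

    The internal estimate is log2(sample) plus Gaussian noise of SD
    ``weber_w``; the subject reads out the numerosity whose log magnitude is
    nearest the estimate (equivalent to a matching criterion of half the
    log-distance to the nearest alternative) and responds at the first test
    exactly when that readout equals the test numerosity.  A ``lapse_rate``
    fraction of responses is random.
    """
    est = math.log2(sample) + rng.normal(0.0, params.weber_w)
    est_num = int(NUMEROSITIES[int(np.argmin(np.abs(_LOG2_LEVELS - est)))])
    respond_match = est_num == test1
    if rng.random() < params.lapse_rate:
        respond_match = bool(rng.random() < 0.5)
    choice = Choice.RESPOND_AT_TEST1 if respond_match else Choice.RESPOND_AT_TEST2
    correct = respond_match == is_match
    return choice, correct, est_num


def simulate_behavior(
    trials: list[TrialRecord], params: BehaviorParams, rng: np.random.Generator
) -> None:
    """Fill choice/correct/estimated_numerosity on all trials in place."""
    for t in trials:
        choice, correct, est = simulate_choice(
            t.sample_numerosity, t.test1_numerosity, t.is_match, params, rng
        )
        t.choice = choice
        t.correct = correct
        t.estimated_numerosity = est


# ---------------------------------------------------------------------------
# Firing-rate profiles and spike emission
# ---------------------------------------------------------------------------


def _logistic(t: np.ndarray, mid: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((t - mid) / steepness))


def rate_profile(
    neuron: NeuronSpec,
    trial: TrialRecord,
    timing: stimgen.SequentialTiming | None,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant firing-rate profile for one neuron on one trial.

    Returns ``(edges_ms, rates_hz)`` with ``len(edges) == len(rates) + 1``.
    Stimulus-driven sample responses are shifted by the neuron's latency;
    delay-period components are anchored to delay onset.  On error trials the
    tuning argument is the subject's estimated numerosity.
    """
    n_drive = trial.sample_numerosity
    if (
        config.error_corruption
        and trial.correct is False
        and trial.estimated_numerosity is not None
    ):
        n_drive = trial.estimated_numerosity

    lat = neuron.latency_ms
    cuts = {0.0, trial.trial_end}
    sample_windows: list[tuple[float, float]] = []
    if neuron.population is Population.SEQ_SAMPLE and trial.format is Format.SEQ:
        assert timing is not None
        on = timing.item_onsets(trial.sample_on) + lat
        off = timing.item_offsets(trial.sample_on) + lat
        sample_windows = list(zip(on, off))
    elif neuron.population is Population.SIM_SAMPLE and trial.format is Format.SIM:
        sample_windows = [(trial.sample_on + lat, trial.sample_off + lat)]
    for a, b in sample_windows:
        cuts.add(min(a, trial.trial_end))
        cuts.add(min(b, trial.trial_end))

    delay_populations = (Population.DELAY_NUM, Population.FORMAT_ONLY)
    if neuron.population in delay_populations:
        grid = np.arange(trial.delay_on, trial.delay_off, config.rate_step_ms)
        cuts.update(grid.tolist())
        cuts.add(trial.delay_off)

    edges = np.array(sorted(cuts))
    mids = 0.5 * (edges[:-1] + edges[1:])
    rates = np.full(mids.shape, neuron.baseline_rate)

    if sample_windows and neuron.preferred_numerosity is not None:
        tun = tuning_value(neuron.preferred_numerosity, n_drive, neuron.tuning_width_sigma)
        for a, b in sample_windows:
            rates[(mids >= a) & (mids < b)] += neuron.gain * tun

    if neuron.population in delay_populations:
        in_delay = (mids >= trial.delay_on) & (mids < trial.delay_off)
        t_rel = mids[in_delay] - trial.delay_on
        decay = _logistic(t_rel, config.crossover_ms, config.crossover_steepness_ms)
        fmt_ind = 1.0 if trial.format is Format.SEQ else 0.0
        add = neuron.format_signal_amp * fmt_ind * decay
        if neuron.population is Population.DELAY_NUM:
            tun = tuning_value(neuron.preferred_numerosity, n_drive, neuron.tuning_width_sigma)
            add = add + neuron.gain * tun * (1.0 - decay)
        rates[in_delay] += add

    return edges, rates


def simulate_spikes(
    edges_ms: np.ndarray, rates_hz: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a piecewise-constant-rate Poisson spike train (times in ms)."""
    if np.any(rates_hz < 0):
        raise ValueError("negative rate in profile")
    durations_s = np.diff(edges_ms) / 1000.0
    counts = rng.poisson(rates_hz * durations_s)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    times = np.empty(total)
    pos = 0
    for i, c in enumerate(counts):
        if c:
            times[pos : pos + c] = rng.uniform(edges_ms[i], edges_ms[i + 1], size=c)
            pos += c
    times.sort()
    return times


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A simulated session with spikes and retained ground truth."""

    trials: pd.DataFrame
    trial_records: list[TrialRecord]
    timings: dict[int, stimgen.SequentialTiming]
    displays: dict[int, stimgen.DotDisplay]
    neurons: list[NeuronSpec]
    spikes: dict[int, dict[int, np.ndarray]]  # neuron_id -> trial_id -> times
    config: SimConfig
    seed: int

    def neuron_frame(self) -> pd.DataFrame:
        rows = []
        for nsp in self.neurons:
            rows.append(
                {
                    "neuron_id": nsp.neuron_id,
                    "population": nsp.population.value,
                    "preferred_numerosity": (
                        np.nan
                        if nsp.preferred_numerosity is None
                        else nsp.preferred_numerosity
                    ),
                    "baseline_rate": nsp.baseline_rate,
                    "gain": nsp.gain,
                    "tuning_width_sigma": nsp.tuning_width_sigma,
                    "format_signal_amp": nsp.format_signal_amp,
                    "latency_ms": nsp.latency_ms,
                }
            )
        return pd.DataFrame(rows)


def make_neuron_specs(config: SimConfig, rng: np.random.Generator) -> list[NeuronSpec]:
    """Draw ground-truth neuron parameters for all populations."""
    config.validate()
    specs: list[NeuronSpec] = []
    plan = [
        (Population.SEQ_SAMPLE, config.n_seq_sample),
        (Population.SIM_SAMPLE, config.n_sim_sample),
        (Population.DELAY_NUM, config.n_delay_num),
        (Population.FORMAT_ONLY, config.n_format_only),
        (Population.NONSEL, config.n_nonsel),
    ]
    neuron_id = 0
    for pop, count in plan:
        for i in range(count):
            tuned = pop in (Population.SEQ_SAMPLE, Population.SIM_SAMPLE, Population.DELAY_NUM)
            preferred = int(NUMEROSITIES[i % 4]) if tuned else None
            baseline = float(
                np.clip(rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma), 0.5, 30.0)
            )
            specs.append(
                NeuronSpec(
                    neuron_id=neuron_id,
                    population=pop,
                    preferred_numerosity=preferred,
                    baseline_rate=baseline,
                    gain=float(rng.uniform(*config.gain_range_hz)) if tuned else 0.0,
                    tuning_width_sigma=float(rng.uniform(*config.tuning_sigma_range)),
                    format_signal_amp=(
                        float(rng.uniform(*config.format_amp_range_hz))
                        if pop in (Population.DELAY_NUM, Population.FORMAT_ONLY)
                        else 0.0
                    ),
                    latency_ms=config.latency_ms,
                )
            )
            neuron_id += 1
    return specs


def build_dataset(config: SimConfig | None = None, seed: int = 0) -> Dataset:
    """Simulate a full session: stimuli, behavior, neurons and spikes.

    A single master seed deterministically spawns independent streams for
    session structure, behavior, neuron parameters and per-neuron spiking, so
    identical ``(config, seed)`` pairs yield identical datasets.
    """
    if config is None:
        config = SimConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    session_ss, behavior_ss, spec_ss, spike_ss = ss.spawn(4)

    session = gen_session(
        config.trials_per_condition,
        np.random.default_rng(session_ss),
        seq_control=config.seq_control,
    )
    simulate_behavior(session.trials, config.behavior, np.random.default_rng(behavior_ss))
    neurons = make_neuron_specs(config, np.random.default_rng(spec_ss))

    spikes: dict[int, dict[int, np.ndarray]] = {}
    neuron_streams = spike_ss.spawn(len(neurons))
    for nsp, child in zip(neurons, neuron_streams):
        nrng = np.random.default_rng(child)
        per_trial: dict[int, np.ndarray] = {}
        for t in session.trials:
            edges, rates = rate_profile(nsp, t, session.timings.get(t.trial_id), config)
            if config.overdispersion > 0:
                k = 1.0 / config.overdispersion
                rates = rates * nrng.gamma(k, 1.0 / k)
            per_trial[t.trial_id] = simulate_spikes(edges, rates, nrng)
        spikes[nsp.neuron_id] = per_trial

    return Dataset(
        trials=trials_to_frame(session.trials),
        trial_records=session.trials,
        timings=session.timings,
        displays=session.displays,
        neurons=neurons,
        spikes=spikes,
        config=config,
        seed=seed,
    )
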