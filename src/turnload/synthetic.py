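"""Synthetic flight telemetry and heartbeat streams.

No pilot dataset is publicly deposited, so the pipeline is exercised on
simulated data.  Two streams are generated per subject:

* a telemetry track following a configurable flight plan — the default plan
  is the nine-turn traffic-pattern exercise whose turn parameters (pre/post
  headings and altitudes, speeds) drive the worked examples throughout the
  test-suite;
* a beat-to-beat pulse-interval series whose autonomic structure depends on
  the load class of the maneuver in progress.  Inside a turn the
  instantaneous mean interval is 60000 / base_hr of the active class,
  additively modulated by a low-frequency (sympathetic/baroreflex band) and a
  high-frequency (respiratory band) sinusoid plus Gaussian noise; beats are
  emitted by cumulative-interval construction.  Class presets encode the
  qualitative physiology — high load (climbing) raises heart rate and
  suppresses short-term variability, low load (leveling) does the opposite —
  without claiming any subject-level effect size.

A fraction of intervals is corrupted (halved or doubled), mimicking
missed/false detections of an optical sensor, so the artifact-repair stage
has real work to do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CLASS_NAMES, FlightTrack, RRSeries, TurnSegment
from .segmentation import classify_altitude_change, heading_delta, signed_heading_step

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlightLeg:
    """One straight leg of a flight plan.

    The aircraft turns onto ``target_heading`` at the start of the leg while
    ramping to ``entry_altitude`` (defaults to ``target_altitude``), then
    flies straight for ``leg_duration`` seconds.  If ``entry_altitude`` and
    ``target_altitude`` differ, the difference is flown as an en-route
    climb/descent in the middle of the straight portion, away from any turn.
    """

    target_heading: float
    target_altitude: float
    speed: float
    leg_duration: float
    entry_altitude: float | None = None

    def __post_init__(self):
        if not 0 <= self.target_heading < 360:
            raise ValueError("heading must lie in [0, 360)")
        if self.target_altitude <= 0:
            raise ValueError("altitude must be positive")

    @property
    def entry_alt(self) -> float:
        return self.target_altitude if self.entry_altitude is None else self.entry_altitude


@dataclass(frozen=True)
class FlightPlan:
    legs: tuple[FlightLeg, ...]

    def __post_init__(self):
        object.__setattr__(self, "legs", tuple(self.legs))
        if len(self.legs) == 0:
            raise ValueError("empty flight plan")

    @property
    def n_turns(self) -> int:
        return len(self.legs) - 1


def default_flight_plan(leg_duration: float = 60.0) -> FlightPlan:
    """The nine-turn exercise: two climbing, four leveling, three descending.

    Leg altitudes are chosen so that each turn reproduces its printed
    pre/post altitude pair; the single en-route descent (3000→2500 ft) is
    flown mid-leg, outside any turn.
    """
    spec = [
        # (heading, target_alt, speed, entry_alt)
        (127, 1800, 75, None),
        (40, 3000, 75, None),       # turn 1: climbing 1800→3000, Δ87°
        (330, 4000, 75, None),      # turn 2: climbing 3000→4000, Δ70°
        (150, 4000, 90, None),      # turn 3: leveling, Δ180°
        (180, 2500, 90, 3000),      # turn 4: descending 4000→3000, Δ30°; then en-route to 2500
        (127, 2500, 90, None),      # turn 5: leveling, Δ53°
        (37, 2500, 90, None),       # turn 6: leveling, Δ90°
        (307, 2500, 90, None),      # turn 7: leveling, Δ90°
        (217, 2400, 75, None),      # turn 8: descending 2500→2400, Δ90°
        (127, 2200, 75, None),      # turn 9: descending 2400→2200, Δ90°
    ]
    return FlightPlan(
        tuple(
            FlightLeg(h, alt, spd, leg_duration=leg_duration, entry_altitude=ent)
            for h, alt, spd, ent in spec
        )
    )


@dataclass(frozen=True)
class LoadClassParams:
    """Generative heartbeat parameters for one load class.

    ``base_hr`` sets the mean heart rate (bpm); ``lf_amp``/``hf_amp`` (ms)
    the amplitudes of the low- and high-frequency interval modulation at
    ``lf_freq``/``hf_freq`` (Hz); ``noise_sd`` (ms) beat-to-beat Gaussian
    noise; ``artifact_prob`` the chance that an emitted interval is corrupted
    (halved or doubled).
    """

    class_id: int
    base_hr: float
    lf_amp: float
    hf_amp: float
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    noise_sd: float = 0.0
    artifact_prob: float = 0.0

    def __post_init__(self):
        if not 40 <= self.base_hr <= 200:
            raise ValueError("base_hr out of [40, 200]")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.artifact_prob < 0.5:
            raise ValueError("artifact_prob out of [0, 0.5)")
        for f in (self.lf_freq, self.hf_freq):
            if not 0 < f < 0.5:
                raise ValueError("modulation frequencies must lie in (0, 0.5) Hz")


#: Class presets: short-term variability ordered climbing < descending <
#: leveling and heart rate ordered the other way, mirroring the direction of
#: the load effect (free parameters, not measured values).
DEFAULT_CLASS_PARAMS: dict[int, LoadClassParams] = {
    1: LoadClassParams(1, base_hr=95, lf_amp=15, hf_amp=12, noise_sd=12, artifact_prob=0.02),
    2: LoadClassParams(2, base_hr=82, lf_amp=25, hf_amp=32, noise_sd=18, artifact_prob=0.02),
    3: LoadClassParams(3, base_hr=88, lf_amp=20, hf_amp=26, noise_sd=16, artifact_prob=0.02),
}

DEFAULT_BASELINE_PARAMS = LoadClassParams(
    2, base_hr=78, lf_amp=20, hf_amp=22, noise_sd=14, artifact_prob=0.02
)


# ---------------------------------------------------------------------------
# telemetry


def _plan_timeline(plan: FlightPlan, turn_rate: float, level_band: float = 50.0):
    """Piecewise-linear profiles (time knots per channel) plus ground truth.

    Returns (knots_t, heading_unwrapped, altitude, speed, segments).  Heading
    is kept on an unwrapped (cumulative) scale so turns follow the shorter
    circular arc; callers reduce it mod 360.
    """
    kt, kh, ka, ks = [0.0], [plan.legs[0].target_heading], [plan.legs[0].entry_alt], [
        plan.legs[0].speed
    ]
    segments: list[TurnSegment] = []

    def add_knot(t, h, a, s):
        kt.append(t), kh.append(h), ka.append(a), ks.append(s)

    leg0 = plan.legs[0]
    t = leg0.leg_duration
    add_knot(t, kh[0], leg0.target_altitude, leg0.speed)

    for prev, leg in zip(plan.legs[:-1], plan.legs[1:]):
        delta = heading_delta(prev.target_heading % 360, leg.target_heading % 360)
        step = signed_heading_step(prev.target_heading % 360, leg.target_heading % 360)
        turn_dur = max(delta / turn_rate, 1.0)
        h_end = kh[-1] + step
        alt_start = ka[-1]
        add_knot(t + turn_dur, h_end, leg.entry_alt, leg.speed)
        segments.append(
            TurnSegment(
                start_time=t,
                end_time=t + turn_dur,
                pre_heading=prev.target_heading % 360,
                post_heading=leg.target_heading % 360,
                heading_delta=delta,
                altitude_change=leg.entry_alt - alt_start,
                class_id=classify_altitude_change(leg.entry_alt - alt_start, level_band),
            )
        )
        t += turn_dur
        # straight portion; any en-route altitude change sits in its middle half
        if leg.entry_alt != leg.target_altitude:
            add_knot(t + 0.25 * leg.leg_duration, h_end, leg.entry_alt, leg.speed)
            add_knot(
                t + 0.75 * leg.leg_duration, h_end, leg.target_altitude, leg.speed
            )
        t += leg.leg_duration
        add_knot(t, h_end, leg.target_altitude, leg.speed)

    return np.array(kt), np.array(kh), np.array(ka), np.array(ks), segments


def generate_flight_track(
    plan: FlightPlan,
    sample_interval: float = 1.0,
    turn_rate: float = 0.5,
    seed: int = 0,
    heading_jitter: float = 0.1,
    altitude_jitter: float = 5.0,
    speed_jitter: float = 0.5,
) -> FlightTrack:
    """Sample a telemetry track for ``plan``.

    Heading ramps between leg targets at ``turn_rate`` deg/s along the
    shorter circular arc; altitude ramps linearly during turns; small
    Gaussian jitter is added to every channel.  Deterministic given ``seed``.
    """
    if sample_interval <= 0 or turn_rate <= 0:
        raise ValueError("sample_interval and turn_rate must be positive")
    track, _ = generate_flight_track_with_truth(
        plan, sample_interval, turn_rate, seed, heading_jitter, altitude_jitter, speed_jitter
    )
    return track


def generate_flight_track_with_truth(
    plan: FlightPlan,
    sample_interval: float = 1.0,
    turn_rate: float = 0.5,
    seed: int = 0,
    heading_jitter: float = 0.1,
    altitude_jitter: float = 5.0,
    speed_jitter: float = 0.5,
) -> tuple[FlightTrack, list[TurnSegment]]:
    """Like :func:`generate_flight_track` but also return ground-truth turns."""
    rng = np.random.default_rng(seed)
    kt, kh, ka, ks, segments = _plan_timeline(plan, turn_rate)
    time = np.arange(0.0, kt[-1] + sample_interval / 2, sample_interval)
    heading = np.interp(time, kt, kh)
    altitude = np.interp(time, kt, ka)
    speed = np.interp(time, kt, ks)
    heading = (heading + rng.normal(0, heading_jitter, time.size)) % 360.0
    altitude = altitude + rng.normal(0, altitude_jitter, time.size)
    speed = speed + rng.normal(0, speed_jitter, time.size)
    return FlightTrack(time=time, heading=heading, altitude=altitude, speed=speed), segments


# ---------------------------------------------------------------------------
# heartbeats


def generate_rr_series(
    track: FlightTrack,
    segments: list[TurnSegment],
    params_by_class: dict[int, LoadClassParams] | None = None,
    baseline_params: LoadClassParams | None = None,
    seed: int = 0,
    lf_phase: float = 0.0,
    hf_phase: float = 0.0,
) -> RRSeries:
    """Emit a beat series over the track's time span.

    At each beat time the active parameter set is that of the enclosing turn
    segment (baseline outside turns); the next interval is drawn as
    mean + LF + HF + noise (ms), optionally corrupted into an artifact.
    """
    params_by_class = params_by_class or DEFAULT_CLASS_PARAMS
    baseline_params = baseline_params or DEFAULT_BASELINE_PARAMS
    missing = {1, 2, 3} - set(params_by_class)
    if missing:
        raise ValueError(f"missing class params for {sorted(missing)}")

    rng = np.random.default_rng(seed)
    t0, t_end = float(track.time[0]), float(track.time[-1])
    starts = np.array([s.start_time for s in segments]) if segments else np.empty(0)

    def active_params(t: float) -> LoadClassParams:
        if starts.size:
            k = int(np.searchsorted(starts, t, side="right")) - 1
            if k >= 0 and t < segments[k].end_time:
                return params_by_class[segments[k].class_id]
        return baseline_params

    beat_times = [t0]
    intervals: list[float] = []
    t = t0
    while True:
        p = active_params(t)
        rr = (
            60000.0 / p.base_hr
            + p.lf_amp * np.sin(2 * np.pi * p.lf_freq * t + lf_phase)
            + p.hf_amp * np.sin(2 * np.pi * p.hf_freq * t + hf_phase)
            + (rng.normal(0, p.noise_sd) if p.noise_sd > 0 else 0.0)
        )
        rr = max(rr, 300.0)  # refractory floor
        if p.artifact_prob > 0 and rng.random() < p.artifact_prob:
            rr = rr * 2.0 if rng.random() < 0.5 else rr / 2.0
        if t + rr / 1000.0 > t_end:
            break
        t += rr / 1000.0
        beat_times.append(t)
        intervals.append(rr)
    if not intervals:
        raise ValueError("track too short for a single beat")
    return RRSeries(beat_times=np.array(beat_times), intervals=np.array(intervals))


# ---------------------------------------------------------------------------
# datasets


@dataclass
class SyntheticDataset:
    """One simulated subject: telemetry, heartbeats and ground-truth turns."""

    subject: int
    track: FlightTrack
    rr: RRSeries
    true_segments: list[TurnSegment]
    seed: int


def make_dataset(
    n_subjects: int,
    plan: FlightPlan | None = None,
    params_by_class: dict[int, LoadClassParams] | None = None,
    baseline_params: LoadClassParams | None = None,
    seed: int = 0,
    turn_rate: float = 0.5,
    sample_interval: float = 1.0,
    subject_hr_sd: float = 3.0,
    subject_amp_log_sd: float = 0.08,
) -> list[SyntheticDataset]:
    """Simulate ``n_subjects`` independent subjects flying ``plan``.

    Each subject gets its own RNG stream (spawned from the master seed), a
    heart-rate offset ~ N(0, ``subject_hr_sd``) applied to every class, and a
    log-normal scaling of modulation/noise amplitudes — crude inter-subject
    heterogeneity.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    plan = plan or default_flight_plan()
    params_by_class = params_by_class or DEFAULT_CLASS_PARAMS
    baseline_params = baseline_params or DEFAULT_BASELINE_PARAMS

    datasets = []
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for subj, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        hr_off = rng.normal(0, subject_hr_sd)
        amp_scale = float(np.exp(rng.normal(0, subject_amp_log_sd)))
        lf_phase, hf_phase = rng.uniform(0, 2 * np.pi, 2)

        def adjust(p: LoadClassParams) -> LoadClassParams:
            return replace(
                p,
                base_hr=float(np.clip(p.base_hr + hr_off, 40, 200)),
                lf_amp=p.lf_amp * amp_scale,
                hf_amp=p.hf_amp * amp_scale,
                noise_sd=p.noise_sd * amp_scale,
            )

        track, truth = generate_flight_track_with_truth(
            plan, sample_interval=sample_interval, turn_rate=turn_rate, seed=sub_seed
        )
        rr = generate_rr_series(
            track,
            truth,
            {k: adjust(p) for k, p in params_by_class.items()},
            adjust(baseline_params),
            seed=sub_seed + 1,
            lf_phase=lf_phase,
            hf_phase=hf_phase,
        )
        datasets.append(
            SyntheticDataset(subject=subj, track=track, rr=rr, true_segments=truth, seed=sub_seed)
        )
    return datasets
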