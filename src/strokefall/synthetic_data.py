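"""Synthetic multi-IMU fall / non-fall recordings with cohort-dependent kinematics.

Emulates a three-sensor wearable (left hip, right hip, lower back; 3-axis
accelerometer in g, 3-axis gyroscope in deg/s, 500 Hz) recording laboratory
falls and non-falls from a stroke cohort and an age-ranged control cohort.
The raw study data are not public, so every downstream stage of the analysis
(filtering, windowing, feature extraction, cohort-dependent classification,
paired statistics) is exercised on these generated recordings instead.

Event taxonomy
--------------
* ``lateral_fall`` / ``ap_fall`` — loss of balance ending on the ground.
  Phase structure: instability (growing angular velocity about the fall
  axis: roll-dominant for lateral, pitch-dominant for anterior-posterior)
  → descent (acceleration magnitude drops toward free fall) → impact
  (short high-g spike) → rest (static ~1 g, lying).
* ``near_fall`` — instability followed by a compensatory recovery burst and
  a return to baseline; no impact, no ground contact.
* ``adl`` — activities of daily living (walk, sit, lie, sit-to-stand,
  jump); jump is a deliberate hard negative with a sub-1 g flight phase
  and a landing spike.

Cohort differences are encoded parametrically (slower gait, longer
instability, weaker compensatory response, lateralised asymmetry, and an
optional fall-direction-specific signature scale) so that effect recovery by
the downstream classifier is testable, and can be switched off entirely
(``null_cohorts``) for null calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

SAMPLING_RATE = 500  # Hz, fixed by the device
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

LOCATIONS = ("lhip", "rhip", "back")
MODALITIES = ("acc", "gyr")
AXES = ("x", "y", "z")

#: Canonical channel order used by every array in the package.
CHANNELS: tuple[str, ...] = tuple(
    f"{loc}_{mod}_{ax}" for loc in LOCATIONS for mod in MODALITIES for ax in AXES
)
ACCEL_IDX = np.array([i for i, c in enumerate(CHANNELS) if "_acc_" in c])
GYRO_IDX = np.array([i for i, c in enumerate(CHANNELS) if "_gyr_" in c])

FALL_SUBTYPES = ("lateral_fall", "ap_fall")
NONFALL_SUBTYPES = ("adl", "near_fall")
SUBTYPES = FALL_SUBTYPES + NONFALL_SUBTYPES
ADL_KINDS = ("walk", "sit", "lie", "sit_to_stand", "jump")

# channel indices, per location, of accel/gyro axes (x, y, z)
_ACC = {loc: [CHANNELS.index(f"{loc}_acc_{a}") for a in AXES] for loc in LOCATIONS}
_GYR = {loc: [CHANNELS.index(f"{loc}_gyr_{a}") for a in AXES] for loc in LOCATIONS}


class GeneratorError(ValueError):
    """Invalid request to the synthetic-data generator."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class KinematicParams:
    """Per-subject kinematic ground truth driving event synthesis.

    Amplitudes are in the sensor units (g, deg/s); durations in ms.
    ``ap_signature_scale`` / ``lat_signature_scale`` scale the pre-impact
    signature (instability growth rate and descent depth) of AP and lateral
    falls respectively; 1.0 is the canonical vivid fall, values < 1 produce
    subtler pre-impact motion.
    """

    gait_freq_hz: float = 1.9
    gait_asym: float = 0.05
    instab_duration_ms: float = 450.0
    instab_growth_dps2: float = 600.0
    descent_duration_ms: float = 280.0
    impact_peak_g: float = 6.5
    comp_gain: float = 1.0
    noise_sd_g: float = 0.05
    noise_sd_dps: float = 2.0
    #: amplitude of slow accelerometer baseline wander (bias instability /
    #: postural sway), summed sinusoids at 0.05-0.5 Hz per channel.
    baseline_wander_g: float = 0.03
    #: probe-construction knob: keep the post-impact rest phase upright
    #: instead of lying on the fall side.  Used by generators that must
    #: confine the fall signature to a short pre-impact interval — the
    #: sustained orientation change of a lying subject is low-frequency
    #: content that zero-phase filtering would otherwise smear backwards
    #: into pre-impact windows.
    rest_upright: bool = False
    ap_signature_scale: float = 1.0
    lat_signature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.instab_duration_ms <= 0 or self.descent_duration_ms <= 0:
            raise GeneratorError("phase durations must be positive")
        if not 0 < self.impact_peak_g <= ACCEL_RANGE_G:
            raise GeneratorError(
                f"impact peak must be in (0, {ACCEL_RANGE_G}] g, got {self.impact_peak_g}"
            )
        if self.noise_sd_g < 0 or self.noise_sd_dps < 0:
            raise GeneratorError("noise SDs must be non-negative")


@dataclass
class SubjectProfile:
    subject_id: str
    cohort: str  # "control" | "stroke"
    severity: str = "stable"  # "stable" | "unstable"
    gait_speed: float = 1.2  # m/s
    kinematics: KinematicParams = field(default_factory=KinematicParams)

    def __post_init__(self) -> None:
        if self.cohort not in ("control", "stroke"):
            raise GeneratorError(f"unknown cohort {self.cohort!r}")
        if self.severity not in ("stable", "unstable"):
            raise GeneratorError(f"unknown severity {self.severity!r}")
        if self.severity == "unstable" and self.cohort != "stroke":
            raise GeneratorError("unstable severity is only defined for the stroke cohort")
        if self.gait_speed <= 0:
            raise GeneratorError("gait_speed must be positive")


@dataclass
class IMURecording:
    """One subject's 18-channel session at 500 Hz.

    ``data`` is (n_frames, 18) float32 in canonical :data:`CHANNELS` order;
    accelerometer channels in g, gyroscope channels in deg/s, clipped to the
    sensor ranges (±16 g, ±2000 deg/s).
    """

    subject_id: str
    data: np.ndarray
    sampling_rate: int = SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise GeneratorError("recording must be (n_frames, 18)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class EventAnnotation:
    event_id: str
    subject_id: str
    activity_class: str  # "fall" | "non_fall"
    subtype: str
    adl_kind: str | None = None
    region_start_frame: int = 0
    region_end_frame: int = 0
    true_impact_frame: int | None = None
    defective: bool = False
    #: generator ground truth: absolute frames of phase boundaries (falls
    #: and near-falls only); keys such as "instability_start",
    #: "descent_start", "impact", "rest_start".
    phases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise GeneratorError(f"unknown subtype {self.subtype!r}")
        expected_class = "fall" if self.subtype in FALL_SUBTYPES else "non_fall"
        if self.activity_class != expected_class:
            raise GeneratorError(
                f"subtype {self.subtype} inconsistent with class {self.activity_class}"
            )
        if self.region_start_frame >= self.region_end_frame:
            raise GeneratorError("event region must be non-empty (start < end)")
        is_fall = self.subtype in FALL_SUBTYPES
        if is_fall != (self.true_impact_frame is not None):
            raise GeneratorError("true_impact_frame present iff the event is a fall")
        if self.true_impact_frame is not None and not (
            self.region_start_frame <= self.true_impact_frame < self.region_end_frame
        ):
            raise GeneratorError("true_impact_frame must lie within the event region")


@dataclass
class Dataset:
    """A generated cohort study: profiles, one recording per subject, annotations."""

    profiles: list[SubjectProfile]
    recordings: dict[str, IMURecording]
    annotations: list[EventAnnotation]

    def subject_ids(self, cohort: str | None = None) -> list[str]:
        return [p.subject_id for p in self.profiles if cohort is None or p.cohort == cohort]


@dataclass
class CohortSpec:
    """Generating distribution for one cohort's subject profiles."""

    gait_speed_mean: float
    gait_speed_sd: float
    base: KinematicParams = field(default_factory=KinematicParams)
    jitter: float = 0.08  # relative SD of per-subject lognormal jitter

    def draw(self, rng: np.random.Generator) -> tuple[float, KinematicParams]:
        speed = float(np.clip(rng.normal(self.gait_speed_mean, self.gait_speed_sd), 0.3, 2.5))
        values = {}
        for f in fields(KinematicParams):
            base = getattr(self.base, f.name)
            if f.name in ("noise_sd_g", "noise_sd_dps") or base == 0:
                values[f.name] = base
            else:
                values[f.name] = base * float(rng.lognormal(0.0, self.jitter))
        values["impact_peak_g"] = min(values["impact_peak_g"], ACCEL_RANGE_G)
        return speed, KinematicParams(**values)


def _scaled(params: KinematicParams, multipliers: Mapping[str, float]) -> KinematicParams:
    updates = {k: getattr(params, k) * v for k, v in multipliers.items()}
    if "impact_peak_g" in updates:
        updates["impact_peak_g"] = min(updates["impact_peak_g"], ACCEL_RANGE_G)
    return replace(params, **updates)


# Cohort-level kinematic differences: slower and more asymmetric gait,
# longer instability, weaker compensatory response for stroke.  Magnitudes
# are free generator parameters, not estimates of the real cohorts.
DEFAULT_STROKE_MULTIPLIERS: dict[str, float] = {
    "gait_freq_hz": 0.75,
    "gait_asym": 4.0,
    "instab_duration_ms": 1.5,
    "instab_growth_dps2": 0.8,
    "descent_duration_ms": 1.1,
    "comp_gain": 0.6,
}

# Additional shifts for stroke subjects labelled unstable ambulators.
DEFAULT_UNSTABLE_MULTIPLIERS: dict[str, float] = {
    "gait_asym": 1.5,
    "instab_duration_ms": 1.25,
    "comp_gain": 0.6,
}


def control_spec() -> CohortSpec:
    return CohortSpec(gait_speed_mean=1.22, gait_speed_sd=0.19)


def stroke_spec(
    multipliers: Mapping[str, float] | None = None,
) -> CohortSpec:
    mult = DEFAULT_STROKE_MULTIPLIERS if multipliers is None else multipliers
    return CohortSpec(
        gait_speed_mean=0.88,
        gait_speed_sd=0.29,
        base=_scaled(KinematicParams(), mult),
    )


# Study-session event composition per cohort (totals over all subjects).
STUDY_COMPOSITION: dict[str, dict[str, int]] = {
    "stroke": {"lateral_fall": 327, "ap_fall": 112, "adl": 259, "near_fall": 156},
    "control": {"lateral_fall": 283, "ap_fall": 120, "adl": 303, "near_fall": 243},
}


@dataclass
class DatasetConfig:
    n_control: int = 15
    n_stroke: int = 20
    n_unstable: int = 5
    #: per-cohort event totals by subtype; distributed as evenly as possible
    #: over the cohort's subjects.  None → ``repetitions`` of each subtype
    #: per subject.
    event_counts: dict[str, dict[str, int]] | None = None
    repetitions: int = 2
    control: CohortSpec = field(default_factory=control_spec)
    stroke: CohortSpec = field(default_factory=stroke_spec)
    unstable_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNSTABLE_MULTIPLIERS)
    )
    #: force both cohorts to draw from the control generating distribution
    #: (severity labels are still assigned); used for null calibration.
    null_cohorts: bool = False
    #: cycle of ADL kinds assigned to each subject's bare "adl" requests.
    adl_kinds: tuple[str, ...] = ADL_KINDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise GeneratorError("repetitions must be >= 1")
        if min(self.n_control, self.n_stroke) < 0 or self.n_unstable < 0:
            raise GeneratorError("subject counts must be non-negative")
        if self.n_unstable > self.n_stroke:
            raise GeneratorError("n_unstable cannot exceed n_stroke")
        if self.event_counts is not None:
            for cohort, counts in self.event_counts.items():
                for subtype, count in counts.items():
                    if subtype not in SUBTYPES:
                        raise GeneratorError(f"unknown subtype {subtype!r}")
                    if count < 0:
                        raise GeneratorError("event counts must be non-negative")


def study_composition_config(seed: int = 0) -> DatasetConfig:
    """The default study conditions: 20 stroke (5 unstable) + 15 control
    subjects with the session's per-cohort event composition."""
    return DatasetConfig(event_counts={k: dict(v) for k, v in STUDY_COMPOSITION.items()}, seed=seed)


# ---------------------------------------------------------------------------
# event synthesis (per-subtype templates)
# ---------------------------------------------------------------------------

_G = 9.81  # only used to scale oscillation amplitudes with gait speed


def _segment(n: int) -> np.ndarray:
    """Quiet upright stance: gravity on each sensor's z axis."""
    seg = np.zeros((n, len(CHANNELS)))
    for loc in LOCATIONS:
        seg[:, _ACC[loc][2]] = 1.0
    return seg


def _add_noise(seg: np.ndarray, p: KinematicParams, rng: np.random.Generator) -> np.ndarray:
    if p.noise_sd_g > 0:
        seg[:, ACCEL_IDX] += rng.normal(0.0, p.noise_sd_g, (seg.shape[0], len(ACCEL_IDX)))
    if p.noise_sd_dps > 0:
        seg[:, GYRO_IDX] += rng.normal(0.0, p.noise_sd_dps, (seg.shape[0], len(GYRO_IDX)))
    return seg


def _walk_into(seg: np.ndarray, sl: slice, p: KinematicParams, speed: float, phase: float = 0.0) -> None:
    """Overlay gait oscillation on an upright segment slice."""
    n = seg[sl].shape[0]
    t = np.arange(n) / SAMPLING_RATE
    f = p.gait_freq_hz
    amp = 0.16 * speed  # g; heel-strike oscillation grows with speed
    # left/right alternation with paretic-side asymmetry
    stride = np.sin(2 * np.pi * f * t + phase)
    harm = 0.4 * np.sin(4 * np.pi * f * t + 2 * phase)
    left_gain = 1.0 + 0.5 * p.gait_asym
    right_gain = max(1.0 - 0.5 * p.gait_asym, 0.1)
    for loc, gain in (("lhip", left_gain), ("rhip", right_gain), ("back", 1.0)):
        ai = _ACC[loc]
        seg[sl, ai[2]] += amp * gain * (stride + harm)
        seg[sl, ai[0]] += 0.3 * amp * gain * np.sin(2 * np.pi * f * t + phase + 0.8)
        gi = _GYR[loc]
        seg[sl, gi[1]] += 25.0 * speed * gain * np.cos(2 * np.pi * f * t + phase)
        seg[sl, gi[0]] += 12.0 * speed * p.gait_asym * np.sin(2 * np.pi * f * t + phase)


def _adl_segment(kind: str, p: KinematicParams, speed: float, rng: np.random.Generator) -> np.ndarray:
    if kind == "walk":
        n = 1400
        seg = _segment(n)
        _walk_into(seg, slice(0, n), p, speed, phase=float(rng.uniform(0, 2 * np.pi)))
    elif kind == "lie":
        # entirely static lying posture: gravity on x, nothing else.
        n = 900
        seg = np.zeros((n, len(CHANNELS)))
        for loc in LOCATIONS:
            seg[:, _ACC[loc][0]] = 1.0
    elif kind in ("sit", "sit_to_stand"):
        n = 1000
        seg = _segment(n)
        b0, b1 = 300, 300 + 400  # 800 ms transition bump
        t = np.linspace(0, np.pi, b1 - b0)
        direction = 1.0 if kind == "sit" else -1.0
        for loc in LOCATIONS:
            seg[b0:b1, _ACC[loc][2]] += direction * 0.35 * np.sin(t)
            seg[b0:b1, _ACC[loc][0]] += direction * 0.25 * np.sin(t)
            seg[b0:b1, _GYR[loc][1]] += direction * 70.0 * np.sin(t)
    elif kind == "jump":
        n = 900
        seg = _segment(n)
        # crouch, push-off, flight (~0.1 g), landing spike, settle
        push0, flight0, flight1 = 300, 360, 480
        land1 = flight1 + 15  # 30 ms landing spike
        for loc in LOCATIONS:
            zi = _ACC[loc][2]
            seg[push0:flight0, zi] = np.linspace(1.0, 1.9, flight0 - push0)
            seg[flight0:flight1, zi] = 0.1
            spike = 4.0 * np.sin(np.linspace(0, np.pi, 2 * (land1 - flight1)))
            seg[flight1:land1, zi] = spike[: land1 - flight1]
            seg[flight1:land1, _GYR[loc][1]] = 150.0 * np.sin(
                np.linspace(0, np.pi, land1 - flight1)
            )
    else:
        raise GeneratorError(f"unknown ADL kind {kind!r}")
    return _add_noise(seg, p, rng)


def _instability(
    n: int, p: KinematicParams, axis: int, sig_scale: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Growing angular velocity about the fall axis with accompanying tilt.

    axis 0 = roll (lateral fall), axis 1 = pitch (AP fall).  Returns an
    upright segment whose gyro ramps as ``growth * t`` and whose gravity
    vector rotates with the integrated angle (capped at 65 deg), plus the
    final tilt angle in degrees so the next phase can continue from it.
    """
    seg = _segment(n)
    t = np.arange(n) / SAMPLING_RATE
    growth = p.instab_growth_dps2 * sig_scale
    omega = growth * t * (1.0 + 0.25 * np.sin(2 * np.pi * 3.1 * t))  # deg/s
    theta = np.clip(np.cumsum(omega) / SAMPLING_RATE, 0.0, 65.0)  # deg
    th = np.radians(theta)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    for loc in LOCATIONS:
        seg[:, _GYR[loc][axis]] += sign * omega
        zi = _ACC[loc][2]
        ti = _ACC[loc][axis]  # x for roll-tilt, y for pitch-tilt
        seg[:, zi] = np.cos(th)
        seg[:, ti] += sign * np.sin(th)
    return seg, float(theta[-1])


def _fall_segment(
    subtype: str, p: KinematicParams, speed: float, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    lead_in = 650
    axis = 0 if subtype == "lateral_fall" else 1
    sig = p.lat_signature_scale if subtype == "lateral_fall" else p.ap_signature_scale
    n_i = max(int(round(p.instab_duration_ms * SAMPLING_RATE / 1000)), 10)
    n_d = max(int(round(p.descent_duration_ms * SAMPLING_RATE / 1000)), 10)
    n_imp = int(rng.integers(10, 31))  # 20-60 ms spike
    n_rest = 150

    pre = _segment(lead_in)
    _walk_into(pre, slice(0, lead_in), p, speed, phase=float(rng.uniform(0, 2 * np.pi)))
    instab, theta_end = _instability(n_i, p, axis, sig, rng)

    # descent: accel magnitude ramps from ~1 g to a floor set by the
    # signature scale (vivid fall -> near free-fall); the body keeps
    # rotating from the instability's end angle with a signature-scaled
    # excursion, so a subtle fall stays subtle all the way to impact.
    floor = float(np.clip(1.0 - 0.85 * sig, 0.15, 0.95))
    descent = np.zeros((n_d, len(CHANNELS)))
    mag = np.linspace(1.0, floor, n_d)
    tilt = np.radians(np.linspace(theta_end, min(85.0, theta_end + 60.0 * sig), n_d))
    for loc in LOCATIONS:
        descent[:, _ACC[loc][2]] = mag * np.cos(tilt)
        descent[:, _ACC[loc][axis]] = mag * np.sin(tilt)
        descent[:, _GYR[loc][axis]] = sig * (
            180.0 + 60.0 * np.sin(np.linspace(0, np.pi, n_d))
        )

    # odd-length half-sine so the centre frame carries exactly the peak
    n_spike = 2 * n_imp + 1
    impact = np.zeros((n_spike, len(CHANNELS)))
    spike = np.sin(np.linspace(0, np.pi, n_spike))
    for loc, atten in (("lhip", 1.0), ("rhip", 0.9), ("back", 0.8)):
        impact[:, _ACC[loc][axis]] = atten * p.impact_peak_g * spike
        impact[:, _GYR[loc][axis]] = -120.0 * spike

    rest = np.zeros((n_rest, len(CHANNELS)))
    rest_axis = 2 if p.rest_upright else axis
    for loc in LOCATIONS:
        rest[:, _ACC[loc][rest_axis]] = 1.0  # lying on the fall side (or upright probe)

    seg = np.concatenate([pre, instab, descent, impact, rest])
    phases = {
        "instability_start": lead_in,
        "descent_start": lead_in + n_i,
        "impact": lead_in + n_i + n_d + n_imp,  # spike peak (centre frame)
        "rest_start": lead_in + n_i + n_d + n_spike,
    }
    return _add_noise(seg, p, rng), phases


def _near_fall_segment(
    p: KinematicParams, speed: float, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    lead_in = 400
    axis = int(rng.integers(0, 2))
    n_i = max(int(round(0.8 * p.instab_duration_ms * SAMPLING_RATE / 1000)), 10)
    n_c = 120  # 240 ms compensatory burst
    n_out = 500

    pre = _segment(lead_in)
    _walk_into(pre, slice(0, lead_in), p, speed, phase=float(rng.uniform(0, 2 * np.pi)))
    instab, _ = _instability(n_i, p, axis, 0.8, rng)

    comp = _segment(n_c)
    burst = np.sin(np.linspace(0, np.pi, n_c))
    for loc in LOCATIONS:
        comp[:, _GYR[loc][axis]] += -p.comp_gain * 250.0 * burst
        comp[:, _ACC[loc][2]] += 0.3 * p.comp_gain * burst
        comp[:, _ACC[loc][axis]] += -0.2 * p.comp_gain * burst

    out = _segment(n_out)
    _walk_into(out, slice(0, n_out), p, speed, phase=float(rng.uniform(0, 2 * np.pi)))

    seg = np.concatenate([pre, instab, comp, out])
    phases = {
        "instability_start": lead_in,
        "compensation_start": lead_in + n_i,
        "recovery_start": lead_in + n_i + n_c,
    }
    return _add_noise(seg, p, rng), phases


# ---------------------------------------------------------------------------
# subject- and cohort-level generation
# ---------------------------------------------------------------------------

_GAP = 200  # baseline frames between events
_LEAD_BASELINE = 400  # frames of quiet stance opening every recording


def generate_subject(
    profile: SubjectProfile,
    events: Sequence[str | tuple[str, str]],
    seed: int,
    max_frames: int | None = None,
) -> tuple[IMURecording, list[EventAnnotation]]:
    """Synthesize one subject's recording containing the requested events.

    ``events`` entries are subtype names (``"lateral_fall"``, ``"ap_fall"``,
    ``"near_fall"``, ``"adl"``) or ``("adl", kind)`` pairs; bare ``"adl"``
    entries cycle through the ADL kinds.  Events are placed in randomized
    order separated by quiet-stance gaps.  Fully reproducible given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    requested: list[tuple[str, str | None]] = []
    adl_cycle = 0
    for ev in events:
        if isinstance(ev, tuple):
            subtype, kind = ev
            if subtype != "adl" or kind not in ADL_KINDS:
                raise GeneratorError(f"unknown event request {ev!r}")
            requested.append((subtype, kind))
        elif ev == "adl":
            requested.append(("adl", ADL_KINDS[adl_cycle % len(ADL_KINDS)]))
            adl_cycle += 1
        elif ev in SUBTYPES:
            requested.append((ev, None))
        else:
            raise GeneratorError(f"unknown subtype {ev!r}")

    order = rng.permutation(len(requested))
    p, speed = profile.kinematics, profile.gait_speed

    segments: list[np.ndarray] = [_add_noise(_segment(_LEAD_BASELINE), p, rng)]
    annotations: list[EventAnnotation] = []
    cursor = _LEAD_BASELINE
    for idx in order:
        subtype, kind = requested[idx]
        phases: dict = {}
        if subtype in FALL_SUBTYPES:
            seg, phases = _fall_segment(subtype, p, speed, rng)
        elif subtype == "near_fall":
            seg, phases = _near_fall_segment(p, speed, rng)
        else:
            seg = _adl_segment(kind, p, speed, rng)
        if max_frames is not None and cursor + seg.shape[0] + _GAP > max_frames:
            raise GeneratorError(
                f"event {subtype} does not fit the recording budget of {max_frames} frames"
            )
        start = cursor
        end = cursor + seg.shape[0]
        impact = start + phases["impact"] if "impact" in phases else None
        annotations.append(
            EventAnnotation(
                event_id=f"{profile.subject_id}_e{int(idx):03d}",
                subject_id=profile.subject_id,
                activity_class="fall" if subtype in FALL_SUBTYPES else "non_fall",
                subtype=subtype,
                adl_kind=kind,
                region_start_frame=start,
                region_end_frame=end,
                true_impact_frame=impact,
                phases={k: start + v for k, v in phases.items()},
            )
        )
        segments.append(seg)
        segments.append(_add_noise(_segment(_GAP), p, rng))
        cursor = end + _GAP

    data = np.concatenate(segments)
    if p.baseline_wander_g > 0:
        t = np.arange(data.shape[0]) / SAMPLING_RATE
        for ci in ACCEL_IDX:
            wander = np.zeros_like(t)
            for _ in range(3):
                f = rng.uniform(0.05, 0.5)
                a = rng.uniform(0.3, 1.0) * p.baseline_wander_g
                wander += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            data[:, ci] += wander
    data[:, ACCEL_IDX] = np.clip(data[:, ACCEL_IDX], -ACCEL_RANGE_G, ACCEL_RANGE_G)
    data[:, GYRO_IDX] = np.clip(data[:, GYRO_IDX], -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    annotations.sort(key=lambda a: a.region_start_frame)
    return IMURecording(profile.subject_id, data.astype(np.float32)), annotations


def _distribute(total: int, n_subjects: int, minimum: int) -> list[int]:
    if n_subjects == 0:
        if total:
            raise GeneratorError("events requested for an empty cohort")
        return []
    base, rem = divmod(total, n_subjects)
    if total and base < minimum:
        raise GeneratorError(
            f"cannot distribute {total} events over {n_subjects} subjects "
            f"with >= {minimum} repetitions each"
        )
    return [base + (1 if i < rem else 0) for i in range(n_subjects)]


def generate_cohort_dataset(config: DatasetConfig) -> Dataset:
    """Generate the full two-cohort study dataset described by ``config``.

    Subject profiles are drawn from the per-cohort generating distributions
    (identical distributions when ``null_cohorts`` is set); the first
    ``n_unstable`` stroke subjects additionally receive the unstable-
    ambulator parameter shifts and the ``unstable`` severity label.  Each
    subject's random stream is derived from the master seed and the subject
    index, so subjects are independent of cohort-size changes elsewhere.
    """
    master = np.random.SeedSequence(config.seed)
    profiles: list[SubjectProfile] = []
    recordings: dict[str, IMURecording] = {}
    annotations: list[EventAnnotation] = []

    cohort_sizes = {"stroke": config.n_stroke, "control": config.n_control}
    for cohort_code, cohort in enumerate(("stroke", "control")):
        n = cohort_sizes[cohort]
        spec_ = config.control if (cohort == "control" or config.null_cohorts) else config.stroke
        if config.event_counts is not None:
            counts = config.event_counts.get(cohort, {})
            per_subject = {
                st: _distribute(counts.get(st, 0), n, config.repetitions) for st in SUBTYPES
            }
        else:
            per_subject = {st: [config.repetitions] * n for st in SUBTYPES}

        for i in range(n):
            sid = f"{cohort[:2]}{i + 1:02d}"
            seq = np.random.SeedSequence(entropy=(config.seed, cohort_code, i))
            prof_rng = np.random.default_rng(seq)
            speed, kin = spec_.draw(prof_rng)
            severity = "stable"
            if cohort == "stroke" and i < config.n_unstable:
                severity = "unstable"
                if not config.null_cohorts:
                    kin = _scaled(kin, config.unstable_multipliers)
                    speed *= 0.75
            profile = SubjectProfile(sid, cohort, severity, speed, kin)
            events: list[str | tuple[str, str]] = []
            for st in SUBTYPES:
                if st == "adl":
                    events.extend(
                        ("adl", config.adl_kinds[j % len(config.adl_kinds)])
                        for j in range(per_subject[st][i])
                    )
                else:
                    events.extend([st] * per_subject[st][i])
            subject_seed = int(seq.generate_state(1)[0] % (2**31))
            rec, anns = generate_subject(profile, events, subject_seed)
            profiles.append(profile)
            recordings[sid] = rec
            annotations.extend(anns)
    return Dataset(profiles, recordings, annotations)


def derive_unstable_labels(
    dataset: Dataset,
    speed_threshold: float = 0.75,
    trunk_range_threshold_dps: float = 80.0,
) -> dict[str, bool]:
    """Surrogate unstable-ambulator labelling from observable gait.

    Re-derives a severity label per stroke subject by thresholding gait
    speed and the lower-trunk roll angular-velocity range (5th-95th
    percentile of the back gyro roll channel) during walking ADLs: a
    subject is labelled unstable when the gait is slow *or* the trunk
    swings widely.  This mimics deriving the label from a gait assessment
    instead of trusting generator ground truth; thresholds are free
    parameters of the surrogate criterion.
    """
    roll = CHANNELS.index("back_gyr_x")
    labels: dict[str, bool] = {}
    for p in dataset.profiles:
        if p.cohort != "stroke":
            continue
        rec = dataset.recordings[p.subject_id]
        segments = [
            rec.data[a.region_start_frame : a.region_end_frame, roll]
            for a in dataset.annotations
            if a.subject_id == p.subject_id and a.adl_kind == "walk"
        ]
        if segments:
            walk = np.concatenate(segments).astype(np.float64)
            trunk_range = float(np.nanpercentile(walk, 95) - np.nanpercentile(walk, 5))
        else:
            trunk_range = 0.0
        labels[p.subject_id] = (
            p.gait_speed < speed_threshold or trunk_range > trunk_range_threshold_dps
        )
    return labels


def inject_defects(dataset: Dataset, fraction: float, seed: int) -> Dataset:
    """Flag ``floor(fraction * n_events)`` events defective by dropping channels.

    For each selected event, 1-3 randomly chosen channels are replaced by
    NaN within the event region (emulating a damaged cable) and the
    annotation's ``defective`` flag is set.  Returns a new dataset; the
    input is not mutated.
    """
    if not 0 <= fraction < 1:
        raise GeneratorError("fraction must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_defect = math.floor(fraction * len(dataset.annotations))
    order = sorted(range(len(dataset.annotations)), key=lambda i: dataset.annotations[i].event_id)
    chosen = set(rng.choice(order, size=n_defect, replace=False).tolist()) if n_defect else set()

    recordings = {sid: rec for sid, rec in dataset.recordings.items()}
    touched: set[str] = set()
    new_annotations: list[EventAnnotation] = []
    for i, ann in enumerate(dataset.annotations):
        if i not in chosen:
            new_annotations.append(replace(ann, phases=dict(ann.phases)))
            continue
        if ann.subject_id not in touched:
            rec = recordings[ann.subject_id]
            recordings[ann.subject_id] = IMURecording(
                rec.subject_id, rec.data.copy(), rec.sampling_rate
            )
            touched.add(ann.subject_id)
        n_drop = int(rng.integers(1, 4))
        ch = rng.choice(len(CHANNELS), size=n_drop, replace=False)
        data = recordings[ann.subject_id].data
        data[ann.region_start_frame : ann.region_end_frame, ch] = np.nan
        new_annotations.append(replace(ann, defective=True, phases=dict(ann.phases)))
    return Dataset(list(dataset.profiles), recordings, new_annotations)
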