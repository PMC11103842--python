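"""Seeded synthetic bilateral-accelerometry cohorts.

The generator emulates the data conditions the analysis pipeline assumes:
24 h recordings from two independently powered wrist devices at 32 Hz in
signed 8-bit counts, a sleep block with no arm activity, daytime activity
bouts shared between the arms (bimanual daily activity) with the affected
arm's oscillation amplitude scaled down by a deficit factor monotone in a
latent motor ability ``u`` in [0, 1], device start-time offsets of up to
±15 s, and trailing stretches of constant gravity-only signal left by bands
resting on a table after removal.

Activity bouts oscillate in the 3-10 Hz band — above the pipeline's 3 Hz
high-pass cutoff — because the filter removes posture and gravity; synthetic
movement placed below the cutoff would simply vanish from the output.

Clinical scores are noisy monotone readouts of the same latent ability, so
the generated cohort has, by construction, the positive coupling between
affected-arm acceleration and M-MAS / MAL that the correlation analysis is
meant to detect. Every output byte is determined by ``SynthParams.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ParameterError
from .preprocess import COUNTS_PER_G, GRAVITY_MS2
from .raw_io import (
    ClinicalScores,
    CohortRow,
    RawRecording,
    write_cohort_table,
    write_raw_recording,
)

BASE_EPOCH = 1_600_000_000.0  # arbitrary fixed recording start for T1


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration; defaults reproduce the study's conditions."""

    n_patients: int = 18
    seed: int = 0
    duration_h: float = 24.0
    rate_hz: float = 32.0
    sleep_start_h: float = 13.0  # hours after recording start (daytime fit-on)
    sleep_duration_h: float = 8.0
    bout_rate_per_h: float = 30.0
    bout_duration_mean_s: float = 20.0
    bout_duration_sd_s: float = 10.0
    bout_amplitude_mean_ms2: float = 2.5
    bout_amplitude_sd_ms2: float = 1.0
    bout_band_hz: tuple[float, float] = (3.0, 10.0)
    deficit_floor: float = 0.15  # deficit_link(0); deficit_link(1) == 1
    deficit_link: Callable[[float], float] | None = None
    score_noise_sd: float = 0.06
    improvement_mean: float = 0.15
    improvement_sd: float = 0.10
    sync_offset_range_s: float = 15.0
    trailing_idle_range_s: float = 900.0
    noise_sd_ms2: float = 0.10
    shared_schedule: bool = True
    n_dropout: int = 0  # extra incomplete patients exercising exclusion paths

    def link(self, u: float) -> float:
        """Affected-arm amplitude factor; monotone, link(1) == 1."""
        if self.deficit_link is not None:
            return float(self.deficit_link(u))
        return self.deficit_floor + (1.0 - self.deficit_floor) * float(u)


@dataclass(frozen=True)
class SessionTruth:
    """Injected per-session nuisance parameters, for test assertions."""

    sync_offset_s: float  # right start minus left start, seconds
    sync_offset_raw_samples: int
    idle_left_s: float
    idle_right_s: float
    deficit_factor: float


@dataclass
class PatientTruth:
    patient_id: str
    affected_side: str
    u: dict[str, float] = field(default_factory=dict)  # session -> ability
    sessions: dict[str, SessionTruth] = field(default_factory=dict)


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            pid: {
                "affected_side": pt.affected_side,
                "u": pt.u,
                "sessions": {s: dataclasses.asdict(st) for s, st in pt.sessions.items()},
            }
            for pid, pt in self.patients.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def score_from_ability(u: float, params: SynthParams, rng: np.random.Generator) -> ClinicalScores:
    """Noisy monotone readout of latent ability onto the clinical scales.

    M-MAS is ``round(15 * clip(u + e, 0, 1))`` and each MAL subscale is
    ``round(150 * clip(u + e', 0, 1)) / 30`` (the 1/30 item grid), with
    independent Gaussian noise and round-half-away-from-zero rounding.
    """
    if not 0.0 <= u <= 1.0:
        raise ParameterError(f"ability u must lie in [0, 1], got {u}")
    eps = rng.normal(0.0, params.score_noise_sd, size=3)
    mas = int(_round_half_away(15.0 * np.clip(u + eps[0], 0.0, 1.0)))
    mal_aou = float(_round_half_away(150.0 * np.clip(u + eps[1], 0.0, 1.0)) / 30.0)
    mal_qom = float(_round_half_away(150.0 * np.clip(u + eps[2], 0.0, 1.0)) / 30.0)
    return ClinicalScores(mas=mas, mal_aou=mal_aou, mal_qom=mal_qom)


def _slow_gravity(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly re-orienting unit-gravity vector (all spectral content < 0.2 Hz)."""
    t = np.arange(n, dtype=np.float64) / fs
    def slow_angle(center: float, spread: float) -> np.ndarray:
        ang = np.full(n, center + rng.uniform(-spread, spread))
        for _ in range(3):
            f = rng.uniform(0.005, 0.15)
            a = rng.uniform(0.05, 0.35)
            phi = rng.uniform(0, 2 * np.pi)
            ang = ang + a * np.sin(2 * np.pi * f * t + phi)
        return ang
    theta = slow_angle(1.2, 0.8)
    phi = slow_angle(0.0, np.pi)
    g = np.empty((n, 3), dtype=np.float32)
    g[:, 0] = np.sin(theta) * np.cos(phi)
    g[:, 1] = np.sin(theta) * np.sin(phi)
    g[:, 2] = np.cos(theta)
    return g * GRAVITY_MS2


def _wake_mask_seconds(span_s: float, params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Wake intervals (start, end in seconds) within [0, span_s)."""
    starts, ends = [], []
    day = 24.0 * 3600.0
    s0 = params.sleep_start_h * 3600.0
    s1 = s0 + params.sleep_duration_h * 3600.0
    t = 0.0
    n_days = int(math.ceil(span_s / day)) + 1
    sleep = [(s0 + k * day, s1 + k * day) for k in range(-1, n_days)]
    edges = sorted(sleep)
    cur = 0.0
    for a, b in edges:
        a, b = max(a, 0.0), min(b, span_s)
        if a > cur:
            starts.append(cur)
            ends.append(a)
        cur = max(cur, b)
        if cur >= span_s:
            break
    if cur < span_s:
        starts.append(cur)
        ends.append(span_s)
    return np.array(starts), np.array(ends)


def _bout_schedule(span_s: float, params: SynthParams, rng: np.random.Generator):
    """Poisson bout start times over the wake intervals, with marks."""
    starts, ends = _wake_mask_seconds(span_s, params)
    lengths = ends - starts
    wake_s = float(lengths.sum())
    n_bouts = rng.poisson(params.bout_rate_per_h * wake_s / 3600.0)
    if n_bouts == 0 or wake_s == 0:
        return []
    # Uniform over the union of wake intervals.
    u = np.sort(rng.uniform(0.0, wake_s, size=n_bouts))
    offsets = np.concatenate(([0.0], np.cumsum(lengths)))
    seg = np.searchsorted(offsets, u, side="right") - 1
    t0 = starts[seg] + (u - offsets[seg])
    bouts = []
    for t in t0:
        dur = max(2.0, rng.normal(params.bout_duration_mean_s, params.bout_duration_sd_s))
        amp = max(0.2, rng.normal(params.bout_amplitude_mean_ms2, params.bout_amplitude_sd_ms2))
        freq = rng.uniform(*params.bout_band_hz)
        phase = rng.uniform(0.0, 2 * np.pi)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        bouts.append((float(t), dur, amp, freq, phase, d))
    return bouts


def _render_bouts(n: int, fs: float, bouts) -> np.ndarray:
    """Sum of Hann-enveloped band-limited oscillations, shape (n, 3)."""
    out = np.zeros((n, 3), dtype=np.float32)
    for t0, dur, amp, freq, phase, d in bouts:
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + int(round(dur * fs)))
        if i1 <= i0:
            continue
        m = i1 - i0
        tt = np.arange(m) / fs
        env = np.hanning(m) if m > 2 else np.ones(m)
        wave = (amp * env * np.sin(2 * np.pi * freq * tt + phase)).astype(np.float32)
        out[i0:i1] += wave[:, None] * d.astype(np.float32)
    return out


def _quantize(accel_ms2: np.ndarray) -> np.ndarray:
    counts = np.rint(accel_ms2 * (COUNTS_PER_G / GRAVITY_MS2))
    return np.clip(counts, -128, 127).astype(np.int16)


def simulate_recording_pair(
    u: float,
    affected_side: str,
    params: SynthParams,
    rng: np.random.Generator,
    start_time: float = BASE_EPOCH,
) -> tuple[RawRecording, RawRecording, SessionTruth]:
    """One session's left/right raw recordings for a patient with ability ``u``.

    Both arms see the same bout schedule (bimanual activity) with the
    affected arm's oscillation amplitude multiplied by the deficit factor;
    each device adds its own sensor noise, start-time offset, and trailing
    gravity-only idle stretch.
    """
    if params.bout_amplitude_mean_ms2 + GRAVITY_MS2 > 1.9 * 2 * GRAVITY_MS2:
        raise ParameterError("bout amplitude implies systematic 8-bit saturation")
    fs = params.rate_hz
    n = int(round(params.duration_h * 3600.0 * fs))
    pad = int(round(params.sync_offset_range_s * fs))
    n_world = n + 2 * pad

    factor = params.link(u)
    offset_raw = int(round(rng.uniform(-params.sync_offset_range_s, params.sync_offset_range_s) * fs))

    span_s = n_world / fs
    if params.shared_schedule:
        bouts_l = bouts_r = _bout_schedule(span_s, params, rng)
    else:
        bouts_l = _bout_schedule(span_s, params, rng)
        bouts_r = _bout_schedule(span_s, params, rng)
    world_l = _render_bouts(n_world, fs, bouts_l)
    world_r = world_l if bouts_r is bouts_l else _render_bouts(n_world, fs, bouts_r)

    factor_l = factor if affected_side == "left" else 1.0
    factor_r = factor if affected_side == "right" else 1.0

    recs = []
    idles = []
    for arm, world, arm_factor, i0 in (
        ("left", world_l, factor_l, pad),
        ("right", world_r, factor_r, pad + offset_raw),
    ):
        sig = arm_factor * world[i0 : i0 + n].astype(np.float64)
        sig += _slow_gravity(n, fs, rng)
        sig += rng.normal(0.0, params.noise_sd_ms2, size=(n, 3))
        idle_s = rng.uniform(0.0, params.trailing_idle_range_s)
        idle_n = int(round(idle_s * fs))
        if idle_n:
            sig = np.vstack([sig, np.repeat(sig[-1:], idle_n, axis=0)])
            # Freeze the idle tail at the final posture: gravity only, no noise.
            sig[n:] = sig[n - 1]
        t0 = start_time if arm == "left" else start_time + offset_raw / fs
        recs.append(
            RawRecording(
                arm_label=arm, start_time=t0, sample_rate_hz=fs, samples=_quantize(sig)
            )
        )
        idles.append(idle_s)

    truth = SessionTruth(
        sync_offset_s=offset_raw / fs,
        sync_offset_raw_samples=offset_raw,
        idle_left_s=idles[0],
        idle_right_s=idles[1],
        deficit_factor=factor,
    )
    return recs[0], recs[1], truth


def draw_patient_truths(params: SynthParams, rng: np.random.Generator) -> list[PatientTruth]:
    """Latent abilities and affected sides for the cohort."""
    truths = []
    for i in range(params.n_patients + params.n_dropout):
        pid = f"p{i + 1:02d}"
        side = "left" if rng.uniform() < 0.5 else "right"
        u1 = float(rng.uniform(0.05, 0.95))
        u2 = float(np.clip(u1 + rng.normal(params.improvement_mean, params.improvement_sd), 0.0, 1.0))
        truths.append(PatientTruth(patient_id=pid, affected_side=side, u={"T1": u1, "T2": u2}))
    return truths


def simulate_cohort(params: SynthParams, out_dir: str | Path) -> tuple[list[CohortRow], GroundTruth]:
    """Write a full synthetic cohort to disk: recordings, metadata, ground truth.

    Produces ``n_patients`` complete patients (two sessions each). With
    ``n_dropout >= 1`` one extra patient lacks the T2 session entirely, and
    with ``n_dropout >= 2`` a second extra patient has a truncated (too
    short) right-arm T1 file — both exercising the pipeline's exclusion
    paths the way incomplete study participants would.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    truths = draw_patient_truths(params, rng)
    gt = GroundTruth(patients={t.patient_id: t for t in truths})

    rows: list[CohortRow] = []
    for i, pt in enumerate(truths):
        is_missing_t2 = params.n_dropout >= 1 and i == params.n_patients
        is_bad_arm = params.n_dropout >= 2 and i == params.n_patients + 1
        for s_idx, session in enumerate(("T1", "T2")):
            if is_missing_t2 and session == "T2":
                continue
            start = BASE_EPOCH + s_idx * 14 * 24 * 3600.0
            left, right, st = simulate_recording_pair(
                pt.u[session], pt.affected_side, params, rng, start_time=start
            )
            pt.sessions[session] = st
            lpath = out_dir / f"{pt.patient_id}_{session}_left.csv"
            rpath = out_dir / f"{pt.patient_id}_{session}_right.csv"
            write_raw_recording(left, lpath)
            if is_bad_arm and session == "T1":
                # Truncated export: keep the header and the first 100 rows only.
                lines = write_raw_recording(right, rpath).read_text().splitlines()[:102]
                rpath.write_text("\n".join(lines) + "\n")
            else:
                write_raw_recording(right, rpath)
            scores = score_from_ability(pt.u[session], params, rng)
            rows.append(
                CohortRow(
                    patient_id=pt.patient_id,
                    affected_side=pt.affected_side,
                    session=session,
                    scores=scores,
                    left_file=lpath,
                    right_file=rpath,
                )
            )
    write_cohort_table(rows, out_dir / "cohort.csv")
    gt.to_json(out_dir / "ground_truth.json")
    return rows, gt
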