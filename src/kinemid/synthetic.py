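"""Synthetic multi-joint kick-waveform generator with two-timescale drift.

Emulates the structure of a fatiguing karate training session: each subject
performs, per leg, ``n_sets`` sets of submaximal (K-80) kicks — every set
split into ``blocks_per_set`` blocks of ``kicks_per_block`` kicks — plus a
small number of maximal-intensity (K-100) kicks at fixed time points
(pre-session, after each set, post-session).

The waveform model: each of the 27 joint-angle variables of a kick is a
smooth cubic B-spline curve on normalized time [0, 1] whose coefficient
vector is a sum of

* a grand-mean template (shared by everyone),
* a subject offset (the individual movement signature, spread subject_sd),
* a leg offset (left/right asymmetry, spread leg_sd),
* a slow set-level drift state — a random walk over sets with step
  set_drift_sd (the tens-of-minutes fatigue timescale),
* a block offset per within-set block index, drawn once and REUSED in every
  set (the tens-of-seconds timescale that repeats with the set rhythm),
* a non-repeating per-(set, block) offset with spread block_drift_sd,
* i.i.d. per-kick coefficient noise with spread noise_sd.

Each kick is evaluated on its own time grid (duration uniform in
``kick_duration_range`` at ``sampling_rate``), passed through a smooth
monotone random time warp of magnitude ``warp_sd`` (fraction of duration),
and — for K-100 — amplitude-scaled by ``intensity_gain`` with a shortened
duration.  All randomness derives from one seed, split into independent
per-subject streams so a subject's data do not change when ``n_subjects``
does.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import ParameterError, SchemaError
from .preprocess import N_VARIABLES, VARIABLE_NAMES

logger = logging.getLogger("kinemid.synthetic")

LEGS_DEFAULT = ("left", "right")
INTENSITIES = ("K80", "K100")


# ---------------------------------------------------------------------------
# Protocol and generator parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSpec:
    """Session structure: sets, blocks, kicks, and maximal-intensity probes.

    Defaults reproduce the study protocol: 9 sets x 3 blocks x 10 kicks of
    K-80 per leg (270), and 11 K-100 time points (pre + after each of the 9
    sets + post) x 3 kicks per leg (33), i.e. 2*(270+33) = 606 kicks per
    subject, sampled at 333 Hz.
    """

    n_subjects: int = 16
    n_sets: int = 9
    blocks_per_set: int = 3
    kicks_per_block: int = 10
    k100_timepoints: int = 11
    k100_kicks_per_timepoint: int = 3
    legs: tuple[str, ...] = LEGS_DEFAULT
    sampling_rate: float = 333.0
    kick_duration_range: tuple[float, float] = (0.4, 0.8)

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sets", "blocks_per_set", "kicks_per_block",
                     "k100_kicks_per_timepoint"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.k100_timepoints, (int, np.integer)) or self.k100_timepoints < 0:
            raise ParameterError(f"k100_timepoints must be an integer >= 0, got {self.k100_timepoints!r}")
        if len(self.legs) == 0:
            raise ParameterError("legs must be a non-empty label set")
        if len(set(self.legs)) != len(self.legs):
            raise ParameterError("legs must be distinct labels")
        if self.sampling_rate <= 0:
            raise ParameterError(f"sampling_rate must be positive, got {self.sampling_rate}")
        lo, hi = self.kick_duration_range
        if not (0 < lo <= hi):
            raise ParameterError(f"kick_duration_range must satisfy 0 < min <= max, got {self.kick_duration_range}")

    @property
    def k80_kicks_per_leg(self) -> int:
        return self.n_sets * self.blocks_per_set * self.kicks_per_block

    @property
    def k100_kicks_per_leg(self) -> int:
        return self.k100_timepoints * self.k100_kicks_per_timepoint

    @property
    def kicks_per_subject(self) -> int:
        return len(self.legs) * (self.k80_kicks_per_leg + self.k100_kicks_per_leg)

    @property
    def total_kicks(self) -> int:
        return self.n_subjects * self.kicks_per_subject


@dataclass(frozen=True)
class GeneratorParams:
    """Effect sizes of the waveform model (all in degrees of joint angle,
    except warp_sd which is a fraction of kick duration).

    The defaults encode a regime consistent with the study's findings:
    between-subject signature spread well above kick-to-kick noise (perfect
    individual separability), and set/block drift of the same order as the
    noise (intra-individual tasks well above chance but imperfect).
    """

    n_basis: int = 8
    template_scale: float = 20.0    # grand-mean coefficient spread
    subject_sd: float = 3.5
    leg_sd: float = 1.75
    intensity_gain: float = 1.15
    k100_duration_factor: float = 0.9
    set_drift_sd: float = 0.4
    block_effect_sd: float = 0.25
    block_drift_sd: float = 0.12
    noise_sd: float = 1.5
    warp_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_basis, (int, np.integer)) or self.n_basis < 4:
            raise ParameterError(f"n_basis must be an integer >= 4 (cubic splines), got {self.n_basis!r}")
        for name in ("template_scale", "subject_sd", "leg_sd", "set_drift_sd",
                     "block_effect_sd", "block_drift_sd", "noise_sd", "warp_sd"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("intensity_gain", "k100_duration_factor"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _bspline_knots(n_basis: int) -> np.ndarray:
    k = 3
    return np.concatenate([np.zeros(k), np.linspace(0.0, 1.0, n_basis - k + 1), np.ones(k)])


def bspline_design(times: np.ndarray, n_basis: int) -> np.ndarray:
    """(len(times), n_basis) cubic B-spline basis matrix on [0, 1]."""
    t = np.clip(np.asarray(times, float), 0.0, 1.0)
    return BSpline.design_matrix(t, _bspline_knots(n_basis), 3).toarray()


@dataclass(frozen=True)
class TemplateSet:
    """Deterministic function of (ProtocolSpec, GeneratorParams).

    Arrays are coefficient tensors over (variable, basis):
    ``grand`` (V, B); ``subject_offsets`` (S, V, B);
    ``leg_offsets`` (S, L, V, B); ``drift_states`` (S, n_sets+1, V, B) with
    state 0 the pre-session state and state s the state during set s;
    ``block_offsets`` (blocks_per_set, V, B) shared across sets and subjects;
    ``block_drifts`` (S, n_sets, blocks_per_set, V, B) non-repeating.
    """

    protocol: ProtocolSpec
    params: GeneratorParams
    grand: np.ndarray
    subject_offsets: np.ndarray
    leg_offsets: np.ndarray
    drift_states: np.ndarray
    block_offsets: np.ndarray
    block_drifts: np.ndarray

    def kick_coefficients(self, subject: int, leg_idx: int, state_idx: int,
                          block_idx: int | None, set_idx: int | None) -> np.ndarray:
        """(V, B) coefficient matrix before per-kick noise."""
        c = (self.grand
             + self.subject_offsets[subject]
             + self.leg_offsets[subject, leg_idx]
             + self.drift_states[subject, state_idx])
        if block_idx is not None:
            c = c + self.block_offsets[block_idx] + self.block_drifts[subject, set_idx, block_idx]
        return c


def build_templates(protocol: ProtocolSpec, params: GeneratorParams) -> TemplateSet:
    """Draw the template hierarchy from the generator seed.

    Stream layout: one root SeedSequence spawns a global child (grand mean
    and the shared block offsets) and one child per subject (subject/leg
    offsets, drift walk, non-repeating block drifts), so per-subject
    templates are invariant to n_subjects.
    """
    V, B = N_VARIABLES, params.n_basis
    S, L = protocol.n_subjects, len(protocol.legs)
    root = np.random.SeedSequence(params.seed)
    global_ss, *subject_ss = root.spawn(1 + S)
    g = np.random.default_rng(global_ss)
    grand = g.normal(0.0, params.template_scale, size=(V, B))
    block_offsets = g.normal(0.0, params.block_effect_sd, size=(protocol.blocks_per_set, V, B))

    subject_offsets = np.empty((S, V, B))
    leg_offsets = np.empty((S, L, V, B))
    drift_states = np.empty((S, protocol.n_sets + 1, V, B))
    block_drifts = np.empty((S, protocol.n_sets, protocol.blocks_per_set, V, B))
    for s, ss in enumerate(subject_ss):
        template_stream, _kick_stream = ss.spawn(2)
        r = np.random.default_rng(template_stream)
        subject_offsets[s] = r.normal(0.0, params.subject_sd, size=(V, B))
        leg_offsets[s] = r.normal(0.0, params.leg_sd, size=(L, V, B))
        steps = r.normal(0.0, params.set_drift_sd, size=(protocol.n_sets, V, B))
        drift_states[s, 0] = 0.0
        drift_states[s, 1:] = np.cumsum(steps, axis=0)
        block_drifts[s] = r.normal(
            0.0, params.block_drift_sd, size=(protocol.n_sets, protocol.blocks_per_set, V, B)
        )
    return TemplateSet(protocol, params, grand, subject_offsets, leg_offsets,
                       drift_states, block_offsets, block_drifts)


# ---------------------------------------------------------------------------
# Kick records and dataset
# ---------------------------------------------------------------------------

@dataclass
class KickRecord:
    """One kick: condition labels plus the 27 angle waveforms.

    ``set_index`` is the set 1..n_sets for K-80 kicks and the time point
    0..k100_timepoints-1 for K-100 kicks; ``block`` is 1..blocks_per_set for
    K-80 and 0 for K-100; ``kick`` counts within the block/time point
    (1-based).  ``waveforms`` is (n_samples, 27) in registry column order,
    degrees.
    """

    subject: int
    leg: str
    intensity: str
    set_index: int
    block: int
    kick: int
    waveforms: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        w = np.asarray(self.waveforms, dtype=float)
        if w.ndim != 2 or w.shape[1] != N_VARIABLES:
            raise SchemaError(f"waveforms must be (n_samples, {N_VARIABLES}), got {w.shape}")
        if w.shape[0] < 2:
            raise SchemaError("kick must have at least 2 samples")
        if self.intensity not in INTENSITIES:
            raise SchemaError(f"intensity must be one of {INTENSITIES}, got {self.intensity!r}")
        self.waveforms = w

    def with_waveforms(self, waveforms: np.ndarray) -> "KickRecord":
        return KickRecord(self.subject, self.leg, self.intensity, self.set_index,
                          self.block, self.kick, waveforms, self.sampling_rate)


@dataclass
class KickDataset:
    """All kicks of a (synthetic) study plus protocol metadata."""

    protocol: ProtocolSpec
    params: GeneratorParams
    records: list[KickRecord]

    def __len__(self) -> int:
        return len(self.records)

    def iter_records(self) -> Iterator[KickRecord]:
        return iter(self.records)

    def select(self, **conditions) -> list[KickRecord]:
        out = []
        for r in self.records:
            if all(getattr(r, k if k != "set" else "set_index") == v for k, v in conditions.items()):
                out.append(r)
        return out


def _monotone_warp(times01: np.ndarray, rng: np.random.Generator, warp_sd: float) -> np.ndarray:
    """Smooth monotone warp of [0,1]: cumulative softplus of a random cubic.

    The deviation from identity is rescaled to maximum magnitude ``warp_sd``
    (fraction of duration); endpoints are fixed, monotonicity enforced.
    """
    if warp_sd == 0.0:
        return times01
    coeffs = rng.normal(0.0, 1.0, size=4)
    p = np.polyval(coeffs, times01)
    rate = np.logaddexp(0.0, p)  # softplus, strictly positive
    w = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * np.diff(times01))])
    w /= w[-1]
    dev = w - times01
    peak = np.max(np.abs(dev))
    if peak > 0:
        w = times01 + dev * (warp_sd / peak)
    w = np.maximum.accumulate(w)
    return np.clip(w, 0.0, 1.0)


def generate_dataset(protocol: ProtocolSpec, params: GeneratorParams) -> KickDataset:
    """Generate one KickRecord per protocol slot; bit-for-bit seed-determined.

    Per-kick randomness (noise, warp, duration) is drawn from a dedicated
    per-subject stream in a fixed slot order: for each leg, all K-80 kicks
    (set-major, then block, then kick), then all K-100 kicks (time-point
    major).
    """
    templates = build_templates(protocol, params)
    # Re-derive the per-subject streams: spawning a freshly constructed
    # SeedSequence is deterministic, and subject s always receives root
    # child 1+s, so per-subject data are invariant to n_subjects.
    root = np.random.SeedSequence(params.seed)
    subject_ss = root.spawn(1 + protocol.n_subjects)[1:]
    kick_streams = [ss.spawn(2)[1] for ss in subject_ss]

    V, B = N_VARIABLES, params.n_basis
    fs = protocol.sampling_rate
    lo, hi = protocol.kick_duration_range
    records: list[KickRecord] = []
    for s in range(protocol.n_subjects):
        rng = np.random.default_rng(kick_streams[s])
        for leg_idx, leg in enumerate(protocol.legs):
            for set_i in range(1, protocol.n_sets + 1):
                for block_i in range(1, protocol.blocks_per_set + 1):
                    for kick_i in range(1, protocol.kicks_per_block + 1):
                        coef = templates.kick_coefficients(s, leg_idx, set_i, block_i - 1, set_i - 1)
                        rec = _evaluate_kick(coef, rng, params, fs, lo, hi, gain=1.0)
                        records.append(KickRecord(s, leg, "K80", set_i, block_i, kick_i, rec, fs))
            for tp in range(protocol.k100_timepoints):
                state = min(tp, protocol.n_sets)
                for kick_i in range(1, protocol.k100_kicks_per_timepoint + 1):
                    coef = templates.kick_coefficients(s, leg_idx, state, None, None)
                    rec = _evaluate_kick(coef, rng, params, fs,
                                         lo * params.k100_duration_factor,
                                         hi * params.k100_duration_factor,
                                         gain=params.intensity_gain)
                    records.append(KickRecord(s, leg, "K100", tp, 0, kick_i, rec, fs))
    logger.info("generated %d kicks (%d subjects x %d per subject)",
                len(records), protocol.n_subjects, protocol.kicks_per_subject)
    return KickDataset(protocol, params, records)


def _evaluate_kick(coef: np.ndarray, rng: np.random.Generator, params: GeneratorParams,
                   fs: float, dur_lo: float, dur_hi: float, gain: float) -> np.ndarray:
    duration = rng.uniform(dur_lo, dur_hi)
    n_samples = max(int(round(duration * fs)) + 1, 8)
    t = np.linspace(0.0, 1.0, n_samples)
    warped = _monotone_warp(t, rng, params.warp_sd)
    noisy = coef + rng.normal(0.0, params.noise_sd, size=coef.shape)
    basis = bspline_design(warped, params.n_basis)  # (n, B)
    return gain * (basis @ noisy.T)  # (n, V)


# ---------------------------------------------------------------------------
# Segmentation ground truth helper
# ---------------------------------------------------------------------------

def make_segmentation_example(
    n_samples: int, start_index: int, peak_index: int,
    rng: np.random.Generator | None = None, noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Synthetic foot-position and knee-angle channels with known events.

    Position is flat then ramps forward from ``start_index``; the knee
    extension angle rises smoothly to a single peak at ``peak_index``.
    The optional noise is band-limited (smooth), matching the contract of
    the segmenter, whose inputs are low-pass-filtered recordings.
    Returns (position, knee_angle, (start_index, peak_index)).
    """
    if not (0 <= start_index < peak_index < n_samples):
        raise ParameterError("need 0 <= start_index < peak_index < n_samples")
    pos = np.zeros(n_samples)
    ramp = np.arange(n_samples - start_index, dtype=float)
    pos[start_index:] = 0.01 * ramp ** 1.5
    t = np.arange(n_samples, dtype=float)
    width = max(peak_index - start_index, 2) / 1.5
    knee = 120.0 * np.exp(-0.5 * ((t - peak_index) / width) ** 2)
    if rng is not None and noise_sd > 0:
        u = t / n_samples
        def smooth_noise(amplitude: float) -> np.ndarray:
            freqs = rng.integers(1, 4, size=3)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            amps = rng.normal(0.0, amplitude / np.sqrt(3), size=3)
            return sum(a * np.sin(2 * np.pi * f * u + ph)
                       for a, f, ph in zip(amps, freqs, phases))
        pos = pos + smooth_noise(noise_sd * 0.01)
        knee = knee + smooth_noise(noise_sd)
    return pos, knee, (start_index, peak_index)


# ---------------------------------------------------------------------------
# I/O: long-format CSV + JSON sidecar
# ---------------------------------------------------------------------------

def dataset_to_frame(dataset: KickDataset) -> pd.DataFrame:
    """Long format: one row per (kick, sample, variable)."""
    chunks = []
    for r in dataset.records:
        n = r.waveforms.shape[0]
        tsec = np.arange(n) / r.sampling_rate
        df = pd.DataFrame({
            "subject": np.repeat(r.subject, n * N_VARIABLES),
            "leg": r.leg,
            "intensity": r.intensity,
            "set": r.set_index,
            "block": r.block,
            "kick": r.kick,
            "timepoint_s": np.repeat(tsec, N_VARIABLES),
            "variable": np.tile(np.asarray(VARIABLE_NAMES), n),
            "value_deg": r.waveforms.reshape(-1),
        })
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def write_dataset(dataset: KickDataset, out_dir: str | Path, compress: bool = False) -> dict[str, Path]:
    """Write the long-format CSV plus a JSON sidecar with the specs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / ("kicks.csv.gz" if compress else "kicks.csv")
    dataset_to_frame(dataset).to_csv(csv_path, index=False)
    sidecar = out / "dataset.json"
    meta = {
        "protocol": asdict(dataset.protocol),
        "generator": asdict(dataset.params),
        "n_records": len(dataset),
        "variables": list(VARIABLE_NAMES),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return {"csv": csv_path, "sidecar": sidecar}


def read_dataset(in_dir: str | Path) -> KickDataset:
    """Read a dataset written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "dataset.json").read_text())
    proto_d = sidecar["protocol"]
    proto_d["legs"] = tuple(proto_d["legs"])
    proto_d["kick_duration_range"] = tuple(proto_d["kick_duration_range"])
    protocol = ProtocolSpec(**proto_d)
    params = GeneratorParams(**sidecar["generator"])
    csv_path = in_dir / "kicks.csv"
    if not csv_path.exists():
        csv_path = in_dir / "kicks.csv.gz"
    df = pd.read_csv(csv_path)
    records = []
    var_order = {name: i for i, name in enumerate(VARIABLE_NAMES)}
    keys = ["subject", "leg", "intensity", "set", "block", "kick"]
    for (subject, leg, intensity, set_i, block, kick), g in df.groupby(keys, sort=False):
        n = g["timepoint_s"].nunique()
        w = np.empty((n, N_VARIABLES))
        g = g.sort_values(["timepoint_s", "variable"], kind="stable")
        vals = g["value_deg"].to_numpy().reshape(n, -1)
        names_sorted = sorted(VARIABLE_NAMES)
        for j, name in enumerate(names_sorted):
            w[:, var_order[name]] = vals[:, j]
        records.append(KickRecord(int(subject), str(leg), str(intensity), int(set_i),
                                  int(block), int(kick), w, protocol.sampling_rate))
    return KickDataset(protocol, params, records)
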