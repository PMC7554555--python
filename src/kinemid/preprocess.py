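"""Kinematic preprocessing: from raw joint-angle waveforms to feature vectors.

The chain mirrors standard motion-capture practice for waveform
classification: zero-phase Butterworth low-pass filtering, kick segmentation
(from first forward foot motion to maximum knee extension), time
normalization to a fixed percentage grid (101 points), assembly of the
27 variables x 101 points = 2727-dimensional per-kick feature vector, and a
column-wise z-score followed by an affine map of the training range onto
(-1, 1).

The 27 variables are nine joint/segment angles (left/right ankle, knee and
hip, the sternoclavicular joint, and the left/right thigh-to-thorax angles),
each decomposed into Cardan angles about three axes (planes x, y, z).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .errors import ParameterError, SchemaError, SegmentationError

logger = logging.getLogger("kinemid.preprocess")

# ---------------------------------------------------------------------------
# Variable registry
# ---------------------------------------------------------------------------

#: The nine joint/segment angles of the partial body model.
JOINT_NAMES: tuple[str, ...] = (
    "ankle_left",
    "ankle_right",
    "hip_left",
    "hip_right",
    "knee_left",
    "knee_right",
    "sternoclavicular",
    "thigh_thorax_left",
    "thigh_thorax_right",
)

PLANES: tuple[str, ...] = ("x", "y", "z")

#: Fixed, versioned column-ordering registry: lexicographic by (joint, plane).
#: Feature column v*n_grid + t holds variable ``VARIABLE_REGISTRY[v]`` at grid
#: point t.  Changing this ordering is a breaking change to stored features.
VARIABLE_REGISTRY: tuple[tuple[str, str], ...] = tuple(
    (joint, plane) for joint in sorted(JOINT_NAMES) for plane in PLANES
)
REGISTRY_VERSION = 1

N_VARIABLES = len(VARIABLE_REGISTRY)  # 27
DEFAULT_GRID_POINTS = 101


def variable_name(var: tuple[str, str]) -> str:
    return f"{var[0]}_{var[1]}"


VARIABLE_NAMES: tuple[str, ...] = tuple(variable_name(v) for v in VARIABLE_REGISTRY)


# ---------------------------------------------------------------------------
# Zero-phase low-pass filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Butterworth zero-phase low-pass filter specification.

    ``order`` is the *stated* filter order (must be even).  Under the
    ``effective`` convention (Winter's) the forward-backward application of
    an ``order/2`` design with a raised cut-off yields an effective
    ``order``-th order magnitude response with -3 dB at ``cutoff_hz``.  Under
    ``per-pass`` the full ``order`` is designed as given and applied
    forward-backward without cut-off correction.
    """

    order: int = 6
    cutoff_hz: float = 15.0
    convention: str = "effective"  # {"effective", "per-pass"}

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2 != 0:
            raise ParameterError(f"filter order must be a positive even integer, got {self.order}")
        if not math.isfinite(self.cutoff_hz) or self.cutoff_hz <= 0:
            raise ParameterError(f"cutoff must be a positive finite frequency, got {self.cutoff_hz}")
        if self.convention not in ("effective", "per-pass"):
            raise ParameterError(f"unknown filter convention {self.convention!r}")

    def design(self, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (b, a) of the per-pass design for ``sampling_rate``."""
        nyq = sampling_rate / 2.0
        if self.cutoff_hz >= nyq:
            raise ParameterError(
                f"cutoff {self.cutoff_hz} Hz >= Nyquist {nyq} Hz at fs={sampling_rate}"
            )
        if self.convention == "effective":
            n_pass = self.order // 2
            cutoff = self.cutoff_hz / pass_correction_factor(n_pass)
        else:
            n_pass = self.order
            cutoff = self.cutoff_hz
        if cutoff >= nyq:
            raise ParameterError(
                f"corrected cutoff {cutoff:.2f} Hz >= Nyquist {nyq} Hz; lower the cutoff"
            )
        b, a = signal.butter(n_pass, cutoff / nyq, btype="low")
        return b, a


def pass_correction_factor(order_per_pass: int) -> float:
    """Cut-off correction for a dual-pass (forward-backward) Butterworth.

    The per-pass -3 dB frequency must be raised by 1/C with
    C = (2**(1/2) - 1) ** (1 / (2 n)) so the combined two-pass response is
    -3 dB at the nominal cut-off.
    """
    return (math.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order_per_pass))


def lowpass_zero_phase(
    samples: np.ndarray, sampling_rate: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Apply the zero-phase low-pass filter along axis 0.

    Accepts a 1-D waveform or an (n_samples, n_channels) array; returns an
    array of identical shape.  Forward-backward application cancels phase
    lag and preserves unit DC gain.
    """
    samples = np.asarray(samples, dtype=float)
    min_len = 3 * (spec.order + 1)
    if samples.shape[0] <= min_len:
        raise ParameterError(
            f"signal of length {samples.shape[0]} too short for order-{spec.order} "
            f"zero-phase filtering (need > {min_len} samples)"
        )
    if not np.all(np.isfinite(samples)):
        raise SchemaError("waveform contains non-finite samples")
    b, a = spec.design(sampling_rate)
    return signal.filtfilt(b, a, samples, axis=0)


# ---------------------------------------------------------------------------
# Cardan angles
# ---------------------------------------------------------------------------

def cardan_angles(
    matrices: np.ndarray,
    sequence: str = "XYZ",
    gimbal_tol_deg: float = 0.5,
    atol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a sequence of rotation matrices into Cardan angles (degrees).

    Parameters
    ----------
    matrices : (n, 3, 3) or (3, 3) array of proper rotation matrices.
    sequence : intrinsic Cardan sequence; the default "XYZ" is the
        X-Y'-Z'' (flexion, abduction, rotation) convention.
    gimbal_tol_deg : the middle angle being within this tolerance of +-90
        degrees flags gimbal proximity.

    Returns
    -------
    angles : (n, 3) array of (alpha, beta, gamma) in degrees.
    gimbal : (n,) boolean mask of samples near gimbal lock.
    """
    R = np.asarray(matrices, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    if R.ndim != 3 or R.shape[1:] != (3, 3):
        raise SchemaError(f"expected (n, 3, 3) rotation matrices, got shape {R.shape}")
    eye = np.eye(3)
    for i, m in enumerate(R):
        if not np.allclose(m @ m.T, eye, atol=max(atol, 1e-6)):
            raise SchemaError(f"matrix {i} is not orthonormal within {atol}")
        if not np.isclose(np.linalg.det(m), 1.0, atol=max(atol, 1e-6)):
            raise SchemaError(f"matrix {i} has determinant != +1 (improper rotation)")
    angles = Rotation.from_matrix(R).as_euler(sequence, degrees=True)
    gimbal = np.abs(np.abs(angles[:, 1]) - 90.0) < gimbal_tol_deg
    if np.any(gimbal):
        logger.warning("gimbal proximity flagged for %d of %d samples", int(gimbal.sum()), len(R))
    if single:
        return angles[0], gimbal[0]
    return angles, gimbal


def compose_cardan(angles_deg: Sequence[float], sequence: str = "XYZ") -> np.ndarray:
    """Recompose a rotation matrix from Cardan angles (inverse of decomposition)."""
    return Rotation.from_euler(sequence, np.asarray(angles_deg, float), degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# Kick segmentation
# ---------------------------------------------------------------------------

def segment_kick(
    foot_forward_position: np.ndarray,
    knee_extension_angle: np.ndarray,
    sampling_rate: float,
    v_min: float = 0.05,
) -> tuple[int, int]:
    """Locate the analyzed kick phase.

    Start: first sample where the forward (x-axis) velocity of the kicking
    foot, from central differences of the (already filtered) position,
    exceeds ``v_min``.  End: maximum knee extension angle at or after the
    start.  Returns (start_index, end_index), start < end.
    """
    pos = np.asarray(foot_forward_position, dtype=float)
    knee = np.asarray(knee_extension_angle, dtype=float)
    if pos.shape != knee.shape or pos.ndim != 1:
        raise SchemaError(
            f"position and knee-angle waveforms must be 1-D and equal length, "
            f"got {pos.shape} vs {knee.shape}"
        )
    if len(pos) < 3:
        raise SchemaError("need at least 3 samples to segment a kick")
    velocity = np.gradient(pos) * sampling_rate
    above = np.nonzero(velocity > v_min)[0]
    if len(above) == 0:
        raise SegmentationError(
            f"no forward motion above v_min={v_min} (max velocity {velocity.max():.4g})"
        )
    start = int(above[0])
    end = start + int(np.argmax(knee[start:]))
    if end <= start:
        raise SegmentationError(
            f"knee extension maximum at segment start (index {start}); "
            "no kick phase after motion onset"
        )
    return start, end


# ---------------------------------------------------------------------------
# Time normalization
# ---------------------------------------------------------------------------

def time_normalize(
    samples: np.ndarray, n_points: int = DEFAULT_GRID_POINTS, method: str = "linear"
) -> np.ndarray:
    """Resample a waveform onto ``n_points`` equally spaced percent-time points.

    Works on a 1-D waveform or an (n_samples, n_channels) array (axis 0 is
    time).  The first and last input samples are preserved exactly.
    """
    x = np.asarray(samples, dtype=float)
    if n_points < 2:
        raise ParameterError(f"n_points must be >= 2, got {n_points}")
    if x.shape[0] < 2:
        raise SchemaError(f"waveform must have >= 2 samples, got {x.shape[0]}")
    t_in = np.linspace(0.0, 1.0, x.shape[0])
    t_out = np.linspace(0.0, 1.0, n_points)
    if method == "linear":
        if x.ndim == 1:
            out = np.interp(t_out, t_in, x)
        else:
            out = np.empty((n_points,) + x.shape[1:], dtype=float)
            for j in range(x.shape[1]):
                out[:, j] = np.interp(t_out, t_in, x[:, j])
    elif method == "cubic":
        out = CubicSpline(t_in, x, axis=0)(t_out)
    else:
        raise ParameterError(f"unknown interpolation method {method!r}")
    # endpoint exactness regardless of interpolation arithmetic
    out[0] = x[0]
    out[-1] = x[-1]
    return out


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ("subject", "leg", "intensity", "set", "block", "kick")


@dataclass
class FeatureMatrix:
    """n_kicks x (n_variables * n_gridpoints) feature matrix with labels.

    ``labels`` carries one row per kick with columns
    (subject, leg, intensity, set, block, kick); ``state`` tracks the
    normalization applied to ``values`` and ``stats`` holds the fitted
    normalizer when state != "raw".
    """

    values: np.ndarray
    labels: pd.DataFrame
    n_grid: int = DEFAULT_GRID_POINTS
    state: str = "raw"  # {"raw", "z", "z+minmax"}
    stats: "NormalizerStats | None" = None
    registry_version: int = REGISTRY_VERSION

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise SchemaError("feature values must be 2-D")
        if len(self.labels) != self.values.shape[0]:
            raise SchemaError("labels and values row counts differ")
        if self.values.shape[1] != N_VARIABLES * self.n_grid:
            raise SchemaError(
                f"expected {N_VARIABLES * self.n_grid} feature columns, got {self.values.shape[1]}"
            )
        if (self.stats is None) != (self.state == "raw"):
            raise SchemaError("fitted statistics must be present iff state != raw")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]

    def column_names(self) -> list[str]:
        return [f"{name}_t{t:03d}" for name in VARIABLE_NAMES for t in range(self.n_grid)]


def assemble_features(kicks: Iterable, n_grid: int = DEFAULT_GRID_POINTS) -> FeatureMatrix:
    """Stack time-normalized kicks into a raw FeatureMatrix.

    Each kick must expose ``waveforms`` as an (n_grid, 27) array in registry
    column order plus the label attributes (subject, leg, intensity,
    set_index, block, kick).  Rows follow input order; columns are
    variable-major (variable v occupies columns v*n_grid .. (v+1)*n_grid-1).
    """
    rows: list[np.ndarray] = []
    labels: list[tuple] = []
    for k in kicks:
        w = np.asarray(k.waveforms, dtype=float)
        ident = f"subject={k.subject} leg={k.leg} intensity={k.intensity} set={k.set_index} block={k.block} kick={k.kick}"
        if w.ndim != 2 or w.shape[1] != N_VARIABLES:
            raise SchemaError(
                f"kick [{ident}] has {w.shape[1] if w.ndim == 2 else '?'} variables, expected {N_VARIABLES}"
            )
        if w.shape[0] != n_grid:
            raise SchemaError(
                f"kick [{ident}] has {w.shape[0]} grid points, expected {n_grid}; time-normalize first"
            )
        if not np.all(np.isfinite(w)):
            raise SchemaError(f"kick [{ident}] contains non-finite samples")
        rows.append(w.T.reshape(-1))  # variable-major
        labels.append((k.subject, k.leg, k.intensity, k.set_index, k.block, k.kick))
    if not rows:
        raise SchemaError("no kicks to assemble")
    values = np.vstack(rows)
    label_df = pd.DataFrame(labels, columns=list(LABEL_COLUMNS))
    logger.info("assembled feature matrix %d x %d", values.shape[0], values.shape[1])
    return FeatureMatrix(values=values, labels=label_df, n_grid=n_grid)


def disassemble_features(fm: FeatureMatrix) -> np.ndarray:
    """Inverse of assembly: (n_kicks, n_grid, 27) waveform stack."""
    n = len(fm)
    return fm.values.reshape(n, N_VARIABLES, fm.n_grid).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# Column normalization: z-score then (-1, 1) min-max
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizerStats:
    mean: np.ndarray
    sd: np.ndarray          # population SD; zero-variance columns replaced by 1
    z_min: np.ndarray       # per-column min/max of the z-scored training data
    z_max: np.ndarray
    constant: np.ndarray    # mask of zero-variance training columns


def fit_normalizer(train_values: np.ndarray) -> NormalizerStats:
    """Fit the per-column z-score + (-1, 1) min-max transform on training rows."""
    x = np.asarray(train_values, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise SchemaError("training matrix must be non-empty and 2-D")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population (ddof=0)
    constant = sd == 0.0
    if np.any(constant):
        logger.warning(
            "%d zero-variance feature columns; SD replaced by 1 (constant features carry no information)",
            int(constant.sum()),
        )
    sd = np.where(constant, 1.0, sd)
    z = (x - mean) / sd
    return NormalizerStats(mean=mean, sd=sd, z_min=z.min(axis=0), z_max=z.max(axis=0), constant=constant)


def apply_normalizer(values: np.ndarray, stats: NormalizerStats) -> np.ndarray:
    """Apply fitted z + min-max stats; training extremes map exactly to +-1."""
    z = (np.asarray(values, dtype=float) - stats.mean) / stats.sd
    span = stats.z_max - stats.z_min
    safe_span = np.where(span == 0.0, 1.0, span)
    out = 2.0 * (z - stats.z_min) / safe_span - 1.0
    return np.where(span == 0.0, 0.0, out)


def invert_normalizer(normalized: np.ndarray, stats: NormalizerStats) -> np.ndarray:
    """Invert the transform back to raw units (constant columns restore the mean)."""
    span = stats.z_max - stats.z_min
    z = (np.asarray(normalized, dtype=float) + 1.0) / 2.0 * np.where(span == 0.0, 0.0, span) + stats.z_min
    z = np.where(span == 0.0, 0.0, z)
    return z * stats.sd + stats.mean


def normalize_features(fm: FeatureMatrix, stats: NormalizerStats | None = None) -> FeatureMatrix:
    """Return a z+minmax FeatureMatrix; fits stats on ``fm`` itself if not given."""
    if fm.state != "raw":
        raise SchemaError(f"expected a raw FeatureMatrix, got state {fm.state!r}")
    if stats is None:
        stats = fit_normalizer(fm.values)
    return FeatureMatrix(
        values=apply_normalizer(fm.values, stats),
        labels=fm.labels,
        n_grid=fm.n_grid,
        state="z+minmax",
        stats=stats,
    )


# ---------------------------------------------------------------------------
# Whole-chain convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    """Processing-chain parameters: filter, grid, interpolation, scope."""

    filter_order: int = 6
    filter_cutoff_hz: float = 15.0
    filter_convention: str = "effective"
    n_grid: int = DEFAULT_GRID_POINTS
    interpolation: str = "linear"
    normalize_scope: str = "fold"  # {"fold", "global"}

    def __post_init__(self) -> None:
        if self.normalize_scope not in ("fold", "global"):
            raise ParameterError(f"normalize_scope must be 'fold' or 'global', got {self.normalize_scope!r}")

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.filter_order, self.filter_cutoff_hz, self.filter_convention)


def preprocess_dataset(dataset, config: PreprocessConfig = PreprocessConfig()) -> FeatureMatrix:
    """Filter and time-normalize every kick of a KickDataset, then assemble.

    Returns a *raw* FeatureMatrix (classification normalizes per training
    fold; variability statistics use the unscaled time-normalized angles).
    """
    spec = config.filter_spec()
    processed = []
    for rec in dataset.records:
        filtered = lowpass_zero_phase(rec.waveforms, rec.sampling_rate, spec)
        norm = time_normalize(filtered, config.n_grid, config.interpolation)
        processed.append(rec.with_waveforms(norm))
    logger.info("preprocessed %d kicks (filter %dth-order %g Hz, %d grid points)",
                len(processed), config.filter_order, config.filter_cutoff_hz, config.n_grid)
    return assemble_features(processed, n_grid=config.n_grid)
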