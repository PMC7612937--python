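"""Waveform containers, file I/O, beat segmentation and fiducial detection.

The analysis operates on one cardiac cycle of co-sampled central (aortic)
pressure and aortic flow velocity.  This module defines the containers for
those signals (:class:`SampledWaveform`, :class:`BeatRecord`), reads and
writes the delimited-text waveform format, segments continuous recordings
into beats at the pressure foot, locates the fiducial landmarks the
decomposition needs (pressure foot, peak flow, valve closure), and
ensemble-averages beats.

Conventions
-----------
* pressure in mmHg, velocity in m/s, time in s;
* a beat starts at its pressure foot, with time re-zeroed there and
  0-based sample indexing;
* diastolic blood pressure (DBP) of a beat is the pressure at its foot.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    EmptySetError,
    FlatFlowError,
    FormatError,
    NoValveClosureError,
    SamplingError,
)

__all__ = [
    "SampledWaveform",
    "Fiducials",
    "BeatRecord",
    "load_subject_config",
    "read_waveform_file",
    "write_waveform_file",
    "segment_beats",
    "make_beat",
    "detect_fiducials",
    "ensemble_average",
]

#: relative tolerance on grid uniformity
_GRID_RTOL = 1e-9
#: default fraction of peak flow used for the valve-closure down-crossing
VC_FRACTION = 0.02
#: default dicrotic-notch fallback search window after the pressure peak (s)
NOTCH_WINDOW = (0.15, 0.45)
#: default velocity noise floor (m/s)
NOISE_FLOOR = 1e-6


@dataclass(frozen=True)
class SampledWaveform:
    """A uniformly sampled signal.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, uniform and strictly increasing.
    v : ndarray
        Sample values; the unit is carried in ``unit``.
    unit : str
        One of ``"mmHg"``, ``"m/s"``, ``"mL/s"`` (informational).
    """

    t: np.ndarray
    v: np.ndarray
    unit: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise SamplingError("t and v must be 1-D arrays of equal length")
        if t.size < 16:
            raise SamplingError(f"waveform too short: {t.size} samples (< 16)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise SamplingError("waveform contains non-finite samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise SamplingError("time grid is not strictly increasing")
        dt = steps.mean()
        if np.max(np.abs(steps - dt)) > _GRID_RTOL * max(abs(t[-1] - t[0]), dt):
            raise SamplingError("time grid is non-uniform beyond tolerance")

    @property
    def dt(self) -> float:
        return float((self.t[-1] - self.t[0]) / (self.t.size - 1))

    @property
    def n(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class Fiducials:
    """Landmark sample indices of one beat.

    ``i_foot`` is the pressure onset (always 0 for a segmented beat),
    ``i_qpeak`` the peak-flow sample, ``i_vc`` valve closure (end systole)
    and ``i_end`` the last sample of the beat.
    """

    i_foot: int
    i_qpeak: int
    i_vc: int
    i_end: int

    def __post_init__(self):
        if not (self.i_foot == 0 <= self.i_qpeak < self.i_vc < self.i_end):
            raise ValueError(
                "fiducials must satisfy i_foot = 0 <= i_qpeak < i_vc < i_end; "
                f"got {self}"
            )

    @property
    def systole(self) -> slice:
        """Samples from pressure onset up to and including valve closure."""
        return slice(self.i_foot, self.i_vc + 1)


@dataclass(frozen=True)
class BeatRecord:
    """One cardiac cycle of co-sampled pressure and flow velocity.

    Attributes
    ----------
    pressure : SampledWaveform
        Central pressure in mmHg, starting at the pressure foot.
    velocity : SampledWaveform
        Aortic flow velocity in m/s on the same grid.
    fiducials : Fiducials
    rho : float
        Blood density, kg/m³.
    area : float
        Aortic luminal cross-sectional area, m².
    dbp : float
        Diastolic pressure, mmHg; equals ``pressure.v[0]``.
    """

    pressure: SampledWaveform
    velocity: SampledWaveform
    fiducials: Fiducials
    rho: float
    area: float
    dbp: float

    def __post_init__(self):
        if self.rho <= 0:
            raise ConfigError(f"blood density must be positive, got {self.rho}")
        if self.area <= 0:
            raise ConfigError(f"aortic area must be positive, got {self.area}")
        if self.pressure.n != self.velocity.n:
            raise SamplingError("pressure and velocity are not co-sampled")
        if abs(self.pressure.dt - self.velocity.dt) > _GRID_RTOL:
            raise SamplingError("pressure and velocity grids differ")
        if self.fiducials.i_end != self.pressure.n - 1:
            raise ValueError("fiducials.i_end does not match beat length")
        if abs(self.dbp - self.pressure.v[0]) > 1e-9 * max(1.0, abs(self.dbp)):
            raise ValueError("dbp must equal the pressure at the beat foot")

    # convenience views -------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.pressure.t

    @property
    def p(self) -> np.ndarray:
        return self.pressure.v

    @property
    def u(self) -> np.ndarray:
        return self.velocity.v

    @property
    def q(self) -> np.ndarray:
        """Volumetric flow in m³/s (U·A)."""
        return self.velocity.v * self.area

    @property
    def dt(self) -> float:
        return self.pressure.dt

    @property
    def pp(self) -> float:
        """Pulse pressure SBP − DBP in mmHg."""
        return float(self.p.max() - self.dbp)


# ---------------------------------------------------------------------------
# subject configuration


_CONFIG_DEFAULTS = {
    "rho_kg_m3": 1060.0,
    "vc_fraction": VC_FRACTION,
    "notch_window_s": list(NOTCH_WINDOW),
    "noise_floor_ms": NOISE_FLOOR,
}


def load_subject_config(source) -> dict:
    """Load subject constants from a YAML/key-value file, path or mapping.

    Required key: ``area_m2``.  ``rho_kg_m3`` defaults to 1060.  Optional
    fiducial-threshold overrides: ``vc_fraction``, ``notch_window_s``,
    ``noise_floor_ms``.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = dict(_CONFIG_DEFAULTS)
    cfg.update(raw)
    if "area_m2" not in cfg:
        raise ConfigError("subject config must provide area_m2")
    if cfg["area_m2"] <= 0:
        raise ConfigError(f"area_m2 must be positive, got {cfg['area_m2']}")
    if cfg["rho_kg_m3"] <= 0:
        raise ConfigError(f"rho_kg_m3 must be positive, got {cfg['rho_kg_m3']}")
    return cfg


# ---------------------------------------------------------------------------
# fiducial detection


def _detect_indices(p, u, dt, vc_fraction=VC_FRACTION, notch_window=NOTCH_WINDOW,
                    noise_floor=NOISE_FLOOR):
    """Locate peak flow and valve closure on raw arrays of one beat."""
    u_peak = float(np.max(u))
    if u_peak <= noise_floor:
        raise FlatFlowError(
            f"velocity never exceeds the noise floor ({noise_floor} m/s)"
        )
    i_qpeak = int(np.argmax(u))
    thr = vc_fraction * u_peak
    below = np.nonzero(u[i_qpeak + 1:] < thr)[0]
    if below.size:
        i_vc = i_qpeak + 1 + int(below[0])
    else:
        i_vc = _dicrotic_notch(p, dt, notch_window)
        if i_vc is None or i_vc <= i_qpeak:
            raise NoValveClosureError(
                "no flow down-crossing and no dicrotic notch before beat end"
            )
    if i_vc >= len(p) - 1:
        raise NoValveClosureError("valve closure found only at the beat end")
    return i_qpeak, i_vc


def _dicrotic_notch(p, dt, window):
    """First local pressure minimum within ``window`` seconds after the peak."""
    i_pk = int(np.argmax(p))
    lo = i_pk + int(round(window[0] / dt))
    hi = min(i_pk + int(round(window[1] / dt)), len(p) - 1)
    for i in range(max(lo, 1), hi):
        if p[i] <= p[i - 1] and p[i] < p[i + 1]:
            return i
    return None


def detect_fiducials(beat: BeatRecord, *, vc_fraction=VC_FRACTION,
                     notch_window=NOTCH_WINDOW,
                     noise_floor=NOISE_FLOOR) -> Fiducials:
    """(Re-)detect the fiducial landmarks of a beat.

    The foot is sample 0 of the segmented beat; peak flow is the global
    velocity maximum; valve closure is the first down-crossing of velocity
    through ``vc_fraction`` of its peak after peak flow, falling back to a
    dicrotic-notch search on the pressure wave.
    """
    i_qpeak, i_vc = _detect_indices(
        beat.p, beat.u, beat.dt, vc_fraction, notch_window, noise_floor
    )
    return Fiducials(0, i_qpeak, i_vc, beat.pressure.n - 1)


def make_beat(t, p, u, rho, area, *, vc_fraction=VC_FRACTION,
              notch_window=NOTCH_WINDOW, noise_floor=NOISE_FLOOR) -> BeatRecord:
    """Build a :class:`BeatRecord` from raw arrays, detecting fiducials.

    ``t`` is re-zeroed at the first sample (the pressure foot); ``dbp`` is
    the pressure there.
    """
    t = np.asarray(t, dtype=float)
    i_qpeak, i_vc = _detect_indices(
        np.asarray(p, float), np.asarray(u, float), float(t[1] - t[0]),
        vc_fraction, notch_window, noise_floor,
    )
    fid = Fiducials(0, i_qpeak, i_vc, len(t) - 1)
    return BeatRecord(
        pressure=SampledWaveform(t - t[0], p, "mmHg"),
        velocity=SampledWaveform(t - t[0], u, "m/s"),
        fiducials=fid,
        rho=float(rho),
        area=float(area),
        dbp=float(np.asarray(p, float)[0]),
    )


# ---------------------------------------------------------------------------
# segmentation


def segment_beats(t, p, u, beat_index=None):
    """Split a continuous recording into beats at the pressure feet.

    Returns a list of ``(t, p, u)`` array triples (views re-zeroed later by
    :func:`make_beat`).  When ``beat_index`` labels are supplied they define
    the partition directly; otherwise feet are detected as the pressure
    minima immediately preceding steep systolic upstrokes.

    The partition is lossless from the first detected foot onward:
    concatenating the returned beats reproduces those samples exactly.
    """
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    u = np.asarray(u, float)
    if beat_index is not None:
        beat_index = np.asarray(beat_index)
        bounds = np.nonzero(np.diff(beat_index) != 0)[0] + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(t)]))
        return [(t[a:b], p[a:b], u[a:b]) for a, b in zip(starts, ends)]

    dt = float(t[1] - t[0])
    dp = np.diff(p)
    thr = 0.3 * dp.max()
    cand = np.nonzero(dp > thr)[0]
    if cand.size == 0:
        raise FlatFlowError("no systolic upstroke found in the recording")
    # first index of each distinct upstroke: candidates separated from the
    # previous candidate by more than a 250 ms refractory gap start a new one
    gap = int(round(0.25 / dt))
    starts = np.nonzero(np.diff(cand) > gap)[0] + 1
    keep = [int(cand[i]) for i in np.concatenate(([0], starts))]
    feet = []
    back = int(round(0.2 / dt))
    for i in keep:
        lo = max(0, i - back)
        feet.append(lo + int(np.argmin(p[lo:i + 1])))
    feet = sorted(set(feet))
    bounds = feet + [len(t)]
    return [
        (t[a:b], p[a:b], u[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= 16
    ]


# ---------------------------------------------------------------------------
# file I/O

_TIME_COL = "time_s"
_PRESSURE_COL = "pressure_mmhg"
_VELOCITY_COL = "velocity_ms"
_FLOW_COL = "flow_mls"
_BEAT_COL = "beat_index"


def read_waveform_file(path, config) -> list[BeatRecord]:
    """Read a delimited-text waveform file into segmented beats.

    The file must have a header row naming ``time_s``, ``pressure_mmhg``
    and one of ``velocity_ms`` or ``flow_mls`` (comma- or tab-delimited;
    ``#`` lines are comments).  Volumetric flow is converted to velocity
    with U = Q/A using ``area_m2`` from the subject config.
    """
    cfg = load_subject_config(config)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse waveform file {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in (_TIME_COL, _PRESSURE_COL):
        if col not in df.columns:
            raise FormatError(f"waveform file is missing column '{col}'")
    if _VELOCITY_COL in df.columns:
        u = df[_VELOCITY_COL].to_numpy(float)
    elif _FLOW_COL in df.columns:
        # mL/s -> m³/s -> m/s
        u = df[_FLOW_COL].to_numpy(float) * 1e-6 / cfg["area_m2"]
    else:
        raise FormatError(
            f"waveform file is missing column '{_VELOCITY_COL}' or '{_FLOW_COL}'"
        )
    t = df[_TIME_COL].to_numpy(float)
    p = df[_PRESSURE_COL].to_numpy(float)
    # validate grid uniformity up front for a clear error
    SampledWaveform(t, p, "mmHg")
    beat_index = df[_BEAT_COL].to_numpy() if _BEAT_COL in df.columns else None
    beats = []
    for tb, pb, ub in segment_beats(t, p, u, beat_index):
        beats.append(
            make_beat(
                tb, pb, ub, cfg["rho_kg_m3"], cfg["area_m2"],
                vc_fraction=cfg["vc_fraction"],
                notch_window=tuple(cfg["notch_window_s"]),
                noise_floor=cfg["noise_floor_ms"],
            )
        )
    if not beats:
        raise EmptySetError("no complete beats found in waveform file")
    return beats


def write_waveform_file(path, t, p, flow, *, kind="velocity", beat_index=None,
                        header_lines=()):
    """Write a waveform file in the format :func:`read_waveform_file` reads.

    ``kind`` selects the third column: ``"velocity"`` (m/s) or ``"flow"``
    (mL/s).  ``header_lines`` are written as ``#`` comments.
    """
    if kind == "velocity":
        col = _VELOCITY_COL
    elif kind == "flow":
        col = _FLOW_COL
    else:
        raise ConfigError(f"unknown flow column kind '{kind}'")
    data = {_TIME_COL: t, _PRESSURE_COL: p, col: flow}
    if beat_index is not None:
        data[_BEAT_COL] = beat_index
    df = pd.DataFrame(data)
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# ensemble averaging


def ensemble_average(beats) -> BeatRecord:
    """Duration-normalised ensemble average of a sequence of beats.

    Each beat is mapped to relative time in [0, 1], resampled to the median
    beat length, and averaged pointwise; fiducials are re-detected on the
    averaged beat.  Averaging is permutation-invariant.
    """
    beats = list(beats)
    if not beats:
        raise EmptySetError("ensemble_average needs at least one beat")
    if len(beats) == 1:
        return beats[0]
    n_out = int(np.median([b.pressure.n for b in beats]))
    dur = float(np.median([b.t[-1] for b in beats]))
    rel_out = np.linspace(0.0, 1.0, n_out)
    ps = []
    us = []
    for b in beats:
        rel = b.t / b.t[-1]
        ps.append(np.interp(rel_out, rel, b.p))
        us.append(np.interp(rel_out, rel, b.u))
    p_avg = np.mean(ps, axis=0)
    u_avg = np.mean(us, axis=0)
    t_out = rel_out * dur
    return make_beat(t_out, p_avg, u_avg, beats[0].rho, beats[0].area)
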