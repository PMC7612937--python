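"""Time-varying emission coefficient γ at the aortic root.

γ(t) = P_f(t)/P_b(t) is the ratio of forward to backward pressure at the
aortic root.  It combines a reflection coefficient close to unity (the
closed or nearly closed valve re-reflecting incoming waves) with an
ejection term proportional to aortic flow: using P_f,b = ±Z_c·Q_f,b,

    γ = 1 + Z_c·Q/P_b,

and since P_b ≈ DBP/2 in early systole,

    γ ≈ 1 + 2·Z_c·Q/DBP,        γ_peak ≈ 1 + 2·Z_c·Q_peak/DBP.

The module computes γ, its flow-based approximations and the RMSE metrics
comparing γ with the flow wave and the approximation with the exact γ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError
from .units import mmhg_to_pa
from .waveform import Fiducials
from .wsa import WSAResult

__all__ = [
    "GammaTrace",
    "GammaFlowComparison",
    "emission_coefficient",
    "gamma_approximation",
    "gamma_peak_approximation",
    "compare_gamma_flow",
    "compare_gamma_measured_vs_approx",
]

#: guard on the backward pressure (mmHg) below which γ is not evaluated
PB_GUARD_MMHG = 1.0


@dataclass(frozen=True)
class GammaTrace:
    """Emission coefficient over one beat.

    ``gamma`` is P_f/P_b on samples where P_b exceeds the 1 mmHg guard
    (``valid``); elsewhere it is NaN, never extrapolated.  ``gamma_approx``
    is the flow-based approximation 1 + 2·Z_c·Q/DBP on the full grid.
    """

    gamma: np.ndarray
    gamma_approx: np.ndarray
    gamma_peak: float
    i_gamma_peak: int
    valid: np.ndarray


def emission_coefficient(wsa: WSAResult, q=None) -> GammaTrace:
    """γ(t) = P_f/P_b from a traditional wave separation.

    ``q`` (volumetric flow, m³/s) is optional; when given the flow-based
    approximation 1 + 2·Z_c·Q/DBP is filled in, otherwise it is NaN.
    """
    pb = np.asarray(wsa.pb, float)
    pf = np.asarray(wsa.pf, float)
    valid = pb > PB_GUARD_MMHG
    if not np.any(valid):
        raise DegenerateSignalError(
            "backward pressure never exceeds the 1 mmHg guard"
        )
    gamma = np.full(pb.shape, np.nan)
    gamma[valid] = pf[valid] / pb[valid]
    i_peak = int(np.nanargmax(gamma))
    if q is not None:
        approx = gamma_approximation(q, wsa.zc_flow, wsa.dbp)
    else:
        approx = np.full(pb.shape, np.nan)
    return GammaTrace(
        gamma=gamma, gamma_approx=approx,
        gamma_peak=float(gamma[i_peak]), i_gamma_peak=i_peak, valid=valid,
    )


def gamma_approximation(q, zc_flow, dbp_mmhg):
    """Flow-based approximation γ ≈ 1 + 2·Z_c·Q/DBP (all in Pa internally)."""
    if dbp_mmhg <= 0:
        raise DegenerateSignalError(f"DBP must be positive, got {dbp_mmhg}")
    return 1.0 + 2.0 * zc_flow * np.asarray(q, float) / mmhg_to_pa(dbp_mmhg)


def gamma_peak_approximation(q_peak, zc_flow, dbp_mmhg) -> float:
    """Peak-emission approximation γ_peak ≈ 1 + 2·Z_c·Q_peak/DBP."""
    return float(gamma_approximation(q_peak, zc_flow, dbp_mmhg))


@dataclass(frozen=True)
class GammaFlowComparison:
    """Relative RMSEs (%) between normalised γ and flow, per window.

    Windows: early systole (foot → peak flow), late systole (peak flow →
    valve closure), whole cycle.  ``dt_peaks`` = t(γ_peak) − t(Q_peak) in
    seconds.
    """

    rmse_early: float
    rmse_late: float
    rmse_cycle: float
    dt_peaks: float


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def compare_gamma_flow(gamma: GammaTrace, q, fiducials: Fiducials,
                       dt: float) -> GammaFlowComparison:
    """Relative RMSE between peak-normalised γ and flow waves.

    γ is baseline-subtracted (its diastolic level is 1) before peak
    normalisation: γ̃ = (γ−1)/max(γ−1); the flow is normalised by its own
    peak, Q̃ = Q/max(Q).  RMSEs are 100·RMS(γ̃ − Q̃) over each window;
    invalid (guarded) γ samples are excluded.
    """
    q = np.asarray(q, float)
    g = gamma.gamma
    g_excess = g - 1.0
    peak_excess = np.nanmax(g_excess)
    q_peak = np.max(q)
    if not peak_excess > 0:
        raise DegenerateSignalError("γ never exceeds 1: nothing to normalise")
    if not q_peak > 0:
        raise DegenerateSignalError("flow never positive: nothing to normalise")
    g_n = g_excess / peak_excess
    q_n = q / q_peak
    diff = g_n - q_n
    ok = gamma.valid

    def window_rmse(sl):
        d = diff[sl][ok[sl]]
        return _rms(d)

    early = slice(fiducials.i_foot, fiducials.i_qpeak + 1)
    late = slice(fiducials.i_qpeak + 1, fiducials.i_vc + 1)
    whole = slice(None)
    dt_peaks = (gamma.i_gamma_peak - int(np.argmax(q))) * dt
    return GammaFlowComparison(
        rmse_early=100.0 * window_rmse(early),
        rmse_late=100.0 * window_rmse(late),
        rmse_cycle=100.0 * window_rmse(whole),
        dt_peaks=float(dt_peaks),
    )


def compare_gamma_measured_vs_approx(gamma: GammaTrace,
                                     window: slice = slice(None)) -> float:
    """Whole-cycle relative RMSE (%) between measured and approximated γ.

    100·RMS(γ − γ_approx)/γ_peak over valid samples of ``window``.
    """
    if np.all(np.isnan(gamma.gamma_approx)):
        raise DegenerateSignalError("gamma_approx was not computed (no flow)")
    ok = gamma.valid[window]
    d = (gamma.gamma - gamma.gamma_approx)[window][ok]
    return 100.0 * _rms(d) / gamma.gamma_peak
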