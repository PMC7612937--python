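"""Traditional time-domain wave separation and related hemodynamic primitives.

Given co-sampled central pressure P(t) and flow velocity U(t), the
time-domain (Parker) separation accumulates first differences from the
pressure foot,

    P_f = ½ Σ (dP + ρc dU) + DBP/2,
    P_b = ½ Σ (dP − ρc dU) + DBP/2,

so that P_f + P_b = P at every sample and both components start at DBP/2
(the backward wave reflects against the closed aortic valve with unity
coefficient in late diastole).  The wave speed c comes from the
sum-of-squares estimator, and the water-hammer pressure ρcU expresses the
pressure generated by coupling ejected flow to the aortic characteristic
impedance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, ParameterError
from .units import mmhg_to_pa, pa_to_mmhg
from .waveform import BeatRecord

__all__ = [
    "WSAResult",
    "estimate_pwv_sum_of_squares",
    "separate_forward_backward",
    "water_hammer_pressure",
    "separate_beat",
]


@dataclass(frozen=True)
class WSAResult:
    """Forward/backward pressure components and the constants behind them.

    ``pf`` and ``pb`` are in mmHg and satisfy ``pf + pb == P`` pointwise;
    ``c`` is the wave speed (m/s); ``zc_velocity`` = ρc (Pa·s/m) and
    ``zc_flow`` = ρc/A (Pa·s/m³) are the two characteristic-impedance
    conventions (velocity- and flow-based).
    """

    pf: np.ndarray
    pb: np.ndarray
    c: float
    zc_velocity: float
    zc_flow: float
    dbp: float


def estimate_pwv_sum_of_squares(p_mmhg, u, rho) -> float:
    """Sum-of-squares single-site pulse wave velocity.

    c = (1/ρ)·sqrt(Σ dP² / Σ dU²) with first differences over the whole
    beat and pressure in Pa.  Exact when the beat is reflection-free
    (dP = ρc dU throughout).
    """
    p_pa = mmhg_to_pa(np.asarray(p_mmhg, float))
    u = np.asarray(u, float)
    if p_pa.size < 2:
        raise ParameterError("need at least 2 samples to estimate wave speed")
    dp = np.diff(p_pa)
    du = np.diff(u)
    du2 = float(np.sum(du * du))
    if du2 <= 0.0:
        raise DegenerateSignalError(
            "flat velocity trace: sum-of-squares wave speed is undefined"
        )
    return float(np.sqrt(np.sum(dp * dp) / du2) / rho)


def separate_forward_backward(p_mmhg, u, rho, c, dbp) -> WSAResult:
    """Time-domain separation of pressure into forward and backward waves.

    Traces must start at the pressure foot (``p_mmhg[0] == dbp``); running
    sums of ½(dP ± ρc dU) are anchored at DBP/2.  ``zc_flow`` is filled by
    :func:`separate_beat`; here it is ρc per unit area 1 (callers passing
    raw arrays usually only need ``pf``/``pb``).
    """
    if c <= 0:
        raise ParameterError(f"wave speed must be positive, got {c}")
    p = np.asarray(p_mmhg, float)
    u = np.asarray(u, float)
    rcdu_mmhg = pa_to_mmhg(rho * c * np.diff(u))
    dp = np.diff(p)
    half = dbp / 2.0
    pf = half + 0.5 * np.concatenate(([0.0], np.cumsum(dp + rcdu_mmhg)))
    pb = half + 0.5 * np.concatenate(([0.0], np.cumsum(dp - rcdu_mmhg)))
    return WSAResult(
        pf=pf, pb=pb, c=float(c),
        zc_velocity=float(rho * c), zc_flow=float(rho * c), dbp=float(dbp),
    )


def water_hammer_pressure(u, rho, c):
    """Water-hammer pressure ρcU in mmHg (cardiac-aortic coupling pressure)."""
    if c <= 0:
        raise ParameterError(f"wave speed must be positive, got {c}")
    return pa_to_mmhg(rho * c * np.asarray(u, float))


def separate_beat(beat: BeatRecord, c: float | None = None) -> WSAResult:
    """Run the traditional separation on a :class:`BeatRecord`.

    When ``c`` is not given it is estimated with the sum-of-squares method
    on the beat itself.
    """
    if c is None:
        c = estimate_pwv_sum_of_squares(beat.p, beat.u, beat.rho)
    res = separate_forward_backward(beat.p, beat.u, beat.rho, c, beat.dbp)
    return WSAResult(
        pf=res.pf, pb=res.pb, c=res.c,
        zc_velocity=beat.rho * c, zc_flow=beat.rho * c / beat.area,
        dbp=beat.dbp,
    )
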