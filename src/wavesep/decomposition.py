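"""Five-component separation of the central blood pressure wave.

The central pressure P(t) over one beat is split into five additive parts
with distinct biophysical and temporal origins:

* ``P_μ`` — constant microcirculation (asymptotic) pressure at which flow
  to the microcirculation ceases; the baseline of the decomposition.
* ``P_his(t)`` — history pressure: waves generated in previous cardiac
  cycles, obtained by prolonging the previous beat's diastolic decay into
  the current cycle.
* ``P_wh(t)`` — cardiac-aortic coupling (water-hammer) pressure ρcU.
* ``P_down(t)`` — backward-travelling reflections, from all impedance
  mismatch sites downstream of the aortic root, arising within the current
  cycle.
* ``P_Ao(t)`` — forward re-reflections of ``P_down`` at the aortic root;
  algebraically equal in magnitude to ``P_down`` when the foot velocity is
  zero (the two are nevertheless computed independently and checked).

P_μ and the decay rate B come from a monoexponential fit
``P_μ + (P_es − P_μ)·exp(−B t)`` to the diastolic limb, with P_es fixed to
the end-systolic pressure.  The within-cycle pressure
``P_cc = P − P_his − P_μ`` starts at exactly zero at the foot and is
separated into forward (``P_cc,f``) and backward (``P_down``) parts by the
time-domain method applied to (P_cc, U); finally ``P_Ao = P_cc,f − P_wh``.

Component contributions are book-kept as percentage areas under the
(absolute) pressure curve during systole, and beats can be grouped into
10-mmHg pulse-pressure spans for cohort-style summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import EmptySetError, FitError
from .waveform import BeatRecord, ensemble_average
from .wsa import estimate_pwv_sum_of_squares, water_hammer_pressure
from .units import pa_to_mmhg

__all__ = [
    "DiastolicFit",
    "FiveComponentDecomposition",
    "ContributionSummary",
    "fit_diastolic_decay",
    "history_pressure",
    "within_cycle_pressure",
    "split_within_cycle",
    "aortic_rereflections",
    "decompose",
    "systolic_area_contributions",
    "bin_by_pulse_pressure",
    "COMPONENT_NAMES",
]

COMPONENT_NAMES = ("p_mu", "p_his", "p_wh", "p_down", "p_ao")

#: skip the first 10 ms after valve closure (notch oscillations)
_FIT_DELAY_S = 0.010
#: minimum diastolic samples for a meaningful fit
_MIN_FIT_SAMPLES = 10
#: diastolic range (mmHg) below which the decay is considered absent
_FLAT_DIASTOLE_MMHG = 0.05


@dataclass(frozen=True)
class DiastolicFit:
    """Monoexponential diastolic decay P_μ + (P_es − P_μ)·exp(−B t).

    ``t`` is re-zeroed at valve closure.  ``p_mu`` (mmHg), the decay rate
    ``b`` (1/s) and the decay amplitude (giving the fitted end-systolic
    level ``p_mu + amplitude``) are estimated by least squares; ``p_es``
    records the measured pressure at valve closure.  Freeing the
    amplitude instead of pinning the curve to the single valve-closure
    sample keeps the fit exact for clean decays while preventing that
    sample's noise from being amplified into the asymptote.  ``clipped``
    flags a solution on the (0, DBP) constraint boundary for ``p_mu``.
    """

    p_mu: float
    b: float
    p_es: float
    amplitude: float
    window: tuple[int, int]
    rms_residual: float
    clipped: bool = False

    def extrapolate(self, t):
        """Evaluate the fitted decay at times ``t`` (s, from valve closure)."""
        return self.p_mu + self.amplitude * np.exp(-self.b * np.asarray(t))


@dataclass(frozen=True)
class FiveComponentDecomposition:
    """The five pressure components of one beat (all mmHg).

    ``p_mu`` is a scalar; the four traces share the beat grid.  The parts
    satisfy ``p_mu + p_his + p_wh + p_down + p_ao == P`` pointwise and the
    intermediate within-cycle pressure ``p_cc`` starts at exactly zero.
    """

    p_mu: float
    p_his: np.ndarray
    p_wh: np.ndarray
    p_down: np.ndarray
    p_ao: np.ndarray
    p_cc: np.ndarray
    p_cc_f: np.ndarray
    fit: DiastolicFit
    c: float
    beat: BeatRecord

    def reconstruction(self):
        return self.p_mu + self.p_his + self.p_wh + self.p_down + self.p_ao

    def as_frame(self):
        """Component-per-column table (pandas) for export."""
        import pandas as pd

        b = self.beat
        return pd.DataFrame(
            {
                "time_s": b.t,
                "pressure_mmhg": b.p,
                "p_mu_mmhg": np.full(b.p.size, self.p_mu),
                "p_his_mmhg": self.p_his,
                "p_wh_mmhg": self.p_wh,
                "p_down_mmhg": self.p_down,
                "p_ao_mmhg": self.p_ao,
            }
        )


@dataclass(frozen=True)
class ContributionSummary:
    """Percentage of the systolic pressure-curve area per component.

    Percentages are of the total area under the pressure wave from the
    foot to valve closure and sum to 100.  ``pp`` is the pulse pressure,
    ``pp_bin`` the 10-mmHg span label, ``gamma_peak`` the peak emission
    coefficient of the beat (filled by the pipeline; NaN if not computed).
    """

    pct: dict
    pp: float
    pp_bin: str
    gamma_peak: float = float("nan")


# ---------------------------------------------------------------------------
# diastolic fit


def fit_diastolic_decay(beat: BeatRecord) -> DiastolicFit:
    """Fit P_μ + (P_es − P_μ)·exp(−B t) to the diastolic limb of a beat.

    The window runs from 10 ms after valve closure to the beat end with
    time re-zeroed at valve closure; parameters are P_μ ∈ (0, DBP), the
    decay rate B > 0 and the decay amplitude P_es − P_μ ≥ 0.
    """
    fid = beat.fiducials
    i_vc = fid.i_vc
    i_start = i_vc + max(1, int(round(_FIT_DELAY_S / beat.dt)))
    i_end = fid.i_end
    if i_end - i_start + 1 < _MIN_FIT_SAMPLES:
        raise FitError(
            f"only {max(0, i_end - i_start + 1)} diastolic samples "
            f"(need >= {_MIN_FIT_SAMPLES})"
        )
    p_es = float(beat.p[i_vc])
    t_fit = beat.t[i_start:i_end + 1] - beat.t[i_vc]
    p_fit = beat.p[i_start:i_end + 1]
    if p_fit.max() - p_fit.min() < _FLAT_DIASTOLE_MMHG:
        raise FitError(
            "diastolic pressure is flat: no exponential decay to fit",
            diagnostics={"range_mmhg": float(p_fit.max() - p_fit.min())},
        )

    def residuals(theta):
        p_mu, amp, b = theta
        return p_mu + amp * np.exp(-b * t_fit) - p_fit

    # crude initial guess: asymptote below the last diastolic value
    p_mu0 = min(max(0.5 * p_fit[-1], 1e-3), 0.95 * beat.dbp)
    amp0 = max(p_es - p_mu0, 1.0)
    b0 = 1.0
    eps = 1e-9
    sol = least_squares(
        residuals,
        x0=[p_mu0, amp0, b0],
        bounds=([eps, 0.0, eps], [beat.dbp - eps, np.inf, np.inf]),
        method="trf",
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitError(
            "diastolic fit did not converge",
            diagnostics={"residual_mmhg": float(np.sqrt(np.mean(sol.fun ** 2)))},
        )
    p_mu, amp, b = sol.x
    clipped = bool(p_mu <= 2 * eps or p_mu >= beat.dbp - 2 * eps)
    if b <= 2 * eps or amp <= 0.0:
        raise FitError(
            "decay rate collapsed to zero (no exponential decay present)",
            diagnostics={"b": float(b), "amplitude": float(amp)},
        )
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return DiastolicFit(
        p_mu=float(p_mu), b=float(b), p_es=p_es, amplitude=float(amp),
        window=(int(i_start), int(i_end)), rms_residual=rms, clipped=clipped,
    )


def history_pressure(fit: DiastolicFit, beat: BeatRecord) -> np.ndarray:
    """History pressure P_his(t) = (DBP − P_μ)·exp(−B t) from the beat foot.

    Prolongs the previous cycle's diastolic decay into the current beat; at
    the foot P_μ + P_his equals DBP exactly, so the pre-ejection pressure
    is entirely microcirculation + history.  When the fit comes from the
    same beat this assumes periodic steady state.
    """
    return (beat.dbp - fit.p_mu) * np.exp(-fit.b * beat.t)


# ---------------------------------------------------------------------------
# within-cycle separation


def within_cycle_pressure(p, p_his, p_mu):
    """Within-cycle pressure P_cc = P − P_his − P_μ (zero at the foot)."""
    return np.asarray(p, float) - np.asarray(p_his, float) - p_mu


def split_within_cycle(p_cc, u, rho, c):
    """Separate P_cc into downstream reflections and its forward part.

    P_down = ½ Σ (dP_cc − ρc dU)  (backward; all downstream reflections)
    P_cc,f = ½ Σ (dP_cc + ρc dU)  (forward; water hammer + re-reflections)

    Both start at 0 and sum to P_cc exactly.
    """
    p_cc = np.asarray(p_cc, float)
    u = np.asarray(u, float)
    dp = np.diff(p_cc)
    rcdu = pa_to_mmhg(rho * c * np.diff(u))
    p_down = 0.5 * np.concatenate(([0.0], np.cumsum(dp - rcdu)))
    p_cc_f = 0.5 * np.concatenate(([0.0], np.cumsum(dp + rcdu)))
    return p_down, p_cc_f


def aortic_rereflections(p_cc_f, p_wh):
    """Aortic re-reflection pressure P_Ao = P_cc,f − P_wh."""
    return np.asarray(p_cc_f, float) - np.asarray(p_wh, float)


# ---------------------------------------------------------------------------
# orchestration


def decompose(beat: BeatRecord, *, fit: DiastolicFit | None = None,
              c: float | None = None) -> FiveComponentDecomposition:
    """Run the full five-component separation on one beat.

    ``fit`` may be supplied from the preceding beat of a recording; by
    default the beat's own diastolic fit is used (periodicity assumption).
    ``c`` defaults to the sum-of-squares estimate on this beat.
    """
    if fit is None:
        fit = fit_diastolic_decay(beat)
    if c is None:
        c = estimate_pwv_sum_of_squares(beat.p, beat.u, beat.rho)
    p_his = history_pressure(fit, beat)
    p_cc = within_cycle_pressure(beat.p, p_his, fit.p_mu)
    p_down, p_cc_f = split_within_cycle(p_cc, beat.u, beat.rho, c)
    p_wh = water_hammer_pressure(beat.u, beat.rho, c)
    p_ao = aortic_rereflections(p_cc_f, p_wh)
    decomp = FiveComponentDecomposition(
        p_mu=fit.p_mu, p_his=p_his, p_wh=p_wh, p_down=p_down, p_ao=p_ao,
        p_cc=p_cc, p_cc_f=p_cc_f, fit=fit, c=float(c), beat=beat,
    )
    resid = np.max(np.abs(decomp.reconstruction() - beat.p))
    rng = max(np.ptp(beat.p), 1e-12)
    if resid > 1e-6 * rng:
        raise FitError(
            f"five-component reconstruction residual {resid:.3g} mmHg "
            f"exceeds 1e-6 of the pressure range"
        )
    return decomp


# ---------------------------------------------------------------------------
# systolic-area bookkeeping and pulse-pressure binning


def _trapz(y, dt):
    return float(np.trapezoid(y, dx=dt))


def systolic_area_contributions(decomp: FiveComponentDecomposition,
                                gamma_peak: float = float("nan")
                                ) -> ContributionSummary:
    """Percentage area of each component under the systolic pressure curve.

    Areas are trapezoidal from the foot to valve closure; the constant
    P_μ contributes P_μ·T_sys (a rectangle).  Negative momentary values
    (possible for P_down early in systole) enter algebraically.  The five
    percentages sum to 100.
    """
    beat = decomp.beat
    sys_ = beat.fiducials.systole
    dt = beat.dt
    t_sys = beat.t[decomp.beat.fiducials.i_vc] - beat.t[0]
    total = _trapz(beat.p[sys_], dt)
    areas = {
        "p_mu": decomp.p_mu * t_sys,
        "p_his": _trapz(decomp.p_his[sys_], dt),
        "p_wh": _trapz(decomp.p_wh[sys_], dt),
        "p_down": _trapz(decomp.p_down[sys_], dt),
        "p_ao": _trapz(decomp.p_ao[sys_], dt),
    }
    pct = {k: 100.0 * v / total for k, v in areas.items()}
    pp = beat.pp
    return ContributionSummary(
        pct=pct, pp=pp, pp_bin=pp_bin_label(pp), gamma_peak=gamma_peak
    )


_BIN_EDGES = (30.0, 40.0, 50.0, 60.0, 70.0)


def pp_bin_label(pp: float, width: float = 10.0) -> str:
    """10-mmHg pulse-pressure span label: '<30', '30-40', ..., '>70'.

    Spans are left-closed/right-open; PP = 70 falls in the open top span.
    """
    lo, hi = 30.0, 70.0
    if pp < lo:
        return f"<{lo:.0f}"
    if pp >= hi:
        return f">{hi:.0f}"
    k = int((pp - lo) // width)
    a = lo + k * width
    return f"{a:.0f}-{a + width:.0f}"


def bin_by_pulse_pressure(beats, width: float = 10.0):
    """Group beats into 10-mmHg pulse-pressure spans.

    Returns an ordered dict mapping span label to a dict with the member
    beats, their ensemble average and its :class:`ContributionSummary`.
    Only non-empty spans are emitted.
    """
    beats = list(beats)
    if not beats:
        raise EmptySetError("bin_by_pulse_pressure needs at least one beat")
    order = ["<30"] + [f"{a:.0f}-{a + width:.0f}" for a in _BIN_EDGES[:-1]] + [">70"]
    groups: dict[str, list] = {}
    for b in beats:
        groups.setdefault(pp_bin_label(b.pp, width), []).append(b)
    out = {}
    for label in order:
        if label not in groups:
            continue
        avg = ensemble_average(groups[label])
        summary = systolic_area_contributions(decompose(avg))
        out[label] = {"beats": groups[label], "average": avg, "summary": summary}
    return out
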