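"""End-to-end per-beat analysis: separation, decomposition, γ and metrics.

Ties the lower-level modules together for the common case "I have a beat
(or a recording), give me everything": traditional wave separation, the
five-component decomposition with systolic-area bookkeeping, the emission
coefficient with its flow approximation and the RMSE comparison metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decomposition import (
    ContributionSummary,
    FiveComponentDecomposition,
    decompose,
    fit_diastolic_decay,
    systolic_area_contributions,
)
from .emission import (
    GammaFlowComparison,
    GammaTrace,
    compare_gamma_flow,
    compare_gamma_measured_vs_approx,
    emission_coefficient,
)
from .waveform import BeatRecord
from .wsa import WSAResult, separate_beat

__all__ = ["BeatAnalysis", "analyse_beat", "analyse_beats"]


@dataclass(frozen=True)
class BeatAnalysis:
    """Everything the pipeline computes for one beat."""

    beat: BeatRecord
    wsa: WSAResult
    decomposition: FiveComponentDecomposition
    gamma: GammaTrace
    gamma_flow: GammaFlowComparison
    gamma_vs_approx_rmse: float
    summary: ContributionSummary


def analyse_beat(beat: BeatRecord, *, fit=None, c=None) -> BeatAnalysis:
    """Full analysis of a single beat.

    ``fit`` may carry the preceding beat's diastolic fit (multi-beat
    recordings); ``c`` overrides the sum-of-squares wave-speed estimate.
    """
    wsa = separate_beat(beat, c=c)
    decomp = decompose(beat, fit=fit, c=wsa.c)
    gamma = emission_coefficient(wsa, q=beat.q)
    gamma_flow = compare_gamma_flow(gamma, beat.q, beat.fiducials, beat.dt)
    rmse_approx = compare_gamma_measured_vs_approx(gamma)
    summary = systolic_area_contributions(decomp, gamma_peak=gamma.gamma_peak)
    return BeatAnalysis(
        beat=beat, wsa=wsa, decomposition=decomp, gamma=gamma,
        gamma_flow=gamma_flow, gamma_vs_approx_rmse=rmse_approx,
        summary=summary,
    )


def analyse_beats(beats) -> list[BeatAnalysis]:
    """Analyse a beat sequence; each beat's history uses the previous
    beat's diastolic fit (the first beat falls back to its own)."""
    out = []
    prev_fit = None
    for beat in beats:
        out.append(analyse_beat(beat, fit=prev_fit))
        prev_fit = fit_diastolic_decay(beat)
    return out
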