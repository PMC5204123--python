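"""Quantal analysis of endplate recordings.

Per muscle fibre, spontaneous miniature endplate potentials (MEPPs) and
nerve-evoked endplate potentials (EPPs) are recorded at some resting
potential.  For comparability across fibres all amplitudes are first
normalised to a standard resting potential of -80 mV assuming a linear
driving force with an AChR reversal potential of 0 mV:

    v_std = v * (V_std - E_rev) / (V_rest - E_rev)

Large EPPs are then corrected for nonlinear summation,

    V' = v / (1 - f * v / E),    f = 0.8,

where E is the driving force at the standard resting potential (80 mV).
Quantal content follows by the direct method: corrected EPP divided by the
mean corrected MEPP amplitude (quantal size).  Computation is per fibre;
muscle summaries aggregate per-fibre quantal contents, never ratios of
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FibreRecording",
    "QuantalEstimate",
    "normalize_to_rp",
    "nls_correct",
    "quantal_content",
    "summarize_by_muscle",
]

STANDARD_RP = -80.0  # mV
F_FACTOR = 0.8
E_REV = 0.0  # mV, AChR reversal potential


class EphysError(ValueError):
    pass


@dataclass(frozen=True)
class FibreRecording:
    """One muscle fibre's intracellular recording summary."""

    resting_potential: float  # mV, < 0
    epp_amplitude: float  # mV, > 0
    mepp_amplitudes: tuple  # mV each, > 0
    mepp_frequency: float = float("nan")  # events / s
    epp_rise_time: float = float("nan")  # ms
    epp_decay_time: float = float("nan")  # ms
    muscle: str = ""
    fibre: str = ""

    def __post_init__(self) -> None:
        if not (self.resting_potential < 0):
            raise EphysError(
                f"fibre {self.fibre!r}: resting potential must be negative, "
                f"got {self.resting_potential}"
            )
        if not (self.epp_amplitude > 0):
            raise EphysError(f"fibre {self.fibre!r}: EPP amplitude must be > 0")
        object.__setattr__(
            self, "mepp_amplitudes", tuple(float(m) for m in self.mepp_amplitudes)
        )
        if any(m <= 0 for m in self.mepp_amplitudes):
            raise EphysError(f"fibre {self.fibre!r}: MEPP amplitudes must be > 0")


@dataclass(frozen=True)
class QuantalEstimate:
    """Quantal content for one fibre, with every intermediate retained."""

    epp_at_standard_rp: float
    epp_nls_corrected: float
    mean_mepp_at_standard_rp: float
    quantal_content: float
    f_factor: float = F_FACTOR
    reversal_potential: float = E_REV
    standard_rp: float = STANDARD_RP
    muscle: str = ""
    fibre: str = ""


def normalize_to_rp(
    v: float,
    rp: float,
    standard_rp: float = STANDARD_RP,
    e_rev: float = E_REV,
) -> float:
    """Scale an amplitude to a standard resting potential.

    Linear driving-force proportionality: the synaptic current is assumed
    constant, so the voltage deflection scales with (V_rest - E_rev).
    """
    if rp == e_rev:
        raise EphysError("zero driving force: resting potential equals reversal")
    return v * (standard_rp - e_rev) / (rp - e_rev)


def nls_correct(v: float, f: float = F_FACTOR, E: float = abs(STANDARD_RP - E_REV)) -> float:
    """Correct an EPP amplitude for nonlinear summation: V' = v / (1 - f v / E).

    ``E`` is the driving-force magnitude (mV) at the potential the amplitude
    is referred to.  Defined only for v < E/f; at or beyond that the signal
    saturates and the correction is meaningless.
    """
    if E <= 0:
        raise EphysError(f"driving force E must be > 0, got {E}")
    if f < 0:
        raise EphysError(f"f factor must be >= 0, got {f}")
    if f > 0 and v >= E / f:
        raise EphysError(
            f"amplitude {v} mV >= E/f = {E / f:.3f} mV: nonlinear-summation "
            "correction undefined (saturation)"
        )
    return v / (1.0 - f * v / E)


def nls_invert(v_prime: float, f: float = F_FACTOR, E: float = abs(STANDARD_RP - E_REV)) -> float:
    """Inverse of :func:`nls_correct`: v = V' / (1 + f V' / E)."""
    if E <= 0:
        raise EphysError(f"driving force E must be > 0, got {E}")
    return v_prime / (1.0 + f * v_prime / E)


def quantal_content(
    rec: FibreRecording,
    f: float = F_FACTOR,
    e_rev: float = E_REV,
    standard_rp: float = STANDARD_RP,
    mepp_reference: str = "standard",
) -> QuantalEstimate:
    """Direct-method quantal content for one fibre.

    Pipeline: normalise the EPP and every MEPP to the standard resting
    potential, correct the EPP for nonlinear summation with driving force
    E = \\|standard_rp - e_rev\\|, then divide by the mean corrected MEPP.

    ``mepp_reference`` selects the denominator's reference potential:
    ``"standard"`` (default) corrects MEPPs to the standard resting
    potential; ``"epp_rp"`` leaves them at the fibre's own resting
    potential (two conventions both in circulation for the direct method).
    """
    if len(rec.mepp_amplitudes) == 0:
        raise EphysError(f"fibre {rec.fibre!r}: empty MEPP list")
    if mepp_reference not in ("standard", "epp_rp"):
        raise EphysError(f"unknown mepp_reference {mepp_reference!r}")
    try:
        epp_std = normalize_to_rp(rec.epp_amplitude, rec.resting_potential,
                                  standard_rp, e_rev)
        E = abs(standard_rp - e_rev)
        epp_corr = nls_correct(epp_std, f=f, E=E)
        if mepp_reference == "standard":
            mepps = [
                normalize_to_rp(m, rec.resting_potential, standard_rp, e_rev)
                for m in rec.mepp_amplitudes
            ]
        else:
            mepps = list(rec.mepp_amplitudes)
        mean_mepp = float(np.mean(mepps))
    except EphysError as exc:
        raise EphysError(f"fibre {rec.fibre!r}: {exc}") from exc
    return QuantalEstimate(
        epp_at_standard_rp=epp_std,
        epp_nls_corrected=epp_corr,
        mean_mepp_at_standard_rp=mean_mepp,
        quantal_content=epp_corr / mean_mepp,
        f_factor=f,
        reversal_potential=e_rev,
        standard_rp=standard_rp,
        muscle=rec.muscle,
        fibre=rec.fibre,
    )


def summarize_by_muscle(estimates: Sequence[QuantalEstimate]) -> pd.DataFrame:
    """Per-muscle mean ± s.e.m. of per-fibre quantal estimates.

    Aggregates the per-fibre quantal contents (never a ratio of pooled
    means).  Returns one row per muscle with n, mean and s.e.m. for the
    corrected EPP, mean MEPP and quantal content.
    """
    if len(estimates) == 0:
        raise EphysError("no estimates to summarize")
    df = pd.DataFrame(
        {
            "muscle": [e.muscle for e in estimates],
            "epp_nls_corrected": [e.epp_nls_corrected for e in estimates],
            "mean_mepp": [e.mean_mepp_at_standard_rp for e in estimates],
            "quantal_content": [e.quantal_content for e in estimates],
        }
    )

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    out = df.groupby("muscle", sort=False).agg(
        n=("quantal_content", "size"),
        epp_mean=("epp_nls_corrected", "mean"),
        epp_sem=("epp_nls_corrected", _sem),
        mepp_mean=("mean_mepp", "mean"),
        mepp_sem=("mean_mepp", _sem),
        qc_mean=("quantal_content", "mean"),
        qc_sem=("quantal_content", _sem),
    )
    return out.reset_index()
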