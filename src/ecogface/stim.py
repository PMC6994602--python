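"""Statistics for electrical-stimulation outcomes.

Electrical stimulation of ventral temporal sites can distort face
perception.  Outcomes are summarized as counts per fusiform region
(posterior, pFG: y < -45 mm; mid, mFG: -45 <= y <= -35 mm) and per
selectivity class, and compared with a classical one-tailed
two-proportion z-test on pooled variance.  The charge delivered per
stimulation trial is the product of pulse width, current, frequency and
duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StimulationParams",
    "TwoProportionResult",
    "two_proportion_z_one_tailed",
    "charge_per_trial",
]


@dataclass(frozen=True)
class StimulationParams:
    """Parameters of one stimulation trial.

    current_ma : stimulation current in mA (clinical range 3-8 mA)
    frequency_hz : pulse train frequency in Hz (typically 50 Hz)
    pulse_width_ms : single pulse width in ms (typically 0.2 ms)
    duration_s : train duration in s (1-3 s)
    montage : "bipolar" or "unipolar"
    """

    current_ma: float
    frequency_hz: float
    pulse_width_ms: float
    duration_s: float
    montage: str = "bipolar"

    def __post_init__(self) -> None:
        for name in ("current_ma", "frequency_hz", "pulse_width_ms", "duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.montage not in ("bipolar", "unipolar"):
            raise ValueError("montage must be 'bipolar' or 'unipolar'")


@dataclass(frozen=True)
class TwoProportionResult:
    z: float
    p_one_tailed: float
    p1: float
    p2: float
    pooled: float


def two_proportion_z_one_tailed(
    k1: int, n1: int, k2: int, n2: int, *, continuity_correction: bool = False
) -> TwoProportionResult:
    """One-tailed two-proportion z-test with pooled variance.

    Tests H1: p1 > p2 where p1 = k1/n1, p2 = k2/n2.  The statistic is

        z = (p1 - p2) / sqrt(p̂ (1 - p̂) (1/n1 + 1/n2)),   p̂ = (k1+k2)/(n1+n2)

    and the p-value is the upper tail of the standard normal.  With
    ``continuity_correction`` a Yates-type term ``(1/n1 + 1/n2)/2`` is
    subtracted from the numerator's magnitude.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    p1 = k1 / n1
    p2 = k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1): variance undefined")
    diff = p1 - p2
    if continuity_correction:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = np.sign(diff) * max(abs(diff) - cc, 0.0)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = diff / se
    p = float(stats.norm.sf(z))
    return TwoProportionResult(z=float(z), p_one_tailed=p, p1=p1, p2=p2, pooled=pooled)


def charge_per_trial(params: StimulationParams) -> float:
    """Charge metric for one stimulation trial, in μC.

    Product of pulse width (ms), current (mA), frequency (Hz) and
    duration (s): with 0.2 ms pulses at 3 mA, 50 Hz for 1 s this gives
    30 μC.
    """
    return (
        params.pulse_width_ms
        * params.current_ma
        * params.frequency_hz
        * params.duration_s
    )
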