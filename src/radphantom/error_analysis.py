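"""Measurement-error decomposition against the CT gold standard.

The per-pair error is Error = l_fulllength - l_CT.  Per-system summaries
decompose the error set into

    MAE  = mean |e|            RMSE = sqrt(mean e^2)
    Bias = mean e              SD   = population standard deviation

which satisfy RMSE^2 = Bias^2 + SD^2 exactly under the population (divide by
n) convention — the identity that pins down which convention a printed error
table used.  Group-level descriptives (for the per-method comparison) use
the *sample* SD (divide by n - 1) and midpoint-interpolated quantiles
(Hyndman–Fan type 5); both conventions are exposed because published error
tables mix them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_reference import GoldStandard
from .phantom import MarkerPair

__all__ = [
    "ErrorRecord",
    "SystemSummary",
    "GroupDescriptives",
    "ErrorAnalysisError",
    "compute_errors",
    "summarize_system",
    "group_descriptives",
]

_QUANTILE_METHODS = {5: "hazen", 7: "linear"}


class ErrorAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorRecord:
    system: str
    method: str
    pair: MarkerPair
    error: float  # mm, measured minus gold


@dataclass(frozen=True)
class SystemSummary:
    mae: float
    rmse: float
    bias: float
    sd: float  # population convention

    def identity_gap(self) -> float:
        """rmse^2 - (bias^2 + sd^2); zero up to round-off."""
        return self.rmse**2 - (self.bias**2 + self.sd**2)


@dataclass(frozen=True)
class GroupDescriptives:
    n: int
    mean: float
    sd_sample: float
    median: float
    q1: float
    q3: float


def compute_errors(measurements, gold: GoldStandard,
                   system: str = "", method: str = "") -> list[ErrorRecord]:
    """Error = l_fulllength - l_CT for every measured pair."""
    records = []
    for m in measurements:
        l_ct = gold.distance(m.pair)  # raises if the pair is missing
        records.append(ErrorRecord(system=system, method=method,
                                   pair=m.pair, error=m.l_mm - l_ct))
    return records


def _as_errors(errors) -> np.ndarray:
    arr = np.asarray(
        [e.error if isinstance(e, ErrorRecord) else float(e) for e in errors],
        dtype=float,
    )
    if arr.size < 2:
        raise ErrorAnalysisError("need at least 2 errors")
    return arr


def summarize_system(errors) -> SystemSummary:
    """MAE / RMSE / Bias / population SD of a system's error set."""
    e = _as_errors(errors)
    return SystemSummary(
        mae=float(np.mean(np.abs(e))),
        rmse=float(np.sqrt(np.mean(e**2))),
        bias=float(np.mean(e)),
        sd=float(np.std(e, ddof=0)),
    )


def group_descriptives(errors, quantile_type: int = 5) -> GroupDescriptives:
    """Mean, sample SD, median and quartiles of a method group's errors.

    ``quantile_type`` selects the Hyndman–Fan quantile rule: 5 (midpoint
    interpolation, the default that matches published IQRs) or 7 (the common
    linear-interpolation default of most software).
    """
    e = _as_errors(errors)
    try:
        method = _QUANTILE_METHODS[quantile_type]
    except KeyError:
        raise ErrorAnalysisError(
            f"unsupported quantile type {quantile_type}; use 5 or 7"
        ) from None
    q1, med, q3 = np.quantile(e, [0.25, 0.5, 0.75], method=method)
    return GroupDescriptives(
        n=int(e.size),
        mean=float(np.mean(e)),
        sd_sample=float(np.std(e, ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )
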