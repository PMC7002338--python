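"""Reporter-output statistics for counter-silencing screens.

Promoter activity is read out as the *specific reporter output*:
fluorescence divided by backscatter (a biomass proxy) at a fixed
cultivation time, by default 5 h. Constructs are compared between effector
conditions; the effector dissociates the counter-silencing transcription
factor from its operator, so a construct that is activated by TF binding
shows a higher output without effector than with it.

Classification uses Welch's two-sided unequal-variance t-test on replicate
specific outputs (the safer default for triplicate fluorescence data):
p >= alpha -> unchanged; otherwise counter_silenced when the minus-effector
mean exceeds the plus-effector mean, repressed otherwise. No
multiple-testing correction is applied across constructs by default
(each construct is called at per-construct alpha); an optional
Benjamini-Hochberg step is available for screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterSeries",
    "ResponseCall",
    "specific_output",
    "fold_change",
    "classify_response",
    "analyze_plate",
]


@dataclass
class ReporterSeries:
    """One replicate's backscatter + fluorescence time series."""

    strain: str
    construct_id: str
    condition: str  # plus_effector | minus_effector
    replicate: int
    timepoints: np.ndarray  # hours
    backscatter: np.ndarray  # a.u.
    fluorescence: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.backscatter = np.asarray(self.backscatter, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not (len(self.timepoints) == len(self.backscatter)
                == len(self.fluorescence)):
            raise ValueError("time, backscatter and fluorescence must align")
        if self.condition not in ("plus_effector", "minus_effector"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ResponseCall:
    construct_id: str
    fold_change: float
    p_value: float
    call: str  # counter_silenced | repressed | unchanged
    mean_minus: float = np.nan
    mean_plus: float = np.nan
    test: str = "welch"


def specific_output(series: ReporterSeries, at_time: float = 5.0) -> float:
    """Fluorescence / backscatter at the timepoint nearest ``at_time`` h."""
    t = series.timepoints
    if at_time < t.min() or at_time > t.max():
        raise ValueError(f"time {at_time} h outside measured range "
                         f"[{t.min()}, {t.max()}]")
    i = int(np.argmin(np.abs(t - at_time)))
    if series.backscatter[i] <= 0:
        raise ValueError(f"non-positive backscatter at t={t[i]} h")
    return float(series.fluorescence[i] / series.backscatter[i])


def fold_change(minus_effector_outputs: Sequence[float],
                plus_effector_outputs: Sequence[float]) -> float:
    """mean(minus-effector) / mean(plus-effector) specific outputs."""
    minus = np.asarray(minus_effector_outputs, dtype=float)
    plus = np.asarray(plus_effector_outputs, dtype=float)
    if len(minus) == 0 or len(plus) == 0:
        raise ValueError("need at least one replicate per condition")
    if plus.mean() == 0:
        raise ValueError("plus-effector mean is zero; fold change undefined")
    return float(minus.mean() / plus.mean())


def classify_response(minus_reps: Sequence[float], plus_reps: Sequence[float],
                      alpha: float = 0.05,
                      construct_id: str = "") -> ResponseCall:
    """Three-way response call from replicate specific outputs.

    Welch's two-sided t-test; non-significant -> unchanged; significant
    with higher minus-effector mean -> counter_silenced (the TF activates
    by displacing the silencer), otherwise repressed. Degenerate input
    (zero variance in both groups with equal means) is called unchanged.
    """
    minus = np.asarray(minus_reps, dtype=float)
    plus = np.asarray(plus_reps, dtype=float)
    if len(minus) < 3 or len(plus) < 3:
        raise ValueError("need >= 3 replicates per condition")
    fc = fold_change(minus, plus)
    if minus.std() == 0 and plus.std() == 0 and minus.mean() == plus.mean():
        return ResponseCall(construct_id, fc, 1.0, "unchanged",
                            minus.mean(), plus.mean())
    t, p = stats.ttest_ind(minus, plus, equal_var=False)
    p = float(p)
    if not np.isfinite(p) or p >= alpha:
        call = "unchanged"
    elif minus.mean() > plus.mean():
        call = "counter_silenced"
    else:
        call = "repressed"
    return ResponseCall(construct_id, fc, p, call,
                        float(minus.mean()), float(plus.mean()))


def analyze_plate(plate: pd.DataFrame, at_time: float = 5.0,
                  alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Per-construct response calls from a long-format plate table.

    Expected columns: strain, construct, condition, replicate, time_h,
    backscatter, fluorescence. ``fdr=True`` applies Benjamini-Hochberg
    across constructs before calling.
    """
    required = {"construct", "condition", "replicate", "time_h",
                "backscatter", "fluorescence"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")

    outputs: dict[tuple[str, str], list[float]] = {}
    for (construct, condition, _rep), grp in plate.groupby(
            ["construct", "condition", "replicate"]):
        series = ReporterSeries(
            strain=str(grp["strain"].iloc[0]) if "strain" in grp else "",
            construct_id=str(construct), condition=str(condition),
            replicate=int(_rep), timepoints=grp["time_h"].to_numpy(),
            backscatter=grp["backscatter"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
        )
        outputs.setdefault((str(construct), str(condition)), []).append(
            specific_output(series, at_time))

    constructs = sorted({c for c, _ in outputs})
    calls = [classify_response(outputs[(c, "minus_effector")],
                               outputs[(c, "plus_effector")],
                               alpha=alpha, construct_id=c)
             for c in constructs]
    if fdr and calls:
        reject, p_adj = _benjamini_hochberg([c.p_value for c in calls], alpha)
        for call, rej, padj in zip(calls, reject, p_adj):
            call.p_value = padj
            if not rej:
                call.call = "unchanged"
    return pd.DataFrame({
        "construct": [c.construct_id for c in calls],
        "mean_minus": [c.mean_minus for c in calls],
        "mean_plus": [c.mean_plus for c in calls],
        "fold": [c.fold_change for c in calls],
        "p": [c.p_value for c in calls],
        "call": [c.call for c in calls],
    })


def _benjamini_hochberg(pvals: Sequence[float],
                        alpha: float) -> tuple[np.ndarray, np.ndarray]:
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj
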