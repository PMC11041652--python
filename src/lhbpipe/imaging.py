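"""Trial-aligned dF/F0, AUC response classification, plasticity, RAF.

Per trial, dF/F0 = 100 x (F - F0)/F0 with F0 the mean raw fluorescence over
the 3 s preceding cue onset.  A neuron's cue response is classified by
comparing per-trial AUCs over the 1.5-s pre-cue baseline window against the
1.5-s anticipatory window (cue + delay) with a rank-sum test; the class is
excited / inhibited / non-responsive by p <= alpha and the sign of the
median AUC difference.  A 2 x 3 chi-square contingency across phases
quantifies the learning-dependent redistribution of response classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    AnalysisConfig,
    Cue,
    ExclusionError,
    Klass,
    NeuronTraceSet,
    TrialTraceWindow,
    logger,
)
from .ephys import _rank_test

KLASS_ORDER = [Klass.INHIBITED, Klass.NON_RESPONSIVE, Klass.EXCITED]


@dataclass
class WindowResponse:
    neuron_id: str
    cue: Cue
    auc_baseline: np.ndarray   # per trial, % x s
    auc_window: np.ndarray
    p_value: float
    klass: Klass


@dataclass
class PlasticityTable:
    """2 x 3 contingency of response classes (rows: phases; columns:
    inhibited, non-responsive, excited)."""

    counts: np.ndarray
    chi2: float
    p_value: float
    df: int
    dropped_columns: list[Klass]


@dataclass(frozen=True)
class RegionFluorescence:
    signal: float
    background: float

    @property
    def raf(self) -> float:
        return (self.signal - self.background) / (self.signal + self.background)


def compute_dff(
    traces: NeuronTraceSet, cfg: AnalysisConfig | None = None
) -> NeuronTraceSet:
    """Per-trial dF/F0 (percent); trials with non-positive F0 are dropped."""
    cfg = cfg or AnalysisConfig()
    w = traces.window
    f0_slice = w.sample_slice(-cfg.dff_f0_window_s, 0.0)
    f0 = traces.raw_f[:, f0_slice].mean(axis=1)
    valid = f0 > 0
    if not valid.all():
        for i in np.flatnonzero(~valid):
            logger.warning(
                "%s/%s: dropping trial %d (non-positive F0)",
                traces.neuron_id, traces.session_id, i,
            )
    dff = 100.0 * (traces.raw_f[valid] - f0[valid, None]) / f0[valid, None]
    return NeuronTraceSet(
        neuron_id=traces.neuron_id,
        session_id=traces.session_id,
        phase=traces.phase,
        window=w,
        cue_per_trial=[c for c, v in zip(traces.cue_per_trial, valid) if v],
        raw_f=traces.raw_f[valid],
        dff_pct=dff,
    )


def trial_window_auc(
    dff_trial: np.ndarray, window: TrialTraceWindow, span_s: tuple[float, float]
) -> float:
    """Trapezoidal integral of a trial trace over event-relative
    ``[start, end)`` seconds, with linear interpolation at the window
    boundaries so the integral always spans the full window length."""
    start, end = span_s
    t = window.time_axis()
    y = np.asarray(dff_trial, dtype=float)
    if start < t[0] or end > t[-1] or end <= start:
        raise ValueError(f"window [{start}, {end}) outside the trial trace")
    inner = (t > start) & (t < end)
    tt = np.concatenate([[start], t[inner], [end]])
    yy = np.concatenate([
        [np.interp(start, t, y)], y[inner], [np.interp(end, t, y)]
    ])
    return float(np.trapezoid(yy, tt))


def classify_cue_response(
    neuron: NeuronTraceSet,
    cue: Cue,
    response_window: str = "anticipatory",
    cfg: AnalysisConfig | None = None,
) -> WindowResponse:
    """Classify one neuron's response to a cue (or to the airpuff).

    ``response_window`` is ``"anticipatory"`` ([0, 1.5) s: cue plus delay) or
    ``"us"`` (the 0.5-s airpuff epoch: [1.5, 2.0) s on paired CS+ trials,
    [0, 0.5) s on unpredicted-US trials).  Baseline AUC covers the 1.5 s
    immediately before cue onset.
    """
    cfg = cfg or AnalysisConfig()
    if neuron.dff_pct is None:
        neuron = compute_dff(neuron, cfg)
    mask = neuron.trial_mask(cue)
    if mask.sum() < cfg.min_trials_per_cue:
        raise ExclusionError(
            f"{neuron.neuron_id}: {int(mask.sum())} {cue.value} trials "
            f"(need at least {cfg.min_trials_per_cue})"
        )
    if response_window == "anticipatory":
        span = cfg.anticipatory_window_s
    elif response_window == "us":
        span = (0.0, 0.5) if cue is Cue.US_UNPREDICTED else cfg.us_window_s
    else:
        raise ValueError("response_window must be 'anticipatory' or 'us'")
    base_span = (-cfg.imaging_baseline_window_s, 0.0)
    w = neuron.window
    trials = neuron.dff_pct[mask]
    auc_base = np.array([trial_window_auc(tr, w, base_span) for tr in trials])
    auc_win = np.array([trial_window_auc(tr, w, span) for tr in trials])
    p = _rank_test(auc_base, auc_win, cfg.paired_test)
    direction = np.median(auc_win) - np.median(auc_base)
    if p <= cfg.alpha and direction > 0:
        klass = Klass.EXCITED
    elif p <= cfg.alpha and direction < 0:
        klass = Klass.INHIBITED
    else:
        klass = Klass.NON_RESPONSIVE
    return WindowResponse(
        neuron_id=neuron.neuron_id,
        cue=cue,
        auc_baseline=auc_base,
        auc_window=auc_win,
        p_value=p,
        klass=klass,
    )


def class_counts(responses: list[WindowResponse]) -> np.ndarray:
    """Counts over (inhibited, non-responsive, excited)."""
    out = np.zeros(3, dtype=int)
    for r in responses:
        out[KLASS_ORDER.index(r.klass)] += 1
    return out


def plasticity_contingency(
    hab_counts: np.ndarray, cond_counts: np.ndarray
) -> PlasticityTable:
    """Pearson chi-square on the 2 x 3 phase-by-class table.

    Class columns that are empty in both phases are dropped (with a log
    message) and the degrees of freedom adjusted.  Callers are responsible
    for the longitudinal inclusion rule: a neuron enters both rows only if
    it was tracked in at least one habituation and one conditioning session.
    """
    table = np.asarray([hab_counts, cond_counts], dtype=float)
    if table.shape != (2, 3) or table.sum(axis=1).min() == 0:
        raise ValueError("need non-empty class counts for both phases")
    keep = table.sum(axis=0) > 0
    dropped = [k for k, used in zip(KLASS_ORDER, keep) if not used]
    for k in dropped:
        logger.warning("dropping empty response-class column %s", k.value)
    sub = table[:, keep]
    if sub.shape[1] < 2:
        raise ValueError("contingency test needs at least 2 non-empty classes")
    chi2, p, df, _ = stats.chi2_contingency(sub, correction=False)
    return PlasticityTable(
        counts=table.astype(int), chi2=float(chi2), p_value=float(p),
        df=int(df), dropped_columns=dropped,
    )


def relative_fluorescence(signal: float, background: float) -> RegionFluorescence:
    """Relative arbitrary fluorescence (signal - background)/(signal +
    background) for histological expression quantification."""
    if signal < 0 or background < 0:
        raise ValueError("intensities must be nonnegative")
    if signal + background == 0:
        raise ValueError("RAF undefined: both intensities are zero")
    return RegionFluorescence(signal=float(signal), background=float(background))
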