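"""Fiber-photometry photon-count analysis.

Counts (10-ms bins) are smoothed with a 10-sample running average, aligned
to cue/US onsets, and converted to %dF/F0 with F0 the mean smoothed count
over the 3 s preceding the event.  A sensor recording is considered valid
when the habituation-session trial-averaged response to any stimulus shows
at least 3 epochs (50 ms each) whose mean leaves the baseline mean by more
than two baseline standard deviations.  Peak responses are averaged over
consecutive 5-trial bins per cue, and the cue main effect on binned peaks
during conditioning is assessed with a two-factor (cue x bin) analysis of
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Cue,
    Phase,
    PhotometrySeries,
    TrialTraceWindow,
    align_trials,
    logger,
)


@dataclass(frozen=True)
class PhotometryConfig:
    smooth_window: int = 10
    smooth_mode: str = "centered"      # or "trailing"
    epoch_s: float = 0.05
    sd_multiplier: float = 2.0
    min_epochs: int = 3
    f0_window_s: float = 3.0
    peak_window_s: tuple[float, float] = (0.0, 1.5)
    validity_baseline_s: float = 3.0
    validity_response_s: tuple[float, float] = (0.0, 1.5)
    bin_trials: int = 5
    pre_s: float = 5.0
    total_s: float = 15.0


@dataclass
class SensorTrialResponse:
    animal_id: str
    sensor: str
    cue: Cue
    phase: Phase
    trial_ordinal: int        # order within (phase, cue)
    dff_pct: np.ndarray
    peak: float


@dataclass
class ValidityReport:
    valid: bool
    responsive_epochs: dict[str, list[int]]
    degenerate: bool = False


@dataclass
class CueEffectReport:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    mean_peak: dict[str, float]


def smooth_counts(counts: np.ndarray, window: int = 10,
                  mode: str = "centered") -> np.ndarray:
    """Running average with edge truncation (shorter windows at the ends).

    ``centered`` covers ``[i - window//2, i + (window+1)//2)``; ``trailing``
    covers the ``window`` samples ending at ``i``.
    """
    x = np.asarray(counts, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError("smoothing window longer than the series")
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(x.size)
    if mode == "centered":
        lo = np.maximum(i - window // 2, 0)
        hi = np.minimum(i + (window + 1) // 2, x.size)
    elif mode == "trailing":
        lo = np.maximum(i - window + 1, 0)
        hi = i + 1
    else:
        raise ValueError("mode must be 'centered' or 'trailing'")
    return (c[hi] - c[lo]) / (hi - lo)


def _window(series: PhotometrySeries, cfg: PhotometryConfig) -> TrialTraceWindow:
    return TrialTraceWindow(
        sample_rate_hz=series.sample_rate_hz, pre_s=cfg.pre_s, total_s=cfg.total_s
    )


def photometry_dff(
    series: PhotometrySeries, cfg: PhotometryConfig | None = None
) -> list[SensorTrialResponse]:
    """Smooth, align, and convert each event window to %dF/F0.

    F0 is the mean smoothed count over the 3 s before the event onset (cue
    onset, or airpuff onset for unpredicted-US trials); trials with a
    non-positive F0 are dropped with a log message.
    """
    cfg = cfg or PhotometryConfig()
    smoothed = smooth_counts(series.counts, cfg.smooth_window, cfg.smooth_mode)
    window = _window(series, cfg)
    mat, kept = align_trials(smoothed, series.event_times_s, window)
    cues = [c for c, k in zip(series.event_cues, kept) if k]
    phases = [p for p, k in zip(series.phase_per_event, kept) if k]
    f0_slice = window.sample_slice(-cfg.f0_window_s, 0.0)
    peak_slice = window.sample_slice(*cfg.peak_window_s)
    out: list[SensorTrialResponse] = []
    ordinals: dict[tuple[Phase, Cue], int] = {}
    for row, cue, phase in zip(mat, cues, phases):
        k = (phase, cue)
        ordinals[k] = ordinals.get(k, -1) + 1
        f0 = row[f0_slice].mean()
        if f0 <= 0:
            logger.warning(
                "%s: dropping %s/%s trial with non-positive baseline",
                series.animal_id, phase.value, cue.value,
            )
            continue
        dff = 100.0 * (row - f0) / f0
        out.append(
            SensorTrialResponse(
                animal_id=series.animal_id,
                sensor=series.sensor,
                cue=cue,
                phase=phase,
                trial_ordinal=ordinals[k],
                dff_pct=dff,
                peak=float(dff[peak_slice].max()),
            )
        )
    return out


def signal_validity(
    avg_response: np.ndarray,
    window: TrialTraceWindow,
    cfg: PhotometryConfig | None = None,
) -> tuple[bool, list[int], bool]:
    """Validity of one trial-averaged smoothed-count response.

    Returns (valid, responsive epoch indices, degenerate flag).  Valid means
    at least ``min_epochs`` consecutive-50-ms epoch means fall outside
    baseline mean +/- 2 SD (epochs need not be consecutive with each other).
    A constant baseline (SD 0) is degenerate: any epoch differing from the
    baseline at all counts as responsive.
    """
    cfg = cfg or PhotometryConfig()
    avg = np.asarray(avg_response, dtype=float)
    base = avg[window.sample_slice(-cfg.validity_baseline_s, 0.0)]
    m, sd = base.mean(), base.std()
    resp = avg[window.sample_slice(*cfg.validity_response_s)]
    ep_len = int(round(cfg.epoch_s * window.sample_rate_hz))
    n_ep = resp.size // ep_len
    means = resp[: n_ep * ep_len].reshape(n_ep, ep_len).mean(axis=1)
    degenerate = sd == 0
    if degenerate:
        hits = np.flatnonzero(means != m)
    else:
        thr = cfg.sd_multiplier * sd
        hits = np.flatnonzero(np.abs(means - m) > thr)
    valid = hits.size >= cfg.min_epochs
    return bool(valid), hits.tolist(), bool(degenerate)


def check_signal_validity(
    series: PhotometrySeries, cfg: PhotometryConfig | None = None
) -> ValidityReport:
    """Animal-level validity: the habituation trial-averaged response to any
    stimulus (CS+, CS-, or unpredicted US) must pass :func:`signal_validity`."""
    cfg = cfg or PhotometryConfig()
    smoothed = smooth_counts(series.counts, cfg.smooth_window, cfg.smooth_mode)
    window = _window(series, cfg)
    hab = [
        (t, c) for t, c, p in zip(
            series.event_times_s, series.event_cues, series.phase_per_event
        ) if p is Phase.HABITUATION
    ]
    epochs: dict[str, list[int]] = {}
    any_valid = False
    any_degenerate = False
    for cue in Cue:
        times = [t for t, c in hab if c is cue]
        if not times:
            continue
        mat, _ = align_trials(smoothed, times, window)
        if not mat.size:
            continue
        ok, hits, degen = signal_validity(mat.mean(axis=0), window, cfg)
        epochs[cue.value] = hits
        any_valid = any_valid or ok
        any_degenerate = any_degenerate or degen
    return ValidityReport(
        valid=any_valid, responsive_epochs=epochs, degenerate=any_degenerate
    )


def binned_peak_responses(
    responses: list[SensorTrialResponse], cfg: PhotometryConfig | None = None
) -> pd.DataFrame:
    """Mean peak %dF/F0 per consecutive non-overlapping 5-trial bin, per
    animal, phase, and cue.  A trailing partial bin is kept and flagged."""
    cfg = cfg or PhotometryConfig()
    if not responses:
        return pd.DataFrame(
            columns=["animal_id", "sensor", "phase", "cue", "bin_index",
                     "mean_peak", "n_trials", "partial"]
        )
    df = pd.DataFrame({
        "animal_id": [r.animal_id for r in responses],
        "sensor": [r.sensor for r in responses],
        "phase": [r.phase.value for r in responses],
        "cue": [r.cue.value for r in responses],
        "trial_ordinal": [r.trial_ordinal for r in responses],
        "peak": [r.peak for r in responses],
    })
    df["bin_index"] = df["trial_ordinal"] // cfg.bin_trials
    g = (
        df.groupby(["animal_id", "sensor", "phase", "cue", "bin_index"])
        .agg(mean_peak=("peak", "mean"), n_trials=("peak", "size"))
        .reset_index()
    )
    g["partial"] = g["n_trials"] < cfg.bin_trials
    return g


def cue_effect_test(
    binned: pd.DataFrame, phase: Phase = Phase.CONDITIONING
) -> CueEffectReport:
    """Cue main effect on binned mean peaks, two-factor (cue x bin) ANOVA.

    Rows are pooled across animals; the interaction term is included when
    replicate rows leave residual degrees of freedom, otherwise the additive
    model is used.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    sub = binned[
        (binned["phase"] == Phase(phase).value)
        & (binned["cue"].isin([Cue.CS_PLUS.value, Cue.CS_MINUS.value]))
    ].copy()
    n_bins = sub.groupby("cue")["bin_index"].nunique()
    if len(n_bins) < 2 or n_bins.min() < 2:
        raise ValueError("cue effect test needs both cues with >= 2 bins")
    sub["cue"] = pd.Categorical(sub["cue"])
    n_cells = sub.groupby(["cue", "bin_index"], observed=True).ngroups
    interaction = len(sub) - n_cells > 0
    formula = (
        "mean_peak ~ C(cue) * C(bin_index)"
        if interaction
        else "mean_peak ~ C(cue) + C(bin_index)"
    )
    fit = ols(formula, data=sub).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(cue)"]
    means = sub.groupby("cue", observed=True)["mean_peak"].mean().to_dict()
    f = float(row["F"])
    return CueEffectReport(
        f_statistic=0.0 if np.isnan(f) else f,
        df_num=int(row["df"]),
        df_den=int(table.loc["Residual", "df"]),
        p_value=1.0 if np.isnan(row["PR(>F)"]) else float(row["PR(>F)"]),
        mean_peak={str(k): float(v) for k, v in means.items()},
    )
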