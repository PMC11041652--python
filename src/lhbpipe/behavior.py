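"""Eyeblink scoring: eye-area normalization, CR amplitude, discrimination.

The conditioned response (CR) is the anticipatory eyeblink, quantified as
the mean normalized eye area between cue onset (0 s) and airpuff onset
(1.5 s); lower values mean stronger anticipatory closure.  The
discrimination score is the CS- mean CR minus the CS+ mean CR, positive
when blinking is selective for the punishment-predictive cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    AnalysisConfig,
    BehaviorSession,
    Cue,
    InsufficientDataError,
    Phase,
    logger,
)


@dataclass
class BehaviorSummary:
    mouse_id: str
    phase: Phase
    cr_amplitude_per_trial: np.ndarray  # percent, CS trials only
    cue_per_trial: list[Cue]
    cr_mean_csplus: float
    cr_mean_csminus: float
    discrimination_score: float


@dataclass
class LearningTestReport:
    """Paired comparison of per-mouse discrimination scores across phases."""

    t_statistic: float
    df: int
    p_value: float
    mean_habituation: float
    mean_conditioning: float


def normalize_eye_trace(
    session: BehaviorSession, cfg: AnalysisConfig | None = None
) -> BehaviorSession:
    """Normalize each trial to percent of its pre-cue baseline mean.

    The baseline is the mean eye area over the ``behavior_f0_window_s``
    seconds before cue onset; trials with a non-positive baseline are
    dropped with a log message.
    """
    cfg = cfg or AnalysisConfig()
    w = session.window
    base_slice = w.sample_slice(-cfg.behavior_f0_window_s, 0.0)
    baselines = session.eye_area[:, base_slice].mean(axis=1)
    valid = baselines > 0
    if not valid.all():
        for i in np.flatnonzero(~valid):
            logger.warning(
                "%s/%s: dropping trial %d (non-positive baseline)",
                session.mouse_id, session.phase.value, i,
            )
    norm = 100.0 * session.eye_area[valid] / baselines[valid, None]
    return BehaviorSession(
        mouse_id=session.mouse_id,
        phase=session.phase,
        window=w,
        cue_per_trial=[c for c, v in zip(session.cue_per_trial, valid) if v],
        eye_area=session.eye_area[valid],
        norm_eye_pct=norm,
    )


def cr_amplitude(
    trial_norm: np.ndarray, session_window, cfg: AnalysisConfig | None = None
) -> float:
    """Mean normalized eye area (percent) over the CR window [0, 1.5) s."""
    cfg = cfg or AnalysisConfig()
    sl = session_window.sample_slice(*cfg.cr_window_s)
    return float(np.mean(np.asarray(trial_norm)[sl]))


def session_summary(
    session: BehaviorSession, cfg: AnalysisConfig | None = None
) -> BehaviorSummary:
    """CR amplitudes per CS trial and the session discrimination score."""
    cfg = cfg or AnalysisConfig()
    if session.norm_eye_pct is None:
        session = normalize_eye_trace(session, cfg)
    cs_idx = [
        i for i, c in enumerate(session.cue_per_trial)
        if c in (Cue.CS_PLUS, Cue.CS_MINUS)
    ]
    cues = [session.cue_per_trial[i] for i in cs_idx]
    amps = np.array([
        cr_amplitude(session.norm_eye_pct[i], session.window, cfg)
        for i in cs_idx
    ])
    plus = amps[[c is Cue.CS_PLUS for c in cues]]
    minus = amps[[c is Cue.CS_MINUS for c in cues]]
    if plus.size == 0 or minus.size == 0:
        raise InsufficientDataError(
            f"{session.mouse_id}: need at least one trial of each CS"
        )
    return BehaviorSummary(
        mouse_id=session.mouse_id,
        phase=session.phase,
        cr_amplitude_per_trial=amps,
        cue_per_trial=cues,
        cr_mean_csplus=float(plus.mean()),
        cr_mean_csminus=float(minus.mean()),
        discrimination_score=float(minus.mean() - plus.mean()),
    )


def discrimination_score(summary: BehaviorSummary) -> float:
    """CS- mean CR minus CS+ mean CR, in percent points."""
    return summary.discrimination_score


def learning_test(
    hab_scores: np.ndarray, cond_scores: np.ndarray
) -> LearningTestReport:
    """Paired t-test of per-mouse discrimination scores, habituation versus
    conditioning."""
    hab = np.asarray(hab_scores, dtype=float)
    cond = np.asarray(cond_scores, dtype=float)
    if hab.size != cond.size or hab.size < 2:
        raise InsufficientDataError("need paired scores for at least 2 mice")
    t, p = stats.ttest_rel(cond, hab)
    return LearningTestReport(
        t_statistic=float(t),
        df=hab.size - 1,
        p_value=float(p),
        mean_habituation=float(hab.mean()),
        mean_conditioning=float(cond.mean()),
    )
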