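"""End-to-end synthetic benchmark experiments.

Each function builds a synthetic cohort with the generators, runs the
corresponding analysis stage on it, and returns summary numbers: null-
calibration rates of the classifiers, planted-class recovery rates, the
rate/modulation coupling, decoder performance under perfect neuron-behavior
coupling, behavioral learning statistics, and the sensor-potentiation
contrast.  They are the package's own regression benchmarks and are used by
both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import learning_test, session_summary
from .core import AnalysisConfig, Cue, Klass, Phase
from .decoding import DecoderConfig, decode_neuron, decoding_significance
from .ephys import (
    classify_fs_response,
    rate_modulation_correlation,
    spike_train_features,
)
from .imaging import classify_cue_response, compute_dff, trial_window_auc
from .photometry import (
    binned_peak_responses,
    check_signal_validity,
    cue_effect_test,
    photometry_dff,
)
from .synth import (
    BehaviorParams,
    CalciumCohortParams,
    PhotometryParams,
    SpikeCohortParams,
    generate_behavior,
    generate_calcium_cohort,
    generate_photometry,
    generate_spike_cohort,
    generate_task_schedule,
)


def fs_null_calibration(seed: int, n_neurons: int = 2000) -> float:
    """Fraction of planted-null neurons called foot-shock modulated.

    The cohort has effect ratio 1 everywhere (40 stimulation trials), so the
    classifier should fire at about its significance level.
    """
    params = SpikeCohortParams(
        n_neurons=n_neurons, effect_ratio=1.0, duration_s=60.0, seed=seed
    )
    recs, _ = generate_spike_cohort(params)
    called = [
        classify_fs_response(r).klass is not Klass.NON_RESPONSIVE for r in recs
    ]
    return float(np.mean(called))


def fs_recovery(seed: int, n_neurons: int = 300) -> float:
    """Fraction of planted excited/inhibited neurons recovering their class
    at effect ratio 2, 5 Hz baseline, 40 stimulation trials."""
    params = SpikeCohortParams(
        n_neurons=n_neurons, effect_ratio=2.0,
        baseline_rate_median_hz=5.0, baseline_rate_sigma=0.0,
        frac_excited=0.5, frac_inhibited=0.5, frac_nonmod=0.0,
        duration_s=60.0, seed=seed,
    )
    recs, truth = generate_spike_cohort(params)
    pred = [classify_fs_response(r).klass.value for r in recs]
    return float(np.mean([a == b for a, b in zip(pred, truth["klass"])]))


def coupling_experiment(
    seed: int, n_neurons: int = 200, coupling_rho: float = -0.5
) -> tuple[float, float]:
    """Measured Pearson r (and p) between spontaneous rate and foot-shock
    modulation index on a cohort planted with rate/modulation coupling."""
    params = SpikeCohortParams(
        n_neurons=n_neurons, coupling_rho=coupling_rho, seed=seed
    )
    recs, _ = generate_spike_cohort(params)
    feats = [spike_train_features(r) for r in recs]
    resps = [classify_fs_response(r) for r in recs]
    return rate_modulation_correlation(resps, feats)


def calcium_null_calibration(seed: int, n_sessions: int = 2000) -> float:
    """Fraction of planted non-responsive neuron-sessions called cue
    modulated (conditioning CS+ classification)."""
    hab = generate_task_schedule(Phase.HABITUATION, seed)
    cond = generate_task_schedule(Phase.CONDITIONING, seed + 1)
    params = CalciumCohortParams(
        n_neurons=n_sessions, prob_excited=0.0, prob_inhibited=0.0,
        prob_nonresponsive=1.0, seed=seed,
    )
    pairs, _ = generate_calcium_cohort(params, hab, cond)
    called = [
        classify_cue_response(c, Cue.CS_PLUS).klass is not Klass.NON_RESPONSIVE
        for _, c in pairs
    ]
    return float(np.mean(called))


def calcium_recovery(seed: int, n_neurons: int = 300) -> float:
    """Fraction of planted responsive neurons recovering their class at
    20 % amplitude, 5 % noise, 30 CS+ trials."""
    hab = generate_task_schedule(Phase.HABITUATION, seed)
    cond = generate_task_schedule(Phase.CONDITIONING, seed + 1)
    params = CalciumCohortParams(
        n_neurons=n_neurons, prob_excited=0.5, prob_inhibited=0.5,
        prob_nonresponsive=0.0, response_amp_cond=20.0, noise_sd=5.0,
        seed=seed,
    )
    pairs, truth = generate_calcium_cohort(params, hab, cond)
    pred = [classify_cue_response(c, Cue.CS_PLUS).klass.value for _, c in pairs]
    want = [
        Klass.EXCITED.value if a > 0 else Klass.INHIBITED.value
        for a in truth["neurons"]["amp_cond"]
    ]
    return float(np.mean([a == b for a, b in zip(pred, want)]))


def plasticity_experiment(seed: int, n_neurons: int = 300):
    """Phase-by-class contingency on the default cohort (amplitudes grow
    from habituation to conditioning)."""
    from .imaging import class_counts, plasticity_contingency

    hab = generate_task_schedule(Phase.HABITUATION, seed)
    cond = generate_task_schedule(Phase.CONDITIONING, seed + 1)
    params = CalciumCohortParams(n_neurons=n_neurons, seed=seed)
    pairs, _ = generate_calcium_cohort(params, hab, cond)
    hab_resp = [classify_cue_response(h, Cue.CS_PLUS) for h, _ in pairs]
    cond_resp = [classify_cue_response(c, Cue.CS_PLUS) for _, c in pairs]
    return plasticity_contingency(
        class_counts(hab_resp), class_counts(cond_resp)
    )


def decoder_experiment(
    seed: int,
    n_neurons: int = 50,
    n_repeats: int = 100,
    neuron_coupling: float = 1.0,
):
    """Decode trial-wise eyeblink from each planted responsive neuron.

    The behavioral cohort is generated with the given neuron-behavior
    coupling; decoding pools CS+ and CS- trials of the conditioning session.
    Returns (list of DecodingResult, SignificanceReport).
    """
    hab = generate_task_schedule(Phase.HABITUATION, seed)
    cond = generate_task_schedule(Phase.CONDITIONING, seed + 1)
    cal_params = CalciumCohortParams(n_neurons=3 * n_neurons, seed=seed)
    pairs, truth = generate_calcium_cohort(cal_params, hab, cond)
    responsive = truth["neurons"].index[
        truth["neurons"]["klass"] != Klass.NON_RESPONSIVE.value
    ][:n_neurons]
    if len(responsive) < n_neurons:
        raise ValueError("cohort too small for the requested neuron count")
    beh = generate_behavior(
        BehaviorParams(n_mice=1, neuron_coupling=neuron_coupling, seed=seed),
        hab, cond, truth,
    )
    summary = session_summary(beh[0][1])
    cr = summary.cr_amplitude_per_trial
    cfg = AnalysisConfig()
    dcfg = DecoderConfig(n_repeats=n_repeats, seed=seed)
    results = []
    for i in responsive:
        ts = compute_dff(pairs[i][1], cfg)
        cs = [c in (Cue.CS_PLUS, Cue.CS_MINUS) for c in ts.cue_per_trial]
        aucs = np.array([
            trial_window_auc(tr, ts.window, cfg.anticipatory_window_s)
            for tr, keep in zip(ts.dff_pct, cs) if keep
        ])
        results.append(decode_neuron(aucs, cr, dcfg, neuron_id=ts.neuron_id))
    return results, decoding_significance(results)


def behavior_experiment(seed: int, learner: bool = True, n_mice: int = 10):
    """Per-mouse discrimination scores across phases plus the paired test."""
    hab = generate_task_schedule(Phase.HABITUATION, seed)
    cond = generate_task_schedule(Phase.CONDITIONING, seed + 1)
    mice = generate_behavior(
        BehaviorParams(n_mice=n_mice, learner=learner, seed=seed), hab, cond
    )
    hab_scores = [session_summary(h).discrimination_score for h, _ in mice]
    cond_scores = [session_summary(c).discrimination_score for _, c in mice]
    return hab_scores, cond_scores, learning_test(hab_scores, cond_scores)


def _sensor_binned(
    sensor: str, profile: str, n_mice: int, seed: int
) -> tuple[pd.DataFrame, list[bool]]:
    """Binned peak table pooled over mice; two conditioning sessions per
    mouse give 60 conditioning trials per cue."""
    frames, valid = [], []
    for m in range(n_mice):
        hab_s = generate_task_schedule(Phase.HABITUATION, seed + 100 + m)
        cond_a = generate_task_schedule(Phase.CONDITIONING, seed + 200 + m)
        cond_b = generate_task_schedule(Phase.CONDITIONING, seed + 300 + m)
        ser_a = generate_photometry(
            PhotometryParams.for_profile(sensor, profile, seed=seed + m),
            hab_s, cond_a,
        )
        ser_b = generate_photometry(
            PhotometryParams.for_profile(sensor, profile, seed=seed + 500 + m),
            hab_s, cond_b,
        )
        valid.append(check_signal_validity(ser_a).valid)
        resp = photometry_dff(ser_a)
        extra = [
            r for r in photometry_dff(ser_b) if r.phase is Phase.CONDITIONING
        ]
        offset: dict = {}
        for r in resp:
            key = (r.phase, r.cue)
            offset[key] = max(offset.get(key, -1), r.trial_ordinal)
        for r in extra:
            r.trial_ordinal += offset[(r.phase, r.cue)] + 1
            r.animal_id = ser_a.animal_id
        frames.append(binned_peak_responses(resp + extra))
    return pd.concat(frames, ignore_index=True), valid


def photometry_experiment(seed: int) -> dict:
    """Cue main effect per sensor: one CS+-potentiating ACh-like cohort
    (6 mice) and three stable cohorts (3 mice each)."""
    out = {}
    cohorts = [
        ("ACh", "potentiating", 6, seed),
        ("Glu", "stable", 3, seed + 1000),
        ("GABA", "stable", 3, seed + 2000),
        ("5HT", "stable", 3, seed + 3000),
    ]
    for sensor, profile, n_mice, s in cohorts:
        binned, valid = _sensor_binned(sensor, profile, n_mice, s)
        report = cue_effect_test(binned, Phase.CONDITIONING)
        out[sensor] = {
            "profile": profile,
            "report": report,
            "all_valid": bool(all(valid)),
        }
    return out
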