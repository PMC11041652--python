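"""Synthetic task schedules and multimodal recordings with planted truth.

Every generator is a pure function of its parameters and seed.  The planted
statistical structure mirrors what the analysis stages assume:

* spike cohorts — log-normal spontaneous rates, gamma-renewal interspike
  intervals with burst riders, and a foot-shock rate step whose direction is
  coupled to the baseline rate through a Gaussian copula (excitation more
  common in low-firing neurons);
* calcium cohorts — excited / inhibited / non-responsive classes whose
  cue-locked transient amplitude grows from habituation to conditioning,
  with a shared per-trial response gain that behavior can couple to;
* behavior — anticipatory eye closure on CS+ trials that deepens with
  learning, full blink during airpuffs;
* photometry — Poisson photon counts whose event-locked rate transients are
  either stable across learning (Glu/GABA/5-HT-like) or CS+-potentiating
  (ACh-like).

Per-entity random streams are derived from the master seed with
``np.random.default_rng([master_seed, stream, index])`` so cohorts are
reproducible element-by-element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BehaviorSession,
    Cue,
    Klass,
    NeuronTraceSet,
    Phase,
    PhotometrySeries,
    SpikeTrainRecording,
    Trial,
    TrialSchedule,
    TrialTraceWindow,
)

HABITUATION_COUNTS = {Cue.CS_PLUS: 30, Cue.CS_MINUS: 30, Cue.US_UNPREDICTED: 5}
CONDITIONING_COUNTS = {Cue.CS_PLUS: 30, Cue.CS_MINUS: 30}


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------


def generate_task_schedule(phase: Phase, seed: int) -> TrialSchedule:
    """Random session schedule: 30 CS+, 30 CS- (plus 5 unpredicted airpuffs
    during habituation) in shuffled order, ITIs i.i.d. uniform on [30, 45] s.
    """
    phase = Phase(phase)
    rng = np.random.default_rng([int(seed), 0])
    counts = (
        HABITUATION_COUNTS if phase is Phase.HABITUATION else CONDITIONING_COUNTS
    )
    cues = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(cues)
    itis = rng.uniform(30.0, 45.0, size=len(cues))
    onsets = 30.0 + np.cumsum(itis) - itis[0]
    trials = [
        Trial(
            trial_index=i,
            cue=cue,
            onset_s=float(onsets[i]),
            paired_us=(phase is Phase.CONDITIONING and cue is Cue.CS_PLUS),
        )
        for i, cue in enumerate(cues)
    ]
    return TrialSchedule(trials=trials, phase=phase)


# ---------------------------------------------------------------------------
# spike cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeCohortParams:
    """Cohort of foot-shock-stimulated neurons.

    ``coupling_rho`` is the Gaussian-copula correlation between log baseline
    rate and the latent modulation propensity; thresholding the propensity
    into discrete classes attenuates the realized rate/modulation Pearson r
    to roughly 0.9 x rho at the default class proportions.
    """

    n_neurons: int = 200
    baseline_rate_median_hz: float = 4.0
    baseline_rate_sigma: float = 1.0
    coupling_rho: float = -0.5
    frac_excited: float = 0.68
    frac_inhibited: float = 0.19
    frac_nonmod: float = 0.13
    effect_ratio: float = 2.5
    burst_prob: float = 0.15
    isi_shape_range: tuple[float, float] = (0.6, 1.8)
    n_fs_trials: int = 40
    fs_iti_s: float = 5.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.frac_excited + self.frac_inhibited + self.frac_nonmod
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not -1.0 <= self.coupling_rho <= 0.0:
            raise ValueError(
                "coupling_rho must lie in [-1, 0]; stronger coupling than a "
                "perfect copula is infeasible"
            )
        if self.effect_ratio <= 0:
            raise ValueError("effect_ratio must be positive")
        if self.n_fs_trials < 1:
            raise ValueError("n_fs_trials must be >= 1")


def _renewal_train(
    rng: np.random.Generator,
    t_knots: np.ndarray,
    lam_knots: np.ndarray,
    shape: float,
) -> np.ndarray:
    """Gamma-renewal spikes under a piecewise-constant rate (time rescaling)."""
    total = lam_knots[-1]
    if total <= 0:
        return np.empty(0)
    ops = []
    acc = 0.0
    n_guess = int(total + 10 * np.sqrt(total) + 50)
    while acc <= total:
        inc = rng.gamma(shape, 1.0 / shape, size=n_guess)
        inc[inc < 1e-7] = 1e-7
        cs = acc + np.cumsum(inc)
        ops.append(cs)
        acc = cs[-1]
        n_guess = max(n_guess // 4, 50)
    op_times = np.concatenate(ops)
    op_times = op_times[op_times <= total]
    return np.interp(op_times, lam_knots, t_knots)


def _add_burst_riders(
    rng: np.random.Generator, spikes: np.ndarray, burst_prob: float,
    duration_s: float,
) -> np.ndarray:
    """Each spike seeds, with probability ``burst_prob``, 2-4 extra spikes at
    cumulative 5-15 ms lags."""
    if burst_prob <= 0 or spikes.size == 0:
        return spikes
    seeds = spikes[rng.random(spikes.size) < burst_prob]
    extras = []
    for t in seeds:
        m = int(rng.integers(2, 5))
        lags = np.cumsum(rng.uniform(0.005, 0.015, size=m))
        extras.append(t + lags)
    if not extras:
        return spikes
    out = np.concatenate([spikes, *extras])
    out = np.unique(out)
    return out[(out >= 0) & (out <= duration_s)]


def generate_spike_cohort(
    params: SpikeCohortParams,
) -> tuple[list[SpikeTrainRecording], pd.DataFrame]:
    """Simulate a cohort of spike-train recordings plus its ground truth.

    Returns the recordings and a table with columns ``neuron_id, klass,
    baseline_rate_hz, effect_ratio, true_modulation, isi_shape``.
    """
    p = params
    master = np.random.default_rng([int(p.seed), 1])
    z = master.multivariate_normal(
        [0.0, 0.0],
        [[1.0, p.coupling_rho], [p.coupling_rho, 1.0]],
        size=p.n_neurons,
        method="cholesky",
    )
    z_rate, z_mod = z[:, 0], z[:, 1]
    rates = p.baseline_rate_median_hz * np.exp(p.baseline_rate_sigma * z_rate)
    # class assignment by propensity quantile: bottom slab inhibited,
    # top slab excited, middle non-modulated
    order = np.argsort(z_mod, kind="stable")
    klass: list[Klass] = [Klass.NON_RESPONSIVE] * p.n_neurons
    n_inh = int(round(p.frac_inhibited * p.n_neurons))
    n_exc = int(round(p.frac_excited * p.n_neurons))
    n_exc = min(n_exc, p.n_neurons - n_inh)
    for i in order[:n_inh]:
        klass[i] = Klass.INHIBITED
    for i in order[p.n_neurons - n_exc:]:
        klass[i] = Klass.EXCITED
    ratio_of = {Klass.EXCITED: p.effect_ratio,
                Klass.INHIBITED: 1.0 / p.effect_ratio,
                Klass.NON_RESPONSIVE: 1.0}
    ratios = np.array([ratio_of[k] for k in klass])
    shapes = master.uniform(*p.isi_shape_range, size=p.n_neurons)

    fs_onsets = p.duration_s + 3.0 + p.fs_iti_s * np.arange(p.n_fs_trials)
    total_dur = float(fs_onsets[-1] + 4.0)

    recs = []
    rows = []
    for i in range(p.n_neurons):
        rng = np.random.default_rng([int(p.seed), 2, i])
        r, ratio = float(rates[i]), float(ratios[i])
        # piecewise-constant rate: baseline everywhere, stepped for 1 s
        # after each foot-shock onset
        t_knots = [0.0]
        lam_knots = [0.0]
        for on in fs_onsets:
            t_knots += [on, on + 1.0]
        t_knots.append(total_dur)
        t_knots = np.array(t_knots)
        seg_rates = np.empty(t_knots.size - 1)
        seg_rates[0::2] = r
        seg_rates[1::2] = r * ratio
        lam_knots = np.concatenate([[0.0], np.cumsum(np.diff(t_knots) * seg_rates)])
        spikes = _renewal_train(rng, t_knots, lam_knots, float(shapes[i]))
        spikes = _add_burst_riders(rng, spikes, p.burst_prob, total_dur)
        recs.append(
            SpikeTrainRecording(
                neuron_id=f"n{i:04d}",
                spike_times_s=spikes,
                duration_s=total_dur,
                fs_event_times_s=fs_onsets.copy(),
            )
        )
        rows.append({
            "neuron_id": f"n{i:04d}",
            "klass": klass[i].value,
            "baseline_rate_hz": r,
            "effect_ratio": ratio,
            "true_modulation": (ratio - 1.0) / (ratio + 1.0),
            "isi_shape": float(shapes[i]),
        })
    return recs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calcium cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalciumCohortParams:
    """Cohort of longitudinally tracked neurons imaged at 5 Hz.

    Amplitudes are %dF/F0 at the transient peak for excited neurons
    (inhibited neurons carry the negated amplitude).  ``trial_gain_sd`` sets
    the trial-to-trial variability of a response gain shared by every
    responsive neuron; behavior generation can couple eyeblink depth to it.
    """

    n_neurons: int = 100
    prob_excited: float = 0.35
    prob_inhibited: float = 0.15
    prob_nonresponsive: float = 0.50
    response_amp_hab: float = 2.0
    response_amp_cond: float = 20.0
    us_amp: float = 30.0
    rise_s: float = 0.05
    decay_s: float = 0.5
    noise_sd: float = 5.0
    trial_gain_sd: float = 0.35
    f_rest: float = 100.0
    sample_rate_hz: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.prob_excited + self.prob_inhibited + self.prob_nonresponsive
        if abs(s - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _transient_kernel(
    window: TrialTraceWindow, rise_s: float, decay_s: float, onset_s: float
) -> np.ndarray:
    """Unit-peak rise/decay transient sampled on the trial time axis.

    Normalized so that the maximum of the *cue-onset* sampling (onset 0)
    equals one; a kernel placed off-grid peaks slightly below one.
    """
    t = window.time_axis()
    if decay_s > window.total_s - window.pre_s:
        raise ValueError("kernel decay longer than the post-event window")
    def raw(ts: np.ndarray) -> np.ndarray:
        out = np.exp(-ts / decay_s) - np.exp(-ts / rise_s)
        return np.where(ts >= 0, out, 0.0)
    ref = raw(t - 0.0)
    peak = ref.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: no positive samples")
    return raw(t - onset_s) / peak


def generate_calcium_cohort(
    params: CalciumCohortParams,
    hab_schedule: TrialSchedule,
    cond_schedule: TrialSchedule,
) -> tuple[list[tuple[NeuronTraceSet, NeuronTraceSet]], dict]:
    """Simulate paired habituation/conditioning trace sets per neuron.

    Returns per-neuron (habituation, conditioning) pairs and a ground-truth
    dict with a per-neuron table (``neurons``) and the shared per-trial
    response gains (``trial_gain``, keyed by phase).
    """
    p = params
    window = TrialTraceWindow(sample_rate_hz=p.sample_rate_hz)
    rng = np.random.default_rng([int(p.seed), 3])
    klass_values = (Klass.EXCITED, Klass.INHIBITED, Klass.NON_RESPONSIVE)
    klass_idx = rng.choice(
        3, size=p.n_neurons,
        p=[p.prob_excited, p.prob_inhibited, p.prob_nonresponsive],
    )
    klass = [klass_values[i] for i in klass_idx]
    schedules = {Phase.HABITUATION: hab_schedule, Phase.CONDITIONING: cond_schedule}
    gains = {
        ph: np.clip(
            rng.normal(1.0, p.trial_gain_sd, size=len(sched.trials)), 0.0, None
        )
        for ph, sched in schedules.items()
    }
    amps = {Phase.HABITUATION: p.response_amp_hab,
            Phase.CONDITIONING: p.response_amp_cond}
    cue_kernel = _transient_kernel(window, p.rise_s, p.decay_s, 0.0)
    us_kernels = {
        ph: _transient_kernel(window, p.rise_s, p.decay_s, sched.us_onset_delay_s)
        for ph, sched in schedules.items()
    }

    pairs = []
    for i in range(p.n_neurons):
        sign = {Klass.EXCITED: 1.0, Klass.INHIBITED: -1.0,
                Klass.NON_RESPONSIVE: 0.0}[klass[i]]
        nrng = np.random.default_rng([int(p.seed), 4, i])
        sets = {}
        for ph, sched in schedules.items():
            cues = [t.cue for t in sched.trials]
            n_tr = len(cues)
            sig = np.zeros((n_tr, window.n_samples))
            for j, trial in enumerate(sched.trials):
                g = gains[ph][j]
                if trial.cue is Cue.CS_PLUS:
                    sig[j] += sign * amps[ph] * g * cue_kernel
                    if trial.paired_us:
                        sig[j] += sign * p.us_amp * g * us_kernels[ph]
                elif trial.cue is Cue.US_UNPREDICTED:
                    sig[j] += sign * p.us_amp * g * cue_kernel
            noise = nrng.normal(0.0, p.noise_sd, size=sig.shape) if p.noise_sd else 0.0
            raw_f = p.f_rest * (1.0 + (sig + noise) / 100.0)
            sets[ph] = NeuronTraceSet(
                neuron_id=f"c{i:04d}",
                session_id=f"{ph.value}-1",
                phase=ph,
                window=window,
                cue_per_trial=cues,
                raw_f=raw_f,
            )
        pairs.append((sets[Phase.HABITUATION], sets[Phase.CONDITIONING]))

    truth = pd.DataFrame({
        "neuron_id": [f"c{i:04d}" for i in range(p.n_neurons)],
        "klass": [k.value for k in klass],
        "amp_hab": [
            {Klass.EXCITED: p.response_amp_hab,
             Klass.INHIBITED: -p.response_amp_hab,
             Klass.NON_RESPONSIVE: 0.0}[k] for k in klass
        ],
        "amp_cond": [
            {Klass.EXCITED: p.response_amp_cond,
             Klass.INHIBITED: -p.response_amp_cond,
             Klass.NON_RESPONSIVE: 0.0}[k] for k in klass
        ],
    })
    return pairs, {"neurons": truth, "trial_gain": gains}


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorParams:
    """Eyeblink cohort.  Depths are fractional eye closure during the CR
    window on CS+ trials (CS- trials stay at zero mean closure);
    ``neuron_coupling`` correlates per-trial closure with the calcium
    cohort's shared response gain."""

    n_mice: int = 10
    learner: bool = True
    cr_depth_hab: float = 0.05
    cr_depth_cond: float = 0.30
    blink_noise_sd: float = 0.05
    neuron_coupling: float = 0.0
    baseline_px: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.cr_depth_hab, self.cr_depth_cond):
            if not 0.0 <= d <= 1.0:
                raise ValueError("CR depths must lie in [0, 1]")
        if not 0.0 <= self.neuron_coupling <= 1.0:
            raise ValueError("neuron_coupling must lie in [0, 1]")


def generate_behavior(
    params: BehaviorParams,
    hab_schedule: TrialSchedule,
    cond_schedule: TrialSchedule,
    calcium_truth: dict | None = None,
) -> list[tuple[BehaviorSession, BehaviorSession]]:
    """Simulate (habituation, conditioning) eye-area sessions per mouse."""
    p = params
    if p.neuron_coupling > 0 and calcium_truth is None:
        raise ValueError("neuron_coupling > 0 requires calcium ground truth")
    window = TrialTraceWindow(sample_rate_hz=10.0)
    schedules = {Phase.HABITUATION: hab_schedule, Phase.CONDITIONING: cond_schedule}
    depths = {Phase.HABITUATION: p.cr_depth_hab if p.learner else 0.0,
              Phase.CONDITIONING: p.cr_depth_cond if p.learner else 0.0}
    out = []
    for m in range(p.n_mice):
        rng = np.random.default_rng([int(p.seed), 5, m])
        sessions = {}
        for ph, sched in schedules.items():
            n_tr = len(sched.trials)
            cr_slice = window.sample_slice(0.0, 1.5)
            if p.neuron_coupling > 0:
                g = calcium_truth["trial_gain"][ph]
                sd = g.std() or 1.0
                a = (g - g.mean()) / sd
            else:
                a = np.zeros(n_tr)
            area = np.empty((n_tr, window.n_samples))
            for j, trial in enumerate(sched.trials):
                base = p.baseline_px * rng.uniform(0.9, 1.1)
                row = np.full(window.n_samples, base)
                if trial.cue in (Cue.CS_PLUS, Cue.CS_MINUS):
                    depth = depths[ph] if trial.cue is Cue.CS_PLUS else 0.0
                    d = depth * (1.0 + 0.35 * p.neuron_coupling * a[j])
                    if p.blink_noise_sd:
                        d += rng.normal(0.0, p.blink_noise_sd)
                    d = float(np.clip(d, 0.0, 1.0))
                    row[cr_slice] = base * (1.0 - d)
                    if trial.paired_us:
                        us0 = sched.us_onset_delay_s
                        row[window.sample_slice(us0, us0 + sched.us_duration_s)] = (
                            base * 0.05
                        )
                else:  # unpredicted airpuff, aligned at onset
                    row[window.sample_slice(0.0, sched.us_duration_s)] = base * 0.05
                area[j] = np.maximum(row, 1.0)
            sessions[ph] = BehaviorSession(
                mouse_id=f"m{m:02d}",
                phase=ph,
                window=window,
                cue_per_trial=[t.cue for t in sched.trials],
                eye_area=area,
            )
        out.append((sessions[Phase.HABITUATION], sessions[Phase.CONDITIONING]))
    return out


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhotometryParams:
    """One neurotransmitter-sensor animal.

    Amplitudes are fractional peak rate changes of the Poisson photon rate.
    ``stable`` profiles keep CS amplitudes identical across learning;
    ``potentiating`` doubles the CS+ amplitude after conditioning.
    """

    sensor: str = "ACh"
    sensor_profile: str = "potentiating"
    base_rate: float = 50.0
    amp_cs_plus_hab: float = 0.3
    amp_cs_minus_hab: float = 0.3
    amp_cs_plus_cond: float = 0.6
    amp_cs_minus_cond: float = 0.3
    amp_us: float = 0.8
    rise_s: float = 0.05
    decay_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.sensor_profile not in ("stable", "potentiating"):
            raise ValueError("sensor_profile must be stable or potentiating")

    @classmethod
    def for_profile(cls, sensor: str, profile: str, seed: int = 0,
                    amp: float = 0.3, **kw) -> "PhotometryParams":
        """Stable: identical CS amplitudes everywhere; potentiating: CS+
        amplitude doubles after learning."""
        gain = 2.0 if profile == "potentiating" else 1.0
        return cls(
            sensor=sensor, sensor_profile=profile, seed=seed,
            amp_cs_plus_hab=amp, amp_cs_minus_hab=amp,
            amp_cs_plus_cond=amp * gain, amp_cs_minus_cond=amp, **kw,
        )


def generate_photometry(
    params: PhotometryParams,
    hab_schedule: TrialSchedule,
    cond_schedule: TrialSchedule,
) -> PhotometrySeries:
    """Simulate a photon-count series spanning habituation then conditioning
    (concatenated with a 30-s gap), with cue/US rate transients."""
    p = params
    rng = np.random.default_rng([int(p.seed), 6])
    bin_w = 0.01
    rate_hz = 1.0 / bin_w
    amps = {
        (Phase.HABITUATION, Cue.CS_PLUS): p.amp_cs_plus_hab,
        (Phase.HABITUATION, Cue.CS_MINUS): p.amp_cs_minus_hab,
        (Phase.CONDITIONING, Cue.CS_PLUS): p.amp_cs_plus_cond,
        (Phase.CONDITIONING, Cue.CS_MINUS): p.amp_cs_minus_cond,
    }
    kernel_len = int(round(4.0 * rate_hz))
    tk = np.arange(kernel_len) * bin_w
    kernel = np.exp(-tk / p.decay_s) - np.exp(-tk / p.rise_s)
    kernel /= kernel.max()

    segments = []
    ev_times, ev_cues, ev_phases = [], [], []
    offset = 0.0
    for phase, sched in (
        (Phase.HABITUATION, hab_schedule),
        (Phase.CONDITIONING, cond_schedule),
    ):
        n_bins = int(round((sched.duration_s + 10.0) / bin_w))
        rel = np.ones(n_bins)

        def bump(t_on: float, amp: float) -> None:
            i0 = int(np.floor(t_on * rate_hz))
            sl = rel[i0 : i0 + kernel_len]
            sl += amp * kernel[: sl.size]

        for trial in sched.trials:
            if trial.cue is Cue.US_UNPREDICTED:
                bump(trial.onset_s, p.amp_us)
            else:
                bump(trial.onset_s, amps[(phase, trial.cue)])
                if trial.paired_us:
                    bump(trial.onset_s + sched.us_onset_delay_s, p.amp_us)
            ev_times.append(offset + trial.onset_s)
            ev_cues.append(trial.cue)
            ev_phases.append(phase)
        segments.append(rng.poisson(p.base_rate * rel))
        offset += n_bins * bin_w + 30.0
        segments.append(rng.poisson(p.base_rate, size=int(round(30.0 / bin_w))))
    counts = np.concatenate(segments[:-1])  # drop trailing gap
    return PhotometrySeries(
        animal_id=f"{p.sensor}-{p.seed}",
        sensor=p.sensor,
        counts=counts,
        bin_width_s=bin_w,
        event_times_s=np.array(ev_times),
        event_cues=ev_cues,
        phase_per_event=ev_phases,
    )
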