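"""Spike-train featurization, foot-shock classification, and embedding.

Spontaneous-activity statistics (rate, CV, burst index, ISI histogram,
autocorrelograms) are computed with the 1-s post-foot-shock windows excised
from the recording; interspike intervals never span an excised window.
Foot-shock response classification compares per-trial spike counts in the
1 s before versus the 1 s after each shock onset with a Wilcoxon rank-sum
(Mann-Whitney) test, and summarizes effect size with the bounded modulation
index (FR_stim - FR_base) / (FR_stim + FR_base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    AnalysisConfig,
    ExclusionError,
    InsufficientDataError,
    Klass,
    SpikeTrainRecording,
)

ISI_HIST_BINS = 100          # 10-ms bins spanning 1 s
ISI_HIST_RANGE_S = 1.0
ACG_BIN_S = 0.001            # 1-ms autocorrelogram bins
ACG_LONG_LAGS = 500
ACG_SHORT_LAGS = 100
BURST_ISI_S = 0.025
MIN_FS_TRIALS = 20           # strictly more than this many trials required


@dataclass
class SpikeFeatureSet:
    """Spontaneous-activity features of one neuron."""

    neuron_id: str
    firing_rate_hz: float
    cv: float
    burst_index: float
    isi_hist: np.ndarray
    acg_500: np.ndarray
    acg_100: np.ndarray


@dataclass
class EmbeddingInput:
    """The 15-feature matrix fed to the 2-D embedding, with fitted PCAs."""

    features_15: np.ndarray
    feature_names: list[str]
    pca_models: dict


@dataclass
class FSResponse:
    """Foot-shock response classification of one neuron."""

    neuron_id: str
    fr_baseline_hz: float
    fr_stimulus_hz: float
    per_trial_counts: np.ndarray  # (n_trials, 2): baseline, stimulus
    p_value: float
    klass: Klass
    modulation_index: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# spontaneous features
# ---------------------------------------------------------------------------


def _spontaneous_segments(rec: SpikeTrainRecording) -> list[tuple[float, float]]:
    """Recording intervals outside the 1-s post-foot-shock windows."""
    segs = []
    cursor = 0.0
    for on in np.sort(rec.fs_event_times_s):
        stop = min(max(on, cursor), rec.duration_s)
        if stop > cursor:
            segs.append((cursor, stop))
        cursor = max(cursor, min(on + 1.0, rec.duration_s))
    if rec.duration_s > cursor:
        segs.append((cursor, rec.duration_s))
    return segs


def _segment_isis(rec: SpikeTrainRecording) -> tuple[list[np.ndarray], float, int]:
    """Per-segment spike ISIs, total spontaneous duration, and spike count."""
    isis, total_dur, n_spikes = [], 0.0, 0
    for a, b in _spontaneous_segments(rec):
        total_dur += b - a
        seg = rec.spike_times_s[
            (rec.spike_times_s >= a) & (rec.spike_times_s < b)
        ]
        n_spikes += seg.size
        if seg.size >= 2:
            isis.append(np.diff(seg))
    return isis, total_dur, n_spikes


def _acg(spike_segments: list[np.ndarray], n_lags: int) -> np.ndarray:
    """Positive-lag autocorrelogram, 1-ms bins, normalized by spike count."""
    max_lag = n_lags * ACG_BIN_S
    hist = np.zeros(n_lags)
    n_spikes = 0
    for seg in spike_segments:
        n_spikes += seg.size
        hi = np.searchsorted(seg, seg + max_lag, side="right")
        for i, h in enumerate(hi):
            d = seg[i + 1 : h] - seg[i]
            if d.size:
                idx = np.minimum((d / ACG_BIN_S).astype(int), n_lags - 1)
                np.add.at(hist, idx, 1.0)
    return hist / max(n_spikes, 1)


def spike_train_features(rec: SpikeTrainRecording) -> SpikeFeatureSet:
    """Spontaneous firing rate, CV, burst index, ISI histogram, and the two
    autocorrelogram ranges for one neuron."""
    isi_list, spont_dur, n_spikes = _segment_isis(rec)
    if n_spikes < 2 or not isi_list:
        raise InsufficientDataError(
            f"{rec.neuron_id}: fewer than 2 spontaneous spikes"
        )
    isis = np.concatenate(isi_list)
    hist, _ = np.histogram(isis, bins=ISI_HIST_BINS, range=(0.0, ISI_HIST_RANGE_S))
    in_range = hist.sum()
    isi_hist = hist / in_range if in_range else hist.astype(float)
    segs = [
        rec.spike_times_s[(rec.spike_times_s >= a) & (rec.spike_times_s < b)]
        for a, b in _spontaneous_segments(rec)
    ]
    acg = _acg(segs, ACG_LONG_LAGS)
    return SpikeFeatureSet(
        neuron_id=rec.neuron_id,
        firing_rate_hz=n_spikes / spont_dur,
        cv=float(isis.std() / isis.mean()),
        burst_index=float(np.mean(isis < BURST_ISI_S)),
        isi_hist=isi_hist,
        acg_500=acg,
        acg_100=acg[:ACG_SHORT_LAGS].copy(),
    )


# ---------------------------------------------------------------------------
# cohort embedding
# ---------------------------------------------------------------------------


def _block_pcs(block: np.ndarray, n_components: int, seed: int):
    from sklearn.decomposition import PCA

    usable = min(n_components, block.shape[0], block.shape[1])
    pca = PCA(n_components=usable, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(block)
    if usable < n_components:
        import warnings

        warnings.warn(
            f"feature block is rank-deficient ({usable} < {n_components} "
            "components); padding with zeros"
        )
        scores = np.hstack(
            [scores, np.zeros((block.shape[0], n_components - usable))]
        )
    return scores, pca


def build_embedding_input(
    features: list[SpikeFeatureSet], seed: int = 0
) -> EmbeddingInput:
    """Assemble the 15-feature matrix: 4 cohort-level PCs of the ISI
    histogram, 4 of each autocorrelogram range, plus rate, CV, burst index;
    each feature z-scored across the cohort."""
    isi = np.stack([f.isi_hist for f in features])
    a500 = np.stack([f.acg_500 for f in features])
    a100 = np.stack([f.acg_100 for f in features])
    pcs_isi, pca_isi = _block_pcs(isi, 4, seed)
    pcs_500, pca_500 = _block_pcs(a500, 4, seed)
    pcs_100, pca_100 = _block_pcs(a100, 4, seed)
    scalars = np.array(
        [[f.firing_rate_hz, f.cv, f.burst_index] for f in features]
    )
    mat = np.hstack([pcs_isi, pcs_500, pcs_100, scalars])
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    mat = (mat - mat.mean(axis=0)) / sd
    names = (
        [f"isi_pc{i+1}" for i in range(4)]
        + [f"acg500_pc{i+1}" for i in range(4)]
        + [f"acg100_pc{i+1}" for i in range(4)]
        + ["firing_rate", "cv", "burst_index"]
    )
    return EmbeddingInput(
        features_15=mat,
        feature_names=names,
        pca_models={"isi": pca_isi, "acg_500": pca_500, "acg_100": pca_100},
    )


def cohort_embedding(
    features: list[SpikeFeatureSet], seed: int = 0, perplexity: float = 30.0
) -> tuple[np.ndarray, EmbeddingInput]:
    """t-SNE embedding of the cohort's 15-feature vectors into 2-D."""
    from sklearn.manifold import TSNE

    if len(features) < 10:
        raise InsufficientDataError("embedding needs at least 10 neurons")
    emb_in = build_embedding_input(features, seed=seed)
    perp = min(perplexity, (len(features) - 1) / 3)
    coords = TSNE(
        n_components=2, perplexity=perp, random_state=seed, init="pca"
    ).fit_transform(emb_in.features_15)
    return coords, emb_in


# ---------------------------------------------------------------------------
# foot-shock classification
# ---------------------------------------------------------------------------


def fs_modulation_index(fr_stimulus: float, fr_baseline: float) -> float:
    """(FR_stim - FR_base) / (FR_stim + FR_base); 0 when both rates are 0
    (degenerate case, flagged by the caller)."""
    if fr_stimulus < 0 or fr_baseline < 0:
        raise ValueError("firing rates must be nonnegative")
    denom = fr_stimulus + fr_baseline
    if denom == 0:
        return 0.0
    return (fr_stimulus - fr_baseline) / denom


def _rank_test(x: np.ndarray, y: np.ndarray, paired: bool) -> float:
    """Two-sided rank test p-value with mid-rank tie handling; p = 1 when the
    samples cannot differ (all values tied)."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    if paired:
        d = y - x
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(x, y, zero_method="zsplit").pvalue)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def classify_fs_response(
    rec: SpikeTrainRecording, cfg: AnalysisConfig | None = None
) -> FSResponse:
    """Classify a neuron as foot-shock excited / inhibited / non-modulated.

    Per-trial spike counts in the 1 s before and after each shock onset are
    compared with a two-sided rank-sum test; class requires p <= alpha and a
    consistent direction of the window-mean rates.  Neurons with 20 or fewer
    stimulation trials are excluded.
    """
    cfg = cfg or AnalysisConfig()
    if rec.n_fs_trials <= MIN_FS_TRIALS:
        raise ExclusionError(
            f"{rec.neuron_id}: {rec.n_fs_trials} foot-shock trials "
            f"(need more than {MIN_FS_TRIALS})"
        )
    s = rec.spike_times_s
    on = rec.fs_event_times_s
    base = (np.searchsorted(s, on) - np.searchsorted(s, on - 1.0)).astype(float)
    stim = (np.searchsorted(s, on + 1.0) - np.searchsorted(s, on)).astype(float)
    fr_b, fr_s = float(base.mean()), float(stim.mean())  # 1-s windows -> Hz
    p = _rank_test(base, stim, cfg.paired_test)
    if p <= cfg.alpha and fr_s > fr_b:
        klass = Klass.EXCITED
    elif p <= cfg.alpha and fr_s < fr_b:
        klass = Klass.INHIBITED
    else:
        klass = Klass.NON_RESPONSIVE
    return FSResponse(
        neuron_id=rec.neuron_id,
        fr_baseline_hz=fr_b,
        fr_stimulus_hz=fr_s,
        per_trial_counts=np.column_stack([base, stim]),
        p_value=p,
        klass=klass,
        modulation_index=fs_modulation_index(fr_s, fr_b),
        degenerate=(fr_s + fr_b == 0),
    )


def rate_modulation_correlation(
    responses: list[FSResponse], features: list[SpikeFeatureSet]
) -> tuple[float, float]:
    """Pearson correlation between spontaneous firing rate and foot-shock
    modulation index across the cohort, with its two-sided p-value."""
    if len(responses) < 3 or len(responses) != len(features):
        raise InsufficientDataError(
            "need matched rate/modulation values for at least 3 neurons"
        )
    rates = np.array([f.firing_rate_hz for f in features])
    mods = np.array([r.modulation_index for r in responses])
    if np.ptp(rates) == 0 or np.ptp(mods) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(rates, mods)
    return float(r), float(p)
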