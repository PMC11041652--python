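# lhbpipe

Analysis pipeline for cue–punishment Pavlovian conditioning recordings of
the lateral habenula (LHb), with a matched synthetic-data generator.

In the underlying experimental design, head-fixed mice learn that one
auditory cue (CS+) predicts an aversive airpuff to the eye while a second
cue (CS−) does not. The LHb's contribution to this learning is probed with
four recording modalities, each with its own quantitative pipeline:

1. **Single-unit electrophysiology** (anesthetized, foot-shock stimulation):
   spontaneous spike-train featurization (firing rate, CV, burst index,
   ISI histogram, autocorrelograms), a 15-feature t-SNE embedding,
   foot-shock excited/inhibited classification by rank-sum test on
   per-trial counts, and the bounded modulation index
   (FR_stim − FR_base)/(FR_stim + FR_base).
2. **Two-photon calcium imaging** (awake, longitudinal): trial-wise
   ΔF/F0 = 100·(F − F0)/F0, AUC-window response classification
   (1.5-s pre-cue baseline vs. 1.5-s anticipatory window), and a 2×3
   χ² contingency of response classes across learning phases.
3. **Behavior**: eye-area traces normalized to the 5-s pre-cue baseline,
   conditioned-response (CR) amplitude over [0, 1.5) s, and the
   discrimination score (CS− mean CR − CS+ mean CR).
4. **Per-neuron eyeblink decoding**: an RBF-kernel SVM predicts low- vs.
   high-blink trials (session-wise 40th/60th CR percentiles, dead band
   excluded) from the neuron's cue-window AUC, against a label-shuffle null.
5. **Fiber photometry** of neurotransmitter sensors (Glu, GABA, 5-HT, ACh):
   photon-count smoothing, ΔF/F0 transients, a baseline-±2 SD epoch
   validity rule, 5-trial binned peak responses, and a cue × bin ANOVA for
   the cue main effect.

Because raw recordings of this kind are rarely redistributable, the package
ships a first-class synthetic-data module that plants the statistical
structure each stage assumes (task schedules, rate-coupled foot-shock
responses, calcium plasticity, learning-dependent eyeblink, stable vs.
potentiating sensors), with ground-truth tables for every cohort.

## Worked example

```python
import lhbpipe as lp

# a synthetic cohort of foot-shock-stimulated neurons
params = lp.SpikeCohortParams(n_neurons=200, coupling_rho=-0.5, seed=1)
recs, truth = lp.generate_spike_cohort(params)

feats = [lp.spike_train_features(r) for r in recs]
resps = [lp.classify_fs_response(r) for r in recs]
n_exc = sum(r.klass is lp.Klass.EXCITED for r in resps)
n_inh = sum(r.klass is lp.Klass.INHIBITED for r in resps)
r, p = lp.rate_modulation_correlation(resps, feats)
print(f"excited {n_exc}, inhibited {n_inh}, rate/modulation r={r:.2f} (p={p:.1e})")
```

prints

```
excited 137, inhibited 41, rate/modulation r=-0.22 (p=1.4e-03)
```

i.e. most planted-excited neurons are recovered, and the spontaneous firing
rate anticorrelates with the foot-shock modulation index — excitation is
more common in low-firing neurons, inhibition in high-firing ones, as
planted through the generator's copula coupling.

A thin CLI wraps the same functions, e.g.
`lhbpipe simulate --out data/ --seed 1` followed by
`lhbpipe classify-fs --spikes data/ --out fs_table.csv`.

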