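# coldstate

Analysis pipeline for studying **cold-induced energy compensation (CIEC)** in
mice: when the ambient temperature drops, energy expenditure rises
immediately, but food intake catches up only hours later, and the animals
alternate between conserving energy (staying immobile) and seeking food.
`coldstate` implements the computational side of this phenotype for
behavioural neuroscientists and metabolic physiologists:

1. **Behavioural-state segmentation.** Home-cage behaviour, annotated every
   second into a 15-action vocabulary (sitting, shivering, eating, walking,
   bedding retrieval, ...), is modelled with a three-state categorical hidden
   Markov model. With observations $o_{1:T}$, transition matrix $A$, emission
   matrix $B$ and initial distribution $\pi$, the model is fitted by
   multi-sequence Baum–Welch EM and decoded with the Viterbi algorithm; the
   fitted states are mapped to semantic labels — state 1 *energy
   conservation*, state 2 *exploration with feeding*, state 3 *exploration
   without feeding* — from their emission profiles.
2. **State metrics.** Occupancy fractions, bout tables, transition counts
   (outbound transitions from the energy-conserving state in particular) and
   transition-entry times that serve as photometry event markers; plus
   real-time place-preference (RTPP) side fractions and open-field
   centre-zone metrics (centre zone = concentric square holding 40% of the
   arena area).
3. **Fibre photometry.** Two-channel recordings (470 nm calcium signal,
   410 nm calcium-independent reference) are converted to
   $\Delta F/F = (F_{470} - \hat F)/\hat F$ where $\hat F$ is the
   least-squares prediction of the signal channel from the reference, which
   cancels shared motion artifact and photobleaching. Segments aligned to
   feeding onsets (−20 to +10 s) or state-transition times (−10 to +10 s)
   are summarised by trapezoidal AUC and signed peak $\Delta F/F$.
4. **Indirect calorimetry.** Energy expenditure from the abbreviated Weir
   equation, $\mathrm{EE}\ (\mathrm{kcal/h}) = 60\,(3.941\,\dot V_{O_2} +
   1.106\,\dot V_{CO_2})/1000$ with flows in ml/min; hourly binning of EE and
   intake (diet energy density 3.56 kcal/g, 20-mg pellets); a sliding-window
   Pearson correlation $r(h)$ between pooled hourly EE and intake; and
   detection of the CIEC onset as the earliest hour at which $r$ reaches a
   threshold and stays above it.

Because the corresponding experimental datasets are not publicly deposited,
the package ships a first-class `synthetic_data` module that generates every
input kind (ethograms from a known chain, photometry with programmed
transients, calorimetry with a programmed coupling onset, RTPP trajectories
with a target preference) together with its ground truth, so every stage is
testable end to end.

## Worked example

```python
import numpy as np
from coldstate.ethogram import encode_observations
from coldstate import hmm, state_metrics as sm, calorimetry as calo
from coldstate.synthetic_data import (EthogramGenConfig, simulate_ethogram,
                                      CalorimetryGenConfig, simulate_calorimetry)

# --- behavioural-state segmentation on three 180-min ethograms
cfg = EthogramGenConfig(seed=1)
ethograms, truth = simulate_ethogram(cfg)
obs = [encode_observations(e) for e in ethograms]
fit = hmm.baum_welch_fit(hmm.init_params(3, jitter=0.3, seed=1), obs)
labels = hmm.assign_semantic_labels(fit.params)
states = hmm.relabel(hmm.viterbi_decode(fit.params, obs[0])[0], labels)
occ = sm.occupancy_fractions(states)
tc = sm.transition_counts(states)
print(f"EM iterations: {fit.n_iter} (converged={fit.converged})")
print("occupancy:", {k: round(v, 3) for k, v in occ.fractions.items()})
print("outbound transitions from state 1:", tc.outbound[1],
      f"(1->2: {tc.count(1, 2)}, 1->3: {tc.count(1, 3)})")
print(f"decoding accuracy vs ground truth: "
      f"{np.mean(states.states == truth[0].states):.3f}")

# --- coupling onset from 24 simulated calorimetry cages
series, gt = simulate_calorimetry(CalorimetryGenConfig(seed=1))
pooled = calo.pool_hourly([calo.hourly_bin(s, gt["cold_onset_min"]) for s in series])
profile = calo.ee_intake_correlation_profile(pooled, window_h=1)
onset = calo.detect_ciec_onset(profile, threshold=0.5)
print(f"EE-intake coupling onset: {onset.onset_h} h after cold onset "
      f"(programmed: {gt['coupling_onset_h']:.0f} h)")
```

Output:

```
EM iterations: 9 (converged=True)
occupancy: {1: 0.323, 2: 0.362, 3: 0.315}
outbound transitions from state 1: 163 (1->2: 96, 1->3: 67)
decoding accuracy vs ground truth: 0.990
EE-intake coupling onset: 6 h after cold onset (programmed: 5 h)
```

The occupancy fractions are the decoded analogue of "percentage of time in
each state"; the outbound counts from state 1 are the quantity compared
across experimental manipulations; the detected onset sits one hour after
the programmed coupling onset because the ±1-h correlation window only fills
with coupled hours once the onset has fully passed.

A command-line interface mirrors the library
(`coldstate simulate|ethogram|hmm|metrics|photometry|calo ...`); run
`coldstate --help` for the command tree.

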