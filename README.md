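# gaitintent

Offline intent recognition for lower-limb assistive-device control from
**bilateral** neuromechanical signals — and a synthetic gait-signal
generator to drive it.

Powered prostheses, orthoses and exoskeletons must predict the user's next
locomotor activity *before* the step begins. The standard framework
extracts a 300 ms signal window before each heel-contact (HC) or toe-off
(TO) gait event and classifies the upcoming mode — level walking (LW),
ramp ascent/descent (RA/RD), stair ascent/descent (SA/SD) — with one
classifier per (leg × event × incoming mode), each restricted to the
legal transitions from its incoming mode (from LW: all five modes; from
any other mode: stay, or return to LW). Almost all deployed systems use
only the instrumented (ipsilateral) leg. This package implements the full
pipeline needed to ask, on synthetic data with known ground truth, what
the *contralateral* leg adds:

* `gaitintent.synth` — bilateral multi-rate signal generator (7 EMG
  channels/leg at 1 kHz; knee/ankle goniometers and thigh/shank 6-axis
  IMUs at 500 Hz) with harmonic gait-cycle templates, mode transitions
  with leading/trailing-leg asymmetry, and exact ground-truth events;
* `gaitintent.preprocess` — causal Butterworth conditioning (20 Hz
  high-pass + 60/180/300 Hz notches for EMG; 10/25 Hz low-pass for
  goniometer/IMU) and derived joint velocities (46 channels bilaterally);
* `gaitintent.events` — dual-minima gait segmentation: mid-swing peaks of
  the sagittal shank angular velocity, with TO/HC as the flanking minima;
* `gaitintent.features` — per-event windows and the classical feature
  sets: 10 per EMG channel (MAV, waveform length, zero crossings, slope
  sign changes, AR(6) coefficients via Burg) and 6 per mechanical channel
  (mean, SD, max, min, first, last) — 166 features per side, 332
  bilaterally;
* `gaitintent.classify` — the 20-cell mode-specific classifier bank
  (LDA + PCA-95% by default; linear SVM and MLP backends), k-fold
  cross-validation, steady-state/transitional error accounting;
* `gaitintent.select` — sequential forward selection of contralateral
  sensors from the all-ipsilateral baseline;
* `gaitintent.report` — the modality × laterality × backend comparison
  grid, replicate-seeded studies, paired t and sign tests.

## Worked example

Simulate one "subject" (both standard circuits, LW–SA–LW–RD–LW and
LW–RA–LW–SD–LW, 8 repetitions), run the full pipeline, and compare
ipsilateral (I) with bilateral (B) fused sensor sets:

```python
from gaitintent.report import run_session
from gaitintent.features import laterality_view
from gaitintent.classify import ClassifierConfig, cross_validate

session = run_session(seed=0, n_strides=4, reps=8)
print(f"decisions: {session.dataset.n_events}, features: {session.dataset.n_features}")
print(f"events matched to ground truth: {session.n_matched_events}/{session.n_detected_events}")
for lat in ("I", "B"):
    view = laterality_view(session.dataset, lat, "all")
    rep = cross_validate(view, ClassifierConfig(seed=0), k=10, seed=0)
    print(f"{lat}: {view.n_features} features | overall {100*rep.overall:.2f}% | "
          f"steady-state {100*rep.steady_state:.2f}% | transitional {100*rep.transitional:.2f}%")
```

prints

```
decisions: 1136, features: 332
events matched to ground truth: 1216/1216
I: 166 features | overall 2.39% | steady-state 0.00% | transitional 28.30%
B: 332 features | overall 1.86% | steady-state 0.00% | transitional 22.84%
```

Every detected gait event matched the generator's ground truth; with only
the event-side leg's 166 features the bank mispredicts 2.4% of decisions
(28% of the rare transitional ones), and fusing both legs' sensors cuts
both figures — the contralateral leg has already committed to the new
terrain half a stride before the trailing leg's transitional decision, so
it carries exactly the information the ipsilateral window lacks.

The same pipeline is scriptable from the shell:

```sh
gaitintent simulate --circuit 1 --strides 4 --delta 1 --noise 0.25 --seed 0 --out trial/
gaitintent preprocess --in trial/ --out processed/
gaitintent segment --in trial/ --out events.csv
gaitintent featurize --in processed/ --events events.csv --out features/
gaitintent evaluate --features features/ --laterality B --k 10 --seed 0 --report report.json
gaitintent run-experiment --seeds 0,1,2 --out results/
```

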