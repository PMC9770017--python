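# quadgait

Analysis of whole-body responses to a cutaneous perturbation of one hindlimb
during quadrupedal treadmill locomotion — and a synthetic session generator
to validate every step of that analysis.

## The problem

When the dorsum of a cat's hind paw meets an obstacle, cutaneous afferents
(superficial peroneal nerve) trigger coordinated corrections in **all four
limbs**, and the correction depends strongly on *when* in the step cycle the
input arrives: a stimulus during swing evokes limb elevation (the stumbling
*corrective* reaction), the same stimulus during stance reinforces support
(the stumbling *preventive* reaction). Experiments probe this by stimulating
the nerve with a short train at four phases of the ipsilateral hindlimb
cycle — mid-stance, stance-to-swing, mid-swing, swing-to-stance — while the
animal walks on a treadmill, and comparing three consecutive cycles: the
**control** cycle before the stimulus, the **stimulated** cycle, and the
first **post** cycle.

`quadgait` implements the full measurement chain from raw marker
trajectories (60 Hz), multi-channel EMG (5000 Hz) and stimulus times to the
per-phase effect tables:

* **Gait events** — stance onset (paw contact from toe height, refined to
  sub-frame precision) and stance offset (most caudal toe excursion); cycles
  between successive onsets with `cycle = stance + swing` exactly.
* **Phase classification** — each stimulus is placed in its ipsilateral
  cycle and classified by normalized sub-phase fraction: mid-phases use
  centred 40% windows, transitions ±10%; anything else is excluded.
* **Cycle triads** — control/stimulated/post cycles for all four limbs
  (ipsilateral and contralateral hindlimbs, homolateral and diagonal
  forelimbs), with collision and completeness checks.
* **Spatiotemporal metrics** — support-period decomposition (maximal
  intervals of constant limb support: 4 doubles, 4 triples, quadrupedal —
  nine categories; a canonical walk shows eight periods per cycle), step
  length `|x_lead − x_trail|` at the leading limb's contact, stride length
  `|x(onset) − x(offset)| + v_belt · t_swing`, joint angles
  (hip/knee/ankle) and maximal marker heights.
* **EMG** — zero-phase 30–1000 Hz band-pass, envelope, double-threshold
  burst detection, burst duration and mean rectified amplitude normalized
  to the control-cycle burst (control ≡ 100%).
* **Statistics** — per-animal triad means → animals × (control, stim, post)
  matrices; Friedman rank test across the three cycles (animals as blocks),
  Bonferroni-adjusted Wilcoxon post hoc vs control, Shapiro–Wilk reported;
  percent changes are per-animal vs own control, then averaged.

Because the underlying animal recordings are not publicly deposited, the
package ships a first-class **synthetic session generator**
(`quadgait.synthetic`): footfall schedules, forward-kinematic marker
trajectories, phase-gated EMG, and stimulus injection that regenerates the
affected cycles with configurable effect sizes. The shipped
`paper_effects.yaml` encodes the published group effect sizes (e.g. +23.5%
ipsilateral swing at mid-swing, +279.2% contra–homo diagonal support at
stance-to-swing, +251% ipsilateral semitendinosus amplitude), so the whole
pipeline can be validated by parameter recovery.

## Worked example

```python
from quadgait.io_core import SessionConfig
from quadgait.synthetic import generate_session
from quadgait.pipeline import analyze_session, recovered_percent_changes

cfg = SessionConfig(seed=1)              # 7 animals, 10 stimuli/phase
sess = generate_session(cfg, with_emg=True, emg_muscles=("ST",))
ana = analyze_session([(r.markers, r.stimuli, r.emg) for r in sess.animals],
                      belt_speeds=[r.params.belt_speed for r in sess.animals])
for name, (value, n) in recovered_percent_changes(ana.metrics).items():
    print(f"{name:40s} {value:+8.2f}%  (n={n})")
```

prints (values are group percent changes of the stimulated vs control cycle):

```
ipsi_swing_mid_swing                       +23.10%  (n=7)
ipsi_cycle_mid_swing                        +6.00%  (n=7)
ipsi_swing_stance_to_swing                 +13.72%  (n=7)
contra_swing_mid_stance                     +5.15%  (n=7)
homo_swing_swing_to_stance                 -10.31%  (n=7)
contra_homo_support_mid_swing              +48.11%  (n=7)
contra_homo_support_stance_to_swing       +280.64%  (n=7)
ipsi_toe_height_stance_to_swing           +354.61%  (n=7)
contra_step_length_mid_swing               -13.35%  (n=7)
ipsi_st_amplitude_stance_to_swing         +255.22%  (n=6)
```

i.e. the analysis recovers the injected effect sizes (+23.5%, +13.7%,
+5.1%, −10.5%, +49.3%, +279.2%, +358.4%, −13.3%, +251.0%) to within the
sampling noise of a 7-animal session. The semitendinosus (ST) row uses
n = 6 animals because that muscle is recorded in six of the seven.

A `quadgait` command-line tool wraps the same pipeline
(`simulate`, `detect-events`, `analyze`, `stats`, `report`); see
`quadgait --help`.

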