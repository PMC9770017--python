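# Phase-specific perturbation profiles: the published group effect sizes of
# superficial peroneal nerve stimulation during quadrupedal treadmill
# locomotion, expressed as stimulated/control ratios. These are the default
# study conditions of the synthetic session generator; the analysis pipeline
# is expected to recover them.
mid_stance:
  swing_multiplier: {contra_hind: 1.051}      # contralateral swing +5.1%
  emg_duration_gain: {homo_fore/BB: 0.934}    # homolateral BB duration -6.6%
stance_to_swing:
  swing_multiplier: {ipsi_hind: 1.137}        # ipsilateral swing +13.7%
  stance_multiplier: {contra_hind: 1.028}     # contralateral stance +2.8%
  cycle_multiplier: {contra_hind: 1.026}      # contralateral cycle +2.6%
  toe_height_gain: 4.584                      # ipsilateral max toe height +358.4%
  support_gain_contra_homo: 3.792             # contra-homo diagonal support +279.2%
  min_angle_multiplier: {knee: 0.708, ankle: 0.848}  # peak flexion -29.2% / -15.2%
  emg_amplitude_gain:
    ipsi_hind/ST: 3.510                       # +251.0%
    ipsi_hind/BFP: 3.434                      # +243.4%
    ipsi_hind/SRT: 1.130                      # +13.0%
  emg_duration_gain:
    ipsi_hind/BFP: 1.319                      # +31.9%
    ipsi_hind/ST: 1.331                       # +33.1%
mid_swing:
  swing_multiplier: {ipsi_hind: 1.235}        # ipsilateral swing +23.5%
  cycle_multiplier: {ipsi_hind: 1.060}        # ipsilateral cycle +6.0%
  toe_height_gain: 3.313                      # ipsilateral max toe height +231.3%
  support_gain_contra_homo: 1.493             # contra-homo double support +49.3%
  step_length_ratio: {contra_hind: 0.867}     # contralateral step length -13.3%
  min_angle_multiplier: {knee: 0.839, ankle: 0.812}  # peak flexion -16.1% / -18.8%
  emg_amplitude_gain:
    ipsi_hind/BFP: 1.783                      # +78.3%
    contra_hind/BFP: 1.208                    # +20.8%
    contra_hind/ST: 1.314                     # +31.4%
    contra_hind/VL: 1.155                     # +15.5%
    ipsi_hind/SRT: 1.136                      # +13.6%
    diag_fore/ECU: 1.164                      # +16.4%
  emg_duration_gain:
    ipsi_hind/SRT: 1.299                      # +29.9%
    ipsi_hind/BFP: 1.433                      # +43.3%
    contra_hind/VL: 1.101                     # +10.1%
    contra_hind/LG: 1.073                     # +7.3%
    contra_hind/SOL: 1.056                    # +5.6%
    contra_hind/SRT: 0.945                    # -5.5%
swing_to_stance:
  swing_multiplier: {homo_fore: 0.895}        # homolateral forelimb swing -10.5%
  emg_amplitude_gain:
    contra_hind/SRT: 1.070                    # +7.0%
    contra_hind/ST: 1.533                     # +53.3%
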