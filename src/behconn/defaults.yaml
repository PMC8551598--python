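# Default synthetic-cohort configuration.
#
# These are SYNTHETIC defaults for testing and demonstration: the behavioural
# profile means mirror the qualitative shape of the three data-driven profiles
# (C1 conduct/hyperactivity/peer problems, C2 inattention/executive function,
# C3 learning problems) against a typically-developing comparison group with
# all scales at the T-score population mean of 50. They are generator
# parameters, not estimates from any cohort.

groups: [comparison, C1, C2, C3]
n_per_group: 50
scale_names: [Inattention, Hyperactivity, Learning, ExecutiveFunction, Aggression, PeerRelations]
group_profile_means:
  comparison: [50, 50, 50, 50, 50, 50]
  C1: [62, 70, 58, 60, 72, 68]
  C2: [72, 58, 60, 70, 52, 55]
  C3: [55, 50, 75, 52, 52, 54]
behaviour_noise_sd: 5.0
tscore_range: [10, 90]

n_regions: 100
n_timepoints: 266          # 270 volumes acquired, first 4 discarded
icn_labels: [visual, somatomotor, dorsal_attention, ventral_attention,
             fronto_parietal, default_mode, limbic, subcortical]
base_block_covariance:
  within_icn: 0.30
  between_icn: 0.10
  variance: 1.0
# (icn_a, icn_b, additive covariance delta, groups affected)
group_effect:
  - [limbic, dorsal_attention, 0.15, [C2]]
  - [default_mode, default_mode, 0.10, [C1]]
  - [subcortical, default_mode, 0.12, [C3]]

covariate_model:
  age_range: [5.0, 15.0]   # years
  p_female: 0.31
  fd_median: 0.15          # mm, per-subject log-normal baseline
  fd_sigma: 0.35           # log-sd of the between-subject baseline
  fd_within_sigma: 0.30    # log-sd of per-volume variation around baseline
  spike_prob: 0.02         # probability a volume is a motion spike
  spike_extra: [0.4, 1.2]  # uniform FD increment (mm) added on spike volumes
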