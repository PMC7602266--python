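"""Windowed EMG feature extraction on one synthetic trial.

Builds a single 3 s, 8-channel trial, computes the ten per-channel features on
the full 600-sample window, and prints channel 0's values. Amplitude features
(MAV/STD/RMS/LOG/AAC) are in the signal's arbitrary units; spectral locations
(MNF/MDF/PKF) are in Hz; PSR is a unitless ratio in (0, 1].
"""

from emgsign.features import FeatureConfig, extract_features
from emgsign.synthetic import EmgCohortConfig, generate_emg_cohort

trials, _ = generate_emg_cohort(EmgCohortConfig(n_subjects=1, n_motions=1, n_trials=1, seed=0))
series = extract_features(trials[0], FeatureConfig())

print(f"trial: subject={series.subject_id} motion={series.motion_label} "
      f"windows x channels x features = {series.values.shape}")
for name, value in zip(series.feature_names, series.values[0, 0]):
    print(f"  {name:>4}: {value:10.4f}")
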