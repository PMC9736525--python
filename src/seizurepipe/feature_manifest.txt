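hrv_mean
hrv_median
hrv_mode
hrv_std
hrv_var
hrv_abs_dev
hrv_p25
hrv_p75
hrv_iqr
hrv_kurtosis
hrv_skewness
hrv_geometric_mean
hrv_harmonic_mean
hrv_median_diff
hrv_nn50
hrv_rmssd
ptt_mean
ptt_median
ptt_mode
ptt_std
ptt_var
ptt_abs_dev
ptt_p25
ptt_p75
ptt_iqr
ptt_kurtosis
ptt_skewness
ptt_geometric_mean
ptt_harmonic_mean
ptt_median_diff
ptt_nn50
ptt_rmssd
hrv_vlf
hrv_lf
hrv_hf
hrv_tp
hrv_plf
hrv_phf
hrv_lf_hf
eeg1_mean
eeg1_median
eeg1_mode
eeg1_std
eeg1_var
eeg1_abs_dev
eeg1_p25
eeg1_p75
eeg1_iqr
eeg1_kurtosis
eeg1_skewness
eeg1_harmonic_mean
eeg1_mean_power
eeg1_max_power
eeg1_freq_at_max_power
eeg1_median_entropy
eeg1_max_entropy
eeg1_min_entropy
eeg2_mean
eeg2_median
eeg2_mode
eeg2_std
eeg2_var
eeg2_abs_dev
eeg2_p25
eeg2_p75
eeg2_iqr
eeg2_kurtosis
eeg2_skewness
eeg2_harmonic_mean
eeg2_mean_power
eeg2_max_power
eeg2_freq_at_max_power
eeg2_median_entropy
eeg2_max_entropy
eeg2_min_entropy
eeg3_mean
eeg3_median
eeg3_mode
eeg3_std
eeg3_var
eeg3_abs_dev
eeg3_p25
eeg3_p75
eeg3_iqr
eeg3_kurtosis
eeg3_skewness
eeg3_harmonic_mean
eeg3_mean_power
eeg3_max_power
eeg3_freq_at_max_power
eeg3_median_entropy
eeg3_max_entropy
eeg3_min_entropy
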