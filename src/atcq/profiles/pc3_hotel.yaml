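# PC3 prostate cancer cells in the microfluidic cell hotel, full serum.
# Venus onset ~2 h after cytokinesis, Cherry ~2 h later; cycling cells
# degrade Venus within ~4 h of Cherry onset; 27.5% of post-mitotic cells
# exceed the 14 h double-positive threshold; 30% of daughter pairs decide
# asynchronously with G1-entry deltas of 1-6 h.
name: pc3_hotel
founder_mode: asynchronous
founder_spread_h: 30.0
venus_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
cherry_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
dp_dwell_transient: {dist: uniform, low: 2.5, high: 5.5}
dp_dwell_prolonged: {dist: shifted_expon, shift: 15.0, scale: 8.0}
g1_duration: {dist: uniform, low: 8.0, high: 12.0}
sgm_duration: {dist: uniform, low: 10.0, high: 14.0}
pair_fate_probs: {sync_g0: 0.275, sync_g1: 0.425, async: 0.30}
async_delta: {dist: uniform, low: 1.0, high: 6.0}
p_spontaneous_g0: 0.275
venus_rise_h: 3.0
cherry_rise_h: 3.0
venus_fall_h: 3.0
cherry_fall_h: 3.0
p_reporter_silent: 0.0
motility_sigma: 0.4
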