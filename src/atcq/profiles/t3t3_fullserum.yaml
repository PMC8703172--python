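# NIH/3T3 fibroblasts, full serum. Venus onset 2-4 h after cytokinesis,
# Cherry 3-4 h later; transient double-positive dwell 5-10 h; 64.4% of
# post-mitotic cells exceed the 14 h threshold; 30% of pairs asynchronous
# with deltas 1-15 h. p_sync_g0 is calibrated so that the per-cell marginal
# P(dwell > 14 h) = p_sync_g0 + 0.5 * p_async * P(d + delta > 14) equals
# p_spontaneous_g0 (overlap probability 0.60714 for U[5,10] + U[1,15]).
name: t3t3_fullserum
founder_mode: asynchronous
founder_spread_h: 30.0
venus_onset_delay: {dist: uniform, low: 2.0, high: 4.0}
cherry_onset_delay: {dist: uniform, low: 3.0, high: 4.0}
dp_dwell_transient: {dist: uniform, low: 5.0, high: 10.0}
dp_dwell_prolonged: {dist: shifted_expon, shift: 15.0, scale: 10.0}
g1_duration: {dist: uniform, low: 4.0, high: 8.0}
sgm_duration: {dist: uniform, low: 8.0, high: 12.0}
pair_fate_probs: {sync_g0: 0.5529286, sync_g1: 0.1470714, async: 0.30}
async_delta: {dist: uniform, low: 1.0, high: 15.0}
p_spontaneous_g0: 0.644
motility_sigma: 0.4
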