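# PC3 + Gas6 treatment preset: more synchronous G0 entry among daughter
# pairs, longer transient G0 dwells, larger asynchrony deltas, and fewer
# founders committing to division (founder_p_g0 override). p_spontaneous_g0
# is the calibrated daughter marginal (0.55 + 0.15 * 0.6538462).
name: pc3_gas6
founder_mode: asynchronous
founder_spread_h: 30.0
venus_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
cherry_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
dp_dwell_transient: {dist: uniform, low: 5.0, high: 10.0}
dp_dwell_prolonged: {dist: shifted_expon, shift: 15.0, scale: 12.0}
g1_duration: {dist: uniform, low: 8.0, high: 12.0}
sgm_duration: {dist: uniform, low: 10.0, high: 14.0}
pair_fate_probs: {sync_g0: 0.55, sync_g1: 0.15, async: 0.30}
async_delta: {dist: uniform, low: 2.0, high: 15.0}
p_spontaneous_g0: 0.6480769
founder_p_g0: 0.65
motility_sigma: 0.4
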