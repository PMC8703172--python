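# NIH/3T3 under serum starvation: trajectories collapse into prolonged G0.
name: t3t3_lowserum
founder_mode: asynchronous
founder_spread_h: 30.0
venus_onset_delay: {dist: uniform, low: 2.0, high: 4.0}
cherry_onset_delay: {dist: uniform, low: 3.0, high: 4.0}
dp_dwell_transient: {dist: uniform, low: 5.0, high: 10.0}
dp_dwell_prolonged: {dist: shifted_expon, shift: 15.0, scale: 25.0}
g1_duration: {dist: uniform, low: 4.0, high: 8.0}
sgm_duration: {dist: uniform, low: 8.0, high: 12.0}
pair_fate_probs: {sync_g0: 0.8696429, sync_g1: 0.0303571, async: 0.10}
async_delta: {dist: uniform, low: 1.0, high: 15.0}
p_spontaneous_g0: 0.90
motility_sigma: 0.4
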