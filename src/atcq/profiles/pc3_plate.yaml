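# PC3 cells imaged on a plate: same reporter kinetics as the cell hotel but
# a lower spontaneous-G0 fraction (20%) and higher motility.
name: pc3_plate
founder_mode: asynchronous
founder_spread_h: 30.0
venus_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
cherry_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
dp_dwell_transient: {dist: uniform, low: 2.5, high: 5.5}
dp_dwell_prolonged: {dist: shifted_expon, shift: 15.0, scale: 8.0}
g1_duration: {dist: uniform, low: 8.0, high: 12.0}
sgm_duration: {dist: uniform, low: 10.0, high: 14.0}
pair_fate_probs: {sync_g0: 0.20, sync_g1: 0.50, async: 0.30}
async_delta: {dist: uniform, low: 1.0, high: 6.0}
p_spontaneous_g0: 0.20
motility_sigma: 0.8
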