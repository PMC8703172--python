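# Serum-free cohort seeded from sorted S/G2/M (double-negative) cells.
# Founders are past the restriction point: they finish the cycle, divide,
# and both daughters arrest in a double-positive G0. 15% of clones are
# reporter-silent, so ~85% of cells are double positive at 72 h.
name: serumfree_from_sgm
founder_mode: sgm_arrest
founder_spread_h: 0.0
venus_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
cherry_onset_delay: {dist: uniform, low: 1.5, high: 2.5}
dp_dwell_transient: {dist: uniform, low: 2.5, high: 5.5}
dp_dwell_prolonged: {dist: shifted_expon, shift: 15.0, scale: 30.0}
g1_duration: {dist: uniform, low: 8.0, high: 12.0}
sgm_duration: {dist: uniform, low: 1.0, high: 12.0}
pair_fate_probs: {sync_g0: 1.0, sync_g1: 0.0, async: 0.0}
async_delta: {dist: uniform, low: 1.0, high: 6.0}
p_spontaneous_g0: 1.0
p_reporter_silent: 0.15
motility_sigma: 0.4
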