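# ltrmir scan configuration (defaults, spelled out)
# Any key may be omitted; CLI flags override file values.

# window sweep (nt)
window_min = 100
window_max = 140
window_step = 5

# dumbbell acceptance
mfe_max = -30.0
min_arm_stem_bp = 8
min_basal_helix_bp = 0
min_paired_fraction = 0.5
single_hairpin_mode = false

# Pol III elements
tata_consensus = TATAWAW
tata_max_mismatch = 0
abox_consensus = TRGCNNARYNNG
abox_max_mismatch = 1
bbox_consensus = GTTCRANNC
bbox_max_mismatch = 1
term_min_run = 4
tata_upstream_min = 15
tata_upstream_max = 40
terminator_downstream = 25
require_terminator = true
require_promoter = true

# scanning
strand = +
backend = builtin
dedup_identical = true
box_count_mode = cassettes
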