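# Default pad-model configuration: every published constant in one place.
# Run e.g.:  frogpad all --config examples/pad.toml --out run1/

[geometry]
length_mm = 1.5            # pad model box, proximal -> distal
width_mm = 1.0             # lateral
height_mm = 0.45           # ventral -> dorsal
hole_diameter_mm = 0.1     # mucus ducts
hole_pitch_mm = 0.14       # centre-to-centre within a row
row_spacing_mm = 0.25      # centre-to-centre between rows
n_rows = 3
holes_per_row = 5
recess_shape = "quarter_cylinder"   # proximal epiphysis of the distal phalanx

[resolution]
nx = 30                    # 0.05 mm voxels; use 60x40x18 for the fine grid
ny = 20
nz = 9

[material]
E_MPa = 20.0               # collagenous tissue
nu = 0.33
sigma_t_MPa = 20.0

[load]
total_force_N = 3.815e-3   # 7 g x 9.81 m/s^2 / 18 digits
face = "proximal"
direction = [-1.0, 0.0, 0.0]

[schedule]
total_reduction = 0.60     # remove 60% of the initial solid volume
step = 0.025               # in 2.5% stages (24 stages)
inner_iters_max = 30
convergence_tol = 0.01

[optimiser]
penalty_p = 3.0
filter_radius_voxels = 1.5
freeze_ventral = true      # removal of the ventral surface prohibited
threshold = 0.5            # STL iso-level

[peel]
attachment_frac = 0.25     # septum ventral attachment, fraction of pad length
inclination_deg = 70.0     # dorsodistal pull above the ventral plane
R_Jm2 = 50.0               # adhesion energy for the Kendall sweep

[budget]
demands = [1.27, 3.815e-3] # single-pad record load; per-digit body weight

[output]
directory = "frogpad_run"
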