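# Default dimensional parameter set (units: cm, day, g, cells).
#
# The simulator's baseline conditions: the Hill-kinetics rate constants and
# mechanical moduli follow the magnitudes established in the continuum
# wound-healing modeling literature; zeta and a_c_III are the reference values
# of the default contracture scenario. delta_N and k_rho are completed at load
# time so that the unwounded dermal equilibrium is an exact fixed point of the
# reaction kinetics (see morphograft.params.derive_equilibrium_parameters).

# --- (myo)fibroblast kinetics -------------------------------------------------
r_F = 0.924          # cell division rate, 1/(day (cells/cm^3)^q)
r_F_max = 2.0        # max division enhancement by the signal, dimensionless
a_c_I = 1.0e-8       # signal conc. at half-max division enhancement, g/cm^3
kappa_F = 1.0e-6     # crowding coefficient, cm^3/cells
q = -0.42            # division exponent, dimensionless
k_F = 3.0e6          # signal-dependent differentiation rate, cm^3/(g day)
delta_N = 0.019124   # fibroblast apoptosis rate, 1/day (completed at load)
delta_M = 6.0e-2     # myofibroblast apoptosis rate, 1/day

# --- cell transport -----------------------------------------------------------
D_F = 1.0e-7         # density-dependent motility coefficient, cm^5/(cells day)
chi_F = 2.0e-3       # chemotactic coefficient, cm^5/(g day)

# --- signaling molecule -------------------------------------------------------
k_c = 4.0e-13        # max net secretion rate, g/(cells day)
eta_I = 2.0          # myo/fibro ratio in secretion, dimensionless
eta_II = 0.5         # myo/fibro ratio in MMP secretion, dimensionless
a_c_II = 1.0e-8      # half-max secretion concentration, g/cm^3
a_c_III = 2.0e8      # MMP-secretion-inhibition coefficient, cm^3/g
a_c_IV = 1.0e-9      # half-max collagen-secretion enhancement conc., g/cm^3
delta_c = 8.0e-4     # signal breakdown rate, cm^6/(cells g day)
D_c = 2.9e-3         # signal diffusion coefficient, cm^2/day

# --- collagen -----------------------------------------------------------------
k_rho = 7.59375e-8   # collagen secretion rate, g/(cells day) (completed at load)
k_rho_max = 10.0     # max secretion enhancement, dimensionless
delta_rho = 6.0e-6   # collagen breakdown rate, cm^6/(cells g day)

# --- mechanics ----------------------------------------------------------------
mu_1 = 1.0e2         # shear viscosity, N day/cm^2
mu_2 = 1.0e2         # bulk viscosity, N day/cm^2
nu = 0.49            # Poisson's ratio, dimensionless
E_I = 3.2e1          # Young's modulus coefficient, N/(cm^2 (g/cm^3)^(1/2))
xi = 4.4e-2          # myofibroblast traction coefficient, N/(cm^2) per (cells/cm^3)(cm^3/g)
R_const = 0.3        # traction saturation constant, g/cm^3
zeta = 9.0e2         # rate of morphoelastic change, cm^6/(cells g day)
rho_t = 1.02         # total tissue mass density, g/cm^3

# --- equilibria and initial conditions ----------------------------------------
N_bar = 1.0e4        # equilibrium fibroblast density, cells/cm^3
M_bar = 0.0          # equilibrium myofibroblast density, cells/cm^3
c_bar = 0.0          # equilibrium signal concentration, g/cm^3
rho_bar = 0.1125     # equilibrium collagen concentration, g/cm^3
c_w = 1.0e-8         # max initial graft signal concentration, g/cm^3
I_w = 0.2            # min initial fibroblast fraction in the graft, dimensionless

# --- graft geometry -----------------------------------------------------------
s1 = 2.5             # graft half-side (boundary location), cm
s2 = 0.10            # blend half-width graft <-> unwounded dermis, cm
theta_r = 0.7853981633974483   # graft rotation angle, rad (pi/4)
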