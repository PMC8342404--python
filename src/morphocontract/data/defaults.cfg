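# Default parameter set of the 1D morphoelastic skin-contraction model.
# Units: see morphocontract.params.ParameterSet.  delta_N and q are tied by
# delta_N = r_F (1 - kappa_F N_bar) N_bar**q with N_bar = 1e4 cells/cm^3.
D_c       = 2.88e-3     # cm^2/day
D_F       = 1e-7        # cm^5/(cells day)
chi_F     = 2e-3        # cm^5/(g day)
k_c       = 4e-13       # g/(cells day)
r_F       = 9.24e-1     # cm^{3q}/(cells^q day)
r_F_max   = 2           # -
k_rho     = 7.6e-8      # g/(cells day)
k_rho_max = 10          # -
a_c_I     = 1e-8        # g/cm^3
a_c_II    = 2e8         # cm^3/g
a_c_III   = 1e-8        # g/cm^3
a_c_IV    = 1e-9        # g/cm^3
eta_I     = 2           # -
eta_II    = 5e-1        # -
k_F       = 1.08e7      # cm^3/(g day)
kappa_F   = 1e-6        # cm^3/cells
# q is a consequence of the other parameters (logistic balance
# delta_N = r_F (1 - kappa_F N_bar) N_bar**q); stored at full precision so
# the equilibrium is an exact fixed point, prints as -4.151e-1 to 4 s.f.
q         = -0.41506929253841877   # -
delta_c   = 5e-4        # cm^6/(cells g day)
delta_N   = 2e-2        # 1/day
delta_M   = 6e-2        # 1/day
delta_rho = 6e-6        # cm^6/(cells g day)
zeta      = 4e2         # cm^6/(cells g day)
rho_t     = 1.09        # g/cm^3
mu        = 1e2         # (N day)/cm^2
E         = 2.1e2       # N/((g cm)^0.5)
xi        = 4.4e-2      # (N g)/(cells cm^2)
R         = 9.95e-1     # g/cm^3
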