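# Default parameter ranges for corpus generation.
#
# The 25 entries flagged `varied: true` are drawn uniformly per simulated
# patient/wound and form the surrogate input vector, in this order.  The
# remaining entries are fixed for every simulation.  Values are
# physiologically plausible magnitudes for human dermis (time in days,
# space in cm, densities in g/cm^3, cells in cells/cm^3); most ranges span
# +/-20% around the nominal, the wound length and the signaling secretion
# rate are varied more widely (the latter so that the stability filter
# k_c < delta_c * rho_bar * a_c_II is genuinely active during sampling).
parameters:
  L:          {min: 1.0,      max: 4.0,      varied: true}   # wound half-length [cm]
  D_c:        {min: 2.32e-3,  max: 3.48e-3,  varied: true}   # signaling diffusivity
  D_F:        {min: 0.8e-7,   max: 1.2e-7,   varied: true}   # cell random walk
  chi_F:      {min: 1.6e-3,   max: 2.4e-3,   varied: true}   # chemotaxis
  k_c:        {min: 2.0e-13,  max: 8.0e-13,  varied: true}   # signaling secretion
  a_c_I:      {min: 0.8e-8,   max: 1.2e-8,   varied: true}   # proliferation saturation
  a_c_II:     {min: 0.8e-8,   max: 1.2e-8,   varied: true}   # secretion saturation
  a_c_III:    {min: 1.6e8,    max: 2.4e8,    varied: true}   # protease inhibition
  a_c_IV:     {min: 0.8e-9,   max: 1.2e-9,   varied: true}   # collagen-secretion saturation
  eta_I:      {min: 1.6,      max: 2.4,      varied: true}   # myofib. collagen secretion weight
  eta_II:     {min: 0.4,      max: 0.6,      varied: true}   # myofib. protease weight
  k_F:        {min: 0.864e7,  max: 1.296e7,  varied: true}   # differentiation rate
  r_F:        {min: 0.739,    max: 1.109,    varied: true}   # proliferation rate
  r_F_max:    {min: 1.6,      max: 2.4,      varied: true}   # max proliferation enhancement
  kappa_F:    {min: 0.8e-6,   max: 1.2e-6,   varied: true}   # crowding
  k_rho_max:  {min: 8.0,      max: 12.0,     varied: true}   # collagen secretion enhancement
  delta_c:    {min: 4.0e-4,   max: 6.0e-4,   varied: true}   # signaling decay
  delta_N:    {min: 0.016,    max: 0.024,    varied: true}   # fibroblast apoptosis
  delta_M:    {min: 0.048,    max: 0.072,    varied: true}   # myofibroblast apoptosis
  delta_rho:  {min: 4.8e-6,   max: 7.2e-6,   varied: true}   # collagen degradation
  mu:         {min: 80.0,     max: 120.0,    varied: true}   # viscosity
  E_stiff:    {min: 25.6,     max: 38.4,     varied: true}   # stiffness scale
  xi:         {min: 0.96e-3,  max: 1.44e-3,  varied: true}   # traction magnitude
  R_traction: {min: 0.24,     max: 0.36,     varied: true}   # traction collagen saturation
  zeta:       {min: 120.0,    max: 180.0,    varied: true}   # plasticity rate

  # fixed parameters
  rho_t:                   {value: 1.02}    # tissue density [g/cm^3]
  N_bar:                   {value: 1.0e4}   # equilibrium fibroblasts [cells/cm^3]
  rho_bar:                 {value: 0.1}     # equilibrium collagen [g/cm^3]
  c_w:                     {value: 1.0e-8}  # initial wound signaling [g/cm^3]
  steepness:               {value: 40.0}    # initial wound-profile steepness [1/cm]
  wound_cell_fraction:     {value: 0.2}
  wound_collagen_fraction: {value: 0.2}
  domain_length:           {value: 10.0}    # half-domain [cm]
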