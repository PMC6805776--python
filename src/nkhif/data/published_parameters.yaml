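# Published parameterization of the NK-cell HIF-1a regulatory network.
# Units: basal rates a* in nM/h, decay/catalytic rates d*/k* in 1/h unless
# noted; thresholds xi* and equilibrium levels (a11, phi) in nM; efficacies
# rho* and the binding force K_O2 dimensionless.  States are normalized to
# their untreated t=0 values, so these numbers act on dimensionless states.
#
# role: fixed  -- held at this value during calibration
#       free   -- estimated (the 25-parameter default free set)
#       tied   -- resolved algebraically (a1 = 0, d8 = k8) before evaluation
values:
  a1: 0.0          # IL-15 external regulation rate
  a2: 0.848        # AKT basal activation rate
  a3: 0.037        # mTOR basal activation rate
  a5: 0.211        # HIF-1b basal synthesis rate
  a7: 0.0          # NF-kB basal activation rate
  a8: 0.0          # STAT3 basal activation rate
  a9: 0.0          # HIF-1a mRNA basal synthesis rate
  a11: 4.17        # PHD equilibrium level in normoxia
  d1: 0.062        # IL-15 basal decay rate
  d2: 0.848        # AKT basal decay rate
  d3: 0.919        # mTOR basal decay rate
  d4: 0.623        # HIF-1a basal decay rate
  d5: 0.196        # HIF-1b basal decay rate
  d6: 0.301        # HIF-1 complex basal decay rate
  d7: 0.914        # NF-kB basal decay rate
  d8: 0.577        # STAT3 basal decay rate (tied to k8)
  d9: 0.934        # HIF-1a mRNA basal decay rate
  d10: 0.935       # HIF-1a-aOH degradation rate
  k1: 2.0e-5       # AKT activation rate via IL-15
  k2: 0.307        # mTOR activation rate via AKT
  k3: 0.181        # STAT3-regulated HIF-1a mRNA production rate
  k4: 76.196       # association rate of HIF-1a and HIF-1b [1/(nM h)]
  k5: 75.895       # HIF-1 complex dissociation rate
  k6: 25.001       # STAT3 activation rate via IL-15
  k7: 2.903        # IL-15-regulated NF-kB activation rate
  k8: 0.577        # STAT3 activation rate via mTOR
  k9: 0.753        # NF-kB-regulated HIF-1a mRNA production rate
  k10: 421.353     # catalytic rate, FIH-mediated HIF-1a hydroxylation
  k11: 0.211       # catalytic rate, HIF-1a-aOH dehydroxylation [nM/h]
  k12: 0.061       # catalytic rate, PHD-mediated HIF-1a-aOH hydroxylation
  k13: 12.152      # catalytic rate, PHD-mediated HIF-1a hydroxylation
  k14: 16.528      # hypoxia(HIF-1)-induced NF-kB activation rate
  k15: 0.088       # mTOR-induced NF-kB activation rate
  kS: 9.0e-4       # maximal STAT3-regulated AKT activation rate [nM/h]
  k_alpha: 1.034   # HIF-1a synthesis (translation) rate
  n2: 2.0          # Hill coefficient, STAT3-mediated AKT regulation
  xi28: 38.44      # threshold, STAT3-mediated AKT regulation
  xi4: 15.018      # Michaelis constant, HIF-1a as FIH substrate
  xi44: 128.022    # Michaelis constant, HIF-1a as PHD substrate
  xi10: 8.127      # Michaelis constant, HIF-1a-aOH as PHD substrate
  Delta: 200.0     # hypoxia-regulated PHD production at equilibrium
  phi: 0.829       # FIH equilibrium level
  K_O2: 0.96       # FIH/PHD oxygen-dependent binding force in normoxia
  rho3: 1.0        # efficacy of S3I-201 (STAT3 inhibitor)
  rho4: 0.863      # inhibitory effect of DMOG on IL-15-mediated STAT3 activation
  rho6: 0.99       # efficacy of DMOG as PHD/FIH inhibitor
  rho_rapa: 1.0    # efficacy of rapamycin as mTOR inhibitor (assumed)
  rho_nfkb: 1.0    # efficacy of the NF-kB inhibitor (assumed)
  alpha1: 1.163    # HIF-1-mediated mTOR inhibition, numerator constant
  alpha2: 0.386    # HIF-1-mediated mTOR inhibition, saturation constant
roles:
  tied: [a1, d8]
  free: [a5, d1, d2, d3, d4, d5, d6, d7, d9, d10,
         rho3, rho4, k3, k4, k6, k7, k8, k9, k13, k14,
         k_alpha, xi10, phi, alpha1, alpha2]
  # everything else: fixed
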