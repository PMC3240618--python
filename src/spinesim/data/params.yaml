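# Default parameter table of the spine model.
# Units: concentrations µM, time s, volumes µm³, distances as noted.
# Rate constants without a literature anchor are calibrated against the
# model's printed anchors (see docs/methods.md and scripts/calibrate_model.py);
# values marked "pinned" are recomputed at assembly so the resting state
# (Ca_cyt 60 nM, IP3 100 nM, cleft 2 mM, ER 0.5 mM) is an exact fixed point.

compartments:
  cleft: 0.0015
  PSD: 0.002
  cytosol: 0.02
  ER: 0.002

diffusion:
  D: 760.0            # effective lateral diffusion coefficient, µm²/s
  height: 0.02      # extracellular sheet height, µm
  alpha: 0.72919    # accessible volume fraction (tuned: 40 µM single-release
                    # peak at 1000 nm without uptake)
  sigma0: 0.27      # initial spread of vesicle content, µm (peak cleft
                    # glutamate ~1.5 mM)
  ambient: 0.0      # resting extracellular glutamate, µM

transporters:
  density: 500.0           # µM beyond the exclusion radius
  exclusion_radius: 200.0  # nm
  k_bind: 1.78878        # /(µM·s); tuned: 32 µM peak at 1000 nm with uptake
  k_unbind: 1.0            # /s
  k_translocate: 10.0      # /s

mglur:
  R_total: 8.0        # five receptors in the perisynaptic zone, as µM
  G_total: 40.0
  PLC_total: 1.2
  PIP2_total: 10.0
  kon_glu: 0.95       # /(µM·s); sets how far receptor occupancy runs
                      # behind brief glutamate transients (frequency coding)
  Kd_glu: 1.575       # µM, inactive states; calibrated: binding EC50 0.56 µM
  Ka0: 0.0667         # constitutive activation equilibrium; with Ka1 sets the
                      # basal:maximal G-protein drive ratio, calibrated so the
                      # GaGTP concentration-response midpoint sits at 5.6 µM
  Ka1: 2.0            # agonist-bound activation equilibrium
  k_act: 5.0          # /s, conformational base rate
  kon_G: 1.0
  Kd_G: 2.0
  k_cat: 2.276          # /s nucleotide exchange per active ternary complex
  k_hyd: 0.02         # /s receptor-independent GTPase (small; clearance is
                      # dominated by the PLC GAP cycle)
  k_reassoc: 10.0     # /(µM·s)
  kon_plc: 114.0      # /(µM·s), multiplied by Ca/(Ca+K_plc_ca)
  koff_plc: 4.0       # /s
  k_gap: 9.2          # /s, GAP hydrolysis inside the PLC* complex
  K_plc_ca: 0.2       # µM
  k_pip2: 0.9        # /(µM·s), PLC*-catalyzed PIP2 hydrolysis
  k_pip2_rep: 0.3     # /s membrane replenishment
  V_3k: 1.5           # µM/s IP3 3-kinase Vmax
  Km_3k: 0.5          # µM
  K_3k_ca: 1.0        # µM (calcium/CaM activation)
  n_3k_ca: 2
  ip3_source: 0.832  # µM/s constitutive IP3 production (basal turnover;
                      # calibrated against the transient decay tau)
  V_5p: 1.0           # µM/s IP3 5-phosphatase Vmax; pinned at assembly
                      # (basal IP3 100 nM), so transient decay saturates
  Km_5p: 0.12         # µM
  k_dag_clear: 0.2
  k_ip2_clear: 0.05
  k_ip4_clear: 0.05

ip3r:
  ip3r_permeability: 0.925    # /s; calibrated: 200 nM Ca peak, 5 releases at 50 Hz
  ip3r_subunits_required: 3 # channel opens with >=3 of 4 open-competent subunits
  serca_vmax: 240.0         # µM/s cytosol-referenced; calibrated with decay tau
  serca_K: 0.2              # µM

calcium:
  ca_cleft_rest: 2000.0
  ca_er_rest: 500.0
  pmca_vmax: 15.0     # µM/s; calibrated with decay tau 800 ms
  pmca_K: 0.3
  ncx_vmax: 25.0
  ncx_K: 2.0
  pm_leak: 6.5e-4     # /s; pinned at assembly (resting balance)
  k_ex_ca: 300.0      # /s PSD->cytosol Ca diffusion
  k_ex_ip3: 50.0      # /s PSD<->cytosol IP3 diffusion

iglur:
  n_ampa: 80
  n_nmda: 20
  nmda_ca_coefficient: 8050.8  # µM/s per fully open receptor fraction unit;
                              # calibrated: 516 nM full-model single-release peak

geometry:
  mglur_location_nm: 100.0
  iglur_location_nm: 20.0
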