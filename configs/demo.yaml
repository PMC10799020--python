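# Demo cohort: eight conditions mirroring a patch/FRAP study of pairwise and
# tripartite receptor complexes (free vs IgG-crosslinked partner, +/- ligand).
# Group-mean mobile fractions follow the published condition means; D values
# sit in the few x 10^-2 um^2/s range typical of transmembrane receptors.
beam:
  w: 0.77            # Gaussian spot e^-2 radius, um
  K: 3.0             # bleach parameter (~68% bleach depth)
  n_pre: 10
  n_post: 240
  monitor_interval: 0.5   # s
noise:
  scheme: signal-scaled
  sigma0: 0.02
cell_cv: 0.15        # between-cell CV on D (lognormal) and R_f (logit-normal)
alpha: 0.05
conditions:
  - {condition: "NRP1+ENG",        crosslinked: "no",  ligand: "none",   n_cells: 30, D: 0.025, R_f: 0.64}
  - {condition: "NRP1+ENG",        crosslinked: "yes", ligand: "none",   n_cells: 30, D: 0.025, R_f: 0.39}
  - {condition: "NRP1+ENG",        crosslinked: "yes", ligand: "VEGF-A", n_cells: 30, D: 0.025, R_f: 0.26}
  - {condition: "VEGFR2+ENG",      crosslinked: "no",  ligand: "none",   n_cells: 30, D: 0.020, R_f: 0.62}
  - {condition: "VEGFR2+ENG",      crosslinked: "yes", ligand: "none",   n_cells: 30, D: 0.020, R_f: 0.42}
  - {condition: "NRP1+VEGFR2",     crosslinked: "no",  ligand: "none",   n_cells: 30, D: 0.025, R_f: 0.56}
  - {condition: "NRP1+VEGFR2",     crosslinked: "yes", ligand: "none",   n_cells: 30, D: 0.025, R_f: 0.34}
  - {condition: "NRP1+VEGFR2+ENG", crosslinked: "yes", ligand: "none",   n_cells: 30, D: 0.025, R_f: 0.18}
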