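# Annotated proxsim configuration.
#
# Lengths are in simulation units where 1 unit = 1 nm, so the default cell
# radius of 5000 corresponds to 5 um and the ligation distance of 50 to
# 50 nm.  All mean counts are UMIs per cell.

simulation:
  # Panel of targeted surface proteins.  Names may not contain ":".
  protein_names: ["CD3", "CD28", "PD1"]

  # Mean non-interacting (monomer-bound) probe counts per protein, one
  # entry per protein, for the probe-A and probe-B panels.
  probe_a_means: [100, 80, 20]
  probe_b_means: [100, 60, 20]

  # Mean protein-complex counts for ordered pairs "A-target:B-target".
  # Either a sparse mapping (below) or a full n x n matrix.  Homodimers are
  # the diagonal pairs.
  complex_means:
    "CD3:CD3": 40
    "CD3:CD28": 25
    "CD28:CD3": 25

  # Negative-binomial dispersion of the per-cell count draws
  # (variance = mu + mu^2 / n_NB).  1.5 reproduces the overdispersion of
  # experimental Jurkat/Raji data.
  nb_dispersion: 1.5

  # Geometry.
  radius: 5000          # cell radius, nm
  ligation_distance: 50 # max A/B chord distance for ligation, nm

  # Per-protein probability that a bound antibody is nonspecific.
  # A scalar applies to every protein.
  nonspecific_prob: 0.0

  n_cells: 100
  seed: 0

  # "negative_binomial" (default) or "none" (counts fixed at their means).
  variance_mode: negative_binomial

# Optional: disable the free-oligo (non-proximal probe) output.  The LR and
# ensemble methods require it and refuse to run without it.
output:
  nonproximal: true
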