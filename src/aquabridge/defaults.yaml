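# Default run configuration.  Every geometric criterion and calibration the
# reports depend on is declared here, not hard-coded, and is echoed into the
# run manifest of every analysis.

criteria:
  # Hydrogen bond: heavy donor-acceptor distance (A); the angle criterion
  # applies only when hydrogens are present in the topology.
  hbond_distance_A: 3.5
  hbond_angle_deg: 120.0
  # Salt bridge: charged-group nitrogen to carboxylate oxygen, inclusive.
  salt_bridge_A: 4.0
  # Hydrophobic contact: minimal carbon-carbon distance, inclusive.
  hydrophobic_A: 4.5
  # Covalent D-H search radius used to locate donor hydrogens.
  dh_bond_A: 1.25

classification:
  # Focal residue (Ballesteros-Weinstein code) for the direct/water/none
  # three-way classification, and the pocket residue set eligible for
  # water bridges.  Defaults are the class A GPCR sodium pocket.
  focal_bw: "2.50"
  pocket_bw: ["2.50", "3.35", "3.39", "7.45", "7.46"]

trajectory:
  stride: 1
  # Frame interval in ns; trajectory formats store unreliable or unit-
  # ambiguous time stamps, so the interval is always declared.
  dt_ns: 0.1
  # Whether water coordinates are assumed wrapped into the primary box.
  # Minimum-image distances are used either way; this flag is metadata.
  waters_wrapped: true

lifetimes:
  # integral | exponential_fit
  tau_method: integral
  plateau_tol: 0.02
  # plateau estimate removed before integration/fitting:
  #   occupancy — the indicator's mean occupancy (stationary plateau of the
  #               intermittent estimator; low-variance default)
  #   tail     — mean of the last tail_fraction of lags
  plateau: occupancy
  tail_fraction: 0.1

linker_design:
  # Reach model: modeled_reach(n) = anchor_offset_A + n * per_methylene_A.
  # per_methylene: projection of one methylene along an extended all-anti
  # chain axis.  anchor_offset: anchor-nitrogen-to-chain bond plus the
  # extent of the warhead head group, calibrated once so that the known
  # 11.2 A anchor-to-pocket distance of the naltrindole-derived series
  # selects the 5- and 6-carbon linkers.
  per_methylene_A: 1.25
  anchor_offset_A: 4.3
  tolerance_A: 0.7
  n_min: 1
  n_max: 12

stats:
  # Multiple-testing correction over the comparison table: none | holm
  correction: none

seed: 0
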