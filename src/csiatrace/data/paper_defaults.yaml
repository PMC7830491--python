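# Default study conditions: a six-colony coral feeding experiment with three
# nutritional regimes (autotrophy, mixotrophy, heterotrophy), host and
# symbiont tissue fractions, and Artemia nauplii prey.
#
# delta15N cells for glutamic acid (Glu, trophic AA) and phenylalanine
# (Phe, source AA) are the published group means +/- SD for this design.
# Two cells are not published and are filled by stated assumption:
#   - host Phe does not differ between treatments; 8.0 +/- 1.3 permil is used
#     for all three (anchored on the reported ~8 permil autotrophic host level).
#   - host Glu under mixotrophy is unreported; the midpoint of the autotrophic
#     and heterotrophic host means (9.6 +/- 1.6 permil) is used.  ASSUMPTION.
#
# delta13C cells cover the five essential amino acids used for multivariate
# fingerprinting (valine, leucine, isoleucine, methionine, phenylalanine).
# Prey values are the published Artemia table.  Host/symbiont values are
# reconstructed from the reported anchors: isoleucine -18 permil autotrophic
# vs ~-22 permil under feeding; methionine 4 permil more negative under
# heterotrophy than autotrophy; all other AAs at a -26 permil baseline; the
# same values are used for host and symbiont (the two fractions' delta13C
# fingerprints are reported as indistinguishable), SD 1.5 permil.
name: paper_defaults

constants:
  beta: -0.36        # permil; delta15N(Glu) - delta15N(Phe) in primary producers
  tdf: 4.54          # permil; trophic discrimination factor per trophic level

design:
  n_colonies: 6
  treatments: [autotrophy, mixotrophy, heterotrophy]
  compartments: [host, symbiont]
  n_prey: 3
  colony_sd: 0.0     # optional colony random effect (permil), default off

instrument:
  derivatization_delta:        # delta13C of derivatization carbon, per AA
    default: -30.0
  nitrogen_response: {intercept: 0.5, slope: 0.98}   # measured = a + b * true
  drift_slope: {C13: 0.01, N15: 0.01}                # permil per injection
  noise_sd: {C13: 0.3, N15: 0.5}                     # analytical SD per injection
  replicates: {C13: 2, N15: 3}
  standards_interval: 18       # max sample injections between standard blocks
  standard_block_size: 3

stats:
  n_perm: 999
  alpha: 0.05
  permanova_treatments: [autotrophy, heterotrophy]

# (treatment, compartment, aa, element) -> mean, sd   [permil]
parameters:
  # --- delta15N, symbiont ---
  - {treatment: autotrophy,   compartment: symbiont, aa: Glu, element: N15, mean: 3.71,  sd: 1.23}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Glu, element: N15, mean: 8.49,  sd: 1.98}
  - {treatment: heterotrophy, compartment: symbiont, aa: Glu, element: N15, mean: 12.65, sd: 2.19}
  - {treatment: autotrophy,   compartment: symbiont, aa: Phe, element: N15, mean: 3.72,  sd: 1.21}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Phe, element: N15, mean: 7.60,  sd: 1.25}
  - {treatment: heterotrophy, compartment: symbiont, aa: Phe, element: N15, mean: 8.10,  sd: 1.82}
  # --- delta15N, host ---
  - {treatment: autotrophy,   compartment: host, aa: Glu, element: N15, mean: 8.28,  sd: 1.62}
  - {treatment: mixotrophy,   compartment: host, aa: Glu, element: N15, mean: 9.60,  sd: 1.60}  # ASSUMPTION: midpoint
  - {treatment: heterotrophy, compartment: host, aa: Glu, element: N15, mean: 10.96, sd: 1.45}
  - {treatment: autotrophy,   compartment: host, aa: Phe, element: N15, mean: 8.00,  sd: 1.30}  # ASSUMPTION: constant host Phe
  - {treatment: mixotrophy,   compartment: host, aa: Phe, element: N15, mean: 8.00,  sd: 1.30}
  - {treatment: heterotrophy, compartment: host, aa: Phe, element: N15, mean: 8.00,  sd: 1.30}
  # --- delta15N, prey (Artemia) ---
  - {treatment: prey, compartment: prey, aa: Glu, element: N15, mean: 14.17, sd: 0.22}
  - {treatment: prey, compartment: prey, aa: Phe, element: N15, mean: 8.03,  sd: 0.04}
  # --- delta13C, prey (Artemia essential AAs) ---
  - {treatment: prey, compartment: prey, aa: Val, element: C13, mean: -30.527, sd: 1.393}
  - {treatment: prey, compartment: prey, aa: Leu, element: C13, mean: -27.465, sd: 1.064}
  - {treatment: prey, compartment: prey, aa: Ile, element: C13, mean: -21.086, sd: 1.046}
  - {treatment: prey, compartment: prey, aa: Met, element: C13, mean: -19.899, sd: 1.021}
  - {treatment: prey, compartment: prey, aa: Phe, element: C13, mean: -25.540, sd: 1.083}
  # --- delta13C, host tissue ---
  - {treatment: autotrophy,   compartment: host, aa: Val, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: host, aa: Val, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: host, aa: Val, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: host, aa: Leu, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: host, aa: Leu, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: host, aa: Leu, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: host, aa: Ile, element: C13, mean: -18.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: host, aa: Ile, element: C13, mean: -22.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: host, aa: Ile, element: C13, mean: -22.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: host, aa: Met, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: host, aa: Met, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: host, aa: Met, element: C13, mean: -30.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: host, aa: Phe, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: host, aa: Phe, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: host, aa: Phe, element: C13, mean: -26.0, sd: 1.5}
  # --- delta13C, symbiont fraction (same fingerprint as host) ---
  - {treatment: autotrophy,   compartment: symbiont, aa: Val, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Val, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: symbiont, aa: Val, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: symbiont, aa: Leu, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Leu, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: symbiont, aa: Leu, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: symbiont, aa: Ile, element: C13, mean: -18.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Ile, element: C13, mean: -22.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: symbiont, aa: Ile, element: C13, mean: -22.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: symbiont, aa: Met, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Met, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: symbiont, aa: Met, element: C13, mean: -30.0, sd: 1.5}
  - {treatment: autotrophy,   compartment: symbiont, aa: Phe, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: mixotrophy,   compartment: symbiont, aa: Phe, element: C13, mean: -26.0, sd: 1.5}
  - {treatment: heterotrophy, compartment: symbiont, aa: Phe, element: C13, mean: -26.0, sd: 1.5}

# Certified reference amino acids for sequence calibration.  The two
# high-15N anchors (alanine +43.25, valine +30.19 permil) are certified
# reference values; the remaining certified deltas are SYNTHETIC stand-ins
# chosen to span the stated working range (-6.69 to +43.25 permil for
# nitrogen) across seven amino acids, with plausible carbon values.
standards:
  - {aa: Ala, n15: 43.25, c13: -23.04}
  - {aa: Val, n15: 30.19, c13: -12.12}
  - {aa: Leu, n15: 10.55, c13: -28.31}
  - {aa: Ile, n15: 17.30, c13: -17.54}
  - {aa: Met, n15: 25.02, c13: -24.82}
  - {aa: Glu, n15: 5.56,  c13: -16.65}
  - {aa: Phe, n15: -6.69, c13: -22.60}
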