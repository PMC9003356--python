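# Declared constraint sets for the paired-site model presets.
#
# A 7-state stem model lumps the ten non-pairing dinucleotides into a single
# mismatch state MM.  Exchangeabilities listed here are the symmetric s_ij of
# a general time-reversible generator Q_ij = s_ij * pi_j; every state pair not
# listed (and not covered by a pattern) has rate zero.  Only single-nucleotide
# moves are allowed in the default presets: a compensatory change such as
# AU -> GC proceeds through a wobble intermediate (AU -> GU -> GC).
#
# These presets are declared, documented parameterisations of the RNA7/RNA16
# model families; an alternative constraint set can be transcribed here
# without code changes.

RNA7G:
  states: 7
  description: >
    Two-rate 7-state model: alpha on single-nucleotide moves between pairing
    states, beta on single-nucleotide moves between a pairing state and the
    lumped mismatch state.  Free rate parameters: 1 (alpha/beta after overall
    rate normalisation).
  alpha_edges:
    - [AU, GU]
    - [GU, GC]
    - [UA, UG]
    - [UG, CG]
  beta_edges:
    - [AU, MM]
    - [GU, MM]
    - [GC, MM]
    - [UA, MM]
    - [UG, MM]
    - [CG, MM]
  free_rate_params: 1

RNA7A:
  states: 7
  description: >
    General reversible 7-state model: all 21 exchangeabilities free (20 after
    overall rate normalisation), including double-substitution moves.
  free_rate_params: 20

RNA16:
  states: 16
  description: >
    General reversible 16-state model restricted to single-nucleotide moves:
    the 48 exchangeabilities between dinucleotides differing at exactly one
    position are free (47 after normalisation); double moves have rate zero.
  single_substitutions_only: true
  free_rate_params: 47

RNA16REV:
  states: 16
  description: >
    Fully general reversible 16-state model: all 120 exchangeabilities free
    (119 after normalisation), double-substitution moves included.
  single_substitutions_only: false
  free_rate_params: 119
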