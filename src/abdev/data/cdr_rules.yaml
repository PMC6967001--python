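# Sequence-anchor rules for locating the six CDRs in antibody variable
# domains (Kabat-style definitions located by conserved anchor residues,
# without requiring a numbering scheme).
#
# Coordinates produced from these rules are 0-based half-open, per chain.
#
# Light chain:
#   L1 starts immediately after the conserved FR1 Cys (searched for in
#      cys_window); permitted lengths 10-17; the residue after L1 is Trp.
#   L2 starts a fixed 15 framework residues after the end of L1 and has
#      fixed length 7.
#   L3 starts a fixed 32 framework residues after the end of L2, immediately
#      after the conserved FR3 Cys; lengths 7-11; followed by F-G-x-G.
# Heavy chain:
#   H1 starts 4 residues after the conserved FR1 Cys (searched for in
#      cys_window); lengths 10-12; the residue after H1 is Trp.
#   H2 starts a fixed 14 framework residues after the end of H1; lengths
#      16-19; the residue after H2 is Lys or Arg.
#   H3 starts a fixed 32 framework residues after the end of H2, with the
#      conserved Cys three residues before its start (C-x-x motif, typically
#      C-A-R); lengths 3-25; followed by W-G-x-G.
light:
  L1:
    cys_window: [16, 30]     # search window (0-based) for the FR1 anchor Cys
    start_after_cys: 1       # L1 begins this many residues after the Cys
    length_range: [10, 17]
    terminator: ["W"]        # residue immediately after the region
  L2:
    gap_after_previous: 15
    length_range: [7, 7]
  L3:
    gap_after_previous: 32
    cys_offset_before_start: 1
    length_range: [7, 11]
    end_motif: "FGxG"
heavy:
  H1:
    cys_window: [16, 30]
    start_after_cys: 4
    length_range: [10, 12]
    terminator: ["W"]
  H2:
    gap_after_previous: 14
    length_range: [16, 19]
    terminator: ["K", "R"]
  H3:
    gap_after_previous: 32
    cys_offset_before_start: 3
    length_range: [3, 25]
    end_motif: "WGxG"
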