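# Physicochemical classifications of the 20 standard amino acids.
#
# Each scheme is a partition: every amino acid (one-letter code) appears in
# exactly one class per scheme.  The partitions follow the IMGT "IMGT classes
# of the 20 common amino acids" conventions for hydropathy, volume, chemical
# class, charge, hydrogen donor/acceptor atoms and polarity.  The acidity
# scheme is the classic four-way split used in protein chemistry textbooks
# (neutral apolar / neutral polar / acidic / basic).
acidity:
  neutral apolar: [G, A, V, L, I, P, F, M, W]
  neutral polar: [S, T, C, Y, N, Q]
  acidic: [D, E]
  basic: [K, R, H]
hydropathy:
  hydrophobic: [A, C, I, L, M, F, W, V]
  neutral: [G, H, P, S, T, Y]
  hydrophilic: [R, N, D, Q, E, K]
volume:
  very small: [A, G, S]
  small: [N, D, C, P, T]
  medium: [Q, E, H, V]
  large: [R, I, L, K, M]
  very large: [F, W, Y]
chemical:
  aliphatic: [A, G, I, L, P, V]
  aromatic: [F, W, Y]
  sulfur: [C, M]
  hydroxyl: [S, T]
  basic: [R, H, K]
  acidic: [D, E]
  amide: [N, Q]
charge:
  positive: [R, H, K]
  negative: [D, E]
  uncharged: [A, C, F, G, I, L, M, N, P, Q, S, T, V, W, Y]
hydrogen:
  donor: [R, K, W]
  acceptor: [D, E]
  donor and acceptor: [H, N, Q, S, T, Y]
  none: [A, C, G, F, I, L, M, P, V]
polarity:
  polar: [R, N, D, Q, E, H, K, S, T, Y]
  nonpolar: [A, C, G, I, L, M, F, P, W, V]
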