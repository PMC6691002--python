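# Default NB-ARC and TIR motif definitions for conifer NLR classification.
#
# Pattern symbols: an amino-acid letter = that exact residue at the position;
# 'h' = any residue of the configured hydrophobic set; 'x' = any residue.
# 'discriminant' lists 1-based pattern positions that must match exactly and
# are never relaxed by the mismatch tolerance.
#
# The RNL-diagnostic RNBS-D (CFLDLGxFP) and the MHD variants (QHD for RNL,
# VHD for CNL2, MHD for CNL/TNL) are fixed by their published consensus; the
# discriminant scheme encodes the conserved aspartate D4 followed by a
# subfamily-specific cysteine (C5 CNL / C6 CNL2 / C7 TNL) or glycine (G6 RNL)
# in RNBS-D.  The remaining entries are curated from the standard published
# NB-ARC consensus motifs (P-loop, Kinase-2/3, RNBS-A/C, GLPL); they are data,
# not code, and can be re-transcribed without touching the scanner.

hydrophobic: AVLIMFWY

motifs:
  # --- motifs conserved across all NLR subfamilies (chain anchors) ---
  - name: PLOOP
    tag: SHARED
    pattern: G h G G h G K T T
    discriminant: [6, 7, 8]
  - name: KIN2
    tag: SHARED
    pattern: h h h h D D h W
    discriminant: [5, 6, 8]
  - name: KIN3
    tag: SHARED
    pattern: G S R h h h T T R
    discriminant: [1, 2, 9]
  - name: RNBS_C
    tag: SHARED
    pattern: S Y x x L S x x E
    discriminant: [6, 9]
  - name: GLPL
    tag: SHARED
    pattern: G L P L A
    discriminant: [1, 2, 3, 4]

  # --- RNBS-A: subfamily-specific; the CNL2 RNBS-A is polymorphic and
  #     carries no usable consensus, so no CNL2 entry exists ---
  - name: RNBS_A
    tag: TNL
    pattern: F h E N h R E
    discriminant: [3, 4, 6]
  - name: RNBS_A
    tag: CNL
    pattern: F D x h A W h C
    discriminant: [2, 6, 8]
  - name: RNBS_A
    tag: RNL
    pattern: F E x h A W h G
    discriminant: [2, 6, 8]

  # --- RNBS-D: nine-position frame with conserved D4; cysteine position
  #     (C5/C6/C7) or glycine (G6) discriminates the subfamilies ---
  - name: RNBS_D
    tag: RNL
    pattern: C F L D L G x F P
    discriminant: [1, 4, 6]
  - name: RNBS_D
    tag: CNL
    pattern: h F L D C x x F P
    discriminant: [4, 5]
  - name: RNBS_D
    tag: CNL2
    pattern: h F L D x C x F P
    discriminant: [4, 6]
  - name: RNBS_D
    tag: TNL
    pattern: h F L D x x C F P
    discriminant: [4, 7]

  # --- MHD variants: Q1 strictly required in RNL, V1 in CNL2, the
  #     conventional M1 in CNL and TNL ---
  - name: MHD
    tag: RNL
    pattern: Q H D
    discriminant: [1, 2, 3]
  - name: MHD
    tag: CNL2
    pattern: V H D
    discriminant: [1, 2, 3]
  - name: MHD
    tag: CNL
    pattern: M H D
    discriminant: [1, 2, 3]
  - name: MHD
    tag: TNL
    pattern: M H D
    discriminant: [1, 2, 3]

  # --- TIR-domain motifs, carried for reporting only (TIR presence is
  #     established from domain hits, not from a motif chain) ---
  - name: TIR1
    tag: SHARED
    pattern: h D h F h S H
    discriminant: [7]
  - name: TIR2
    tag: SHARED
    pattern: L x x A h E x S
    discriminant: [6]
  - name: TIR3
    tag: SHARED
    pattern: h P h F Y x V
    discriminant: [5]
  - name: TIR4
    tag: SHARED
    pattern: W C L x E L
    discriminant: [1]
  - name: TIR5
    tag: SHARED
    pattern: h h h G W
    discriminant: [5]
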