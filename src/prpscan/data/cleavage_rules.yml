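# Protease cleavage-site specificity rules, expressed as per-slot residue
# sets over the substrate window P4-P3-P2-P1 | P1'-P2' (cleavage between P1
# and P1').  Encoded after the publicly documented specificities of the
# ExPASy PeptideCutter tool (Keil-style rules), so that any discrepancy is
# auditable and fixable here without touching code.
#
# Semantics (see prpscan.cleave):
#   clauses:    cleavage candidates; a clause matches when every listed slot
#               matches ("in": residue must be one of; "not_in": residue must
#               not be one of, absent residues pass).
#   exceptions: if any exception clause matches, cleavage is blocked.
#   overrides:  if any override clause matches, cleavage fires regardless.
# Ambiguous residues (X, B, Z, U, J, O) never satisfy an "in" slot and never
# trigger an exception slot.

rules:
  - name: "Aspartic acid-N endopeptidase"
    provenance: "Asp-N: cleaves on the amino side of aspartate (P1' = D)"
    clauses:
      - {P1prime: {in: "D"}}

  - name: "Aspartic acid-N endopeptidase + N-terminal glutamic acid"
    provenance: "Asp-N variant also accepting glutamate at P1'"
    clauses:
      - {P1prime: {in: "DE"}}

  - name: "Chymotrypsin"
    provenance: >-
      Chymotrypsin, high specificity: after F/Y/W, not before proline;
      W additionally blocked before M.
    clauses:
      - {P1: {in: "FY"}, P1prime: {not_in: "P"}}
      - {P1: {in: "W"}, P1prime: {not_in: "MP"}}

  - name: "Chymotrypsin (low specificity)"
    provenance: >-
      Chymotrypsin, low specificity: additionally after L/M/H with the
      documented H/M/L context blocks.  Shipped for completeness; not part
      of the default 13-enzyme panel.
    default: false
    clauses:
      - {P1: {in: "FLY"}, P1prime: {not_in: "P"}}
      - {P1: {in: "W"}, P1prime: {not_in: "MP"}}
      - {P1: {in: "M"}, P1prime: {not_in: "PY"}}
      - {P1: {in: "H"}, P1prime: {not_in: "DMPW"}}

  - name: "Clostripain"
    provenance: "Clostripain (Arg-C): after arginine"
    clauses:
      - {P1: {in: "R"}}

  - name: "Glutamyl endopeptidase"
    provenance: "Glu-C (V8, phosphate buffer): after glutamate"
    clauses:
      - {P1: {in: "E"}}

  - name: "Lysyl endopeptidase"
    provenance: "LysC: after lysine (cleaves K-P bonds too)"
    clauses:
      - {P1: {in: "K"}}

  - name: "Peptidyl-Lys metalloendopeptidase"
    provenance: "LysN: before lysine (P1' = K)"
    clauses:
      - {P1prime: {in: "K"}}

  - name: "Pepsin"
    provenance: >-
      Pepsin pH > 2 (default; the pH 1.3 variant restricts the residue set
      to F/L): hydrophobic/aromatic residue at P1 or P1', blocked by P at
      P3/P2/P2', by H/K/R at P3 and by R at P1.
    clauses:
      - P1: {in: "FLWY"}
        P3: {not_in: "HKRP"}
        P2: {not_in: "P"}
        P2prime: {not_in: "P"}
      - P1prime: {in: "FLWY"}
        P1: {not_in: "R"}
        P3: {not_in: "HKRP"}
        P2: {not_in: "P"}
        P2prime: {not_in: "P"}

  - name: "Pepsin (pH1.3)"
    provenance: "Pepsin at pH 1.3: as pepsin pH > 2 but only F/L at P1/P1'"
    default: false
    clauses:
      - P1: {in: "FL"}
        P3: {not_in: "HKRP"}
        P2: {not_in: "P"}
        P2prime: {not_in: "P"}
      - P1prime: {in: "FL"}
        P1: {not_in: "R"}
        P3: {not_in: "HKRP"}
        P2: {not_in: "P"}
        P2prime: {not_in: "P"}

  - name: "Prolyl-endopeptidase"
    provenance: >-
      Prolyl endopeptidase (prolyl oligopeptidase): after proline preceded
      by a basic residue (H/K/R at P2), not before proline.
    clauses:
      - {P2: {in: "HKR"}, P1: {in: "P"}, P1prime: {not_in: "P"}}

  - name: "Proteinase K"
    provenance: "Proteinase K: after aliphatic/aromatic residues A/E/F/I/L/T/V/W/Y"
    clauses:
      - {P1: {in: "AEFILTVWY"}}

  - name: "Staphylococcal peptidase I"
    provenance: "Staphylococcal peptidase I: after glutamate, blocked by E at P2"
    clauses:
      - {P1: {in: "E"}, P2: {not_in: "E"}}

  - name: "Thermolysin"
    provenance: >-
      Thermolysin: before A/F/I/L/M/V, blocked by acidic P1 (D/E) and by
      proline at P2'.
    clauses:
      - {P1: {not_in: "DE"}, P1prime: {in: "AFILMV"}, P2prime: {not_in: "P"}}

  - name: "Trypsin"
    provenance: >-
      Trypsin: after K/R, not before proline, with the documented
      higher-order exception triplets (P2,P1,P1') CKD, DKD, CKH, CKY, CRK,
      RRH, RRR blocking cleavage, and WKP / MRP cleaving despite proline.
    clauses:
      - {P1: {in: "KR"}, P1prime: {not_in: "P"}}
    exceptions:
      - {P2: {in: "C"}, P1: {in: "K"}, P1prime: {in: "D"}}
      - {P2: {in: "D"}, P1: {in: "K"}, P1prime: {in: "D"}}
      - {P2: {in: "C"}, P1: {in: "K"}, P1prime: {in: "H"}}
      - {P2: {in: "C"}, P1: {in: "K"}, P1prime: {in: "Y"}}
      - {P2: {in: "C"}, P1: {in: "R"}, P1prime: {in: "K"}}
      - {P2: {in: "R"}, P1: {in: "R"}, P1prime: {in: "H"}}
      - {P2: {in: "R"}, P1: {in: "R"}, P1prime: {in: "R"}}
    overrides:
      - {P2: {in: "W"}, P1: {in: "K"}, P1prime: {in: "P"}}
      - {P2: {in: "M"}, P1: {in: "R"}, P1prime: {in: "P"}}
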