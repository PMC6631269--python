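# SMARTS -> pKa rule table for dominant-microspecies assignment.
#
# Each rule names an ionizable group, a SMARTS pattern, the index of the
# ionizable atom within the pattern match, the rule kind and a representative
# pKa (acids: pKa of the group; bases: pKa of the conjugate acid).
# At a given pH, an acid with pKa < pH is deprotonated at the site atom and a
# base whose conjugate acid has pKa > pH is protonated.  Rules are applied in
# listed order; an atom is modified at most once.  Groups whose pKa sits on
# the neutral side of physiological pH are listed anyway so the table
# documents why they are left untouched.
rules:
  - name: sulfonic_acid
    smarts: "[SX4](=O)(=O)[OX2H1]"
    site: 3
    kind: acid
    pka: -1.0
  - name: phosphonic_acid
    smarts: "[PX4](=O)[OX2H1]"
    site: 2
    kind: acid
    pka: 2.0
  - name: carboxylic_acid
    smarts: "[CX3](=O)[OX2H1]"
    site: 2
    kind: acid
    pka: 4.2
  - name: tetrazole
    smarts: "[nX3H;$([nH]1nnnc1),$([nH]1nncn1)]"
    site: 0
    kind: acid
    pka: 4.9
  - name: imide
    smarts: "[NX3H1]([CX3]=O)[CX3]=O"
    site: 0
    kind: acid
    pka: 9.5
  - name: arylsulfonamide
    smarts: "[SX4](=O)(=O)[NX3;H1,H2]"
    site: 3
    kind: acid
    pka: 10.1
  - name: phenol
    smarts: "[c][OX2H1]"
    site: 1
    kind: acid
    pka: 10.0
  - name: thiol
    smarts: "[CX4][SX2H1]"
    site: 1
    kind: acid
    pka: 10.5
  - name: guanidine
    smarts: "[NX3][CX3](=[NX2;!$(N=[CX3]([NX3])=N)])[NX3]"
    site: 2
    kind: base
    pka: 13.6
  - name: amidine
    smarts: "[CX3;!$([CX3]([NX3])([NX3])=N)](=[NX2])[NX3]"
    site: 1
    kind: base
    pka: 12.4
  - name: aliphatic_amine
    smarts: "[NX3;A;+0;!$([NX3]-[a]);!$([NX3]-[CX3]=[O,N,S]);!$([NX3]-[SX4]);!$([NX3]-[SX3]);!$([NX3]-[NX2]);!$([NX3]-[N]=O);!$([NX3]-[OX2]);!$([NX3]=*);!$([NX3]-[CX2]#N);$([NX3]-[CX4])]"
    site: 0
    kind: base
    pka: 10.6
  - name: imidazole
    smarts: "[nX2;$(n1c[nH]cc1)]"
    site: 0
    kind: base
    pka: 7.0
  - name: pyridine
    smarts: "[nX2;$(n1ccccc1)]"
    site: 0
    kind: base
    pka: 5.2
  - name: aniline
    smarts: "[NX3;H1,H2;$([NX3]-[a]);!$([NX3]-[CX3]=[O,N,S])]"
    site: 0
    kind: base
    pka: 4.6
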