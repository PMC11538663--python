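# Cancer-adipose conversion (CAC) regulatory network -- SYNTHETIC RECONSTRUCTION.
# Topology follows the published circuit description (EMT core: SNAIL1/ZEB1/
# miR-200/miR-145/miR-34 with the p53-MDM2 axis; metastasis module: LIN28/
# let-7/BACH1/RKIP; MAPK: MEK/ERK; adipogenesis: PPARg/CEBPa; drug inputs
# TGF-beta, MEK inhibitor, rosiglitazone). The published kinetic tables are
# not redistributable here; these parameters were calibrated with
# scripts/calibrate_network.py so the model reproduces the reported TGF-beta
# bifurcation thresholds (3.2, 3.9, 4.1, 4.3, 7.5), the drug-condition
# attractor counts (1/2/3/5/1), and the combination-drug intervention
# outcomes. Concentrations and rates are dimensionless model units.
name: cancer-adipose-conversion
options:
  tgfb_autoregulation: false
nodes:
- name: TGFB
  input: true
- name: MEKI
  input: true
- name: ROSI
  input: true
- name: SNAIL1
  g: 0.5
  k: 1.0
- name: ZEB1
  g: 0.18
  k: 1.0
- name: miR200
  g: 0.3982153284444445
  k: 1.0
- name: miR145
  g: 0.3
  k: 1.0
- name: miR34
  g: 0.3
  k: 1.0
- name: P53
  g: 1.6
  k: 1.0
- name: MDM2
  g: 0.25
  k: 1.0
- name: LIN28
  g: 0.4
  k: 1.0
- name: LET7
  g: 0.4
  k: 1.0
- name: BACH1
  g: 0.5
  k: 1.0
- name: RKIP
  g: 0.5
  k: 1.0
- name: MEK
  g: 0.35
  k: 1.0
- name: ERK
  g: 0.3
  k: 1.0
- name: PPARG
  g: 0.12
  k: 1.0
- name: CEBPA
  g: 0.05
  k: 1.0
inputs:
  TGFB: 1.0
  MEKI: 0.001
  ROSI: 0.1
regulations:
- source: TGFB
  target: SNAIL1
  lam: 8.0
  S: 6.0
  n: 2
  mode: synthesis
- source: PPARG
  target: SNAIL1
  lam: 0.9
  S: 1.5
  n: 2
  mode: synthesis
- source: miR34
  target: SNAIL1
  lam: 0.8
  S: 0.5
  n: 2
  mode: synthesis
- source: miR200
  target: SNAIL1
  lam: 0.8
  S: 0.5
  n: 2
  mode: synthesis
- source: SNAIL1
  target: ZEB1
  lam: 12.0
  S: 1.3589104739321216
  n: 4
  mode: synthesis
- source: miR200
  target: ZEB1
  lam: 0.05
  S: 0.4
  n: 4
  mode: synthesis
- source: miR145
  target: ZEB1
  lam: 0.8
  S: 0.5
  n: 2
  mode: synthesis
- source: TGFB
  target: ZEB1
  lam: 1.5
  S: 5.0
  n: 2
  mode: synthesis
- source: P53
  target: miR200
  lam: 3.0
  S: 0.6
  n: 2
  mode: synthesis
- source: ZEB1
  target: miR200
  lam: 0.05
  S: 0.6
  n: 4
  mode: synthesis
- source: SNAIL1
  target: miR200
  lam: 0.7
  S: 1.2
  n: 2
  mode: synthesis
- source: P53
  target: miR145
  lam: 3.0
  S: 0.6
  n: 2
  mode: synthesis
- source: ZEB1
  target: miR145
  lam: 0.7
  S: 1.0
  n: 2
  mode: synthesis
- source: P53
  target: miR34
  lam: 3.0
  S: 0.6
  n: 2
  mode: synthesis
- source: SNAIL1
  target: miR34
  lam: 0.7
  S: 1.0
  n: 2
  mode: synthesis
- source: SNAIL1
  target: P53
  lam: 0.5
  S: 1.2
  n: 2
  mode: synthesis
- source: PPARG
  target: P53
  lam: 0.92
  S: 2.0
  n: 2
  mode: synthesis
- source: MDM2
  target: P53
  lam: 4.0
  S: 0.8
  n: 2
  mode: degradation
- source: P53
  target: MDM2
  lam: 2.5
  S: 0.7
  n: 2
  mode: synthesis
- source: ZEB1
  target: MDM2
  lam: 3.5
  S: 1.2
  n: 2
  mode: synthesis
- source: SNAIL1
  target: LIN28
  lam: 3.0
  S: 1.2
  n: 2
  mode: synthesis
- source: LET7
  target: LIN28
  lam: 0.7
  S: 0.5
  n: 2
  mode: synthesis
- source: LIN28
  target: LET7
  lam: 0.5
  S: 0.6
  n: 2
  mode: synthesis
- source: P53
  target: LET7
  lam: 2.0
  S: 0.6
  n: 2
  mode: synthesis
- source: ZEB1
  target: LET7
  lam: 0.8
  S: 1.0
  n: 2
  mode: synthesis
- source: LET7
  target: BACH1
  lam: 0.5
  S: 0.5
  n: 2
  mode: synthesis
- source: TGFB
  target: RKIP
  lam: 6.0
  S: 5.574610226522822
  n: 6
  mode: synthesis
- source: ERK
  target: RKIP
  lam: 0.05
  S: 0.8
  n: 6
  mode: synthesis
- source: SNAIL1
  target: RKIP
  lam: 0.05
  S: 2.1500573812665413
  n: 6
  mode: synthesis
- source: miR200
  target: RKIP
  lam: 0.05
  S: 0.3
  n: 4
  mode: synthesis
- source: RKIP
  target: MEK
  lam: 0.3
  S: 0.5
  n: 4
  mode: synthesis
- source: ZEB1
  target: MEK
  lam: 4.0
  S: 0.8
  n: 2
  mode: synthesis
- source: ERK
  target: MEK
  lam: 0.85
  S: 1.0
  n: 2
  mode: synthesis
- source: MEKI
  target: MEK
  lam: 0.05
  S: 0.015
  n: 2
  mode: synthesis
- source: MEK
  target: ERK
  lam: 6.0
  S: 0.6
  n: 2
  mode: synthesis
- source: ERK
  target: ERK
  lam: 2.0
  S: 0.8
  n: 2
  mode: synthesis
- source: ERK
  target: ERK
  lam: 0.6
  S: 1.5
  n: 4
  mode: synthesis
- source: PPARG
  target: PPARG
  lam: 3.0
  S: 1.0
  n: 4
  mode: synthesis
- source: CEBPA
  target: PPARG
  lam: 3.0
  S: 0.8
  n: 2
  mode: synthesis
- source: ROSI
  target: PPARG
  lam: 12.0
  S: 12.0
  n: 1
  mode: synthesis
- source: ZEB1
  target: PPARG
  lam: 0.5
  S: 1.0
  n: 2
  mode: synthesis
- source: ERK
  target: PPARG
  lam: 0.4
  S: 0.8
  n: 2
  mode: synthesis
- source: SNAIL1
  target: PPARG
  lam: 0.1
  S: 1.2692395587110092
  n: 6
  mode: synthesis
- source: TGFB
  target: PPARG
  lam: 4.0
  S: 5.152077216682325
  n: 6
  mode: synthesis
- source: CEBPA
  target: CEBPA
  lam: 4.5
  S: 0.8
  n: 4
  mode: synthesis
- source: PPARG
  target: CEBPA
  lam: 2.5
  S: 1.2
  n: 2
  mode: synthesis
- source: ROSI
  target: CEBPA
  lam: 6.0
  S: 4.0
  n: 1
  mode: synthesis
- source: ZEB1
  target: CEBPA
  lam: 2.5
  S: 1.0
  n: 4
  mode: synthesis
- source: TGFB
  target: CEBPA
  lam: 2.4
  S: 4.460000000000006
  n: 6
  mode: synthesis
- source: RKIP
  target: CEBPA
  lam: 0.1
  S: 0.5
  n: 4
  mode: synthesis
- source: SNAIL1
  target: CEBPA
  lam: 0.1
  S: 1.8826295465334333
  n: 6
  mode: synthesis
- source: ERK
  target: CEBPA
  lam: 0.8
  S: 1.0
  n: 2
  mode: synthesis
- source: TGFB
  target: TGFB
  lam: 2.0
  S: 4.0
  n: 2
  mode: synthesis
  variant: tgfb_autoregulation
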