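# Demonstration cohort: four breeds at the frequencies used in the worked
# fault-probability examples, plus a two-population Schipperke split.
seed: 20191028
missing_rate: 0.01
breeds:
  - breed: BULT
    populations:
      - label: US
        n: 50
        frequencies:
          TYRP1: {B: 0.94, bs: 0.03, bc: 0.03}
          MC1R: {E: 1.0}
          CBD103: {ky: 1.0}
          ASIP: {ay: 0.8, at: 0.2}
  - breed: SKIP
    populations:
      - label: US
        n: 44
        frequencies:
          MC1R: {E: 1.0}
          CBD103: {KB_kbr: 0.95, ky: 0.05}
          ASIP: {a: 0.6, at: 0.4}
          T: {tailless: 0.02, t_wt: 0.98}
      - label: UK
        n: 6
        frequencies:
          MC1R: {E: 0.5, e: 0.5}
          CBD103: {KB_kbr: 0.95, ky: 0.05}
          ASIP: {a: 0.6, at: 0.4}
          T: {tailless: 0.08, t_wt: 0.92}
  - breed: GDANE
    populations:
      - label: US
        n: 60
        frequencies:
          CBD103: {KB_kbr: 0.66, ky: 0.34}
          MITF: {S: 0.94, sp: 0.06}
          PSMB7: {H: 0.79, h: 0.21}
          MC1R: {E: 0.9, EM: 0.1}
          ASIP: {ay: 0.95, at: 0.05}
  - breed: SHET
    populations:
      - label: US
        n: 40
        frequencies:
          MITF: {S: 0.94, sp: 0.06}
          MC1R: {E: 1.0}
          CBD103: {ky: 1.0}
          ASIP: {ay: 0.3, at: 0.6, a: 0.1}
      - label: UK
        n: 30
        frequencies:
          MITF: {S: 0.84, sp: 0.16}
          MC1R: {E: 1.0}
          CBD103: {ky: 1.0}
          ASIP: {ay: 0.3, at: 0.6, a: 0.1}
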