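# Default 12-gene catalogue: allele hierarchies (rank 0 = most dominant),
# assayed markers per derived allele (wild-type alleles are called by
# exclusion), expression modes, and lethal flags.
genes:
  ASIP:
    mode: hierarchy
    alleles:
      # ayt = cis combination of the ay point mutations and the at SINE
      # insertion on one chromosome; its dominance position is unverified
      # and its phenotype is reported as uncharacterized.
      - {symbol: ayt, rank: 0, markers: [asip_ay, asip_at]}
      - {symbol: ay, rank: 1, markers: [asip_ay]}
      - {symbol: aw, rank: 2, wild_type: true}
      - {symbol: at, rank: 3, markers: [asip_at]}
      - {symbol: a, rank: 4, markers: [asip_a]}
  MC1R:
    mode: hierarchy
    alleles:
      - {symbol: EM, rank: 0, markers: [mc1r_em]}
      - {symbol: EG, rank: 1, markers: [mc1r_eg]}
      - {symbol: E, rank: 2, wild_type: true}
      - {symbol: e, rank: 3, markers: [mc1r_e]}
  CBD103:
    mode: hierarchy
    alleles:
      # The assay cannot separate dominant black KB from brindle kbr.
      - {symbol: KB_kbr, rank: 0, markers: [cbd103_kb]}
      - {symbol: ky, rank: 1, wild_type: true}
  TYRP1:
    mode: compound_recessive
    alleles:
      - {symbol: B, rank: 0, wild_type: true}
      - {symbol: bs, rank: 1, markers: [tyrp1_bs]}
      - {symbol: bc, rank: 2, markers: [tyrp1_bc]}
  MITF:
    mode: overlay
    alleles:
      - {symbol: S, rank: 0, wild_type: true}
      - {symbol: sp, rank: 1, markers: [mitf_sp]}
    breed_overrides:
      GDANE: {mitf_mode: co_dominant}
      SHET: {mitf_mode: recessive}
  PSMB7:
    mode: overlay
    alleles:
      - {symbol: H, rank: 0, wild_type: true}
      - {symbol: h, rank: 1, lethal_homozygous: true, markers: [psmb7_h]}
  RALY:
    mode: overlay
    alleles:
      - {symbol: saddle_dup, rank: 0, markers: [raly_dup]}
      - {symbol: raly_wt, rank: 1, wild_type: true}
  FGF5:
    mode: overlay
    alleles:
      - {symbol: short, rank: 0, wild_type: true}
      - {symbol: long, rank: 1, markers: [fgf5_long]}
  KRT71:
    mode: overlay
    alleles:
      - {symbol: curl, rank: 0, markers: [krt71_curl]}
      - {symbol: no_curl, rank: 1, wild_type: true}
  T:
    mode: overlay
    alleles:
      - {symbol: tailless, rank: 0, lethal_homozygous: true, markers: [t_tailless]}
      - {symbol: t_wt, rank: 1, wild_type: true}
  BMP3:
    mode: overlay
    alleles:
      - {symbol: bmp3_wt, rank: 0, wild_type: true}
      - {symbol: short_muzzle, rank: 1, markers: [bmp3_short_muzzle]}
  EAR:
    mode: overlay
    alleles:
      - {symbol: drop, rank: 0, markers: [ear_drop]}
      - {symbol: erect, rank: 1, wild_type: true}
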