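# Curated registry tolerance codes for the demonstration breeds, plus the
# trait -> gene mapping and the probability recipe each trait requires.
# Tolerance codes: N = not allowed, n.p. = not preferred, Y = allowed,
# amb. = ambiguously worded, not_recognized = breed not recognized.
traits:
  brown:
    gene: TYRP1
    fault_alleles: [bs, bc]
    inheritance: CH
    factors:
      - {gene: TYRP1, alleles: [bs, bc], mode: homozygous_recessive}
  solid_red:
    gene: MC1R
    fault_alleles: [e]
    inheritance: R
    factors:
      - {gene: MC1R, alleles: [e], mode: homozygous_recessive}
  piebald_spotting:
    # Shetland Sheepdog: the spotting variant behaves recessively in this breed.
    gene: MITF
    fault_alleles: [sp]
    inheritance: R
    factors:
      - {gene: MITF, alleles: [sp], mode: homozygous_recessive}
  fawn_and_white:
    # Fawn base (homozygous ky at CBD103) with at least one copy of the
    # co-dominantly expressed white-spotting allele.
    gene: MITF
    fault_alleles: [sp]
    inheritance: D
    factors:
      - {gene: CBD103, alleles: [ky], mode: homozygous_recessive}
      - {gene: MITF, alleles: [sp], mode: het_or_hom}
  fawn_harlequin:
    # Fawn base with exactly one harlequin copy (homozygotes are not viable);
    # reported on the conception scale, without live-birth renormalization.
    gene: PSMB7
    fault_alleles: [h]
    inheritance: D
    factors:
      - {gene: CBD103, alleles: [ky], mode: homozygous_recessive}
      - {gene: PSMB7, alleles: [h], mode: heterozygous_only}
  natural_bobtail:
    gene: T
    fault_alleles: [tailless]
    inheritance: D
    live_birth: true
    lethal_alleles:
      - {gene: T, allele: tailless}
    factors:
      - {gene: T, alleles: [tailless], mode: heterozygous_only}

standards:
  # Bull Terrier: always a black nose, never brown pigmentation.
  - {breed: BULT, registry: AKC, trait: brown, tolerance: N}
  - {breed: BULT, registry: UKC, trait: brown, tolerance: N}
  - {breed: BULT, registry: KC, trait: brown, tolerance: N}
  - {breed: BULT, registry: FCI, trait: brown, tolerance: N}
  # Schipperke: solid black everywhere except the KC, which allows any
  # solid colour.
  - {breed: SKIP, registry: AKC, trait: solid_red, tolerance: N}
  - {breed: SKIP, registry: UKC, trait: solid_red, tolerance: N}
  - {breed: SKIP, registry: FCI, trait: solid_red, tolerance: N}
  - {breed: SKIP, registry: KC, trait: solid_red, tolerance: Y}
  # Shetland Sheepdog: piebald disallowed by the AKC, tolerated but not
  # preferred by FCI and KC, allowed by the UKC.
  - {breed: SHET, registry: AKC, trait: piebald_spotting, tolerance: N}
  - {breed: SHET, registry: FCI, trait: piebald_spotting, tolerance: "n.p."}
  - {breed: SHET, registry: KC, trait: piebald_spotting, tolerance: "n.p."}
  - {breed: SHET, registry: UKC, trait: piebald_spotting, tolerance: Y}
  # Great Dane: white spotting and harlequin allowed only on a black base.
  - {breed: GDANE, registry: AKC, trait: fawn_and_white, tolerance: N}
  - {breed: GDANE, registry: UKC, trait: fawn_and_white, tolerance: N}
  - {breed: GDANE, registry: KC, trait: fawn_and_white, tolerance: N}
  - {breed: GDANE, registry: FCI, trait: fawn_and_white, tolerance: N}
  - {breed: GDANE, registry: AKC, trait: fawn_harlequin, tolerance: N}
  - {breed: GDANE, registry: UKC, trait: fawn_harlequin, tolerance: N}
  - {breed: GDANE, registry: KC, trait: fawn_harlequin, tolerance: N}
  - {breed: GDANE, registry: FCI, trait: fawn_harlequin, tolerance: N}
  # Black Russian Terrier placeholder: any non-solid colour is disallowed,
  # but the participating frequencies are breed-survey data not shipped here.
  - {breed: BRT, registry: FCI, trait: solid_red, tolerance: N}
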