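import itertools

import pytest

from coatmorph import (
    GenotypeCall,
    predict_phenotype,
    resolve_expressed_allele,
)
from coatmorph.trait_model import ConfigError

from oracles import core_phenotype_oracle


def call(gene, a, b, **kw):
    return GenotypeCall(gene, (a, b), **kw)


class TestResolveExpressedAllele:
    def test_fawn_dominant_over_recessive_black(self, catalog):
        expressed = resolve_expressed_allele(call("ASIP", "ay", "a"), catalog["ASIP"])
        assert expressed.symbol == "ay"

    @pytest.mark.parametrize("gene,symbol", [
        ("ASIP", "at"), ("MC1R", "e"), ("CBD103", "ky"), ("TYRP1", "bc"),
    ])
    def test_homozygote_expresses_itself(self, catalog, gene, symbol):
        expressed = resolve_expressed_allele(call(gene, symbol, symbol), catalog[gene])
        assert expressed.symbol == symbol

    def test_tyrp1_compound_heterozygote_is_brown_class(self, catalog):
        expressed = resolve_expressed_allele(call("TYRP1", "bs", "bc"), catalog["TYRP1"])
        assert not expressed.is_wild_type

    def test_tyrp1_one_wild_type_copy_is_black_class(self, catalog):
        expressed = resolve_expressed_allele(call("TYRP1", "bs", "B"), catalog["TYRP1"])
        assert expressed.is_wild_type

    def test_unknown_symbol_is_config_error(self, catalog):
        with pytest.raises(ConfigError):
            resolve_expressed_allele(call("ASIP", "ay", "zz"), catalog["ASIP"])

    def test_missing_genotype_rejected(self, catalog):
        missing = GenotypeCall("ASIP", (), missing=True)
        with pytest.raises(ValueError):
            resolve_expressed_allele(missing, catalog["ASIP"])

    def test_dominance_monotonicity(self, catalog):
        # replacing one allele with a more dominant one never makes the
        # expressed allele more recessive
        model = catalog["MC1R"]
        symbols = ["EM", "EG", "E", "e"]
        for partner in symbols:
            ranks = [
                resolve_expressed_allele(call("MC1R", s, partner), model).rank
                for s in symbols
            ]
            assert ranks == sorted(ranks)


class TestPredictPhenotype:
    def test_ee_with_dominant_black_is_solid_phaeomelanin(self):
        rep = predict_phenotype({
            "MC1R": call("MC1R", "e", "e"),
            "CBD103": call("CBD103", "KB_kbr", "KB_kbr"),
            "ASIP": call("ASIP", "ay", "ay"),
        })
        assert rep.pigment_pattern == "solid_phaeomelanin"

    def test_ancestral_baseline(self):
        rep = predict_phenotype({
            "MC1R": call("MC1R", "E", "E"),
            "CBD103": call("CBD103", "ky", "ky"),
            "ASIP": call("ASIP", "aw", "aw"),
            "TYRP1": call("TYRP1", "B", "B"),
            "MITF": call("MITF", "S", "S"),
            "PSMB7": call("PSMB7", "H", "H"),
            "RALY": call("RALY", "raly_wt", "raly_wt"),
            "FGF5": call("FGF5", "short", "short"),
            "KRT71": call("KRT71", "no_curl", "no_curl"),
            "T": call("T", "t_wt", "t_wt"),
        })
        assert rep.pigment_pattern == "wolf_sable"
        assert rep.eumelanin_shade == "black"
        assert rep.mask == "absent"
        assert rep.grizzle == "absent"
        assert rep.saddle == "not_capable"
        assert rep.white_spotting == "absent"
        assert rep.harlequin == "absent"
        assert rep.coat_length == "short"
        assert rep.curl == "absent"
        assert rep.tail == "normal"
        assert rep.viability

    def test_core_sweep_matches_rule_table_oracle(self, core_genotype_space):
        for genotypes in core_genotype_space:
            rep = predict_phenotype(genotypes)
            pattern, mask, grizzle = core_phenotype_oracle(
                genotypes["ASIP"].allele_pair,
                genotypes["MC1R"].allele_pair,
                genotypes["CBD103"].allele_pair,
            )
            assert rep.pigment_pattern == pattern
            assert rep.mask == mask
            assert rep.grizzle == grizzle

    def test_asip_masked_under_ee_and_dominant_black(self, core_genotype_space):
        # changing ASIP never changes the report when MC1R is e/e or CBD103
        # carries KB
        asip_pairs = list(itertools.combinations_with_replacement(
            ["ay", "aw", "at", "a"], 2))
        for mc1r, cbd in [
            (("e", "e"), ("ky", "ky")),
            (("E", "e"), ("KB_kbr", "ky")),
            (("EM", "e"), ("KB_kbr", "KB_kbr")),
        ]:
            reps = [
                predict_phenotype({
                    "MC1R": GenotypeCall("MC1R", mc1r),
                    "CBD103": GenotypeCall("CBD103", cbd),
                    "ASIP": GenotypeCall("ASIP", pair),
                })
                for pair in asip_pairs
            ]
            first = reps[0]
            for rep in reps[1:]:
                assert rep.pigment_pattern == first.pigment_pattern
                assert rep.mask == first.mask
                assert rep.grizzle == first.grizzle

    def test_mask_masked_on_solid_eumelanin(self):
        rep = predict_phenotype({
            "MC1R": call("MC1R", "EM", "E"),
            "CBD103": call("CBD103", "KB_kbr", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
        })
        assert rep.pigment_pattern == "solid_eumelanin_or_brindle"
        assert rep.mask == "masked_by_epistasis"

    def test_grizzle_requires_tan_point_background(self):
        base = {
            "CBD103": call("CBD103", "ky", "ky"),
            "MC1R": call("MC1R", "EG", "E"),
        }
        on_tan = predict_phenotype({**base, "ASIP": call("ASIP", "at", "at")})
        assert on_tan.grizzle == "expressed"
        on_fawn = predict_phenotype({**base, "ASIP": call("ASIP", "ay", "at")})
        assert on_fawn.grizzle == "carried_unexpressed"

    def test_em_outranks_eg(self):
        rep = predict_phenotype({
            "CBD103": call("CBD103", "ky", "ky"),
            "MC1R": call("MC1R", "EM", "EG"),
            "ASIP": call("ASIP", "at", "at"),
        })
        assert rep.grizzle == "carried_unexpressed"
        assert rep.mask == "present"

    def test_saddle_capable_only_on_tan_points(self):
        base = {
            "CBD103": call("CBD103", "ky", "ky"),
            "MC1R": call("MC1R", "E", "E"),
            "RALY": call("RALY", "saddle_dup", "raly_wt"),
        }
        tan = predict_phenotype({**base, "ASIP": call("ASIP", "at", "at")})
        assert tan.saddle == "capable"
        fawn = predict_phenotype({**base, "ASIP": call("ASIP", "ay", "at")})
        assert fawn.saddle == "not_capable"

    def test_ayt_reported_uncharacterized(self):
        rep = predict_phenotype({
            "CBD103": call("CBD103", "ky", "ky"),
            "MC1R": call("MC1R", "E", "E"),
            "ASIP": call("ASIP", "ayt", "ay"),
        })
        assert rep.pigment_pattern == "ayt_uncharacterized"

    def test_brown_nose_even_under_ee(self):
        rep = predict_phenotype({
            "MC1R": call("MC1R", "e", "e"),
            "CBD103": call("CBD103", "ky", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
            "TYRP1": call("TYRP1", "bs", "bc"),
        })
        assert rep.pigment_pattern == "solid_phaeomelanin"
        assert rep.nose_shade == "brown"

    @pytest.mark.parametrize("mode,expected", [
        ("co_dominant", "expressed"),
        ("recessive", "absent"),
        (None, "breed_dependent"),
    ])
    def test_mitf_heterozygote_by_breed_mode(self, mode, expected):
        cfg = {"mitf_mode": mode} if mode else None
        rep = predict_phenotype({
            "MC1R": call("MC1R", "E", "E"),
            "CBD103": call("CBD103", "ky", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
            "MITF": call("MITF", "S", "sp"),
        }, breed_config=cfg)
        assert rep.white_spotting == expected

    def test_harlequin_one_copy_and_lethality(self):
        base = {
            "MC1R": call("MC1R", "E", "E"),
            "CBD103": call("CBD103", "KB_kbr", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
        }
        het = predict_phenotype({**base, "PSMB7": call("PSMB7", "H", "h")})
        assert het.harlequin == "capable_if_merle" and het.viability
        hom = predict_phenotype({**base, "PSMB7": call("PSMB7", "h", "h")})
        assert hom.harlequin == "absent" and not hom.viability

    def test_curl_gated_on_coat_length(self):
        base = {
            "MC1R": call("MC1R", "E", "E"),
            "CBD103": call("CBD103", "ky", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
            "KRT71": call("KRT71", "curl", "no_curl"),
        }
        long = predict_phenotype({**base, "FGF5": call("FGF5", "long", "long")})
        assert long.coat_length == "long" and long.curl == "expressed"
        short = predict_phenotype({**base, "FGF5": call("FGF5", "long", "short")})
        assert short.coat_length == "short" and short.curl == "carried_masked"

    def test_tailless_bobtail_and_lethality(self):
        base = {
            "MC1R": call("MC1R", "E", "E"),
            "CBD103": call("CBD103", "ky", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
        }
        het = predict_phenotype({**base, "T": call("T", "tailless", "t_wt")})
        assert het.tail == "natural_bobtail" and het.viability
        hom = predict_phenotype({**base, "T": call("T", "tailless", "tailless")})
        assert not hom.viability

    def test_viability_false_only_for_lethal_homozygotes(self, core_genotype_space):
        for genotypes in core_genotype_space:
            assert predict_phenotype(genotypes).viability

    def test_missing_core_gene_warns_not_crashes(self):
        rep = predict_phenotype({"ASIP": call("ASIP", "ay", "ay")})
        assert rep.pigment_pattern == "unknown"
        assert rep.warnings

    def test_polygenic_genotypes_reported_with_qualifier(self):
        rep = predict_phenotype({
            "MC1R": call("MC1R", "E", "E"),
            "CBD103": call("CBD103", "ky", "ky"),
            "ASIP": call("ASIP", "ay", "ay"),
            "BMP3": call("BMP3", "bmp3_wt", "short_muzzle"),
            "EAR": call("EAR", "drop", "erect"),
        })
        assert "polygenic context" in rep.muzzle_genotype
        assert "polygenic context" in rep.ear_genotype


class TestCatalog:
    def test_table_catalogue_contents(self, catalog):
        assert set(catalog.gene_ids) == {
            "ASIP", "MC1R", "CBD103", "TYRP1", "MITF", "PSMB7", "RALY",
            "FGF5", "KRT71", "T", "BMP3", "EAR",
        }
        assert {a.symbol for a in catalog["ASIP"].alleles} == {"ayt", "ay", "aw", "at", "a"}
        assert {a.symbol for a in catalog["MC1R"].alleles} == {"EM", "EG", "E", "e"}

    def test_lethal_flags(self, catalog):
        lethal = {
            (a.gene_id, a.symbol)
            for m in catalog for a in m.alleles if a.lethal_homozygous
        }
        assert lethal == {("PSMB7", "h"), ("T", "tailless")}

    def test_by_exclusion_alleles_have_no_markers(self, catalog):
        assert catalog["ASIP"].allele("aw").markers == ()
        assert catalog["MC1R"].allele("E").markers == ()

    def test_tyrp1_is_compound_recessive(self, catalog):
        assert catalog["TYRP1"].mode == "compound_recessive"

    def test_ranks_unique_per_gene(self, catalog):
        for model in catalog:
            ranks = [a.rank for a in model.alleles]
            assert len(set(ranks)) == len(ranks)
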