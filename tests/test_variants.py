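"""Quartet variant filter cascade, inheritance classes and partition."""

import itertools

import pytest

from quartetnet import (
    AnnotatedVariant,
    GenotypeCall,
    classify_inheritance,
    consequence_filter,
    deleteriousness_filter,
    generate_quartet_variants,
    partition_siblings,
    qc_filter,
    rarity_filter,
    run_cascade,
)
from quartetnet.quartet import FATHER, MOTHER, SIB_M, SIB_F, MEMBERS
from quartetnet.variants import (
    DE_NOVO, HEMIZYGOUS_X, INHERITED_MATERNAL, INHERITED_PATERNAL,
    MENDELIAN_ERROR, NOT_CARRIED, DropLog,
)


def gt(alleles=(0, 1), depth=35, gq=60, base_q=38):
    return GenotypeCall(alleles=alleles, depth=depth, gq=gq, base_q=base_q)


def variant(genotypes=None, **kw):
    defaults = dict(
        chrom="chr1", pos=1000, ref="A", alt="G", gene="GENE1",
        consequence="nonsynonymous_snv",
        freq_db1=0.001, freq_db2=0.001, freq_db3=0.001,
        conservation=3.0, deleteriousness="deleterious",
    )
    defaults.update(kw)
    if genotypes is None:
        genotypes = {m: gt((0, 1) if m != FATHER else (0, 1)) for m in MEMBERS}
    return AnnotatedVariant(genotypes=genotypes, **defaults)


class TestQcFilter:
    def test_good_calls_kept(self):
        assert len(qc_filter([variant()])) == 1

    def test_one_low_depth_member_drops_variant(self):
        g = {m: gt() for m in MEMBERS}
        g[FATHER] = gt(depth=19)
        assert qc_filter([variant(genotypes=g)]) == []

    def test_thresholds_inclusive(self):
        g = {m: gt(depth=20, gq=20, base_q=30) for m in MEMBERS}
        assert len(qc_filter([variant(genotypes=g)])) == 1

    def test_missing_member_dropped_and_logged(self):
        g = {m: gt() for m in (FATHER, MOTHER, SIB_M)}
        log = DropLog()
        assert qc_filter([variant(genotypes=g)], log=log) == []
        assert any("missing genotype" in reason for _, _, reason in log.entries)


class TestRarityFilter:
    def test_rare_in_all_panels_kept(self):
        # frequencies as printed for the hemizygous nonsynonymous X variant
        v = variant(freq_db1=0.0013, freq_db2=0.0017, freq_db3=0.0006)
        assert len(rarity_filter([v])) == 1

    def test_novel_all_missing_kept(self):
        v = variant(freq_db1=None, freq_db2=None, freq_db3=None)
        assert len(rarity_filter([v])) == 1

    def test_one_common_panel_drops(self):
        v = variant(freq_db2=0.02)
        assert rarity_filter([v]) == []

    def test_boundary_inclusive(self):
        assert len(rarity_filter([variant(freq_db1=0.01)])) == 1


class TestConsequenceFilter:
    @pytest.mark.parametrize("cons,kept", [
        ("synonymous", False),
        ("other", False),
        ("nonsynonymous_snv", True),
        ("stopgain", True),
        ("stoploss", True),
        ("splicing", True),
        ("frameshift_indel", True),
        ("nonframeshift_indel", True),
    ])
    def test_consequence_classes(self, cons, kept):
        out = consequence_filter([variant(consequence=cons)])
        assert bool(out) is kept

    def test_unknown_consequence_strict_raises(self):
        with pytest.raises(ValueError, match="unknown consequence"):
            consequence_filter([variant(consequence="weird")], strict=True)


class TestDeleteriousnessFilter:
    def test_conserved_and_damaging_kept(self):
        v = variant(conservation=3.37, deleteriousness="deleterious")
        assert len(deleteriousness_filter([v])) == 1

    def test_conservation_boundary(self):
        assert deleteriousness_filter([variant(conservation=1.9)]) == []
        assert len(deleteriousness_filter([variant(conservation=2.0)])) == 1

    def test_benign_dropped(self):
        assert deleteriousness_filter([variant(deleteriousness="benign")]) == []

    def test_missing_annotations_pass(self):
        v = variant(conservation=None, deleteriousness=None)
        assert len(deleteriousness_filter([v])) == 1

    def test_conjunctive_when_both_present(self):
        v = variant(conservation=1.0, deleteriousness="deleterious")
        assert deleteriousness_filter([v]) == []


class TestInheritanceClassification:
    def quartet(self, fa, mo, sm, sf=(0, 0)):
        return {FATHER: gt(fa), MOTHER: gt(mo), SIB_M: gt(sm), SIB_F: gt(sf)}

    def test_de_novo_requires_hom_ref_parents(self):
        v = variant(genotypes=self.quartet((0, 0), (0, 0), (0, 1)))
        assert classify_inheritance(v, SIB_M) == DE_NOVO

    def test_paternal_and_maternal(self):
        v = variant(genotypes=self.quartet((0, 1), (0, 0), (0, 1)))
        assert classify_inheritance(v, SIB_M) == INHERITED_PATERNAL
        v = variant(genotypes=self.quartet((0, 0), (0, 1), (0, 1)))
        assert classify_inheritance(v, SIB_M) == INHERITED_MATERNAL

    def test_hemizygous_x_with_carrier_mother(self):
        v = variant(
            chrom="chrX", pos=19_032_163,
            genotypes={FATHER: gt((0,)), MOTHER: gt((0, 1)),
                       SIB_M: gt((1,)), SIB_F: gt((0, 0))},
        )
        assert classify_inheritance(v, SIB_M) == HEMIZYGOUS_X

    def test_x_par_locus_is_diploid_not_hemizygous(self):
        # PAR1 position: ordinary autosomal-style classification
        v = variant(
            chrom="chrX", pos=100_000,
            genotypes=self.quartet((0, 1), (0, 0), (0, 1)),
        )
        assert classify_inheritance(v, SIB_M) == INHERITED_PATERNAL

    def test_hom_alt_father_is_paternal_not_error(self):
        v = variant(genotypes={
            FATHER: GenotypeCall((1, 1), 35, 60, 38), MOTHER: gt((0, 0)),
            SIB_M: gt((0, 1)), SIB_F: gt((0, 0)),
        }, alt="T")
        assert classify_inheritance(v, SIB_M) == INHERITED_PATERNAL

    def test_mendelian_error_on_male_x(self):
        # son's X comes from the mother; a paternal-only X alt is inconsistent
        v = variant(
            chrom="chrX", pos=19_032_163,
            genotypes={FATHER: gt((1,)), MOTHER: gt((0, 0)),
                       SIB_M: gt((1,)), SIB_F: gt((0, 0))},
        )
        assert classify_inheritance(v, SIB_M) == MENDELIAN_ERROR

    def test_not_carried(self):
        v = variant(genotypes=self.quartet((0, 1), (0, 0), (0, 0)))
        assert classify_inheritance(v, SIB_M) == NOT_CARRIED


class TestPartition:
    def test_no_variants(self):
        part = partition_siblings([])
        assert part.counts() == {k: 0 for k in part.counts()}
        assert part.total_inherited == 0

    def test_both_children_shared(self):
        g = {FATHER: gt((0, 1)), MOTHER: gt((0, 0)),
             SIB_M: gt((0, 1)), SIB_F: gt((0, 1))}
        part = partition_siblings([variant(genotypes=g)])
        assert len(part.shared) == 1 and part.total_inherited == 1

    def test_neither_child_excluded_with_log(self):
        g = {FATHER: gt((0, 1)), MOTHER: gt((0, 0)),
             SIB_M: gt((0, 0)), SIB_F: gt((0, 0))}
        log = DropLog()
        part = partition_siblings([variant(genotypes=g)], log=log)
        assert part.total_inherited == 0
        assert log.counts() == {"partition": 1}

    def test_tallies_sum_to_list_lengths(self, small_spec):
        vs, _ = generate_quartet_variants(small_spec)
        part = partition_siblings(run_cascade(vs))
        for name, tally in part.tallies().items():
            assert sum(tally.values()) == len(getattr(part, name))


class TestCascadeProperties:
    def test_each_filter_is_monotone_subset(self, small_spec):
        vs, _ = generate_quartet_variants(small_spec)
        for f in (qc_filter, rarity_filter, consequence_filter, deleteriousness_filter):
            out = f(vs)
            assert len(out) <= len(vs)
            assert all(v in vs for v in out)

    def test_annotation_filters_commute(self, small_spec):
        vs, _ = generate_quartet_variants(small_spec)
        filters = {
            "rarity": rarity_filter,
            "consequence": consequence_filter,
            "deleteriousness": deleteriousness_filter,
        }
        results = set()
        for order in itertools.permutations(filters.values()):
            out = vs
            for f in order:
                out = f(out)
            results.add(tuple(v.key for v in out))
        assert len(results) == 1

    def test_partition_conserves_total(self, small_spec):
        vs, _ = generate_quartet_variants(small_spec)
        survivors = run_cascade(vs)
        part = partition_siblings(survivors)
        child_carried = sum(
            1 for v in survivors
            if any(v.genotype(c) and v.genotype(c).carries_alt for c in (SIB_M, SIB_F))
        )
        assert sum(part.counts().values()) == child_carried

    def test_planted_truth_recovery_all_classes(self, small_spec):
        vs, truth = generate_quartet_variants(small_spec)
        part = partition_siblings(run_cascade(vs))
        expected = truth.counts()
        assert len(part.shared) == expected["shared"]
        n_hemi = len(part.hemizygous_x_male)
        n_dn_m, n_dn_f = len(part.de_novo_male), len(part.de_novo_female)
        assert n_hemi == small_spec.hemizygous_x_count
        assert len(part.male_exclusive) + n_hemi + n_dn_m == expected["male_only"]
        assert len(part.female_exclusive) + n_dn_f == expected["female_only"]
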