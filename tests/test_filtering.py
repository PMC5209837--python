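"""Variant filter cascade and genotype-configuration classification."""

import itertools

import numpy as np
import pytest

from alecross import datasets
from alecross import filtering as flt

SAMPLES = ("P", "E", "B")
ROLES = flt.SampleRoles(parent="P", evolved="E", backcrossed="B")


def record(alleles, depths=(50, 50, 50), quals=(99, 99, 99), pos=100,
           ref="C", chrom="c1", in_cnv=None):
    alts = tuple(
        dict.fromkeys(
            a
            for al in alleles
            for a in ((al,) if isinstance(al, str) else (al or ()))
            if a is not None and a != ref
        )
    )
    calls = tuple(
        flt.SampleCall(sample=s, allele=a, depth=d, quality=q)
        for s, a, d, q in zip(SAMPLES, alleles, depths, quals)
    )
    return flt.VariantRecord(
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_alleles=alts,
        calls=calls,
        in_cnv=in_cnv or {},
    )


def random_records(seed: int, n: int = 60) -> list[flt.VariantRecord]:
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        alleles = []
        for _ in SAMPLES:
            r = rng.random()
            if r < 0.08:
                alleles.append(None)
            elif r < 0.2:
                alleles.append(("C", "T"))
            else:
                alleles.append(str(rng.choice(["C", "T", "G"])))
        recs.append(
            record(
                alleles,
                depths=tuple(int(d) for d in rng.integers(0, 80, 3)),
                quals=tuple(int(q) for q in rng.integers(0, 255, 3)),
                pos=int(i * 10 + 1),
                in_cnv={s: bool(rng.random() < 0.1) for s in SAMPLES},
            )
        )
    return recs


class TestDepthQualityFilter:
    def test_boundary_plus_one_retained(self):
        recs = [record(("C", "T", "T"), depths=(21, 21, 21), quals=(61, 61, 61))]
        assert flt.filter_by_quality(recs, flt.FilterConfig()) == recs

    def test_thresholds_are_strict(self):
        at_depth = record(("C", "T", "T"), depths=(20, 50, 50))
        at_quality = record(("C", "T", "T"), quals=(60, 99, 99))
        assert flt.filter_by_quality([at_depth, at_quality], flt.FilterConfig()) == []

    def test_missing_call_dropped_not_raised(self):
        recs = [record(("C", None, "T"))]
        assert flt.filter_by_quality(recs, flt.FilterConfig()) == []

    def test_empty_input(self):
        assert flt.filter_by_quality([], flt.FilterConfig()) == []


class TestPolymorphismFilter:
    def test_monomorphic_dropped(self):
        assert flt.retain_polymorphic([record(("C", "C", "C"))]) == []

    def test_parent_ref_evolved_alt_retained(self):
        recs = [record(("G", "A", "A"), ref="G")]
        assert flt.retain_polymorphic(recs) == recs

    def test_single_allele_with_missing_dropped(self):
        assert flt.retain_polymorphic([record(("C", None, "C"))]) == []


class TestHeterozygousFilter:
    def test_het_call_dropped(self):
        assert flt.remove_heterozygous([record((("C", "T"), "C", "C"))]) == []

    def test_all_homozygous_retained(self):
        recs = [record(("C", "T", "C"))]
        assert flt.remove_heterozygous(recs) == recs

    def test_empty(self):
        assert flt.remove_heterozygous([]) == []


class TestCnvFilter:
    def test_contained_position_dropped(self):
        recs = [record(("C", "T", "C"), pos=500, chrom="chrI")]
        regions = {"E": [("chrI", 400, 600)]}
        assert flt.remove_cnv_overlap(recs, regions) == []

    def test_no_regions_is_identity(self):
        recs = [record(("C", "T", "C"))]
        assert flt.remove_cnv_overlap(recs, {}) == recs

    def test_half_open_end_boundary_retained(self):
        # 1-based position 601 is 0-based 600, outside [400, 600)
        recs = [record(("C", "T", "C"), pos=601, chrom="chrI")]
        assert flt.remove_cnv_overlap(recs, {"P": [("chrI", 400, 600)]}) == recs
        # brute-force membership oracle over the boundary region
        for pos in range(395, 606):
            member_oracle = pos - 1 in range(400, 600)
            assert flt.position_in_regions("chrI", pos, [("chrI", 400, 600)]) == member_oracle

    def test_any_vs_all_mode(self):
        recs = [record(("C", "T", "C"), pos=500, in_cnv={"P": True, "E": False, "B": False})]
        assert flt.remove_cnv_overlap(recs, mode="any") == []
        assert flt.remove_cnv_overlap(recs, mode="all") == recs

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            flt.remove_cnv_overlap([record(("C", "T", "C"))], {"P": [("c1", 100, 50)]})


class TestStatusClassification:
    @pytest.mark.parametrize(
        "alleles,status",
        [
            (("C", "T", "C"), flt.VariantStatus.LOST_IN_BACKCROSS),
            (("T", "C", "C"), flt.VariantStatus.SEGREGATING),
            (("C", "C", "C"), flt.VariantStatus.NOT_EVOLVED_SPECIFIC),
            (("C", "T", "G"), flt.VariantStatus.INCONSISTENT),
        ],
    )
    def test_configurations(self, alleles, status):
        assert flt.classify_status(record(alleles), ROLES) == status

    def test_parent_differing_from_reference_is_still_baseline(self):
        # evolved matches the published reference but differs from the parent
        rec = record(("A", "C", "A"), ref="C")
        assert flt.classify_status(rec, ROLES) == flt.VariantStatus.LOST_IN_BACKCROSS

    def test_missing_role_call_rejected(self):
        with pytest.raises(ValueError):
            flt.classify_status(record(("C", None, "T")), ROLES)


class TestCascade:
    def test_packaged_trio_table(self):
        result = flt.run_cascade(
            datasets.trio_filtered_variants(), flt.FilterConfig(), datasets.trio_roles()
        )
        s = result.summary
        assert s["after_cnv"] == 10
        assert (s["n_snps"], s["n_indels"]) == (7, 3)
        assert (s["lost_in_backcross"], s["segregating"]) == (8, 2)
        segregating_orfs = {
            r.annotation.split(";")[0]
            for r in result.with_status(flt.VariantStatus.SEGREGATING)
        }
        assert segregating_orfs == {"GUT1", "UBR2"}

    def test_monomorphic_clean_input_yields_nothing(self):
        cfg = flt.FilterConfig(min_depth=0, min_quality=0)
        recs = [record(("C", "C", "C"), pos=p) for p in (1, 2, 3)]
        assert flt.run_cascade(recs, cfg, ROLES).records == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_filters_idempotent_and_order_independent(self, seed):
        cfg = flt.FilterConfig()
        recs = random_records(seed)
        filters = [
            lambda r: flt.filter_by_quality(r, cfg),
            flt.retain_polymorphic,
            flt.remove_heterozygous,
            lambda r: flt.remove_cnv_overlap(r, {}),
        ]
        for f in filters:
            once = f(recs)
            assert f(once) == once  # idempotent
        expected = [r for r in recs if all(r in f(recs) for f in filters)]
        for order in itertools.permutations(range(4)):
            out = recs
            for i in order:
                out = filters[i](out)
            assert out == expected

    @pytest.mark.parametrize("seed", [3, 4])
    def test_counts_monotonically_non_increasing(self, seed):
        result = flt.run_cascade(random_records(seed), flt.FilterConfig(), ROLES)
        s = result.summary
        stages = [
            s["input"], s["after_depth_quality"], s["after_polymorphic"],
            s["after_heterozygous"], s["after_cnv"],
        ]
        assert all(a >= b for a, b in zip(stages, stages[1:]))
        original = random_records(seed)
        assert all(rec in original for rec in result.records)


class TestVcfRoundTrip:
    def test_write_is_deterministic_and_read_recovers_records(self, tmp_path):
        recs = datasets.trio_filtered_variants()
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        from alecross import io

        io.write_vcf(recs, p1)
        io.write_vcf(recs, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = io.read_vcf(p1)
        assert [
            (r.chromosome, r.position, r.ref_allele, tuple(c.allele for c in r.calls))
            for r in back
        ] == [
            (r.chromosome, r.position, r.ref_allele, tuple(c.allele for c in r.calls))
            for r in recs
        ]
        result = flt.run_cascade(back, flt.FilterConfig(), datasets.trio_roles())
        assert (result.summary["lost_in_backcross"], result.summary["segregating"]) == (8, 2)
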