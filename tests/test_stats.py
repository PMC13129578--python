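import pytest

from svtable import (
    chromosome_summary,
    genotype_concordance,
    hom_het_ratio,
    length_histogram,
    sample_summary,
    select_marker_candidates,
    type_proportions,
)
from svtable.datasets import validation_marker_grids
from svtable.model import Cohort, MergedSite, ReferenceGenome
from svtable.stats import ChromSummary, SampleSummary


def make_site(pos, sv_type="DEL", length=100, genotypes=None, chrom="chr1"):
    end = pos if sv_type in ("INS", "BND") else pos + (length or 0)
    return MergedSite(
        chrom=chrom, pos=pos, sv_type=sv_type, length=length, end=end,
        stdev_pos=0.0, stdev_len=0.0, precise=True,
        genotypes=genotypes or {"A": "0/1", "B": "0/0", "C": "0/0"},
    )


SAMPLES = ["A", "B", "C"]


class TestChromosomeSummary:
    def test_unit_density(self):
        genome = ReferenceGenome([("chr1", "A" * 1000)])
        # treat the 1 kb toy contig as 1 "Mb" by scaling: use real formula on 1e6
        cohort = Cohort(samples=SAMPLES, sites=[make_site(p) for p in (100, 300, 500, 700, 900)])
        rows = chromosome_summary(cohort, genome)
        assert rows[0].n_sites == 5
        assert rows[0].density == pytest.approx(5 / (1000 / 1e6))

    def test_whole_genome_density_matches_published_arithmetic(self):
        # 59,983 sites over a 372.92 Mb genome -> 160.85 per Mb
        total = ChromSummary("Total", 59983, 372_920_000, 17516)
        assert round(total.density, 2) == 160.85

    def test_three_genotype_membership(self):
        sites = [
            make_site(100, genotypes={"A": "0/0", "B": "0/1", "C": "1/1"}),
            make_site(60000, genotypes={"A": "0/0", "B": "0/1", "C": "0/1"}),
        ]
        genome = ReferenceGenome([("chr1", "A" * 100000)])
        rows = chromosome_summary(Cohort(samples=SAMPLES, sites=sites), genome)
        assert rows[0].n_three_genotype == 1

    def test_totals_row_aggregates(self, sim_bundle):
        genome, _, _, cohort = sim_bundle
        rows = chromosome_summary(cohort, genome)
        assert rows[-1].chrom == "Total"
        assert rows[-1].n_sites == sum(r.n_sites for r in rows[:-1]) == len(cohort.sites)
        assert rows[-1].n_three_genotype == sum(r.n_three_genotype for r in rows[:-1])

    def test_unknown_chrom_rejected(self):
        genome = ReferenceGenome([("chr1", "AAAA")])
        cohort = Cohort(samples=SAMPLES, sites=[make_site(10, chrom="chr9")])
        with pytest.raises(KeyError):
            chromosome_summary(cohort, genome)


class TestSampleSummary:
    def test_zygosity_and_type_breakdown(self):
        sites = [
            make_site(100, "DEL", genotypes={"A": "0/1", "B": "1/1", "C": "0/0"}),
            make_site(60000, "INS", genotypes={"A": "1/1", "B": "0/0", "C": "0/0"}),
        ]
        rows = sample_summary(Cohort(samples=SAMPLES, sites=sites))
        a = rows[0]
        assert a.type_counts == {"DEL": 1, "INS": 1}
        assert a.n_hom == 1 and a.n_het == 1 and a.total == 2
        assert rows[2].total == 0  # all-0/0 sample

    def test_totals_identity_on_random_cohort(self, sim_bundle):
        _, _, _, cohort = sim_bundle
        for row in sample_summary(cohort):
            # brute-force recount oracle
            n = sum(
                1
                for s in cohort.sites
                if s.genotypes.get(row.sample_id, "0/0") != "0/0"
            )
            assert row.total == n == sum(row.type_counts.values())


# (hom, het) tallies per non-reference cultivar from the published cohort
_PUBLISHED_HOM_HET = [
    (1819, 9773), (3755, 7755), (6447, 7014), (6236, 8166), (6108, 5585),
    (4950, 9151), (6704, 6613), (6615, 10838), (7489, 12066), (4354, 13246),
    (8240, 11632), (5732, 11375), (7460, 13757),
]


class TestHomHetRatio:
    def test_reference_derived_sample_ratio(self):
        # the cultivar whose reads built the reference: 158 hom / 6,048 het
        summ = SampleSummary("ref_cultivar", n_hom=158, n_het=6048)
        assert hom_het_ratio(summ) == pytest.approx(0.026, abs=5e-4)

    def test_mean_ratio_over_published_cohort(self):
        ratios = [
            hom_het_ratio(SampleSummary(f"c{i}", n_hom=h, n_het=e))
            for i, (h, e) in enumerate(_PUBLISHED_HOM_HET)
        ]
        assert sum(ratios) / len(ratios) == pytest.approx(0.64, abs=5e-3)

    def test_zero_hom(self):
        assert hom_het_ratio(SampleSummary("x", n_hom=0, n_het=10)) == 0.0

    def test_no_het_undefined(self):
        with pytest.raises(ZeroDivisionError):
            hom_het_ratio(SampleSummary("x", n_hom=5, n_het=0))


class TestLengthHistogram:
    def test_half_open_boundaries(self):
        sites = [make_site(p, length=l) for p, l in ((100, 50), (60000, 99), (120000, 100))]
        hist = length_histogram(Cohort(samples=SAMPLES, sites=sites))
        counts = dict(hist)
        assert counts[(50, 100)] == 2 and counts[(100, 150)] == 1

    def test_overflow_bin_and_closure(self):
        sites = [
            make_site(100, length=10000),    # last regular bin (closed at 10,000)
            make_site(60000, length=10001),  # overflow
            make_site(120000, length=25000),
        ]
        hist = length_histogram(Cohort(samples=SAMPLES, sites=sites))
        assert dict(hist)[(9950, 10000)] == 1
        assert hist[-1] == ((10000, None), 2)

    def test_bnd_excluded(self):
        sites = [make_site(p, "BND", None) for p in (100, 60000, 120000)]
        hist = length_histogram(Cohort(samples=SAMPLES, sites=sites))
        assert sum(c for _, c in hist) == 0

    def test_counts_sum_to_length_defined_sites(self, sim_bundle):
        _, _, _, cohort = sim_bundle
        hist = length_histogram(cohort)
        n_defined = sum(1 for s in cohort.sites if s.length is not None)
        assert sum(c for _, c in hist) == n_defined
        assert all(c >= 0 for _, c in hist)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            length_histogram(Cohort(samples=SAMPLES, sites=[]), bin_width=0)


class TestTypeProportions:
    def test_fractions_over_all_sites(self):
        sites = [
            make_site(100, "DEL"), make_site(60000, "DEL"),
            make_site(120000, "INS", 60), make_site(180000, "BND", None),
        ]
        props = type_proportions(Cohort(samples=SAMPLES, sites=sites))
        assert props["DEL"] == pytest.approx(0.5)
        assert props["BND"] == pytest.approx(0.25)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_single_type(self):
        props = type_proportions(Cohort(samples=SAMPLES, sites=[make_site(1)]))
        assert props == {"DEL": 1.0}

    def test_published_type_composition(self):
        # a cohort with the published type tally: 29,058 DEL, 24,867 INS,
        # 545 INV, 470 DUP, remainder BND, 59,983 sites in all
        counts = {"DEL": 29058, "INS": 24867, "INV": 545, "DUP": 470, "BND": 5043}
        sites = []
        pos = 0
        for sv_type, n in counts.items():
            length = None if sv_type == "BND" else 100
            for _ in range(n):
                pos += 1
                sites.append(make_site(pos, sv_type, length))
        props = type_proportions(Cohort(samples=SAMPLES, sites=sites))
        assert round(props["DEL"] * 100, 2) == 48.44
        assert round(props["INS"] * 100, 2) == 41.46
        assert props["INV"] * 100 == pytest.approx(0.90, abs=0.015)
        assert round(props["DUP"] * 100, 2) == 0.78

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            type_proportions(Cohort(samples=SAMPLES, sites=[]))


def three_gt(sample_gts):
    return dict(zip(SAMPLES, sample_gts))


class TestSelectMarkerCandidates:
    def make_cohort(self):
        sites = [
            make_site(100, "DEL", 63, three_gt(["0/0", "0/1", "1/1"])),     # keep
            make_site(60000, "INS", 1001, three_gt(["0/0", "0/1", "1/1"])),  # too long
            make_site(120000, "INV", 100, three_gt(["0/0", "0/1", "1/1"])),  # wrong type
            make_site(180000, "DEL", 100, three_gt(["0/1", "0/1", "1/1"])),  # not 3-genotype
            make_site(240000, "INS", 200, three_gt(["1/1", "0/1", "0/0"])),  # ref sample 1/1
        ]
        return Cohort(samples=SAMPLES, sites=sites)

    def test_selection_rules(self):
        cohort = self.make_cohort()
        kept = select_marker_candidates(cohort)
        assert [s.pos for s in kept] == [100, 240000]

    def test_reference_sample_exclusion(self):
        cohort = self.make_cohort()
        kept = select_marker_candidates(cohort, reference_sample="A")
        assert [s.pos for s in kept] == [100]

    def test_reference_filter_never_grows_output(self, sim_bundle):
        _, _, _, cohort = sim_bundle
        base = select_marker_candidates(cohort)
        for sample in cohort.samples:
            sub = select_marker_candidates(cohort, reference_sample=sample)
            assert set(s.key for s in sub) <= set(s.key for s in base)

    def test_unknown_reference_sample(self):
        with pytest.raises(KeyError):
            select_marker_candidates(self.make_cohort(), reference_sample="Z")


class TestGenotypeConcordance:
    def test_published_validation_grids(self):
        predicted, observed = validation_marker_grids()
        result = genotype_concordance(predicted, observed)
        rates = [result.per_marker[m] for m in predicted.index]
        assert [round(r * 14) for r in rates] == [13, 13, 12, 14, 13, 14, 14, 13, 13]
        assert result.mean * 100 == pytest.approx(94.4, abs=0.05)

    def test_discrepant_cultivars_identified(self):
        predicted, observed = validation_marker_grids()
        result = genotype_concordance(predicted, observed)
        m3 = sorted(s for m, s, _, _ in result.mismatches if m == "marker3")
        assert m3 == ["Murcott tangor", "Pummelo"]

    def test_identity(self):
        predicted, _ = validation_marker_grids()
        result = genotype_concordance(predicted, predicted.copy())
        assert all(r == 1.0 for r in result.per_marker.values())
        assert result.mean == 1.0 and result.mismatches == []

    def test_symmetric(self):
        predicted, observed = validation_marker_grids()
        a = genotype_concordance(predicted, observed)
        b = genotype_concordance(observed, predicted)
        assert a.per_marker == b.per_marker and a.mean == b.mean

    def test_shape_mismatch_rejected(self):
        predicted, observed = validation_marker_grids()
        with pytest.raises(ValueError):
            genotype_concordance(predicted, observed.iloc[:, :-1])
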