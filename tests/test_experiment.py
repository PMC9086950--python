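"""Treatment grids, rank-sum statistics, census pairing, and VCF export."""

import numpy as np
import pysam
import pytest

from haplosim.experiment import (
    EQUAL_CHROMOSOMES,
    Treatment,
    TreatmentGrid,
    compare_population_types,
    diploid_census_for_pairing,
    exact_rank_sum_test,
    export_vcf,
    figure1_full_preset,
    normal_approx_rank_sum_test,
    run_grid,
)
from haplosim.gametogenesis import MeiosisParams
from haplosim.genome_core import HAPLODIPLOID, Population
from haplosim.lifecycle import SimulationConfig


# --- rank-sum statistics ---------------------------------------------------


def test_exact_rank_sum_extreme_arrangement():
    """[5,6,7] vs [1,2,3]: the most extreme of the C(6,3)=20 assignments in
    each direction, so the exact two-sided p is 2/20 = 0.1."""
    w, p = exact_rank_sum_test([5, 6, 7], [1, 2, 3])
    assert w == 15.0
    assert p == pytest.approx(0.1)


def test_identical_samples_are_not_distinguishable():
    res = compare_population_types([4, 4, 4], [4, 4, 4])
    assert res.mean_difference == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert res.method == "exact"


def test_exact_one_sided_tails():
    _, p_greater = exact_rank_sum_test([5, 6, 7], [1, 2, 3], "greater")
    _, p_less = exact_rank_sum_test([5, 6, 7], [1, 2, 3], "less")
    assert p_greater == pytest.approx(1 / 20)
    assert p_less == pytest.approx(1.0)


def test_normal_approximation_matches_exact_at_n8():
    """Cross-validation of the two rank-sum computations at n=8 per group."""
    rng = np.random.default_rng(10)
    x = rng.normal(1.0, 1.0, 8)
    y = rng.normal(0.0, 1.0, 8)
    w_e, p_e = exact_rank_sum_test(x, y)
    w_n, p_n = normal_approx_rank_sum_test(x, y)
    assert w_e == w_n
    assert abs(p_e - p_n) < 0.01


def test_compare_selects_method_by_sample_size():
    rng = np.random.default_rng(11)
    small = compare_population_types(rng.normal(size=5), rng.normal(size=5))
    large = compare_population_types(rng.normal(size=30), rng.normal(size=30))
    assert small.method == "exact"
    assert large.method == "normal_approx"
    with pytest.raises(ValueError):
        compare_population_types([], [1.0])


# --- census pairing and grids ----------------------------------------------


def test_equal_chromosome_pairing():
    """A 1000+1000 haplodiploid arm (3000 genomes) pairs with a 750+750
    diploid arm; censuses not divisible into an equal-sex diploid raise."""
    assert diploid_census_for_pairing(1000, 1000, EQUAL_CHROMOSOMES) == (750, 750)
    assert diploid_census_for_pairing(100, 100, EQUAL_CHROMOSOMES) == (75, 75)
    assert diploid_census_for_pairing(100, 100, "equal_individuals") == (100, 100)
    with pytest.raises(ValueError, match="not matchable"):
        diploid_census_for_pairing(101, 100, EQUAL_CHROMOSOMES)


def _tiny_template(seed=0):
    return SimulationConfig(
        mode=HAPLODIPLOID, Nm=8, Nf=8,
        meiosis=MeiosisParams(L=200, mu=5e-4, r=1e-3),
        s=0.0, h=0.0, burn_in=10, run_generations=60, seed=seed,
    )


def test_grid_tables_are_reproducible():
    grid = TreatmentGrid(
        treatments=[Treatment("neutral", 0.0, 0.0)],
        replicates=2,
        base_seed=99,
    )
    a = run_grid(grid, _tiny_template())
    b = run_grid(grid, _tiny_template())
    assert a.equals(b)
    assert set(a["mode"]) == {"haplodiploid", "diploid"}
    assert len(a) == 4
    # per-replicate seeds are distinct and below 2^31
    assert a["seed"].nunique() == 4
    assert (a["seed"] < 2**31).all()


def test_full_scale_grid_requires_acknowledgement():
    grid, template = figure1_full_preset(0)
    with pytest.raises(RuntimeError, match="acknowledge_long_run"):
        run_grid(grid, template)


# --- directionality at the scaled preset -----------------------------------


def test_equal_chromosome_comparison_directionality(scaled_arms):
    """With mutation influx equalized (300 genome copies in both arms),
    haplodiploids fix more advantageous mutations, and the gap widens as
    h decreases (h=0 vs h=0.5)."""
    hap_h0 = scaled_arms[("hap", 0.0)]
    hap_h5 = scaled_arms[("hap", 0.5)]
    dip_h0 = scaled_arms[("dip_equal_chrom", 0.0)]
    dip_h5 = scaled_arms[("dip_equal_chrom", 0.5)]
    res_h0 = compare_population_types(hap_h0, dip_h0, alternative="greater")
    assert res_h0.p_value < 0.01
    assert res_h0.mean_difference > 0
    res_h5 = compare_population_types(hap_h5, dip_h5, alternative="greater")
    assert res_h0.mean_difference > res_h5.mean_difference


# --- VCF export -------------------------------------------------------------


def test_vcf_mutation_free_population_is_header_only(tmp_path):
    pop = Population.founders(HAPLODIPLOID, 2, 2)
    path = tmp_path / "empty.vcf"
    export_vcf(pop, path, L=100)
    with pysam.VariantFile(str(path)) as vcf:
        assert list(vcf) == []


def test_vcf_genotypes_and_coordinates(tmp_path):
    """Locus 0 becomes POS=1; haploid males are written as single-allele
    genotypes, females as unphased diploid genotypes."""
    pop = Population.founders(HAPLODIPLOID, 2, 2)
    reg = pop.registry
    at0 = reg.new_record(position=0, s=0.01, h=0.25, origin_generation=4)
    at9 = reg.new_record(position=9, s=-0.002, h=0.0)
    pop.males[0].genomes[0].mutation_ids.append(at0.id)
    pop.females[0].genomes[0].mutation_ids.append(at9.id)
    pop.females[1].genomes[0].mutation_ids.append(at9.id)
    pop.females[1].genomes[1].mutation_ids.append(at9.id)
    reg.counts = reg.recount(pop)
    path = tmp_path / "pop.vcf"
    export_vcf(pop, path, L=100)

    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
        assert [rec.pos for rec in records] == [1, 10]  # 1-based
        first, second = records
        assert first.info["S"] == pytest.approx(0.01)
        assert first.info["H"] == pytest.approx(0.25)
        assert first.info["ORIGIN"] == 4
        # haploid male carrying the variant at locus 0
        assert first.samples["M0"]["GT"] == (1,)
        assert first.samples["M1"]["GT"] == (0,)
        assert first.samples["F0"]["GT"] == (0, 0)
        # female heterozygote and homozygote at locus 9
        assert second.samples["F0"]["GT"] == (0, 1)
        assert second.samples["F1"]["GT"] == (1, 1)
        assert second.samples["M0"]["GT"] == (0,)
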