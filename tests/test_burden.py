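"""Panel filtering, Poisson tail, burden tests, rank-sum, candidate flags."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammainc

from paracons import (
    DnmRecord,
    GeneAnnotationRow,
    GeneExpectation,
    MultiplicityConfig,
    ParalogScoreTrack,
    assign_site_class,
    class_zscore_comparison,
    family_burden_test,
    filter_reference_panel,
    flag_candidate_genes,
    log10_poisson_upper_tail,
    poisson_upper_tail,
    zscore_track,
)
from paracons.expectation import FamilyExpectation


def _dnm(gene="g1", consequence="missense", position=1, aa_ref=None, **kw):
    defaults = dict(proband_id="p", cohort="DD")
    defaults.update(kw)
    return DnmRecord(
        gene_id=gene,
        consequence=consequence,
        protein_position=position,
        aa_ref=aa_ref,
        **defaults,
    )


def _track(gene="g1", conserved=(True, False, True, False), residues="MKWV"):
    t = ParalogScoreTrack(
        gene, residues, np.where(np.asarray(conserved, bool), 9.0, 3.0)
    )
    return zscore_track(t)


# ---------------------------------------------------------------------------
# filter_reference_panel
# ---------------------------------------------------------------------------

def test_empty_panel_keeps_everything():
    dnms = [_dnm(position=i) for i in range(1, 4)]
    assert filter_reference_panel(dnms, set()) == dnms


def test_panel_removes_exact_genomic_match():
    dnms = [
        _dnm(chrom="1", pos=100, ref="A", alt="G"),
        _dnm(chrom="1", pos=200, ref="C", alt="T"),
    ]
    kept = filter_reference_panel(dnms, {("1", 100, "A", "G")})
    assert len(kept) == 1
    assert kept[0].pos == 200


def test_panel_protein_level_match():
    dnms = [_dnm(position=5, aa_ref="K", aa_alt="R")]
    kept = filter_reference_panel(dnms, {("g1", "K", 5, "R")})
    assert kept == []


def test_panel_matches_set_difference_oracle(rng):
    dnms = [
        _dnm(
            chrom=str(rng.integers(1, 3)),
            pos=int(rng.integers(1, 30)),
            ref="A",
            alt="G",
            position=None,
        )
        for _ in range(60)
    ]
    panel = {
        (str(rng.integers(1, 3)), int(rng.integers(1, 30)), "A", "G")
        for _ in range(20)
    }
    kept = filter_reference_panel(dnms, panel)
    expected = [d for d in dnms if d.genomic_key() not in panel]
    assert kept == expected


# ---------------------------------------------------------------------------
# assign_site_class
# ---------------------------------------------------------------------------

def test_positive_z_is_conserved():
    track = _track()
    assert track.zscore_at(1) > 0
    assert assign_site_class(_dnm(position=1), track) == "conserved"


def test_zero_z_is_nonconserved():
    track = zscore_track(ParalogScoreTrack("g1", "MKW", np.array([5, 5, 5])))
    assert track.zscore_at(2) == 0.0
    assert assign_site_class(_dnm(position=2), track) == "nonconserved"


def test_batch_matches_per_record_oracle(rng):
    track = _track(conserved=rng.random(20) < 0.5, residues="A" * 20)
    for pos in range(1, 21):
        got = assign_site_class(_dnm(position=pos), track)
        want = "conserved" if track.para_zscore[pos - 1] > 0 else "nonconserved"
        assert got == want


def test_position_out_of_range_errors():
    with pytest.raises(IndexError):
        assign_site_class(_dnm(position=99), _track())


def test_aa_ref_mismatch_errors():
    with pytest.raises(ValueError, match="g1 p.1"):
        assign_site_class(_dnm(position=1, aa_ref="W"), _track())


def test_aa_ref_match_ok():
    assert assign_site_class(_dnm(position=1, aa_ref="M"), _track()) == "conserved"


# ---------------------------------------------------------------------------
# poisson_upper_tail
# ---------------------------------------------------------------------------

def naive_tail(k, lam, n_terms=400):
    """Independent oracle: direct term summation in plain floats."""
    term = math.exp(-lam) * lam**k / math.factorial(k)
    total = 0.0
    j = k
    while term > 0 and j < k + n_terms:
        total += term
        j += 1
        term *= lam / j
    return total


def test_observed_zero_gives_one():
    assert poisson_upper_tail(0, 0.5) == 1.0
    assert poisson_upper_tail(0, 100.0) == 1.0


def test_closed_form_partial_sum():
    # P(X >= 3 | 1) = 1 - e^-1 (1 + 1 + 1/2)
    expected = 1 - math.exp(-1) * 2.5
    assert poisson_upper_tail(3, 1.0) == pytest.approx(expected, rel=1e-12)


def test_matches_naive_summation_oracle():
    for lam in (0.1, 0.5, 1.0, 2.5, 5.0):
        for k in range(0, 31):
            assert poisson_upper_tail(k, lam) == pytest.approx(
                naive_tail(k, lam), rel=1e-10
            )


def test_matches_incomplete_gamma():
    # independent closed form: P(X >= k) = gammainc(k, lam) (regularized lower)
    for lam in (0.3, 1.0, 4.0, 20.0):
        for k in (1, 2, 5, 10, 40):
            assert poisson_upper_tail(k, lam) == pytest.approx(
                float(gammainc(k, lam)), rel=1e-9
            )


def test_monotone_in_observed_and_lambda():
    ps = [poisson_upper_tail(k, 2.0) for k in range(0, 15)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    ps = [poisson_upper_tail(5, lam) for lam in (0.5, 1.0, 2.0, 4.0)]
    assert all(a < b for a, b in zip(ps, ps[1:]))


def test_log_space_stability_aggregate_burden():
    p = poisson_upper_tail(753, 49.92)
    assert math.isfinite(p) and p > 0
    assert p < 1e-100
    log10p = log10_poisson_upper_tail(753, 49.92)
    assert math.isfinite(log10p)
    assert log10p < -500


def test_deep_tail_finite_beyond_float_range():
    # log-scale result stays finite where the linear-scale p would be ~1e-1500
    log10p = log10_poisson_upper_tail(2000, 10.0)
    assert math.isfinite(log10p)
    assert log10p < -1000


def test_invalid_lambda_errors():
    with pytest.raises(ValueError):
        poisson_upper_tail(3, 0.0)
    with pytest.raises(ValueError):
        poisson_upper_tail(3, -1.0)


# ---------------------------------------------------------------------------
# family_burden_test
# ---------------------------------------------------------------------------

def _family_exp(**overrides):
    base = dict(
        gene_id="g1",
        synonymous=0.3,
        missense=0.4,
        nonsense=0.1,
        frameshift=0.125,
        missense_conserved=0.1,
        missense_nonconserved=0.3,
        n_conserved_sites=2,
        n_nonconserved_sites=2,
    )
    base.update(overrides)
    return FamilyExpectation("fam.1", [GeneExpectation(**base)])


def test_zero_observed_all_p_one():
    config = MultiplicityConfig(n_families=10)
    results = family_burden_test(_family_exp(), [], {"g1": _track()}, config)
    assert all(r.p_value == 1.0 for r in results)
    assert not any(r.significant for r in results)
    assert all(r.observed == 0 for r in results)


def test_conserved_category_direct_computation():
    config = MultiplicityConfig(n_families=1, n_categories=5)
    track = _track()
    dnms = [_dnm(position=1, proband_id=f"p{i}") for i in range(7)]
    results = family_burden_test(_family_exp(), dnms, {"g1": track}, config)
    by_cat = {r.category: r for r in results}
    r = by_cat["missense_conserved"]
    assert r.observed == 7
    assert r.expected == pytest.approx(0.1)
    assert r.p_value == pytest.approx(naive_tail(7, 0.1), rel=1e-9)
    assert r.significant == (r.p_value < 0.05 / 5)


def test_bonferroni_threshold_paper_scale():
    config = MultiplicityConfig(alpha=0.05, n_categories=5, n_families=2871)
    assert config.threshold == pytest.approx(3.48e-6, rel=5e-3)


def test_category_additivity(rng):
    track = _track(conserved=rng.random(30) < 0.5, residues="A" * 30)
    dnms = [
        _dnm(position=int(rng.integers(1, 31)), proband_id=f"p{i}")
        for i in range(25)
    ]
    config = MultiplicityConfig(n_families=5)
    results = family_burden_test(_family_exp(), dnms, {"g1": track}, config)
    by_cat = {r.category: r for r in results}
    assert (
        by_cat["missense_conserved"].observed
        + by_cat["missense_nonconserved"].observed
        == by_cat["missense"].observed
    )


def test_ptv_and_combined_categories():
    track = _track()
    dnms = [
        _dnm(consequence="nonsense", position=2, proband_id="p1"),
        _dnm(consequence="frameshift", position=None, proband_id="p2"),
        _dnm(consequence="splice", position=None, proband_id="p3"),
        _dnm(consequence="missense", position=1, proband_id="p4"),  # conserved
        _dnm(consequence="missense", position=2, proband_id="p5"),  # nonconserved
        _dnm(consequence="synonymous", position=3, proband_id="p6"),
    ]
    config = MultiplicityConfig(n_families=1)
    by_cat = {
        r.category: r
        for r in family_burden_test(_family_exp(), dnms, {"g1": track}, config)
    }
    assert by_cat["ptv"].observed == 3
    assert by_cat["missense"].observed == 2
    assert by_cat["missense_conserved"].observed == 1
    assert by_cat["missense_plus_ptv_conserved"].observed == 4
    assert by_cat["missense_plus_ptv_conserved"].expected == pytest.approx(
        0.1 + 0.1 + 0.125
    )


def test_records_outside_family_are_skipped():
    config = MultiplicityConfig(n_families=1)
    dnms = [_dnm(gene="not_in_family", position=1)]
    results = family_burden_test(_family_exp(), dnms, {"g1": _track()}, config)
    assert all(r.observed == 0 for r in results)


def test_per_cohort_breakdown():
    track = _track()
    dnms = [
        _dnm(position=1, cohort="DD", proband_id="p1"),
        _dnm(position=1, cohort="ASD", proband_id="p2"),
        _dnm(position=1, cohort="DD", proband_id="p3"),
    ]
    config = MultiplicityConfig(n_families=1)
    by_cat = {
        r.category: r
        for r in family_burden_test(_family_exp(), dnms, {"g1": track}, config)
    }
    assert by_cat["missense"].per_cohort == {"DD": 2, "ASD": 1}
    assert by_cat["missense"].per_gene == {"g1": 3}


def test_null_calibration():
    """Type-I error of the upper-tail Poisson test at lambda large enough
    for near-continuous p-values: fraction of p < 0.05 over 2,000 simulated
    null families sits in the binomial 99% band around the achieved level."""
    rng = np.random.default_rng(7)
    lam = rng.uniform(200, 500, size=2000)
    obs = rng.poisson(lam)
    p = np.array([poisson_upper_tail(int(o), float(l)) for o, l in zip(obs, lam)])
    frac = (p < 0.05).mean()
    assert 0.04 <= frac <= 0.06


# ---------------------------------------------------------------------------
# class_zscore_comparison
# ---------------------------------------------------------------------------

def test_identical_samples_p_one():
    stat, p = class_zscore_comparison([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert p == 1.0
    assert stat == pytest.approx(4.5)


def test_exact_small_sample_enumeration():
    za, zb = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    stat, p = class_zscore_comparison(za, zb)
    assert stat == 0.0
    # oracle: enumerate all C(6,3)=20 rank assignments
    ranks = range(1, 7)
    u_obs = 0
    count_extreme = 0
    total = 0
    for combo in itertools.combinations(ranks, 3):
        total += 1
        u = sum(combo) - 6  # rank-sum minus min
        if u <= u_obs or u >= 9 - u_obs:
            count_extreme += 1
    assert p == pytest.approx(count_extreme / total)
    assert p == pytest.approx(0.1)


def test_shift_monotone_p():
    rng = np.random.default_rng(5)
    base = rng.normal(size=60)
    ps = []
    for shift in (0.2, 0.8, 1.6):
        _, p = class_zscore_comparison(list(base), list(base + shift))
        ps.append(p)
    assert ps[0] > ps[1] > ps[2]


def test_empty_sample_errors():
    with pytest.raises(ValueError):
        class_zscore_comparison([], [1.0])


def test_asymptotic_matches_scipy_with_ties():
    rng = np.random.default_rng(9)
    a = rng.integers(0, 5, 30).astype(float)
    b = rng.integers(1, 6, 40).astype(float)
    stat, p = class_zscore_comparison(a, b)
    ref = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    assert p == pytest.approx(float(ref.pvalue))


# ---------------------------------------------------------------------------
# flag_candidate_genes
# ---------------------------------------------------------------------------

def _row(rpkm=2.0, pli=0.95, z=1.0):
    return GeneAnnotationRow("g", brain_rpkm=rpkm, pli=pli, missense_constraint_z=z)


def test_candidate_via_pli_branch():
    call = flag_candidate_genes(_row(), True, True)
    assert call.candidate
    assert "pli" in call.reasons


def test_rpkm_exactly_one_not_brain_expressed():
    call = flag_candidate_genes(_row(rpkm=1.0), True, True)
    assert not call.candidate
    assert "not_brain_expressed" in call.reasons


def test_pli_exactly_point_nine_is_constrained():
    call = flag_candidate_genes(_row(rpkm=5.0, pli=0.9, z=0.0), True, True)
    assert call.candidate


def test_missense_z_branch():
    call = flag_candidate_genes(_row(pli=0.0, z=3.10), True, True)
    assert call.candidate
    assert "missense_z" in call.reasons


def test_z_exactly_cutoff_not_constrained():
    call = flag_candidate_genes(_row(pli=0.0, z=3.09), True, True)
    assert not call.candidate


def test_requires_family_and_dnm():
    assert not flag_candidate_genes(_row(), False, True).candidate
    assert not flag_candidate_genes(_row(), True, False).candidate


def test_missing_annotation_not_evaluable():
    row = GeneAnnotationRow("g")
    call = flag_candidate_genes(row, True, True)
    assert not call.candidate
    assert not call.evaluable
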