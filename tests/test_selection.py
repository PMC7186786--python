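"""Window scans, recombination interpolation, ANCOVA, and EHH/iHS against
brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editsweep.selection import (
    ancova_editing_effect,
    build_balancing_input,
    ehh,
    ihs,
    ihs_unstandardized,
    interpolate_recomb,
    poly_div_windows,
    window_snp_counts,
)
from editsweep.sim import simulate_haplotypes


# ---------------------------------------------------------------------------
# windows

def test_window_counts_half_open_convention():
    centers = pd.DataFrame({"chrom": ["c"], "pos": [10_000]})
    snps = pd.DataFrame({"chrom": ["c"] * 3, "pos": [5_000, 14_999, 15_000]})
    w = window_snp_counts(centers, snps, 10_000)
    # [-5000, +5000): 5000 included, 14999 included, 15000 excluded
    assert w.loc[0, "snp_count"] == 2


def test_window_counts_exclude_center_and_empty():
    centers = pd.DataFrame({"chrom": ["c"], "pos": [100]})
    w = window_snp_counts(centers, pd.DataFrame({"chrom": ["c"], "pos": [100]}), 1000)
    assert w.loc[0, "snp_count"] == 0
    w = window_snp_counts(centers, pd.DataFrame({"chrom": [], "pos": []}), 1000)
    assert w.loc[0, "snp_count"] == 0


def test_window_counts_translation_invariant():
    rng = np.random.default_rng(5)
    pos = np.sort(rng.integers(0, 100_000, 300))
    centers = pd.DataFrame({"chrom": ["c"] * 10, "pos": pos[::30]})
    snps = pd.DataFrame({"chrom": ["c"] * 300, "pos": pos})
    base = window_snp_counts(centers, snps, 10_000)["snp_count"]
    shifted = window_snp_counts(
        centers.assign(pos=centers["pos"] + 12_345),
        snps.assign(pos=snps["pos"] + 12_345),
        10_000,
    )["snp_count"]
    assert list(base) == list(shifted)


def test_planted_thinning_detected_by_rank_test():
    """15% diversity thinning around edited centers at ~300 centers/class."""
    from editsweep.sim import SimulationParams, generate_population, generate_reference
    from scipy import stats

    params = SimulationParams(
        genome_length=4_000_000, n_chromosomes=4, n_genes=40,
        n_edit_sites=320, p_poly_edited=1.0, sweep_diversity_factor=0.85,
        seed=21,
    )
    ref = generate_reference(params)
    pop = generate_population(ref, params)
    em = pop.snps["is_edited"].to_numpy()
    centers = pop.snps.assign(is_edited=em)
    w = window_snp_counts(centers, pop.snps, 10_000)
    e = w[w["is_edited"]]["snp_count"]
    u = w[~w["is_edited"]].sample(500, random_state=0)["snp_count"]
    p = stats.mannwhitneyu(e, u, alternative="less").pvalue
    assert p < 0.01


def test_poly_div_ratio_and_scale_invariance():
    centers = pd.DataFrame({"chrom": ["c"], "pos": [50_000]})
    snps = pd.DataFrame({"chrom": ["c"] * 20,
                         "pos": np.linspace(46_000, 54_000, 20, dtype=int)})
    div = pd.DataFrame({"chrom": ["c"] * 10,
                        "pos": np.linspace(46_100, 53_900, 10, dtype=int)})
    w = poly_div_windows(window_snp_counts(centers, snps, 10_000), div, 10_000)
    assert w.loc[0, "poly_div_ratio"] == pytest.approx(2.0)
    # doubling both leaves the ratio unchanged
    snps2 = pd.concat([snps, snps.assign(pos=snps["pos"] + 1)])
    div2 = pd.concat([div, div.assign(pos=div["pos"] + 1)])
    w2 = poly_div_windows(window_snp_counts(centers, snps2, 10_000), div2, 10_000)
    assert w2.loc[0, "poly_div_ratio"] == pytest.approx(2.0)


def test_zero_divergence_window_retained_with_missing_ratio():
    centers = pd.DataFrame({"chrom": ["c"], "pos": [100]})
    w = poly_div_windows(
        window_snp_counts(centers, pd.DataFrame({"chrom": ["c"], "pos": [150]}), 1000),
        pd.DataFrame({"chrom": [], "pos": []}), 1000,
    )
    assert len(w) == 1 and np.isnan(w.loc[0, "poly_div_ratio"])


# ---------------------------------------------------------------------------
# recombination interpolation

def test_interpolation_examples():
    m = pd.DataFrame({"chrom": ["c", "c"], "pos": [0, 1_000_000], "cM": [0.0, 10.0]})
    assert interpolate_recomb(m, "c", 500_000) == pytest.approx(5.0)
    assert interpolate_recomb(m, "c", 1_000_000) == pytest.approx(10.0)
    assert interpolate_recomb(m, "c", 2_000_000) == pytest.approx(10.0)  # clamped


def test_interpolation_matches_segment_search_oracle():
    rng = np.random.default_rng(8)
    pos = np.sort(rng.choice(100_000, 50, replace=False))
    cm = np.cumsum(rng.random(50))
    m = pd.DataFrame({"chrom": "c", "pos": pos, "cM": cm})
    for q in rng.integers(pos[0], pos[-1], 200):
        i = np.searchsorted(pos, q, side="right") - 1
        if pos[i] == q:
            expect = cm[i]
        else:
            frac = (q - pos[i]) / (pos[i + 1] - pos[i])
            expect = cm[i] + frac * (cm[i + 1] - cm[i])
        assert interpolate_recomb(m, "c", int(q)) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# ANCOVA

def _ancova_windows(rng, n_per_class, effect):
    recomb = rng.uniform(0, 5, 2 * n_per_class)
    gc = rng.uniform(0.3, 0.6, 2 * n_per_class)
    edited = np.r_[np.ones(n_per_class, bool), np.zeros(n_per_class, bool)]
    ratio = 2.0 + 0.1 * recomb + 0.5 * gc + rng.normal(0, 0.3, 2 * n_per_class)
    ratio[edited] *= 1.0 + effect
    return pd.DataFrame(
        {"poly_div_ratio": ratio, "recomb_rate": recomb, "gc": gc,
         "is_edited": edited}
    )


def test_ancova_detects_planted_reduction():
    rng = np.random.default_rng(31)
    rep = ancova_editing_effect(_ancova_windows(rng, 200, -0.20))
    assert rep.p_value < 0.05
    assert rep.coef_editing < 0


def test_ancova_null_p_uniform():
    rng = np.random.default_rng(32)
    ps = [ancova_editing_effect(_ancova_windows(rng, 40, 0.0)).p_value
          for _ in range(500)]
    from scipy import stats

    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_ancova_gc_only_effect_not_attributed_to_editing():
    rng = np.random.default_rng(33)
    df = _ancova_windows(rng, 150, 0.0)
    df["poly_div_ratio"] += 3.0 * df["gc"]
    rep = ancova_editing_effect(df)
    assert rep.p_value > 0.05


def test_ancova_requires_min_windows():
    rng = np.random.default_rng(34)
    with pytest.raises(ValueError, match=">= 10 windows"):
        ancova_editing_effect(_ancova_windows(rng, 5, 0.0))


# ---------------------------------------------------------------------------
# EHH / iHS

def _ehh_oracle(hap, core, allele, marker):
    """Pair-sharing definition: fraction of carrier pairs identical from the
    core out to ``marker`` (inclusive)."""
    carriers = [h for h in hap if h[core] == allele]
    n = len(carriers)
    lo, hi = (marker, core) if marker < core else (core, marker)
    same = sum(
        1
        for x, y in itertools.combinations(carriers, 2)
        if np.array_equal(x[lo : hi + 1], y[lo : hi + 1])
    )
    return same / (n * (n - 1) / 2)


def test_ehh_identical_carriers_stay_one():
    hap = np.array([[0, 1, 0, 1, 1], [0, 1, 0, 1, 1], [1, 0, 1, 0, 0]])
    curve = ehh(hap, 2, 0)
    assert np.allclose(curve.left, 1.0) and np.allclose(curve.right, 1.0)


def test_ehh_drops_to_zero_at_first_difference():
    hap = np.array([[0, 0, 0], [1, 0, 0]])
    curve = ehh(hap, 1, 0)
    assert curve.left[0] == 0.0
    assert curve.right[0] == 1.0


def test_ehh_needs_two_carriers():
    hap = np.array([[1, 1, 1], [0, 0, 0], [0, 1, 0]])
    with pytest.raises(ValueError, match="carriers"):
        ehh(hap, 0, 1)


def test_ehh_six_haplotype_toy_matches_oracle():
    rng = np.random.default_rng(2)
    hap = rng.integers(0, 2, (6, 9))
    hap[:3, 4] = 1
    hap[3:, 4] = 0
    for allele in (0, 1):
        curve = ehh(hap, 4, allele)
        for k, m in enumerate(range(3, -1, -1)):
            assert curve.left[k] == pytest.approx(_ehh_oracle(hap, 4, allele, m))
        for k, m in enumerate(range(5, 9)):
            assert curve.right[k] == pytest.approx(_ehh_oracle(hap, 4, allele, m))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n_hap=st.integers(4, 8),
    n_markers=st.integers(3, 10),
)
def test_ehh_matches_oracle_property(data, n_hap, n_markers):
    bits = data.draw(
        st.lists(
            st.lists(st.integers(0, 1), min_size=n_markers, max_size=n_markers),
            min_size=n_hap, max_size=n_hap,
        )
    )
    hap = np.array(bits, dtype=np.uint8)
    core = data.draw(st.integers(0, n_markers - 1))
    for allele in (0, 1):
        if (hap[:, core] == allele).sum() < 2:
            continue
        curve = ehh(hap, core, allele)
        for k, m in enumerate(range(core - 1, -1, -1)):
            assert curve.left[k] == pytest.approx(_ehh_oracle(hap, core, allele, m))
        for k, m in enumerate(range(core + 1, n_markers)):
            assert curve.right[k] == pytest.approx(_ehh_oracle(hap, core, allele, m))


def _ihh_oracle(hap, core, map_pos, floor):
    """Trapezoidal iHH from oracle EHH values, same truncation rule."""
    def side(markers):
        xs, ys = [0.0], [1.0]
        for m in markers:
            xs.append(abs(map_pos[m] - map_pos[core]))
            ys.append(_ehh_oracle(hap, core, side_allele, m))
        ys = np.array(ys)
        below = np.flatnonzero(ys < floor)
        stop = below[0] if len(below) else len(ys) - 1
        if stop == 0:
            return 0.0
        return float(np.trapezoid(ys[: stop + 1], np.array(xs)[: stop + 1]))

    out = {}
    for side_allele in (0, 1):
        out[side_allele] = side(range(core - 1, -1, -1)) + side(
            range(core + 1, hap.shape[1])
        )
    return out


def test_ihs_matches_oracle_on_random_instances():
    rng = np.random.default_rng(77)
    n_checked = 0
    while n_checked < 50:
        hap = rng.integers(0, 2, (rng.integers(4, 9), rng.integers(3, 11)))
        core = int(rng.integers(0, hap.shape[1]))
        map_pos = np.sort(rng.random(hap.shape[1])) * 2
        res = ihs_unstandardized(hap, core, map_pos, 0.05)
        if min((hap[:, core] == 0).sum(), (hap[:, core] == 1).sum()) < 2:
            assert res is None
            continue
        oracle = _ihh_oracle(hap, core, map_pos, 0.05)
        if res is None:
            assert 0.0 in oracle.values()
            continue
        ihh_a, ihh_d, u = res
        assert ihh_a == pytest.approx(oracle[0])
        assert ihh_d == pytest.approx(oracle[1])
        assert u == pytest.approx(np.log(oracle[0] / oracle[1]))
        n_checked += 1


def test_uihs_zero_for_mirror_symmetric_structure():
    # derived and ancestral carriers have identical haplotype structure
    block = np.array([[0, 0, 1, 0, 1], [1, 0, 1, 1, 0]])
    hap = np.vstack([block, block])
    hap[:2, 2] = 1
    hap[2:, 2] = 0
    res = ihs_unstandardized(hap, 2, np.arange(5, dtype=float), 0.05)
    assert res is not None
    assert res[2] == pytest.approx(0.0)


def test_ihs_standardization_within_bins():
    cores = pd.DataFrame({"chrom": ["c"] * 30, "pos": range(30)})
    rng = np.random.default_rng(11)
    haps = {}
    for i in range(30):
        hap, pos, cm = simulate_haplotypes(40, 21, 0.4, False, rng)
        haps[("c", i)] = (hap, 10, cm)
    df = ihs(cores, haps, min_bin_n=5)
    for _, grp in df.dropna(subset=["ihs"]).groupby("freq_bin"):
        if len(grp) >= 5:
            assert grp["ihs"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["ihs"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_ihs_planted_sweep_scores_lower():
    rng = np.random.default_rng(13)
    cores, haps, planted = [], {}, {}
    for i in range(120):
        sweep = i % 2 == 0
        freq = float(rng.uniform(0.2, 0.5))
        hap, pos, cm = simulate_haplotypes(80, 41, freq, sweep, rng)
        haps[("c", i)] = (hap, 20, cm)
        cores.append({"chrom": "c", "pos": i})
        planted[i] = sweep
    df = ihs(pd.DataFrame(cores), haps)
    df["sweep"] = df["pos"].map(planted)
    from scipy import stats

    sub = df.dropna(subset=["ihs"])
    p = stats.mannwhitneyu(
        sub[sub["sweep"]]["ihs"], sub[~sub["sweep"]]["ihs"], alternative="less"
    ).pvalue
    assert sub[sub["sweep"]]["ihs"].median() < sub[~sub["sweep"]]["ihs"].median()
    assert p < 0.01


# ---------------------------------------------------------------------------
# balancing-selection input

def _informative(n, spacing=100):
    kinds = ["poly" if i % 3 else "div" for i in range(n)]
    return pd.DataFrame(
        {"chrom": "c", "pos": np.arange(1, n + 1) * spacing, "kind": kinds}
    )


def _map():
    return pd.DataFrame(
        {"chrom": ["c", "c"], "pos": [0, 1_000_000], "cM": [0.0, 20.0]}
    )


def test_balancing_window_exact_size():
    info = _informative(500)
    focal = pd.DataFrame({"chrom": ["c"], "pos": [250 * 100]})
    tables = build_balancing_input(focal, info, _map(), window_sites=200)
    win = tables[("c", 25_000)]
    assert len(win) == 200
    assert not win["short_window"].any()


def test_balancing_window_short_near_end_flagged():
    info = _informative(160)
    focal = pd.DataFrame({"chrom": ["c"], "pos": [10 * 100]})
    tables = build_balancing_input(focal, info, _map(), window_sites=200)
    win = tables[("c", 1000)]
    assert len(win) < 200
    assert win["short_window"].all()


def test_balancing_distances_match_interpolation_oracle():
    info = _informative(300)
    focal = pd.DataFrame({"chrom": ["c"], "pos": [15_000]})
    tables = build_balancing_input(focal, info, _map(), window_sites=50)
    win = tables[("c", 15_000)]
    m = _map()
    f_cm = interpolate_recomb(m, "c", 15_000)
    for row in win.itertuples(index=False):
        assert row.cm_dist == pytest.approx(
            abs(interpolate_recomb(m, "c", row.pos) - f_cm)
        )
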