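"""Pooled heterozygosity, EHH/XP-EHH, candidate calling, interval algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import ehh_by_pairs, sweep_line_merge, trapezoid_quadrature
from test_popgen import _gm_from_haps
from sweepscan.selscan import (
    ScanConfig,
    StandardizationError,
    _ihh_all_cores,
    call_candidates,
    common_regions,
    ehh,
    empirical_pvalues,
    fst_scan,
    hp_scan,
    ihh,
    intersect_candidates,
    merge_regions,
    pooled_heterozygosity,
    regions_to_frame,
    xpehh_scan,
    xpehh_site,
)

# --- pooled heterozygosity


@pytest.mark.parametrize(
    "maj,mnr,expected",
    [
        ([10, 10, 10], [0, 0, 0], 0.0),
        ([10, 5, 5], [5, 5, 10], 0.5),
        ([30], [10], 0.375),
    ],
)
def test_hp_direct_arithmetic(maj, mnr, expected):
    assert pooled_heterozygosity(np.array(maj), np.array(mnr)) == pytest.approx(expected)


@given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100)), min_size=1, max_size=50))
@settings(deadline=None)
def test_hp_bounded_between_zero_and_half(counts):
    maj = np.array([max(a, b) for a, b in counts], dtype=float)
    mnr = np.array([min(a, b) for a, b in counts], dtype=float)
    hp = pooled_heterozygosity(maj, mnr)
    if np.isnan(hp):
        assert maj.sum() + mnr.sum() == 0
    else:
        assert 0.0 <= hp <= 0.5


def _windows(L, size=20_000, step=10_000):
    from sweepscan.popgen import make_windows

    return make_windows({"chr1": L}, size, step)


def test_hp_scan_constant_windows_cannot_standardize(rng):
    hap = rng.integers(0, 2, size=(10, 200)).astype(np.int8)
    hap = np.tile(hap[:, :50], (1, 4))  # identical content in every window
    pos = np.concatenate([np.sort(rng.choice(10_000, 50, replace=False)) + k * 10_000
                          for k in range(4)]).astype(np.int64)
    gm = _gm_from_haps(hap, pos=pos, contig_len=40_000)
    w = pd.DataFrame({"contig": ["chr1"] * 4,
                      "start": [0, 10_000, 20_000, 30_000],
                      "end": [10_000, 20_000, 30_000, 40_000]})
    with pytest.raises(StandardizationError):
        hp_scan(gm, w, ScanConfig(min_snps=10))


def test_hp_scan_standardization_identity(rng):
    hap = rng.integers(0, 2, size=(20, 600)).astype(np.int8)
    pos = np.sort(rng.choice(100_000, 600, replace=False)).astype(np.int64)
    gm = _gm_from_haps(hap, pos=pos, contig_len=100_000)
    tab = hp_scan(gm, _windows(100_000))
    z = tab["ZHp"].dropna().values
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std() == pytest.approx(1.0, abs=1e-9)


def test_hp_scan_recovers_planted_low_diversity_window(rng):
    hits = 0
    for rep in range(20):
        r = np.random.default_rng(900 + rep)
        hap = r.integers(0, 2, size=(24, 1000)).astype(np.int8)
        pos = np.sort(r.choice(200_000, 1000, replace=False)).astype(np.int64)
        planted = (pos >= 100_000) & (pos < 120_000)
        hap[:, planted] = 0
        hap[0, planted] = 1  # keep sites segregating but nearly monomorphic
        gm = _gm_from_haps(hap, pos=pos, contig_len=200_000)
        tab = hp_scan(gm, _windows(200_000))
        best = tab.loc[tab["ZHp"].idxmin()]
        if 100_000 <= (best.start + best.end) / 2 <= 120_000:
            hits += 1
    assert hits >= 16  # >= 80% of replicates


# --- EHH / iHH


def test_ehh_identical_haplotypes_stay_at_one():
    hap = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.int8), (6, 1))
    pos = np.array([0, 100, 200, 300, 400])
    curve = ehh(hap, pos, 2, "right", max_extend_bp=10_000, contig_length=5_000)
    assert curve[0] == (0.0, 1.0)
    assert all(e == 1.0 for _, e in curve)
    assert curve[-1][0] == 4_799  # contig end (5000 - 1 - 200)


def test_ehh_all_distinct_drops_to_zero_immediately():
    # two extension sites render all four haplotypes distinct
    hap = np.array(
        [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]], dtype=np.int8
    )
    pos = np.array([0, 10, 20])
    curve = ehh(hap, pos, 0, "right", ehh_cutoff=0.05)
    # after two sites all four haplotypes are distinct -> EHH = 0
    assert curve[-1][1] == 0.0


def test_ehh_hand_worked_four_haplotypes():
    # haplotypes by site: AAB, AAB, ABA, BBB; core = middle site
    hap = np.array(
        [[0, 0, 1], [0, 0, 1], [0, 1, 0], [1, 1, 1]], dtype=np.int8
    )
    pos = np.array([0, 50, 100])
    left = ehh(hap, pos, 1, "left", ehh_cutoff=0.0)
    # one extension site with class counts (3,1): (C(3,2)+C(1,2))/C(4,2) = 0.5
    assert left[1][1] == pytest.approx(0.5)
    assert left[1][1] == pytest.approx(ehh_by_pairs(hap, 1, 0))


def test_ehh_monotone_non_increasing(rng):
    for _ in range(25):
        n, m = 12, 40
        hap = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        pos = np.sort(rng.choice(100_000, m, replace=False))
        core = int(rng.integers(0, m))
        for direction in ("left", "right"):
            curve = ehh(hap, pos, core, direction, ehh_cutoff=0.0)
            es = [e for _, e in curve]
            assert all(b <= a + 1e-12 for a, b in zip(es, es[1:]))


def test_ihh_rectangle_and_triangle():
    assert ihh([(0, 1), (500, 1)], [(0, 1), (500, 1)]) == pytest.approx(1000)
    assert ihh([(0, 1), (400, 0)], [(0, 1)]) == pytest.approx(200)


def test_ihh_matches_quadrature_oracle(rng):
    for _ in range(50):
        k = int(rng.integers(2, 12))
        d = np.sort(rng.uniform(0, 5000, k))
        d[0] = 0.0
        e = np.sort(rng.uniform(0, 1, k))[::-1]
        e[0] = 1.0
        left = list(zip(d, e))
        right = list(zip(d / 2, e))
        assert ihh(left, right) == pytest.approx(
            trapezoid_quadrature(left) + trapezoid_quadrature(right), abs=1e-9
        )


def test_fast_ihh_equals_per_core_walk(rng):
    hap = rng.integers(0, 2, size=(10, 80)).astype(np.int8)
    pos = np.sort(rng.choice(50_000, 80, replace=False)).astype(np.int64)
    fast = _ihh_all_cores(hap, pos, 0.05, 1_000_000, 50_000)
    for c in range(0, 80, 7):
        slow = ihh(
            ehh(hap, pos, c, "left", 0.05, 1_000_000, 50_000),
            ehh(hap, pos, c, "right", 0.05, 1_000_000, 50_000),
        )
        assert fast[c] == pytest.approx(slow, rel=1e-12)


# --- XP-EHH


def test_xpehh_identical_panels_zero():
    rng = np.random.default_rng(3)
    hap = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
    pos = np.sort(rng.choice(10_000, 30, replace=False))
    assert xpehh_site(hap, hap.copy(), pos, 10) == pytest.approx(0.0)


def test_xpehh_sign_monomorphic_vs_diverse_panel(rng):
    m = 30
    pos = np.sort(rng.choice(10_000, m, replace=False))
    mono = np.tile(rng.integers(0, 2, m).astype(np.int8), (8, 1))
    diverse = rng.integers(0, 2, size=(8, m)).astype(np.int8)
    assert xpehh_site(mono, diverse, pos, 15) > 0


def test_xpehh_antisymmetric_under_group_swap(rng):
    checked = 0
    while checked < 100:
        m = int(rng.integers(10, 40))
        pos = np.sort(rng.choice(100_000, m, replace=False))
        a = rng.integers(0, 2, size=(8, m)).astype(np.int8)
        b = rng.integers(0, 2, size=(8, m)).astype(np.int8)
        core = int(rng.integers(0, m))
        x_ab = xpehh_site(a, b, pos, core)
        if np.isnan(x_ab):
            continue
        x_ba = xpehh_site(b, a, pos, core)
        assert x_ab == pytest.approx(-x_ba, abs=1e-12)
        checked += 1


def test_xpehh_hand_built_panel_matches_manual_table():
    # group A: two haplotype classes; group B: all distinct.  Manual EHH
    # tables computed by pair counting with the oracle.
    hapA = np.array(
        [[0, 0, 1, 0, 1],
         [0, 0, 1, 0, 1],
         [1, 1, 0, 0, 0],
         [1, 1, 0, 0, 0]], dtype=np.int8)
    hapB = np.array(
        [[0, 0, 0, 0, 0],
         [0, 1, 1, 0, 1],
         [1, 0, 1, 0, 0],
         [1, 1, 0, 0, 1]], dtype=np.int8)
    pos = np.array([0, 100, 200, 300, 400])
    core = 2

    def manual_ihh(h):
        total = 0.0
        for walk in ([1, 0], [3, 4]):
            d_prev, e_prev = 0.0, 1.0
            for j in walk:
                d = abs(pos[j] - pos[core])
                e = ehh_by_pairs(h, core, j)
                total += (d - d_prev) * (e + e_prev) / 2
                d_prev, e_prev = d, e
                if e < 0.05:
                    break
        return total

    expected = np.log(manual_ihh(hapA) / manual_ihh(hapB))
    got = xpehh_site(hapA, hapB, pos, core, ehh_cutoff=0.05, max_extend_bp=200)
    assert got == pytest.approx(expected, rel=1e-9)


def _two_group_scan(rng, plant=False, L=200_000, m=800):
    pos = np.sort(rng.choice(L, m, replace=False)).astype(np.int64)
    hapA = rng.integers(0, 2, size=(16, m)).astype(np.int8)
    hapB = rng.integers(0, 2, size=(16, m)).astype(np.int8)
    if plant:
        core = (pos >= 90_000) & (pos < 130_000)
        hapA[:, core] = hapA[0, core]  # one shared haplotype in A
    gmA = _gm_from_haps(hapA, pos=pos, contig_len=L)
    gmB = _gm_from_haps(hapB, pos=pos, contig_len=L)
    return gmA, gmB


def test_xpehh_scan_identical_groups_all_zero(rng):
    gmA, _ = _two_group_scan(rng)
    w = _windows(200_000)
    tab = xpehh_scan(gmA, gmA, w, ScanConfig())
    assert np.nanmax(np.abs(tab["mean_xpehh_std"].values)) == 0.0
    assert len(call_candidates(tab, ScanConfig(), "xpehh")) == 0


def test_xpehh_scan_standardization_identity(rng):
    gmA, gmB = _two_group_scan(rng, plant=True)
    w = _windows(200_000)
    tab = xpehh_scan(gmA, gmB, w, ScanConfig())
    # window means are built from per-SNP standardized scores
    assert np.isfinite(tab["mean_xpehh_std"]).sum() > 5
    assert (tab["n_pos_snps"] + tab["n_neg_snps"] <= tab["n_snps"]).all()


def test_xpehh_scan_planted_sweep_ranks_top(rng):
    hits = 0
    for rep in range(20):
        r = np.random.default_rng(5000 + rep)
        gmA, gmB = _two_group_scan(r, plant=True)
        tab = xpehh_scan(gmA, gmB, _windows(200_000), ScanConfig())
        focal = (tab.start < 130_000) & (tab.end > 90_000)
        thresh = np.nanquantile(tab["mean_xpehh_std"].values, 0.99)
        if np.nanmax(tab.loc[focal, "mean_xpehh_std"].values) >= thresh:
            hits += 1
    assert hits >= 16


def test_xpehh_scan_requires_phase(rng):
    gmA, gmB = _two_group_scan(rng)
    gmA.haplotypes[2, 5] = -1  # unphased call for a called genotype
    with pytest.raises(ValueError, match="phased"):
        xpehh_scan(gmA, gmB, _windows(200_000), ScanConfig())


# --- Fst scan


def test_fst_scan_identical_groups_no_candidates(rng):
    gmA, _ = _two_group_scan(rng)
    tab = fst_scan(gmA, gmA, _windows(200_000), ScanConfig())
    assert len(call_candidates(tab, ScanConfig(), "fst")) == 0


def test_fst_scan_fixture_top_window(rng):
    m = 800
    L = 400_000
    pos = np.sort(rng.choice(L, m, replace=False)).astype(np.int64)
    hapA = rng.integers(0, 2, size=(16, m)).astype(np.int8)
    hapB = hapA ^ rng.integers(0, 2, size=(16, m), dtype=np.int8) * (
        rng.random(m) < 0.1
    )
    hot = (pos >= 200_000) & (pos < 220_000)
    hapA[:, hot] = 0
    hapB[:, hot] = 1
    gmA = _gm_from_haps(hapA.astype(np.int8), pos=pos, contig_len=L)
    gmB = _gm_from_haps(hapB.astype(np.int8), pos=pos, contig_len=L)
    tab = fst_scan(gmA, gmB, _windows(L), ScanConfig())
    best = tab.loc[tab["ZFst"].idxmax()]
    assert 200_000 <= (best.start + best.end) / 2 <= 220_000
    z = tab["ZFst"].dropna().values
    assert z.mean() == pytest.approx(0, abs=1e-9)
    assert z.std() == pytest.approx(1, abs=1e-9)


# --- empirical P and calling


def test_empirical_p_unique_max():
    p = empirical_pvalues(np.array([1.0, 5.0, 2.0, 3.0]), "upper")
    assert p[1] == pytest.approx(1 / 4)
    assert p[0] == pytest.approx(1.0)


def test_empirical_p_total_tie():
    p = empirical_pvalues(np.ones(7), "upper")
    assert np.all(p == 1.0)


def test_empirical_p_rank_fraction(rng):
    # with p_i = rank/N, exactly the top floor(0.01 N) values sit at or
    # below 0.01, and one fewer strictly below it (no ties here)
    x = rng.normal(size=1000)
    p = empirical_pvalues(x, "upper")
    assert (p <= 0.01).sum() == 10
    assert (p < 0.01).sum() == 9


def test_call_mixed_sign_window_rejected():
    df = pd.DataFrame(
        {
            "contig": ["c", "c"],
            "start": [0, 10_000],
            "end": [20_000, 30_000],
            "mean_abs_xpehh_std": [5.0, 5.0],
            "emp_p_xpehh": [0.001, 0.001],
            "n_pos_snps": [12, 12],
            "n_neg_snps": [1, 0],
        }
    )
    out = call_candidates(df, ScanConfig(), "xpehh")
    assert list(out["start"]) == [10_000]
    assert out["direction"].tolist() == ["A"]


def test_call_zhp_boundary_value_included():
    df = pd.DataFrame(
        {"contig": ["c"] * 3, "start": [0, 10_000, 20_000],
         "end": [20_000, 30_000, 40_000], "ZHp": [-4.0, -3.999, -5.0]}
    )
    out = call_candidates(df, ScanConfig(), "hp")
    assert list(out["start"]) == [0, 20_000]  # ZHp <= -4 exactly qualifies


def test_call_predicates_match_bruteforce(rng):
    n = 200
    df = pd.DataFrame(
        {
            "contig": ["c"] * n,
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 20_000,
            "ZFst": rng.normal(size=n) * 2,
            "emp_p_fst": rng.uniform(0, 1, n),
        }
    )
    cfg = ScanConfig()
    out = call_candidates(df, cfg, "fst")
    expected = df[(df.ZFst > cfg.zfst_min) & (df.emp_p_fst < cfg.emp_p_max)]
    assert list(out["start"]) == list(expected["start"])


# --- intersection and merging


def test_intersect_disjoint_and_identity():
    a = pd.DataFrame({"contig": ["c"], "start": [0], "end": [20_000], "ZFst": [4.0]})
    b = pd.DataFrame(
        {"contig": ["c"], "start": [30_000], "end": [50_000],
         "mean_xpehh_std": [3.0], "direction": ["A"]}
    )
    assert intersect_candidates(a, b).empty
    b2 = b.assign(start=[0], end=[20_000])
    out = intersect_candidates(a, b2)
    assert len(out) == 1
    assert out["direction"][0] == "A"


def test_intersect_matches_set_oracle(rng):
    starts_a = rng.choice(50, 20, replace=False) * 10_000
    starts_b = rng.choice(50, 20, replace=False) * 10_000
    a = pd.DataFrame({"contig": "c", "start": starts_a, "end": starts_a + 20_000})
    b = pd.DataFrame({"contig": "c", "start": starts_b, "end": starts_b + 20_000})
    out = intersect_candidates(a, b)
    assert set(out["start"]) == set(starts_a) & set(starts_b)


def test_merge_overlapping_and_bookended():
    df = pd.DataFrame({"contig": ["c", "c"], "start": [0, 10_000],
                       "end": [20_000, 30_000]})
    regions = merge_regions(df, source="hp")
    assert [(r.start, r.end) for r in regions] == [(0, 30_000)]
    df2 = pd.DataFrame({"contig": ["c", "c"], "start": [0, 30_000],
                        "end": [20_000, 50_000]})
    assert len(merge_regions(df2, source="hp")) == 2


def test_merge_opposite_directions_stay_separate():
    df = pd.DataFrame(
        {"contig": ["c", "c"], "start": [0, 10_000], "end": [20_000, 30_000],
         "direction": ["A", "B"]}
    )
    regions = merge_regions(df, source="fst_xpehh")
    assert len(regions) == 2


def test_merge_matches_sweep_line_oracle(rng):
    for _ in range(20):
        starts = rng.choice(100, size=25, replace=False) * 10_000
        df = pd.DataFrame(
            {"contig": "c", "start": starts, "end": starts + 20_000}
        ).sort_values("start")
        regions = merge_regions(df, source="hp")
        oracle = sweep_line_merge([("c", int(s), int(s) + 20_000) for s in starts])
        assert [(r.contig, r.start, r.end) for r in regions] == oracle


def test_common_regions_interval_intersection():
    f = pd.DataFrame({"contig": ["c"] * 2, "start": [0, 10_000],
                      "end": [20_000, 30_000], "ZFst": [4.0, 4.5]})
    x = pd.DataFrame({"contig": ["c"], "start": [20_000], "end": [40_000],
                      "mean_xpehh_std": [3.0], "direction": ["A"]})
    out = common_regions(f, x)
    assert [(r.start, r.end, r.direction) for r in out] == [(20_000, 30_000, "A")]
    frame = regions_to_frame(out)
    assert frame.iloc[0]["source"] == "fst_xpehh"
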