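"""Marker detection, trajectory binning, dynamic pairs and SOM modules."""

import numpy as np
import pandas as pd
import pytest

from screglink import (
    GenePeakCorrelation,
    ValidationError,
    design_pair_table,
    detect_dynamic,
    dynamic_modules,
    find_all_markers,
    find_markers,
    pearson_baseline,
    simulate,
    standard_scenarios,
    trajectory_curves,
)
from screglink.core import LocalCorrelation
from screglink.dynamics import _test_columns
from screglink.pairing import PairTable
from conftest import all_pairs_table, make_paired


def fake_local(L, pair_prefix="g"):
    """Wrap an arbitrary matrix as a LocalCorrelation for unit tests."""
    p = L.shape[1]
    rows = [
        dict(gene_id=f"{pair_prefix}{j:03d}", peak_id=f"chr1:{j*1000}-{j*1000+500}",
             distance_bp=0, relation="overlap", gene_strand="+",
             peak_chrom="chr1", peak_start=j * 1000, peak_end=j * 1000 + 500)
        for j in range(p)
    ]
    return LocalCorrelation(
        L=L, pair_table=PairTable.from_pairs(rows),
        global_index=L.mean(axis=0), zeroed_dropouts=False,
    )


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def test_constant_column_gives_p_one_not_marker():
    L = np.ones((20, 2))
    local = fake_local(L)
    groups = pd.Series(["A"] * 10 + ["B"] * 10)
    res = find_all_markers(local, groups)
    assert (res["p_value"] == 1.0).all()
    assert not res["is_marker"].any()


def test_small_group_skipped_with_warning():
    L = np.random.default_rng(0).normal(size=(13, 3))
    groups = pd.Series(["A"] * 10 + ["B"] * 2 + ["C"])
    res = find_all_markers(fake_local(L), groups)
    assert set(res["group"]) == {"A"}


def test_find_markers_validation_and_symmetry():
    rng = np.random.default_rng(1)
    L = rng.normal(size=(30, 4))
    L[:15, 0] += 1.0  # group A shifted on pair 0
    local = fake_local(L)
    groups = pd.Series(["A"] * 15 + ["B"] * 15)
    with pytest.raises(ValidationError):
        find_markers(local, groups, "A", "A")
    ab = find_markers(local, groups, "A", "B")
    ba = find_markers(local, groups, "B", "A")
    np.testing.assert_allclose(ab["delta_L"], -ba["delta_L"])
    np.testing.assert_allclose(ab["p_value"], ba["p_value"])
    assert ab.loc[0, "is_marker"]


def test_marker_recovery_on_cluster_preset():
    """A pair coupled only in one cluster is flagged for that cluster."""
    cfg = standard_scenarios(123)["cluster_marker"]
    data, truth = simulate(cfg)
    res = GenePeakCorrelation(data, design_pair_table(cfg)).fit()
    mk = res.find_all_markers("group")
    planted = truth.loc[truth.label == "marker", "pair_key"].item()
    hit = mk[(mk["group"] == "g1") & (mk["pair_key"] == planted)]
    assert hit["is_marker"].item()
    assert hit["delta_L"].item() > 0
    # decoys are not flagged anywhere
    decoys = mk[mk["pair_key"] != planted]
    assert not decoys["is_marker"].any()


def test_bh_qvalues_monotone_after_sorting():
    rng = np.random.default_rng(2)
    L = rng.normal(size=(40, 30))
    groups = pd.Series(rng.choice(["A", "B"], size=40))
    res = find_all_markers(fake_local(L), groups)
    for _, fam in res.groupby("group"):
        fam = fam.sort_values("p_value")
        assert (np.diff(fam["q_value"]) >= -1e-15).all()
        assert (fam["q_value"] >= fam["p_value"] - 1e-15).all()


def test_ttest_option_runs():
    rng = np.random.default_rng(3)
    L = rng.normal(size=(24, 2))
    groups = pd.Series(["A"] * 12 + ["B"] * 12)
    res = find_all_markers(fake_local(L), groups, method="ttest")
    assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()


# ---------------------------------------------------------------------------
# trajectory curves
# ---------------------------------------------------------------------------

def _local_and_data(n=100, p=3, seed=0, L=None):
    data = make_paired(n=n, g=2, q=2, seed=seed)
    rng = np.random.default_rng(seed)
    if L is None:
        L = rng.normal(size=(n, p))
    return fake_local(L), data


def test_constant_curves_have_zero_variability():
    local, data = _local_and_data(L=np.full((100, 3), 0.5))
    curves = trajectory_curves(local, data, ["a", "b"], group_key="group",
                               n_bins=10)
    np.testing.assert_allclose(curves.curve, 0.5)
    np.testing.assert_allclose(curves.variability, 0.0)
    sel = detect_dynamic(curves, method="sd_threshold", k=1.0)
    assert not sel.dynamic_mask.any()


def test_equal_count_bins_have_equal_size():
    local, data = _local_and_data(n=100)
    curves = trajectory_curves(local, data, ["a", "b"], group_key="group",
                               n_bins=10, binning="equal_count")
    assert (curves.bins["n_cells"] == 10).all()
    # occupancy rows sum to one
    np.testing.assert_allclose(curves.occupancy.sum(axis=1), 1.0, atol=1e-12)
    # bins ordered by pseudotime
    assert (np.diff(curves.bins["t_min"]) >= 0).all()


def test_curve_entries_are_exact_bin_means():
    local, data = _local_and_data(n=60)
    curves = trajectory_curves(local, data, ["a", "b"], group_key="group",
                               n_bins=6)
    t = data.cell_meta["pseudotime"].to_numpy()
    order = np.argsort(t, kind="mergesort")
    members = np.array_split(order, 6)
    for b, m in enumerate(members):
        np.testing.assert_allclose(curves.curve[:, b], local.L[m].mean(axis=0),
                                   atol=1e-15)


def test_equal_width_empty_bin_raises():
    local, data = _local_and_data(n=30)
    # pile all pseudotime at the extremes -> middle bins empty
    data.cell_meta["pseudotime"] = np.r_[np.zeros(15), np.ones(15)]
    with pytest.raises(ValidationError, match="equal_count"):
        trajectory_curves(local, data, ["a", "b"], group_key="group",
                          n_bins=5, binning="equal_width")


def test_path_restricts_cells():
    local, data = _local_and_data(n=100)
    n_a = int((data.cell_meta["group"] == "a").sum())
    curves = trajectory_curves(local, data, ["a"], group_key="group", n_bins=5)
    assert curves.bins["n_cells"].sum() == n_a
    assert list(curves.occupancy.columns) == ["a"]


# ---------------------------------------------------------------------------
# dynamic detection
# ---------------------------------------------------------------------------

def _curves_with(curve, **kw):
    from screglink.dynamics import TrajectoryCurves

    p, B = curve.shape
    return TrajectoryCurves(
        curve=curve, bins=pd.DataFrame({"bin": range(B)}),
        occupancy=pd.DataFrame(np.ones((B, 1)), columns=["a"]),
        pair_keys=[f"pair{j}" for j in range(p)], path=["a"],
        binning="equal_count", **kw,
    )


def test_detect_dynamic_top_n_and_bounds():
    rng = np.random.default_rng(4)
    curve = rng.normal(size=(10, 8)) * 0.01
    curve[3] += np.linspace(0, 3, 8)  # one strongly varying pair
    curves = _curves_with(curve)
    top1 = detect_dynamic(curves, method="top_n", k=1)
    assert top1.dynamic_keys() == ["pair3"]
    all_sel = detect_dynamic(curves, method="top_n", k=10)
    assert all_sel.dynamic_mask.all()
    with pytest.raises(ValidationError):
        detect_dynamic(curves, method="top_n", k=0)


def test_sd_threshold_affine_invariant():
    rng = np.random.default_rng(5)
    curve = rng.normal(size=(20, 10))
    curve[[2, 7]] *= 8.0
    base = detect_dynamic(_curves_with(curve), method="sd_threshold", k=1.0)
    scaled = detect_dynamic(_curves_with(3.5 * curve - 2.0),
                            method="sd_threshold", k=1.0)
    np.testing.assert_array_equal(base.dynamic_mask, scaled.dynamic_mask)


def test_sign_flipping_coupling_found_by_dynamics_not_pearson():
    """Couplings that vary over pseudotime but average to ~0 are invisible
    to the whole-population Pearson baseline yet selected as dynamic."""
    from screglink import PairDesign, SimConfig

    def flip(t, g):
        return 0.8 * np.sin(2 * np.pi * t)

    designs = tuple(
        PairDesign(f"g{i:04d}", f"chr1:{i*2000}-{i*2000+500}",
                   flip if i < 10 else 0.0,
                   "flip" if i < 10 else "flat")
        for i in range(100)
    )
    cfg = SimConfig(n_cells=5000, n_genes=100, n_peaks=100, seed=17,
                    pair_designs=designs)
    data, truth = simulate(cfg)
    pairs = design_pair_table(cfg)
    res = GenePeakCorrelation(data, pairs).fit()
    curves = res.trajectory_curves(path=["g0", "g1", "g2", "g3"],
                                   group_key="group")
    sel = detect_dynamic(curves, method="sd_threshold", k=1.0)
    flips = set(truth.loc[truth.label == "flip", "pair_key"])
    found = set(sel.dynamic_keys())
    assert len(found & flips) >= 9  # >= 90% of truly varying pairs
    n_baseline = int((pearson_baseline(data, pairs)["pearson_r"].abs()
                      >= 0.1).sum())
    assert len(found) > n_baseline


def test_ramp_preset_selects_exactly_the_ramped_pairs():
    cfg = standard_scenarios(7)["ramp"]
    data, truth = simulate(cfg)
    res = GenePeakCorrelation(data, design_pair_table(cfg)).fit()
    curves = res.trajectory_curves(path=["g0", "g1", "g2", "g3"],
                                   group_key="group")
    sel = detect_dynamic(curves, method="top_n", k=10)
    assert set(sel.dynamic_keys()) == set(truth.loc[truth.label == "ramp",
                                                    "pair_key"])


# ---------------------------------------------------------------------------
# SOM modules
# ---------------------------------------------------------------------------

def test_identical_curves_collapse_to_one_module():
    base = np.sin(np.linspace(0, 3, 12))
    curve = np.tile(base, (8, 1))
    curves = detect_dynamic(_curves_with(curve), method="top_n", k=8)
    mod = dynamic_modules(curves, m_units=2, seed=11)
    assert mod.module_ids.nunique() == 1


def test_som_determinism_and_validation():
    rng = np.random.default_rng(6)
    curve = rng.normal(size=(12, 10))
    curves = detect_dynamic(_curves_with(curve), method="top_n", k=12)
    m1 = dynamic_modules(curves, m_units=3, seed=42)
    m2 = dynamic_modules(curves, m_units=3, seed=42)
    pd.testing.assert_series_equal(m1.module_ids, m2.module_ids)
    np.testing.assert_array_equal(m1.prototypes, m2.prototypes)
    with pytest.raises(ValidationError):
        dynamic_modules(curves, m_units=20, seed=1)
    with pytest.raises(ValidationError):
        dynamic_modules(curves, m_units=3, seed=None)


def test_som_recovers_three_template_shapes():
    """Rising / rise-then-fall / falling curves sort into distinct modules."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(8)
    B = 20
    t = np.linspace(0, 1, B)
    templates = [t, np.sin(np.pi * t), 1 - t]
    curve = np.vstack([
        tmpl + 0.15 * rng.normal(size=B)
        for tmpl in templates for _ in range(30)
    ])
    labels = np.repeat([0, 1, 2], 30)
    curves = detect_dynamic(_curves_with(curve), method="top_n", k=90)
    aris = []
    for seed in range(10):
        mod = dynamic_modules(curves, m_units=3, seed=seed)
        aris.append(adjusted_rand_score(labels, mod.module_ids.to_numpy()))
    assert np.median(aris) >= 0.7


# ---------------------------------------------------------------------------
# Pearson baseline
# ---------------------------------------------------------------------------

def test_pearson_baseline_matches_direct_formula(toy_data, toy_pairs):
    out = pearson_baseline(toy_data, toy_pairs)
    X = toy_data.rna.toarray()
    Y = toy_data.atac.toarray()
    for key, r in out["pearson_r"].items():
        g, pk = key.split("~")
        xi = toy_data.gene_index([g])[0]
        yi = toy_data.peak_index([pk])[0]
        x, y = X[:, xi], Y[:, yi]
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected, abs=1e-12)


def test_pearson_baseline_extremes_and_groups():
    import scipy.sparse as sp

    data = make_paired(n=10, g=2, q=2, seed=4)
    X = np.tile(np.arange(10.0)[:, None], (1, 2))
    data.rna = sp.csr_matrix(X)
    data.atac = sp.csr_matrix(np.column_stack([X[:, 0], X[::-1, 0]]))
    pairs = all_pairs_table(data)
    out = pearson_baseline(data, pairs)
    key_same = "gene0~chr1:0-500"
    key_anti = "gene0~chr1:1000-1500"
    assert out.loc[key_same, "pearson_r"] == pytest.approx(1.0)
    assert out.loc[key_anti, "pearson_r"] == pytest.approx(-1.0)
    by_group = pearson_baseline(data, pairs, group_key="group")
    assert {"a", "b"} <= set(by_group.columns)


def test_pearson_baseline_zero_variance_is_nan():
    import scipy.sparse as sp

    data = make_paired(n=8, g=1, q=1, seed=5)
    data.rna = sp.csr_matrix(np.ones((8, 1)))
    pairs = all_pairs_table(data)
    out = pearson_baseline(data, pairs)
    assert out["pearson_r"].isna().all()
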