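import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdrift import density
from methdrift.genome import GeneModel
from oracles import brute_force_equal_count_bins


def test_compute_bsdens():
    assert density.compute_bsdens(3600, 10) == pytest.approx(10.0)
    assert density.compute_bsdens(1000, 0) == 0.0
    with pytest.raises(ValueError, match="zero-length"):
        density.compute_bsdens(0, 1)


def test_compute_gene_density_hand_case():
    genes = [
        GeneModel("A", "chr1", 1000, 2000, "+"),
        GeneModel("B", "chr1", 5000, 9000, "-"),
    ]
    # locus window midpoint = pos + 18
    loci = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [1082, 1882, 5982, 4990],  # mids 1100, 1900, 6000, 5008
            "n_cpg": [2] * 4,
            "depth_D1": [100] * 4,
            "meth_D1": [20, 40, 60, 80],
        }
    )
    out = density.compute_gene_density(genes, loci)
    assert out.loc["A", "n_loci"] == 2
    assert out.loc["A", "bsdens"] == pytest.approx(100 * 2 * 36 / 1000)
    assert out.loc["A", "mean_meth"] == pytest.approx(0.3)
    # oriented fractions on the + strand: (mid - start) / (len - 1)
    assert out.loc["A", "pos_min"] == pytest.approx(100 / 999)
    assert out.loc["A", "pos_max"] == pytest.approx(900 / 999)
    # B is minus-strand: mid 6000 -> (8999 - 6000) / 3999; mid 5008 -> near 1
    assert out.loc["B", "n_loci"] == 2
    assert out.loc["B", "pos_min"] == pytest.approx(2999 / 3999)
    assert out.loc["B", "pos_max"] == pytest.approx(3991 / 3999)


def test_compute_gene_density_peaks():
    genes = [GeneModel("A", "chr1", 1000, 2000, "+")]
    peaks = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [1100, 5000], "end": [1350, 5250]}
    )
    out = density.compute_gene_density(genes, peaks=peaks)
    assert out.loc["A", "n_peaks"] == 1
    assert out.loc["A", "peak_density"] == pytest.approx(100 * 250 / 1000)


def test_gene_density_matches_generator_truth(tes_dataset):
    out = density.compute_gene_density(tes_dataset.genes, tes_dataset.loci)
    truth_counts = tes_dataset.truth_loci["gene_id"].value_counts()
    counted = out["n_loci"][out["n_loci"] > 0]
    assert counted.sort_index().equals(truth_counts.sort_index())
    truth = tes_dataset.truth_genes.set_index("gene_id")
    np.testing.assert_allclose(
        out["bsdens"].to_numpy(), truth["bsdens_true"].to_numpy(), atol=1e-5
    )


def test_gc_rich_coverage_extremes_and_short_sequence():
    assert density.compute_gc_rich_coverage("G" * 500) == 100.0
    assert density.compute_gc_rich_coverage("A" * 500) == 0.0
    assert density.compute_gc_rich_coverage("GC" * 10, window=100) == 100.0
    assert density.compute_gc_rich_coverage("AT" * 10, window=100) == 0.0
    with pytest.raises(ValueError, match="empty"):
        density.compute_gc_rich_coverage("")


def test_gc_rich_coverage_matches_brute_force():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=600))
    window = 100
    got = density.compute_gc_rich_coverage(seq, window=window)
    is_gc = np.array([c in "GC" for c in seq])
    covered = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - window + 1):
        if is_gc[i:i + window].mean() > 0.5:
            covered[i:i + window] = True
    assert got == pytest.approx(100.0 * covered.mean())


def _density_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"G{i:03d}" for i in range(n)], name="gene_id")
    return pd.DataFrame(
        {
            "length": rng.integers(1000, 10000, n),
            "n_loci": rng.poisson(3, n),
            "bsdens": rng.random(n) * 5,
            "mean_meth": rng.random(n),
            "pos_min": rng.random(n),
            "pos_max": rng.random(n),
            "n_peaks": rng.poisson(1, n),
            "peak_density": rng.random(n) * 5,
        },
        index=idx,
    )


def test_quintile_di_table_matches_oracle():
    dens = _density_frame(103)
    rng = np.random.default_rng(1)
    classes = pd.Series(
        rng.choice(["down", "up", "minimal"], 103, p=[0.4, 0.3, 0.3]),
        index=dens.index,
    )
    table = density.quintile_di_table(dens, classes)
    ref = dens.loc[(dens["n_loci"] > 0) & classes.notna()]
    assert table.attrs["n_reference_genes"] == len(ref)
    # equal-count sizes with remainder in the lowest bins
    oracle_bins = brute_force_equal_count_bins(range(len(ref)), 5)
    assert list(table["n_genes"]) == [len(b) for b in oracle_bins]
    # per-bin counts recomputed by explicit sort
    order = ref.assign(_gid=ref.index).sort_values(["bsdens", "_gid"])
    pos = 0
    ref_down = int((classes.reindex(ref.index) == "down").sum())
    ref_up = int((classes.reindex(ref.index) == "up").sum())
    for row in table.itertuples(index=False):
        ids = order.index[pos:pos + row.n_genes]
        pos += row.n_genes
        sub = classes.reindex(ids)
        assert row.n_down == int((sub == "down").sum())
        assert row.n_up == int((sub == "up").sum())
        expected_p = sps.fisher_exact([[row.n_down, row.n_up],
                                       [ref_down, ref_up]])[1]
        assert row.fisher_p == pytest.approx(expected_p)


def test_quintile_di_table_needs_enough_genes():
    dens = _density_frame(3)
    classes = pd.Series(["down", "up", "down"], index=dens.index)
    with pytest.raises(ValueError, match="at least 5"):
        density.quintile_di_table(dens, classes)


def test_gene_subset_criteria():
    dens = pd.DataFrame(
        {
            "n_loci": [0, 2, 2, 2, 2],
            "bsdens": [0.0, 1.0, 0.1, 0.9, 0.2],
            "mean_meth": [np.nan, 0.9, 0.2, 0.5, 0.6],
            "pos_min": [np.nan, 0.8, 0.05, 0.3, 0.76],
            "pos_max": [np.nan, 0.95, 0.2, 0.6, 0.99],
        },
        index=pd.Index(list("VWXYZ"), name="gene_id"),
    )
    assert list(density.gene_subset(dens, "meth_hi")) == ["W", "Z"]
    assert list(density.gene_subset(dens, "meth_lo")) == ["X"]
    assert list(density.gene_subset(dens, "three_prime_quartile")) == ["W", "Z"]
    assert list(density.gene_subset(dens, "five_prime_quartile")) == ["X"]
    assert list(density.gene_subset(dens, "quartile_4")) == ["W", "Z"]
    assert list(density.gene_subset(dens, "dens_hi")) == ["W", "Y"]
    with pytest.raises(ValueError, match="unknown subset"):
        density.gene_subset(dens, "nope")
    with pytest.raises(ValueError, match="out of range"):
        density.gene_subset(dens, "quartile_5")
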