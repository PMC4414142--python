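import numpy as np
import pandas as pd
import pytest

from methdrift import subdomain
from methdrift.genome import GeneModel
from methdrift.subdomain import (
    CONTROL,
    FIVE_PRIME,
    MID,
    OTHER,
    SUBREGION,
    THREE_PRIME,
    SubdomainParams,
)

PLUS = GeneModel("GP", "chr1", 10_000, 20_000, "+")   # TSS 10000, TES 19999
MINUS = GeneModel("GM", "chr1", 10_000, 20_000, "-")  # TSS 19999, TES 10000


def test_classify_expression_thresholds():
    assert subdomain.classify_expression(-0.6, 0.01) == "down"
    assert subdomain.classify_expression(0.6, 0.01) == "up"
    assert subdomain.classify_expression(0.1, 0.5) == "minimal"
    # boundary values are excluded, not silently classified
    assert subdomain.classify_expression(0.6, 0.05) == "excluded"
    assert subdomain.classify_expression(0.5, 0.01) == "excluded"
    assert subdomain.classify_expression(0.3, 0.5) == "excluded"


def test_classify_expression_table_matches_scalar():
    rng = np.random.default_rng(3)
    expr = pd.DataFrame(
        {"gene_id": [f"G{i}" for i in range(300)],
         "logFC": rng.normal(0, 1, 300), "FDR": rng.random(300)}
    )
    vec = subdomain.classify_expression_table(expr)
    scalar = [subdomain.classify_expression(l, f)
              for l, f in zip(expr["logFC"], expr["FDR"])]
    assert list(vec) == scalar


@pytest.mark.parametrize(
    "center,expected",
    [
        (19_199, SUBREGION),     # 800 bp upstream of TES
        (19_899, THREE_PRIME),   # 100 bp upstream (inside TES window)
        (21_000, THREE_PRIME),   # ~1000 bp downstream of TES
        (11_000, FIVE_PRIME),    # 1000 bp into the gene
        (14_500, MID),           # >3000 bp from both anchors
        (9_500, OTHER),          # upstream of the gene
        (22_500, OTHER),         # beyond the TES window
    ],
)
def test_classify_enrichment_location_plus(center, expected):
    assert subdomain.classify_enrichment_location(PLUS, center) == expected


def test_classify_enrichment_location_minus_strand():
    # TES at 10000: subregion -1300..-500 upstream of TES inside the body
    assert subdomain.classify_enrichment_location(MINUS, 10_800) == SUBREGION
    assert subdomain.classify_enrichment_location(MINUS, 10_100) == THREE_PRIME
    assert subdomain.classify_enrichment_location(MINUS, 9_000) == THREE_PRIME
    assert subdomain.classify_enrichment_location(MINUS, 19_000) == FIVE_PRIME
    assert subdomain.classify_enrichment_location(MINUS, 14_500) == MID


def test_subregion_precedence_over_three_prime():
    # -800 is inside both the subregion and the +/-2000 TES window
    assert subdomain.classify_enrichment_location(PLUS, 19_199) == SUBREGION


def test_chromosome_mismatch_rejected():
    with pytest.raises(ValueError, match="chromosome mismatch"):
        subdomain.classify_enrichment_location(PLUS, 19_199, chrom="chr2")


def _peak(chrom, center, enr=10.0, width=250):
    return {"chrom": chrom, "start": center - width // 2,
            "end": center - width // 2 + width,
            "enr_D_1": enr, "enr_D_2": enr, "enr_PR_1": enr, "enr_PR_2": enr}


def test_assign_gene_subdomains():
    peaks = pd.DataFrame([
        _peak("chr1", 19_199),          # subregion of GP
        _peak("chr1", 14_500),          # mid of GP
        _peak("chr1", 11_000, enr=2.0),  # below the enrichment gate: ignored
    ])
    member = subdomain.assign_gene_subdomains([PLUS], peaks, min_enrichment=5.0)
    row = member.loc["GP"]
    assert bool(row[SUBREGION]) and bool(row[MID]) and bool(row["any_peak"])
    assert not row[FIVE_PRIME] and not row[THREE_PRIME]


def test_assign_gene_subdomains_exclusive_keeps_highest_precedence():
    peaks = pd.DataFrame([_peak("chr1", 19_199), _peak("chr1", 14_500)])
    member = subdomain.assign_gene_subdomains([PLUS], peaks, exclusive=True)
    row = member.loc["GP"]
    assert bool(row[SUBREGION]) and not row[MID]


def test_any_peak_without_subdomain_marks_control_exclusion():
    # a peak overlapping the gene body in the 2000-3000 bp dead zone
    # contributes no subdomain but still disqualifies the gene as control
    peaks = pd.DataFrame([_peak("chr1", 12_500)])
    member = subdomain.assign_gene_subdomains([PLUS], peaks)
    row = member.loc["GP"]
    assert bool(row["any_peak"])
    assert not row[list(subdomain.SUBDOMAINS)].any()


def test_subdomain_contingency_counts():
    genes = [
        GeneModel("A", "chr1", 10_000, 20_000, "+"),
        GeneModel("B", "chr1", 40_000, 50_000, "+"),
        GeneModel("C", "chr1", 70_000, 80_000, "+"),
        GeneModel("D", "chr1", 100_000, 110_000, "+"),
        GeneModel("E", "chr1", 130_000, 140_000, "+"),
    ]
    peaks = pd.DataFrame([_peak("chr1", 19_900), _peak("chr1", 49_900)])
    member = subdomain.assign_gene_subdomains(genes, peaks)
    classes = pd.Series(
        ["down", "up", "down", "up", "minimal"], index=[g.gene_id for g in genes]
    )
    res = subdomain.subdomain_contingency(member, classes)
    assert (res[CONTROL].n1, res[CONTROL].n2) == (1, 1)  # C, D
    assert (res[THREE_PRIME].n1, res[THREE_PRIME].n2) == (1, 1)  # A, B
    assert res[THREE_PRIME].p == pytest.approx(1.0)


def test_subdomain_contingency_empty_control_raises():
    member = pd.DataFrame(
        {s: [True] for s in subdomain.SUBDOMAINS} | {"any_peak": [True]},
        index=pd.Index(["A"], name="gene_id"),
    )
    with pytest.raises(ValueError, match="empty control"):
        subdomain.subdomain_contingency(member, pd.Series(["down"], index=["A"]))


def test_metagene_profile_orientation_and_zero_fill():
    track = pd.DataFrame(
        {"chrom": ["chr1"], "start": [18_000], "end": [20_000], "value": [3.0]}
    )
    classes = pd.Series(["down"], index=["GP"])
    prof = subdomain.metagene_profile(track, [PLUS], classes,
                                      anchor="TES", window_bp=2000, step_bp=500)
    # TES at 19999: covered for distances in [-1999, 0], zero beyond
    assert prof.loc[-500, "down"] == pytest.approx(3.0)
    assert prof.loc[0, "down"] == pytest.approx(3.0)
    assert prof.loc[500, "down"] == pytest.approx(0.0)
    assert prof.loc[-2000, "down"] == pytest.approx(0.0)

    # minus-strand gene: same oriented coverage profile
    track_m = pd.DataFrame(
        {"chrom": ["chr1"], "start": [10_000], "end": [12_001], "value": [3.0]}
    )
    prof_m = subdomain.metagene_profile(track_m, [MINUS],
                                        pd.Series(["down"], index=["GM"]),
                                        anchor="TES", window_bp=2000, step_bp=500)
    assert prof_m.loc[-500, "down"] == pytest.approx(3.0)
    assert prof_m.loc[500, "down"] == pytest.approx(0.0)


def test_max_difference_window():
    a = np.array([0.0, 0.0, 5.0, 5.0, 0.0])
    b = np.zeros(5)
    d = np.array([-100.0, -50.0, 0.0, 50.0, 100.0])
    lo, hi, mean = subdomain.max_difference_window(a, b, d, min_width_bins=2)
    assert (lo, hi) == (0.0, 50.0)
    assert mean == pytest.approx(5.0)
    with pytest.raises(ValueError, match="shorter"):
        subdomain.max_difference_window(a[:1], b[:1], d[:1], min_width_bins=2)
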