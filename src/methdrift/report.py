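"""Self-contained contingency checks on the reference gene counts.

Reference down- vs up-regulated gene counts by methylation-enrichment
subdomain (for autosomal genes with highly significant differential
expression) and the increase/decrease locus counts of the
consistent-change RRBS reference set are bundled here so the Fisher
machinery can be exercised — and its output checked — with no
sequencing data.
"""

from __future__ import annotations

import pandas as pd

from .stats import fisher_exact_2x2

# (n_down, n_up) by subdomain; control = significant expression change,
# no overlap with methylation-enriched regions
REFERENCE_SUBDOMAIN_COUNTS: dict[str, tuple[int, int]] = {
    "control": (723, 665),
    "five_prime": (76, 61),
    "mid": (375, 329),
    "three_prime": (178, 89),
    "three_prime_subregion": (85, 28),
}

# expected Fisher probabilities vs control; bounds checked within a
# factor of two (the sidedness used for the reference values is not
# recorded, and one- vs two-sided differs by about that factor here)
EXPECTED_P: dict[str, float] = {
    "three_prime": 1.3e-5,
    "three_prime_subregion": 9.7e-7,
}

# consistent-change RRBS locus counts (increase, decrease)
REFERENCE_ID_COUNTS: tuple[int, int] = (17661, 15842)


def reference_id_ratio() -> float:
    """Increase/decrease ratio of the consistent-change locus reference set."""
    i, d = REFERENCE_ID_COUNTS
    return i / d


def reference_tables_report() -> pd.DataFrame:
    """Recompute the subdomain Fisher tests from the bundled counts.

    Returns one row per subdomain with the recomputed two-sided
    probability, the expected value where one is recorded, and a
    pass/fail flag (within a factor of two of the expected probability;
    for subdomains without a recorded value, pass means p > 0.05).
    """
    ctrl = REFERENCE_SUBDOMAIN_COUNTS["control"]
    rows = []
    for name, (n_down, n_up) in REFERENCE_SUBDOMAIN_COUNTS.items():
        if name == "control":
            continue
        p = fisher_exact_2x2(n_down, n_up, ctrl[0], ctrl[1])
        expected = EXPECTED_P.get(name)
        if expected is not None:
            ok = expected / 2 <= p <= expected * 2
        else:
            ok = p > 0.05
        rows.append(
            {
                "subdomain": name,
                "n_down": n_down,
                "n_up": n_up,
                "fisher_p": p,
                "expected_p": expected,
                "passes": ok,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["control"] = ctrl
    df.attrs["reference_id_ratio"] = round(reference_id_ratio(), 2)
    return df


def format_report(df: pd.DataFrame) -> str:
    lines = [
        "Reference contingency checks (two-sided Fisher's exact test vs control "
        f"{df.attrs['control']})",
        f"consistent-change locus I/D ratio: {df.attrs['reference_id_ratio']:.2f} "
        f"({REFERENCE_ID_COUNTS[0]}/{REFERENCE_ID_COUNTS[1]})",
        "",
    ]
    for row in df.itertuples(index=False):
        has_expected = row.expected_p is not None and not pd.isna(row.expected_p)
        exp = f"{row.expected_p:.2g}" if has_expected else "p > 0.05"
        status = "PASS" if row.passes else "FAIL"
        lines.append(
            f"  {row.subdomain:<22s} ({row.n_down:>4d} vs {row.n_up:>4d})  "
            f"p = {row.fisher_p:.3g}  expected {exp:<10s} [{status}]"
        )
    return "\n".join(lines)
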