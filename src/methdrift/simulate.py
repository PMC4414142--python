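"""Synthetic methylome + transcriptome generator.

The generator emulates the statistical structure the analysis stages
assume, so the whole pipeline is testable without any sequencing data:

* gene models with log-normal lengths on a few autosomes;
* a bimodal locus methylation distribution (Beta mixture with modes near
  0.1 and 0.9, mirroring bisulfite data where most CpGs are either
  largely unmethylated or largely methylated);
* an age-drift parameter ``drift_delta``: the probability that a locus
  gains methylation in the older (poor-responder) group follows
  ``logistic(drift_gain * (fmc_D − 0.5) * drift_delta)``, so drift pushes
  intermediate loci toward the extremes;
* binomial methylated-read counts over negative-binomial depths, per
  group and replicate;
* MBD-capture (MeCap) peak enrichment increasing with methylation level
  and CpG density, with log-normal experimental noise;
* an expression table in which the odds of down-regulation increase with
  standardised gene bsDens and with 3′-end locus localisation:
  ``logit P(down | DE) = beta0 + beta_dens * z(bsDens) + beta_tes * 1[3'-localised]``.

Every planted quantity is recorded in truth tables so generator truth can
serve as the oracle for downstream statistics.  A single integer seed
drives one spawned random stream per output, so adding outputs never
perturbs existing ones, and identical seeds give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as mio
from .core import READ_LEN
from .genome import GeneModel

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "generate_worked_fixture", "PRESETS", "preset_config"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe the baseline (null) condition: no methylation
    drift and no density/localisation effect on expression.  Presets
    (``preset_config``) switch on the planted effects.
    """

    seed: int = 0
    n_genes: int = 3000
    n_chroms: int = 3
    include_sex_chrom: bool = False
    # gene length ~ LogNormal(meanlog, sdlog), clipped below
    length_meanlog: float = 8.5
    length_sdlog: float = 0.9
    min_length: int = 600
    # per-gene GC-rich fraction ~ Beta(a, b); kappa concentrates locus /
    # peak mass toward the TES (0 = uniform, 1 = fully 3'-weighted)
    gc_frac_a: float = 2.0
    gc_frac_b: float = 5.0
    kappa: float = 0.5
    # locus methylation mixture: modes near 0.1 and 0.9
    meth_low_a: float = 2.0
    meth_low_b: float = 10.0
    meth_high_a: float = 10.0
    meth_high_b: float = 2.0
    meth_low_weight: float = 0.55
    # age drift
    drift_delta: float = 0.0
    drift_gain: float = 6.0
    delta_sigma: float = 0.08
    # sequencing depth ~ NegBin(mean, size), replicates per group
    depth_mean: float = 40.0
    depth_size: float = 5.0
    n_replicates: int = 3
    # loci per gene ~ Poisson(locus_rate * length * gc_rich_frac)
    locus_rate: float = 0.004
    # MeCap: anchor peaks on a fraction of loci; enrichment model
    peak_prob: float = 0.25
    peak_width: int = 250
    enr_scale: float = 6.0
    enr_sigma: float = 0.3
    n_experiments: int = 2
    # expression model
    beta0: float = math.log(1.21)
    beta_dens: float = 0.0
    beta_tes: float = 0.0
    frac_de: float = 0.30
    frac_minimal: float = 0.45

    def validate(self) -> None:
        if not 0 <= self.meth_low_weight <= 1:
            raise ValueError("meth_low_weight must be in [0, 1]")
        if not 0 <= self.kappa <= 1:
            raise ValueError("kappa must be in [0, 1]")
        if self.drift_delta < 0:
            raise ValueError("drift_delta must be >= 0")
        if self.frac_de + self.frac_minimal > 1:
            raise ValueError("frac_de + frac_minimal must be <= 1")
        if self.n_genes < 1 or self.n_replicates < 1 or self.n_experiments < 1:
            raise ValueError("counts must be positive")
        if self.min_length < 2 * READ_LEN:
            raise ValueError(f"min_length must be >= {2 * READ_LEN}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named study conditions: ``null``, ``drift``, ``tes_effect``, ``full``."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SyntheticConfig(seed=seed, **params)


PRESETS: dict[str, dict] = {
    "null": {},
    "drift": {"drift_delta": 0.3},
    "tes_effect": {"beta_dens": math.log(1.5), "beta_tes": math.log(3.0), "kappa": 0.9},
    "full": {"drift_delta": 0.3, "beta_dens": math.log(1.5),
             "beta_tes": math.log(3.0), "kappa": 0.9},
}


@dataclass
class SyntheticDataset:
    """In-memory bundle of generated tables plus planted truth."""

    config: SyntheticConfig
    genes: list[GeneModel]
    gc_map: pd.DataFrame           # gene_id, gc_rich_frac
    loci: pd.DataFrame             # wide RRBS locus table
    peaks: pd.DataFrame            # MeCap peak table
    track: pd.DataFrame            # merged donor-enrichment bedGraph
    expression: pd.DataFrame       # gene_id, logFC, FDR
    truth_loci: pd.DataFrame
    truth_genes: pd.DataFrame

    def write(self, outdir) -> dict:
        """Write all outputs as plain-text files plus a manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_gene_models_bed(self.genes, outdir / "genes.bed")
        mio.write_rrbs(self.loci, outdir / "rrbs_loci.tsv")
        mio.write_mecap_peaks(self.peaks, outdir / "mecap_peaks.tsv")
        mio.write_bedgraph(self.track, outdir / "mecap_track.bedgraph")
        mio._write_tsv(self.gc_map, outdir / "gc_map.tsv")
        mio._write_tsv(self.expression, outdir / "expression.tsv")
        mio._write_tsv(self.truth_loci, outdir / "truth_loci.tsv")
        mio._write_tsv(self.truth_genes, outdir / "truth_genes.tsv")
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "n_genes": len(self.genes),
            "n_loci": len(self.loci),
            "n_peaks": len(self.peaks),
            "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


def sample_methylation_mixture(rng: np.random.Generator, n: int,
                               config: SyntheticConfig) -> np.ndarray:
    """Draw baseline (donor) locus methylation from the bimodal mixture."""
    low = rng.random(n) < config.meth_low_weight
    out = np.empty(n)
    out[low] = rng.beta(config.meth_low_a, config.meth_low_b, low.sum())
    out[~low] = rng.beta(config.meth_high_a, config.meth_high_b, (~low).sum())
    return out


def _locus_fractions(rng: np.random.Generator, n: int, kappa: float) -> np.ndarray:
    """Fractional gene positions; kappa mixes uniform with 3'-weighted Beta(4,1)."""
    tes_weighted = rng.random(n) < kappa
    out = np.empty(n)
    out[~tes_weighted] = rng.random((~tes_weighted).sum())
    out[tes_weighted] = rng.beta(4.0, 1.0, tes_weighted.sum())
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one complete synthetic study (see module docstring)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_loci, rng_peaks, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # ---- gene models -----------------------------------------------------
    n = config.n_genes
    lengths = np.maximum(
        rng_genes.lognormal(config.length_meanlog, config.length_sdlog, n).astype(int),
        config.min_length,
    )
    chrom_ids = rng_genes.integers(1, config.n_chroms + 1, n)
    chroms = np.array([f"chr{c}" for c in chrom_ids], dtype=object)
    if config.include_sex_chrom:
        on_x = rng_genes.random(n) < 0.05
        chroms[on_x] = "chrX"
    strands = np.where(rng_genes.random(n) < 0.5, "+", "-")
    gaps = rng_genes.integers(2000, 20000, n)
    # lay genes end to end per chromosome with random gaps
    starts = np.zeros(n, dtype=int)
    cursor: dict[str, int] = {}
    for i in range(n):
        c = chroms[i]
        pos = cursor.get(c, 10_000) + int(gaps[i])
        starts[i] = pos
        cursor[c] = pos + int(lengths[i])
    ends = starts + lengths
    width = len(str(n))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n)]
    genes = [
        GeneModel(gene_ids[i], str(chroms[i]), int(starts[i]), int(ends[i]), str(strands[i]))
        for i in range(n)
    ]
    gc_frac = rng_genes.beta(config.gc_frac_a, config.gc_frac_b, n)
    gc_map = pd.DataFrame({"gene_id": gene_ids, "gc_rich_frac": np.round(gc_frac, 6)})

    # ---- RRBS loci -------------------------------------------------------
    lam = config.locus_rate * lengths * gc_frac
    n_loci_per_gene = rng_loci.poisson(lam)
    gene_of_locus = np.repeat(np.arange(n), n_loci_per_gene)
    m = len(gene_of_locus)
    frac = _locus_fractions(rng_loci, m, config.kappa)
    glen = lengths[gene_of_locus]
    gstart = starts[gene_of_locus]
    gstrand = strands[gene_of_locus]
    mid = np.where(
        gstrand == "+",
        gstart + (frac * (glen - 1)).astype(int),
        gstart + glen - 1 - (frac * (glen - 1)).astype(int),
    )
    pos = np.clip(mid - READ_LEN // 2, gstart, gstart + glen - READ_LEN)
    n_cpg = 1 + rng_loci.poisson(2.2, m)

    fmc_d_true = sample_methylation_mixture(rng_loci, m, config)
    p_inc = expit(config.drift_gain * (fmc_d_true - 0.5) * config.drift_delta)
    increase = rng_loci.random(m) < p_inc
    mag = np.abs(rng_loci.normal(0.0, config.delta_sigma, m))
    fmc_pr_true = np.clip(fmc_d_true + np.where(increase, mag, -mag), 0.0, 1.0)

    loci_cols: dict[str, np.ndarray] = {
        "chrom": chroms[gene_of_locus],
        "pos": pos,
        "n_cpg": n_cpg,
    }
    p_nb = config.depth_size / (config.depth_size + config.depth_mean)
    for group, fmc_true in (("D", fmc_d_true), ("PR", fmc_pr_true)):
        for r in range(1, config.n_replicates + 1):
            depth = rng_loci.negative_binomial(config.depth_size, p_nb, m)
            meth = rng_loci.binomial(depth, fmc_true)
            loci_cols[f"depth_{group}{r}"] = depth
            loci_cols[f"meth_{group}{r}"] = meth
    loci = pd.DataFrame(loci_cols)
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)

    truth_loci = pd.DataFrame(
        {
            "chrom": chroms[gene_of_locus],
            "pos": pos,
            "gene_id": np.array(gene_ids, dtype=object)[gene_of_locus],
            "fmc_D_true": np.round(fmc_d_true, 6),
            "fmc_PR_true": np.round(fmc_pr_true, 6),
            "p_increase": np.round(p_inc, 6),
            "direction_true": np.where(increase, "increase", "decrease"),
        }
    ).iloc[order].reset_index(drop=True)

    # ---- MeCap peaks (anchored on a locus subset) ------------------------
    anchor = rng_peaks.random(m) < config.peak_prob
    a_idx = np.nonzero(anchor)[0]
    half = config.peak_width // 2
    p_start = np.maximum(mid[a_idx] - half, 0)
    p_end = p_start + config.peak_width
    cpg_density = n_cpg[a_idx].astype(float)
    peak_cols: dict[str, np.ndarray] = {
        "chrom": chroms[gene_of_locus[a_idx]],
        "start": p_start,
        "end": p_end,
    }
    for group, fmc_true in (("D", fmc_d_true), ("PR", fmc_pr_true)):
        base = config.enr_scale * fmc_true[a_idx] * cpg_density
        for e in range(1, config.n_experiments + 1):
            noise = rng_peaks.lognormal(0.0, config.enr_sigma, len(a_idx))
            peak_cols[f"enr_{group}_{e}"] = np.round(base * noise, 6)
    peaks = pd.DataFrame(peak_cols)
    p_order = np.lexsort((peaks["start"].to_numpy(), peaks["chrom"].to_numpy()))
    peaks = peaks.iloc[p_order].reset_index(drop=True)
    track = _merged_track(peaks)

    # ---- expression ------------------------------------------------------
    bsdens = 100.0 * n_loci_per_gene * READ_LEN / lengths
    has_loci = n_loci_per_gene > 0
    # 3'-localised: every locus of the gene within the TES-proximal quartile
    tes_local = np.zeros(n, dtype=bool)
    if m:
        min_frac = np.full(n, np.inf)
        np.minimum.at(min_frac, gene_of_locus, frac)
        tes_local = has_loci & (min_frac > 0.75)
    z = np.zeros(n)
    if has_loci.sum() > 1:
        mu = bsdens[has_loci].mean()
        sd = bsdens[has_loci].std()
        if sd > 0:
            z = np.where(has_loci, (bsdens - mu) / sd, 0.0)
    p_down = expit(config.beta0 + config.beta_dens * z + config.beta_tes * tes_local)

    u = rng_expr.random(n)
    is_de = u < config.frac_de
    is_min = (u >= config.frac_de) & (u < config.frac_de + config.frac_minimal)
    down = is_de & (rng_expr.random(n) < p_down)
    logfc = np.empty(n)
    fdr = np.empty(n)
    de_mag = 0.51 + rng_expr.exponential(0.8, n)
    logfc[is_de] = np.where(down[is_de], -de_mag[is_de], de_mag[is_de])
    fdr[is_de] = 10 ** (-rng_expr.uniform(2, 8, n)[is_de])
    logfc[is_min] = rng_expr.uniform(-0.29, 0.29, n)[is_min]
    fdr[is_min] = rng_expr.uniform(0.06, 1.0, n)[is_min]
    rest = ~is_de & ~is_min
    logfc[rest] = rng_expr.uniform(0.3, 0.5, n)[rest] * np.where(
        rng_expr.random(n)[rest] < 0.5, -1, 1
    )
    fdr[rest] = rng_expr.uniform(0.0, 1.0, n)[rest]
    expression = pd.DataFrame(
        {"gene_id": gene_ids, "logFC": np.round(logfc, 4), "FDR": fdr}
    )

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "bsdens_true": np.round(bsdens, 6),
            "tes_localized": tes_local,
            "p_down": np.round(p_down, 6),
            "is_de": is_de,
            "is_minimal": is_min,
            "down": down,
        }
    )

    return SyntheticDataset(
        config=config,
        genes=genes,
        gc_map=gc_map,
        loci=loci,
        peaks=peaks,
        track=track,
        expression=expression,
        truth_loci=truth_loci,
        truth_genes=truth_genes,
    )


def _merged_track(peaks: pd.DataFrame) -> pd.DataFrame:
    """Merge peak intervals into a non-overlapping donor-enrichment track."""
    d_cols = [c for c in peaks.columns if c.startswith("enr_D_")]
    vals = peaks[d_cols].mean(axis=1).to_numpy()
    rows = []
    for chrom, sub in peaks.assign(_v=vals).groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        acc: list[float] = []
        for s, e, v in zip(sub["start"], sub["end"], sub["_v"]):
            if cur_s is None:
                cur_s, cur_e, acc = int(s), int(e), [v]
            elif int(s) < cur_e:
                cur_e = max(cur_e, int(e))
                acc.append(v)
            else:
                rows.append((chrom, cur_s, cur_e, float(np.mean(acc))))
                cur_s, cur_e, acc = int(s), int(e), [v]
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, float(np.mean(acc))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def generate_worked_fixture(seed: int = 42) -> SyntheticDataset:
    """Miniature dataset (~20 genes, ~200 loci) with hand-checkable sizes."""
    config = SyntheticConfig(
        seed=seed,
        n_genes=20,
        n_chroms=2,
        locus_rate=0.02,
        drift_delta=0.3,
        beta_dens=math.log(1.5),
        beta_tes=math.log(3.0),
        kappa=0.7,
        frac_de=0.5,
        frac_minimal=0.3,
    )
    return generate_dataset(config)
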