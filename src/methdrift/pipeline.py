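"""End-to-end orchestration: simulate or load inputs, run every analysis
stage in dependency order, and write provenance-stamped result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import core, density, drift, io as mio, resampling, subdomain
from .simulate import SyntheticConfig, generate_dataset, preset_config

log = logging.getLogger(__name__)

DEFAULTS = {
    "min_cpg": 2,
    "min_depth": 20,
    "min_abs_delta": 0.0,
    "bin_width": 0.05,
    "min_bin_count": 20,
    "min_enrichment": 5.0,
    "n_iter": 1000,
    "resample_tol": 1e-3,
    "autosomes_only": True,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance(cfg: dict, seed: int) -> list[str]:
    return [
        f"methdrift {__version__}",
        f"seed={seed}",
        f"config_hash={_config_hash(cfg)}",
    ]


def _load_inputs(cfg: dict):
    """Resolve inputs either from a simulation preset or from file paths."""
    sim = cfg.get("simulate")
    if sim is not None:
        seed = int(sim.get("seed", 0))
        preset = sim.get("preset", "null")
        overrides = {k: v for k, v in sim.items() if k not in ("preset", "seed")}
        ds = generate_dataset(preset_config(preset, seed=seed, **overrides))
        return ds.genes, ds.loci, ds.peaks, ds.track, ds.expression, seed
    inputs = cfg.get("inputs")
    if inputs is None:
        raise ValueError("config needs either a 'simulate' or an 'inputs' section")
    for key in ("genes", "rrbs", "expression"):
        if key not in inputs:
            raise ValueError(f"missing input path: config key inputs.{key}")
    genes = mio.read_gene_models(inputs["genes"], inputs.get("genes_format", "BED6"))
    loci = mio.read_rrbs(inputs["rrbs"], inputs.get("rrbs_dialect", "pipeline_tsv"))
    peaks, track = (None, None)
    if "mecap_peaks" in inputs:
        peaks, track = mio.read_mecap(inputs["mecap_peaks"], inputs.get("mecap_track"))
    expr = mio.read_expression(inputs["expression"])
    return genes, loci, peaks, track, expr, int(cfg.get("seed", 0))


def run_pipeline(cfg: dict, outdir, dry_run: bool = False) -> dict:
    """Run every stage and write TSV/JSON outputs under ``outdir``.

    Returns the summary dictionary.  With ``dry_run`` the configuration
    and inputs are validated but nothing is computed or written.
    """
    params = {**DEFAULTS, **cfg.get("params", {})}
    genes, loci, peaks, track, expr, seed = _load_inputs(cfg)
    if dry_run:
        return {"validated": True, "n_genes": len(genes), "n_loci": len(loci)}
    header = _provenance(cfg, seed)
    outdir = Path(outdir)

    if params["autosomes_only"]:
        genes = [g for g in genes if g.chrom not in ("chrX", "chrY", "X", "Y")]

    # stage 1: filters and change classification
    mask = core.locus_pass_filter(loci, params["min_cpg"], params["min_depth"])
    log.info("locus filter: %d/%d pass", int(mask.sum()), len(mask))
    loci_f = loci.loc[mask].reset_index(drop=True)
    calls = core.classify_locus_change(loci_f, min_abs_delta=params["min_abs_delta"])

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": seed, "n_genes": len(genes),
                     "n_loci": len(loci), "n_loci_pass": int(mask.sum())}

    # stage 2: drift
    tables["methylation_histogram"] = drift.methylation_histogram(
        loci_f, bin_width=params["bin_width"])
    dtab = drift.drift_table(loci_f, calls, bin_width=params["bin_width"],
                             min_bin_count=params["min_bin_count"])
    tables["drift_table"] = dtab
    summary["reference_id_ratio"] = dtab.attrs.get("reference_ratio")

    # stage 3: concordance (needs peaks)
    if peaks is not None and len(peaks):
        pcalls = core.classify_peak_change(peaks, min_enrichment=params["min_enrichment"],
                                           min_fold=1.5)
        inc_mask = (pcalls["direction"] == core.INCREASE).to_numpy()
        if inc_mask.any():
            try:
                conc = core.rrbs_within_peaks_test(loci_f, calls, peaks, inc_mask)
                summary["concordance"] = {
                    "subset_increase": conc.n1, "subset_decrease": conc.n2,
                    "subset_ratio": conc.ratio, "reference_ratio": conc.ref_ratio,
                    "fisher_p": conc.p,
                }
            except ValueError as err:
                log.warning("concordance skipped: %s", err)

    # stage 4: subdomain contingency
    classes = subdomain.classify_expression_table(expr)
    classes.index = pd.Index(expr["gene_id"])
    if peaks is not None and len(peaks):
        member = subdomain.assign_gene_subdomains(
            genes, peaks, min_enrichment=params["min_enrichment"])
        try:
            cont = subdomain.subdomain_contingency(member, classes)
            tables["subdomain_contingency"] = pd.DataFrame(
                [
                    {"subdomain": name, "n_down": r.n1, "n_up": r.n2,
                     "fisher_p": r.p}
                    for name, r in cont.items()
                ]
            )
        except ValueError as err:
            log.warning("subdomain contingency skipped: %s", err)

    # stage 5: densities and quintiles.  Density and positional categories
    # describe where bisulfite loci *are* (a sequence property), so they use
    # every observed locus; the depth/CpG filter applies only to change calls.
    dens = density.compute_gene_density(genes, loci, peaks)
    dens = dens.assign(expr_class=classes.reindex(dens.index))
    tables["gene_density"] = dens.reset_index()
    qt = density.quintile_di_table(dens, classes, metric="bsdens")
    tables["quintiles_bsdens"] = qt
    summary["top_quintile_di_ratio"] = float(qt["di_ratio"].iloc[-1])
    summary["top_quintile_p"] = float(qt["fisher_p"].iloc[-1])

    # stage 6: matched resampling
    ref = dens.loc[dens["n_loci"] > 0].copy()
    qs = resampling.quartile_category_series(
        ref, n_iter=params["n_iter"], seed=seed, tol=params["resample_tol"])
    tables["resampling_quartiles"] = qs
    tes_row = qs.loc[qs["quartile"] == 4]
    if len(tes_row):
        summary["tes_quartile_di_ratio"] = float(tes_row["di_ratio"].iloc[0])
        summary["tes_quartile_p"] = float(tes_row["p"].iloc[0])

    written = mio.write_results(tables, outdir, summary=summary, header_lines=header)
    log.info("wrote %d tables to %s", len(written), outdir)
    return summary
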