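"""End-to-end orchestration over a declarative run configuration.

``run_pipeline`` executes: synthetic-data generation (optional) -> isoform
usage (DIU) -> splice events (PSI / Bayes factors / calls, directional
shifts) -> expression linkage -> miRNA enrichment -> 3'-end validation, and
writes every stage table plus a single JSON summary carrying the config hash
and seeds.  Thresholds default to the analysis' headline rules: DIU
FDR <= 1%, BF >= 5 in >= 10% of individuals with |mean dPSI| >= 0.05,
enrichment FDR <= 10% with fold >= 1.5.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import events as ev
from . import io as pio
from . import linkage, mirna, simulate, threeprime, usage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration with the analysis' default thresholds."""

    out_dir: str = "isoshift_run"
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    # thresholds (defaults are the analysis' stated decision rules)
    diu_fdr: float = 0.01
    min_gene_tpm: float = 1.0
    bf_threshold: float = 5.0
    bf_frac: float = 0.10
    min_mean_dpsi: float = 0.05
    enrich_fdr: float = 0.10
    min_fold: float = 1.5
    # sampling controls
    n_permutations_shannon: int = 500
    n_permutations_link: int = 100
    n_resamples_enrichment: int = 1000
    metagene_window: int = 250
    assignment_radius: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = simulate.SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic inputs and return the summary dict.

    All stage tables are written under ``config.out_dir``; the summary (also
    written as ``summary.json``) reports significant DIU gene counts, the
    per-category significant-event counts and negative fractions, enrichment
    hits, linkage statistics and the 3'-end validation comparison, plus the
    config hash and seed for provenance.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    hashed = config.to_dict()
    hashed.pop("out_dir", None)  # provenance hash covers the science, not the path
    chash = pio.config_hash(hashed)
    rng_master = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s) % (2**31) for s in rng_master.generate_state(4)]

    def _stage(name):
        logger.info("stage %-14s t=%.1fs", name, time.time() - t0)

    try:
        _stage("simulate")
        quant, sheet, truth_iso = simulate.simulate_isoform_matrix(sim)
        events_df, annotations, _, truth_ev = simulate.simulate_event_counts(sim)
        truth = truth_iso.merge(truth_ev)
        expr = simulate.simulate_expression_changes(sim, truth)
        pio.write_tpm(quant, out / "isoform_tpm.tsv", chash)
        pio.write_table(sheet, out / "sample_sheet.tsv", header_hash=chash)
        pio.write_table(events_df, out / "event_counts.tsv", header_hash=chash)
        pio.write_table(annotations, out / "event_annotations.tsv", header_hash=chash)
        pio.write_table(expr.reset_index(), out / "log2_fold_changes.tsv", header_hash=chash)

        _stage("diu")
        props = usage.compute_proportions(pio.read_tpm(out / "isoform_tpm.tsv"),
                                          pio.read_table(out / "sample_sheet.tsv"),
                                          min_gene_tpm=config.min_gene_tpm)
        diu = usage.diu_table(props, fdr=config.diu_fdr)
        pio.write_table(diu, out / "diu_results.tsv", header_hash=chash)
        dsh_per_gene, dsh_summary = usage.delta_shannon(
            props, n_permutations=config.n_permutations_shannon, seed=stage_seeds[0])
        pio.write_table(dsh_per_gene, out / "delta_shannon.tsv", header_hash=chash)

        _stage("events")
        psi_records, calls = ev.call_events(
            pio.read_table(out / "event_counts.tsv"), sheet,
            bf_threshold=config.bf_threshold, bf_frac=config.bf_frac,
            min_mean_dpsi=config.min_mean_dpsi)
        pio.write_table(psi_records, out / "psi_records.tsv", header_hash=chash)
        pio.write_table(calls, out / "event_calls.tsv", header_hash=chash)
        shifts = {cat: ev.directional_shift(calls, cat)
                  for cat in sorted(calls["category"].unique())}
        _, cv_tests = ev.dispersion_summary(psi_records, calls)

        _stage("linkage")
        link = linkage.gene_level_link(
            psi_records, annotations, expr,
            n_permutations=config.n_permutations_link, seed=stage_seeds[1],
            significant_events=set(calls.loc[calls["significant"], "event_id"]))
        pio.write_table(link.table, out / "link_results.tsv", header_hash=chash)
        sig_tandem = set(calls.loc[calls["significant"]
                                   & (calls["category"] == "TandemUTR"), "event_id"])
        scan = linkage.trans_factor_scan(
            expr, psi_records, annotations, "TandemUTR",
            significant_events=sig_tandem or None)  # all events when none called
        pio.write_table(scan, out / "trans_factor_scan.tsv", header_hash=chash)

        _stage("mirna")
        tandem_calls = calls[calls["category"] == "TandemUTR"]
        # shortened = significant with negative mean shift
        utr_calls = tandem_calls.assign(
            significant=tandem_calls["significant"] & (tandem_calls["mean_delta_psi"] < 0))
        regions, truth_utr = simulate.simulate_utr_sequences(sim, utr_calls)
        truth = truth.merge(truth_utr)
        pio.write_regions(regions, out / "utr_regions", header_hash=chash)
        mirnas = simulate.default_mirna_set(sim)
        pio.write_table(mirnas, out / "mirnas.tsv", header_hash=chash)
        _, density_tests = mirna.density_by_class(regions, mirnas)
        enrich = mirna.mirna_enrichment(
            regions, mirnas, n_resamples=config.n_resamples_enrichment,
            seed=stage_seeds[2], fdr=config.enrich_fdr, min_fold=config.min_fold)
        pio.write_table(enrich, out / "mirna_enrichment.tsv", header_hash=chash)

        _stage("threeprime")
        reads, sites = simulate.simulate_threeprime_reads(sim, truth)
        sites = sites.merge(
            utr_calls[["event_id", "significant"]].assign(
                sig_class=lambda d: np.where(d["significant"],
                                             "shortened_significant", "unchanged")),
            on="event_id", how="left").drop(columns=["significant"])
        pio.write_bed(reads, out / "threeprime_reads.bed", chash)
        profiles, _ = threeprime.metagene(reads, sites, window=config.metagene_window,
                                          sheet=sheet)
        pio.write_table(profiles, out / "metagene_profiles.tsv", header_hash=chash)
        psi3, comparison3 = threeprime.psi_from_threeprime(
            reads, sites, sheet, assignment_radius=config.assignment_radius)
        pio.write_table(psi3, out / "threeprime_psi.tsv", header_hash=chash)

        truth.to_json(out / "truth.json")
    except Exception as err:  # pragma: no cover - abort contract
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_genes_tested": int(len(diu)),
        "n_diu_significant": int(diu["significant"].sum()),
        "frac_delta_shannon_positive": dsh_summary["frac_positive"],
        "n_events": int(calls.shape[0]),
        "per_category": {
            cat: {
                "n_significant": s.n_significant,
                "frac_negative": s.frac_negative,
                "p_one_sample": s.p_one_sample,
                "p_two_sample": s.p_two_sample,
                "cv_p_value": cv_tests.get(cat, {}).get("p_value"),
            }
            for cat, s in shifts.items()
        },
        "link_ks_stat": link.ks_stat,
        "link_ks_p": link.ks_p,
        "link_frac_positive": link.frac_positive,
        "n_scan_candidates": int(scan["candidate"].sum()),
        "n_enriched_mirnas": int(enrich["significant"].sum()),
        "enriched_mirnas": enrich.loc[enrich["significant"], "mirna_id"].tolist(),
        "utr_density_tests": density_tests,
        "threeprime_comparison": comparison3,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    summary["runtime_s"] = round(time.time() - t0, 2)  # not in the byte-stable file
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
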