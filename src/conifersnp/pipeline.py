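"""End-to-end orchestration on synthetic data, with a reproducibility manifest.

Runs the stages in dependency order — simulate, per-dataset calling, merging
and Fisher combination, flanking masking, assembly QC, target and array
candidate selection, genotype simulation and array QC — logging the count at
every filtering step. The manifest snapshots the configuration, seed,
per-stage row counts and SHA-256 digests of each table, so a re-run with the
same config and seed reproduces every digest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assembly_qc, combine, genotype_qc, simulate, targets
from .site_calling import CallerParams, call_dataset

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},  # SimConfig field overrides
    "caller": {},    # CallerParams field overrides
    "combine": {"p_f": 0.10},
    "targets": {"ps_threshold": 1e-4},
    "orientation": {"n_refs": 50, "reads_per_ref": 200,
                    "misorientation_rate": 0.1, "alpha": 0.05},
    "array": {"n_samples": 260, "no_call_rate": 0.02, "call_threshold": 0.15,
              "call_rate": 0.85, "family_alpha": 0.05,
              "priority_fraction": 0.2},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    manifest: dict
    tables: dict = field(default_factory=dict)
    sequences: dict = field(default_factory=dict)


def _digest(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(index=False)
    elif isinstance(obj, dict):
        payload = json.dumps(obj, sort_keys=True, default=str)
    else:
        payload = str(obj)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_config(source) -> dict:
    """Merge a config mapping (or YAML file path) over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str,)) or hasattr(source, "read"):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    for key, value in source.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _default_class_plan(n: int) -> dict:
    plan = {}
    remaining = n
    for cls, want in (("C5", 2), ("C3", 2), ("C7", 1), ("C2", 1)):
        if remaining >= want and (cls not in ("C3", "C5") or want >= 2):
            plan[cls] = want
            remaining -= want
    if remaining:
        plan["C1"] = remaining
    return plan


def run_pipeline(config=None, outdir=None) -> PipelineResult:
    """Execute the full synthetic pipeline; returns manifest and stage tables."""
    cfg = load_config(config)
    seed = cfg.get("seed")
    if seed is None:
        raise PipelineError("config", "seed required when simulation is requested")

    counts: dict = {}
    digests: dict = {}
    tables: dict = {}

    # --- simulate ---------------------------------------------------------
    sim_cfg = simulate.SimConfig(seed=seed, **cfg["simulate"])
    reference, truth = simulate.simulate_reference(sim_cfg)
    pileups = simulate.simulate_pileups(reference, truth, sim_cfg)
    counts["reference_sequences"] = len(reference)
    counts["planted_variants"] = len(truth)
    counts["pileup_rows"] = len(pileups)
    logger.info("simulated %d isotigs, %d planted variants", len(reference), len(truth))

    # --- per-dataset calling ----------------------------------------------
    params = CallerParams(**cfg["caller"])
    snp_tables, indel_tables = {}, {}
    for ds in sim_cfg.dataset_ids:
        trusted = ds not in simulate.DEFAULT_INDEL_UNTRUSTED
        snps, indels = call_dataset(pileups, dataset_id=ds, params=params,
                                    indel_trusted=trusted)
        snp_tables[ds] = snps
        indel_tables[ds] = indels
        counts[f"calls_{ds}"] = len(snps)

    # --- merge + flanking mask --------------------------------------------
    combined = combine.merge_datasets(
        snp_tables, indel_tables,
        indel_untrusted=simulate.DEFAULT_INDEL_UNTRUSTED)
    p_f = cfg["combine"]["p_f"]
    mask = combine.select_flanking_variants(combined, p_f=p_f)
    per_ds_alleles = combine.per_dataset_allele_sets(snp_tables, p_f=p_f)
    masked_ref, per_ds_masked, indel_track = combine.build_masked_reference(
        reference, mask, per_ds_alleles)
    counts["combined_variants"] = len(combined)
    counts["masked_snp_positions"] = mask.n_masked_snps()
    counts["masked_indel_positions"] = mask.n_masked_indels()

    # --- assembly QC -------------------------------------------------------
    plan = _default_class_plan(len(reference))
    matches, expected = simulate.simulate_match_table(plan, seed=seed)
    rename = dict(zip(sorted(expected), sorted(reference)))
    matches = matches.assign(qseqid=matches["qseqid"].map(rename))
    confidence_tbl = assembly_qc.classify_isotigs(
        matches, isotig_ids=list(reference))
    confidence = dict(zip(confidence_tbl["isotig"],
                          confidence_tbl["confidence_class"]))
    stats = assembly_qc.assembly_stats([len(s) for s in reference.values()])

    ocfg = cfg["orientation"]
    stranded = simulate.simulate_stranded_counts(
        ocfg["n_refs"], ocfg["reads_per_ref"], ocfg["misorientation_rate"],
        seed=seed)
    orientation = assembly_qc.orient_table(stranded, alpha=ocfg["alpha"])
    recovered = (orientation["orientation"].to_numpy()
                 == stranded["true_orientation"].to_numpy())
    counts["orientation_recovered"] = int(recovered.sum())
    counts["orientation_refs"] = len(stranded)

    # --- target selection --------------------------------------------------
    isogroup_map = pd.DataFrame({
        "isotig": list(reference),
        "isogroup": [f"ig_{name}" for name in reference],
        "length": [len(s) for s in reference.values()],
    })
    tcfg = targets.SelectionConfig(**cfg["targets"])
    target_tbl, target_ledger = targets.filter_target_snps(
        combined, isogroup_map, confidence=confidence,
        indel_positions=mask.indels, config=tcfg)
    counts["target_snps"] = len(target_tbl)
    counts["target_rejected"] = len(target_ledger)

    acfg = cfg["array"]
    n_priority = int(len(reference) * acfg["priority_fraction"])
    priority = set(sorted(reference)[:n_priority])
    keys = [(r.isotig, r.pos) for r in target_tbl.itertuples()]
    scores = simulate.simulate_design_scores(keys, seed=seed)
    selected, sel_ledger = targets.select_array_candidates(
        target_tbl, priority_isotigs=priority, design_scores=scores, config=tcfg)
    counts["array_candidates"] = len(selected)
    counts["array_rejected"] = len(sel_ledger)

    # --- genotyping-array QC ----------------------------------------------
    n_loci = len(selected)
    if n_loci:
        maf = np.clip(selected["mean_freq"].to_numpy(), 0.05, 0.5)
        calls, geno_truth = simulate.simulate_genotypes(
            n_loci, acfg["n_samples"], maf,
            no_call_rate=acfg["no_call_rate"], seed=seed)
        locus_ids = [f"{r.isotig}_{r.pos}" for r in selected.itertuples()]
        per_locus = genotype_qc.qc_matrix(calls, locus_ids=locus_ids,
                                          min_call_rate=acfg["call_rate"])
        summary = genotype_qc.summarize_array(
            per_locus, n_attempted=n_loci, n_assayed=n_loci,
            family_alpha=acfg["family_alpha"])
    else:
        per_locus = pd.DataFrame()
        summary = genotype_qc.summarize_counts(0, 0, 0, 0)
    counts["array_attempted"] = summary.n_attempted
    counts["array_successful"] = summary.n_successful

    tables.update({
        "pileups": pileups,
        "combined": combined,
        "confidence": confidence_tbl,
        "orientation": orientation,
        "stranded_truth": stranded,
        "targets": target_tbl,
        "target_ledger": target_ledger,
        "selected": selected,
        "selection_ledger": sel_ledger,
        "per_locus_qc": per_locus,
        "isogroup_map": isogroup_map,
        "matches": matches,
    })
    for name, tbl in tables.items():
        digests[name] = _digest(tbl)
    digests["reference"] = _digest(reference)
    digests["masked_reference"] = _digest(masked_ref)

    manifest = {
        "config": cfg,
        "seed": seed,
        "counts": counts,
        "digests": digests,
        "assembly_stats": vars(stats),
        "array_summary": {
            "n_attempted": summary.n_attempted,
            "n_assayed": summary.n_assayed,
            "n_called": summary.n_called,
            "n_successful": summary.n_successful,
            "n_hwe_deviant": summary.n_hwe_deviant,
            "bonferroni_alpha": summary.bonferroni_alpha,
            "percentages": summary.percentages,
        },
    }
    result = PipelineResult(manifest=manifest, tables=tables,
                            sequences={"reference": reference,
                                       "masked_reference": masked_ref,
                                       "per_dataset_masked": per_ds_masked,
                                       "indel_track": indel_track})
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir):
    from . import io as cio
    out = cio.ensure_dir(outdir)
    cio.write_fasta(result.sequences["reference"], out / "reference.fasta")
    cio.write_fasta(result.sequences["masked_reference"], out / "reference.masked.fasta")
    cio.write_bed(result.sequences["indel_track"], out / "indel_mask.bed")
    for name, tbl in result.tables.items():
        if isinstance(tbl, pd.DataFrame):
            cio.write_table(tbl, out / f"{name}.tsv")
    cio.write_vcf(result.tables["combined"], out / "combined.vcf")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)


def report(manifest: dict) -> str:
    """Human-readable per-stage accounting of a completed run."""
    lines = ["pipeline run report", "===================", ""]
    lines.append(f"seed: {manifest['seed']}")
    lines.append("")
    lines.append("stage counts:")
    for key, value in manifest["counts"].items():
        lines.append(f"  {key:28s} {value}")
    st = manifest["assembly_stats"]
    lines.append("")
    lines.append("assembly statistics:")
    lines.append(f"  sequences {st['n_sequences']}  mean {st['mean']:.0f}"
                 f"  median {st['median']:.0f}  N50 {st['n50']}  total {st['total']}")
    arr = manifest["array_summary"]
    lines.append("")
    lines.append("array summary:")
    lines.append(f"  attempted {arr['n_attempted']}  assayed {arr['n_assayed']}"
                 f"  called {arr['n_called']}  successful {arr['n_successful']}")
    for key, value in (arr["percentages"] or {}).items():
        lines.append(f"  {key:28s} {value}")
    c = manifest["counts"]
    lines.append("")
    lines.append("filter conservation:")
    lines.append(f"  targets: {c['target_snps']} retained + "
                 f"{c['target_rejected']} rejected")
    lines.append(f"  array:   {c['array_candidates']} selected + "
                 f"{c['array_rejected']} rejected")
    return "\n".join(lines)
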