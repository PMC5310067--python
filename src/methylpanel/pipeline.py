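"""End-to-end orchestration: simulate -> call -> stats -> network -> PLS-DA.

Every stage reads only the declared TSV/FASTQ artifacts of the previous
stage and writes its own into the run directory, so a run can be resumed or
re-executed from any intermediate. A manifest records the configuration,
seed, input hashes and per-stage record counts; re-running with the same
configuration and seed reproduces the deterministic artifacts byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, plsda, simulate, stats
from .panel import Amplicon, builtin_panel, load_panel, validate_panel


@dataclass
class RunConfig:
    out_dir: str = "methylpanel_run"
    panel_fasta: str | None = None       # None -> packaged synthetic panel
    panel_tsv: str | None = None
    reads: str | None = None             # None + simulate -> generated
    sample_sheet: str | None = None
    simulate: bool = True
    seed: int = 0
    cv_seed: int = 0
    depth: int | None = None             # None -> log-uniform 9..2704
    min_conversion: float = 0.97
    cv_threshold: float = 0.05
    sd_threshold: float = 0.01
    p_threshold: float = 0.05
    fwer_sites: float = 0.05
    fwer_network: float = 0.10
    pls_components: int = 2
    pls_cv: str = "loo"                  # loo | none
    pls_missing: str = "impute"          # impute | drop
    pls_sign_mapping: str = "coding"
    n_control: int = 24
    n_mild: int = 23
    n_intermediary: int = 13
    n_severe: int = 12
    n_nec_missing: int = 9
    n_duplicated: int = 4
    stages: tuple[str, ...] = ("simulate", "call", "stats", "plsda", "report")

    def __post_init__(self) -> None:
        for name in ("min_conversion", "cv_threshold", "sd_threshold",
                     "p_threshold", "fwer_sites", "fwer_network"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config_panel(config: RunConfig) -> list[Amplicon]:
    if config.panel_fasta:
        return load_panel(config.panel_fasta, config.panel_tsv)
    return builtin_panel()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    panel = _load_config_panel(config)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}

    report = validate_panel(panel)
    report.to_csv(out / "panel_validation.tsv", sep="\t", index=False)
    manifest["stages"]["panel"] = {"n_amplicons": len(panel),
                                   "n_discrepancies": len(report)}

    reads_path = Path(config.reads) if config.reads else out / "reads.fastq"
    sheet_path = (
        Path(config.sample_sheet) if config.sample_sheet else out / "samples.tsv"
    )

    if "simulate" in config.stages and config.simulate:
        root = np.random.SeedSequence(config.seed)
        s_design, s_p, s_reads = [
            np.random.default_rng(s) for s in root.spawn(3)
        ]
        design = simulate.build_design(
            n_control=config.n_control, n_mild=config.n_mild,
            n_intermediary=config.n_intermediary, n_severe=config.n_severe,
            n_nec_missing=config.n_nec_missing, n_duplicated=config.n_duplicated,
            seed=config.seed,
        )
        truth = simulate.TruthModel()
        sample_p = simulate.simulate_sample_methylation(design, truth, panel, s_p)
        reads, read_truth = simulate.simulate_reads(
            sample_p, panel, design, truth, s_reads, depth=config.depth
        )
        simulate.write_fastq(reads, reads_path)
        simulate.write_sample_sheet(design, sheet_path)
        sample_p.to_csv(out / "truth_sample_p.tsv", sep="\t", index=False)
        read_truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "n_libraries": len(design.libraries), "n_reads": len(reads)
        }

    sheet = pd.read_csv(sheet_path, sep="\t")
    manifest["inputs"] = {
        "reads": _sha256(reads_path), "sample_sheet": _sha256(sheet_path)
    }

    if "call" in config.stages:
        reads = simulate.read_fastq(reads_path)
        read_table, counts = calling.call_reads(
            reads, panel, sheet,
            min_conversion=config.min_conversion,
        )
        sites, regions = calling.aggregate(
            read_table, panel,
            cv_threshold=config.cv_threshold, sd_threshold=config.sd_threshold,
        )
        read_table.to_csv(out / "read_calls.tsv", sep="\t", index=False)
        sites.to_csv(out / "methylation_sites.tsv", sep="\t", index=False)
        regions.to_csv(out / "methylation_regions.tsv", sep="\t", index=False)
        counts["measurements_failing_coverage"] = int((~regions["retained"]).sum())
        (out / "filter_log.json").write_text(json.dumps(counts, indent=2))
        manifest["stages"]["call"] = counts

    if "stats" in config.stages:
        sites = pd.read_csv(out / "methylation_sites.tsv", sep="\t")
        regions = pd.read_csv(out / "methylation_regions.tsv", sep="\t")
        _run_stats(config, out, panel, sheet, sites, regions, manifest)

    if "plsda" in config.stages:
        region_table = pd.read_csv(out / "region_table.tsv", sep="\t")
        _run_plsda(config, out, region_table, manifest)

    if "report" in config.stages:
        make_report(out)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _run_stats(config, out, panel, sheet, sites, regions, manifest) -> None:
    region_table = stats.build_region_table(regions, sheet)
    region_table.to_csv(out / "region_table.tsv", sep="\t", index=False)

    # region-level comparisons (logit scale): CF vs control and 4 severity strata
    comp_rows = []
    for (gene, tissue), block in region_table.groupby(["gene", "tissue"]):
        vals = stats.logit_array(block["region_mean"].to_numpy(), eps=1e-3)
        grp = block["group"].to_numpy()
        two = {
            "control": vals[grp == "control"],
            "CF": vals[grp != "control"],
        }
        strata = {g: vals[grp == g] for g in simulate.GROUPS if (grp == g).sum() >= 2}
        for label, groups in (("cf_vs_control", two), ("severity", strata)):
            if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
                continue
            c = stats.compare_groups(
                groups, variable=f"{gene}|{tissue}", alpha=config.p_threshold
            )
            comp_rows.append(
                {"gene": gene, "tissue": tissue, "comparison": label,
                 "test": c.test, "statistic": c.statistic, "p": c.pvalue,
                 "significant": c.significant, "levene_p": c.levene_p}
            )
    pd.DataFrame(comp_rows).to_csv(out / "region_comparisons.tsv", sep="\t", index=False)

    # per-CpG Fisher tests, one Bonferroni family per tissue
    site_results = []
    for tissue in simulate.TISSUES:
        tables = stats.build_site_tables(sites, sheet, tissue)
        if len(tables):
            res = stats.per_cpg_fisher(tables, fwer=config.fwer_sites)
            res.insert(0, "tissue", tissue)
            site_results.append(res)
    site_res = (
        pd.concat(site_results, ignore_index=True)
        if site_results
        else pd.DataFrame()
    )
    site_res.to_csv(out / "site_tests.tsv", sep="\t", index=False)

    # co-methylation networks per stratum
    edge_frames = []
    for stratum, mask in (
        ("control", region_table["group"] == "control"),
        ("CF", region_table["group"] != "control"),
    ):
        wide = stats.region_wide(region_table[mask])
        if wide.shape[1] >= 2:
            edge_frames.append(
                stats.comethylation_network(wide, stratum, fwer=config.fwer_network)
            )
    edges = pd.concat(edge_frames, ignore_index=True) if edge_frames else pd.DataFrame()
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)

    # repeatability from technical duplicates
    rep_out: dict = {}
    if sheet["replicate"].max() >= 2:
        pairs = stats.replicate_pairs_logit(regions, sheet)
        if len(pairs) and (~np.isnan(pairs).any(axis=1)).any():
            est = stats.estimate_repeatability(pairs)
            rep_out = {"sd_logit": est.sd, "df": est.df,
                       "n_pairs": est.n_pairs, "n_missing": est.n_missing}
    (out / "repeatability.json").write_text(json.dumps(rep_out, indent=2))

    # genotype-methylation association per dosage locus and tissue
    geno_rows = []
    dosage_cols = [c for c in sheet.columns if c.startswith("dosage_")]
    subj_dosage = sheet[["subject_id"] + dosage_cols].drop_duplicates("subject_id")
    for col in dosage_cols:
        gene = col[len("dosage_"):]
        sub = region_table[region_table["gene"] == gene]
        for tissue, block in sub.groupby("tissue"):
            merged = block.merge(subj_dosage, on="subject_id")
            try:
                r, p, n = stats.genotype_association(
                    merged["region_mean"].to_numpy(), merged[col].to_numpy()
                )
            except stats.StatsError:
                continue
            geno_rows.append({"gene": gene, "tissue": tissue, "r": r, "p": p, "n": n})
    pd.DataFrame(geno_rows).to_csv(out / "genotype_association.tsv", sep="\t", index=False)

    manifest["stages"]["stats"] = {
        "n_region_comparisons": len(comp_rows),
        "n_site_tests": len(site_res),
        "n_significant_sites": int(site_res["significant"].sum()) if len(site_res) else 0,
        "n_network_edges": int(edges["significant"].sum()) if len(edges) else 0,
    }


def _run_plsda(config, out, region_table, manifest) -> None:
    wide = stats.region_wide(region_table)
    labels = (
        region_table[["subject_id", "group"]]
        .drop_duplicates("subject_id")
        .set_index("subject_id")
        .loc[wide.index, "group"]
    )
    y = np.where(labels == "control", plsda.CONTROL_CODE, plsda.CASE_CODE)
    summary = plsda.evaluate_descriptor_sets(
        wide, y,
        n_components=config.pls_components,
        cv=config.pls_cv if config.pls_cv != "none" else "resub",
        missing=config.pls_missing,
        sign_mapping=config.pls_sign_mapping,
    )
    model = plsda.fit_plsda(
        wide, y, config.pls_components, config.pls_missing, config.pls_sign_mapping
    )
    report = plsda.classify(model, wide, y, config.pls_missing)
    report.table.to_csv(out / "pls_scores.tsv", sep="\t", index=False)
    summary_d = {
        row["descriptor_set"]: row["percent_correct"]
        for _, row in summary.iterrows()
    }
    (out / "pls_summary.json").write_text(
        json.dumps({"percent_correct": summary_d, "cv": config.pls_cv,
                    "resubstitution_both": report.percent_correct}, indent=2)
    )
    manifest["stages"]["plsda"] = {"n_samples": report.n_classified}


def make_report(out_dir: str | Path) -> dict:
    """Bundle the run's headline tables: differentially methylated sites
    with direction per tissue, significant network edges per stratum,
    percent correct per descriptor set, repeatability SD and df."""
    out = Path(out_dir)
    missing = [
        name for name in
        ("site_tests.tsv", "network_edges.tsv", "pls_summary.json",
         "repeatability.json")
        if not (out / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    site_res = pd.read_csv(out / "site_tests.tsv", sep="\t")
    diff = (
        site_res[site_res["significant"]]
        [["tissue", "gene", "site", "direction", "p", "q"]]
        if len(site_res)
        else site_res
    )
    diff.to_csv(out / "report_differential_sites.tsv", sep="\t", index=False)
    edges = pd.read_csv(out / "network_edges.tsv", sep="\t")
    sig_edges = edges[edges["significant"]] if len(edges) else edges
    sig_edges.to_csv(out / "report_network_edges.tsv", sep="\t", index=False)
    summary = {
        "differential_sites": len(diff),
        "network_edges": len(sig_edges),
        "pls": json.loads((out / "pls_summary.json").read_text()),
        "repeatability": json.loads((out / "repeatability.json").read_text()),
    }
    (out / "report_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """A quick full-chain configuration on the packaged synthetic panel: a
    reduced cohort (12 controls, 24 patients) sequenced at a fixed depth of
    1600 reads per amplicon — deep enough for the coverage filter's binomial
    SD to retain measurements across the panel's methylation range — so the
    demo completes in minutes."""
    return RunConfig(
        out_dir=out_dir, seed=seed, depth=1600,
        n_control=12, n_mild=12, n_intermediary=6, n_severe=6,
        n_nec_missing=4, n_duplicated=2,
    )
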