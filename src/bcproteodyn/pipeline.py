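"""Composite workflows wiring the analysis stages, with a run manifest.

Two pipelines mirror the study's two datasets: the cohort workflow
(QC -> complex co-expression -> TNBC differential expression -> elastic-net
drug-response prediction) and the perturbation workflow (profile
summarisation -> IC50 screen -> clustering -> opposite-dynamics selection ->
pathway consistency -> PDP detection).  Every run writes a manifest
recording the stage order, configuration hash, seed and outputs, so reruns
at a fixed seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import FuzzyCMeans, zscore_profiles
from .complexes import compare_levels, enumerate_pairs, pair_correlations
from .de import differential_expression, select_signature, signature_separation
from .dynamics import (ic50_screen, opposite_dynamics_select,
                       pathway_consistency, pdp_detect, summarize_timecourse)
from .enpredict import ENConfig, compare_layer_combos, knn_impute
from .io import (DrugResponseTable, OmicsMatrix, PathwayAnnotation, RunConfig,
                 SampleAnnotation, TimeCourseExperiment, write_matrix)
from .qc import run_qc


def _config_hash(cfg: RunConfig) -> str:
    payload = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class Manifest:
    """Ordered record of pipeline stages and their outputs."""

    def __init__(self, cfg: RunConfig, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.data = {
            "software_version": __version__,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "stages": [],
        }

    def record(self, stage: str, outputs: list[str], **extra) -> None:
        self.data["stages"].append({"stage": stage, "outputs": outputs, **extra})
        self.write()

    def write(self) -> None:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_cohort_pipeline(matrices: dict[str, OmicsMatrix],
                        ann: SampleAnnotation,
                        response: DrugResponseTable,
                        catalog,
                        cfg: RunConfig,
                        out_dir,
                        drugs=None,
                        combos=("M", "D", "E", "DE", "MDE")) -> dict:
    """QC -> complexes -> differential expression -> elastic net.

    ``matrices`` uses layer tags ``M`` (mutation), ``E`` (transcript) and
    ``D`` (protein, replicate-level).  Returns the in-memory results and
    writes TSV outputs plus a manifest under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(cfg, out)
    results: dict = {}

    # --- qc ---
    filtered, averaged, report = run_qc(
        matrices["D"], ann, cfg.max_missing_fraction, cfg.outlier_z_threshold,
        cfg.cv_n_bins,
    )
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    write_matrix(averaged, out / "protein_averaged.tsv")
    manifest.record("qc", ["qc_report.tsv", "protein_averaged.tsv"],
                    n_features_after=report.n_features_after)
    results["qc_report"] = report
    results["protein_averaged"] = averaged

    # --- complexes ---
    pairs = enumerate_pairs(catalog, averaged)
    prot_tab = pair_correlations(pairs, averaged, "protein",
                                 cfg.min_co_observed)
    transcript = matrices["E"]
    pairs_t = enumerate_pairs(catalog, transcript)
    tran_tab = pair_correlations(pairs_t, transcript, "transcript",
                                 cfg.min_co_observed)
    table = pd.concat([prot_tab, tran_tab], ignore_index=True)
    table.to_csv(out / "complex_pairs.tsv", sep="\t", index=False)
    pr = prot_tab["pearson_r"].dropna()
    tr = tran_tab["pearson_r"].dropna()
    if len(pr) >= 2 and len(tr) >= 2:
        t, p, med_p, med_t = compare_levels(pr, tr)
        results["complex_comparison"] = {
            "t": t, "p": p, "median_protein_r": med_p,
            "median_transcript_r": med_t,
        }
    manifest.record("complexes", ["complex_pairs.tsv"],
                    n_pairs_protein=len(pr), n_pairs_transcript=len(tr))
    results["complex_pairs"] = table

    # --- differential expression ---
    line_tnbc = (ann.table.drop_duplicates("cell_line")
                 .set_index("cell_line")["tnbc"])
    labels = line_tnbc.reindex(averaged.sample_ids).to_numpy(dtype=bool)
    dep = differential_expression(averaged, labels, cfg.de_p_threshold,
                                  cfg.de_fc_up, cfg.de_fc_down,
                                  cfg.equal_var_ttest)
    dep.to_csv(out / "dep_table.tsv", sep="\t")
    signature = select_signature(dep, cfg.signature_n)
    (out / "signature.txt").write_text("\n".join(signature) + "\n")
    sep_score = (signature_separation(averaged, labels, signature)
                 if len(signature) >= 2 else float("nan"))
    manifest.record("de", ["dep_table.tsv", "signature.txt"],
                    n_deps=int(dep["is_dep"].sum()),
                    signature_separation=sep_score)
    results["dep_table"] = dep
    results["signature"] = signature
    results["signature_separation"] = sep_score

    # --- elastic net ---
    en_cfg = ENConfig.preset(cfg.en_preset, seed=cfg.seed)
    layers = {
        "M": matrices["M"],
        "E": matrices["E"],
        "D": knn_impute(averaged),
    }
    drug_list = list(drugs) if drugs is not None else response.drugs
    en_table = compare_layer_combos(layers, response, drug_list, combos,
                                    en_cfg, seed=cfg.seed)
    en_table.to_csv(out / "predictive_power.tsv", sep="\t", index=False)
    manifest.record("enpredict", ["predictive_power.tsv"],
                    n_models=int(en_table["valid"].sum()))
    results["predictive_power"] = en_table
    return results


def run_perturbation_pipeline(tc: TimeCourseExperiment,
                              response: DrugResponseTable,
                              pathways: PathwayAnnotation | None,
                              cfg: RunConfig,
                              out_dir) -> dict:
    """Summarise -> IC50 screen -> fuzzy clustering -> opposite dynamics ->
    pathway consistency -> PDPs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(cfg, out)
    results: dict = {}

    profiles = summarize_timecourse(tc)
    screen = ic50_screen(profiles, response, cfg.ic50_tau,
                         cfg.ic50_max_missing_timepoints)
    screen.to_csv(out / "ic50_screen.tsv", sep="\t")
    manifest.record("ic50_screen", ["ic50_screen.tsv"],
                    n_classified=int((screen["ic50_class"] != "none").sum()))
    results["ic50_screen"] = screen

    # clustering is a grouping aid over mean profiles (averaged across lines
    # within each subtype group), per drug
    memberships = {}
    for drug in tc.drugs:
        for group, lines in (("tnbc", tc.tnbc_lines()),
                             ("non_tnbc", tc.non_tnbc_lines())):
            cols = [c for c in profiles.values.columns
                    if c[0] in lines and c[1] == drug]
            prof = profiles.values.loc[:, cols]
            prof = prof.T.groupby(level="time_h").mean().T.dropna()
            Z, ok = zscore_profiles(prof.to_numpy())
            if len(Z) < cfg.n_clusters:
                continue
            fcm = FuzzyCMeans(n_clusters=cfg.n_clusters, m=cfg.fuzzifier_m,
                              random_state=cfg.seed).fit(Z)
            mem = pd.DataFrame(fcm.membership_, index=prof.index[ok],
                               columns=[f"cluster{i + 1}"
                                        for i in range(cfg.n_clusters)])
            memberships[(drug, group)] = mem
            mem.to_csv(out / f"fuzzy_membership_{drug}_{group}.tsv", sep="\t")
    manifest.record("fuzzy_clustering",
                    [f"fuzzy_membership_{d}_{g}.tsv" for d, g in memberships])
    results["memberships"] = memberships

    selection = opposite_dynamics_select(
        tc, cfg.trend_p_threshold, cfg.trend_fc_threshold, cfg.monotone_rho,
        cfg.intersect_drugs,
    )
    (out / "opposite_proteins.txt").write_text(
        "\n".join(selection.selected) + "\n")
    manifest.record("opposite_dynamics", ["opposite_proteins.txt"],
                    n_selected=len(selection.selected))
    results["selection"] = selection

    if pathways:
        ptable = pathway_consistency(selection, pathways, tc,
                                     cfg.pathway_tnbc_min,
                                     cfg.pathway_non_tnbc_min)
        ptable.to_csv(out / "pathway_consistency.tsv", sep="\t")
        manifest.record("pathway_consistency", ["pathway_consistency.tsv"],
                        n_pass=int(ptable["passes"].sum()))
        results["pathway_consistency"] = ptable

    pdps = {}
    for drug in tc.drugs:
        pdps[drug] = pdp_detect(tc, drug, cfg.pdp_frac_threshold,
                                cfg.de_p_threshold, cfg.de_fc_up,
                                cfg.de_fc_down)
        (out / f"pdp_{drug}.txt").write_text("\n".join(pdps[drug]) + "\n")
    manifest.record("pdp", [f"pdp_{d}.txt" for d in tc.drugs],
                    counts={d: len(v) for d, v in pdps.items()})
    results["pdps"] = pdps
    return results
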