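"""End-to-end pipeline orchestration.

Runs the stages in dependency order from one YAML-style config:

    simulate -> features -> classify/contrast -> preprocess -> associate
             -> concordance -> network -> composition -> report

writing TSV outputs plus a JSON run manifest (seed, stage row/feature
counts, SHA-256 hashes of outputs) into the output directory.  Re-running
with the same config and seed reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import differential_abundance
from .composition import compare_composition, estimate_composition
from .concordance import (across_gene_correlation, rrho_map,
                          within_gene_correlation)
from .network import CoexpressionNetwork, module_trait_partial_correlation
from .perifusion import build_feature_table
from .preprocess import (compare_cv, feature_cv, preprocess_proteome,
                         preprocess_rna)
from .responders import classify_hyper_responders, prevalence, t2d_effect_summary
from .simulate import GeneratorConfig, simulate_cohort, write_cohort

__all__ = ["run_pipeline", "report", "default_config"]

logger = logging.getLogger(__name__)

TECHNICAL_COVARIATES = ["purity", "culture_time", "digestion_time",
                        "cold_ischemia_time"]


def default_config(outdir="run", seed: int = 0) -> dict:
    return {
        "out": str(outdir),
        "seed": seed,
        "simulate": {},
        "stages": {s: True for s in
                   ("simulate", "features", "responders", "preprocess",
                    "associate", "concordance", "network", "composition",
                    "report")},
        "network": {"beta": 8.0, "corr": "bicor", "min_module_size": 30,
                    "merge_threshold": 0.75},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    manifest["outputs"][path.name] = {"sha256": _sha256(path),
                                      "rows": int(df.shape[0])}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cfg = default_config() | dict(config)
    stages = default_config()["stages"] | dict(cfg.get("stages", {}))
    outdir = Path(cfg["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed,
                      "stages": {}, "outputs": {}}

    sim_kwargs = dict(cfg.get("simulate") or {})
    sim_kwargs.setdefault("seed", seed)
    gen = GeneratorConfig(**sim_kwargs)
    try:
        bundle = simulate_cohort(gen)
        write_cohort(bundle, outdir)
        for f in outdir.glob("*.tsv"):
            manifest["outputs"][f.name] = {"sha256": _sha256(f)}
        manifest["stages"]["simulate"] = {
            "n_donors": int(len(bundle.donors)),
            "n_traces": len(bundle.traces),
            "config": dataclasses.asdict(gen),
        }

        features = None
        if stages.get("features"):
            features = build_feature_table(bundle.traces, bundle.protocols)
            _write(features, outdir / "secretion_features.tsv", manifest)
            manifest["stages"]["features"] = {"rows": int(len(features))}

        if stages.get("responders") and features is not None:
            calls = classify_hyper_responders(features)
            _write(calls, outdir / "responder_calls.tsv", manifest)
            prev = {}
            for cls in ("fat_hr", "leu_hr"):
                frac, ci = prevalence(calls, cls)
                prev[cls] = {"fraction": frac, "ci_low": ci[0], "ci_high": ci[1]}
            manifest["stages"]["responders"] = {"prevalence": prev}
            if bundle.donors["group"].nunique() == 2:
                contrasts = t2d_effect_summary(features, bundle.donors)
                _write(contrasts, outdir / "t2d_contrasts.tsv", manifest)
            else:
                manifest["stages"]["responders"]["contrast"] = "single group"

        protein = rna = None
        if stages.get("preprocess") and bundle.protein is not None:
            protein, plog = preprocess_proteome(bundle.protein)
            batches = bundle.donors.set_index("donor_id")["batch"].reindex(
                bundle.rna.columns)
            rna, rlog = preprocess_rna(bundle.rna, batches.to_numpy())
            _write(protein, outdir / "protein_processed.tsv", manifest,
                   index=True)
            _write(rna, outdir / "rna_processed.tsv", manifest, index=True)
            (outdir / "processing_log.json").write_text(
                json.dumps({"protein": plog, "rna": rlog}, indent=1))
            cv = compare_cv(feature_cv(protein, log_base=10),
                            feature_cv(rna, log_base=2))
            manifest["stages"]["preprocess"] = {
                "n_proteins": int(protein.shape[0]),
                "n_genes": int(rna.shape[0]), "cv_summary": cv,
            }

        de_p = de_r = None
        two_groups = bundle.donors["group"].nunique() == 2
        if stages.get("associate") and protein is not None and two_groups:
            groups = bundle.donors.set_index("donor_id")["group"]
            de_p = differential_abundance(protein,
                                          groups.reindex(protein.columns))
            de_r = differential_abundance(rna, groups.reindex(rna.columns))
            _write(de_p, outdir / "de_protein.tsv", manifest)
            _write(de_r, outdir / "de_rna.tsv", manifest)
            manifest["stages"]["associate"] = {
                "de_protein_significant": int(de_p["significant"].sum()),
                "de_rna_significant": int(de_r["significant"].sum()),
            }

        if stages.get("concordance") and protein is not None and de_p is not None:
            mapping = bundle.omics_truth["protein"].set_index(
                "feature_id")["gene_id"]
            r_across, n_shared = across_gene_correlation(protein, rna, mapping)
            _, summary = within_gene_correlation(protein, rna, mapping)
            de_p_idx = de_p.set_index("feature")
            de_r_idx = de_r.set_index("feature")
            score_p = pd.Series(
                np.sign(de_p_idx["log2fc"]) * -np.log10(
                    np.maximum(de_p_idx["p"], 1e-300)),
                index=mapping.reindex(de_p_idx.index).to_numpy())
            score_r = pd.Series(
                np.sign(de_r_idx["log2fc"]) * -np.log10(
                    np.maximum(de_r_idx["p"], 1e-300)),
                index=de_r_idx.index)
            grid = rrho_map(score_p, score_r)
            pd.DataFrame(grid.logp).to_csv(outdir / "rrho_grid.tsv", sep="\t",
                                           index=False)
            manifest["outputs"]["rrho_grid.tsv"] = {
                "sha256": _sha256(outdir / "rrho_grid.tsv")}
            manifest["stages"]["concordance"] = {
                "across_gene_r": r_across, "n_shared_genes": n_shared,
                "within_gene": summary, "rrho_max_logp": grid.max_logp,
            }

        if stages.get("network") and protein is not None:
            net = CoexpressionNetwork(**cfg.get("network", {})).fit(protein)
            modules = pd.DataFrame({"feature": protein.index,
                                    "module": net.labels_})
            _write(modules, outdir / "modules.tsv", manifest)
            _write(net.eigengenes_, outdir / "eigengenes.tsv", manifest,
                   index=True)
            donors = bundle.donors.set_index("donor_id").reindex(
                protein.columns)
            auc = build_feature_table(bundle.traces, bundle.protocols) \
                if features is None else features
            piv = auc.pivot(index="donor_id", columns="segment", values="auc")
            traits = pd.concat(
                [donors[["age", "bmi", "hba1c"]],
                 piv.reindex(protein.columns).add_prefix("auc_")], axis=1)
            mt = module_trait_partial_correlation(
                net.eigengenes_, traits, donors[TECHNICAL_COVARIATES])
            _write(mt, outdir / "module_trait.tsv", manifest)
            manifest["stages"]["network"] = {
                "n_modules": net.n_modules_,
                "unassigned": int((net.labels_ == 0).sum()),
                "significant_cells": int(mt["significant"].sum()),
            }

        if stages.get("composition") and protein is not None:
            markers = {ct: sub["feature_id"].tolist() for ct, sub in
                       bundle.omics_truth["markers"].groupby("cell_type")}
            comp = estimate_composition(protein, markers)
            _write(comp, outdir / "composition.tsv", manifest, index=True)
            groups = bundle.donors.set_index("donor_id")["group"].reindex(
                comp.index)
            cc = compare_composition(comp, groups.to_numpy())
            _write(cc, outdir / "composition_contrast.tsv", manifest)
            manifest["stages"]["composition"] = {
                "cell_types": list(comp.columns)}

        if stages.get("report"):
            report(outdir, manifest)
    except Exception:
        (outdir / "manifest.json.failed").write_text(
            json.dumps(manifest, indent=1, default=str))
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return manifest


def report(run_dir, manifest: dict | None = None) -> Path:
    """Markdown summary report with figures for a completed run directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    if manifest is None:
        mf = run_dir / "manifest.json"
        manifest = json.loads(mf.read_text()) if mf.exists() else {"stages": {}}
    lines = ["# Islet phenotyping run report", ""]

    donors_f = run_dir / "donors.tsv"
    donors = pd.read_csv(donors_f, sep="\t") if donors_f.exists() else None

    # average traces by group
    tr_f = run_dir / "traces_G.tsv"
    if tr_f.exists() and donors is not None:
        tr = pd.read_csv(tr_f, sep="\t")
        tr = tr.merge(donors[["donor_id", "group"]], on="donor_id")
        fig, ax = plt.subplots(figsize=(7, 3))
        for grp, sub in tr.groupby("group"):
            prof = sub.groupby("time_min")["value"].mean()
            ax.plot(prof.index, prof.to_numpy(), label=grp)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("insulin (pmol/mL)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "report_traces.png", dpi=100)
        plt.close(fig)
        lines += ["## Average glucose-arm traces by group", "",
                  "![traces](report_traces.png)", ""]

    resp = manifest.get("stages", {}).get("responders")
    if resp:
        lines += ["## Hyper-responder prevalence (Clopper-Pearson 95% CI)", ""]
        for cls, d in resp["prevalence"].items():
            lines.append(f"- {cls}: {100 * d['fraction']:.1f}% "
                         f"({100 * d['ci_low']:.1f}-{100 * d['ci_high']:.1f}%)")
        lines.append("")
    elif donors is not None and donors["group"].nunique() < 2:
        lines += ["## Contrasts", "", "single group: contrast skipped", ""]

    ct_f = run_dir / "t2d_contrasts.tsv"
    if ct_f.exists():
        ct = pd.read_csv(ct_f, sep="\t")
        sub = ct[ct["feature"].str.endswith(":auc")]
        lines += ["## ND vs T2D secretion contrasts (AUC)", "",
                  sub[["feature", "percent_difference", "p", "q"]]
                  .round(4).to_markdown(index=False), ""]

    mt_f = run_dir / "module_trait.tsv"
    if mt_f.exists():
        mt = pd.read_csv(mt_f, sep="\t")
        piv = mt.pivot(index="module", columns="trait", values="r")
        fig, ax = plt.subplots(figsize=(8, 5))
        im = ax.imshow(piv.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(piv.shape[1]), piv.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(piv.shape[0]), piv.index, fontsize=6)
        fig.colorbar(im, label="partial r")
        fig.tight_layout()
        fig.savefig(run_dir / "report_module_trait.png", dpi=100)
        plt.close(fig)
        lines += ["## Module-trait partial correlations", "",
                  "![module-trait](report_module_trait.png)", ""]

    rr_f = run_dir / "rrho_grid.tsv"
    if rr_f.exists():
        grid = pd.read_csv(rr_f, sep="\t").to_numpy()
        fig, ax = plt.subplots(figsize=(4, 3.5))
        v = np.nanmax(np.abs(grid)) or 1.0
        im = ax.imshow(grid, origin="lower", cmap="RdBu_r", vmin=-v, vmax=v)
        ax.set_xlabel("RNA rank threshold bin")
        ax.set_ylabel("protein rank threshold bin")
        fig.colorbar(im, label="signed -log10 p")
        fig.tight_layout()
        fig.savefig(run_dir / "report_rrho.png", dpi=100)
        plt.close(fig)
        lines += ["## RNA-protein RRHO", "", "![rrho](report_rrho.png)", ""]

    comp_f = run_dir / "composition.tsv"
    if comp_f.exists() and donors is not None:
        comp = pd.read_csv(comp_f, sep="\t", index_col=0)
        merged = comp.merge(donors.set_index("donor_id")[["group"]],
                            left_index=True, right_index=True)
        fig, ax = plt.subplots(figsize=(6, 3))
        cts = [c for c in comp.columns]
        data = [merged.loc[merged["group"] == g, ct]
                for ct in cts for g in sorted(merged["group"].unique())]
        ax.boxplot(data, tick_labels=[f"{ct}\n{g}" for ct in cts for g in
                                      sorted(merged["group"].unique())])
        ax.set_ylabel("composition score")
        plt.setp(ax.get_xticklabels(), fontsize=6)
        fig.tight_layout()
        fig.savefig(run_dir / "report_composition.png", dpi=100)
        plt.close(fig)
        lines += ["## Cell composition", "",
                  "![composition](report_composition.png)", ""]

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
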