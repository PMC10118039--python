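"""End-to-end orchestration: simulate (or load), process, and report.

Stages run in dependency order — merge -> blank filter -> presence ->
{richness, Var[C], PCA, classification}; rates -> {models, carbon} — and a
failure in one branch is collected and reported rather than silently
suppressing the others. All stage outputs are plain delimited-text files the
report references by path; the report itself is JSON plus a short text
summary.
"""

from __future__ import annotations

import json
import traceback
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from exometab import carbon, cca, classify, features, io, ordination, richness
from exometab import primary_stats, simulate
from exometab.config import RunConfig
from exometab.vocab import SPECIES


def run_all(
    config: RunConfig,
    outdir: str | Path,
    inputs: dict[str, str | Path] | None = None,
    n_features: int = 300,
    n_decoys: int = 30,
) -> dict:
    """Run every stage on user inputs or on a fresh simulation.

    ``inputs`` may carry paths for ``field``, ``hydro``, ``metadata``,
    ``rates`` and optionally ``annotations``; when omitted, synthetic data
    are generated under ``config.seed``. Returns the report dict (also
    written to ``report.json`` and ``summary.txt`` in ``outdir``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "outputs": {}, "summary": {}, "errors": {}}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # collected, not fatal: other branches still run
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            report["errors"][name + "_trace"] = traceback.format_exc(limit=3)
            return None

    annotations = None
    if inputs is None:
        rng_truth = simulate.random_truth(
            n_features,
            np.random.default_rng(config.seed),
            n_decoys=n_decoys,
            blank_contaminant_fraction=0.05,
        )
        field, hydro, metadata, ledger = simulate.generate_feature_tables(
            rng_truth, seed=config.seed
        )
        rates = simulate.generate_primary_rates(
            simulate.default_primary_truth(), seed=config.seed + 1
        )
        io.write_feature_table(field, outdir / "field_features.tsv")
        io.write_feature_table(hydro, outdir / "hydro_features.tsv")
        io.write_sample_metadata(metadata, outdir / "samples.tsv")
        io.write_table(ledger, outdir / "truth_ledger.tsv")
        io.write_primary_rates(rates, outdir / "primary_rates.tsv")
        report["outputs"]["truth_ledger"] = str(outdir / "truth_ledger.tsv")
    else:
        metadata = io.read_sample_metadata(inputs["metadata"])
        field = io.read_feature_table(inputs["field"], metadata)
        hydro = io.read_feature_table(inputs["hydro"], metadata)
        rates = io.read_primary_rates(inputs["rates"]) if "rates" in inputs else None
        if "annotations" in inputs:
            annotations = io.read_annotation_table(inputs["annotations"])

    # ---- feature branch
    merged = features.merge_feature_tables(field, hydro, config)
    io.write_table(merged, outdir / "merged_features.tsv", index=True)
    report["outputs"]["merged"] = str(outdir / "merged_features.tsv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, removal_log = features.filter_blanks(merged, metadata, config)
    io.write_table(removal_log, outdir / "blank_removals.tsv")
    presence = features.call_group_presence(filtered, metadata, config)
    io.write_table(presence.astype(int), outdir / "presence_groups.tsv", index=True)
    sample_presence = features.call_sample_presence(filtered, metadata, config)
    io.write_table(sample_presence.astype(int), outdir / "presence_samples.tsv", index=True)
    report["outputs"]["presence_groups"] = str(outdir / "presence_groups.tsv")
    report["outputs"]["presence_samples"] = str(outdir / "presence_samples.tsv")

    def _richness():
        venn = richness.venn_report_table(presence)
        io.write_table(venn, outdir / "venn_report.tsv")
        report["outputs"]["venn"] = str(outdir / "venn_report.tsv")
        report["summary"]["venn"] = venn.to_dict(orient="records")
        return venn

    def _varc():
        rows = []
        for sp in SPECIES:
            res = cca.binary_varc_for_species(sample_presence, metadata, sp)
            rows.append(cca.varc_report(res, sp))
        tab = pd.DataFrame(rows)
        io.write_table(tab, outdir / "varc_secondary.tsv")
        report["outputs"]["varc"] = str(outdir / "varc_secondary.tsv")
        report["summary"]["varc_secondary"] = {
            r["subset"]: r["var_c"] for r in rows
        }
        return tab

    def _pca():
        res = ordination.pca_binary(sample_presence, n_components=3)
        io.write_table(res.scores, outdir / "pca_binary_scores.tsv", index=True)
        io.write_table(res.loadings, outdir / "pca_binary_loadings.tsv", index=True)
        report["outputs"]["pca_binary_scores"] = str(outdir / "pca_binary_scores.tsv")
        report["summary"]["pca_binary_explained"] = [float(x) for x in res.explained_fraction]
        return res

    def _classify():
        tallies = classify.classify_all_groups(merged, presence, metadata, annotations, config)
        tab = classify.tally_table(tallies)
        io.write_table(tab, outdir / "class_tallies.tsv")
        report["outputs"]["class_tallies"] = str(outdir / "class_tallies.tsv")
        report["summary"]["n_unknown_per_group"] = {
            f"{t.species}|{t.condition}": t.n_unknown for t in tallies
        }
        return tab

    stage("richness", _richness)
    stage("varc", _varc)
    stage("pca", _pca)
    stage("classify", _classify)

    # ---- primary-rate branch
    if rates is not None and not rates.empty:
        def _model():
            contrasts = primary_stats.contrast_table(rates, config)
            io.write_table(contrasts, outdir / "contrasts.tsv")
            report["outputs"]["contrasts"] = str(outdir / "contrasts.tsv")
            report["summary"]["n_significant_contrasts"] = int(contrasts["significant"].sum())
            return contrasts

        def _carbon():
            ledger_tab = carbon.carbon_ledger(rates)
            io.write_table(ledger_tab, outdir / "carbon_ledger.tsv")
            report["outputs"]["carbon_ledger"] = str(outdir / "carbon_ledger.tsv")
            shares = ledger_tab.dropna(subset=["share_pct"])
            report["summary"]["carbon_shares"] = {
                f"{r.species}|{r.condition}|{r.metabolite_group}": r.share_pct
                for r in shares.itertuples(index=False)
            }
            counts = carbon.count_detected(rates, replicate_level=True)
            io.write_table(counts, outdir / "detected_counts.tsv")
            report["outputs"]["detected_counts"] = str(outdir / "detected_counts.tsv")
            return ledger_tab

        def _primary_varc():
            rows = []
            for sp in SPECIES:
                res = cca.primary_varc_for_species(rates, sp)
                rows.append(cca.varc_report(res, sp))
            tab = pd.DataFrame(rows)
            io.write_table(tab, outdir / "varc_primary.tsv")
            report["outputs"]["varc_primary"] = str(outdir / "varc_primary.tsv")
            report["summary"]["varc_primary"] = {r["subset"]: r["var_c"] for r in rows}
            return tab

        stage("model", _model)
        stage("carbon", _carbon)
        stage("primary_varc", _primary_varc)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=io._jsonify), encoding="utf-8"
    )
    (outdir / "summary.txt").write_text(_text_summary(report), encoding="utf-8")
    return report


def _text_summary(report: dict) -> str:
    lines = ["exometab pipeline summary", "=" * 25]
    s = report["summary"]
    for v in s.get("venn", []):
        lines.append(
            f"{v['species']}: FIELD {v['n_field_total']} / HYDRO {v['n_hydro_total']} "
            f"(shared {v['n_shared']})"
        )
    for sp, vc in s.get("varc_secondary", {}).items():
        lines.append(f"Var[C] secondary {sp}: {vc:.3f}")
    for sp, vc in s.get("varc_primary", {}).items():
        lines.append(f"Var[C] primary {sp}: {vc:.3f}")
    if "pca_binary_explained" in s:
        pct = ", ".join(f"{100 * x:.1f}%" for x in s["pca_binary_explained"])
        lines.append(f"binary PCA explained (PC1-3): {pct}")
    if "n_significant_contrasts" in s:
        lines.append(f"significant FIELD-vs-HYDRO contrasts: {s['n_significant_contrasts']}")
    if report.get("errors"):
        lines.append("stage errors: " + ", ".join(k for k in report["errors"] if not k.endswith("_trace")))
    return "\n".join(lines) + "\n"
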