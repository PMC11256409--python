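"""End-to-end pipeline driver.

Runs simulate -> triage -> cluster -> profile -> annotate -> diversity ->
signatures -> classify on one synthetic study, writing every stage's
declared output table plus a manifest of SHA-256 checksums. Identical
config and seed reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import annot, catalog, io as vio, ml, profiler, signatures as sig, stats, triage
from .config import RunConfig
from .synthgen import generate_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger("virowas")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis on a simulated study; returns the report."""
    if config.sim is None:
        raise ValueError("run_pipeline requires a simulation config (config.sim)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    _stage("simulate")
    sim = config.sim
    study = generate_cohort(sim)
    inputs_dir = outdir / "inputs"
    study.write(inputs_dir)

    _stage("triage")
    decisions = triage.triage_contigs(study.contig_features)
    triage_frame = triage.decisions_frame(decisions)
    vio.write_tsv(triage_frame, outdir / "triage.tsv")
    viral_ids = set(triage_frame.loc[triage_frame.verdict == "viral", "contig_id"])
    report["triage"] = triage_frame["verdict"].value_counts().to_dict()

    _stage("cluster")
    lengths = {name: len(seq) for name, seq in study.genomes.items()}
    # keep study contigs that passed triage, every near-duplicate assembly,
    # and the external-catalog genomes
    keep = {
        name
        for name in lengths
        if name in viral_ids or study.source[name] == "external" or name.startswith("dup")
    }
    seg_by_pair: dict[tuple[str, str], list[catalog.AlignmentSegment]] = defaultdict(list)
    for r in study.alignments.itertuples(index=False):
        if r.query_id in keep and r.subject_id in keep:
            seg_by_pair[(r.query_id, r.subject_id)].append(
                catalog.AlignmentSegment(
                    r.query_id, r.subject_id, int(r.q_start), int(r.q_end),
                    int(r.s_start), int(r.s_end), float(r.percent_identity),
                )
            )
    sims = {
        pair: catalog.pair_similarity(segs, lengths[pair[0]], lengths[pair[1]])
        for pair, segs in seg_by_pair.items()
    }
    cat = catalog.cluster_votus(
        {k: lengths[k] for k in keep},
        sims,
        id_threshold=config.cluster_identity,
        cov_threshold=config.cluster_coverage,
        strict=config.cluster_strict,
    )
    cat = catalog.integrate_external(cat, study.source)
    features_by_id = study.contig_features.set_index("contig_id")
    for rep in cat.clusters:
        if rep in features_by_id.index:
            tier, _ = catalog.quality_tier(
                float(features_by_id.loc[rep, "completeness"]),
                float(features_by_id.loc[rep, "contamination"]),
            )
            cat.tier[rep] = tier
    vio.write_tsv(cat.to_frame(), outdir / "clusters.tsv")
    report["catalog"] = {
        "n_votus": len(cat.clusters),
        "n_members": len(cat.members),
    }

    _stage("annotate")
    hits = [
        annot.ProteinHit(
            r.protein_id, r.votu_id, r.target_family,
            float(r.percent_identity), float(r.query_coverage),
            float(r.subject_coverage), float(r.bit_score),
        )
        for r in study.protein_hits.itertuples(index=False)
    ]
    evidence = [
        annot.HostEvidence(r.votu_id, r.host_genome_id, "crispr_spacer", bit_score=float(r.bit_score))
        for r in study.spacer_hits.itertuples(index=False)
    ] + [
        annot.HostEvidence(
            r.votu_id, r.host_genome_id, "genome_alignment",
            percent_identity=float(r.percent_identity),
            viral_coverage=float(r.viral_coverage),
        )
        for r in study.genome_aln_hits.itertuples(index=False)
    ]
    gene_counts = {
        v: int(features_by_id.loc[v, "total_gene_count"]) for v in study.votus
    }
    annotation = annot.annotate_votus(hits, gene_counts, evidence)
    vio.write_tsv(annotation, outdir / "annotation.tsv")
    kingdom_map = dict(zip(annotation.votu_id, annotation.kingdom))
    family_map = dict(zip(annotation.votu_id, annotation.family))
    report["annotation"] = annotation["kingdom"].value_counts().to_dict()

    _stage("profile")
    profiles = study.profiles()
    vio.write_tsv(profiles["VLP"], outdir / "profile_vlp.tsv", index=True)
    vio.write_tsv(profiles["bulk"], outdir / "profile_bulk.tsv", index=True)
    for modality, prof in profiles.items():
        fam = profiler.aggregate_family(prof, family_map)
        vio.write_tsv(fam, outdir / f"profile_family_{modality.lower()}.tsv", index=True)

    _stage("diversity")
    groups = study.groups()
    diversity_rows = []
    permanova_results = {}
    for modality, prof in profiles.items():
        for sample in prof.index:
            for subset in ("all", "eukaryotic", "prokaryotic"):
                observed, shannon = stats.alpha_diversity(
                    prof.loc[sample], kingdom_map, subset
                )
                diversity_rows.append(
                    {
                        "sample_id": sample,
                        "modality": modality,
                        "subset": subset,
                        "observed": observed,
                        "shannon": shannon,
                    }
                )
        dist = stats.bray_curtis(prof)
        vio.write_tsv(dist, outdir / f"distance_{modality.lower()}.tsv", index=True)
        coords, explained = stats.pcoa(dist)
        vio.write_tsv(coords, outdir / f"pcoa_{modality.lower()}.tsv", index=True)
        res = stats.permanova(
            dist, groups, n_perm=config.n_permutations, seed=config.seed
        )
        permanova_results[modality] = res.__dict__
    # modality separation on the combined profile
    combined = pd.concat([profiles["VLP"], profiles["bulk"]])
    modality_labels = study.sample_sheet.set_index("sample_id")["modality"]
    res = stats.permanova(
        stats.bray_curtis(combined), modality_labels,
        n_perm=config.n_permutations, seed=config.seed,
    )
    permanova_results["modality"] = res.__dict__
    vio.write_tsv(pd.DataFrame(diversity_rows), outdir / "alpha.tsv")
    (outdir / "permanova.json").write_text(
        json.dumps(permanova_results, indent=2, sort_keys=True) + "\n"
    )
    report["permanova"] = permanova_results

    _stage("signatures")
    results, concordance = sig.call_signatures(
        profiles["VLP"], profiles["bulk"], groups,
        alpha=config.alpha, min_prevalence=config.min_prevalence,
    )
    sig_frame = sig.signatures_frame(results)
    vio.write_tsv(sig_frame, outdir / "signatures.tsv")
    (outdir / "concordance.json").write_text(
        json.dumps(
            {
                "table": concordance.table,
                "odds_ratio": concordance.odds_ratio,
                "p_value": concordance.p_value,
            },
            indent=2,
        )
        + "\n"
    )
    called = {
        r.votu_id: r.status
        for r in results
        if r.status in ("case_enriched", "control_enriched")
    }
    report["signatures"] = sig_frame["status"].value_counts().to_dict()
    report["concordance"] = {
        "odds_ratio": concordance.odds_ratio,
        "p_value": concordance.p_value,
    }
    if any(s == "case_enriched" for s in called.values()) and any(
        s == "control_enriched" for s in called.values()
    ):
        occurrences = sig.functional_enrichment(
            study.function_presence, called, alpha=config.alpha
        )
        vio.write_tsv(
            pd.DataFrame([o.__dict__ for o in occurrences]), outdir / "functions.tsv"
        )
        report["functions"] = {
            "n_significant": sum(o.significant for o in occurrences)
        }
    else:
        report["functions"] = {"skipped": "need both signature groups"}

    _stage("classify")
    if called:
        feats = sorted(called)
        bundles = []
        for modality, prof in profiles.items():
            labels = groups.loc[prof.index].map(
                {"IBD": "case", "control": "control"}
            )
            bundles.append(
                ml.DatasetBundle(
                    f"{sim.cohort_id}_{modality}", prof[feats], labels
                )
            )
        rf_params = {"n_estimators": config.rf_n_estimators}
        reports = {
            b.dataset_id: ml.cv_auc(
                b, n_repeats=config.cv_repeats, n_folds=config.cv_folds,
                seed=config.seed, **rf_params,
            )
            for b in bundles
        }
        selected = ml.top_union(
            {k: r.feature_ranking for k, r in reports.items()}, k=config.top_k
        )
        (outdir / "selected_features.txt").write_text("\n".join(selected) + "\n")
        matrix = ml.cross_dataset(bundles, selected, seed=config.seed, **rf_params)
        vio.write_tsv(matrix, outdir / "auc_matrix.tsv", index=True)
        report["ml"] = {
            "cv_auc": {k: r.mean_auc for k, r in reports.items()},
            "n_selected": len(selected),
        }
        if len(bundles) >= 3:
            lodo_auc = ml.lodo(bundles, selected, seed=config.seed, **rf_params)
            vio.write_tsv(lodo_auc.to_frame(), outdir / "lodo.tsv", index=True)
            report["ml"]["lodo"] = lodo_auc.to_dict()
        else:
            report["ml"]["lodo"] = "skipped: needs >= 3 dataset bundles"
        (outdir / "cv_report.json").write_text(
            json.dumps(
                {
                    k: {
                        "mean_auc": r.mean_auc,
                        "fold_aucs": r.fold_aucs.tolist(),
                        "feature_ranking": r.feature_ranking,
                    }
                    for k, r in reports.items()
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    else:
        report["ml"] = {"skipped": "no signatures called"}

    _stage("manifest")
    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report["n_output_files"] = len(manifest)
    return report
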