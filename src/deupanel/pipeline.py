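"""End-to-end orchestration: QC → encoding → outlier consensus → mixtures.

Every stage writes plain delimited text (TSV) or JSON — desk-scale data,
diff-friendly outputs — and the run manifest records configuration, stage
counts, derived seeds and artifact checksums so a run is fully auditable
and reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mixture, outliers, qc, symbols
from ._utils import COUNT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    counts_path: str
    out_dir: str
    annotation_path: str | None = None
    consensus_path: str | None = None
    concentrations: tuple = (40, 80, 150, 300)
    control_ppm: int = 150
    max_total_error: float = 0.55
    min_copies: float = 20.0
    error_combination: str = "quadrature"
    # symbol scheme
    up_strong: float = 1.37
    up_mod: float = 1.17
    stable_low: float = 0.82
    down_mod_low: float = 0.70
    # outlier detection
    epsilon: float | None = 0.13     # None -> select from the k-distance curve
    min_samples: int = 5
    top_k: int = 6
    gap_mode: str = "fixed-k"
    # mixture settings
    k_choices: tuple = (4, 6)
    k_range: tuple = (2, 9)
    n_restarts: int = 5
    mahalanobis_threshold: float = 2.42
    run_loo: bool = True
    # stage toggles
    run_encode: bool = True
    run_outliers: bool = True
    run_mixture: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key in ("concentrations", "k_choices", "k_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_counts(path, expected_ppms=None) -> pd.DataFrame:
    """Read and strictly validate a duplicate-count TSV.

    Rejects malformed rows, unknown concentrations and duplicated
    (gene_id, ppm) pairs, naming the offending line numbers (header = line 1).
    """
    counts = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lines = counts.index + 2  # header occupies line 1
    bad = counts[(counts["rep1"] < 0) | (counts["rep2"] < 0)]
    if not bad.empty:
        raise ValueError(f"{path}: negative counts at lines {list(lines[bad.index])}")
    if expected_ppms is not None:
        unknown = counts[~counts["ppm"].isin(expected_ppms)]
        if not unknown.empty:
            first = unknown.iloc[0]
            raise ValueError(
                f"{path}: unexpected concentration {first['ppm']} ppm at line "
                f"{int(lines[unknown.index[0]])} (expected {sorted(expected_ppms)})"
            )
    dup_mask = counts.duplicated(["gene_id", "ppm"], keep=False)
    if dup_mask.any():
        dup_lines = [int(x) for x in lines[counts.index[dup_mask]]]
        raise ValueError(f"{path}: duplicated (gene_id, ppm) rows at lines {dup_lines}")
    return counts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    config: dict
    stage_counts: dict
    seeds: dict
    artifacts: dict
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages and write every intermediate artifact."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage_counts: dict = {}
    seeds = {"master": config.seed}

    def write_tsv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        artifacts[name] = _sha256(path)

    def write_json(name: str, obj) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
        artifacts[name] = _sha256(path)

    # --- stage: QC filtering -------------------------------------------
    counts = read_counts(config.counts_path, expected_ppms=config.concentrations)
    stage_counts["input_records"] = int(len(counts))
    consensus = None
    if config.consensus_path:
        consensus = {line.strip() for line in Path(config.consensus_path).read_text().splitlines()
                     if line.strip()}
    filter_config = qc.FilterConfig(
        max_total_error=config.max_total_error,
        min_copies=config.min_copies,
        control_ppm=config.control_ppm,
        consensus_genes=consensus,
        error_combination=config.error_combination,
    )
    counts = qc.deduplicate_genes(counts, filter_config)
    qc_table = qc.apply_filters(counts, filter_config)
    profiles = qc.retained_profiles(qc_table, filter_config)
    stage_counts["input_genes"] = int(qc_table["gene_id"].nunique())
    stage_counts["retained"] = int(len(profiles))
    for verdict in (qc.EXCLUDED_ERROR, qc.EXCLUDED_LOWCOUNT, qc.EXCLUDED_NONCONSENSUS):
        stage_counts[verdict] = int((qc_table["verdict"] == verdict).sum())
    logger.info("QC filter: %d/%d genes retained (error > %.2f or control mean < %g excluded)",
                stage_counts["retained"], stage_counts["input_genes"],
                config.max_total_error, config.min_copies)
    write_tsv("qc_report.tsv", qc_table)
    write_tsv("profiles.tsv", profiles)

    census = None
    singletons: list = []
    if config.run_encode and len(profiles):
        scheme = symbols.SymbolScheme(config.up_strong, config.up_mod,
                                      config.stable_low, config.down_mod_low)
        triplets = {
            row["gene_id"]: symbols.encode_triplet(
                (row["r40"], row["r80"], row["r300"]), scheme)
            for _, row in profiles.iterrows()
        }
        census = symbols.census_patterns(triplets, profiles)
        singletons = symbols.find_singletons(census)
        stage_counts["observed_patterns"] = census.n_observed
        stage_counts["singletons"] = len(singletons)
        write_tsv("patterns.tsv", census.table())

    centroid_table = None
    ranking = None
    noise_genes: list = []
    consensus_report = None
    if config.run_outliers and len(profiles):
        annotation = _load_annotation(config.annotation_path, profiles)
        centroid_table = outliers.pathway_centroids(profiles, annotation)
        cent = centroid_table.centroids.reset_index()
        write_tsv("pathway_centroids.tsv", cent)
        ranking = outliers.rank_by_centroid_distance(profiles, centroid_table.global_center)
        write_tsv("centroid_distances.tsv", ranking)
        top_genes, method = outliers.select_top_by_gap(ranking, config.top_k, config.gap_mode)
        stage_counts["centroid_outliers"] = len(top_genes)

        kdist = outliers.kdist_profile(profiles, k=config.min_samples)
        write_tsv("kdist_curve.tsv", pd.DataFrame({"rank": np.arange(1, len(kdist) + 1),
                                                   "kdist": kdist}))
        eps = config.epsilon if config.epsilon is not None else outliers.select_epsilon(kdist)
        seeds["epsilon"] = float(eps)
        labels = outliers.dbscan(profiles, eps=eps, min_samples=config.min_samples)
        dbscan_noise = sorted(labels.index[labels == outliers.NOISE])
        noise_genes = dbscan_noise
        stage_counts["dbscan_noise"] = len(dbscan_noise)
        write_tsv("dbscan_labels.tsv",
                  labels.rename_axis("gene_id").reset_index())

        consensus_report = outliers.consensus_venn(
            top_genes, dbscan_noise, singletons, profiles["gene_id"])
        write_json("venn_regions.json",
                   {"regions": consensus_report.region_genes,
                    "core": sorted(consensus_report.core),
                    "selection_method": method})

    mixture_outputs = {}
    if config.run_mixture and len(profiles):
        clustered = profiles[~profiles["gene_id"].isin(noise_genes)].reset_index(drop=True)
        stage_counts["clustered"] = int(len(clustered))
        X = clustered[["r40", "r80", "r300"]].to_numpy()
        gene_ids = clustered["gene_id"].to_numpy()

        scan = mixture.model_scan(X, k_range=range(config.k_range[0], config.k_range[1] + 1),
                                  seed=config.seed, n_restarts=config.n_restarts)
        write_tsv("model_scan.tsv", scan)

        kmeans_labels = mixture.fit_kmeans(X, k=max(config.k_choices), seed=config.seed)
        stage_counts["kmeans_silhouette"] = float(mixture.silhouette_mean(X, kmeans_labels))

        fitted = {}
        for k in config.k_choices:
            model = mixture.fit_gmm_tied(X, k=k, seed=config.seed,
                                         n_restarts=config.n_restarts)
            fitted[k] = model
            write_json(f"gmm_k{k}.json", {
                "k": k,
                "weights": model.weights_.tolist(),
                "means": model.means_.tolist(),
                "tied_covariance": model.covariance_.tolist(),
                "log_likelihood": model.log_likelihood_,
                "bic": model.bic_,
                "labels": {g: int(l) for g, l in zip(gene_ids, model.labels_)},
                "best_seed": model.best_seed_,
            })
            boundary = mixture.mahalanobis_boundary(
                model, X, gene_ids, threshold=config.mahalanobis_threshold)
            write_tsv(f"boundary_k{k}.tsv", boundary)

        if len(config.k_choices) >= 2:
            k_a, k_b = config.k_choices[:2]
            trans = mixture.transition_table(fitted[k_a].labels_, fitted[k_b].labels_,
                                             name_a=f"GMM{k_a}", name_b=f"GMM{k_b}")
            write_json("sankey.json", trans.sankey)
            if config.run_loo:
                stability = mixture.loo_ari(X, gene_ids, k_a=k_a, k_b=k_b,
                                            seed=config.seed, n_restarts=3)
                write_tsv("loo_stability.tsv", stability.table)
                stage_counts["mean_ari_difference"] = stability.mean_difference
        mixture_outputs = {"fitted_k": list(config.k_choices)}

    if "clustered" in stage_counts and "dbscan_noise" in stage_counts:
        assert stage_counts["clustered"] == stage_counts["retained"] - stage_counts["dbscan_noise"]

    manifest = RunManifest(
        config=config.to_dict(),
        stage_counts=stage_counts,
        seeds=seeds,
        artifacts=artifacts,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "run_manifest.json").write_text(manifest.to_json())
    report = write_report(manifest, out)
    (out / "report.txt").write_text(report)
    return manifest


def _load_annotation(path, profiles: pd.DataFrame) -> pd.Series:
    """Annotation mapping gene -> pathway; genes default to one shared bin."""
    if path is None:
        return pd.Series("all", index=profiles["gene_id"].to_numpy())
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    series = ann.set_index("gene_id")["pathway"]
    missing = profiles.loc[~profiles["gene_id"].isin(series.index), "gene_id"]
    if len(missing):
        raise ValueError(f"genes missing pathway annotation: {list(missing[:5])}")
    return series


def write_report(manifest: RunManifest, out_dir) -> str:
    """Render a deterministic human-readable summary from a saved run.

    Regenerating the report from the same manifest and artifacts yields
    identical text.
    """
    out = Path(out_dir)
    sc = manifest.stage_counts
    lines = ["# Pipeline run summary", ""]
    lines.append(f"Input genes: {sc.get('input_genes', 0)}")
    lines.append(f"Retained after QC: {sc.get('retained', 0)}")
    for key in ("excluded_error", "excluded_lowcount", "excluded_nonconsensus"):
        if key in sc:
            lines.append(f"  {key}: {sc[key]}")
    if "observed_patterns" in sc:
        lines.append(f"Observed trajectory patterns: {sc['observed_patterns']} of 125 theoretical")
        lines.append(f"Singleton patterns: {sc.get('singletons', 0)}")
    if "dbscan_noise" in sc:
        lines.append(f"Density outliers (DBSCAN noise): {sc['dbscan_noise']}")
    if "clustered" in sc:
        lines.append(f"Genes clustered after outlier removal: {sc['clustered']}")
    if "mean_ari_difference" in sc:
        lines.append(f"Mean leave-one-out ARI difference: {sc['mean_ari_difference']:+.4f}")

    cent_path = out / "pathway_centroids.tsv"
    if cent_path.exists():
        lines += ["", "## Pathway centroids (mean ratio profiles)"]
        cent = pd.read_csv(cent_path, sep="\t")
        for _, row in cent.iterrows():
            lines.append(f"  {row['pathway']}: ({row['r40']:.3f}, {row['r80']:.3f}, "
                         f"{row['r300']:.3f})  n={int(row['n_genes'])}")
        dist_path = out / "centroid_distances.tsv"
        if dist_path.exists():
            dist = pd.read_csv(dist_path, sep="\t")
            top = ", ".join(dist["gene_id"].head(6))
            lines.append(f"  Most distant genes from the Global Center: {top}")

    for k in manifest.config.get("k_choices", []):
        model_path = out / f"gmm_k{k}.json"
        if model_path.exists():
            model = json.loads(model_path.read_text())
            lines += ["", f"## Tied-covariance mixture, k={k} "
                          f"(logL={model['log_likelihood']:.1f}, BIC={model['bic']:.1f})"]
            labels = model["labels"]
            for comp in range(k):
                members = sorted(g for g, l in labels.items() if l == comp)
                mean = model["means"][comp]
                lines.append(f"  cluster {comp + 1} (n={len(members)}): centroid "
                             f"({mean[0]:.3f}, {mean[1]:.3f}, {mean[2]:.3f})")
                lines.append(f"    genes: {', '.join(members)}")
    if sc.get("retained", 0) == 0:
        lines.append("No genes retained; clustering skipped.")
    return "\n".join(lines) + "\n"
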