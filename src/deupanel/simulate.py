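"""Synthetic duplicate-count panels with known ground truth.

The generator emulates a NanoString-style panel measured in technical
duplicate at four deuterium concentrations (40, 80, 150, 300 ppm; 150 ppm
control).  Each gene draws

* a module membership (cluster-structured 3-D ratio profile: centroid plus
  isotropic noise) or a planted far-off outlier profile used exactly;
* a log-normal control baseline count;
* a true duplicate CV; the two replicates at each concentration are the
  expected count times (1 ± δ) with δ ~ Uniform(-2·cv, 2·cv), so that
  E|δ| — and hence the expectation of |x1-x2|/(x1+x2) — equals the drawn CV.
  The bounded support caps any single gene's summed propagated error, which
  keeps the planted QC verdicts an exact oracle for the filter.

A configurable number of genes is planted to fail the downstream QC filter,
either by deterministic high dispersion (summed propagated error > 0.55) or
by a low control baseline (< 20 copies).  The truth sidecar (module label,
outlier flag, fail reason, true profile) is written separately and is never
consumed by the analysis pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default module centroids in (r40, r80, r300) ratio space: six coordinated
#: expression programs spanning strong enrichment response (top) to basal
#: stability (bottom).
DEFAULT_CLUSTER_CENTROIDS = (
    (0.906, 0.984, 1.666),
    (0.792, 0.929, 1.565),
    (0.982, 0.975, 1.460),
    (0.820, 0.952, 1.343),
    (0.957, 0.903, 1.264),
    (0.830, 0.897, 1.180),
)

#: Default mixing weights, proportional to the module sizes 17:18:13:17:9:17.
DEFAULT_CLUSTER_WEIGHTS = tuple(w / 91.0 for w in (17, 18, 13, 17, 9, 17))

#: Default planted sentinel-outlier profiles: far-off single-gene
#: trajectories (efflux-pump-like V-shape, receptor suppression,
#: amplifier dip, two strong cytokine inductions).
DEFAULT_OUTLIER_PROFILES = (
    (1.122, 0.585, 1.268),
    (0.81, 0.81, 1.00),
    (1.00, 0.76, 1.01),
    (1.00, 1.00, 1.99),
    (1.00, 1.00, 2.05),
)

@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic panel.

    Defaults mirror the analysed panel: 102 genes, four concentrations with
    150 ppm control, six ratio-space modules, five planted far-off outliers,
    six high-error and two low-count QC failures.
    """

    n_genes: int = 102
    concentrations: tuple = (40, 80, 150, 300)
    control_ppm: int = 150
    cluster_centroids: tuple = DEFAULT_CLUSTER_CENTROIDS
    cluster_weights: tuple = DEFAULT_CLUSTER_WEIGHTS
    ratio_noise_sd: float = 0.08
    outlier_profiles: tuple = DEFAULT_OUTLIER_PROFILES
    baseline_log_mean: float = 6.2   # natural log; exp(6.2) ~ 490 copies
    baseline_log_sd: float = 1.2
    duplicate_cv_range: tuple = (0.005, 0.05)
    n_qc_fail_error: int = 6
    n_qc_fail_lowcount: int = 2
    round_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.control_ppm not in self.concentrations:
            raise ValueError("control_ppm must be one of the concentrations")
        if len(self.cluster_centroids) == 0:
            raise ValueError("at least one cluster centroid required")
        if len(self.cluster_weights) != len(self.cluster_centroids):
            raise ValueError("one weight per centroid required")
        w = np.asarray(self.cluster_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-8 or (w < 0).any():
            raise ValueError("cluster_weights must be a simplex")
        cents = np.asarray(self.cluster_centroids, dtype=float)
        outs = np.asarray(self.outlier_profiles, dtype=float) if self.outlier_profiles else np.empty((0, 3))
        if (cents <= 0).any() or (outs <= 0).any():
            raise ValueError("centroids and outlier profiles must be strictly positive")
        if self.ratio_noise_sd < 0:
            raise ValueError("ratio_noise_sd must be nonnegative")
        lo, hi = self.duplicate_cv_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("duplicate_cv_range must lie within [0, 1)")
        n_special = len(self.outlier_profiles) + self.n_qc_fail_error + self.n_qc_fail_lowcount
        if n_special > self.n_genes:
            raise ValueError("planted outliers and QC failures exceed n_genes")


@dataclass
class SyntheticPanel:
    """Counts table plus the ground-truth sidecar of one generated panel."""

    counts: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def annotation(self) -> pd.DataFrame:
        """Pathway-bin annotation derived from the truth (module_k / sentinel /
        unassigned), with every gene flagged as consensus."""
        pathway = []
        for _, row in self.truth.iterrows():
            if row["is_outlier"]:
                pathway.append("sentinel")
            elif pd.notna(row["cluster_id"]):
                pathway.append(f"module_{int(row['cluster_id'])}")
            else:
                pathway.append("unassigned")
        return pd.DataFrame({
            "gene_id": self.truth["gene_id"],
            "pathway": pathway,
            "is_consensus": True,
        })


def generate_panel(config: GeneratorConfig | None = None) -> SyntheticPanel:
    """Generate a duplicate-count panel with known truth (deterministic per seed)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i + 1:04d}" for i in range(n)]

    # role assignment: outliers, error-fails, lowcount-fails, then clustered
    perm = rng.permutation(n)
    n_out = len(config.outlier_profiles)
    out_idx = perm[:n_out]
    err_idx = perm[n_out:n_out + config.n_qc_fail_error]
    low_idx = perm[n_out + config.n_qc_fail_error:
                   n_out + config.n_qc_fail_error + config.n_qc_fail_lowcount]
    special = set(out_idx) | set(err_idx) | set(low_idx)

    centroids = np.asarray(config.cluster_centroids, dtype=float)
    weights = np.asarray(config.cluster_weights, dtype=float)
    noncontrol = [c for c in config.concentrations if c != config.control_ppm]

    cluster_id = np.full(n, -1)
    is_outlier = np.zeros(n, dtype=bool)
    fail_reason = np.array([""] * n, dtype=object)
    profiles = np.ones((n, len(noncontrol)))
    baselines = np.empty(n)
    cvs = rng.uniform(*config.duplicate_cv_range, size=n)

    for i in range(n):
        baseline = float(np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd)))
        if i in special:
            if i in set(out_idx):
                is_outlier[i] = True
                profiles[i] = config.outlier_profiles[int(np.flatnonzero(out_idx == i)[0])]
                baseline = max(baseline, 40.0)
            elif i in set(err_idx):
                fail_reason[i] = "error"
                cluster = rng.choice(len(centroids), p=weights)
                cluster_id[i] = cluster + 1
                profiles[i] = _noisy_profile(centroids[cluster], config, rng)
                baseline = max(baseline, 100.0)
            else:
                fail_reason[i] = "lowcount"
                cluster = rng.choice(len(centroids), p=weights)
                cluster_id[i] = cluster + 1
                profiles[i] = _noisy_profile(centroids[cluster], config, rng)
                baseline = float(rng.uniform(5.0, 15.0))
        else:
            cluster = rng.choice(len(centroids), p=weights)
            cluster_id[i] = cluster + 1
            profiles[i] = _noisy_profile(centroids[cluster], config, rng)
            baseline = max(baseline, 40.0)
        baselines[i] = baseline

    ratio_at = {c: profiles[:, j] for j, c in enumerate(noncontrol)}
    ratio_at[config.control_ppm] = np.ones(n)

    rows = []
    for i in range(n):
        for c in config.concentrations:
            expected = baselines[i] * ratio_at[c][i]
            if fail_reason[i] == "error":
                delta = 0.35  # deterministic dispersion: guaranteed filter failure
            else:
                delta = rng.uniform(-2.0 * cvs[i], 2.0 * cvs[i])  # E|delta| = cv
            rep1 = expected * (1.0 + delta)
            rep2 = expected * (1.0 - delta)
            if config.round_counts:
                rep1, rep2 = round(rep1), round(rep2)
            rows.append({
                "gene_id": gene_ids[i], "ppm": c,
                "rep1": max(rep1, 0), "rep2": max(rep2, 0),
            })

    counts = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "cluster_id": pd.array([c if c > 0 else pd.NA for c in cluster_id], dtype="Int64"),
        "is_outlier": is_outlier,
        "qc_fail_reason": fail_reason,
        **{f"true_r{c}": ratio_at[c] for c in noncontrol},
    })
    return SyntheticPanel(counts=counts, truth=truth, config=config)


def _noisy_profile(centroid, config, rng):
    prof = centroid + rng.normal(0.0, config.ratio_noise_sd, size=centroid.shape)
    return np.clip(prof, 0.05, None)  # ratios stay strictly positive


def write_panel(panel: SyntheticPanel, directory) -> dict:
    """Write counts, truth sidecar and derived annotation as TSV files.

    Returns the written paths.  The counts table round-trips losslessly
    through :func:`deupanel.pipeline.read_counts`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "truth": directory / "truth.tsv",
        "annotation": directory / "annotation.tsv",
    }
    panel.counts.to_csv(paths["counts"], sep="\t", index=False)
    panel.truth.to_csv(paths["truth"], sep="\t", index=False)
    panel.annotation().to_csv(paths["annotation"], sep="\t", index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    """Read a truth sidecar written by :func:`write_panel`."""
    truth = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    truth["cluster_id"] = truth["cluster_id"].astype("Int64")
    truth["qc_fail_reason"] = truth["qc_fail_reason"].fillna("")
    return truth
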