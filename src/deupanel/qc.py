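"""Duplicate-based quality control for dose-graded expression panels.

Each gene is measured in technical duplicate at every deuterium concentration
(40, 80, 150 and 300 ppm, with 150 ppm the physiological control).  Replicate
disagreement is summarised by the dimensionless statistic

    CV = |x1 - x2| / (x1 + x2),

the relative error of each control-normalised expression ratio is obtained by
propagating the CVs of its numerator and denominator concentrations, and the
three per-ratio errors (40, 80, 300 ppm) are summed into a per-gene total.
Genes whose total exceeds ``max_total_error`` (default 0.55) or whose mean
control count falls below ``min_copies`` (default 20) are excluded; an
optional consensus-gene list restricts the retained set further.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import check_counts_table

logger = logging.getLogger(__name__)

RETAINED = "retained"
EXCLUDED_ERROR = "excluded_error"
EXCLUDED_LOWCOUNT = "excluded_lowcount"
EXCLUDED_NONCONSENSUS = "excluded_nonconsensus"

RATIO_COLUMNS = ("r40", "r80", "r300")


@dataclass
class FilterConfig:
    """Thresholds and options of the multi-step duplicate filter.

    Parameters
    ----------
    max_total_error : float
        Upper bound on the summed per-ratio relative error (strict: a gene is
        excluded only when its total error exceeds this value).
    min_copies : float
        Minimum mean control count (strict: excluded only when below).
    control_ppm : int
        Concentration used as the normalisation control.
    consensus_genes : set of str, optional
        When given, genes passing the numeric filters but absent from this
        list are marked ``excluded_nonconsensus``.
    error_combination : {"quadrature", "linear_sum"}
        How the two CVs entering a ratio are combined.  Quadrature
        (root-sum-square) is the standard propagation for a quotient of
        independent measurements and is the default; ``linear_sum`` is the
        conservative alternative.
    """

    max_total_error: float = 0.55
    min_copies: float = 20.0
    control_ppm: int = 150
    consensus_genes: set | None = None
    error_combination: str = "quadrature"

    def __post_init__(self) -> None:
        if self.max_total_error <= 0:
            raise ValueError("max_total_error must be positive")
        if self.min_copies < 0:
            raise ValueError("min_copies must be nonnegative")
        if self.error_combination not in ("quadrature", "linear_sum"):
            raise ValueError(f"unknown error_combination {self.error_combination!r}")


def compute_cv(rep1, rep2):
    """Duplicate dispersion |rep1 - rep2| / (rep1 + rep2), in [0, 1].

    Accepts scalars or arrays; raises if any replicate pair sums to zero.
    The statistic is taken as an absolute value: it measures dispersion, so
    it must be nonnegative and symmetric in its arguments.
    """
    r1 = np.asarray(rep1, dtype=float)
    r2 = np.asarray(rep2, dtype=float)
    total = r1 + r2
    if np.any(total <= 0):
        raise ValueError("CV undefined: replicate pair sums to zero")
    cv = np.abs(r1 - r2) / total
    return cv if cv.ndim else float(cv)


def compute_ratio(gene_counts: pd.DataFrame, ppm: int, control_ppm: int = 150) -> float:
    """Mean duplicate count at ``ppm`` divided by the mean at the control.

    ``gene_counts`` holds the rows of a single gene.  Ratios are formed from
    duplicate means (not per-replicate ratios), matching the panel's
    "average copy number" convention.
    """
    means = {}
    for c in (ppm, control_ppm):
        rows = gene_counts[gene_counts["ppm"] == c]
        if rows.empty:
            raise ValueError(f"gene has no row at {c} ppm")
        means[c] = float(rows[["rep1", "rep2"]].to_numpy().mean())
    if means[control_ppm] <= 0:
        raise ValueError("zero control mean: ratio undefined")
    return means[ppm] / means[control_ppm]


def propagate_ratio_error(cv_ppm, cv_control, combination: str = "quadrature"):
    """Relative error of a ratio from the CVs of numerator and denominator.

    Quadrature (default) combines independent errors as
    sqrt(cv_ppm**2 + cv_control**2); ``linear_sum`` adds them.
    """
    c1 = np.asarray(cv_ppm, dtype=float)
    c2 = np.asarray(cv_control, dtype=float)
    if np.any((c1 < 0) | (c1 > 1)) or np.any((c2 < 0) | (c2 > 1)):
        raise ValueError("CVs must lie in [0, 1]")
    if combination == "quadrature":
        err = np.sqrt(c1**2 + c2**2)
    elif combination == "linear_sum":
        err = c1 + c2
    else:
        raise ValueError(f"unknown combination {combination!r}")
    return err if err.ndim else float(err)


def total_error(ratio_errors) -> float:
    """Arithmetic sum of the per-ratio relative errors (one per non-control ppm)."""
    errs = np.asarray(list(ratio_errors), dtype=float)
    if not np.all(np.isfinite(errs)):
        raise ValueError("non-finite ratio error")
    return float(errs.sum())


def _records(counts: pd.DataFrame) -> pd.DataFrame:
    """Split a raw table into measurement records.

    Symbols measured more than once appear as repeated (gene_id, ppm) rows;
    occurrence order pairs rows into records unless a ``record_id`` column is
    already present.
    """
    counts = counts.copy()
    if "record_id" not in counts.columns:
        counts["record_id"] = counts.groupby(["gene_id", "ppm"]).cumcount()
    return counts


def deduplicate_genes(counts: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Resolve symbols measured more than once, keeping the lower-error record.

    Ties keep the first record in file order; every dropped record is logged.
    """
    config = config or FilterConfig()
    counts = _records(check_counts_table(counts))
    if counts["record_id"].eq(0).all():
        return counts.drop(columns="record_id")

    keep = []
    for gene, grp in counts.groupby("gene_id", sort=False):
        record_ids = sorted(grp["record_id"].unique())
        if len(record_ids) == 1:
            keep.append(grp)
            continue
        errors = {}
        for rid in record_ids:
            rec = grp[grp["record_id"] == rid]
            qc = _qc_one(rec, config)
            errors[rid] = qc["total_error"]
        best = min(record_ids, key=lambda r: (errors[r], r))
        for rid in record_ids:
            if rid != best:
                logger.info(
                    "dropping duplicate record %d of gene %s (total error %.4f >= %.4f)",
                    rid, gene, errors[rid], errors[best],
                )
        keep.append(grp[grp["record_id"] == best])
    return pd.concat(keep, ignore_index=True).drop(columns="record_id")


def _qc_one(gene_counts: pd.DataFrame, config: FilterConfig) -> dict:
    """CVs, ratios, propagated errors and total error for one gene record."""
    ppms = sorted(gene_counts["ppm"].unique())
    if config.control_ppm not in ppms:
        raise ValueError("gene missing control concentration")
    cv = {}
    mean = {}
    for c in ppms:
        row = gene_counts[gene_counts["ppm"] == c].iloc[0]
        cv[c] = compute_cv(row["rep1"], row["rep2"])
        mean[c] = (row["rep1"] + row["rep2"]) / 2.0
    out = {"cv_by_ppm": cv, "mean_by_ppm": mean}
    noncontrol = [c for c in ppms if c != config.control_ppm]
    ratios = {}
    errors = {}
    for c in noncontrol:
        ratios[c] = compute_ratio(gene_counts, c, config.control_ppm)
        errors[c] = propagate_ratio_error(cv[c], cv[config.control_ppm], config.error_combination)
    out["ratio_by_ppm"] = ratios
    out["ratio_error_by_ppm"] = errors
    out["total_error"] = total_error(errors.values())
    return out


def apply_filters(counts: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Run the full multi-step filter and give every gene a verdict.

    Returns one row per gene: per-ppm CV and mean, the control-normalised
    ratio profile, per-ratio propagated errors, the total error and a verdict
    in {retained, excluded_error, excluded_lowcount, excluded_nonconsensus}.
    Exclusion reasons are prioritised lowcount > error > nonconsensus, so a
    low-abundance gene is reported as such even when its error also fails.
    """
    config = config or FilterConfig()
    counts = check_counts_table(counts)
    if counts.duplicated(["gene_id", "ppm"]).any():
        raise ValueError("duplicated (gene_id, ppm) rows; run deduplicate_genes first")

    rows = []
    for gene, grp in counts.groupby("gene_id", sort=False):
        qc = _qc_one(grp, config)
        control_mean = qc["mean_by_ppm"][config.control_ppm]
        if control_mean < config.min_copies:
            verdict = EXCLUDED_LOWCOUNT
        elif qc["total_error"] > config.max_total_error:
            verdict = EXCLUDED_ERROR
        elif config.consensus_genes is not None and gene not in config.consensus_genes:
            verdict = EXCLUDED_NONCONSENSUS
        else:
            verdict = RETAINED
        row = {"gene_id": gene}
        for c, v in qc["cv_by_ppm"].items():
            row[f"cv_{c}"] = v
        for c, v in qc["mean_by_ppm"].items():
            row[f"mean_{c}"] = v
        for c, v in qc["ratio_by_ppm"].items():
            row[f"r{c}"] = v
        for c, v in qc["ratio_error_by_ppm"].items():
            row[f"err_{c}"] = v
        row["total_error"] = qc["total_error"]
        row["verdict"] = verdict
        rows.append(row)
    return pd.DataFrame(rows)


def retained_profiles(qc_table: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Ratio profiles (gene_id, r40, r80, r300) of the retained genes."""
    config = config or FilterConfig()
    kept = qc_table[qc_table["verdict"] == RETAINED]
    cols = ["gene_id"] + [c for c in kept.columns if c.startswith("r") and c[1:].isdigit()]
    return kept[cols].reset_index(drop=True)


class DuplicateQCFilter(TransformerMixin, BaseEstimator):
    """Transformer wrapping the duplicate-error filter.

    ``fit`` computes the QC table from a duplicate-count DataFrame;
    ``transform`` returns the retained ratio profiles.  Fitted attributes:

    - ``qc_table_`` : per-gene CVs, ratios, errors and verdicts
    - ``profiles_`` : retained ratio-profile DataFrame
    """

    def __init__(self, max_total_error: float = 0.55, min_copies: float = 20.0,
                 control_ppm: int = 150, consensus_genes=None,
                 error_combination: str = "quadrature"):
        self.max_total_error = max_total_error
        self.min_copies = min_copies
        self.control_ppm = control_ppm
        self.consensus_genes = consensus_genes
        self.error_combination = error_combination

    def _config(self) -> FilterConfig:
        consensus = set(self.consensus_genes) if self.consensus_genes is not None else None
        return FilterConfig(
            max_total_error=self.max_total_error,
            min_copies=self.min_copies,
            control_ppm=self.control_ppm,
            consensus_genes=consensus,
            error_combination=self.error_combination,
        )

    def fit(self, X: pd.DataFrame, y=None):
        config = self._config()
        counts = deduplicate_genes(X, config)
        self.qc_table_ = apply_filters(counts, config)
        self.profiles_ = retained_profiles(self.qc_table_, config)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        return self.profiles_
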