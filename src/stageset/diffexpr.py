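"""Replicate-concordance differential expression and detection calls.

Two detection layers, mirroring the classic probe-set array workflow:

1. Present/Absent calls — per (gene, sample), a one-sided signed-rank test
   of the gene's probe intensities against a background level (computed on
   the log2 scale, where multiplicative noise is symmetric).

2. Change calls — every experimental replicate is compared with every
   reference replicate (3 x 3 = 9 pairwise comparisons); each comparison is
   a two-sided signed-rank test on the matched per-probe log-ratios.  A gene
   is selected when at least ``ceil(concordance_cutoff * n_pairs)`` of the
   pairwise calls agree in direction (default 0.77: at least 7 of 9) AND the
   fold change of condition-mean signals passes the two-fold filter.  The
   Fisher-combined p over the pairwise tests is reported as a ranking aid
   but never used for selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import ExpressionMatrix, GeneSetCollection
from .stats import signed_rank_pvalues, signed_rank_test, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "DEConfig",
    "summarize_signal",
    "detection_call",
    "pairwise_change_calls",
    "concordance_select",
    "required_concordant_count",
    "marker_panel",
]

_LOG_FLOOR = 1.0  # intensity floor before log-ratios; arrays do not go below ~1


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the two detection layers.

    detection_alpha, change_alpha: per-test significance levels (0.05).
    concordance_cutoff: fraction of pairwise comparisons that must agree
        (0.77, i.e. at least 7 of 9 with triplicates).
    fc_threshold: fold-change filter on condition means (2.0).
    signal_summary: probe -> gene summarizer, "median" or "trimmed_mean".
    min_present: optional floor on Present calls in the experimental
        condition for a gene to be selectable (0 = off).
    paired: matched-probe signed-rank (default) or unmatched rank-sum.
    """

    detection_alpha: float = 0.05
    change_alpha: float = 0.05
    concordance_cutoff: float = 0.77
    fc_threshold: float = 2.0
    signal_summary: str = "median"
    min_present: int = 0
    paired: bool = True

    def __post_init__(self) -> None:
        for name in ("detection_alpha", "change_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.concordance_cutoff <= 1.0:
            raise ValueError("concordance_cutoff must lie in (0, 1]")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if self.signal_summary not in ("median", "trimmed_mean"):
            raise ValueError(f"unknown signal_summary {self.signal_summary!r}")


def required_concordant_count(n_pairs: int, cutoff: float) -> int:
    """Smallest c with c / n_pairs >= cutoff (ceiling semantics)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    c = math.ceil(cutoff * n_pairs - 1e-9)
    return max(c, 1)


def _probe_blocks(matrix: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    """Gene ids and a (n_genes, n_probes, n_samples) probe-value cube.

    Requires a constant probe count per gene (the generator's layout);
    ragged matrices are handled gene by gene in a slow path by callers.
    """
    genes = matrix.gene_ids
    ids = matrix.feature_ids.astype(str)
    counts = pd.Series(ids).value_counts()
    if counts.nunique() != 1:
        raise ValueError("probe cube requires a constant probe count per gene")
    p = int(counts.iloc[0])
    order = pd.Series(np.arange(ids.size)).groupby(ids, sort=False).apply(list)
    rows = np.concatenate([order[g] for g in genes])
    cube = matrix.values[rows].reshape(len(genes), p, -1)
    return genes, cube


def summarize_signal(matrix: ExpressionMatrix, method: str = "median") -> pd.DataFrame:
    """Collapse probes to one signal per (gene, sample).

    Median (default) or 10%-trimmed mean of the probe intensities; a
    gene-level matrix passes through unchanged.  Returns a frame indexed by
    gene with one column per sample.
    """
    cols = list(matrix.samples.sample_ids)
    if not matrix.is_probe_level:
        return pd.DataFrame(matrix.values, index=matrix.feature_ids.astype(str), columns=cols)
    if method == "median":
        agg = lambda a: np.median(a, axis=1)  # noqa: E731
    elif method == "trimmed_mean":
        agg = lambda a: _sps.trim_mean(a, 0.1, axis=1)  # noqa: E731
    else:
        raise ValueError(f"unknown signal summary method {method!r}")
    genes, cube = _probe_blocks(matrix)
    return pd.DataFrame(agg(cube), index=genes, columns=cols)


def detection_call(
    matrix: ExpressionMatrix, background: float, cfg: DEConfig | None = None
) -> pd.DataFrame:
    """Present/Absent call per (gene, sample).

    One-sided signed-rank test of log2 probe intensities against the log2
    background; Present iff p < detection_alpha.  Genes with fewer than 3
    probes are conservatively Absent with p = 1 (warned).
    """
    cfg = cfg or DEConfig()
    if background < 0:
        raise ValueError("background must be >= 0")
    if not matrix.is_probe_level:
        raise ValueError("detection calls need a probe-level matrix")
    bg = np.log2(max(background, _LOG_FLOOR))
    genes, cube = _probe_blocks(matrix)
    n_genes, n_probes, n_samples = cube.shape
    logv = np.log2(np.maximum(cube, _LOG_FLOOR))
    if n_probes < 3:
        logger.warning("fewer than 3 probes per gene: all calls Absent, p = 1")
        pvals = np.ones((n_genes, n_samples))
    else:
        diffs = (logv - bg).transpose(0, 2, 1).reshape(n_genes * n_samples, n_probes)
        pvals = signed_rank_pvalues(diffs, alternative="greater").reshape(
            n_genes, n_samples
        )
    sample_ids = list(matrix.samples.sample_ids)
    return pd.DataFrame(
        {
            "feature_id": np.repeat(genes, n_samples),
            "sample_id": np.tile(sample_ids, n_genes),
            "detection_p": pvals.ravel(),
            "status": np.where(pvals.ravel() < cfg.detection_alpha, "Present", "Absent"),
        }
    )


def pairwise_change_calls(
    matrix: ExpressionMatrix,
    cond_exp: str,
    cond_ref: str,
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """All replicate-pairwise change calls for one ordered comparison.

    Every experimental replicate is tested against every reference
    replicate (n_exp x n_ref calls per gene).  Per pair: a two-sided
    signed-rank test on matched per-probe log2 ratios; direction is the
    sign of the median log-ratio when p < change_alpha, else NoChange.
    """
    cfg = cfg or DEConfig()
    if not matrix.is_probe_level:
        raise ValueError("change calls need a probe-level matrix")
    sheet = matrix.samples
    exp_samples = sheet.samples_of(cond_exp)
    ref_samples = sheet.samples_of(cond_ref)
    genes, cube = _probe_blocks(matrix)
    logv = np.log2(np.maximum(cube, _LOG_FLOOR))
    col = {s: i for i, s in enumerate(sheet.sample_ids)}
    frames = []
    for se in exp_samples:
        for sr in ref_samples:
            d = logv[:, :, col[se]] - logv[:, :, col[sr]]
            if cfg.paired:
                pv = signed_rank_pvalues(d, alternative="two-sided")
            else:
                pv = np.array(
                    [
                        rank_sum_test(logv[g, :, col[se]], logv[g, :, col[sr]])
                        for g in range(len(genes))
                    ]
                )
            med = np.median(d, axis=1)
            direction = np.where(
                pv < cfg.change_alpha,
                np.where(med > 0, "Increase", np.where(med < 0, "Decrease", "NoChange")),
                "NoChange",
            )
            frames.append(
                pd.DataFrame(
                    {
                        "feature_id": genes,
                        "exp_sample": se,
                        "ref_sample": sr,
                        "direction": direction,
                        "change_p": pv,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def concordance_select(
    calls: pd.DataFrame,
    signals: pd.DataFrame,
    cond_exp: str,
    cond_ref: str,
    sheet,
    cfg: DEConfig | None = None,
    detections: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate pairwise calls into per-gene concordance records.

    concordance = max(n_increase, n_decrease) / n_pairs.  A gene is
    selected when the majority direction reaches the required concordant
    count and the fold change of condition-mean gene signals passes the
    threshold in the matching direction.  combined_p is Fisher's
    combination of the pairwise p-values (reported only).
    """
    cfg = cfg or DEConfig()
    if calls.empty:
        raise ValueError("no pairwise calls supplied (n_pairs = 0)")
    exp_samples = sheet.samples_of(cond_exp)
    ref_samples = sheet.samples_of(cond_ref)
    mean_exp = signals[exp_samples].mean(axis=1)
    mean_ref = signals[ref_samples].mean(axis=1)
    fold = np.maximum(mean_exp, 1e-9) / np.maximum(mean_ref, _LOG_FLOOR)

    grouped = calls.groupby("feature_id", sort=False)
    n_pairs = grouped.size()
    n_inc = grouped["direction"].apply(lambda s: int((s == "Increase").sum()))
    n_dec = grouped["direction"].apply(lambda s: int((s == "Decrease").sum()))
    combined = grouped["change_p"].apply(
        lambda p: float(_sps.combine_pvalues(np.clip(p, 1e-300, 1.0), method="fisher")[1])
    )

    present_ok = None
    if cfg.min_present > 0 and detections is not None:
        det = detections[detections["sample_id"].isin(exp_samples)]
        n_present = (
            det.assign(is_p=det["status"] == "Present")
            .groupby("feature_id")["is_p"]
            .sum()
        )
        present_ok = n_present >= cfg.min_present

    records = []
    for gene in n_pairs.index:
        n = int(n_pairs[gene])
        inc, dec = int(n_inc[gene]), int(n_dec[gene])
        required = required_concordant_count(n, cfg.concordance_cutoff)
        fc = float(fold[gene])
        conc = max(inc, dec) / n
        direction = "None"
        selected = False
        if inc >= required and inc >= dec and fc >= cfg.fc_threshold:
            direction, selected = "Up", True
        elif dec >= required and dec > inc and fc <= 1.0 / cfg.fc_threshold:
            direction, selected = "Down", True
        if selected and present_ok is not None and not bool(present_ok.get(gene, False)):
            selected, direction = False, "None"
        records.append(
            {
                "feature_id": gene,
                "n_pairs": n,
                "n_increase": inc,
                "n_decrease": dec,
                "n_nochange": n - inc - dec,
                "concordance": conc,
                "combined_p": float(combined[gene]),
                "fold_change": fc,
                "direction": direction,
                "selected": selected,
            }
        )
    return pd.DataFrame.from_records(records)


def differential_expression(
    matrix: ExpressionMatrix,
    cond_exp: str,
    cond_ref: str,
    cfg: DEConfig | None = None,
    signals: pd.DataFrame | None = None,
    detections: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: pairwise calls + concordance selection."""
    cfg = cfg or DEConfig()
    if signals is None:
        signals = summarize_signal(matrix, cfg.signal_summary)
    calls = pairwise_change_calls(matrix, cond_exp, cond_ref, cfg)
    return concordance_select(
        calls, signals, cond_exp, cond_ref, matrix.samples, cfg, detections
    )


def marker_panel(
    records: pd.DataFrame,
    detections: pd.DataFrame,
    markers: GeneSetCollection,
    sheet,
    cond_exp: str,
    cond_ref: str,
) -> pd.DataFrame:
    """Marker report: change status plus Present counts per condition.

    Markers missing from the concordance table are listed with status
    ``not represented`` rather than raising.
    """
    rec = records.set_index("feature_id")
    det = detections.copy()
    cond_of = dict(zip(sheet.sample_ids, sheet.conditions))
    det["condition"] = det["sample_id"].map(cond_of)
    present = (
        det[det["status"] == "Present"]
        .groupby(["feature_id", "condition"])
        .size()
        .unstack(fill_value=0)
    )
    rows = []
    for set_name in markers.names():
        for marker in sorted(markers[set_name]):
            if marker not in rec.index:
                rows.append(
                    {
                        "set_name": set_name,
                        "feature_id": marker,
                        "status": "not represented",
                        "fold_change": np.nan,
                        f"present_{cond_exp}": 0,
                        f"present_{cond_ref}": 0,
                    }
                )
                continue
            r = rec.loc[marker]
            status = {"Up": "Up", "Down": "Down"}.get(str(r["direction"]), "Unchanged")
            if not bool(r["selected"]):
                status = "Unchanged"
            pe = int(present.get(cond_exp, pd.Series(dtype=int)).get(marker, 0))
            pr = int(present.get(cond_ref, pd.Series(dtype=int)).get(marker, 0))
            rows.append(
                {
                    "set_name": set_name,
                    "feature_id": marker,
                    "status": status,
                    "fold_change": float(r["fold_change"]),
                    f"present_{cond_exp}": pe,
                    f"present_{cond_ref}": pr,
                }
            )
    return pd.DataFrame.from_records(rows)
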