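"""Stroma and proliferation signatures and geometric-mean scores.

Responding tumors under PD-1 blockade show two coordinated transcriptional
shifts: up-regulation of cancer-associated-fibroblast (CAF) markers (stroma
remodeling) and down-regulation of cell-division programs (G2M checkpoint
and E2F targets).  This module derives both signatures from a differential
expression table, scores samples by the geometric mean of cohort-mean-
normalized expression, and classifies response from the combination of the
two scores.

Scores are computed on FPKM (or normalized counts) after dividing each gene
by its mean over the cohort being scored, so the stroma and proliferation
scores are dimensionless and center on 1 for an average sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix

#: FPKM pseudocount applied before mean-normalization (below meaningful expression)
EPSILON = 0.01

__all__ = [
    "Signature",
    "mean_normalize",
    "derive_stroma_signature",
    "derive_proliferation_signature",
    "geometric_mean_score",
    "combination_classify",
    "write_signature",
]


@dataclass
class Signature:
    """A named gene set with its direction of regulation in responders."""

    name: str
    gene_ids: list[str]
    direction: str  # "up_in_responders" | "down_in_responders"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature genes must be unique")
        if self.direction not in ("up_in_responders", "down_in_responders"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)


def mean_normalize(
    matrix: ExpressionMatrix, cohort_samples: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Normalize each gene to its mean expression over the cohort.

    normalized[g, s] = (x[g, s] + eps) / mean_over_cohort(x[g, .] + eps)
    with eps = 0.01.  The per-gene cohort mean is computed over
    ``cohort_samples`` only (default: all samples), but every sample in the
    matrix is normalized.  By construction the cohort-mean of each gene's
    normalized values is exactly 1.
    """
    if cohort_samples is None:
        cohort_samples = matrix.sample_ids
    cohort_samples = list(cohort_samples)
    if not cohort_samples:
        raise ValueError("cohort must contain at least one sample")
    missing = [s for s in cohort_samples if s not in matrix.data.columns]
    if missing:
        raise ValueError(f"cohort samples absent from matrix: {missing}")
    shifted = matrix.data + EPSILON
    means = shifted[cohort_samples].mean(axis=1)
    return ExpressionMatrix(shifted.div(means, axis=0), "normalized")


def derive_stroma_signature(
    de: pd.DataFrame,
    caf_markers: Iterable[str],
    k: int = 10,
    alpha: float = 0.05,
) -> Signature:
    """Top-``k`` CAF markers significantly up-regulated in responders.

    Candidates are markers with log2fc > 0 and unadjusted p < ``alpha``,
    ranked by p ascending, ties broken by |log2fc| descending, then by gene
    id.  Fewer than ``k`` candidates yields a shorter signature with a
    warning; zero candidates is an error.
    """
    caf_markers = list(dict.fromkeys(caf_markers))
    if not caf_markers:
        raise ValueError("CAF marker set is empty")
    present = [g for g in caf_markers if g in de.index]
    sub = de.loc[present]
    cand = sub[(sub["log2fc"] > 0) & (sub["p_value"] < alpha)]
    if cand.empty:
        raise ValueError(
            "no CAF marker is significantly up-regulated in responders"
        )
    # p ascending, then |log2fc| descending, then gene id (lexsort: last key
    # is primary)
    order = np.lexsort(
        (
            cand.index.to_numpy(),
            -cand["log2fc"].abs().to_numpy(),
            cand["p_value"].to_numpy(),
        )
    )
    ranked = cand.iloc[order]
    genes = list(ranked.index[:k])
    if len(genes) < k:
        warnings.warn(
            f"only {len(genes)} qualifying CAF markers (requested {k})",
            stacklevel=2,
        )
    return Signature(
        name="stroma",
        gene_ids=genes,
        direction="up_in_responders",
        provenance={
            "k": k,
            "alpha": alpha,
            "p_values": de.loc[genes, "p_value"].to_dict(),
            "log2fc": de.loc[genes, "log2fc"].to_dict(),
        },
    )


def derive_proliferation_signature(
    de: pd.DataFrame,
    g2m: Iterable[str],
    e2f: Iterable[str],
    min_abs_log2fc: float = 1.0,
) -> Signature:
    """Cell-division genes down-regulated in responders.

    Unique genes from the merged G2M-checkpoint and E2F-targets sets with
    log2fc <= -``min_abs_log2fc`` (inclusive threshold on |log2fc|).
    """
    merged = list(dict.fromkeys([*g2m, *e2f]))
    if not merged:
        raise ValueError("G2M and E2F sets are both empty")
    present = [g for g in merged if g in de.index]
    sub = de.loc[present]
    genes = list(sub.index[sub["log2fc"] <= -min_abs_log2fc])
    if not genes:
        raise ValueError(
            "no cell-cycle gene is down-regulated past the fold-change threshold"
        )
    return Signature(
        name="proliferation",
        gene_ids=genes,
        direction="down_in_responders",
        provenance={
            "min_abs_log2fc": min_abs_log2fc,
            "p_values": de.loc[genes, "p_value"].to_dict(),
            "log2fc": de.loc[genes, "log2fc"].to_dict(),
        },
    )


def geometric_mean_score(
    normalized: ExpressionMatrix, signature: Signature
) -> pd.Series:
    """Per-sample geometric mean of the signature genes' normalized values."""
    if normalized.value_kind != "normalized":
        raise ValueError("scores are computed on mean-normalized expression")
    missing = [g for g in signature.gene_ids if g not in normalized.data.index]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    sub = normalized.data.loc[signature.gene_ids]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("normalized values must be strictly positive")
    scores = np.exp(np.log(sub).mean(axis=0))
    scores.name = f"{signature.name}_score"
    return scores


def _confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    return tp, fn, tn, fp


def fit_combination_threshold(
    combination_scores: Sequence[float], responder: Sequence[bool]
) -> float:
    """Threshold on the combination score maximizing Youden's J.

    Candidate cuts are the midpoints between adjacent distinct scores plus
    the extremes (predict responder iff score >= threshold), so a fully
    separable training set yields the center of the margin; ties in J
    resolve to the smaller threshold.
    """
    s = np.asarray(combination_scores, dtype=float)
    y = np.asarray(responder, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training labels must contain both classes")
    uniq = np.unique(s)
    candidates = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]])
    )
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = s >= t
        tp, fn, tn, fp = _confusion(pred, y)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def combination_classify(
    scores: pd.DataFrame,
    training_labels: pd.Series | dict | None = None,
    threshold: float | None = None,
    method: str = "log_ratio",
    two_threshold: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Classify response from the stroma and proliferation scores jointly.

    The default rule reduces the 2-D score plane to a single axis,
    combination_score = ln(stroma) - ln(proliferation), which is high for
    responders (high stroma, low proliferation); a sample is called a
    responder iff its combination score is >= the threshold.  The threshold
    is either given or fitted on ``training_labels`` (sample id -> bool or
    responder/non-responder label) by maximizing Youden's J.

    ``method="two_threshold"`` instead applies independent cutoffs:
    responder iff stroma >= t1 and proliferation <= t2, with
    ``two_threshold=(t1, t2)``.

    Returns a copy of ``scores`` with ``combination_score`` and
    ``predicted_label`` ("responder"/"non-responder") columns, plus the
    fitted threshold in ``.attrs["threshold"]``.
    """
    out = scores.copy()
    out["combination_score"] = np.log(out["stroma_score"]) - np.log(
        out["proliferation_score"]
    )
    if method == "two_threshold":
        if two_threshold is None:
            raise ValueError("two_threshold=(t1, t2) required for this method")
        t1, t2 = two_threshold
        pred = (out["stroma_score"] >= t1) & (out["proliferation_score"] <= t2)
        out["predicted_label"] = np.where(pred, "responder", "non-responder")
        return out
    if method != "log_ratio":
        raise ValueError(f"unknown method {method!r}")
    if threshold is None:
        if training_labels is None:
            raise ValueError("supply either a threshold or training labels")
        labels = pd.Series(training_labels)
        truth = _as_bool_labels(labels.loc[out.index])
        threshold = fit_combination_threshold(
            out["combination_score"].to_numpy(), truth
        )
    pred = out["combination_score"] >= threshold
    out["predicted_label"] = np.where(pred, "responder", "non-responder")
    out.attrs["threshold"] = float(threshold)
    return out


_RESPONDER_LABELS = {"DR", "pCR", "DC", "responder", "R", "True", "1"}
_NONRESPONDER_LABELS = {"NR", "PD", "SR", "non-responder", "N", "False", "0"}


def _as_bool_labels(labels: pd.Series) -> np.ndarray:
    if labels.dtype == bool:
        return labels.to_numpy()
    out = np.empty(len(labels), dtype=bool)
    for i, v in enumerate(labels):
        s = str(v)
        if s in _RESPONDER_LABELS:
            out[i] = True
        elif s in _NONRESPONDER_LABELS:
            out[i] = False
        else:
            raise ValueError(f"unrecognized response label {v!r}")
    return out


def write_signature(signature: Signature, gmt_path, provenance_path=None) -> None:
    """Write a signature as GMT plus an optional provenance side-car TSV."""
    from .cohort_io import write_gmt

    write_gmt(
        {signature.name: signature.gene_ids},
        gmt_path,
        descriptions={signature.name: signature.direction},
    )
    if provenance_path is not None:
        rows = []
        prov_p = signature.provenance.get("p_values", {})
        prov_l = signature.provenance.get("log2fc", {})
        for g in signature.gene_ids:
            rows.append(
                {"gene_id": g, "log2fc": prov_l.get(g), "p_value": prov_p.get(g)}
            )
        pd.DataFrame(rows).to_csv(provenance_path, sep="\t", index=False)
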