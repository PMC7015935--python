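"""End-to-end discovery workflow: counts -> signatures -> scores -> labels.

Convenience layer tying the stages together the way the discovery cohort is
analyzed: filter low-expression genes, run the NB differential expression
between durable responders and non-responders, derive the stroma and
proliferation signatures, score every sample on mean-normalized FPKM, and
classify response from the combination score.
"""

from __future__ import annotations

import pandas as pd

from .cohort_io import ExpressionMatrix, counts_to_fpkm, filter_low_expression
from .diffexp import estimate_size_factors, nb_two_group_test
from .signatures import (
    Signature,
    combination_classify,
    derive_proliferation_signature,
    derive_stroma_signature,
    geometric_mean_score,
    mean_normalize,
)

__all__ = ["run_discovery", "score_cohort"]


def run_discovery(
    counts: ExpressionMatrix,
    samples: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    gene_lengths: pd.Series,
    group_a: str = "DR",
    group_b: str = "NR",
) -> dict:
    """Derive signatures and scores from a labeled discovery cohort.

    ``samples`` needs columns ``sample_id`` and ``response_label``;
    ``gene_sets`` needs keys ``CAF_MARKERS``, ``G2M_CHECKPOINT`` and
    ``E2F_TARGETS``.  Returns a dict with the DE table, both signatures,
    the per-sample score table (with predicted labels from a threshold
    fitted on the cohort itself) and the fitted threshold.
    """
    labels = samples.set_index("sample_id")["response_label"]
    filtered = filter_low_expression(counts)
    size_factors = estimate_size_factors(filtered)
    de = nb_two_group_test(
        filtered, labels, size_factors, group_a=group_a, group_b=group_b
    )
    stroma_sig = derive_stroma_signature(de, gene_sets["CAF_MARKERS"])
    prolif_sig = derive_proliferation_signature(
        de, gene_sets["G2M_CHECKPOINT"], gene_sets["E2F_TARGETS"]
    )
    fpkm = counts_to_fpkm(filtered, gene_lengths)
    scores = score_cohort(fpkm, stroma_sig, prolif_sig)
    scores["true_label"] = labels.loc[scores.index].to_numpy()
    classified = combination_classify(scores, training_labels=labels)
    return {
        "de": de,
        "stroma_signature": stroma_sig,
        "proliferation_signature": prolif_sig,
        "scores": classified,
        "threshold": classified.attrs.get("threshold"),
        "size_factors": size_factors,
    }


def score_cohort(
    fpkm: ExpressionMatrix,
    stroma_signature: Signature,
    proliferation_signature: Signature,
) -> pd.DataFrame:
    """Stroma and proliferation scores for every sample in one cohort.

    Normalization is per-cohort: each gene is divided by its mean over the
    samples being scored together.
    """
    normalized = mean_normalize(fpkm)
    return pd.DataFrame(
        {
            "stroma_score": geometric_mean_score(normalized, stroma_signature),
            "proliferation_score": geometric_mean_score(
                normalized, proliferation_signature
            ),
        }
    )
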