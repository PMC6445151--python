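"""Expression preprocessing: TPM normalization, log transform, zero filter.

Raw RNA-seq counts are made comparable across samples with
transcripts-per-kilobase-million (TPM), log2(1+x)-stabilized, and genes with
too many zeros are dropped before network estimation. Column centering is
deliberately left to the association step so that matrices stay in
interpretable units here.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import ExpressionMatrix

__all__ = ["tpm_normalize", "log_transform", "filter_zero_genes"]


def tpm_normalize(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Transcripts per kilobase million.

    Per sample: rate_j = count_j / (length_j in kb); TPM_j =
    rate_j / sum_i(rate_i) * 1e6, so every sample with any nonzero count
    sums to one million. All-zero samples are left at zero with a warning.
    """
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise KeyError(f"no length for gene(s): {missing[:5]}")
    vals = counts.values
    if np.any(vals < 0):
        raise ValueError("counts must be nonnegative")
    kb = np.array([lengths[g] for g in counts.gene_ids], dtype=float) / 1000.0
    rates = vals / kb[np.newaxis, :]
    totals = rates.sum(axis=1)
    zero_samples = totals == 0
    if np.any(zero_samples):
        warnings.warn(
            f"{int(zero_samples.sum())} all-zero sample(s) left at 0 after TPM",
            stacklevel=2,
        )
    safe = np.where(zero_samples, 1.0, totals)
    tpm = rates / safe[:, np.newaxis] * 1e6
    tpm[zero_samples, :] = 0.0
    return ExpressionMatrix(
        tpm, list(counts.gene_ids), list(counts.sample_ids), counts.group_label
    )


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(1 + x); input must be nonnegative."""
    if np.any(X.values < 0):
        raise ValueError("log_transform requires nonnegative values")
    return ExpressionMatrix(
        np.log2(1.0 + X.values), list(X.gene_ids), list(X.sample_ids), X.group_label
    )


def filter_zero_genes(X: ExpressionMatrix, max_zero_fraction: float) -> ExpressionMatrix:
    """Drop genes whose fraction of exactly-zero values strictly exceeds
    ``max_zero_fraction``; gene order is otherwise preserved."""
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    frac = (X.values == 0.0).mean(axis=0)
    keep = frac <= max_zero_fraction
    return ExpressionMatrix(
        X.values[:, keep],
        [g for g, k in zip(X.gene_ids, keep) if k],
        list(X.sample_ids),
        X.group_label,
    )
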