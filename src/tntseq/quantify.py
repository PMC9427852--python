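"""TPM quantification, protein-coding filtering and sample correlations.

TPM (transcripts per million) for gene *g* in one sample is

    TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j)

where ``c`` are raw read counts and ``L`` the effective gene length in
nucleotides (here: the union-exon length from the annotation table). Every
sample column of a TPM matrix therefore sums to one million over the genes
included.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EXPRESSED_RULES = ("any_sample", "all_samples", "mean")


def _check_annotation_covers(matrix: pd.DataFrame, annotation: pd.DataFrame) -> None:
    missing = matrix.index.difference(annotation.index)
    if len(missing) > 0:
        raise KeyError(
            f"{len(missing)} gene(s) missing from annotation, e.g. {missing[0]!r}"
        )


def counts_to_tpm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw count matrix (genes x samples) to TPM.

    Parameters
    ----------
    counts
        Non-negative counts, index = gene_id.
    annotation
        Gene annotation indexed by gene_id with an ``effective_length`` column
        (>= 1, nucleotides). Must cover every counted gene.
    """
    _check_annotation_covers(counts, annotation)
    lengths = annotation.loc[counts.index, "effective_length"].astype(float)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"effective_length < 1 for gene {bad!r}")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero) > 0:
        raise ValueError(
            f"sample {zero[0]!r} has no reads on annotated genes; TPM undefined"
        )
    return rate.div(colsum, axis=1) * 1e6


def filter_protein_coding(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Restrict a matrix to protein-coding genes, preserving row order."""
    _check_annotation_covers(matrix, annotation)
    keep = annotation.loc[matrix.index, "biotype"] == "protein_coding"
    return matrix.loc[keep.values]


def expressed_genes(tpm: pd.DataFrame, threshold: float = 1.0,
                    rule: str = "any_sample") -> set[str]:
    """Genes whose TPM exceeds ``threshold`` (strict >) under the given rule.

    ``rule`` is one of ``any_sample`` (TPM > t in at least one sample),
    ``all_samples`` or ``mean``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if rule not in EXPRESSED_RULES:
        raise ValueError(f"rule must be one of {EXPRESSED_RULES}")
    if tpm.shape[0] == 0 or tpm.shape[1] == 0:
        return set()
    if rule == "any_sample":
        mask = (tpm > threshold).any(axis=1)
    elif rule == "all_samples":
        mask = (tpm > threshold).all(axis=1)
    else:
        mask = tpm.mean(axis=1) > threshold
    return set(tpm.index[mask])


def sample_correlation(tpm_a: Iterable[float] | pd.Series,
                       tpm_b: Iterable[float] | pd.Series,
                       log_transform: bool = True,
                       pseudocount: float = 1.0) -> float:
    """Pearson correlation between two sample columns.

    By default computed on log2(TPM + pseudocount); this is the transform
    behind inter-sample correlation heatmaps.
    """
    x = np.asarray(tpm_a, dtype=float)
    y = np.asarray(tpm_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sample vectors must share gene order and length")
    if log_transform:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for the log transform")
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def correlation_matrix(tpm: pd.DataFrame, log_transform: bool = True,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """All pairwise sample correlations of a TPM matrix."""
    vals = tpm.values.astype(float)
    if log_transform:
        vals = np.log2(vals + pseudocount)
    r = np.corrcoef(vals.T)
    return pd.DataFrame(r, index=tpm.columns, columns=tpm.columns)
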