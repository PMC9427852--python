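"""Translation efficiency (TE) and dual-omics gene classes.

TE of a gene is its translatome TPM divided by its transcriptome TPM, the
standard ribosome-engagement summary for paired transcriptome/translatome
libraries of the same samples. TE is computed per matched replicate and
averaged on the log2 scale; it is only defined for genes passing the
expression filter (TPM above ``min_tpm`` in both layers).

Dual-omics classes cross the transcriptome DE call (up / constant / down)
with the translatome DE call for the same condition pair, yielding eight
informative cells plus "unchanged". Two cells are anchored to the oocyte
GV -> MII analysis that motivated them: Class I = translationally up but
transcriptionally constant, Class IV = down in both layers (higher
transcription and translation in the first condition). The remaining
numbering is this package's own documented convention (see docs), chosen so
that classes I, III, IV and V are exactly the translationally changed genes
whose transcription is constant or decreased, and so that swapping the two
conditions maps I <-> V, II <-> IV, III <-> VI and VII <-> VIII.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diffexpr import call_degs

log = logging.getLogger(__name__)

#: (transcriptome_call, translatome_call) -> class label
CLASS_GRID: dict[tuple[str, str], str] = {
    ("constant", "up"): "I",
    ("up", "up"): "II",
    ("down", "up"): "III",
    ("down", "down"): "IV",
    ("constant", "down"): "V",
    ("up", "down"): "VI",
    ("up", "constant"): "VII",
    ("down", "constant"): "VIII",
    ("constant", "constant"): "unchanged",
}

CALLS = ("up", "constant", "down")


def compute_te(tpm_transcriptome: pd.DataFrame, tpm_translatome: pd.DataFrame,
               condition: str | None = None, min_tpm: float = 1.0) -> pd.DataFrame:
    """Per-gene TE for one condition from matched replicate TPM columns.

    Parameters
    ----------
    tpm_transcriptome, tpm_translatome
        TPM matrices whose columns are this condition's replicates, paired
        by position across the two layers. Gene indices must be identical
        (a mismatch is an error, not a silent intersection).
    condition
        Optional label recorded in the output.
    min_tpm
        Expression filter: a gene gets a TE only if its replicate-mean TPM
        is strictly above ``min_tpm`` in both layers.

    Returns
    -------
    DataFrame indexed by gene_id with columns tpm_transcriptome,
    tpm_translatome (replicate means), te, log2_te and (optionally)
    condition.
    """
    if min_tpm <= 0:
        raise ValueError("min_tpm must be > 0")
    if not tpm_transcriptome.index.equals(tpm_translatome.index):
        raise ValueError("transcriptome and translatome gene sets must match exactly")
    if tpm_transcriptome.shape[1] != tpm_translatome.shape[1]:
        raise ValueError("layers must have the same number of replicate columns")
    tx = tpm_transcriptome.values.astype(float)
    tl = tpm_translatome.values.astype(float)
    mean_tx = tx.mean(axis=1)
    mean_tl = tl.mean(axis=1)
    keep = (mean_tx > min_tpm) & (mean_tl > min_tpm)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(tl) - np.log2(tx)
    valid = np.isfinite(log_ratio)
    n_valid = valid.sum(axis=1)
    log2_te = np.where(n_valid > 0,
                       np.nansum(np.where(valid, log_ratio, 0.0), axis=1)
                       / np.maximum(n_valid, 1),
                       np.nan)
    keep &= n_valid > 0

    out = pd.DataFrame(
        {
            "tpm_transcriptome": mean_tx[keep],
            "tpm_translatome": mean_tl[keep],
            "te": 2.0 ** log2_te[keep],
            "log2_te": log2_te[keep],
        },
        index=tpm_transcriptome.index[keep],
    )
    if condition is not None:
        out["condition"] = condition
    return out


def high_te_genes(profiles: pd.DataFrame, log2_te_threshold: float = 1.0) -> set[str]:
    """Genes with log2 TE strictly above the threshold (presets 0, 1, 2 = TE > 1, 2, 4)."""
    if not np.isfinite(log2_te_threshold) and log2_te_threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    return set(profiles.index[profiles["log2_te"] > log2_te_threshold])


def _layer_calls(de: pd.DataFrame, p_threshold: float, lfc_threshold: float) -> pd.Series:
    up, down = call_degs(de, p_threshold, lfc_threshold)
    calls = pd.Series("constant", index=de.index, dtype=object)
    calls.loc[list(up)] = "up"
    calls.loc[list(down)] = "down"
    return calls


def classify_dual_omics(transcriptome_de: pd.DataFrame, translatome_de: pd.DataFrame,
                        p_threshold: float = 0.05,
                        lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Assign each gene a dual-omics class from its two-layer DE results.

    Both DE tables must compare the same condition pair with the same
    direction convention. A gene present in only one layer's results is
    treated as constant in the missing layer (logged).
    """
    tx_calls = _layer_calls(transcriptome_de, p_threshold, lfc_threshold)
    tl_calls = _layer_calls(translatome_de, p_threshold, lfc_threshold)
    genes = tx_calls.index.union(tl_calls.index)
    only_tx = tx_calls.index.difference(tl_calls.index)
    only_tl = tl_calls.index.difference(tx_calls.index)
    if len(only_tx) or len(only_tl):
        log.info("%d gene(s) in one layer only; treated as constant in the other",
                 len(only_tx) + len(only_tl))
    tx = tx_calls.reindex(genes, fill_value="constant")
    tl = tl_calls.reindex(genes, fill_value="constant")
    labels = [CLASS_GRID[(a, b)] for a, b in zip(tx, tl)]
    return pd.DataFrame(
        {"transcriptome_call": tx, "translatome_call": tl, "class_label": labels},
        index=genes,
    )


def class_counts(classes: pd.DataFrame) -> pd.Series:
    order = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "unchanged"]
    return classes["class_label"].value_counts().reindex(order, fill_value=0)


def cross_species_overlap(set_a: Iterable[str], set_b: Iterable[str],
                          homolog_map: Mapping[str, str] | None = None
                          ) -> tuple[int, int, int]:
    """Overlap of two gene sets across species through a one-to-one homolog map.

    Returns ``(count_a_only, count_shared, count_b_only)``. Genes of A with
    no homolog (or whose homolog is absent from B) count as A-specific, and
    symmetrically for B. ``homolog_map`` maps A-species ids to B-species ids;
    ``None`` means identity (same id space).
    """
    a, b = set(set_a), set(set_b)
    if homolog_map is None:
        mapped = {g: g for g in a}
    else:
        targets = list(homolog_map.values())
        if len(targets) != len(set(targets)):
            raise ValueError("homolog map is not one-to-one (duplicated targets)")
        mapped = {g: homolog_map[g] for g in a if g in homolog_map}
    shared = {g for g, h in mapped.items() if h in b}
    shared_in_b = {mapped[g] for g in shared}
    return len(a) - len(shared), len(shared), len(b) - len(shared_in_b)


def overlap_percentages(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Shared fraction (percent) relative to each species' own set."""
    a_only, shared, b_only = counts
    na, nb = a_only + shared, b_only + shared
    return (100.0 * shared / na if na else 0.0,
            100.0 * shared / nb if nb else 0.0)
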