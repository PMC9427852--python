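"""ERCC spike-in estimate of non-specific capture in the translatome assay.

Synthetic ERCC spike-in RNAs added to the lysate before ribosome affinity
purification are not translated, so any spike-in reads in the translatome
library reflect non-specific binding. The estimator compares the spike-in
read *share* of each library:

    input_fraction     = spike reads / total reads   (transcriptome)
    captured_fraction  = spike reads / total reads   (translatome)
    nonspecific        = captured_fraction / input_fraction

reported per sample and as a mean across samples, plus a pooled-count
estimate. Per-spike capture ratios are returned as diagnostics for
abundance-dependent bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SpikeInReport:
    spike_ids: list[str]
    input_fraction: pd.Series      # per sample
    captured_fraction: pd.Series   # per sample
    per_sample_nonspecific: pd.Series
    nonspecific_fraction: float    # mean over samples
    pooled_nonspecific: float      # from summed counts over samples
    per_spike: pd.DataFrame = field(repr=False, default=None)


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.Series):
        return counts.to_frame("sample_1")
    return counts


def estimate_nonspecific_binding(transcriptome_counts,
                                 translatome_counts,
                                 spike_ids: Sequence[str]) -> SpikeInReport:
    """Estimate the non-specific (false-positive) capture fraction.

    Both inputs are count tables (Series for one sample or DataFrames with
    matching sample columns) whose index contains the spike-in ids alongside
    endogenous genes.
    """
    tx = _as_frame(transcriptome_counts)
    tl = _as_frame(translatome_counts)
    spike_ids = list(spike_ids)
    for name, df in (("transcriptome", tx), ("translatome", tl)):
        missing = [s for s in spike_ids if s not in df.index]
        if missing:
            raise KeyError(f"spike id(s) missing from {name} counts: {missing[:3]}")
    tx_spike = tx.loc[spike_ids].sum(axis=0)
    tl_spike = tl.loc[spike_ids].sum(axis=0)
    tx_total = tx.sum(axis=0)
    tl_total = tl.sum(axis=0)
    if (tx_spike == 0).any():
        bad = tx_spike.index[tx_spike == 0][0]
        raise ValueError(f"no spike-in reads in transcriptome sample {bad!r}; "
                         "estimator undefined")
    input_fraction = tx_spike / tx_total
    captured_fraction = tl_spike / tl_total
    per_sample = captured_fraction / input_fraction
    pooled = float((tl_spike.sum() / tl_total.sum())
                   / (tx_spike.sum() / tx_total.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_spike = pd.DataFrame({
            "input_share": tx.loc[spike_ids].sum(axis=1) / tx_total.sum(),
            "captured_share": tl.loc[spike_ids].sum(axis=1) / tl_total.sum(),
        })
        per_spike["capture_ratio"] = (per_spike["captured_share"]
                                      / per_spike["input_share"])
    return SpikeInReport(
        spike_ids=spike_ids,
        input_fraction=input_fraction,
        captured_fraction=captured_fraction,
        per_sample_nonspecific=per_sample,
        nonspecific_fraction=float(per_sample.mean()),
        pooled_nonspecific=pooled,
        per_spike=per_spike,
    )
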