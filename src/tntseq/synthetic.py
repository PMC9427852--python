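"""Ground-truth-labelled simulators for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* paired transcriptome/translatome NB count matrices with planted
  dual-omics classes and per-gene translation efficiencies;
* 3'-UTR sequence sets with motif instances planted at different rates in
  target and background genes (plus fixtures with planted CPE/PAS pairs);
* ERCC-like spike-in capture with a known non-specific binding probability.

Counts are negative binomial parameterised by mean and dispersion alpha
with Var = mu + alpha * mu^2 (``dispersion = 0`` switches to a
deterministic rounding mode). Gene abundances are drawn log-normal
(log2 mean 5, sd 2 by default) to span the dynamic range of TPM data.
Identical spec + seed reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import ALPHABET, PositionWeightMatrix
from .te_class import CLASS_GRID

#: inverse of the class grid: label -> (transcriptome_call, translatome_call)
CALLS_OF_CLASS = {v: k for k, v in CLASS_GRID.items()}

#: default planted class mix: changed genes dominated by Class I and IV,
#: mirroring the oocyte GV->MII pattern
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "unchanged": 0.80, "I": 0.05, "IV": 0.06, "II": 0.02, "III": 0.02,
    "V": 0.02, "VI": 0.01, "VII": 0.01, "VIII": 0.01,
}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults are the shipped conditions."""

    n_genes: int = 2000
    n_per_condition: int = 3
    dispersion: float = 0.05
    lfc_magnitude: float = 2.0           # |log2FC| of planted up/down calls
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    mean_log2_expression: float = 5.0
    sd_log2_expression: float = 2.0
    te_log2_mean: float = 0.0
    te_log2_sd: float = 0.5
    depth: float = 1e6                   # expected library size, reads
    size_factor_sd: float = 0.1          # log2 sd of per-sample depth jitter
    # --- UTR simulation ---
    n_target_genes: int = 200
    n_background_genes: int = 1000
    target_insertion_rate: float = 5.0   # Poisson motif instances per target UTR
    background_insertion_rate: float = 1.0
    utr_length_mean: int = 1000
    utr_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    # --- spike-in simulation ---
    n_spikes: int = 92
    spike_fraction: float = 0.02         # spike share of transcriptome reads
    spike_nonspecific_probability: float = 0.167
    seed: int = 0

    def validate(self) -> None:
        fr = dict(self.class_fractions)
        unknown = set(fr) - set(CALLS_OF_CLASS)
        if unknown:
            raise ValueError(f"unknown class labels in class_fractions: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be >= 0")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.spike_nonspecific_probability <= 1:
            raise ValueError("spike_nonspecific_probability must be in [0, 1]")
        if min(self.target_insertion_rate, self.background_insertion_rate) < 0:
            raise ValueError("insertion rates must be >= 0")
        comp = np.asarray(self.utr_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("utr_composition must be 4 probabilities summing to 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return np.rint(mean).astype(np.int64)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(n, p).astype(np.int64)


def simulate_paired_counts(spec: SimulationSpec, seed: int | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired transcriptome/translatome counts with planted classes.

    Returns ``(transcriptome, translatome, truth)``. Count columns are
    ``A_1..A_n, B_1..B_n`` (conditions A and B); the truth table records the
    planted class, per-layer log2 fold changes, the planted TE and each
    sample's depth-jitter factor (in ``truth.attrs['size_factors']``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, m = spec.n_genes, spec.n_per_condition
    genes = [f"G{i + 1:05d}" for i in range(n)]

    labels = list(spec.class_fractions)
    probs = np.array([spec.class_fractions[c] for c in labels])
    cls = rng.choice(len(labels), size=n, p=probs)
    class_label = np.array(labels, dtype=object)[cls]

    def lfc_of(call: str) -> float:
        return {"up": spec.lfc_magnitude, "down": -spec.lfc_magnitude,
                "constant": 0.0}[call]

    tx_lfc = np.array([lfc_of(CALLS_OF_CLASS[c][0]) for c in class_label])
    tl_lfc = np.array([lfc_of(CALLS_OF_CLASS[c][1]) for c in class_label])

    base = 2.0 ** rng.normal(spec.mean_log2_expression, spec.sd_log2_expression, n)
    te = 2.0 ** rng.normal(spec.te_log2_mean, spec.te_log2_sd, n)

    cols = [f"A_{j + 1}" for j in range(m)] + [f"B_{j + 1}" for j in range(m)]
    sf = {}
    layers = {}
    for layer, layer_base, layer_lfc in (("transcriptome", base, tx_lfc),
                                         ("translatome", base * te, tl_lfc)):
        mean_a = layer_base * (spec.depth / layer_base.sum())
        mean_b = mean_a * 2.0 ** layer_lfc
        jitter = 2.0 ** rng.normal(0.0, spec.size_factor_sd, 2 * m)
        mat = np.empty((n, 2 * m), dtype=np.int64)
        for j in range(2 * m):
            mu = (mean_a if j < m else mean_b) * jitter[j]
            mat[:, j] = _nb_draw(rng, mu, spec.dispersion)
        layers[layer] = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                                     columns=cols)
        sf[layer] = dict(zip(cols, jitter))

    truth = pd.DataFrame(
        {
            "class_label": class_label,
            "transcriptome_call": [CALLS_OF_CLASS[c][0] for c in class_label],
            "translatome_call": [CALLS_OF_CLASS[c][1] for c in class_label],
            "transcriptome_lfc": tx_lfc,
            "translatome_lfc": tl_lfc,
            "te": te,
            "base_mean": base,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth.attrs["size_factors"] = sf
    return layers["transcriptome"], layers["translatome"], truth


# ---------------------------------------------------------------------------
# UTR sequences
# ---------------------------------------------------------------------------

def cpeb_like_pwm(motif_id: str = "M_CPEB_LIKE", rbp_name: str = "CPEB-like",
                  consensus: str = "UUUUAU", purity: float = 0.94
                  ) -> PositionWeightMatrix:
    """A sharp demo PWM around a U-rich CPE-like consensus."""
    idx = {c: i for i, c in enumerate(ALPHABET)}
    L = len(consensus)
    p = np.full((L, 4), (1.0 - purity) / 3.0)
    for i, ch in enumerate(consensus.upper().replace("T", "U")):
        p[i, idx[ch]] = purity
    return PositionWeightMatrix(motif_id, rbp_name, p)


def _sample_instance(rng: np.random.Generator,
                     motif: PositionWeightMatrix | str) -> str:
    if isinstance(motif, str):
        return motif.upper().replace("T", "U")
    picks = [rng.choice(4, p=row) for row in motif.probabilities]
    return "".join(ALPHABET[i] for i in picks)


def _plant(rng: np.random.Generator, seq: list[str], instance: str,
           occupied: list[tuple[int, int]], tries: int = 50) -> int | None:
    L, n = len(instance), len(seq)
    if L > n:
        raise ValueError("motif longer than UTR")
    for _ in range(tries):
        pos = int(rng.integers(0, n - L + 1))
        if all(pos + L <= s or pos >= e for s, e in occupied):
            seq[pos: pos + L] = list(instance)
            occupied.append((pos, pos + L))
            return pos
    return None


def simulate_utrs(spec: SimulationSpec,
                  motif: PositionWeightMatrix | str | None = None,
                  seed: int | None = None
                  ) -> tuple[dict[str, str], pd.DataFrame]:
    """Target/background UTR sets with planted motif instances.

    Target genes (ids ``T...``) receive Poisson(``target_insertion_rate``)
    instances of the motif per UTR, background genes (ids ``B...``)
    Poisson(``background_insertion_rate``); instances are sampled from the
    PWM (or are the literal consensus for a string motif) and placed at
    non-overlapping uniform positions. The truth table records every
    planted position.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if motif is None:
        motif = cpeb_like_pwm()
    comp = np.asarray(spec.utr_composition, dtype=float)
    utrs: dict[str, str] = {}
    rows = []
    groups = [("T", spec.n_target_genes, spec.target_insertion_rate),
              ("B", spec.n_background_genes, spec.background_insertion_rate)]
    for prefix, n_genes, rate in groups:
        for i in range(n_genes):
            gid = f"{prefix}{i + 1:05d}"
            length = max(50, int(rng.normal(spec.utr_length_mean,
                                            spec.utr_length_mean / 4)))
            seq = list(rng.choice(list(ALPHABET), size=length, p=comp))
            n_plant = int(rng.poisson(rate))
            occupied: list[tuple[int, int]] = []
            positions = []
            for _ in range(n_plant):
                pos = _plant(rng, seq, _sample_instance(rng, motif), occupied)
                if pos is not None:
                    positions.append(pos)
            utrs[gid] = "".join(seq)
            rows.append({"gene_id": gid,
                         "group": "target" if prefix == "T" else "background",
                         "n_planted": len(positions),
                         "planted_positions": sorted(positions)})
    truth = pd.DataFrame(rows).set_index("gene_id")
    return utrs, truth


def simulate_cpe_pas_utrs(n_genes: int = 20, gap: int = 34,
                          cpe: str = "UUUUAU", pas: str = "AAUAAA",
                          length: int = 300, seed: int = 0
                          ) -> tuple[dict[str, str], pd.DataFrame]:
    """UTR fixtures with one planted CPE-PAS pair at a chosen nearest-end gap.

    The background is G/C-only so the planted elements are the only
    U/A-containing matches and pairing is exactly recoverable.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    need = len(cpe) + gap + len(pas)
    if need > length:
        raise ValueError("length too short for the requested gap")
    utrs: dict[str, str] = {}
    rows = []
    for i in range(n_genes):
        gid = f"P{i + 1:05d}"
        seq = list(rng.choice(["G", "C"], size=length))
        start = int(rng.integers(0, length - need + 1))
        cpe_start = start
        pas_start = start + len(cpe) + gap
        seq[cpe_start: cpe_start + len(cpe)] = list(cpe)
        seq[pas_start: pas_start + len(pas)] = list(pas)
        utrs[gid] = "".join(seq)
        rows.append({"gene_id": gid, "cpe_start": cpe_start,
                     "pas_start": pas_start, "gap": gap})
    return utrs, pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# spike-ins
# ---------------------------------------------------------------------------

def simulate_spikeins(spec: SimulationSpec, seed: int | None = None
                      ) -> tuple[pd.Series, pd.Series, list[str]]:
    """Transcriptome and translatome count vectors with ERCC-like spikes.

    Spike molecules make up ``spike_fraction`` of the transcriptome read
    mass; in the translatome they survive only by non-specific binding with
    probability ``spike_nonspecific_probability`` (endogenous mRNAs are
    captured in proportion to their abundance). Both libraries are
    multinomial samples at ``depth`` reads.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p_ns = spec.spike_nonspecific_probability
    endo_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    spike_ids = [f"ERCC-{i + 1:05d}" for i in range(spec.n_spikes)]
    endo = 2.0 ** rng.normal(spec.mean_log2_expression, spec.sd_log2_expression,
                             spec.n_genes)
    spike = 2.0 ** rng.normal(spec.mean_log2_expression, spec.sd_log2_expression,
                              spec.n_spikes)
    f = spec.spike_fraction
    spike *= (endo.sum() * f / (1.0 - f)) / spike.sum()

    tx_mass = np.concatenate([endo, spike])
    tl_mass = np.concatenate([endo, spike * p_ns])
    depth = int(spec.depth)
    index = pd.Index(endo_ids + spike_ids, name="gene_id")
    tx = pd.Series(rng.multinomial(depth, tx_mass / tx_mass.sum()), index=index,
                   name="transcriptome")
    tl = pd.Series(rng.multinomial(depth, tl_mass / tl_mass.sum()), index=index,
                   name="translatome")
    return tx, tl, spike_ids


def spec_with(spec: SimulationSpec, **overrides) -> SimulationSpec:
    """A copy of the spec with fields replaced (convenience for sweeps)."""
    return replace(spec, **overrides)
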