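"""3'-UTR RNA-binding-protein motif scanning and enrichment.

The scanner mirrors the standard FIMO procedure on the sense strand only
(RNA has no reverse complement to scan): every length-L window of a UTR is
scored with the motif's log2 likelihood ratio against a zero-order
background model,

    score(w) = sum_i log2( p_i(w_i) / b(w_i) ),

and the score's p-value — the probability that a background-generated
window scores at least as high — is computed *exactly* by dynamic
programming over the discretised score distribution (bin width
``SCORE_BIN`` in log2 units). Hits are windows whose score p-value falls
below a threshold.

Downstream, hit scores are min-max normalised over the motif's attainable
score range, a strict normalised-score cutoff removes weak sites, per-gene
occurrences are counted per RBP, and target-vs-background enrichment uses a
one-sided Welch t-test on the per-gene occurrence values.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALPHABET = "ACGU"
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

#: discretisation bin width (log2 units) for the exact score-distribution DP
SCORE_BIN = 1e-3
#: floor applied to PWM cells when forming log-odds scores
PROB_FLOOR = 1e-4

MAX_MOTIF_LENGTH = 30

HIT_COLUMNS = ["gene_id", "motif_id", "rbp_name", "start", "end",
               "raw_score", "score_pvalue", "normalized_score"]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position nucleotide probabilities of one RNA motif (columns A,C,G,U)."""

    motif_id: str
    rbp_name: str
    probabilities: np.ndarray  # shape (L, 4)
    source: str = ""

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id!r}: probability matrix must be L x 4")
        if not 1 <= p.shape[0] <= MAX_MOTIF_LENGTH:
            raise ValueError(
                f"motif {self.motif_id!r}: length {p.shape[0]} outside "
                f"[1, {MAX_MOTIF_LENGTH}]")
        if (p < 0).any():
            raise ValueError(f"motif {self.motif_id!r}: negative probabilities")
        if np.abs(p.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError(f"motif {self.motif_id!r}: rows must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    def log_odds(self, background: Sequence[float] = UNIFORM_BACKGROUND) -> np.ndarray:
        """Per-position log2 likelihood-ratio scores (cells floored at PROB_FLOOR)."""
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
            raise ValueError("background must be 4 positive probabilities summing to 1")
        return np.log2(np.maximum(self.probabilities, PROB_FLOOR) / bg)

    def score_range(self, background: Sequence[float] = UNIFORM_BACKGROUND
                    ) -> tuple[float, float]:
        """(min, max) attainable window scores."""
        lo = self.log_odds(background)
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence on a 3'-UTR; [start, end) is 0-based half-open."""

    gene_id: str
    motif_id: str
    rbp_name: str
    start: int
    end: int
    raw_score: float
    score_pvalue: float
    normalized_score: float


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def load_motif_compendium(path: str | Path) -> list[PositionWeightMatrix]:
    """Parse a MEME minimal motif file into validated PWMs.

    T and U are the same letter; zero-probability cells are floored at 1e-4
    and each row renormalised. Rows whose stated probabilities do not sum to
    one (beyond rounding) are renormalised with a warning. Duplicate motif
    ids are an error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pwms: list[PositionWeightMatrix] = []
    seen: set[str] = set()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line.upper().startswith("MOTIF"):
            i += 1
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path.name}: MOTIF line without identifier: {line!r}")
        motif_id = parts[1]
        rbp_name = parts[2] if len(parts) > 2 else motif_id
        if motif_id in seen:
            raise ValueError(f"{path.name}: duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        # locate the letter-probability matrix header
        j = i + 1
        while j < n and not lines[j].strip().lower().startswith("letter-probability"):
            if lines[j].strip().upper().startswith("MOTIF"):
                break
            j += 1
        if j >= n or not lines[j].strip().lower().startswith("letter-probability"):
            raise ValueError(
                f"{path.name}: motif {motif_id!r} has no letter-probability matrix")
        m = re.search(r"\bw\s*=\s*(\d+)", lines[j])
        width = int(m.group(1)) if m else None
        rows: list[list[float]] = []
        j += 1
        while j < n:
            stripped = lines[j].strip()
            if not stripped or stripped.upper().startswith(("MOTIF", "URL")):
                break
            try:
                vals = [float(x) for x in stripped.split()]
            except ValueError:
                break
            if len(vals) != 4:
                raise ValueError(
                    f"{path.name}: motif {motif_id!r} row {len(rows) + 1} has "
                    f"{len(vals)} columns, expected 4")
            rows.append(vals)
            j += 1
        if not rows:
            raise ValueError(f"{path.name}: motif {motif_id!r} has an empty matrix")
        if width is not None and width != len(rows):
            raise ValueError(
                f"{path.name}: motif {motif_id!r} declares w= {width} but has "
                f"{len(rows)} rows")
        p = np.asarray(rows, dtype=float)
        if (p < 0).any():
            raise ValueError(f"{path.name}: motif {motif_id!r} has negative entries")
        sums = p.sum(axis=1)
        if (np.abs(sums - 1.0) > 0.01).any():
            log.warning("motif %s: %d row(s) do not sum to 1; renormalising",
                        motif_id, int((np.abs(sums - 1.0) > 0.01).sum()))
        p = np.maximum(p, PROB_FLOOR)
        p = p / p.sum(axis=1, keepdims=True)
        pwms.append(PositionWeightMatrix(motif_id, rbp_name, p, source=path.name))
        i = j
    if not pwms:
        log.warning("no motifs found in %s", path)
    return pwms


def demo_compendium() -> list[PositionWeightMatrix]:
    """The small bundled demo compendium (synthetic stand-in motifs).

    Consensus-style PWMs named after well-known oocyte translational
    regulators; constructed in-repo for demonstrations and tests, not
    curated from motif databases.
    """
    from importlib.resources import files
    return load_motif_compendium(str(files("tntseq") / "data" / "demo_motifs.meme"))


def write_motif_compendium(pwms: Iterable[PositionWeightMatrix],
                           path: str | Path,
                           background: Sequence[float] = UNIFORM_BACKGROUND) -> None:
    """Write PWMs in MEME minimal motif format (RNA alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f U %.5f\n\n" % tuple(background))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.rbp_name}\n")
            fh.write(f"letter-probability matrix: alphabet= ACGU w= {pwm.length} "
                     f"nsites= 20 E= 0\n")
            for row in pwm.probabilities:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": -1}


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an RNA/DNA string (T = U, case-folded) to codes 0..3, N -> -1."""
    seq = sequence.upper()
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid sequence letter {exc.args[0]!r}") from None


def score_distribution(pwm: PositionWeightMatrix,
                       background: Sequence[float] = UNIFORM_BACKGROUND,
                       bin_width: float = SCORE_BIN
                       ) -> tuple[np.ndarray, int, np.ndarray]:
    """Exact discretised null distribution of window scores.

    Per-position scores are rounded to integer multiples of ``bin_width``
    and their sum distribution under the background model is built by
    position-wise convolution.

    Returns ``(int_scores, min_sum, tail)`` where ``int_scores`` is the
    L x 4 integer score matrix, ``min_sum`` the smallest attainable integer
    sum, and ``tail[k]`` = P(sum >= min_sum + k).
    """
    bg = np.asarray(background, dtype=float)
    int_scores = np.rint(pwm.log_odds(bg) / bin_width).astype(np.int64)
    mins = int_scores.min(axis=1)
    maxs = int_scores.max(axis=1)
    dist = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.length):
        span = maxs[i] - mins[i]
        new = np.zeros(dist.size + span)
        for b in range(4):
            off = int_scores[i, b] - mins[i]
            new[off: off + dist.size] += bg[b] * dist
        dist = new
        cur_lo += mins[i]
    tail = np.cumsum(dist[::-1])[::-1]
    return int_scores, cur_lo, tail


def score_pvalue(score_int: int, min_sum: int, tail: np.ndarray) -> float:
    """P(background window score >= score) from a precomputed tail table."""
    k = score_int - min_sum
    if k <= 0:
        return 1.0
    if k >= tail.size:
        return 0.0
    return float(min(tail[k], 1.0))


def scan_pwm(sequence: str, pwm: PositionWeightMatrix,
             background: Sequence[float] = UNIFORM_BACKGROUND,
             pvalue_threshold: float = 1e-4,
             gene_id: str = "",
             _dist: tuple[np.ndarray, int, np.ndarray] | None = None
             ) -> list[MotifHit]:
    """Scan one sequence with one PWM on the sense strand.

    Every window with score p-value strictly below ``pvalue_threshold``
    becomes a hit; overlapping hits are allowed, windows containing N are
    skipped, and a sequence shorter than the motif yields no hits.
    """
    codes = encode_sequence(sequence)
    L = pwm.length
    n_win = codes.size - L + 1
    if n_win <= 0:
        return []
    int_scores, min_sum, tail = _dist if _dist is not None else \
        score_distribution(pwm, background)
    lo = pwm.log_odds(background)
    score_min, score_max = pwm.score_range(background)
    span = score_max - score_min

    win_int = np.zeros(n_win, dtype=np.int64)
    win_raw = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for i in range(L):
        c = codes[i: i + n_win]
        ok = c >= 0
        valid &= ok
        safe = np.where(ok, c, 0)
        win_int += int_scores[i, safe]
        win_raw += lo[i, safe]

    hits: list[MotifHit] = []
    for pos in np.nonzero(valid)[0]:
        p = score_pvalue(int(win_int[pos]), min_sum, tail)
        if p < pvalue_threshold:
            norm = (win_raw[pos] - score_min) / span if span > 0 else float("nan")
            hits.append(MotifHit(gene_id, pwm.motif_id, pwm.rbp_name,
                                 int(pos), int(pos) + L,
                                 float(win_raw[pos]), p, float(norm)))
    return hits


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    df = pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS)
    return df


def scan_utrs(utrs: Mapping[str, str], pwms: Iterable[PositionWeightMatrix],
              background: Sequence[float] = UNIFORM_BACKGROUND,
              pvalue_threshold: float = 1e-4) -> pd.DataFrame:
    """Scan every UTR with every PWM; returns a hit table (one row per hit)."""
    frames: list[MotifHit] = []
    for pwm in pwms:
        dist = score_distribution(pwm, background)
        for gid, seq in utrs.items():
            frames.extend(scan_pwm(seq, pwm, background, pvalue_threshold,
                                   gene_id=gid, _dist=dist))
    return hits_to_frame(frames)


def normalize_and_filter(hits: pd.DataFrame,
                         threshold: float = 0.8) -> pd.DataFrame:
    """Keep hits with min-max normalised score >= threshold.

    Normalisation is over the motif's attainable score range (already stored
    on each hit), so the filter is deterministic and dataset-independent.
    Motifs with a degenerate (zero-width) score range carry NaN normalised
    scores and are dropped with a warning.
    """
    degenerate = hits["normalized_score"].isna()
    if degenerate.any():
        bad = sorted(hits.loc[degenerate, "motif_id"].unique())
        log.warning("dropping motif(s) with degenerate score range: %s", bad)
    return hits.loc[~degenerate & (hits["normalized_score"] >= threshold)].copy()


# ---------------------------------------------------------------------------
# occurrence counting and enrichment
# ---------------------------------------------------------------------------

def occurrence_table(hits: pd.DataFrame, genes: Iterable[str],
                     utr_lengths: Mapping[str, int] | None = None,
                     per_kb: bool = False) -> pd.DataFrame:
    """Per-gene, per-RBP occurrence of retained motif hits.

    Occurrence is the number of retained hits of *any* motif of the RBP in
    the gene's 3'-UTR; with ``per_kb`` it is divided by the UTR length in
    kilobases. Genes without a known UTR (absent from ``utr_lengths`` when
    lengths are supplied) are excluded and logged.
    """
    genes = list(genes)
    if per_kb and utr_lengths is None:
        raise ValueError("per_kb requires utr_lengths")
    if utr_lengths is not None:
        missing = [g for g in genes if g not in utr_lengths]
        if missing:
            log.info("excluding %d gene(s) without UTR sequence", len(missing))
        genes = [g for g in genes if g in utr_lengths]
    rbps = sorted(hits["rbp_name"].unique()) if len(hits) else []
    table = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=rbps)
    if len(hits):
        counts = (hits[hits["gene_id"].isin(genes)]
                  .groupby(["gene_id", "rbp_name"]).size().unstack(fill_value=0)
                  .reindex(index=table.index, columns=table.columns, fill_value=0))
        table += counts.astype(float)
    if per_kb:
        kb = pd.Series({g: utr_lengths[g] / 1000.0 for g in genes})
        table = table.div(kb, axis=0)
    return table


def enrich(target_genes: Iterable[str], background_genes: Iterable[str],
           occurrences: pd.DataFrame, epsilon: float = 0.01,
           lfc_threshold: float = 1.0, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Target-vs-background occurrence enrichment per RBP.

    One-sided Welch t-test (alternative: target mean > background mean) on
    per-gene occurrence values, and log2 fold change of means with a small
    epsilon. The significance rule (log2FC > threshold and p below the
    cutoff, defaults 1 and 1e-5) is recorded in the ``significant`` column;
    p-values are not multiplicity-adjusted.
    """
    target = [g for g in target_genes if g in occurrences.index]
    background = [g for g in background_genes if g in occurrences.index]
    if set(target) & set(background):
        raise ValueError("target and background gene sets must be disjoint")
    if len(target) < 2 or len(background) < 2:
        raise ValueError("need at least 2 genes in each of target and background")
    t_occ = occurrences.loc[target]
    b_occ = occurrences.loc[background]
    rows = []
    for rbp in occurrences.columns:
        a, b = t_occ[rbp].values, b_occ[rbp].values
        mt, mb = float(a.mean()), float(b.mean())
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = 0.0 if mt > mb else 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False,
                                      alternative="greater").pvalue)
        lfc = float(np.log2((mt + epsilon) / (mb + epsilon)))
        rows.append((rbp, mt, mb, lfc, p,
                     bool(lfc > lfc_threshold and p < p_threshold)))
    out = pd.DataFrame(rows, columns=["rbp_name", "mean_occurrence_target",
                                      "mean_occurrence_background",
                                      "log2_fold_change", "p_value",
                                      "significant"]).set_index("rbp_name")
    return out.sort_values("p_value")


def co_occurrence(hits: pd.DataFrame, rbp_list: Sequence[str],
                  genes: Iterable[str] | None = None
                  ) -> dict[tuple[str, ...], int]:
    """Upset-style intersection counts of RBP target gene sets.

    For every non-empty subset of ``rbp_list``, the number of genes carrying
    at least one retained hit of *every* RBP in the subset.
    """
    if len(rbp_list) == 0:
        raise ValueError("rbp_list must be non-empty")
    sub = hits[hits["rbp_name"].isin(rbp_list)]
    if genes is not None:
        sub = sub[sub["gene_id"].isin(set(genes))]
    targets = {rbp: set(sub.loc[sub["rbp_name"] == rbp, "gene_id"])
               for rbp in rbp_list}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(rbp_list) + 1):
        for combo in itertools.combinations(sorted(rbp_list), r):
            shared = set.intersection(*(targets[rbp] for rbp in combo))
            counts[combo] = len(shared)
    return counts
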