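"""Promoter extraction and PWM scanning with information-weighted scores.

A binding-site prediction scores each sequence window by the information
content weighted match

    current(w) = sum_i I(i) * f(i, b_i),   I(i) = sum_b f(i,b) ln(4 f(i,b)),

min-max normalised per matrix to the matrix similarity score (MSS) in [0, 1].
A hit must also pass the analogous core similarity score (CSS) over the most
informative stretch of consecutive positions.  This is the classic
TRANSFAC/Match scoring convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Pseudocount applied when converting counts to scan frequencies: each base
#: receives 1% of the column total / 4, so zero counts never produce log 0.
SCAN_PSEUDOCOUNT = 0.01

#: Number of consecutive positions forming the scoring core.
CORE_LENGTH = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class PWM:
    """Position count matrix with TRANSFAC-style derived quantities."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # L x 4, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Column-normalised frequencies; pseudocount is a fraction of the
        column total spread evenly over the four bases."""
        totals = self.counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        f = self.counts + pseudocount * totals / 4.0
        return f / f.sum(axis=1, keepdims=True)

    def information(self, pseudocount: float = SCAN_PSEUDOCOUNT) -> np.ndarray:
        return pwm_information(self.frequencies(pseudocount))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix_id, self.tf_name, self.counts[::-1, ::-1].copy())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.frequencies().argmax(axis=1))


def pwm_information(freqs: np.ndarray) -> np.ndarray:
    """Per-position information vector I(i) = sum_b f ln(4 f), with 0 ln 0 = 0.

    Zero for a uniform column, ln 4 for a degenerate one.
    """
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=1)


def consensus_to_pwm(consensus: str, pseudocount: float = 0.0,
                     matrix_id: str | None = None, tf_name: str | None = None) -> PWM:
    """Build a count PWM from a consensus: 1 for the consensus base at each
    position, ``pseudocount`` for the other three."""
    consensus = consensus.upper()
    bad = set(consensus) - set(_BASES)
    if bad:
        raise ValueError(f"ambiguous bases in consensus: {sorted(bad)}")
    counts = np.full((len(consensus), 4), float(pseudocount))
    for i, b in enumerate(consensus):
        counts[i, _BASE_INDEX[b]] = 1.0
    name = matrix_id or f"M_{consensus}"
    return PWM(matrix_id=name, tf_name=tf_name or name, counts=counts)


# ---------------------------------------------------------------------------
# Promoter extraction


def extract_promoters(
    genes: pd.DataFrame,
    genome: dict[str, str],
    up: int = 500,
    down: int = 100,
) -> pd.DataFrame:
    """Strand-aware promoter windows [-up, +down) around each gene's TSS.

    The TSS is the annotated gene start on the + strand and the gene end on
    the - strand; minus-strand promoters are reverse complemented so the
    returned sequence always reads 5'->3' into the gene.  Windows running off
    a contig edge are clipped and flagged ``truncated``.
    """
    rows = []
    for rec in genes.itertuples(index=False):
        if rec.chrom not in genome:
            raise KeyError(f"chromosome {rec.chrom!r} of gene {rec.gene_id} not in genome")
        contig = genome[rec.chrom]
        L = len(contig)
        if rec.strand == "+":
            tss0 = rec.start - 1  # 0-based TSS
            lo, hi = tss0 - up, tss0 + down
            a, b = max(0, lo), min(L, hi)
            seq = contig[a:b]
        else:
            tss0 = rec.end - 1
            lo, hi = tss0 - down + 1, tss0 + up + 1
            a, b = max(0, lo), min(L, hi)
            seq = reverse_complement(contig[a:b])
        rows.append(
            {
                "gene_id": rec.gene_id,
                "sequence": seq.upper(),
                "truncated": (b - a) != (up + down),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "sequence", "truncated"])


# ---------------------------------------------------------------------------
# Match-style scanning


def _core_offset(info: np.ndarray, core_length: int) -> int:
    """Start of the most informative stretch of ``core_length`` positions."""
    L = info.size
    if L <= core_length:
        return 0
    sums = np.convolve(info, np.ones(core_length), mode="valid")
    return int(sums.argmax())


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Sum of weights[i, codes[o+i]] for every offset o; NaN where any N."""
    L = weights.shape[0]
    n_off = codes.size - L + 1
    if n_off <= 0:
        return np.empty(0)
    scores = np.zeros(n_off)
    ns = np.zeros(n_off, dtype=bool)
    padded = np.vstack([weights.T, np.zeros((1, L))])  # row 4: N placeholder
    for i in range(L):
        col = codes[i : i + n_off]
        scores += padded[col, i]
        ns |= col == 4
    scores[ns] = np.nan
    return scores


def _scan_one(
    codes: np.ndarray, weights: np.ndarray, w_min: float, w_max: float,
    core_slice: slice, c_min: float, c_max: float, cutoff_mss: float, cutoff_css: float,
) -> tuple[np.ndarray, np.ndarray]:
    scores = _window_scores(codes, weights)
    if scores.size == 0:
        return np.empty(0, int), np.empty(0)
    span = (w_max - w_min) or 1.0
    mss = (scores - w_min) / span
    core_w = weights[core_slice]
    core_scores = _window_scores(codes, core_w)
    # align: core at offset o of the matrix starts at o + core_slice.start
    start = core_slice.start
    core_for_offset = core_scores[start : start + mss.size]
    cspan = (c_max - c_min) or 1.0
    css = (core_for_offset - c_min) / cspan
    with np.errstate(invalid="ignore"):
        ok = (mss >= cutoff_mss) & (css >= cutoff_css)
    idx = np.flatnonzero(ok)
    return idx, mss[idx]


def match_scan(
    promoters: pd.DataFrame,
    pwms: list[PWM],
    mss_cutoff: float = 0.95,
    css_cutoff: float = 0.90,
    core_length: int = CORE_LENGTH,
    pseudocount: float = SCAN_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Scan both strands of every promoter with every PWM.

    Returns a hit table (gene_id, tf, matrix_id, start, end, strand, mss)
    with 0-based half-open coordinates on the promoter.  Windows containing
    N are skipped; matrices longer than a promoter yield no hits (warning).
    """
    hits = []
    prepared = []
    for pwm in pwms:
        fwd = pwm
        for strand, mat in (("+", fwd), ("-", fwd.reverse_complement())):
            f = mat.frequencies(pseudocount)
            info = pwm_information(f)
            weights = info[:, None] * f
            # score the best/worst windows through the same accumulation
            # path as real windows, so the consensus hits MSS = 1.0 exactly
            best = weights.argmax(axis=1).astype(np.int8)
            worst = weights.argmin(axis=1).astype(np.int8)
            w_max = float(_window_scores(best, weights)[0])
            w_min = float(_window_scores(worst, weights)[0])
            off = _core_offset(info, core_length)
            cs = slice(off, min(off + core_length, len(mat)))
            cw = weights[cs]
            c_max = float(_window_scores(best[cs], cw)[0])
            c_min = float(_window_scores(worst[cs], cw)[0])
            prepared.append(
                (pwm, strand, weights, w_min, w_max, cs, c_min, c_max)
            )
    warned = set()
    for prom in promoters.itertuples(index=False):
        codes = encode(prom.sequence)
        for pwm, strand, weights, w_min, w_max, cs, c_min, c_max in prepared:
            if len(pwm) > codes.size:
                if pwm.matrix_id not in warned:
                    warnings.warn(
                        f"PWM {pwm.matrix_id} longer than promoter; skipped",
                        stacklevel=2,
                    )
                    warned.add(pwm.matrix_id)
                continue
            idx, mss = _scan_one(
                codes, weights, w_min, w_max, cs, c_min, c_max, mss_cutoff, css_cutoff
            )
            for o, s in zip(idx, mss):
                hits.append(
                    (prom.gene_id, pwm.tf_name, pwm.matrix_id,
                     int(o), int(o) + len(pwm), strand, float(s))
                )
    return pd.DataFrame(
        hits, columns=["gene_id", "tf", "matrix_id", "start", "end", "strand", "mss"]
    ).sort_values(["gene_id", "start", "end", "tf", "strand"]).reset_index(drop=True)


def resolve_overlaps(hits: pd.DataFrame, max_overlap: float = 0.5) -> pd.DataFrame:
    """Collapse same-TF hits overlapping by more than ``max_overlap`` of the
    shorter site, keeping the best score (ties -> leftmost).  Hits of
    different TFs are never collapsed."""
    if hits.empty:
        return hits.copy()
    kept_rows = []
    for (_, _), group in hits.groupby(["gene_id", "tf"], sort=True):
        group = group.sort_values(["mss", "start"], ascending=[False, True], kind="stable")
        chosen: list[tuple[int, int]] = []
        for row in group.itertuples():
            keep = True
            for s, e in chosen:
                ov = min(e, row.end) - max(s, row.start)
                shorter = min(e - s, row.end - row.start)
                if ov > max_overlap * shorter:
                    keep = False
                    break
            if keep:
                chosen.append((row.start, row.end))
                kept_rows.append(row.Index)
    out = hits.loc[sorted(kept_rows)]
    return out.sort_values(["gene_id", "start", "end", "tf"]).reset_index(drop=True)
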