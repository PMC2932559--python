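"""Rare/abundant partitioning and identity-based sub-classification of the rare biosphere.

Rarity is defined per sample either by a count cutoff (n = 1, n <= 2, n <= 5,
n <= 10) or a relative-abundance cutoff (a <= 0.004%); abundance by the strict
complements (n > 10, a > 1%).  Rare OTUs are then sub-classified by pairwise
sequence identity:

* NUNN (non-unique, non-novel): > 85% identical to an abundant OTU over an
  alignment of at least 100 bp;
* UNN (unique, non-novel): fails the NUNN gate but > 85% identical to a
  reference-database relative;
* UN (unique, novel): neither.

Percent identity is computed by exact Smith-Waterman local alignment
(match +1, mismatch -1, gap open -2, gap extend -1).  Among all optimal-score
alignments the canonical one maximizes the number of matched columns, then
minimizes the total number of alignment columns; identity is
matches / columns x 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .otu_io import CountTable

__all__ = [
    "RarityCutoff",
    "parse_cutoff",
    "count_cutoff_for_proportion",
    "partition",
    "filter_table",
    "IdentityHit",
    "percent_identity",
    "RareClassification",
    "classify_rare",
]


# -- cutoffs ---------------------------------------------------------------

@dataclass(frozen=True)
class RarityCutoff:
    """A rare (<=) or abundant (>) cutoff on counts or relative abundance."""
    mode: str       # "count" | "proportion"
    threshold: float
    side: str       # "rare" | "abundant"

    def __post_init__(self):
        if self.mode not in ("count", "proportion"):
            raise ValueError("mode must be 'count' or 'proportion'")
        if self.side not in ("rare", "abundant"):
            raise ValueError("side must be 'rare' or 'abundant'")
        if self.mode == "count":
            if self.threshold < 1 or self.threshold != int(self.threshold):
                raise ValueError("count thresholds must be positive integers")
        elif not 0 < self.threshold < 1:
            raise ValueError("proportion thresholds must lie in (0, 1)")

    def __str__(self) -> str:
        if self.mode == "count":
            op = "<=" if self.side == "rare" else ">"
            return f"n{op}{int(self.threshold)}"
        op = "<=" if self.side == "rare" else ">"
        return f"a{op}{self.threshold * 100:g}%"


def parse_cutoff(text: str) -> RarityCutoff:
    """Parse cutoff strings like 'n=1', 'n<=5', 'n>10', 'a<=0.004%', 'a>1%'."""
    s = text.strip().replace(" ", "")
    if not s or s[0] not in "na":
        raise ValueError(f"cannot parse cutoff: {text!r}")
    mode = "count" if s[0] == "n" else "proportion"
    body = s[1:]
    if body.startswith("<="):
        side, value = "rare", body[2:]
    elif body.startswith(">"):
        side, value = "abundant", body[1:]
    elif body.startswith("="):
        side, value = "rare", body[1:]
    else:
        raise ValueError(f"cannot parse cutoff: {text!r}")
    if mode == "proportion":
        if not value.endswith("%"):
            raise ValueError(f"proportion cutoffs need a % sign: {text!r}")
        threshold = float(value[:-1]) / 100.0
    else:
        threshold = float(value)
    return RarityCutoff(mode, threshold, side)


def count_cutoff_for_proportion(total_reads: int, proportion: float) -> int:
    """Largest integer count not exceeding ``proportion`` of ``total_reads``.

    E.g. a 0.004% cutoff corresponds to n <= 3 in a 77,361-read sample and
    n <= 2 in a 51,836-read sample.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 < proportion < 1:
        raise ValueError("proportion must lie in (0, 1)")
    return math.floor(proportion * total_reads)


def partition(table: CountTable, sample: str, cutoff: RarityCutoff) -> tuple[set, set]:
    """Split a sample's observed OTUs into (rare, abundant) at the cutoff.

    For a rare-side cutoff the rare set is {0 < count <= threshold} and the
    abundant set its complement among observed OTUs; an abundant-side cutoff
    selects {count > threshold} as abundant, complement rare.
    """
    col = table.column(sample)
    observed = col[col > 0]
    if cutoff.mode == "proportion":
        thr = count_cutoff_for_proportion(int(col.sum()), cutoff.threshold)
    else:
        thr = int(cutoff.threshold)
    low = set(observed.index[observed <= thr])
    high = set(observed.index) - low
    return (low, high)


def filter_table(table: CountTable, cutoff: RarityCutoff, keep: str = "rare") -> CountTable:
    """Zero out counts outside the requested per-sample partition side.

    OTUs that end up absent everywhere are dropped; useful for computing
    beta-diversity among rare (or abundant) members only.
    """
    if keep not in ("rare", "abundant"):
        raise ValueError("keep must be 'rare' or 'abundant'")
    df = table.df.copy()
    for sample in table.sample_ids:
        rare, abundant = partition(table, sample, cutoff)
        drop = abundant if keep == "rare" else rare
        if drop:
            df.loc[list(drop), sample] = 0
    return CountTable(df, drop_empty=True)


# -- Smith-Waterman percent identity ----------------------------------------

# lexicographic composite: (score << 22) + (matches << 11) - columns, additive
# per alignment column; requires len(a) + len(b) < 2048 and scores in int64
_SCORE_SHIFT = 1 << 22
_MATCH_SHIFT = 1 << 11
_MAX_LEN = 1000

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1

_COMP_MATCH = MATCH * _SCORE_SHIFT + _MATCH_SHIFT - 1
_COMP_MISMATCH = MISMATCH * _SCORE_SHIFT - 1
_COMP_OPEN = GAP_OPEN * _SCORE_SHIFT - 1
_COMP_EXTEND = GAP_EXTEND * _SCORE_SHIFT - 1
_NEG_INF = np.int64(-(1 << 60))


@dataclass(frozen=True)
class IdentityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    matches: int
    score: int

    def __post_init__(self):
        if self.alignment_length >= 1:
            expected = self.matches / self.alignment_length * 100.0
            if abs(expected - self.percent_identity) > 1e-9:
                raise ValueError("identity inconsistent with matches/length")


def _sw_composite(a: str, b: str) -> int:
    """Best composite (score, matches, -columns) over all local alignments."""
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return 0
    bx = np.frombuffer(b.encode(), dtype=np.uint8)
    prev_h = np.zeros(nb + 1, dtype=np.int64)
    prev_m = np.full(nb, _NEG_INF, dtype=np.int64)
    prev_ix = np.full(nb, _NEG_INF, dtype=np.int64)
    best = np.int64(0)
    col_idx = np.arange(nb, dtype=np.int64)
    for ch in a.encode():
        subs = np.where(bx == ch, _COMP_MATCH, _COMP_MISMATCH)
        m_row = prev_h[:-1] + subs
        ix_row = np.maximum(prev_m + _COMP_OPEN, prev_ix + _COMP_EXTEND)
        # horizontal gaps via a running-max scan:
        # iy[j] = max_{k<j} m[k] + open + (j-1-k)*extend
        scan = np.maximum.accumulate(m_row + _COMP_OPEN - _COMP_EXTEND * col_idx)
        iy_row = np.empty(nb, dtype=np.int64)
        iy_row[0] = _NEG_INF
        iy_row[1:] = scan[:-1] + _COMP_EXTEND * col_idx[:-1]
        h_row = np.maximum(np.maximum(m_row, ix_row), np.maximum(iy_row, 0))
        best = max(best, np.int64(m_row.max()))
        prev_h[1:] = h_row
        prev_m, prev_ix = m_row, ix_row
    return int(best)


def _decode_composite(comp: int) -> tuple[int, int, int]:
    """(score, matches, columns) from a positive composite value."""
    score = comp >> 22
    rem = comp & (_SCORE_SHIFT - 1)
    matches = (rem + _MATCH_SHIFT - 1) // _MATCH_SHIFT
    columns = matches * _MATCH_SHIFT - rem
    return score, matches, columns


def percent_identity(seq1: str, seq2: str, query_id: str = "query",
                     subject_id: str = "subject") -> IdentityHit:
    """Exact local-alignment percent identity between two DNA strings."""
    if not seq1 or not seq2:
        raise ValueError("sequences must be non-empty")
    if len(seq1) > _MAX_LEN or len(seq2) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} bp are not supported")
    comp = _sw_composite(seq1.upper(), seq2.upper())
    if comp <= 0:
        return IdentityHit(query_id, subject_id, 0.0, 0, 0, 0)
    score, matches, columns = _decode_composite(comp)
    return IdentityHit(query_id, subject_id, matches / columns * 100.0,
                       columns, matches, score)


# -- NUNN / UNN / UN classification -----------------------------------------

@dataclass
class RareClassification:
    """Per-OTU rare-biosphere labels with supporting identity evidence."""
    labels: dict[str, str]                       # otu_id -> NUNN | UNN | UN
    best_abundant_hit: dict[str, IdentityHit]    # evidence for stage 1
    best_reference_identity: dict[str, float]    # evidence for stage 2
    weights: dict[str, int]                      # reads per rare OTU

    def proportions(self, weighted: bool = True) -> dict[str, float]:
        """Category proportions (%), read-weighted or OTU-weighted."""
        out = {}
        if weighted:
            total = sum(self.weights.values())
            for cat in ("NUNN", "UNN", "UN"):
                w = sum(self.weights[o] for o, l in self.labels.items() if l == cat)
                out[cat] = 100.0 * w / total if total else 0.0
        else:
            total = len(self.labels)
            for cat in ("NUNN", "UNN", "UN"):
                out[cat] = 100.0 * sum(
                    1 for l in self.labels.values() if l == cat) / total if total else 0.0
        return out


def _best_hit(query: str, query_id: str, subjects: Mapping[str, str]) -> IdentityHit | None:
    """Best subject by (identity, alignment length, lexicographic id)."""
    best: IdentityHit | None = None
    for sid in sorted(subjects):
        hit = percent_identity(query, subjects[sid], query_id, sid)
        if best is None or (hit.percent_identity, hit.alignment_length, ) > \
                (best.percent_identity, best.alignment_length):
            best = hit
    return best


def classify_rare(rare_seqs: Mapping[str, str],
                  abundant_seqs: Mapping[str, str],
                  reference_seqs: Mapping[str, str] | None = None,
                  reference_identity: Mapping[str, float] | None = None,
                  weights: Mapping[str, int] | None = None,
                  min_identity: float = 85.0,
                  min_aln_len: int = 100) -> RareClassification:
    """Two-stage NUNN/UNN/UN decision for each rare OTU.

    Stage 1: best hit against the abundant representative set; identity
    strictly > ``min_identity`` with alignment length >= ``min_aln_len``
    labels the OTU NUNN.  Stage 2: best identity against the reference —
    either alignment against ``reference_seqs`` (same length gate) or a
    precomputed ``reference_identity`` map (taken as-is, e.g. classifier
    output); strictly > ``min_identity`` labels UNN, otherwise UN.
    """
    overlap = set(rare_seqs) & set(abundant_seqs)
    if overlap:
        raise ValueError(f"rare and abundant sets overlap: {sorted(overlap)[:5]}")
    if reference_seqs is None and reference_identity is None:
        raise ValueError("provide reference_seqs or reference_identity")
    weights = dict(weights) if weights else {o: 1 for o in rare_seqs}
    missing = [o for o in rare_seqs if rare_seqs[o] == ""]
    if missing:
        raise ValueError(f"missing representative sequence for: {missing[:5]}")

    labels: dict[str, str] = {}
    abundant_hits: dict[str, IdentityHit] = {}
    ref_ident: dict[str, float] = {}
    for otu in sorted(rare_seqs):
        seq = rare_seqs[otu]
        hit = _best_hit(seq, otu, abundant_seqs)
        if hit is not None:
            abundant_hits[otu] = hit
        if hit is not None and hit.percent_identity > min_identity \
                and hit.alignment_length >= min_aln_len:
            labels[otu] = "NUNN"
            continue
        if reference_identity is not None and otu in reference_identity:
            ident = float(reference_identity[otu])
        elif reference_seqs:
            ref_hit = _best_hit(seq, otu, reference_seqs)
            ident = ref_hit.percent_identity if ref_hit is not None \
                and ref_hit.alignment_length >= min_aln_len else 0.0
        else:
            ident = 0.0
        ref_ident[otu] = ident
        labels[otu] = "UNN" if ident > min_identity else "UN"
    return RareClassification(labels, abundant_hits, ref_ident,
                              {o: int(weights.get(o, 1)) for o in rare_seqs})
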