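"""Attention-based interpretability: per-base profiles, high-attention
regions, motif enrichment and merging, positional density, and
high-attention k-mer pair mining.

The pipeline mirrors attention-guided motif discovery for DNA language
models: average the per-head attention matrices of the last encoder layer,
score each token by its mean attention, decompose token scores onto the
bases each overlapping k-mer covers, normalize per enhancer-promoter pair
as (mean - min)/max, call maximal runs of bases above a threshold, test
candidate subsequences for enrichment in interacting pairs with the
hypergeometric upper tail, and greedily merge enriched candidates into
position weight matrices.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .nn.model import AttentionStack, EPIModel
from .tokenizer import ROLE_ENH, ROLE_PROM, TokenSequence, Vocabulary, assemble_pair

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


# ---------------------------------------------------------------------------
# attention -> per-base profiles
# ---------------------------------------------------------------------------

def average_heads(stack: AttentionStack | np.ndarray, layer: int = -1,
                  batch_index: int = 0) -> np.ndarray:
    """Mean over heads of one record's attention matrices (default last layer)."""
    if isinstance(stack, AttentionStack):
        mats = stack.layers[layer][batch_index]
    else:
        mats = np.asarray(stack)
    if mats.ndim != 3:
        raise ValueError("expected per-head matrices of shape (H, L, L)")
    if mats.shape[1] != mats.shape[2]:
        raise ValueError("attention matrices must be square")
    return mats.mean(axis=0)


def token_profile(matrix: np.ndarray, roles: np.ndarray,
                  target: str = "all", direction: str = "row") -> np.ndarray:
    """Mean attention of each token toward the selected target positions.

    ``direction='row'`` scores attention emitted by each token (row means);
    ``'column'`` scores attention received.  ``target`` restricts the
    averaged positions to 'all', 'enhancer', or 'promoter'.
    """
    matrix = np.asarray(matrix)
    roles = np.asarray(roles)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != roles.size:
        raise ValueError("matrix/roles shape mismatch")
    if direction == "column":
        matrix = matrix.T
    elif direction != "row":
        raise ValueError("direction must be 'row' or 'column'")
    if target == "all":
        cols = slice(None)
    elif target == "enhancer":
        cols = roles == ROLE_ENH
    elif target == "promoter":
        cols = roles == ROLE_PROM
    else:
        raise ValueError("target must be 'all', 'enhancer' or 'promoter'")
    return matrix[:, cols].mean(axis=1)


def base_decompose(token_scores: np.ndarray, k: int, element_length: int) -> np.ndarray:
    """Spread k-mer token scores onto bases: each base's score is the mean of
    the scores of all k-mers covering it (1..k tokens at the edges)."""
    token_scores = np.asarray(token_scores, dtype=np.float64)
    n_tokens = element_length - k + 1
    if token_scores.size != n_tokens:
        raise ValueError(
            f"expected {n_tokens} token scores for length {element_length}, "
            f"got {token_scores.size}"
        )
    sums = np.zeros(element_length)
    counts = np.zeros(element_length)
    for t in range(n_tokens):
        sums[t : t + k] += token_scores[t]
        counts[t : t + k] += 1
    return sums / counts


def normalize_profile(raw: np.ndarray, method: str = "ratio") -> np.ndarray:
    """Per-pair profile normalization; the argmin base always maps to 0.

    ``method='ratio'`` is (mean - min)/max, which lands in [0, 1] for
    nonnegative attention but compresses the dynamic range when attention
    is diffuse (a flat profile maps near 0 everywhere).  ``'minmax'`` is the
    standard (mean - min)/(max - min), mapping the peak to exactly 1.
    """
    raw = np.asarray(raw, dtype=np.float64)
    mx = raw.max()
    if mx <= 0 or np.allclose(raw, 0):
        raise ValueError("normalization undefined for an all-zero profile")
    if method == "ratio":
        return (raw - raw.min()) / mx
    if method == "minmax":
        rng = mx - raw.min()
        if rng == 0:
            return np.zeros_like(raw)
        return (raw - raw.min()) / rng
    raise ValueError("method must be 'ratio' or 'minmax'")


@dataclasses.dataclass
class BaseAttentionProfile:
    role: str                 # 'enhancer' or 'promoter'
    raw: np.ndarray           # per-base mean attention
    normalized: np.ndarray    # (raw - min)/max, min/max over the whole EP pair

    def __len__(self) -> int:
        return len(self.raw)


def pair_base_profiles(avg_matrix: np.ndarray, tokens: TokenSequence, k: int,
                       target: str = "all", direction: str = "row",
                       method: str = "ratio",
                       ) -> tuple[BaseAttentionProfile, BaseAttentionProfile]:
    """Per-base raw and normalized attention for one enhancer-promoter pair.

    The normalization min/max are taken jointly over all bases of the pair,
    so the two elements share a scale.
    """
    scores = token_profile(avg_matrix, tokens.roles, target=target,
                           direction=direction)
    enh_scores = scores[tokens.enhancer_slice]
    prom_scores = scores[tokens.promoter_slice]
    enh_len = enh_scores.size + k - 1
    prom_len = prom_scores.size + k - 1
    enh_raw = base_decompose(enh_scores, k, enh_len)
    prom_raw = base_decompose(prom_scores, k, prom_len)
    joint = np.concatenate([enh_raw, prom_raw])
    norm = normalize_profile(joint, method=method)
    return (
        BaseAttentionProfile("enhancer", enh_raw, norm[:enh_len]),
        BaseAttentionProfile("promoter", prom_raw, norm[enh_len:]),
    )


# ---------------------------------------------------------------------------
# high-attention regions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HighAttentionRegion:
    role: str
    start: int            # base offset within the element, half-open
    end: int
    peak: float           # max normalized score in the run
    mean: float           # mean normalized score in the run
    peak_offset: int      # absolute base offset of the peak within the element
    record: int = -1      # source record id
    seq: str = ""         # the region subsequence, when sequences are attached

    def __len__(self) -> int:
        return self.end - self.start


def call_regions(normalized: np.ndarray, threshold: float = 0.5,
                 min_len: int = 6, role: str = "enhancer",
                 record: int = -1) -> list[HighAttentionRegion]:
    """Maximal runs of bases with normalized score >= threshold, kept when at
    least ``min_len`` long."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    normalized = np.asarray(normalized)
    above = normalized >= threshold
    regions = []
    for m in re.finditer(rb"\x01+", above.astype(np.uint8).tobytes()):
        s, e = m.start(), m.end()
        if e - s >= min_len:
            seg = normalized[s:e]
            regions.append(HighAttentionRegion(
                role=role, start=s, end=e,
                peak=float(seg.max()), mean=float(seg.mean()),
                peak_offset=s + int(seg.argmax()), record=record,
            ))
    return regions


def extract_high_attention_regions(
    model: EPIModel, pairs: Sequence[tuple[str, str]], vocab: Vocabulary,
    threshold: float = 0.5, min_len: int = 6, batch_size: int = 8,
    target: str = "all", direction: str = "row", method: str = "minmax",
) -> list[HighAttentionRegion]:
    """Run the model over assembled pairs and call regions on both elements,
    attaching subsequences and record indices.

    Region calling defaults to the min-max rescaled profile: the ratio
    normalization compresses the dynamic range when attention is diffuse,
    which would leave a fixed threshold with nothing to call; min-max pins
    the per-pair peak at 1 so the threshold selects the top of the profile
    regardless of overall contrast.
    """
    regions: list[HighAttentionRegion] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        toks = [assemble_pair(e, p, vocab) for e, p in chunk]
        ids = np.stack([t.ids for t in toks])
        out = model.forward_classify(ids)
        for b, (tok, (enh_seq, prom_seq)) in enumerate(zip(toks, chunk)):
            avg = average_heads(out.attention, batch_index=b)
            enh_prof, prom_prof = pair_base_profiles(avg, tok, vocab.k,
                                                     target=target,
                                                     direction=direction,
                                                     method=method)
            rec = start + b
            for prof, seq in ((enh_prof, enh_seq), (prom_prof, prom_seq)):
                for r in call_regions(prof.normalized, threshold, min_len,
                                      role=prof.role, record=rec):
                    r.seq = seq[r.start : r.end]
                    regions.append(r)
    return regions


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability of >= k positive pairs among the
    n pairs containing a sequence, out of N pairs of which K are positive."""
    if not (0 <= k <= min(K, n) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclasses.dataclass
class MotifCandidate:
    seq: str
    instances: list[str]      # one aligned instance per supporting region
    region_ids: list[int]     # indices (into the region list) supporting it
    k: int   # positive EP pairs containing the sequence
    K: int   # all positive EP pairs
    n: int   # EP pairs containing the sequence
    N: int   # all EP pairs
    p_value: float

    @property
    def support(self) -> int:
        return len(self.instances)


@dataclasses.dataclass
class PWM:
    """Per-position base frequencies of aligned motif instances."""

    matrix: np.ndarray    # (width, 4), columns over ACGT summing to 1
    consensus: str
    support: int          # number of aligned instances
    p_value: float = 1.0

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def _contains(pair: tuple[str, str], sub: str) -> bool:
    return sub in pair[0] or sub in pair[1]


def candidate_windows(region: HighAttentionRegion, min_len: int = 6,
                      max_len: int = 12) -> list[str]:
    """All subsequence windows of the region that cover its peak base, at
    widths min_len..max_len.

    Region boundaries carry a few bases of background flank (per-base scores
    are smoothed over the k covering tokens), so a single trimmed string
    rarely recurs exactly across records.  Enumerating every peak-covering
    window lets the enrichment test pick out the windows that align exactly
    on a recurring motif instance.
    """
    seq = region.seq
    center = region.peak_offset - region.start
    out = []
    for w in range(min_len, min(max_len, len(seq)) + 1):
        lo = max(0, center - w + 1)
        hi = min(center, len(seq) - w)
        for s in range(lo, hi + 1):
            out.append(seq[s : s + w])
    return out


def _best_overlap(a: str, b: str, overlap_min: int, mismatch_max: int
                  ) -> int | None:
    """Best offset of b relative to a (may be negative); None if no overlap of
    >= overlap_min with <= mismatch_max mismatches exists."""
    best, best_score = None, -1
    for off in range(-(len(b) - overlap_min), len(a) - overlap_min + 1):
        lo = max(0, off)
        hi = min(len(a), off + len(b))
        if hi - lo < overlap_min:
            continue
        mism = sum(a[i] != b[i - off] for i in range(lo, hi))
        score = (hi - lo) - 2 * mism
        if mism <= mismatch_max and score > best_score:
            best, best_score = off, score
    return best


def _pwm_from_aligned(instances: list[tuple[str, int]], p_value: float) -> PWM:
    lo = min(off for _, off in instances)
    hi = max(off + len(s) for s, off in instances)
    width = hi - lo
    counts = np.zeros((width, 4))
    for s, off in instances:
        for i, base in enumerate(s):
            if base in _BASE_INDEX:
                counts[off - lo + i, _BASE_INDEX[base]] += 1
    covered = counts.sum(axis=1) > 0
    counts = counts[covered]
    matrix = counts / counts.sum(axis=1, keepdims=True)
    consensus = "".join(BASE_ORDER[i] for i in matrix.argmax(axis=1))
    return PWM(matrix=matrix, consensus=consensus, support=len(instances),
               p_value=p_value)


def score_candidates(
    regions: Sequence[HighAttentionRegion],
    pair_sequences: Sequence[tuple[str, str]],
    labels: Sequence[int],
    min_candidate_len: int = 6,
    max_candidate_len: int = 12,
    min_region_support: int = 2,
) -> list[MotifCandidate]:
    """Turn positive-record regions into enrichment-scored candidates.

    Candidate strings are peak-covering windows of positive-record regions
    (widths ``min_candidate_len..max_candidate_len``); a candidate seen in
    fewer than ``min_region_support`` distinct regions is dropped before the
    (comparatively costly) containment counting.  k/n count the positive/all
    EP pairs containing each surviving candidate in either element; K/N are
    the positive/total pair counts.
    """
    labels = np.asarray(labels)
    N = len(pair_sequences)
    K = int((labels == 1).sum())
    groups: dict[str, list[int]] = {}
    for ridx, r in enumerate(regions):
        if labels[r.record] != 1 or not r.seq:
            continue
        for cand in set(candidate_windows(r, min_candidate_len, max_candidate_len)):
            groups.setdefault(cand, []).append(ridx)
    out = []
    for cand, ridxs in groups.items():
        if len(ridxs) < min_region_support:
            continue
        n = sum(1 for pair in pair_sequences if _contains(pair, cand))
        kk = sum(1 for pair, lab in zip(pair_sequences, labels)
                 if lab == 1 and _contains(pair, cand))
        out.append(MotifCandidate(cand, [cand] * len(ridxs), ridxs, kk, K, n, N,
                                  enrichment_pvalue(kk, K, n, N)))
    return out


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def merge_candidates(candidates: Sequence[MotifCandidate],
                     overlap_min: int = 6, mismatch_max: int = 1,
                     min_width: int = 6,
                     ) -> tuple[list[PWM], dict[int, int]]:
    """Greedy merge of enriched candidates into PWMs.

    Candidates are visited by decreasing support; each either joins the
    first existing motif whose anchor it matches (substring, or overlap of
    >= overlap_min with <= mismatch_max mismatches at the best offset) or
    seeds a new motif.  Instances are offset-aligned into frequency
    matrices.  Returns the PWMs sorted by support and a mapping from
    candidate index (into ``candidates``) to its motif's position in the
    returned list.
    """
    order = sorted(range(len(candidates)),
                   key=lambda i: (-candidates[i].support,
                                  candidates[i].p_value, candidates[i].seq))
    anchors: list[str] = []
    aligned: list[list[tuple[str, int]]] = []
    members: list[list[int]] = []
    pvals: list[float] = []
    for ci in order:
        cand = candidates[ci]
        placed = False
        for i, anchor in enumerate(anchors):
            if cand.seq in anchor:
                off = anchor.index(cand.seq)
            elif anchor in cand.seq:
                off = -cand.seq.index(anchor)
            else:
                found = _best_overlap(anchor, cand.seq, overlap_min, mismatch_max)
                if found is None:
                    continue
                off = found
            aligned[i].extend((s, off) for s in cand.instances)
            members[i].append(ci)
            pvals[i] = min(pvals[i], cand.p_value)
            placed = True
            break
        if not placed:
            anchors.append(cand.seq)
            aligned.append([(s, 0) for s in cand.instances])
            members.append([ci])
            pvals.append(cand.p_value)
    pwms = [_pwm_from_aligned(insts, p) for insts, p in zip(aligned, pvals)]
    keep = [i for i, p in enumerate(pwms) if p.width >= min_width]
    keep.sort(key=lambda i: -pwms[i].support)
    assignment = {ci: rank for rank, i in enumerate(keep) for ci in members[i]}
    return [pwms[i] for i in keep], assignment


def discover_motifs(
    regions: Sequence[HighAttentionRegion],
    pair_sequences: Sequence[tuple[str, str]],
    labels: Sequence[int],
    p_cutoff: float = 0.005,
    overlap_min: int = 6,
    mismatch_max: int = 1,
    min_candidate_len: int = 6,
    max_candidate_len: int = 12,
    min_region_support: int = 2,
    correction: str = "bh",
) -> tuple[list[PWM], pd.DataFrame]:
    """Full motif discovery: score, filter at ``p_cutoff``, merge to PWMs.

    Significance is assessed on Benjamini-Hochberg adjusted p-values by
    default (``correction='none'`` uses raw p-values): many overlapping
    candidate windows are tested per run, so an uncorrected cutoff would
    admit a steady trickle of false motifs on label-free data.

    Returns the merged PWMs (sorted by support) and the full candidate
    table (one row per candidate, including those failing the cutoff).
    """
    if correction not in ("bh", "none"):
        raise ValueError("correction must be 'bh' or 'none'")
    candidates = score_candidates(regions, pair_sequences, labels,
                                  min_candidate_len, max_candidate_len,
                                  min_region_support)
    qvals = bh_adjust([c.p_value for c in candidates])
    table = pd.DataFrame(
        [{"seq": c.seq, "support": c.support, "k": c.k, "K": c.K,
          "n": c.n, "N": c.N, "p_value": c.p_value, "q_value": q}
         for c, q in zip(candidates, qvals)],
        columns=["seq", "support", "k", "K", "n", "N", "p_value", "q_value"],
    )
    crit = qvals if correction == "bh" else np.array([c.p_value for c in candidates])
    kept = [c for c, v in zip(candidates, crit) if v <= p_cutoff]
    pwms, _ = merge_candidates(kept, overlap_min, mismatch_max)
    return pwms, table


# ---------------------------------------------------------------------------
# MEME export
# ---------------------------------------------------------------------------

def export_meme(pwms: Sequence[PWM], path: str | Path | None = None) -> str:
    """Serialize PWMs in MEME minimal motif format."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "strands: + -", "",
             "Background letter frequencies",
             "A 0.25 C 0.25 G 0.25 T 0.25", ""]
    for i, p in enumerate(pwms):
        col_sums = p.matrix.sum(axis=1)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM {i} columns do not sum to 1")
        lines.append(f"MOTIF {p.consensus} motif_{i + 1}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {p.width} "
            f"nsites= {p.support} E= {p.p_value:.3g}"
        )
        for row in p.matrix:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_meme(source: str | Path) -> list[PWM]:
    """Parse MEME minimal format back into PWMs (inverse of export_meme)."""
    if isinstance(source, Path) or "\n" not in source:
        text = Path(source).read_text()
    else:
        text = source
    pwms = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            consensus = lines[i].split()[1]
            i += 1
            header = lines[i]
            w = int(re.search(r"w=\s*(\d+)", header).group(1))
            ns = re.search(r"nsites=\s*(\d+)", header)
            support = int(ns.group(1)) if ns else 0
            rows = [list(map(float, lines[i + 1 + j].split())) for j in range(w)]
            matrix = np.array(rows)
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            pwms.append(PWM(matrix=matrix, consensus=consensus, support=support))
            i += 1 + w
        else:
            i += 1
    return pwms


# ---------------------------------------------------------------------------
# positional density and common/specific classification
# ---------------------------------------------------------------------------

def position_density(regions: Sequence[HighAttentionRegion], element_length: int,
                     bins: int = 50, role: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of region midpoints over element positions.

    Returns (counts, bin_edges); total counts equal the number of regions
    considered.  ``role`` optionally restricts to one element type.
    """
    mids = [0.5 * (r.start + r.end) for r in regions
            if role is None or r.role == role]
    return np.histogram(mids, bins=bins, range=(0, element_length))


def classify_common_specific(
    regions: Sequence[HighAttentionRegion],
    pair_sequences: Sequence[tuple[str, str]],
    labels: Sequence[int],
    min_support: int = 3,
    p_cutoff: float = 0.005,
    min_candidate_len: int = 6,
    max_candidate_len: int = 12,
    overlap_min: int = 6,
    mismatch_max: int = 1,
    correction: str = "bh",
) -> tuple[list[str], pd.DataFrame]:
    """Label each positive-record region 'common' or 'specific'.

    A region is common iff one of its candidate windows is significantly
    enriched (p <= ``p_cutoff``) and merges into a motif whose support
    reaches ``min_support``; regions whose candidates have low counts or
    fail enrichment are specific.  Regions on negative records get an empty
    label.  Also returns per-record counts of each label (their means are
    the per-sequence summary).
    """
    candidates = score_candidates(regions, pair_sequences, labels,
                                  min_candidate_len, max_candidate_len,
                                  min_region_support=1)
    crit = (bh_adjust([c.p_value for c in candidates]) if correction == "bh"
            else np.array([c.p_value for c in candidates]))
    kept_idx = [i for i, c in enumerate(candidates) if crit[i] <= p_cutoff]
    kept = [candidates[i] for i in kept_idx]
    pwms, assignment = merge_candidates(kept, overlap_min, mismatch_max)
    common_regions: set[int] = set()
    for local_i, c in enumerate(kept):
        motif = assignment.get(local_i)
        if motif is not None and pwms[motif].support >= min_support:
            common_regions.update(c.region_ids)
    lab_arr = np.asarray(labels)
    out_labels: list[str] = []
    counts: dict[int, Counter] = {}
    for ridx, r in enumerate(regions):
        if lab_arr[r.record] != 1:
            out_labels.append("")
            continue
        label = "common" if ridx in common_regions else "specific"
        out_labels.append(label)
        counts.setdefault(r.record, Counter())[label] += 1
    per_seq = pd.DataFrame(
        [{"record": rec, "common": c.get("common", 0),
          "specific": c.get("specific", 0)} for rec, c in sorted(counts.items())],
        columns=["record", "common", "specific"],
    )
    return out_labels, per_seq


# ---------------------------------------------------------------------------
# high-attention k-mer pair mining
# ---------------------------------------------------------------------------

def count_kmer_pairs(avg_matrix: np.ndarray, tokens: TokenSequence,
                     vocab: Vocabulary, threshold: float | None = None,
                     cross_segment_only: bool = True) -> Counter:
    """High-attention (enhancer k-mer, promoter k-mer) cells of one record.

    Each cell with attention >= threshold (default 10/L) contributes one
    count to the (row k-mer, column k-mer) pair.
    """
    L = avg_matrix.shape[0]
    thr = threshold if threshold is not None else 10.0 / L
    if thr <= 0:
        raise ValueError("pair-mining threshold must be positive")
    if cross_segment_only:
        enh_idx = np.flatnonzero(tokens.roles == ROLE_ENH)
        prom_idx = np.flatnonzero(tokens.roles == ROLE_PROM)
        sub = avg_matrix[np.ix_(enh_idx, prom_idx)]
        ii, jj = np.nonzero(sub >= thr)
        rows, cols = enh_idx[ii], prom_idx[jj]
    else:
        rows, cols = np.nonzero(avg_matrix >= thr)
    out: Counter = Counter()
    for i, j in zip(rows, cols):
        out[(vocab.decode_id(int(tokens.ids[i])),
             vocab.decode_id(int(tokens.ids[j])))] += 1
    return out


def summarize_kmer_pairs(counts_pos: Counter, counts_neg: Counter,
                         top_m: int = 1000) -> pd.DataFrame:
    """Compare the top-m pair lists of the two classes; flag pairs exclusive
    to the positive top list."""
    top_pos = [p for p, _ in counts_pos.most_common(top_m)]
    top_neg = set(p for p, _ in counts_neg.most_common(top_m))
    rows = [{
        "kmer_a": a, "kmer_b": b,
        "count_pos": counts_pos[(a, b)],
        "count_neg": counts_neg[(a, b)],
        "exclusive_to_pos": (a, b) not in top_neg,
    } for a, b in top_pos]
    return pd.DataFrame(rows, columns=["kmer_a", "kmer_b", "count_pos",
                                       "count_neg", "exclusive_to_pos"])


def mine_kmer_pairs(
    model: EPIModel,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
    vocab: Vocabulary,
    threshold: float | None = None,
    top_m: int = 1000,
    batch_size: int = 8,
    cross_segment_only: bool = True,
) -> pd.DataFrame:
    """Count high-attention (enhancer 6-mer, promoter 6-mer) pairs.

    For every record, each cell of the head-averaged last-layer attention
    matrix linking an enhancer token to a promoter token with attention
    >= threshold (default 10/L, ten times the uniform row weight)
    contributes one count to that k-mer pair.  Counts accumulate separately
    for positive and negative records; the ``top_m`` pairs per class are
    compared and pairs exclusive to the positive top list are flagged.
    """
    if threshold is not None and threshold <= 0:
        raise ValueError("pair-mining threshold must be positive")
    labels = np.asarray(labels)
    counts = {0: Counter(), 1: Counter()}
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        toks = [assemble_pair(e, p, vocab) for e, p in chunk]
        ids = np.stack([t.ids for t in toks])
        out = model.forward_classify(ids)
        for b, tok in enumerate(toks):
            avg = average_heads(out.attention, batch_index=b)
            counts[int(labels[start + b])] += count_kmer_pairs(
                avg, tok, vocab, threshold, cross_segment_only)
    return summarize_kmer_pairs(counts[1], counts[0], top_m)
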