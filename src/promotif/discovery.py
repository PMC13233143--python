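"""Attention-guided motif discovery with hypergeometric enrichment.

The discovery chain, given per-sequence [CLS]->token attention:

1. average attention heads within a layer (``aggregate_heads``);
2. normalize per sequence to the maximum token score (``normalize_scores``),
   giving s-hat in (0, 1] with max exactly 1;
3. rank layers by a z-score-like specificity ``Sp = (max(s) - mean) / sd``
   and combine the informative layers (``select_layers``);
4. mark tokens with ``s > mean`` and ``s > 2 * min(s)``, concatenate
   maximal runs of marked tokens, and keep regions of >= 4 bp as candidate
   motifs (``select_candidate_motifs``);
5. count motif occurrences across all sequences with an Aho-Corasick
   automaton (``count_occurrences``), discard motifs with fewer than three
   instances, and test positive-class over-representation with the
   upper-tail hypergeometric probability, Benjamini-Hochberg corrected at
   alpha = 0.01;
6. greedily merge redundant significant motifs by best gapless overlap and
   export +/-12 bp windows around instance centers.

Model-comparison set logic (significant-in-B but not in-A) isolates motifs
private to the tissue-specific classifier.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .attention import AttentionProfile, TokenSpan

DNA = set("ACGT")


# ---------------------------------------------------------------------------
# Token scoring (attention -> normalized scores -> layer choice)
# ---------------------------------------------------------------------------

def aggregate_heads(profile: AttentionProfile, layer: int) -> np.ndarray:
    """Mean [CLS]->token attention over the heads of a (1-based) layer.

    Head-sum and head-mean differ by the constant H, which cancels under
    max-normalization, so the downstream scores do not depend on this
    choice.
    """
    if not 1 <= layer <= profile.n_layers:
        raise ValueError(f"layer {layer} outside [1, {profile.n_layers}]")
    return profile.cls_attention[layer - 1].mean(axis=0)


def normalize_scores(alpha: np.ndarray) -> np.ndarray:
    """Per-sequence max-normalization: s_j = alpha_j / max(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    m = alpha.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero attention vector")
    return alpha / m


def layer_specificity(shat: np.ndarray) -> float:
    """Specificity ``Sp = (max(s) - mean(s)) / sd(s)`` (sample sd).

    A layer whose attention is concentrated on few tokens scores high; a
    uniform layer has sd 0 and scores 0 by convention.
    """
    shat = np.asarray(shat, dtype=float)
    if shat.size < 2:
        raise ValueError("specificity undefined for single-token sequences")
    sd = shat.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((shat.max() - shat.mean()) / sd)


def select_layers(
    per_layer_shat: Sequence[np.ndarray],
    strategy: str = "mid_plus_final",
) -> np.ndarray:
    """Combine per-layer normalized scores into one vector per sequence.

    Strategies:

    * ``"mid_plus_final"`` — mean of the middle layers averaged with the
      final layer, then re-normalized to max 1.  For a 12-layer model the
      middle layers are 5-7; for smaller models the middle third is used.
    * ``"layer:<i>"`` — a single 1-based layer.
    * ``"top_sp"`` — the layer with the highest specificity score.
    """
    mats = [np.asarray(s, dtype=float) for s in per_layer_shat]
    L = len(mats)
    if L == 0:
        raise ValueError("no layers")
    if strategy.startswith("layer:"):
        idx = int(strategy.split(":", 1)[1])
        if not 1 <= idx <= L:
            raise ValueError(f"layer {idx} outside [1, {L}]")
        return normalize_scores(mats[idx - 1])
    if strategy == "top_sp":
        sps = [layer_specificity(m) for m in mats]
        return normalize_scores(mats[int(np.argmax(sps))])
    if strategy == "mid_plus_final":
        if L >= 7:
            middle = [mats[4], mats[5], mats[6]]  # layers 5, 6, 7
        else:
            lo, hi = L // 3, max(L // 3 + max(1, L // 3), L // 3 + 1)
            middle = mats[lo:hi] or [mats[L // 2]]
        combined = (np.mean(middle, axis=0) + mats[-1]) / 2.0
        return normalize_scores(combined)
    raise ValueError(f"unknown layer strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Candidate motifs
# ---------------------------------------------------------------------------

@dataclass
class CandidateMotif:
    """A candidate motif with its occurrence bookkeeping.

    ``instances`` are (sequence_id, start, end, mean_score) tuples in
    sequence-local coordinates; enrichment counts are presence-based
    (``n`` sequences contain the motif, ``k`` of them positive).
    """

    motif_sequence: str
    instances: list[tuple[str, int, int, float]] = field(default_factory=list)
    source: str | None = None
    n: int = 0
    k: int = 0
    p_value: float | None = None
    q_value: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if len(self.motif_sequence) < 4:
            raise ValueError(f"motif {self.motif_sequence!r} shorter than 4 bp")

    @property
    def n_instances(self) -> int:
        return len(self.instances)


def select_candidate_motifs(
    shat: np.ndarray,
    spans: Sequence[TokenSpan],
    sequence: str,
    seq_id: str = "",
    min_length: int = 4,
) -> list[CandidateMotif]:
    """Mark high-attention tokens and emit maximal runs as candidate regions.

    A token passes if ``s_j > mean(s)`` and ``s_j > 2 * min(s)`` (both
    strict).  Consecutive passing tokens are concatenated into one region;
    regions shorter than ``min_length`` bp are discarded.  When
    ``2 * min(s) >= 1`` no token can pass the second condition and the
    result is empty (a uniform-attention sequence carries no candidate).
    """
    shat = np.asarray(shat, dtype=float)
    if shat.shape[0] != len(spans):
        raise ValueError("score vector not aligned to spans")
    mu = shat.mean()
    floor = 2.0 * shat.min()
    passing = (shat > mu) & (shat > floor)
    out: list[CandidateMotif] = []
    j = 0
    while j < len(spans):
        if not passing[j]:
            j += 1
            continue
        j0 = j
        while j < len(spans) and passing[j]:
            j += 1
        start, end = spans[j0].start, spans[j - 1].end
        if end - start >= min_length:
            region = sequence[start:end]
            out.append(CandidateMotif(
                region,
                instances=[(seq_id, start, end, float(shat[j0:j].mean()))],
            ))
    return out


def dedupe_candidates(candidates: Iterable[CandidateMotif]) -> list[CandidateMotif]:
    """Pool candidates with identical motif strings, unioning instances."""
    by_seq: dict[str, CandidateMotif] = {}
    for cand in candidates:
        if cand.motif_sequence in by_seq:
            by_seq[cand.motif_sequence].instances.extend(cand.instances)
        else:
            by_seq[cand.motif_sequence] = CandidateMotif(
                cand.motif_sequence, list(cand.instances), cand.source)
    return list(by_seq.values())


# ---------------------------------------------------------------------------
# Aho-Corasick multi-pattern matching
# ---------------------------------------------------------------------------

class AhoCorasick:
    """Classic Aho-Corasick automaton over the DNA alphabet.

    Builds the goto/fail/output structure once and scans each text in a
    single pass, reporting every (possibly overlapping) occurrence of every
    pattern.
    """

    def __init__(self, patterns: Sequence[str]):
        if not patterns:
            raise ValueError("no patterns")
        for p in patterns:
            if not p or set(p) - DNA:
                raise ValueError(f"pattern {p!r} contains non-ACGT symbols")
        self.patterns = list(patterns)
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._output: list[list[int]] = [[]]
        for idx, pat in enumerate(self.patterns):
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto.append({})
                    self._fail.append(0)
                    self._output.append([])
                    self._goto[state][ch] = nxt
                state = nxt
            self._output[state].append(idx)
        queue: deque[int] = deque()
        for ch, s in self._goto[0].items():
            queue.append(s)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0) if self._goto[f].get(ch, 0) != nxt else 0
                self._output[nxt] = self._output[nxt] + self._output[self._fail[nxt]]

    def iter_matches(self, text: str):
        """Yield (start, pattern_index) for every occurrence in ``text``."""
        state = 0
        goto, fail, output = self._goto, self._fail, self._output
        patterns = self.patterns
        for pos, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            for idx in output[state]:
                yield pos + 1 - len(patterns[idx]), idx


def count_occurrences(
    motifs: Sequence[str],
    sequences: Sequence[tuple[str, int, str]],
) -> dict[str, dict]:
    """Count motif occurrences over a labeled sequence set.

    ``sequences`` holds (sequence_id, label, sequence).  For each motif:
    ``n`` = sequences containing at least one occurrence, ``k`` = such
    sequences with label 1, and all occurrence positions are recorded
    (overlapping occurrences counted).  Motifs must be uppercase ACGT.
    """
    ac = AhoCorasick(list(motifs))
    stats = {m: {"n": 0, "k": 0, "positions": []} for m in motifs}
    for seq_id, label, seq in sequences:
        seen: set[int] = set()
        for start, idx in ac.iter_matches(seq):
            motif = ac.patterns[idx]
            stats[motif]["positions"].append((seq_id, start))
            seen.add(idx)
        for idx in seen:
            motif = ac.patterns[idx]
            stats[motif]["n"] += 1
            if label == 1:
                stats[motif]["k"] += 1
    return stats


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def hypergeometric_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for X ~ Hypergeom(N, K, n): k positives among n carriers."""
    _check_counts(N, K, n, k)
    return float(hypergeom.pmf(k, N, K, n))


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail enrichment probability P(X >= k), X ~ Hypergeom(N, K, n).

    N sequences of which K are positive; n carry the motif, k of the
    carriers are positive.  The upper tail is the over-representation
    p-value (the pmf alone is not monotone in enrichment).
    """
    _check_counts(N, K, n, k)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k < n - (N - K):
        raise ValueError(f"impossible table: k={k} < n-(N-K)={n - (N - K)}")


def fdr_correct(
    p_values: Sequence[float], alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def filter_min_instances(
    motifs: Sequence[CandidateMotif], min_instances: int = 3
) -> list[CandidateMotif]:
    """Discard motifs with fewer than ``min_instances`` total occurrences."""
    return [m for m in motifs if m.n_instances >= min_instances]


# ---------------------------------------------------------------------------
# Gapless merging
# ---------------------------------------------------------------------------

def best_ungapped_overlap(a: str, b: str) -> tuple[int, int]:
    """Best ungapped alignment of two motifs over all relative offsets.

    Returns (matches, offset) where ``offset`` is the position of ``b``'s
    first base relative to ``a``'s (may be negative).  Ties resolve to the
    smallest offset.
    """
    best_m, best_off = -1, 0
    for off in range(-(len(b) - 1), len(a)):
        lo = max(0, off)
        hi = min(len(a), off + len(b))
        if hi <= lo:
            continue
        m = sum(1 for i in range(lo, hi) if a[i] == b[i - off])
        if m > best_m:
            best_m, best_off = m, off
    return best_m, best_off


@dataclass
class _Consensus:
    """Column-wise base counts for a growing merged motif."""

    counts: list[dict[str, int]]
    members: list[CandidateMotif]
    offset0: int = 0  # offset of column 0 in the original coordinate frame

    @classmethod
    def from_motif(cls, motif: CandidateMotif) -> "_Consensus":
        return cls([{b: 1} for b in motif.motif_sequence], [motif])

    def consensus(self) -> str:
        # majority base; ties resolve alphabetically for determinism
        return "".join(
            max(sorted(col), key=lambda b: (col[b], -ord(b))) for col in self.counts
        )

    def absorb(self, motif: CandidateMotif, offset: int) -> None:
        seq = motif.motif_sequence
        if offset < 0:
            # extend the frame leftwards so the motif starts at column 0
            self.counts = [dict() for _ in range(-offset)] + self.counts
            offset = 0
        for i, b in enumerate(seq):
            col = offset + i
            if col >= len(self.counts):
                self.counts.append({})
            self.counts[col][b] = self.counts[col].get(b, 0) + 1
        self.members.append(motif)


def merge_motifs_gapless(
    motifs: Sequence[CandidateMotif],
    similarity_threshold: float = 0.8,
) -> list[CandidateMotif]:
    """Greedily collapse redundant motifs by best gapless overlap.

    Motifs are processed longest-first (ties lexicographic).  A motif joins
    an existing cluster when its best ungapped overlap with the cluster
    consensus matches at least ``similarity_threshold`` times the length of
    the shorter of the two; the consensus extends by union at the best
    offset with majority base at conflicts.  Instance lists are unioned.
    The operation is idempotent: re-merging the output changes nothing.
    """
    if not 0 < similarity_threshold <= 1:
        raise ValueError("similarity threshold must be in (0, 1]")
    merged = list(motifs)
    # iterate single-pass greedy merging to a fixpoint so the operation is
    # idempotent even when freshly built consensi are themselves similar
    while True:
        nxt = _merge_once(merged, similarity_threshold)
        if len(nxt) == len(merged):
            return nxt
        merged = nxt


def _merge_once(
    motifs: Sequence[CandidateMotif], similarity_threshold: float
) -> list[CandidateMotif]:
    order = sorted(motifs, key=lambda m: (-len(m.motif_sequence), m.motif_sequence))
    clusters: list[_Consensus] = []
    for motif in order:
        placed = False
        for cl in clusters:
            cons = cl.consensus()
            matches, offset = best_ungapped_overlap(cons, motif.motif_sequence)
            shorter = min(len(cons), len(motif.motif_sequence))
            if matches >= similarity_threshold * shorter:
                cl.absorb(motif, offset)
                placed = True
                break
        if not placed:
            clusters.append(_Consensus.from_motif(motif))
    merged: list[CandidateMotif] = []
    for cl in clusters:
        instances = [inst for m in cl.members for inst in m.instances]
        seen = set()
        uniq = []
        for inst in instances:
            key = (inst[0], inst[1], inst[2])
            if key not in seen:
                seen.add(key)
                uniq.append(inst)
        rep = CandidateMotif(cl.consensus(), uniq,
                             source=cl.members[0].source)
        rep.n = max((m.n for m in cl.members), default=0)
        rep.k = max((m.k for m in cl.members), default=0)
        ps = [m.p_value for m in cl.members if m.p_value is not None]
        qs = [m.q_value for m in cl.members if m.q_value is not None]
        rep.p_value = min(ps) if ps else None
        rep.q_value = min(qs) if qs else None
        sig = [m.significant for m in cl.members if m.significant is not None]
        rep.significant = any(sig) if sig else None
        merged.append(rep)
    return merged


# ---------------------------------------------------------------------------
# Window export and set logic
# ---------------------------------------------------------------------------

def extract_instance_windows(
    motifs: Sequence[CandidateMotif],
    sequences: Mapping[str, str],
    flank: int = 12,
) -> list[tuple[str, str]]:
    """Export +/-``flank`` bp windows around motif instance centers.

    Window = [center - flank, center + flank) clipped at sequence bounds,
    center = floor of the instance midpoint.  Returns (header, window)
    pairs ready for FASTA; headers carry motif, sequence id and offset so
    the windows feed de-novo motif tools directly.
    """
    out: list[tuple[str, str]] = []
    for mi, motif in enumerate(motifs):
        for seq_id, start, end, _score in motif.instances:
            seq = sequences[seq_id]
            center = (start + end) // 2
            lo, hi = max(0, center - flank), min(len(seq), center + flank)
            header = f"{motif.motif_sequence}|m{mi}|{seq_id}|{lo}"
            out.append((header, seq[lo:hi]))
    return out


def write_windows_fasta(windows: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for header, seq in windows:
            fh.write(f">{header}\n{seq}\n")


def motif_set_difference(
    significant_b: Sequence[CandidateMotif],
    significant_a: Sequence[CandidateMotif],
    matching: str = "exact",
    similarity_threshold: float = 0.8,
) -> list[CandidateMotif]:
    """Motifs significant for Model B but absent from Model A.

    ``matching="exact"`` removes B motifs whose string occurs in A;
    ``matching="similar"`` additionally treats a pair as shared when its
    best ungapped overlap reaches ``similarity_threshold`` of the shorter
    motif.  The result isolates motifs private to the tissue-specific
    model.
    """
    if matching not in ("exact", "similar"):
        raise ValueError(f"unknown matching mode {matching!r}")
    a_strings = {m.motif_sequence for m in significant_a}
    out = []
    for mb in significant_b:
        if mb.motif_sequence in a_strings:
            continue
        if matching == "similar":
            shared = False
            for ma in significant_a:
                matches, _ = best_ungapped_overlap(ma.motif_sequence, mb.motif_sequence)
                shorter = min(len(ma.motif_sequence), len(mb.motif_sequence))
                if matches >= similarity_threshold * shorter:
                    shared = True
                    break
            if shared:
                continue
        out.append(mb)
    return out


def motif_table(motifs: Sequence[CandidateMotif], N: int, K: int) -> pd.DataFrame:
    """Tabulate motifs for TSV export."""
    return pd.DataFrame([
        {
            "motif": m.motif_sequence, "length": len(m.motif_sequence),
            "N": N, "K": K, "n": m.n, "k": m.k,
            "instances": m.n_instances,
            "p_value": m.p_value, "q_value": m.q_value,
            "significant": m.significant, "source": m.source,
        }
        for m in sorted(motifs, key=lambda m: (m.q_value if m.q_value is not None else 2,
                                               m.motif_sequence))
    ])
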