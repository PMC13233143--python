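"""End-to-end discovery pipeline: records + attention provider -> motifs.

Glues the module-level operations into the canonical run used by the CLI
and by calibration experiments:

correct-prediction filter -> per-sequence attention -> layer combination
-> candidate regions (positive sequences) -> occurrence counting over all
retained sequences -> minimum-instance filter -> hypergeometric
enrichment -> BH-FDR -> gapless merging of the significant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import discovery
from .attention import AttentionProvider, filter_correct_predictions
from .datasets import PromoterRecord
from .discovery import CandidateMotif


@dataclass
class DiscoveryResult:
    """Everything a discovery run produced."""

    tested: list[CandidateMotif]
    significant: list[CandidateMotif]  # merged
    table: pd.DataFrame
    N: int
    K: int
    retention: dict[str, int]
    shat_by_id: dict = field(repr=False, default_factory=dict)


def discover_motifs(
    records: Sequence[PromoterRecord],
    provider: AttentionProvider,
    layer_strategy: str = "mid_plus_final",
    alpha: float = 0.01,
    min_instances: int = 3,
    merge_threshold: float = 0.8,
    min_motif_length: int = 4,
    filter_correct: bool = True,
    candidate_source: str = "positives",
) -> DiscoveryResult:
    """Run the full attention-guided motif discovery chain.

    Candidates are harvested from positive sequences by default (the class
    whose regulatory grammar is being interpreted); occurrence counting
    and enrichment always use all retained sequences of both classes.
    """
    if candidate_source not in ("positives", "all"):
        raise ValueError(f"bad candidate_source {candidate_source!r}")
    if filter_correct:
        retained, retention = filter_correct_predictions(records, provider)
    else:
        retained, retention = list(records), {}
    if not retained:
        raise ValueError("no records retained; classifier never correct")

    shat_by_id: dict[str, tuple] = {}
    candidates: list[CandidateMotif] = []
    for rec in retained:
        profile = provider.attend(rec.transcript_id, rec.sequence)
        per_layer = [
            discovery.normalize_scores(discovery.aggregate_heads(profile, layer))
            for layer in range(1, profile.n_layers + 1)
        ]
        shat = discovery.select_layers(per_layer, strategy=layer_strategy)
        shat_by_id[rec.transcript_id] = (shat, profile.spans)
        if candidate_source == "positives" and rec.label != 1:
            continue
        candidates.extend(discovery.select_candidate_motifs(
            shat, profile.spans, rec.sequence, seq_id=rec.transcript_id,
            min_length=min_motif_length,
        ))

    N = len(retained)
    K = sum(1 for r in retained if r.label == 1)
    pooled = discovery.dedupe_candidates(candidates)
    if not pooled:
        return DiscoveryResult([], [], discovery.motif_table([], N, K), N, K,
                               retention, shat_by_id)

    seq_triplets = [(r.transcript_id, r.label, r.sequence) for r in retained]
    stats = discovery.count_occurrences(
        [m.motif_sequence for m in pooled], seq_triplets)
    for m in pooled:
        st = stats[m.motif_sequence]
        m.n, m.k = st["n"], st["k"]
        # replace harvested instances with the full occurrence scan,
        # keeping the mean attention recorded at harvest for that sequence
        harvest_score = {inst[0]: inst[3] for inst in m.instances}
        m.instances = [
            (seq_id, start, start + len(m.motif_sequence),
             harvest_score.get(seq_id, float("nan")))
            for seq_id, start in st["positions"]
        ]

    tested = discovery.filter_min_instances(pooled, min_instances)
    if tested:
        pvals = [discovery.hypergeometric_enrichment(N, K, m.n, m.k) for m in tested]
        qvals, flags = discovery.fdr_correct(pvals, alpha=alpha)
        for m, p, q, sig in zip(tested, pvals, qvals, flags):
            m.p_value, m.q_value, m.significant = float(p), float(q), bool(sig)
    significant = discovery.merge_motifs_gapless(
        [m for m in tested if m.significant], merge_threshold)
    table = discovery.motif_table(tested, N, K)
    return DiscoveryResult(tested, significant, table, N, K, retention, shat_by_id)
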