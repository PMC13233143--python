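"""Classifier/attention provider contract and a deterministic toy model.

Motif discovery and SHAP attribution consume three capabilities only:

* ``tokenize(sequence)`` -> list of :class:`TokenSpan`
* ``attend(seq_id, sequence)`` -> :class:`AttentionProfile` with the
  per-layer, per-head softmaxed [CLS]->token attention rows
* ``predict(seq_id, sequence)`` -> :class:`Prediction`

Any object with these methods (a fine-tuned transformer adapter, a cached
attention file, or the toy model below) can drive the whole pipeline; the
downstream code never inspects model internals.  Layer indices are 1-based
throughout.

The toy model concentrates [CLS] attention on "planted" intervals with a
configurable sharpness, so pipeline behaviour under known ground truth is
fully controlled: per head, the weight of token *j* is proportional to
``exp(kappa * overlap_fraction(token_j, planted))`` plus optional seeded
noise, softmax-normalized.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .datasets import PromoterRecord


@dataclass(frozen=True)
class TokenSpan:
    """A token and its character span (0-based, half-open) in the sequence."""

    token_text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.token_text) or len(self.token_text) < 1:
            raise ValueError(f"inconsistent span {self.start}:{self.end} "
                             f"for token {self.token_text!r}")


@dataclass
class AttentionProfile:
    """Per-layer, per-head [CLS]->token attention for one sequence.

    ``cls_attention`` has shape (L, H, J); every head's row is a softmaxed
    distribution over the J tokens (sums to 1).  ``spans`` locate each
    token in the input sequence.
    """

    cls_attention: np.ndarray
    spans: list[TokenSpan]
    hidden_dim: int = 768

    def __post_init__(self) -> None:
        a = np.asarray(self.cls_attention, dtype=float)
        if a.ndim != 3:
            raise ValueError(f"cls_attention must be (L, H, J), got shape {a.shape}")
        if a.shape[2] != len(self.spans):
            raise ValueError(f"J={a.shape[2]} != number of spans {len(self.spans)}")
        if (a < 0).any():
            raise ValueError("attention weights must be non-negative")
        sums = a.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each head's [CLS] row must sum to 1")
        self.cls_attention = a

    @property
    def n_layers(self) -> int:
        return self.cls_attention.shape[0]

    @property
    def n_heads(self) -> int:
        return self.cls_attention.shape[1]

    @property
    def n_tokens(self) -> int:
        return self.cls_attention.shape[2]


@dataclass(frozen=True)
class Prediction:
    predicted_label: int
    positive_logit: float
    positive_probability: float


@runtime_checkable
class AttentionProvider(Protocol):
    """Structural type of the model contract the pipeline consumes."""

    def tokenize(self, sequence: str) -> list[TokenSpan]: ...

    def attend(self, seq_id: str, sequence: str) -> AttentionProfile: ...

    def predict(self, seq_id: str, sequence: str) -> Prediction: ...


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize(
    sequence: str,
    k: int | None = None,
    vocabulary: Sequence[str] | None = None,
) -> list[TokenSpan]:
    """Segment a sequence into spans that tile it exactly.

    Either non-overlapping fixed-``k`` segmentation (the final span may be
    shorter than ``k``), or greedy longest-match segmentation under a
    ``vocabulary`` that must include every single nucleotide occurring in
    the sequence (which guarantees totality).
    """
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    if (k is None) == (vocabulary is None):
        raise ValueError("provide exactly one of k or vocabulary")
    spans: list[TokenSpan] = []
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        for start in range(0, len(sequence), k):
            end = min(start + k, len(sequence))
            spans.append(TokenSpan(sequence[start:end], start, end))
        return spans
    vocab = set(vocabulary)
    max_len = max(len(t) for t in vocab)
    pos = 0
    while pos < len(sequence):
        for length in range(min(max_len, len(sequence) - pos), 0, -1):
            cand = sequence[pos:pos + length]
            if cand in vocab:
                spans.append(TokenSpan(cand, pos, pos + length))
                pos += length
                break
        else:
            raise ValueError(
                f"vocabulary cannot tokenize position {pos} "
                f"({sequence[pos]!r} missing); include all single nucleotides"
            )
    return spans


def _overlap_fraction(span: TokenSpan, intervals: Sequence[tuple[int, int]]) -> float:
    """Fraction of the token covered by the union of planted intervals."""
    if not intervals:
        return 0.0
    covered = 0
    for s, e in intervals:
        covered += max(0, min(span.end, e) - max(span.start, s))
    return min(covered, span.end - span.start) / (span.end - span.start)


class ToyAttentionModel:
    """Deterministic test double for a fine-tuned sequence classifier.

    Attention: per layer and head, token logits are ``kappa *
    overlap_fraction(token, planted intervals)`` plus Gaussian noise of
    scale ``noise`` (seeded per sequence/layer/head), then softmaxed.
    ``kappa=0`` with ``noise=0`` yields uniform rows.

    Prediction: by default label 1 iff the sequence has any planted
    interval, with probability a logistic function of the planted base
    count (``predict="planted"``).  With ``predict="label"`` the model
    returns the true label supplied in ``labels`` — an idealized,
    always-correct classifier useful for calibration experiments where
    conditioning on the correctness of a planting-driven classifier would
    bias the retained set.
    """

    def __init__(
        self,
        planted: Mapping[str, Sequence[tuple[int, int]]],
        kappa: float = 8.0,
        n_layers: int = 4,
        n_heads: int = 2,
        seed: int = 0,
        noise: float = 0.0,
        token_k: int = 8,
        vocabulary: Sequence[str] | None = None,
        hidden_dim: int = 768,
        predict: str = "planted",
        labels: Mapping[str, int] | None = None,
    ) -> None:
        if not np.isfinite(kappa) or kappa < 0:
            raise ValueError("kappa must be finite and >= 0")
        if predict not in ("planted", "label"):
            raise ValueError("predict must be 'planted' or 'label'")
        if predict == "label" and labels is None:
            raise ValueError("predict='label' requires labels")
        self.planted = {k: list(v) for k, v in planted.items()}
        self.kappa = kappa
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.seed = seed
        self.noise = noise
        self.token_k = token_k
        self.vocabulary = list(vocabulary) if vocabulary is not None else None
        self.hidden_dim = hidden_dim
        self.predict_mode = predict
        self.labels = dict(labels) if labels is not None else None

    # -- contract -----------------------------------------------------------
    def tokenize(self, sequence: str) -> list[TokenSpan]:
        if self.vocabulary is not None:
            return tokenize(sequence, vocabulary=self.vocabulary)
        return tokenize(sequence, k=self.token_k)

    def _seq_rng(self, seq_id: str) -> np.random.Generator:
        return np.random.default_rng(
            (self.seed * 2654435761 + zlib.crc32(seq_id.encode())) % (2**31)
        )

    def attend(self, seq_id: str, sequence: str) -> AttentionProfile:
        spans = self.tokenize(sequence)
        intervals = self.planted.get(seq_id, [])
        for s, e in intervals:
            if s < 0 or e > len(sequence):
                raise ValueError(f"planted interval [{s},{e}) outside {seq_id}")
        base = np.array([self.kappa * _overlap_fraction(sp, intervals) for sp in spans])
        rng = self._seq_rng(seq_id)
        logits = base[None, None, :] + (
            rng.normal(0.0, self.noise, size=(self.n_layers, self.n_heads, len(spans)))
            if self.noise > 0 else 0.0
        )
        logits = np.broadcast_to(logits, (self.n_layers, self.n_heads, len(spans)))
        z = logits - logits.max(axis=2, keepdims=True)
        w = np.exp(z)
        w = w / w.sum(axis=2, keepdims=True)
        return AttentionProfile(w, spans, hidden_dim=self.hidden_dim)

    def predict(self, seq_id: str, sequence: str) -> Prediction:
        if self.predict_mode == "label":
            label = int(self.labels[seq_id])
            logit = 4.0 if label == 1 else -4.0
        else:
            intervals = self.planted.get(seq_id, [])
            planted_bp = sum(e - s for s, e in intervals)
            logit = planted_bp - 0.5
            label = int(planted_bp > 0)
        prob = 1.0 / (1.0 + np.exp(-logit))
        return Prediction(label, float(logit), float(prob))

    # -- SHAP scorer --------------------------------------------------------
    def masked_logit(self, seq_id: str, sequence: str, keep: np.ndarray) -> float:
        """Positive-class logit when only tokens flagged in ``keep`` are visible.

        Masked tokens contribute no planted overlap; the all-mask baseline
        therefore scores like a sequence with nothing planted.  This is the
        black-box scorer Kernel SHAP perturbs.
        """
        spans = self.tokenize(sequence)
        if len(keep) != len(spans):
            raise ValueError("keep mask length != number of tokens")
        intervals = self.planted.get(seq_id, [])
        visible_bp = sum(
            (sp.end - sp.start) * _overlap_fraction(sp, intervals)
            for sp, k in zip(spans, keep) if k
        )
        return float(visible_bp - 0.5)


# ---------------------------------------------------------------------------
# Filtering and caching
# ---------------------------------------------------------------------------

def filter_correct_predictions(
    records: Sequence[PromoterRecord],
    provider: AttentionProvider,
) -> tuple[list[PromoterRecord], dict[str, int]]:
    """Keep records the classifier predicts correctly.

    Attention-based interpretation is only meaningful where the model is
    right; this mirrors extracting attention solely from correct
    predictions.  Returns the retained subset and per-class retention
    counts.
    """
    kept: list[PromoterRecord] = []
    counts = {"kept_pos": 0, "kept_neg": 0, "dropped_pos": 0, "dropped_neg": 0}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.transcript_id} has no label")
        pred = provider.predict(rec.transcript_id, rec.sequence)
        suffix = "pos" if rec.label == 1 else "neg"
        if pred.predicted_label == rec.label:
            kept.append(rec)
            counts[f"kept_{suffix}"] += 1
        else:
            counts[f"dropped_{suffix}"] += 1
    return kept, counts


def save_attention_cache(path, profiles: Mapping[str, AttentionProfile],
                         predictions: Mapping[str, Prediction] | None = None) -> None:
    """Serialize attention profiles (and predictions) to a JSON container."""
    payload = {}
    for seq_id, prof in profiles.items():
        entry = {
            "spans": [[sp.token_text, sp.start, sp.end] for sp in prof.spans],
            "cls_attention": prof.cls_attention.tolist(),
            "hidden_dim": prof.hidden_dim,
        }
        if predictions and seq_id in predictions:
            p = predictions[seq_id]
            entry["prediction"] = [p.predicted_label, p.positive_logit,
                                   p.positive_probability]
        payload[seq_id] = entry
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_attention_cache(path) -> tuple[dict[str, AttentionProfile], dict[str, Prediction]]:
    with open(path) as fh:
        payload = json.load(fh)
    profiles, predictions = {}, {}
    for seq_id, entry in payload.items():
        spans = [TokenSpan(t, s, e) for t, s, e in entry["spans"]]
        profiles[seq_id] = AttentionProfile(
            np.asarray(entry["cls_attention"]), spans, entry.get("hidden_dim", 768))
        if "prediction" in entry:
            lab, logit, prob = entry["prediction"]
            predictions[seq_id] = Prediction(int(lab), logit, prob)
    return profiles, predictions
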